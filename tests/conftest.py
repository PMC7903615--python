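import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fibroscreen import ExpressionMatrix

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def build_matrix(values: dict[str, list[float]], timepoints: list[float],
                 n_replicates: int, condition_of=None) -> ExpressionMatrix:
    """Assemble a small single-arm matrix from per-gene flat value lists.

    ``values[gene]`` holds the abundances sample-by-sample in timepoint-major
    order (all replicates of t0, then t1, ...).
    """
    sample_ids, meta = [], []
    for t in timepoints:
        for r in range(1, n_replicates + 1):
            sid = f"t{t:g}h_r{r}"
            sample_ids.append(sid)
            cond = condition_of(t) if condition_of else (
                "control" if t == 0 else "injured")
            meta.append((sid, cond, float(t), r))
    frame = pd.DataFrame(
        {g: v for g, v in values.items()}, index=sample_ids).T
    frame.columns = sample_ids
    samples = pd.DataFrame(
        meta, columns=["sample_id", "condition", "timepoint_h", "replicate"]
    ).set_index("sample_id")
    return ExpressionMatrix(frame.astype(float), samples)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 timepoints x 3 replicates, hand-specified values."""
    timepoints = [0.0, 12.0, 24.0, 72.0]
    rng = np.random.default_rng(11)
    base = {"Areg": 100.0, "Flat1": 50.0, "Flat2": 200.0}
    mult = {"Areg": {0.0: 1, 12.0: 10, 24.0: 10, 72.0: 1},
            "Flat1": {t: 1 for t in timepoints},
            "Flat2": {t: 1 for t in timepoints}}
    values = {}
    for g in base:
        vals = []
        for t in timepoints:
            for _ in range(3):
                vals.append(base[g] * mult[g][t]
                            * 2 ** (0.05 * rng.standard_normal()))
        values[g] = vals
    return build_matrix(values, timepoints, 3)


TUTORIAL_CONFIG = """\
simulate:
  seed: {seed}
  n_genes: {n_genes}
  n_replicates: 3
  noise_log2_sd: {noise}
  peak_fold: 10.0
  timepoints_h: [0, 6, 12, 24, 72, 120, 168, 240]
  fibrosis_timepoints_h: [0, 72, 168, 240]
  class_proportions: {{TRANSIENT: 0.1, SUSTAINED: 0.1, FLAT: 0.8}}
  aliases: {{G000001: Areg}}
  overlap: {{Areg: SUSTAINED}}
screen:
  induction_fold: {induction_fold}
  induction_timepoints_h: [12, 24]
  return_timepoint_h: 72
  return_band: 0.2
  sustained_fold: 2.0
  alpha: 0.01
  require_significance: true
  test_method: welch_t
  fibrosis_baseline: matched_control
"""


@pytest.fixture
def tutorial_config(tmp_path):
    """Pipeline YAML: 60 genes, one aliased Areg-like overlap gene, zero noise."""
    path = tmp_path / "config.yaml"
    path.write_text(TUTORIAL_CONFIG.format(
        seed=42, n_genes=60, noise=0.0, induction_fold=2.0))
    return path
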