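"""Synthetic time-course expression data with planted temporal classes.

Emulates the statistical structure of the two kinds of datasets the screen
consumes, with known ground truth so every downstream stage is testable
without any download:

* a single-arm wound-healing course — one baseline timepoint (0 h) and a
  grid of post-injury timepoints with replicate arrays at each, like an
  oral-mucosa wound-healing microarray series;
* a two-arm fibrosis course — control (PBS) and treated (bleomycin) arms
  sampled at each timepoint, like a bleomycin-induced skin-fibrosis
  series.

Each gene follows a :class:`TemporalTemplate`: a per-timepoint expected
fold multiplier on top of a gene-specific log-normal baseline.  Replicate
noise is multiplicative log-normal (additive Gaussian in log2), the
standard error model for array/RNA abundances; it keeps values strictly
positive.  A TRANSIENT template with peak fold 10 is the amphiregulin-like
wound shape (10x at 12-24 h, back to baseline by 72 h); a SUSTAINED
template holds its fold at every post-injury timepoint, the fibrosis
shape.

Randomness: one stream per dataset, split deterministically from the seed
into per-gene child streams, so the same seed is bit-reproducible and
adding genes never perturbs earlier genes' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import CONTROL_CONDITION, ExpressionMatrix

__all__ = [
    "TRANSIENT",
    "SUSTAINED",
    "LATE",
    "REPRESSED",
    "FLAT",
    "CLASS_LABELS",
    "SyntheticDataError",
    "InvalidConfigurationError",
    "UnknownGeneError",
    "TemporalTemplate",
    "SimulationConfig",
    "make_template",
    "largest_remainder_counts",
    "generate_timecourse",
    "generate_fibrosis_course",
]

TRANSIENT = "TRANSIENT"
SUSTAINED = "SUSTAINED"
LATE = "LATE"
REPRESSED = "REPRESSED"
FLAT = "FLAT"
CLASS_LABELS = (TRANSIENT, SUSTAINED, LATE, REPRESSED, FLAT)

INJURED_CONDITION = "injured"
TREATED_CONDITION = "treated"


class SyntheticDataError(Exception):
    pass


class InvalidConfigurationError(SyntheticDataError):
    pass


class UnknownGeneError(SyntheticDataError):
    """An overlap gene is absent from the shared truth."""


@dataclass(frozen=True)
class TemporalTemplate:
    """Expected fold multiplier per timepoint for one temporal class.

    ``timepoint_multipliers[t]`` scales the gene's baseline abundance at
    timepoint t; a FLAT template is identically 1.  ``peak_fold`` is the
    multiplier at the template's peak (e.g. 10 for an amphiregulin-like
    transient gene).
    """

    class_label: str
    peak_fold: float
    timepoint_multipliers: dict[float, float]

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InvalidConfigurationError(
                f"unknown class label {self.class_label!r}")
        if self.peak_fold <= 0:
            raise InvalidConfigurationError("peak_fold must be positive")
        if any(m < 0 for m in self.timepoint_multipliers.values()):
            raise InvalidConfigurationError("multipliers must be >= 0")

    def multiplier(self, t: float) -> float:
        return self.timepoint_multipliers[float(t)]


def make_template(class_label: str, peak_fold: float,
                  timepoints_h: list[float],
                  induction_timepoints_h: tuple[float, float] = (12.0, 24.0),
                  return_timepoint_h: float = 72.0) -> TemporalTemplate:
    """Build a class template on a timepoint grid.

    Anchor multipliers per class (t = 0 is always 1):

    * ``FLAT``       — 1 everywhere.
    * ``TRANSIENT``  — peak_fold across the induction window
      (default 12-24 h), exactly 1 at and after the return timepoint
      (default 72 h).
    * ``SUSTAINED``  — peak_fold at every post-injury timepoint.
    * ``LATE``       — 1 through the induction window, peak_fold at and
      after the return timepoint.
    * ``REPRESSED``  — 1/peak_fold at every post-injury timepoint.

    Grid timepoints between anchors are filled by log-linear
    interpolation; only the anchors are contract-bearing.
    """
    tps = [float(t) for t in timepoints_h]
    first_ind, last_ind = (float(induction_timepoints_h[0]),
                           float(induction_timepoints_h[-1]))
    ret = float(return_timepoint_h)
    if class_label == FLAT:
        return TemporalTemplate(FLAT, peak_fold, {t: 1.0 for t in tps})
    anchors: dict[float, float]
    if class_label == TRANSIENT:
        anchors = {0.0: 1.0, first_ind: peak_fold, last_ind: peak_fold, ret: 1.0}
        tail = 1.0
    elif class_label == SUSTAINED:
        return TemporalTemplate(
            SUSTAINED, peak_fold,
            {t: (1.0 if t == 0.0 else peak_fold) for t in tps})
    elif class_label == REPRESSED:
        return TemporalTemplate(
            REPRESSED, peak_fold,
            {t: (1.0 if t == 0.0 else 1.0 / peak_fold) for t in tps})
    elif class_label == LATE:
        anchors = {0.0: 1.0, last_ind: 1.0, ret: peak_fold}
        tail = peak_fold
    else:
        raise InvalidConfigurationError(f"unknown class label {class_label!r}")
    anchor_t = np.array(sorted(anchors))
    anchor_log2 = np.log2([anchors[t] for t in sorted(anchors)])
    mult = {}
    for t in tps:
        if t in anchors:
            mult[t] = anchors[t]  # anchors are contract-bearing: keep exact
        elif t > anchor_t[-1]:
            mult[t] = tail
        else:
            mult[t] = float(2.0 ** np.interp(t, anchor_t, anchor_log2))
    return TemporalTemplate(class_label, peak_fold, mult)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated dataset.

    Defaults emulate a multi-timepoint injury course: an 8-point grid from
    0 to 240 h with triplicate arrays, gene baselines log-normal around
    2^7 with 1.5 log2-units of spread, and 0.2 log2-units of replicate
    noise (a typical array-replicate CV of ~15%).
    """

    n_genes: int
    seed: int
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {TRANSIENT: 0.1, SUSTAINED: 0.1, FLAT: 0.8})
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 72.0, 120.0,
                                       168.0, 240.0)
    n_replicates: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.2
    peak_fold: float = 10.0
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise InvalidConfigurationError("n_genes must be positive")
        if not self.timepoints_h:
            raise InvalidConfigurationError("timepoints_h must be non-empty")
        tps = tuple(float(t) for t in self.timepoints_h)
        if tps[0] != 0.0:
            raise InvalidConfigurationError("first timepoint must be 0")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise InvalidConfigurationError("timepoints_h must be strictly increasing")
        object.__setattr__(self, "timepoints_h", tps)
        if self.n_replicates < 1:
            raise InvalidConfigurationError("n_replicates must be >= 1")
        if self.noise_log2_sd < 0:
            raise InvalidConfigurationError("noise_log2_sd must be >= 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigurationError(
                f"class_proportions must sum to 1 (got {total})")
        unknown = [c for c in self.class_proportions if c not in CLASS_LABELS]
        if unknown:
            raise InvalidConfigurationError(f"unknown class(es) {unknown}")


def largest_remainder_counts(n: int, proportions: dict[str, float]
                             ) -> dict[str, int]:
    """Apportion n among classes by largest remainder; sums exactly to n.

    Remainder ties are broken by the insertion order of ``proportions``.
    """
    quotas = {c: n * p for c, p in proportions.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    shortfall = n - sum(counts.values())
    order = sorted(proportions, key=lambda c: -(quotas[c] - counts[c]))
    for c in order[:shortfall]:
        counts[c] += 1
    return counts


def _gene_ids(config: SimulationConfig) -> list[str]:
    width = max(6, len(str(config.n_genes)))
    ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]
    return [config.aliases.get(g, g) for g in ids]


def _assign_classes(config: SimulationConfig) -> list[str]:
    counts = largest_remainder_counts(config.n_genes, config.class_proportions)
    classes: list[str] = []
    for label in config.class_proportions:
        classes.extend([label] * counts[label])
    return classes


def _simulate(genes: list[str], classes: list[str],
              templates: dict[str, TemporalTemplate],
              sample_meta: pd.DataFrame, config: SimulationConfig,
              stream_key: int) -> pd.DataFrame:
    """Draw the abundance matrix; one child RNG stream per gene."""
    root = np.random.SeedSequence(config.seed, spawn_key=(stream_key,))
    children = root.spawn(len(genes))
    n_samples = len(sample_meta)
    tp = sample_meta["timepoint_h"].to_numpy(dtype=float)
    is_control = (sample_meta["condition"] == CONTROL_CONDITION).to_numpy()
    rows = np.empty((len(genes), n_samples))
    for i, (gene, label) in enumerate(zip(genes, classes)):
        rng = np.random.default_rng(children[i])
        baseline_log2 = (config.baseline_log2_mean
                         + config.baseline_log2_sd * rng.standard_normal())
        template = templates[label]
        log2_mult = np.array([
            0.0 if ctrl else np.log2(template.multiplier(t))
            for t, ctrl in zip(tp, is_control)
        ])
        eps = config.noise_log2_sd * rng.standard_normal(n_samples)
        rows[i] = 2.0 ** (baseline_log2 + log2_mult + eps)
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                        columns=sample_meta.index)


def generate_timecourse(config: SimulationConfig,
                        templates: dict[str, TemporalTemplate] | None = None,
                        ) -> tuple[ExpressionMatrix, dict[str, tuple[str, float]]]:
    """Simulate a single-arm injury time course with planted classes.

    Classes are apportioned per ``config.class_proportions`` (largest
    remainder) and assigned blockwise in the proportions' insertion order.
    Samples at 0 h carry the ``control`` condition; later timepoints are
    ``injured``.  Returns the matrix and the truth mapping
    gene_id -> (class_label, peak_fold).
    """
    if templates is None:
        templates = {
            label: make_template(label, config.peak_fold,
                                 list(config.timepoints_h))
            for label in config.class_proportions
        }
    genes = _gene_ids(config)
    classes = _assign_classes(config)
    meta_rows = []
    for t in config.timepoints_h:
        condition = CONTROL_CONDITION if t == 0.0 else INJURED_CONDITION
        for r in range(1, config.n_replicates + 1):
            meta_rows.append((f"W_t{t:g}h_r{r}", condition, t, r))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition",
                                            "timepoint_h", "replicate"]
                        ).set_index("sample_id")
    values = _simulate(genes, classes, templates, meta, config, stream_key=0)
    truth = {g: (c, templates[c].peak_fold if c != FLAT else 1.0)
             for g, c in zip(genes, classes)}
    return ExpressionMatrix(values, meta), truth


def generate_fibrosis_course(
    config: SimulationConfig,
    shared_truth: dict[str, tuple[str, float]],
    overlap_spec: dict[str, str],
    templates: dict[str, TemporalTemplate] | None = None,
) -> tuple[ExpressionMatrix, dict[str, tuple[str, float]]]:
    """Simulate a two-arm (control vs treated) fibrosis course.

    The gene universe is that of ``shared_truth`` (the wound course).
    ``overlap_spec`` maps gene_id -> fibrosis-course class; e.g. a gene
    TRANSIENT in the wound becoming SUSTAINED here is the amphiregulin
    pattern.  All genes not named are FLAT in the treated arm; the control
    arm is at baseline throughout.  Returns the matrix and the
    fibrosis-course truth.
    """
    unknown = [g for g in overlap_spec if g not in shared_truth]
    if unknown:
        raise UnknownGeneError(
            f"overlap gene(s) {unknown} absent from shared truth")
    bad = [c for c in overlap_spec.values() if c not in CLASS_LABELS]
    if bad:
        raise InvalidConfigurationError(f"unknown overlap class(es) {bad}")
    if templates is None:
        templates = {
            label: make_template(label, config.peak_fold,
                                 list(config.timepoints_h))
            for label in CLASS_LABELS
        }
    genes = list(shared_truth)
    classes = [overlap_spec.get(g, FLAT) for g in genes]
    meta_rows = []
    for t in config.timepoints_h:
        for condition in (CONTROL_CONDITION, TREATED_CONDITION):
            for r in range(1, config.n_replicates + 1):
                arm = "PBS" if condition == CONTROL_CONDITION else "BLM"
                meta_rows.append((f"F_{arm}_t{t:g}h_r{r}", condition, t, r))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition",
                                            "timepoint_h", "replicate"]
                        ).set_index("sample_id")
    values = _simulate(genes, classes, templates, meta, config, stream_key=1)
    truth = {g: (c, templates[c].peak_fold if c != FLAT else 1.0)
             for g, c in zip(genes, classes)}
    return ExpressionMatrix(values, meta), truth
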