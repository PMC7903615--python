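"""The discovery screen: per-gene temporal fold changes, significance tests,
transient / sustained classification, and the cross-dataset intersection.

The screen encodes the temporal pattern that distinguishes scarless wound
healing from fibrosis.  In a scarless (oral mucosa) wound-healing time
course, repair genes are *transiently* induced: expression rises at least
``induction_fold``-fold (default 2x) at the early induction timepoints
(default 12 h and 24 h) and returns to within ``return_band`` (default
+/-20%) of baseline by the return timepoint (default 72 h = 3 days).  In a
fibrosis course the same genes may instead stay high: *sustained*
upregulation means the fold change versus matched controls exceeds
``sustained_fold`` at every treated timepoint.  Genes transient in the
wound course AND sustained in the fibrosis course are the candidate
fibrosis drivers (the amphiregulin pattern).

Fold changes are ratios of geometric means across replicates (i.e.
arithmetic means in log2), matching a multiplicative noise model.
Significance is a per-timepoint two-sample test of log2 replicate values
against baseline, Welch's t by default, with the gate at p < 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import CONTROL_CONDITION, ExpressionMatrix

__all__ = [
    "TRANSIENT_INDUCED",
    "INDUCED_NOT_RETURNED",
    "NOT_INDUCED",
    "SUSTAINED_UP",
    "NOT_SUSTAINED",
    "ScreenError",
    "MissingTimepointError",
    "MissingGroupError",
    "ScreenCriteria",
    "GeneTimeProfile",
    "ScreenResult",
    "CandidateHit",
    "TestOutcome",
    "group_compare",
    "compute_fold_changes",
    "classify_transient",
    "classify_sustained_up",
    "intersect_screens",
]

logger = logging.getLogger("fibroscreen.screen")

# Wound-course labels.
TRANSIENT_INDUCED = "TRANSIENT_INDUCED"
INDUCED_NOT_RETURNED = "INDUCED_NOT_RETURNED"
NOT_INDUCED = "NOT_INDUCED"
# Fibrosis-course labels.
SUSTAINED_UP = "SUSTAINED_UP"
NOT_SUSTAINED = "NOT_SUSTAINED"


class ScreenError(Exception):
    """Base class for screen configuration / input errors."""


class MissingTimepointError(ScreenError):
    """A timepoint required by the criteria is absent from the profiles."""


class MissingGroupError(ScreenError):
    """A required replicate group (baseline or timepoint) has no samples."""


@dataclass(frozen=True)
class ScreenCriteria:
    """All thresholds of the screen.

    Attributes
    ----------
    induction_fold
        Minimum fold change (inclusive) at every induction timepoint.
    induction_timepoints_h
        Early timepoints at which induction is required (hours).
    induction_policy
        ``"all"`` (default) requires the fold threshold at every induction
        timepoint; ``"any"`` at at least one.
    return_timepoint_h
        Timepoint at which expression must be back near baseline.
    return_band
        Half-width of the baseline-return band on the fold-change scale:
        FC(return) must lie in [1 - band, 1 + band], both ends inclusive.
    sustained_fold
        Minimum fold change (inclusive) at every treated timepoint for a
        sustained-upregulation call.
    alpha
        Significance level for the per-timepoint test (strict: p < alpha).
    require_significance
        Gate induction / sustained calls on per-timepoint significance.
    test_method
        ``"welch_t"`` or ``"mann_whitney"`` on log2 replicate values.
    fdr_correction
        Apply Benjamini-Hochberg across genes within each timepoint before
        gating.  Off by default.
    """

    induction_fold: float = 2.0
    induction_timepoints_h: tuple[float, ...] = (12.0, 24.0)
    induction_policy: str = "all"
    return_timepoint_h: float = 72.0
    return_band: float = 0.20
    sustained_fold: float = 2.0
    alpha: float = 0.01
    require_significance: bool = True
    test_method: str = "welch_t"
    fdr_correction: bool = False

    def __post_init__(self) -> None:
        if not self.induction_timepoints_h:
            raise ScreenError("induction_timepoints_h must be non-empty")
        object.__setattr__(
            self, "induction_timepoints_h",
            tuple(float(t) for t in self.induction_timepoints_h),
        )
        if self.induction_fold <= 1:
            raise ScreenError("induction_fold must exceed 1")
        if self.sustained_fold <= 1:
            raise ScreenError("sustained_fold must exceed 1")
        if self.return_timepoint_h <= max(self.induction_timepoints_h):
            raise ScreenError(
                "return_timepoint_h must exceed the last induction timepoint"
            )
        if not 0 < self.return_band < 1:
            raise ScreenError("return_band must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ScreenError("alpha must be in (0, 1)")
        if self.test_method not in ("welch_t", "mann_whitney"):
            raise ScreenError(f"unknown test_method {self.test_method!r}")
        if self.induction_policy not in ("all", "any"):
            raise ScreenError(f"induction_policy must be 'all' or 'any'")


@dataclass
class GeneTimeProfile:
    """Per-gene fold change and p-value at each timepoint versus baseline.

    ``fold_change[t]`` is the ratio of geometric-mean abundance at t to the
    geometric-mean baseline abundance (linear scale, > 0; 1 at baseline).
    ``p_value[t]`` may be NaN when the test is unavailable (degenerate
    replication); ``degenerate[t]`` flags limiting-case or unavailable
    tests.
    """

    gene_id: str
    fold_change: dict[float, float]
    p_value: dict[float, float]
    n_replicates: dict[float, int]
    degenerate: dict[float, bool] = field(default_factory=dict)

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.fold_change)


@dataclass
class ScreenResult:
    """One temporal class label per gene, with the supporting profiles."""

    labels: dict[str, str]
    profiles: dict[str, GeneTimeProfile]
    criteria: ScreenCriteria
    gate_counts: dict[str, int] = field(default_factory=dict)

    @property
    def timepoints(self) -> list[float]:
        for profile in self.profiles.values():
            return profile.timepoints
        return []

    def genes_with_label(self, label: str) -> list[str]:
        return [g for g, lab in self.labels.items() if lab == label]


@dataclass(frozen=True)
class CandidateHit:
    """A gene transient in the wound course and sustained in fibrosis."""

    gene_id: str
    wound_class: str
    fibrosis_class: str
    max_wound_fc: float
    min_fibrosis_fc: float


@dataclass(frozen=True)
class TestOutcome:
    statistic: float
    p_value: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# two-sample comparison


def group_compare(values_a, values_b, method: str = "welch_t") -> TestOutcome:
    """Two-sided two-sample comparison of two replicate groups.

    ``welch_t`` is Welch's unequal-variance t test; ``mann_whitney`` is the
    Mann-Whitney U test (exact null distribution for small tie-free
    samples).  The p-value is invariant under swapping the groups.

    Zero within-group variance in both groups is handled as the limiting
    case: p = 1 when the means are equal, p = 0 when they differ, with the
    degeneracy flagged.  Welch's t with fewer than 2 values per group
    cannot be formed at all and returns p = NaN with the flag set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "welch_t":
        if a.size < 2 or b.size < 2:
            return TestOutcome(math.nan, math.nan, degenerate=True)
        # constancy detected by range, not variance: the two-pass variance of
        # identical floats can be ~1e-15 from rounding in the mean
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            if a[0] == b[0]:
                return TestOutcome(0.0, 1.0, degenerate=True)
            return TestOutcome(math.copysign(math.inf, a[0] - b[0]),
                               0.0, degenerate=True)
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        return TestOutcome(float(stat), float(p))
    if method == "mann_whitney":
        if a.size < 1 or b.size < 1:
            return TestOutcome(math.nan, math.nan, degenerate=True)
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            if a[0] == b[0]:
                return TestOutcome(a.size * b.size / 2.0, 1.0, degenerate=True)
            return TestOutcome(float(a.size * b.size if a[0] > b[0] else 0.0),
                               0.0, degenerate=True)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return TestOutcome(float(res.statistic), float(res.pvalue))
    raise ScreenError(f"unknown test method {method!r}")


# ---------------------------------------------------------------------------
# fold-change profiles


def _geomean_log2(block: np.ndarray) -> np.ndarray:
    """Per-row arithmetic mean of log2 values (log2 of the geometric mean)."""
    return np.log2(block).mean(axis=1)


def _test_block(log2_a: np.ndarray, log2_b: np.ndarray, method: str
                ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample test of log2 replicate blocks a vs b.

    Returns (p_values, degenerate_flags), handling the zero-variance and
    tiny-n limiting cases per :func:`group_compare`.
    """
    n_genes = log2_a.shape[0]
    pvals = np.full(n_genes, np.nan)
    degen = np.zeros(n_genes, dtype=bool)
    if method == "welch_t":
        if log2_a.shape[1] < 2 or log2_b.shape[1] < 2:
            return pvals, np.ones(n_genes, dtype=bool)
        both_const = (np.ptp(log2_a, axis=1) == 0) & (np.ptp(log2_b, axis=1) == 0)
        regular = ~both_const
        if regular.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                _, p = stats.ttest_ind(log2_a[regular], log2_b[regular],
                                       axis=1, equal_var=False)
            pvals[regular] = p
        if both_const.any():
            equal = log2_a[:, 0] == log2_b[:, 0]
            pvals[both_const & equal] = 1.0
            pvals[both_const & ~equal] = 0.0
            degen[both_const] = True
        return pvals, degen
    # mann_whitney: no vectorized exact path across mixed tie structures
    for i in range(n_genes):
        outcome = group_compare(log2_a[i], log2_b[i], "mann_whitney")
        pvals[i] = outcome.p_value
        degen[i] = outcome.degenerate
    return pvals, degen


def compute_fold_changes(
    matrix: ExpressionMatrix,
    baseline: str = "time_zero",
    criteria: ScreenCriteria | None = None,
) -> dict[str, GeneTimeProfile]:
    """Per-gene fold change and p-value at each timepoint versus baseline.

    Parameters
    ----------
    matrix
        The expression matrix; non-positive cells are raised to the
        positivity floor (half the smallest positive value) before the log
        transform, and counted in the log.
    baseline
        * ``"time_zero"`` — single-arm time course: every timepoint t > 0
          is compared with the pooled samples at t = 0.
        * ``"matched_control"`` — two-arm course: at each timepoint the
          treated arm is compared with the control arm at the same
          timepoint, falling back to the pooled control arm when no
          timepoint-matched controls exist (the fallback is logged).
        * ``"pooled_control"`` — treated samples at each timepoint versus
          all control samples.
    criteria
        Supplies the test method and the BH option; defaults used if None.

    Returns a mapping gene_id -> :class:`GeneTimeProfile`.  The baseline
    timepoint (t = 0 for ``time_zero``) carries FC = 1 and p = 1 by
    definition.
    """
    criteria = criteria or ScreenCriteria()
    floored = matrix.floored()
    if floored.floored_cells:
        logger.warning("raised %d non-positive cell(s) to the positivity floor",
                       floored.floored_cells)
    values = floored.values.to_numpy(dtype=float)
    genes = floored.gene_ids
    samples = floored.samples

    def cols(ids: list[str]) -> np.ndarray:
        idx = [floored.sample_ids.index(s) for s in ids]
        return values[:, idx]

    profiles: dict[str, GeneTimeProfile] = {
        g: GeneTimeProfile(g, {}, {}, {}, {}) for g in genes
    }
    per_timepoint_p: dict[float, np.ndarray] = {}
    per_timepoint_deg: dict[float, np.ndarray] = {}
    per_timepoint_fc: dict[float, np.ndarray] = {}
    per_timepoint_n: dict[float, int] = {}

    if baseline == "time_zero":
        base_ids = floored.select_samples(timepoint_h=0.0)
        if not base_ids:
            raise MissingGroupError("no baseline samples at timepoint 0")
        base_log2 = np.log2(cols(base_ids))
        base_mean = base_log2.mean(axis=1)
        for t in floored.timepoints_h:
            if t == 0.0:
                per_timepoint_fc[t] = np.ones(len(genes))
                per_timepoint_p[t] = np.ones(len(genes))
                per_timepoint_deg[t] = np.zeros(len(genes), dtype=bool)
                per_timepoint_n[t] = len(base_ids)
                continue
            group_ids = floored.select_samples(timepoint_h=t)
            if not group_ids:
                raise MissingGroupError(f"no samples at timepoint {t} h")
            log2_t = np.log2(cols(group_ids))
            per_timepoint_fc[t] = 2.0 ** (log2_t.mean(axis=1) - base_mean)
            p, deg = _test_block(log2_t, base_log2, criteria.test_method)
            per_timepoint_p[t], per_timepoint_deg[t] = p, deg
            per_timepoint_n[t] = len(group_ids)
    elif baseline in ("matched_control", "pooled_control"):
        control_ids_all = floored.select_samples(condition=CONTROL_CONDITION)
        if not control_ids_all:
            raise MissingGroupError("no control-arm samples in matrix")
        pooled_log2 = np.log2(cols(control_ids_all))
        treated_conditions = [c for c in floored.conditions
                              if c != CONTROL_CONDITION]
        if not treated_conditions:
            raise MissingGroupError("no treated-arm samples in matrix")
        treated_mask = samples["condition"] != CONTROL_CONDITION
        treated_timepoints = sorted(
            samples.loc[treated_mask, "timepoint_h"].unique().tolist()
        )
        for t in treated_timepoints:
            treated_ids = [
                s for s in floored.select_samples(timepoint_h=t)
                if samples.loc[s, "condition"] != CONTROL_CONDITION
            ]
            if not treated_ids:
                raise MissingGroupError(f"no treated samples at {t} h")
            if baseline == "matched_control":
                ctrl_ids = floored.select_samples(
                    condition=CONTROL_CONDITION, timepoint_h=t)
                if not ctrl_ids:
                    logger.info(
                        "no matched controls at %s h; using pooled control arm", t)
                    ctrl_log2 = pooled_log2
                    n_ctrl = len(control_ids_all)
                else:
                    ctrl_log2 = np.log2(cols(ctrl_ids))
                    n_ctrl = len(ctrl_ids)
            else:
                ctrl_log2 = pooled_log2
                n_ctrl = len(control_ids_all)
            log2_t = np.log2(cols(treated_ids))
            per_timepoint_fc[t] = 2.0 ** (log2_t.mean(axis=1)
                                          - ctrl_log2.mean(axis=1))
            p, deg = _test_block(log2_t, ctrl_log2, criteria.test_method)
            per_timepoint_p[t], per_timepoint_deg[t] = p, deg
            per_timepoint_n[t] = len(treated_ids)
    else:
        raise ScreenError(f"unknown baseline selector {baseline!r}")

    if criteria.fdr_correction:
        from statsmodels.stats.multitest import multipletests
        for t, p in per_timepoint_p.items():
            finite = np.isfinite(p)
            if finite.sum() > 0:
                adj = p.copy()
                adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
                per_timepoint_p[t] = adj

    for t in per_timepoint_fc:
        fc = per_timepoint_fc[t]
        p = per_timepoint_p[t]
        deg = per_timepoint_deg[t]
        n = per_timepoint_n[t]
        for i, g in enumerate(genes):
            profiles[g].fold_change[t] = float(fc[i])
            profiles[g].p_value[t] = float(p[i])
            profiles[g].n_replicates[t] = n
            profiles[g].degenerate[t] = bool(deg[i])
    return profiles


# ---------------------------------------------------------------------------
# classification


def _passes_significance(profile: GeneTimeProfile, t: float,
                         criteria: ScreenCriteria) -> bool:
    """p < alpha, with an unavailable test (NaN p) failing the gate."""
    p = profile.p_value.get(t, math.nan)
    return (not math.isnan(p)) and p < criteria.alpha


def classify_transient(profiles: dict[str, GeneTimeProfile],
                       criteria: ScreenCriteria | None = None) -> ScreenResult:
    """Label each gene of a single-arm wound course.

    * ``TRANSIENT_INDUCED`` — FC >= induction_fold at every induction
      timepoint (or any, per policy), FC at the return timepoint within
      [1 - band, 1 + band] (both ends inclusive), and, when the gate is
      on, p < alpha at every induction timepoint.
    * ``INDUCED_NOT_RETURNED`` — induction (incl. significance) passes but
      the baseline-return test fails.
    * ``NOT_INDUCED`` — anything else.
    """
    criteria = criteria or ScreenCriteria()
    needed = [*criteria.induction_timepoints_h, criteria.return_timepoint_h]
    labels: dict[str, str] = {}
    counts = {"genes_in": len(profiles), "induced": 0, "significant": 0,
              "returned": 0, TRANSIENT_INDUCED: 0, INDUCED_NOT_RETURNED: 0,
              NOT_INDUCED: 0}
    for gene, profile in profiles.items():
        missing = [t for t in needed if t not in profile.fold_change]
        if missing:
            raise MissingTimepointError(
                f"gene {gene}: criteria timepoint(s) {missing} absent from profile"
            )
        fold_ok = [profile.fold_change[t] >= criteria.induction_fold
                   for t in criteria.induction_timepoints_h]
        induced = all(fold_ok) if criteria.induction_policy == "all" else any(fold_ok)
        if induced:
            counts["induced"] += 1
        significant = (not criteria.require_significance) or all(
            _passes_significance(profile, t, criteria)
            for t in criteria.induction_timepoints_h
        )
        if induced and significant:
            counts["significant"] += 1
        fc_return = profile.fold_change[criteria.return_timepoint_h]
        returned = (1.0 - criteria.return_band <= fc_return
                    <= 1.0 + criteria.return_band)
        if induced and significant and returned:
            counts["returned"] += 1
            labels[gene] = TRANSIENT_INDUCED
        elif induced and significant:
            labels[gene] = INDUCED_NOT_RETURNED
        else:
            labels[gene] = NOT_INDUCED
        counts[labels[gene]] += 1
    logger.info("transient screen: %s", counts)
    return ScreenResult(labels, profiles, criteria, counts)


def classify_sustained_up(profiles: dict[str, GeneTimeProfile],
                          criteria: ScreenCriteria | None = None,
                          ) -> ScreenResult:
    """Label each gene of a two-arm fibrosis course.

    ``SUSTAINED_UP`` requires FC >= sustained_fold at EVERY treated
    timepoint ("upregulated throughout"), and p < alpha at every treated
    timepoint when the gate is on; otherwise ``NOT_SUSTAINED``.  Treated
    timepoints are all timepoints with t > 0 present in the profiles.
    """
    criteria = criteria or ScreenCriteria()
    labels: dict[str, str] = {}
    counts = {"genes_in": len(profiles), SUSTAINED_UP: 0, NOT_SUSTAINED: 0}
    for gene, profile in profiles.items():
        treated = [t for t in profile.timepoints if t > 0]
        if not treated:
            raise MissingTimepointError(
                f"gene {gene}: no treated timepoints in profile")
        fold_ok = all(profile.fold_change[t] >= criteria.sustained_fold
                      for t in treated)
        sig_ok = (not criteria.require_significance) or all(
            _passes_significance(profile, t, criteria) for t in treated
        )
        labels[gene] = SUSTAINED_UP if (fold_ok and sig_ok) else NOT_SUSTAINED
        counts[labels[gene]] += 1
    logger.info("sustained screen: %s", counts)
    return ScreenResult(labels, profiles, criteria, counts)


def intersect_screens(wound_result: ScreenResult,
                      fibrosis_result: ScreenResult) -> list[CandidateHit]:
    """Genes transient in the wound course AND sustained in fibrosis.

    The intersection is over shared gene ids; hits are ordered by
    descending maximum wound fold change, then gene id (the stable ranked
    order used for results files).
    """
    transient = set(wound_result.genes_with_label(TRANSIENT_INDUCED))
    sustained = set(fibrosis_result.genes_with_label(SUSTAINED_UP))
    hits = []
    for gene in transient & sustained:
        wound_profile = wound_result.profiles[gene]
        fib_profile = fibrosis_result.profiles[gene]
        max_wound = max(wound_profile.fold_change[t]
                        for t in wound_profile.timepoints if t > 0)
        min_fib = min(fib_profile.fold_change[t]
                      for t in fib_profile.timepoints if t > 0)
        hits.append(CandidateHit(gene, TRANSIENT_INDUCED, SUSTAINED_UP,
                                 max_wound, min_fib))
    hits.sort(key=lambda h: (-h.max_wound_fc, h.gene_id))
    logger.info("intersection: %d candidate hit(s)", len(hits))
    return hits
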