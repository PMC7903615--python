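"""Screen contracts: fold-change arithmetic against a scalar brute-force
oracle, classification boundary behaviour, statistical tests against
exhaustive enumeration, and the label-set invariants."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import stdtr

from fibroscreen import (
    INDUCED_NOT_RETURNED,
    NOT_INDUCED,
    NOT_SUSTAINED,
    SUSTAINED_UP,
    TRANSIENT_INDUCED,
    ExpressionMatrix,
    GeneTimeProfile,
    MissingTimepointError,
    ScreenCriteria,
    ScreenError,
    classify_sustained_up,
    classify_transient,
    compute_fold_changes,
    group_compare,
    intersect_screens,
)
from fibroscreen.screen import ScreenResult

from conftest import build_matrix


def profile(gene, fc, p=None):
    """Build a GeneTimeProfile from dicts t -> FC (and optional t -> p)."""
    p = p or {t: (1.0 if t == 0 else 1e-6) for t in fc}
    return GeneTimeProfile(gene, dict(fc), dict(p),
                           {t: 3 for t in fc}, {t: False for t in fc})


# ---------------------------------------------------------------------------
# group_compare


class TestGroupCompare:
    def test_identical_groups_welch(self):
        out = group_compare([1, 2, 3], [1, 2, 3], "welch_t")
        assert out.statistic == 0.0 and out.p_value == 1.0

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    def test_swap_symmetry(self, a, b):
        for method in ("welch_t", "mann_whitney"):
            p_ab = group_compare(a, b, method).p_value
            p_ba = group_compare(b, a, method).p_value
            assert p_ab == pytest.approx(p_ba, abs=1e-12) or (
                math.isnan(p_ab) and math.isnan(p_ba))

    def test_zero_variance_limiting_cases(self):
        equal = group_compare([2, 2, 2], [2, 2, 2], "welch_t")
        assert equal.p_value == 1.0 and equal.degenerate
        unequal = group_compare([3, 3, 3], [2, 2, 2], "welch_t")
        assert unequal.p_value == 0.0 and unequal.degenerate

    def test_single_value_welch_unavailable(self):
        out = group_compare([1.0], [1, 2, 3], "welch_t")
        assert math.isnan(out.p_value) and out.degenerate

    def test_mann_whitney_exact_matches_enumeration(self):
        """Exact two-sided MW p for n=4 vs n=4 equals enumeration over all
        C(8,4)=70 equally likely rank splits under the null."""
        a = [1.3, 2.7, 0.4, 5.1]
        b = [3.3, 6.2, 4.4, 7.9]
        pooled = sorted(a + b)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}

        def u_stat(group_ranks):
            r = sum(group_ranks)
            return r - 4 * 5 / 2

        u_obs = u_stat([ranks[v] for v in a])
        mid = 4 * 4 / 2
        splits = list(itertools.combinations(range(8), 4))
        assert len(splits) == 70
        extreme = sum(
            abs(u_stat([i + 1 for i in split]) - mid) >= abs(u_obs - mid)
            for split in splits)
        expected_p = extreme / 70
        out = group_compare(a, b, "mann_whitney")
        assert out.p_value == pytest.approx(expected_p, abs=1e-12)

    def test_unknown_method_rejected(self):
        with pytest.raises(ScreenError):
            group_compare([1, 2], [3, 4], "anova")


# ---------------------------------------------------------------------------
# fold-change profiles


def scalar_oracle_profiles(matrix: ExpressionMatrix):
    """Independent per-gene, per-timepoint re-implementation.

    Plain-Python loops: fold change as ratio of geometric means, Welch's t
    assembled by hand with p from the t CDF.
    """
    out = {}
    base_samples = [s for s in matrix.sample_ids
                    if matrix.samples.loc[s, "timepoint_h"] == 0.0]
    for gene in matrix.gene_ids:
        fc, pv = {}, {}
        base = [math.log2(matrix.values.loc[gene, s]) for s in base_samples]
        for t in matrix.timepoints_h:
            group_samples = [s for s in matrix.sample_ids
                            if matrix.samples.loc[s, "timepoint_h"] == t]
            vals = [math.log2(matrix.values.loc[gene, s]) for s in group_samples]
            if t == 0.0:
                fc[t], pv[t] = 1.0, 1.0
                continue
            mean_t = sum(vals) / len(vals)
            mean_0 = sum(base) / len(base)
            fc[t] = 2.0 ** (mean_t - mean_0)
            var_t = sum((v - mean_t) ** 2 for v in vals) / (len(vals) - 1)
            var_0 = sum((v - mean_0) ** 2 for v in base) / (len(base) - 1)
            se2 = var_t / len(vals) + var_0 / len(base)
            t_stat = (mean_t - mean_0) / math.sqrt(se2)
            df = se2 ** 2 / (
                (var_t / len(vals)) ** 2 / (len(vals) - 1)
                + (var_0 / len(base)) ** 2 / (len(base) - 1))
            pv[t] = 2.0 * stdtr(df, -abs(t_stat))
        out[gene] = (fc, pv)
    return out


class TestComputeFoldChanges:
    def test_identity_when_treated_equals_baseline(self):
        values = {"g1": [5.0, 6.0, 7.0] * 3}
        matrix = build_matrix(values, [0.0, 12.0, 24.0], 3)
        profiles = compute_fold_changes(matrix, "time_zero")
        assert profiles["g1"].fold_change == pytest.approx(
            {0.0: 1.0, 12.0: 1.0, 24.0: 1.0})

    def test_tenfold_induction_recovered_exactly(self):
        """Baseline {100,100,100} vs 24 h {1000,1000,1000} gives FC = 10,
        the amphiregulin-scale induction."""
        values = {"Areg": [100.0] * 3 + [1000.0] * 3}
        matrix = build_matrix(values, [0.0, 24.0], 3)
        profiles = compute_fold_changes(matrix, "time_zero")
        assert profiles["Areg"].fold_change[24.0] == pytest.approx(10.0, rel=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        timepoints = [0.0, 12.0, 24.0, 72.0]
        values = {f"g{i}": (2.0 ** (6 + rng.standard_normal(12))).tolist()
                  for i in range(20)}
        matrix = build_matrix(values, timepoints, 3)
        profiles = compute_fold_changes(matrix, "time_zero")
        oracle = scalar_oracle_profiles(matrix)
        for gene, (fc, pv) in oracle.items():
            for t in timepoints:
                assert profiles[gene].fold_change[t] == pytest.approx(
                    fc[t], rel=1e-12)
                assert profiles[gene].p_value[t] == pytest.approx(
                    pv[t], abs=1e-9)

    def test_no_baseline_raises(self):
        matrix = build_matrix({"g": [1.0] * 6}, [12.0, 24.0], 3,
                              condition_of=lambda t: "injured")
        # timepoints lack 0 h entirely
        samples = matrix.samples
        with pytest.raises(ScreenError):
            compute_fold_changes(matrix, "time_zero")

    def test_matched_control_baseline(self):
        # two-arm: control flat at 100, treated at 400 -> FC 4 per timepoint
        sample_ids = []
        meta = []
        vals = []
        for t in (0.0, 72.0):
            for cond in ("control", "treated"):
                for r in (1, 2, 3):
                    sid = f"{cond}_t{t:g}_r{r}"
                    sample_ids.append(sid)
                    meta.append((sid, cond, t, r))
                    vals.append(100.0 if (cond == "control" or t == 0.0) else 400.0)
        values = pd.DataFrame([vals], index=pd.Index(["g"], name="gene_id"),
                              columns=sample_ids)
        samples = pd.DataFrame(meta, columns=["sample_id", "condition",
                                              "timepoint_h", "replicate"]
                               ).set_index("sample_id")
        profiles = compute_fold_changes(ExpressionMatrix(values, samples),
                                        "matched_control")
        assert profiles["g"].fold_change[72.0] == pytest.approx(4.0, rel=1e-12)
        assert profiles["g"].fold_change[0.0] == pytest.approx(1.0, rel=1e-12)


# ---------------------------------------------------------------------------
# classification


class TestClassifyTransient:
    def test_areg_pattern_is_transient(self):
        res = classify_transient({"Areg": profile(
            "Areg", {0: 1.0, 12: 10.0, 24: 10.0, 72: 1.0})})
        assert res.labels["Areg"] == TRANSIENT_INDUCED

    def test_failing_one_induction_timepoint_is_not_induced(self):
        res = classify_transient({"g": profile(
            "g", {0: 1.0, 12: 10.0, 24: 1.5, 72: 1.0})})
        assert res.labels["g"] == NOT_INDUCED

    def test_return_band_closed_at_both_ends(self):
        inside = classify_transient({"g": profile(
            "g", {0: 1.0, 12: 3.0, 24: 3.0, 72: 1.20})})
        outside = classify_transient({"g": profile(
            "g", {0: 1.0, 12: 3.0, 24: 3.0, 72: 1.21})})
        low_inside = classify_transient({"g": profile(
            "g", {0: 1.0, 12: 3.0, 24: 3.0, 72: 0.80})})
        assert inside.labels["g"] == TRANSIENT_INDUCED
        assert outside.labels["g"] == INDUCED_NOT_RETURNED
        assert low_inside.labels["g"] == TRANSIENT_INDUCED

    def test_induction_threshold_inclusive(self):
        res = classify_transient({"g": profile(
            "g", {0: 1.0, 12: 2.0, 24: 2.0, 72: 1.0})})
        assert res.labels["g"] == TRANSIENT_INDUCED

    def test_significance_gate_blocks_unsupported_induction(self):
        weak_p = {0: 1.0, 12: 0.5, 24: 1e-6, 72: 0.9}
        res = classify_transient({"g": profile(
            "g", {0: 1.0, 12: 10.0, 24: 10.0, 72: 1.0}, weak_p)})
        assert res.labels["g"] == NOT_INDUCED
        no_gate = classify_transient(
            {"g": profile("g", {0: 1.0, 12: 10.0, 24: 10.0, 72: 1.0}, weak_p)},
            ScreenCriteria(require_significance=False))
        assert no_gate.labels["g"] == TRANSIENT_INDUCED

    def test_missing_criteria_timepoint_raises(self):
        with pytest.raises(MissingTimepointError):
            classify_transient({"g": profile("g", {0: 1.0, 12: 5.0, 72: 1.0})})

    def test_every_gene_gets_exactly_one_label(self):
        profiles = {f"g{i}": profile(
            f"g{i}", {0: 1.0, 12: float(i), 24: float(i), 72: 1.0})
            for i in range(1, 8)}
        res = classify_transient(profiles)
        assert set(res.labels) == set(profiles)
        assert res.gate_counts["genes_in"] == sum(
            res.gate_counts[lab] for lab in
            (TRANSIENT_INDUCED, INDUCED_NOT_RETURNED, NOT_INDUCED))


class TestClassifySustained:
    def test_sustained_throughout(self):
        res = classify_sustained_up({"g": profile(
            "g", {0: 1.0, 72: 5.0, 168: 4.0, 240: 3.0})})
        assert res.labels["g"] == SUSTAINED_UP

    def test_flat_gene_not_sustained(self):
        res = classify_sustained_up({"g": profile(
            "g", {0: 1.0, 72: 1.0, 168: 1.0, 240: 1.0})})
        assert res.labels["g"] == NOT_SUSTAINED

    def test_one_failing_timepoint_breaks_throughout(self):
        res = classify_sustained_up({"g": profile(
            "g", {0: 1.0, 72: 5.0, 168: 5.0, 240: 1.1})})
        assert res.labels["g"] == NOT_SUSTAINED


class TestIntersect:
    def make_result(self, labels, fc_by_gene, kind="wound"):
        profiles = {g: profile(g, fc_by_gene[g]) for g in labels}
        return ScreenResult(labels, profiles, ScreenCriteria())

    def test_shared_hit_only(self):
        fcs = {g: {0: 1.0, 12: 5.0, 24: 5.0, 72: 1.0}
               for g in ("A", "B", "C", "D")}
        wound = self.make_result(
            {"A": TRANSIENT_INDUCED, "B": TRANSIENT_INDUCED,
             "C": TRANSIENT_INDUCED}, fcs)
        fib = self.make_result(
            {"A": SUSTAINED_UP, "D": SUSTAINED_UP}, fcs)
        hits = intersect_screens(wound, fib)
        assert [h.gene_id for h in hits] == ["A"]
        assert hits[0].max_wound_fc == pytest.approx(5.0)

    def test_disjoint_sets_empty(self):
        fcs = {g: {0: 1.0, 12: 5.0, 24: 5.0, 72: 1.0} for g in ("A", "B")}
        wound = self.make_result({"A": TRANSIENT_INDUCED}, fcs)
        fib = self.make_result({"B": SUSTAINED_UP}, fcs)
        assert intersect_screens(wound, fib) == []

    def test_empty_inputs(self):
        empty = ScreenResult({}, {}, ScreenCriteria())
        assert intersect_screens(empty, empty) == []


# ---------------------------------------------------------------------------
# invariants


def random_profiles(n=50, seed=13):
    rng = np.random.default_rng(seed)
    profiles = {}
    for i in range(n):
        fc = {0.0: 1.0}
        pv = {0.0: 1.0}
        for t in (12.0, 24.0, 72.0):
            fc[t] = float(2.0 ** rng.normal(0.5, 1.5))
            pv[t] = float(rng.uniform(0, 0.05))
        profiles[f"g{i:03d}"] = GeneTimeProfile(
            f"g{i:03d}", fc, pv, {t: 3 for t in fc}, {t: False for t in fc})
    return profiles


class TestMonotonicity:
    def transient_set(self, profiles, **kw):
        res = classify_transient(profiles, ScreenCriteria(**kw))
        return set(res.genes_with_label(TRANSIENT_INDUCED))

    def test_stricter_thresholds_only_shrink_the_transient_set(self):
        profiles = random_profiles()
        default = self.transient_set(profiles)
        assert self.transient_set(profiles, induction_fold=3.0) <= default
        assert self.transient_set(profiles, return_band=0.1) <= default
        assert self.transient_set(profiles, alpha=0.001) <= default
        # and relaxing the band only grows it
        assert default <= self.transient_set(profiles, return_band=0.4)


class TestPermutationInvariance:
    def test_row_and_column_shuffles_leave_labels_unchanged(self, tiny_matrix):
        res = classify_transient(compute_fold_changes(tiny_matrix, "time_zero"))
        rng = np.random.default_rng(0)
        rows = rng.permutation(tiny_matrix.n_genes)
        cols = rng.permutation(tiny_matrix.n_samples)
        shuffled = ExpressionMatrix(
            tiny_matrix.values.iloc[rows, cols],
            tiny_matrix.samples.iloc[cols])
        res2 = classify_transient(compute_fold_changes(shuffled, "time_zero"))
        assert res.labels == res2.labels
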