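import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutshift import (
    AnalysisError,
    CohortConfig,
    OtuTable,
    SampleRecord,
    bh_adjust,
    interval_log_ratio,
    label_trajectory,
    permutation_test,
    select_significant_sets,
    simulate_cohort,
    to_relative_abundance,
)
from gutshift.temporal import GroupPermutationTest, IntervalChangeMatrix


def exhaustive_permutation_p(values: np.ndarray, labels: np.ndarray) -> float:
    """Independent oracle: two-sided p over ALL relabelings with the observed
    group sizes, by full enumeration of label assignments."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    n1 = int(labels.sum())
    obs = values[labels].mean() - values[~labels].mean()
    count = total = 0
    for comb in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        stat = values[mask].mean() - values[~mask].mean()
        total += 1
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    return count / total


def _meta_pair(n_subj=4):
    recs = []
    for i in range(n_subj):
        grp = "GDM" if i < n_subj // 2 else "control"
        for tp in ("t1", "t2"):
            recs.append(SampleRecord(f"S{i}_{tp}", f"S{i}", grp, tp))
    return recs


def _comp(meta, values):
    return pd.DataFrame(values, index=[r.sample_id for r in meta], columns=["fA", "fB"])


class TestRelativeAbundance:
    def test_closed_forms(self):
        t = OtuTable(["s1", "s2"], ["a", "b"], np.array([[2, 2], [0, 5]]))
        comp = to_relative_abundance(t)
        assert np.allclose(comp.loc["s1"], [0.5, 0.5])
        assert np.allclose(comp.loc["s2"], [0.0, 1.0])

    def test_zero_sum_sample_named(self):
        t = OtuTable(["ok", "bad"], ["a"], np.array([[3], [0]]))
        with pytest.raises(ValueError, match="bad"):
            to_relative_abundance(t)

    def test_rows_sum_to_one(self, small_comp):
        assert np.allclose(small_comp.sum(axis=1), 1.0)


class TestIntervalLogRatio:
    def test_identity_gives_zero(self):
        meta = _meta_pair(6)
        vals = np.tile([0.3, 0.7], (12, 1))
        change = interval_log_ratio(_comp(meta, vals), meta, "t2_vs_t1")
        assert np.allclose(change.L, 0.0)

    def test_doubling_approaches_ln2(self):
        meta = _meta_pair(6)
        vals = np.array([[0.2, 0.8] if r.timepoint == "t1" else [0.4, 0.6] for r in meta])
        change = interval_log_ratio(_comp(meta, vals), meta, "t2_vs_t1", epsilon=1e-12)
        assert np.allclose(change.to_dataframe()["fA"], np.log(2), atol=1e-9)

    def test_antisymmetry_exact(self, small_cohort, small_comp):
        _, _, meta, _ = small_cohort
        fwd = interval_log_ratio(small_comp, meta, "t2_vs_t1")
        # reversed interval computed by swapping timepoint roles in metadata
        swapped = [
            SampleRecord(r.sample_id, r.subject_id, r.group, {"t1": "t2", "t2": "t1"}.get(r.timepoint, r.timepoint))
            for r in meta
        ]
        rev = interval_log_ratio(small_comp, swapped, "t2_vs_t1")
        assert np.array_equal(fwd.L, -rev.L)

    def test_subject_intercept_cancels(self):
        meta = _meta_pair(6)
        rng = np.random.default_rng(1)
        base = rng.dirichlet([2, 3], size=12)
        change0 = interval_log_ratio(_comp(meta, base), meta, "t2_vs_t1")
        # add a constant per-subject offset on the log scale at both timepoints
        offs = np.repeat(rng.normal(size=6), 2)
        shifted = np.exp(np.log(base) + offs[:, None])
        change1 = interval_log_ratio(_comp(meta, shifted), meta, "t2_vs_t1", epsilon=1e-300)
        assert np.allclose(change0.L, change1.L, atol=1e-9)

    def test_missing_timepoint_excluded(self):
        meta = _meta_pair(8)[:-1]  # last subject loses t2
        vals = np.tile([0.5, 0.5], (len(meta), 1))
        change = interval_log_ratio(_comp(meta, vals), meta, "t2_vs_t1")
        assert change.excluded_subjects == ["S7"]

    def test_too_few_subjects_is_analysis_error(self):
        meta = _meta_pair(4)
        vals = np.tile([0.5, 0.5], (8, 1))
        with pytest.raises(AnalysisError, match="need >= 3"):
            interval_log_ratio(_comp(meta, vals), meta, "t2_vs_t1")


class TestPermutationTest:
    def _change(self, L, groups):
        n, f = L.shape
        return IntervalChangeMatrix(
            interval="t2_vs_t1",
            subjects=[f"S{i}" for i in range(n)],
            features=[f"F{j}" for j in range(f)],
            L=L,
            epsilon=1e-6,
            group_of={f"S{i}": g for i, g in enumerate(groups)},
        )

    def test_worked_example_matches_enumeration(self):
        vals = np.array([1.0, 1.2, 0.8, -1.0, -0.9, -1.1])
        labels = np.array([True] * 3 + [False] * 3)
        assert exhaustive_permutation_p(vals, labels) == pytest.approx(2 / 20)
        res = permutation_test(self._change(vals[:, None], ["GDM"] * 3 + ["control"] * 3), n_perm=10000, seed=0)
        assert abs(res["p_perm"][0] - 0.1) < 0.02

    def test_constant_matrix_gives_p_one(self):
        L = np.ones((8, 3))
        res = permutation_test(self._change(L, ["GDM"] * 4 + ["control"] * 4), n_perm=200, seed=0)
        assert np.allclose(res["stat_obs"], 0.0)
        assert np.allclose(res["p_perm"], 1.0)

    def test_feature_order_equivariance(self, rng):
        L = rng.normal(size=(10, 6))
        groups = ["GDM"] * 5 + ["control"] * 5
        res = permutation_test(self._change(L, groups), n_perm=300, seed=3)
        perm = [4, 2, 0, 5, 1, 3]
        res2 = permutation_test(self._change(L[:, perm], groups), n_perm=300, seed=3)
        assert np.array_equal(res["p_perm"].to_numpy()[perm], res2["p_perm"].to_numpy())

    def test_p_floor_and_seed_reproducibility(self, rng):
        L = rng.normal(size=(12, 4))
        L[:6] += 5.0
        groups = ["GDM"] * 6 + ["control"] * 6
        a = permutation_test(self._change(L, groups), n_perm=500, seed=9)
        b = permutation_test(self._change(L, groups), n_perm=500, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert (a["p_perm"] >= 1 / 501).all()

    def test_single_group_rejected(self):
        with pytest.raises(AnalysisError):
            permutation_test(self._change(np.zeros((4, 2)), ["GDM"] * 4))

    def test_monte_carlo_close_to_enumeration_small_n(self):
        rng = np.random.default_rng(12)
        for _ in range(8):
            n = int(rng.integers(4, 7))
            n1 = n // 2
            vals = rng.normal(size=n)
            labels = np.zeros(n, dtype=bool)
            labels[:n1] = True
            oracle = exhaustive_permutation_p(vals, labels)
            est = GroupPermutationTest(n_perm=10000, random_state=int(rng.integers(1e6))).fit(
                vals[:, None], labels
            )
            assert abs(est.p_values_[0] - oracle) < 0.02


class TestBHAdjust:
    def test_published_clinical_column(self):
        from gutshift.clinical import REFERENCE_CLINICAL_P

        q = bh_adjust(list(REFERENCE_CLINICAL_P.values()))
        by = dict(zip(REFERENCE_CLINICAL_P, q))
        assert round(by["hba1c"], 4) == 0.0192
        assert round(by["total_weight_gain"], 4) == 0.1208
        assert round(by["tg"], 4) == 0.5778
        assert round(by["urea"], 4) == 0.9300

    def test_all_equal_and_m1(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
        assert np.allclose(bh_adjust([0.37]), 0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_decreases_and_permutation_invariant(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        q2 = bh_adjust(np.asarray(p)[order])
        assert np.allclose(np.sort(q), np.sort(q2))


class TestSetSelection:
    def _df(self, q):
        return pd.DataFrame({"feature_id": [f"F{i}" for i in range(len(q))], "q_bh": q})

    def test_all_q_one_empty(self):
        res = {"t2_vs_t1": self._df([1.0, 1.0]), "t3_vs_t2": self._df([1.0])}
        assert select_significant_sets(res, 0.1) == ([], [])

    def test_threshold_one_selects_all(self):
        res = {"t2_vs_t1": self._df([0.99, 0.5]), "t3_vs_t2": self._df([0.7])}
        s1, s2 = select_significant_sets(res, 1.0)
        assert s1 == ["F0", "F1"] and s2 == ["F0"]


class TestTrajectoryLabels:
    def test_label_rules(self):
        meta = _meta_pair(6)
        # fA: zero abundance in GDM -> low; fB increases strongly -> increasing
        vals = []
        for r in meta:
            if r.group == "GDM":
                vals.append([0.0, 1.0] if r.timepoint == "t1" else [0.0, 1.0])
            else:
                vals.append([0.5, 0.5] if r.timepoint == "t1" else [0.2, 0.8])
        comp = _comp(meta, np.array(vals))
        change = interval_log_ratio(comp, meta, "t2_vs_t1")
        lab = label_trajectory(change, comp, meta, tau_low=1e-4, delta_stable=0.1)
        by = lab.set_index("feature_id")
        assert by.loc["fA", "label_gdm"] == "low"
        assert by.loc["fB", "label_control"] == "increasing"
        assert by.loc["fA", "label_control"] == "decreasing"

    def test_zero_mean_log_ratio_is_stable(self):
        meta = _meta_pair(6)
        comp = _comp(meta, np.tile([0.4, 0.6], (12, 1)))
        change = interval_log_ratio(comp, meta, "t2_vs_t1")
        lab = label_trajectory(change, comp, meta)
        assert set(lab["label_gdm"]) == {"stable"}


def test_null_symmetry_zero_effect():
    """With effect 0 the empirical group difference of mean log-ratios over
    all features is within 3 standard errors of zero."""
    cfg = CohortConfig(n_features=150, n_planted_set1=0, n_planted_set2=0, effect_log_units=0.0, seed=5)
    table, meta, _ = simulate_cohort(cfg)
    comp = to_relative_abundance(table)
    change = interval_log_ratio(comp, meta, "t2_vs_t1")
    g = change.group_vector
    diffs = change.L[g].mean(axis=0) - change.L[~g].mean(axis=0)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3 * se
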