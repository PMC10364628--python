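import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutshift import (
    AnalysisError,
    OtuTable,
    SampleRecord,
    alpha_diversity,
    alpha_group_test,
    lda_project,
    top_mad_features,
)
from gutshift.diversity import DiscriminantProjection, mean_absolute_deviation, rank_sum_test


def _table(counts, sample_ids=None, feature_ids=None):
    counts = np.asarray(counts)
    sids = sample_ids or [f"s{i}" for i in range(counts.shape[0])]
    fids = feature_ids or [f"f{j}" for j in range(counts.shape[1])]
    return OtuTable(sids, fids, counts)


class TestAlphaDiversity:
    def test_uniform_four_closed_form(self):
        rec = alpha_diversity(_table([[5, 5, 5, 5]])).iloc[0]
        assert rec["observed"] == 4
        assert rec["shannon"] == pytest.approx(np.log(4))
        assert rec["simpson"] == pytest.approx(0.75)

    def test_single_feature(self):
        rec = alpha_diversity(_table([[9, 0, 0]])).iloc[0]
        assert rec["observed"] == 1
        assert rec["shannon"] == pytest.approx(0.0)
        assert rec["simpson"] == pytest.approx(0.0)

    def test_duplicate_samples_identical_indices(self, rng):
        counts = rng.integers(0, 50, size=(1, 20))
        t = _table(np.vstack([counts, counts]))
        rec = alpha_diversity(t)
        assert rec.iloc[0]["shannon"] == rec.iloc[1]["shannon"]
        assert rec.iloc[0]["simpson"] == rec.iloc[1]["simpson"]

    def test_empty_sample_excluded_with_warning(self):
        t = _table([[1, 1], [0, 0]])
        with pytest.warns(UserWarning, match="empty"):
            rec = alpha_diversity(t)
        assert list(rec["sample_id"]) == ["s0"]

    def test_bounds_on_random_compositions(self, rng):
        counts = rng.integers(0, 200, size=(1000, 15)) + np.eye(15, dtype=int)[rng.integers(0, 15, 1000)]
        rec = alpha_diversity(_table(counts))
        obs = rec["observed"].to_numpy()
        sh = rec["shannon"].to_numpy()
        si = rec["simpson"].to_numpy()
        assert np.all(sh >= -1e-12) and np.all(sh <= np.log(obs) + 1e-12)
        assert np.all(si >= 0) and np.all(si < 1)


class TestGroupTest:
    def _meta(self, n=3):
        recs = []
        for i in range(n):
            recs.append(SampleRecord(f"g{i}", f"G{i}", "GDM", "t1"))
            recs.append(SampleRecord(f"c{i}", f"C{i}", "control", "t1"))
        return recs

    def test_identical_values_p_one(self):
        records = pd.DataFrame(
            {"sample_id": ["g0", "g1", "g2", "c0", "c1", "c2"],
             "observed": [5] * 6, "shannon": [1.0] * 6, "simpson": [0.5] * 6}
        )
        res = alpha_group_test(records, self._meta(), "t1")
        assert np.allclose(res["p_value"], 1.0)

    def test_full_separation_exact_p(self):
        stat, p = rank_sum_test(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        assert p == pytest.approx(2 / 20)

    def test_exact_close_to_asymptotic_at_n10(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=10), rng.normal(size=10)
            _, p_exact = rank_sum_test(x, y, exact_max_n=10)
            _, p_asym = rank_sum_test(x, y, exact_max_n=0)
            assert abs(p_exact - p_asym) < 0.02

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=9)
        _, p1 = rank_sum_test(x, y)
        _, p2 = rank_sum_test(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2)

    def test_one_group_empty_is_error(self):
        records = pd.DataFrame({"sample_id": ["g0"], "observed": [5], "shannon": [1.0], "simpson": [0.5]})
        meta = [SampleRecord("g0", "G0", "GDM", "t1")]
        with pytest.raises(AnalysisError):
            alpha_group_test(records, meta, "t1")


class TestTopMAD:
    def test_mad_closed_form(self):
        assert mean_absolute_deviation([0.0, 2.0]) == pytest.approx(1.0)

    def test_constant_feature_excluded(self):
        t = _table([[10, 5, 1], [10, 1, 5]])
        ranked = top_mad_features(t, n_top=5)
        assert "f0" not in ranked  # constant relative abundance across samples
        assert set(ranked) == {"f1", "f2"}

    def test_n_top_caps_at_survivors(self):
        t = _table([[3, 1], [1, 3]])
        assert len(top_mad_features(t, n_top=100)) == 2

    def test_ranking_by_variability(self, rng):
        base = rng.dirichlet(np.ones(6), size=20)
        base[:, 0] += np.repeat([0.0, 2.0], 10)  # feature 0 most variable
        counts = np.rint(base / base.sum(1, keepdims=True) * 10000).astype(int)
        ranked = top_mad_features(_table(counts), n_top=3)
        assert ranked[0] == "f0"


class TestLDA:
    def test_separation_axis_alignment(self, rng):
        n = 30
        X = rng.normal(scale=0.2, size=(2 * n, 2))
        X[:n, 0] += 4.0
        y = ["a"] * n + ["b"] * n
        proj = DiscriminantProjection(shrinkage=0.1, n_components=1).fit(X, y)
        direction = proj.scalings_[:, 0]
        cos = direction[0] / np.linalg.norm(direction)
        assert abs(cos) > 0.99

    def test_permuted_labels_no_real_separation(self, rng):
        """Label permutation oracle: observed between/within ratio of permuted
        labels does not exceed the permutation 95th percentile."""
        X = rng.normal(size=(40, 3))
        y = np.array(["a", "b"] * 20)

        def ratio(labels):
            proj = DiscriminantProjection(shrinkage=0.2, n_components=1).fit(X, labels)
            z = proj.transform(X)[:, 0]
            za, zb = z[labels == "a"], z[labels == "b"]
            within = za.var(ddof=1) + zb.var(ddof=1)
            return (za.mean() - zb.mean()) ** 2 / within

        y_perm = rng.permutation(y)
        obs = ratio(y_perm)
        null = np.array([ratio(rng.permutation(y)) for _ in range(60)])
        assert obs <= np.quantile(null, 0.95) * 1.5

    def test_shrinkage_one_identity_scaling(self, rng):
        """At shrinkage 1 the within-scatter is (trace/p)*I, so discriminants
        are the eigenvectors of the between-class scatter."""
        n = 20
        X = rng.normal(scale=0.5, size=(2 * n, 3))
        X[:n] += np.array([3.0, 0.0, 0.0])
        y = ["a"] * n + ["b"] * n
        proj = DiscriminantProjection(shrinkage=1.0, n_components=1).fit(X, y)
        d = proj.scalings_[:, 0]
        d = d / np.linalg.norm(d)
        mu_diff = X[:n].mean(axis=0) - X[n:].mean(axis=0)
        mu_diff = mu_diff / np.linalg.norm(mu_diff)
        assert abs(d @ mu_diff) > 0.999

    def test_singular_without_shrinkage_suggests_fix(self, rng):
        X = rng.normal(size=(8, 50))  # many more features than samples
        y = ["a"] * 4 + ["b"] * 4
        with pytest.raises(AnalysisError, match="shrinkage"):
            DiscriminantProjection(shrinkage=0.0).fit(X, y)

    def test_project_six_classes(self, small_cohort, small_comp):
        _, table, meta, _ = small_cohort
        top = top_mad_features(table, n_top=40)
        class_of = {r.sample_id: f"{r.group}_{r.timepoint}" for r in meta}
        sub = small_comp[top]
        out = lda_project(sub, [class_of[s] for s in sub.index])
        assert {"LD1", "LD2"} <= set(out.columns)
        assert len(out) == len(sub)
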