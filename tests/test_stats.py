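"""Statistical stage: transforms, enrichment, ANOVA, Mantel, CCA."""

import math

import numpy as np
import pandas as pd
import pytest

from coculture import stats
from oracles import hypergeometric_greater


class TestTransform:
    def test_examples(self):
        out = stats.transform_fluxes(np.array([0.5, 9.0, 0.0]))
        assert out == pytest.approx([0.0, 1.0, 0.0])

    def test_dataframe_type_preserved(self):
        df = pd.DataFrame({"x": [2.0, 0.3]}, index=["p1", "p2"])
        out = stats.transform_fluxes(df)
        assert isinstance(out, pd.DataFrame)
        assert list(out.index) == ["p1", "p2"]
        assert out.loc["p1", "x"] == pytest.approx(math.log10(3.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stats.transform_fluxes(np.array([-1.0]))


class TestEnrichment:
    def test_identical_composition_not_enriched(self):
        overall = {"mutualistic": 40, "neutral": 60}
        subset = {"mutualistic": 20, "neutral": 30}
        pvals = stats.enrichment_test(overall, subset)
        assert all(p > 0.5 for p in pvals.values())

    def test_pure_subset_is_enriched(self):
        overall = {"mutualistic": 15, "neutral": 15, "commensal": 10}
        subset = {"mutualistic": 10, "neutral": 0, "commensal": 0}
        pvals = stats.enrichment_test(overall, subset)
        assert pvals["mutualistic"] < 0.05
        assert pvals["neutral"] > 0.5

    def test_closed_form_tail(self):
        # Table (10,0; 0,10), alternative greater: p = 1 / C(20,10).
        assert stats.fisher_greater(10, 0, 0, 10) == pytest.approx(
            1.0 / math.comb(20, 10))

    def test_zero_margin_gives_one(self):
        assert stats.fisher_greater(0, 0, 5, 5) == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            assert stats.fisher_greater(a, b, c, d) == pytest.approx(
                hypergeometric_greater(a, b, c, d), rel=1e-9, abs=1e-12)


class TestANOVA:
    def test_identical_groups(self):
        F, p = stats.transfer_count_anova({"x": [3, 3, 3], "y": [3, 3, 3]})
        assert (F, p) == (0.0, 1.0)

    def test_separated_constant_groups(self):
        F, p = stats.transfer_count_anova({"x": [0, 0, 0], "y": [10, 10, 10]})
        assert F == float("inf") and p == 0.0

    def test_matches_scipy_on_generic_data(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(1)
        groups = {k: list(rng.normal(loc, 1.0, 12))
                  for k, loc in [("a", 0.0), ("b", 0.5), ("c", 1.0)]}
        F, p = stats.transfer_count_anova(groups)
        ref = f_oneway(*groups.values())
        assert F == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            stats.transfer_count_anova({"x": [1.0]})


class TestMantel:
    def _matrix(self, seed, n=8, m=3):
        return np.random.default_rng(seed).uniform(0, 5, size=(n, m))

    def test_identity_gives_r_one(self):
        X = self._matrix(0)
        res = stats.mantel_test(X, X.copy(), seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_monotone_distance_transform_invariance(self):
        # A positive affine map of the coordinates scales every pairwise
        # distance monotonically; the Spearman statistic stays exactly 1.
        x = np.random.default_rng(2).uniform(1, 4, size=(10, 1))
        res = stats.mantel_test(x, 3.0 * x + 5.0, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_seed_reproducible(self):
        X, Y = self._matrix(3), self._matrix(4)
        r1 = stats.mantel_test(X, Y, seed=11)
        r2 = stats.mantel_test(X, Y, seed=11)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_constant_matrix_flagged(self):
        X = self._matrix(5)
        res = stats.mantel_test(X, np.ones_like(X), seed=0)
        assert not res.ok and math.isnan(res.r)

    def test_agrees_with_skbio(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        X, Y = self._matrix(6), self._matrix(7)
        ours = stats.mantel_test(X, Y, seed=0)
        ref_r, ref_p, _ = skbio_mantel(
            DistanceMatrix(squareform(pdist(X))),
            DistanceMatrix(squareform(pdist(Y))),
            method="spearman", permutations=999, alternative="greater", seed=0)
        assert ours.r == pytest.approx(ref_r, abs=1e-12)
        assert ours.p == pytest.approx(ref_p, abs=0.05)  # permutation noise


class TestCCA:
    def _blocks(self):
        # Three row blocks whose response profiles are exact functions of
        # the block: a block indicator should constrain ~all inertia.
        rng = np.random.default_rng(8)
        profiles = np.array([[5.0, 1.0, 0.5], [1.0, 6.0, 2.0], [0.5, 1.0, 7.0]])
        rows, indicators = [], []
        for block in range(3):
            for _ in range(4):
                rows.append(profiles[block])
                indicators.append([1.0 if block == b else 0.0 for b in range(2)])
        return np.array(rows), np.array(indicators)

    def test_block_structure_fully_constrained(self):
        Y, X = self._blocks()
        res = stats.cca(Y, X)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-10)

    def test_inertia_identity(self):
        rng = np.random.default_rng(9)
        Y = rng.uniform(0.1, 5, size=(10, 4))
        X = rng.normal(size=(10, 2))
        res = stats.cca(Y, X)
        # Total inertia is the chi-square statistic over the grand total.
        P = Y / Y.sum()
        r, c = P.sum(1), P.sum(0)
        chi2 = ((P - np.outer(r, c)) ** 2 / np.outer(r, c)).sum()
        assert res.total_inertia == pytest.approx(chi2, abs=1e-12)
        assert (res.constrained_inertia + res.unconstrained_inertia
                == pytest.approx(res.total_inertia, abs=1e-8))
        assert 0.0 <= res.proportion_constrained <= 1.0

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        Y = rng.uniform(0.1, 5, size=(9, 3))
        X = rng.normal(size=(9, 2))
        base = stats.cca(Y, X)
        perm = rng.permutation(9)
        shuffled = stats.cca(Y[perm], X[perm])
        assert shuffled.proportion_constrained == pytest.approx(
            base.proportion_constrained, abs=1e-10)

    def test_collinear_columns_dropped(self, caplog):
        rng = np.random.default_rng(11)
        Y = rng.uniform(0.1, 5, size=(8, 3))
        x = rng.normal(size=(8, 1))
        X = np.hstack([x, 2 * x])
        with caplog.at_level("WARNING", logger="coculture.stats"):
            res = stats.cca(Y, X)
        assert any("rank deficient" in rec.message for rec in caplog.records)
        assert stats.cca(Y, x).proportion_constrained == pytest.approx(
            res.proportion_constrained, abs=1e-10)

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import cca as skbio_cca

        rng = np.random.default_rng(12)
        Y = pd.DataFrame(rng.uniform(0.1, 5, size=(10, 4)))
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        ours = stats.cca(Y, X)
        ref = skbio_cca(Y, X)
        n_constrained = len(ours.eigenvalues)
        ref_prop = float(ref.proportion_explained.iloc[:n_constrained].sum())
        assert ours.proportion_constrained == pytest.approx(ref_prop, abs=1e-8)
        ref_eigs = ref.eigvals.to_numpy()[:n_constrained]
        assert np.allclose(np.sort(ours.eigenvalues), np.sort(ref_eigs), atol=1e-10)

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError):
            stats.cca(np.array([[1.0, -1.0]]), np.array([[1.0]]))
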