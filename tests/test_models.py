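"""PERMANOVA, multivariate dispersion and Poisson richness models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from amfsoil.commstats import DistanceMatrix, distance_matrix
from amfsoil.models import (BetaDispersion, Permanova, PoissonRichness,
                            dispersion_test, permanova, poisson_richness_test)

IDS4 = ["s1", "s2", "s3", "s4"]


def toy_dm():
    """Within-group distance 1, between-group distance 2, groups {a,a,b,b}."""
    d = np.full((4, 4), 2.0)
    d[0, 1] = d[1, 0] = 1.0
    d[2, 3] = d[3, 2] = 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(IDS4, d)


def groups4():
    return pd.DataFrame({"g": ["a", "a", "b", "b"]}, index=IDS4)


class TestPermanova:
    def test_hand_partition_via_gower_identity(self):
        res = permanova(toy_dm(), groups4(), ["g"], n_perm=9, seed=0)
        t = res.table
        assert t.loc["Total", "SS"] == pytest.approx(4.5)
        assert t.loc["g", "SS"] == pytest.approx(3.5)
        assert t.loc["g", "pseudo_F"] == pytest.approx(7.0)
        assert t.loc["g", "R2"] == pytest.approx(7.0 / 9.0)
        assert t.loc["g", "df"] == 1 and t.loc["Residuals", "df"] == 2

    def test_all_identical_samples_error(self):
        dm = DistanceMatrix(IDS4, np.zeros((4, 4)))
        with pytest.raises(ValueError):
            permanova(dm, groups4(), ["g"], n_perm=9)

    def test_single_level_factor_error(self):
        fac = pd.DataFrame({"g": ["a"] * 4}, index=IDS4)
        with pytest.raises(ValueError):
            permanova(toy_dm(), fac, ["g"], n_perm=9)

    def test_equals_classical_anova_on_1d_euclidean(self, rng):
        """On 1-D Euclidean distances the pseudo-F is the one-way ANOVA F."""
        y = rng.normal(size=12)
        g = np.repeat(["a", "b", "c"], 4)
        d = np.abs(y[:, None] - y[None, :])
        ids = [f"s{i}" for i in range(12)]
        res = permanova(DistanceMatrix(ids, d),
                        pd.DataFrame({"g": g}, index=ids), ["g"], n_perm=9, seed=0)
        f_classic = sps.f_oneway(*(y[g == lv] for lv in "abc")).statistic
        assert res.pseudo_F.iloc[0] == pytest.approx(f_classic)

    def test_matches_independent_implementation(self, toy_counts):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova
        m = toy_counts.normalise()
        dm = distance_matrix(m)
        res = permanova(dm, m.meta.astype({"plot": str}), ["plot"],
                        n_perm=99, seed=1)
        sk = sk_permanova(skbio.DistanceMatrix(dm.values, ids=dm.ids),
                          grouping=list(m.meta["plot"]), permutations=99)
        assert res.pseudo_F.iloc[0] == pytest.approx(sk["test statistic"])

    def test_two_factor_sequential_partition(self, rng):
        n = 16
        ids = [f"s{i}" for i in range(n)]
        fac = pd.DataFrame({"f1": np.repeat(["a", "b"], n // 2),
                            "f2": np.tile(np.repeat(["x", "y"], n // 4), 2)},
                           index=ids)
        x = rng.dirichlet(np.ones(5), size=n)
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(2) / (
            x.sum(1)[:, None] + x.sum(1)[None, :])
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(ids, d)
        one = permanova(dm, fac, ["f1"], n_perm=9, seed=0)
        two = permanova(dm, fac, ["f1", "f2"], n_perm=9, seed=0)
        # terms partition the total and never inflate the residual
        t = two.table
        assert (t.loc[["f1", "f2"], "SS"].sum() + t.loc["Residuals", "SS"]
                == pytest.approx(t.loc["Total", "SS"]))
        assert t.loc["Residuals", "SS"] <= one.table.loc["Residuals", "SS"] + 1e-12
        assert t.loc[["f1", "f2"], "R2"].sum() <= 1.0
        # first-term SS unchanged by adding a second sequential term
        assert t.loc["f1", "SS"] == pytest.approx(one.table.loc["f1", "SS"])

    def test_permutation_p_never_zero(self):
        res = permanova(toy_dm(), groups4(), ["g"], n_perm=999, seed=3)
        assert 0 < res.p_perm.iloc[0] <= 1

    def test_summary_mentions_terms(self):
        res = permanova(toy_dm(), groups4(), ["g"], n_perm=9, seed=0)
        assert "g" in res.summary() and "Residuals" in res.summary()


def euclid_dm(points, ids):
    p = np.asarray(points, dtype=float)
    d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(2))
    return DistanceMatrix(ids, d)


class TestBetaDispersion:
    def test_identical_geometry_gives_zero_f(self):
        pts = [(0, 0), (2, 0), (1, 2), (10, 0), (12, 0), (11, 2)]
        ids = list("abcdef")
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        res = dispersion_test(euclid_dm(pts, ids), groups)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_anova_on_2d_toy(self):
        """Tight vs dispersed group: distances to centroids computed by hand."""
        pts = np.array([(0, 0), (1, 0), (0, 1), (2, 2),
                        (20, 0), (28, 0), (20, 9), (30, 12)], dtype=float)
        ids = [f"s{i}" for i in range(8)]
        groups = pd.Series(["t"] * 4 + ["d"] * 4, index=ids)
        res = dispersion_test(euclid_dm(pts, ids), groups)
        z_hand = []
        for block in (pts[:4], pts[4:]):
            c = block.mean(0)
            z_hand.extend(np.sqrt(((block - c) ** 2).sum(1)))
        f_hand = sps.f_oneway(z_hand[:4], z_hand[4:]).statistic
        assert res.F == pytest.approx(f_hand, rel=1e-6)
        assert np.allclose(sorted(res.distances), sorted(z_hand), atol=1e-8)

    def test_degrees_of_freedom_follow_group_structure(self, rng):
        sizes = {"g1": 8, "g2": 9, "g3": 6, "g4": 4}
        ids = [f"s{i}" for i in range(27)]
        labels = np.repeat(list(sizes), list(sizes.values()))
        pts = rng.normal(size=(27, 3))
        res = dispersion_test(euclid_dm(pts, ids), pd.Series(labels, index=ids))
        assert (res.df1, res.df2) == (3, 23)

    def test_small_group_rejected(self):
        ids = list("abc")
        groups = pd.Series(["g1", "g1", "g2"], index=ids)
        with pytest.raises(ValueError):
            BetaDispersion(euclid_dm([(0, 0), (1, 0), (5, 5)], ids), groups)

    def test_spatial_median_centre_runs(self, toy_counts):
        dm = distance_matrix(toy_counts.normalise())
        res = dispersion_test(dm, toy_counts.meta["plot"], centre="spatial_median")
        assert np.isfinite(res.F) and res.centre == "spatial_median"

    def test_matches_independent_implementation(self, toy_counts):
        """Centroid distances agree with R vegan's betadisper on the same
        matrix (values frozen from vegan 2.7-1, type="centroid", which uses
        the same negative-eigenvalue correction)."""
        dm = distance_matrix(toy_counts.normalise())
        res = dispersion_test(dm, toy_counts.meta["plot"])
        vegan = {"A1": 0.08042973, "A2": 0.08042973,
                 "B1": 0.05550416, "B2": 0.05550416}
        for sid, expect in vegan.items():
            assert res.distances[sid] == pytest.approx(expect, abs=1e-7)


class TestPoissonRichness:
    def test_identical_groups_give_zero_chi2(self):
        rich = pd.Series([5, 5, 5, 5], index=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        res = poisson_richness_test(rich, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_two_group_deviance_closed_form(self):
        """chi2 equals the null-model deviance when groups fit exactly."""
        rich = pd.Series([2, 2, 8, 8], index=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        res = poisson_richness_test(rich, groups)
        mu = 5.0
        expected = 2 * sum(y * np.log(y / mu) - (y - mu) for y in [2, 2, 8, 8])
        assert res.chi2 == pytest.approx(expected, rel=1e-8)
        assert res.df == 1

    def test_group_means_are_arithmetic_means(self, rng):
        rich = pd.Series(rng.poisson(6, size=12),
                         index=[f"s{i}" for i in range(12)])
        groups = pd.Series(np.repeat(["a", "b", "c"], 4), index=rich.index)
        res = poisson_richness_test(rich, groups)
        for lv in "abc":
            assert res.group_means[lv] == pytest.approx(rich[groups == lv].mean())

    def test_matches_statsmodels_glm(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        rich = pd.Series(rng.poisson([4, 4, 4, 4, 9, 9, 9, 9]),
                         index=[f"s{i}" for i in range(8)])
        groups = pd.Series(np.repeat(["a", "b"], 4), index=rich.index)
        res = poisson_richness_test(rich, groups)
        x = sm.add_constant((groups == "b").astype(float).values)
        fit = sm.GLM(rich.values, x, family=sm.families.Poisson()).fit()
        null = sm.GLM(rich.values, np.ones((8, 1)),
                      family=sm.families.Poisson()).fit()
        assert res.chi2 == pytest.approx(null.deviance - fit.deviance, rel=1e-6)

    def test_single_group_rejected(self):
        rich = pd.Series([1, 2], index=["a", "b"])
        with pytest.raises(ValueError):
            PoissonRichness(rich, pd.Series(["x", "x"], index=["a", "b"]))
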