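import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

from assemblage.data_model import ValidationError, geographic_distance
from assemblage.multivariate import (
    alpha_env_correlation,
    anosim,
    forward_select,
    group_difference_letters,
    mantel,
    partial_mantel,
    pca_environment,
    pcnm_vectors,
    pcoa,
    pcoa_embedding,
    permanova,
    temporal_control_matrix,
    variance_partition,
)


def euclid_dm(points, ids=None):
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] == 1:
        pts = pts.T
    d = squareform(pdist(pts))
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(d, ids=ids)


class TestPca:
    def test_perfectly_correlated_pair(self):
        x = np.arange(10.0)
        meta = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_environment(meta, ["a", "b"])
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_is_trace(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(rng.normal(0, 1, (10, 4)), columns=list("abcd"))
        res = pca_environment(meta, list("abcd"))
        assert res.eigenvalues.sum() == pytest.approx(4.0)

    def test_independent_variables_near_equal_proportions(self):
        rng = np.random.default_rng(1)
        meta = pd.DataFrame(rng.normal(0, 1, (5000, 4)), columns=list("abcd"))
        res = pca_environment(meta, list("abcd"))
        assert np.allclose(res.proportion_explained, 0.25, atol=0.03)

    def test_constant_variable_named(self):
        meta = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1, 2, 3.0]})
        with pytest.raises(ValidationError, match="a"):
            pca_environment(meta, ["a", "b"])


class TestPcoa:
    def test_line_recovered(self):
        d = euclid_dm([0.0, 1.0, 3.0, 6.0])
        res = pcoa(d)
        assert len(res.eigenvalues) == 1
        x = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.abs(np.diff(x))
        np.testing.assert_allclose(gaps, [1, 2, 3], atol=1e-10)

    def test_full_reconstruction_of_bray_like_matrix(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, (6, 4))
        d = DistanceMatrix(squareform(pdist(pts)), ids=list("abcdef"))
        coords = pcoa_embedding(d)
        re = squareform(pdist(coords))
        np.testing.assert_allclose(re, d.data, atol=1e-9)

    def test_negative_eigenvalues_reported(self):
        # non-Euclidean: violates the triangle-embedding in any dimension
        m = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1],
                      [1, 1, 1, 0]]) * 1.0
        m[0, 1] = m[1, 0] = 2.9
        res = pcoa(DistanceMatrix(m, ids=list("abcd")))
        assert len(res.negative_eigenvalues) > 0


class TestAnosim:
    def test_full_separation_r1(self):
        d = euclid_dm([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        g = ["a"] * 3 + ["b"] * 3
        res = anosim(d, g, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(4)
        d = euclid_dm(rng.normal(0, 1, (20, 3)))
        stats_ = [anosim(d, rng.permutation(["a"] * 10 + ["b"] * 10),
                         n_perm=49, seed=s).statistic for s in range(40)]
        assert abs(np.mean(stats_)) < 0.05

    def test_exhaustive_p_convergence(self):
        rng = np.random.default_rng(5)
        d = euclid_dm(rng.normal(0, 1, (6, 2)))
        g = np.array(["a", "a", "a", "b", "b", "b"])
        ranks = stats.rankdata(squareform(d.data, checks=False))
        iu, ju = np.triu_indices(6, k=1)

        def r_stat(labels):
            labels = np.asarray(labels)
            within = labels[iu] == labels[ju]
            return (ranks[~within].mean() - ranks[within].mean()) / (6 * 5 / 4)

        obs = r_stat(g)
        perms = [r_stat(p) for p in itertools.permutations(g)]
        p_exact = np.mean([r >= obs for r in perms])
        res = anosim(d, g, n_perm=9999, seed=1)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_matches_skbio(self):
        rng = np.random.default_rng(6)
        d = euclid_dm(rng.normal(0, 1, (12, 3)))
        g = ["a"] * 6 + ["b"] * 6
        ours = anosim(d, g, n_perm=99, seed=0)
        theirs = skbio_anosim(d, g, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_singleton_group_rejected(self):
        d = euclid_dm([0.0, 1, 2])
        with pytest.raises(ValidationError):
            anosim(d, ["a", "a", "b"], n_perm=9)


class TestPermanova:
    def test_equals_classical_anova_on_1d(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 15)
        g = np.repeat(["a", "b", "c"], 5)
        d = euclid_dm(x)
        res = permanova(d, g, n_perm=9, seed=0)
        f = stats.f_oneway(*[x[g == lab] for lab in "abc"]).statistic
        assert res.statistic == pytest.approx(f, abs=1e-10)

    def test_duplicated_groups_r2_one(self):
        d = euclid_dm([0.0, 0.0, 5.0, 5.0])
        res = permanova(d, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert res.extra["R2"] == pytest.approx(1.0)

    def test_matches_skbio(self):
        rng = np.random.default_rng(8)
        d = euclid_dm(rng.normal(0, 1, (12, 3)))
        g = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, g, n_perm=99, seed=0)
        theirs = skbio_permanova(d, g, permutations=99)
        assert ours.statistic == pytest.approx(theirs["test statistic"])


class TestMantel:
    def test_self_correlation(self):
        d = euclid_dm([0.0, 1, 3, 7, 2])
        res = mantel(d, d, method="pearson", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_spearman_rank_invariance(self):
        d1 = euclid_dm([0.0, 1, 3, 7, 2])
        d2 = DistanceMatrix(d1.data ** 3, ids=list(d1.ids))
        res = mantel(d1, d2, method="spearman", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_exhaustive_p_convergence(self):
        rng = np.random.default_rng(9)
        d1 = euclid_dm(rng.normal(0, 1, (5, 2)))
        d2 = euclid_dm(rng.normal(0, 1, (5, 2)))
        x = squareform(d1.data, checks=False)

        def r_of(perm):
            y = squareform(d2.data[np.ix_(perm, perm)], checks=False)
            return np.corrcoef(x, y)[0, 1]

        obs = r_of(list(range(5)))
        rs = [r_of(list(p)) for p in itertools.permutations(range(5))]
        p_exact = np.mean([r >= obs for r in rs])
        res = mantel(d1, d2, method="pearson", n_perm=9999, seed=2)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_matches_skbio_r(self):
        rng = np.random.default_rng(10)
        d1 = euclid_dm(rng.normal(0, 1, (8, 2)))
        d2 = euclid_dm(rng.normal(0, 1, (8, 2)))
        ours = mantel(d1, d2, method="pearson", n_perm=99, seed=0)
        r_skbio, _, _ = skbio_mantel(d1, d2, method="pearson",
                                     permutations=0)
        assert ours.statistic == pytest.approx(r_skbio)


class TestPartialMantel:
    def test_matches_closed_form_on_hand_matrices(self):
        a = DistanceMatrix(np.array([[0, 1, 2, 3], [1, 0, 1.5, 2.5],
                                     [2, 1.5, 0, 1], [3, 2.5, 1, 0.]]),
                           ids=list("wxyz"))
        b = DistanceMatrix(np.array([[0, 2, 1, 4], [2, 0, 3, 1],
                                     [1, 3, 0, 2], [4, 1, 2, 0.]]),
                           ids=list("wxyz"))
        c = DistanceMatrix(np.array([[0, 1, 1, 2], [1, 0, 2, 1],
                                     [1, 2, 0, 1], [2, 1, 1, 0.]]),
                           ids=list("wxyz"))
        res = partial_mantel(a, b, c, method="pearson", n_perm=99, seed=0)
        va = squareform(a.data, checks=False)
        vb = squareform(b.data, checks=False)
        vc = squareform(c.data, checks=False)
        r12 = np.corrcoef(va, vb)[0, 1]
        r13 = np.corrcoef(va, vc)[0, 1]
        r23 = np.corrcoef(vb, vc)[0, 1]
        expected = (r12 - r13 * r23) / np.sqrt((1 - r13 ** 2)
                                               * (1 - r23 ** 2))
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_self_control_gives_zero(self):
        rng = np.random.default_rng(11)
        d1 = euclid_dm(rng.normal(0, 1, (8, 2)))
        d2 = euclid_dm(rng.normal(0, 1, (8, 2)))
        res = partial_mantel(d1, d2, d2, method="pearson", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_reduces_to_simple_with_independent_control(self):
        rng = np.random.default_rng(12)
        d1 = euclid_dm(rng.normal(0, 1, (30, 3)))
        d2 = DistanceMatrix(d1.data + squareform(
            np.abs(rng.normal(0, 0.05, 30 * 29 // 2))), ids=list(d1.ids))
        d3 = euclid_dm(rng.normal(0, 1, (30, 3)), ids=list(d1.ids))
        simple = mantel(d1, d2, "pearson", 99, 0).statistic
        partial = partial_mantel(d1, d2, d3, "pearson", 99, 0).statistic
        assert partial == pytest.approx(simple, abs=0.1)


class TestTemporalMatrix:
    def test_single_month_zero_matrix(self):
        meta = pd.DataFrame({"month": ["May"] * 4},
                            index=[f"s{i}" for i in range(4)])
        assert temporal_control_matrix(meta).data.sum() == 0

    def test_balanced_three_months_fraction(self):
        n_per, months = 4, ["May", "Aug", "Oct"]
        meta = pd.DataFrame({"month": np.repeat(months, n_per)},
                            index=[f"s{i}" for i in range(3 * n_per)])
        d = temporal_control_matrix(meta)
        n = 3 * n_per
        frac = d.data[np.triu_indices(n, 1)].mean()
        same = 3 * n_per * (n_per - 1) / 2
        expected = 1 - same / (n * (n - 1) / 2)
        assert frac == pytest.approx(expected)


class TestPcnm:
    def test_transect_matches_vegan_reference(self):
        """Regular 12-point transect reproduces the classical sinusoid-like
        eigenfunctions; the leading one matches vegan::pcnm output
        (precomputed independently in R) up to sign and scale."""
        meta = pd.DataFrame({"longitude": np.arange(12.0),
                             "latitude": np.zeros(12)},
                            index=[f"s{i}" for i in range(12)])
        P = pcnm_vectors(geographic_distance(meta))
        assert P.shape[1] == 7  # vegan keeps 7 positive eigenvectors too
        vegan_pcnm1 = np.array([-0.182, -0.323, -0.389, -0.367, -0.26,
                                -0.094, 0.094, 0.26, 0.367, 0.389, 0.323,
                                0.182])
        v1 = P.iloc[:, 0].to_numpy()
        r = np.corrcoef(v1, vegan_pcnm1)[0, 1]
        assert abs(r) > 0.9999
        # antisymmetric about the transect midpoint
        np.testing.assert_allclose(v1, -v1[::-1], atol=1e-9)

    def test_rank_bound(self):
        rng = np.random.default_rng(13)
        meta = pd.DataFrame({"longitude": rng.uniform(0, 1, 9),
                             "latitude": rng.uniform(0, 1, 9)},
                            index=[f"s{i}" for i in range(9)])
        P = pcnm_vectors(geographic_distance(meta))
        assert P.shape[1] <= 8

    def test_scale_equivariance(self):
        rng = np.random.default_rng(14)
        lon, lat = rng.uniform(0, 1, 8), rng.uniform(0, 1, 8)
        ids = [f"s{i}" for i in range(8)]
        m1 = pd.DataFrame({"longitude": lon, "latitude": lat}, index=ids)
        m2 = pd.DataFrame({"longitude": 2 * lon, "latitude": 2 * lat},
                          index=ids)
        P1 = pcnm_vectors(geographic_distance(m1))
        P2 = pcnm_vectors(geographic_distance(m2))
        assert P1.shape == P2.shape
        for col in range(P1.shape[1]):
            v1 = P1.iloc[:, col] / np.linalg.norm(P1.iloc[:, col])
            v2 = P2.iloc[:, col] / np.linalg.norm(P2.iloc[:, col])
            assert abs(abs(v1 @ v2) - 1) < 1e-8

    def test_identical_points_rejected(self):
        meta = pd.DataFrame({"longitude": [1.0, 1.0], "latitude": [2.0, 2.0]},
                            index=["a", "b"])
        with pytest.raises(ValidationError):
            pcnm_vectors(geographic_distance(meta))


class TestForwardSelection:
    def test_planted_signal_selected_alone(self):
        rng = np.random.default_rng(3)
        env = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=list("efg"))
        y = env["e"].to_numpy()[:, None] + rng.normal(0, 0.01, (30, 1))
        fs = forward_select(y, env, alpha=0.05, n_perm=199, seed=2)
        assert fs.selected == ["e"]

    def test_pure_noise_mostly_empty(self):
        empty = 0
        n_runs = 30
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            y = rng.normal(0, 1, (30, 2))
            X = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
            fs = forward_select(y, X, alpha=0.05, n_perm=199, seed=s)
            empty += fs.selected == []
        assert empty / n_runs >= 0.9

    def test_duplicate_column_never_selected_twice(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 30)
        X = pd.DataFrame({"a": base, "a_dup": base,
                          "b": rng.normal(0, 1, 30)})
        y = base[:, None] + rng.normal(0, 0.05, (30, 1))
        fs = forward_select(y, X, alpha=0.05, n_perm=199, seed=5)
        assert not ({"a", "a_dup"} <= set(fs.selected))


class TestVariancePartition:
    def test_fraction_identity_random_designs(self):
        for s in range(5):
            rng = np.random.default_rng(s)
            Y = rng.normal(0, 1, (25, 3))
            env = pd.DataFrame(rng.normal(0, 1, (25, 2)), columns=["e1", "e2"])
            tr = pd.DataFrame(rng.normal(0, 1, (25, 2)), columns=["x", "y"])
            pc = pd.DataFrame(rng.normal(0, 1, (25, 2)), columns=["p1", "p2"])
            v = variance_partition(Y, env, tr, pc, n_perm=19, seed=s)
            frac7 = sum(val for key, val in v.fractions.items()
                        if key != "residual")
            assert frac7 == pytest.approx(v.full_adj_r2, abs=1e-10)
            assert v.fractions["residual"] == pytest.approx(
                1 - v.full_adj_r2, abs=1e-10)

    def test_planted_orthogonal_design(self):
        rng = np.random.default_rng(21)
        n = 200  # adjusted-R2 noise of random predictors scales as 1/n
        e = rng.normal(0, 1, (n, 1))
        env = pd.DataFrame(e, columns=["e"])
        tr = pd.DataFrame(rng.normal(0, 1, (n, 1)), columns=["t"])
        pc = pd.DataFrame(rng.normal(0, 1, (n, 1)), columns=["p"])
        Y = e + rng.normal(0, 0.05, (n, 1))
        v = variance_partition(Y, env, tr, pc, n_perm=99, seed=0)
        assert v.fractions["env"] == pytest.approx(v.full_adj_r2, abs=0.02)
        for key in ("trend", "pcnm"):
            assert abs(v.fractions[key]) < 0.02
        assert v.set_p_values["env"] <= 0.05

    def test_all_empty_sets_not_testable(self):
        rng = np.random.default_rng(22)
        v = variance_partition(rng.normal(0, 1, (10, 2)), None, None, None,
                               n_perm=9, seed=0)
        assert not v.testable


class TestLetters:
    def test_identical_groups_share_letter(self):
        v = np.tile([1.0, 1.1, 0.9], 3)
        g = np.repeat(["a", "b", "c"], 3)
        v = np.concatenate([[1.0, 1.1, 0.9]] * 3)
        out = group_difference_letters(v, g)
        assert set(out["letters"]) == {"a"}

    def test_separated_means_distinct_letters(self):
        rng = np.random.default_rng(23)
        v = np.concatenate([rng.normal(mu, 0.01, 5) for mu in (0, 10, 20)])
        g = np.repeat(["lo", "mid", "hi"], 5)
        out = group_difference_letters(v, g)
        assert len(set(out["letters"])) == 3
        assert out.index[0] == "hi"  # descending mean order

    def test_duncan_variant_runs(self):
        rng = np.random.default_rng(24)
        v = np.concatenate([rng.normal(mu, 1.0, 8) for mu in (0, 0.2, 6)])
        g = np.repeat(["a", "b", "c"], 8)
        out = group_difference_letters(v, g, method="duncan")
        # the two near-identical groups share a letter; the far one does not
        la, lb, lc = (out.loc[x, "letters"] for x in ("a", "b", "c"))
        assert set(la) & set(lb)
        assert not (set(lc) & set(la))

    def test_stability_over_seeds_with_large_effects(self):
        patterns = set()
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            sizes = (24, 84, 84)
            v = np.concatenate([rng.normal(mu, 1.0, n)
                                for mu, n in zip((0, 5, 10), sizes)])
            g = np.concatenate([[lab] * n
                                for lab, n in zip(("g0", "g5", "g10"), sizes)])
            out = group_difference_letters(v, g)
            patterns.add(tuple(out["letters"]))
        assert patterns == {("a", "b", "c")}


class TestAlphaEnvCorrelation:
    def test_exact_match_r_one(self):
        idx = [f"s{i}" for i in range(6)]
        alpha = pd.DataFrame({"shannon": [1, 2, 3, 4, 5, 6.0]}, index=idx)
        meta = pd.DataFrame({"Temp": [1, 2, 3, 4, 5, 6.0]}, index=idx)
        out = alpha_env_correlation(alpha, meta, ["Temp"])
        assert out.loc[("shannon", "Temp"), "r"] == pytest.approx(1.0)

    def test_hand_computed_r(self):
        idx = list("abcde")
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 6.0])
        alpha = pd.DataFrame({"richness": x}, index=idx)
        meta = pd.DataFrame({"Temp": y}, index=idx)
        out = alpha_env_correlation(alpha, meta, ["Temp"])
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum()
                              * ((y - y.mean()) ** 2).sum()))
        assert out.loc[("richness", "Temp"), "r"] == pytest.approx(expected)

    def test_constant_column_reported_missing(self):
        idx = list("abcd")
        alpha = pd.DataFrame({"shannon": [1, 2, 3, 4.0]}, index=idx)
        meta = pd.DataFrame({"Temp": [5.0] * 4}, index=idx)
        out = alpha_env_correlation(alpha, meta, ["Temp"])
        assert np.isnan(out.loc[("shannon", "Temp"), "r"])

    def test_independent_pairs_mostly_small_r(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            idx = [f"s{i}" for i in range(100)]
            alpha = pd.DataFrame({"shannon": rng.normal(0, 1, 100)},
                                 index=idx)
            meta = pd.DataFrame({"Temp": rng.normal(0, 1, 100)}, index=idx)
            out = alpha_env_correlation(alpha, meta, ["Temp"])
            hits += abs(out.loc[("shannon", "Temp"), "r"]) < 0.3
        assert hits >= 19
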