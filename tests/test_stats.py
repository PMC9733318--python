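"""GLM fitting, effect sizes, distances, clustering, ordination, PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rootscope.stats import (
    GlmFit,
    GlmSpec,
    braycurtis,
    cliffs_delta,
    complete_linkage,
    fit_quasipoisson,
    jaccard_distance,
    pcoa,
    permanova,
)


def simulate_quasipoisson(
    rng, n, beta0=1.0, beta_s=0.3, beta_p=-0.5, beta_p2=0.0, phi=1.0
):
    """Counts from log mu = b0 + bS*S + bP*P + bP2*P^2, variance phi*mu
    (phi > 1 via a negative-binomial mixture with matching variance)."""
    size = rng.integers(2, 13, size=n)
    pd_ = rng.uniform(0.1, 2.0, size=n)
    genome = rng.uniform(3.0, 7.0, size=n)
    mu = np.exp(beta0 + beta_s * size + beta_p * pd_ + beta_p2 * pd_**2)
    if phi <= 1.0:
        y = rng.poisson(mu)
    else:
        # NB2 with variance mu + mu^2/r = phi*mu  =>  r = mu/(phi-1)
        r = mu / (phi - 1.0)
        y = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(
        {
            "size": size,
            "mean_genome": genome,
            "avg_pd": pd_,
            "n_ppm": y,
            "n_cppm": np.minimum(y, rng.poisson(np.maximum(mu / 2, 0.1))),
        }
    )


class TestQuasiPoissonGlm:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings(
        "ignore::statsmodels.tools.sm_exceptions.PerfectSeparationWarning"
    )
    def test_intercept_only_closed_form(self):
        # a constant response is a degenerate (perfectly fitting) model;
        # statsmodels flags it, the closed form still applies
        data = pd.DataFrame(
            {"size": [2, 2, 2], "mean_genome": [1, 1, 1], "avg_pd": [0, 0, 0],
             "n_ppm": [2, 2, 2], "n_cppm": [2, 2, 2]}
        )
        fit = fit_quasipoisson(data, GlmSpec(response="n_ppm", covariates=()),
                               max_size=None)
        assert fit.beta["intercept"] == pytest.approx(np.log(2), abs=1e-8)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_at_n_2000(self):
        rng = np.random.default_rng(0)
        data = simulate_quasipoisson(rng, 2000)
        fit = fit_quasipoisson(
            data,
            GlmSpec(response="n_ppm", covariates=("size", "avg_pd")),
            max_size=None,
        )
        for name, true in (("intercept", 1.0), ("size", 0.3), ("avg_pd", -0.5)):
            assert abs(fit.beta[name] - true) < 3 * fit.se[name]

    def test_overdispersion_inflates_se_not_beta(self):
        rng = np.random.default_rng(1)
        reps_poisson, reps_od = [], []
        for _ in range(10):
            d1 = simulate_quasipoisson(rng, 1500, phi=1.0)
            d2 = simulate_quasipoisson(rng, 1500, phi=2.0)
            spec = GlmSpec(response="n_ppm", covariates=("size", "avg_pd"))
            reps_poisson.append(fit_quasipoisson(d1, spec, max_size=None))
            reps_od.append(fit_quasipoisson(d2, spec, max_size=None))
        mean_beta_p = np.mean([f.beta["size"] for f in reps_poisson])
        mean_beta_o = np.mean([f.beta["size"] for f in reps_od])
        assert mean_beta_o == pytest.approx(mean_beta_p, abs=0.01)
        ratio = np.mean(
            [o.se["size"] / p.se["size"] for o, p in zip(reps_od, reps_poisson)]
        )
        assert ratio == pytest.approx(np.sqrt(2), rel=0.15)
        assert np.mean([f.dispersion for f in reps_od]) == pytest.approx(2.0, rel=0.2)

    def test_r2_formula_is_deviance_ratio(self):
        rng = np.random.default_rng(2)
        data = simulate_quasipoisson(rng, 500)
        fit = fit_quasipoisson(data, GlmSpec(response="n_ppm"), max_size=None)
        assert fit.r2 == pytest.approx(
            1 - fit.residual_deviance / fit.null_deviance, abs=1e-12
        )

    def test_rank_deficiency_and_small_n_rejected(self):
        data = pd.DataFrame(
            {"size": [2, 2, 2, 2, 2, 2, 2, 2], "mean_genome": [1] * 8,
             "avg_pd": [0.5] * 8, "n_ppm": [3, 4, 5, 3, 4, 5, 3, 4],
             "n_cppm": [1] * 8}
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_quasipoisson(data, GlmSpec(response="n_ppm"), max_size=None)
        with pytest.raises(ValueError, match="at least"):
            fit_quasipoisson(data.head(3), GlmSpec(response="n_ppm"), max_size=None)

    def test_size_cap_filters_records(self):
        rng = np.random.default_rng(3)
        data = simulate_quasipoisson(rng, 800)
        data.loc[:, "size"] = rng.integers(2, 21, size=len(data))
        fit = fit_quasipoisson(
            data, GlmSpec(response="n_ppm", covariates=("size",)), max_size=12
        )
        assert fit.n_obs == int((data["size"] <= 12).sum())


class TestCliffsDelta:
    def test_identical_samples_give_zero(self):
        assert cliffs_delta((1, 2, 3), (1, 2, 3)) == 0.0

    def test_complete_dominance_is_one(self):
        assert cliffs_delta((4, 5), (1, 2)) == 1.0
        assert cliffs_delta((1, 2), (4, 5)) == -1.0

    def test_enumerated_mixed_case(self):
        assert cliffs_delta((1, 3), (2, 2)) == 0.0

    def test_antisymmetry_and_bounds_on_random_samples(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 15))
            y = rng.normal(size=rng.integers(2, 15))
            d = cliffs_delta(x, y)
            assert d == pytest.approx(-cliffs_delta(y, x))
            assert -1.0 <= d <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta((), (1,))


class TestJaccard:
    def test_identity_disjoint_and_counted_example(self):
        assert jaccard_distance({"a"}, {"a"}) == 0.0
        assert jaccard_distance({"a"}, {"b"}) == 1.0
        assert jaccard_distance({"a", "b"}, {"b", "c"}) == pytest.approx(1 - 1 / 3)

    def test_both_empty_defined_as_zero(self):
        assert jaccard_distance(set(), set()) == 0.0

    def test_triangle_inequality_on_random_triples(self, rng):
        universe = list(range(12))
        for _ in range(100):
            a, b, c = (
                set(rng.choice(universe, size=rng.integers(0, 8), replace=False))
                for _ in range(3)
            )
            assert jaccard_distance(a, c) <= (
                jaccard_distance(a, b) + jaccard_distance(b, c) + 1e-12
            )


class TestBrayCurtis:
    def test_identity_disjoint_and_counted_example(self):
        assert braycurtis([1, 2], [1, 2]) == 0.0
        assert braycurtis([1, 0], [0, 2]) == 1.0
        assert braycurtis([1, 1], [1, 3]) == pytest.approx(2 / 6)

    def test_negative_counts_and_all_zero_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            braycurtis([1, -1], [1, 1])
        with pytest.raises(ValueError, match="all-zero"):
            braycurtis([0, 0], [0, 0])


class TestCompleteLinkage:
    def test_two_points_single_merge(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        merges = complete_linkage(d)
        assert merges == [(0, 1, pytest.approx(0.4), 2)]

    def test_closest_pair_merges_first(self):
        d = np.array(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.8], [0.9, 0.8, 0.0]]
        )
        merges = complete_linkage(d)
        assert merges[0][:2] == (0, 1)
        # complete linkage: cluster {0,1} joins 2 at max(0.9, 0.8)
        assert merges[1][2] == pytest.approx(0.9)

    def test_heights_non_decreasing_on_random_matrix(self, rng):
        x = rng.random((8, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        merges = complete_linkage(d)
        heights = [m[2] for m in merges]
        assert heights == sorted(heights)

    def test_agrees_with_scipy_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        x = rng.random((10, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        ours = complete_linkage(d)
        theirs = linkage(squareform(d, checks=False), method="complete")
        np.testing.assert_allclose(
            [m[2] for m in ours], theirs[:, 2], rtol=1e-12
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage(np.zeros((2, 3)))


class TestPcoa:
    def test_two_points_on_first_axis(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        coords, eigvals = pcoa(d)
        assert coords.shape == (2, 1)
        np.testing.assert_allclose(np.abs(coords[:, 0]), 0.5, atol=1e-12)

    def test_euclidean_round_trip(self, rng):
        x = rng.random((7, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        coords, eigvals = pcoa(d)
        recon = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d, atol=1e-8)
        assert (eigvals[2:] < 1e-8).all()  # planar data: 2 informative axes

    def test_duplicated_point_is_coincident(self):
        d = np.array(
            [[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]
        )
        coords, _ = pcoa(d)
        np.testing.assert_allclose(coords[0], coords[2], atol=1e-10)

    def test_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.random((9, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        coords, eigvals = pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            eigvals[:3], ref.eigvals.values[:3], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(coords[:, 0]), np.abs(ref.samples.values[:, 0]), atol=1e-8
        )


class TestPermanova:
    @staticmethod
    def two_clouds(rng, sep):
        a = rng.normal(0, 1, size=(10, 3))
        b = rng.normal(sep, 1, size=(10, 3))
        x = np.vstack([a, b])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = ["a"] * 10 + ["b"] * 10
        return d, labels

    def test_separated_clouds_detected(self, rng):
        d, labels = self.two_clouds(rng, sep=10.0)
        f, r2, p = permanova(d, labels, n_perm=199, rng=rng)
        assert r2 > 0.8
        # at the permutation floor, allowing one tie (a permutation can
        # reproduce the original bipartition or its complement)
        assert p <= 2 / 200

    def test_exact_enumeration_on_tiny_instance(self):
        # 3 vs 3 points in 1-D: compare against full enumeration of the
        # 20 label assignments (C(6,3)).
        x = np.array([0.0, 0.2, 0.4, 1.0, 1.1, 1.3])[:, None]
        d = np.abs(x - x.T)
        labels = np.array(["a", "a", "a", "b", "b", "b"])

        def f_stat(assign):
            ss_total = (d**2).sum() / (2 * 6)
            ss_w = 0.0
            for g in ("a", "b"):
                idx = np.flatnonzero(assign == g)
                ss_w += (d[np.ix_(idx, idx)] ** 2).sum() / (2 * 3)
            ss_b = ss_total - ss_w
            return (ss_b / 1) / (ss_w / 4)

        f_obs = f_stat(labels)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            assign = np.array(["b"] * 6)
            assign[list(combo)] = "a"
            total += 1
            if f_stat(assign) >= f_obs - 1e-12:
                count += 1
        exact_p = count / total  # exact permutation distribution

        f, r2, p = permanova(d, labels, n_perm=9999,
                             rng=np.random.default_rng(0))
        assert f == pytest.approx(f_obs)
        assert p == pytest.approx(exact_p, abs=0.02)

    def test_agrees_with_skbio_f_statistic(self, rng):
        skbio = pytest.importorskip("skbio")
        d, labels = self.two_clouds(rng, sep=1.0)
        f, r2, p = permanova(d, labels, n_perm=99, rng=rng)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d), grouping=list(labels), permutations=99
        )
        assert f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_singleton_group_and_single_group_rejected(self, rng):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError, match="singleton"):
            permanova(d, ["a", "a", "a", "b"], n_perm=9, rng=rng)
        with pytest.raises(ValueError, match="two groups"):
            permanova(d, ["a", "a", "a", "a"], n_perm=9, rng=rng)
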