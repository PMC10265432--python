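import numpy as np
import pandas as pd
import pytest

from ema_rt.latent_corr import (
    fit_bivariate2_manifest,
    fit_bivariate3,
    person_covariate_corr,
)
from ema_rt.reliability import wp_reliability_at


def simulate_pair(seed, P, O, Ia, Ib, r_between, r_within,
                  s2p=(0.4, 0.3), s2o=(0.2, 0.15), s2e=(0.3, 0.25)):
    """Direct bivariate nested simulation, independent of synthgen."""
    rng = np.random.default_rng(seed)
    cp = r_between * np.sqrt(s2p[0] * s2p[1])
    co = r_within * np.sqrt(s2o[0] * s2o[1])
    u = rng.multivariate_normal(
        [0, 0], [[s2p[0], cp], [cp, s2p[1]]], size=P
    )
    v = rng.multivariate_normal(
        [0, 0], [[s2o[0], co], [co, s2o[1]]], size=P * O
    ).reshape(P, O, 2)
    ya = (
        u[:, 0][:, None, None] + v[:, :, 0][:, :, None]
        + rng.normal(0, np.sqrt(s2e[0]), (P, O, Ia))
    )
    yb = (
        u[:, 1][:, None, None] + v[:, :, 1][:, :, None]
        + rng.normal(0, np.sqrt(s2e[1]), (P, O, Ib))
    )

    def unroll(y, I):
        return pd.DataFrame(
            {
                "person_id": np.repeat(np.arange(P), O * I),
                "occasion_id": np.tile(np.repeat(np.arange(O), I), P),
                "value": y.ravel(),
            }
        )

    return unroll(ya, Ia), unroll(yb, Ib), u


def occ_means(obs):
    return obs.groupby(["person_id", "occasion_id"], as_index=False)["value"].mean()


@pytest.fixture(scope="module")
def pair_sim():
    truth = (0.55, 0.35)
    a, b, u = simulate_pair(31, 120, 25, 8, 10, *truth)
    return a, b, u, truth


class TestBivariate3:
    def test_copy_gives_unit_correlations(self):
        a, _, _ = simulate_pair(1, 15, 6, 4, 4, 0.0, 0.0)
        res = fit_bivariate3(a, a.copy())
        assert res.r_between == pytest.approx(1.0, abs=1e-3)
        assert res.r_within == pytest.approx(1.0, abs=1e-3)

    def test_independent_measures_near_zero(self):
        a, b, _ = simulate_pair(12, 200, 12, 5, 5, 0.0, 0.0)
        res = fit_bivariate3(a, b)
        assert abs(res.r_between) < 0.05
        assert abs(res.r_within) < 0.05

    def test_recovery(self, pair_sim):
        a, b, _, (rb, rw) = pair_sim
        res = fit_bivariate3(a, b)
        assert res.converged
        assert res.r_between == pytest.approx(rb, abs=0.08)
        assert res.r_within == pytest.approx(rw, abs=0.05)

    def test_symmetry_under_measure_swap(self, pair_sim):
        a, b, _, _ = pair_sim
        r1 = fit_bivariate3(a, b)
        r2 = fit_bivariate3(b, a)
        assert r1.r_between == pytest.approx(r2.r_between, abs=1e-3)
        assert r1.r_within == pytest.approx(r2.r_within, abs=1e-3)

    def test_cauchy_schwarz_at_optimum(self, pair_sim):
        a, b, _, _ = pair_sim
        res = fit_bivariate3(a, b)
        ca = res.components_a
        cb = res.components_b
        assert abs(res.cross_cov_person) <= np.sqrt(ca.var_person * cb.var_person) + 1e-12
        assert abs(res.cross_cov_occasion) <= (
            np.sqrt(ca.var_occasion * cb.var_occasion) + 1e-12
        )

    def test_partial_occasion_overlap_allowed(self):
        a, b, _ = simulate_pair(17, 40, 10, 4, 4, 0.5, 0.3)
        # drop 30% of occasions from each side, differently
        rng = np.random.default_rng(0)
        a = a[rng.random(len(a)) > 0.0]
        keys_a = a["occasion_id"] % 10 != 3
        keys_b = b["occasion_id"] % 10 != 7
        res = fit_bivariate3(a[keys_a], b[keys_b])
        assert res.converged
        assert res.r_between == pytest.approx(0.5, abs=0.2)

    def test_no_shared_occasions_errors(self):
        a, b, _ = simulate_pair(2, 10, 4, 3, 3, 0.0, 0.0)
        b = b.copy()
        b["occasion_id"] = b["occasion_id"] + 100
        with pytest.raises(ValueError, match="share no"):
            fit_bivariate3(a, b)

    def test_single_item_measure_admitted(self):
        a, b, _ = simulate_pair(9, 30, 8, 4, 1, 0.5, 0.3)
        res = fit_bivariate3(a, b, level1_b=False)
        assert res.converged
        assert res.components_b.var_item is None


class TestBivariate2Manifest:
    def test_copy_gives_unit_correlations(self):
        a, _, _ = simulate_pair(1, 15, 6, 4, 4, 0.0, 0.0)
        ma = occ_means(a)
        res = fit_bivariate2_manifest(ma, ma.copy())
        assert res.r_between == pytest.approx(1.0, abs=1e-3)
        assert res.r_within == pytest.approx(1.0, abs=1e-3)

    def test_within_correlation_attenuated(self, pair_sim):
        a, b, _, (rb, rw) = pair_sim
        latent = fit_bivariate3(a, b)
        manifest = fit_bivariate2_manifest(occ_means(a), occ_means(b))
        assert manifest.r_within < latent.r_within
        rel_a = wp_reliability_at(0.2, 0.3, 8)
        rel_b = wp_reliability_at(0.15, 0.25, 10)
        expected = latent.r_within * np.sqrt(rel_a * rel_b)
        assert manifest.r_within == pytest.approx(expected, abs=0.03)

    def test_low_reliability_measure_strongly_attenuated(self):
        # a few very noisy items: manifest within-person r collapses
        a, b, _ = simulate_pair(23, 60, 20, 3, 10, 0.5, 0.6,
                                s2o=(0.1, 0.15), s2e=(2.0, 0.25))
        latent = fit_bivariate3(a, b)
        manifest = fit_bivariate2_manifest(occ_means(a), occ_means(b))
        assert manifest.r_within < 0.6 * latent.r_within

    def test_rejects_duplicate_occasion_rows(self):
        a, b, _ = simulate_pair(2, 10, 4, 3, 3, 0.0, 0.0)
        with pytest.raises(ValueError, match="one mean"):
            fit_bivariate2_manifest(a, occ_means(b))

    def test_three_level_with_zero_item_variance_matches_manifest(self):
        a, b, _ = simulate_pair(4, 25, 8, 1, 1, 0.5, 0.3)
        r3 = fit_bivariate3(a, b, level1_a=False, level1_b=False)
        r2 = fit_bivariate2_manifest(a, b)
        assert r3.r_between == pytest.approx(r2.r_between, abs=1e-5)
        assert r3.r_within == pytest.approx(r2.r_within, abs=1e-5)


class TestPersonCovariate:
    def test_true_intercept_approaches_one(self):
        a, _, u = simulate_pair(5, 40, 15, 8, 1, 0.0, 0.0)
        cov = pd.Series(u[:, 0], index=np.arange(40))
        r = person_covariate_corr(a, cov)
        assert r > 0.95

    def test_simulated_half_correlation_recovered(self):
        rng = np.random.default_rng(40)
        a, _, u = simulate_pair(40, 198, 20, 8, 1, 0.0, 0.0)
        z = u[:, 0] / np.sqrt(0.4)
        cov = pd.Series(
            0.5 * z + np.sqrt(1 - 0.25) * rng.standard_normal(198),
            index=np.arange(198),
        )
        r = person_covariate_corr(a, cov)
        assert r == pytest.approx(0.5, abs=0.07)

    def test_permuted_covariate_near_zero(self):
        rng = np.random.default_rng(14)
        a, _, u = simulate_pair(14, 198, 10, 6, 1, 0.0, 0.0)
        cov = pd.Series(rng.permutation(u[:, 0]), index=np.arange(198))
        assert abs(person_covariate_corr(a, cov)) < 0.05

    def test_constant_covariate_undefined(self):
        a, _, _ = simulate_pair(2, 10, 4, 3, 3, 0.0, 0.0)
        cov = pd.Series(np.ones(10), index=np.arange(10))
        with pytest.raises(ValueError, match="constant"):
            person_covariate_corr(a, cov)

    def test_missing_covariate_errors(self):
        a, _, _ = simulate_pair(2, 10, 4, 3, 3, 0.0, 0.0)
        cov = pd.Series(np.ones(5), index=np.arange(5))
        with pytest.raises(ValueError, match="missing"):
            person_covariate_corr(a, cov)
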