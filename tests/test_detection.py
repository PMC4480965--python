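"""Decision layer: sigma draws, tail probabilities, EFDR/EFNR calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikevar import biological_share, calibrate_alpha, classify, efdr_efnr, sigma_draws, tail_probabilities
from spikevar.detection import (
    CalibrationError,
    calibrate_thresholds,
    default_alpha_grid,
    default_gamma_grid,
    plugin_sigma,
    technical_share_summary,
)

from conftest import chain_from_arrays

pi_vectors = st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30).map(np.array)


class TestSigmaDraws:
    def test_zero_delta_gives_zero_sigma(self):
        chains = chain_from_arrays(
            mu=np.full((3, 2), 5.0),
            delta=np.zeros((3, 2)),
            phi=np.ones((3, 4)),
            s=np.full((3, 4), 0.4),
            theta=np.full(3, 0.5),
        )
        assert np.all(sigma_draws(chains) == 0.0)

    def test_single_draw_delegates_to_biological_share(self):
        mu = np.array([[3.0, 40.0]])
        delta = np.array([[0.5, 1.2]])
        phi = np.array([[0.8, 1.0, 1.2]])
        s = np.array([[0.3, 0.4, 0.5]])
        chains = chain_from_arrays(mu=mu, delta=delta, phi=phi, s=s, theta=[0.6])
        pss = np.median(phi[0] * s[0])
        expect = biological_share(mu[0], delta[0], 0.6, pss)
        np.testing.assert_allclose(sigma_draws(chains)[0], expect)

    def test_two_draw_hand_computed(self):
        """Values reproduced by direct elementwise evaluation of the share."""
        chains = chain_from_arrays(
            mu=[[10.0, 2.0], [12.0, 3.0]],
            delta=[[0.5, 1.0], [0.4, 2.0]],
            phi=[[1.0, 1.0], [0.9, 1.1]],
            s=[[0.4, 0.4], [0.5, 0.3]],
            theta=[0.5, 0.25],
        )
        sig = sigma_draws(chains)
        for t, (theta, pss) in enumerate(
            [(0.5, np.median([0.4, 0.4])), (0.25, np.median([0.45, 0.33]))]
        ):
            for k, (m, d) in enumerate(zip(chains.mu[t], chains.delta[t])):
                num = d * (theta + 1)
                expect = num / (1.0 / (pss * m) + theta + num)
                assert sig[t, k] == pytest.approx(expect)

    def test_plugin_mode_uses_posterior_medians(self):
        chains = chain_from_arrays(
            mu=[[10.0, 2.0], [12.0, 3.0], [11.0, 2.5]],
            delta=[[0.5, 1.0], [0.4, 2.0], [0.45, 1.5]],
            phi=np.ones((3, 2)),
            s=np.full((3, 2), 0.4),
            theta=[0.5, 0.25, 0.4],
        )
        expect = biological_share(
            np.median(chains.mu, axis=0), np.median(chains.delta, axis=0), 0.4, 0.4
        )
        np.testing.assert_allclose(plugin_sigma(chains), expect)


class TestTailProbabilities:
    def test_gamma_zero_all_positive(self):
        sig = np.array([[0.1, 0.9], [0.2, 0.8]])
        np.testing.assert_array_equal(tail_probabilities(sig, 0.0, "high"), [1.0, 1.0])

    def test_direct_count(self):
        sig = np.array([0.9, 0.7, 0.85, 0.6])[:, None]
        assert tail_probabilities(sig, 0.79, "high")[0] == pytest.approx(0.5)

    def test_ties_do_not_count(self):
        sig = np.array([[0.5], [0.5], [0.7], [0.3]])
        assert tail_probabilities(sig, 0.5, "high")[0] == pytest.approx(0.25)
        assert tail_probabilities(sig, 0.5, "low")[0] == pytest.approx(0.25)

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            tail_probabilities(np.empty((0, 3)), 0.5, "high")

    @settings(deadline=None, derandomize=True)
    @given(g1=st.floats(0.0, 0.99), g2=st.floats(0.0, 0.99))
    def test_monotone_in_gamma_and_disjoint(self, g1, g2):
        rng = np.random.default_rng(0)
        sig = rng.uniform(0, 1, size=(50, 4))
        lo, hi = sorted([g1, g2])
        assert np.all(
            tail_probabilities(sig, hi, "high") <= tail_probabilities(sig, lo, "high")
        )
        assert np.all(
            tail_probabilities(sig, lo, "low") <= tail_probabilities(sig, hi, "low")
        )
        assert np.all(
            tail_probabilities(sig, g1, "high") + tail_probabilities(sig, g1, "low") <= 1.0
        )


class TestEfdrEfnr:
    def test_all_confident(self):
        efdr, efnr, n = efdr_efnr(np.array([1.0, 1.0, 1.0]), 0.9)
        assert efdr == 0.0 and n == 3 and np.isnan(efnr)

    def test_hand_computed_fixture(self):
        efdr, efnr, n = efdr_efnr(np.array([0.9, 0.8, 0.6]), 0.75)
        assert efdr == pytest.approx(0.15)
        assert efnr == pytest.approx(0.6)
        assert n == 2

    def test_empty_selection_flagged(self):
        efdr, efnr, n = efdr_efnr(np.array([0.3, 0.2]), 0.9)
        assert np.isnan(efdr) and n == 0
        assert efnr == pytest.approx(0.25)

    @settings(deadline=None, derandomize=True)
    @given(pi=pi_vectors, a1=st.floats(0.01, 0.98), a2=st.floats(0.01, 0.98))
    def test_efdr_monotone_nonincreasing_in_alpha(self, pi, a1, a2):
        lo, hi = sorted([a1, a2])
        e_lo, f_lo, _ = efdr_efnr(pi, lo)
        e_hi, f_hi, _ = efdr_efnr(pi, hi)
        if np.isfinite(e_lo) and np.isfinite(e_hi):
            assert e_hi <= e_lo + 1e-12
        if np.isfinite(f_lo) and np.isfinite(f_hi):
            assert f_lo <= f_hi + 1e-12


class TestCalibrateAlpha:
    def test_symmetric_toy_returns_largest_tied_alpha(self):
        pi = np.array([0.2, 0.8])
        grid = default_alpha_grid()
        a = calibrate_alpha(pi, grid)
        # EFDR = EFNR = 0.2 for every alpha in [0.2, 0.8); ties -> largest
        assert a == pytest.approx(grid[grid < 0.8].max())

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            pi = rng.uniform(0, 1, 25)
            grid = default_alpha_grid()
            best, best_d = None, np.inf
            for a in grid:
                efdr, efnr, _ = efdr_efnr(pi, a)
                if np.isfinite(efdr) and np.isfinite(efnr) and abs(efdr - efnr) <= best_d:
                    best, best_d = a, abs(efdr - efnr)
            assert calibrate_alpha(pi, grid) == pytest.approx(best)

    def test_degenerate_all_equal(self):
        # one side is always undefined: either everything or nothing selected
        with pytest.raises(CalibrationError):
            calibrate_alpha(np.full(5, 0.6), np.array([0.7, 0.8]))

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            calibrate_alpha(np.array([0.2, 0.8]), np.array([0.9, 0.7]))


class TestCalibrateThresholds:
    def _concentrated_chains(self, center=0.9, n_draws=400, n_genes=30):
        """Chains whose sigma concentrates near ``center`` for every gene."""
        rng = np.random.default_rng(7)
        theta = np.full(n_draws, 0.4)
        pss = 0.4
        sig = np.clip(rng.normal(center, 0.02, size=(n_draws, n_genes)), 0.01, 0.99)
        # invert sigma -> delta so sigma_draws reproduces sig exactly
        mu = np.full((n_draws, n_genes), 10.0)
        inv = 1.0 / (pss * mu)
        delta = sig * (inv + theta[:, None]) / ((1 - sig) * (theta[:, None] + 1))
        phi = np.ones((n_draws, 3))
        s = np.full((n_draws, 3), pss)
        return chain_from_arrays(mu=mu, delta=delta, phi=phi, s=s, theta=theta)

    def test_concentrated_sigma_high_rule_and_error_contract(self):
        """All sigma mass near 0.9: the high rule's EFDR(=EFNR) crossing is ~0
        below the mass, and the hopeless low rule raises with the table."""
        chains = self._concentrated_chains(0.9)
        try:
            res = calibrate_thresholds(chains, target_rate=0.10)
            table = res.table
            assert res.gamma_H <= 0.95
        except CalibrationError as err:
            # the low rule has no defined crossing below gamma_H; the error
            # must carry the full table
            table = err.table
            assert table is not None
        sub = table[(table.side == "high") & (table.gamma < 0.8)]
        assert np.all(sub.efdr.dropna() < 0.05)

    def test_mixed_population_selects_ordered_thresholds(self):
        rng = np.random.default_rng(9)
        n_draws, q0 = 400, 40
        centers = np.where(np.arange(q0) < 25, 0.85, 0.15)
        sig = np.clip(rng.normal(centers, 0.08, size=(n_draws, q0)), 0.01, 0.99)
        theta = np.full(n_draws, 0.4)
        mu = np.full((n_draws, q0), 10.0)
        inv = 1.0 / (0.4 * mu)
        delta = sig * (inv + 0.4) / ((1 - sig) * 1.4)
        chains = chain_from_arrays(
            mu=mu, delta=delta, phi=np.ones((n_draws, 3)), s=np.full((n_draws, 3), 0.4), theta=theta
        )
        res = calibrate_thresholds(chains, target_rate=0.10)
        assert 0.0 < res.gamma_L <= res.gamma_H < 1.0
        assert 0.5 < res.alpha_H < 1.0 and 0.5 < res.alpha_L < 1.0

    def test_n_detected_monotone_in_alpha(self):
        chains = self._concentrated_chains(0.7)
        sig = sigma_draws(chains)
        pi = tail_probabilities(sig, 0.6, "high")
        ns = [efdr_efnr(pi, a)[2] for a in default_alpha_grid()]
        assert np.all(np.diff(ns) <= 0)

    def test_target_rate_domain(self):
        chains = self._concentrated_chains()
        with pytest.raises(ValueError):
            calibrate_thresholds(chains, target_rate=0.6)


class TestClassify:
    def _chains(self):
        rng = np.random.default_rng(8)
        n_draws, q0 = 300, 40
        mu = np.exp(rng.normal(2, 1, (n_draws, q0)))
        delta = np.exp(rng.normal(np.log(0.5), 0.8, (1, q0)) + rng.normal(0, 0.2, (n_draws, q0)))
        phi = rng.dirichlet(np.full(5, 50.0), n_draws) * 5
        s = rng.uniform(0.35, 0.45, (n_draws, 5))
        theta = rng.uniform(0.3, 0.5, n_draws)
        return chain_from_arrays(mu=mu, delta=delta, phi=phi, s=s, theta=theta)

    def test_flags_match_rule_and_are_pure(self):
        chains = self._chains()
        r1 = classify(chains, 0.79, 0.7925, 0.41, 0.765)
        r2 = classify(chains, 0.79, 0.7925, 0.41, 0.765)
        np.testing.assert_array_equal(r1.hvg_flags, r1.pi_H > 0.7925)
        np.testing.assert_array_equal(r1.lvg_flags, r1.pi_L > 0.765)
        np.testing.assert_array_equal(r1.hvg_flags, r2.hvg_flags)
        np.testing.assert_array_equal(r1.pi_H, r2.pi_H)

    def test_no_gene_both_hvg_and_lvg(self):
        chains = self._chains()
        res = classify(chains, 0.6, 0.55, 0.6, 0.55)
        assert not np.any(res.hvg_flags & res.lvg_flags)

    def test_gamma_order_enforced(self):
        chains = self._chains()
        with pytest.raises(ValueError):
            classify(chains, 0.4, 0.8, 0.6, 0.8)

    def test_frame_ranked_by_sigma(self):
        chains = self._chains()
        res = classify(chains, 0.79, 0.7925, 0.41, 0.765)
        df = res.to_frame()
        top = df.loc[df["rank"] == 1, "sigma_median"].iloc[0]
        assert top == pytest.approx(df.sigma_median.max())


def test_technical_share_summary_hand_computed():
    """Single draw, hand-evaluated technical shares; both aggregations."""
    chains = chain_from_arrays(
        mu=[[10.0, 2.0]], delta=[[0.5, 1.0]], phi=[[1.0, 1.0]], s=[[0.4, 0.4]], theta=[0.5]
    )
    shares = []
    for m, d in [(10.0, 0.5), (2.0, 1.0)]:
        shares.append(0.5 / (1.0 / (0.4 * m) + 0.5 + d * 1.5))
    out = technical_share_summary(chains)
    assert out["mean"] == pytest.approx(np.mean(shares))
    assert out["median"] == pytest.approx(np.median(shares))


def test_default_grids_match_reported_precision():
    a = default_alpha_grid()
    assert a[0] == pytest.approx(0.5025) and a[-1] == pytest.approx(0.9975)
    # the reported evidence thresholds are representable grid points
    assert np.any(np.isclose(a, 0.7925)) and np.any(np.isclose(a, 0.7650))
    g = default_gamma_grid()
    assert np.any(np.isclose(g, 0.79)) and np.any(np.isclose(g, 0.41))
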