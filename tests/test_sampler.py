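"""Sampler: conjugate conditionals, Metropolis kernels, adaptation, chains."""

import dataclasses

import numpy as np
import pytest

from spikevar import McmcConfig, PriorSpec, chain_diagnostics, run_mcmc
from spikevar.sampler import (
    AdaptiveStep,
    ChainStore,
    adapt_step,
    block_log_target,
    gibbs_mu,
    gibbs_nu,
    gibbs_rho,
    initial_state,
    mh_update,
)

from conftest import chain_from_arrays, make_dataset, make_state


class TestGibbsConditionals:
    def test_nu_prior_recovery(self):
        """With no counts and negligible biological rates, nu is drawn from
        (approximately) its Gamma(1/theta, 1/(s theta)) prior."""
        data = make_dataset([[0, 0], [0, 0]], n_tech=1, spike_mu=1e-9)
        state = make_state(data, mu_bio=[1e-9], theta=0.5, s=[0.4, 0.4])
        state.rho = np.ones((1, 2))
        rng = np.random.default_rng(0)
        draws = np.array([gibbs_nu(data, state, 0, rng) for _ in range(20_000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 0.4) < 3 * se

    def test_nu_analytic_moments(self):
        data = make_dataset([[3, 1], [7, 2]], n_tech=1, spike_mu=12.0)
        state = make_state(data, mu_bio=[5.0], theta=0.8, s=[0.4, 0.3], nu=[0.4, 0.3])
        state.rho = np.array([[1.3, 0.7]])
        rng = np.random.default_rng(1)
        draws = np.array([gibbs_nu(data, state, 0, rng) for _ in range(100_000)])
        shape = 1 / 0.8 + 3 + 7
        rate = 1 / (0.4 * 0.8) + state.phi[0] * 5.0 * 1.3 + 12.0
        assert abs(draws.mean() - shape / rate) < 3 * np.sqrt(shape) / rate / np.sqrt(len(draws))
        var = shape / rate**2
        se_var = np.sqrt(2 * shape + 3 * shape**2) / rate**2 / np.sqrt(len(draws)) * 2
        assert abs(draws.var(ddof=1) - var) < 3 * se_var

    def test_nu_theta_zero_degenerate(self):
        data = make_dataset([[1, 1], [2, 2]], n_tech=1)
        state = make_state(data, theta=0.0, s=[0.37, 0.41])
        assert gibbs_nu(data, state, 1, np.random.default_rng(0)) == 0.41

    def test_rho_prior_recovery_and_concentration(self):
        data = make_dataset([[0, 0], [1, 1]], n_tech=1)
        state = make_state(data, mu_bio=[1e-12], delta=[0.6])
        rng = np.random.default_rng(2)
        draws = np.array([gibbs_rho(data, state, 0, 0, rng) for _ in range(50_000)])
        assert abs(draws.mean() - 1.0) < 0.02
        assert abs(draws.var(ddof=1) - 0.6) < 0.03
        # large count with large rate: concentrates at x / (phi nu mu)
        data2 = make_dataset([[4000, 1], [1, 1]], n_tech=1)
        state2 = make_state(data2, mu_bio=[1000.0], delta=[0.5], nu=[1.0, 1.0], phi=[1.0, 1.0])
        d2 = np.array([gibbs_rho(data2, state2, 0, 0, rng) for _ in range(200)])
        assert abs(d2.mean() - 4.0) < 0.1

    def test_rho_delta_zero_degenerate(self):
        data = make_dataset([[1, 1], [2, 2]], n_tech=1)
        state = make_state(data, delta=[0.0])
        assert gibbs_rho(data, state, 0, 0, np.random.default_rng(0)) == 1.0

    def test_mu_analytic_mean(self):
        data = make_dataset([[6, 11], [1, 1]], n_tech=1)
        state = make_state(data, mu_bio=[5.0], delta=[0.4], nu=[0.35, 0.5])
        state.rho = np.array([[0.8, 1.4]])
        rng = np.random.default_rng(3)
        draws = np.array([gibbs_mu(data, state, 0, rng) for _ in range(100_000)])
        rate = float((state.phi * state.nu) @ state.rho[0])
        mean = 17.0 / rate  # shape = sum of counts under the 1/mu prior
        assert abs(draws.mean() - mean) < 3 * np.sqrt(17.0) / rate / np.sqrt(len(draws))

    def test_mu_all_zero_gene_guarded(self):
        data = make_dataset([[0, 0], [1, 1]], n_tech=1)
        state = make_state(data)
        state.rho = np.ones((1, 2))
        with pytest.raises(ValueError, match="propriety"):
            gibbs_mu(data, state, 0, np.random.default_rng(0))
        with pytest.raises(ValueError, match="positive count"):
            data.validate(require_expressed=True)


class TestMetropolis:
    @pytest.fixture()
    def instance(self):
        data = make_dataset([[4, 2, 6], [1, 8, 3], [9, 11, 7]], n_tech=1, spike_mu=14.0)
        state = make_state(data, mu_bio=[4.0, 6.0], delta=[0.4, 0.8], nu=[0.4, 0.45, 0.35])
        return data, state

    def test_degenerate_proposal_always_accepts(self, instance):
        data, state = instance
        rng = np.random.default_rng(4)
        accepted = 0
        for _ in range(1000):
            state, ok = mh_update("theta", state, data, AdaptiveStep(np.log(1e-9)), rng)
            accepted += ok
        assert accepted == 1000

    def test_rejected_kappa_leaves_phi_bit_identical(self, instance):
        data, state = instance
        rng = np.random.default_rng(5)
        phi_before = state.phi.copy()
        rejections = 0
        for _ in range(50):
            new_state, ok = mh_update("kappa", state, data, AdaptiveStep(np.log(50.0)), rng)
            if not ok:
                rejections += 1
                assert new_state is state
                assert np.array_equal(new_state.phi, phi_before)
            else:
                state = new_state
                phi_before = state.phi.copy()
        assert rejections > 0

    @pytest.mark.parametrize("block", ["theta", ("delta", 0), ("s", 1)])
    def test_detailed_balance_three_point(self, instance, block):
        """MH with a symmetric 3-point proposal satisfies pi_i P_ij = pi_j P_ji
        under the implemented conditional log-densities."""
        data, state = instance
        name = block if isinstance(block, str) else block[0]
        values = [0.3, 0.5, 0.9]
        logpi = []
        for v in values:
            st = dataclasses.replace(state)
            if name == "theta":
                st.theta = v
            elif name == "delta":
                st.delta = state.delta.copy()
                st.delta[block[1]] = v
            else:
                st.s = state.s.copy()
                st.s[block[1]] = v
            logpi.append(block_log_target(block, data, st, PriorSpec()))
        pi = np.exp(np.array(logpi) - max(logpi))
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:
                    P[i, j] = 0.5 * min(1.0, pi[j] / pi[i])
            P[i, i] = 1.0 - P[i].sum()
        for i in range(3):
            for j in range(3):
                assert pi[i] * P[i, j] == pytest.approx(pi[j] * P[j, i], rel=1e-12)


class TestAdaptation:
    def test_tie_decreases(self):
        step = adapt_step(AdaptiveStep(0.0), accepted_fraction=0.44, batch_index=3)
        assert step.log_step == pytest.approx(-0.01)

    def test_first_batch_increment(self):
        up = adapt_step(AdaptiveStep(0.0), 0.9, 1)
        down = adapt_step(AdaptiveStep(0.0), 0.1, 1)
        assert up.log_step == pytest.approx(0.01)
        assert down.log_step == pytest.approx(-0.01)

    def test_late_batches_shrink(self):
        step = adapt_step(AdaptiveStep(0.0), 0.9, 40_000)
        assert step.log_step == pytest.approx(1.0 / np.sqrt(40_000))

    def test_acceptance_rates_stabilise(self, small_sim):
        """Post-burn-in (frozen) acceptance sits in [0.25, 0.60] for every
        adapted block on a well-specified simulated run."""
        _, data, _ = small_sim
        from spikevar import filter_low_expression

        data, _ = filter_low_expression(data, 1)
        chains = run_mcmc(data, config=McmcConfig(n_iter=6000, burn_in=4000, thin=2, seed=21))
        for name, rates in chains.acceptance.items():
            rates = np.atleast_1d(rates)
            assert np.all(rates > 0.25) and np.all(rates < 0.60), (name, rates)


class TestRunMcmc:
    def test_seed_determinism(self, small_sim):
        _, data, _ = small_sim
        from spikevar import filter_low_expression

        data, _ = filter_low_expression(data, 1)
        cfg = McmcConfig(n_iter=400, burn_in=200, thin=2, seed=7)
        a = run_mcmc(data, config=cfg)
        b = run_mcmc(data, config=cfg)
        for name in ("mu", "delta", "phi", "s", "nu", "theta"):
            assert np.array_equal(getattr(a, name), getattr(b, name)), name

    def test_phi_sum_and_spike_mu_invariants(self, small_sim):
        _, data, _ = small_sim
        from spikevar import filter_low_expression

        data, _ = filter_low_expression(data, 1)
        for marg in (True, False):
            cfg = McmcConfig(n_iter=300, burn_in=100, thin=1, seed=9, marginalise_rho=marg)
            chains = run_mcmc(data, config=cfg)
            np.testing.assert_allclose(chains.phi.sum(axis=1), chains.phi0, rtol=1e-10)
            np.testing.assert_array_equal(
                chains.spike_mu, data.spike_input[data.is_technical]
            )

    def test_validation_rejects_improper_dataset(self):
        data = make_dataset([[0, 0], [3, 1], [5, 2]], n_tech=1)
        with pytest.raises(ValueError, match="g0"):
            run_mcmc(data, config=McmcConfig(n_iter=100, burn_in=50, thin=1, seed=0))

    def test_prior_recovery_without_likelihood(self, small_sim):
        """With the likelihood switched off the chain reproduces the priors
        (theta, delta, s all Gamma(1,1): mean 1, variance 1)."""
        _, data, _ = small_sim
        from spikevar import filter_low_expression

        data, _ = filter_low_expression(data, 1)
        cfg = McmcConfig(n_iter=30_000, burn_in=2000, thin=5, seed=13, prior_only=True)
        chains = run_mcmc(data, config=cfg)
        assert abs(chains.theta.mean() - 1.0) < 0.25
        assert abs(chains.delta.mean() - 1.0) < 0.1
        assert abs(chains.s.mean() - 1.0) < 0.1
        assert abs(chains.delta.var() - 1.0) < 0.3

    def test_chainstore_roundtrips(self, small_sim, tmp_path):
        _, data, _ = small_sim
        from spikevar import filter_low_expression

        data, _ = filter_low_expression(data, 1)
        chains = run_mcmc(data, config=McmcConfig(n_iter=200, burn_in=100, thin=2, seed=3))
        chains.to_hdf5(tmp_path / "c.h5")
        back = ChainStore.from_hdf5(tmp_path / "c.h5")
        np.testing.assert_array_equal(back.mu, chains.mu)
        np.testing.assert_array_equal(back.theta, chains.theta)
        assert list(back.bio_gene_ids) == list(chains.bio_gene_ids)
        assert back.config == chains.config
        chains.export_text(tmp_path / "txt")
        assert (tmp_path / "txt" / "chain_theta.tsv").exists()


class TestDiagnostics:
    def _chains(self, cols):
        cols = np.column_stack(cols)
        return chain_from_arrays(
            mu=np.abs(cols) + 0.1,
            delta=np.abs(cols) + 0.1,
            phi=np.ones((len(cols), 2)),
            s=np.full((len(cols), 2), 0.4),
            theta=np.abs(cols[:, 0]) + 0.1,
        )

    def test_iid_chain_ess_near_n(self):
        n = 5000
        x = np.random.default_rng(0).standard_normal(n)
        chains = chain_from_arrays(
            mu=np.exp(x)[:, None],
            delta=np.full((n, 1), 0.5),
            phi=np.ones((n, 2)),
            s=np.full((n, 2), 0.4),
            theta=np.exp(x),
        )
        table = chain_diagnostics(chains)
        ess = float(table.loc[table.parameter == "theta", "ess"].iloc[0])
        assert abs(ess - n) < 0.15 * n

    def test_constant_chain_flagged_degenerate(self):
        n = 100
        chains = chain_from_arrays(
            mu=np.full((n, 1), 2.0),
            delta=np.full((n, 1), 0.5),
            phi=np.ones((n, 2)),
            s=np.full((n, 2), 0.4),
            theta=np.full(n, 0.7),
        )
        table = chain_diagnostics(chains)
        row = table[table.parameter == "theta"].iloc[0]
        assert row.degenerate
        assert row.ess == n

    def test_ar1_chain_ess(self):
        n, rho = 20_000, 0.9
        rng = np.random.default_rng(1)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for t in range(1, n):
            x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * rng.standard_normal()
        chains = chain_from_arrays(
            mu=np.exp(x)[:, None],
            delta=np.full((n, 1), 0.5),
            phi=np.ones((n, 2)),
            s=np.full((n, 2), 0.4),
            theta=np.exp(x),
        )
        table = chain_diagnostics(chains)
        ess = float(table.loc[table.parameter == "theta", "ess"].iloc[0])
        expect = n * (1 - rho) / (1 + rho)
        assert abs(ess - expect) < 0.25 * expect
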