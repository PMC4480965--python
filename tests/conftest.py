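"""Shared fixtures: small synthetic instances and hand-built chain stores."""

import numpy as np
import pytest

from spikevar import ExpressionDataset, ModelState, SimulationSpec, simulate_dataset
from spikevar.sampler import ChainStore, McmcConfig, PriorSpec


def make_dataset(counts, n_tech=1, spike_mu=None, require_expressed=False):
    """Dataset from a raw count array; the last ``n_tech`` genes are technical."""
    counts = np.asarray(counts)
    q, n = counts.shape
    is_tech = np.zeros(q, dtype=bool)
    is_tech[q - n_tech :] = True
    spike = np.full(q, np.nan)
    spike[q - n_tech :] = spike_mu if spike_mu is not None else 10.0
    data = ExpressionDataset(
        counts=counts,
        gene_ids=np.array([f"g{i}" for i in range(q)], dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(n)], dtype=object),
        is_technical=is_tech,
        spike_input=spike,
    )
    if require_expressed:
        data.validate(require_expressed=True)
    return data


def make_state(dataset, mu_bio=None, delta=None, phi=None, s=None, theta=0.5, nu=None, rho=None):
    """A valid ModelState consistent with ``dataset`` (defaults are benign)."""
    q, n = dataset.counts.shape
    bio = ~dataset.is_technical
    mu = np.empty(q)
    mu[bio] = 5.0 if mu_bio is None else mu_bio
    mu[~bio] = dataset.spike_input[~bio]
    phi = np.full(n, 1.0) if phi is None else np.asarray(phi, float)
    phi = float(n) * phi / phi.sum()
    kappa = np.log(phi) - np.log(phi[0])
    kappa[0] = 0.0
    return ModelState(
        mu=mu,
        delta=np.full(int(bio.sum()), 0.3) if delta is None else np.asarray(delta, float),
        phi=phi,
        kappa=kappa,
        s=np.full(n, 0.4) if s is None else np.asarray(s, float),
        theta=theta,
        nu=np.full(n, 0.4) if nu is None else np.asarray(nu, float),
        is_technical=dataset.is_technical.copy(),
        phi0=float(n),
        rho=rho,
    )


def chain_from_arrays(mu, delta, phi, s, theta, nu=None):
    """Hand-built ChainStore for detection-layer tests."""
    mu = np.atleast_2d(np.asarray(mu, float))
    delta = np.atleast_2d(np.asarray(delta, float))
    phi = np.atleast_2d(np.asarray(phi, float))
    s = np.atleast_2d(np.asarray(s, float))
    theta = np.atleast_1d(np.asarray(theta, float))
    t, q0 = mu.shape
    n = phi.shape[1]
    return ChainStore(
        mu=mu,
        delta=delta,
        phi=phi,
        s=s,
        nu=s.copy() if nu is None else np.atleast_2d(np.asarray(nu, float)),
        theta=theta,
        bio_gene_ids=np.array([f"g{i}" for i in range(q0)], dtype=object),
        tech_gene_ids=np.array(["spike_0"], dtype=object),
        spike_mu=np.array([10.0]),
        phi0=float(phi[0].sum()),
        priors=PriorSpec(),
        config=McmcConfig(n_iter=2 * max(t, 2), burn_in=0, thin=1, seed=0),
        dataset_digest="synthetic",
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset with known truth (30 bio + 8 tech, 12 cells)."""
    rng = np.random.Generator(np.random.Philox(99))
    q0, n_tech, n = 30, 8, 12
    mu = np.concatenate([10.0 ** rng.uniform(0, 2.5, q0), 10.0 ** rng.uniform(0.5, 2.5, n_tech)])
    spec = SimulationSpec(
        q=q0 + n_tech,
        q0=q0,
        n=n,
        mu=mu,
        delta=np.exp(rng.normal(np.log(0.4), 0.6, q0)),
        phi=np.full(n, 1.0),
        s=rng.uniform(0.31, 0.44, n),
        theta=0.4,
        seed=17,
    )
    data, latents = simulate_dataset(spec)
    return spec, data, latents
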