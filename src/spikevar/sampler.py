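"""Posterior inference via adaptive Metropolis-within-Gibbs.

Two kernels target the same posterior:

* the default **marginalised** kernel integrates the biological random
  effects rho out analytically (negative-binomial likelihood) and updates
  mu, delta, nu, s, theta and kappa with adaptively tuned random-walk
  Metropolis moves (log scale; kappa on the natural scale as a joint block
  with kappa_1 fixed at 0);
* the **explicit-augmentation** kernel keeps rho as latent variables, which
  makes the rho, mu and nu conditionals conjugate (Gibbs); it is retained as
  an oracle and user option.

Proposal scales adapt in batches during burn-in only (Roberts-Rosenthal
increments, frozen afterwards so the retained chain is ergodic).  All
randomness flows from a single counter-based Philox stream seeded by the
configuration, so identical seed and configuration reproduce a chain
bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import _mcmc_explicit, _mcmc_marginal
from .baseline import deseq_size_factors
from .dataset import ExpressionDataset
from .model import ModelState, marginal_loglik, phi_from_kappa

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "AdaptiveStep",
    "ChainStore",
    "adapt_step",
    "initial_state",
    "run_mcmc",
    "gibbs_nu",
    "gibbs_rho",
    "gibbs_mu",
    "mh_update",
    "block_log_target",
    "chain_diagnostics",
]


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-parameters of the proper priors (all Gamma laws shape-rate).

    The biological expression rates mu_i carry the scale-invariant
    non-informative prior p(mu) proportional to 1/mu (flat on the log
    scale), restricted to (0, mu_max] as a safety bound; it yields a proper
    posterior exactly when every biological gene has a positive count in at
    least one cell.  A literally-flat prior on (0, inf) would make the
    posterior improper whenever a dispersion delta_i reaches the cell count
    n, since the mu_i conditional tail decays only as mu^(-n/delta_i).
    Everything else is proper and weakly informative by default; phi/phi0
    carries a symmetric Dirichlet prior with the given concentration.
    """

    theta_shape: float = 1.0
    theta_rate: float = 1.0
    delta_shape: float = 1.0
    delta_rate: float = 1.0
    s_shape: float = 1.0
    s_rate: float = 1.0
    phi_concentration: float = 1.0
    mu_max: float = 1e12

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"prior hyper-parameter {f.name} must be > 0")


@dataclass(frozen=True)
class McmcConfig:
    """Chain length, adaptation and reproducibility settings."""

    n_iter: int = 4000
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0
    adapt_batch: int = 50
    target_accept: float = 0.44
    initial_log_step: dict | None = None
    marginalise_rho: bool = True
    prior_only: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1 or (self.n_iter - self.burn_in) // self.thin < 2:
            raise ValueError("need at least 2 retained draws: (n_iter - burn_in)/thin >= 2")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must be in (0, 1)")
        if self.adapt_batch < 1:
            raise ValueError("adapt_batch must be positive")


@dataclass
class AdaptiveStep:
    """Log proposal scale for one Metropolis block."""

    log_step: float


def adapt_step(
    step: AdaptiveStep,
    accepted_fraction: float,
    batch_index: int,
    target_accept: float = 0.44,
) -> AdaptiveStep:
    """One Roberts-Rosenthal adaptation: move the log step by
    min(0.01, batch_index^{-1/2}), up if the batch acceptance exceeded the
    target, down otherwise (ties decrease).  Call during burn-in only."""
    inc = min(0.01, batch_index ** -0.5)
    if accepted_fraction > target_accept:
        return AdaptiveStep(step.log_step + inc)
    return AdaptiveStep(step.log_step - inc)


@dataclass
class ChainStore:
    """Thinned post-burn-in draws plus everything needed to reproduce them."""

    mu: np.ndarray  # (draws, q0) biological expression rates
    delta: np.ndarray  # (draws, q0)
    phi: np.ndarray  # (draws, n)
    s: np.ndarray  # (draws, n)
    nu: np.ndarray  # (draws, n)
    theta: np.ndarray  # (draws,)
    bio_gene_ids: np.ndarray
    tech_gene_ids: np.ndarray
    spike_mu: np.ndarray
    phi0: float
    priors: PriorSpec
    config: McmcConfig
    dataset_digest: str = ""
    acceptance: dict = field(default_factory=dict)
    batch_log: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    @property
    def n_bio(self) -> int:
        return self.mu.shape[1]

    @property
    def n_cells(self) -> int:
        return self.phi.shape[1]

    def summary(self) -> pd.DataFrame:
        """Posterior medians of the per-biological-gene parameters."""
        return pd.DataFrame(
            {
                "gene_id": self.bio_gene_ids,
                "mu_median": np.median(self.mu, axis=0),
                "delta_median": np.median(self.delta, axis=0),
            }
        )

    # -- serialisation ------------------------------------------------------
    def to_hdf5(self, path) -> None:
        import h5py

        from .io import atomic_write

        with atomic_write(path) as tmp:
            with h5py.File(tmp, "w") as h:
                g = h.create_group("draws")
                for name in ("mu", "delta", "phi", "s", "nu", "theta"):
                    g.create_dataset(name, data=getattr(self, name))
                ids = h.create_group("ids")
                str_dt = h5py.string_dtype()
                ids.create_dataset(
                    "bio_gene_ids", data=[str(g) for g in self.bio_gene_ids], dtype=str_dt
                )
                ids.create_dataset(
                    "tech_gene_ids", data=[str(g) for g in self.tech_gene_ids], dtype=str_dt
                )
                h.create_dataset("spike_mu", data=self.spike_mu)
                acc = h.create_group("acceptance")
                for k, v in self.acceptance.items():
                    acc.create_dataset(k, data=np.asarray(v))
                if self.batch_log is not None:
                    h.create_dataset("batch_log", data=self.batch_log)
                h.attrs["phi0"] = self.phi0
                h.attrs["dataset_digest"] = self.dataset_digest
                h.attrs["priors"] = json.dumps(dataclasses.asdict(self.priors))
                h.attrs["config"] = json.dumps(dataclasses.asdict(self.config))

    @classmethod
    def from_hdf5(cls, path) -> "ChainStore":
        import h5py

        with h5py.File(path, "r") as h:
            draws = {k: h["draws"][k][()] for k in h["draws"]}
            acc = {k: h["acceptance"][k][()] for k in h["acceptance"]}
            return cls(
                mu=draws["mu"],
                delta=draws["delta"],
                phi=draws["phi"],
                s=draws["s"],
                nu=draws["nu"],
                theta=draws["theta"],
                bio_gene_ids=h["ids"]["bio_gene_ids"].asstr()[()],
                tech_gene_ids=h["ids"]["tech_gene_ids"].asstr()[()],
                spike_mu=h["spike_mu"][()],
                phi0=float(h.attrs["phi0"]),
                priors=PriorSpec(**json.loads(h.attrs["priors"])),
                config=McmcConfig(**json.loads(h.attrs["config"])),
                dataset_digest=str(h.attrs["dataset_digest"]),
                acceptance=acc,
                batch_log=h["batch_log"][()] if "batch_log" in h else None,
            )

    def export_text(self, directory) -> None:
        """One delimited file per parameter family (draws as rows)."""
        from pathlib import Path

        from .io import atomic_write

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = {
            "mu": pd.DataFrame(self.mu, columns=self.bio_gene_ids),
            "delta": pd.DataFrame(self.delta, columns=self.bio_gene_ids),
            "phi": pd.DataFrame(self.phi),
            "s": pd.DataFrame(self.s),
            "nu": pd.DataFrame(self.nu),
            "theta": pd.DataFrame({"theta": self.theta}),
        }
        for name, frame in frames.items():
            with atomic_write(directory / f"chain_{name}.tsv") as tmp:
                frame.to_csv(tmp, sep="\t", index=False)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def initial_state(dataset: ExpressionDataset, phi0: float | None = None) -> ModelState:
    """Data-driven warm start.

    s from the empirical per-cell capture proportion of spike-in molecules,
    phi from the biological median-of-ratios factors divided by s (rescaled
    to sum to phi0, default n), mu from size-factor-scaled mean counts,
    delta and theta from method-of-moments dispersions (delta floor-clamped
    at 1e-3; theta from the spike-in genes' excess variance) and nu = s.
    """
    n = dataset.n
    if phi0 is None:
        phi0 = float(n)
    bio = ~dataset.is_technical
    tech = dataset.is_technical
    xb = dataset.counts[bio].astype(float)
    xt = dataset.counts[tech].astype(float)
    spike = dataset.spike_input[tech]

    s = xt.sum(axis=0) / spike.sum()
    s = np.clip(s, max(1e-3, 0.01 * max(np.median(s), 1e-3)), None)

    omega_B, n_usable = deseq_size_factors(xb)
    if n_usable == 0 or not np.all(np.isfinite(omega_B)):
        omega_B = np.ones(n)
    phi = omega_B / s
    phi = phi0 * phi / phi.sum()
    kappa = np.log(phi) - np.log(phi[0])
    kappa[0] = 0.0

    denom = phi * s
    mu_b = (xb / denom[None, :]).mean(axis=1)
    mu_b = np.clip(mu_b, 1e-8, None)

    y = xb / denom[None, :]
    m = y.mean(axis=1)
    v = y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = (v - m) / m**2
    delta = np.clip(np.nan_to_num(mom, nan=0.0), 1e-3, 50.0)

    # unexplained-noise warm start: spike-in counts are Poisson(nu_j mu_i),
    # so their per-gene excess variance over the squared mean estimates theta
    yt = xt / s[None, :]
    mt = yt.mean(axis=1)
    vt = yt.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # Var(x/s) ~ mu * mean(1/s) + theta * mu^2 for Poisson-Gamma counts
        theta_mom = (vt - mt * np.mean(1.0 / s)) / mt**2
    theta_mom = theta_mom[np.isfinite(theta_mom)]
    theta0 = float(np.clip(np.median(theta_mom), 0.02, 5.0)) if theta_mom.size else 0.5

    mu = np.empty(dataset.q)
    mu[bio] = mu_b
    mu[tech] = spike
    return ModelState(
        mu=mu,
        delta=delta,
        phi=phi,
        kappa=kappa,
        s=s,
        theta=theta0,
        nu=s.copy(),
        is_technical=dataset.is_technical.copy(),
        phi0=phi0,
    )


def _initial_log_steps(
    dataset: ExpressionDataset, config: McmcConfig, state: ModelState
) -> dict:
    """Fisher-informed initial proposal scales (adaptation refines them).

    Overdispersion caps the information a count carries about log-scale
    location parameters: a count x with dispersion delta contributes roughly
    x / (1 + delta x) rather than x.  Scales start at 2.4 x the resulting
    posterior-sd guesses (2.38/sqrt(dim) x sd for the joint kappa block).
    """
    n = dataset.n
    bio = ~dataset.is_technical
    xb = dataset.counts[bio].astype(float)
    xt = dataset.counts[~bio].astype(float)
    delta0 = state.delta
    rowsum_b = xb.sum(axis=1)
    info_bio = (xb / (1.0 + delta0[:, None] * xb)).sum(axis=0)  # per cell
    info_all = info_bio + xt.sum(axis=0)
    theta0 = max(state.theta, 0.1)
    steps = {
        "mu": np.log(2.4 * np.sqrt(1.0 / (rowsum_b + 1.0) + delta0 / n)),
        "delta": np.full(int(bio.sum()), np.log(max(2.4 * np.sqrt(2.0 / n), 0.3))),
        "nu": np.log(2.4 / np.sqrt(info_all + 1.0)),
        "s": np.full(n, np.log(2.4 * np.sqrt(theta0 / (1.0 + theta0)))),
        "theta": np.array([np.log(max(2.4 * np.sqrt(2.0 / n), 0.2))]),
        # conditional information about kappa_j: overdispersion-capped for the
        # marginalised kernel, full Poisson (given rho) for the explicit one
        "kappa": np.array(
            [
                np.log(
                    2.38
                    / np.sqrt(max(n - 1, 1))
                    * float(
                        np.median(
                            1.0
                            / np.sqrt(
                                (info_bio if config.marginalise_rho else xb.sum(axis=0)) + 1.0
                            )
                        )
                    )
                )
            ]
        ),
    }
    if config.initial_log_step:
        for k, v in config.initial_log_step.items():
            steps[k] = np.full_like(steps[k], float(v))
    return steps


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def run_mcmc(
    dataset: ExpressionDataset,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
) -> ChainStore:
    """Fit the model by MCMC and return the thinned post-burn-in draws.

    The dataset must satisfy the posterior-propriety condition (every
    biological gene expressed in at least one cell) and contain at least one
    technical gene; violations raise with the offending gene names.  Each
    sweep updates, in order, mu, delta, nu, s, theta, kappa (and rho last in
    the explicit variant); technical-gene rates stay fixed at the spike-in
    input throughout.
    """
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    dataset.validate(require_expressed=True)
    if config.prior_only and not config.marginalise_rho:
        raise NotImplementedError("prior-only mode is implemented for the marginalised kernel")

    bio = ~dataset.is_technical
    tech = dataset.is_technical
    xb = dataset.counts[bio].astype(np.float64)
    xt = dataset.counts[tech].astype(np.float64)
    state = initial_state(dataset)
    steps = _initial_log_steps(dataset, config, state)
    q0, n = xb.shape
    rng = np.random.Generator(np.random.Philox(config.seed))

    mu_full = np.concatenate([state.mu[bio], state.mu[tech]])
    if config.marginalise_rho:
        dim = _mcmc_marginal.noise_dim(q0, n)
        normals = rng.standard_normal((config.n_iter, dim))
        logu = np.log(rng.random((config.n_iter, dim)))
        res = _mcmc_marginal.run_marginal_sweeps(
            xb,
            xt,
            mu_full.copy(),
            state.delta.copy(),
            state.kappa.copy(),
            state.s.copy(),
            float(state.theta),
            state.nu.copy(),
            float(state.phi0),
            priors.delta_shape,
            priors.delta_rate,
            priors.s_shape,
            priors.s_rate,
            priors.theta_shape,
            priors.theta_rate,
            priors.phi_concentration,
            priors.mu_max,
            config.n_iter,
            config.burn_in,
            config.thin,
            config.adapt_batch,
            config.target_accept,
            steps["mu"],
            steps["delta"],
            steps["nu"],
            steps["s"],
            steps["theta"],
            steps["kappa"],
            normals,
            logu,
            not config.prior_only,
        )
        (mu_d, delta_d, phi_d, s_d, nu_d, theta_d) = res[:6]
        acceptance = dict(zip(("mu", "delta", "nu", "s", "theta", "kappa"), res[6:12]))
        batch_log = res[12]
    else:
        rho0 = np.ones((q0, n))
        out, acceptance = _mcmc_explicit.run_explicit_sweeps(
            xb,
            xt,
            state.mu[bio].copy(),
            state.mu[tech].copy(),
            state.delta.copy(),
            state.kappa.copy(),
            state.s.copy(),
            float(state.theta),
            state.nu.copy(),
            rho0,
            float(state.phi0),
            priors,
            config.n_iter,
            config.burn_in,
            config.thin,
            config.adapt_batch,
            config.target_accept,
            {k: steps[k] for k in ("delta", "s", "theta", "kappa")},
            rng,
        )
        mu_d, delta_d = out["mu"], out["delta"]
        phi_d, s_d, nu_d, theta_d = out["phi"], out["s"], out["nu"], out["theta"]
        batch_log = None

    for name, arr in (("mu", mu_d), ("delta", delta_d), ("theta", theta_d)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite draws in {name}; diagnostic state dumped")
    return ChainStore(
        mu=mu_d,
        delta=delta_d,
        phi=phi_d,
        s=s_d,
        nu=nu_d,
        theta=theta_d,
        bio_gene_ids=dataset.gene_ids[bio],
        tech_gene_ids=dataset.gene_ids[tech],
        spike_mu=dataset.spike_input[tech],
        phi0=float(state.phi0),
        priors=priors,
        config=config,
        dataset_digest=dataset.digest(),
        acceptance=acceptance,
        batch_log=batch_log,
    )


# ---------------------------------------------------------------------------
# single-site conditionals (reference implementations; used as test oracles)
# ---------------------------------------------------------------------------

def _bio_index(dataset: ExpressionDataset, gene: int) -> int:
    if dataset.is_technical[gene]:
        raise ValueError("gene is technical")
    return int((~dataset.is_technical[:gene]).sum())


def gibbs_nu(dataset: ExpressionDataset, state: ModelState, cell: int, rng) -> float:
    """Draw nu_j from its exact full conditional (explicit-rho variant).

    Gamma(1/theta + sum_i x_ij,
          1/(s_j theta) + sum_bio phi_j mu_i rho_ij + sum_tech mu_i);
    theta = 0 degenerates to nu_j = s_j.
    """
    if state.theta == 0:
        return float(state.s[cell])
    bio = ~dataset.is_technical
    shape = 1.0 / state.theta + dataset.counts[:, cell].sum()
    rate = 1.0 / (state.s[cell] * state.theta) + state.mu[~bio].sum()
    if bio.any():
        if state.rho is None:
            raise ValueError("explicit-rho state required")
        rate += state.phi[cell] * float(state.mu[bio] @ state.rho[:, cell])
    return float(rng.gamma(shape) / rate)


def gibbs_rho(dataset: ExpressionDataset, state: ModelState, gene: int, cell: int, rng) -> float:
    """Draw rho_ij ~ Gamma(1/delta_i + x_ij, 1/delta_i + phi_j nu_j mu_i);
    delta_i = 0 returns the degenerate value 1."""
    k = _bio_index(dataset, gene)
    d = state.delta[k]
    if d == 0:
        return 1.0
    shape = 1.0 / d + dataset.counts[gene, cell]
    rate = 1.0 / d + state.phi[cell] * state.nu[cell] * state.mu[gene]
    return float(rng.gamma(shape) / rate)


def gibbs_mu(dataset: ExpressionDataset, state: ModelState, gene: int, rng) -> float:
    """Draw mu_i ~ Gamma(sum_j x_ij, sum_j phi_j nu_j rho_ij), the conjugate
    conditional under the scale-invariant 1/mu prior (biological genes only).

    An all-zero gene would give shape 0 (no conditional exists); the
    posterior-propriety validation rejects such datasets before sampling.
    """
    k = _bio_index(dataset, gene)
    total = dataset.counts[gene].sum()
    if total == 0:
        raise ValueError(
            "all-zero biological gene reached the sampler; dataset validation "
            "should have rejected it (posterior propriety)"
        )
    if state.rho is None:
        raise ValueError("explicit-rho state required")
    rate = float((state.phi * state.nu) @ state.rho[k])
    return float(rng.gamma(float(total)) / rate)


# ---------------------------------------------------------------------------
# generic Metropolis block (reference implementation)
# ---------------------------------------------------------------------------

def block_log_target(
    block,
    dataset: ExpressionDataset,
    state: ModelState,
    priors: PriorSpec,
    marginalise_rho: bool = True,
) -> float:
    """Log full-conditional density (up to a constant) of one block, in the
    block's sampling coordinates (log scale for theta/delta/s; natural scale
    for kappa with the softmax Jacobian folded into the phi term)."""
    ll = marginal_loglik(dataset, state, marginalise_rho=marginalise_rho)
    name = block if isinstance(block, str) else block[0]
    if name == "theta":
        th = state.theta
        inv = 1.0 / th
        pr = priors.theta_shape * np.log(th) - priors.theta_rate * th
        pr += float(
            np.sum(-inv * np.log(state.s * th) - gammaln(inv) + inv * np.log(state.nu))
            - np.sum(state.nu / (state.s * th))
        )
    elif name == "delta":
        i = block[1]
        d = state.delta[i]
        pr = priors.delta_shape * np.log(d) - priors.delta_rate * d
    elif name == "s":
        j = block[1]
        sj = state.s[j]
        inv = 1.0 / state.theta
        pr = (priors.s_shape - inv) * np.log(sj) - priors.s_rate * sj - state.nu[j] / (
            sj * state.theta
        )
    elif name == "kappa":
        pr = priors.phi_concentration * float(np.log(state.phi / state.phi0).sum())
    else:
        raise ValueError(f"unknown block {block!r}")
    return ll + float(pr)


def mh_update(
    block,
    state: ModelState,
    dataset: ExpressionDataset,
    step: AdaptiveStep,
    rng,
    priors: PriorSpec | None = None,
    marginalise_rho: bool = True,
) -> tuple[ModelState, bool]:
    """One random-walk Metropolis move on a single block.

    ``block`` is "theta", ("delta", i), ("s", j) or "kappa".  Positive
    scalars are proposed on the log scale (Jacobian included); kappa is a
    joint proposal on the natural scale with kappa[0] held at 0, and phi is
    recomputed from kappa for every proposal.  A non-finite proposal density
    is an automatic rejection.  Rejection returns the original state object
    unchanged (phi bit-identical).
    """
    priors = priors or PriorSpec()
    sd = np.exp(step.log_step)
    cur = block_log_target(block, dataset, state, priors, marginalise_rho)
    name = block if isinstance(block, str) else block[0]
    prop = dataclasses.replace(state)
    if name == "theta":
        prop.theta = float(state.theta * np.exp(sd * rng.standard_normal()))
    elif name == "delta":
        i = block[1]
        prop.delta = state.delta.copy()
        prop.delta[i] = state.delta[i] * np.exp(sd * rng.standard_normal())
    elif name == "s":
        j = block[1]
        prop.s = state.s.copy()
        prop.s[j] = state.s[j] * np.exp(sd * rng.standard_normal())
    elif name == "kappa":
        prop.kappa = state.kappa.copy()
        prop.kappa[1:] += sd * rng.standard_normal(len(state.kappa) - 1)
        prop.phi = phi_from_kappa(prop.kappa, state.phi0)
    else:
        raise ValueError(f"unknown block {block!r}")
    new = block_log_target(block, dataset, prop, priors, marginalise_rho)
    if name in ("theta", "delta", "s"):
        # log-scale proposal Jacobian
        if name == "theta":
            new += np.log(prop.theta) - np.log(state.theta)
        elif name == "delta":
            new += np.log(prop.delta[block[1]]) - np.log(state.delta[block[1]])
        else:
            new += np.log(prop.s[block[1]]) - np.log(state.s[block[1]])
    delta_lt = new - cur
    if np.isfinite(delta_lt) and np.log(rng.random()) < delta_lt:
        return prop, True
    return state, False


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def chain_diagnostics(chains: ChainStore, ess_floor: float = 100.0) -> pd.DataFrame:
    """Effective sample size and split-chain R-hat per scalar parameter.

    The single chain is split into two halves for the R-hat computation.
    Constant (degenerate) chains are flagged and reported with ESS equal to
    the draw count; parameters with ESS below ``ess_floor`` are flagged.
    """
    import arviz as az

    if chains.n_draws < 2:
        raise ValueError("need at least 2 retained draws")
    names: list[str] = []
    cols: list[np.ndarray] = []
    for fam, labels in (
        ("theta", [""]),
        ("mu", chains.bio_gene_ids),
        ("delta", chains.bio_gene_ids),
        ("phi", range(chains.n_cells)),
        ("s", range(chains.n_cells)),
        ("nu", range(chains.n_cells)),
    ):
        arr = getattr(chains, fam)
        arr = arr[:, None] if arr.ndim == 1 else arr
        for k, lab in enumerate(labels):
            names.append(fam if lab == "" else f"{fam}[{lab}]")
            cols.append(arr[:, k])
    mat = np.column_stack(cols)  # (draws, params)
    degenerate = np.ptp(mat, axis=0) == 0.0

    ess = np.array([float(az.ess(mat[:, k])) for k in range(mat.shape[1])])
    t = chains.n_draws
    if t >= 4:
        half = t // 2
        split = np.stack([mat[:half], mat[half : 2 * half]], axis=0)  # (2, half, P)
        rhat = np.array([float(az.rhat(split[:, :, k])) for k in range(mat.shape[1])])
    else:
        rhat = np.full(mat.shape[1], np.nan)
    ess = np.where(degenerate, float(t), ess)
    rhat = np.where(degenerate, np.nan, rhat)
    return pd.DataFrame(
        {
            "parameter": names,
            "ess": ess,
            "rhat": rhat,
            "degenerate": degenerate,
            "low_ess": (~degenerate) & (ess < ess_floor),
        }
    )
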