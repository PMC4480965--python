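"""Hierarchical Poisson-Gamma model for spike-in-annotated counts.

The count of gene *i* in cell *j* is modelled as

    X_ij | nu_j, rho_ij ~ Poisson(phi_j^{I_i} nu_j mu_i rho_ij^{I_i})

where I_i = 1 for biological genes and 0 for technical (spike-in) genes,
mu_i is the normalised expression rate (known and equal to the spike-in
input for technical genes), phi_j is the cell's total-mRNA-content size
factor, and two multiplicative Gamma random effects carry the noise:

    nu_j  | s_j, theta ~ Gamma(1/theta, 1/(s_j theta))   (shape-rate)
    rho_ij| delta_i    ~ Gamma(1/delta_i, 1/delta_i)

so that E(nu_j) = s_j, Var(nu_j) = s_j^2 theta (cell-level unexplained
technical noise, strength theta) and E(rho_ij) = 1, Var(rho_ij) = delta_i
(gene-level biological cell-to-cell heterogeneity).  All Gamma laws in this
package are shape-rate.  Integrating rho out gives a negative binomial with
mean phi_j nu_j mu_i and dispersion delta_i for biological counts.

Marginally over both effects the moments are

    E(X_ij)   = phi_j^{I_i} s_j mu_i
    Var(X_ij) = m + theta m^2 + I_i delta_i (theta+1) m^2,   m = E(X_ij)

whose three addends are the Poisson baseline, the technical inflation and
the biological heterogeneity component.  Evaluated at a reference cell with
phi_j s_j replaced by the across-cell median (phi s)*, the biological share
of the variance is

    sigma_i = delta_i (theta+1) / ( [(phi s)* mu_i]^{-1} + theta
                                     + delta_i (theta+1) )

which is the statistic the detection layer thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .dataset import ExpressionDataset

__all__ = [
    "ModelState",
    "VarianceDecomposition",
    "expected_count",
    "count_variance",
    "count_variance_components",
    "biological_share",
    "hvg_contour_delta",
    "phi_from_kappa",
    "nb_logpmf",
    "marginal_loglik",
    "variance_decomposition",
]

_PHI_SUM_RTOL = 1e-8


@dataclass
class ModelState:
    """One joint configuration of all model parameters and latents.

    ``mu`` has length q (technical entries fixed at the spike-in input),
    ``delta`` has one entry per biological gene (in dataset gene order),
    ``phi``/``kappa``/``s``/``nu`` have length n, ``theta`` is scalar and
    ``rho`` (biological genes x cells) is present only in the explicit-
    augmentation sampler variant.
    """

    mu: np.ndarray
    delta: np.ndarray
    phi: np.ndarray
    kappa: np.ndarray
    s: np.ndarray
    theta: float
    nu: np.ndarray
    is_technical: np.ndarray
    phi0: float
    rho: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        self.is_technical = np.asarray(self.is_technical, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.phi)
        if self.kappa[0] != 0.0:
            raise ValueError("identifiability anchor violated: kappa[0] must be 0")
        if not np.isclose(self.phi.sum(), self.phi0, rtol=_PHI_SUM_RTOL):
            raise ValueError("sum of phi must equal phi0")
        if len(self.kappa) != n or len(self.s) != n or len(self.nu) != n:
            raise ValueError("per-cell arrays have inconsistent lengths")
        if len(self.delta) != int((~self.is_technical).sum()):
            raise ValueError("delta must have one entry per biological gene")
        if np.any(self.mu <= 0) or np.any(self.delta < 0) or self.theta < 0:
            raise ValueError("positivity constraints violated")

    def check_matches(self, dataset: ExpressionDataset) -> None:
        if len(self.mu) != dataset.q or len(self.phi) != dataset.n:
            raise ValueError("state dimensions do not match dataset")
        if not np.array_equal(self.is_technical, dataset.is_technical):
            raise ValueError("technical indicators differ between state and dataset")
        if not np.array_equal(
            self.mu[dataset.is_technical], dataset.spike_input[dataset.is_technical]
        ):
            raise ValueError("technical mu must equal the dataset's spike_input")


@dataclass
class VarianceDecomposition:
    """Per-biological-gene variance shares at the reference cell."""

    baseline_share: np.ndarray
    technical_share: np.ndarray
    biological_share: np.ndarray
    sigma: np.ndarray
    phi_s_star: float
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def expected_count(state: ModelState, gene: int, cell: int) -> float:
    """Marginal mean count phi_j^{I_i} s_j mu_i."""
    phi = 1.0 if state.is_technical[gene] else state.phi[cell]
    return float(phi * state.s[cell] * state.mu[gene])


def count_variance_components(
    state: ModelState, gene: int, cell: int
) -> tuple[float, float, float]:
    """The three variance addends: (Poisson baseline, technical, biological)."""
    m = expected_count(state, gene, cell)
    technical = state.theta * m * m
    if state.is_technical[gene]:
        biological = 0.0
    else:
        bio_index = int((~state.is_technical[:gene]).sum())
        biological = state.delta[bio_index] * (state.theta + 1.0) * m * m
    return m, technical, biological


def count_variance(state: ModelState, gene: int, cell: int) -> float:
    """Marginal count variance (sum of the three components)."""
    return float(sum(count_variance_components(state, gene, cell)))


# ---------------------------------------------------------------------------
# biological variance share and HVG contours
# ---------------------------------------------------------------------------

def biological_share(mu_i, delta_i, theta, phi_s_star):
    """Biological share sigma_i of the count variance at the reference cell.

    sigma_i = delta_i (theta+1) / ( [(phi s)* mu_i]^{-1} + theta
                                     + delta_i (theta+1) ),  in [0, 1].
    """
    mu_i = np.asarray(mu_i, dtype=float)
    phi_s_star = np.asarray(phi_s_star, dtype=float)
    if np.any(mu_i <= 0) or np.any(phi_s_star <= 0):
        raise ValueError("mu_i and phi_s_star must be positive")
    delta_i = np.asarray(delta_i, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(delta_i < 0) or np.any(theta < 0):
        raise ValueError("delta_i and theta must be non-negative")
    num = delta_i * (theta + 1.0)
    out = num / (1.0 / (phi_s_star * mu_i) + theta + num)
    return out if out.ndim else float(out)


def hvg_contour_delta(mu_i, theta, phi_s_star, gamma):
    """The delta at which sigma_i equals ``gamma`` exactly.

    delta = [gamma / (1 - gamma)] * [ ((phi s)* mu_i)^{-1} + theta ] / (1 + theta)

    Genes above this contour in the (mu, delta) plane have a biological
    variance share exceeding gamma; the contour decreases with mu_i.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0) or np.any(gamma >= 1):
        raise ValueError("gamma must lie in [0, 1); the contour diverges at 1")
    mu_i = np.asarray(mu_i, dtype=float)
    phi_s_star = np.asarray(phi_s_star, dtype=float)
    if np.any(mu_i <= 0) or np.any(phi_s_star <= 0):
        raise ValueError("mu_i and phi_s_star must be positive")
    theta = np.asarray(theta, dtype=float)
    out = (gamma / (1.0 - gamma)) * (1.0 / (phi_s_star * mu_i) + theta) / (1.0 + theta)
    return out if out.ndim else float(out)


def phi_from_kappa(kappa: np.ndarray, phi0: float) -> np.ndarray:
    """Size factors from the unconstrained reparameterisation.

    phi_j = phi0 * exp(kappa_j) / sum_k exp(kappa_k), with kappa_1 = 0 as the
    identifiability anchor, so that sum_j phi_j = phi0.  Exponentials are
    max-shifted for stability.
    """
    kappa = np.asarray(kappa, dtype=float)
    if kappa[0] != 0.0:
        raise ValueError("kappa[0] must be 0 (identifiability anchor)")
    z = np.exp(kappa - kappa.max())
    return phi0 * z / z.sum()


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------

def nb_logpmf(x, mean, delta):
    """Negative-binomial log-pmf with mean ``mean`` and dispersion ``delta``.

    Var = mean + delta * mean^2; delta = 0 is the exact Poisson limit.  For
    very small positive delta (inverse size r = 1/delta > 1e6) a series form
    avoids catastrophic cancellation in lgamma differences.
    """
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    delta = np.asarray(delta, dtype=float)
    x, mean, delta = np.broadcast_arrays(x, mean, delta)
    out = np.empty(x.shape, dtype=float)

    pois = delta == 0.0
    tiny = (delta > 0.0) & (delta < 1e-6)
    reg = ~pois & ~tiny

    with np.errstate(divide="ignore", invalid="ignore"):
        if pois.any():
            xm, mm = x[pois], mean[pois]
            out[pois] = np.where(xm > 0, xm * np.log(mm), 0.0) - mm - gammaln(xm + 1.0)
        if reg.any():
            xr, mr, dr = x[reg], mean[reg], delta[reg]
            r = 1.0 / dr
            c = gammaln(xr + r) - gammaln(r) - xr * np.log(r)
            out[reg] = (
                c
                - gammaln(xr + 1.0)
                + np.where(xr > 0, xr * np.log(mr), 0.0)
                - (xr + r) * np.log1p(mr * dr)
            )
        if tiny.any():
            xt, mt, dt = x[tiny], mean[tiny], delta[tiny]
            # lgamma(x+r) - lgamma(r) - x log r = sum_k log(1 + k*delta) ~ delta*x*(x-1)/2
            c = dt * xt * (xt - 1.0) / 2.0
            out[tiny] = (
                c
                - gammaln(xt + 1.0)
                + np.where(xt > 0, xt * np.log(mt), 0.0)
                - (xt + 1.0 / dt) * np.log1p(mt * dt)
            )
    return out if out.ndim else float(out)


def _poisson_logpmf(x, mean):
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, x * np.log(mean), 0.0) - mean - gammaln(x + 1.0)


def marginal_loglik(
    dataset: ExpressionDataset, state: ModelState, marginalise_rho: bool = True
) -> float:
    """Log density of the counts given (mu, delta, phi, s, theta, nu).

    With ``marginalise_rho=True`` the biological random effects rho are
    integrated out analytically, giving negative-binomial terms with mean
    phi_j nu_j mu_i and dispersion delta_i; technical genes contribute
    Poisson(nu_j mu_i) terms.  With the flag off, biological terms are
    Poisson conditional on the explicit ``state.rho`` plus the Gamma prior
    density of rho (delta_i = 0 entries are the degenerate rho = 1 limit).
    """
    state.check_matches(dataset)
    bio = ~dataset.is_technical
    xb = dataset.counts[bio].astype(float)
    xt = dataset.counts[dataset.is_technical].astype(float)
    mu_b = state.mu[bio][:, None]
    mu_t = state.mu[dataset.is_technical][:, None]
    pn = state.phi * state.nu  # length n

    ll = float(_poisson_logpmf(xt, mu_t * state.nu[None, :]).sum())
    if marginalise_rho:
        mean_b = mu_b * pn[None, :]
        ll += float(nb_logpmf(xb, mean_b, state.delta[:, None]).sum())
    else:
        if state.rho is None:
            raise ValueError("explicit-rho likelihood requested but state.rho is None")
        rho = np.asarray(state.rho, dtype=float)
        mean_b = mu_b * pn[None, :] * rho
        ll += float(_poisson_logpmf(xb, mean_b).sum())
        d = state.delta[:, None]
        pos = np.broadcast_to(d > 0, rho.shape)
        if pos.any():
            dd = np.broadcast_to(d, rho.shape)[pos]
            rr = rho[pos]
            r = 1.0 / dd
            ll += float(
                (r * np.log(r) - gammaln(r) + (r - 1.0) * np.log(rr) - r * rr).sum()
            )
        if np.any(~pos & ~np.isclose(rho, 1.0)):
            raise ValueError("delta = 0 requires rho = 1 (degenerate limit)")
    return ll


def variance_decomposition(
    dataset: ExpressionDataset, state: ModelState
) -> VarianceDecomposition:
    """Decompose each biological gene's variance at the reference cell.

    The reference cell has phi_j s_j equal to (phi s)*, the across-cell
    median, so the three shares are proportional to
    [(phi s)* mu_i]^{-1}, theta and delta_i (theta + 1).
    """
    state.check_matches(dataset)
    phi_s_star = float(np.median(state.phi * state.s))
    bio = ~dataset.is_technical
    mu = state.mu[bio]
    inv_m = 1.0 / (phi_s_star * mu)
    bio_term = state.delta * (state.theta + 1.0)
    total = inv_m + state.theta + bio_term
    return VarianceDecomposition(
        baseline_share=inv_m / total,
        technical_share=state.theta / total,
        biological_share=bio_term / total,
        sigma=bio_term / total,
        phi_s_star=phi_s_star,
        gene_ids=dataset.gene_ids[bio],
    )
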