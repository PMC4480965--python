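"""Explicit-augmentation sampler: the biological random effects rho are kept
as latent variables, giving conjugate Gibbs updates for rho, mu and nu.

This variant targets exactly the same posterior as the marginalised
(negative-binomial) kernel and serves as its oracle in tests; it is written
in plain vectorised numpy and intended for small instances.  delta, s, theta
and kappa have no conjugate conditional in either variant and use the same
adaptive random-walk Metropolis moves.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaincinv, gammaln

from ._mcmc_marginal import _phi_from_kappa  # numba fn, works on ndarray


def _rw_accept(logu, delta_log_target):
    ok = np.isfinite(delta_log_target)
    return ok & (logu < delta_log_target)


def truncated_gamma(rng, shape, rate, upper):
    """Exact draw from Gamma(shape, rate) truncated to (0, upper].

    Inverse-CDF sampling; the truncation implements the bounded flat prior
    on the expression rates (it essentially never binds for realistic data
    but keeps the posterior proper on tiny instances).
    """
    cap = gammainc(shape, rate * upper)
    u = rng.random(np.shape(shape)) * cap
    return gammaincinv(shape, u) / rate


def run_explicit_sweeps(
    xb,
    xt,
    mu_b,
    mu_t,
    delta,
    kappa,
    s,
    theta,
    nu,
    rho,
    phi0,
    priors,
    n_iter,
    burn_in,
    thin,
    adapt_batch,
    target_accept,
    steps,
    rng,
):
    """Run the explicit-rho sweeps; returns draw arrays and acceptance stats.

    ``steps`` is a dict of log-step arrays for the Metropolis blocks
    (delta, s, theta, kappa) and is adapted in place during burn-in.
    """
    q0, n = xb.shape
    a_d, b_d = priors.delta_shape, priors.delta_rate
    a_s, b_s = priors.s_shape, priors.s_rate
    a_t, b_t = priors.theta_shape, priors.theta_rate
    dir_c = priors.phi_concentration

    rowsum_b = xb.sum(axis=1)
    colsum_all = xb.sum(axis=0) + xt.sum(axis=0)
    colsum_b = xb.sum(axis=0)
    sum_mu_t = mu_t.sum()
    phi = _phi_from_kappa(kappa, phi0)

    n_keep = (n_iter - burn_in) // thin
    out = {
        "mu": np.empty((n_keep, q0)),
        "delta": np.empty((n_keep, q0)),
        "phi": np.empty((n_keep, n)),
        "s": np.empty((n_keep, n)),
        "nu": np.empty((n_keep, n)),
        "theta": np.empty(n_keep),
    }
    bat = {k: np.zeros_like(steps[k]) for k in steps}
    post = {k: np.zeros_like(steps[k]) for k in steps}

    keep = 0
    for t in range(n_iter):
        pn = phi * nu

        # Gibbs: mu_i ~ Gamma(sum_j x_ij, sum_j phi_j nu_j rho_ij)
        # (scale-invariant 1/mu prior), truncated at the prior's safety bound
        rate_mu = rho @ pn
        mu_b = truncated_gamma(rng, rowsum_b, rate_mu, priors.mu_max)

        # MH: delta (log scale); target uses the Gamma(1/d, 1/d) rho density
        z = rng.standard_normal(q0)
        logu = np.log(rng.random(q0))
        d_new = delta * np.exp(np.exp(steps["delta"]) * z)
        slog_rho = np.log(rho).sum(axis=1)
        srho = rho.sum(axis=1)

        def _rho_loglik(d):
            r = 1.0 / d
            return n * (r * np.log(r) - gammaln(r)) + (r - 1.0) * slog_rho - r * srho

        dlt = (
            _rho_loglik(d_new)
            - _rho_loglik(delta)
            + a_d * (np.log(d_new) - np.log(delta))
            - b_d * (d_new - delta)
        )
        acc = _rw_accept(logu, dlt)
        delta = np.where(acc, d_new, delta)
        (bat if t < burn_in else post)["delta"][acc] += 1.0

        # Gibbs: nu_j ~ Gamma(1/theta + sum_i x_ij,
        #                     1/(s_j theta) + phi_j sum_bio mu_i rho_ij + sum_tech mu_i)
        rate_nu = 1.0 / (s * theta) + phi * (mu_b @ rho) + sum_mu_t
        nu = rng.gamma(1.0 / theta + colsum_all) / rate_nu

        # MH: s (log scale; only the nu prior and the s prior involve s)
        z = rng.standard_normal(n)
        logu = np.log(rng.random(n))
        s_new = s * np.exp(np.exp(steps["s"]) * z)
        dlt = (
            (a_s - 1.0 / theta) * (np.log(s_new) - np.log(s))
            - b_s * (s_new - s)
            - (nu / theta) * (1.0 / s_new - 1.0 / s)
        )
        acc = _rw_accept(logu, dlt)
        s = np.where(acc, s_new, s)
        (bat if t < burn_in else post)["s"][acc] += 1.0

        # MH: theta (log scale)
        z = float(rng.standard_normal())
        logu = float(np.log(rng.random()))
        th_new = theta * np.exp(np.exp(steps["theta"][0]) * z)

        def _nu_loglik(th):
            inv = 1.0 / th
            return float(
                np.sum(-inv * np.log(s * th) - gammaln(inv) + inv * np.log(nu) - nu / (s * th))
            )

        dlt = (
            _nu_loglik(th_new)
            - _nu_loglik(theta)
            + a_t * (np.log(th_new) - np.log(theta))
            - b_t * (th_new - theta)
        )
        if np.isfinite(dlt) and logu < dlt:
            theta = th_new
            (bat if t < burn_in else post)["theta"][0] += 1.0

        # MH: kappa joint block (natural scale, kappa[0] fixed at 0)
        z = rng.standard_normal(n - 1)
        logu = float(np.log(rng.random()))
        kn = kappa.copy()
        kn[1:] += np.exp(steps["kappa"][0]) * z
        phin = _phi_from_kappa(kn, phi0)
        a_col = nu * (mu_b @ rho)  # sum_i mu_i rho_ij nu_j per cell
        dlt = float(
            np.sum((colsum_b + dir_c) * (np.log(phin) - np.log(phi)))
            - np.sum((phin - phi) * a_col)
        )
        if np.isfinite(dlt) and logu < dlt:
            kappa, phi = kn, phin
            (bat if t < burn_in else post)["kappa"][0] += 1.0

        # Gibbs: rho_ij ~ Gamma(1/delta_i + x_ij, 1/delta_i + phi_j nu_j mu_i)
        inv_d = (1.0 / delta)[:, None]
        rate_rho = inv_d + mu_b[:, None] * (phi * nu)[None, :]
        rho = rng.gamma(inv_d + xb) / rate_rho

        # adaptation (burn-in only)
        if t < burn_in and (t + 1) % adapt_batch == 0:
            b = (t + 1) // adapt_batch
            inc = min(0.01, 1.0 / np.sqrt(b))
            for k in steps:
                frac = bat[k] / adapt_batch
                steps[k] += np.where(frac > target_accept, inc, -inc)
                bat[k][:] = 0.0

        if t >= burn_in and (t - burn_in) % thin == thin - 1:
            out["mu"][keep] = mu_b
            out["delta"][keep] = delta
            out["phi"][keep] = phi
            out["s"][keep] = s
            out["nu"][keep] = nu
            out["theta"][keep] = theta
            keep += 1

    n_post = n_iter - burn_in
    accept = {k: post[k] / n_post for k in post}
    return out, accept
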