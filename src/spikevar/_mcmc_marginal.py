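"""Compiled sweep kernel for the marginalised (negative-binomial) sampler.

All Metropolis blocks propose on the log scale (kappa on the natural scale)
and the acceptance ratios are written in incremental form: terms that cancel
between the current and proposed state are never evaluated.  Proposal noise
is pre-drawn outside (from a counter-based Philox stream) and passed in, so
the kernel itself is purely deterministic.

Noise layout per sweep (row of ``normals`` / ``logu``), with q0 biological
genes and n cells:

    [0, q0)              mu
    [q0, 2 q0)           delta
    [2 q0, 2 q0 + n)     nu
    [2 q0+n, 2 q0+2n)    s
    2 q0 + 2 n           theta
    [2 q0+2n+1, 2 q0+3n) kappa (joint block, n-1 normals, 1 uniform)
"""

import math

import numpy as np
from numba import njit

BLOCKS = ("mu", "delta", "nu", "s", "theta", "kappa")


def noise_dim(q0: int, n: int) -> int:
    return 2 * q0 + 3 * n


@njit(cache=True)
def _lgamma_ratio(x, r):
    # lgamma(x + r) - lgamma(r) - x*log(r); series form avoids cancellation
    # for large r (small dispersion).  x is a non-negative integer count.
    if x == 0.0:
        return 0.0
    if r > 1e6:
        return x * (x - 1.0) / (2.0 * r)
    return math.lgamma(x + r) - math.lgamma(r) - x * math.log(r)


@njit(cache=True)
def _phi_from_kappa(kappa, phi0):
    n = kappa.shape[0]
    mx = kappa[0]
    for j in range(1, n):
        if kappa[j] > mx:
            mx = kappa[j]
    z = np.empty(n)
    tot = 0.0
    for j in range(n):
        z[j] = math.exp(kappa[j] - mx)
        tot += z[j]
    for j in range(n):
        z[j] = phi0 * z[j] / tot
    return z


@njit(cache=True)
def _nu_logprior(nu_j, s_j, theta):
    # Gamma(1/theta, 1/(s_j theta)) log-density, constants in nu kept because
    # theta updates need them.
    inv = 1.0 / theta
    return (
        -inv * math.log(s_j * theta)
        - math.lgamma(inv)
        + inv * math.log(nu_j)
        - nu_j / (s_j * theta)
    )


@njit(cache=True)
def run_marginal_sweeps(
    xb,
    xt,
    mu,
    delta,
    kappa,
    s,
    theta,
    nu,
    phi0,
    a_d,
    b_d,
    a_s,
    b_s,
    a_t,
    b_t,
    dir_c,
    mu_max,
    n_iter,
    burn_in,
    thin,
    adapt_batch,
    target_accept,
    ls_mu,
    ls_delta,
    ls_nu,
    ls_s,
    ls_theta,
    ls_kappa,
    normals,
    logu,
    lik_on,
):
    q0, n = xb.shape
    qt = xt.shape[0]

    rowsum_b = np.zeros(q0)
    colsum_b = np.zeros(n)
    colsum_t = np.zeros(n)
    for i in range(q0):
        for j in range(n):
            rowsum_b[i] += xb[i, j]
            colsum_b[j] += xb[i, j]
    for i in range(qt):
        for j in range(n):
            colsum_t[j] += xt[i, j]
    sum_mu_t = 0.0
    # technical rates live in the tail of mu (after the q0 biological entries)
    for i in range(qt):
        sum_mu_t += mu[q0 + i]

    phi = _phi_from_kappa(kappa, phi0)

    n_keep = (n_iter - burn_in) // thin
    mu_draws = np.empty((n_keep, q0))
    delta_draws = np.empty((n_keep, q0))
    phi_draws = np.empty((n_keep, n))
    s_draws = np.empty((n_keep, n))
    nu_draws = np.empty((n_keep, n))
    theta_draws = np.empty(n_keep)

    # per-scalar-block acceptance counters: batch (adaptation) and post burn-in
    bat_mu = np.zeros(q0)
    bat_delta = np.zeros(q0)
    bat_nu = np.zeros(n)
    bat_s = np.zeros(n)
    bat_theta = np.zeros(1)
    bat_kappa = np.zeros(1)
    post_mu = np.zeros(q0)
    post_delta = np.zeros(q0)
    post_nu = np.zeros(n)
    post_s = np.zeros(n)
    post_theta = np.zeros(1)
    post_kappa = np.zeros(1)

    n_batches = burn_in // adapt_batch
    batch_log = np.zeros((n_batches, 6))

    keep = 0
    for t in range(n_iter):
        # ---- mu (biological genes; scale-invariant prior 1/mu) ------------
        # flat on log mu: Jacobian and prior cancel exactly under the
        # log-scale proposal, leaving the likelihood ratio alone
        for i in range(q0):
            step = math.exp(ls_mu[i])
            lm = math.log(mu[i])
            lm_new = lm + step * normals[t, i]
            mu_new = math.exp(lm_new)
            if mu_new > mu_max:  # safety bound of the prior support
                continue
            d = 0.0
            if lik_on:
                di = delta[i]
                ri = 1.0 / di
                acc = 0.0
                for j in range(n):
                    pn = phi[j] * nu[j]
                    acc += (xb[i, j] + ri) * (
                        math.log1p(mu_new * di * pn) - math.log1p(mu[i] * di * pn)
                    )
                d += rowsum_b[i] * (lm_new - lm) - acc
            if math.isfinite(d) and logu[t, i] < d:
                mu[i] = mu_new
                if t < burn_in:
                    bat_mu[i] += 1.0
                else:
                    post_mu[i] += 1.0

        # ---- delta (biological dispersion; Gamma(a_d, b_d) prior) ---------
        for i in range(q0):
            step = math.exp(ls_delta[i])
            ld = math.log(delta[i])
            ld_new = ld + step * normals[t, q0 + i]
            d_new = math.exp(ld_new)
            r_new = 1.0 / d_new
            r_old = 1.0 / delta[i]
            d = a_d * (ld_new - ld) - b_d * (d_new - delta[i])
            if lik_on:
                acc = 0.0
                for j in range(n):
                    x = xb[i, j]
                    m = mu[i] * phi[j] * nu[j]
                    if x > 0.0:
                        acc += _lgamma_ratio(x, r_new) - _lgamma_ratio(x, r_old)
                    acc -= (x + r_new) * math.log1p(m * d_new) - (
                        x + r_old
                    ) * math.log1p(m * delta[i])
                d += acc
            if math.isfinite(d) and logu[t, q0 + i] < d:
                delta[i] = d_new
                if t < burn_in:
                    bat_delta[i] += 1.0
                else:
                    post_delta[i] += 1.0

        # ---- nu (cell technical random effects) ---------------------------
        for j in range(n):
            step = math.exp(ls_nu[j])
            ln = math.log(nu[j])
            ln_new = ln + step * normals[t, 2 * q0 + j]
            nu_new = math.exp(ln_new)
            # prior including Jacobian: (1/theta) d(log nu) - d(nu)/(s theta)
            d = (1.0 / theta) * (ln_new - ln) - (nu_new - nu[j]) / (s[j] * theta)
            if lik_on:
                acc = 0.0
                for i in range(q0):
                    a = mu[i] * delta[i] * phi[j]
                    acc += (xb[i, j] + 1.0 / delta[i]) * (
                        math.log1p(a * nu_new) - math.log1p(a * nu[j])
                    )
                d += (
                    (colsum_b[j] + colsum_t[j]) * (ln_new - ln)
                    - sum_mu_t * (nu_new - nu[j])
                    - acc
                )
            if math.isfinite(d) and logu[t, 2 * q0 + j] < d:
                nu[j] = nu_new
                if t < burn_in:
                    bat_nu[j] += 1.0
                else:
                    post_nu[j] += 1.0

        # ---- s (capture efficiency; Gamma(a_s, b_s) prior) ----------------
        for j in range(n):
            step = math.exp(ls_s[j])
            lsj = math.log(s[j])
            ls_new = lsj + step * normals[t, 2 * q0 + n + j]
            s_new = math.exp(ls_new)
            d = (
                (a_s - 1.0 / theta) * (ls_new - lsj)
                - b_s * (s_new - s[j])
                - (nu[j] / theta) * (1.0 / s_new - 1.0 / s[j])
            )
            if math.isfinite(d) and logu[t, 2 * q0 + n + j] < d:
                s[j] = s_new
                if t < burn_in:
                    bat_s[j] += 1.0
                else:
                    post_s[j] += 1.0

        # ---- theta (Gamma(a_t, b_t) prior) --------------------------------
        it = 2 * q0 + 2 * n
        step = math.exp(ls_theta[0])
        lt = math.log(theta)
        lt_new = lt + step * normals[t, it]
        th_new = math.exp(lt_new)
        d = a_t * (lt_new - lt) - b_t * (th_new - theta)
        for j in range(n):
            d += _nu_logprior(nu[j], s[j], th_new) - _nu_logprior(nu[j], s[j], theta)
        if math.isfinite(d) and logu[t, it] < d:
            theta = th_new
            if t < burn_in:
                bat_theta[0] += 1.0
            else:
                post_theta[0] += 1.0

        # ---- kappa -> phi (joint block, natural scale, kappa[0] fixed) ----
        step = math.exp(ls_kappa[0])
        kn = kappa.copy()
        for j in range(1, n):
            kn[j] = kappa[j] + step * normals[t, it + j]
        phin = _phi_from_kappa(kn, phi0)
        d = 0.0
        for j in range(n):
            d += dir_c * (math.log(phin[j]) - math.log(phi[j]))
        if lik_on:
            for j in range(n):
                d += colsum_b[j] * (math.log(phin[j]) - math.log(phi[j]))
            for i in range(q0):
                a = mu[i] * delta[i]
                ri = 1.0 / delta[i]
                for j in range(n):
                    d -= (xb[i, j] + ri) * (
                        math.log1p(a * phin[j] * nu[j])
                        - math.log1p(a * phi[j] * nu[j])
                    )
        # uniform slot for the kappa block is logu[t, it + 1]
        if math.isfinite(d) and logu[t, it + 1] < d:
            kappa = kn
            phi = phin
            if t < burn_in:
                bat_kappa[0] += 1.0
            else:
                post_kappa[0] += 1.0

        # ---- adaptation (burn-in only, batches of adapt_batch) ------------
        if t < burn_in and (t + 1) % adapt_batch == 0:
            b = (t + 1) // adapt_batch
            inc = min(0.01, 1.0 / math.sqrt(b))
            fb = float(adapt_batch)
            for i in range(q0):
                ls_mu[i] += inc if bat_mu[i] / fb > target_accept else -inc
                ls_delta[i] += inc if bat_delta[i] / fb > target_accept else -inc
            for j in range(n):
                ls_nu[j] += inc if bat_nu[j] / fb > target_accept else -inc
                ls_s[j] += inc if bat_s[j] / fb > target_accept else -inc
            ls_theta[0] += inc if bat_theta[0] / fb > target_accept else -inc
            ls_kappa[0] += inc if bat_kappa[0] / fb > target_accept else -inc
            if b - 1 < n_batches:
                batch_log[b - 1, 0] = bat_mu.sum() / (fb * q0)
                batch_log[b - 1, 1] = bat_delta.sum() / (fb * q0)
                batch_log[b - 1, 2] = bat_nu.sum() / (fb * n)
                batch_log[b - 1, 3] = bat_s.sum() / (fb * n)
                batch_log[b - 1, 4] = bat_theta[0] / fb
                batch_log[b - 1, 5] = bat_kappa[0] / fb
            bat_mu[:] = 0.0
            bat_delta[:] = 0.0
            bat_nu[:] = 0.0
            bat_s[:] = 0.0
            bat_theta[0] = 0.0
            bat_kappa[0] = 0.0

        # ---- storage ------------------------------------------------------
        if t >= burn_in and (t - burn_in) % thin == thin - 1:
            for i in range(q0):
                mu_draws[keep, i] = mu[i]
                delta_draws[keep, i] = delta[i]
            for j in range(n):
                phi_draws[keep, j] = phi[j]
                s_draws[keep, j] = s[j]
                nu_draws[keep, j] = nu[j]
            theta_draws[keep] = theta
            keep += 1

    n_post = float(n_iter - burn_in)
    return (
        mu_draws,
        delta_draws,
        phi_draws,
        s_draws,
        nu_draws,
        theta_draws,
        post_mu / n_post,
        post_delta / n_post,
        post_nu / n_post,
        post_s / n_post,
        post_theta / n_post,
        post_kappa / n_post,
        batch_log,
    )
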