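"""HVG/LVG decision layer.

For every retained posterior draw, each biological gene's biological
variance share sigma_i is evaluated with that draw's parameters (including
the draw's own median phi_j s_j, so threshold uncertainty propagates).  Tail
posterior probabilities

    pi_i^H(gamma_H) = P(sigma_i > gamma_H | data)
    pi_i^L(gamma_L) = P(sigma_i < gamma_L | data)

are estimated as fractions of draws, and a gene is flagged highly (lowly)
variable when the probability exceeds an evidence threshold alpha_H
(alpha_L).  The evidence thresholds are calibrated where the expected false
discovery rate and expected false negative rate of the rule coincide;
when no variance-contribution threshold gamma is pre-specified, the gamma
whose EFDR(=EFNR) crossing is closest to a target rate (e.g. 10%) is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import biological_share
from .sampler import ChainStore

__all__ = [
    "DetectionResult",
    "CalibrationResult",
    "CalibrationError",
    "sigma_draws",
    "plugin_sigma",
    "tail_probabilities",
    "efdr_efnr",
    "calibrate_alpha",
    "calibrate_thresholds",
    "classify",
    "default_alpha_grid",
    "default_gamma_grid",
    "technical_share_summary",
]


def default_alpha_grid() -> np.ndarray:
    """Evidence-threshold grid 0.5 + k*0.0025, k = 1..199."""
    return 0.5 + 0.0025 * np.arange(1, 200)


def default_gamma_grid() -> np.ndarray:
    """Variance-contribution grid 0.01..0.99 in steps of 0.01."""
    return np.round(np.arange(0.01, 1.0, 0.01), 10)


def technical_share_summary(chains: ChainStore) -> dict:
    """Overall share of count variance explained by unexplained technical
    noise in the reference cell.

    Per gene, the technical share is theta / ([(phi s)* mu_i]^{-1} + theta +
    delta_i (theta+1)), summarised by its posterior median; because the
    across-gene aggregation of the headline number is a matter of
    convention, both the mean and the median over genes are reported.
    """
    pss = np.median(chains.phi * chains.s, axis=1)
    denom = (
        1.0 / (pss[:, None] * chains.mu)
        + chains.theta[:, None]
        + chains.delta * (chains.theta[:, None] + 1.0)
    )
    share = np.median(chains.theta[:, None] / denom, axis=0)
    return {"mean": float(share.mean()), "median": float(np.median(share))}


def sigma_draws(chains: ChainStore) -> np.ndarray:
    """Per-draw, per-gene biological variance share (draws x genes).

    Each draw uses its own reference-cell scale (phi s)* = median_j of that
    draw's phi_j s_j, so the full posterior uncertainty propagates into the
    tail probabilities.
    """
    pss = np.median(chains.phi * chains.s, axis=1)  # (draws,)
    num = chains.delta * (chains.theta[:, None] + 1.0)
    return num / (1.0 / (pss[:, None] * chains.mu) + chains.theta[:, None] + num)


def plugin_sigma(chains: ChainStore) -> np.ndarray:
    """Plug-in sigma from posterior medians (for plotting contours only)."""
    pss = float(np.median(np.median(chains.phi, axis=0) * np.median(chains.s, axis=0)))
    return biological_share(
        np.median(chains.mu, axis=0),
        np.median(chains.delta, axis=0),
        float(np.median(chains.theta)),
        pss,
    )


def tail_probabilities(sigma_matrix: np.ndarray, gamma: float, side: str) -> np.ndarray:
    """Per-gene fraction of draws beyond ``gamma``.

    ``side="high"`` counts draws with sigma strictly greater than gamma,
    ``side="low"`` strictly smaller; ties never count as exceedances.
    """
    sigma_matrix = np.asarray(sigma_matrix)
    if sigma_matrix.size == 0 or sigma_matrix.shape[0] == 0:
        raise ValueError("empty draw set")
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must lie in [0, 1)")
    if side == "high":
        return (sigma_matrix > gamma).mean(axis=0)
    if side == "low":
        return (sigma_matrix < gamma).mean(axis=0)
    raise ValueError("side must be 'high' or 'low'")


def efdr_efnr(pi: np.ndarray, alpha: float) -> tuple[float, float, int]:
    """Expected false discovery and false negative rates of the rule pi > alpha.

    EFDR is the mean of (1 - pi) over flagged genes, EFNR the mean of pi over
    unflagged ones; an empty selection (or empty complement) leaves the
    corresponding rate undefined, returned as NaN with n_detected in
    {0, len(pi)}.
    """
    pi = np.asarray(pi, dtype=float)
    sel = pi > alpha
    n_det = int(sel.sum())
    efdr = float((1.0 - pi[sel]).mean()) if n_det > 0 else float("nan")
    efnr = float(pi[~sel].mean()) if n_det < pi.size else float("nan")
    return efdr, efnr, n_det


class CalibrationError(RuntimeError):
    """Raised when no grid point yields a defined EFDR/EFNR crossing."""

    def __init__(self, message: str, table: pd.DataFrame | None = None):
        super().__init__(message)
        self.table = table


def calibrate_alpha(pi: np.ndarray, alpha_grid: np.ndarray | None = None) -> float:
    """Evidence threshold where EFDR and EFNR coincide (closest grid point).

    Returns the grid alpha minimising |EFDR - EFNR| among points where both
    are defined; ties break toward the largest alpha (most conservative).
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.ndim != 1 or len(alpha_grid) == 0:
        raise ValueError("alpha_grid must be a non-empty 1-D array")
    if np.any(np.diff(alpha_grid) <= 0) or alpha_grid[0] <= 0 or alpha_grid[-1] >= 1:
        raise ValueError("alpha_grid must be strictly increasing within (0, 1)")
    rates = np.array([efdr_efnr(pi, a)[:2] for a in alpha_grid])
    defined = np.isfinite(rates).all(axis=1)
    if not defined.any():
        raise CalibrationError(
            "EFDR and EFNR are never simultaneously defined on this alpha grid; "
            "widen the grid"
        )
    diff = np.abs(rates[:, 0] - rates[:, 1])
    idx = np.flatnonzero(defined)
    best = idx[diff[idx] <= diff[idx].min() + 0.0][-1]
    return float(alpha_grid[best])


@dataclass
class CalibrationResult:
    """Calibrated thresholds plus the full (gamma, alpha, EFDR, EFNR, n) table."""

    gamma_H: float
    alpha_H: float
    gamma_L: float
    alpha_L: float
    table: pd.DataFrame
    target_rate: float = 0.1


def calibrate_thresholds(
    chains: ChainStore,
    target_rate: float = 0.10,
    gamma_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
) -> CalibrationResult:
    """Choose (gamma, alpha) pairs for the high and low rules.

    For every gamma on the grid, the EFDR=EFNR crossing alpha is found; the
    (gamma_H, gamma_L) pair with gamma_L <= gamma_H whose crossing rates are
    jointly closest to ``target_rate`` is selected (ties toward the larger
    gamma_H and the smaller gamma_L, both conservative).  When the two
    rules' independent optima are already ordered this coincides with
    picking each side separately.
    """
    if not (0.0 < target_rate < 0.5):
        raise ValueError("target_rate must lie in (0, 0.5)")
    if gamma_grid is None:
        gamma_grid = default_gamma_grid()
    sig = sigma_draws(chains)
    rows = []
    for side in ("high", "low"):
        for g in np.asarray(gamma_grid, dtype=float):
            pi = tail_probabilities(sig, g, side)
            try:
                a = calibrate_alpha(pi, alpha_grid)
            except CalibrationError:
                rows.append((side, g, np.nan, np.nan, np.nan, 0))
                continue
            efdr, efnr, n_det = efdr_efnr(pi, a)
            rows.append((side, g, a, efdr, efnr, n_det))
    table = pd.DataFrame(
        rows, columns=["side", "gamma", "alpha", "efdr", "efnr", "n_detected"]
    )

    ok = np.isfinite(table.alpha) & np.isfinite(table.efdr) & np.isfinite(table.efnr)
    hi = table[(table.side == "high") & ok]
    lo = table[(table.side == "low") & ok]
    if hi.empty or lo.empty:
        missing = "high" if hi.empty else "low"
        raise CalibrationError(
            f"no gamma on the grid yields a defined EFDR/EFNR crossing ({missing} rule)",
            table=table,
        )
    # joint selection: the (gamma_H, gamma_L) pair with gamma_L <= gamma_H
    # minimising the summed distance of the crossing rates to the target;
    # ties resolve to the larger gamma_H, then the smaller gamma_L
    best = None
    d_hi = (hi.efdr - target_rate).abs().to_numpy()
    d_lo = (lo.efdr - target_rate).abs().to_numpy()
    for ih in range(len(hi)):
        gh = float(hi.gamma.iloc[ih])
        usable = np.flatnonzero(lo.gamma.to_numpy() <= gh)
        if usable.size == 0:
            continue
        il = usable[np.argmin(d_lo[usable])]
        key = (d_hi[ih] + d_lo[il], -gh, float(lo.gamma.iloc[il]))
        if best is None or key < best[0]:
            best = (key, ih, il)
    if best is None:
        raise CalibrationError(
            "no (gamma_H, gamma_L) pair with gamma_L <= gamma_H has defined crossings",
            table=table,
        )
    _, ih, il = best
    return CalibrationResult(
        gamma_H=float(hi.gamma.iloc[ih]),
        alpha_H=float(hi.alpha.iloc[ih]),
        gamma_L=float(lo.gamma.iloc[il]),
        alpha_L=float(lo.alpha.iloc[il]),
        table=table,
        target_rate=target_rate,
    )


@dataclass
class DetectionResult:
    """Per-gene tail probabilities, flags and posterior summaries."""

    gamma_H: float
    alpha_H: float
    gamma_L: float
    alpha_L: float
    gene_ids: np.ndarray
    pi_H: np.ndarray
    pi_L: np.ndarray
    hvg_flags: np.ndarray
    lvg_flags: np.ndarray
    sigma_median: np.ndarray
    mu_median: np.ndarray
    delta_median: np.ndarray
    efdr_efnr_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_hvg(self) -> int:
        return int(self.hvg_flags.sum())

    @property
    def n_lvg(self) -> int:
        return int(self.lvg_flags.sum())

    def to_frame(self) -> pd.DataFrame:
        """Gene table ranked by the posterior-median biological share."""
        df = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mu_median": self.mu_median,
                "delta_median": self.delta_median,
                "sigma_median": self.sigma_median,
                "pi_high": self.pi_H,
                "pi_low": self.pi_L,
                "hvg": self.hvg_flags,
                "lvg": self.lvg_flags,
            }
        )
        df["rank"] = (-df.sigma_median).rank(method="first").astype(int)
        return df


def classify(
    chains: ChainStore,
    gamma_H: float,
    alpha_H: float,
    gamma_L: float,
    alpha_L: float,
    table: pd.DataFrame | None = None,
) -> DetectionResult:
    """Apply the tail-probability rules at fixed thresholds.

    A pure function of (chains, thresholds): flags are pi_H > alpha_H and
    pi_L > alpha_L exactly.  gamma_L must not exceed gamma_H, which makes
    the per-draw events {sigma > gamma_H} and {sigma < gamma_L} disjoint, so
    pi_H + pi_L <= 1 and no gene passes both rules when both alphas exceed
    one half.
    """
    if gamma_L > gamma_H:
        raise ValueError("gamma_L must not exceed gamma_H (rules could overlap)")
    sig = sigma_draws(chains)
    pi_h = tail_probabilities(sig, gamma_H, "high")
    pi_l = tail_probabilities(sig, gamma_L, "low")
    return DetectionResult(
        gamma_H=float(gamma_H),
        alpha_H=float(alpha_H),
        gamma_L=float(gamma_L),
        alpha_L=float(alpha_L),
        gene_ids=chains.bio_gene_ids,
        pi_H=pi_h,
        pi_L=pi_l,
        hvg_flags=pi_h > alpha_H,
        lvg_flags=pi_l > alpha_L,
        sigma_median=np.median(sig, axis=0),
        mu_median=np.median(chains.mu, axis=0),
        delta_median=np.median(chains.delta, axis=0),
        efdr_efnr_table=table,
    )
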