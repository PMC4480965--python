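"""Stepwise comparator: DESeq-style size factors and a CV^2-fit HVG caller.

This is the three-step alternative the integrated model is compared against:
(1) normalise with per-cell median-of-ratios factors computed separately from
biological and technical genes, (2) fit the squared coefficient of variation
against the mean on the spike-ins (pure technical variability), (3) flag
biological genes whose CV^2 significantly exceeds the technical prediction.
Genes with any zero count must be excluded from the factor medians (their
geometric mean is zero), which is what makes these estimators unstable when
technical noise is strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset

__all__ = ["BaselineSizeFactors", "deseq_size_factors", "size_factors", "brennecke_hvg"]


@dataclass
class BaselineSizeFactors:
    """Per-cell normalising factors from biological (omega_B) and technical
    (omega_T) genes; undefined factors are NaN, never silently 1."""

    omega_B: np.ndarray
    omega_T: np.ndarray
    n_usable_bio: int
    n_usable_tech: int

    @property
    def defined(self) -> bool:
        return bool(
            np.all(np.isfinite(self.omega_B)) and np.all(np.isfinite(self.omega_T))
        )


def deseq_size_factors(counts: np.ndarray) -> tuple[np.ndarray, int]:
    """Median-of-ratios size factors over zero-free genes.

    For each cell j, the median over genes i (restricted to genes with a
    positive count in every cell) of x_ij divided by the gene's across-cell
    geometric mean.  Geometric means are computed in log space.  Returns
    (factors, number of usable genes); with no usable gene the factors are
    all NaN (flagged undefined).
    """
    counts = np.asarray(counts, dtype=float)
    usable = (counts > 0).all(axis=1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        return np.full(counts.shape[1], np.nan), 0
    logx = np.log(counts[usable])
    log_gm = logx.mean(axis=1, keepdims=True)
    ratios = np.exp(logx - log_gm)
    return np.median(ratios, axis=0), n_usable


def size_factors(dataset: ExpressionDataset) -> BaselineSizeFactors:
    """Both factor sets for a spike-in annotated dataset."""
    bio = ~dataset.is_technical
    omega_B, n_bio = deseq_size_factors(dataset.counts[bio])
    omega_T, n_tech = deseq_size_factors(dataset.counts[~bio])
    return BaselineSizeFactors(omega_B, omega_T, n_bio, n_tech)


def _technical_cv2_fit(mean_tech: np.ndarray, cv2_tech: np.ndarray) -> tuple[float, float]:
    """Fit CV^2 = a0 + a1/mean on spike-ins (gamma GLM, identity link).

    Convention pinned here (the original fit's details are not restated by
    the method we compare against): spike-ins with positive CV^2 and mean at
    or above the 20% quantile of spike-in means enter the fit; if that
    leaves fewer than 2 points, all positive-CV^2 spike-ins are used.
    """
    import statsmodels.api as sm

    ok = cv2_tech > 0
    lo = np.quantile(mean_tech[ok], 0.2) if ok.sum() >= 2 else -np.inf
    use = ok & (mean_tech >= lo)
    if use.sum() < 2:
        use = ok
    if use.sum() < 2:
        raise ValueError("need at least 2 usable spike-in genes for the technical fit")
    exog = np.column_stack([np.ones(use.sum()), 1.0 / mean_tech[use]])
    try:
        import warnings

        with warnings.catch_warnings():
            # identity link on the Gamma family is the published convention
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                cv2_tech[use], exog, family=sm.families.Gamma(sm.families.links.Identity())
            ).fit()
        a0, a1 = fit.params
    except Exception:
        a0, a1 = np.linalg.lstsq(exog, cv2_tech[use], rcond=None)[0]
    return float(a0), float(a1)


def brennecke_hvg(
    dataset: ExpressionDataset,
    factors: BaselineSizeFactors | None = None,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Flag biological genes whose CV^2 exceeds the spike-in technical fit.

    Counts are normalised by omega_B (biological genes) and omega_T
    (technical genes); per-gene sample mean and CV^2 are computed from the
    normalised counts; the technical CV^2-vs-mean relationship fitted on the
    spike-ins predicts each biological gene's technical CV^2, and the test
    statistic (n-1) * CV^2_i / prediction_i is referred to a chi-squared
    distribution with n-1 degrees of freedom (upper tail), with
    Benjamini-Hochberg correction at ``fdr_threshold``.

    Returns a per-biological-gene table with ``hvg`` flags.
    """
    if factors is None:
        factors = size_factors(dataset)
    if not factors.defined:
        raise ValueError("size factors undefined (no zero-free genes); cannot proceed")
    if factors.n_usable_tech < 2:
        raise ValueError("need at least 2 usable spike-in genes")
    n = dataset.n
    bio = ~dataset.is_technical
    xb = dataset.counts[bio] / factors.omega_B[None, :]
    xt = dataset.counts[~bio] / factors.omega_T[None, :]

    def _mean_cv2(x):
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(m > 0, v / m**2, np.nan)
        return m, cv2

    m_b, cv2_b = _mean_cv2(xb)
    m_t, cv2_t = _mean_cv2(xt)
    a0, a1 = _technical_cv2_fit(m_t, cv2_t)

    with np.errstate(divide="ignore", invalid="ignore"):
        pred = a0 + a1 / m_b
        stat = (n - 1) * cv2_b / pred
    pval = np.where(
        np.isfinite(stat) & (pred > 0), stats.chi2.sf(stat, df=n - 1), 1.0
    )
    reject, qval, _, _ = multipletests(pval, alpha=fdr_threshold, method="fdr_bh")
    # a gene sitting below the technical prediction can never be called HVG
    reject &= np.nan_to_num(cv2_b) > pred
    return pd.DataFrame(
        {
            "gene_id": dataset.gene_ids[bio],
            "mean_norm": m_b,
            "cv2": cv2_b,
            "cv2_technical": pred,
            "pval": pval,
            "qval": qval,
            "hvg": reject,
        }
    )
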