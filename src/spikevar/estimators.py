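"""scikit-learn-style estimator facade.

``NoiseModel`` wraps posterior inference (fit = run the MCMC) and
``VariableGeneDetector`` wraps threshold calibration and classification.
Both follow the sklearn conventions — constructor parameters mirrored by
``get_params``/``set_params``, fitted attributes with trailing underscores —
so they compose with sklearn tooling; the module-level functions in
:mod:`spikevar.sampler` and :mod:`spikevar.detection` remain the underlying
surface the estimators delegate to.

Note the domain convention: ``X`` is genes x cells (genes as rows), matching
how count matrices are distributed, not sklearn's samples x features.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .dataset import ExpressionDataset
from .detection import calibrate_thresholds, classify, sigma_draws
from .sampler import ChainStore, McmcConfig, PriorSpec, chain_diagnostics, run_mcmc

__all__ = ["NoiseModel", "VariableGeneDetector"]


class NoiseModel(BaseEstimator):
    """Bayesian hierarchical noise model for spike-in-annotated counts.

    Parameters
    ----------
    n_iter, burn_in, thin, seed, adapt_batch, target_accept, marginalise_rho :
        MCMC settings, see :class:`spikevar.sampler.McmcConfig`.
    priors :
        :class:`spikevar.sampler.PriorSpec` or None for the defaults.

    Attributes (after ``fit``)
    --------------------------
    chains_ : ChainStore of thinned posterior draws.
    theta_ : posterior median of the unexplained technical noise.
    mu_, delta_ : per-biological-gene posterior medians.
    phi_, s_, nu_ : per-cell posterior medians.
    sigma_ : per-gene posterior median biological variance share.
    """

    def __init__(
        self,
        n_iter: int = 4000,
        burn_in: int = 2000,
        thin: int = 2,
        seed: int = 0,
        adapt_batch: int = 50,
        target_accept: float = 0.44,
        marginalise_rho: bool = True,
        priors: PriorSpec | None = None,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.adapt_batch = adapt_batch
        self.target_accept = target_accept
        self.marginalise_rho = marginalise_rho
        self.priors = priors

    def _config(self) -> McmcConfig:
        return McmcConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.seed,
            adapt_batch=self.adapt_batch,
            target_accept=self.target_accept,
            marginalise_rho=self.marginalise_rho,
        )

    def fit(self, X, y=None, *, is_technical=None, spike_input=None, gene_ids=None, cell_ids=None):
        """Run posterior inference.

        ``X`` is either an :class:`ExpressionDataset` or a genes x cells
        integer matrix accompanied by ``is_technical`` and ``spike_input``
        arrays (per gene; spike_input is the known molecules/cell for
        technical genes).
        """
        if isinstance(X, ExpressionDataset):
            dataset = X
        else:
            X = np.asarray(X)
            if is_technical is None or spike_input is None:
                raise ValueError("array input needs is_technical and spike_input")
            q, n = X.shape
            dataset = ExpressionDataset(
                counts=X,
                gene_ids=np.asarray(gene_ids, dtype=object)
                if gene_ids is not None
                else np.array([f"gene_{i}" for i in range(q)], dtype=object),
                cell_ids=np.asarray(cell_ids, dtype=object)
                if cell_ids is not None
                else np.array([f"cell_{j}" for j in range(n)], dtype=object),
                is_technical=is_technical,
                spike_input=spike_input,
            )
        self.chains_ = run_mcmc(dataset, self.priors or PriorSpec(), self._config())
        self.theta_ = float(np.median(self.chains_.theta))
        self.mu_ = np.median(self.chains_.mu, axis=0)
        self.delta_ = np.median(self.chains_.delta, axis=0)
        self.phi_ = np.median(self.chains_.phi, axis=0)
        self.s_ = np.median(self.chains_.s, axis=0)
        self.nu_ = np.median(self.chains_.nu, axis=0)
        self.sigma_ = np.median(sigma_draws(self.chains_), axis=0)
        return self

    def diagnostics(self, ess_floor: float = 100.0):
        """Per-parameter effective sample size and split R-hat."""
        self._check_fitted()
        return chain_diagnostics(self.chains_, ess_floor=ess_floor)

    def _check_fitted(self):
        if not hasattr(self, "chains_"):
            raise AttributeError("NoiseModel is not fitted yet; call fit first")


class VariableGeneDetector(BaseEstimator):
    """HVG/LVG detector over a posterior sample.

    With ``gamma_high``/``gamma_low`` left as None the variance-contribution
    thresholds are calibrated so the EFDR(=EFNR) crossing is closest to
    ``target_rate``; otherwise only the evidence thresholds alpha are
    calibrated at the given gammas.

    Attributes (after ``fit``)
    --------------------------
    result_ : DetectionResult with per-gene probabilities and flags.
    gamma_high_, alpha_high_, gamma_low_, alpha_low_ : applied thresholds.
    calibration_ : CalibrationResult (None when both gammas were fixed).
    hvg_, lvg_ : boolean flags per biological gene.
    """

    def __init__(
        self,
        target_rate: float = 0.10,
        gamma_high: float | None = None,
        gamma_low: float | None = None,
        alpha_high: float | None = None,
        alpha_low: float | None = None,
    ):
        self.target_rate = target_rate
        self.gamma_high = gamma_high
        self.gamma_low = gamma_low
        self.alpha_high = alpha_high
        self.alpha_low = alpha_low

    def fit(self, X: ChainStore, y=None):
        """Calibrate thresholds on a ChainStore and classify its genes."""
        if not isinstance(X, ChainStore):
            raise TypeError("VariableGeneDetector fits on a ChainStore")
        table = None
        if self.gamma_high is None or self.gamma_low is None or (
            self.alpha_high is None or self.alpha_low is None
        ):
            self.calibration_ = calibrate_thresholds(X, target_rate=self.target_rate)
            table = self.calibration_.table
            gh = self.gamma_high if self.gamma_high is not None else self.calibration_.gamma_H
            gl = self.gamma_low if self.gamma_low is not None else self.calibration_.gamma_L
            ah = self.alpha_high if self.alpha_high is not None else self.calibration_.alpha_H
            al = self.alpha_low if self.alpha_low is not None else self.calibration_.alpha_L
        else:
            self.calibration_ = None
            gh, gl, ah, al = self.gamma_high, self.gamma_low, self.alpha_high, self.alpha_low
        self.result_ = classify(X, gh, ah, gl, al, table=table)
        self.gamma_high_, self.alpha_high_ = gh, ah
        self.gamma_low_, self.alpha_low_ = gl, al
        self.hvg_ = self.result_.hvg_flags
        self.lvg_ = self.result_.lvg_flags
        return self

    def fit_predict(self, X: ChainStore, y=None) -> np.ndarray:
        """Labels per biological gene: 1 = HVG, -1 = LVG, 0 = neither."""
        self.fit(X)
        return self.hvg_.astype(int) - self.lvg_.astype(int)
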