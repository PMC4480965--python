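# Methods

## Model

`spikevar` models a genes × cells matrix of non-negative integer expression
counts `X_ij` (UMI molecule counts, or read counts with a re-interpreted
scale) in which a subset of rows are technical spike-in genes whose true
input amount per cell is known. Counts follow a hierarchical Poisson–Gamma
model:

    X_ij | nu_j, rho_ij  ~  Poisson( phi_j^{I_i} · nu_j · mu_i · rho_ij^{I_i} )
    nu_j  | s_j, theta   ~  Gamma( 1/theta,   1/(s_j·theta) )
    rho_ij| delta_i      ~  Gamma( 1/delta_i, 1/delta_i )

with `I_i = 1` for biological genes and `0` for spike-ins. **All Gamma
distributions in this package are shape–rate**, so that `E(nu_j) = s_j`,
`Var(nu_j) = s_j²·theta`, `E(rho_ij) = 1` and `Var(rho_ij) = delta_i`.

* `mu_i` — normalised expression rate; fixed to the known input amount for
  spike-ins, a free parameter for biological genes.
* `phi_j` — cell size factor (total mRNA content). Applies to biological
  genes only: spike-ins are added at a fixed amount per cell regardless of
  the cell's mRNA content.
* `s_j` — capture/reverse-transcription efficiency; applies to all genes.
* `theta` — a single unexplained-technical-noise parameter. The cell-level
  random effect `nu_j` fluctuates around `s_j` with squared coefficient of
  variation `theta`; it perturbs *all* genes of a cell in the same way.
* `delta_i` — biological cell-to-cell overdispersion of gene `i`.

Integrating the random effects out gives
`E(X_ij) = phi_j^{I_i} s_j mu_i = m` and the three-part variance

    Var(X_ij) = m  +  theta·m²  +  I_i · delta_i (theta+1) · m²
                (Poisson)  (technical)   (biological)

Evaluated at a reference cell — `phi_j s_j` replaced by the across-cell
median `(phi s)*` — the biological share of the variance is

    sigma_i = delta_i (theta+1) / ( [(phi s)* mu_i]^{-1} + theta + delta_i (theta+1) )

the statistic the detection layer thresholds. Inverting `sigma_i = gamma`
gives the HVG contour in the (mu, delta) plane, a decreasing function of mu.

**Identifiability.** The scale of the `phi_j` is arbitrary; the package
adopts the softmax reparameterisation `phi_j = phi0·exp(kappa_j)/Σ exp(kappa_k)`
with `kappa_1 = 0`, which enforces `Σ phi_j = phi0`. The default `phi0 = n`
gives mean-one size factors. Rescaling `phi0` leaves every relative quantity
(mu ratios, sigma, contours, the HVG/LVG calls) unchanged.

## Priors

* biological `mu_i`: the scale-invariant non-informative prior
  `p(mu) ∝ 1/mu` (flat on log mu) on `(0, mu_max]`, `mu_max = 1e12`.
  This choice is deliberate: under a literally flat prior on `(0, ∞)` the
  `mu_i` conditional tail decays as `mu^{-n/delta_i}`, so the posterior is
  improper whenever `delta_i ≥ n` carries prior mass — small instances
  demonstrably drive chains into that flat tail. With the 1/mu prior the
  posterior is proper exactly under the propriety condition below, and the
  conjugate conditional becomes `Gamma(Σ_j x_ij, Σ_j phi_j nu_j rho_ij)`.
* `theta, delta_i, s_j ~ Gamma(1, 1)` (shape–rate), `phi/phi0 ~` symmetric
  `Dirichlet(1)`. All user-overridable through `PriorSpec`. These are
  declared weakly-informative defaults, not a claim about any particular
  historical analysis.

**Propriety condition.** Every biological gene must have a positive count in
at least one cell; `run_mcmc` validates this and names offending genes. The
default low-expression filter (drop biological genes with total count
strictly below `n`, i.e. averaging under one molecule per cell) guarantees
it as a side effect. Technical genes are never filtered.

## Posterior inference

Adaptive Metropolis-within-Gibbs, two kernels targeting the same posterior:

* **Marginalised (default).** `rho` integrated out analytically: biological
  counts are negative binomial with mean `phi_j nu_j mu_i` and dispersion
  `delta_i`; technical counts Poisson(`nu_j mu_i`). Updates per sweep, in
  order: `mu` (per gene), `delta` (per gene), `nu` (per cell), `s` (per
  cell), `theta`, `kappa` (one joint (n−1)-dimensional block; `phi`
  recomputed after every proposal). All positive scalars are proposed on the
  log scale with the Jacobian included; `kappa` on the natural scale. The hot
  loop is numba-compiled; acceptance ratios are written incrementally so
  terms that cancel are never evaluated, and `lgamma(x+r) − lgamma(r)` uses
  a series form when `r = 1/delta > 1e6` to avoid cancellation.
* **Explicit-augmentation (oracle / option).** `rho` kept latent, giving
  conjugate Gibbs draws for `rho`, `mu` and `nu` (the `nu` conditional is
  `Gamma(1/theta + Σ_i x_ij, 1/(s_j theta) + Σ_bio phi_j mu_i rho_ij + Σ_tech mu_i)`);
  `delta`, `s`, `theta`, `kappa` use the same Metropolis moves (none of them
  is conjugate in either variant — `s_j` has a generalized-inverse-Gaussian
  conditional, but a log-scale Metropolis step is used for uniformity). The
  acceptance suite verifies the two kernels' theta/delta marginals agree.

**Adaptation.** Proposal log-scales start at Fisher-informed guesses
(counts' information about log-location parameters is capped by
overdispersion at roughly `x/(1+delta·x)`) and adapt in batches of 50 during
burn-in only: ±`min(0.01, batch^{-1/2})` toward a 0.44 acceptance target,
ties decreasing; adaptation is frozen afterwards so the retained chain is
ergodic.

**Reproducibility.** All randomness flows from one counter-based Philox
stream seeded by `McmcConfig.seed`; proposal noise for the compiled kernel
is pre-drawn from it. Identical seed + configuration reproduces a chain
bit-exactly. Note the pre-drawn noise is held in memory
(`2·n_iter·(2·q0+3n)` doubles), which bounds practical `n_iter` on very
large instances.

**Initialisation.** `s` from the empirical capture proportion
`Σ_tech x_ij / Σ_tech mu_i`; `phi` from biological median-of-ratios factors
divided by `s`, rescaled to `phi0`; `mu` from size-factor-scaled mean
counts; `delta` from method-of-moments dispersions floor-clamped at `1e-3`;
`theta` from the spike-ins' method-of-moments excess variance clipped to
[0.02, 5] (theta mixes slowly, so starting near the data value matters at
reduced iteration counts); `nu = s`.

## Detection of highly / lowly variable genes

For each retained draw, `sigma_i` is evaluated with that draw's parameters,
including the draw's own `(phi s)*` (full posterior propagation; a plug-in
mode from posterior medians exists for plotting contours). Tail posterior
probabilities `pi_i^H(gamma_H) = P(sigma_i > gamma_H | data)` and
`pi_i^L(gamma_L) = P(sigma_i < gamma_L | data)` are fractions of draws (ties
at the threshold never count). A gene is flagged when the probability
exceeds an evidence threshold `alpha`.

`alpha` is calibrated where the rule's expected false discovery rate
(mean of `1 − pi` over flagged genes) and expected false negative rate
(mean of `pi` over unflagged genes) coincide — on a discrete grid, the
`alpha` minimising |EFDR − EFNR| with ties toward the larger (more
conservative) value. The grids are `alpha = 0.5 + k·0.0025, k = 1..199` and
`gamma = 0.01..0.99` in 0.01 steps, matching the printed precision of the
reference thresholds. When no `gamma` is pre-specified, the
`(gamma_H, gamma_L)` pair with `gamma_L ≤ gamma_H` whose crossing rates are
jointly closest to the target (default EFDR = EFNR = 10%) is selected, ties
toward larger `gamma_H` / smaller `gamma_L`; the joint constraint keeps the
two rules disjoint (so no gene can be both HVG and LVG) and reduces to
independent per-side selection whenever the independent optima are already
ordered. Degenerate cases (empty selection or empty complement) yield
flagged NaNs, and a calibration with no defined crossing raises an error
carrying the full (gamma, alpha, EFDR, EFNR, n) table.

The overall technical variance share (`technical_share_summary`) aggregates
the per-gene posterior-median technical shares across genes; since the
across-gene aggregation of such a headline number is a matter of
convention, both the mean and the median are reported.

## Synthetic data

`simulate_dataset` draws `nu`, `rho` and then Poisson counts exactly per the
model (with `theta = 0` / `delta_i = 0` short-circuiting to the degenerate
limits) and returns the latents for oracle tests. The `esc_like_template`
emulates the magnitudes of a 41-cell mouse ESC UMI dataset: biological rates
log-uniform over 0.1–1000 molecules, spike-in inputs log-uniform over
1–1000, capture efficiencies uniform on [0.31, 0.44], mean-one log-normal
size factors (sd 0.3 on the log scale), dispersions log-normal around 0.6
(giving the strong biological-heterogeneity regime where the median sigma
is large), default `theta = 0.4`. Template parameter values are drawn from
these documented ranges at template-construction time (config, not code
constants). What the generator does **not** emulate: read-level artefacts
(amplification, mapping), batch structure, cell subpopulations, or
mean-dispersion coupling; a green simulation-based test therefore
establishes correctness of the inference machinery under the model, not
robustness to real-data misspecification.

The `fig3_benchmark` harness replays the size-factor stability study:
datasets are simulated over a grid of `theta` values and the first cell's
capture constant is estimated by (a) the spike-in median-of-ratios factor
`omega^T` and (b) the model's posterior median of `s_1`. The default design
is 40 replicates × 6 theta values (the full 400-replicate design is a
parameter away). Two caveats discovered while implementing it: at strong
noise the median-of-ratios estimator is typically *undefined* (no spike-in
is zero-free across 41 cells), which the harness reports via the usable
fraction; and the model's own across-replicate spread necessarily grows with
`theta` before prior shrinkage bounds it, because a single `nu_j` per cell
caps what any method can learn about `s_j` (irreducible CV ≈ sqrt(theta)) —
"stable" is a statement relative to the stepwise estimator, not flatness.

## Baseline comparator

The stepwise pipeline: per-cell median-of-ratios size factors computed
separately over zero-free biological (`omega^B`) and technical (`omega^T`)
genes (geometric means in log space; zero usable genes yields flagged-NaN
factors, never silent ones; excluded genes remain in downstream analysis);
then a CV²-vs-mean technical fit on the spike-ins and a per-gene chi-squared
test. The fit convention pinned here: gamma-family GLM with identity link of
spike-in CV² on 1/mean, restricted to spike-ins with positive CV² and mean
at or above the 20% quantile of spike-in means (falling back to all, then to
least squares if the GLM fails); test statistic
`(n−1)·CV²_i / (a0 + a1/mean_i)` against the upper tail of chi-squared with
n−1 degrees of freedom, Benjamini–Hochberg corrected. This is a documented
convention in the spirit of the published method, pinned by fixture tests,
not an exact reproduction of it.

## Numerical choices

* NB/Poisson log-pmfs via log-gamma functions with `log1p` forms; exact
  Poisson limits at `delta = 0` and `theta = 0` (never naive `1/delta`).
* `(phi s)*` uses the standard sample median (midpoint of central order
  statistics for even n); `kappa → phi` via max-shifted exponentials.
* `theta = 0` is excluded from the sampling support (log-scale proposals);
  the Poisson limit exists only in the simulator and the likelihood API.
* Non-finite proposal log-densities are automatic rejections; non-finite
  draws abort the run.
* Effective sample sizes via `arviz`; the split R-hat statistic is computed
  by splitting the single chain into halves (two pseudo-chains). Constant
  chains are flagged degenerate and reported with ESS equal to the draw
  count.

## Known limitations

* `theta` (and consequently `s_j`) mixes slowly — the usual coupling of a
  variance hyper-parameter with its latent effects. Use long chains and
  check `chain_diagnostics`; no interweaving/reparameterisation scheme is
  implemented.
* Single-chain inference with seed offsets only; no parallel orchestration.
* The cross-validation workflow refits one full MCMC per spike-in fold with
  the parent run's settings; it is expensive at full data scale.
* No differential expression, gene-ontology enrichment, plotting GUI, or
  GPU path.
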