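# spikevar

Bayesian spike-in-calibrated variance decomposition and variable-gene
detection for single-cell RNA-seq counts.

Single-cell experiments suffer high levels of unexplained technical noise,
so a gene whose counts vary strongly across cells is not necessarily
biologically heterogeneous. When synthetic spike-in RNAs (e.g. the ERCC set)
are added to every cell's lysate at a known amount, their counts calibrate
the technical noise: any departure from Poisson behaviour in a spike-in is
technical by construction. `spikevar` fits one joint hierarchical model to
biological and spike-in genes in which the cell-specific normalising
constants are model parameters, decomposes each gene's count variance into
Poisson baseline, technical and biological components, and flags highly and
lowly variable genes (HVG/LVG) with calibrated posterior-probability rules.
It is aimed at analysts of UMI-based scRNA-seq count matrices with spike-in
annotation.

## Model

For gene *i* in cell *j* (with *I_i* = 1 for biological genes, 0 for
spike-ins):

    X_ij | nu_j, rho_ij ~ Poisson( phi_j^{I_i} nu_j mu_i rho_ij^{I_i} )
    nu_j | s_j, theta   ~ Gamma(1/theta, 1/(s_j theta))        (shape-rate)
    rho_ij | delta_i    ~ Gamma(1/delta_i, 1/delta_i)

`phi_j` is the cell's mRNA-content size factor (constrained to sum to *n*),
`s_j` its capture efficiency, `theta` the strength of unexplained technical
noise shared by all genes, and `delta_i` the biological cell-to-cell
overdispersion of gene *i*; spike-in `mu_i` are fixed at the known input
amounts, which identifies everything else. Marginally,

    Var(X_ij) = m + theta m^2 + I_i delta_i (theta+1) m^2,   m = E(X_ij),

and the biological share of a gene's variance in a typical (reference) cell,

    sigma_i = delta_i(theta+1) / ( [(phi s)* mu_i]^{-1} + theta + delta_i(theta+1) ),

drives detection: a gene is HVG when P(sigma_i > gamma_H | data) > alpha_H,
LVG when P(sigma_i < gamma_L | data) > alpha_L, with thresholds calibrated
so that the rule's expected false discovery and false negative rates
coincide (default 10%). Inference is adaptive Metropolis-within-Gibbs on a
marginalised negative-binomial likelihood (an explicit-augmentation Gibbs
variant is available and serves as an internal oracle); see
`docs/methods.md` for priors, kernels and numerical details.

## Worked example

```python
from spikevar import NoiseModel, VariableGeneDetector, filter_low_expression, simulate_dataset
from spikevar.simulate import esc_like_template

spec = esc_like_template(q0=200, n_tech=46, n=41, theta=0.4, seed=7)
data, _ = simulate_dataset(spec)
data, report = filter_low_expression(data)     # drop genes averaging < 1 molecule/cell
print(f"{data.q0} biological + {data.n_technical} spike-in genes, {data.n} cells "
      f"({report.n_removed} low-expression genes removed)")

model = NoiseModel(n_iter=4000, burn_in=2000, thin=2, seed=11).fit(data)
print(f"unexplained technical noise theta: {model.theta_:.3f}")

detector = VariableGeneDetector(target_rate=0.10).fit(model.chains_)
print(f"thresholds: gamma_H={detector.gamma_high_:.2f} (alpha_H={detector.alpha_high_:.4f}), "
      f"gamma_L={detector.gamma_low_:.2f} (alpha_L={detector.alpha_low_:.4f})")
print(f"{detector.hvg_.sum()} HVG, {detector.lvg_.sum()} LVG")
print(detector.result_.to_frame().nlargest(3, "sigma_median")[
    ["gene_id", "mu_median", "delta_median", "sigma_median", "pi_high"]].to_string(index=False))
```

prints

```
121 biological + 46 spike-in genes, 41 cells (79 low-expression genes removed)
unexplained technical noise theta: 0.503
thresholds: gamma_H=0.71 (alpha_H=0.5800), gamma_L=0.70 (alpha_L=0.5300)
43 HVG, 75 LVG
   gene_id  mu_median  delta_median  sigma_median  pi_high
gene_00142  14.977251      6.791339      0.937875      1.0
gene_00006  97.693194      4.400079      0.929316      1.0
gene_00177 660.321826      3.418013      0.913669      1.0
```

The simulated truth had `theta = 0.4`; the posterior median lands at 0.50
with the truth well inside the 95% interval. The three top-ranked genes are
those whose biological component explains the largest posterior-median share
of their count variance (93–94%), each with a tail posterior probability of
1.0 of exceeding the calibrated 71% variance-contribution threshold.
`sigma_median` is the natural ranking of genes by biological heterogeneity,
independent of any threshold choice.

The same pipeline runs from the shell on delimited or MatrixMarket count
files plus a spike-in table (`gene_id`, `molecules_per_cell`):

```sh
spikevar run --counts counts.tsv --spikes spikes.tsv --out results/ --seed 1
spikevar crossval --counts counts.tsv --spikes spikes.tsv --out cv/ --seed 1
```

`run` writes the chain store (HDF5), detection and calibration tables (TSV)
and a reproducibility log; `crossval` re-fits the model with each spike-in
relabelled as biological in turn, validating the rate estimates against
their known inputs. `simulate`, `baseline` (the stepwise median-of-ratios +
CV²-fit comparator) and `diagnostics` complete the interface.

## Acceptance script

`scripts/acceptance.py` re-runs the package's end-to-end analysis from
scratch — simulating an ESC-like spike-in dataset, applying the
low-expression filter, fitting the model by MCMC and calibrating the
HVG/LVG thresholds — and writes a JSON results manifest:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
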