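# panelgvar

Temporal, contemporaneous and between-person symptom networks from
wave-structured occurrence panels, estimated with a **fixed-effects lag-1
panel graphical vector autoregression (panel GVAR)**.

## Who this is for

Researchers modelling how symptoms and related features (e.g. substance
use) evolve and interact over a small number of fixed follow-up waves in a
large cohort — the typical shape of electronic-health-record-derived
panels, where each individual contributes binary feature occurrences at T
regular intervals. The package covers the full analysis chain: a synthetic
cohort generator with known generative structure, pre-processing
(eligibility filtering, near-zero-variance screening, covariate
residualization), maximum-likelihood estimation, bootstrap edge stability,
permutation comparison of group-specific sub-networks with FDR control,
and Spinglass community analysis.

## The model

For individual *i* at wave *t* the p-vector of (residualized) feature
values is

```
y_it = mu + a_i + eta_it
eta_it = B eta_{i,t-1} + zeta_it,   zeta_it ~ N(0, Sigma_zeta)
a_i ~ N(0, Sigma_B)
```

with the within-person process stationary (spectral radius of B below 1,
S0 = B S0 B' + Sigma_zeta). Stacking the T waves gives a pT-dimensional
Gaussian whose parameters (B, Omega_zeta = Sigma_zeta^-1,
Omega_B = Sigma_B^-1, mu) are estimated by minimising the ML discrepancy
between the model-implied and the sample stacked moments; chi-square,
RMSEA (with noncentrality CI), CFI and TLI summarise fit.

Three networks are read off the fit:

- **temporal** — partial directed correlations (PDC): entry *j → i* is the
  correlation of node *j* at *t−1* with node *i* at *t* given all other
  nodes at *t−1*; diagonal entries are autocorrelations. Edges are
  classified autocorrelative / unidirectional / bidirectional, and
  centrality is the sum of absolute non-autoregressive weights entering
  (c_in) or leaving (c_out) a node.
- **contemporaneous** and **between-person** — partial correlations
  −K_ij/√(K_ii K_jj) from the respective precisions.

Edge stability uses repeated 75% refits with calibrated percentile
confidence intervals; edges whose 95% CI crosses zero are forced to 0.
Group networks restricted to common features are compared by per-node
trajectory permutation with Benjamini–Hochberg FDR at 5%. Community
structure aggregates 1000 stochastic Spinglass (Potts annealing) runs into
node–node co-occurrence probabilities.

## Worked example

```python
from panelgvar import PanelGVAR
from panelgvar.simulate import smd_like_config, generate_population

cfg = smd_like_config(n_individuals=2000, p=8, seed=7)   # binary cohort
panel = generate_population(cfg)
model = PanelGVAR.from_panel(panel)    # eligibility, screening, residuals
results = model.fit()
print(results.summary(top_edges=5))
```

prints

```
Fixed-effects lag-1 panel graphical VAR
=======================================================
features (p):        8
waves (T):           6
individuals (n):     1921
converged:           True (max|grad| = 2.28e-06)
chi2(1080) = 1278.1, p = 2.666e-05
RMSEA = 0.0098 [95% CI 0.0068, 0.0122]
CFI = 0.955, TLI = 0.953
-------------------------------------------------------
strongest temporal edges (PDC, top 5):
        f_08 -> f_08       z = +0.0669  (auto)
        f_03 -> f_03       z = +0.0645  (auto)
        f_02 -> f_02       z = +0.0501  (auto)
        f_08 -> f_03       z = -0.0494  (cross)
        f_01 -> f_01       z = +0.0455  (auto)
```

1921 of 2000 simulated individuals pass the eligibility filter (at least
5 of 6 observed waves). The saturated model fits the 1080 remaining
degrees of freedom closely (RMSEA < 0.05 is excellent fit), and the
strongest temporal edges are the autocorrelations — features predicting
their own recurrence three months later — with weights on the same scale
as real symptom panels (z around 0.05–0.10). `results.centrality()`,
`results.prune()`, `results.simulate_recovery()` and
`results.to_networks()` expose centrality tables, the saturated-vs-sparse
likelihood-ratio comparison, recoverability simulation and the raw
matrices; `panelgvar.stability.bootstrap_edges`,
`panelgvar.compare.permute_and_compare` and
`panelgvar.community.community_cooccurrence` drive the remaining stages.
A `panelgvar` command-line interface wraps the same pipeline
(`simulate | preprocess | fit | bootstrap | run | fit-from-moments`).

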