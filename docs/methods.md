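# Methods

## Model and estimation

The core model is a fixed-effects lag-1 panel graphical VAR for p features
observed at T fixed waves. Individual heterogeneity enters only through a
random intercept a_i ~ N(0, Sigma_B); within-person dynamics follow
eta_t = B eta_{t-1} + zeta_t with innovation covariance Sigma_zeta, started
from the stationary distribution (S0 solving S0 = B S0 B' + Sigma_zeta).
The implied pT x pT stacked covariance has within-person blocks
B^{t-s} S0 plus Sigma_B in every cell block, and the implied mean
replicates one mean per feature across waves (stationary means).

Estimation minimises the Gaussian ML discrepancy

    F = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - pT
        + (m - mu_T(theta))' Sigma(theta)^-1 (m - mu_T(theta))

over theta = (B, Omega_zeta, Omega_B, mu). The mean term is included so mu
is identified and the degrees-of-freedom bookkeeping (pT mean moments, p
mean parameters) is coherent; for residualized data the sample means are
essentially zero and the term is negligible. chi2 = (n-1) F_hat. The
saturated df are

    df = [pT + pT(pT+1)/2] - [p^2 + 2 p(p+1)/2 + p]

(8625 for p = 23, T = 6).

Numerical choices:

- Precisions are parameterised by Cholesky factors with log-diagonals, so
  every iterate is positive definite by construction.
- Gradients are fully analytic. The only non-trivial piece is the Lyapunov
  sensitivity, handled by an adjoint solve: with P = dF/dS0 (direct), Q
  solving Q = B' Q B + sym(P) gives dF/dSigma_zeta = Q and the B
  contribution 2 Q B S0. Finite-difference agreement is asserted in the
  test suite to 1e-6.
- Optimiser: L-BFGS-B from a deterministic start (B = 0.1 I, the average
  within-wave variance split evenly between the within- and between-person
  components, means from wave-averaged sample means); gradient tolerance
  1e-8; no random initialisation, so fits are reproducible without seeds.
- Stationarity is enforced by a smooth spectral-radius penalty active only
  above rho(B) = 0.995; accepted optima are always well inside the
  stationary region.
- The discrete Lyapunov equation is solved by a dense Kronecker solve for
  p <= 12 (faster at network sizes used in resampling loops) and by the
  bilinear transform above that.

Fit indices use the standard closed forms: RMSEA =
sqrt(max(chi2 - df, 0)/(df (n-1))) with a noncentrality-inversion 95% CI
(bisection to 1e-6); CFI and TLI against the independence baseline
(diagonal covariance, free means, giving baseline chi2 = -(n-1) log|R|).
If the baseline fits no worse than the target model the TLI is clamped,
with a warning.

Pruning computes Wald z statistics for every edge parameter (temporal
coefficients and off-diagonal precision entries) from the inverse observed
information — the Hessian of F obtained by central differences of the
analytic gradient — fixes those with p > alpha (default 0.01) to zero in a
direct symmetric parameterisation started at the saturated optimum, and
reports the likelihood-ratio Delta-chi2 on Delta-df pruned parameters.
Pruning is single-pass, not recursive.

## Networks

Temporal edges are partial directed correlations, defined operationally:
the correlation of node j at t-1 with node i at t conditioning on the
remaining p-1 nodes at t-1, evaluated on the model-implied lag-augmented
covariance [[S0, S0 B'], [B S0, S0]]. This definition is unambiguous,
reduces to zero exactly where B is zero, is sign-consistent with B, and is
verified in tests against a brute-force Schur-complement oracle to 1e-8.
Contemporaneous and between-person networks are the standardized
precisions (-K_ij / sqrt(K_ii K_jj)). Centrality sums absolute
non-autoregressive weights; display thresholds are cosmetic options only
and never touch analysis outputs.

## Bootstrap edge stability

Each of 250 (default) iterations drops a random 25% of individuals
without replacement, re-runs residualization and moment stacking on the
retained 75% (the feature set is frozen to the full-model retained
features, so dimensionality cannot shift mid-bootstrap) and refits from a
warm start at the full-sample optimum. Per-edge means and percentile 95%
intervals are reported; edges whose interval crosses zero are forced to 0.

The percentile band is calibrated: deviations of m-of-n subsample
estimates around the full-sample value carry only sqrt(n/m - 1) (about
0.58 at 25% holdout) of the estimator's sampling standard deviation, so
raw percentiles systematically under-cover and leave true-zero edges
un-forced whenever the full-sample estimate strays ~1.2 sd from zero. The
default therefore rescales percentile deviations by sqrt(m/(n-m)) — the
standard m-out-of-n subsampling correction — which restores ~95% coverage
of zero for true-zero edges while leaving strong edges untouched. The raw
band is available via `ci_calibration="raw"`. No normal approximation is
used; the band remains quantile-shaped.

## Permutation comparison

Groups are first restricted to the intersection of their retained feature
sets and refitted on that common topology. The permutation unit is the
per-node individual trajectory: within each group, each feature's length-T
vector is independently re-assigned across individuals. This preserves
marginal prevalences and autocorrelative structure while destroying
cross-node coupling — the null of interest for edge differences. A fully
i.i.d. cell shuffle is available (`permutation_unit="cell"`). Each
permuted dataset is re-residualized, re-stacked and refitted; p-values
follow the counting rule #(|permuted diff| >= |observed diff|) /
completed iterations (an add-one variant is available), and
Benjamini-Hochberg FDR at 5% is applied separately per group pair and
matrix type. Because trajectory permutation preserves autocorrelation,
permuted differences centre at zero for cross-lagged edges but at the
observed group difference for autocorrelative edges; the calibration tests
therefore check centring off the diagonal.

## Community analysis

The symmetrized (average of w_ij and w_ji; max-magnitude rule available)
bootstrap-stabilized temporal matrix is the default input. Partitions come
from igraph's Spinglass Potts annealer (negative-weight implementation for
signed graphs; start temperature 1, cooling 0.99, stop 0.01, gamma 1), run
per connected component since the annealer requires connectivity; isolated
nodes become singletons. Over many runs (default 1000) the co-occurrence
matrix records how often two nodes share a community; communities are
ranked by exact-node-set frequency and heatmap order comes from
average-linkage clustering of 1 - co-occurrence. Run-to-run variability
stems only from per-run seeds derived from the master seed.

## Synthetic cohorts

The generator emulates an EHR-derived symptom cohort: by default 6462
individuals, 23 binary occurrence features, six three-month waves,
baseline covariates on the demographic scale of a secondary-care
population (age ~ N(43.5, 16.1^2), gender, five ethnicity levels, four
medication flags), per-wave documentation volume (negative-binomial entry
counts, log-normal words per entry), MCAR wave missingness at 5.5% (mean
observed waves ~ 5.67 of 6), and weak documentation-volume confounding.
Covariate effects are additive on the latent scale and constant across
waves, so per-wave OLS residualization removes them exactly. The first
wave is drawn from the stationary distribution, avoiding burn-in bias.
Binary mode thresholds each latent feature at a configured empirical
quantile (prevalences roughly 5-35% by default).

What the generator does not emulate: informative (non-MCAR) missingness,
NLP extraction error, calendar irregularity within waves, diagnosis
assignment logic, or non-Gaussian latent dynamics. Passing tests therefore
demonstrate correctness of the estimation machinery and the operating
characteristics of the resampling procedures under the assumed model, not
robustness to those real-data complications. Exact parameter recovery is
only defined for the continuous latent scale; binarization attenuates
coefficients, so recovery checks use continuous mode while the binary mode
exercises end-to-end realism.

## Problem sizes in the validation harness

The test suite and acceptance script use scaled designs chosen to make
Monte-Carlo error small relative to each tolerance: moment-agreement
checks use 100 000-200 000 individuals with innovation scales ~0.6 (sample
-variance sd ~ 0.002 against a 0.01-0.02 band); recovery uses p = 6,
T = 6, n = 2000 over 20 seeds; bootstrap behaviour uses 100 iterations
over 10 replicates at n = 2000; permutation error control uses p = 5,
n = 1500 per group, 100 permutations over 20 replicates; community
recovery uses 1000 runs on a planted two-module graph.

## Known limitations

- Lag-1 and fixed temporal effects only; no regularized (LASSO) variant.
- Pairwise-complete moments can be indefinite under heavy missingness; the
  nearest-PSD repair is logged but large repairs signal that the simple
  person-mean imputation (`missing_policy="impute"`) may be preferable.
- The Wald-based prune uses a numerical Hessian; at large p (23 features:
  ~1100 parameters) this is the slowest step of the pipeline.
- Permutation p-values have resolution 1/iterations; with the default 250
  iterations the smallest attainable q-value is limited accordingly.
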