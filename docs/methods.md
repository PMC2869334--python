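# Methods

## Model and likelihood

`diaryvar` models the n diary variables of every subject k in a group as
one shared first-order vector autoregression,

    X_k(t) = B X_k(t-1) + eps_k(t),    eps_k(t) ~ N(0, Sigma),

with innovations independent across occasions and subjects. Estimation is
by the conditional likelihood: each subject's first occasion is
conditioned on, so the pooled sample consists of N = Σ_k (T_k − 1)
predictor/response day pairs and the exact conditional Gaussian
log-likelihood is

    loglik = −(N n / 2) log 2π + (N / 2) log det K − ½ Σ_pairs e' K e,

where K = Sigma^{-1} is the innovation concentration matrix and
e = x(t) − B x(t−1). No intercepts are fitted: series are detrended and
standardized upstream, so the error model is mean-zero (an intercept
option would add n parameters; it is deliberately not the default).
Conditional ML does not require stationarity of the level, only stable
dynamics; quasi-ML asymptotics make the standard errors reasonably robust
to non-Gaussian innovations.

A `GraphStructure` declares which off-diagonal entries of B (directed,
lagged edges) and of K (undirected, contemporaneous edges) are free;
everything else is constrained to exactly zero. Diagonal entries of both
matrices are always free — autocorrelations carry no information about
cross-variable influence and are never part of the searched pattern. The
free-parameter count is |directed| + |undirected| + 2n.

## Constrained fitting

The unconstrained fit is per-equation OLS (with identical regressors in
every equation, GLS equals OLS), with Sigma the ML residual covariance
(divisor N; the divisor only shifts all log-likelihoods by the same
amount within a model dimension, so N vs N − p does not affect rankings).

Under constraints the fit alternates two exact coordinate maximizations:

1. **GLS for B given K.** The normal equations restricted to the free
   coefficients are `Σ K[i,i'] (X'X)[j,j'] b[i',j'] = (K Y'X)[i,j]`, a
   small dense solve (at most n² unknowns).
2. **Covariance selection for K given B.** Maximize
   `log det K − tr(K S)` over the zero pattern, S being the current ML
   residual covariance. For chordal (decomposable) undirected graphs the
   maximizer is closed-form via the junction tree:
   `K = Σ_cliques [S_CC^{-1}]^0 − Σ_separators [S_SS^{-1}]^0`. Every
   undirected graph on ≤ 3 vertices is chordal, and on 4 vertices only
   the three chordless 4-cycles are not; those use iterative
   proportional scaling over maximal cliques to a moment-matching
   tolerance of 1e-10. Either way the fitted inverse matches S exactly
   on the diagonal and on the edge set, and K is exactly zero elsewhere.

Each step maximizes the same likelihood, so the iterate sequence is
non-decreasing (asserted at every iteration) and bounded by the
unconstrained likelihood. Iteration stops when the relative increase
falls below `tol = 1e-8` (default), with `max_iter = 200`. Two closed
forms shortcut the loop: a complete directed pattern makes B = OLS
optimal for any K (one covariance-selection step suffices), and a
complete undirected pattern makes step 2 a plain inverse. Fits are
warm-started from the OLS solution projected onto the constraint
pattern, which typically halves the iteration count without affecting
the optimum (the alternation is a block ascent on a problem whose blocks
are exactly solvable).

## Association measures

* **PCC**: `PCC_ij = −K_ij / sqrt(K_ii K_jj)`, unit diagonal, exact
  zeros off the undirected edge set. For the unconstrained fit this
  equals the sample partial correlation of residual series i and j given
  the other residual series (tested against that brute-force oracle).
* **PDC**: with `tau_jj` the conditional variance of predictor j at t−1
  given the other predictors (reciprocal diagonal of the inverse pooled
  predictor moment matrix) and `sigma_ii` the residual variance of
  equation i, the default `variant="exact"` is

      PDC_ij = B_ij sqrt(tau_jj) / sqrt(B_ij² tau_jj + sigma_ii),

  which is algebraically the partial correlation between X_i(t) and
  X_j(t−1) given the remaining t−1 variables (tested against the
  double-regression oracle), hence always in (−1, 1), zero exactly where
  B_ij = 0, and sharing B_ij's sign. `variant="rescaled"` returns the
  first-order form `B_ij sqrt(tau_jj / sigma_ii)`; the two agree to
  first order for small coefficients and the exact form is preferred
  because it is oracle-verifiable and bounded.
* **Test bounds**: under the null a partial-correlation estimate is
  asymptotically N(0, 1/N), so the pointwise two-sided bound at level
  0.95 is `1.96 / sqrt(N)` with N = Σ_k (T_k − 1); an estimate is
  flagged only if its magnitude strictly exceeds the bound. Using the
  pooled N (rather than an autocorrelation-adjusted effective size) is a
  convention; the null simulations in the test suite confirm ~5%
  pointwise error at study scale. Wald z-tests for individual free
  coefficients use standard errors from the inverse GLS information
  matrix at the optimum; a selected edge whose null is not rejected is
  labelled "not well identified" — the data cannot distinguish the
  selected model from the smaller one without that edge.

## Structure search and model uncertainty

All `2^(n(n−1)+n(n−1)/2)` structures are enumerated in binary-counter
order over the lexicographically sorted candidate-edge list (directed
bits first) — 512 models at n = 3, 262,144 at n = 4 — and each is fitted
and scored by AIC (or BIC). Ties are broken by fewer parameters, then
enumeration order; a model whose fit fails is excluded and counted.
Unrestricted searches above n = 5 are refused without an explicit
`force` flag. Models with Δ ≤ 2 of the minimum form the competitive set.

Honesty note on recovery rates: when the generating structure is sparse,
every absent candidate edge contributes an independent (χ²₁ − 2)⁺ term
to the true model's Δ, so the probability that the truth itself sits in
the Δ ≤ 2 set is bounded near 0.72 for a 3-variable truth with six
absent candidate edges, *regardless of sample size*. Exact recovery of a
sparse truth by the competitive set is therefore not a high-probability
event; what is reliable (and what the tests assert elsewhere) is that
strong true edges are always in the best model and that a group's own
truth out-scores a wrong structure by a wide margin.

## Group comparison

The three-step comparison: (1) a global likelihood-ratio test of one
common model against group-specific parameters,
`T = 2 (Σ_g loglik_g − loglik_pooled)`, chi-square with
(G − 1) × n_params degrees of freedom (26 for two groups at n = 4 with
the saturated model — performed before any structure selection, so the
saturated structure is the default); (2) an independent exhaustive
search per group; (3) a link-by-link PDC/PCC contrast of the two
selected models, flagging edges present in only one group. The df
convention follows directly from the parameter-count difference;
analyses that select structure before testing would need a different
effective df.

## Preprocessing

Order: impute → detrend → standardize.

* **Imputation**: per (subject, variable) series, an AR(p) (default
  p = 1) is estimated by Yule–Walker on pairwise-complete
  autocovariances (explosive pairwise estimates are shrunk to spectral
  radius 0.98). Each missing cell gets
  `w_f * forward + w_b * backward`, the two one-directional AR
  predictions weighted by inverse cumulative h-step forecast-error
  variance (`weights="equal"` gives the plain average); leading/trailing
  runs use the single available direction. Requires ≥ p + 2 observed
  values and < 50% missingness per series. Note that using backward
  predictions leaks future information into imputed cells; at a few
  percent missingness this induces negligible bias, but it is visible in
  principle and documented here because the generator lets you study it.
* **Detrending**: an ordinary least-squares polynomial (default degree
  5) in the occasion index is subtracted from each individual series,
  fitted in numpy's scaled-domain basis for conditioning. Differencing
  is deliberately not offered: differencing a trend-stationary series
  manufactures serial dependence a finite-order VAR cannot represent.
  Caveat: removing degree + 1 = 6 degrees of freedom of smooth variation
  from a T = 112 series also removes genuine low-frequency VAR
  variation, which biases lagged coefficient estimates by O((d+1)/T);
  on synthetic data this shows up as spurious reverse-direction partial
  correlations of magnitude ~0.03–0.1 that are absent without
  detrending. Consumers should treat marginal lagged edges near the
  significance bound with corresponding caution.
* **Standardization**: each series is divided by its own sample standard
  deviation (ddof = 1; the choice of divisor only rescales all series
  jointly). Means are not re-subtracted beyond what detrending removed.
  Standardization is cosmetic for PDC/PCC (both are scale-invariant,
  verified by a scale-equivariance test) but makes raw coefficients
  comparable across variables. The SD used is that of the detrended
  series.

## Synthetic generator

`simulate_panel` draws each subject independently from the VAR recursion
started at zero with a 200-step burn-in (geometric forgetting at
spectral radius ≤ 0.95 makes initialization bias negligible), Gaussian
innovations by default (a unit-variance scaled-t option with df = 5
exercises robustness to heavy tails), an optional per-variable
polynomial trend added after the dynamics, and MCAR masking. Specs with
spectral radius ≥ 1 are rejected, never clipped. `make_parameters`
builds coefficient matrices with cross-effect magnitudes drawn from a
requested range (default 0.25–0.45, random signs), diagonal
autocorrelations in 0.1–0.6, rescaled if needed to spectral radius
≤ 0.95, and assembles the concentration matrix with unit diagonal and
edge entries equal to minus the target partial correlation (default
0.2–0.35), rejection-sampling until positive definite.

`study_shape_fixture` emulates the shape of a two-group eating-disorder
diary study: 16 + 19 subjects, 112 daily occasions, four variables
(eating behaviour, depression, eating control, anxiety), ~6.3% MCAR
missingness, a gentle cubic trend, cross-effects 0.3–0.4 and
contemporaneous partials 0.25–0.35, and opposite planted lagged
eating/depression links in the two groups. Anxiety is attached to the
rest only through a contemporaneous link with depression, so the
three-variable eat/dep/ctl margin is itself an exact sparse graphical
VAR(1) — convenient for fast end-to-end runs over the 512-model space.

What the generator does *not* emulate: bounded/discrete visual-analogue
scales, subject-level parameter heterogeneity, non-MCAR missingness
(e.g. missed entries on bad days), circadian or weekday structure, and
measurement reactivity. Passing tests therefore demonstrate correctness
of the estimation and selection machinery under the stated model, not
robustness to these real-data features.

## Problem sizes used by the tests and acceptance script

Oracle and calibration checks run at the study scale (16–35 subjects,
112 days): 500 replicates for the LRT and pointwise-flag null rates, 200
replicates for parameter-recovery bias, 50 replicates of the 512-model
search for competitive-set recovery, and a single full 262,144-model
search at n = 4. The whole suite runs in a few minutes on one CPU.

## Known limitations

Order-1 dynamics only (no VAR(p > 1) or multi-lag Granger tests); no
exogenous covariates; Gaussian likelihood (quasi-ML otherwise); pooled
coefficients within a group (no random effects); frequency-domain
(partial coherence) analysis out of scope; exhaustive search is
exponential in n and capped at n = 5 by default.
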