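# Methods

## Model

Observations are the first *k* lower record values `x_{L(1)} > … > x_{L(k)}`
of an i.i.d. sequence from the exponentiated half-logistic distribution
(EHLD) with CDF

    F(x) = ((1 − e^{−θx}) / (1 + e^{−θx}))^λ = tanh(θx/2)^λ,   x > 0,

where λ > 0 is the shape parameter of interest and θ > 0 (a reciprocal
scale) is a nuisance parameter.  The density is decreasing for λ ≤ 1 and
right-skewed unimodal for λ > 1; record samples are small by nature, which
is what motivates the pivotal and Bayesian routes alongside maximum
likelihood.

Throughout, `h1(θ) = log((1 + e^{−θx_{L(k)}})/(1 − e^{−θx_{L(k)}}))` is the
sufficient reduction for λ: the record likelihood is
`θ^k λ^k 2^k e^{−λ h1(θ)} × (record factor in θ only)`.

## Estimators

* **Maximum likelihood.**  The λ-score gives `λ(θ) = k/h1(θ)` in closed
  form, so the joint MLE is a one-dimensional profile maximisation in θ
  (512-point log-grid scan over `[10⁻⁶/x̄, 100/x̄]`, x̄ the mean record,
  followed by bounded Brent to 10⁻¹² and a joint-score verification).  Wald
  intervals use the expected information; its (θ,θ) and cross entries are
  `Q1(λ)/θ²` and `Q2(λ)/θ`, given by infinite series (below).  Wald lower
  bounds may be negative and are reported as computed (an optional floor at
  zero exists).

* **Pivotal quantities.**  `T_k = λ h1(θ) ~ Gamma(k, 1)` gives the
  known-θ unbiased estimator `(k−1)/h1(θ)` (exact MSE `λ²/(k−2)`) and an
  exact χ²-interval.  For unknown θ, the λ-free pivot
  `W(θ) = −2 Σ_{j<k} log[(T_j/T_{j+1})^j] ~ χ²_{2k−2}` is strictly
  increasing in θ; `θ̂_p` solves `W(θ) = 2k−4`, and the generalized pivotal
  quantity `T_k/h1(θ*)` — with θ* solving `W(θ*) = W`, `W ~ χ²_{2k−2}`,
  over N Monte-Carlo draws — yields percentile intervals for λ without any
  information matrix.  N defaults to 10,000; percentiles are
  linear-interpolation (type-7) empirical quantiles.

* **Bayes with MAP plug-in.**  λ carries a gamma prior, θ the conditional
  reference prior 1/θ.  Integrating λ out leaves a 1-D marginal posterior
  for θ; its maximiser is plugged into the conditional λ-posterior:
  - *vague model* (shape = rate = 0.01): λ | data ~ Gamma(k+α, β+h1(θ̂_MAP));
  - *hierarchical model*: the gamma rate is mixed uniformly over (0, c)
    (shape fixed at 1), giving posterior mean `(k−1)h3/h2` with
    `h2 = h1^{1−k} − (ck+h1)/(c+h1)^k` and
    `h3 = h1^{−k} − (c(k+1)+h1)/(c+h1)^{k+1}`; c defaults to 5 and the
    result is insensitive to it, tending to the unbiased pivotal estimator
    as c → ∞.
  No MCMC is used anywhere; the plug-in posterior for λ is available in
  closed form (three gamma kernels, so its CDF is a sum of incomplete-gamma
  terms).

## Numerical choices

* **Stable logarithms.**  `h1` and the per-record ratios are computed via
  `log1p`/`expm1`; for θx > 25 the asymptote `log g ≈ log 2 − θx` replaces
  the direct form, which keeps `log g` finite over the whole axis (needed by
  the W-root bracket expansion).  `log h2` is assembled from `log g` so that
  the h1^{1−k} factor cannot overflow as θ grows.

* **Information series.**  `Q1, Q2` are evaluated by blockwise numpy
  summation (block doubled from 512 terms) of the five auxiliary series,
  with inner harmonic and alternating-harmonic sums accumulated
  cumulatively.  Truncation stops when the neglected term, *scaled by its
  λ-power prefactor* (λ^{k+1} for the first pair, λ^i and λ^k for the rest),
  falls below `tol = 10⁻¹²`; a raw-term cutoff would lose accuracy for
  λ ≫ 1.  Exceeding `max_terms = 10⁶` raises an explicit convergence error,
  never a silent result.  The series are validated against Monte-Carlo
  expectations of the analytic second derivatives of the log-likelihood
  (3-SE criterion at 10⁵ replicates).

* **Root solving.**  `W(θ) = w` is solved by bracket expansion plus
  vectorised bisection (90 halvings, residual-checked), which lets one GPQ
  interval solve all N draws simultaneously; `θ̂_p` is polished by Brent to
  10⁻¹⁴.

* **Interior posterior modes.**  The improper 1/θ prior makes every
  marginal θ-posterior diverge slowly (like −log θ) as θ → 0⁺, so the
  global supremum is a boundary artifact; the MAP estimators therefore
  target the *interior* local maximum found on the scan grid (multiple
  interior maxima trigger a warning and the highest is refined).  Samples
  whose smallest record collapses toward zero can lack an interior mode
  entirely — roughly 4% (vague) to 8–11% (hierarchical, growing with c) of
  chains at θ=1, λ=2, k=10.  Such samples raise an explicit error at the
  API level; inside the simulation engine the profile-likelihood maximiser
  stands in (see below).

* **Hierarchical θ-posterior form.**  Integrating the joint posterior over
  λ analytically yields `θ^{k−1} · h2(θ) · (record factor)` — the package's
  default (`variant="integrated"`), which reproduces the published
  real-data estimates (θ̂_HMAP = 0.137, λ̂_HB = 5.891).  A transcription of
  the same density with h2 in the *denominator* also circulates; it is
  exposed as `variant="as-printed"` but has no interior maximum on the
  rainfall data, and the quadrature cross-check (integrating the joint
  posterior numerically) agrees with the integrated form.

* **Credible-interval convention.**  Both highest-posterior-density (HPD,
  found by minimising interval length over the lower-tail mass — equivalent
  to equal density for these unimodal posteriors) and equal-tail intervals
  are implemented.  HPD is the default because it is what reproduces the
  published real-data intervals: for the rainfall records the hierarchical
  95% HPD interval has length 7.43 against the published 7.461, whereas the
  equal-tail interval has length 7.62.  The reporting layer always records
  which convention was used.

* **Noninformative priors.**  The Jeffreys and reference priors are
  density evaluations only; both need `[λQ2(λ)]²/Q1(λ) < k` for a real
  square root.  Numerically the constraint quantity climbs toward k without
  crossing it, so the radicand decays to zero rather than changing sign —
  consistent with these priors being unusable for objective posterior
  inference here, which is why the Bayesian machinery uses the vague and
  hierarchical models instead.

## Synthetic data

Record chains are simulated by the exact exponential-spacings construction:
`−log F(x_{L(i)})` is a cumulative sum of i.i.d. standard exponentials, so
`x_{L(i)} = F⁻¹(e^{−T_i})`.  This is the exact joint law of lower records
of an infinite i.i.d. sequence (record values are independent of record
times, so no finite-sequence truncation is emulated).  It reproduces real
record data's defining features — strict decrease, heavy lower tail of the
last record — but not measurement rounding, serial dependence, or
climate-style nonstationarity; passing tests therefore certify the
estimators under the model's own sampling law, not robustness to those
departures.

A single integer seed determines every stochastic run; simulation
replicates derive sub-streams from (seed, cell coordinates, replicate
index, attempt).

## Monte-Carlo evaluation engine

Each cell of the evaluation grid (λ ∈ {2,4,6,8}, k ∈ {10,12,14,16}, θ=1)
draws `reps` record chains and computes the four λ estimators (joint MLE,
pivotal plug-in, vague-Bayes mean, hierarchical-Bayes mean per c ∈
{5,100,500}) plus the 95% Wald and GPQ intervals, aggregating MSE, bias and
coverage with Monte-Carlo standard errors.  Defaults follow the published
design (10,000 replications; GPQ inner draws 10,000, configurable down to
2,000 — coverage is insensitive below that; the packaged test-scale runs
use 1,000 replications × 2,000 inner draws, and the acceptance script
6,000 × 2,000, sizes chosen so the full run completes comfortably on one
CPU).

Failure policy: replicates without an interior posterior mode are *not*
re-drawn — at several percent frequency, re-drawing would condition the
sample space and measurably bias the coverage columns (re-drawing was
observed to push GPQ coverage from 0.950 to 0.969).  Instead the
profile-MLE θ̂ stands in for the missing MAP estimate, and the count is
reported in the cell diagnostics.  Re-draws with a derived sub-seed are
reserved for genuine numerical failures, which are rare; a cell with more
than 0.1% unrecovered failures errors out.

### What the engine does and does not reproduce

Under this exact sampling law the engine reproduces the published coverage
probabilities to a few thousandths (Wald 0.976 vs 0.977, GPQ 0.950 vs
0.954 at λ=2, k=10), the known-θ closed-form laws exactly within
Monte-Carlo error, the estimator efficiency *ordering*
(hierarchical < pivotal < vague-Bayes < MLE in MSE) and the near-equality
across c.  The published *absolute* MSE levels for the plug-in estimators
are noticeably smaller than what the exact record law yields and smaller
than the study's own known-θ closed-form MSE bound for the same data, so
the engine's MSE columns should be read on their own scale; the test suite
asserts the reproducible quantities quantitatively and flags the MSE-level
gap rather than calibrating it away.

## Known limitations

* All Bayesian summaries are plug-in approximations (θ fixed at its MAP),
  not full joint posteriors; they inherit the MAP's non-existence issue for
  chains whose last record is extreme.
* The pivotal θ estimator requires k ≥ 3 and is noisy for small k (its
  median approaches θ slowly in k).
* The Q1/Q2 series slow down for very large λ (convergence error beyond
  λ ~ 10³ at small k); the Wald machinery is intended for the moderate-λ
  regimes where record inference is practical.
* Only lower records of the EHLD are supported; the pivot algebra is
  written against this family.
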