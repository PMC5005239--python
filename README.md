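# ehld-records

Inference for the shape parameter of the **exponentiated half-logistic
distribution (EHLD)** when the data are **lower record values** — the
successive minima of a sequence, as in record-low annual rainfall, fastest
race times, or weakest failure strengths.  Record samples are tiny and
skewed, so alongside maximum likelihood the package implements the
pivotal-quantity and hierarchical-Bayes estimators that behave better in
this regime, together with their interval procedures and a Monte-Carlo
evaluation engine.

The EHLD has CDF

```
F(x) = ((1 − e^{−θx}) / (1 + e^{−θx}))^λ ,   x > 0,  θ, λ > 0,
```

with shape λ (the parameter of interest) and reciprocal scale θ (a
nuisance).  Writing `h1(θ) = log((1+e^{−θx_{L(k)}})/(1−e^{−θx_{L(k)}}))`
for the smallest observed record `x_{L(k)}`, the package provides:

| route | point estimate of λ | interval |
|---|---|---|
| likelihood | joint MLE `λ̂ = k/h1(θ̂)` via 1-D profile | Wald, from the expected-information series Q1, Q2 |
| pivotal | `λ̂_p = (k−1)/h1(θ̂_p)`, with θ̂_p solving `W(θ) = 2k−4`, `W ~ χ²_{2k−2}` | exact χ² (θ known) or generalized-pivotal Monte-Carlo (θ unknown) |
| Bayes (vague gamma prior) | posterior mean `(k+α)/(β+h1(θ̂_MAP))` | gamma HPD / equal-tail |
| Bayes (hierarchical, rate ~ U(0,c)) | posterior mean `(k−1)h3(θ̂_HMAP)/h2(θ̂_HMAP)` | closed-form HPD / equal-tail |

All Bayesian summaries are MAP plug-ins — no MCMC.  See
[docs/methods.md](docs/methods.md) for the model, the numerical choices and
the known limitations.

## Worked example

The packaged dataset is the chain of ten record-low annual rainfall totals
(inches) at the Los Angeles Civic Center, 1877–2012:
21.26, 11.35, 10.40, 9.21, 6.73, 5.59, 5.58, 4.85, 4.42, 3.21.

```
$ ehldrec report --seed 0
ehld-records analysis (k = 10 lower records, level = 0.95)

theta estimates
  MLE        0.184
  pivotal    0.138
  MAP        0.155
  HMAP c=5     0.137
  HMAP c=100   0.137
  HMAP c=500   0.137

lambda estimates and 95% intervals
  MLE (Wald)           7.996   (1.433, 14.560)   length 13.127
  pivotal (GPQ)        5.897   (2.702, 15.386)   length 12.684
  Bayes vague          7.051   (3.028, 11.494)   length 8.466
  Bayes hier c=5       5.890   (2.371, 9.802)   length 7.431
  Bayes hier c=100     5.890   (2.371, 9.802)   length 7.431
  Bayes hier c=500     5.890   (2.371, 9.802)   length 7.431

credible intervals: hpd
```

Reading this: the four θ estimates agree that the rainfall records are
compatible with a long-scale EHLD (θ ≈ 0.14–0.18 per inch), and the shape
estimates λ ≈ 5.9–8.0 all say the distribution is strongly right-skewed
unimodal (λ ≫ 1).  The hierarchical-Bayes interval is the shortest, and its
estimate is essentially unchanged across c = 5, 100, 500 — the robustness
that motivates that prior.  The GPQ interval is Monte-Carlo based
(N = 10,000 draws by default) and reproducible under `--seed`.

The same numbers are available programmatically:

```python
from ehld_records import la_rainfall_records, mle, lambda_posterior_hier

sample = la_rainfall_records()
lam_hat, theta_hat = mle(sample)          # 7.996, 0.184
post = lambda_posterior_hier(sample, c=5) # mean 5.890, HPD (2.371, 9.802)
```

Other subcommands: `ehldrec fit` (MLE + Wald), `ehldrec pivotal`
(θ̂_p, λ̂_p, exact/GPQ intervals), `ehldrec bayes` (both posterior models),
`ehldrec simulate` (the Monte-Carlo table below).  `--help` lists options;
input files are one value per line (`--records` for a ready record chain,
`--raw` to extract lower records from a raw series).

## Monte-Carlo evaluation

`ehldrec simulate` reruns the estimator comparison: record chains from the
standard EHLD (θ = 1) over λ ∈ {2,4,6,8} and k ∈ {10,…,16}, reporting MSE
and bias of the four estimators plus coverage of the Wald and GPQ
intervals, with Monte-Carlo standard errors and a fixed seed:

```
$ ehldrec simulate --lam 2 --k 10 --c 5 --reps 2000 --gpq-draws 1000 --seed 11 --text-out table.txt
```

At (λ=2, k=10) the engine gives CP(Wald) ≈ 0.975 and CP(GPQ) ≈ 0.950 —
the GPQ interval holds its nominal level where the Wald interval
overcovers — and the hierarchical-Bayes estimator has the smallest MSE of
the four, nearly unchanged across c.

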