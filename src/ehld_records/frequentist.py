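"""Likelihood and pivotal-quantity inference for the EHLD shape parameter.

Two routes to the shape parameter ``lambda`` with the reciprocal scale
``theta`` as nuisance:

* **Maximum likelihood.**  The score in lambda gives the closed form
  ``lambda(theta) = k / h1(theta)``, so the joint MLE is found by maximising
  the one-dimensional profile log-likelihood in theta (robust down to k = 3)
  and verified against the joint score.  Wald intervals use the expected
  Fisher information, whose (theta, theta) and cross entries are the series
  Q1(lambda)/theta^2 and Q2(lambda)/theta.

* **Pivotal quantities.**  T_k = lambda * h1(theta) ~ Gamma(k, 1) yields the
  unbiased estimator (k-1)/h1(theta) and an exact chi-square interval for
  known theta.  For unknown theta, the lambda-free pivot
  W(theta) = -2 sum_j log (T_j/T_{j+1})^j ~ chi2_{2k-2} is strictly
  increasing in theta; solving W(theta) = 2k-4 estimates theta, and the
  generalized pivotal quantity T_k / h1(theta*) (Monte-Carlo over theta*
  solving W(theta*) = W ~ chi2_{2k-2}) gives an interval for lambda that
  needs no information matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .core import (
    DEFAULT_SERIES,
    ConvergenceError,
    EHLDParams,
    RecordSample,
    SeriesConfig,
    h1,
    log_g,
    q1_q2,
)

__all__ = [
    "FisherInfo",
    "PivotalState",
    "EstimateReport",
    "loglik",
    "score",
    "mle",
    "fisher_info",
    "wald_ci",
    "pivotal_state",
    "theta_pivotal",
    "lambda_pivotal",
    "exact_ci_lambda",
    "gpq_ci_lambda",
]

# solver policy: residual/step tolerance and the geometric theta bracket
# [lo/xbar, hi/xbar] used by every 1-D search, xbar = mean record value
_XTOL = 1e-12
_BRACKET = (1e-6, 100.0)
_SCAN_POINTS = 512


@dataclass(frozen=True)
class FisherInfo:
    """Expected information for (lambda, theta) and its inverse diagonal."""

    i11: float  # k / lambda^2
    i12: float  # Q2(lambda) / theta
    i22: float  # Q1(lambda) / theta^2
    var_lam: float
    var_theta: float


@dataclass(frozen=True)
class PivotalState:
    """Derived pivotal quantities for a record sample at a trial theta."""

    z: np.ndarray  # Z_i = -log F(x_{L(i)}), increasing
    s: np.ndarray  # spacings S_i = Z_i - Z_{i-1}, iid Exp(1) at true params
    t: np.ndarray  # partial sums T_j ~ Gamma(j, 1)
    u: np.ndarray  # U_j = (T_j / T_{j+1})^j, iid U(0,1) at the true theta
    w: float       # W = -2 sum log U_j ~ chi2_{2k-2}; free of lambda


@dataclass(frozen=True)
class EstimateReport:
    """A point estimate with method tag and optional interval."""

    method: str
    point: float
    interval: Optional[tuple[float, float]] = None
    level: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interval is not None and not self.interval[0] < self.interval[1]:
            raise ValueError("interval bounds must satisfy lower < upper")
        if self.level is not None and not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")


def _log_one_minus_exp2(theta, values):
    """sum log(1 - e^{-2 theta x_i}), stable via expm1."""
    return np.sum(np.log(-np.expm1(-2.0 * theta * np.asarray(values))), axis=-1)


def loglik(params: EHLDParams, sample: RecordSample) -> float:
    """Log-likelihood of the first k lower records.

    k log(theta) + k log(lambda) + k log 2 - lambda h1(theta)
    - theta sum x_i - sum log(1 - e^{-2 theta x_i}).
    """
    x = sample.as_array()
    k = sample.k
    return float(
        k * np.log(params.theta)
        + k * np.log(params.lam)
        + k * np.log(2.0)
        - params.lam * h1(params.theta, sample)
        - params.theta * x.sum()
        - _log_one_minus_exp2(params.theta, x)
    )


def score(params: EHLDParams, sample: RecordSample) -> tuple[float, float]:
    """Gradient of the log-likelihood, (d/dlam, d/dtheta).

    d/dlam   = k/lambda - h1(theta)
    d/dtheta = k/theta + lambda x_k / sinh(theta x_k)
               - sum x_i coth(theta x_i)
    """
    x = sample.as_array()
    k = sample.k
    y = params.theta * x
    d_lam = k / params.lam - h1(params.theta, sample)
    d_theta = (
        k / params.theta
        + params.lam * x[-1] / np.sinh(y[-1])
        - float(np.sum(x / np.tanh(y)))
    )
    return float(d_lam), float(d_theta)


def _profile_loglik(theta, sample: RecordSample):
    """Profile log-likelihood in theta with lambda = k/h1(theta) plugged in.

    Vectorised over theta.  The -k term is lambda*log F contribution at the
    profile optimum.
    """
    th = np.asarray(theta, dtype=float)
    x = sample.as_array()
    k = sample.k
    hv = h1(th, sample)
    return (
        k * np.log(th)
        + k * np.log(k / hv)
        + k * np.log(2.0)
        - k
        - np.multiply.outer(th, x).sum(axis=-1)
        - _log_one_minus_exp2(np.expand_dims(th, -1) if th.ndim else th, x)
    )


def _theta_bracket(sample: RecordSample) -> tuple[float, float]:
    xbar = float(np.mean(sample.values))
    return _BRACKET[0] / xbar, _BRACKET[1] / xbar


def _maximize_scalar(fun, lo: float, hi: float, n_scan: int = _SCAN_POINTS):
    """Log-grid scan + bounded refinement of a unimodal objective on [lo, hi].

    Returns (argmax, n_evals, converged).  The scan guards against flat tails
    and seeds Brent refinement inside the bracketing grid cell.  ``fun`` must
    accept an array of theta values (all objectives here vectorise).
    """
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_scan))
    vals = np.asarray(fun(grid))
    j = int(np.nanargmax(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, n_scan - 1)]
    res = optimize.minimize_scalar(
        lambda t: -fun(t), bounds=(a, b), method="bounded", options={"xatol": _XTOL}
    )
    interior = 0 < j < n_scan - 1
    return float(res.x), n_scan + int(res.nfev), bool(res.success and interior)


def mle(sample: RecordSample, init: Optional[EHLDParams] = None) -> tuple[EstimateReport, EstimateReport]:
    """Joint MLE of (lambda, theta) by profiling lambda out.

    The score in lambda gives lambda(theta) = k/h1(theta) in closed form, so
    only a 1-D maximisation in theta remains; the joint score is verified at
    the optimum.  Returns (lambda report, theta report).
    """
    if sample.k < 2:
        raise ValueError("joint MLE requires k >= 2 records")
    lo, hi = _theta_bracket(sample)
    if init is not None:
        lo, hi = min(lo, init.theta / 10), max(hi, init.theta * 10)

    def obj(t):
        return _profile_loglik(t, sample)

    theta_hat, nev, ok = _maximize_scalar(obj, lo, hi)
    lam_hat = sample.k / float(h1(theta_hat, sample))
    g = score(EHLDParams(theta=theta_hat, lam=lam_hat), sample)
    if not ok or abs(g[1]) > 1e-6 * max(1.0, abs(obj(theta_hat))):
        raise ConvergenceError(
            f"profile MLE did not converge: theta={theta_hat:.6g}, score={g}, evals={nev}"
        )
    diag = {"evals": nev, "converged": True, "score": g}
    return (
        EstimateReport(method="mle", point=lam_hat, diagnostics=diag),
        EstimateReport(method="mle", point=theta_hat, diagnostics=diag),
    )


def fisher_info(params: EHLDParams, k: int, cfg: SeriesConfig = DEFAULT_SERIES) -> FisherInfo:
    """Expected Fisher information for (lambda, theta) from the Q1/Q2 series.

    Valid (positive definite) only when [lambda Q2]^2 / Q1 < k; otherwise an
    explicit error names the violated constraint.
    """
    q1, q2 = q1_q2(params.lam, k, cfg)
    i11 = k / params.lam**2
    i12 = q2 / params.theta
    i22 = q1 / params.theta**2
    det = i11 * i22 - i12**2
    if det <= 0 or i11 <= 0 or i22 <= 0:
        raise ConvergenceError(
            "information matrix not positive definite: constraint "
            f"[lambda*Q2]^2/Q1 < k violated (lam={params.lam:.6g}, k={k})"
        )
    return FisherInfo(
        i11=i11, i12=i12, i22=i22, var_lam=i22 / det, var_theta=i11 / det
    )


def wald_ci(
    sample: RecordSample,
    level: float = 0.95,
    cfg: SeriesConfig = DEFAULT_SERIES,
    floor_at_zero: bool = False,
) -> tuple[EstimateReport, EstimateReport]:
    """Wald intervals for lambda and theta about the joint MLE.

    Symmetric estimate +/- z * SE with SE from the inverse expected
    information; the lower bound may be negative and is reported as computed
    unless ``floor_at_zero``.  Returns (lambda report, theta report).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    lam_rep, th_rep = mle(sample)
    info = fisher_info(EHLDParams(theta=th_rep.point, lam=lam_rep.point), sample.k, cfg)
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for rep, var in ((lam_rep, info.var_lam), (th_rep, info.var_theta)):
        lo = rep.point - z * np.sqrt(var)
        hi_ = rep.point + z * np.sqrt(var)
        if floor_at_zero:
            lo = max(lo, 0.0)
        out.append(
            EstimateReport(
                method="wald",
                point=rep.point,
                interval=(float(lo), float(hi_)),
                level=level,
                diagnostics={"var": float(var), **rep.diagnostics},
            )
        )
    return out[0], out[1]


def _w_of_theta(theta, sample: RecordSample):
    """The lambda-free pivot W(theta) = 2 sum_j j (log g_{j+1} - log g_j).

    Vectorised over theta (appends the record axis last); strictly increasing
    in theta from 0 to infinity.
    """
    th = np.asarray(theta, dtype=float)
    lg = log_g(th[..., None], sample.as_array())
    j = np.arange(1, sample.k)
    return 2.0 * np.sum(j * (lg[..., 1:] - lg[..., :-1]), axis=-1)


def pivotal_state(theta: float, sample: RecordSample, lam: float = 1.0) -> PivotalState:
    """All pivotal quantities of the sample at a trial (theta, lam).

    At the true parameters: S_i are iid Exp(1), T_j ~ Gamma(j,1), U_j iid
    U(0,1) and W ~ chi2_{2k-2}.  W does not depend on lam (it cancels in the
    ratios T_j/T_{j+1}), and T_k = lam * h1(theta).
    """
    if not (np.isfinite(theta) and theta > 0):
        raise ValueError("theta must be positive and finite")
    x = sample.as_array()
    z = -lam * np.log(np.tanh(0.5 * theta * x))  # = lam * g_i, increasing in i
    s = np.diff(z, prepend=0.0)
    t = z.copy()
    if sample.k >= 2:
        j = np.arange(1, sample.k)
        u = (t[:-1] / t[1:]) ** j
        w = float(-2.0 * np.sum(np.log(u)))
    else:
        u = np.empty(0)
        w = 0.0
    return PivotalState(z=z, s=s, t=t, u=u, w=w)


def _solve_w_equals(sample: RecordSample, targets: np.ndarray) -> np.ndarray:
    """Solve W(theta) = target for each target by vectorised bisection.

    W is strictly increasing with W(0+) = 0 and W ~ linear growth at
    infinity, so a root always exists; the upper bracket doubles until it
    majorises every target (capped, then ConvergenceError).
    """
    targets = np.asarray(targets, dtype=float)
    scale = 1.0 / float(np.mean(sample.values))
    lo = np.full(targets.shape, 1e-12 * scale)
    hi = np.full(targets.shape, scale)
    for _ in range(200):
        need = _w_of_theta(hi, sample) < targets
        if not need.any():
            break
        hi = np.where(need, hi * 2.0, hi)
    else:
        raise ConvergenceError("bracket expansion for W(theta)=w failed")
    for _ in range(200):
        need = _w_of_theta(lo, sample) > targets
        if not need.any():
            break
        lo = np.where(need, lo / 4.0, lo)
    else:
        raise ConvergenceError("bracket contraction for W(theta)=w failed")
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        below = _w_of_theta(mid, sample) < targets
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    root = 0.5 * (lo + hi)
    resid = _w_of_theta(root, sample) - targets
    if not np.all(np.abs(resid) < 1e-6 * np.maximum(1.0, targets)):
        raise ConvergenceError("bisection on W(theta)=w did not reach tolerance")
    return root


def theta_pivotal(sample: RecordSample) -> EstimateReport:
    """Estimate theta by solving W(theta) = 2k - 4.

    W(theta)/(2k-4) converges in probability to 1 as k grows, and W is
    strictly increasing, so the root is unique.  Requires k >= 3.
    """
    if sample.k < 3:
        raise ValueError("theta_pivotal requires k >= 3 (2k-4 must be positive)")
    target = 2.0 * sample.k - 4.0
    root = float(_solve_w_equals(sample, np.asarray(target)))
    root = optimize.brentq(
        lambda t: float(_w_of_theta(t, sample)) - target,
        root * 0.5,
        root * 2.0,
        xtol=1e-14,
        rtol=8.9e-16,
    )
    resid = float(_w_of_theta(root, sample)) - target
    return EstimateReport(
        method="pivotal", point=float(root), diagnostics={"w_residual": resid}
    )


def lambda_pivotal(sample: RecordSample, theta: Optional[float] = None) -> EstimateReport:
    """The unbiased-type estimator (k-1)/h1(theta).

    With theta known the estimator is exactly unbiased with MSE
    lambda^2/(k-2); with theta omitted the pivotal estimate of theta is
    plugged in (requires k >= 3) and unbiasedness is lost.
    """
    if theta is None:
        theta = theta_pivotal(sample).point
        tag = "pivotal-plugin"
    else:
        if not theta > 0:
            raise ValueError("theta must be positive")
        tag = "pivotal-known-theta"
    if sample.k < 2:
        raise ValueError("lambda_pivotal requires k >= 2")
    point = (sample.k - 1) / float(h1(theta, sample))
    return EstimateReport(method=tag, point=point, diagnostics={"theta": float(theta)})


def exact_ci_lambda(sample: RecordSample, theta: float, level: float = 0.95) -> EstimateReport:
    """Exact interval for lambda with theta known.

    2 T_k = 2 lambda h1(theta) ~ chi2_{2k}, so the equal-tail interval is
    (chi2_{lower tail a/2, 2k}, chi2_{upper tail a/2, 2k}) / (2 h1(theta)).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    hv = float(h1(theta, sample))
    lo = stats.chi2.ppf(alpha / 2.0, 2 * sample.k) / (2.0 * hv)
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * sample.k) / (2.0 * hv)
    return EstimateReport(
        method="exact-known-theta",
        point=(sample.k - 1) / hv,
        interval=(float(lo), float(hi)),
        level=level,
    )


def gpq_draws_lambda(sample: RecordSample, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws of the generalized pivotal quantity T_k / h1(theta*).

    Per draw: W ~ chi2_{2(k-1)}; theta* solves W(theta) = W (unique root);
    T_k ~ chi2_{2k}/2.  The draws' percentiles estimate interval endpoints
    for lambda without any information-matrix input.
    """
    w = rng.chisquare(2 * (sample.k - 1), n_draws)
    t_k = rng.chisquare(2 * sample.k, n_draws) / 2.0
    theta_star = _solve_w_equals(sample, w)
    return t_k / h1(theta_star, sample)


def gpq_ci_lambda(
    sample: RecordSample,
    level: float = 0.95,
    n_draws: int = 10_000,
    seed=0,
) -> EstimateReport:
    """Generalized-pivotal interval for lambda with theta unknown.

    Empirical (alpha/2, 1-alpha/2) percentiles (linear interpolation) of
    ``n_draws`` GPQ draws; deterministic under a fixed seed.  The point
    estimate reported is the median draw.
    """
    if sample.k < 2:
        raise ValueError("GPQ interval requires k >= 2")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if n_draws < 100:
        raise ValueError("n_draws too small for percentile estimation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = gpq_draws_lambda(sample, n_draws, rng)
    alpha = 1.0 - level
    lo, mid, hi = np.percentile(draws, [100 * alpha / 2.0, 50.0, 100 * (1 - alpha / 2.0)])
    return EstimateReport(
        method="gpq",
        point=float(mid),
        interval=(float(lo), float(hi)),
        level=level,
        diagnostics={"n_draws": int(n_draws), "seed": None if isinstance(seed, np.random.Generator) else int(seed)},
    )
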