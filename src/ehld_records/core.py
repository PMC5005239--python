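"""Exponentiated half-logistic distribution (EHLD) and record-value primitives.

The EHLD has CDF

    F(x) = ((1 - e^{-theta x}) / (1 + e^{-theta x}))^lambda
         = tanh(theta x / 2)^lambda,            x > 0,

where ``theta`` is the reciprocal of a scale parameter and ``lambda`` is the
shape parameter.  The density is decreasing for ``lambda <= 1`` and right-skewed
unimodal for ``lambda > 1``.

This module provides the distribution functions, exact simulation of lower
record values via the exponential-spacings construction, and the auxiliary
functions shared by the likelihood, pivotal and Bayesian machinery:

* ``h1(theta)`` -- the log half-logistic survival-odds evaluated at the last
  (smallest) record, the sufficient reduction for lambda;
* ``q1_q2(lam, k)`` -- the series terms Q1, Q2 of the expected Fisher
  information for the first k lower records;
* ``h2_h3(theta, c, sample)`` -- the normalising functions of the hierarchical
  posterior for lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EHLDParams",
    "RecordSample",
    "SeriesConfig",
    "ConvergenceError",
    "cdf",
    "pdf",
    "quantile",
    "sample_lower_records",
    "sample_record_matrix",
    "h1",
    "log_g",
    "q1_q2",
    "h2_h3",
]

_LOG2 = float(np.log(2.0))


class ConvergenceError(RuntimeError):
    """A series or iterative solver failed to converge within its budget."""


@dataclass(frozen=True)
class EHLDParams:
    """Parameter pair of the EHLD.

    theta : reciprocal scale (units 1/x), > 0
    lam   : shape, dimensionless, > 0
    """

    theta: float
    lam: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be a positive finite real, got {self.theta}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"lam must be a positive finite real, got {self.lam}")


@dataclass(frozen=True)
class RecordSample:
    """The first k lower record values, strictly decreasing positives."""

    values: tuple[float, ...]

    def __init__(self, values: Sequence[float]) -> None:
        vals = tuple(float(v) for v in values)
        if len(vals) < 1:
            raise ValueError("a record sample needs at least one value")
        arr = np.asarray(vals)
        if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
            raise ValueError("record values must be positive finite reals")
        bad = np.nonzero(np.diff(arr) >= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"lower records must strictly decrease; values[{i}]={arr[i]} "
                f"and values[{i + 1}]={arr[i + 1]} violate this"
            )
        object.__setattr__(self, "values", vals)

    @property
    def k(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class SeriesConfig:
    """Truncation policy for the infinite series h5..h9 behind Q1 and Q2.

    ``tol`` bounds the magnitude of the neglected contribution to Q1/Q2
    (prefactor-scaled, see :func:`q1_q2`); ``max_terms`` caps the number of
    outer-series terms before a :class:`ConvergenceError` is raised.
    """

    tol: float = 1e-12
    max_terms: int = 10**6

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_terms < 1000:
            raise ValueError("max_terms must be at least 1000")


DEFAULT_SERIES = SeriesConfig()


def _check_x(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("x must be positive and finite")
    return arr


def cdf(x, params: EHLDParams):
    """EHLD CDF, tanh(theta x / 2)^lambda. Accepts scalar or array x > 0."""
    arr = _check_x(x)
    out = np.tanh(0.5 * params.theta * arr) ** params.lam
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def pdf(x, params: EHLDParams):
    """EHLD density theta*lam*tanh(theta x/2)^lam / sinh(theta x)."""
    arr = _check_x(x)
    y = params.theta * arr
    with np.errstate(over="ignore"):
        out = params.theta * params.lam * np.tanh(0.5 * y) ** params.lam / np.sinh(y)
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def quantile(u, params: EHLDParams):
    """Inverse CDF: (2/theta) * atanh(u^(1/lam)) for u in (0, 1)."""
    arr = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    out = (2.0 / params.theta) * np.arctanh(arr ** (1.0 / params.lam))
    return float(out) if np.isscalar(u) or out.ndim == 0 else out


def sample_record_matrix(n: int, k: int, params: EHLDParams, rng: np.random.Generator) -> np.ndarray:
    """n independent lower-record chains of length k, one per row.

    Exact construction: Z_i = -log F(X_{L(i)}) are partial sums of iid
    standard exponentials, so X_{L(i)} = quantile(exp(-T_i)).  Record
    occurrence is rare in raw iid sequences, which makes rejection-style
    simulation impractical; this inversion is exact and O(n k).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    t = np.cumsum(rng.standard_exponential((n, k)), axis=1)
    # u^{1/lam} = exp(-T/lam); atanh stays accurate as the argument -> 1.
    return (2.0 / params.theta) * np.arctanh(np.exp(-t / params.lam))


def sample_lower_records(k: int, params: EHLDParams, seed) -> RecordSample:
    """Draw the first k lower record values from the EHLD.

    ``seed`` may be an integer or a ``numpy.random.Generator``; a fixed
    integer seed makes the draw reproducible.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row = sample_record_matrix(1, k, params, rng)[0]
    return RecordSample(row)


def log_g(theta, x):
    """log of g(theta, x) = log((1+e^{-theta x})/(1-e^{-theta x})), elementwise.

    Stable over the whole positive axis: for theta*x > 25 the direct form
    underflows (g ~ 2 e^{-theta x}), so the asymptote log 2 - theta*x is used;
    for small theta*x, expm1 keeps g ~ log(2/(theta x)) accurate.
    """
    y = np.asarray(theta, dtype=float) * np.asarray(x, dtype=float)
    ysafe = np.minimum(y, 25.0)
    with np.errstate(divide="ignore"):
        g = np.log1p(np.exp(-ysafe)) - np.log(-np.expm1(-ysafe))
        out = np.where(y > 25.0, _LOG2 - y, np.log(g))
    return out


def _g(theta, x):
    """g(theta, x) itself (h1 is g at the last record)."""
    y = np.asarray(theta, dtype=float) * np.asarray(x, dtype=float)
    return np.log1p(np.exp(-y)) - np.log(-np.expm1(-y))


def h1(theta, sample: RecordSample):
    """h1(theta) = log((1+e^{-theta x_{L(k)}})/(1-e^{-theta x_{L(k)}})).

    Uses only the last (smallest) record; strictly decreasing in theta, with
    limits +inf at 0+ and 0 at infinity.  Accepts scalar or array theta.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th <= 0) or np.any(~np.isfinite(th)):
        raise ValueError("theta must be positive and finite")
    out = _g(th, sample.values[-1])
    return float(out) if out.ndim == 0 else out


def _series_tables(lam: float, k: int, i_max: int, jmax: int):
    """Raw terms of the h5..h9 series for j = 1..jmax.

    Returns (t5, t6, t9, t7, t8) where t7/t8 have one row per record index
    i = 1..i_max.  The inner harmonic sum H_j and alternating sum A_{2j-1}
    are accumulated cumulatively, not recomputed per term.
    """
    j = np.arange(1, jmax + 1, dtype=float)
    harm = np.cumsum(1.0 / j)                       # H_j = sum_{l<=j} 1/l
    l = np.arange(1, 2 * jmax, dtype=float)
    alt_full = np.cumsum((-1.0) ** (l + 1) / l)     # A_m = sum_{l<=m} (-1)^{l+1}/l
    alt = alt_full[2 * np.arange(1, jmax + 1) - 2]  # A_{2j-1}
    even = (1.0 + (-1.0) ** (j + 1)) / (j + 1.0)    # 0 at even j, 2/(j+1) at odd j

    t5 = even * ((j - 1 + lam) ** -k - (j + 3 + lam) ** -k) * harm
    t6 = (1.0 / j) * ((2 * j - 2 + lam) ** -k - (2 * j + 2 + lam) ** -k) * alt
    t9 = (1.0 / (2 * j - 1)) * ((2 * j - 2 + lam) ** -k - (2 * j + lam) ** -k)
    i = np.arange(1, i_max + 1, dtype=float)[:, None]
    t7 = even * ((j - 1 + lam) ** -i + (j + 3 + lam) ** -i - 2 * (j + 1 + lam) ** -i) * harm
    t8 = (1.0 / j) * ((2 * j - 2 + lam) ** -i + (2 * j + 2 + lam) ** -i - 2 * (2 * j + lam) ** -i) * alt
    return t5, t6, t9, t7, t8


def q1_q2(lam: float, k: int, cfg: SeriesConfig = DEFAULT_SERIES) -> tuple[float, float]:
    """Series terms Q1(lambda), Q2(lambda) of the expected Fisher information.

    Q1 = k + lam^{k+1} [h5 + h6]/2 - sum_{i=1}^k lam^i [h7_i + h8_i]/2
    Q2 = -lam^k h9,

    so that E[-d2 logL / dtheta2] = Q1/theta^2 and the cross term is
    Q2/theta.  Each outer series is truncated once the neglected term,
    *scaled by its lambda-power prefactor*, falls below ``cfg.tol`` (a raw
    term cutoff would lose accuracy for lambda well above 1, where the
    prefactor lam^{k+1} is large).  Evaluation is blockwise in numpy with the
    block doubled until converged.

    Raises :class:`ConvergenceError` if ``cfg.max_terms`` is exhausted.
    """
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError("lam must be positive and finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    lam = float(lam)
    jmax = 512
    lam_i = lam ** np.arange(1, k + 1, dtype=float)
    while True:
        t5, t6, t9, t7, t8 = _series_tables(lam, k, k, jmax)
        # even-j terms of t5/t7 vanish: judge the tail on the last two terms
        tail = max(
            float(np.abs(t5[-2:]).max()) * lam ** (k + 1),
            float(np.abs(t6[-1])) * lam ** (k + 1),
            float(np.abs(t9[-1])) * lam**k,
            float((np.abs(t7[:, -2:]).max(axis=1) * lam_i).max()),
            float((np.abs(t8[:, -1]) * lam_i).max()),
        )
        if tail < cfg.tol:
            q1 = (
                k
                + lam ** (k + 1) * (t5.sum() + t6.sum()) / 2.0
                - float(np.sum(lam_i * (t7.sum(axis=1) + t8.sum(axis=1)) / 2.0))
            )
            q2 = -(lam**k) * float(t9.sum())
            return float(q1), float(q2)
        jmax *= 2
        if jmax > cfg.max_terms:
            raise ConvergenceError(
                f"Q1/Q2 series not converged within max_terms={cfg.max_terms} "
                f"at lam={lam}, k={k} (tail={tail:.3e} >= tol={cfg.tol})"
            )


def h2_h3(theta: float, c: float, sample: RecordSample) -> tuple[float, float]:
    """Normalising functions of the hierarchical lambda-posterior.

    h2 = h1^{-(k-1)} - (c k + h1) / (c + h1)^k
    h3 = h1^{-k}     - (c (k+1) + h1) / (c + h1)^{k+1}

    Both are positive for theta, c > 0 and k >= 2; the hierarchical posterior
    mean of lambda is (k-1) h3 / h2, which tends to the unbiased pivotal
    estimator (k-1)/h1 as c -> infinity.
    """
    if sample.k < 2:
        raise ValueError("h2/h3 require k >= 2")
    if not c > 0:
        raise ValueError("c must be positive")
    hv = h1(theta, sample)
    h2v = hv ** (-(sample.k - 1)) - (c * sample.k + hv) / (c + hv) ** sample.k
    h3v = hv ** (-sample.k) - (c * (sample.k + 1) + hv) / (c + hv) ** (sample.k + 1)
    return float(h2v), float(h3v)
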