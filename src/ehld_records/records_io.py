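"""Loading record data, extracting lower records, and building analysis reports."""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np

from . import __version__
from .bayes import PriorConfig, lambda_posterior_hier, lambda_posterior_vague
from .core import RecordSample
from .frequentist import gpq_ci_lambda, lambda_pivotal, theta_pivotal, wald_ci

__all__ = [
    "extract_lower_records",
    "load_records",
    "la_rainfall_records",
    "analyze",
]


def extract_lower_records(observations: Sequence[float]) -> RecordSample:
    """Extract the lower record chain from a raw iid series.

    The first observation is always a record; later observations are records
    only when *strictly* below every preceding one (ties are not records).
    """
    obs = [float(v) for v in observations]
    if not obs:
        raise ValueError("cannot extract records from an empty series")
    arr = np.asarray(obs)
    if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
        raise ValueError("observations must be positive finite reals")
    records = [obs[0]]
    for v in obs[1:]:
        if v < records[-1]:
            records.append(v)
    return RecordSample(records)


def _parse_lines(lines: list[str], source: str) -> list[float]:
    values = []
    for lineno, raw in enumerate(lines, start=1):
        text = raw.strip().rstrip(",")
        if not text or text.startswith("#"):
            continue
        try:
            values.append(float(text))
        except ValueError:
            if lineno == 1:  # tolerate a single-column CSV header
                continue
            raise ValueError(
                f"{source}:{lineno}: non-numeric value {text!r}"
            ) from None
    if not values:
        raise ValueError(f"{source}: no numeric values found")
    return values


def load_records(path, mode: str = "records") -> RecordSample:
    """Load a record sample from a text file (one value per line / 1-col CSV).

    ``mode="records"`` validates that the file already holds a strictly
    decreasing record chain; ``mode="raw"`` treats it as the original series
    and extracts the lower records.
    """
    if mode not in ("records", "raw"):
        raise ValueError("mode must be 'records' or 'raw'")
    with open(path) as fh:
        values = _parse_lines(fh.readlines(), str(path))
    if mode == "raw":
        return extract_lower_records(values)
    return RecordSample(values)


def la_rainfall_records() -> RecordSample:
    """The packaged 10-value Los Angeles annual-rainfall lower record chain.

    Annual rainfall (inches) at the Los Angeles Civic Center, 1877-2012:
    the ten successive record-low years.
    """
    text = resources.files("ehld_records").joinpath("data/la_rainfall_records.txt").read_text()
    return RecordSample(_parse_lines(text.splitlines(), "la_rainfall_records.txt"))


def analyze(
    sample: RecordSample,
    level: float = 0.95,
    prior: PriorConfig = PriorConfig(),
    c_list: Sequence[float] = (5.0, 100.0, 500.0),
    gpq_draws: int = 10_000,
    seed: int = 0,
    interval_kind: str = "hpd",
) -> dict:
    """Full analysis report: every point estimate and interval, as a dict.

    Mirrors the structure of the real-data tables: four estimates of theta
    (MLE, pivotal, MAP, hierarchical MAP per c), four estimates of lambda
    (MLE, pivotal plug-in, vague Bayes mean, hierarchical Bayes mean per c),
    and 95% Wald / GPQ / credible intervals with their lengths.  JSON-ready.
    """
    lam_wald, th_wald = wald_ci(sample, level)
    th_p = theta_pivotal(sample)
    lam_p = lambda_pivotal(sample)
    gpq = gpq_ci_lambda(sample, level=level, n_draws=gpq_draws, seed=seed)
    vague = lambda_posterior_vague(sample, prior, level, interval=interval_kind)
    hier = {c: lambda_posterior_hier(sample, c, level, interval=interval_kind) for c in c_list}

    def iv(bounds):
        lo, hi = bounds
        return {"lower": lo, "upper": hi, "length": hi - lo}

    return {
        "tool": {"name": "ehld-records", "version": __version__},
        "sample": {"k": sample.k, "values": list(sample.values)},
        "settings": {
            "level": level,
            "prior_shape": prior.prior_shape,
            "prior_rate": prior.prior_rate,
            "c_list": [float(c) for c in c_list],
            "gpq_draws": gpq_draws,
            "seed": seed,
            "interval_kind": interval_kind,
        },
        "theta": {
            "mle": th_wald.point,
            "pivotal": th_p.point,
            "map": vague.theta_map,
            "hmap": {str(c): hier[c].theta_map for c in c_list},
        },
        "lambda": {
            "mle": lam_wald.point,
            "pivotal": lam_p.point,
            "bayes": vague.lam_mean,
            "hier": {str(c): hier[c].lam_mean for c in c_list},
        },
        "intervals": {
            "wald": iv(lam_wald.interval),
            "gpq": iv(gpq.interval),
            "bayes": iv(vague.lam_interval),
            "hier": {str(c): iv(hier[c].lam_interval) for c in c_list},
        },
    }


def report_text(report: dict) -> str:
    """Fixed-width rendering of an analysis report (3-decimal rounding)."""
    c_list = report["settings"]["c_list"]
    th = report["theta"]
    la = report["lambda"]
    iv = report["intervals"]
    lines = [
        f"ehld-records analysis (k = {report['sample']['k']} lower records, "
        f"level = {report['settings']['level']})",
        "",
        "theta estimates",
        f"  MLE        {th['mle']:.3f}",
        f"  pivotal    {th['pivotal']:.3f}",
        f"  MAP        {th['map']:.3f}",
    ]
    for c in c_list:
        lines.append(f"  HMAP c={c:<5g} {th['hmap'][str(c)]:.3f}")
    lines += ["", "lambda estimates and 95% intervals"]

    def fmt(label, point, bounds):
        return (
            f"  {label:<18} {point:7.3f}   "
            f"({bounds['lower']:.3f}, {bounds['upper']:.3f})   length {bounds['length']:.3f}"
        )

    lines.append(fmt("MLE (Wald)", la["mle"], iv["wald"]))
    lines.append(fmt("pivotal (GPQ)", la["pivotal"], iv["gpq"]))
    lines.append(fmt("Bayes vague", la["bayes"], iv["bayes"]))
    for c in c_list:
        lines.append(fmt(f"Bayes hier c={c:g}", la["hier"][str(c)], iv["hier"][str(c)]))
    lines.append("")
    lines.append(f"credible intervals: {report['settings']['interval_kind']}")
    return "\n".join(lines) + "\n"
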