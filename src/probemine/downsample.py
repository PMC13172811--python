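"""Reliability statistics for screening on subsampled data.

When a file is screened at an extraction fraction x (percent), the
matched count c_x for a probe is roughly proportional to the full-data
count c_100. Expressing each observation as a detected proportion
y = 100 * c_x / c_100 and regressing y on x gives a linear calibration
y = a*x + b; inverting it back-calculates a 100%-equivalent estimate
from any subsampled count:

    c_100_hat = 100 * c_obs / (a*x + b)

The relative error of that estimate shrinks as the true full-data
abundance m grows; empirically the decay is well described by

    err(m) = A * exp(-B * log10 m)

fitted by least squares after log-linearization. Inverting the decay
model at an error tolerance gives the matched-read abundance above
which back-calculation is trustworthy at that tolerance. These
thresholds are dataset-dependent guides, not universal cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExtractionObservation",
    "LinearModel",
    "ErrorDecayModel",
    "observations_from_counts",
    "fit_linear",
    "back_calculate",
    "relative_error",
    "fit_error_decay",
    "invert_error_decay",
    "analyze_counts",
]


@dataclass(frozen=True)
class ExtractionObservation:
    """One (probe, file) pair observed at one extraction fraction.

    y is the detected proportion 100 * c_x / c_100 relative to the
    full-extraction reference count.
    """

    x: float  # extraction fraction, percent, in (0, 100]
    c_x: int
    c_100: int

    def __post_init__(self) -> None:
        if not (0 < self.x <= 100):
            raise ValueError(f"extraction fraction must be in (0, 100], got {self.x}")
        if self.c_100 <= 0:
            raise ValueError("reference count c_100 must be positive")
        if self.c_x < 0:
            raise ValueError("observed count must be >= 0")

    @property
    def y(self) -> float:
        return 100.0 * self.c_x / self.c_100


@dataclass(frozen=True)
class LinearModel:
    """Calibration line y = slope * x + intercept (both in percent units)."""

    slope: float
    intercept: float

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class ErrorDecayModel:
    """Relative-error decay err(m) = amplitude * exp(-decay * log10 m)."""

    amplitude: float
    decay: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    def predict(self, m: float) -> float:
        return self.amplitude * math.exp(-self.decay * math.log10(m))


def observations_from_counts(counts: pd.DataFrame) -> list[ExtractionObservation]:
    """Build observations from a tidy counts table.

    Expects columns (probe, file, extraction_pct, matched); rows with
    extraction_pct == 100 define the per-(probe, file) reference counts.
    Pairs whose reference count is zero are excluded (their detected
    proportion is undefined), as are the reference rows themselves.
    """
    required = {"probe", "file", "extraction_pct", "matched"}
    if missing := required - set(counts.columns):
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    ref = (counts[counts["extraction_pct"] == 100]
           .set_index(["probe", "file"])["matched"])
    obs: list[ExtractionObservation] = []
    for row in counts[counts["extraction_pct"] < 100].itertuples():
        key = (row.probe, row.file)
        if key not in ref.index or ref[key] <= 0:
            continue
        obs.append(ExtractionObservation(x=float(row.extraction_pct),
                                         c_x=int(row.matched),
                                         c_100=int(ref[key])))
    return obs


def fit_linear(observations: Sequence[ExtractionObservation]) -> LinearModel:
    """Ordinary least squares of detected proportion on extraction fraction.

    All observations are pooled unweighted into a single fit.
    """
    if len(observations) < 2:
        raise ValueError("need at least two observations")
    x = np.array([o.x for o in observations], dtype=float)
    y = np.array([o.y for o in observations], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("all extraction fractions identical; line is undetermined")
    res = stats.linregress(x, y)
    return LinearModel(slope=float(res.slope), intercept=float(res.intercept))


def back_calculate(c_obs: float, x: float, model: LinearModel) -> float:
    """Estimate the 100%-extraction count from a subsampled count."""
    predicted = model.predict(x)
    if predicted <= 0:
        raise ValueError(
            f"calibration predicts non-positive proportion ({predicted:.4f}%) "
            f"at extraction {x}%; back-calculation undefined"
        )
    return 100.0 * c_obs / predicted


def relative_error(estimate: float, actual: float) -> float:
    """Absolute relative error, in percent of the actual value."""
    if actual <= 0:
        raise ValueError("actual count must be positive")
    return 100.0 * abs(estimate - actual) / actual


def fit_error_decay(points: Iterable[tuple[float, float]]) -> ErrorDecayModel:
    """Fit err = A * exp(-B * log10 m) by least squares in log space.

    ``points`` are (m, err) pairs with m > 0 and err > 0; the fit
    regresses ln(err) on log10(m), so A = exp(intercept), B = -slope.
    """
    pts = [(m, e) for m, e in points]
    if any(m <= 0 or e <= 0 for m, e in pts):
        raise ValueError("error-decay fit requires m > 0 and err > 0")
    if len(pts) < 2:
        raise ValueError("need at least two points")
    log_m = np.array([math.log10(m) for m, _ in pts])
    ln_e = np.array([math.log(e) for _, e in pts])
    if np.all(log_m == log_m[0]):
        raise ValueError("all abundances identical; decay is undetermined")
    res = stats.linregress(log_m, ln_e)
    return ErrorDecayModel(amplitude=float(math.exp(res.intercept)),
                           decay=float(-res.slope))


def invert_error_decay(model: ErrorDecayModel, err_threshold: float) -> int:
    """Matched-read abundance at which the model predicts the given error.

    Solves err_threshold = A * exp(-B * log10 m) for m:
    m = 10 ** (ln(A / err_threshold) / B), rounded to the nearest integer.
    """
    if err_threshold <= 0:
        raise ValueError("error threshold must be positive")
    if err_threshold > model.amplitude:
        raise ValueError(
            f"error threshold {err_threshold}% exceeds the model amplitude "
            f"{model.amplitude}%; the model never predicts that much error at m >= 1"
        )
    exponent = math.log(model.amplitude / err_threshold) / model.decay
    return round(10.0 ** exponent)


def analyze_counts(counts: pd.DataFrame,
                   err_thresholds: Sequence[float] = (1, 5, 10, 20)):
    """Full downsampling-reliability analysis of a tidy counts table.

    Returns ``(calibration, back_table, decay_models, threshold_table)``:
    the pooled linear calibration, a per-observation table with
    back-calculated estimates and relative errors, one error-decay model
    per extraction fraction, and the matched-read thresholds at the
    requested error tolerances (rows: tolerance, columns: extraction).
    """
    obs = observations_from_counts(counts)
    calibration = fit_linear(obs)

    rows = []
    for o in obs:
        est = back_calculate(o.c_x, o.x, calibration)
        rows.append({
            "extraction_pct": o.x,
            "matched": o.c_x,
            "reference_100pct": o.c_100,
            "back_calculated": est,
            "relative_error_pct": relative_error(est, o.c_100),
        })
    back_table = pd.DataFrame(rows)

    decay_models: dict[float, ErrorDecayModel] = {}
    for x in sorted(back_table["extraction_pct"].unique()):
        sub = back_table[(back_table["extraction_pct"] == x)
                         & (back_table["relative_error_pct"] > 0)]
        if sub["reference_100pct"].nunique() >= 2:
            decay_models[x] = fit_error_decay(
                zip(sub["reference_100pct"], sub["relative_error_pct"]))

    threshold_rows = {}
    for err in err_thresholds:
        row = {}
        for x, model in decay_models.items():
            try:
                row[x] = invert_error_decay(model, err)
            except ValueError:
                row[x] = math.nan
        threshold_rows[err] = row
    threshold_table = pd.DataFrame.from_dict(threshold_rows, orient="index")
    threshold_table.index.name = "relative_error_threshold_pct"
    threshold_table.columns.name = "extraction_pct"
    return calibration, back_table, decay_models, threshold_table
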