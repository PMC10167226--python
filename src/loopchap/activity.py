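"""Amorphous-aggregation chaperone activity from turbidity kinetics.

Thermally destabilized model substrates (citrate synthase, rhodanese)
aggregate amorphously; aggregation is followed as absorbance at 360 nm.
Chaperone activity is quantified as the *aggregation mass*: the area under
the turbidity trace, normalized to the substrate-alone control (100%).
Across a panel of loop-motif variants the aggregation mass is regressed on
combined motif hydropathy, and the fitted line predicts the activity of new
variants with a mean-response confidence band.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LoopchapError, TraceError
from .hydropathy import HydropathyScore


@dataclass(frozen=True)
class AggregationTrace:
    """One time-resolved turbidity or ThT measurement.

    times are in seconds and must be strictly increasing; the molar ratio is
    substrate:chaperone on a monomer-subunit basis (``None`` for
    substrate-alone controls).
    """

    times: np.ndarray
    signal: np.ndarray
    substrate: str = ""
    chaperone: str | None = None
    ratio: float | None = None
    replicate: int = 0
    temperature: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise TraceError("times and signal must be 1-D arrays of equal length")
        if t.size < 4:
            raise TraceError("a trace needs at least 4 points")
        if not np.all(np.diff(t) > 0):
            raise TraceError("times must be strictly increasing")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
            raise TraceError("times and signal must be finite")


@dataclass(frozen=True)
class AggregationMassResult:
    variant_id: str
    ratio: float | None
    mass_pct: float
    sd_pct: float
    n_replicates: int


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of aggregation mass (%) on combined hydropathy.

    Carries the sufficient statistics (``x_mean``, ``x_sumsq``,
    ``residual_sd``, ``n``) needed to evaluate mean-response confidence
    bands at arbitrary x without the training data.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residual_sd: float
    n: int
    x_mean: float
    x_sumsq: float
    x_scale_name: str = ""
    ratio: float | None = None


@dataclass(frozen=True)
class ActivityPrediction:
    variant_id: str
    x: float
    predicted_pct: float
    ci_low: float
    ci_high: float
    level: float


def baseline_correct(trace: AggregationTrace, n_initial: int = 3) -> AggregationTrace:
    """Subtract the mean of the first ``n_initial`` points from the signal.

    Negative values are retained: clipping would bias downstream AUC ratios.
    """
    if n_initial < 1:
        raise TraceError("n_initial must be >= 1")
    if n_initial >= trace.times.size:
        raise TraceError("n_initial must be smaller than the number of points")
    offset = float(np.mean(trace.signal[:n_initial]))
    return replace(trace, signal=trace.signal - offset)


def _auc(trace: AggregationTrace, window: tuple[float, float]) -> float:
    """Trapezoidal AUC over ``window``, interpolating the window endpoints."""
    lo, hi = window
    t, y = trace.times, trace.signal
    inside = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inside], [hi]))
    yy = np.concatenate(
        ([np.interp(lo, t, y)], y[inside], [np.interp(hi, t, y)])
    )
    return float(np.trapezoid(yy, tt))


def aggregation_mass(
    traces: Sequence[AggregationTrace],
    control: Sequence[AggregationTrace],
    baseline_points: int | None = 3,
) -> AggregationMassResult:
    """Aggregation mass of replicate traces relative to the substrate control.

    Per-replicate trapezoidal AUCs are computed over the common time window
    of all traces, then ``mass_pct = 100 * mean(AUC) / mean(control AUC)``
    with the standard deviation of per-replicate masses as ``sd_pct``.
    """
    traces, control = list(traces), list(control)
    if not traces or not control:
        raise TraceError("need at least one trace and one control replicate")
    subs = {tr.substrate for tr in traces} | {tr.substrate for tr in control}
    if len(subs) > 1:
        raise TraceError(f"mixed substrates in aggregation_mass: {sorted(subs)}")
    if baseline_points:
        traces = [baseline_correct(tr, baseline_points) for tr in traces]
        control = [baseline_correct(tr, baseline_points) for tr in control]
    lo = max(tr.times[0] for tr in traces + control)
    hi = min(tr.times[-1] for tr in traces + control)
    if hi <= lo:
        raise TraceError("traces and control share no overlapping time window")
    aucs = np.array([_auc(tr, (lo, hi)) for tr in traces])
    ctrl_auc = float(np.mean([_auc(tr, (lo, hi)) for tr in control]))
    if ctrl_auc == 0:
        raise TraceError("control AUC is zero; cannot normalize")
    masses = 100.0 * aucs / ctrl_auc
    chaps = {tr.chaperone for tr in traces if tr.chaperone}
    ratios = {tr.ratio for tr in traces if tr.ratio is not None}
    return AggregationMassResult(
        variant_id=chaps.pop() if len(chaps) == 1 else "",
        ratio=ratios.pop() if len(ratios) == 1 else None,
        mass_pct=float(np.mean(masses)),
        sd_pct=float(np.std(masses, ddof=1)) if len(masses) > 1 else 0.0,
        n_replicates=len(masses),
    )


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope, intercept, R², slope-t p-value and residual sd for y ~ x."""
    n = x.size
    if n < 3:
        raise LoopchapError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise LoopchapError("zero variance in x; regression undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    sse = float(np.sum((y - fitted) ** 2))
    residual_sd = math.sqrt(sse / (n - 2))
    return res, residual_sd


def fit_activity_regression(
    scores: pd.DataFrame | Iterable[HydropathyScore],
    masses: pd.DataFrame | Iterable[AggregationMassResult],
    ratio: float | None = None,
) -> RegressionModel:
    """OLS of mass_pct on combined hydropathy, matched on variant_id.

    ``scores`` needs columns variant_id/combined (plus optional scale_name);
    ``masses`` needs variant_id/mass_pct (plus optional ratio, used to
    select a single molar-ratio panel when ``ratio`` is given).
    """
    sdf = scores if isinstance(scores, pd.DataFrame) else pd.DataFrame(
        [{"variant_id": s.variant_id, "combined": s.combined,
          "scale_name": s.scale_name} for s in scores]
    )
    mdf = masses if isinstance(masses, pd.DataFrame) else pd.DataFrame(
        [{"variant_id": m.variant_id, "mass_pct": m.mass_pct, "ratio": m.ratio}
         for m in masses]
    )
    if ratio is not None and "ratio" in mdf.columns:
        mdf = mdf[mdf["ratio"] == ratio]
    merged = sdf.merge(mdf, on="variant_id", how="inner")
    if len(merged) < 3:
        raise LoopchapError(
            f"only {len(merged)} variants matched; regression needs >= 3"
        )
    x = merged["combined"].to_numpy(dtype=float)
    y = merged["mass_pct"].to_numpy(dtype=float)
    res, residual_sd = _ols(x, y)
    return RegressionModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        residual_sd=residual_sd,
        n=int(x.size),
        x_mean=float(np.mean(x)),
        x_sumsq=float(np.sum((x - np.mean(x)) ** 2)),
        x_scale_name=str(sdf["scale_name"].iloc[0]) if "scale_name" in sdf else "",
        ratio=ratio,
    )


def predict_activity(
    model: RegressionModel,
    score: HydropathyScore | float,
    level: float = 0.95,
    clamp: bool = False,
) -> ActivityPrediction:
    """Predicted aggregation mass with a mean-response confidence interval.

    The interval is the CI of the *mean response* (the regression line), not
    a prediction interval for a new observation:
    ``se = s * sqrt(1/n + (x - x̄)² / Sxx)`` with a t quantile on n-2 df.
    With ``clamp`` the point and bounds are truncated to [0, 100] since the
    response is a percentage of the control.
    """
    if isinstance(score, HydropathyScore):
        x, vid = score.combined, score.variant_id
    else:
        x, vid = float(score), ""
    df = model.n - 2
    if df < 1:
        raise LoopchapError("confidence interval undefined with n - 2 < 1 df")
    point = model.intercept + model.slope * x
    se = model.residual_sd * math.sqrt(
        1.0 / model.n + (x - model.x_mean) ** 2 / model.x_sumsq
    )
    tq = float(stats.t.ppf(0.5 + level / 2.0, df))
    lo, hi = point - tq * se, point + tq * se
    if clamp:
        point = min(max(point, 0.0), 100.0)
        lo = min(max(lo, 0.0), 100.0)
        hi = min(max(hi, 0.0), 100.0)
    return ActivityPrediction(
        variant_id=vid, x=x, predicted_pct=float(point),
        ci_low=float(lo), ci_high=float(hi), level=level,
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R² and two-sided slope-t p-value for paired values.

    Identical statistics to :func:`fit_activity_regression` on the same
    pairs (the squared Pearson r equals the OLS R², and the slope t-test
    equals the correlation t-test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    res, _ = _ols(x, y)
    if np.ptp(y) == 0:
        raise LoopchapError("zero variance in y; correlation undefined")
    return float(res.rvalue**2), float(res.pvalue)
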