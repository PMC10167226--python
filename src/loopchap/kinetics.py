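"""Amyloid formation kinetics: sigmoid fits and the nucleation rate law.

Aβ42 fibril formation monitored by thioflavin T (ThT) fluorescence is
analyzed at two levels:

1. An empirical sigmoid ``F = F0 + A / (1 + exp[r_max (τ½ − t)])`` per
   trace, from which the aggregation half time τ½ and maximal growth rate
   r_max are extracted.

2. The integrated rate law of the nucleation–elongation–secondary-
   nucleation model for the normalized fibril mass M(t)/M(∞), a closed-form
   first-order perturbative solution of the moment equations

       dP/dt = k_n m^n_C + k_2 m^n_2 M,   dM/dt = 2 k_+ m P,   m = m0 − M.

   Only two combinations of the microscopic rate constants are identifiable
   from M(t) at a single monomer concentration:

       λ = sqrt(2 k_+ k_n m0^n_C)        (primary pathway)
       κ = sqrt(2 k_+ k_2 m0^(n_2 + 1))  (secondary pathway)

   The closed form is accurate in the secondary-nucleation-dominated regime
   (λ ≲ κ/5, the regime of unseeded Aβ42); its half-time error grows to
   ~20% as λ → κ.

The *global fit* holds all rate constants shared across a dilution series
of a chaperone except one (k_n, k_+ or k_2), which is free per condition;
ranking the three constrained fits by residual sum of squares identifies
the microscopic step the chaperone inhibits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .activity import AggregationTrace
from .errors import FitConvergenceError, LoopchapError, TraceError

FREE_CONSTANTS = ("k_n", "k_plus", "k_2")


@dataclass(frozen=True)
class KineticParams:
    """Microscopic rate constants and reaction orders of the rate law.

    Units: k_n in M^(1-n_c) s^-1, k_plus in M^-1 s^-1, k_2 in M^-n_2 s^-1,
    m0 in mol/L.  Defaults for the reaction orders (n_c = n_2 = 2) follow
    the standard Aβ42 convention; m0 defaults to 3 µM.
    """

    k_n: float
    k_plus: float
    k_2: float
    n_c: float = 2.0
    n_2: float = 2.0
    m0: float = 3e-6

    def __post_init__(self):
        if min(self.k_n, self.k_plus, self.k_2) < 0:
            raise LoopchapError("rate constants must be >= 0")
        if self.m0 <= 0:
            raise LoopchapError("m0 must be > 0")
        if self.n_c < 1 or self.n_2 < 1:
            raise LoopchapError("reaction orders must be >= 1")

    @property
    def lam(self) -> float:
        """λ = sqrt(2 k_+ k_n m0^n_c), 1/s."""
        return math.sqrt(2.0 * self.k_plus * self.k_n * self.m0**self.n_c)

    @property
    def kappa(self) -> float:
        """κ = sqrt(2 k_+ k_2 m0^(n_2+1)), 1/s."""
        return math.sqrt(2.0 * self.k_plus * self.k_2 * self.m0 ** (self.n_2 + 1))


@dataclass(frozen=True)
class RateLawCoefficients:
    """Derived coefficients of the integrated rate law (all functions of λ, κ)."""

    lam: float
    kappa: float
    c_plus: float
    c_minus: float
    k_inf: float
    k_inf_tilde: float
    b_plus: float
    b_minus: float


def kinetic_coeffs(p: KineticParams) -> RateLawCoefficients:
    """Coefficients C±, k∞, k̃∞, B± for the secondary-nucleation branch.

    k̃∞ is computed stably as sqrt(k∞² + λ⁴/κ²), using the identity
    −4 C₊ C₋ κ² = λ⁴/κ².  Requires κ > 0; the κ = 0 (primary-only) limit is
    a separate branch of :func:`simulate_mass_fraction`.
    """
    lam, kap = p.lam, p.kappa
    if kap <= 0:
        raise LoopchapError("kinetic_coeffs requires kappa > 0; use the "
                            "primary-nucleation limit branch instead")
    c_plus = lam**2 / (2.0 * kap**2)
    k_inf = math.sqrt(2.0 * kap**2 / (p.n_2 * (p.n_2 + 1.0)) + 2.0 * lam**2 / p.n_c)
    k_inf_tilde = math.sqrt(k_inf**2 + lam**4 / kap**2)
    return RateLawCoefficients(
        lam=lam,
        kappa=kap,
        c_plus=c_plus,
        c_minus=-c_plus,
        k_inf=k_inf,
        k_inf_tilde=k_inf_tilde,
        b_plus=(k_inf + k_inf_tilde) / (2.0 * kap),
        b_minus=(k_inf - k_inf_tilde) / (2.0 * kap),
    )


def _mass_fraction_lam_kap(
    times: np.ndarray, lam: float, kap: float, n_c: float, n_2: float
) -> np.ndarray:
    """Closed-form M(t)/M(∞) parameterized directly by (λ, κ).

    All exp(κt) factors are combined in log space and the outer exponent is
    applied to the log of the bracket, so the evaluation cannot overflow for
    any κt.  B₋ + C₊ ≥ 0 holds algebraically (|B₋|/C₊ = λ²/(2κ²B₊) ≤ 1), so
    the log1p argument is bounded in (−1, 0].
    """
    t = np.asarray(times, dtype=float)
    if lam == 0.0:
        # unseeded, no primary nucleation: nothing ever aggregates
        return np.zeros_like(t)
    if kap == 0.0:
        # primary nucleation + elongation only (κ -> 0 limit of the rate law)
        k_inf0 = lam * math.sqrt(2.0 / n_c)
        logm = (k_inf0**2 / lam**2) * np.log1p(lam**2 * t / k_inf0) - k_inf0 * t
        return -np.expm1(logm)
    c_plus = lam**2 / (2.0 * kap**2)
    k_inf = math.sqrt(2.0 * kap**2 / (n_2 * (n_2 + 1.0)) + 2.0 * lam**2 / n_c)
    k_tilde = math.sqrt(k_inf**2 + lam**4 / kap**2)
    b_plus = (k_inf + k_tilde) / (2.0 * kap)
    b_minus = (k_inf - k_tilde) / (2.0 * kap)
    power = k_inf**2 / (kap * k_tilde)
    kt = kap * t
    log_f1 = math.log(b_plus + c_plus) - np.logaddexp(
        math.log(b_plus), math.log(c_plus) + kt
    )
    with np.errstate(divide="ignore"):
        # the log1p argument lies in (-1, 0] algebraically; rounding can
        # cross -1, where -inf correctly propagates to M = 1
        arg = np.maximum(b_minus * np.exp(-kt) / c_plus, -1.0)
        log_f2 = (
            math.log(c_plus) + kt + np.log1p(arg) - math.log(b_minus + c_plus)
        )
    logm = power * (log_f1 + log_f2) - k_inf * t
    return -np.expm1(logm)


def simulate_mass_fraction(p: KineticParams, times: Sequence[float]) -> np.ndarray:
    """Normalized fibril mass M(t)/M(∞) on a time grid (seconds).

    Returns values in [0, 1] with M(0) = 0.  k_n = 0 (no seeds, no primary
    nucleation) yields the identically-zero unseeded limit; k_2 = 0 uses the
    primary-nucleation-only limit branch.
    """
    t = np.asarray(times, dtype=float)
    if t.size and t.min() < 0:
        raise LoopchapError("times must be >= 0")
    return _mass_fraction_lam_kap(t, p.lam, p.kappa, p.n_c, p.n_2)


# ---------------------------------------------------------------------------
# Empirical sigmoid (half time / maximal growth rate)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidalFit:
    """Least-squares fit of F = F0 + A / (1 + exp[r_max (τ½ − t)])."""

    f0: float
    amplitude: float
    r_max: float
    tau_half: float
    covariance: np.ndarray
    r_squared: float
    tau_in_range: bool

    def __call__(self, t) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float), self.f0, self.amplitude,
                       self.r_max, self.tau_half)


def sigmoid(t, f0, amplitude, r_max, tau_half):
    """The empirical aggregation sigmoid; F(τ½) = F0 + A/2 by construction."""
    z = np.clip(r_max * (tau_half - t), -700, 700)
    return f0 + amplitude / (1.0 + np.exp(z))


def fit_sigmoid(trace: AggregationTrace | tuple, min_r_squared: float = 0.5
                ) -> SigmoidalFit:
    """Fit the empirical sigmoid to one trace.

    Deterministic: initial guesses come from the data (baseline, amplitude,
    crossing time) plus a fixed grid of growth-rate multipliers; the best
    converged fit by SSE wins.  Raises :class:`FitConvergenceError` when no
    start converges to an acceptable fit (A > 0, r_max > 0, R² above
    ``min_r_squared``), e.g. for a monotone-decreasing trace.
    """
    if isinstance(trace, AggregationTrace):
        t, y = trace.times, trace.signal
    else:
        t, y = (np.asarray(a, dtype=float) for a in trace)
    if t.size < 5:
        raise TraceError("sigmoid fit needs at least 5 points")
    f0_guess = float(np.median(y[: max(3, t.size // 10)]))
    a_guess = float(np.max(y) - f0_guess)
    if a_guess <= 0:
        raise FitConvergenceError("no positive amplitude in trace")
    half_level = f0_guess + a_guess / 2.0
    above = np.nonzero(y >= half_level)[0]
    tau_guess = float(t[above[0]]) if above.size else float(np.median(t))
    span = float(t[-1] - t[0])
    r_guess = 10.0 / span  # transition over ~1/10 of the observation window

    best = None
    for mult in (0.2, 1.0, 5.0, 25.0):
        p0 = (f0_guess, a_guess, r_guess * mult, tau_guess)
        try:
            popt, pcov = optimize.curve_fit(
                sigmoid, t, y, p0=p0,
                bounds=([-np.inf, 1e-12, 1e-12, -np.inf],
                        [np.inf, np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((sigmoid(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitConvergenceError("sigmoid fit did not converge from any start")
    sse, popt, pcov = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    f0, amp, r_max, tau = (float(v) for v in popt)
    if amp <= 0 or r_max <= 0 or r2 < min_r_squared:
        raise FitConvergenceError(
            f"sigmoid fit rejected (A={amp:.3g}, r_max={r_max:.3g}, R²={r2:.3f})"
        )
    return SigmoidalFit(
        f0=f0, amplitude=amp, r_max=r_max, tau_half=tau,
        covariance=pcov, r_squared=r2,
        tau_in_range=bool(t[0] <= tau <= t[-1]),
    )


@dataclass(frozen=True)
class NormalizedTrace:
    """Replicate-averaged ThT trace mapped to the [0, 1] fibril-mass scale."""

    times: np.ndarray
    signal: np.ndarray
    n_replicates: int
    fallback_used: bool = False


def normalize_tht(
    traces: Sequence[AggregationTrace], method: str = "sigmoid"
) -> NormalizedTrace:
    """Normalize replicates to [0, 1], then average pointwise.

    ``method="sigmoid"`` (default) maps each replicate through (F − F0)/A
    from its own sigmoid fit; replicates whose fit fails (or has negligible
    amplitude) fall back to min/max normalization and set
    ``fallback_used``.  ``method="minmax"`` normalizes every replicate by
    its own range directly — either convention is defensible for ThT data.
    Replicates on different time grids are interpolated onto the first
    replicate's grid.
    """
    if method not in ("sigmoid", "minmax"):
        raise LoopchapError("method must be 'sigmoid' or 'minmax'")
    traces = list(traces)
    if not traces:
        raise TraceError("normalize_tht needs at least one replicate")
    grid = traces[0].times
    normed, fallback = [], False
    for tr in traces:
        try:
            if method == "minmax":
                raise FitConvergenceError("min/max requested")
            fit = fit_sigmoid(tr)
            yn = (tr.signal - fit.f0) / fit.amplitude
        except (FitConvergenceError, TraceError):
            fallback = method == "sigmoid"
            lo, hi = float(np.min(tr.signal)), float(np.max(tr.signal))
            yn = (tr.signal - lo) / (hi - lo) if hi > lo else np.zeros_like(tr.signal)
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            yn = np.interp(grid, tr.times, yn)
        normed.append(yn)
    return NormalizedTrace(
        times=grid.copy(),
        signal=np.mean(normed, axis=0),
        n_replicates=len(traces),
        fallback_used=fallback,
    )


def halftime_delay(fits: Mapping[float, SigmoidalFit]):
    """Relative half times τ½(ratio)/τ½(0) per chaperone:substrate ratio."""
    import pandas as pd

    if 0 not in fits and 0.0 not in fits:
        raise LoopchapError("halftime_delay requires the 0% (control) condition")
    tau0 = fits[0 if 0 in fits else 0.0].tau_half
    rows = [
        {"ratio_pct": r, "tau_half_s": f.tau_half, "tau_rel": f.tau_half / tau0}
        for r, f in sorted(fits.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Constrained global fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalFitResult:
    """One constrained global fit of a chaperone dilution series.

    Exactly one rate constant (``free_constant``) varies per condition; the
    others are shared.  Only the products k_+·k_n and k_+·k_2 (equivalently
    λ², κ²) are identifiable from M(t), so per-condition values are reported
    as multiplicative factors on the control's product, plus the products
    themselves.
    """

    free_constant: str
    lam0: float
    kappa0: float
    factors: dict
    residual_sum_squares: float
    n_conditions: int
    n_starts: int
    seed: int
    m0: float
    n_c: float
    n_2: float

    @property
    def kplus_kn(self) -> float:
        """Control-condition product k_+ k_n = λ²/(2 m0^n_c)."""
        return self.lam0**2 / (2.0 * self.m0**self.n_c)

    @property
    def kplus_k2(self) -> float:
        """Control-condition product k_+ k_2 = κ²/(2 m0^(n_2+1))."""
        return self.kappa0**2 / (2.0 * self.m0 ** (self.n_2 + 1.0))


def _panel_arrays(panel: Mapping[float, object]):
    out = {}
    for cond, item in panel.items():
        if isinstance(item, NormalizedTrace):
            out[float(cond)] = (item.times, item.signal)
        else:
            t, y = item
            out[float(cond)] = (np.asarray(t, dtype=float),
                                np.asarray(y, dtype=float))
    return out


def _condition_lam_kap(log_lam2, log_kap2, log_f, free_constant):
    """(λ, κ) for one condition given control log-params and its log-factor."""
    dl = log_f if free_constant in ("k_n", "k_plus") else 0.0
    dk = log_f if free_constant in ("k_2", "k_plus") else 0.0
    return math.exp(0.5 * (log_lam2 + dl)), math.exp(0.5 * (log_kap2 + dk))


def global_fit(
    panel: Mapping[float, object],
    free_constant: str,
    m0: float = 3e-6,
    n_c: float = 2.0,
    n_2: float = 2.0,
    n_starts: int = 16,
    seed: int = 0,
) -> GlobalFitResult:
    """Constrained global fit of normalized ThT curves across a dilution series.

    ``panel`` maps chaperone:substrate ratio (%, with 0 = substrate alone)
    to a :class:`NormalizedTrace` or a ``(times, values)`` pair on the
    [0, 1] mass-fraction scale.  One of ``k_n``/``k_plus``/``k_2`` is free
    per condition (as a factor on the corresponding identifiable product);
    everything else is shared.  Optimization runs in log(λ², κ², factors)
    space with a moment-based initial guess refined by a seeded
    Latin-hypercube multi-start (±3 decades on λ², κ²).
    """
    if free_constant not in FREE_CONSTANTS:
        raise LoopchapError(f"free_constant must be one of {FREE_CONSTANTS}")
    data = _panel_arrays(panel)
    if 0.0 not in data:
        raise LoopchapError("global_fit requires the 0% (control) condition")
    conds = sorted(data)
    others = [c for c in conds if c != 0.0]

    spreads = [float(np.ptp(y)) for _, y in data.values()]
    if max(spreads) < 1e-12:
        raise LoopchapError("degenerate panel: all curves are flat")

    # --- moment-based initial guess from the control curve ----------------
    t0, y0 = data[0.0]
    fit0 = fit_sigmoid((t0, y0))
    kap_init = 1.5 * fit0.r_max  # max growth rate of the rate law ~ κ

    def _halftime_of(lam, kap):
        tt = np.linspace(0.0, max(4.0 * fit0.tau_half, t0[-1]), 600)
        yy = _mass_fraction_lam_kap(tt, lam, kap, n_c, n_2)
        if yy[-1] < 0.5:
            return np.inf
        return float(np.interp(0.5, yy, tt))

    # solve λ so the model half time matches the fitted one (monotone in λ)
    lo, hi = kap_init * 1e-6, kap_init
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if _halftime_of(mid, kap_init) > fit0.tau_half:
            lo = mid
        else:
            hi = mid
    lam_init = math.sqrt(lo * hi)

    # per-condition factor guesses from half-time shifts
    factor_init = []
    for c in others:
        try:
            fc = fit_sigmoid(data[c])
            shift = fc.tau_half / fit0.tau_half
        except (FitConvergenceError, TraceError):
            shift = 1.0
        factor_init.append(-2.0 * math.log(max(shift, 1e-3)))

    x0 = np.array([2 * math.log(lam_init), 2 * math.log(kap_init), *factor_init])

    def residuals(x):
        log_l2, log_k2 = x[0], x[1]
        res = []
        for i, c in enumerate(conds):
            log_f = 0.0 if c == 0.0 else x[1 + others.index(c) + 1]
            lam, kap = _condition_lam_kap(log_l2, log_k2, log_f, free_constant)
            t, y = data[c]
            with np.errstate(all="ignore"):
                model = _mass_fraction_lam_kap(t, lam, kap, n_c, n_2)
            res.append(model - y)
        # extreme multi-start parameters can overflow to NaN; penalize them
        return np.nan_to_num(np.concatenate(res), nan=10.0)

    starts = [x0]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=2, seed=seed)
        offsets = (sampler.random(n_starts - 1) - 0.5) * 2 * 3 * math.log(10)
        for off in offsets:
            xs = x0.copy()
            xs[0] += off[0]
            xs[1] += off[1]
            starts.append(xs)

    best = None
    for xs in starts:
        try:
            sol = optimize.least_squares(residuals, xs, method="lm",
                                         max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitConvergenceError("global fit did not converge from any start")
    rss, x = best
    factors = {0.0: 1.0}
    for i, c in enumerate(others):
        factors[c] = float(math.exp(x[2 + i]))
    return GlobalFitResult(
        free_constant=free_constant,
        lam0=float(math.exp(0.5 * x[0])),
        kappa0=float(math.exp(0.5 * x[1])),
        factors=factors,
        residual_sum_squares=rss,
        n_conditions=len(conds),
        n_starts=n_starts,
        seed=seed,
        m0=m0,
        n_c=n_c,
        n_2=n_2,
    )


def rank_global_fits(
    panel: Mapping[float, object],
    m0: float = 3e-6,
    n_c: float = 2.0,
    n_2: float = 2.0,
    n_starts: int = 16,
    seed: int = 0,
) -> list[GlobalFitResult]:
    """Fit all three candidate free constants; return fits sorted by RSS.

    The first element identifies the microscopic step whose per-condition
    modulation best explains the panel.
    """
    fits = [
        global_fit(panel, fc, m0=m0, n_c=n_c, n_2=n_2,
                   n_starts=n_starts, seed=seed)
        for fc in FREE_CONSTANTS
    ]
    return sorted(fits, key=lambda f: f.residual_sum_squares)
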