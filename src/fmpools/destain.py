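"""Normalization, QC, and destaining statistics for FM-dye fluorescence traces.

The quantities implemented here follow the standard analysis of FM-dye
destaining time courses:

* traces are background-divided and expressed as F/F(0) after subtracting the
  plateau remaining when every recycling vesicle has been destained;
* the *fractional destaining* rate, ``k = -(dF/dt)/F``, is estimated over
  short windows by dividing the OLS slope of the window (the "magenta line")
  by the fitted intensity at the window start (the "green circle");
* full 1 Hz time courses are fit with a single exponential
  ``F(t) = e^(-k t)`` (rate bounded to [0, 0.3] min^-1) or with the weighted
  sum of two exponentials, and lack of fit is quantified with a
  Wald-Wolfowitz runs test on the residual signs.

All rates are in min^-1; trace times are in seconds (frame period 4 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.sandbox.stats.runs import runstest_1samp

__all__ = [
    "ROITrace",
    "NormalizedTrace",
    "FracDestainEstimate",
    "ExpFit",
    "ResidualReport",
    "PopulationSummary",
    "normalize_trace",
    "baseline_slope",
    "fractional_destain",
    "corrected_fractional_destain",
    "fold_decrease",
    "fit_single_exp",
    "fit_double_exp",
    "residual_report",
    "population_summary",
]

SINGLE_EXP_BOUNDS = (0.0, 0.3)  # min^-1, printed fit bounds
SINGLE_EXP_START = 0.002  # bound-clipped equivalent of the printed start point
OUTLIER_THRESHOLD = 0.25  # max |residual| defining an outlier trace
SMOOTH_WINDOW = 5  # frames, centered moving average of residuals
QC_MAX_BASELINE_LOSS = 1.5  # %/min, acceptance criterion


@dataclass
class ROITrace:
    """One region's raw fluorescence time course with background metadata."""

    times: np.ndarray  # s, strictly increasing, frame period ~4 s
    F_raw: np.ndarray  # a.u.
    background: np.ndarray | float  # a.u., per frame or scalar
    prep_id: str = "prep0"
    roi_id: str = "roi0"
    channel: str = "dye1"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.F_raw = np.asarray(self.F_raw, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class NormalizedTrace:
    """Background-divided, plateau-subtracted F/F(0) trace."""

    times: np.ndarray  # s
    F: np.ndarray  # dimensionless
    plateau_subtracted: bool = True
    prep_id: str = "prep0"
    roi_id: str = "roi0"
    channel: str = "dye1"

    @property
    def times_min(self) -> np.ndarray:
        return self.times / 60.0


@dataclass
class FracDestainEstimate:
    """Windowed fractional-destaining statistic k_hat = -slope / F_start."""

    window: tuple[float, float]  # min
    slope: float  # min^-1 (of F/F(0))
    F_start: float  # fitted intensity at window start
    k_hat: float  # min^-1
    corrected: bool = False
    baseline_rate: float = 0.0  # min^-1 subtracted when corrected
    baseline_window: tuple[float, float] | None = None


@dataclass
class ExpFit:
    """Single- or double-exponential decay fit of a normalized trace."""

    kind: str  # "single" | "double"
    k: float | None = None  # single: rate, min^-1
    w_fast: float | None = None  # double: weight of the faster component
    k_fast: float | None = None
    k_slow: float | None = None
    residuals: np.ndarray | None = None
    times_min: np.ndarray | None = None
    sse: float = np.nan
    converged: bool = True
    identifiable: bool = True

    def predict(self, t_min: np.ndarray) -> np.ndarray:
        if self.kind == "single":
            return np.exp(-self.k * t_min)
        return self.w_fast * np.exp(-self.k_fast * t_min) \
            + (1 - self.w_fast) * np.exp(-self.k_slow * t_min)


@dataclass
class ResidualReport:
    """Structure diagnostics of a fit's residual series."""

    smoothed: np.ndarray  # centered moving average, window 5, edge-truncated
    max_abs_deviation: float  # of the raw residuals
    outlier: bool  # max |raw residual| > 0.25
    statistic: float  # runs-test z statistic
    p_value: float
    n_frames: int


@dataclass
class PopulationSummary:
    """Mean +/- s.e.m. across preparations of per-prep median traces."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_preps: int
    per_prep_median: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# normalization & QC
# ---------------------------------------------------------------------------

def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Frames whose acquisition times fall in the half-open window [t0, t1)."""
    t0, t1 = window
    return (times >= t0) & (times < t1)


def normalize_trace(
    raw: ROITrace,
    baseline_window: tuple[float, float],
    plateau_window: tuple[float, float],
) -> NormalizedTrace:
    """Divide by background, subtract the post-20 Hz plateau, scale to F/F(0).

    ``F = (F_raw/bg - plateau) / (baseline - plateau)`` where ``plateau`` and
    ``baseline`` are means of the background-divided signal over the two
    windows (seconds, half-open).  The baseline-window mean is 1 afterwards.
    """
    ratio = raw.F_raw / np.asarray(raw.background, dtype=float)
    mb = _window_mask(raw.times, baseline_window)
    mp = _window_mask(raw.times, plateau_window)
    if not mb.any() or not mp.any():
        raise ValueError("baseline/plateau window outside trace")
    baseline = ratio[mb].mean()
    plateau = ratio[mp].mean()
    denom = baseline - plateau
    if denom <= 1e-12:
        if np.allclose(ratio, plateau, atol=1e-9):
            # flat trace (e.g. raw equal to background): zero signal
            return NormalizedTrace(raw.times.copy(), np.zeros_like(ratio),
                                   prep_id=raw.prep_id, roi_id=raw.roi_id,
                                   channel=raw.channel)
        raise ValueError(
            f"degenerate normalization: baseline {baseline:.4g} <= "
            f"plateau {plateau:.4g}")
    return NormalizedTrace(raw.times.copy(), (ratio - plateau) / denom,
                           prep_id=raw.prep_id, roi_id=raw.roi_id,
                           channel=raw.channel)


def baseline_slope(
    trace: NormalizedTrace | ROITrace,
    window: tuple[float, float],
) -> tuple[float, bool]:
    """Baseline fluorescence loss in %/min over a rest window, plus QC verdict.

    OLS slope over the window expressed as percent of the fitted
    window-start intensity per minute.  A trace is accepted when the loss is
    at most 1.5 %/min in absolute value (boundary inclusive).
    """
    F = trace.F if isinstance(trace, NormalizedTrace) else trace.F_raw
    m = _window_mask(trace.times, window)
    if m.sum() < 3:
        raise ValueError("baseline window must contain at least 3 frames")
    t_min = (trace.times[m] - window[0]) / 60.0
    slope, intercept = np.polyfit(t_min, F[m], 1)
    loss = -slope / intercept * 100.0
    accept = abs(loss) <= QC_MAX_BASELINE_LOSS * (1 + 1e-9)  # <= is inclusive
    return float(loss), bool(accept)


# ---------------------------------------------------------------------------
# fractional destaining
# ---------------------------------------------------------------------------

def fractional_destain(
    trace: NormalizedTrace,
    window: tuple[float, float],
    t0_min: float = 0.0,
) -> FracDestainEstimate:
    """Windowed fractional-destaining estimate over ``window`` (minutes).

    The window is half-open, measured from ``t0_min`` (the onset of the
    destaining train, minutes in trace time).  The slope comes from an OLS
    line through all frames in the window; ``F_start`` is the fitted value at
    the window start; ``k_hat = -slope / F_start``.
    """
    t_min = trace.times_min - t0_min
    m = _window_mask(t_min, window)
    if m.sum() < 3:
        raise ValueError("window must contain at least 3 frames")
    x = t_min[m] - window[0]
    slope, f_start = np.polyfit(x, trace.F[m], 1)
    if f_start <= 0:
        raise ValueError("undefined estimate: fitted F at window start <= 0")
    return FracDestainEstimate(window=tuple(window), slope=float(slope),
                               F_start=float(f_start),
                               k_hat=float(-slope / f_start))


def corrected_fractional_destain(
    est: FracDestainEstimate,
    b: float,
    baseline_window: tuple[float, float] | None = None,
) -> FracDestainEstimate:
    """Subtract a baseline loss rate ``b`` (min^-1) from the estimate."""
    return FracDestainEstimate(
        window=est.window, slope=est.slope, F_start=est.F_start,
        k_hat=est.k_hat - b, corrected=True, baseline_rate=b,
        baseline_window=baseline_window)


def fold_decrease(k_early: float | FracDestainEstimate,
                  k_late: float | FracDestainEstimate) -> float:
    """Ratio of early to late fractional destaining (1 = constant rate)."""
    if isinstance(k_early, FracDestainEstimate):
        k_early = k_early.k_hat
    if isinstance(k_late, FracDestainEstimate):
        k_late = k_late.k_hat
    if k_late == 0:
        raise ZeroDivisionError("late fractional destaining is zero")
    return k_early / k_late


# ---------------------------------------------------------------------------
# exponential fits
# ---------------------------------------------------------------------------

def _window_times(trace: NormalizedTrace,
                  window: tuple[float, float] | None,
                  t0_min: float):
    t_min = trace.times_min - t0_min
    if window is None:
        m = t_min >= 0
    else:
        m = _window_mask(t_min, window)
    return t_min[m], trace.F[m]


def fit_single_exp(
    trace: NormalizedTrace,
    window: tuple[float, float] | None = None,
    t0_min: float = 0.0,
) -> ExpFit:
    """Constrained single-exponential fit ``F = e^(-k t)``.

    The amplitude is fixed at 1 (the model form has no free amplitude) and k
    is bounded to [0, 0.3] min^-1; the solver starts at 0.002 and a second
    start at the log-slope estimate guards against the bound.  t is in
    minutes from the destain onset.  Non-convergence is flagged, not raised.
    """
    t, F = _window_times(trace, window, t0_min)

    def resid(k):
        return np.exp(-k[0] * t) - F

    starts = [SINGLE_EXP_START]
    pos = F > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        k_ls = -np.polyfit(t[pos], np.log(F[pos]), 1)[0]
        starts.append(float(np.clip(k_ls, *SINGLE_EXP_BOUNDS)))
    best = None
    ok = True
    for s in starts:
        try:
            sol = least_squares(resid, [s], bounds=([SINGLE_EXP_BOUNDS[0]],
                                                    [SINGLE_EXP_BOUNDS[1]]))
        except Exception:
            ok = False
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return ExpFit(kind="single", k=np.nan, converged=False)
    k = float(best.x[0])
    r = F - np.exp(-k * t)
    return ExpFit(kind="single", k=k, residuals=r, times_min=t,
                  sse=float(np.sum(r ** 2)), converged=ok and best.success)


def fit_double_exp(
    trace: NormalizedTrace,
    window: tuple[float, float] | None = None,
    t0_min: float = 0.0,
    n_starts: int = 5,
) -> ExpFit:
    """Fit the weighted sum of two exponentials with unit total amplitude.

    ``F = w e^(-kf t) + (1-w) e^(-ks t)`` with ``0 <= w <= 1`` and rates
    positive; multiple starts; the output is ordered ``k_fast >= k_slow``.
    A degenerate (effectively single-exponential) solution is flagged
    non-identifiable: the weight then carries no information.
    """
    t, F = _window_times(trace, window, t0_min)

    def resid(p):
        w, kf, ks = p
        return w * np.exp(-kf * t) + (1 - w) * np.exp(-ks * t) - F

    lo, hi = [0.0, 0.0, 0.0], [1.0, 5.0, 5.0]
    start_list = [(0.39, 0.2, 0.032), (0.5, 0.1, 0.01), (0.5, 0.5, 0.05),
                  (0.2, 1.0, 0.1), (0.8, 0.05, 0.005)][:n_starts]
    best = None
    for s in start_list:
        try:
            sol = least_squares(resid, s, bounds=(lo, hi))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return ExpFit(kind="double", converged=False)
    w, kf, ks = best.x
    if kf < ks:
        kf, ks = ks, kf
        w = 1.0 - w
    r = F - (w * np.exp(-kf * t) + (1 - w) * np.exp(-ks * t))
    # degenerate when the two rates coincide or one component vanishes
    identifiable = (kf - ks) > 1e-3 * max(kf, 1e-12) and 1e-3 < w < 1 - 1e-3
    return ExpFit(kind="double", w_fast=float(w), k_fast=float(kf),
                  k_slow=float(ks), residuals=r, times_min=t,
                  sse=float(np.sum(r ** 2)), converged=best.success,
                  identifiable=bool(identifiable))


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, truncated (not padded) at the edges."""
    n = len(x)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def residual_report(fit: ExpFit) -> ResidualReport:
    """Runs-test lack-of-fit diagnostics on a fit's residual series.

    Smooths the raw residuals with a centered 5-frame moving average (for
    display and the reported deviation profile), flags the trace as an
    outlier when any raw residual exceeds 0.25 in magnitude, and tests for
    serial structure with the Wald-Wolfowitz runs test on the signs of the
    raw residuals.  Small p-values mean the decay deviates systematically
    from the fitted exponential.
    """
    r = np.asarray(fit.residuals, dtype=float)
    if len(r) < 10:
        raise ValueError("need at least 10 residuals")
    smoothed = _moving_average(r, SMOOTH_WINDOW)
    max_dev = float(np.max(np.abs(r)))
    stat, p = runstest_1samp(r, cutoff=0, correction=True)
    return ResidualReport(smoothed=smoothed, max_abs_deviation=max_dev,
                          outlier=max_dev > OUTLIER_THRESHOLD,
                          statistic=float(stat), p_value=float(p),
                          n_frames=len(r))


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def population_summary(traces: list[NormalizedTrace]) -> PopulationSummary:
    """Median within each preparation per frame, then mean +/- s.e.m. across.

    All traces must share a common time grid.
    """
    if not traces:
        raise ValueError("empty group")
    times = traces[0].times
    rows = []
    for tr in traces:
        if len(tr.times) != len(times) or not np.allclose(tr.times, times):
            raise ValueError("traces must share a common time base")
        rows.append({"prep": tr.prep_id, "F": tr.F})
    med = (pd.DataFrame([{"prep": r["prep"],
                          **{i: v for i, v in enumerate(r["F"])}}
                         for r in rows])
           .groupby("prep").median())
    mean = med.mean(axis=0).to_numpy()
    n = med.shape[0]
    sem = med.std(axis=0, ddof=1).to_numpy() / np.sqrt(n) if n > 1 \
        else np.zeros_like(mean)
    return PopulationSummary(times=times, mean=mean, sem=sem, n_preps=n,
                             per_prep_median=med)
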