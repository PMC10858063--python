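"""Three-component piecewise-linear segmentation of SmO2 windows.

Within a round the SmO2 trace shows an initial stable delay, a fast linear
desaturation, and a new lower equilibrium; within a recovery it shows a
delay, a fast resaturation, and a slow resaturation.  Each window is
modelled as three ordinary-least-squares line segments.  Candidate
breakpoints are searched exhaustively on the sample grid (which makes the
estimator deterministic), but the *reported* breakpoints are the continuous
times where adjacent fitted lines intersect::

    b = (a2 - a1) / (s1 - s2)

for lines ``y = a1 + s1 t`` and ``y = a2 + s2 t``.  Phase identity is
imposed only through the middle segment's slope being strictly the most
negative (desaturation) or most positive (resaturation) of the three; the
delay and equilibrium slopes are left unconstrained.

Heart rate at a breakpoint is read from the HR trace by linear
interpolation at the (fractional) intersection time.  Residual variability
per phase is summarised by the raw median absolute deviation about the
fitted line (no consistency scaling), robust to the skew of steady-state
exercise data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import UniformWindow

__all__ = [
    "SegmentationConfig",
    "LineSegment",
    "ExercisePhaseFit",
    "RecoveryPhaseFit",
    "FitFailure",
    "fit_three_phase",
    "fit_window",
    "brute_force_three_phase",
    "heart_rate_at",
    "phase_residual_mad",
]


class FitFailure(RuntimeError):
    """No feasible three-segment candidate exists for this window."""


@dataclass(frozen=True)
class SegmentationConfig:
    #: shortest admissible segment, seconds (5 s resolves the shortest
    #: delay-like features seen at round start while averaging 1 Hz noise)
    min_segment_s: float = 5.0
    #: flag the fit low-confidence when a continuous intersection departs
    #: further than this from its grid breakpoint
    low_confidence_tol_s: float = 2.0


@dataclass(frozen=True)
class LineSegment:
    """One fitted line ``y = intercept + slope * t`` over ``span`` (half-open)."""

    intercept: float
    slope: float
    span: tuple[float, float]
    n_samples: int

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ExercisePhaseFit:
    """Within-round three-line model: delay -> fast desaturation -> equilibrium."""

    TD: float  # time delay to fast desaturation, s
    FDR: float  # fast desaturation rate, %/s (negative)
    DD: float  # desaturation duration, s
    SS_level: float  # mean fitted saturation over the equilibrium, %
    HRS: float  # heart rate at start of fast desaturation, bpm (nan if absent)
    HRE: float  # heart rate at end of fast desaturation, bpm
    MAD_FD: float  # residual MAD during fast desaturation, %
    MAD_Eq: float  # residual MAD during equilibrium, %
    segments: tuple[LineSegment, LineSegment, LineSegment]
    sse: float
    low_confidence: bool = False


@dataclass(frozen=True)
class RecoveryPhaseFit:
    """Between-round three-line model: delay -> fast resaturation -> slow resaturation."""

    RD: float  # resaturation delay, s
    FRR: float  # fast resaturation rate, %/s (positive)
    FRD: float  # fast resaturation duration, s
    SR_slope: float  # slow resaturation slope, %/s
    HRSF: float  # heart rate at start of fast resaturation, bpm
    HREF: float  # heart rate at end of fast resaturation, bpm
    MAD_FR: float  # residual MAD during fast resaturation, %
    MAD_SR: float  # residual MAD during slow resaturation, %
    segments: tuple[LineSegment, LineSegment, LineSegment]
    sse: float
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# vectorised grid search
# ---------------------------------------------------------------------------

def _interval_ols(prefix: np.ndarray, i: np.ndarray, j: np.ndarray):
    """OLS slope/intercept/SSE for half-open sample intervals [i, j).

    ``prefix`` holds cumulative sums of (1, t, t^2, y, y^2, t*y) with a
    leading zero row, so interval sums are prefix[j] - prefix[i].
    """
    s = prefix[j] - prefix[i]
    n, st, stt, sy, syy, sty = (s[..., k] for k in range(6))
    denom = n * stt - st * st
    slope = (n * sty - st * sy) / denom
    intercept = (sy - slope * st) / n
    sse = syy - intercept * sy - slope * sty
    return slope, intercept, np.maximum(sse, 0.0)


def _candidate_grid(n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """All (b1, b2) pairs with segment lengths >= m, b1-major then b2 order."""
    pairs = [
        (b1, b2)
        for b1 in range(m, n - 2 * m + 1)
        for b2 in range(b1 + m, n - m + 1)
    ]
    if not pairs:
        raise FitFailure(f"window of {n} samples too short for 3 segments of {m}")
    arr = np.array(pairs, dtype=int)
    return arr[:, 0], arr[:, 1]


def _search(t: np.ndarray, y: np.ndarray, direction: str, m: int):
    """Return (b1, b2, slopes, intercepts, sse_total) of the SSE-minimal
    feasible candidate; ties resolved toward smaller b1 then smaller b2."""
    n = t.size
    data = np.column_stack([np.ones(n), t, t * t, y, y * y, t * y])
    prefix = np.vstack([np.zeros(6), np.cumsum(data, axis=0)])
    b1, b2 = _candidate_grid(n, m)
    zeros = np.zeros_like(b1)
    ends = np.full_like(b1, n)
    s1, a1, e1 = _interval_ols(prefix, zeros, b1)
    s2, a2, e2 = _interval_ols(prefix, b1, b2)
    s3, a3, e3 = _interval_ols(prefix, b2, ends)
    if direction == "desaturation":
        feasible = (s2 < s1) & (s2 < s3)
    elif direction == "resaturation":
        feasible = (s2 > s1) & (s2 > s3)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not feasible.any():
        raise FitFailure(
            f"no feasible breakpoint pair: middle slope never the most "
            f"{'negative' if direction == 'desaturation' else 'positive'} "
            f"(trace may be flat or monotone the wrong way)"
        )
    total = e1 + e2 + e3
    total[~feasible] = np.inf
    k = int(np.argmin(total))  # first minimum == smallest b1, then b2
    return (
        int(b1[k]),
        int(b2[k]),
        (float(s1[k]), float(s2[k]), float(s3[k])),
        (float(a1[k]), float(a2[k]), float(a3[k])),
        float(total[k]),
    )


def _intersection(a1: float, s1: float, a2: float, s2: float, fallback: float):
    """Continuous intersection of two lines; fall back to the grid time when
    the lines are (numerically) parallel."""
    if s1 == s2:
        return fallback, True
    return (a2 - a1) / (s1 - s2), False


def brute_force_three_phase(
    t: np.ndarray, y: np.ndarray, direction: str, min_segment: int = 5
):
    """Reference three-segment fit by explicit enumeration with ``np.polyfit``.

    Independent of the prefix-sum search path; intended for validating the
    grid search on small windows.  Returns ``(b1, b2, sse)`` of the winner
    or raises FitFailure.
    """
    n = len(t)
    best = None
    for b1 in range(min_segment, n - 2 * min_segment + 1):
        for b2 in range(b1 + min_segment, n - min_segment + 1):
            sl, ic, sse = [], [], 0.0
            for i, j in ((0, b1), (b1, b2), (b2, n)):
                coef = np.polyfit(t[i:j], y[i:j], 1)
                resid = y[i:j] - np.polyval(coef, t[i:j])
                sl.append(coef[0])
                ic.append(coef[1])
                sse += float(resid @ resid)
            if direction == "desaturation":
                ok = sl[1] < sl[0] and sl[1] < sl[2]
            else:
                ok = sl[1] > sl[0] and sl[1] > sl[2]
            if ok and (best is None or sse < best[2]):
                best = (b1, b2, sse)
    if best is None:
        raise FitFailure("no feasible candidate (brute force)")
    return best


def heart_rate_at(window: UniformWindow, t: float) -> float:
    """HR at (possibly fractional) window-local time ``t`` by linear
    interpolation of the 1 Hz trace; NaN when HR is absent around ``t``."""
    if window.hr is None:
        return float("nan")
    lo, hi = float(window.local_time[0]), float(window.local_time[-1])
    tc = min(max(t, lo), hi)
    j = int(np.searchsorted(window.local_time, tc, side="right")) - 1
    j = min(max(j, 0), window.local_time.size - 2)
    t0, t1 = window.local_time[j], window.local_time[j + 1]
    h0, h1 = window.hr[j], window.hr[j + 1]
    if not (np.isfinite(h0) and np.isfinite(h1)):
        return float("nan")
    if tc == t0:
        return float(h0)
    return float(h0 + (h1 - h0) * (tc - t0) / (t1 - t0))


def phase_residual_mad(window: UniformWindow, segment: LineSegment) -> float:
    """Median absolute deviation of SmO2 about a fitted segment line.

    Raw MAD (no 1.4826 consistency constant): the robust spread statistic
    itself is reported, in % saturation.
    """
    t0, t1 = segment.span
    mask = (window.local_time >= t0 - 1e-9) & (window.local_time < t1 - 1e-9)
    if mask.sum() < 3:
        raise ValueError("segment span must contain >= 3 samples")
    resid = window.smo2[mask] - segment.predict(window.local_time[mask])
    return float(np.median(np.abs(resid)))


def fit_three_phase(
    window: UniformWindow,
    direction: str,
    config: SegmentationConfig = SegmentationConfig(),
):
    """Fit the three-line model to one window.

    Exhaustive search over breakpoint pairs on the sample grid, OLS line per
    segment, feasibility via the middle-slope-extremum rule, winner by total
    SSE (ties toward earlier breakpoints).  Reported breakpoints are the
    continuous intersections of adjacent fitted lines.

    Returns an :class:`ExercisePhaseFit` for ``direction="desaturation"`` or
    a :class:`RecoveryPhaseFit` for ``"resaturation"``; raises
    :class:`FitFailure` when no candidate is feasible.
    """
    t = np.asarray(window.local_time, dtype=float)
    y = np.asarray(window.smo2, dtype=float)
    step = float(t[1] - t[0])
    m = max(2, int(round(config.min_segment_s / step)))
    if t.size < 3 * m:
        raise FitFailure(f"window has {t.size} samples; needs >= {3 * m}")

    b1, b2, slopes, intercepts, sse = _search(t, y, direction, m)
    s1, s2, s3 = slopes
    a1, a2, a3 = intercepts

    bp1, par1 = _intersection(a1, s1, a2, s2, float(t[b1]))
    bp2, par2 = _intersection(a2, s2, a3, s3, float(t[b2]))
    low_conf = (
        par1
        or par2
        or abs(bp1 - t[b1]) > config.low_confidence_tol_s
        or abs(bp2 - t[b2]) > config.low_confidence_tol_s
    )

    end = float(t[-1]) + step
    segments = (
        LineSegment(a1, s1, (float(t[0]), float(t[b1])), b1),
        LineSegment(a2, s2, (float(t[b1]), float(t[b2])), b2 - b1),
        LineSegment(a3, s3, (float(t[b2]), end), t.size - b2),
    )
    mad_mid = phase_residual_mad(window, segments[1])
    mad_last = phase_residual_mad(window, segments[2])
    hr_bp1 = heart_rate_at(window, bp1)
    hr_bp2 = heart_rate_at(window, bp2)

    if direction == "desaturation":
        ss_level = float(np.mean(segments[2].predict(t[b2:])))
        return ExercisePhaseFit(
            TD=bp1,
            FDR=s2,
            DD=bp2 - bp1,
            SS_level=ss_level,
            HRS=hr_bp1,
            HRE=hr_bp2,
            MAD_FD=mad_mid,
            MAD_Eq=mad_last,
            segments=segments,
            sse=sse,
            low_confidence=low_conf,
        )
    return RecoveryPhaseFit(
        RD=bp1,
        FRR=s2,
        FRD=bp2 - bp1,
        SR_slope=s3,
        HRSF=hr_bp1,
        HREF=hr_bp2,
        MAD_FR=mad_mid,
        MAD_SR=mad_last,
        segments=segments,
        sse=sse,
        low_confidence=low_conf,
    )


def fit_window(window: UniformWindow, config: SegmentationConfig = SegmentationConfig()):
    """Dispatch on window kind: rounds desaturate, rests resaturate."""
    direction = "desaturation" if window.kind == "round" else "resaturation"
    return fit_three_phase(window, direction, config)
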