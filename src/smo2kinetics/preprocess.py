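"""Artifact smoothing, resampling, window slicing and occlusion latency.

The raw optical signal is exported at 1 Hz; isolated movement artifacts
(sensor shifts during strikes/footwork) appear as single-sample excursions
and are removed with a running 5 s median before any windowing, so that
round/rest boundaries see an already-smoothed trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .session import SampleSeries, SessionRecord, SessionValidationError

__all__ = [
    "UniformWindow",
    "median_filter",
    "resample_to_1hz",
    "extract_windows",
    "occlusion_latency",
    "filter_record",
    "OcclusionDetectionFailure",
]


class OcclusionDetectionFailure(RuntimeError):
    """No qualifying post-inflation decline found."""


@dataclass(frozen=True)
class UniformWindow:
    """One analysis window (a round or an inter-round rest) for one leg.

    ``local_time`` restarts at the window start; the default layout yields
    180 samples per round and 60 per rest at 1 Hz.
    """

    kind: str  # "round" | "rest"
    index: int  # 1-based round number (rest i follows round i)
    leg: str
    local_time: np.ndarray
    smo2: np.ndarray
    hr: np.ndarray | None
    start: float  # session time of window start

    @property
    def duration(self) -> float:
        step = float(self.local_time[1] - self.local_time[0])
        return float(self.local_time[-1]) + step - float(self.local_time[0])


def median_filter(series: SampleSeries, width: float = 5.0) -> SampleSeries:
    """Running median over a centred window, shrinking symmetrically at edges.

    ``width`` is in seconds and must correspond to an odd number of samples
    at the series' step (5 samples at 1 Hz for the default 5 s).  The
    symmetric shrink keeps output length equal to input length without
    padding: at distance ``d`` from an edge the half-width is ``min(k, d)``,
    so the first and last samples pass through unchanged.
    """
    if width < 1:
        raise ValueError("filter width must be >= 1 s")
    n_samples = int(round(width / series.step))
    if n_samples % 2 == 0 or n_samples < 1:
        raise ValueError(
            f"width {width} s is {n_samples} samples at step {series.step} s; must be odd"
        )
    k = n_samples // 2
    x = series.smo2
    n = x.size
    out = np.empty_like(x)
    for i in range(n):
        h = min(k, i, n - 1 - i)
        out[i] = np.median(x[i - h : i + h + 1])
    return replace(series, smo2=out)


def filter_record(record: SessionRecord, width: float = 5.0) -> SessionRecord:
    """Apply the median filter to both legs' SmO2 traces (HR untouched)."""
    filtered = {leg: median_filter(s, width) for leg, s in record.series.items()}
    return replace(record, series=filtered)


def resample_to_1hz(series: SampleSeries) -> tuple[SampleSeries, bool]:
    """Average consecutive non-overlapping 0.5 s sample pairs to 1 Hz.

    Mirrors the device-export convention (0.5 s update averaged to 1 s).
    Each output sample is stamped at the midpoint of its pair, keeping
    samples of a linear trend exactly on the underlying line.  Returns the
    resampled series and a flag that is True when an odd trailing input
    sample was dropped.
    """
    step = series.step
    if abs(step - 0.5) > 0.05:
        raise SessionValidationError(
            f"resample_to_1hz expects 0.5 s input step, got {step:.3f} s"
        )
    n_pairs = series.time.size // 2
    dropped = bool(series.time.size % 2)
    t = series.time[: 2 * n_pairs].reshape(n_pairs, 2).mean(axis=1)
    smo2 = series.smo2[: 2 * n_pairs].reshape(n_pairs, 2).mean(axis=1)
    hr = None
    if series.hr is not None:
        hr = series.hr[: 2 * n_pairs].reshape(n_pairs, 2).mean(axis=1)
    return SampleSeries(t, smo2, hr), dropped


def _slice(series: SampleSeries, start: float, end: float) -> slice:
    i0 = int(np.searchsorted(series.time, start - 1e-9, side="left"))
    i1 = int(np.searchsorted(series.time, end - 1e-9, side="left"))
    return slice(i0, i1)


def extract_windows(record: SessionRecord, legs: tuple[str, ...] = ("lead", "rear")) -> list[UniformWindow]:
    """Slice each leg's trace into round and inter-round rest windows.

    Windows overlapping an unanalysable span (long sensor dropout) are
    excluded.  Local time restarts at 0 at every window start.
    """
    layout = record.layout
    windows: list[UniformWindow] = []
    spans: list[tuple[str, int, float, float]] = []
    for i in range(1, layout.n_rounds + 1):
        spans.append(("round", i, *layout.round_window(i)))
        if i < layout.n_rounds:
            spans.append(("rest", i, *layout.rest_window(i)))
    for leg in legs:
        series = record.series[leg]
        for kind, idx, start, end in spans:
            if any(b0 < end and b1 > start for b0, b1 in record.bad_spans):
                continue  # unanalysable: long gap inside this window
            sl = _slice(series, start, end)
            windows.append(
                UniformWindow(
                    kind=kind,
                    index=idx,
                    leg=leg,
                    local_time=series.time[sl] - start,
                    smo2=series.smo2[sl],
                    hr=None if series.hr is None else series.hr[sl],
                    start=start,
                )
            )
    return windows


def occlusion_latency(
    series: SampleSeries,
    inflation_time: float,
    k_sd: float = 3.0,
    persistence: int = 2,
    search_window: float = 10.0,
    min_baseline: float = 10.0,
) -> float:
    """Latency from cuff inflation to the onset of the SmO2 decline.

    Used on arterial-occlusion calibration recordings (0.5 s sampling) to
    verify sensor responsiveness.  The baseline mean and SD are taken from
    the pre-inflation samples; the decline onset is the sample *preceding*
    the first post-inflation sample that falls below
    ``baseline_mean - k_sd * baseline_sd`` and keeps falling for at least
    ``persistence`` further samples.

    Returns the latency in seconds; raises OcclusionDetectionFailure when no
    qualifying decline occurs within ``search_window`` seconds.
    """
    t, y = series.time, series.smo2
    pre = t < inflation_time
    if t[pre].size == 0 or inflation_time - t[pre][0] < min_baseline:
        raise SessionValidationError("need >= 10 s of pre-inflation baseline")
    base_mean = float(np.mean(y[pre]))
    base_sd = float(np.std(y[pre]))
    threshold = base_mean - k_sd * base_sd
    post = np.flatnonzero((t >= inflation_time) & (t <= inflation_time + search_window))
    for j in post:
        if y[j] >= threshold:
            continue
        tail = y[j : j + persistence + 1]
        if tail.size >= persistence + 1 and np.all(np.diff(tail) < 0):
            onset = t[j - 1] if j > 0 else t[j]
            return float(max(onset, inflation_time) - inflation_time)
    raise OcclusionDetectionFailure(
        f"no decline below {threshold:.2f}% with {persistence}-sample "
        f"persistence within {search_window:g} s of inflation"
    )
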