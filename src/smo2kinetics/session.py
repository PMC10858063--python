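"""Session containers and disk I/O for round-based SmO2/HR recordings.

A session is a continuous near-infrared-spectroscopy recording of muscle
oxygen saturation (SmO2, %) from one sensor per leg plus heart rate (bpm),
exported as a uniform 1 Hz time series, together with the round/rest layout
of the training session, a punch log, and athlete metadata.

Time convention: seconds, ``t = 0`` at session start; windows are half-open
``[start, start + duration)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampleSeries",
    "SessionLayout",
    "PunchLog",
    "AthleteMeta",
    "SessionRecord",
    "ValidityReport",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "check_signal_validity",
]

#: Fat thickness (mm) over the muscle above which the optical NIRS signal is
#: considered unreliable (adipose tissue absorbs/scatters the NIR photons).
FAT_THICKNESS_LIMIT_MM = 14.0

#: Gaps up to this many seconds are bridged by linear interpolation; longer
#: dropouts leave the affected analysis windows marked unanalysable.
MAX_INTERP_GAP_S = 2.0


class SessionFormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


class SessionValidationError(ValueError):
    """Raised when parsed data violate a session invariant."""


@dataclass(frozen=True)
class SampleSeries:
    """A uniformly sampled SmO2 (+ optional HR) trace.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing with a constant step.
    smo2 : array of float
        Muscle oxygen saturation per sample, percent in [0, 100].
    hr : array of float or None
        Heart rate per sample (bpm, > 0); NaN marks missing samples.
    """

    time: np.ndarray
    smo2: np.ndarray
    hr: np.ndarray | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        smo2 = np.asarray(self.smo2, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "smo2", smo2)
        if self.hr is not None:
            object.__setattr__(self, "hr", np.asarray(self.hr, dtype=float))
        if time.ndim != 1 or time.size < 2:
            raise SessionValidationError("time series needs >= 2 samples")
        if smo2.shape != time.shape:
            raise SessionValidationError("smo2 and time length mismatch")
        if self.hr is not None and self.hr.shape != time.shape:
            raise SessionValidationError("hr and time length mismatch")
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise SessionValidationError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], atol=1e-6):
            raise SessionValidationError("time step must be constant")
        finite = np.isfinite(smo2)
        if np.any((smo2[finite] < 0.0) | (smo2[finite] > 100.0)):
            raise SessionValidationError("smo2 outside [0, 100]")
        if self.hr is not None:
            hr_finite = self.hr[np.isfinite(self.hr)]
            if np.any(hr_finite <= 0):
                raise SessionValidationError("hr must be > 0 where present")

    @property
    def step(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def span(self) -> tuple[float, float]:
        """Half-open [first sample, last sample + step)."""
        return float(self.time[0]), float(self.time[-1]) + self.step


@dataclass(frozen=True)
class SessionLayout:
    """Round/rest structure of a training session.

    Defaults follow the standard professional sparring format of six 3-min
    rounds separated by 1-min recoveries.  Rest windows are the inter-round
    recoveries only (``n_rounds - 1`` of them).
    """

    n_rounds: int = 6
    round_duration: float = 180.0
    rest_duration: float = 60.0
    session_start: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.round_duration <= 0 or self.rest_duration < 0:
            raise SessionValidationError("degenerate layout")

    @property
    def round_start_times(self) -> np.ndarray:
        period = self.round_duration + self.rest_duration
        return self.session_start + period * np.arange(self.n_rounds)

    @property
    def total_duration(self) -> float:
        """Duration covered by rounds and inter-round rests."""
        return (
            self.n_rounds * self.round_duration
            + (self.n_rounds - 1) * self.rest_duration
        )

    def round_window(self, index: int) -> tuple[float, float]:
        """Half-open [start, end) of 1-based round *index*."""
        start = float(self.round_start_times[index - 1])
        return start, start + self.round_duration

    def rest_window(self, index: int) -> tuple[float, float]:
        """Half-open [start, end) of the rest after 1-based round *index*."""
        if index >= self.n_rounds:
            raise SessionValidationError("rest index beyond inter-round rests")
        _, round_end = self.round_window(index)
        return round_end, round_end + self.rest_duration


@dataclass(frozen=True)
class PunchLog:
    """Punches thrown during the session, in one of two dialects.

    Preferred: ``event_times`` — sorted punch times (session seconds).
    Fallback: ``round_counts`` — per-round totals when only counts exist.
    """

    modality: str
    event_times: np.ndarray | None = None
    round_counts: dict[int, int] | None = None

    MODALITIES = ("bag", "pad", "spar")

    def __post_init__(self) -> None:
        if self.modality not in self.MODALITIES:
            raise SessionValidationError(f"unknown modality {self.modality!r}")
        if self.event_times is None and self.round_counts is None:
            raise SessionValidationError("punch log needs events or counts")
        if self.event_times is not None:
            ev = np.sort(np.asarray(self.event_times, dtype=float))
            object.__setattr__(self, "event_times", ev)
            if ev.size and ev[0] < 0:
                raise SessionValidationError("negative punch time")
        if self.round_counts is not None:
            for rnd, cnt in self.round_counts.items():
                if cnt < 0 or int(cnt) != cnt:
                    raise SessionValidationError(
                        f"round {rnd}: count must be a non-negative integer"
                    )

    @property
    def has_events(self) -> bool:
        return self.event_times is not None


@dataclass(frozen=True)
class AthleteMeta:
    """Athlete identity and sensor placement metadata."""

    athlete_id: str
    fat_thickness_mm: float
    #: maps each SmO2 channel name to the boxing-stance leg it instruments
    channel_legs: dict[str, str] = field(
        default_factory=lambda: {"smo2_lead": "lead", "smo2_rear": "rear"}
    )

    def __post_init__(self) -> None:
        if self.fat_thickness_mm < 0:
            raise SessionValidationError("fat thickness must be >= 0")
        legs = set(self.channel_legs.values())
        if legs != {"lead", "rear"}:
            raise SessionValidationError("both legs must be labelled")


@dataclass(frozen=True)
class ValidityReport:
    """Advisory signal-validity check result."""

    valid: bool
    fat_thickness_mm: float
    message: str


@dataclass(frozen=True)
class SessionRecord:
    """One athlete-session: per-leg SmO2 series + HR, layout, punches, meta."""

    series: dict[str, SampleSeries]  # keyed by leg: "lead" / "rear"
    layout: SessionLayout
    punches: PunchLog
    meta: AthleteMeta
    #: [start, end) spans left unanalysable by long gaps
    bad_spans: tuple[tuple[float, float], ...] = ()
    #: sample times filled by short-gap interpolation
    interpolated_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        legs = set(self.series)
        if legs != {"lead", "rear"}:
            raise SessionValidationError("series must cover lead and rear legs")
        spans = {leg: s.span for leg, s in self.series.items()}
        ref = spans["lead"]
        if any(not np.allclose(sp, ref) for sp in spans.values()):
            raise SessionValidationError("legs must share one time base")
        # a sample stamped at t represents [t - step/2, t + step/2), so the
        # layout may start up to one step before the first timestamp
        lo, hi = ref
        step = self.series["lead"].step
        if self.layout.session_start < lo - step or (
            self.layout.session_start + self.layout.total_duration > hi + step
        ):
            raise SessionValidationError("layout exceeds recording span")


def check_signal_validity(meta: AthleteMeta) -> ValidityReport:
    """Flag sessions whose adipose layer is too thick for reliable NIRS.

    The check is advisory: analysis proceeds on flagged sessions, with the
    report attached as a warning.  The boundary itself (14 mm) is *not*
    exceeded by equality — a strictly greater thickness is required to flag.
    """
    t = meta.fat_thickness_mm
    if t < 0:
        raise SessionValidationError("fat thickness must be >= 0")
    if t > FAT_THICKNESS_LIMIT_MM:
        return ValidityReport(
            False, t, f"fat thickness {t:.1f} mm exceeds {FAT_THICKNESS_LIMIT_MM:.0f} mm; "
            "SmO2 signal likely attenuated",
        )
    return ValidityReport(True, t, "fat thickness within NIRS-valid range")


# ---------------------------------------------------------------------------
# disk formats
# ---------------------------------------------------------------------------

_TS_COLUMNS = ["time_s", "smo2_lead", "smo2_rear", "hr"]


def _fill_gaps(
    time: np.ndarray, values: np.ndarray, step: float
) -> tuple[np.ndarray, np.ndarray, list[float], list[tuple[float, float]]]:
    """Reindex to a uniform grid; interpolate short gaps, report long ones."""
    grid = np.round((time - time[0]) / step).astype(int)
    n = grid[-1] + 1
    full = np.full(n, np.nan)
    full[grid] = values
    full_t = time[0] + step * np.arange(n)
    missing = np.isnan(full)
    interp_times: list[float] = []
    bad: list[tuple[float, float]] = []
    if missing.any():
        idx = np.flatnonzero(missing)
        # group consecutive missing indices into gaps
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            gap_len = run.size * step
            lo, hi = run[0], run[-1]
            if gap_len <= MAX_INTERP_GAP_S and lo > 0 and hi < n - 1:
                full[run] = np.interp(full_t[run], time, values)
                interp_times.extend(full_t[run].tolist())
            else:
                bad.append((float(full_t[lo]), float(full_t[hi] + step)))
    return full_t, full, interp_times, bad


def read_layout_config(path: str | Path) -> tuple[SessionLayout, AthleteMeta, str]:
    """Parse the key-value layout/metadata config.

    Recognised keys: n_rounds, round_s, rest_s, athlete_id, fat_thickness_mm,
    modality.  Lines starting with '#' are comments.
    """
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SessionFormatError(f"layout config line not key=value: {raw!r}")
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    try:
        layout = SessionLayout(
            n_rounds=int(kv.get("n_rounds", 6)),
            round_duration=float(kv.get("round_s", 180)),
            rest_duration=float(kv.get("rest_s", 60)),
        )
        meta = AthleteMeta(
            athlete_id=kv.get("athlete_id", "anon"),
            fat_thickness_mm=float(kv.get("fat_thickness_mm", 0.0)),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, SessionValidationError):
            raise
        raise SessionFormatError(f"bad layout config value: {exc}") from exc
    return layout, meta, kv.get("modality", "bag")


def write_layout_config(
    path: str | Path, layout: SessionLayout, meta: AthleteMeta, modality: str
) -> None:
    lines = [
        f"n_rounds = {layout.n_rounds}",
        f"round_s = {layout.round_duration:g}",
        f"rest_s = {layout.rest_duration:g}",
        f"athlete_id = {meta.athlete_id}",
        f"fat_thickness_mm = {meta.fat_thickness_mm:g}",
        f"modality = {modality}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_punch_log(path: str | Path, modality: str) -> PunchLog:
    """Read a punch log CSV; dialect auto-detected from the header.

    ``time_s`` rows give event times; ``round,count`` rows give per-round
    totals.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == ["time_s"]:
        return PunchLog(modality=modality, event_times=df["time_s"].to_numpy())
    if cols == ["round", "count"]:
        counts = {int(r): int(c) for r, c in zip(df["round"], df["count"])}
        return PunchLog(modality=modality, round_counts=counts)
    raise SessionFormatError(
        f"punch log header must be [time_s] or [round,count], got {cols}"
    )


def write_punch_log(path: str | Path, punches: PunchLog) -> None:
    if punches.has_events:
        pd.DataFrame({"time_s": punches.event_times}).to_csv(path, index=False)
    else:
        items = sorted(punches.round_counts.items())
        pd.DataFrame(items, columns=["round", "count"]).to_csv(path, index=False)


def read_session(
    timeseries_path: str | Path,
    layout_path: str | Path,
    punches_path: str | Path | None = None,
) -> SessionRecord:
    """Read and validate one athlete-session from disk.

    The time-series CSV must carry columns ``time_s, smo2_lead, smo2_rear,
    hr`` (hr may be empty).  Missing rows are treated as sensor dropouts:
    gaps of at most 2 s are linearly interpolated and flagged; longer gaps
    mark their span unanalysable.
    """
    df = pd.read_csv(timeseries_path)
    if list(df.columns) != _TS_COLUMNS:
        raise SessionFormatError(
            f"expected columns {_TS_COLUMNS}, got {list(df.columns)}"
        )
    time = df["time_s"].to_numpy(dtype=float)
    if time.size < 2:
        raise SessionValidationError("time series needs >= 2 samples")
    if np.any(np.diff(time) <= 0):
        raise SessionValidationError("time must be strictly increasing")
    step = float(np.median(np.diff(time)))

    layout, meta, modality = read_layout_config(layout_path)

    interp: list[float] = []
    bad: list[tuple[float, float]] = []
    filled: dict[str, np.ndarray] = {}
    grid_t: np.ndarray | None = None
    for col in ("smo2_lead", "smo2_rear", "hr"):
        vals = df[col].to_numpy(dtype=float)
        if col.startswith("smo2"):
            finite = np.isfinite(vals)
            if np.any((vals[finite] < 0) | (vals[finite] > 100)):
                raise SessionValidationError(f"{col} outside [0, 100]")
        grid_t, full, it, b = _fill_gaps(time, vals, step)
        filled[col] = full
        interp.extend(it)
        bad.extend(b)

    hr = filled["hr"]
    if np.all(np.isnan(hr)):
        hr = None
    series = {
        meta.channel_legs[col]: SampleSeries(grid_t, filled[col], hr)
        for col in ("smo2_lead", "smo2_rear")
    }

    if punches_path is not None:
        punches = read_punch_log(punches_path, modality)
    else:
        punches = PunchLog(modality=modality, event_times=np.empty(0))

    return SessionRecord(
        series=series,
        layout=layout,
        punches=punches,
        meta=meta,
        bad_spans=tuple(sorted(set(bad))),
        interpolated_times=tuple(sorted(set(interp))),
    )


def write_session(
    record: SessionRecord,
    timeseries_path: str | Path,
    layout_path: str | Path,
    punches_path: str | Path | None = None,
) -> None:
    """Write a session back to the CSV + config formats read_session reads."""
    leg_for = {v: k for k, v in record.meta.channel_legs.items()}
    lead = record.series["lead"]
    rear = record.series["rear"]
    cols = {
        "time_s": lead.time,
        leg_for["lead"]: lead.smo2,
        leg_for["rear"]: rear.smo2,
        "hr": lead.hr if lead.hr is not None else np.full(lead.time.size, np.nan),
    }
    pd.DataFrame(cols)[_TS_COLUMNS].to_csv(timeseries_path, index=False)
    write_layout_config(layout_path, record.layout, record.meta, record.punches.modality)
    if punches_path is not None:
        write_punch_log(punches_path, record.punches)
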