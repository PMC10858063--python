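"""Punch-to-phase attribution and derived per-round quantities.

Punch events are attributed to the kinetic phase in which they fall using
the fitted breakpoints (half-open intervals, so every punch belongs to
exactly one phase), and the fast-desaturation rate is normalised to total
phase desaturation per punch thrown in that phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import ExercisePhaseFit
from .session import PunchLog

__all__ = [
    "PhasePunchCounts",
    "NormalisedDesaturation",
    "count_punches_by_phase",
    "normalise_desaturation",
]


@dataclass(frozen=True)
class PhasePunchCounts:
    """Punches thrown in the delay (TD), fast desaturation (FD), and whole
    round (RT).  TD/FD are None for count-only logs (phase attribution
    impossible without event times)."""

    TD_count: int | None
    FD_count: int | None
    RT_count: int
    phase_resolved: bool = True

    def __post_init__(self) -> None:
        if self.RT_count < 0:
            raise ValueError("counts must be non-negative")
        if self.phase_resolved:
            if self.TD_count is None or self.FD_count is None:
                raise ValueError("phase-resolved counts need TD and FD")
            if self.TD_count < 0 or self.FD_count < 0:
                raise ValueError("counts must be non-negative")
            if self.TD_count + self.FD_count > self.RT_count:
                raise ValueError("phase counts exceed round total")


@dataclass(frozen=True)
class NormalisedDesaturation:
    """Fast desaturation normalised to duration and punches thrown:
    total % saturation change across the phase per punch (negative)."""

    fdren: float
    defined: bool = True


def count_punches_by_phase(
    punches: PunchLog,
    fit: ExercisePhaseFit,
    round_index: int,
    round_start: float,
    round_duration: float,
) -> PhasePunchCounts:
    """Count punches per kinetic phase of one round.

    Event times are session seconds; intervals are round-local and
    half-open: delay ``[0, TD)``, fast desaturation ``[TD, TD + DD)``,
    round total ``[0, round_duration)``.  A punch exactly at ``t = TD``
    therefore counts toward the fast desaturation.

    Count-only logs populate the round total and leave the phase counts
    unresolved.
    """
    if not punches.has_events:
        total = (punches.round_counts or {}).get(round_index, 0)
        return PhasePunchCounts(None, None, int(total), phase_resolved=False)
    local = np.asarray(punches.event_times, dtype=float) - round_start
    in_round = local[(local >= 0) & (local < round_duration)]
    td_n = int(np.count_nonzero(in_round < fit.TD))
    fd_n = int(np.count_nonzero((in_round >= fit.TD) & (in_round < fit.TD + fit.DD)))
    return PhasePunchCounts(td_n, fd_n, int(in_round.size))


def normalise_desaturation(
    fit: ExercisePhaseFit, counts: PhasePunchCounts
) -> NormalisedDesaturation:
    """FDReN = (FDR x DD) / FD_count, % saturation change per punch.

    The numerator is the total saturation change across the fast
    desaturation; dividing by punches thrown *in that phase* yields the
    per-punch cost, computed per athlete-round before any averaging.
    Undefined (flagged, not infinite) when no punch fell in the phase.
    """
    if not counts.phase_resolved or not counts.FD_count:
        return NormalisedDesaturation(float("nan"), defined=False)
    return NormalisedDesaturation(fit.FDR * fit.DD / counts.FD_count)
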