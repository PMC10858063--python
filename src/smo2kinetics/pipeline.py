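"""End-to-end drivers: session -> filtered windows -> fits -> metrics -> stats.

The fits frame produced here is the long table every downstream stage
consumes: one row per (athlete, training, leg, window) carrying the fitted
phase parameters, the heart rates at the breakpoints, the residual MADs and
the punch metrics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .metrics import count_punches_by_phase, normalise_desaturation
from .preprocess import extract_windows, filter_record
from .segmentation import (
    ExercisePhaseFit,
    FitFailure,
    SegmentationConfig,
    fit_window,
)
from .session import SessionRecord, check_signal_validity
from .stats import effects_frame, rm_anova
from . import report

__all__ = [
    "analyse_session",
    "analyse_cohort",
    "run_group_stats",
    "EXERCISE_OUTCOMES",
    "RECOVERY_OUTCOMES",
]

EXERCISE_OUTCOMES = ["TD", "HRS", "FDR", "FDReN", "DD", "MAD_FD", "HRE", "MAD_Eq"]
RECOVERY_OUTCOMES = ["RD", "HRSF", "FRR", "FRD", "MAD_FR", "HREF", "MAD_SR"]


def analyse_session(
    record: SessionRecord,
    training: str | None = None,
    config: SegmentationConfig = SegmentationConfig(),
    filter_width: float = 5.0,
) -> pd.DataFrame:
    """Run filtering, windowing, segmentation and punch metrics on one session.

    Returns the long fits frame; windows whose three-phase fit fails are
    skipped with a warning rather than aborting the session.
    """
    validity = check_signal_validity(record.meta)
    if not validity.valid:
        warnings.warn(f"{record.meta.athlete_id}: {validity.message}")
    training = training or record.punches.modality
    filtered = filter_record(record, filter_width)
    rows = []
    for window in extract_windows(filtered):
        try:
            fit = fit_window(window, config)
        except FitFailure as exc:
            warnings.warn(
                f"{record.meta.athlete_id} {window.kind} {window.index} "
                f"({window.leg}): {exc}"
            )
            continue
        row: dict = {
            "athlete": record.meta.athlete_id,
            "training": training,
            "leg": window.leg,
            "kind": window.kind,
            "round": window.index,
            "sse": fit.sse,
            "low_confidence": fit.low_confidence,
        }
        if isinstance(fit, ExercisePhaseFit):
            row.update(
                TD=fit.TD, FDR=fit.FDR, DD=fit.DD, SS_level=fit.SS_level,
                HRS=fit.HRS, HRE=fit.HRE, MAD_FD=fit.MAD_FD, MAD_Eq=fit.MAD_Eq,
            )
            start, _ = record.layout.round_window(window.index)
            counts = count_punches_by_phase(
                record.punches, fit, window.index, start, record.layout.round_duration
            )
            norm = normalise_desaturation(fit, counts)
            row.update(
                punches_td=counts.TD_count,
                punches_fd=counts.FD_count,
                punches_rt=counts.RT_count,
                FDReN=norm.fdren if norm.defined else np.nan,
            )
        else:
            row.update(
                RD=fit.RD, FRR=fit.FRR, FRD=fit.FRD, SR_slope=fit.SR_slope,
                HRSF=fit.HRSF, HREF=fit.HREF, MAD_FR=fit.MAD_FR, MAD_SR=fit.MAD_SR,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def analyse_cohort(cohort, **kwargs) -> pd.DataFrame:
    """Analyse ``(athlete_id, modality, record, truth)`` tuples into one frame."""
    frames = [
        analyse_session(record, training=modality, **kwargs)
        for _, modality, record, _ in cohort
    ]
    return pd.concat(frames, ignore_index=True)


def run_group_stats(
    fits: pd.DataFrame,
    exercise_outcomes: list[str] = EXERCISE_OUTCOMES,
    recovery_outcomes: list[str] = RECOVERY_OUTCOMES,
) -> pd.DataFrame:
    """Training x leg x round repeated-measures ANOVA per outcome.

    Exercise outcomes use the round windows, recovery outcomes the rest
    windows; punches thrown get the training x round analysis (punch counts
    do not differ by leg).  Returns one row per (outcome, effect).
    """
    frames = []
    rounds = fits[fits["kind"] == "round"]
    rests = fits[fits["kind"] == "rest"]

    def _complete_cases(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
        # within-subject ANOVA needs complete cases: drop athletes with any
        # undefined cell for this outcome (e.g. FDReN with no phase punches)
        bad = table.loc[table[outcome].isna(), "athlete"].unique()
        if len(bad):
            warnings.warn(
                f"{outcome}: dropping incomplete athletes {sorted(bad)}"
            )
        return table[~table["athlete"].isin(bad)]

    def _run(table, outcome, within):
        tbl = _complete_cases(table, outcome)
        if tbl["athlete"].nunique() < 2:
            warnings.warn(f"{outcome}: fewer than 2 complete athletes; skipped")
            return
        df = effects_frame(rm_anova(tbl, outcome, "athlete", within))
        df.insert(0, "outcome", outcome)
        frames.append(df)

    for outcome in exercise_outcomes:
        _run(rounds, outcome, ["training", "leg", "round"])
    for outcome in recovery_outcomes:
        _run(rests, outcome, ["training", "leg", "round"])
    if "punches_rt" in fits.columns:
        lead = rounds[rounds["leg"] == "lead"]
        for outcome in ("punches_td", "punches_fd", "punches_rt"):
            _run(lead, outcome, ["training", "round"])
    return pd.concat(frames, ignore_index=True)


def cohort_tables(fits: pd.DataFrame):
    """Follow-up contrasts + formatted exercise/recovery summary tables."""
    contrast_frames = []
    for outcome in EXERCISE_OUTCOMES + list(report.PUNCH_METRICS):
        sub = fits[fits["kind"] == "round"]
        if outcome in sub.columns:
            contrast_frames.append(report.paired_cell_contrasts(sub, outcome))
    for outcome in RECOVERY_OUTCOMES:
        sub = fits[fits["kind"] == "rest"]
        if outcome in sub.columns:
            contrast_frames.append(report.paired_cell_contrasts(sub, outcome))
    contrasts = pd.concat(contrast_frames, ignore_index=True)
    exercise, recovery = report.build_tables(fits, contrasts)
    return exercise, recovery, contrasts
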