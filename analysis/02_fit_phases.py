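"""Fit the three-phase model to every round and recovery of the cohort.

Reads the sessions written by 01_simulate_cohort.py, median-filters each
SmO2 trace, fits the piecewise-linear components per window, attaches punch
metrics, and writes the long fits table.
"""

import argparse
from pathlib import Path

import pandas as pd

from smo2kinetics.pipeline import analyse_session
from smo2kinetics.session import read_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sessions", type=Path, default=ROOT / "scratch" / "sessions")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "fits.csv")
    args = ap.parse_args()

    frames = []
    for ts in sorted(args.sessions.glob("*_timeseries.csv")):
        stem = ts.name.replace("_timeseries.csv", "")
        record = read_session(
            ts,
            args.sessions / f"{stem}_layout.cfg",
            args.sessions / f"{stem}_punches.csv",
        )
        frames.append(analyse_session(record))
    fits = pd.concat(frames, ignore_index=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fits.to_csv(args.out, index=False)

    rounds = fits[fits["kind"] == "round"]
    print(f"fitted {len(fits)} windows from {fits['athlete'].nunique()} athletes "
          f"-> {args.out}")
    print(f"  low-confidence fits: {int(fits['low_confidence'].sum())}")
    r1 = rounds[(rounds["round"] == 1) & (rounds["leg"] == "lead")]
    print("  round-1 lead-leg delay (s) by training:")
    print(r1.groupby("training")["TD"].agg(["mean", "std"]).round(1).to_string())


if __name__ == "__main__":
    main()
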