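"""Simulate the study cohort: 10 athletes x {bag, pad, spar} sessions.

Writes one session per athlete-modality (time-series CSV, layout config,
punch log) plus the generating ground truth, mirroring how real exported
recordings would arrive on disk.  Sessions go under scratch/ (they are
reproducible from the seed); the ground-truth JSON accompanies them for
the parameter-recovery checks downstream.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from smo2kinetics.session import write_session
from smo2kinetics.simulate import simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n-athletes", type=int, default=10)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "sessions")
    args = ap.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(args.n_athletes, seed=args.seed)
    for athlete, modality, record, truth in cohort:
        stem = f"{athlete}_{modality}"
        write_session(
            record,
            args.out / f"{stem}_timeseries.csv",
            args.out / f"{stem}_layout.cfg",
            args.out / f"{stem}_punches.csv",
        )
        (args.out / f"{stem}_truth.json").write_text(
            json.dumps(asdict(truth), default=str, indent=1)
        )
    n = len(cohort)
    punches = {m: [] for m in ("bag", "pad", "spar")}
    for _, modality, record, _ in cohort:
        punches[modality].append(record.punches.event_times.size / 6)
    print(f"wrote {n} sessions ({args.n_athletes} athletes x 3 modalities) to {args.out}")
    for m, vals in punches.items():
        print(f"  {m}: mean punches per round {sum(vals)/len(vals):.1f}")


if __name__ == "__main__":
    main()
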