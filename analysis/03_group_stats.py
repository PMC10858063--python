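"""Repeated-measures ANOVA over the fitted phase components.

Each outcome gets the training x leg x round within-subject decomposition
(training x round for punch counts), with adjusted partial eta squared and
its size class; significant omnibus effects are the license for the
cell-wise follow-up contrasts built in 04.
"""

import argparse
from pathlib import Path

import pandas as pd

from smo2kinetics.pipeline import run_group_stats

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", type=Path, default=ROOT / "results" / "fits.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "effects.csv")
    args = ap.parse_args()

    fits = pd.read_csv(args.fits)
    effects = run_group_stats(fits)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    effects.to_csv(args.out, index=False)

    sig = effects[effects["p"] < 0.05]
    print(f"{len(effects)} effects tested -> {args.out}; {len(sig)} significant at 0.05")
    mains = sig[~sig["effect"].str.contains(":")]
    print("significant main effects (outcome, effect, F, p, adj_pes, class):")
    print(mains[["outcome", "effect", "F", "p", "adj_pes", "size_class"]]
          .round({"F": 1, "p": 4, "adj_pes": 2}).to_string(index=False))


if __name__ == "__main__":
    main()
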