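#!/usr/bin/env python
"""Score trial records into detection sensitivities: per-confidence tallies,
six-point empirical ROC curves, trapezoidal eAUC, and the chance-level
(0.50) exclusion rule.

Reads trials.csv (from 01_simulate.py), writes eauc.csv and roc_points.csv,
and reports the attrition and per-emotion sensitivity ranges.
"""

import argparse
from pathlib import Path

from emoroc.design import EMOTIONS
from emoroc.pipeline import read_trials
from emoroc.sdt import apply_exclusion, score_trials


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1, help="Unused; scoring is deterministic.")
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    records = read_trials(args.out / "trials.csv")
    table, roc_points = score_trials(records)
    retained, excluded = apply_exclusion(table)

    table.to_csv(args.out / "eauc.csv")
    roc_points.to_csv(args.out / "roc_points.csv", index=False)

    print(f"scored {len(table)} participants from {len(records)} trials")
    for pid, emos in sorted(excluded.items()):
        print(f"  excluded {pid}: eAUC at or below chance in {', '.join(emos)}")
    print(f"retained {len(retained)}/{len(table)} participants")
    means = retained[list(EMOTIONS)].mean()
    print("mean eAUC per emotion (retained):")
    for e in EMOTIONS:
        print(f"  {e}: {means[e]:.3f}")
    print(f"wrote eauc.csv and roc_points.csv to {args.out}")


if __name__ == "__main__":
    main()
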