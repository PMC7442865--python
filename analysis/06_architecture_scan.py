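#!/usr/bin/env python
"""Scan two-hidden-layer architectures over the 5..13 neuron grid.

Evaluates every (h1, h2) cell with a reduced number of trials per cell and
reports the ranking by mean validation score together with each cell's
test-split expanded uncertainty.  The clinically chosen 7/10 layout is
highlighted.
"""

import argparse
from pathlib import Path

import pandas as pd

from acutono import calibration


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--trials-per-arch", type=int, default=10)
    args = ap.parse_args()

    features = pd.read_csv(args.results / "features.csv")
    table = calibration.scan_architectures(
        features, neuron_range=range(5, 14),
        n_trials_per_arch=args.trials_per_arch, seed=args.seed, max_iter=150,
    )
    out = args.results / "architecture_scan.csv"
    table.to_csv(out, index=False)

    print(f"scanned {len(table)} architectures -> {out}")
    print("top five by mean validation score:")
    print(table.head(5).to_string(index=False))
    ref = table[(table.h1 == 7) & (table.h2 == 10)].iloc[0]
    print(f"reference cell (7, 10): rank {int(ref['rank'])}/81, "
          f"mean score {ref.mean_score:.3f}, "
          f"test U {ref.test_expanded_uncertainty:.2f} mm Hg")


if __name__ == "__main__":
    main()
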