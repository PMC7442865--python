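#!/usr/bin/env python
"""Calibrate the feature->IOP map with the repeated-training ensemble.

Trains many independently initialised 9-7-10-1 networks on the feature
table from step 02, ranks them by validation slope/R rank-sum, keeps the
best tenth, and writes the selected models plus their test-split agreement.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from acutono import agreement, calibration


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--n-trials", type=int, default=200)
    ap.add_argument("--keep-fraction", type=float, default=0.1)
    args = ap.parse_args()

    features = pd.read_csv(args.results / "features.csv")
    seed = int(np.random.SeedSequence([args.seed, 11]).generate_state(1)[0] % (2**31))
    ensemble = calibration.run_trials(features, n_trials=args.n_trials,
                                      keep_fraction=args.keep_fraction, seed=seed)
    ensemble.assert_test_isolation()
    print(f"trained {len(ensemble.models)} trials "
          f"({ensemble.n_failures} failures), kept {len(ensemble.selected)}")

    models_dir = args.results / "models"
    models_dir.mkdir(exist_ok=True)
    for rank, idx in enumerate(ensemble.selected):
        ensemble.models[idx].to_json(models_dir / f"model_{rank:03d}.json")
    pd.DataFrame({"test_index": ensemble.test_index}).to_csv(
        args.results / "test_index.csv", index=False)

    test = features.loc[ensemble.test_index]
    agr = agreement.ensemble_agreement(ensemble, test, k_p=2.0)
    rep = agr["ensemble_report"]
    doc = {"ensemble": rep.to_dict(),
           "mean_slope_over_selected": agr["mean_slope"],
           "sd_slope_over_selected": agr["sd_slope"],
           "mean_expanded_uncertainty_over_selected": agr["mean_expanded_uncertainty"]}
    (args.results / "agreement.json").write_text(json.dumps(doc, indent=2))

    print(f"test split (n={rep.n}): slope {rep.slope:.3f}, R {rep.r:.3f}")
    print(f"bias {rep.bias:+.2f} mm Hg, expanded uncertainty "
          f"U = {rep.expanded_uncertainty:.2f} mm Hg (k_p = {rep.k_p:g})")
    print(f"selected-model slopes: {agr['mean_slope']:.3f} ± {agr['sd_slope']:.3f}; "
          f"mean per-model U {agr['mean_expanded_uncertainty']:.2f} mm Hg")
    print("meets the 5 mm Hg approval limit" if rep.meets_iso_limit
          else "exceeds the 5 mm Hg approval limit")


if __name__ == "__main__":
    main()
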