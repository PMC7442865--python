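#!/usr/bin/env python
"""Draw the regression and Bland-Altman panels for the calibrated ensemble.

Loads the selected models from step 04, averages their predictions on the
untouched test split, and writes the two-panel agreement figure.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from acutono import agreement
from acutono.calibration import CalibrationModel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    features = pd.read_csv(args.results / "features.csv")
    test_idx = pd.read_csv(args.results / "test_index.csv")["test_index"]
    test = features.loc[test_idx]
    models = [CalibrationModel.from_json(p)
              for p in sorted((args.results / "models").glob("model_*.json"))]
    pred = np.mean([m.predict(test) for m in models], axis=0)
    ref = test["reference_iop"].to_numpy()

    report = agreement.bland_altman(ref, pred, k_p=2.0)
    fig_path = args.results / "agreement.png"
    agreement.plot_agreement(ref, pred, report, path=fig_path)
    print(f"{len(models)} models, {report.n} test measurements -> {fig_path}")
    print(f"slope {report.slope:.3f}, R {report.r:.3f}, "
          f"U {report.expanded_uncertainty:.2f} mm Hg, bias {report.bias:+.2f} mm Hg")


if __name__ == "__main__":
    main()
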