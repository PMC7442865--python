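#!/usr/bin/env python
"""Tabulate measurement success rates for the simulated study.

Formats the category verdicts from step 02 into the count/share table and,
for reference, reruns the same share arithmetic on the published clinical
count column (504 / 56 / 264 / 4 of 828).
"""

import argparse
from pathlib import Path

import pandas as pd

from acutono import workflow


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = workflow.make_table2(args.results / "categories.csv")
    table.to_csv(args.results / "success_rate.csv", index=False)
    print("simulated study:")
    print(table.to_string(index=False))
    rate = table.attrs["self_administered_success_rate"]
    print(f"self-administered success rate: {100 * rate:.1f}%")

    clinical = pd.DataFrame(
        {"category": ["expectancy_compliant", "no_start", "quality_fail",
                      "pressure_deviation"],
         "count": [504, 56, 264, 4]}
    )
    print("\nclinical count column, same arithmetic:")
    print(workflow.make_table2(clinical).to_string(index=False))


if __name__ == "__main__":
    main()
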