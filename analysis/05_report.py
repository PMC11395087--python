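#!/usr/bin/env python
"""Assemble the preprocessing x model comparison report.

Tabulates train/test R² and RMSE per run, percent changes of the test
metrics against each family's raw-spectra baseline, and the best run by
minimal test RMSE.  Reads results/runs.json, writes results/report.json
and results/report.txt.
"""

import argparse
import json
from pathlib import Path

from ginkgoflav.evaluation import build_report, report_to_text, write_report
from ginkgoflav.modeling import ModelRun


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--runs", type=Path,
                        default=Path("results/runs.json"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    runs = [ModelRun(**r) for r in json.loads(args.runs.read_text())]
    report = build_report(runs)
    write_report(report, args.out)
    print(report_to_text(report))
    print(f"wrote {args.out / 'report.json'} and report.txt")


if __name__ == "__main__":
    main()
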