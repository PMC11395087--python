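#!/usr/bin/env python
"""Render, calibrate and segment every scene; extract mean leaf spectra.

Streams the 407 synthetic cubes one at a time: white/dark reflectance
calibration, RGB rendering at 670/550/450 nm, grayscale- and excess-green
Otsu masks intersected and cleaned to the largest component, then the
per-band mean over leaf pixels.  Writes the spectra table (one row per
sample joined to its true TFC) and segmentation QC under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ginkgoflav.pipeline import PipelineConfig, extract_spectra_table
from ginkgoflav.simulate import SimulationConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = PipelineConfig(simulation=SimulationConfig(seed=args.seed))
    table, qc = extract_spectra_table(cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "spectra.csv", index=False,
                 float_format="%.10f")
    pixel_counts = [row["pixel_count"] for row in qc["per_sample"]]
    qc_summary = {
        "n_samples": len(table),
        "mean_iou_vs_truth": qc["mean_iou"],
        "min_iou_vs_truth": float(min(row["iou_vs_truth"]
                                      for row in qc["per_sample"])),
        "median_leaf_pixels": float(np.median(pixel_counts)),
    }
    (args.out / "segmentation_qc.json").write_text(
        json.dumps(qc_summary, indent=2, sort_keys=True))

    print(f"extracted {len(table)} mean spectra "
          f"({len(table.columns) - 4} bands each)")
    print(f"segmentation recovered the true masks with mean IoU "
          f"{qc['mean_iou']:.4f} (min {qc_summary['min_iou_vs_truth']:.4f}); "
          f"median leaf size {qc_summary['median_leaf_pixels']:.0f} px")
    print(f"wrote {args.out / 'spectra.csv'}")


if __name__ == "__main__":
    main()
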