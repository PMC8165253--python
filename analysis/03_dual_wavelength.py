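#!/usr/bin/env python
"""Dual-wavelength artery/vein contrast on the synthetic vessel phantom.

Simulates 800 and 1,064 nm acquisitions of a branching artery/vein phantom,
reconstructs and envelope-detects both, segments vessels on the summed image,
and compares per-vessel mean photoacoustic amplitude (PAA) after total-energy
normalization.  Arteries (high so2) should be brighter at 1,064 nm and veins
at 800 nm; the sign of the normalized 1,064 - 800 difference should separate
the two classes.  Writes results/vessel_paa.csv.
"""

import argparse
import csv
from pathlib import Path

from pamesoscope import experiments


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    ex = experiments.vessel_dualwave_experiment(seed=args.seed)
    print(f"segmented {ex.segmentation.n_labels} vessels "
          f"({sum(ex.segmentation.voxel_counts.values())} voxels total)")
    rows = []
    correct = 0
    for label in sorted(ex.segmentation.voxel_counts):
        cls = ex.label_class[label]
        p800 = ex.paa[label][800.0]
        p1064 = ex.paa[label][1064.0]
        sign = ex.label_diff_sign[label]
        expected = 1 if cls == "artery" else -1
        ok = sign == expected
        correct += ok
        print(f"  vessel {label} ({cls:6s}): PAA 800 nm {p800:.3e}, "
              f"1064 nm {p1064:.3e}, difference sign "
              f"{'+' if sign > 0 else '-'} ({'ok' if ok else 'MISMATCH'})")
        rows.append([label, cls, ex.segmentation.voxel_counts[label],
                     p800, p1064, sign])
    n = ex.segmentation.n_labels
    print(f"sign separation: {correct}/{n} vessels classified by the "
          f"difference sign alone")

    args.outdir.mkdir(parents=True, exist_ok=True)
    with open(args.outdir / "vessel_paa.csv", "w", newline="") as f:
        wtr = csv.writer(f)
        wtr.writerow(["label", "class", "voxels", "paa_800nm_norm",
                      "paa_1064nm_norm", "diff_sign"])
        wtr.writerows(rows)
    print(f"wrote {args.outdir / 'vessel_paa.csv'}")


if __name__ == "__main__":
    main()
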