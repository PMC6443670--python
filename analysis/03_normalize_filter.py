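#!/usr/bin/env python
"""Normalize intensities against the control group and filter embryos.

Batch normalization anchors each imaging batch on its control embryos and
sets the control population-average peak to 1.  The perturbed group is then
filtered by the two retention rules: normalized peak inside [0.60, 1.43]
(endogenous signaling) and ventral−dorsal half difference of at least 0.2
(a measurable gradient).  Writes normalized.tsv and filter_report.tsv per
cohort.
"""

import argparse
from pathlib import Path

from dvscale.io import read_profiles, write_filter_report, write_normalized
from dvscale.normalize import batch_normalize, filter_embryos

CONTROLS = {"intraspecies": "WT", "interspecies": "Tu"}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--root", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    for cohort, control in CONTROLS.items():
        profiles = read_profiles(args.root / cohort / "profiles.tsv")
        normed = filter_embryos(
            batch_normalize(profiles, control_group=control),
            control_group=control,
        )
        write_normalized(normed, args.root / cohort / "normalized.tsv")
        write_filter_report(normed, args.root / cohort / "filter_report.tsv")
        perturbed = [p for p in normed if p.group != control]
        kept = sum(p.retained for p in perturbed)
        print(
            f"{cohort}: control={control}; retained {kept}/{len(perturbed)} "
            f"perturbed embryos after the peak-range and gradient rules"
        )


if __name__ == "__main__":
    main()
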