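#!/usr/bin/env python
"""Generate the study's synthetic datasets and save them with ground truth.

Writes an ALPS-layout phantom (noise-free and SNR-25 variants), a crossing
phantom, a dispersion phantom, a vessel-tube volume, and an aging cohort
under results/phantoms/.  All downstream analysis scripts start from these.
"""

import argparse
from pathlib import Path

import numpy as np

from alpsim.io_formats import write_table, write_volume, VolumeImage
from alpsim.synthetic_data import (
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    generate_vessel_volume,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/phantoms"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    for tag, spec in (
        ("alps_clean", PhantomSpec.alps(seed=args.seed)),
        ("alps_snr25", PhantomSpec.alps(snr=25.0, seed=args.seed)),
        ("alps_pvs10", PhantomSpec.alps(pvs_fraction=0.10, seed=args.seed)),
        ("crossing", PhantomSpec.crossing(65.0, 0.3, seed=args.seed)),
        ("dispersion", PhantomSpec.dispersion(16.0, 4.0, seed=args.seed)),
    ):
        ph = generate_phantom(spec)
        ph.save(out / tag)
        print(f"{tag}: {len(ph.truth)} regions, "
              f"{int((ph.rois.labels > 0).sum())} labelled voxels")

    vol, truth = generate_vessel_volume(
        shape=(30, 30, 30), tubes=[((15.0, 15.0, 15.0), (0, 0, 1.0), 2.0)],
        seed=args.seed,
    )
    write_volume(out / "vessel.nii.gz", vol)
    write_volume(out / "vessel_truth.nii.gz", VolumeImage(truth.vectors))
    print(f"vessel: {int(truth.mask.sum())} tube voxels")

    cohort = generate_cohort(
        CohortSpec(
            n_subjects=50,
            rois={
                "SCR": {"asymmetry": (1.8, -0.004), "dab": (0.5, -0.002)},
                "SLF": {"asymmetry": (1.6, -0.002), "dab": (0.4, -0.001)},
            },
            noise_sd=0.05,
            seed=args.seed,
        )
    )
    write_table(out / "cohort.tsv", cohort)
    print(f"cohort: {cohort['subject'].nunique()} subjects")


if __name__ == "__main__":
    main()
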