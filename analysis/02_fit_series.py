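#!/usr/bin/env python
"""Fit every simulated spectrum to the Randles circuit and tabulate the
recovered parameters against the generating values.

Expected outcome: on the noiseless series every parameter returns to its
generating value to well within 0.1%; on the 0.5%-noise series the
well-identified parameters (Ru, Y0, alpha, Rp) stay within a few percent
while the terms whose contribution sits below the noise floor -- the tiny
Warburg coefficient (~1e-9 of |Z|) and the blank sample's milliohm Ru
(~1e-6 of |Z|) -- are unrecoverable, as they should be.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from eisdep.eis_fit import fit_randles
from eisdep.io import read_spectrum_csv
from eisdep.synthetic_data import TAU441_SERIES

RESULTS = Path(__file__).resolve().parents[1] / "results"
TRUTH = {label: params for label, _m, params in TAU441_SERIES}


def main() -> None:
    rows = []
    for variant in ("spectra_noiseless", "spectra_noisy"):
        for path in sorted((RESULTS / variant).glob("*.csv")):
            s = read_spectrum_csv(path)
            truth = TRUTH[s.label]
            fit = fit_randles(s)
            p = fit.params
            rel = np.abs(p.as_array() / truth.as_array() - 1.0)
            rows.append(
                {
                    "variant": variant.removeprefix("spectra_"),
                    "sample": s.label,
                    "r_u_ohm": p.r_u,
                    "y0": p.y0,
                    "alpha": p.alpha,
                    "w_d": p.w_d,
                    "r_p_ohm": p.r_p,
                    "residual_norm": fit.residual_norm,
                    "max_rel_error": rel.max(),
                    "max_rel_error_excl_wd": np.delete(rel, 3).max(),
                }
            )
    table = pd.DataFrame(rows).sort_values(["variant", "sample"])
    out = RESULTS / "fitted_parameters.csv"
    table.to_csv(out, index=False)
    print(f"wrote {out}")
    noiseless = table[table.variant == "noiseless"]
    print(
        "noiseless series: worst relative parameter error "
        f"{noiseless.max_rel_error.max():.2e} (all five parameters)"
    )
    noisy = table[table.variant == "noisy"]
    errs_ru, errs_rp = [], []
    for _, row in noisy.iterrows():
        truth = TRUTH[row["sample"]]
        if row["sample"] != "blank":  # the blank's milliohm Ru is sub-noise
            errs_ru.append(abs(row.r_u_ohm / truth.r_u - 1))
        errs_rp.append(abs(row.r_p_ohm / truth.r_p - 1))
    print(
        "0.5%-noise series: median relative error "
        f"Ru {np.median(errs_ru):.2e} (protein samples), Rp {np.median(errs_rp):.2e}"
    )
    print(
        "noise-limited as expected: every Wd (~1e-9 of |Z|), the blank's "
        "milliohm Ru, and the most dilute sample's 24-ohm charge-transfer "
        "semicircle riding on a 2.7 kOhm series resistance"
    )


if __name__ == "__main__":
    main()
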