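#!/usr/bin/env python
"""Regenerate the six-sample Tau-441 concentration series as spectrum CSVs.

No raw spectra accompany the published concentration series, so the study
conditions are reconstructed from the fitted Randles parameters: one
spectrum per sample on a 0.1 Hz-1 MHz grid at 10 points/decade, written
noiselessly (the deterministic fixture) and with 0.5% proportional noise
(the measurement-like variant).
"""

from pathlib import Path

from eisdep.io import write_spectrum_csv
from eisdep.synthetic_data import NoiseModel, generate_table3_series

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20240710


def slug(label: str) -> str:
    return label.replace(" ", "_").replace(".", "p")


def main() -> None:
    for sub, noise in (("spectra_noiseless", None), ("spectra_noisy", NoiseModel(0.005, SEED))):
        out = RESULTS / sub
        out.mkdir(parents=True, exist_ok=True)
        _, spectra = generate_table3_series(noise=noise)
        for s in spectra:
            write_spectrum_csv(s, out / f"{slug(s.label)}.csv", seed=None if noise is None else SEED)
        print(f"wrote {len(spectra)} spectra to {out}")
    print("series labels: blank, 218.34, 109.15, 54.58, 27.29, 13.64 nM")


if __name__ == "__main__":
    main()
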