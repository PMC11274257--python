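"""Reading and writing EIS spectra in the package's CSV dialect, and tidy
table export for Nyquist/Bode plotting.

The dialect: a header row naming (case-insensitively) ``frequency_hz``,
``z_real_ohm``, ``z_imag_ohm``; '#'-prefixed comment lines anywhere; plain
'.'-decimal floats regardless of locale.  Rows are canonicalized to
ascending frequency on read; duplicate frequencies are an error.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit_models import (
    ImpedanceSpectrum,
    RandlesParameters,
    evaluate_spectrum,
)

__all__ = [
    "SpectrumParseError",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "export_plots_data",
]

REQUIRED_COLUMNS = ("frequency_hz", "z_real_ohm", "z_imag_ohm")


class SpectrumParseError(ValueError):
    """Structured parse failure naming the offending file and line."""

    def __init__(self, path, line_number, message):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


def read_spectrum_csv(path) -> ImpedanceSpectrum:
    """Read one spectrum from the package's CSV dialect.

    Rows are sorted ascending by frequency; an embedded ``# label: ...``
    comment, if present, becomes the spectrum label.
    """
    path = Path(path)
    label = ""
    header = None
    col_idx = None
    rows = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        for line_number, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comment = line.lstrip("#").strip()
                if comment.lower().startswith("label:"):
                    label = comment.split(":", 1)[1].strip()
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip().lower() for f in fields]
                missing = [c for c in REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise SpectrumParseError(
                        path, line_number, f"missing required column(s) {missing}"
                    )
                col_idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
                continue
            if len(fields) < len(header):
                raise SpectrumParseError(
                    path, line_number, f"expected {len(header)} fields, got {len(fields)}"
                )
            try:
                rows.append(
                    tuple(float(fields[col_idx[c]]) for c in REQUIRED_COLUMNS)
                )
            except ValueError as exc:
                raise SpectrumParseError(path, line_number, f"non-numeric cell: {exc}") from None
    if header is None:
        raise SpectrumParseError(path, 0, "no header row found")
    if len(rows) < 2:
        raise SpectrumParseError(path, 0, f"need >= 2 data rows, got {len(rows)}")
    data = np.array(sorted(rows, key=lambda r: r[0]))
    freq = data[:, 0]
    if np.any(np.diff(freq) == 0):
        dup = freq[np.where(np.diff(freq) == 0)[0][0]]
        raise SpectrumParseError(path, 0, f"duplicate frequency {dup!r} Hz")
    return ImpedanceSpectrum(freq, data[:, 1] + 1j * data[:, 2], label=label)


def write_spectrum_csv(spectrum: ImpedanceSpectrum, path, seed=None) -> None:
    """Write a spectrum at full float precision (repr round-trip).

    Provenance comments carry the label (when non-empty) and the generator
    seed (when given).
    """
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8", newline="") as fh:
            if spectrum.label:
                fh.write(f"# label: {spectrum.label}\n")
            if seed is not None:
                fh.write(f"# generator-seed: {seed}\n")
            fh.write(",".join(REQUIRED_COLUMNS) + "\n")
            for f, z in zip(spectrum.frequencies, spectrum.impedances):
                fh.write(f"{float(f)!r},{float(z.real)!r},{float(z.imag)!r}\n")
    except OSError as exc:
        raise OSError(f"failed writing spectrum to {path}: {exc}") from exc


def export_plots_data(spectrum: ImpedanceSpectrum, params: RandlesParameters) -> dict:
    """Tidy Nyquist/Bode tables for data points and the fitted model curve.

    The model curve is evaluated on a grid 10x denser than the data.
    Returns a dict of DataFrames: ``nyquist_data``, ``nyquist_model``,
    ``bode_data``, ``bode_model``.  Nyquist ordinate is -ZIM; Bode phase is
    in degrees.
    """
    dense = np.logspace(
        np.log10(spectrum.frequencies[0]),
        np.log10(spectrum.frequencies[-1]),
        10 * len(spectrum),
    )
    model = evaluate_spectrum(params, dense)

    def nyquist(s):
        return pd.DataFrame({"z_real_ohm": s.z_real, "neg_z_imag_ohm": -s.z_imag})

    def bode(s):
        return pd.DataFrame(
            {
                "frequency_hz": s.frequencies,
                "magnitude_ohm": s.magnitude,
                "phase_deg": np.degrees(s.phase),
            }
        )

    return {
        "nyquist_data": nyquist(spectrum),
        "nyquist_model": nyquist(model),
        "bode_data": bode(spectrum),
        "bode_model": bode(model),
    }
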