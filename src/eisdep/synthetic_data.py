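"""Seeded synthetic EIS spectra and the Tau-441 concentration-series fixture.

No raw spectra are publicly available for the Tau-441 dilution series, so the
package regenerates them from the published fitted Randles parameters: each
fixture spectrum is the exact circuit response on a log-spaced grid, with
optional proportional Gaussian noise applied independently to the real and
imaginary components.  The module also carries the sample-preparation
arithmetic (mass concentration -> molarity, 1:1 serial dilution).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .circuit_models import ImpedanceSpectrum, RandlesParameters, evaluate_spectrum

__all__ = [
    "NoiseModel",
    "SeriesSpec",
    "TAU441_SERIES",
    "TAU441_CONDUCTIVITY_S_PER_M",
    "log_frequency_grid",
    "molarity_from_mass_concentration",
    "serial_dilution",
    "generate_spectrum",
    "generate_table3_series",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = (0.1, 1e6, 10)  # f_min Hz, f_max Hz, points per decade


@dataclass(frozen=True)
class NoiseModel:
    """Proportional Gaussian measurement noise.

    Each impedance component is multiplied by an independent
    (1 + N(0, relative_sd^2)) draw; ``relative_sd = 0`` reproduces the
    noiseless circuit response.  Deterministic for a given seed.
    """

    relative_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError(f"relative_sd must be >= 0, got {self.relative_sd}")


@dataclass(frozen=True)
class SeriesSpec:
    """A labelled concentration series of Randles parameter sets."""

    rows: tuple  # of (label, molarity_nM, RandlesParameters)
    frequency_grid: tuple = DEFAULT_GRID

    def __post_init__(self) -> None:
        labels = [r[0] for r in self.rows]
        if len(set(labels)) != len(labels):
            raise ValueError("series labels must be unique")
        if any(r[1] < 0 for r in self.rows):
            raise ValueError("molarities must be non-negative (0 = blank)")


# Published fitted parameters for the six-sample Tau-441 dilution series
# (blank = deionized water, then 218.34 nM stock halved four times).  The
# blank-row Ru of 1.228 mOhm is kept verbatim even though it is physically
# implausible for deionized water; see generate_table3_series.
TAU441_SERIES: tuple = (
    ("blank", 0.0, RandlesParameters(1.228e-3, 29.36e-12, 1.0, 23.53e-6, 11.39e3)),
    ("218.34 nM", 218.34, RandlesParameters(313.2, 12.43e-6, 0.7199, 28.53e-6, 3.785e3)),
    ("109.15 nM", 109.15, RandlesParameters(1.153e3, 13.68e-6, 0.6539, 33.99e-6, 2.925e3)),
    ("54.58 nM", 54.58, RandlesParameters(1.178e3, 13.21e-6, 0.6959, 34.94e-6, 4.038e3)),
    ("27.29 nM", 27.29, RandlesParameters(1.787e3, 7.768e-6, 0.7479, 24.28e-6, 8.381e3)),
    ("13.64 nM", 13.64, RandlesParameters(2.682e3, 1.898e-6, 0.8698, 19.89e-6, 23.69)),
)

# Published suspension conductivities (S/m) for the same rows, derived from
# the polarization resistance and the cell constant.
TAU441_CONDUCTIVITY_S_PER_M: dict = {
    "blank": 2.12e-3,
    "218.34 nM": 6.37e-3,
    "109.15 nM": 8.24e-3,
    "54.58 nM": 5.97e-3,
    "27.29 nM": 2.88e-3,
    "13.64 nM": 1.02,
}


def log_frequency_grid(f_min: float, f_max: float, points_per_decade: int) -> np.ndarray:
    """Inclusive log-spaced frequency grid in Hz."""
    if not 0 < f_min < f_max:
        raise ValueError(f"need 0 < f_min < f_max, got ({f_min}, {f_max})")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    decades = math.log10(f_max / f_min)
    n = int(round(decades * points_per_decade)) + 1
    return np.logspace(math.log10(f_min), math.log10(f_max), n)


def molarity_from_mass_concentration(mass_conc: float, molecular_mass: float) -> float:
    """Molar concentration in nM from mass concentration and molecular mass.

    ``mass_conc`` in mg/mL (= g/L), ``molecular_mass`` in kDa (= kg/mol):
    molarity = mass_conc / molecular_mass * 1e6 nmol/L.
    """
    if not mass_conc > 0:
        raise ValueError(f"mass concentration must be > 0, got {mass_conc}")
    if not molecular_mass > 0:
        raise ValueError(f"molecular mass must be > 0, got {molecular_mass}")
    return mass_conc / molecular_mass * 1e6


def serial_dilution(start: float, factor: float, steps: int) -> list:
    """Geometric dilution series [start, start/factor, ...], length steps+1."""
    if not factor > 1:
        raise ValueError(f"dilution factor must be > 1, got {factor}")
    if steps < 0:
        raise ValueError(f"steps must be >= 0, got {steps}")
    return [start / factor**k for k in range(steps + 1)]


def generate_spectrum(
    params: RandlesParameters,
    grid,
    noise: NoiseModel | None = None,
    label: str = "",
) -> ImpedanceSpectrum:
    """Synthetic spectrum: circuit response times independent proportional noise.

    ``grid`` is either an explicit frequency array (Hz) or a
    (f_min, f_max, points_per_decade) tuple.
    """
    if isinstance(grid, tuple) and len(grid) == 3:
        frequencies = log_frequency_grid(*grid)
    else:
        frequencies = np.asarray(grid, dtype=float)
    clean = evaluate_spectrum(params, frequencies, label=label)
    if noise is None or noise.relative_sd == 0:
        return clean
    rng = np.random.default_rng(noise.seed)
    factors = 1.0 + rng.normal(scale=noise.relative_sd, size=(2, len(clean)))
    z = clean.z_real * factors[0] + 1j * clean.z_imag * factors[1]
    return ImpedanceSpectrum(frequencies, z, label=label)


def generate_table3_series(
    noise: NoiseModel | None = None,
    grid: tuple = DEFAULT_GRID,
) -> tuple:
    """The packaged six-sample fixture series.

    Returns (SeriesSpec, list[ImpedanceSpectrum]) with one spectrum per
    published parameter row, labelled by molarity, in dilution order starting
    from the blank.  Per-sample seeds are derived from ``noise.seed`` so that
    samples carry independent noise.
    """
    spec = SeriesSpec(rows=TAU441_SERIES, frequency_grid=grid)
    blank_ru = TAU441_SERIES[0][2].r_u
    if blank_ru < 1:
        logger.warning(
            "blank-row Ru = %.3g ohm is physically implausible for deionized "
            "water; the fixture reproduces the published value verbatim",
            blank_ru,
        )
    spectra = []
    for i, (label, _molarity, params) in enumerate(spec.rows):
        row_noise = None
        if noise is not None:
            row_noise = NoiseModel(noise.relative_sd, seed=noise.seed + i)
        spectra.append(generate_spectrum(params, grid, noise=row_noise, label=label))
    return spec, spectra
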