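"""Impedance -> conductivity/permittivity conversion, Clausius-Mossotti
factor spectra, the Maxwell-Wagner dilute-mixture model, and
dielectrophoresis (DEP) response prediction.

Conventions
-----------
Complex relative permittivity is written eps* = eps' - j*eps'' with
eps'' = sigma/(omega*eps0); the vacuum permittivity is
eps0 = 8.8541878128e-12 F/m.  The real part of the Clausius-Mossotti factor

    f_CM = (eps_p* - eps_m*) / (eps_p* + 2*eps_m*)

sets the DEP direction: Re[f_CM] > 0 means motion toward high field
gradients (positive DEP), and it is bounded in [-0.5, 1] for physically
admissible phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .circuit_models import ImpedanceSpectrum

__all__ = [
    "EPSILON_0",
    "CellGeometry",
    "PermittivitySpectrum",
    "MixtureState",
    "DEPPrediction",
    "conductivity_from_resistance",
    "permittivity_from_impedance",
    "cm_factor_permittivity",
    "cm_factor_impedance",
    "maxwell_wagner_mixture",
    "invert_maxwell_wagner",
    "mixture_state",
    "complex_permittivity",
    "dep_response",
]

EPSILON_0 = 8.8541878128e-12  # F/m

_ZERO_TOL = 1e-12  # |Re f_CM| below this counts as a zero-force point


@dataclass(frozen=True)
class CellGeometry:
    """Parallel-plate measurement cell geometry.

    thickness: electrode separation L (m); area: electrode cross-section
    A (m^2).  The cell constant kappa = L/A (1/m) converts bulk conductivity
    to resistance, sigma = kappa / R.
    """

    thickness: float
    area: float

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if not self.area > 0:
            raise ValueError(f"area must be > 0, got {self.area}")

    @property
    def cell_constant(self) -> float:
        return self.thickness / self.area


@dataclass(frozen=True)
class PermittivitySpectrum:
    """Relative permittivity and conductivity versus frequency.

    Satisfies eps'' = sigma/(omega*eps0) at every grid point.  ``undefined``
    marks points that could not be evaluated (e.g. zero reactance in the
    literal conversion mode); values there are NaN.
    """

    frequencies: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    sigma: np.ndarray
    undefined: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        n = f.size
        arrays = {
            "eps_real": np.asarray(self.eps_real, dtype=float),
            "eps_imag": np.asarray(self.eps_imag, dtype=float),
            "sigma": np.asarray(self.sigma, dtype=float),
        }
        for name, a in arrays.items():
            if a.size != n:
                raise ValueError(f"{name} length {a.size} != frequency grid length {n}")
        und = self.undefined
        und = np.zeros(n, dtype=bool) if und is None else np.asarray(und, dtype=bool)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "eps_real", arrays["eps_real"])
        object.__setattr__(self, "eps_imag", arrays["eps_imag"])
        object.__setattr__(self, "sigma", arrays["sigma"])
        object.__setattr__(self, "undefined", und)

    @property
    def complex_relative(self) -> np.ndarray:
        """eps* = eps' - j*eps'' on the grid."""
        return self.eps_real - 1j * self.eps_imag


@dataclass(frozen=True)
class MixtureState:
    """A particle/medium/suspension permittivity triple with its f_CM."""

    eps_p: complex
    eps_m: complex
    eps_mix: complex
    volume_fraction: float
    f_cm: complex


@dataclass(frozen=True)
class DEPPrediction:
    """Re[f_CM] spectrum with sign bands and crossover frequencies.

    ``sign_bands`` is a list of (f_low, f_high, sign) with sign in
    {"positive", "negative", "zero"}; band edges are crossover-refined.
    ``recommended_band`` is the widest positive band in log-frequency
    (ties broken toward lower frequency), or None when no positive band
    exists.
    """

    frequencies: np.ndarray
    re_fcm: np.ndarray
    sign_bands: list
    crossover_frequencies: list
    recommended_band: tuple | None


def conductivity_from_resistance(resistance: float, geometry: CellGeometry) -> float:
    """Bulk conductivity sigma = kappa / R of a parallel-plate cell (S/m)."""
    if not resistance > 0:
        raise ValueError(f"resistance must be > 0, got {resistance}")
    return geometry.cell_constant / resistance


def permittivity_from_impedance(
    spectrum: ImpedanceSpectrum,
    geometry: CellGeometry,
    mode: Literal["admittance", "literal"] = "admittance",
) -> PermittivitySpectrum:
    """Convert an impedance spectrum to relative permittivity and conductivity.

    ``admittance`` (default) is exact for a parallel-plate cell: with
    Y = 1/Z*, sigma = Re(Y)*kappa, eps' = Im(Y)*kappa/(omega*eps0) and
    eps'' = sigma/(omega*eps0).

    ``literal`` applies the approximate component-wise reading
    eps' = kappa/(omega*eps0*|ZIM|), eps'' = kappa/(omega*eps0*ZR); points
    with zero reactance (or zero resistance) are flagged undefined rather
    than dropped.  This mode exists for comparison only.
    """
    if np.any(np.abs(spectrum.impedances) == 0):
        raise ValueError("spectrum contains zero-magnitude impedances")
    kappa = geometry.cell_constant
    omega = spectrum.omega
    if mode == "admittance":
        y = 1.0 / spectrum.impedances
        sigma = y.real * kappa
        eps_real = y.imag * kappa / (omega * EPSILON_0)
        eps_imag = sigma / (omega * EPSILON_0)
        return PermittivitySpectrum(spectrum.frequencies, eps_real, eps_imag, sigma)
    if mode == "literal":
        zim = spectrum.z_imag
        zr = spectrum.z_real
        undefined = (zim == 0) | (zr == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            eps_real = np.where(undefined, np.nan, kappa / (omega * EPSILON_0 * np.abs(zim)))
            eps_imag = np.where(undefined, np.nan, kappa / (omega * EPSILON_0 * zr))
        sigma = eps_imag * omega * EPSILON_0
        return PermittivitySpectrum(
            spectrum.frequencies, eps_real, eps_imag, sigma, undefined=undefined
        )
    raise ValueError(f"mode must be 'admittance' or 'literal', got {mode!r}")


def cm_factor_permittivity(eps_p, eps_m):
    """Clausius-Mossotti factor from complex relative permittivities.

    f_CM = (eps_p* - eps_m*) / (eps_p* + 2*eps_m*).  Accepts scalars or
    arrays; a (near-)zero denominator is rejected.
    """
    eps_p = np.asarray(eps_p, dtype=complex)
    eps_m = np.asarray(eps_m, dtype=complex)
    den = eps_p + 2.0 * eps_m
    scale = np.maximum(np.abs(eps_p), np.abs(eps_m))
    if np.any(np.abs(den) <= 1e-300 + 1e-15 * scale):
        raise ValueError(
            "degenerate Clausius-Mossotti denominator: eps_p + 2*eps_m ~ 0 "
            "(resonant-cancellation inputs are not physical permittivities)"
        )
    out = (eps_p - eps_m) / den
    return complex(out) if out.ndim == 0 else out


def cm_factor_impedance(z_p, z_m):
    """Clausius-Mossotti factor from particle/medium impedances.

    f_CM = (Zm* - Zp*) / (Zm* + 2*Zp*); identical to the permittivity form
    when Z = kappa/(j*omega*eps0*eps*) for a common cell.
    """
    z_p = np.asarray(z_p, dtype=complex)
    z_m = np.asarray(z_m, dtype=complex)
    den = z_m + 2.0 * z_p
    scale = np.maximum(np.abs(z_p), np.abs(z_m))
    if np.any(np.abs(den) <= 1e-300 + 1e-15 * scale):
        raise ValueError("degenerate Clausius-Mossotti denominator: z_m + 2*z_p ~ 0")
    out = (z_m - z_p) / den
    return complex(out) if out.ndim == 0 else out


def maxwell_wagner_mixture(eps_m, f_cm, delta: float):
    """Effective permittivity of a dilute suspension.

    eps_mix* = eps_m* (1 + 2*delta*f_CM) / (1 - delta*f_CM) for volume
    fraction delta in [0, 1).
    """
    if not 0 <= delta < 1:
        raise ValueError(f"volume fraction must lie in [0, 1), got {delta}")
    eps_m = np.asarray(eps_m, dtype=complex)
    f_cm = np.asarray(f_cm, dtype=complex)
    den = 1.0 - delta * f_cm
    if np.any(np.abs(den) == 0):
        raise ValueError("degenerate mixture denominator: 1 - delta*f_CM = 0")
    out = eps_m * (1.0 + 2.0 * delta * f_cm) / den
    return complex(out) if out.ndim == 0 else out


def invert_maxwell_wagner(eps_mix, eps_m, delta: float):
    """Recover f_CM from a measured mixture permittivity.

    f_CM = (eps_mix* - eps_m*) / (delta * (eps_mix* + 2*eps_m*)); exact
    algebraic inverse of :func:`maxwell_wagner_mixture`.  delta = 0 is
    rejected (f_CM is then unidentifiable).
    """
    if not 0 < delta < 1:
        raise ValueError(f"volume fraction must lie in (0, 1) for inversion, got {delta}")
    eps_mix = np.asarray(eps_mix, dtype=complex)
    eps_m = np.asarray(eps_m, dtype=complex)
    den = eps_mix + 2.0 * eps_m
    if np.any(np.abs(den) == 0):
        raise ValueError("degenerate inversion denominator: eps_mix + 2*eps_m = 0")
    out = (eps_mix - eps_m) / (delta * den)
    return complex(out) if out.ndim == 0 else out


def mixture_state(eps_p: complex, eps_m: complex, delta: float) -> MixtureState:
    """Assemble the particle/medium/mixture state for one frequency point."""
    f_cm = cm_factor_permittivity(eps_p, eps_m)
    eps_mix = maxwell_wagner_mixture(eps_m, f_cm, delta)
    return MixtureState(
        eps_p=complex(eps_p),
        eps_m=complex(eps_m),
        eps_mix=complex(eps_mix),
        volume_fraction=delta,
        f_cm=complex(f_cm),
    )


def complex_permittivity(eps_rel: float, sigma: float, frequencies) -> np.ndarray:
    """Frequency-independent phase model: eps*(omega) = eps_rel - j*sigma/(omega*eps0).

    The standard description of a medium (or homogeneous lossy particle)
    specified by a static relative permittivity and a DC conductivity.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be > 0")
    return eps_rel - 1j * sigma / (2.0 * np.pi * f * EPSILON_0)


def _sign_label(value: float) -> str:
    if abs(value) < _ZERO_TOL:
        return "zero"
    return "positive" if value > 0 else "negative"


def _interp_complex(frequencies: np.ndarray, values: np.ndarray, f: float) -> complex:
    """Log-linear (in frequency) interpolation of a complex spectrum."""
    logf = np.log10(frequencies)
    x = np.log10(f)
    return complex(np.interp(x, logf, values.real) + 1j * np.interp(x, logf, values.imag))


def dep_response(
    frequencies: Sequence[float],
    eps_p_spectrum: Sequence[complex],
    eps_m_spectrum: Sequence[complex],
) -> DEPPrediction:
    """Predict the DEP response from particle and medium permittivity spectra.

    Re[f_CM] is evaluated point-wise; crossover frequencies are refined by
    bisection on log-frequency between bracketing grid points, with the two
    permittivity spectra interpolated log-linearly, to 1e-6 relative
    tolerance.  Points with |Re f_CM| < 1e-12 are classified as zero force.
    """
    f = np.asarray(frequencies, dtype=float)
    eps_p = np.asarray(eps_p_spectrum, dtype=complex)
    eps_m = np.asarray(eps_m_spectrum, dtype=complex)
    if f.size < 2:
        raise ValueError(f"need >= 2 grid points, got {f.size}")
    if not np.all(np.diff(f) > 0) or np.any(f <= 0):
        raise ValueError("frequency grid must be positive and strictly increasing")
    if eps_p.size != f.size or eps_m.size != f.size:
        raise ValueError("spectra must match the frequency grid length")

    re_fcm = np.real(cm_factor_permittivity(eps_p, eps_m))

    def re_fcm_at(freq: float) -> float:
        ep = _interp_complex(f, eps_p, freq)
        em = _interp_complex(f, eps_m, freq)
        return float(np.real(cm_factor_permittivity(ep, em)))

    crossovers: list[float] = []
    signs = [_sign_label(v) for v in re_fcm]
    nonzero_idx = [i for i, s in enumerate(signs) if s != "zero"]
    for i1, i2 in zip(nonzero_idx[:-1], nonzero_idx[1:]):
        if signs[i1] == signs[i2]:
            continue
        if i2 == i1 + 1:
            # bisection on log10(f); bracket guaranteed by the sign change
            lo, hi = np.log10(f[i1]), np.log10(f[i2])
            flo = re_fcm[i1]
            while (hi - lo) > 1e-6 / np.log(10):
                mid = 0.5 * (lo + hi)
                fmid = re_fcm_at(10.0**mid)
                if fmid == 0.0:
                    lo = hi = mid
                    break
                if (fmid > 0) == (flo > 0):
                    lo, flo = mid, fmid
                else:
                    hi = mid
            crossovers.append(float(10.0 ** (0.5 * (lo + hi))))
        else:
            # the zero-force point sits on the grid (a run of |Re f_CM| below
            # threshold); report the run's geometric-mean frequency
            crossovers.append(float(np.sqrt(f[i1 + 1] * f[i2 - 1])))

    # band edges: grid extremes plus refined crossovers
    edges = [float(f[0]), *crossovers, float(f[-1])]
    bands = []
    for lo_f, hi_f in zip(edges[:-1], edges[1:]):
        # classify by the grid points strictly inside the band (fall back to
        # the geometric midpoint for sub-grid-resolution bands)
        inside = re_fcm[(f >= lo_f) & (f <= hi_f)]
        nonzero = inside[np.abs(inside) >= _ZERO_TOL]
        if nonzero.size:
            label = _sign_label(float(np.median(np.sign(nonzero))))
        elif inside.size:
            label = "zero"
        else:
            label = _sign_label(re_fcm_at(float(np.sqrt(lo_f * hi_f))))
        bands.append((lo_f, hi_f, label))

    positive = [b for b in bands if b[2] == "positive"]
    recommended = None
    if positive:
        # widest in decades; ties toward lower frequency (gentler heating)
        widths = [np.log10(b[1] / b[0]) for b in positive]
        best = int(np.argmax(widths))
        recommended = (positive[best][0], positive[best][1])

    return DEPPrediction(
        frequencies=f,
        re_fcm=re_fcm,
        sign_bands=bands,
        crossover_frequencies=crossovers,
        recommended_band=recommended,
    )
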