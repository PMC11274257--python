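"""Complex impedance of Randles-circuit elements and their composition.

The Randles equivalent circuit used throughout this package is the canonical
arrangement for a blocking/faradaic interface probed by electrochemical
impedance spectroscopy (EIS):

    Z(omega) = Ru + [ Z_CPE(omega) || (Rp + Z_W(omega)) ]

with a solution (uncompensated) resistance ``Ru`` in series with the parallel
combination of a constant-phase element (CPE, the non-ideal double layer) and
a charge-transfer branch consisting of the polarization resistance ``Rp`` plus
a semi-infinite Warburg diffusion element ``Z_W``.

Sign convention: e^{+j*omega*t} time dependence, so capacitive reactance is
negative; Nyquist plots show -Im(Z) on the ordinate.  Complex powers use the
principal branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RandlesParameters",
    "ImpedanceSpectrum",
    "to_polar",
    "from_polar",
    "z_resistor",
    "z_cpe",
    "z_warburg",
    "parallel",
    "randles_impedance",
    "evaluate_spectrum",
]


@dataclass(frozen=True)
class RandlesParameters:
    """The five parameters of the Randles equivalent circuit.

    Parameters
    ----------
    r_u : float
        Solution (uncompensated) resistance Ru in ohm, >= 0.
    y0 : float
        CPE admittance coefficient Y0 in S*s^alpha, > 0.
    alpha : float
        CPE exponent, 0 < alpha <= 1.  alpha = 1 is an ideal capacitor
        (Y0 then has units of farad), alpha -> 0 a resistor of 1/Y0.
    w_d : float
        Semi-infinite Warburg coefficient in ohm*s^(-1/2), >= 0, such that
        Z_W = w_d * (j*omega)^(-1/2).
    r_p : float
        Polarization / charge-transfer resistance Rp in ohm, >= 0.
    """

    r_u: float
    y0: float
    alpha: float
    w_d: float
    r_p: float

    def __post_init__(self) -> None:
        if not self.r_u >= 0:
            raise ValueError(f"r_u must be >= 0, got {self.r_u}")
        if not self.y0 > 0:
            raise ValueError(f"y0 must be > 0, got {self.y0}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not self.w_d >= 0:
            raise ValueError(f"w_d must be >= 0, got {self.w_d}")
        if not self.r_p >= 0:
            raise ValueError(f"r_p must be >= 0, got {self.r_p}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r_u, self.y0, self.alpha, self.w_d, self.r_p])

    @classmethod
    def from_array(cls, values) -> "RandlesParameters":
        r_u, y0, alpha, w_d, r_p = (float(v) for v in values)
        return cls(r_u=r_u, y0=y0, alpha=alpha, w_d=w_d, r_p=r_p)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """A frequency sweep of complex impedance samples.

    ``frequencies`` are in Hz, strictly positive and strictly increasing;
    ``impedances`` is a matching complex array in ohm (real part ZR,
    imaginary part ZIM).
    """

    frequencies: np.ndarray
    impedances: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.impedances, dtype=complex)
        if f.ndim != 1 or z.ndim != 1 or f.size != z.size:
            raise ValueError("frequencies and impedances must be 1-D arrays of equal length")
        if f.size < 2:
            raise ValueError(f"spectrum needs >= 2 points, got {f.size}")
        if not np.all(f > 0):
            raise ValueError("all frequencies must be > 0")
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "impedances", z)

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def omega(self) -> np.ndarray:
        """Angular frequency, rad/s."""
        return 2.0 * np.pi * self.frequencies

    @property
    def z_real(self) -> np.ndarray:
        return self.impedances.real

    @property
    def z_imag(self) -> np.ndarray:
        return self.impedances.imag

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.impedances)

    @property
    def phase(self) -> np.ndarray:
        """Phase angle in radians, four-quadrant."""
        return np.angle(self.impedances)

    def restrict(self, f_min: float, f_max: float) -> "ImpedanceSpectrum":
        """Sub-spectrum with f_min <= f <= f_max (inclusive)."""
        mask = (self.frequencies >= f_min) & (self.frequencies <= f_max)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{f_min}, {f_max}] Hz keeps {int(mask.sum())} of "
                f"{len(self)} points; need >= 2"
            )
        return ImpedanceSpectrum(self.frequencies[mask], self.impedances[mask], self.label)


def to_polar(z):
    """Rectangular -> polar: return (|Z|, phase) with a four-quadrant phase.

    ``|Z| = sqrt(ZR^2 + ZIM^2)`` and ``tan(phase) = ZIM/ZR``; Z = 0 maps to
    (0, 0) by convention.  Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=complex)
    mag = np.abs(z)
    phase = np.arctan2(z.imag, z.real)
    if z.ndim == 0:
        return float(mag), float(phase)
    return mag, phase


def from_polar(magnitude, phase):
    """Polar -> rectangular complex impedance."""
    return np.asarray(magnitude) * np.exp(1j * np.asarray(phase))


def z_resistor(r: float, omega=None):
    """Impedance of an ideal resistor: r + 0j, independent of frequency."""
    if r < 0:
        raise ValueError(f"resistance must be >= 0, got {r}")
    if omega is None or np.ndim(omega) == 0:
        return complex(r)
    return np.full(np.shape(omega), complex(r))


def _check_omega(omega) -> np.ndarray:
    w = np.asarray(omega, dtype=float)
    if not np.all(w > 0):
        raise ValueError("omega must be > 0")
    return w


def z_cpe(y0: float, alpha: float, omega):
    """Constant-phase element: Z = 1 / (Y0 * (j*omega)^alpha).

    alpha = 1 reduces to an ideal capacitor 1/(j*omega*Y0); alpha -> 0 to a
    resistor 1/Y0.  Constant phase -alpha*pi/2 at every frequency.
    """
    if not y0 > 0:
        raise ValueError(f"y0 must be > 0, got {y0}")
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    w = _check_omega(omega)
    z = 1.0 / (y0 * (1j * w) ** alpha)
    return complex(z) if z.ndim == 0 else z


def z_warburg(w_d: float, omega):
    """Semi-infinite Warburg diffusion element: Z = Wd * (j*omega)^(-1/2).

    Equivalently Wd*(1-j)/sqrt(2*omega): equal real and negated-imaginary
    magnitudes, constant -45 degree phase.  w_d = 0 means the element is
    absent (a short).
    """
    if w_d < 0:
        raise ValueError(f"w_d must be >= 0, got {w_d}")
    w = _check_omega(omega)
    z = w_d * (1j * w) ** -0.5
    return complex(z) if z.ndim == 0 else z


def parallel(*impedances):
    """Parallel combination of two or more impedances.

    Uses the product form for two elements so that a zero branch (short)
    yields a short instead of dividing by zero.
    """
    if len(impedances) < 2:
        raise ValueError("parallel() needs at least two impedances")
    acc = impedances[0]
    for z in impedances[1:]:
        acc = (acc * z) / (acc + z)
    return acc


def randles_impedance(params: RandlesParameters, omega):
    """Impedance of the Randles circuit Ru + [CPE || (Rp + Warburg)] at omega."""
    w = _check_omega(omega)
    branch = params.r_p + z_warburg(params.w_d, w)
    cpe = z_cpe(params.y0, params.alpha, w)
    z = params.r_u + (cpe * branch) / (cpe + branch)
    return complex(z) if np.ndim(z) == 0 else z


def evaluate_spectrum(params: RandlesParameters, frequencies, label: str = "") -> ImpedanceSpectrum:
    """Evaluate the Randles model on a frequency grid (Hz) -> ImpedanceSpectrum."""
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("frequency grid is empty")
    z = randles_impedance(params, 2.0 * np.pi * f)
    return ImpedanceSpectrum(f, np.atleast_1d(z), label)
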