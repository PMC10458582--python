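"""Forward optical model of a low-finesse fiber-optic Fabry-Perot sensor.

The sensor is an air gap between a cleaved fiber end face (reflectivity
``R1 ~ 0.04``) and a mirrored reflector (``R2 ~ 0.99``).  Light reflected from
the two surfaces interferes; the reflected spectrum is a fringe pattern whose
free spectral range encodes the cavity length ``d``.  Two-beam interference
gives the normalized reflected intensity

    Ir/Ii = (R1 + q^2 R2 - 2 q sqrt(R1 R2) cos(delta))
            / (1 + q^2 R1 R2 - 2 q sqrt(R1 R2) cos(delta)),

with interference phase ``delta = 4 pi n d / lambda + phi0``.  Interference
maxima occur where ``delta`` is an odd multiple of pi.

This module also carries the linear thermal model of the mounted sensor: the
cavity-length drift per degree is the thermal-expansion mismatch between the
expander body (gauge length ``l``, CTE ``alpha1``) and the fiber (CTE
``alpha2``), ``dd/dT = l*alpha1 - (l - d)*alpha2``.

Units at the interface: wavelengths in nm, cavity length in um, gauge length
in mm, CTEs per degC.  Conversions are internal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import GridResolutionError, InvalidGeometryError, InvalidInputError

__all__ = [
    "FPCavityParams",
    "ThermalParams",
    "ReflectionSpectrum",
    "ResolutionWarning",
    "phase",
    "reflectance",
    "reflectance_at_phase",
    "resonance_wavelengths",
    "generate_spectrum",
    "temperature_sensitivity",
    "apply_temperature",
    "DEFAULT_WL_MIN_NM",
    "DEFAULT_WL_MAX_NM",
    "DEFAULT_N_SAMPLES",
]

NM_PER_UM = 1e3
UM_PER_MM = 1e3

# Interrogator span and a grid fine enough that 3-point quadratic peak
# interpolation reaches picometre accuracy (>= ~75 samples per 3.9 nm fringe).
DEFAULT_WL_MIN_NM = 1510.0
DEFAULT_WL_MAX_NM = 1590.0
DEFAULT_N_SAMPLES = 16001

#: Require at least this many grid samples per fringe before simulating.
MIN_SAMPLES_PER_FRINGE = 20


class ResolutionWarning(UserWarning):
    """The wavelength grid under-samples the interference fringes."""


@dataclass(frozen=True)
class FPCavityParams:
    """Physical state of one Fabry-Perot sensor cavity.

    Parameters
    ----------
    d_um : physical cavity length (um); the measurand.
    r1 : reflectivity of the fiber end face.
    r2 : reflectivity of the optical reflector.
    q : light coupling coefficient (fraction of the far-mirror reflection
        coupled back into the lead-in fiber).
    n : refractive index of the cavity medium (1 for air).
    phi0 : additional interference phase (rad).
    """

    d_um: float
    r1: float = 0.04
    r2: float = 0.99
    q: float = 1.0
    n: float = 1.0
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r1 <= 1.0) or not (0.0 <= self.r2 <= 1.0):
            raise InvalidInputError(
                f"reflectivities must be in [0, 1]; got r1={self.r1}, r2={self.r2}"
            )
        if not (0.0 < self.q <= 1.0):
            raise InvalidInputError(f"coupling coefficient must be in (0, 1]; got q={self.q}")
        if self.d_um <= 0.0:
            raise InvalidInputError(f"cavity length must be positive; got d_um={self.d_um}")
        if self.n < 1.0:
            raise InvalidInputError(f"refractive index must be >= 1; got n={self.n}")

    @property
    def d_nm(self) -> float:
        return self.d_um * NM_PER_UM

    @property
    def opd_um(self) -> float:
        """Optical path difference, 2 n d, in um."""
        return 2.0 * self.n * self.d_um

    def with_d(self, d_um: float) -> "FPCavityParams":
        return replace(self, d_um=d_um)


@dataclass(frozen=True)
class ThermalParams:
    """Thermal-expansion mismatch model of the mounted sensor.

    gauge_length_mm : fixed length l of the sensor mounting (mm).
    alpha_expander : CTE of the expander material (per degC).
    alpha_fiber : CTE of the optical fiber (per degC).
    """

    gauge_length_mm: float
    alpha_expander: float
    alpha_fiber: float

    def __post_init__(self) -> None:
        if self.gauge_length_mm <= 0.0:
            raise InvalidInputError("gauge length must be positive")
        if self.alpha_expander < 0.0 or self.alpha_fiber < 0.0:
            raise InvalidInputError("thermal expansion coefficients must be >= 0")


@dataclass
class ReflectionSpectrum:
    """One acquired (or simulated) reflected-spectrum frame.

    wavelengths_nm must be strictly increasing; intensities are the normalized
    ratio Ir/Ii, finite and non-negative (and <= 1 for physical parameters).
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    timestamp_s: float | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.shape != self.intensities.shape:
            raise InvalidInputError("wavelengths and intensities must be 1-D and equal length")
        if self.wavelengths_nm.size < 2:
            raise InvalidInputError("a spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths_nm) > 0.0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0.0):
            raise InvalidInputError("intensities must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def span_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])


def phase(lam_nm, params: FPCavityParams):
    """Interference phase delta = 4 pi n d / lambda + phi0 (rad).

    ``lam_nm`` may be a scalar or array of wavelengths in nm; the cavity
    length is converted to nm internally so the ratio is dimensionless.
    """
    lam = np.asarray(lam_nm, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidInputError("wavelength must be positive")
    delta = 4.0 * np.pi * params.n * params.d_nm / lam + params.phi0
    return float(delta) if np.isscalar(lam_nm) else delta


def reflectance_at_phase(delta, params: FPCavityParams):
    """Normalized reflected intensity Ir/Ii as a function of the phase."""
    cos_d = np.cos(delta)
    cross = 2.0 * params.q * np.sqrt(params.r1 * params.r2)
    num = params.r1 + params.q**2 * params.r2 - cross * cos_d
    den = 1.0 + params.q**2 * params.r1 * params.r2 - cross * cos_d
    return num / den


def reflectance(lam_nm, params: FPCavityParams):
    """Normalized reflected intensity Ir/Ii at wavelength(s) ``lam_nm``.

    Local maxima sit where the phase is an odd multiple of pi (the cross term
    enters both numerator and denominator, but the numerator fraction grows
    faster as cos(delta) -> -1 for R1, R2 < 1).
    """
    return reflectance_at_phase(phase(lam_nm, params), params)


def resonance_wavelengths(
    params: FPCavityParams,
    wl_min_nm: float = DEFAULT_WL_MIN_NM,
    wl_max_nm: float = DEFAULT_WL_MAX_NM,
) -> np.ndarray:
    """Closed-form interference-maximum wavelengths inside a span, ascending.

    Maxima satisfy delta = m*pi for odd m, i.e.
    ``lambda = 4 pi n d / (m*pi - phi0)``.  For ``phi0 = 0`` this is the
    familiar ``lambda = 4 n d / m``.
    """
    if wl_min_nm <= 0 or wl_max_nm <= wl_min_nm:
        raise InvalidInputError("need 0 < wl_min < wl_max")
    opd = 4.0 * np.pi * params.n * params.d_nm
    # m*pi - phi0 = opd / lambda  ->  m = (opd / lambda + phi0) / pi
    m_hi = (opd / wl_min_nm + params.phi0) / np.pi
    m_lo = (opd / wl_max_nm + params.phi0) / np.pi
    first_odd = int(np.ceil(m_lo))
    if first_odd % 2 == 0:
        first_odd += 1
    orders = np.arange(first_odd, np.floor(m_hi) + 1, 2)
    if orders.size == 0:
        return np.empty(0)
    lams = opd / (orders * np.pi - params.phi0)
    return np.sort(lams)


def generate_spectrum(
    params: FPCavityParams,
    wl_min_nm: float = DEFAULT_WL_MIN_NM,
    wl_max_nm: float = DEFAULT_WL_MAX_NM,
    n_samples: int = DEFAULT_N_SAMPLES,
    *,
    timestamp_s: float | None = None,
    channel: str | None = None,
    wavelength_shift_nm: float = 0.0,
    on_coarse_grid: str = "warn",
) -> ReflectionSpectrum:
    """Simulate a reflected-spectrum frame on a uniform wavelength grid.

    ``wavelength_shift_nm`` rigidly shifts the fringe pattern (all peaks move
    by +shift), which is how interrogator wavelength-repeatability jitter is
    emulated.  If the grid resolves a fringe with fewer than
    ``MIN_SAMPLES_PER_FRINGE`` samples, a :class:`ResolutionWarning` is issued
    (``on_coarse_grid="warn"``) or :class:`GridResolutionError` raised
    (``"error"``).
    """
    if n_samples < 2:
        raise InvalidInputError("n_samples must be >= 2")
    if on_coarse_grid not in ("warn", "error", "ignore"):
        raise InvalidInputError("on_coarse_grid must be 'warn', 'error' or 'ignore'")
    wl = np.linspace(wl_min_nm, wl_max_nm, n_samples)
    spacing = (wl_max_nm - wl_min_nm) / (n_samples - 1)
    fsr = wl_min_nm**2 / (2.0 * params.n * params.d_nm)  # smallest FSR in span
    if fsr / spacing < MIN_SAMPLES_PER_FRINGE and on_coarse_grid != "ignore":
        msg = (
            f"grid spacing {spacing:.4g} nm gives only {fsr / spacing:.1f} samples per "
            f"{fsr:.3g} nm fringe at d={params.d_um} um (need >= {MIN_SAMPLES_PER_FRINGE})"
        )
        if on_coarse_grid == "error":
            raise GridResolutionError(msg)
        warnings.warn(msg, ResolutionWarning, stacklevel=2)
    intensities = reflectance(wl - wavelength_shift_nm, params)
    return ReflectionSpectrum(wl, intensities, timestamp_s=timestamp_s, channel=channel)


def temperature_sensitivity(thermal: ThermalParams, d_um: float) -> float:
    """Cavity-length temperature sensitivity dd/dT in um/degC.

    The expander body elongates over the full gauge length l while the fiber
    occupies l - d of it, so the gap changes by
    ``l*alpha1 - (l - d)*alpha2`` per degree.  Requires d < l.
    """
    l_um = thermal.gauge_length_mm * UM_PER_MM
    if d_um < 0:
        raise InvalidInputError("cavity length must be >= 0")
    if d_um >= l_um:
        raise InvalidGeometryError(
            f"cavity length ({d_um} um) must be shorter than the gauge length ({l_um} um)"
        )
    return l_um * thermal.alpha_expander - (l_um - d_um) * thermal.alpha_fiber


def apply_temperature(
    d0_um: float,
    delta_t_c: float,
    thermal: ThermalParams | None = None,
    *,
    sensitivity_um_per_c: float | None = None,
) -> float:
    """Linearized thermally drifted cavity length d0 + (dd/dT)*dT (um).

    The sensitivity is taken from the mismatch model by default; pass
    ``sensitivity_um_per_c`` to use an empirically fitted value instead
    (oven calibrations report the fitted slope directly).
    """
    if sensitivity_um_per_c is None:
        if thermal is None:
            raise InvalidInputError("provide thermal params or an empirical sensitivity")
        sensitivity_um_per_c = temperature_sensitivity(thermal, d0_um)
    return d0_um + sensitivity_um_per_c * delta_t_c
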