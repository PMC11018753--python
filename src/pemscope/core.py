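"""Material constants and closed-form acousto-optic relations.

Time-resolved Brillouin scattering (TRBS) probes a coherent acoustic
phonon wavefront with a delayed laser pulse.  At normal incidence the
reflectivity oscillates at the Brillouin frequency

    f_B = 2 n v / lambda_probe,

which links the optical refractive index ``n``, the longitudinal sound
velocity ``v`` and the vacuum probe wavelength.  Everything in this
module is an algebraic consequence of that relation plus the complex
longitudinal modulus

    M* = M' + i M'' = v^2 rho + i alpha rho v^3 / (pi f_B),

where ``rho`` is the mass density and ``alpha`` the amplitude
attenuation coefficient of the phonon field.

All quantities are SI internally (m, s, Hz, Pa).  Helper constants for
unit-friendly construction (``NM``, ``UM``, ``PS``, ``NS``, ``GHZ``,
``MHZ``) are provided for readability at call sites.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NM", "UM", "MM", "PS", "NS", "US", "MHZ", "GHZ",
    "OpticalConfig", "AcousticMedium", "ComplexModulus",
    "brillouin_frequency", "sound_velocity_from_shift", "acoustic_wavelength",
    "longitudinal_modulus", "nominal_axial_resolution",
    "relative_stiffness_percent", "effective_detection_bandwidth",
    "load_media", "save_media", "PBS", "WATER", "TISSUE", "POLYSTYRENE",
    "PRESETS",
]

NM = 1e-9
UM = 1e-6
MM = 1e-3
PS = 1e-12
NS = 1e-9
US = 1e-6
MHZ = 1e6
GHZ = 1e9


@dataclass(frozen=True)
class OpticalConfig:
    """Probe optics and delay time base of the pump-probe system.

    Parameters
    ----------
    probe_wavelength : float
        Vacuum probe wavelength in metres (default 830 nm).
    pump_wavelength : float
        Pump wavelength in metres; metadata only (default 780 nm).
    sweep_span : float
        Pump-probe delay window in seconds (default 12.5 ns, the
        inverse of the 80 MHz laser repetition rate).
    sampling_period : float
        Delay sampling period in seconds (default 3 ps).
    """

    probe_wavelength: float = 830 * NM
    pump_wavelength: float = 780 * NM
    sweep_span: float = 12.5 * NS
    sampling_period: float = 3 * PS

    def __post_init__(self) -> None:
        if self.probe_wavelength <= 0:
            raise ValueError("probe_wavelength must be positive")
        if self.sampling_period <= 0:
            raise ValueError("sampling_period must be positive")
        if self.sweep_span <= self.sampling_period:
            raise ValueError("sweep_span must exceed sampling_period")

    def time_base(self) -> np.ndarray:
        """Uniform delay axis from 0 (coincidence) to the sweep span."""
        n = int(round(self.sweep_span / self.sampling_period))
        return np.arange(n) * self.sampling_period

    def wavenumber(self, n: float) -> float:
        """Optical wavenumber k = 2 pi n / lambda_probe inside a medium."""
        return 2.0 * math.pi * n / self.probe_wavelength


@dataclass(frozen=True)
class AcousticMedium:
    """Optical and acoustic constants of one homogeneous region.

    ``attenuation`` is the amplitude attenuation of the phonon field in
    1/m; ``scatter_strength`` is the relative photoelastic oscillation
    amplitude of the Brillouin component (dimensionless, 1 for the
    control medium).
    """

    name: str
    refractive_index: float
    mass_density: float
    sound_velocity: float
    attenuation: float = 0.0
    scatter_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.mass_density <= 0:
            raise ValueError("mass_density must be positive")
        if self.sound_velocity < 0:
            raise ValueError("sound_velocity must be non-negative")
        if self.attenuation < 0:
            raise ValueError("attenuation must be non-negative")
        if self.scatter_strength < 0:
            raise ValueError("scatter_strength must be non-negative")

    def with_(self, **kwargs) -> "AcousticMedium":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ComplexModulus:
    """Storage (M') and loss (M'') parts of the longitudinal modulus, Pa."""

    storage: float
    loss: float

    @property
    def complex(self) -> complex:
        return complex(self.storage, self.loss)


def brillouin_frequency(medium: AcousticMedium, probe_wavelength: float) -> float:
    """Brillouin frequency shift f_B = 2 n v / lambda at normal incidence."""
    if probe_wavelength <= 0:
        raise ValueError("probe_wavelength must be positive")
    return 2.0 * medium.refractive_index * medium.sound_velocity / probe_wavelength


def sound_velocity_from_shift(f_B: float, n: float, probe_wavelength: float) -> float:
    """Invert f_B = 2 n v / lambda for the local sound velocity."""
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if f_B < 0:
        raise ValueError("f_B must be non-negative")
    if probe_wavelength <= 0:
        raise ValueError("probe_wavelength must be positive")
    return f_B * probe_wavelength / (2.0 * n)


def acoustic_wavelength(probe_wavelength: float, n: float) -> float:
    """Bragg-matched phonon wavelength lambda_probe / (2 n)."""
    if n < 1:
        raise ValueError("refractive index must be >= 1")
    if probe_wavelength <= 0:
        raise ValueError("probe_wavelength must be positive")
    return probe_wavelength / (2.0 * n)


def longitudinal_modulus(medium: AcousticMedium, f_B: float) -> ComplexModulus:
    """Complex longitudinal modulus M* = v^2 rho + i alpha rho v^3 / (pi f_B)."""
    v, rho, alpha = medium.sound_velocity, medium.mass_density, medium.attenuation
    storage = v * v * rho
    if alpha == 0:
        return ComplexModulus(storage=storage, loss=0.0)
    if f_B <= 0:
        raise ValueError("f_B must be positive when attenuation is non-zero")
    loss = alpha * rho * v**3 / (math.pi * f_B)
    return ComplexModulus(storage=storage, loss=loss)


def nominal_axial_resolution(window_fwhm: float) -> float:
    """Nominal axial resolution: half the analysis window FWHM.

    A wavelet z-sectioning window of FWHM ``z_win`` resolves features
    separated by about ``z_win / 2`` (e.g. 520 nm -> 260 nm,
    1.28 um -> 640 nm).
    """
    if window_fwhm <= 0:
        raise ValueError("window_fwhm must be positive")
    return window_fwhm / 2.0


def relative_stiffness_percent(delta_f: float, baseline_f: float) -> float:
    """Percent stiffness change via the sound-velocity proxy.

    With refractive index held fixed, a relative Brillouin shift maps
    one-to-one onto a relative sound-velocity change, so
    ``100 * delta_f / baseline_f`` is the velocity-proxy percent
    stiffness change (sign preserved).
    """
    if baseline_f <= 0:
        raise ValueError("baseline_f must be positive")
    return 100.0 * delta_f / baseline_f


def effective_detection_bandwidth(detector_bandwidth: float,
                                  repetition_rate: float = 80e6,
                                  sweep_time: float = 100 * US) -> float:
    """Effective bandwidth of an asynchronous-optical-sampling detector.

    Asynchronous optical sampling stretches the 0..1/rep_rate delay
    window over ``sweep_time`` of laboratory time, scaling the
    electronic detector bandwidth by ``repetition_rate * sweep_time``
    (e.g. 5.5 MHz * (80 MHz * 100 us = 8000) = 44 GHz).
    """
    if min(detector_bandwidth, repetition_rate, sweep_time) <= 0:
        raise ValueError("all arguments must be positive")
    return detector_bandwidth * repetition_rate * sweep_time


# --- shipped presets -------------------------------------------------------

#: Phosphate-buffered saline / water-like control medium.  The sound
#: velocity of PBS at room temperature is taken as the literature value
#: for water, 1497 m/s; configurable through ``load_media``.
PBS = AcousticMedium("pbs", refractive_index=1.33, mass_density=1000.0,
                     sound_velocity=1497.0)
WATER = AcousticMedium("water", refractive_index=1.33, mass_density=1000.0,
                       sound_velocity=1497.0)
#: Generic soft tissue: n ~ 1.38 and rho ~ 1200 kg/m^3.
TISSUE = AcousticMedium("tissue", refractive_index=1.38, mass_density=1200.0,
                        sound_velocity=1700.0)
#: Polystyrene culture-dish substrate (literature room-temperature values).
POLYSTYRENE = AcousticMedium("polystyrene", refractive_index=1.59,
                             mass_density=1050.0, sound_velocity=2350.0)

PRESETS = {m.name: m for m in (PBS, WATER, TISSUE, POLYSTYRENE)}


def load_media(path) -> dict[str, AcousticMedium]:
    """Read media definitions from a plain-text key/value config.

    One section per medium::

        [pbs]
        n = 1.33
        rho = 1000
        v = 1497
        alpha = 0
        scatter_strength = 1
    """
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    media = {}
    for name in parser.sections():
        sec = parser[name]
        media[name] = AcousticMedium(
            name=name,
            refractive_index=sec.getfloat("n"),
            mass_density=sec.getfloat("rho"),
            sound_velocity=sec.getfloat("v"),
            attenuation=sec.getfloat("alpha", fallback=0.0),
            scatter_strength=sec.getfloat("scatter_strength", fallback=1.0),
        )
    return media


def save_media(path, media: dict[str, AcousticMedium]) -> None:
    """Write media definitions in the format read by :func:`load_media`."""
    parser = configparser.ConfigParser()
    for name, m in media.items():
        parser[name] = {
            "n": repr(m.refractive_index),
            "rho": repr(m.mass_density),
            "v": repr(m.sound_velocity),
            "alpha": repr(m.attenuation),
            "scatter_strength": repr(m.scatter_strength),
        }
    with open(path, "w") as fh:
        parser.write(fh)
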