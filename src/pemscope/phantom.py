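"""Synthetic time-of-flight signal generator for layered phantoms.

The simulated reflectivity trace is the sum of the three components a
pump-probe measurement produces: a narrow coincidence peak at zero
delay, a slowly decaying thermal background, and the Brillouin
oscillation of the phonon wavefront.  The wavefront position obeys
``dz/dt = v(z)`` and the oscillation phase accumulates at the local
Brillouin frequency

    phi(t) = integral of 2 pi f_B(z(t')) dt',   f_B = 2 n v / lambda.

Both integrals are evaluated in closed form per layer (velocities are
piecewise constant in depth), so traces are exact up to the sampling
grid.  Acoustic transmission across interfaces is treated as total: no
partial reflections or echoes, matching the single-wavefront signal
model; photoelastic amplitude differences enter through each medium's
``scatter_strength`` and the phonon amplitude decays as
``exp(-integral of alpha dz)``.

Every simulation product carries its ground truth (layer boundaries,
instantaneous frequency, surface position) so that analysis code can be
tested as a parameter-recovery problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (GHZ, MHZ, NM, PBS, PS, TISSUE, UM, AcousticMedium,
                   OpticalConfig, brillouin_frequency,
                   sound_velocity_from_shift)

__all__ = [
    "LayerStack", "ScanPhantom", "SimulationConfig", "ToFTrace", "TraceTruth",
    "ScanSimulation", "simulate_trace", "simulate_scan",
    "build_cuticle_phantom", "build_cell_phantom", "build_step_stack",
    "simulate_approach_series", "CUTICLE_DELTA_F",
]


@dataclass(frozen=True)
class LayerStack:
    """Stand-off gap, finite layers, and a semi-infinite backing.

    ``standoff`` is the control-medium gap between the transducer face
    and the specimen surface; the control medium itself is supplied at
    simulation time so one stack can be reused under different
    couplants.
    """

    standoff: float
    layers: tuple[tuple[AcousticMedium, float], ...]
    backing: AcousticMedium

    def __post_init__(self) -> None:
        if self.standoff < 0:
            raise ValueError("standoff must be non-negative")
        for medium, thickness in self.layers:
            if thickness <= 0:
                raise ValueError(f"layer {medium.name!r} thickness must be positive")

    def with_standoff(self, standoff: float) -> "LayerStack":
        return replace(self, standoff=standoff)

    def media_sequence(self, control: AcousticMedium) -> list[tuple[AcousticMedium, float]]:
        """Full depth sequence: (medium, thickness), backing has inf."""
        seq = [(control, self.standoff)] if self.standoff > 0 else []
        seq.extend(self.layers)
        seq.append((self.backing, math.inf))
        return seq

    def boundaries(self) -> np.ndarray:
        """Interface depths (m) measured from the transducer face."""
        th = [self.standoff] + [t for _, t in self.layers]
        return np.cumsum(th)

    def frequency_profile(self, z: np.ndarray, control: AcousticMedium,
                          probe_wavelength: float) -> np.ndarray:
        """Ground-truth f_B at each depth ``z`` (m from the transducer)."""
        seq = self.media_sequence(control)
        edges = np.cumsum([t for _, t in seq[:-1]])
        idx = np.searchsorted(edges, z, side="right")
        freqs = np.array([brillouin_frequency(m, probe_wavelength) for m, _ in seq])
        return freqs[idx]


@dataclass(frozen=True)
class ScanPhantom:
    """Lateral grid of layer stacks sharing one control medium."""

    stacks: tuple[tuple[LayerStack, ...], ...]   # [ix][iy]
    pitch: float
    control: AcousticMedium

    def __post_init__(self) -> None:
        if not self.stacks or not self.stacks[0]:
            raise ValueError("phantom grid must be non-empty")
        ny = len(self.stacks[0])
        if any(len(col) != ny for col in self.stacks):
            raise ValueError("ragged phantom grid")

    @property
    def nx(self) -> int:
        return len(self.stacks)

    @property
    def ny(self) -> int:
        return len(self.stacks[0])

    def stack_at(self, ix: int, iy: int) -> LayerStack:
        return self.stacks[ix][iy]

    def surface_truth(self, tip_height: float | None = None) -> np.ndarray:
        """Ground-truth surface: stand-off per pixel, or height if
        ``tip_height`` is given (height = tip_height - standoff)."""
        z = np.array([[s.standoff for s in col] for col in self.stacks])
        if tip_height is None:
            return z
        return tip_height - z

    @classmethod
    def uniform(cls, stack: LayerStack, nx: int, ny: int, pitch: float,
                control: AcousticMedium) -> "ScanPhantom":
        return cls(tuple(tuple(stack for _ in range(ny)) for _ in range(nx)),
                   pitch, control)


@dataclass(frozen=True)
class SimulationConfig:
    """Signal-composition parameters of one synthetic acquisition.

    Amplitudes are in the (arbitrary) reflectivity units of the
    Brillouin oscillation, whose control-medium amplitude is 1 by
    convention.  ``noise_sigma`` is the standard deviation of additive
    white Gaussian noise per sample.
    """

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    coincidence_amplitude: float = 20.0
    coincidence_width: float = 10 * PS
    thermal_amplitude: float = 5.0
    thermal_decay: float = 5e-9
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.thermal_decay <= 0:
            raise ValueError("thermal_decay must be positive")
        if self.coincidence_width <= 0:
            raise ValueError("coincidence_width must be positive")


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth attached to a simulated trace."""

    boundaries_z: np.ndarray          # interface depths (m)
    boundaries_t: np.ndarray          # wavefront arrival times at interfaces (s)
    wavefront_z: np.ndarray           # z(t) per sample (m)
    instantaneous_f: np.ndarray       # f_B at the wavefront per sample (Hz)
    layer_frequencies: np.ndarray     # f_B of control, layers..., backing (Hz)
    surface_z: float                  # specimen surface depth = standoff (m)


@dataclass(frozen=True)
class ToFTrace:
    """One time-resolved reflectivity signal plus acquisition metadata."""

    time: np.ndarray
    amplitude: np.ndarray
    config: SimulationConfig | None = None
    position: tuple[int, int] | None = None
    truth: TraceTruth | None = None

    def __post_init__(self) -> None:
        if len(self.time) != len(self.amplitude):
            raise ValueError("time and amplitude must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite")

    @property
    def sampling_period(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 0.0

    def with_amplitude(self, amplitude: np.ndarray) -> "ToFTrace":
        return replace(self, amplitude=np.asarray(amplitude, dtype=float))


def _propagate(stack: LayerStack, control: AcousticMedium,
               optics: OpticalConfig, t: np.ndarray):
    """Exact piecewise propagation of the wavefront through the stack.

    Returns per-sample depth, phase, attenuation integral, scatter
    strength and instantaneous frequency, plus interface times/depths.
    """
    seq = stack.media_sequence(control)
    lam = optics.probe_wavelength

    # entry time/depth/phase/attenuation of each segment
    t_edges = [0.0]
    z_edges = [0.0]
    phi_edges = [0.0]
    att_edges = [0.0]
    freqs, vels, scats = [], [], []
    for medium, thickness in seq:
        v = medium.sound_velocity
        f = brillouin_frequency(medium, lam)
        freqs.append(f)
        vels.append(v)
        scats.append(medium.scatter_strength)
        if math.isinf(thickness):
            break
        dt_seg = thickness / v if v > 0 else math.inf
        t_edges.append(t_edges[-1] + dt_seg)
        z_edges.append(z_edges[-1] + thickness)
        phi_edges.append(phi_edges[-1] + 2 * math.pi * f * dt_seg)
        att_edges.append(att_edges[-1] + medium.attenuation * thickness)

    t_entry = np.array(t_edges)
    seg = np.clip(np.searchsorted(t_entry, t, side="right") - 1, 0, len(freqs) - 1)
    dt_in = t - t_entry[seg]
    v_arr = np.array(vels)[seg]
    f_arr = np.array(freqs)[seg]
    z = np.array(z_edges)[seg] + v_arr * dt_in
    phi = np.array(phi_edges)[seg] + 2 * math.pi * f_arr * dt_in
    alpha_arr = np.array([m.attenuation for m, _ in seq])[seg]
    att = np.array(att_edges)[seg] + alpha_arr * v_arr * dt_in
    scat = np.array(scats)[seg]
    truth = TraceTruth(
        boundaries_z=stack.boundaries(),
        boundaries_t=t_entry[1:].copy(),
        wavefront_z=z,
        instantaneous_f=f_arr,
        layer_frequencies=np.array(freqs),
        surface_z=stack.standoff,
    )
    return z, phi, att, scat, truth


def simulate_trace(stack: LayerStack, control: AcousticMedium,
                   cfg: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   position: tuple[int, int] | None = None) -> ToFTrace:
    """Simulate one time-of-flight trace from a layer stack.

    The amplitude is ``coincidence + thermal + Brillouin + noise`` with
    the Brillouin term ``s(z) exp(-int alpha dz) cos(phi(t))`` evaluated
    exactly on the sampling grid.  Pass ``rng`` to draw noise from an
    externally managed stream (used by :func:`simulate_scan` for
    per-position substreams); otherwise ``cfg.seed`` seeds a fresh one.
    """
    t = cfg.optics.time_base()
    _, phi, att, scat, truth = _propagate(stack, control, cfg.optics, t)
    brillouin = scat * np.exp(-att) * np.cos(phi)
    coincidence = cfg.coincidence_amplitude * np.exp(
        -0.5 * (t / cfg.coincidence_width) ** 2)
    thermal = cfg.thermal_amplitude * np.exp(-t / cfg.thermal_decay)
    amplitude = coincidence + thermal + brillouin
    if cfg.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        amplitude = amplitude + rng.normal(0.0, cfg.noise_sigma, size=t.shape)
    return ToFTrace(time=t, amplitude=amplitude, config=cfg,
                    position=position, truth=truth)


@dataclass(frozen=True)
class ScanSimulation:
    """All traces of a lateral scan plus phantom-level ground truth."""

    traces: tuple[tuple[ToFTrace, ...], ...]   # [ix][iy]
    phantom: ScanPhantom
    config: SimulationConfig

    @property
    def nx(self) -> int:
        return len(self.traces)

    @property
    def ny(self) -> int:
        return len(self.traces[0])

    def trace_at(self, ix: int, iy: int) -> ToFTrace:
        return self.traces[ix][iy]

    def surface_truth(self, tip_height: float | None = None) -> np.ndarray:
        return self.phantom.surface_truth(tip_height)

    def frequency_truth(self, z: np.ndarray) -> np.ndarray:
        """Ground-truth f_B(x, y, z) volume on a depth grid."""
        lam = self.config.optics.probe_wavelength
        out = np.empty((self.nx, self.ny, len(z)))
        for ix in range(self.nx):
            for iy in range(self.ny):
                out[ix, iy] = self.phantom.stack_at(ix, iy).frequency_profile(
                    z, self.phantom.control, lam)
        return out


def simulate_scan(phantom: ScanPhantom, cfg: SimulationConfig) -> ScanSimulation:
    """Simulate one trace per lateral grid point.

    Noise is drawn from independent per-position substreams spawned
    from ``cfg.seed`` in row-major (x, then y) order, so the result is
    bit-identical for identical seeds and independent across pixels.
    """
    if phantom.nx == 0 or phantom.ny == 0:
        raise ValueError("empty scan grid")
    children = np.random.SeedSequence(cfg.seed).spawn(phantom.nx * phantom.ny)
    traces = []
    k = 0
    for ix in range(phantom.nx):
        col = []
        for iy in range(phantom.ny):
            rng = np.random.default_rng(children[k])
            k += 1
            col.append(simulate_trace(phantom.stack_at(ix, iy), phantom.control,
                                      cfg, rng=rng, position=(ix, iy)))
        traces.append(tuple(col))
    return ScanSimulation(traces=tuple(traces), phantom=phantom, config=cfg)


#: Relative Brillouin shifts of the nematode cuticle layers (Hz).
CUTICLE_DELTA_F = {
    "cortical": 300 * MHZ,
    "medial": 60 * MHZ,
    "basal": 300 * MHZ,
    "hypodermis": -200 * MHZ,
    "strut": 600 * MHZ,
}

#: Default cuticle layer thicknesses (m).
CUTICLE_THICKNESS = {
    "cortical": 320 * NM,
    "medial": 400 * NM,
    "basal": 320 * NM,
    "hypodermis": 1.5 * UM,
}


def build_cuticle_phantom(standoff: float = 1.0 * UM,
                          delta_f: dict[str, float] | None = None,
                          thickness: dict[str, float] | None = None,
                          strut: bool = False,
                          control: AcousticMedium = PBS,
                          tissue_index: float = 1.38,
                          tissue_density: float = 1200.0,
                          probe_wavelength: float = 830 * NM) -> LayerStack:
    """Nematode-cuticle layer stack parameterised by relative shifts.

    Layers (cortical, medial, basal, hypodermis) are assigned sound
    velocities that reproduce the requested Brillouin shifts relative
    to the control medium at the tissue refractive index; the backing
    continues the hypodermis material (sub-hypodermal tissue).  The
    ``strut`` variant replaces the liquid-filled medial layer with the
    stiff columnar strut material.
    """
    df = dict(CUTICLE_DELTA_F)
    if delta_f:
        df.update(delta_f)
    th = dict(CUTICLE_THICKNESS)
    if thickness:
        th.update(thickness)
    for name, t in th.items():
        if t <= 0:
            raise ValueError(f"thickness of {name!r} must be positive")
    f0 = brillouin_frequency(control, probe_wavelength)

    def layer(name: str, shift_key: str | None = None) -> tuple[AcousticMedium, float]:
        shift = df[shift_key or name]
        v = sound_velocity_from_shift(f0 + shift, tissue_index, probe_wavelength)
        medium = AcousticMedium(name=name, refractive_index=tissue_index,
                                mass_density=tissue_density, sound_velocity=v)
        return medium, th[name]

    layers = (
        layer("cortical"),
        layer("medial", "strut" if strut else "medial"),
        layer("basal"),
        layer("hypodermis"),
    )
    backing = layers[-1][0].with_(name="sub-hypodermis")
    return LayerStack(standoff=standoff, layers=layers, backing=backing)


def build_step_stack(standoff: float, specimen: AcousticMedium) -> LayerStack:
    """Semi-infinite specimen behind a control-medium gap (step phantom)."""
    return LayerStack(standoff=standoff, layers=(), backing=specimen)


def build_cell_phantom(height: float,
                       cell_medium: AcousticMedium | None = None,
                       nx: int = 21, ny: int = 21,
                       pitch: float = 1.0 * UM,
                       tip_height: float | None = None,
                       footprint_radius: float | None = None,
                       control: AcousticMedium = PBS) -> ScanPhantom:
    """Cell-on-dish phantom: a smooth dome of cell material in control medium.

    The dome height profile is a raised cosine of peak ``height`` over a
    circular footprint; per pixel the stand-off is ``tip_height`` minus
    the local height.  Outside the footprint the pixel is pure control
    medium (no surface in range).  ``tip_height`` defaults to
    ``height + 1.5 um`` so the apex sits comfortably inside the depth
    measurement range.
    """
    if height < 0:
        raise ValueError("height must be non-negative")
    if cell_medium is None:
        cell_medium = TISSUE
    if tip_height is None:
        tip_height = height + 1.5 * UM
    if tip_height < height:
        raise ValueError("tip_height must be at least the dome height")
    x = (np.arange(nx) - (nx - 1) / 2) * pitch
    y = (np.arange(ny) - (ny - 1) / 2) * pitch
    if footprint_radius is None:
        footprint_radius = 0.4 * max(x.max() - x.min(), y.max() - y.min(), pitch)
    far = build_step_stack(standoff=tip_height, specimen=control)
    cols = []
    for xi in x:
        col = []
        for yi in y:
            r = math.hypot(xi, yi)
            h = height * math.cos(math.pi * r / (2 * footprint_radius)) ** 2 \
                if r < footprint_radius else 0.0
            if h <= 0 or height == 0:
                col.append(far)
            else:
                col.append(LayerStack(standoff=tip_height - h,
                                      layers=((cell_medium, h),),
                                      backing=cell_medium.with_(name="cell-backing")))
        cols.append(tuple(col))
    return ScanPhantom(stacks=tuple(cols), pitch=pitch, control=control)


def simulate_approach_series(stack: LayerStack, standoffs: Sequence[float],
                             cfg: SimulationConfig,
                             control: AcousticMedium = PBS) -> list[ToFTrace]:
    """One trace per stand-off, emulating a piezo approach to the specimen.

    ``standoffs`` should be non-negative and non-increasing (the tip
    descends).  Each step draws noise from its own substream of
    ``cfg.seed``.
    """
    standoffs = list(standoffs)
    if any(s < 0 for s in standoffs):
        raise ValueError("standoffs must be non-negative")
    if any(b > a for a, b in zip(standoffs, standoffs[1:], strict=False)):
        raise ValueError("standoffs must be non-increasing (approach)")
    children = np.random.SeedSequence(cfg.seed).spawn(max(len(standoffs), 1))
    out = []
    for s, child in zip(standoffs, children):
        rng = np.random.default_rng(child)
        out.append(simulate_trace(stack.with_standoff(s), control, cfg, rng=rng))
    return out
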