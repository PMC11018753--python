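"""Depth-resolved analysis: complex-Morlet transform, ridge, reference.

The instantaneous frequency of a time-of-flight trace encodes the
depth profile of the Brillouin shift.  It is estimated with a
complex-Morlet time-frequency transform

    Psi(f, t) = (pi f_b)^(-1/2) exp(2 pi i f t - t^2 / f_b),

correlating the trace with daughter wavelets on a frequency grid; the
ridge (frequency of maximum coefficient magnitude at each time/depth)
is the depth-resolved Brillouin frequency f_B(z).  Relative shifts
Delta f_B(z) = f_B(z) - f_B0(z) are formed against a reference profile
averaged from control-medium acquisitions, which simultaneously
compensates slow thermo-optic/thermo-acoustic drifts.

Window convention
-----------------
The z-sectioning window ``window_fwhm_z`` (z_win) is the overall
wavelet width quoted in depth units; the Gaussian amplitude envelope of
the wavelet has a depth FWHM of ``z_win / 2``, which equals the nominal
axial resolution.  The bandwidth parameter follows as

    f_b = (z_win / (2 v_ref))^2 / (4 ln 2),

with ``v_ref`` the control-medium sound velocity used for the
time-to-depth mapping.  This makes the ridge of a piecewise-constant
frequency profile equal to the true profile smoothed by a Gaussian of
FWHM z_win / 2 (see docs/methods.md for the calibration argument).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import scipy.fft as sfft

from .core import GHZ, MHZ, NM, UM, AcousticMedium
from .phantom import ToFTrace
from .spectral import DetrendSpec, remove_background

__all__ = ["WaveletSpec", "Spectrogram", "DepthProfile", "morlet", "cwt",
           "extract_ridge", "time_to_depth", "build_reference", "compensate",
           "default_frequency_grid"]

_LN2 = math.log(2.0)


def default_frequency_grid(fmin: float = 3 * GHZ, fmax: float = 8 * GHZ,
                           step: float = 5 * MHZ) -> np.ndarray:
    """Analysis grid covering water and soft-tissue shifts at 830 nm."""
    return np.arange(fmin, fmax + 0.5 * step, step)


def morlet(f: float, f_b: float, t) -> np.ndarray | complex:
    """Complex Morlet mother wavelet value(s) at time(s) ``t``.

    Peak value (pi f_b)^(-1/2) at t = 0; the amplitude envelope has a
    time FWHM of 2 sqrt(f_b ln 2), independent of the centre frequency.
    """
    if f_b <= 0:
        raise ValueError("f_b must be positive")
    t = np.asarray(t, dtype=float) if np.ndim(t) else t
    return (np.pi * f_b) ** -0.5 * np.exp(2j * np.pi * f * t - np.square(t) / f_b)


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet window and analysis frequency grid.

    Exactly one of the window parameterisations is primary:
    ``from_window`` (depth window z_win, the usual route),
    ``from_bandwidth`` (f_b directly, seconds squared) or
    ``from_n_lambda`` (window as a multiple of the acoustic
    wavelength).  The others are derived.
    """

    bandwidth_param: float                       # f_b, s^2
    frequency_grid: np.ndarray = field(default_factory=default_frequency_grid)
    window_fwhm_z: float | None = None           # z_win, m
    n_lambda: float | None = None
    v_ref: float | None = None                   # m/s, depth-mapping velocity

    def __post_init__(self) -> None:
        if self.bandwidth_param <= 0:
            raise ValueError("bandwidth_param must be positive")
        grid = np.asarray(self.frequency_grid, dtype=float)
        if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("frequency_grid must be strictly increasing")
        object.__setattr__(self, "frequency_grid", grid)

    @classmethod
    def from_window(cls, window_fwhm_z: float, v_ref: float,
                    frequency_grid: np.ndarray | None = None) -> "WaveletSpec":
        """Window given as the depth z-sectioning width z_win (m)."""
        if window_fwhm_z <= 0 or v_ref <= 0:
            raise ValueError("window_fwhm_z and v_ref must be positive")
        f_b = (window_fwhm_z / (2.0 * v_ref)) ** 2 / (4.0 * _LN2)
        kw = {} if frequency_grid is None else {"frequency_grid": frequency_grid}
        return cls(bandwidth_param=f_b, window_fwhm_z=window_fwhm_z,
                   v_ref=v_ref, **kw)

    @classmethod
    def from_bandwidth(cls, f_b: float, v_ref: float | None = None,
                       frequency_grid: np.ndarray | None = None) -> "WaveletSpec":
        kw = {} if frequency_grid is None else {"frequency_grid": frequency_grid}
        z_win = None
        if v_ref is not None:
            z_win = 4.0 * math.sqrt(f_b * _LN2) * v_ref
        return cls(bandwidth_param=f_b, window_fwhm_z=z_win, v_ref=v_ref, **kw)

    @classmethod
    def from_n_lambda(cls, n_lambda: float, acoustic_wavelength: float,
                      v_ref: float,
                      frequency_grid: np.ndarray | None = None) -> "WaveletSpec":
        """Window given as N_lambda acoustic wavelengths of depth."""
        spec = cls.from_window(n_lambda * acoustic_wavelength, v_ref,
                               frequency_grid)
        return replace(spec, n_lambda=n_lambda)

    @property
    def envelope_fwhm_t(self) -> float:
        """Time FWHM of the wavelet amplitude envelope, 2 sqrt(f_b ln 2)."""
        return 2.0 * math.sqrt(self.bandwidth_param * _LN2)

    @property
    def window_t(self) -> float:
        """Window duration in time: z_win / v_ref = 2x envelope FWHM."""
        return 2.0 * self.envelope_fwhm_t


@dataclass(frozen=True)
class Spectrogram:
    """Coefficient magnitudes over (frequency, time/depth).

    ``valid`` flags interior columns; half-window margins at both trace
    ends are excluded from ridge statistics rather than zero-padded.
    """

    frequencies: np.ndarray
    times: np.ndarray
    coefficients: np.ndarray         # (n_freq, n_time), magnitudes
    wavelet: WaveletSpec
    valid: np.ndarray | None = None
    depth_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coefficients.shape != (len(self.frequencies), len(self.times)):
            raise ValueError("coefficient shape does not match axes")
        if np.any(self.coefficients < 0):
            raise ValueError("coefficients must be magnitudes (non-negative)")
        if self.valid is None:
            object.__setattr__(self, "valid",
                               np.ones(len(self.times), dtype=bool))


@dataclass(frozen=True)
class DepthProfile:
    """Depth-resolved Brillouin shift for one lateral position."""

    z: np.ndarray
    f_B: np.ndarray
    f_B_ref: np.ndarray
    delta_f: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.z)
        for name in ("f_B", "f_B_ref", "delta_f", "amplitude"):
            if len(getattr(self, name)) != n:
                raise ValueError("profile vectors must have equal length")
        resid = self.delta_f - (self.f_B - self.f_B_ref)
        if np.nanmax(np.abs(resid), initial=0.0) > 1e-3:
            raise ValueError("delta_f must equal f_B - f_B_ref")


def condition_signal(amplitude: np.ndarray, dt: float,
                     spec: WaveletSpec) -> np.ndarray:
    """Prepare a detrended trace for the wavelet transform.

    Two conditioning steps stabilise the near-flat column maxima of a
    ~1.6-period wavelet, whose frequency response is broad enough to
    reach both trace-edge leakage and sub-band background residue:

    * a raised-cosine taper over the half-window margins at both ends
      (those samples are flagged invalid downstream anyway);
    * a high-pass with a smooth edge below the analysis band, removing
      background curvature left by the polynomial subtraction.
    """
    x = np.asarray(amplitude, dtype=float).copy()
    n = len(x)
    n_margin = min(int(round(0.5 * spec.window_t / dt)), max(n // 2 - 1, 1))
    if n_margin > 1:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_margin) / n_margin))
        x[:n_margin] *= ramp
        x[n - n_margin:] *= ramp[::-1]
    f_lo = spec.frequency_grid[0]
    nfft = sfft.next_fast_len(2 * n)
    X = sfft.rfft(x, nfft)
    nu = sfft.rfftfreq(nfft, dt)
    hp = np.clip((nu - 0.25 * f_lo) / (0.5 * f_lo), 0.0, 1.0)
    X *= 0.5 * (1.0 - np.cos(np.pi * hp))
    return sfft.irfft(X, nfft)[:n]


def cwt(trace: ToFTrace, spec: WaveletSpec, chunk: int = 64) -> Spectrogram:
    """Complex-Morlet coefficient magnitudes of a detrended trace.

    The correlation with each daughter wavelet is evaluated in the
    Fourier domain, where the wavelet transfer function is the exact
    Gaussian ``exp(-pi^2 f_b (nu - f)^2)`` (unit peak, analytic — the
    near-zero response at negative frequencies makes the output the
    envelope magnitude of the band around ``f``).
    """
    dt = trace.sampling_period
    nyquist = 0.5 / dt
    freqs = spec.frequency_grid
    if freqs[-1] > nyquist:
        raise ValueError("frequency grid exceeds Nyquist")
    x = condition_signal(trace.amplitude, dt, spec)
    n = len(x)
    f_b = spec.bandwidth_param
    pad = int(math.ceil(4.0 * spec.envelope_fwhm_t / dt))
    nfft = sfft.next_fast_len(n + 2 * pad)
    X = sfft.fft(x, nfft)
    nu = sfft.fftfreq(nfft, dt)
    out = np.empty((len(freqs), n))
    for i in range(0, len(freqs), chunk):
        fs = freqs[i:i + chunk, None]
        H = np.exp(-np.pi ** 2 * f_b * (nu[None, :] - fs) ** 2)
        out[i:i + chunk] = np.abs(sfft.ifft(X[None, :] * H, axis=1)[:, :n])
    margin = 0.5 * spec.window_t
    t = trace.time
    valid = (t >= t[0] + margin) & (t <= t[-1] - margin)
    depth = None
    if spec.v_ref is not None:
        depth = time_to_depth(t, spec.v_ref)
    return Spectrogram(frequencies=freqs, times=t, coefficients=out,
                       wavelet=spec, valid=valid, depth_axis=depth)


def extract_ridge(spectrogram: Spectrogram,
                  top_fraction: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Per-column maximum-magnitude frequency and its magnitude.

    The grid argmax is refined by a parabolic (quadratic) fit of the
    log magnitude across the neighbouring frequencies — the contiguous
    run of bins above ``top_fraction`` of the column maximum.  The log
    magnitude of a Gaussian-band column is exactly quadratic, so the
    fit recovers the vertex while averaging out the spectral ripple
    that makes a bare 3-point interpolation of a broad, nearly flat
    peak unstable.  Ties break toward the lower frequency (first
    maximum); all-zero columns yield NaN.
    """
    coeff = spectrogram.coefficients
    freqs = spectrogram.frequencies
    n_f, n_t = coeff.shape
    k = np.argmax(coeff, axis=0)
    cols = np.arange(n_t)
    amp = coeff[k, cols]
    ridge = freqs[k].astype(float)
    step = float(np.mean(np.diff(freqs)))
    for j in cols:
        a = amp[j]
        if a <= 0:
            ridge[j] = np.nan
            continue
        thr = top_fraction * a
        col = coeff[:, j]
        below = col < thr
        kj = k[j]
        lo = int(np.flatnonzero(below[:kj]).max() + 1) if below[:kj].any() else 0
        hi = int(kj + np.flatnonzero(below[kj:]).min()) if below[kj:].any() else n_f
        # symmetric window about the argmax: an asymmetric run (peak
        # near a grid edge) would tilt the fit and bias the vertex
        m = min(kj - lo, hi - 1 - kj)
        lo, hi = kj - m, kj + m + 1
        if hi - lo < 3:
            # too narrow for a fit: 3-point parabola, vertex within half a bin
            if 0 < kj < n_f - 1 and col[kj - 1] > 0 and col[kj + 1] > 0:
                y0, y1, y2 = np.log(col[kj - 1:kj + 2])
                denom = y0 - 2.0 * y1 + y2
                if denom < 0:
                    delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
                    ridge[j] = freqs[kj] + delta * step
            continue
        f_loc = (freqs[lo:hi] - freqs[kj]) / step
        c2, c1, _ = np.polyfit(f_loc, np.log(col[lo:hi]), 2)
        if c2 < 0:
            vertex = -c1 / (2.0 * c2)
            vertex = float(np.clip(vertex, f_loc[0], f_loc[-1]))
            ridge[j] = freqs[kj] + vertex * step
    return ridge, amp


def time_to_depth(times: np.ndarray,
                  velocity: float | Callable[[float], float] | np.ndarray) -> np.ndarray:
    """Map signal time to axial depth via z = v t.

    ``velocity`` may be a scalar (z = v t exactly), a per-sample array
    (left-Riemann cumulative integral), or a callable v(z) integrated
    forward with left-Riemann steps at the sampling period.
    """
    times = np.asarray(times, dtype=float)
    if np.isscalar(velocity) or isinstance(velocity, (int, float)):
        if velocity < 0:
            raise ValueError("velocity must be non-negative")
        return float(velocity) * times
    if callable(velocity):
        z = np.empty_like(times)
        # propagate from t = 0 to the first sample with v at z = 0
        zc = 0.0
        t_prev = 0.0
        for i, t in enumerate(times):
            v = float(velocity(zc))
            if v < 0:
                raise ValueError("velocity must be non-negative")
            zc += v * (t - t_prev)
            z[i] = zc
            t_prev = t
        return z
    v = np.asarray(velocity, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be non-negative")
    if len(v) != len(times):
        raise ValueError("velocity array must match times")
    dt = np.diff(times, prepend=0.0 if len(times) == 0 else times[0])
    dt[0] = times[0]  # left-Riemann from t = 0
    return np.cumsum(v * dt)


def build_reference(reference_traces: Sequence[ToFTrace], spec: WaveletSpec,
                    detrend: DetrendSpec | None = None) -> np.ndarray:
    """Reference profile f_B0(z): pointwise mean ridge of control traces.

    Averaging ~100 control acquisitions suppresses ridge noise by
    ~1/sqrt(count) and captures slow thermo-optic drift of the
    baseline.  Traces must share one time grid.  Pass ``detrend`` to
    background-subtract raw traces first (None = already detrended).
    """
    traces = list(reference_traces)
    if not traces:
        raise ValueError("need at least one reference trace")
    if detrend is not None:
        traces = [remove_background(tr, detrend) for tr in traces]
    t0 = traces[0].time
    ridges = []
    for tr in traces:
        if len(tr.time) != len(t0) or not np.allclose(tr.time, t0, rtol=1e-9):
            raise ValueError("reference traces have inconsistent time grids")
        ridge, _ = extract_ridge(cwt(tr, spec))
        ridges.append(ridge)
    return np.nanmean(ridges, axis=0)


def compensate(f_B: np.ndarray, reference: np.ndarray,
               z: np.ndarray | None = None,
               amplitude: np.ndarray | None = None) -> DepthProfile:
    """Relative shift Delta f_B(z) = f_B(z) - f_B0(z).

    Subtracting the control-medium reference centres control regions on
    zero and cancels any drift common to measurement and reference.
    """
    f_B = np.asarray(f_B, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if f_B.shape != reference.shape:
        raise ValueError("profile and reference must have equal length")
    if z is None:
        z = np.arange(len(f_B), dtype=float)
    if amplitude is None:
        amplitude = np.full(len(f_B), np.nan)
    return DepthProfile(z=np.asarray(z, dtype=float), f_B=f_B,
                        f_B_ref=reference, delta_f=f_B - reference,
                        amplitude=np.asarray(amplitude, dtype=float))
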