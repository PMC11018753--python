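"""Image assembly, frequency-bin segmentation, layer fits, approach curves."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_widths

from .core import AcousticMedium
from .pipeline import AnalysisOptions, prepare_spectrogram
from .profilometry import SurfaceResult
from .spectral import weighted_average_shift
from .tfa import DepthProfile, extract_ridge

__all__ = ["ScanVolume", "SegmentedMap", "LayerFit", "ApproachStep",
           "assemble_volume", "segment_bins", "fit_layers", "approach_curve"]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ScanVolume:
    """Lateral grid of depth profiles stacked into a 3D image.

    ``surface`` holds the profilometry surface position z_p per pixel
    (NaN where no surface was found); ``provenance`` carries enough
    configuration (seeds, window, grids) to regenerate synthetic
    inputs bit-exactly.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    delta_f: np.ndarray       # (nx, ny, nz)
    amplitude: np.ndarray     # (nx, ny, nz)
    surface: np.ndarray       # (nx, ny), z_p
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (len(self.x), len(self.y), len(self.z))
        if self.delta_f.shape != shape or self.amplitude.shape != shape:
            raise ValueError("volume shape does not match axes")
        if self.surface.shape != shape[:2]:
            raise ValueError("surface map shape does not match lateral axes")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.delta_f)


@dataclass(frozen=True)
class SegmentedMap:
    """Per-voxel index into linearly spaced frequency bins (-1 = missing)."""

    bin_edges: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")


@dataclass(frozen=True)
class LayerFit:
    """One fitted Gaussian layer: thickness is reported as the FWHM."""

    centre: float
    fwhm: float
    amplitude: float
    residual: float
    converged: bool = True

    @property
    def sigma(self) -> float:
        return self.fwhm / _FWHM_PER_SIGMA


def assemble_volume(profiles, surfaces=None, pitch: float = 1.0,
                    provenance: dict | None = None) -> ScanVolume:
    """Stack per-pixel depth profiles into an (x, y, z) volume.

    ``profiles`` is a 2D nested sequence of :class:`DepthProfile` on a
    complete lateral grid sharing one depth grid; ``surfaces`` an
    optional matching grid of :class:`SurfaceResult`.  Profiles carry
    their positions implicitly through grid order, so any consistent
    input ordering yields the same volume.
    """
    rows = [list(col) for col in profiles]
    nx = len(rows)
    ny = len(rows[0])
    if any(len(col) != ny for col in rows):
        raise ValueError("ragged profile grid")
    z0 = rows[0][0].z
    delta = np.empty((nx, ny, len(z0)))
    amp = np.empty_like(delta)
    for ix in range(nx):
        for iy in range(ny):
            p = rows[ix][iy]
            if len(p.z) != len(z0) or not np.allclose(p.z, z0, rtol=1e-9):
                raise ValueError("inconsistent depth grids")
            delta[ix, iy] = p.delta_f
            amp[ix, iy] = p.amplitude
    surface = np.full((nx, ny), np.nan)
    if surfaces is not None:
        for ix, col in enumerate(surfaces):
            for iy, s in enumerate(col):
                if s.found:
                    surface[ix, iy] = s.z_p
    x = np.arange(nx) * pitch
    y = np.arange(ny) * pitch
    return ScanVolume(x=x, y=y, z=z0.copy(), delta_f=delta, amplitude=amp,
                      surface=surface, provenance=provenance or {})


def segment_bins(values, n_bins: int,
                 frequency_range: tuple[float, float]) -> SegmentedMap:
    """Segment shifts into ``n_bins`` linearly spaced frequency bins.

    Accepts a :class:`ScanVolume` or a bare array of Delta f_B values.
    Bins are half-open [e_i, e_{i+1}) with the top edge closed; values
    outside the range and NaN voxels are labelled -1 (missing).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = frequency_range
    if not hi > lo:
        raise ValueError("degenerate frequency range")
    data = values.delta_f if isinstance(values, ScanVolume) else np.asarray(values, dtype=float)
    edges = np.linspace(lo, hi, n_bins + 1)
    labels = np.full(data.shape, -1, dtype=np.int64)
    finite = np.isfinite(data)
    inside = finite & (data >= lo) & (data <= hi)
    width = (hi - lo) / n_bins
    idx = np.minimum(((np.where(inside, data, lo) - lo) // width).astype(np.int64),
                     n_bins - 1)
    labels[inside] = idx[inside]
    return SegmentedMap(bin_edges=edges, labels=labels)


def _gaussians(z, *params):
    out = np.zeros_like(z, dtype=float)
    for k in range(0, len(params), 3):
        a, c, s = params[k:k + 3]
        out += a * np.exp(-0.5 * ((z - c) / s) ** 2)
    return out


def fit_layers(z, delta_f, expected_peaks: int,
               min_prominence: float | None = None) -> list[LayerFit]:
    """Fit ``expected_peaks`` Gaussians over a zero baseline.

    The profile should be reference-compensated so control regions sit
    at zero.  Peaks are initialised from local maxima ranked by
    prominence; thickness is reported as the fitted FWHM.  If fewer
    maxima are detectable a warning is issued and the available peaks
    are fitted; a non-converging fit is returned flagged with the
    initial estimates.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(delta_f, dtype=float)
    ok = np.isfinite(z) & np.isfinite(y)
    z, y = z[ok], y[ok]
    if len(z) < 5:
        raise ValueError("profile too short to fit")
    if min_prominence is None:
        min_prominence = 0.05 * float(np.nanmax(np.abs(y)))
    peaks, props = find_peaks(y, prominence=min_prominence)
    if len(peaks) == 0:
        warnings.warn("no detectable maxima; nothing fitted", stacklevel=2)
        return []
    order = np.argsort(props["prominences"])[::-1]
    kept = np.sort(peaks[order[:expected_peaks]])
    if len(kept) < expected_peaks:
        warnings.warn(f"only {len(kept)} of {expected_peaks} expected maxima "
                      "detected; fitting available peaks", stacklevel=2)
    widths, _, _, _ = peak_widths(y, kept, rel_height=0.5)
    dz = float(np.mean(np.diff(z)))
    p0 = []
    for pk, w in zip(kept, widths):
        sigma0 = max(w * dz / _FWHM_PER_SIGMA, dz)
        p0.extend([y[pk], z[pk], sigma0])
    try:
        popt, _ = curve_fit(_gaussians, z, y, p0=p0, maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.asarray(p0)
        converged = False
    resid = float(np.sqrt(np.mean((y - _gaussians(z, *popt)) ** 2)))
    fits = []
    for k in range(0, len(popt), 3):
        a, c, s = popt[k:k + 3]
        fits.append(LayerFit(centre=float(c), fwhm=float(abs(s)) * _FWHM_PER_SIGMA,
                             amplitude=float(a), residual=resid,
                             converged=converged))
    fits.sort(key=lambda f: f.centre)
    return fits


@dataclass(frozen=True)
class ApproachStep:
    """Analysis of one stand-off step of an approach series."""

    weighted_shift: float
    ridge: np.ndarray
    z: np.ndarray


def approach_curve(traces, control: AcousticMedium,
                   options: AnalysisOptions) -> list[ApproachStep]:
    """Weighted-average shift and depth-resolved ridge per approach step.

    The weighted-average Brillouin shift stays at the control baseline
    while the specimen is beyond the depth measurement range and
    departs monotonically as the stand-off shrinks — the stand-off
    selection signal of the imaging protocol.
    """
    steps = []
    for tr in traces:
        spg = prepare_spectrogram(tr, control, options)
        ridge, _ = extract_ridge(spg)
        ridge = ridge.copy()
        ridge[~spg.valid] = np.nan
        steps.append(ApproachStep(weighted_shift=weighted_average_shift(spg),
                                  ridge=ridge, z=spg.depth_axis))
    return steps
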