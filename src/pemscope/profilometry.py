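"""Surface detection from the medium-frequency amplitude roll-off.

While the phonon wavefront travels through the control medium, the
trace oscillates at the control Brillouin frequency; once it crosses
into the specimen the oscillation moves to the specimen frequency and
the coefficient magnitude at the control frequency rolls off.  After
compensating the attenuation decay ``A(t) = exp(alpha_med v_med t)``
and normalising both factors by their maxima,

    C'(f0, t) = A_hat * C_hat,

the surface position z_p is where C' crosses the half level
``(1 + C'_min) / 2`` on its descending roll-off (linear interpolation
between bracketing samples).  A centroid-of-derivative estimator is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tfa import Spectrogram

__all__ = ["SurfaceResult", "compensate_amplitude", "medium_band_amplitude",
           "detect_surface", "height_map"]


@dataclass(frozen=True)
class SurfaceResult:
    """Detected surface position for one lateral pixel.

    ``crossing_quality`` is the contrast between maximum and minimum
    compensated amplitude in [0, 1]; ``found`` is False when the
    contrast is below threshold (no specimen in range).
    """

    z_p: float
    crossing_quality: float
    found: bool


def compensate_amplitude(medium_band_amplitude: np.ndarray, alpha_med: float,
                         v_med: float, times: np.ndarray,
                         valid: np.ndarray | None = None) -> np.ndarray:
    """Attenuation-compensated, normalised amplitude C' = A_hat * C_hat.

    ``medium_band_amplitude`` is the coefficient magnitude at the
    control-medium Brillouin frequency over time; entries outside
    ``valid`` are returned as NaN and excluded from the normalising
    maxima.
    """
    if alpha_med < 0:
        raise ValueError("alpha_med must be non-negative")
    amp = np.asarray(medium_band_amplitude, dtype=float)
    times = np.asarray(times, dtype=float)
    if valid is None:
        valid = np.ones(len(amp), dtype=bool)
    if not np.any(amp[valid] > 0):
        raise ValueError("amplitude is all zero in the valid window")
    a = np.exp(alpha_med * v_med * times)
    a_hat = a / a[valid].max()
    c_hat = amp / amp[valid].max()
    out = a_hat * c_hat
    out = out / out[valid].max()
    out[~valid] = np.nan
    return out


def medium_band_amplitude(spectrogram: Spectrogram, f0: float,
                          half_width_bins: int = 1) -> np.ndarray:
    """Coefficient magnitude near the control frequency f0.

    Averages the rows within ``half_width_bins`` grid steps of the
    frequency nearest f0 — the single-frequency amplitude response used
    for profilometry.
    """
    k = int(np.argmin(np.abs(spectrogram.frequencies - f0)))
    lo = max(k - half_width_bins, 0)
    hi = min(k + half_width_bins + 1, len(spectrogram.frequencies))
    return spectrogram.coefficients[lo:hi].mean(axis=0)


def detect_surface(compensated: np.ndarray, depth_axis: np.ndarray,
                   min_contrast: float = 0.2,
                   method: str = "half-level") -> SurfaceResult:
    """Locate the specimen surface on the compensated amplitude roll-off.

    ``method`` is ``"half-level"`` (crossing of (1 + C'_min)/2,
    default) or ``"centroid"`` (centroid of the negative derivative of
    C').  When several descending crossings exist the first after the
    global maximum is taken and the quality is down-weighted.
    """
    c = np.asarray(compensated, dtype=float)
    z = np.asarray(depth_axis, dtype=float)
    ok = np.isfinite(c)
    if not ok.any():
        return SurfaceResult(z_p=np.nan, crossing_quality=0.0, found=False)
    idx = np.flatnonzero(ok)
    c = c[idx]
    z = z[idx]
    cmin = float(np.min(c))
    contrast = float(np.clip(1.0 - cmin, 0.0, 1.0))
    if contrast < min_contrast:
        return SurfaceResult(z_p=np.nan, crossing_quality=contrast, found=False)
    level = 0.5 * (1.0 + cmin)
    start = int(np.argmax(c))
    below = c[start:] < level
    crossings = np.flatnonzero(~below[:-1] & below[1:])
    if method == "centroid":
        dc = -np.diff(c[start:])
        dc = np.clip(dc, 0.0, None)
        if dc.sum() <= 0:
            return SurfaceResult(z_p=np.nan, crossing_quality=0.0, found=False)
        zmid = 0.5 * (z[start:-1] + z[start + 1:])
        z_p = float((zmid * dc).sum() / dc.sum())
        quality = contrast
    elif method == "half-level":
        if len(crossings) == 0:
            return SurfaceResult(z_p=np.nan, crossing_quality=contrast,
                                 found=False)
        i = start + crossings[0]
        # linear interpolation between bracketing samples
        frac = (c[i] - level) / (c[i] - c[i + 1])
        z_p = float(z[i] + frac * (z[i + 1] - z[i]))
        quality = contrast
    else:
        raise ValueError(f"unknown method {method!r}")
    if len(crossings) > 1:
        quality *= 0.5
    return SurfaceResult(z_p=z_p, crossing_quality=float(np.clip(quality, 0, 1)),
                         found=True)


def height_map(surfaces, tip_height: float) -> np.ndarray:
    """Specimen height per pixel: tip_height - z_p; NaN where not found.

    ``surfaces`` is a 2D nested sequence of :class:`SurfaceResult` on a
    complete lateral grid.
    """
    rows = list(surfaces)
    out = np.full((len(rows), len(rows[0])), np.nan)
    for ix, col in enumerate(rows):
        for iy, s in enumerate(col):
            if s.found:
                out[ix, iy] = tip_height - s.z_p
    return out
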