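"""Whole-trace processing: detrending, FFT peak frequency, attenuation.

A raw time-of-flight trace carries the Brillouin oscillation on top of
a coincidence peak and a slow thermal background.  The background is
removed by polynomial fit subtraction after dropping an initial
coincidence-exclusion window; the depth-averaged Brillouin frequency is
the in-band peak of the FFT magnitude spectrum, refined below the 1/T
grid by three-point parabolic interpolation on the log magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.fft as sfft
from numpy.polynomial import Polynomial
from scipy.signal import hilbert

from .core import GHZ, PS, AcousticMedium
from .phantom import ToFTrace

__all__ = ["DetrendSpec", "remove_background", "fft_brillouin_shift",
           "weighted_average_shift", "estimate_attenuation"]

DEFAULT_BAND = (3 * GHZ, 8 * GHZ)


@dataclass(frozen=True)
class DetrendSpec:
    """Polynomial background subtraction parameters.

    ``coincidence_exclusion`` drops the initial window dominated by the
    electronic coincidence peak before fitting a least-squares
    polynomial of ``poly_order`` to the remainder.
    """

    poly_order: int = 5
    coincidence_exclusion: float = 50 * PS

    def __post_init__(self) -> None:
        if self.poly_order < 1:
            raise ValueError("poly_order must be >= 1")
        if self.coincidence_exclusion < 0:
            raise ValueError("coincidence_exclusion must be non-negative")


def remove_background(trace: ToFTrace, spec: DetrendSpec | None = None) -> ToFTrace:
    """Drop the coincidence window and subtract a polynomial background."""
    spec = spec or DetrendSpec()
    keep = trace.time >= spec.coincidence_exclusion
    if keep.sum() <= spec.poly_order + 1:
        raise ValueError("coincidence_exclusion leaves too few samples")
    t = trace.time[keep]
    y = trace.amplitude[keep]
    fit = Polynomial.fit(t, y, deg=spec.poly_order)
    return replace(trace, time=t, amplitude=y - fit(t))


def fft_brillouin_shift(trace: ToFTrace,
                        search_band: tuple[float, float] = DEFAULT_BAND) -> float:
    """In-band FFT magnitude peak, parabolic-refined below the 1/T grid.

    Equal-magnitude peaks resolve to the lower frequency (first argmax).
    """
    lo, hi = search_band
    dt = trace.sampling_period
    nyquist = 0.5 / dt
    if not (0 <= lo < hi <= nyquist):
        raise ValueError("search_band must be a non-empty interval within Nyquist")
    n = len(trace.amplitude)
    nfft = sfft.next_fast_len(4 * n)   # mild zero padding smooths the grid
    spec = np.abs(sfft.rfft(trace.amplitude, nfft))
    freqs = sfft.rfftfreq(nfft, dt)
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ValueError("search_band contains no FFT bins")
    idx = np.flatnonzero(band)
    k = idx[np.argmax(spec[idx])]
    # three-point parabolic interpolation on log magnitude
    if 0 < k < len(spec) - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        y0, y1, y2 = np.log(spec[k - 1:k + 2])
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            return float(freqs[k] + delta * (freqs[1] - freqs[0]))
    return float(freqs[k])


def weighted_average_shift(spectrogram) -> float:
    """Coefficient-magnitude-weighted mean frequency of a spectrogram.

    Used for approach curves: the weighted-average Brillouin shift of
    the whole trace departs from the control-medium baseline when the
    specimen enters the depth measurement range.
    """
    coeff = np.asarray(spectrogram.coefficients, dtype=float)
    valid = getattr(spectrogram, "valid", None)
    if valid is not None:
        coeff = coeff[:, valid]
    total = coeff.sum()
    if coeff.size == 0 or total <= 0:
        raise ValueError("spectrogram has no non-zero coefficients")
    return float((spectrogram.frequencies @ coeff.sum(axis=1)) / total)


def estimate_attenuation(reference_traces, control: AcousticMedium,
                         edge_fraction: float = 0.1) -> float:
    """Phonon amplitude attenuation from control-medium traces.

    The analytic-signal envelope of each detrended trace follows
    ``exp(-alpha v t)`` in a homogeneous medium; envelopes are averaged
    over traces and alpha is the negated slope of a log-linear least
    squares fit divided by the control sound velocity.  The first and
    last ``edge_fraction`` of samples are excluded from the fit to
    avoid Hilbert edge artefacts.  A non-decaying envelope yields a
    warning and alpha = 0.
    """
    traces = list(reference_traces)
    if not traces:
        raise ValueError("need at least one reference trace")
    t = traces[0].time
    env = np.mean([np.abs(hilbert(tr.amplitude)) for tr in traces], axis=0)
    n = len(t)
    margin = max(int(edge_fraction * n), 1)
    sl = slice(margin, n - margin)
    slope, _ = np.polyfit(t[sl], np.log(np.maximum(env[sl], 1e-300)), 1)
    if slope >= 0:
        warnings.warn("envelope does not decay; returning alpha = 0",
                      stacklevel=2)
        return 0.0
    return float(-slope / control.sound_velocity)
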