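"""Shared fixtures: media, fast optics, and amortised reference profiles."""

import numpy as np
import pytest

import pemscope as pem
from pemscope.core import GHZ, MHZ, NM, NS, PS, UM


def gabor_ridge_oracle(x, dt, grid, f_b, cols):
    """Brute-force short-time Fourier ridge with a matched Gaussian window.

    Direct time-domain summation at the requested columns — an oracle
    independent of the FFT-based transform path.  Returns the refined
    peak frequency per column (same parabolic-vertex rule on the log
    magnitude).
    """
    sigma = np.sqrt(f_b / 2.0)
    support = int(np.ceil(4 * sigma / dt))
    k = np.arange(-support, support + 1)
    win = np.exp(-(k * dt) ** 2 / f_b)
    osc = np.exp(-2j * np.pi * np.outer(grid, k * dt))
    step = grid[1] - grid[0]
    out = np.full(len(cols), np.nan)
    for i, c in enumerate(cols):
        if c - support < 0 or c + support >= len(x):
            continue
        mags = np.abs(osc @ (x[c + k] * win))
        j = int(np.argmax(mags))
        f = grid[j]
        if 0 < j < len(grid) - 1:
            y0, y1, y2 = np.log(mags[j - 1:j + 2])
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                f += float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)) * step
        out[i] = f
    return out


@pytest.fixture(scope="session")
def fast_optics():
    """Short sweep used by unit tests to keep transforms cheap."""
    return pem.OpticalConfig(sweep_span=6 * NS)


@pytest.fixture(scope="session")
def quiet_cfg(fast_optics):
    return pem.SimulationConfig(optics=fast_optics, noise_sigma=0.0)


@pytest.fixture(scope="session")
def coarse_grid():
    """10 MHz analysis grid over the water/tissue band."""
    return pem.default_frequency_grid(4 * GHZ, 6.5 * GHZ, 10 * MHZ)


@pytest.fixture(scope="session")
def cell_options(coarse_grid):
    return pem.AnalysisOptions(window_fwhm_z=1.28 * UM,
                               frequency_grid=coarse_grid)


@pytest.fixture(scope="session")
def cuticle_options(coarse_grid):
    return pem.AnalysisOptions(window_fwhm_z=520 * NM,
                               frequency_grid=coarse_grid)


@pytest.fixture(scope="session")
def quiet_reference_cell(quiet_cfg, cell_options):
    refs = pem.simulate_reference_traces(pem.PBS, quiet_cfg, count=2)
    return pem.reference_profile(refs, pem.PBS, cell_options)


@pytest.fixture(scope="session")
def quiet_reference_cuticle(quiet_cfg, cuticle_options):
    refs = pem.simulate_reference_traces(pem.PBS, quiet_cfg, count=2)
    return pem.reference_profile(refs, pem.PBS, cuticle_options)
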