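"""Depth-resolved shifts of a nematode-cuticle phantom.

Simulates a layered cuticle (cortical / medial / basal / hypodermis)
behind a 1 um stand-off, analyses it with a 520 nm z-sectioning window
against a control-medium reference, and reads the relative shift at
each layer centre.  Gaussian fits of the cortical and basal peaks give
their apparent thicknesses.
"""

import numpy as np

import pemscope as pem
from pemscope.core import MHZ, NM, UM
from pemscope.imaging import fit_layers

options = pem.AnalysisOptions(window_fwhm_z=520 * NM)
noise = pem.SimulationConfig(noise_sigma=0.05, seed=1)

refs = pem.simulate_reference_traces(
    pem.PBS, pem.SimulationConfig(noise_sigma=0.05, seed=99), count=25)
reference = pem.reference_profile(refs, pem.PBS, options)

stack = pem.build_cuticle_phantom()
trace = pem.simulate_trace(stack, pem.PBS, noise)
profile, _ = pem.analyze_trace(trace, reference, pem.PBS, options)

v = pem.PBS.sound_velocity
tb = trace.truth.boundaries_t
centres = 0.5 * (np.concatenate([[0.0], tb[:-1]]) + tb)
names = ["stand-off (PBS)", "cortical", "medial", "basal", "hypodermis"]
configured = [0, 300, 60, 300, -200]
print("layer            configured   measured (1 seed)")
for name, tc, c in zip(names, centres, configured):
    i = int(np.argmin(np.abs(profile.z - v * tc)))
    print(f"{name:16s} {c:+5d} MHz   {profile.delta_f[i] / MHZ:+7.1f} MHz")
print("  -> thin layers read below their configured contrast: the ridge is")
print("     the true profile smoothed by the ~260 nm resolution kernel")

z_basal = v * 0.5 * (tb[2] + tb[3])
sel = np.isfinite(profile.delta_f) & (profile.z > v * tb[0] - 0.3 * UM)
z, y = profile.z[sel], profile.delta_f[sel]
past = np.flatnonzero((z > z_basal) & (y <= 0.0))
if len(past):
    z, y = z[:past[0]], y[:past[0]]
for fit in fit_layers(z, y, expected_peaks=2):
    print(f"Gaussian layer at z = {fit.centre / UM:.2f} um: "
          f"FWHM {fit.fwhm / NM:.0f} nm, amplitude "
          f"{fit.amplitude / MHZ:+.0f} MHz")
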