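# Methods

## Signal model

A time-of-flight (ToF) trace is modelled as the sum of the three
components a pump-probe reflectivity measurement produces:

1. a **coincidence peak** at zero delay — modelled as a narrow Gaussian
   (amplitude 20, width 10 ps by default; the component is electronic
   and its exact shape is immaterial, it is excluded from analysis);
2. a **thermal background** — a single exponential (amplitude 5, decay
   5 ns by default);
3. the **Brillouin oscillation** of the phonon wavefront,

   `B(t) = s(z(t)) · exp(−∫ α dz) · cos(φ(t))`,

   with wavefront depth `dz/dt = v(z)`, phase accumulating at the local
   Brillouin frequency `dφ/dt = 2π f_B(z)`, per-medium photoelastic
   scatter strength `s` and amplitude attenuation `α`.

Velocities are piecewise constant in depth, so `z(t)`, `φ(t)` and the
attenuation integral are evaluated **in closed form per layer**; traces
are exact on the sampling grid (refining the grid changes nothing but
the sample positions, which the test suite verifies).  Phase is
continuous across interfaces: no spurious broadband transients.
Acoustic transmission across interfaces is treated as total — no
partial reflections or echoes — matching the single-wavefront analysis
model; amplitude differences between media enter only through `s`.

Noise is additive white Gaussian on reflectivity (σ = 0.05 of the
unit Brillouin amplitude by default), drawn from per-position
substreams of a single seed: scans are bit-reproducible and pixels are
statistically independent.  Multiplicative laser noise, detector 1/f
noise and timing jitter are not modelled; conclusions about absolute
precision therefore transfer to real data only in order of magnitude.

Default time base: 3 ps sampling over 0–12.5 ns (the inverse of an
80 MHz repetition rate); probe wavelength 830 nm; analysis truncated to
a 6 µm depth measurement range.

## Depth-resolved analysis

The pipeline is: polynomial background subtraction (order 5, first
50 ps excluded) → truncation to the depth range (plus a guard band,
below) → complex-Morlet transform on a frequency grid (3–8 GHz in
5 MHz steps by default) → ridge extraction → depth mapping `z = v_med t`
with the control-medium velocity → subtraction of a reference profile
`f_B⁰(z)` averaged from control-only acquisitions (100 by default; the
mean, not the median).  Reference subtraction centres control regions
on zero and cancels slow thermo-optic drift along with any systematic
ridge bias shared by measurement and reference.

### Window convention

The z-sectioning window `z_win` (520 nm for sub-micron layer work,
1.28 µm for cells) is the *overall* wavelet width in depth units.  The
Gaussian amplitude envelope of the wavelet is assigned a depth FWHM of
`z_win / 2`, i.e. the bandwidth parameter is

`f_b = (z_win / (2 v_ref))² / (4 ln 2)`.

The reason is a calibration fact about ridge estimation: for a signal
whose instantaneous frequency varies slowly relative to the wavelet
bandwidth, the ridge equals the true `f_B(z)` **smoothed by a Gaussian
whose FWHM is the envelope FWHM** (a weighted-least-squares argument
on the accumulated phase; verified numerically in the tests).  Setting
the envelope FWHM to `z_win / 2` makes the effective resolution kernel
equal the nominal axial resolution `z_win / 2` — with the envelope
FWHM set to `z_win` instead, a 320 nm layer would read under half its
contrast and adjacent sub-micron layers would not resolve at all,
contradicting the resolutions the method is specified to reach.  The
`N_λ` route (`z_win = N_λ · λ_acoustic`) is provided as an equivalent
constructor.

Consequence worth stating plainly: a layer whose thickness is
comparable to the kernel cannot read 100% of its contrast at its
centre.  With the 520 nm window (260 nm kernel), 320 nm layers read
~85% of their configured shift and a 400 nm strut ~96%; layers several
times thicker than the kernel (e.g. the 1.5 µm hypodermis) read their
full contrast.  This is physics of windowed frequency estimation, not
an estimator defect; thickness estimates recover the configured scale
because the flanking layers clip the apparent peak width back.

### Numerical choices

- **Ridge refinement.**  The per-depth column of coefficient
  magnitudes for a ~1.6-period wavelet is extremely broad (GHz) and
  flat near its maximum (curvature ~10⁻⁵ across a 5 MHz grid step), so
  a bare 3-point parabolic interpolation amplifies spectral ripple
  into tens of MHz of jitter.  The ridge is instead the vertex of a
  quadratic fit of the log magnitude over the contiguous run of bins
  above 70% of the column maximum, symmetrised about the argmax (the
  log magnitude of a Gaussian band is exactly quadratic, so the fit is
  unbiased and averages the ripple).  Runs too short for a fit fall
  back to the 3-point parabola with the correction clipped to half a
  bin.  Ties break toward the lower frequency; all-zero columns are
  marked missing.
- **Signal conditioning.**  Before the transform the detrended trace
  is tapered (raised cosine over the half-window margins, which are
  flagged invalid anyway) and high-passed with a smooth edge below the
  analysis band.  Both target the same failure mode: the wavelet's
  broad response reaches trace-edge leakage and sub-band detrending
  residue, which tilt the flat column maxima.  Interior ridge error on
  noise-free homogeneous traces is ~1–2 MHz after conditioning.
- **Edges.**  Half-window margins at both trace ends are flagged
  invalid rather than zero-padded.  The analysis additionally keeps a
  1.5 µm depth guard beyond the 6 µm cap so end-of-trace artefacts fall
  outside the valid region.  The first ~1 µm after the coincidence
  exclusion retains a ~15 MHz systematic from the onset edge; it is
  common to measurement and reference and cancels in `Δf_B`.
- **Depth mapping** uses the control-medium velocity throughout
  (`z = v_med t`); `time_to_depth` also accepts a velocity profile
  (left-Riemann cumulative integral) as an explicit two-pass
  extension.

## Profilometry

The amplitude channel is the coefficient magnitude at the grid
frequency nearest `f_B⁰`, averaged over ±1 grid step.  It is
compensated by the control-medium decay `exp(α_med v_med t)` (α fitted
beforehand from the analytic-signal envelope of control traces,
log-linear least squares) and normalised factor-wise by the respective
maxima.  The surface is the first descending crossing of the half
level `(1 + Ĉ'_min)/2`, linearly interpolated; a
centroid-of-derivative estimator is available behind a flag.  A total
contrast below 0.2 means "no specimen in range".  Note the contrast is
set by the wavelet's frequency response at the specimen's shift: a
polystyrene dish (shift ≫ band) gives near-full roll-off at any
window, while soft tissue (+0.9 GHz) only produces a detectable
roll-off with windows ≳1 µm.  On noise-free step phantoms the
half-level estimator locates surfaces to ~30 nm, far inside the
half-acoustic-wavelength (156 nm) figure of merit.

## Phantoms

- **Control / step** — a semi-infinite specimen behind a control gap.
- **Cell on dish** — a raised-cosine dome of tissue-like material
  (height 3 µm by default) in PBS; stand-off per pixel is the
  tip-to-dish distance minus the local height; outside the footprint
  the pixel is pure control medium.
- **Cuticle** — cortical (320 nm, +300 MHz), medial (400 nm, +60 MHz),
  basal (320 nm, +300 MHz), hypodermis (1.5 µm, −200 MHz, continued by
  the backing), behind a 1 µm stand-off; the strut variant replaces
  the medial layer with +600 MHz material.  Layer velocities invert
  the Brillouin relation at the tissue refractive index (n = 1.38,
  ρ = 1200 kg/m³) around the PBS baseline (n = 1.33, v = 1497 m/s —
  the literature sound velocity of room-temperature saline; the
  baseline frequency is configurable since saline velocities vary with
  temperature).

What passing the phantom tests shows — and does not.  The phantoms
exercise frequency stepping, attenuation, noise and lateral structure,
so recovery tests validate the estimator chain end to end.  They do not
emulate refractive-index heterogeneity, curved interfaces, acoustic
echoes, speckle or organism motion; quantitative transfer to real
specimens rests on the physics shared with the model, not on these
tests.

## Problem sizes

The test suite and the acceptance script scale ensemble sizes to keep
runs quick while leaving comfortable statistical headroom: layer-shift
recovery uses 20 seeds (script: 12) with a 25-trace noisy reference,
thickness fits 8–10 seeds, precision-versus-depth 50 seeds, and unit
tests use a 6 ns sweep and a 10 MHz analysis grid where full defaults
are not needed.  All are package choices, configurable at call sites.

## Known limitations

- Thin-layer plateau bias (above): contrast recovery for layers at the
  kernel scale is ~80–90%, so absolute `Δf_B` of sub-window layers is
  systematically low even at zero noise.
- No acoustic impedance mismatch: interfaces transmit totally, so
  echo artefacts present in strongly mismatched real specimens are
  absent.
- The stiffness percentage is a sound-velocity proxy
  (`100 · Δf / f_B⁰`), valid when refractive index and density are
  taken constant; the modulus route is available separately.
- Temperature enters only through reference compensation; no explicit
  thermo-acoustic material model.
- Surface detection needs a medium-band roll-off; specimens whose
  shift falls inside the wavelet passband at the chosen window (soft
  tissue with sub-micron windows) can be invisible to profilometry
  while remaining visible in `Δf_B`.
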