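# Methods

## Optical model

The sensor is a low-finesse Fabry–Perot cavity: a cleaved single-mode fiber
end face (reflectivity `R1`, default 0.04) and a mirrored quartz reflector
(`R2`, default 0.99) separated by an air gap of physical length `d`. Only
the two first-surface reflections are modeled; the normalized reflected
intensity is the two-beam form

    Ir/Ii = (R1 + q²R2 − 2q√(R1R2)·cos δ) / (1 + q²R1R2 − 2q√(R1R2)·cos δ),
    δ = 4πnd/λ + φ0,

with light-coupling coefficient `q` (default 1), cavity refractive index
`n` (default 1, air) and additional phase `φ0` (default 0). Multi-beam
(Airy) effects, polarization and dispersion are out of scope. With these
defaults, maxima of `Ir/Ii` sit exactly where `δ` is an odd multiple of π,
i.e. at wavelengths `λ = 4nd/m` for odd integers `m`; the free spectral
range near λ is `FSR ≈ λ²/(2nd)`.

Temperature enters through the thermal-expansion mismatch of the mounting:
over a gauge length `l` the expander body (CTE `α1`) elongates while the
fiber (CTE `α2`) occupies `l − d` of the gauge, so

    Δd/ΔT = l·α1 − (l − d)·α2.

With `l = 6 mm`, `α1 = 15×10⁻⁶/°C`, `α2 = 5.5×10⁻⁷/°C`, `d = 0.3 mm` this
is 0.087 μm/°C — small enough that temperature is negligible for μm-scale
displacement monitoring. `apply_temperature` linearizes drift around the
initial cavity length (the sensitivity's `d`-dependence changes the result
by < 1% over tens of μm of travel, far below other error sources); an
empirically fitted sensitivity can be supplied instead of the model value.

## Demodulation

The absolute cavity length is recovered from interference-maximum
wavelengths only (the peak-wavelength method; phase-tracking and
FFT/OPD-domain methods are deliberately excluded). Counting peaks from the
shortest wavelength (`λ1`, the highest interference order — the orientation
is forced by the algebra), order `k` of the first peak follows from any
pair (λ1, λi):

    k = [(2i−3)·λi + λ1] / [2·(λi − λ1)],

which must land near an integer; the residual distance from the nearest
integer is reported, and values beyond `residual_tolerance` (default 0.3)
raise an ambiguity error rather than silently mis-assigning the order. The
cavity length is then `d = (2k+1)·λ1/(4n)`.

Peak detection runs `scipy.signal.find_peaks` on a Savitzky–Golay-smoothed
copy of the frame (window ≈ 1/10 of the dominant fringe period, estimated
by FFT) with a prominence threshold expressed as a fraction of the fringe
amplitude (default 0.25). Two refinements handle the span boundaries:

- A fringe whose crest lies within about half an FSR of the boundary loses
  most of its outer descent and fails the prominence test even though it is
  a genuine resonance. The detector extrapolates one local FSR beyond the
  outermost confident peak and accepts an interior local maximum there,
  provided a full fringe valley separates it from its neighbor (rejecting
  noise bumps riding on a flank). This restores exact agreement between the
  detected count and the closed-form count of odd resonance orders for all
  cavity lengths in the working range.
- Peaks within half a fringe of the boundary are flagged as edge peaks.
  They are reported, but excluded from demodulation by default: a
  truncated fit can be biased by tens of pm, which is enough to corrupt k.

Sub-sample refinement is noise-adaptive. On clean frames a 3-point
quadratic interpolation around the discrete maximum is used (exact to
≪ 1 pm on the default grid). When the residual noise (raw minus smoothed)
exceeds 1/200 of the fringe amplitude, the 3-point stencil becomes
ill-conditioned and a symmetric least-squares parabola over ±0.38 of a
fringe period (recentered up to three times) is used instead; its vertex
precision is close to the single-fringe Cramér–Rao bound (≈ 8 pm at the
default contrast and 0.001 intensity-noise SD).

`demodulate` defaults to the first/last-peak pair (the interrogator
convention). The opt-in `consensus` mode votes k over every (λ1, λj) pair —
judging ambiguity on the widest pair, since close pairs are intrinsically
noisy in k — and then averages the per-peak cavity lengths implied by the
resolved orders, which suppresses independent per-peak wavelength noise by
roughly √(number of peaks).

`track` demodulates a time-ordered frame sequence; frames that fail are
carried as flagged gaps, never interpolated. An optional continuity check
(default threshold 200 μm when enabled) flags half-FSR-scale order slips
while letting genuine ~0.13 mm activation steps pass; it is advisory only,
because steps are signal.

## Expansion analysis

Cavity-length series are segmented into plateaus: a new plateau opens when
a sample departs from the running plateau median by more than `min_step_um`
(default 20 μm) and the departure persists for a second sample (a lone
excursion is treated as an outlier). Step sizes are differences of plateau
medians restricted to a 30 s window on either side of the step — the median
is robust to loading transients, and the window bounds the influence of
slow drift. Baseline resolution is the sample SD over a user-chosen window
that must lie inside a single plateau (≥ 10 unflagged samples).

The opening angle uses a rigid-wedge, left–right-symmetric, small-angle
model: `θ = (Δ_anterior − Δ_posterior)/s` with `s` the anteroposterior
sensor separation (default 900 μm), positive θ meaning wider anterior
opening (V-type, apex posterior). No arc-length correction is applied. The
anterior/posterior channel assignment is a required input — it is a
physical mounting fact and is never inferred from the data. Expected
displacements are always computed from geometry (screw pitch, default
0.8 mm/turn, × turn fraction, default 1/6), never hard-coded.

## Synthetic experiments

`simulate_experiment` emulates the bench protocol end to end so the whole
chain is testable without an instrument. Defaults encode the study
conditions: two channels with initial cavity lengths 285 μm (S1, posterior)
and 300 μm (S2, anterior); three activations about one minute apart
(t = 60, 120, 180 s in a 240 s run at 1 Hz); per-activation steps of 130 μm
mean with the first load split 116.5/143.5 μm — the 27 μm asymmetry is
apportioned symmetrically (±13.5 μm) about the mean because the experiment
only constrains the difference; spectra on a 16001-sample grid over
1510–1590 nm (≥ ~75 samples per 3.9 nm fringe, enough for pm-level peak
interpolation).

Steps are instantaneous (the bench shows at-once distance changes with no
settling or degradation). Interrogator wavelength repeatability (2 pm SD)
is realized as a rigid spectral shift per frame — equivalent at peak level
to per-peak jitter and consistent across orders. Additive Gaussian
intensity noise has SD 0.001 in normalized units, a toolkit choice (no
instrument figure exists); at the default contrast this dominates per-peak
wavelength noise. An optional piecewise-linear temperature profile adds
mismatch-model drift. A fixed seed yields bit-identical datasets.

What the generator does **not** emulate: mechanical compliance of the bone
model and suture, loading transients, epoxy-bond creep, source-spectrum
shape, interrogator-specific peak fitting, or the μm-scale environmental
disturbances that dominated the bench baseline (±2.5 μm SD) and loading
windows (±9.6 μm). Passing round-trip tests therefore demonstrates the
correctness and noise floor of the demodulation chain, not field accuracy;
the bench figures are environmental observations, not reproducible targets.
For the same reason the simulated summary's average-vs-expected error is a
construction artifact (configured 130 μm steps versus the exact 133.3 μm
screw expectation), not a reproduction of the bench error statistics.

`simulate_translation_stage` reproduces the displacement calibration:
equal cavity-length increments (default scenario: five 0.2 mm steps from
300 μm) whose measured-vs-configured fit should have unit slope — the
noiseless round trip achieves |slope − 1| < 10⁻³ and intercept < 0.1 μm.

## Numerical choices and degenerate inputs

- Units at module interfaces: wavelengths nm, cavity length μm, gauge
  length mm, time s, CTE per °C; conversions are internal and tested.
- Demodulable range on the default grid: ~40–2000 μm (below, fewer than two
  fringes fit the span; above, fringes are under-sampled). Coarse grids
  trigger a resolvability warning (< 20 samples per fringe), or an error
  when configured strictly.
- Fringe-order rounding: nearest integer; residual tolerance 0.3.
- Sub-wavelength cavities produce a single broad fringe and correctly
  raise an insufficient-fringes error in demodulation.
- Flat spectra (`R2 = 0`) raise insufficient-fringes; a corrupted frame in
  a sequence becomes one flagged gap without affecting neighbors.
- Time series require strictly increasing timestamps; gaps carry NaN
  length and order −1 and are excluded from all statistics.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
data at the protocol's native scale: 240-frame two-channel experiments,
100-frame jitter runs, 18-frame stage calibrations, and 16001-sample
spectra throughout — a few thousand spectrum evaluations in total.

## Known limitations

- The two-beam model slightly mis-shapes fringes of very high-finesse
  cavities; at R1 = 0.04 the approximation error is far below the noise.
- Eq-level thermal drift is linearized at the initial cavity length.
- Step detection assumes plateaus long enough for a 30 s median window at
  1 Hz; much faster protocols need smaller windows.
- The consensus mode assumes all detected peaks belong to one cavity;
  multiplexed sensors on one channel are not supported.
- The 285/300 μm initial distances and the 3.9/3.85 nm FSR figures from
  the bench are not mutually consistent to the μm level; the toolkit makes
  no attempt to reconcile them and validates by round-trip simulation
  instead.
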