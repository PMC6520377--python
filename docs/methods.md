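# Methods

`slicephys` quantifies structure and function of living myocardial slices —
~300-µm-thick sections of ventricular myocardium cultured under
electromechanical stimulation at a defined preload. This note documents the
models and procedures behind each module, the defaults and why they were
chosen, what the synthetic-data generators do and do not emulate, and the
numerical choices that affect results.

## Sarcomere length from laser diffraction

The sarcomere lattice acts as a diffraction grating: a laser of wavelength λ
(default 633 nm, helium–neon) produces a first-order band at angle θ with
SL·sin θ = m·λ. With the pattern projected onto a grid a distance L (default
20.5 cm) below the slice, the zero-to-first-order band distance x obeys
x = L·tan θ, giving SL = m·λ / sin(arctan(x/L)). The projection originates at
the slice surface, so the laser-to-slice offset above the tissue does not
enter the formula. Measuring bands from raw camera frames is out of scope —
band distances are inputs.

The forward projection is monotone decreasing in SL, and the inverse is exact
(round-trip relative error < 1e-9 over the physiological range, tested). No
band exists at SL ≤ m·λ; both directions raise there.

**Percent stretch** is engineering strain × 100,
`100·(post_distance − resting_length)/resting_length`, with compression
rejected. The stretch required for a target SL comes from an ordinary
least-squares line of percent stretch on SL (`fit_stretch_calibration`),
because diffraction cannot resolve SL below ~2.0 µm and short-SL preloads
must be extrapolated. Rounding to integer percent happens only at the
reporting layer.

## MEA conduction mapping

Recordings come from a rectangular electrode grid; the standard array is
8 × 8 with 700 µm pitch and the four corners absent (60 channels, 4.9 mm side
span), sampled at 50 kHz. Coordinates: x along columns, y along rows, origin
at the top-left electrode, 0-based row-major channel ids over the positions
present.

*Local activation time* is the time of maximum absolute signal in a window
after the stimulus (`max_amplitude`; `max_downstroke` — steepest negative
deflection — is available as an option). Two gates reject unreliable
detections: an SNR gate (peak ≥ 5× the robust pre-stimulus noise, MAD-based)
and a boundary gate (an extremum on the first or last sample of the window is
a truncated deflection, not a peak). Ties resolve to the earlier sample. Maps
average over all stimuli and flag the stimulation electrode; a map with fewer
than 25% of electrodes detected raises.

A configurable post-stimulus blanking interval (default 2 ms) skips the
stimulus artifact on real recordings. Synthetic recordings carry no artifact,
so analyses of generated data use `blanking_ms=0`; with blanking enabled,
electrodes whose spike falls inside the blanked interval are flagged missing
by the boundary gate rather than mistimed.

*Conduction velocity* along an axis (longitudinal or transverse to the fiber
direction) is the inverse slope of an ordinary least-squares fit of
activation time against distance along the axis, restricted to electrodes in
a narrow angular sector about the axis **ray** from the stimulation site.
The sector half-width defaults to 8°: for a point-source elliptical wavefront
with velocities (v_L, v_T), an electrode at angle θ off the fast axis
activates late by a factor √(1 + tan²θ·(v_L/v_T)²), so wide sectors bias the
slope substantially (tens of percent at 30° half-width on the standard grid
at v_L/v_T = 3); 8° admits only near-collinear electrodes on the standard
grid and recovers the axis velocity to well under 2% noise-free (tested over
10–100 cm/s, and within 5% at SNR 10). A non-positive fitted slope (apparent
retrograde propagation / failed capture) raises, as does a sector with fewer
than 4 detected electrodes. Anisotropy is the ratio CV_L:CV_T.

Velocity-vector-field and curved-wavefront methods, repolarisation analysis
and vendor binary formats are out of scope.

## Transient feature extraction

Paced force or Ca²⁺ traces are cut into one window per stimulus (last window
one pacing interval long). Per beat:

- baseline: median of the 20 ms before the stimulus (configurable);
- amplitude: peak minus baseline, gated at 3× the robust baseline noise;
- time to peak: from the stimulus;
- t50 / t90 decay: first crossings, linearly interpolated between samples,
  of 50% and 10% of the amplitude after the peak (t90 = 90% decayed — the
  convention is stated explicitly because names alone are ambiguous);
- maximum rise and decay rates: extrema of a Savitzky–Golay first derivative
  (quadratic, 5 ms window by default); decay rate is reported as a positive
  magnitude. Peak-derivative was chosen over amplitude/time quotients for the
  "rate of rise/decay"; the quotient can be formed from the other features if
  needed.

Feature times are invariant to gain and offset; amplitude and rates scale
with gain (tested).

*Contractility* is peak isometric force normalised to cross-sectional area
(width × nominal 300 µm thickness, mN/mm²) by default, with force-per-width
(mN/mm) as a labelled alternative since both normalisations are in common
use. `max_contractility` takes the maximum over a stepwise stretch protocol
(Frank–Starling apex).

## Isoproterenol dose escalation

The standard series is 1×10⁻⁹ to 3×10⁻⁶ M in half-log increments, using the
1–3 labelling convention (3×10⁻ⁿ for the half-log step, not 10^(n−0.5)), i.e.
8 levels. Two readouts per concentration:

- **Aftercontractions**: diastolic local maxima between 90%-relaxation of the
  paced beat and the next stimulus, with prominence ≥ 10% of the median paced
  amplitude, reported as events/min. Both thresholds are relative, so the
  count is gain-invariant. The numeric criteria (10%, 90%) are package
  defaults; the laboratory procedure states none.
- **Sustained tachyarrhythmia**: after stimulation stops, spontaneous events
  faster than 1.5× the pacing rate continuously for ≥ 10 s. Both values are
  defaults standing in for a qualitative criterion ("sustained when
  stimulation was stopped").

The first concentration showing sustained tachyarrhythmia is the threshold,
mapped to a linear arrhythmogenicity score: tachyarrhythmia at or before zero
drug ("pre-drug") scores 9, thresholds 1e-9 → 8 down to 3e-6 → 1, and no
tachyarrhythmia scores 0. The zero-concentration row of the published scale
is interpreted as the pre-drug state, preserving the 10-level linear scale.

**EC₅₀** comes from a four-parameter logistic on log₁₀ concentration fitted by
least squares, initialised from the response range and the first mid-range
crossing. The fit accepts any response column (which contractile parameter
fed the published curves is not stated). Flat responses, fewer than five
levels, and non-convergence raise.

## Image metrics

All metrics act on 2-D single-channel arrays with a known pixel size
(maximum-project z-stacks first). Default automatic threshold is Otsu's
criterion; a constant image under an automatic threshold raises, and all
thresholds used are part of the outputs.

- `percent_positive_area`: 100 × pixels above threshold / pixels considered
  (viability via calcein, Cx43 or vimentin stained area, etc.).
- `ttubule_density`: positive fraction inside the cell after eroding the mask
  by 1 µm (default) to exclude surface sarcolemma.
- `ttubule_regularity`: masked intensity averaged across the cell width onto
  a profile along the long axis; linear detrend; Hann window; FFT. The result
  is the period of the largest spectral peak in the 1.6–2.4 µm band (which
  brackets the physiological sarcomere range studied) and the peak's power —
  integrated over the window mainlobe, peak bin ± 2 — as a fraction of total
  non-DC power. The metric lies in [0, 1] and reaches ~1 for a pure in-band
  sinusoid regardless of how the period aligns with the profile length
  (windowing confines leakage to the mainlobe). The published "power of the
  regularity" algorithm is not described; this FFT formulation is a standard
  surrogate and its absolute values are comparative only. Caveat: for hard-
  thresholded (square-wave-like) striations, mild disarray suppresses
  harmonics faster than the fundamental and can transiently *raise* the
  normalised peak share; the monotone jitter-sensitivity property is
  guaranteed only for near-sinusoidal profiles.
- `cell_morphometrics`: per labelled region, area (pixel count × pixel size²)
  and the major/minor axis ratio of the moment-equivalent ellipse; regions
  under 10 px are excluded and reported. Ratio is rotation-invariant within
  5% (tested).
- `heterogeneity_index`: coefficient of variation of percent-positive area
  over non-overlapping square tiles (default 20 µm side) under one global
  threshold. Cx43 lateralisation is excluded (no published definition).

Cell segmentation itself is out of scope; masks are inputs.

## Statistics and reporting

Condition tables are long-format (condition, slice, feature, value). Groups
are compared by one-way ANOVA; the post-hoc procedure is Holm-adjusted
pairwise Welch t-tests (the laboratory analysis names only the ANOVA; Holm is
a conservative, assumption-light default and is declared in the output
metadata). Significance tiers at p < 0.05/0.01/0.001 mirror figure-legend
markers. Summaries report mean ± sd/√n. Identical-valued groups yield a
flagged p = 1 rather than an exception. Observations are analysed at the unit
declared in the input table; repeated regions per slice are not modelled
hierarchically, so pseudo-replication is the caller's responsibility.

`run_pipeline` executes the stages named by a YAML config (traces, MEA,
images, contractility) and writes `features.csv`, `summary.csv`,
`comparisons.csv`, `summary.json` and a log; reruns are byte-identical, and a
missing input fails fast with its path.

## Synthetic data

Every generator draws from one `numpy.random.default_rng(seed)` stream, is
bit-reproducible, and returns a `GroundTruth` with all parameters and the
derived quantities the analysis should recover.

- *Diffraction*: forward grating projection plus Gaussian noise on the band
  distance.
- *MEA*: activation delays t_i = √((a_i/v_L)² + (b_i/v_T)²) with electrode
  offsets rotated into the fiber frame (or a plane wave along the fiber
  axis); each spike is a dominant negative Gaussian lobe at t_i plus a
  smaller positive lobe 4σ later, so the biphasic waveform's absolute
  extremum sits exactly at the activation time. White Gaussian noise.
- *Transient trains*: each beat is A·(e^(−t/τ_d) − e^(−t/τ_r)) scaled to peak
  amplitude A. The template's landmarks have closed or one-dimensional
  root-findable forms: time to peak t* = τ_rτ_d/(τ_d−τ_r)·ln(τ_d/τ_r), maximal
  rise rate at onset, maximal decay rate at 2t*, and t50/t90 by bracketing
  root-finding — these are the stored truths. Aftercontractions are scaled
  beats injected into the diastolic interval (placement outside it raises);
  tachyarrhythmia appends spontaneous beats at a fixed rate from an onset
  time to the end of the trace. Truths hold for an isolated beat; at 1 Hz
  pacing with τ_d = 0.2 s a beat's tail is ~0.7% of amplitude at the next
  stimulus, which shifts late-decay landmarks of subsequent beats by more
  than a sample — recovery tests therefore use the first beat, and the
  superposition mirrors real incomplete relaxation.
- *Dose–response*: 4PL with additive noise.
- *Striated images*: stripes along a chosen axis, binary with a set duty
  cycle (positive fraction) or sinusoidal. Striation disarray is modelled as
  independent positional jitter per period cell along the axis (coherent
  across the width) — per-line phase offsets would only rescale the averaged
  profile and leave a normalised spectral metric unchanged. A deterministic
  sub-pixel phase ramp across lines (one pixel total) removes stripe-edge
  quantisation bias in the realised positive fraction. Generation below the
  Nyquist limit raises.
- *Stretch samples*: the calibration line plus Gaussian noise, with five SL
  levels from 2.0–2.4 µm and ~14 slices per level as the default design,
  mirroring the calibration experiment's published group sizes.

Not emulated: optical-mapping movies (transients arrive already extracted),
fluorescence photophysics, motion artifact, stimulus artifacts on MEA
channels, and cell-shaped masks with irregular boundaries. Passing tests
demonstrate that the estimators recover known ground truth under these
idealised conditions; they do not establish robustness to artifacts the
generators omit.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small problems: MEA
recordings of one to three stimuli at 50 kHz (tens of milliseconds of signal
per channel), transient trains of 3–60 beats at 250–2000 Hz sampling,
64 × 256 px images, 50-replicate EC₅₀ simulations and 1000-replicate ANOVA
null simulations. These sizes keep every property statistically decisive
while the whole suite completes in seconds. All randomness is explicitly
seeded; reruns are bit-identical.

## Known limitations

- The CV estimator assumes straight-ray propagation from a point stimulus;
  curved or colliding wavefronts are not modelled.
- Activation detection uses a single extremum per window; fractionated
  or multiphasic field potentials will confuse it.
- The regularity metric's absolute scale depends on the profile extraction
  and windowing; compare values only within one analysis pipeline.
- EC₅₀ fits on 8-point single-replicate curves are sensitive to plateau
  coverage; the bottom/top estimates are poorly constrained when the series
  does not bracket both plateaus.
- The arrhythmogenicity score is ordinal; averaging scores across slices
  (as summary tables do) treats it as interval data.
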