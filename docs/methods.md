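# Methods

`phosim` simulates what a wearer of a thalamic (LGN) visual prosthesis
would see while reading, and scores reading performance the way the
MNREAD test does. This note documents the models, the calibration, the
synthetic-data generators, and the numerical choices, so that results
can be interpreted — and their limits understood — without reading the
source.

## The phosphene model

A prosthesis with electrodes in the lateral geniculate nucleus is
expected to evoke a set of punctate light percepts (phosphenes) whose
positions are fixed in *retinal* coordinates: the pattern rides on the
point of regard. Each phosphene is modeled as a white circular Gaussian
whose one-sigma extent grows linearly with eccentricity ρ (degrees from
the point of regard):

    σ(ρ) = 0.043 ρ + 0.083   [deg]

so a phosphene is ~0.17° across at fixation and ~1° across at 10°
eccentricity. This linear law follows the inverse acuity profile of the
visual field (receptive-field size tracks the magnification factor).

Three device tiers are simulated. Their total phosphene counts and
their counts within 10° of the point of regard are fixed integers,
enforced exactly for every random pattern:

| tier   | total | within 10° | nominal electrode spacing |
|--------|------:|-----------:|--------------------------:|
| high   | 1757  | 381        | 375 µm |
| medium | 1029  | 231        | 475 µm |
| low    | 522   | 124        | 600 µm |

## Pattern generation and density calibration

Phosphene layouts are random but follow a radially symmetric,
center-weighted density d(ρ). Sampling is *stratified*: the central
count is drawn from d restricted to ρ ≤ 10° and the remainder from the
tail on 10° < ρ ≤ 45°, by inverse-CDF sampling of the radial density
with uniform angles. Stratification is what makes the table above exact
per seed; window counts elsewhere hold in expectation.

The central density shape is the two-parameter family

    d(ρ) ∝ (1 + ρ/ρ₀)^(−p)

calibrated by relative least squares against four published counts of
phosphenes in windows centered on the point of regard (218 in 10°×3.5°,
352 in 10°×7°, 223 in 5.7°×5.7°, 45 in 1.7°×1.7°, all for the high
tier), with expectations computed under the stratified construction.
The medium and low tiers share the fitted shape and differ only in
their exact stratum counts.

Two honest caveats, both verifiable from the numbers above:

* **The calibration counts are not exactly representable.** The 10°×7°
  window (corner radius 6.1°) would need ~92% of the central mass while
  the tiny 1.7° window holds ~12%; no monotone radial profile satisfies
  both together with the central/total split. The fit lands within
  ±15% of every window count (−15% on the 10°×7° window, the binding
  constraint; single digits elsewhere). The real device map is
  presumably anisotropic; radial symmetry is the modeling choice here.
* **The density steps at the 10° stratum boundary.** Because the
  central shape that fits the windows is strongly center-weighted, and
  the outer field must still hold ~78% of the phosphenes, density
  cannot decrease monotonically across the boundary. The outer stratum
  therefore uses its own smooth inverse-square-like tail,
  d(ρ) ∝ (1+ρ)^(−2), which spreads the peripheral phosphenes the way
  retinotopic cell density falls off rather than piling them against
  the boundary. Monotonicity holds within each stratum.

The fitter reports per-constraint residuals and flags any residual
above 25%. The field extent ρ_max defaults to 45°.

A derived summary statistic, **perceptual efficiency**, counts the
phosphenes inside a circle whose diameter is five times the MAR at a
measured acuity — the circle spanning the smallest readable letter.
Evaluated at each tier's logistic reading acuity (1.07, 1.26, 1.48
logMAR), the calibrated patterns give ≈20 phosphenes per letter,
consistent with the ~21 ± 3 sampling constant reported for this class
of simulation.

## Rendering

Each frame of simulated vision is produced by the sample-and-splat
pipeline: translate the pattern to the instantaneous gaze position;
for each phosphene, read the stimulus image through a 2-D Gaussian
averaging filter whose σ equals the phosphene's drawn σ (weights
renormalized at image borders; a fully off-screen filter reads 0);
then splat a peak-normalized Gaussian of the sampled brightness at the
same location. Splats add linearly and the composed frame is clipped
to [0, 1] once at the end — this models display saturation and makes
the result independent of phosphene order (the compositor additionally
sorts phosphenes canonically so frames are bit-identical under
permutation).

Numerical choices: kernels are truncated at 3σ (1.1% Gaussian mass
loss); luminance is linear in [0, 1] with no gamma model; the px/deg
mapping is flat with separate horizontal (1920/43) and vertical
(1080/25) scales, σ using their mean. The production compositor is a
numba-compiled separable-Gaussian kernel (~0.04 s per 1920×1080 frame
with the high-tier pattern); the NumPy operations define the semantics
and tests hold the kernel to 1e-6 against a naive double-loop
reference.

## Stimuli

Sentences follow the MNREAD structure: exactly 60 characters including
spaces, 10–13 words, three lines broken as evenly as possible (the
layout minimizes the longest line's character count; ties prefer
top-heavy splits) with no hyphenation. The validated chart corpus is
licensed content, so a fixture generator draws simple child-level
vocabulary under the same constraints; user-supplied sentence files
are validated against them.

Letter size uses the MNREAD convention: the lowercase x-height
subtends 5·10^logMAR arcminutes. The rasterizer calibrates the
font-units→pixel mapping empirically from a rendered 'x' and draws
white-on-black in a Times-class serif (STIX General by default; the
font path is a config item because metrics differ by face).

Two layout parameters deal with a physical constraint: at 1.5 logMAR a
20-character line at natural serif spacing subtends ~50°, wider than
the 43° display. Glyph advances are therefore scaled by a uniform
tracking factor (default 0.80 — letter *size* is exact, spacing is
condensed), and the sentence generator rejects candidates whose widest
line exceeds 9.0 em, mirroring how chart corpora are curated to
typeset as a uniform block. With both, the whole six-size ladder
(1.5 → 1.0 logMAR) fits the default display; anything that still does
not fit raises an explicit overflow error rather than clipping.

## Trials and synthetic gaze

A session is one block of 48 trials: two passes × six font sizes
(descending) × four viewing conditions in the order clear, high,
medium, low — easiest to hardest, each (size, condition) class seen
exactly twice, every sentence used once. Each trial runs Start
(foveate the central dot), Pre-Stimulus (hold fixation 500 ms),
Reading (sentence plus an advance dot at top center; simulation
conditions render gaze-contingent frames at the 60 Hz display refresh),
and End (a continuous 350 ms dwell on the advance dot blanks the
screen; 2000 ms intertrial pause). Reading time t runs from stimulus
onset to dwell *onset* — the 350 ms trigger dwell is excluded. The
fixation tolerance is 2°. The engine runs entirely on the simulated
clock of its gaze trace, so timings in tests are exact.

Synthetic gaze emulates a reading scanpath: per text line, a
left-to-right sequence of fixations (default 4 per line, 200 ms each —
ordinary reading behavior) with instantaneous saccadic jumps, sampled
at the tracker's 300 Hz with isotropic Gaussian jitter of 0.14°
(the instrument's stated precision). Invalid samples are repaired the
way a streaming gaze server degrades: interior gaps up to 100 ms are
linearly interpolated, longer and trailing gaps repeat the last good
value, leading gaps repeat the first.

Word-level reading errors are not produced by any perceptual model:
a scripted observer draws misread words from a binomial whose per-word
success follows a logistic curve in letter size (midpoints 1.07 / 1.26
/ 1.48 logMAR for high/medium/low, 0.2 for clear; k = 13.6 per logMAR,
a ~340%/logMAR peak slope). This exists to exercise the scoring
pipeline end to end with realistically shaped psychometric data.

**What passing tests therefore show — and don't.** The synthetic
session demonstrates that the machinery (schedule, state machine,
rendering, logging, scoring) is correct and reproducible, and that the
scoring recovers the curves the observer was given. It says nothing
about human reading with phosphene vision: no perception, learning,
fatigue, vocalization, head movement, tracker dropout patterns, or
latency is modeled.

## Scoring

For each class (f, v) with observations (nᵢ words, eᵢ misread,
tᵢ seconds):

* accuracy α = mean of (n−e)/n;
* speed β = mean of (n−e)/t, reported in words per minute;
* MNREAD acuity γ_v = Δ₀ + Σ_f Δ_f α_{f,v}, where Δ₀ = 1.5 logMAR is
  the base size and Δ_f = −0.1 the step carried by each font *after*
  the largest (so perfect reading gives exactly the smallest tested
  size, 1.0). The classic base-plus-step parameterization (base 1.6,
  all six fonts weighted) is available behind `include_largest=True`.
  γ is additionally reported clipped to the tested range with an
  out-of-range flag. With one observation per class, 10-word sentences
  and the uniform ladder, γ reduces exactly to the published chart
  rule base − 0.1·(sentences read) + 0.01·(words missed).
* logistic acuity: α(s) = 1/(1+exp(−k(s−m))) fitted by bounded least
  squares (asymptotes fixed at 0 and 1; m initialized at the 50%
  crossing of linear interpolation, k at 10/logMAR; tolerances 1e-10;
  all-0 or all-1 data are flagged degenerate, not fitted). The slope
  is reported as the curve's maximum derivative in %/logMAR (= 25 k).
  Under binomial noise (11 words × 2 repetitions) the median midpoint
  error over 200 synthetic curves is below 0.05 logMAR.
* acuity surplus: for adjacent tiers, (observed acuity difference) −
  0.5·log10(count ratio), the expected gain from 2-D sampling density
  (0.15 logMAR per doubling). With the published tier acuities and
  counts the per-pair surpluses are 0.074 and 0.073 — a consistent
  ~0.07 logMAR of performance beyond the sampling argument.

A note on the viewing distance: a fixed-size stimulus viewed from
distance a instead of the reference r changes the effective demand by
−log10(a/r) logMAR; at the population's ~66.3 cm versus the 65 cm
reference this is ~0.01 logMAR, which is why per-subject distance
compensation is omitted.

## Problem sizes used by the test suite and acceptance script

Chosen as desk-scale defaults: 1000 generated sentences for the
construction check; 20 seeds per tier for window-count and efficiency
means; 200 synthetic psychometric curves for recovery; one full
48-trial session at the native 1920×1080 geometry with ~6000 rendered
frames for the end-to-end run; renderer oracles on 64×64 toys.

## Known limitations

* Radial symmetry of the density profile (see calibration caveats);
  no magno/parvo/konio structure, hemifield asymmetry, or electrode
  dropout.
* Peak-normalized splats and linear luminance are conventions; the
  original hardware's gamma and normalization are unknown.
* The flat px/deg mapping ignores tangent distortion (<1% over this
  field) and the tracking compression alters inter-letter spacing
  relative to printed charts.
* No real-time guarantees: the simulator is offline and clock-exact,
  not latency-faithful.
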