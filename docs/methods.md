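# Methods

This note documents the measurement model, the statistics, the synthetic
data generator and the numerical choices made where the underlying
procedure left the design open.

## Motion measure

Motion on the nest surface is measured as the per-frame count of
*motion-active* pixels inside rectangular surveillance zones.

* **Luminance.** For RGB input, the luminance of a pixel is the channel sum
  R+G+B (24-bit footage: 0–765); for grayscale input the pixel value itself.
  The difference image is `|L(f) − L(f−1)|` computed on that summed value.
  With the default `lum_th = 10` the threshold therefore refers to the total
  RGB luminance; users of grayscale footage should scale `lum_th`
  accordingly if their material was derived from RGB by averaging rather
  than summing.
* **Thresholding is strict** (`diff > lum_th`): a difference exactly equal
  to the threshold is motionless. This fixes the boundary behaviour for
  testability.
* **Morphology.** One binary opening (erosion then dilation) with a 3×3
  *square* structuring element removes isolated super-threshold pixels —
  the stated purpose of the filtering is ambient-noise removal — while
  leaving filled rectangular regions exactly intact. A 3×3 cross was
  considered and rejected because opening with a cross clips the corners of
  filled blocks (a 10×10 block loses 4 of its 100 pixels), which makes zone
  counts depend on blob shape rather than blob area.
* **Conventions.** Coordinates are 0-based and row-major; zone rectangles
  are half-open `(row0, col0, height, width)`. Difference image *i* is
  attributed to the timestamp of the later frame, so an *n*-frame sequence
  yields counts at frame indices 1 … n−1.
* **Calibration.** `px_per_cm = width_px / width_cm`, rounded to the
  requested precision (one decimal by default: 580 px / 66 cm → 8.8 px/cm).
  Zone side length is `side_px / px_per_cm` rounded to two decimals, and
  the zone area is the square of that *rounded* side (100 px → 11.36 cm →
  129.05 cm²), keeping printed side/area pairs mutually consistent.
* **Normalization.** Counts are scaled by the episode-wide maximum over all
  zones and frames, so normalized activity is comparable across sessions of
  different length; an all-zero episode has no defined normalization and is
  rejected.

## Session structure

An episode is a contiguous alternating sequence of `nPd` (no dummy wasp)
and `Pd` (dummy presented) sessions, each a half-open frame range. The MFA
window (onset, end) comes from configuration — synthetic ground truth or
manual annotation; `detect_mfa_bounds` (baseline + k·σ crossing, k = 3 by
default) is offered as a convenience but never silently overrides a
configured value. Sessions straddling an MFA boundary take the phase of
the majority of their frames; the boundary frames themselves count as MFA.
Long uninterrupted sessions can be partitioned into pseudo-sessions of a
fixed step (5 000 frames in the original protocol) for comparable
statistics.

## Histogram-based motion spectra

Per session × zone, counts are sorted into 50 size classes, equally spaced
in the transformed coordinate `y = log10(count + 1)` over `[0,
log10(episode_max + 1)]`.

* The `+1` offset makes zero-count frames representable; the exact bin-edge
  formula of the original analysis is not published, so this geometric
  layout is a declared convention of the package.
* The bin range is anchored to the **episode** maximum, not the session
  maximum, so all spectra of one episode share an abscissa and left/right
  shifts between sessions are meaningful.
* First normalization: relative frequencies (divide by session frame
  count), so every spectrum sums to 1. Second normalization: division by
  the maximum relative frequency over all sessions and zones of the
  episode (`scale_episode`), so the episode-wide maximum equals 1.
* The spectral peak is the argmax of the 3-bin moving-average smoothed
  spectrum; ties break toward the lower bin. `peak_position` is
  `peak_bin / 49` ∈ [0, 1].
* An all-zero session is flagged degenerate with its mass in bin 0.

## Tail-area skewness q_s

`uT_a` is the spectral mass in bins ≥ peak+5, `lT_a` the mass in bins ≤
peak−5, and `q_s = uT_a / lT_a`. The 5-bin offset is the published choice
and is configurable. If either tail is empty the plain quotient is 0 or
undefined; the result is then flagged and the ε-regularized quotient
`(uT_a + ε)/(lT_a + ε)` with ε = 10⁻⁶ is reported, which preserves the
direction of the asymmetry. Note that `q_s` is sensitive to sub-bin
alignment of the spectral peak: for narrow spectra (σ ≲ 2 bins) the ±5-bin
tails sit deep in the distribution's tails and half-bin offsets of the
modal bin move `q_s` by tens of percent. The statistic is meaningful for
the broad spectra real footage produces, and the test suite constructs its
symmetry checks on the bin grid for exactness.

## Base-motion comparison Q_mf

For an episode's mass-flight `nPd` spectra, the de-logarithmised bin
centers (`10^center − 1`; centers rather than edges, a declared convention)
are multiplied by the relative class frequencies and summed, giving a
spectral mean magnitude S. `Q_mf = S(episode b) / S(episode a)` per zone,
reported with mean ± s.e. over zones. Because each episode is normalized
to its own session maxima, Q_mf compares base motion levels independently
of episode-specific detection sensitivity.

## Quantile-based spectra

The empirical quantile function of counts normalized by the episode
maximum, on a grid of step 0.01. Defensiveness proxy: the mean slope
between the 0.30 and 0.90 quantiles, `(Q(0.90) − Q(0.30))/0.60` — burst
cohorts steepen the upper quantiles. Mass-flight proxy: the "low base",
the mean of the quantile values on [0, 0.10]; the exact averaging window of
the original definition is not published, so the lowest decile is the
package's choice and is configurable. At least 100 frames are required.

## Frequency-weight (ripple) analysis

For frame intervals k ∈ {1, 2, 4, 7, 14, 27, 52, 100} (eight geometrically
spaced values; the source names only the endpoints and the count), the
weight of a series is `mean_t |A(t+k) − A(t)|`, displayed against
`frame_rate / k` in Hz. Weights are normalized to unit maximum — per
series, or jointly over a zone set (`frequency_weight_table`) so zones stay
comparable. The statistic is pluggable. For a sinusoid of frequency f the
closed form is `(4/π)·amp·|sin(π f k / rate)|`: maximal at the half-period
lag and zero at the full period, which is what makes a 0.5 Hz ripple
visible at the k = 100 interval of 50 fps footage. The source text states
the analyzed range inconsistently (0.5–50 Hz in the methods, "100 Hz down
to 0.1 Hz" in the results); the 1–100 frame / 0.5–50 Hz convention is
implemented.

## Inhibition models

Both models live on [0, 1], equal 1 outside the MFA window, and describe
the suppression of defensiveness:

* `linear_ramp` — 1 at onset, falling linearly to 0 at the MFA end, then
  jumping back to 1 (progressive inhibition, abrupt release);
* `semicircular` — `1 − √(1 − u²)` with `u = 2(t−onset)/(end−onset) − 1`:
  gradual decline, minimum 0 at mid-MFA, gradual recovery (inhibition
  proportional to the mass-flight turbulence).

The literature attaches the acronyms *pim* (progressive inhibition during
mass flight) and *ipm* (inhibition proportional to mass flight) to these
shapes, but uses them inconsistently between sections; the package
therefore names the models by shape only.

Empirical input is the `log10(q_s)` series of the Pd sessions, min-max
normalized to [0, 1] and placed at the sessions' temporal midpoints (the
abscissa convention is the package's choice). Each model is evaluated at
those midpoints and scored by the Pearson correlation coefficient; the
larger PCC wins, ties are reported as ties, and constant series (or models
evaluated entirely outside the MFA) yield a flagged, undefined comparison.
The whole-nest series is the geometric mean of q_s over zones per session.

## Trade-off analysis

Each consecutive (nPd, Pd) pair contributes one point per zone: abscissa =
mass-flight state of the nPd session (spectral `peak_position`, or quantile
`low_base`), ordinate = defensiveness of the following Pd session (`q_s`,
or quantile slope). Points are scaled per zone and episode by their maxima
into (0, 1]. Scaling by the maximum (rather than min-max) is deliberate: a
pure rescaling maps a hyperbola `y = A/x` onto another hyperbola, so the
−1 log-log slope survives normalization, whereas subtracting minima would
destroy it.

The fit is ordinary least squares on `(log10 x, log10 y)` after clamping
values below ε = 10⁻³ (zero handling on log-log axes is unspecified in the
source). Reported are the slope (−1 on the reference diagonal), R², the
Pearson r of the log pair as the PCC against the reference (−1 for a
perfect trade-off; note the published panels satisfy R² = PCC² exactly,
which identifies their PCC as this correlation), and `A = 10^intercept`,
the hyperbola coefficient. Constant-ordinate clouds are flagged degenerate
with slope and PCC 0; a degenerate abscissa range is an error.

## Synthetic nest scenarios

The generator emulates the *statistical* structure the analysis consumes —
per-pixel luminance changes — not bees. Pixels toggle between two gray
levels 30 apart (super-threshold under either luminance rule); a pixel
"flips" in frame t with a regime-dependent probability, and flip seeds are
dilated to 3×3 blobs (`flicker_blob = 3`) so that simulated motion, like
the multi-pixel body parts of real bees, survives the opening filter. With
`flicker_blob = 1` and morphology off, zone counts are exactly
Binomial(area, p) per frame, which the test suite uses as an oracle.

Regimes and defaults (full-scale scenario: 1280×720 px, 50 Hz, 8.8 px/cm,
five 100×100 px zones, 17 sessions of ~2 min nPd / ~1 min Pd):

| parameter | default | rationale |
|---|---|---|
| quiescent flip-seed rate | 0.005 px⁻¹ frame⁻¹ | sparse baseline flicker; free parameter (no published per-pixel statistics), set so quiescent spectra are well resolved in the 50-bin grid |
| mouth-zone rate | 0.02 | the mouth zone is motion-active at all times |
| baseline wander | lognormal, σ = 0.3, mean-one, AR(1) τ ≈ 5 s | slow excitability drift; gives quiescent spectra finite tails, as pure Bernoulli spectra are narrower than the ±5-bin tail offset |
| shimmer wave speed | 50 cm/s | order of magnitude of observed wave propagation |
| pulse duration | 300 ms | published per-agent pulse duration; sets the trailing band width of the wave front |
| wave launch period | 3 s | salvo spacing; at 1 s the expanding fronts overlap so completely that no quiescent cohort remains during Pd sessions, contradicting the observed dominant-left bimodality. The published ~1 Hz figure is read as within-salvo pulse cycling |
| wave band density | 0.08 | burst counts well above the MFA plateau, keeping the episode maximum on the shimmer bursts |
| MFA recruitment rate | 0.02 at peak, triangular onset→peak→end envelope | colony-wide unrest over several minutes |
| MFA spread delay | 5 s per rank (mouth → near-mouth → center → periphery) | recruitment starts at the mouth zone |
| MFA lulls | multiplicative `exp(−Exp(0.5))` per frame | transient dips below the recruitment ceiling; produce the left-dominant (q_s < 1) log spectra of the plateau |
| ripple | 0.5 Hz for 90 s before onset, amplitude 0.8/0.6/0.4/0.2 by role | the slow pre-MFA unrest, mouth-dominant |

Shimmer-wave strength during MFA is multiplied by a configurable
suppression time course: `linear_ramp`, `semicircular`, `proportional`
(1 − recruitment envelope) or none. This coupling is what downstream model
fitting and trade-off analysis recover.

What the generator does **not** emulate: individual bee trajectories, 3-D
curtain structure, illumination drift, camera noise, compression
artifacts, or empirically calibrated per-pixel statistics (none are
published). Passing tests therefore demonstrate that the analysis chain
recovers planted statistical structure of this form — not that the chain
is robust to every artifact of real field footage.

## Problem sizes

Tests and the acceptance script run a scaled-down scenario (200×160 px,
25 Hz, 36×36 px zones, 24 s nPd / 12 s Pd sessions, MFA across the middle
~60% of the episode) — about 7 800 frames per episode, preserving the
session structure at a fraction of the pixel budget. The full-scale
scenario is the package default for users. The paired trade-off episodes
use 36 s / 24 s sessions, since session-level q_s estimates from very
short sessions are noise-limited.

## Known limitations

* `q_s` quantization sensitivity for narrow spectra (see above).
* The frequency-weight statistic is a substitute for spectral analysis: it
  localizes dominant periods but has broad spectral leakage; it is kept for
  fidelity to the original procedure and is pluggable.
* Automatic MFA-bound detection is a convenience heuristic; phase labels
  should normally come from annotation or ground truth.
* With an empty tail, ε-regularized q_s values depend on ε in magnitude
  (their direction is stable); flagged values should not be averaged
  together with regular ones on a linear scale. Pipeline medians are robust
  to this.
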