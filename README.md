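# nestmotion

Motion quantification and collective-behaviour statistics for video of
giant-honeybee (*Apis dorsata*) nest surfaces.

Giant honeybees nest on a single open comb covered by a living "bee
curtain". The colony alternates between semi-quiescence (an almost
motionless curtain with a busy mouth zone), collective defensive waves
("shimmering") triggered by visual threats such as wasps, and periodic
**mass flight activity (MFA)**, in which the whole curtain restructures
itself. `nestmotion` implements the video-based measurement chain used to
study how mass flight suppresses defensiveness:

1. **Motion detection** — pixel-wise absolute luminance differences between
   consecutive frames are thresholded (`lum_th = 10`, luminance of an RGB
   pixel = R+G+B) and cleaned by one morphological opening; the number of
   *motion-active* pixels inside each 100×100 px surveillance zone per frame
   is the motion activity *A(f)*.
2. **Motion spectra** — per experimental session (with/without a dummy-wasp
   presentation, `Pd`/`nPd`) the counts are binned into 50 logarithmically
   scaled size classes (coordinate `log10(count+1)`, range anchored to the
   episode maximum) and normalized by session length, then by the episode
   maximum.
3. **Skewness quotient** — defensiveness is scored by the tail-area quotient

   `q_s = uT_a / lT_a`,

   the spectral mass more than 5 bins right of the peak over the mass more
   than 5 bins left of it. `q_s > 1` (right-dominant spectrum) indicates
   shimmering on top of the quiescent mode; `q_s < 1` indicates the
   left-dominant spectra typical of the mass-flight plateau.
4. **Ripple detection** — a Fourier-substitute: mean absolute lagged
   differences of *A(f)* over eight frame intervals (1–100 frames,
   i.e. 50–0.5 Hz at 50 fps) expose the slow ripple that precedes MFA onset,
   strongest in the mouth zone.
5. **Inhibition models** — two bounded time courses of defensiveness during
   MFA (a linear ramp with abrupt recovery; a semicircular depression) are
   scored against the normalized `log10(q_s)` series of the Pd sessions by
   Pearson correlation.
6. **Trade-off nomogram** — each (nPd, Pd) session pair yields a point
   (mass-flight state, defensiveness); in log-log coordinates a perfect
   trade-off follows the −45° diagonal of the normalized hyperbola
   `y = A/x`. The package reports the log-log regression slope, R², PCC and
   the coefficient A.

A seeded **synthetic nest-video generator** reproduces the statistical
structure of the recordings (quiescent flicker, expanding shimmer wave
fronts, MFA recruitment with configurable suppression of shimmering, the
pre-MFA ripple) together with frame-level ground truth, so the entire chain
is testable without field footage. The package is aimed at behavioural
ecologists and ethologists quantifying collective motion states from fixed
cameras; everything operates on plain frame stacks, CSV tables and YAML
configuration.

## Worked example

```python
import numpy as np
from nestmotion import RunConfig, run_pipeline, small_scenario

config = RunConfig(scenario=small_scenario(seed=1))
result = run_pipeline(config)

sessions = result.sessions
quiet_pd = sessions.query("stimulus == 'Pd' and phase == 'nMFA'")
mfa_pd = sessions.query("stimulus == 'Pd' and phase == 'MFA'")
print(f"episode maximum count: {result.episode_max} px")
print(f"median q_s, Pd sessions in semi-quiescence: {np.median(quiet_pd.q_s):.2f}")
print(f"median q_s, Pd sessions during mass flight: {np.median(mfa_pd.q_s):.3f}")
fit = result.model_fits.query("zone == 'all'").iloc[0]
print(f"inhibition model preferred by PCC: {fit.preferred} "
      f"(linear {fit.pcc_linear_ramp:.2f} vs semicircular {fit.pcc_semicircular:.2f})")
trade = result.tradeoff_fits.query("zone == 'all' and source == 'quantile'").iloc[0]
print(f"trade-off log-log slope {trade.slope:.2f}, R^2 {trade.r_squared:.2f}, PCC {trade.pcc:.2f}")
```

prints

```
episode maximum count: 769 px
median q_s, Pd sessions in semi-quiescence: 1.70
median q_s, Pd sessions during mass flight: 0.045
inhibition model preferred by PCC: semicircular (linear 0.41 vs semicircular 0.82)
trade-off log-log slope -0.61, R^2 0.44, PCC -0.66
```

The scenario was generated with semicircular suppression of the shimmer
waves during MFA, and that is what the analysis recovers: dummy
presentations elicit right-skewed spectra (`q_s` ≈ 1.7) while the colony is
semi-quiescent, the skewness collapses far below 1 during mass flight, the
semicircular inhibition model wins the PCC comparison, and the
(mass-flight state, defensiveness) points fall on a negatively sloped
log-log line — the trade-off signature.

The same run from the shell:

```bash
nestmotion all --seed 1 --out results/run1       # full bundle of CSV tables
nestmotion simulate --seed 1 --out frames/       # synthetic frames + ground truth
nestmotion tradeoff --sessions results/run1/sessions.csv --out tradeoff.csv
```

Every output table carries the hash of the fully serialized run
configuration, and `manifest.json` records table names, the episode
maximum, and the MFA bounds used.

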