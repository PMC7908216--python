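# Methods

## The scoring model

Left-bundle-branch-block (LBBB) conduction delay produces a stereotyped
mechanical sequence in the left ventricle: the early-activated wall (septum
in the 4-chamber view, anteroseptum in the 3-chamber view) contracts first
and then rebounds, while the opposing late-activated wall is passively
stretched in early systole and reaches its own peak shortening only after
aortic valve closure (AVC). The Regional Strain Pattern Index (RSPI)
decomposes this sequence into four binary components per apical view,
assessed on the basal and mid segmental longitudinal-strain curves:

1. **c1 — early contraction of the early-activated wall**: an interior local
   minimum of strain within the ejection phase `[0, AVC]` whose two-sided
   prominence is at least `contraction_prominence` (default 2 % strain).
2. **c2 — prestretch of the late-activated wall**: positive strain of at
   least `prestretch_threshold` (default +1 %) within the first
   `prestretch_window_fraction` (default 0.5) of the ejection phase.
3. **c3 — early peak within 70 % of ejection**: the earliest qualifying c1
   peak time is at most `0.70 · E`, where `E = AVC − QRS onset`. c3 is only
   scored when c1 is present (`c3 ≤ c1` by construction); the 0.70 fraction
   is a fixed constant of the method, and "does not exceed" is read as
   inclusive (`≤`).
4. **c4 — late-wall peak contraction after AVC**: the global strain minimum
   of a late-wall segment, searched up to `AVC + 0.4·E`, falls strictly
   after AVC. A peak exactly at AVC is the synchronous norm, hence the
   strict inequality.

A wall's components are existential over its basal and mid segments: one
qualifying segment sets the bit. Each component scores one point; the three
views together give a 0–12 total. Totals at or above the cutoff (default 7,
boundary inclusive) define the high-RSPI class. A wall whose traces never
reach the contraction prominence — akinetic or scarred myocardium —
contributes 0 to its components rather than invalidating the view, and a
view with a missing wall is flagged not-assessable and contributes 0.

The classical/heterogeneous pattern classifier reuses the same component
machinery: a view fulfils the classical (LBBB-related) criteria when
`c1 ∧ c2` (early contraction plus opposing prestretch), `c3` and `c4` all
hold, and a patient is *classical* when at least one view is fulfilled. The
criteria name the septal/anteroseptal wall, which is the anatomic early wall
of the 4- and 3-chamber views; the 2-chamber view has no septum, so its
fixed early wall (anterior) is used as the minimal consistent extension.
`include_two_chamber=False` restricts the label to the septum-bearing views;
both behaviours are exposed because the source methodology is ambiguous on
this point.

## Numerical choices

- **Sampling.** Traces are piecewise-linear samples (default generator grid
  5 ms, matching >35 frames/s acquisition). Extrema are located on the
  sample grid without sub-sample interpolation; all ties resolve to the
  earliest time.
- **Peak prominence.** `scipy.signal.find_peaks`/`peak_prominences` on the
  negated strain implements the two-sided-prominence rule; an extremum on a
  window edge never counts for c1 (no rebound), but does count for the
  late-wall global peak search.
- **Smoothing.** A centred moving average of `smoothing_ms` (default 25 ms,
  i.e. 5 samples at the default grid; reflect-padded) is applied to strain
  traces before detection. Clinical speckle-tracking packages apply
  comparable temporal filtering. Without it, threshold crossings by
  uncorrelated sample noise would dominate: the maximum of ~30 independent
  N(0, 0.5 %) draws exceeds the +1 % prestretch threshold about half the
  time, whereas after 5-sample averaging the threshold sits at ≈4.5 effective
  standard deviations. Smoothing is symmetric, so it does not displace the
  symmetric synthetic peaks at zero noise; set `smoothing_ms=0` to disable.
- **Wall roles.** Early/late walls are fixed anatomically per view
  (septal/lateral, anterior/inferior, anteroseptal/posterior). A
  `data_driven` mode swaps the roles when the nominal late wall shows the
  earlier qualifying peak; output flags the mode used.
- **`require_rebound`.** Whether "contraction movement" of the early wall
  demands a rebound is ambiguous in the source description; the default
  (True) requires the two-sided peak, and False accepts a monotone
  shortening whose depth reaches the prominence threshold.
- **Late-peak search window.** How far past AVC the late-wall search extends
  is unstated in the source; the default `0.4·E` comfortably contains
  post-systolic shortening at physiological delays and is configurable.

## Comparison indexes

LVDFT/RR (% of the cycle in diastolic filling), IVMD (aortic minus
pulmonary pre-ejection time, signed), SPWMD (posterior minus septal
peak-inward-motion time from M-mode-style displacement traces, signed),
per-view maximum intraventricular delay (max − min of the four time-to-peak
systolic velocities), maximum time delay (max − min over all 12 basal/mid
segments), maximal opposing-wall delay, and the Yu index (SD of the 12
time-to-peaks). Two conventions are not fixed by the source and are chosen
here: the Yu index uses the sample (n−1) standard deviation, the convention
of the dyssynchrony literature (configurable to population SD), and the
opposing-wall delay is computed level-matched (basal vs basal, mid vs mid)
within each view. CRT response is a ≥15 % reduction (boundary inclusive) of
LV end-systolic volume at follow-up.

## Cohort statistics

- 2×2 diagnostics (test = high RSPI, condition = responder) with Wald 95 %
  CI on the log odds ratio; zero cells yield an infinite/zero OR with
  undefined CI unless the Haldane–Anscombe +0.5 correction is enabled
  (off by default). A zero margin marks only the affected statistic
  undefined.
- Empirical ROC over the integer thresholds 0..13 (positive at score ≥
  threshold); trapezoid AUC, equal to the all-pairs concordance probability
  with ties counted ½; optimal cutoff by Youden's J, ties resolving to the
  larger cutoff. The cutoff criterion is a design choice — the source
  states the chosen cutoff but not the selection rule.
- Univariate logistic regression by Newton/IRLS (statsmodels, gradient
  tolerance 1e−10). For a binary predictor the fitted odds ratio coincides
  with the 2×2 cross-product ratio (an analytic identity, verified to 1e−6
  relative); separation and constant predictors are flagged, not estimated.
- Mann–Whitney U (exact null for tie-free samples of ≤10 per group,
  continuity-corrected normal approximation otherwise), Wilcoxon
  signed-rank (identical pairs give p = 1), Pearson χ², McNemar (exact
  binomial below 25 discordant pairs), Spearman rank correlation. p-values
  are descriptive; no multiplicity correction is applied.
- The Wald CI is the default interval for the odds ratio. On the 2×2
  reconstructed from the published counts (18/1/18/12) it gives ≈1.41–102,
  not the published 1.33–108.17; no standard interval reproduces that CI
  exactly from these counts, so the interval is reported but not treated as
  a reference value.

## The synthetic-data generator

Waveforms are sums of Gaussian bumps on a 5 ms grid over `1.5·E` (default
timing: ejection 300 ms, RR 1000 ms, filling 400 ms, pre-ejection times
140/100 ms). The early wall is either a single end-systolic shortening peak
at AVC (synchronous) or a −12 % early dip (centred at 0.45·E, or 0.75·E for
beyond-70 % cases) with a rebound and mild late stretch; the late wall is a
−15 % main dip centred either at 0.85·E or 60 ms after AVC, plus an optional
+3 % early prestretch bump. These four degrees of freedom realize every
admissible component combination exactly at zero noise. Noise is additive
white Gaussian per sample with a fixed seed; amplitudes, delays, grid and
seed are all spec fields. Cohorts assign each patient a target RSPI total
(decomposed into canonical per-view bits), a responder label with LVESV
drawn consistently (responders' ΔLVESV% uniform on [15, 72], non-responders
on [−22, 14], spanning the clinically observed range), and 12 velocity
traces whose time-to-peak spread grows with the score. Exact-count mode
assigns the responder × high-RSPI cell memberships outright, reproducing a
prescribed 2×2 without sampling.

What the generator does *not* emulate: correlated physiological noise,
drift/after-contraction morphologies beyond the bump family, atrial
fibrillation beat-to-beat variability, apical segments, and scar-related
amplitude loss. Passing round-trip tests therefore demonstrates that the
detectors implement the stated rules faithfully on clean and mildly noisy
morphologies — not that the thresholds are clinically optimal on real
speckle-tracking output.

## Problem sizes used in the checks

The package's verification runs at desk scale: component round-trips over
all 16 bit patterns × 3 views (exact at zero noise, ≥95 % recovery at noise
σ = 0.5 % over 200 seeded replicates), AUC vs an all-pairs oracle on 1000
random cohorts of 8–40 patients, timing-panel statistics vs an
exhaustive-pair oracle on 1000 random 12-tuples, and logistic slope
recovery (|β̂ − β| < 3 SE) in ≥95 % of 200 replicates at n = 500.

## Known limitations

- AVC and all timing annotations are inputs, not detected from Doppler.
- Single representative beat; no multi-beat averaging.
- The "evident peak" thresholds (2 % prominence, +1 % prestretch) are
  operationalizations of visual criteria and may need re-tuning per vendor.
- The scoring uses basal and mid segments only; apical segments are out of
  scope by design.
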