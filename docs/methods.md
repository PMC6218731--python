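# Methods

## Problem and pipeline

The package estimates systolic and diastolic blood pressure (SBP, DBP, in
mmHg) from the photoplethysmogram (PPG) alone — no ECG, no pressure cuff at
inference time. The pipeline mirrors the standard PPG-morphology approach:

1. **Segmentation and screening.** The unit of analysis is a 5 s PPG
   segment sampled at 100 Hz with one reference cuff reading (SBP, DBP).
   Rule-based screening stands in for visual quality control: a segment is
   rejected when it lacks a reference reading, is flat, shows a run of ≥ 25
   samples pinned at its maximum or minimum (saturation or dropout), or has
   an implausible beat count (outside 3–15 beats per 5 s, i.e. 36–180 bpm).
   All thresholds are configurable; the defaults are the loosest rules that
   catch the generator's two artifact types while passing clean segments.
2. **Preprocessing.** Savitzky–Golay smoothing (4th order, 19-sample
   window), beat delineation (adaptive-threshold peak picking with a 0.3 s
   refractory period; feet as minima between peaks), baseline-wander removal
   by subtracting the piecewise-linear interpolant through the pulse feet,
   and two-dimensional normalization of every beat to a 100-point grid over
   unit time with unit amplitude.
3. **Features.** Per normalized pulse: pulse area (trapezoidal integral),
   rising time (normalized time of the systolic peak, a.k.a. crest time),
   and the outermost widths at 25 %, 50 % and 75 % of the amplitude (first
   up-crossing to last down-crossing, interpolated linearly). Per segment:
   the arithmetic mean over complete beats — the cuff reading is constant
   within a segment, so one feature vector per segment is the natural
   resolution. Beats whose window touches the segment edge, or whose
   duration deviates more than 8 % from the segment median (a mis-placed
   edge foot), are excluded from the average.
4. **Selection.** Variance inflation factors, VIF_j = 1/(1−R²_j) with R²
   from an ordinary-least-squares regression of feature j on the rest plus
   intercept. Iterative elimination drops the largest VIF above 10 (ties to
   the later column) and recomputes. On the synthetic data this eliminates
   the 50 % and 75 % widths and retains {area, rising time, width-25}.
5. **Models.** Three regressors, each fitted separately for SBP and DBP on
   the retained features: multiple linear regression (closed-form least
   squares), linear ε-support-vector regression (ε-insensitive L1 loss;
   defaults ε = 2 mmHg on the pressure scale, C = 1 on features
   standardized inside the fit, convergence certified by the normalized
   primal–dual feasibility gap Δ = (J(β)+L(α))/(J(β)+1) < 10⁻³), and a CART
   regression tree (greedy splits on midpoint thresholds minimizing child
   MSE; a node is left pure when its response MSE falls below the all-data
   MSE times 10⁻⁴; defaults depth ≤ 12, ≥ 5 rows per leaf; ties broken
   toward the lowest feature index, then the smallest threshold; rows equal
   to a threshold route right).
6. **Evaluation.** Segment-level 10-fold cross-validation (seeded
   permutation + round robin, fold sizes differing by at most one) yields
   one held-out estimate per segment. Estimates are averaged per case —
   optionally within one reference-BP category — and the per-case
   differences (reference − estimated) are summarised by their mean, sample
   (n−1) SD, Bland–Altman limits of agreement (bias ± 1.96 SD) and an
   ISO-style verdict: |mean| ≤ 5 mmHg and SD ≤ 8 mmHg, boundaries
   inclusive. Categories: hypertensive if SBP ≥ 140 or DBP ≥ 90;
   otherwise hypotensive if SBP < 90; otherwise normotensive. DBP takes no
   part in the hypotensive rule because normotensive reference DBPs reach
   the low 40s. All four thresholds are configurable.

## Synthetic data generator

Real clinical recordings are not shipped; the generator produces 5 s
segments whose pulse morphology is deterministically linked to latent
(SBP, DBP), so that every downstream stage can be tested against known
ground truth.

**Beat model.** One cardiac cycle is a periodized sum of three components:
an asymmetric systolic wave (Gaussian upstroke of width `rise_ratio ·
s_fall`; decay `exp(−½|t/s_fall|^q)` with a free exponent q — the pulse
"fullness"), a symmetric dicrotic Gaussian riding on the decay at a free
delay, and a broad low-amplitude diastolic runoff pedestal that stays below
the 25 % level. Six shape parameters in total. Two lessons from building
it: a symmetric two-Gaussian beat cannot produce short rising times at all
(after periodization the peak position is a pure phase and the foot is set
by the tail balance), and without the fullness exponent the pulse area is
pinned by the rising time and width, leaving no independent area
information.

**Morphology map.** An invertible linear map sends (SBP, DBP) to targets
for (rising time, width-25, area):

    rising_time = 0.330 − 0.00085·SBP + 0.00050·DBP
    width_25    = 0.320 + 0.00280·DBP
    area        = 0.28081 − 0.00020·SBP + 0.00174·DBP

Signs encode the usual qualitative associations: a faster systolic
upstroke at higher systolic pressure, broader and fuller pulses at higher
diastolic pressure, with a small diastolic contribution to the crest time.
The magnitudes were chosen by feasibility analysis: the area line is the
Chebyshev centre (linear program) of the beat family's attainable area
band over the whole pressure box and heart-rate range, with ≈ 0.014
margin. No quantitative shape-to-pressure law is claimed — the map is a
modelling device that makes recovery testable, not a physiological
result.

**Shape solving.** For each segment the six shape parameters are solved so
that the *extracted* morphology equals the map's targets. The forward model
samples the beat at the segment's cardiac period, applies the same
Savitzky–Golay kernel as the analysis chain, and measures foot-to-foot
rising time, outermost widths and area with sub-sample refinement — so the
filter's bias at 100 Hz is part of the construction, and a noiseless
dataset is invertible end-to-end: extracted features match the map within
1.5/N (N = 100) and the tree pipeline recovers pressures with sub-mmHg
overall bias. Soft terms canonicalize the underdetermined solve (systolic
rise width near 0.08 cycles keeps the upstroke resolvable at 100 Hz; the
dicrotic summit near 0.32 of the amplitude keeps the 25 % width on a single
crossing branch). Every segment's solve starts from its case's base
solution, making the shape a deterministic smooth function of the targets.

**Noise model.** Four layers, all scaled by configuration: additive
Gaussian noise (default SD 1 % of pulse amplitude), respiratory baseline
wander (0.25 Hz sinusoid, default 5 % amplitude), optional artifacts
(saturation plateaus and zeroed dropouts, caught by the screening rules),
and beat-to-beat morphology variability implemented as jitter on the
morphology targets with SDs (0.40, 1.30, 0.74) × noise_sd for rising time,
width-25 and area. When solving jittered targets, two additional soft
constraints hold the 50 % and 75 % widths at fixed ratios (0.63, 0.39) of
a blended width reference — 70 % the pre-jitter width trait of the latent
pressure, 30 % the beat's realized width target — so the higher widths are
strongly collinear companions of width-25 in the extracted features (the
vascular-tone coupling is mostly a trait of the pressure, with partial
beat-to-beat co-movement), while the width-25 jitter and the area jitter
(expressed through the fullness/pedestal dimensions) remain mostly
independent noise. These pins are disabled for noiseless data, where
there is no jitter to stabilize and they would trade off exact target
matching at the pressure-box corners. Jittered targets that leave the
attainable manifold are projected onto the nearest realizable shape; the
projection is part of the variability model.

**Study conditions.** Defaults: 32 cases × 30 segments, category mix
(0.80, 0.12, 0.08) for (normotensive, hypertensive, hypotensive) allocated
by largest-remainder apportionment in seeded random order, and per-case
base pressures at evenly spaced quantiles of each category's pressure box
(independently shuffled) with ±3 mmHg per-segment variation — a stratified
recruitment whose composition and pressure spread are stable across seeds,
the way a designed validation cohort would be. Heart rate 58–80 bpm
(resting hospital range; faster rates leave too few samples per beat at
100 Hz for a 19-point filter).
The scale is a deliberate reduction of a realistic 32-case, ~8000-segment
recording campaign to desk size; the per-case structure (segment-level
cross-validation folds, case-level aggregation) is preserved.

**What the generator does not emulate.** Real PPG waveform diversity
(ageing, arrhythmia, probe placement), measurement drift of the reference
cuff, nonstationary heart rate within a segment, and any true
physiological shape-to-pressure law. Passing tests therefore demonstrate
that the pipeline's arithmetic and learning machinery are correct and that
the study's evaluation logic reproduces its reported numbers — not that
the method attains any particular accuracy on clinical data.

## Numerical choices

- Normalized pulse length N = 100: interpolation error (≈ 1/N) is an order
  of magnitude below the morphology effect sizes.
- Savitzky–Golay edges: fit-and-evaluate of the boundary polynomial
  (`mode="interp"`), preserving signal length.
- Width levels are measured on the normalized pulse; multiple crossings
  (dicrotic wave) use the outermost pair, so a dicrotic re-crossing never
  shrinks a width.
- Sample (n−1) SD throughout: it reproduces the reference tables' printed
  SDs from the printed per-case differences where the population SD does
  not. Display rounding is one decimal, half away from zero.
- The SVR wrapper stores the dual coefficients and both objectives; a fit
  whose feasibility gap does not fall below the gap tolerance raises
  rather than returning a silently unconverged model.
- Tree thresholds sit at midpoints of adjacent sorted values, so equality
  at a threshold can only occur at prediction time (routing right).

## Known limitations

- The morphology map is linear and noise-free by construction; real
  PPG-to-pressure relations are nonlinear, subject- and device-specific.
- The quality rules are proxies tuned to the generator's artifact types; a
  learned quality classifier would be needed for field data.
- The published per-case tables are transcribed at one-decimal precision,
  so their summary rows can only be reproduced to within one unit of the
  final printed digit (the published summaries were evidently computed
  from unrounded values).
- Elimination order within the width pair (50 % vs 75 %) is
  noise-dependent; only the retained set is a stable property.
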