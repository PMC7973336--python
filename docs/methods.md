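# Methods

## Forward model

The specimen is modelled as a 2-D top view on the native camera grid
(117.25 µm pitch): a boolean contour mask, a set of focal tumour regions,
and six margin sectors. The radiance reaching the scintillator at
decay-corrected activity `A` (MBq) is

    L(x) = A · [ k_bg + Σ_f k_t · u_f · exp(−d_f / λ) · 1(d_f ≤ d_max) ]

inside the contour and zero outside, in photons/s/cm²/sr. The exponential
depth kernel with scale λ = 0.3 mm and a hard cutoff d_max = 1.0 mm encodes
the ~1 mm positron range in tissue with a smooth, testable form; both are
configurable. `k_bg = 56.5` and `k_t = 17.55` are **calibration constants,
not physics**: with the default focal uptake factor u = 4 they place the
tissue background at 56.5 and a surface (depth-0) focus at 126.7
photons/s/cm²/sr per MBq, the normalised radiances observed clinically.
Deeper foci are attenuated monotonically; a focus below d_max contributes
nothing. The model is deliberately not a 3-D transport code: no 511 keV
photon physics, no optical point spread, no specimen deformation.

Foci are discs at uniform depth. A 2-D depth-per-focus model matches what
the camera sees and keeps every oracle (half-value depth, cutoff,
linearity in activity) computable by hand.

## Acquisition model

Counts per native pixel and 100 s frame are Poisson with mean
`L · gain · t_exp` plus an optional dark offset; the default gain of 10⁻⁴
counts/(photon/s/cm²/sr)/s puts the tissue background near 55 counts per
frame, a realistic emCCD operating point. Decay *within* a frame is
neglected (≤ ~1% over 100 s against the 109.77 min half-life); decay is
applied once at imaging time. Gamma strikes — direct 511 keV hits on the
sensor — are injected per frame as Poisson events: one saturated pixel plus
a horizontal tail of 3–8 pixels halving per step. The clinical literature
gives no quantitative strike rate or amplitude; the defaults (2 per frame,
sensor saturation) are placeholders exposed in configuration. Noiseless
mode returns expected counts unrounded, which makes the processing chain
exactly invertible for pipeline-identity tests.

## Processing chain

Per the acquisition protocol: 8×8 per-frame sum binning (938 µm processed
pitch) → 3×3 pixel × 3 frame spatio-temporal median → Gaussian smoothing
(σ = 3 binned pixels, kernel truncated at 4σ, replicate padding) →
radiance conversion `(counts − dark·b²)/(gain · t_exp · b²)`.

Choices the protocol leaves open, fixed here and switchable in code:

- **Binning before median combination** (on-camera binning semantics).
- **Median edge handling**: replicate padding, keeping the output shape.
- **σ in processed pixels**: the smoothing acts on the binned grid.
- Frames not divisible by the bin factor are cropped with a warning.

The median of 27 samples cannot be moved to a transient value by any
disturbance confined to a single frame (≤ 9 of 27 samples), which is the
protocol's entire purpose; the suite checks this against a brute-force
sort oracle. Note the median output need not equal the transient-free
median bit-for-bit — it may shift to a neighbouring order statistic — but
it is always bounded by the clean neighbourhood extremes.

## Quantification

ROIs (EBG/TBG/THS) are boolean masks in processed-image coordinates.
Radiance statistics are normalised by the decay-corrected activity
`A = A₀·2^(−Δt/109.77 min)`; TBR is the ratio of normalised THS to TBG
means (the divisor cancels). The clinical workflow drew ROIs manually; the
reproducible surrogates here are (a) a default TBG ROI — specimen interior
eroded by 6 binned pixels (to exclude the smoothing roll-off at the
contour) minus dilated hotspots — and (b) for calibration experiments, a
THS ROI over the focus footprint shrunk by 2σ of the smoothing kernel,
where the smoothed profile has returned to its plateau, making the
measurement unbiased by the processing chain. Both are conventions of this
package, not clinical rules.

## Hotspot detection, triage and margin status

Visual reading ("focal area of more than 1 mm in diameter with increased
signal over tissue background") is operationalised as: threshold at TBG
mean + k·SD (default k = 2), 8-connected components inside the specimen,
equivalent circular diameter 2·√(area/π) > 1 mm. A single 938 µm binned
pixel has equivalent diameter 1.06 mm and marginally qualifies; an optional
`min_pixels=2` guard (default off) excludes it. Raising k shrinks the
detected pixel set monotonically; the component *count* is not monotone in
k because components may split, so the tested invariant is set inclusion.

Artifact triage is rule-based: *gamma strike* — saturated peak with a
steeply decaying horizontal run (each step ≤ 0.6× the previous; a smoothed
hotspot decays only a few percent per pixel and never matches) and, when
the raw stack is available, presence in exactly one frame; *white square* —
near-uniform saturated region over > 25% of the field; *ring* — enclosed
hole > 50% of the filled component; otherwise *tumour*. Only
tumour-classified hotspots can flag margins.

Margins: the contour boundary band (6 mm wide) is partitioned into six 60°
angular sectors named superior, medial, posterior, inferior, lateral,
anterior — a 2-D projection convention; physical specimens expose occult
faces by re-orientation, represented by per-image sector maps, and a margin
seen positive in any view is positive. A tumour hotspot is assigned to the
sector containing its centroid, falling back to the nearest sector for
interior centroids (ties flag all tied margins, logged); centroids outside
the specimen are logged and left unassigned. Histopathology status uses the
site rules: sites 1–2 positive only at 0 mm (either component); site 3
positive for invasive < 1 mm or DCIS < 2 mm; an absent component is an
infinite distance.

## Cohort generator

Injected activity ~ truncated normal (246.7, 48.6²) on [185, 334] MBq;
imaging time ~ truncated normal (143.9, 20.5²) on [60, 180] min; per-margin
histopathology positivity ~ Bernoulli(13/385); all configurable. The FAR
call follows a logistic detection model in decay-corrected activity with
separate low/high plateaus for positive margins (sensitivity 1/6 → 5/7) and
negative margins (false-positive rate 19/198 → 49/174), centred at 97 MBq
with width 1 MBq by default — the per-cohort rates observed clinically,
which make the threshold recoverable.

For the calibration experiments the per-specimen tissue background is drawn
from a symmetric truncated normal (mean 56.5, sd 25.3, bounds ±2 sd, so the
mean is preserved exactly) and focal uptake from 1 + Gamma with mean 4 and
sd 2.6 — a moderately right-skewed uptake distribution, chosen so the
population mean and spread of normalised tumour radiance match the
clinically reported 126.7 ± 45.7 while keeping sample means of ~100
specimens well behaved.

What the generator does **not** emulate: ⁹⁹ᵐTc down-scatter, scintillator
positioning errors and air gaps, specimen flattening, reader variability,
within-patient correlation of margin status. Passing tests therefore show
the *analysis chain* is correct under its stated model, not that the model
captures every nuisance of real acquisitions.

## Threshold selection

The ROC sweep tabulates, for every threshold T on a 1 MBq grid spanning
the observed decay-corrected activities, the margin-level confusion matrix
restricted to patients with activity ≥ T, recording subgroup sensitivity
and specificity. This is not a standard classifier ROC and is reported as
such. Two selection criteria are available:

- `"lr"` (default): the maximally selected binomial likelihood-ratio split
  statistic, stratified by histopathology status — the changepoint profile
  of the two detection rates. With few positive margins (≈ 40 in a
  200-patient cohort at clinical prevalence) this localises a 97 MBq
  detection step to within a few MBq.
- `"youden"`: maximise J = sensitivity + specificity − 1 of the ≥ T
  subgroup, ties to the lowest T. Retained for reference, but with a step
  detection model E[J] is flat above the step and deep-tail subgroups
  containing a handful of positives routinely reach sensitivity 1 by
  chance, so the argmax does not concentrate: in simulation this rule
  recovers a 97 MBq step within ±5 MBq in only ~10% of replicates, versus
  ~100% for `"lr"`.

A cohort with no positive (or no negative) margins returns the curve with
selection marked undefined.

## Diagnostic statistics

Sensitivity, specificity and accuracy carry exact Clopper–Pearson 95%
intervals (beta-quantile tail inversion, verified against a numerical
binomial-tail oracle). Predictive values default to logit-transformed
normal intervals — the exact method is not the convention for post-test
probabilities — and the interval method is always labelled in the output;
it is configurable because the method behind published predictive-value
intervals is often unstated. Metrics with zero denominators are explicit
nulls, never 0% or 100%; predictive values are additionally undefined in
strata with no condition positives (resp. negatives), mirroring a
zero-prevalence stratum where no diagnostic performance can be
established. Rate ratios compare per-margin event rates (tp/total,
fp/total) between cohorts. Percentages are reported to one decimal place,
half-up; interval bounds to two.

## Problem sizes and numerical choices

Default phantom grids are 384×384 native pixels (48×48 processed), large
enough for a 10 mm focus plus its 4σ smoothing support inside an 18×15 mm
semi-axis specimen. The calibration experiment uses 100 focus-bearing
specimens (plus 50 focus-free specimens for the background estimate in the
acceptance script) and the threshold-recovery experiment 50 replicates of
200-patient cohorts; both complete in seconds. Ties in threshold selection
break to the lowest threshold; selection scores are compared with a 10⁻¹²
guard against float noise. Degenerate inputs (empty ROIs, empty strata,
all-negative cohorts, non-divisible frame shapes) are rejected or reported
explicitly rather than silently coerced.

## Known limitations

- The artifact triage is heuristic and tuned to the three documented
  morphologies; it is not a learned classifier and will not generalise to
  unseen artifact types.
- The 2-D projection cannot distinguish anterior/posterior faces within a
  single view; margin naming is a convention carried by the sector maps.
- Absolute radiometry is out of scope: gain is a configuration parameter,
  not a calibration against a physical standard.
- The changepoint selection criterion assumes detection rates change at a
  single activity threshold; gradual dose-response curves will yield a
  defensible but model-dependent operating point.
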