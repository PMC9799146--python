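# Methods

`cordmap` re-implements, as a tested library, the analysis chain used to map
muscle responses to epidural electrical stimulation of the human cervical
spinal cord during surgery: evoked-EMG sweeps → per-MEP features → artifact
rejection → recruitment-curve fits → midline-vs-lateral statistics →
segments × muscles activation map → waveform similarity.  Because the
patient recordings such a pipeline consumes are not publicly deposited, the
package ships a synthetic cohort generator with known ground truth; every
stage is validated against that ground truth or against independent
numerical oracles.

## MEP quantification

A motor evoked potential (MEP) is quantified by the rectified area under
the curve (AUC, µV·s) of the baseline-corrected trace in a window
**6.5–75 ms after the first stimulation pulse**, integrated by the
trapezoid rule at the native sampling rate (6–10.4 kHz).  The baseline is
the mean of a 25 ms pre-stimulus interval ending 2 ms before the pulse;
the window reference is always the *first* pulse of the (usually triple)
train.  Peak-peak amplitude is max − min of the same baseline-corrected
window.

Presence of an MEP is defined on the AUC scale as the AUC-equivalent of the
conventional 50 µV peak-peak criterion: ordinary least squares of AUC on
peak-peak (with intercept), evaluated at 50 µV.  On representative data
this calibration lands at ≈ 0.33 µVs, which is the default presence
threshold throughout the mapping stages.

Onset latency is computed on site-average waveforms (never single sweeps):
the first sample whose absolute value strictly exceeds 10 µV, searched from
the start of the analysis window; polarity is ignored because a
"deflection" can go either way.  Absence is a valid outcome, not an error.

## Artifact rejection

For each (participant, muscle, side, segment, electrode-position) group,
pooled across stimulation intensities, windowed waveforms are ranked by
dissimilarity to the group's principal MEP shape: principal components are
computed, every waveform is regressed on the leading components, and the
RMS of the regression residual sorts the sweeps (most artifact-like first).
The number of components is the smallest explaining ≥ 95 % of variance,
capped at 5.

One deliberate design choice: the components are **estimated on the half of
the group closest (RMS) to the pointwise-median waveform**, then all sweeps
are regressed on them.  A plain PCA of the full group lets a single large
artifact *become* the first principal component, which zeroes its own
residual — with 10 identical clean sweeps plus one drift-contaminated
sweep, full-group PCA ranks nothing, while the robust fit isolates the
contaminated sweep immediately.  The median-trimmed fit is robust to up to
half the group being contaminated and leaves the clean-data behavior
unchanged.

The original procedure ended with a human observer adjusting a slider; here
the cutoff is an explicit parameter, either a fraction of sweeps or an
absolute RMS level, recorded in the run log.  Cohort-level cutoffs are
applied on *within-group median-normalized* RMS values, because large-MEP
groups have proportionally larger residuals and a per-group fractional
cutoff on 15–25-sweep blocks rounds to zero rejections.  The pipeline
default (1.5 %) reflects the rejection rate observed in practice for this
kind of intraoperative recording.

## Recruitment curves

MEP size vs stimulus intensity x (mA) is modeled as a softplus,

    y = o + (b / k) · log(1 + exp(k · (x − x_th))),

with offset o (µVs), slope b (µVs/mA), threshold x_th (mA) and k = 20
fixed, applied to x in mA on the 0–8 mA tested range.  At k = 20 the curve
is within 1 part in 10^9 of the rectified line b·(x − x_th) one mA past
threshold, while staying smooth at the threshold; saturating forms are
deliberately out of scope (saturation is rare at intraoperative safety
limits).  `log1p(exp(·))` is computed with `logaddexp` so the linear regime
never overflows.

Within each (participant, muscle, side), all electrode locations are fit
**jointly with one shared offset** — some recordings never tested a
sub-threshold intensity, so a per-location offset is not identifiable.  The
summed squared residual is minimized by a generalized pattern search:
coordinate polling with mesh starting at 0.5 (mA or µVs per coordinate),
expansion ×2 on success (capped at the start size), contraction ×0.5 on
failure, termination when every mesh falls below 1e-4.  Starts: o₀ = min
AUC, x_th₀ = intensity at half-max, b₀ = slope of the upper half of the
tested intensities; 5 multi-starts jittered from a fixed seed table keep
the procedure deterministic and independent of caller RNG state.  Bounds:
o ≥ 0, b ≥ 0, x_th ∈ [−1, 9] mA; threshold estimates on a bound, or with
slope collapsed to 0 (flat data), are flagged `threshold_identifiable =
False` and excluded from ratio statistics.

A consequence of rectification worth knowing: with trace noise of standard
deviation σ, the rectified AUC of a sub-threshold sweep is not the planted
offset but ≈ σ·√(2/π)·T (T the window length — about 0.16 µVs at σ = 3 µV),
and the fitted shared offset absorbs this noise floor.  This mirrors real
recordings, where the recruitment-curve offset likewise soaks up the
rectified noise baseline; it also means fitted offsets on noisy synthetic
cohorts sit above the planted values by design, and weakly responding
muscles near the floor carry little threshold information.  Hardware
clipping at ±0.5 mV additionally saturates the largest MEPs and biases
their fitted slopes downward, as it does in practice.

Midline-vs-lateral effect sizes are summarized per participant as
midline_threshold / lateral_threshold and lateral_slope / midline_slope,
averaged across segments, muscles and sides, with group-level Wilcoxon
signed-rank tests on the paired differences.

## Group statistics

All tests are nonparametric and two-sided at α = 0.05.  The rank-sum
(Mann–Whitney) test is computed exactly for combined n ≤ 12 without ties,
otherwise by normal approximation with tie and continuity correction; the
signed-rank test drops zero differences (counted in the log) and is exact
for n ≤ 15 remaining pairs without tied magnitudes.  Both exact branches
are verified in the test suite against full enumeration.  Per-participant
midline-vs-lateral comparisons are Bonferroni-corrected for the number of
included participants.  Descriptives are reported as mean ± 2 × SE.

The design-stage sample size for a paired Wilcoxon comparison solves the
noncentral-t power equation for the paired t-test as a continuous root
(d = 0.97, α = 0.05 two-sided, power 0.90 → n_t ≈ 13.24), divides by the
asymptotic relative efficiency of the Wilcoxon test under a normal parent
(3/π), and rounds up once at the end — giving 14.  Rounding the t-step to
an integer first would give 15; the continuous-then-ceil convention is the
one consistent with the published design value.  The distribution-free
worst-case ARE (0.864) is available by flag.

## Segmental map, similarity, gradients

The activation map is a segments (C4→T1) × muscles grid of fixed-intensity
AUCs: per-participant arithmetic means per cell, combined across
participants by the **geometric mean** (MEP sizes are approximately
log-normal across people; the map is read on a log scale).  Zero cells are
replaced by half the presence threshold (0.165 µVs) before log-averaging,
with the substitution count logged; cells without any contributing
participant are missing, not zero.  Map summaries suppress cells at or
below 0.33 µVs and report surviving muscles as per-segment percentages of
total AUC; segments with nothing above threshold are reported empty.

Cross-segment similarity is the Spearman rank correlation between two
segments' muscle-AUC vectors (arm and hand muscles), computed per
participant and averaged arithmetically across participants (Fisher-z
averaging available by flag); pairs with fewer than 3 shared muscles are
excluded.  Segments are clustered by single-linkage agglomeration on the
distance 1 − correlation, with flat clusters cut at 70 % of the maximum
merge height.  Single linkage is the conservative choice: merge heights
reflect the *closest* pair between clusters.

Sensitivity re-analysis excludes all responses from (participant, segment)
pairs flagged for T2 signal change or severe foraminal stenosis and reports
the Pearson correlation between the group maps with and without exclusion.

Per-mm gradients convert AUC differences into µVs/mm using cadaveric
normalizers: 12.5 mm between neighboring cervical roots (rostro-caudal) and
6.7 mm from midline to the root entry zone (midline-lateral).  Per muscle,
the segment of maximum lateral AUC is found (ties broken toward the more
caudal segment — a deterministic rule, logged), differences to the
adjacent segment(s) are averaged and divided by 12.5 mm, and the
(lateral − midline) difference at the maximum segment is divided by
6.7 mm.  Differences are signed, as in the source procedure: the
rostro-caudal value is non-negative by the max construction, and the
midline-lateral value is positive whenever lateral stimulation is more
effective.  Muscle values are averaged within participants and contrasted
with a signed-rank test.

## Waveform similarity

MEP shape depends on MEP size, so waveforms are compared only after size
matching: a fixed-intensity site-average MEP is paired with the
recruitment-curve site-average of closest AUC, accepted only if the
difference is < 0.5 µVs (ties broken by earliest acquisition time).
Similarity is the maximum Pearson correlation over time lags within
±12.5 ms on the native sample grid (≤ 0.167 ms resolution at ≥ 6 kHz — no
sub-sample interpolation, which is finer than any effect of interest);
lags with less than 50 % overlap are not tested, and constant waveforms
yield an undefined (None) correlation rather than a number.  Correlations
are computed on baseline-corrected averages (Pearson is offset-invariant,
so this is for transparency only).  Latency differences use the 10 µV
onset criterion on the same averages.  Midline-lateral pairs are contrasted
with pooled rostro-caudal pairs (muscles treated as independent units); an
outside condition is located in the midline-lateral similarity distribution
by percentile (strictly-smaller counting, ties count half).

## Synthetic cohorts — what they emulate and what they do not

`generate_cohort` emulates the intraoperative protocol: per participant, an
intensity ramp 0–8 mA (≥ 5 MEPs per intensity) at the most caudal exposed
segment for midline then lateral electrode positions, followed by
15-sweep fixed-intensity blocks at 120 % of the simulated midline threshold
at every exposed segment and both positions, one stimulation event every
2 s; triple-pulse stimulation; 6 kHz sampling by default; hardware clipping
at ±500 µV.

Ground truth is planted on the AUC scale: each (participant, muscle,
segment, position) carries softplus parameters.  The lateral advantage is
planted both as a threshold shift (midline = lateral + 1.9 mA) and a slope
attenuation (midline = 0.75 × lateral), matching the observation that
lateral stimulation has both lower threshold (≈ +107 % midline/lateral)
and steeper recruitment (≈ +34 % lateral/midline).  Segmental tuning is a
Gaussian profile (σ ≈ 1.2 segments) around each muscle's innervation
center (deltoid/biceps C5, triceps C7, ADM/FDI C8, APB T1 — the six-muscle
montage is configurable because clinical montages vary); leg muscles
respond in a subset of participants without segmental tuning, emulating
propriospinal spread.  Latencies increase arm < hand < leg.  MEP waveforms
are decaying-sinusoid templates whose amplitude is solved so the rectified
windowed integral equals the target AUC exactly — with all noise sources
off, downstream AUC reproduces the planted softplus values to machine
precision (hardware-clipped sweeps excepted).  Band-limited (10–2,000 Hz)
Gaussian noise models the acquisition character; there is no explicit
causal filter because filtering happened in hardware, not analysis.

Noise knobs: `noise_sd` (trace noise, default 3 µV), `auc_cv`
(trial-to-trial MEP size variability, default 0.2 — separate from trace
noise so the noiseless regime is reachable by zeroing both), and
`artifact_rate` (default 0.015, the contamination rate typical of this
setting) with four contamination classes: baseline drift ramp, decaying
stimulation-artifact tail, 60 Hz burst, and a non-time-locked transient.
Every contaminated sweep carries a ground-truth label for rejection tests.

The generator does **not** model volume conduction, axon recruitment
physics, anesthetic depth, motor-unit structure, or inter-muscle
correlation beyond the planted tuning curves.  A green test on synthetic
cohorts therefore establishes that the *analysis* recovers what was
planted — not that the physiological claims hold; the published headline
percentages from patient data serve only as qualitative direction checks
here.

## Numerical conventions and degenerate inputs

- AUC/peak-peak windows exceeding the trace raise errors naming the sweep.
- Identical ranked residuals (e.g. identical sweeps) order by ascending
  sweep id; all rejection cutoffs are deterministic.
- Flat recruitment data fit slope 0 with an unidentifiable-threshold flag;
  all-identical intensities raise.
- All-zero paired differences give p = 1 with a warning.
- Lag-correlation ties break toward the smallest |lag|, then the smaller
  lag, making best_lag(w1, w2) = −best_lag(w2, w1).
- Reports serialize floats rounded to 10 decimals so identical runs are
  byte-identical.

## Known limitations

- The pattern search is a local optimizer; the fixed multi-start table
  makes it deterministic but global recovery is only verified for the
  realistic parameter ranges exercised in the tests.
- Cohort-level rejection assumes group RMS distributions are comparable
  after median normalization; heavily heterogeneous groups may deserve an
  absolute RMS threshold instead.
- The synthetic latency model plants one template per (participant,
  muscle); latency *differences* across conditions are therefore centered
  at zero by construction, which is exactly what the centering test
  verifies, no more.
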