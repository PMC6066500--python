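# Methods

This note documents the models, estimators, and design choices behind
`eegtrack`, in the spirit of a statistical package's methods appendix: what
is computed, under which assumptions, which knobs matter, and what the
synthetic test bench does and does not establish about real data.

## 1. Coherence estimation

**Estimator.** The continuous recording is cut into non-overlapping 1-s
epochs; each kept epoch is Hann-windowed and Fourier-transformed per lead.
Auto- and cross-spectra are means of the per-epoch (cross-)periodograms
over the M kept epochs, giving 1 Hz resolution. Magnitude-squared
coherence per bin is `|S_ij|² / (S_ii S_jj)`; a band value is the
arithmetic mean over all bins with `f_lo ≤ f ≤ f_hi`, endpoints inclusive
(20–30 Hz → 11 bins). An ROI-pair value averages the per-lead-pair band
values over all cross-ROI pairs, excluding any lead shared by both ROIs
(7 × 21 = 147 pairs for the default primary circuit). Pair-averaging is
the default; coherence between ROI-mean signals is available as
`aggregate="roi_mean"` for sensitivity analysis — ROI-averaging signals
before coherence rewards within-ROI phase alignment and typically yields
different absolute values.

**Known estimator properties.** For independent signals the estimator's
expectation is ≈ 1/M (0.0056 at M = 180), not zero; tests therefore bound
independent-noise band coherence at 0.03 rather than 0. The estimator is
invariant to per-lead scaling and to any filter applied identically to
both leads, which is why the 50 Hz low-pass does not bias in-band values.

**Band definitions.** delta 1–4, theta 4–8, alpha 8–13, low beta 13–20,
high beta 20–30 Hz. These are conventional edges (the analysis that
motivated the package prints only the high-beta edges); they are
configurable, and adjacent bands intentionally share their boundary bin
under the inclusive-endpoints rule.

## 2. Preprocessing chain

Fixed order, logged in each epoch set's provenance:
common-average re-reference → zero-phase low-pass (−3 dB at 50 Hz after
forward–backward application of a 6th-order Butterworth whose design
corner is pre-warped so the *combined* response hits −3 dB at 50 Hz;
−30 dB by 100 Hz) → 1-s epochs with closed-form linear detrend (trailing
partial second discarded) → epoch rejection at a 100 µV peak-amplitude
ceiling → ICA → component rejection → reconstruction.

**Why an amplitude gate at 100 µV.** The original workflow used visual
inspection to drop epochs with overt muscle and movement artifact; visual
inspection is not reproducible, so an explicit peak-amplitude criterion
stands in for it. 100 µV sits ~3× above the synthetic background's
per-epoch peaks, so clean epochs essentially never trip it, while
blink-scale deflections (hundreds of µV in real EEG) do.

**ICA.** Components are extracted in a PCA-whitened space whose dimension
defaults to the numerical rank (capped at 64 for dense montages).
The default algorithm is FastICA; extended Infomax (via MNE) is available
as `method="infomax"` and produces equivalent rejections on the synthetic
bench, at roughly an order of magnitude more compute — FastICA is the
default because the package's test bench and batch pipelines run hundreds
of decompositions. Whitened directions spanning the Gaussian background
subspace have no identifiable rotation and may not satisfy FastICA's
convergence tolerance; this is expected and harmless (the non-Gaussian
artifact directions converge first), so the convergence warning is
suppressed inside `decompose_ica`.

**Component rejection rules.** Two automatic rules, applied independently:
*single-channel* — one lead carries > τ_single (default 0.8) of the total
absolute mixing weight; *muscle band* — more than τ_muscle (default 0.5)
of the source's 1–50 Hz Welch power lies in 35–50 Hz. Stereotyped
artifacts (blinks, lateral eye movements, cardiac rhythm) are flagged by
template matching: absolute topography correlation > 0.9 plus a spectral
gate (spectral centroid < 8 Hz for ocular classes; a dominant
autocorrelation period within 20% of the beat period for cardiac). On
synthetic data the templates are the generator's ground-truth mixing
vectors; on real data they would be user-supplied canonical topographies.
Topography correlation is computed with mean removal, so templates defined
before or after average-referencing match equally.

**Order caveat.** ICA is fit on the epochs surviving amplitude rejection
only; reconstruction rebuilds exactly those epochs, and rejected epochs
stay excluded downstream.

## 3. The synthetic EEG model

Each lead carries an independent 1/f Gaussian background (PSD
`n₀ / max(f, 1 Hz)`, default n₀ = 16 µV²/Hz, ≈ 9 µV RMS — a deliberately
clean resting recording). A single shared source, band-limited to
20–30 Hz with flat in-band PSD scaled to `snr_band` (default 9) times the
in-band background power, is projected onto the seed leads with unit
weight and onto the parietal leads with weight γ ∈ [0, 1].

**Zero-sum source topographies.** Within each ROI the projection follows a
dipolar, zero-sum pattern (half the leads positive, half negative with a
compensating magnitude). Scalp topographies of cortical sources are
approximately zero-mean across a dense montage, and the zero-sum property
makes the common-average reference exactly transparent to the source:
without it, the re-reference smears `w̄·s(t)` onto every lead and all
"control" circuits inherit γ-dependent coherence — a referencing confound,
not connectivity. The per-pair closed form
`C(f) = (w_i w_j S)² / ((w_i² S + N)(w_j² S + N))` holds for arbitrary
pair weights, so the ROI-pair ground truth is the mean of this expression
over lead pairs and in-band bins.

**Two ground-truth values per subject.** `coherence_plain` is the raw
closed form above. `coherence_expected` convolves the model PSDs with the
1-s Hann window's spectral kernel before forming the ratio — i.e., it is
the expectation of the actual estimator, which is slightly lower because
the edge bins (20 and 30 Hz) leak power from outside the band
(e.g. plain 0.80 → expected ≈ 0.77 at 180 s). Recovery tests compare
estimates to the expectation form; with average referencing the
expectation also folds in the small `−N/L` cross and `(1−1/L)N` auto
terms the subtracted mean background contributes.

**Artifacts.** Five classes with known topographies and sources: blink
(frontal Gaussian topography, 0.3-s smooth bursts at 0.4/s, 120 µV peak —
realistically large, so the amplitude gate removes most blink epochs);
saccade-like eye movements (lateral frontal gradient, smoothed level
steps); muscle (temporal/neck edge patch, 25–50 Hz carrier with a
linearly rising spectrum so most power sits in the 35–50 Hz flag window,
amplitude-modulated by multi-second contraction bursts); cardiac (1.2 Hz
train of sharp biphasic ~30 ms pulses whose harmonics reach the beta
band, on a fixed center–rim polarity field touching every lead — the one
class that inflates inter-regional band coherence if left in); and a
single-channel spike train on a non-ROI lead. Amplitudes (other than
blink) are sized to ride below the 100 µV gate so that the ICA stage, not
the gate, is what must remove them.

**What the artifact bench shows and does not.** The model's background is
spatially white (independent per lead), which makes the mixture
overcomplete — each ICA component necessarily carries some lead noise, so
"100% artifact removal" is information-theoretically unreachable, exactly
as with real data. Artifact suppression is therefore measured as the
matched-filter residual of the *injected* artifact signal in the cleaned
epochs (how much of the known artifact waveform survives the chain),
which is the quantity a user cares about; it does not claim the removed
components contained nothing else. Real EEG has spatially structured
backgrounds, other artifact morphologies, nonstationarity, and no
ground-truth templates, so passing this bench demonstrates the machinery
is correct, not that any particular clinical recording will be cleaned
this well.

## 4. Tracking task model

The target traverses a four-lobed rose curve `r = A sin 2θ`
(A = 220 px, centered at 320 × 240) at constant path speed — the curve is
arc-length parameterized on a dense grid so "speed in pixels/s" is exact.
The cursor is a lagged pursuit: `cursor(t) = target(t − λ) + N(0, σ²I)`
per 30 Hz sample, with lag and jitter both shrinking exponentially with a
scalar skill: λ = 0.30 e^(−skill) s, σ = 50 e^(−skill) px. Cursor–target
distance is then approximately Rice-distributed with noncentrality
v·λ/σ, which gives the SR-versus-speed curve its sigmoidal shape without
building it in by hand.

**Calibration.** Eight 30-s rounds at speeds 150–1400 px/s produce
(speed, SR) points; a decreasing four-parameter logistic
`SR(v) = L + (U−L)/(1 + e^((v−v50)/s))` is least-squares fitted; the
maximum-error speed is where the fitted curve has completed 95% of its
fall (`v50 + s·ln 19`, the 95%-approach to the lower asymptote — the
"speed associated with maximum error" has no printed formula, and an
asymptote is never attained exactly); the training speed is 60% of that,
exactly. Degenerate round sets (all-equal SR, no low-SR regime) are
errors, not extrapolations.

**Learning gains.** Per subject, γᵢ ~ U(0.05, 0.6) and
Δᵢ = a + b·γᵢ + εᵢ with a = 2, b = 70, sd(ε) = 12 (percent), chosen so
gains average ≈ 24% with a sd in the teens, in the vicinity of the
modeled study's 24.2 ± 21.9%. The coupling range itself is a free choice
(the source analysis prints no coherence distribution). Pre-training
skill is fixed across subjects at 1.75, which lands baseline SR near 60%
at the calibrated speed. The post-training skill is found by numerically
inverting the skill→SR map: the map is evaluated on a fixed
common-random-numbers trace family (making it deterministic and monotone
in skill) and solved by bisection for the target
`SR_post = SR_pre · (1 + Δᵢ/100)`; targets above 99.5% SR are clipped
and flagged in the ground truth. Baseline coupling is independent of
baseline skill by construction, mirroring the modeled study's null
baseline relation.

**Lesions.** Toy 24³ voxel volumes (2 mm isotropic) with three fixed
critical-region blobs (precentral gyrus, superior and inferior parietal
lobules). Every subject receives a lesion blob; the first `n_lesioned`
(default 4 of 12) subjects' lesions are centered on a critical region,
the rest elsewhere. Exclusion is any nonzero critical-ROI overlap, with a
configurable minimum-percent override. Registration is out of scope —
masks are consumed co-registered, guarded by a `space_tag` equality
check.

## 5. Statistics

**Spearman.** r is the Pearson correlation of mid-ranks. Two-sided p by
full permutation enumeration for n ≤ 9 (exact, conditional on the
observed tie pattern) and by the t approximation with n − 2 df above
that; |r| = 1 in the approximate branch falls back to the minimal
attainable 2/n!. The method used is recorded in every result.

**Wilcoxon signed-rank.** Zero differences dropped (classic reduction,
count recorded); mid-ranks for tied absolute differences; two-sided p as
the exact null probability of `|W⁺ − μ| ≥ |w − μ|` computed by
convolution over the 2ⁿ sign assignments for n ≤ 20 (doubled ranks keep
the support integral under mid-ranks), tie-corrected normal approximation
with continuity correction beyond. At the study's n = 12 the exact branch
applies; its discreteness makes the test conservative (realized size
≈ 4% at nominal 5%), which the type-I acceptance band accommodates.

**Multiple testing.** Per-test α = 0.05 with no correction across the
circuit × band table, matching the modeled analysis; a Holm-adjusted
column is emitted for reference but does not drive any headline decision,
and the summary states how many tests were run.

**Model layer.** `TrainingGainModel` fits the prediction table for the
full and lesion-excluded cohorts (the latter only when ≥ 4 subjects
remain), the SR/ER change tests with mean ± sd of percent change, and the
baseline descriptives (coherence vs baseline scores; baseline SR vs ER).

## 6. Problem sizes used in the test bench

The acceptance-style tests run the full machinery at sizes chosen to keep
the whole suite in the tens of minutes on a single CPU while preserving
every qualitative condition: coherence-recovery uses 50 seeds per
coupling target on 61-lead, 180-s recordings (the full recording length;
the lead count is the 5-ring synthetic layout rather than a 256-lead
net); artifact-robustness uses 50 replicates of 19-lead, 60-s recordings
with all five artifact classes; end-to-end recovery uses 100 cohorts of
n = 12 with 37-lead, 30-s EEG and 45-s tracking runs, and the null
(b = 0) calibration uses 400 cohorts at 19 leads / 15 s. Estimator error
at these sizes is documented by the tests themselves (median coherence
recovery error ≈ 0.005, well inside the 0.03 bound). ICA is exercised in
the artifact bench and the acceptance script's cohort analysis; the
100-cohort recovery loop runs artifact-free and skips ICA, since its
question is the brain–behavior link, not cleaning.

## 7. Numerical choices and degenerate inputs

- Coherence is undefined at M = 1 (the estimator is identically 1) and on
  any band bin with zero auto-power; both are errors naming the cause.
- The hexagonal montage's neighbor graph uses exact unit-distance
  adjacency; user CSV montages fall back to a distance rule (≤ 1.5× the
  minimum inter-lead spacing). Seed-ROI ties beyond the six nearest
  neighbors break deterministically by distance then label order.
- The EDF writer stores 16-bit samples with per-lead physical scaling
  re-parsed from the header strings it writes, so a round trip through
  any conforming reader reproduces values to one quantization step;
  recordings are trimmed to whole seconds.
- Synthetic EEG is synthesized in single precision (the tightest
  downstream tolerance is ~10⁻² on coherence); all analysis arithmetic is
  double precision.
- Percent change is undefined at a zero baseline (error), and the ER
  score clips distances at d_ref = 128 px (4× the success radius) before
  normalizing — the distance-weighted error used by the original system
  is not recoverable from its description, so the package uses this
  bounded, monotone variant and exposes d_ref.

## 8. Known limitations

- The generator's coupling is a single shared band-limited source; real
  coherence arises from distributed, nonstationary dynamics and volume
  conduction, none of which are modeled.
- ROI lead sets are configuration; no claim is made that the synthetic
  hexagonal layout's patches correspond to the vendor net's geometry.
- The lesion volumes are geometric toys for exercising overlap and
  exclusion arithmetic, not anatomy.
- The package reproduces an analysis design, not a cohort: published
  cohort-level numbers depend on 12 real subjects whose individual data
  are unavailable, so tests verify recovery of *known synthetic* links,
  specificity, and calibration instead.
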