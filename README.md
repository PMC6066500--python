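# eegtrack

Resting-state EEG frontoparietal coherence and visuomotor pursuit-tracking
analysis, with a fully synthetic study-cohort generator.

## The problem

After a hemiparetic stroke, patients vary enormously in how much they gain
from rehabilitation training, and predictors of individual treatment
response are needed. One candidate predictor is *functional connectivity*
of the frontoparietal circuit measured at rest with dense-array EEG:
magnitude-squared coherence in the high beta band (20–30 Hz) between leads
overlying the ipsilesional primary motor cortex (iM1: the C3-equivalent
seed lead plus its six immediately surrounding electrodes) and an
ipsilesional lateral parietal region (iPAR: 21 leads). The behavioral
outcome is skill on a pursuit-tracking task: a target moves along a
cloverleaf path at a per-subject calibrated speed, and the Success Rate
(SR) score is the percent of 30 Hz samples on which the cursor–target
Euclidean distance is strictly below 32 pixels. The question the package
operationalizes: does baseline iM1–iPAR high-beta coherence predict the
relative pre-to-post training gain in SR — and is that prediction specific
to this circuit and this band?

`eegtrack` implements the full analysis chain as a tested, reusable
library:

- **montage** — electrode layouts, neighbor graphs, named ROI lead sets
  (configuration, not hard-coded vendor geometry), plus a dense hexagonal
  synthetic layout;
- **preprocess** — average re-reference, zero-phase 50 Hz low-pass, 1-s
  epoching with linear detrend, amplitude-based epoch rejection, ICA with
  automatic component rejection (single-channel topographies, 35–50 Hz
  muscle band) and template matching for stereotyped artifacts;
- **coherence** — epoch-averaged Hann periodogram spectra;
  `C_ij(f) = |S_ij|² / (S_ii S_jj)` per 1 Hz bin, band-averaged and
  pair-averaged over ROI lead pairs;
- **behavior** — SR/ER scoring, the sigmoidal speed-calibration fit
  (training speed = 60% of the fitted maximum-error speed), percent-change
  arithmetic;
- **lesion** — infarct/ROI overlap percentages and the "any damage to iM1
  or iPAR" exclusion flags for the secondary analysis;
- **stats / model** — Spearman rank correlation (exact permutation p for
  n ≤ 9) and the Wilcoxon signed-rank test (exact sign-enumeration p for
  n ≤ 20), wrapped in a statsmodels-style `TrainingGainModel` whose
  `fit()` returns a results object with the circuit × band prediction
  table, within-subject change tests, and a text `summary()`;
- **simulate** — a generative model of the whole study with closed-form
  ground truth, so every stage is verifiable without real recordings.

Because no recordings are published for the modeled study, the synthetic
cohort is the test bench: per-subject coupling γ drives both the analytic
band coherence (via a linear source-mixing model) and the true learning
gain (Δᵢ = a + b·γᵢ + εᵢ), and the pipeline's job is to recover that link
from raw simulated data.

## Worked example

```python
from eegtrack import SimulationConfig, generate_cohort
from eegtrack.pipeline import analyze_cohort
from eegtrack.preprocess import PreprocessConfig
from eegtrack.simulate import DEFAULT_ARTIFACT_AMPLITUDES

cfg = SimulationConfig(rng_seed=1, n_rings=4, duration_s=60.0,
                       artifact_amplitudes=DEFAULT_ARTIFACT_AMPLITUDES)
cohort = generate_cohort(cfg)                    # 12 subjects
records, results = analyze_cohort(cohort, PreprocessConfig())
print(results.summary())
```

prints (abridged):

```
Training-gain prediction from baseline band coherence
====================================================================
Subjects: 12   endpoint: % change in SR score   alpha: 0.05 (uncorrected)
Primary circuit: iM1-iPAR   band: high_beta
Primary Spearman r = +0.552, p = 0.0625 (t-approximation, n=12)
...
Lesion-excluded cohort (n=8): primary r = +0.595, p = 0.1323

Within-subject change (Wilcoxon signed-rank)
--------------------------------------------------------------------
SR: 63.1±1.8 -> 77.6±11.0  gain +23.0±16.4%  p=0.0005
ER: 22.8±0.3 -> 20.3±2.0  gain +10.8±8.1%  p=0.0005
```

The primary row is the brain–behavior readout: baseline iM1–iPAR
high-beta coherence versus % change in SR score across the 12 synthetic
subjects (this cohort's own ground-truth γ–Δ rank correlation is +0.48,
so the pipeline recovered the planted link faithfully — including its
strengthening when the four lesioned subjects are excluded). Control
circuits (contralesional M1/PAR, premotor, prefrontal, medial parietal,
primary visual) stay near zero. The change table shows the cohort
improved on both tracking scores; for the error-rate score a falling
value is signed as a positive gain. `results.plot_primary()` draws the
coherence-vs-gain scatter with lesion-excluded subjects in gray.

A command-line interface wraps the same functions
(`eegtrack simulate / analyze / score-trace / calibrate / coherence /
predict`); `eegtrack simulate --seed 1 --out cohort/` writes EDF
recordings, tracking-trace CSVs, NIfTI lesion masks, ground-truth JSON,
and a content-hash manifest, and `eegtrack analyze --in cohort/ --out
report/` reproduces the analysis from those files alone.

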