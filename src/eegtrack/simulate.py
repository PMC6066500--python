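"""Synthetic study-cohort generator with analytic ground truth.

Every stage of the analysis is made verifiable without real recordings:

* **Resting EEG** is built from a linear source-mixing model.  A single
  band-limited (20–30 Hz) source is projected with weight 1 onto the motor
  seed leads and weight ``gamma`` onto the parietal leads; every lead also
  carries an independent 1/f background.  Because the model is linear and
  Gaussian, the inter-regional band coherence implied by the mixing weights
  has a closed form, which is stored as ground truth — both in its plain
  form and as the expectation of the Hann-windowed 1-s-epoch estimator
  (band-edge leakage makes the latter slightly lower), optionally under the
  common-average reference.
* **Stereotyped artifacts** — frontal blink bursts, saccade-like lateral
  eye-movement steps, burst-modulated broadband (25–50 Hz) muscle activity
  over one temporal/neck edge, a periodic ~1.2 Hz cardiac pulse train whose
  sharp beats carry beta-band harmonics on a fixed center–rim topography,
  and a single-channel spike train — are added with known topographies and
  source time courses.
* **Tracking behavior**: the target follows a four-lobed rose curve
  (``r = A sin 2θ``) traversed at constant path speed; the cursor is a
  lagged pursuit with Gaussian jitter, lag and jitter both shrinking
  exponentially with a scalar skill.  Per-subject learning gains follow
  ``Δ_i = a + b·γ_i + ε_i`` and are realized by numerically inverting the
  skill→SR map on the simulated trace family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import behavior
from .behavior import TrackingTrace, fit_calibration
from .montage import Montage, RoiSet, build_synthetic_montage, default_roi_config
from .preprocess import ArtifactTemplate, Recording

__all__ = [
    "SimulationConfig",
    "SubjectTruth",
    "SubjectData",
    "Cohort",
    "noise_psd",
    "source_psd",
    "analytic_band_coherence",
    "expected_band_coherence",
    "gamma_for_coherence",
    "generate_subject_eeg",
    "generate_tracking_session",
    "generate_cohort",
]

HIGH_BETA = (20.0, 30.0)

#: Default stereotyped-artifact amplitudes (microvolt scales per class),
#: sized to ride below the 100 uV epoch-rejection ceiling so the ICA stage,
#: not the amplitude gate, is what removes them.
DEFAULT_ARTIFACT_AMPLITUDES = {
    "blink": 120.0,       # peak (large, as real blinks are; caught by the epoch gate)
    "eye_movement": 25.0, # step amplitude
    "muscle": 24.0,       # overall RMS including silent periods
    "cardiac": 80.0,      # pulse peak
    "spike": 40.0,        # spike peak
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the modeled study: 12 subjects, 180 s of resting EEG at
    1,000 samples/s on a dense (5-ring hexagonal, 61-lead) montage, with
    learning gains linearly linked to the 20–30 Hz inter-regional coupling
    ``γ`` (``Δ_i = a + b·γ_i + ε_i``; a=2, b=70, sd(ε)=12 give gains with
    mean ≈ 25% and sd ≈ 16%).
    """

    n_subjects: int = 12
    fs_eeg: float = 1000.0
    duration_s: float = 180.0
    n_rings: int = 5
    coupling_range: tuple[float, float] = (0.05, 0.6)
    link_intercept: float = 2.0     # a, percent gain
    link_slope: float = 70.0        # b, percent gain per unit gamma
    link_noise_sd: float = 12.0     # sd of epsilon, percent gain
    artifact_amplitudes: dict[str, float] | None = None
    rng_seed: int = 0
    # EEG spectral model
    band: tuple[float, float] = HIGH_BETA
    snr_band: float = 9.0           # in-band shared/background power ratio at gamma=1
    noise_level: float = 16.0       # 1/f background PSD scale, uV^2/Hz at 1 Hz
    # behavior
    fs_track: float = 30.0
    pre_skill: float = 1.75   # fixed pre-training skill; puts baseline SR near 60%
    run_duration_s: float = 90.0
    n_runs: int = 3
    calib_speeds: tuple[float, ...] = (150, 300, 450, 600, 750, 950, 1150, 1400)
    calib_round_s: float = 30.0
    calibrate: bool = True
    fixed_speed: float = 650.0      # used when calibrate=False
    # lesions
    n_lesioned: int = 4

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        lo, hi = self.coupling_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("coupling_range must lie within [0, 1]")
        if self.artifact_amplitudes:
            if any(v < 0 for v in self.artifact_amplitudes.values()):
                raise ValueError("artifact amplitudes must be >= 0")

    @property
    def n_leads(self) -> int:
        return 1 + 3 * self.n_rings * (self.n_rings - 1)


# ---------------------------------------------------------------------------
# Spectral model and analytic coherence
# ---------------------------------------------------------------------------

def noise_psd(freqs: np.ndarray, level: float = 16.0) -> np.ndarray:
    """One-sided 1/f background PSD (uV^2/Hz), flattened below 1 Hz."""
    return level / np.maximum(np.asarray(freqs, float), 1.0)


def source_psd(
    freqs: np.ndarray,
    band: tuple[float, float] = HIGH_BETA,
    snr_band: float = 9.0,
    noise_level: float = 16.0,
) -> np.ndarray:
    """Flat band-limited PSD of the shared source.

    Scaled so the in-band shared power is ``snr_band`` times the in-band
    background power (at unit projection weight).
    """
    freqs = np.asarray(freqs, float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("frequency grid does not cover the coupling band")
    level = snr_band * float(noise_psd(freqs[sel], noise_level).mean())
    psd = np.zeros_like(freqs)
    psd[sel] = level
    return psd


def _band_sel(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)


def roi_weight_pattern(n: int) -> np.ndarray:
    """Zero-sum within-ROI source topography with near-unit magnitudes.

    EEG source topographies are (close to) zero-mean across a dense montage;
    giving the coupling source a dipolar, zero-sum pattern inside each ROI
    makes the common-average reference a no-op on the source and keeps it
    off all other leads.  The first ``ceil(n/2)`` leads get +1, the rest get
    the compensating negative value.
    """
    if n < 2:
        raise ValueError("ROI needs >= 2 leads for a zero-sum pattern")
    n_pos = (n + 1) // 2
    w = np.empty(n)
    w[:n_pos] = 1.0
    w[n_pos:] = -n_pos / (n - n_pos)
    return w


def _pair_band_coherence(wa: np.ndarray, wb: np.ndarray, s: np.ndarray, n: np.ndarray) -> float:
    """Mean over ROI lead pairs and band bins of per-pair coherence.

    For pair weights (a, b): C(f) = (a b S)^2 / ((a^2 S + N)(b^2 S + N)).
    """
    a2 = wa[:, None] ** 2  # (nA, 1)
    b2 = wb[None, :] ** 2  # (1, nB)
    num = (a2[:, :, None] * b2[:, :, None]) * s[None, None, :] ** 2
    den = (a2[:, :, None] * s + n) * (b2[:, :, None] * s + n)
    return float(np.mean(num / den))


def analytic_band_coherence(
    gamma: float,
    band: tuple[float, float] = HIGH_BETA,
    snr_band: float = 9.0,
    noise_level: float = 16.0,
    n_seed: int = 7,
    n_par: int = 21,
) -> float:
    """Closed-form ROI-pair band coherence implied by the mixing model.

    Per 1 Hz bin and lead pair, ``C = (w_i w_j S)^2 / ((w_i^2 S + N)(w_j^2
    S + N))`` with the zero-sum seed pattern on the motor leads and ``gamma``
    times the zero-sum pattern on the parietal leads; the value is the mean
    over lead pairs and in-band bins (no spectral windowing).  With
    ``n_seed = n_par = 1`` this reduces to the single-pair closed form —
    e.g. equal shared and independent band power at unit weights gives 1/4.
    """
    freqs = np.arange(1.0, 51.0)
    s = source_psd(freqs, band, snr_band, noise_level)
    n = noise_psd(freqs, noise_level)
    sel = _band_sel(freqs, band)
    wa = roi_weight_pattern(n_seed) if n_seed > 1 else np.ones(1)
    wb = gamma * (roi_weight_pattern(n_par) if n_par > 1 else np.ones(1))
    return _pair_band_coherence(wa, wb, s[sel], n[sel])


def gamma_for_coherence(
    target: float,
    band: tuple[float, float] = HIGH_BETA,
    snr_band: float = 9.0,
    noise_level: float = 16.0,
    n_seed: int = 7,
    n_par: int = 21,
) -> float:
    """Coupling weight whose plain analytic band coherence equals ``target``."""
    if target < 0:
        raise ValueError("target coherence must be >= 0")
    if target == 0:
        return 0.0
    f = lambda g: analytic_band_coherence(g, band, snr_band, noise_level, n_seed, n_par)
    cmax = f(1.0)
    if target >= cmax:
        raise ValueError(f"target {target} exceeds the model maximum {cmax:.3f} at gamma=1")
    return float(brentq(lambda g: f(g) - target, 0.0, 1.0, xtol=1e-12))


def _window_kernel(fs: int, n_total: int) -> np.ndarray:
    """Squared magnitude of the 1-s Hann window's DTFT on the fine FFT grid."""
    from scipy.signal.windows import hann

    w = np.zeros(n_total)
    w[:fs] = hann(fs, sym=False)
    return np.abs(np.fft.fft(w)) ** 2


_EXPECTED_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _windowed_band_psds(fs: float, duration_s: float, band, snr_band, noise_level):
    """Expected windowed-periodogram PSDs at the in-band analysis bins (cached)."""
    key = (round(fs, 6), round(duration_s, 6), band, snr_band, noise_level)
    if key not in _EXPECTED_CACHE:
        fs_i = int(round(fs))
        n_total = int(round(fs * duration_s))
        fine = np.fft.fftfreq(n_total, d=1.0 / fs)
        s_full = source_psd(np.abs(fine), band, snr_band, noise_level)
        n_full = noise_psd(np.abs(fine), noise_level)
        kern = np.fft.fft(_window_kernel(fs_i, n_total))
        es = np.real(np.fft.ifft(np.fft.fft(s_full) * kern))
        en = np.real(np.fft.ifft(np.fft.fft(n_full) * kern))
        # analysis bins sit at integer Hz = multiples of duration_s on the grid
        step = int(round(duration_s))
        kbins = np.arange(int(band[0]), int(band[1]) + 1) * step
        _EXPECTED_CACHE[key] = (es[kbins].copy(), en[kbins].copy())
    return _EXPECTED_CACHE[key]


def expected_band_coherence(
    gamma: float,
    fs: float = 1000.0,
    duration_s: float = 180.0,
    band: tuple[float, float] = HIGH_BETA,
    snr_band: float = 9.0,
    noise_level: float = 16.0,
    average_reference: bool = False,
    n_leads: int = 61,
    n_seed: int = 7,
    n_par: int = 21,
) -> float:
    """Expectation of the Hann-windowed 1-s-epoch coherence estimator.

    The expected windowed periodogram is the model PSD circularly convolved
    with the window's spectral kernel, which lowers band-edge bins relative
    to the plain closed form.  With ``average_reference=True`` the
    common-average reference is folded in analytically: projection weights
    shrink by the across-lead mean weight and the subtracted mean background
    introduces a small shared noise term (``-N/L`` cross, ``(1-1/L)N``
    auto).
    """
    es_b, en_b = _windowed_band_psds(fs, duration_s, band, snr_band, noise_level)
    wa = roi_weight_pattern(n_seed) if n_seed > 1 else np.ones(1)
    wb = gamma * (roi_weight_pattern(n_par) if n_par > 1 else np.ones(1))
    ab = wa[:, None, None] * wb[None, :, None]
    a2 = (wa**2)[:, None, None]
    b2 = (wb**2)[None, :, None]
    if average_reference:
        # zero-sum source patterns pass the average reference unchanged; the
        # subtracted mean background adds -N/L cross and (1-1/L)N auto terms
        cross = ab * es_b - en_b / n_leads
        auto_a = a2 * es_b + en_b * (1.0 - 1.0 / n_leads)
        auto_b = b2 * es_b + en_b * (1.0 - 1.0 / n_leads)
    else:
        cross = ab * es_b
        auto_a = a2 * es_b + en_b
        auto_b = b2 * es_b + en_b
    return float(np.mean(cross**2 / (auto_a * auto_b)))


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _synth_from_psd(psd: np.ndarray, n_total: int, fs: float, rng: np.random.Generator,
                    size: int | None = None) -> np.ndarray:
    """Gaussian time series with the given one-sided PSD (rfft-grid sampling)."""
    nf = psd.shape[-1]
    shape = (nf,) if size is None else (size, nf)
    # single-precision synthesis: the smallest tolerance anywhere downstream
    # is ~1e-2 on coherence, far above float32 round-off
    z = (
        rng.standard_normal(shape, dtype=np.float32)
        + 1j * rng.standard_normal(shape, dtype=np.float32)
    )
    amp = np.sqrt(psd * n_total * fs / 4.0).astype(np.float32)
    spec = z * amp
    spec[..., 0] = spec[..., 0].real * math.sqrt(2.0)
    if n_total % 2 == 0:
        spec[..., -1] = spec[..., -1].real * math.sqrt(2.0)
    return np.fft.irfft(spec, n=n_total, axis=-1).astype(np.float64)


def _hann_pulse(width: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(width) / max(width - 1, 1))


def _make_artifacts(
    montage: Montage,
    rois: RoiSet,
    n_total: int,
    fs: float,
    amplitudes: dict[str, float],
    rng: np.random.Generator,
) -> list[tuple[str, np.ndarray, np.ndarray, float | None]]:
    """Artifact components as (name, topography, source, period_s) tuples."""
    pos = montage.positions[:, :2]
    center = pos.mean(axis=0)
    rel = pos - center
    radius = float(np.linalg.norm(rel, axis=1).max()) or 1.0
    xu, yu = rel[:, 0] / radius, rel[:, 1] / radius
    t = np.arange(n_total) / fs
    out = []

    def bursts(rate_hz: float, width_s: float, amp_jitter: float = 0.2) -> np.ndarray:
        src = np.zeros(n_total)
        n_events = rng.poisson(rate_hz * n_total / fs)
        starts = rng.integers(0, max(n_total - int(width_s * fs), 1), size=n_events)
        w = int(width_s * fs)
        pulse = _hann_pulse(w)
        for s0 in starts:
            src[s0 : s0 + w] += (1.0 + amp_jitter * rng.standard_normal()) * pulse[: n_total - s0]
        return src

    if amplitudes.get("blink", 0) > 0:
        topo = np.exp(-((xu - 0.0) ** 2 + (yu - 0.95) ** 2) / (2 * 0.35**2))
        src = bursts(rate_hz=0.4, width_s=0.3) * amplitudes["blink"]
        out.append(("blink", topo, src, None))
    if amplitudes.get("eye_movement", 0) > 0:
        # saccade-like level steps, frequent enough to survive the per-epoch
        # linear detrend, smoothed to a ~0.1 s rise time
        topo = xu * np.exp(-((yu - 0.85) ** 2) / (2 * 0.35**2))
        n_steps = rng.poisson(1.5 * n_total / fs) + 1
        times = np.sort(rng.integers(0, n_total, size=n_steps))
        levels = rng.uniform(-1, 1, size=n_steps + 1)
        src = np.zeros(n_total)
        prev = 0
        for k, tm in enumerate(times):
            src[prev:tm] = levels[k]
            prev = tm
        src[prev:] = levels[-1]
        smooth = _hann_pulse(int(0.1 * fs))
        src = np.convolve(src, smooth / smooth.sum(), mode="same") * amplitudes["eye_movement"]
        out.append(("eye_movement", topo, src, None))
    if amplitudes.get("muscle", 0) > 0:
        # neck/temporal EMG: broadband 25-50 Hz (peaked in 35-50 for the
        # automatic rule) in long contraction bursts over the posterior-
        # lateral edge -- the artifact class that corrupts in-band coherence
        # on the parietal leads if not removed
        topo = 0.9 * np.exp(-((xu - 0.8) ** 2 + (yu - 0.5) ** 2) / (2 * 0.4**2))
        freqs = np.fft.rfftfreq(n_total, 1.0 / fs)
        psd = np.where((freqs >= 25) & (freqs <= 50), np.maximum(freqs - 20.0, 0.0), 0.0)
        carrier = _synth_from_psd(psd, n_total, fs, rng)
        env = np.clip(bursts(rate_hz=0.2, width_s=2.5), 0, None)
        src = carrier * env
        rms = np.sqrt(np.mean(src**2)) or 1.0
        src *= amplitudes["muscle"] / rms
        out.append(("muscle", topo, src, None))
    if amplitudes.get("cardiac", 0) > 0:
        # broad topography (touches every lead) and a sharp pulse whose
        # harmonics reach into the beta band -- the artifact class that
        # actually biases inter-regional band coherence if left in
        # center-rim polarity field touching every lead: pulse harmonics add
        # coherent cross-power between central and peripheral lead sets --
        # the confound that inflates inter-regional band coherence when the
        # component is left in
        rho2 = xu**2 + yu**2
        topo = 1.4 * rho2 - 0.63
        period = 1.0 / 1.2
        width = int(0.03 * fs)
        tloc = (np.arange(width) - width / 2) / (0.005 * fs)
        pulse = tloc * np.exp(-(tloc**2) / 2.0)  # Gaussian-derivative beat shape
        pulse /= np.abs(pulse).max()
        src = np.zeros(n_total)
        phase = rng.uniform(0, period)
        beat_starts = np.arange(phase, n_total / fs - width / fs, period)
        for b in (beat_starts * fs).astype(int):
            src[b : b + width] += pulse
        src *= amplitudes["cardiac"]
        out.append(("cardiac", topo, src, period))
    if amplitudes.get("spike", 0) > 0:
        roi_leads = {l for leads in rois.rois.values() for l in leads}
        candidates = [l for l in montage.lead_ids if l not in roi_leads] or list(montage.lead_ids)
        chan = candidates[int(rng.integers(len(candidates)))]
        topo = np.zeros(montage.n_leads)
        topo[montage.index_of([chan])[0]] = 1.0
        src = np.zeros(n_total)
        n_events = rng.poisson(3.0 * n_total / fs) + 1
        w = max(int(0.012 * fs), 3)
        tri = 1.0 - np.abs(np.linspace(-1, 1, w))
        signs = rng.choice((-1.0, 1.0), size=n_events)
        for s0, sgn in zip(rng.integers(0, n_total - w, size=n_events), signs):
            src[s0 : s0 + w] += sgn * tri
        src *= amplitudes["spike"]
        out.append(("spike", topo, src, None))
    return out


@dataclass
class SubjectTruth:
    """Ground truth recorded alongside one generated subject."""

    subject_id: str
    gamma: float
    coherence_plain: float
    coherence_expected: float
    delta_true: float
    delta_clipped: bool = False
    sr_pre_target: float = float("nan")
    sr_post_target: float = float("nan")
    skill_pre: float = float("nan")
    skill_post: float = float("nan")
    v_train: float = float("nan")
    lesion_critical: bool = False
    artifact_topographies: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_sources: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    cardiac_period_s: float | None = None

    def artifact_signal(self) -> np.ndarray | None:
        """Total injected artifact signal in lead space (leads x samples)."""
        if not self.artifact_topographies:
            return None
        parts = [
            np.outer(self.artifact_topographies[k], self.artifact_sources[k])
            for k in self.artifact_topographies
        ]
        return np.sum(parts, axis=0)

    def templates(self) -> list[ArtifactTemplate]:
        """Stereotyped-artifact templates for ICA component matching."""
        out = []
        for kind in ("blink", "eye_movement", "cardiac"):
            if kind in self.artifact_topographies:
                out.append(
                    ArtifactTemplate(
                        kind=kind,
                        topography=self.artifact_topographies[kind],
                        period_s=self.cardiac_period_s if kind == "cardiac" else None,
                    )
                )
        return out


def generate_subject_eeg(
    config: SimulationConfig,
    gamma: float,
    montage: Montage,
    rois: RoiSet,
    rng: np.random.Generator,
    subject_id: str = "S00",
) -> tuple[Recording, SubjectTruth]:
    """Synthesize one subject's resting EEG and its ground-truth entry."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    rois.validate_against(montage)
    fs = config.fs_eeg
    n_total = int(round(fs * config.duration_s))
    freqs = np.fft.rfftfreq(n_total, 1.0 / fs)
    s_psd = source_psd(freqs, config.band, config.snr_band, config.noise_level)
    n_psd = noise_psd(freqs, config.noise_level)
    seed_leads = rois.rois[rois.primary_pair[0]]
    par_leads = rois.rois[rois.primary_pair[1]]
    weights = np.zeros(montage.n_leads)
    weights[montage.index_of(seed_leads)] = roi_weight_pattern(len(seed_leads))
    weights[montage.index_of(par_leads)] = gamma * roi_weight_pattern(len(par_leads))
    shared = _synth_from_psd(s_psd, n_total, fs, rng)
    data = _synth_from_psd(n_psd, n_total, fs, rng, size=montage.n_leads)
    data += weights[:, None] * shared
    truth = SubjectTruth(
        subject_id=subject_id,
        gamma=float(gamma),
        coherence_plain=analytic_band_coherence(
            gamma, config.band, config.snr_band, config.noise_level,
            n_seed=len(seed_leads), n_par=len(par_leads),
        ),
        coherence_expected=expected_band_coherence(
            gamma, fs, config.duration_s, config.band, config.snr_band, config.noise_level,
            n_leads=montage.n_leads,
            n_seed=len(seed_leads), n_par=len(par_leads),
        ),
        delta_true=float("nan"),
    )
    amplitudes = config.artifact_amplitudes
    if amplitudes:
        for name, topo, src, period in _make_artifacts(
            montage, rois, n_total, fs, amplitudes, rng
        ):
            data += np.outer(topo, src)
            truth.artifact_topographies[name] = topo
            truth.artifact_sources[name] = src
            if name == "cardiac":
                truth.cardiac_period_s = period
    return Recording(data=data, fs=fs, montage=montage, reference="Cz"), truth


# ---------------------------------------------------------------------------
# Tracking behavior
# ---------------------------------------------------------------------------

ROSE_AMPLITUDE_PX = 220.0
CENTER_PX = (320.0, 240.0)
LAG0_S = 0.30
JITTER0_PX = 50.0
_N_ROSE = 4096


def _rose_path() -> tuple[np.ndarray, np.ndarray, float]:
    """Arc-length parameterized cloverleaf (rose r = A sin 2θ); unit amplitude."""
    theta = np.linspace(0.0, 2 * np.pi, _N_ROSE, endpoint=False)
    r = np.sin(2 * theta)
    xy = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    seg = np.linalg.norm(np.diff(np.vstack([xy, xy[:1]]), axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return xy, s, float(s[-1])


_ROSE_XY, _ROSE_S, _ROSE_LEN = _rose_path()


def _target_at(arc: np.ndarray, amplitude: float) -> np.ndarray:
    """Positions on the rose at given arc-length values (wrapping)."""
    s = np.mod(arc, amplitude * _ROSE_LEN) / amplitude
    closed = np.vstack([_ROSE_XY, _ROSE_XY[:1]]) * 1.0
    x = np.interp(s, _ROSE_S, closed[:, 0])
    y = np.interp(s, _ROSE_S, closed[:, 1])
    return amplitude * np.stack([x, y], axis=1) + np.asarray(CENTER_PX)


def skill_to_lag_jitter(skill: float) -> tuple[float, float]:
    """Pursuit lag (s) and jitter sd (px), both shrinking with skill."""
    if skill < 0:
        raise ValueError("skill must be >= 0")
    decay = math.exp(-skill)
    return LAG0_S * decay, JITTER0_PX * decay


def generate_tracking_session(
    speed: float,
    skill: float,
    duration: float,
    rng: np.random.Generator,
    fs: float = 30.0,
    amplitude: float = ROSE_AMPLITUDE_PX,
) -> TrackingTrace:
    """One tracking run: constant-speed rose-curve target, lagged noisy cursor."""
    if speed <= 0 or duration <= 0:
        raise ValueError("speed and duration must be positive")
    lag, jitter = skill_to_lag_jitter(skill)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, amplitude * _ROSE_LEN)
    arc = phase + speed * t
    target = _target_at(arc, amplitude)
    cursor = _target_at(arc - speed * lag, amplitude)
    cursor = cursor + jitter * rng.standard_normal((n, 2))
    return TrackingTrace(t=t, target_xy=target, cursor_xy=cursor, fs=fs, speed=speed)


def expected_sr(
    speed: float,
    skill: float,
    duration: float = 90.0,
    n_runs: int = 3,
    design_seed: int = 12345,
    fs: float = 30.0,
) -> float:
    """Skill→SR map evaluated on a fixed simulated trace family.

    Uses common random numbers (a fixed design seed) so the map is a
    deterministic, monotone non-decreasing function of skill suitable for
    numerical inversion.
    """
    rng = np.random.default_rng(design_seed)
    srs = [
        behavior.success_rate(
            generate_tracking_session(speed, skill, duration, rng, fs=fs)
        )
        for _ in range(n_runs)
    ]
    return float(np.mean(srs))


def invert_sr(
    target_sr: float,
    speed: float,
    duration: float = 90.0,
    n_runs: int = 3,
    skill_bracket: tuple[float, float] = (0.0, 8.0),
    design_seed: int = 12345,
) -> tuple[float, bool]:
    """Skill whose expected SR equals ``target_sr``; returns (skill, clipped)."""
    lo, hi = skill_bracket
    f = lambda s: expected_sr(speed, s, duration, n_runs, design_seed) - target_sr
    if f(hi) < 0:
        return hi, True
    if f(lo) > 0:
        return lo, True
    return float(brentq(f, lo, hi, xtol=1e-4)), False


# ---------------------------------------------------------------------------
# Lesion masks
# ---------------------------------------------------------------------------

_GRID = 24
_VOX_MM = (2.0, 2.0, 2.0)


def _blob(center, radius) -> np.ndarray:
    ax = np.arange(_GRID)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    c = np.asarray(center)
    return (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= radius**2


def standard_roi_masks():
    """Toy critical-region masks (precentral gyrus, sup/inf parietal lobules)."""
    from .lesion import VolumeMask

    rois = {
        "precentral_gyrus": _blob((8, 14, 14), 3.5),
        "superior_parietal": _blob((10, 7, 15), 3.0),
        "inferior_parietal": _blob((13, 6, 11), 3.0),
    }
    return {
        k: VolumeMask(grid=v, voxel_size_mm=_VOX_MM, space_tag="synthetic-head")
        for k, v in rois.items()
    }


def _lesion_mask(critical: bool, rng: np.random.Generator):
    from .lesion import VolumeMask

    if critical:
        targets = [(8, 14, 14), (10, 7, 15), (13, 6, 11)]
        c = np.asarray(targets[int(rng.integers(3))]) + rng.integers(-2, 3, size=3)
    else:
        c = np.array([17, 17, 8]) + rng.integers(-2, 3, size=3)
    grid = _blob(c, float(rng.uniform(2.0, 4.5)))
    return VolumeMask(grid=grid, voxel_size_mm=_VOX_MM, space_tag="synthetic-head")


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Everything generated for one synthetic subject."""

    subject_id: str
    recording: Recording
    truth: SubjectTruth
    calib_rounds: list[tuple[float, float]]
    calibration: object | None
    pre_traces: list[TrackingTrace]
    post_traces: list[TrackingTrace]
    lesion: object | None = None  # VolumeMask


@dataclass
class Cohort:
    """A generated synthetic study: montage, ROIs, subjects, ground truth."""

    config: SimulationConfig
    montage: Montage
    rois: RoiSet
    subjects: list[SubjectData]
    roi_masks: dict | None = None

    def truth_frame(self):
        import pandas as pd

        rows = []
        for s in self.subjects:
            t = s.truth
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "gamma": t.gamma,
                    "coherence_plain": t.coherence_plain,
                    "coherence_expected": t.coherence_expected,
                    "delta_true": t.delta_true,
                    "delta_clipped": t.delta_clipped,
                    "sr_pre_target": t.sr_pre_target,
                    "sr_post_target": t.sr_post_target,
                    "v_train": t.v_train,
                    "lesion_critical": t.lesion_critical,
                }
            )
        return pd.DataFrame(rows)


def generate_cohort(
    config: SimulationConfig,
    montage: Montage | None = None,
    rois: RoiSet | None = None,
    with_eeg: bool = True,
    with_lesions: bool = True,
) -> Cohort:
    """Generate a full synthetic study cohort.

    Per subject: coupling ``γ_i`` uniform on ``coupling_range``; resting EEG
    from the mixing model; speed calibration rounds and fitted training
    speed (or ``fixed_speed``); pre and post tracking batteries whose
    expected relative SR gain equals ``Δ_i = a + b·γ_i + ε_i`` (post skill
    found by inverting the skill→SR map; infeasible gains are clipped and
    flagged).  Subject substreams are derived from (rng_seed, subject
    index), so adding subjects never perturbs existing ones.
    """
    cfg = config
    montage = montage or build_synthetic_montage(cfg.n_rings, "C3")
    rois = rois or default_roi_config(montage)
    # the first n_lesioned subjects carry critical-region damage; all random
    # draws come from per-subject substreams keyed on (seed, index), so
    # adding a subject never perturbs existing subjects' data
    lesioned = np.arange(cfg.n_subjects) < min(cfg.n_lesioned, cfg.n_subjects)
    subjects = []
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:02d}"
        rng = np.random.default_rng((cfg.rng_seed, i))
        gamma_i = float(rng.uniform(*cfg.coupling_range))
        eps_i = float(rng.normal(0.0, cfg.link_noise_sd))
        if with_eeg:
            rec, truth = generate_subject_eeg(cfg, gamma_i, montage, rois, rng, sid)
        else:
            rec = None
            truth = SubjectTruth(
                subject_id=sid, gamma=gamma_i,
                coherence_plain=analytic_band_coherence(
                    gamma_i, cfg.band, cfg.snr_band, cfg.noise_level,
                    n_seed=len(rois.rois[rois.primary_pair[0]]),
                    n_par=len(rois.rois[rois.primary_pair[1]]),
                ),
                coherence_expected=float("nan"), delta_true=float("nan"),
            )
        # behavior: calibration, then pre/post batteries
        if cfg.calibrate:
            rounds = []
            for v in cfg.calib_speeds:
                tr = generate_tracking_session(
                    float(v), cfg.pre_skill, cfg.calib_round_s, rng, fs=cfg.fs_track
                )
                rounds.append((float(v), behavior.success_rate(tr)))
            calib = fit_calibration(rounds)
            v_train = calib.v_train
        else:
            rounds, calib, v_train = [], None, cfg.fixed_speed
        delta = cfg.link_intercept + cfg.link_slope * gamma_i + eps_i
        sr_pre = expected_sr(v_train, cfg.pre_skill, cfg.run_duration_s, cfg.n_runs)
        sr_post_target = sr_pre * (1.0 + delta / 100.0)
        clipped = False
        if sr_post_target > 99.5:
            sr_post_target, clipped = 99.5, True
        if sr_post_target < sr_pre:  # negative gains: allow, bracket downward
            skill_post, c2 = invert_sr(
                sr_post_target, v_train, cfg.run_duration_s, cfg.n_runs,
                skill_bracket=(0.0, cfg.pre_skill),
            )
            clipped = clipped or c2
        else:
            skill_post, c2 = invert_sr(
                sr_post_target, v_train, cfg.run_duration_s, cfg.n_runs,
                skill_bracket=(cfg.pre_skill, 8.0),
            )
            clipped = clipped or c2
        pre = [
            generate_tracking_session(v_train, cfg.pre_skill, cfg.run_duration_s, rng, cfg.fs_track)
            for _ in range(cfg.n_runs)
        ]
        post = [
            generate_tracking_session(v_train, skill_post, cfg.run_duration_s, rng, cfg.fs_track)
            for _ in range(cfg.n_runs)
        ]
        truth.delta_true = float(delta)
        truth.delta_clipped = bool(clipped)
        truth.sr_pre_target = float(sr_pre)
        truth.sr_post_target = float(sr_post_target)
        truth.skill_pre = float(cfg.pre_skill)
        truth.skill_post = float(skill_post)
        truth.v_train = float(v_train)
        truth.lesion_critical = bool(lesioned[i])
        sub = SubjectData(
            subject_id=sid, recording=rec, truth=truth,
            calib_rounds=rounds, calibration=calib,
            pre_traces=pre, post_traces=post,
        )
        if with_lesions:
            sub.lesion = _lesion_mask(bool(lesioned[i]), rng)
        subjects.append(sub)
    cohort = Cohort(config=cfg, montage=montage, rois=rois, subjects=subjects)
    if with_lesions:
        cohort.roi_masks = standard_roi_masks()
    return cohort
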