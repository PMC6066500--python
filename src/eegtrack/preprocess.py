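"""Resting-EEG cleaning chain.

Fixed stage order, each stage logged in the epoch set's provenance:

    average re-reference -> 50 Hz zero-phase low-pass -> 1-s epoching with
    linear detrend -> amplitude-based epoch rejection -> ICA decomposition ->
    automatic component flagging -> artifact-free reconstruction.

Component rejection implements two automatic rules — a topography-dominance
rule for components confined to a single channel and a 35–50 Hz band-power
rule for muscle-like components — plus template matching for stereotyped
artifacts (blinks, lateral eye movements, cardiac rhythm) whose mixing
topographies are known, as they are for synthetic recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import Montage

__all__ = [
    "Recording",
    "EpochSet",
    "ComponentDecomposition",
    "ArtifactTemplate",
    "PreprocessConfig",
    "rereference_average",
    "lowpass",
    "epoch_and_detrend",
    "reject_epochs_amplitude",
    "decompose_ica",
    "auto_flag_components",
    "flag_stereotyped_artifacts",
    "reconstruct_clean",
    "clean_pipeline",
]


@dataclass
class Recording:
    """Continuous multichannel EEG: lead x sample matrix in microvolts."""

    data: np.ndarray
    fs: float
    montage: Montage
    reference: str = "Cz"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.montage.n_leads:
            raise ValueError("data must be (n_leads, n_samples) matching the montage")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochSet:
    """Non-overlapping fixed-length epochs with a keep/reject mask."""

    epochs: np.ndarray  # (n_epochs, n_leads, n_samples)
    fs: float
    montage: Montage
    kept_mask: np.ndarray
    epoch_len: float = 1.0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_leads, n_samples)")
        if self.epochs.shape[2] != int(round(self.fs * self.epoch_len)):
            raise ValueError("samples per epoch must equal fs * epoch_len exactly")
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.shape != (self.epochs.shape[0],):
            raise ValueError("kept_mask length must equal epoch count")

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def kept_epochs(self) -> np.ndarray:
        if self.n_kept == 0:
            raise ValueError("no epochs remain after rejection")
        return self.epochs[self.kept_mask]

    def export_csv(self, path) -> None:
        """Write kept epochs as a flat CSV (sample rows x lead columns,
        epochs concatenated) with a JSON sidecar carrying fs, lead order,
        the keep mask, and the processing provenance."""
        import json
        from pathlib import Path

        import pandas as pd

        path = Path(path)
        flat = self.kept_epochs().transpose(0, 2, 1).reshape(-1, self.epochs.shape[1])
        pd.DataFrame(flat, columns=self.montage.lead_ids).to_csv(path, index=False)
        sidecar = {
            "fs": self.fs,
            "epoch_len_s": self.epoch_len,
            "lead_ids": list(self.montage.lead_ids),
            "kept_mask": [bool(v) for v in self.kept_mask],
            "provenance": list(self.provenance),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def rereference_average(rec: Recording) -> Recording:
    """Common average reference: subtract the instantaneous across-lead mean."""
    if rec.data.shape[0] < 2:
        raise ValueError("average reference needs >= 2 leads")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data, reference="average")


def _lowpass_sos(cutoff: float, fs: float, order: int = 6):
    # forward-backward application squares the magnitude response, so the
    # design corner is placed so the *combined* response is -3 dB at cutoff
    corner = cutoff / (2.0**0.5 - 1.0) ** (1.0 / (2 * order))
    return signal.butter(order, corner, btype="low", fs=fs, output="sos")


def lowpass(rec: Recording, cutoff: float = 50.0) -> Recording:
    """Zero-phase low-pass (-3 dB at ``cutoff`` after forward-backward IIR)."""
    if rec.fs <= 2 * cutoff:
        raise ValueError(f"fs={rec.fs} too low for a {cutoff} Hz low-pass")
    sos = _lowpass_sos(cutoff, rec.fs)
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=data)


def epoch_and_detrend(rec: Recording, epoch_len: float = 1.0) -> EpochSet:
    """Segment into non-overlapping epochs and linearly detrend each.

    The trailing partial epoch is discarded; each epoch has its per-lead
    best-fit line removed.
    """
    nsamp = int(round(rec.fs * epoch_len))
    n_ep = rec.data.shape[1] // nsamp
    if n_ep < 1:
        raise ValueError(f"recording shorter than one {epoch_len} s epoch")
    ep = rec.data[:, : n_ep * nsamp].reshape(rec.data.shape[0], n_ep, nsamp)
    ep = np.ascontiguousarray(np.swapaxes(ep, 0, 1))
    # closed-form per-epoch linear detrend (x -> x - a - b t)
    t = np.arange(nsamp) - (nsamp - 1) / 2.0
    denom = float(t @ t)
    slope = (ep @ t) / denom
    ep = ep - ep.mean(axis=2, keepdims=True) - slope[:, :, None] * t
    return EpochSet(
        epochs=ep, fs=rec.fs, montage=rec.montage,
        kept_mask=np.ones(n_ep, dtype=bool), epoch_len=epoch_len,
        provenance=[f"reference={rec.reference}", f"epoch_len={epoch_len}", "detrend=linear"],
    )


def reject_epochs_amplitude(ep: EpochSet, limit_uv: float = 100.0) -> EpochSet:
    """Flag out epochs whose peak absolute amplitude on any lead exceeds limit."""
    if limit_uv <= 0:
        raise ValueError("limit_uv must be positive")
    peaks = np.abs(ep.epochs).max(axis=(1, 2))
    mask = ep.kept_mask & (peaks <= limit_uv)
    return replace(
        ep, kept_mask=mask,
        provenance=ep.provenance + [f"amp_reject_uv={limit_uv} (kept {int(mask.sum())}/{mask.size})"],
    )


@dataclass
class ComponentDecomposition:
    """Linear ICA decomposition of the concatenated kept epochs.

    ``mixing @ sources + mean`` reconstructs the input (to numerical
    tolerance when the component count equals the data rank).
    """

    mixing: np.ndarray        # (n_leads, k)
    sources: np.ndarray       # (k, n_samples_total)
    mean: np.ndarray          # (n_leads,)
    fs: float
    montage: Montage
    rejected: dict[int, str] = field(default_factory=dict)  # component -> reason
    method: str = "fastica"

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def flag(self, comp: int, reason: str) -> None:
        self.rejected[int(comp)] = reason


def decompose_ica(
    ep: EpochSet,
    n_components: int | None = None,
    rng_seed: int = 0,
    method: str = "fastica",
    max_iter: int = 500,
    tol: float = 1e-4,
) -> ComponentDecomposition:
    """ICA on the concatenated kept epochs, deterministic given the seed.

    ``method`` is ``"fastica"`` (default) or ``"infomax"`` (extended Infomax
    via MNE).  Components are extracted in a PCA-whitened space of dimension
    ``n_components`` (default: the numerical rank, capped at 64); requesting
    more components than the data rank is an error.
    """
    kept = ep.kept_epochs()
    n_leads = kept.shape[1]
    x = np.ascontiguousarray(np.swapaxes(kept, 0, 1).reshape(n_leads, -1))
    mean = x.mean(axis=1)
    x = x - mean[:, None]
    t_total = x.shape[1]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    if n_components is None:
        k = min(rank, 64)
    else:
        k = int(n_components)
        if k > rank:
            raise ValueError(
                f"requested {k} components but data rank is {rank}; use fewer components"
            )
    if k < 1 or t_total < k:
        raise ValueError("not enough samples for the requested component count")
    y = vt[:k] * np.sqrt(t_total)  # whitened (unit-variance rows)
    if method == "fastica":
        import warnings

        from sklearn.decomposition import FastICA
        from sklearn.exceptions import ConvergenceWarning

        ica = FastICA(whiten=False, random_state=int(rng_seed), max_iter=max_iter, tol=tol)
        with warnings.catch_warnings():
            # directions spanning the Gaussian background subspace have no
            # preferred rotation and legitimately fail the tolerance check;
            # the non-Gaussian (artifact) directions converge regardless
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            sources = ica.fit_transform(y.T).T
        w = ica.components_
    elif method == "infomax":
        from mne.preprocessing import infomax

        w = infomax(y.T, extended=True, random_state=int(rng_seed), verbose="error")
        sources = w @ y
    else:
        raise ValueError(f"unknown ICA method {method!r}")
    # mixing in lead space: x ~= (U S/sqrt(T) W^-1) @ sources
    mixing = (u[:, :k] * (s[:k] / np.sqrt(t_total))) @ np.linalg.inv(w)
    return ComponentDecomposition(
        mixing=mixing, sources=sources, mean=mean, fs=ep.fs,
        montage=ep.montage, method=method,
    )


def _source_band_fraction(src: np.ndarray, fs: float, band=(35.0, 50.0), total=(1.0, 50.0)) -> float:
    f, p = signal.welch(src, fs=fs, nperseg=min(len(src), int(fs)))
    band_p = p[(f >= band[0]) & (f <= band[1])].sum()
    total_p = p[(f >= total[0]) & (f <= total[1])].sum()
    return float(band_p / total_p) if total_p > 0 else 0.0


def auto_flag_components(
    dec: ComponentDecomposition,
    tau_single: float = 0.8,
    tau_muscle: float = 0.5,
) -> ComponentDecomposition:
    """Automatic rejection rules, applied independently per component.

    single_channel: one lead carries more than ``tau_single`` of the total
    absolute mixing weight.  muscle_band: more than ``tau_muscle`` of the
    source's 1–50 Hz power lies in 35–50 Hz.
    """
    absw = np.abs(dec.mixing)
    totals = absw.sum(axis=0)
    for c in range(dec.n_components):
        if totals[c] > 0 and absw[:, c].max() / totals[c] > tau_single:
            dec.flag(c, "single_channel")
        elif _source_band_fraction(dec.sources[c], dec.fs) > tau_muscle:
            dec.flag(c, "muscle_band")
    return dec


@dataclass(frozen=True)
class ArtifactTemplate:
    """Descriptor of a stereotyped artifact for template matching.

    ``kind`` is one of blink / eye_movement / cardiac.  ``topography`` is a
    lead-space mixing vector (aligned with the montage lead order).  For
    cardiac templates ``period_s`` gives the beat period.
    """

    kind: str
    topography: np.ndarray
    period_s: float | None = None


def _spectral_centroid(src: np.ndarray, fs: float) -> float:
    f, p = signal.welch(src, fs=fs, nperseg=min(len(src), int(fs)))
    sel = (f >= 0.5) & (f <= 50.0)
    f, p = f[sel], p[sel]
    return float((f * p).sum() / p.sum()) if p.sum() > 0 else 0.0


def _autocorr_period(src: np.ndarray, fs: float, max_lag_s: float = 2.0) -> float:
    x = src - src.mean()
    n = len(x)
    max_lag = min(int(max_lag_s * fs), n - 1)
    ac = signal.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    ac = ac / ac[0]
    lo = int(0.25 * fs)  # ignore lags < 0.25 s (i.e. rates > 4 Hz)
    if lo >= len(ac):
        return np.inf
    peak = lo + int(np.argmax(ac[lo:]))
    return peak / fs


def flag_stereotyped_artifacts(
    dec: ComponentDecomposition,
    templates: list[ArtifactTemplate],
    topo_corr_min: float = 0.9,
) -> ComponentDecomposition:
    """Flag components matching known artifact topographies.

    A component is flagged when its mixing column correlates (absolutely)
    above ``topo_corr_min`` with a template topography and its source passes
    that template's spectral gate: spectral centroid < 8 Hz for blink /
    eye-movement templates, a dominant autocorrelation period within 20% of
    the beat period for cardiac templates.
    """
    for c in range(dec.n_components):
        if c in dec.rejected:
            continue
        col = dec.mixing[:, c]
        if np.allclose(col, 0):
            continue
        for tpl in templates:
            topo = np.asarray(tpl.topography, dtype=float)
            if topo.shape != col.shape or np.allclose(topo, 0):
                continue
            r = abs(float(np.corrcoef(col, topo)[0, 1]))
            if not np.isfinite(r) or r < topo_corr_min:
                continue
            src = dec.sources[c]
            if tpl.kind in ("blink", "eye_movement"):
                if _spectral_centroid(src, dec.fs) < 8.0:
                    dec.flag(c, tpl.kind)
                    break
            elif tpl.kind == "cardiac" and tpl.period_s:
                period = _autocorr_period(src, dec.fs)
                if abs(period - tpl.period_s) <= 0.2 * tpl.period_s:
                    dec.flag(c, "cardiac")
                    break
    return dec


def reconstruct_clean(dec: ComponentDecomposition, ep: EpochSet) -> EpochSet:
    """Rebuild kept epochs with flagged components' contributions removed."""
    keep = [c for c in range(dec.n_components) if c not in dec.rejected]
    if not keep:
        raise ValueError("all components flagged; no neural components remain")
    clean = dec.mixing[:, keep] @ dec.sources[keep] + dec.mean[:, None]
    kept_idx = np.nonzero(ep.kept_mask)[0]
    nsamp = ep.epochs.shape[2]
    out = ep.epochs.copy()
    for pos, e in enumerate(kept_idx):
        out[e] = clean[:, pos * nsamp : (pos + 1) * nsamp]
    reasons = sorted(set(dec.rejected.values()))
    return replace(
        ep, epochs=out,
        provenance=ep.provenance
        + [f"ica={dec.method} k={dec.n_components} rejected={len(dec.rejected)} ({','.join(reasons)})"],
    )


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning chain (defaults as used throughout)."""

    lowpass_hz: float = 50.0
    epoch_len_s: float = 1.0
    amp_reject_uv: float = 100.0
    ica: bool = True
    ica_n_components: int | None = None
    ica_seed: int = 0
    ica_method: str = "fastica"
    tau_single: float = 0.8
    tau_muscle: float = 0.5


def clean_pipeline(
    rec: Recording,
    config: PreprocessConfig | None = None,
    templates: list[ArtifactTemplate] | None = None,
) -> EpochSet:
    """Run the full cleaning chain in its fixed order.

    Returns the cleaned epoch set; every stage and its parameters are
    recorded in the provenance list.  With ``config.ica=False`` the chain
    stops after amplitude rejection (used for artifact-free sensitivity
    runs).
    """
    cfg = config or PreprocessConfig()
    rec = rereference_average(rec)
    rec = lowpass(rec, cfg.lowpass_hz)
    ep = epoch_and_detrend(rec, cfg.epoch_len_s)
    ep.provenance.insert(0, f"lowpass_hz={cfg.lowpass_hz}")
    ep = reject_epochs_amplitude(ep, cfg.amp_reject_uv)
    if not cfg.ica:
        ep.provenance.append("ica=skipped")
        return ep
    dec = decompose_ica(
        ep, n_components=cfg.ica_n_components, rng_seed=cfg.ica_seed, method=cfg.ica_method
    )
    dec = auto_flag_components(dec, tau_single=cfg.tau_single, tau_muscle=cfg.tau_muscle)
    if templates:
        dec = flag_stereotyped_artifacts(dec, templates)
    if len(dec.rejected) == dec.n_components:
        raise ValueError("all components flagged; no neural components remain")
    return reconstruct_clean(dec, ep)
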