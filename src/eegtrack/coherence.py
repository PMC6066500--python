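"""Band-averaged magnitude-squared coherence between ROI lead sets.

The estimator is the classic epoch-averaged periodogram: each kept 1-s epoch
is Hann-windowed and Fourier-transformed per lead; auto- and cross-spectra
are the means of the per-epoch (cross-)periodograms over the M kept epochs,
giving 1 Hz frequency resolution.  Magnitude-squared coherence at each bin is

    C_ij(f) = |S_ij(f)|^2 / (S_ii(f) * S_jj(f))  in [0, 1],

and a band value is the arithmetic mean of the per-bin coherence over all
bins with f_lo <= f <= f_hi (endpoints inclusive; 20-30 Hz spans 11 bins).
ROI-pair coherence averages the per-lead-pair band values over every
cross-ROI lead pair, excluding any lead shared by both ROIs.

Note the estimator's small-sample bias: for independent signals the expected
estimate is ~1/M, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .montage import RoiSet

__all__ = [
    "DEFAULT_BANDS",
    "SpectralModel",
    "CoherenceTable",
    "estimate_spectra",
    "msc",
    "roi_pair_coherence",
    "coherence_table",
]

#: Conventional band edges (Hz); endpoints inclusive when band-averaging.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (20.0, 30.0),
}


@dataclass
class SpectralModel:
    """Epoch-averaged auto- and cross-spectra at 1 Hz resolution."""

    freqs: np.ndarray
    auto: dict[str, np.ndarray]
    cross: dict[tuple[str, str], np.ndarray] = field(repr=False)
    n_epochs: int = 0

    def get_cross(self, i: str, j: str) -> np.ndarray:
        if (i, j) in self.cross:
            return self.cross[(i, j)]
        if (j, i) in self.cross:
            return np.conj(self.cross[(j, i)])
        raise KeyError(f"cross-spectrum for pair ({i!r}, {j!r}) was not estimated")


def estimate_spectra(ep, lead_pairs: list[tuple[str, str]]) -> SpectralModel:
    """Estimate auto/cross spectra from kept 1-s epochs for requested pairs.

    Parameters
    ----------
    ep : EpochSet
        Epoched recording (``epochs`` of shape epoch x lead x sample).
    lead_pairs
        Lead-label pairs whose cross-spectra are needed.  Auto-spectra are
        computed for every lead appearing in any pair.  Results are identical
        to a full all-pairs computation restricted to these pairs.
    """
    kept = ep.kept_epochs()
    m = kept.shape[0]
    if m < 2:
        raise ValueError("coherence needs >= 2 kept epochs (estimator is degenerate at M=1)")
    fs = int(round(ep.fs))
    nsamp = kept.shape[2]
    leads = []
    for i, j in lead_pairs:
        for l in (i, j):
            if l not in leads:
                leads.append(l)
    idx = ep.montage.index_of(leads)
    win = hann(nsamp, sym=False)
    scale = 1.0 / (fs * (win**2).sum())
    # rfft over (epoch, lead, sample) for the involved leads only
    spec = np.fft.rfft(kept[:, idx, :] * win, axis=2)
    freqs = np.fft.rfftfreq(nsamp, d=1.0 / fs)
    auto_arr = (np.abs(spec) ** 2).mean(axis=0) * scale
    auto = {lab: auto_arr[k] for k, lab in enumerate(leads)}
    pos = {lab: k for k, lab in enumerate(leads)}
    cross: dict[tuple[str, str], np.ndarray] = {}
    if len(lead_pairs) > len(leads):
        # batched BLAS path: full cross matrix per frequency for the involved
        # leads (results identical to the per-pair computation)
        sw = np.ascontiguousarray(spec.transpose(2, 1, 0))  # (freq, lead, epoch)
        full = (sw @ sw.conj().transpose(0, 2, 1)) * (scale / m)  # (freq, lead, lead)
        for i, j in lead_pairs:
            if (i, j) in cross or (j, i) in cross:
                continue
            cross[(i, j)] = (
                auto[i].astype(complex) if i == j else full[:, pos[i], pos[j]].copy()
            )
    else:
        for i, j in lead_pairs:
            if (i, j) in cross or (j, i) in cross:
                continue
            if i == j:
                cross[(i, j)] = auto[i].astype(complex)
            else:
                cross[(i, j)] = (spec[:, pos[i], :] * np.conj(spec[:, pos[j], :])).mean(axis=0) * scale
    return SpectralModel(freqs=freqs, auto=auto, cross=cross, n_epochs=m)


def band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    f_lo, f_hi = band
    if f_lo > f_hi:
        raise ValueError("band edges reversed")
    sel = np.nonzero((freqs >= f_lo - 1e-9) & (freqs <= f_hi + 1e-9))[0]
    if sel.size == 0:
        raise ValueError(f"band {band} contains no frequency bins")
    return sel


def msc(spec: SpectralModel, i: str, j: str, band: tuple[float, float]) -> float:
    """Band-mean magnitude-squared coherence between leads ``i`` and ``j``."""
    if i == j:
        return 1.0
    sel = band_bins(spec.freqs, band)
    sii, sjj = spec.auto[i][sel], spec.auto[j][sel]
    for lab, s in ((i, sii), (j, sjj)):
        if np.any(s <= 0):
            bad = spec.freqs[sel][np.nonzero(s <= 0)[0][0]]
            raise ValueError(f"zero auto-power on lead {lab!r} at {bad:g} Hz; coherence undefined")
    sij = spec.get_cross(i, j)[sel]
    return float(np.mean(np.abs(sij) ** 2 / (sii * sjj)))


def roi_lead_pairs(rois: RoiSet, pair: tuple[str, str]) -> list[tuple[str, str]]:
    """Cross-ROI lead pairs for a circuit, identical leads excluded."""
    a, b = pair
    return [(i, j) for i in rois.rois[a] for j in rois.rois[b] if i != j]


def roi_pair_coherence(
    spec: SpectralModel, rois: RoiSet, pair: tuple[str, str], band: tuple[float, float]
) -> tuple[float, int]:
    """Mean msc over all cross-ROI lead pairs; returns (value, n_pairs)."""
    pairs = roi_lead_pairs(rois, pair)
    if not pairs:
        raise ValueError(f"no usable lead pairs for circuit {pair}")
    vals = [msc(spec, i, j, band) for i, j in pairs]
    return float(np.mean(vals)), len(pairs)


@dataclass
class CoherenceTable:
    """(circuit, band) -> band coherence, as a tidy DataFrame."""

    table: pd.DataFrame  # columns: roi_pair, band, coherence, n_epochs, n_lead_pairs
    bands: dict[str, tuple[float, float]]

    def value(self, circuit: tuple[str, str], band: str) -> float:
        name = f"{circuit[0]}-{circuit[1]}"
        row = self.table[(self.table.roi_pair == name) & (self.table.band == band)]
        if row.empty:
            raise KeyError(f"no entry for circuit {name!r}, band {band!r}")
        return float(row.coherence.iloc[0])

    def to_csv(self, path, subject_id: str | None = None) -> None:
        df = self.table.copy()
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        df.to_csv(path, index=False)


def coherence_table(
    ep,
    rois: RoiSet,
    bands: dict[str, tuple[float, float]] | None = None,
    aggregate: str = "pairs",
) -> CoherenceTable:
    """Coherence for every configured circuit x band.

    ``aggregate="pairs"`` (default) averages msc over cross-ROI lead pairs;
    ``aggregate="roi_mean"`` first averages the leads within each ROI and
    computes a single msc between the two ROI-mean signals (sensitivity
    analysis).
    """
    bands = dict(bands or DEFAULT_BANDS)
    for name, (lo, hi) in bands.items():
        if not (1.0 <= lo <= hi <= 50.0):
            raise ValueError(f"band {name!r} edges {lo}-{hi} outside [1, 50] Hz")
    circuits = rois.circuits
    rows = []
    if aggregate == "pairs":
        all_pairs = sorted({p for c in circuits for p in roi_lead_pairs(rois, c)})
        spec = estimate_spectra(ep, all_pairs)
        for circuit in circuits:
            for bname, edges in bands.items():
                val, npairs = roi_pair_coherence(spec, rois, circuit, edges)
                rows.append((f"{circuit[0]}-{circuit[1]}", bname, val, spec.n_epochs, npairs))
    elif aggregate == "roi_mean":
        ep2, roi_leads = _roi_mean_epochs(ep, rois)
        spec = estimate_spectra(ep2, [(a, b) for a, b in circuits])
        for circuit in circuits:
            for bname, edges in bands.items():
                val = msc(spec, circuit[0], circuit[1], edges)
                rows.append((f"{circuit[0]}-{circuit[1]}", bname, val, spec.n_epochs, 1))
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    df = pd.DataFrame(rows, columns=["roi_pair", "band", "coherence", "n_epochs", "n_lead_pairs"])
    return CoherenceTable(table=df, bands=bands)


def _roi_mean_epochs(ep, rois: RoiSet):
    """Virtual epoch set whose 'leads' are ROI-mean signals."""
    from .preprocess import EpochSet
    from .montage import Montage

    names = sorted(rois.rois)
    data = np.stack(
        [ep.epochs[:, ep.montage.index_of(rois.rois[n]), :].mean(axis=1) for n in names], axis=1
    )
    pos = np.zeros((len(names), 2))
    pos[:, 0] = np.arange(len(names))  # placeholder positions; labels must be unique
    virt = Montage(tuple(names), pos, {n: frozenset() for n in names})
    ep2 = EpochSet(
        epochs=data, fs=ep.fs, montage=virt, kept_mask=ep.kept_mask.copy(),
        provenance=ep.provenance + ["roi_mean"],
    )
    return ep2, names
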