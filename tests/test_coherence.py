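"""Spectral estimation and band-averaged magnitude-squared coherence."""

import numpy as np
import pytest

from eegtrack.coherence import (
    DEFAULT_BANDS,
    coherence_table,
    estimate_spectra,
    msc,
    roi_lead_pairs,
    roi_pair_coherence,
)
from eegtrack.montage import RoiSet, build_synthetic_montage
from eegtrack.preprocess import EpochSet

HEX2 = build_synthetic_montage(2, "C3")
LEADS = HEX2.lead_ids


def epochs_from(x, fs=1000.0, montage=HEX2):
    n_ep = x.shape[1] // int(fs)
    ep = x[:, : n_ep * int(fs)].reshape(x.shape[0], n_ep, int(fs)).swapaxes(0, 1)
    return EpochSet(np.ascontiguousarray(ep), fs, montage, np.ones(n_ep, bool))


def shared_source_pair(m_epochs=180, shared_scale=1.0, seed=0):
    """Two leads x = s + n1, y = s + n2 with white s, n of equal variance:
    per-bin coherence is (1/2)^2 = 0.25 at every frequency."""
    rng = np.random.default_rng(seed)
    n = m_epochs * 1000
    s = shared_scale * rng.standard_normal(n)
    data = np.zeros((7, n))
    data[0] = s + rng.standard_normal(n)
    data[1] = s + rng.standard_normal(n)
    data[2:] = rng.standard_normal((5, n))
    return epochs_from(data)


def test_self_coherence_is_exactly_one():
    ep = shared_source_pair(8)
    spec = estimate_spectra(ep, [(LEADS[0], LEADS[0])])
    assert msc(spec, LEADS[0], LEADS[0], (20, 30)) == 1.0


def test_single_epoch_is_degenerate():
    ep = shared_source_pair(1)
    with pytest.raises(ValueError, match="2 kept epochs"):
        estimate_spectra(ep, [(LEADS[0], LEADS[1])])


def test_sine_gives_auto_spectrum_peak_at_its_frequency():
    t = np.arange(8000) / 1000.0
    data = np.zeros((7, 8000))
    data[0] = np.sin(2 * np.pi * 10.0 * t)
    data[1:] = np.random.default_rng(0).standard_normal((6, 8000))
    spec = estimate_spectra(epochs_from(data), [(LEADS[0], LEADS[1])])
    peak = spec.freqs[np.argmax(spec.auto[LEADS[0]])]
    assert peak == 10.0


def test_independent_white_noise_band_msc_near_estimator_bias():
    rng = np.random.default_rng(1)
    ep = epochs_from(rng.standard_normal((7, 180_000)))
    spec = estimate_spectra(ep, [(LEADS[0], LEADS[1])])
    val = msc(spec, LEADS[0], LEADS[1], (20, 30))
    assert val <= 0.03  # bias ~ 1/M = 0.0056 at M=180


def test_equal_power_shared_source_gives_one_quarter():
    ep = shared_source_pair(180)
    spec = estimate_spectra(ep, [(LEADS[0], LEADS[1])])
    val = msc(spec, LEADS[0], LEADS[1], (20, 30))
    assert val == pytest.approx(0.25, abs=0.03)


def test_scale_invariance_to_machine_precision():
    ep = shared_source_pair(30)
    spec = estimate_spectra(ep, [(LEADS[0], LEADS[1])])
    base = msc(spec, LEADS[0], LEADS[1], (20, 30))
    scaled = ep.epochs.copy()
    scaled[:, 0, :] *= 3.7
    ep2 = EpochSet(scaled, ep.fs, ep.montage, ep.kept_mask.copy())
    spec2 = estimate_spectra(ep2, [(LEADS[0], LEADS[1])])
    assert msc(spec2, LEADS[0], LEADS[1], (20, 30)) == pytest.approx(base, abs=1e-12)


def test_half_period_shift_of_narrowband_source_leaves_msc_unchanged():
    # magnitude-squared coherence discards phase: delaying one lead by half a
    # period of the shared narrowband source flips its sign but not the msc
    rng = np.random.default_rng(8)
    n = 60_000
    t = np.arange(n) / 1000.0
    s = np.sin(2 * np.pi * 20.0 * t)  # 50-sample period
    data = rng.standard_normal((7, n))
    data[0] += s
    data[1] += s
    shifted = data.copy()
    shifted[1] = np.roll(data[1], 25)  # half period: s -> -s
    a = msc(estimate_spectra(epochs_from(data), [(LEADS[0], LEADS[1])]),
            LEADS[0], LEADS[1], (20, 30))
    b = msc(estimate_spectra(epochs_from(shifted), [(LEADS[0], LEADS[1])]),
            LEADS[0], LEADS[1], (20, 30))
    assert b == pytest.approx(a, abs=0.02)


def test_zero_power_bin_raises_naming_the_bin():
    data = np.zeros((7, 5000))
    data[0] = np.random.default_rng(0).standard_normal(5000)
    ep = epochs_from(data)
    spec = estimate_spectra(ep, [(LEADS[0], LEADS[1])])
    with pytest.raises(ValueError, match="zero auto-power"):
        msc(spec, LEADS[0], LEADS[1], (20, 30))


def test_roi_pair_counts_and_shared_lead_exclusion():
    rois = RoiSet(
        {"A": tuple(LEADS[:3]), "B": tuple(LEADS[3:7])},
        primary_pair=("A", "B"), control_pairs=(),
    )
    assert len(roi_lead_pairs(rois, ("A", "B"))) == 12
    overlapping = RoiSet(
        {"A": tuple(LEADS[:3]), "B": (LEADS[2], LEADS[3])},
        primary_pair=("A", "B"), control_pairs=(),
    )
    assert len(roi_lead_pairs(overlapping, ("A", "B"))) == 3 * 2 - 1


def test_roi_pair_coherence_of_identical_pairs_is_their_common_value():
    ep = shared_source_pair(40)
    rois = RoiSet({"A": (LEADS[0],), "B": (LEADS[1],)}, primary_pair=("A", "B"))
    spec = estimate_spectra(ep, roi_lead_pairs(rois, ("A", "B")))
    val, n_pairs = roi_pair_coherence(spec, rois, ("A", "B"), (20, 30))
    assert n_pairs == 1
    assert val == msc(spec, LEADS[0], LEADS[1], (20, 30))


def test_default_table_covers_all_circuits_and_bands(hex4, rois4):
    rng = np.random.default_rng(3)
    data = rng.standard_normal((hex4.n_leads, 20_000))
    ep = epochs_from(data, montage=hex4)
    table = coherence_table(ep, rois4, DEFAULT_BANDS)
    assert len(table.table) == 7 * 5
    assert ((table.table.coherence >= 0) & (table.table.coherence <= 1)).all()
    primary = table.table[(table.table.roi_pair == "iM1-iPAR")]
    assert set(primary.band) == set(DEFAULT_BANDS)


def test_table_on_dead_recording_errors(hex4, rois4):
    ep = epochs_from(np.zeros((hex4.n_leads, 5000)), montage=hex4)
    with pytest.raises(ValueError, match="zero auto-power"):
        coherence_table(ep, rois4, DEFAULT_BANDS)


def test_band_edges_validated(hex4, rois4):
    ep = epochs_from(np.random.default_rng(0).standard_normal((hex4.n_leads, 4000)),
                     montage=hex4)
    with pytest.raises(ValueError, match="outside"):
        coherence_table(ep, rois4, {"hf": (40.0, 80.0)})


def test_roi_mean_aggregation_mode_runs(hex4, rois4):
    rng = np.random.default_rng(4)
    ep = epochs_from(rng.standard_normal((hex4.n_leads, 10_000)), montage=hex4)
    table = coherence_table(ep, rois4, {"high_beta": (20.0, 30.0)}, aggregate="roi_mean")
    assert len(table.table) == 7
    assert ((table.table.coherence >= 0) & (table.table.coherence <= 1)).all()
    assert (table.table.n_lead_pairs == 1).all()


def test_estimate_error_shrinks_with_more_epochs():
    errs = {}
    for m in (20, 180):
        vals = []
        for seed in range(8):
            ep = shared_source_pair(m, seed=seed)
            spec = estimate_spectra(ep, [(LEADS[0], LEADS[1])])
            vals.append(abs(msc(spec, LEADS[0], LEADS[1], (20, 30)) - 0.25))
        errs[m] = np.median(vals)
    assert errs[180] < errs[20]


def test_batched_and_per_pair_cross_spectra_agree():
    ep = shared_source_pair(12)
    many = [(a, b) for i, a in enumerate(LEADS) for b in LEADS[i + 1:]]
    spec_batched = estimate_spectra(ep, many)  # triggers the BLAS path
    spec_single = estimate_spectra(ep, [(LEADS[0], LEADS[1])])
    np.testing.assert_allclose(
        spec_batched.get_cross(LEADS[0], LEADS[1]),
        spec_single.get_cross(LEADS[0], LEADS[1]),
        rtol=1e-10,
    )
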