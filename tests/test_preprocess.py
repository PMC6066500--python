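"""EEG cleaning chain: re-referencing, filtering, epoching, ICA rejection."""

import numpy as np
import pytest

from eegtrack.montage import build_synthetic_montage
from eegtrack.preprocess import (
    ArtifactTemplate,
    ComponentDecomposition,
    EpochSet,
    PreprocessConfig,
    Recording,
    auto_flag_components,
    clean_pipeline,
    decompose_ica,
    epoch_and_detrend,
    flag_stereotyped_artifacts,
    lowpass,
    reconstruct_clean,
    reject_epochs_amplitude,
    rereference_average,
)

HEX2 = build_synthetic_montage(2, "C3")  # 7 leads


def rec_from(data, fs=1000.0, montage=None):
    m = montage or HEX2
    return Recording(data=np.asarray(data, float), fs=fs, montage=m, reference="Cz")


def white_recording(n_samples=4000, fs=1000.0, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    return rec_from(scale * rng.standard_normal((7, n_samples)), fs)


class TestRereference:
    def test_constant_offset_becomes_zero(self):
        rec = rec_from(np.full((7, 100), 42.0))
        out = rereference_average(rec)
        assert np.all(out.data == 0)
        assert out.reference == "average"

    def test_column_means_vanish_on_random_input(self):
        m4 = build_synthetic_montage(2, "C3")
        rng = np.random.default_rng(1)
        data = rng.normal(size=(7, 10))
        out = rereference_average(rec_from(data))
        np.testing.assert_allclose(out.data.mean(axis=0), 0.0, atol=1e-12)
        # and the operation is idempotent
        again = rereference_average(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_single_lead_errors(self):
        m = build_synthetic_montage(2, "C3")
        rec = Recording(np.zeros((7, 10)), 1000.0, m)
        rec.data = rec.data[:1]
        with pytest.raises(ValueError):
            rereference_average(
                Recording(np.zeros((1, 10)), 1000.0,
                          type(m)(("C3",), np.zeros((1, 2)), {"C3": frozenset()}))
            )


class TestLowpass:
    @staticmethod
    def gain_at(freq, fs=1000.0):
        t = np.arange(int(4 * fs)) / fs
        sig = np.sin(2 * np.pi * freq * t)
        rec = rec_from(np.tile(sig, (7, 1)), fs)
        out = lowpass(rec)
        mid = slice(int(fs), int(3 * fs))  # avoid filter edges
        return np.sqrt(np.mean(out.data[0, mid] ** 2) / np.mean(sig[mid] ** 2))

    def test_passband_and_stopband_contract(self):
        assert 0.94 <= self.gain_at(10.0) <= 1.06
        assert self.gain_at(100.0) <= 0.1
        # -3 dB point lands near the 50 Hz corner
        assert 0.6 <= self.gain_at(50.0) <= 0.8

    def test_dc_passes_unchanged(self):
        rec = rec_from(np.full((7, 2000), 7.5))
        out = lowpass(rec)
        np.testing.assert_allclose(out.data, 7.5, rtol=1e-6)

    def test_zero_phase_no_shift(self):
        fs = 1000.0
        t = np.arange(4000) / fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        out = lowpass(rec_from(np.tile(sig, (7, 1)), fs))
        mid = slice(1000, 3000)
        lag = np.argmax(np.correlate(out.data[0, mid], sig[mid], "full")) - (len(sig[mid]) - 1)
        assert lag == 0

    def test_low_sampling_rate_errors(self):
        with pytest.raises(ValueError):
            lowpass(rec_from(np.zeros((7, 500)), fs=90.0))


class TestEpoching:
    def test_whole_second_segmentation(self):
        ep = epoch_and_detrend(white_recording(5500))
        assert ep.epochs.shape == (5, 7, 1000)  # trailing 0.5 s discarded

    def test_linear_ramp_detrends_to_zero(self):
        ramp = np.tile(np.linspace(0.0, 50.0, 3000), (7, 1))
        ep = epoch_and_detrend(rec_from(ramp))
        np.testing.assert_allclose(ep.epochs, 0.0, atol=1e-9)

    def test_short_recording_errors(self):
        with pytest.raises(ValueError):
            epoch_and_detrend(rec_from(np.zeros((7, 900))))


class TestAmplitudeRejection:
    def test_spike_epoch_flagged_out_data_unchanged(self):
        rec = white_recording(4000, scale=5.0)
        rec.data[3, 2500] = 500.0
        ep = epoch_and_detrend(rec)
        out = reject_epochs_amplitude(ep, 100.0)
        assert list(out.kept_mask) == [True, True, False, True]
        np.testing.assert_array_equal(out.epochs, ep.epochs)

    def test_quiet_data_all_kept(self):
        ep = epoch_and_detrend(rec_from(np.zeros((7, 3000))))
        assert reject_epochs_amplitude(ep, 100.0).n_kept == 3

    def test_all_rejected_makes_downstream_error(self):
        ep = epoch_and_detrend(white_recording(3000, scale=50.0))
        out = reject_epochs_amplitude(ep, 1e-3)
        with pytest.raises(ValueError, match="no epochs"):
            out.kept_epochs()


def _epochset_from_matrix(x, fs=1000.0):
    n_ep = x.shape[1] // int(fs)
    ep = x[:, : n_ep * int(fs)].reshape(x.shape[0], n_ep, int(fs)).swapaxes(0, 1)
    return EpochSet(
        epochs=np.ascontiguousarray(ep), fs=fs, montage=HEX2,
        kept_mask=np.ones(n_ep, bool),
    )


class TestICA:
    def test_recovers_independent_sources(self):
        rng = np.random.default_rng(0)
        sources = rng.laplace(size=(3, 12000))
        mixing = rng.normal(size=(7, 3))
        ep = _epochset_from_matrix(mixing @ sources)
        dec = decompose_ica(ep, n_components=3, rng_seed=0)
        for k in range(3):
            cors = np.abs(np.corrcoef(np.vstack([sources[k], dec.sources]))[0, 1:])
            assert cors.max() >= 0.95

    def test_reconstruction_identity_when_nothing_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 6000))
        ep = _epochset_from_matrix(x)
        dec = decompose_ica(ep, rng_seed=0)
        clean = reconstruct_clean(dec, ep)
        err = np.linalg.norm(clean.epochs - ep.epochs) / np.linalg.norm(ep.epochs)
        assert err <= 1e-6

    def test_seeded_determinism_up_to_sign(self):
        rng = np.random.default_rng(3)
        x = rng.laplace(size=(7, 8000))
        ep = _epochset_from_matrix(x)
        a = decompose_ica(ep, n_components=4, rng_seed=7)
        b = decompose_ica(ep, n_components=4, rng_seed=7)
        np.testing.assert_allclose(np.abs(a.mixing), np.abs(b.mixing), atol=1e-8)

    def test_rank_deficiency_errors_with_suggestion(self):
        rng = np.random.default_rng(4)
        low_rank = rng.normal(size=(7, 2)) @ rng.normal(size=(2, 5000))
        ep = _epochset_from_matrix(low_rank)
        with pytest.raises(ValueError, match="fewer components"):
            decompose_ica(ep, n_components=5, rng_seed=0)


def _manual_decomposition(mixing, sources, fs=1000.0):
    return ComponentDecomposition(
        mixing=np.asarray(mixing, float), sources=np.asarray(sources, float),
        mean=np.zeros(np.asarray(mixing).shape[0]), fs=fs, montage=HEX2,
    )


class TestAutoFlagging:
    def test_single_channel_topography_flagged(self):
        t = np.arange(5000) / 1000.0
        mixing = np.zeros((7, 2))
        mixing[0, 0] = 1.0          # one-channel component
        mixing[:, 1] = 0.5          # distributed component
        sources = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 5 * t)])
        dec = auto_flag_components(_manual_decomposition(mixing, sources))
        assert dec.rejected == {0: "single_channel"}

    def test_forty_hz_source_flagged_as_muscle(self):
        t = np.arange(5000) / 1000.0
        mixing = np.full((7, 2), 0.5)
        sources = np.vstack([np.sin(2 * np.pi * 40 * t), np.sin(2 * np.pi * 10 * t)])
        dec = auto_flag_components(_manual_decomposition(mixing, sources))
        assert dec.rejected == {0: "muscle_band"}


class TestTemplateFlagging:
    def test_blink_template_match(self):
        rng = np.random.default_rng(0)
        topo = np.array([1.0, 0.9, 0.8, 0.1, 0.05, 0.0, 0.0])
        t = np.arange(8000) / 1000.0
        blink_src = np.exp(-(((t % 2.0) - 1.0) / 0.08) ** 2)  # slow bursts
        noise_src = rng.standard_normal(8000)
        mixing = np.stack([topo, rng.uniform(-1, 1, 7)], axis=1)
        dec = _manual_decomposition(mixing, np.vstack([blink_src, noise_src]))
        dec = flag_stereotyped_artifacts(dec, [ArtifactTemplate("blink", topo)])
        assert dec.rejected == {0: "blink"}

    def test_no_template_match_flags_nothing(self):
        rng = np.random.default_rng(1)
        dec = _manual_decomposition(rng.normal(size=(7, 2)), rng.normal(size=(2, 4000)))
        tpl = ArtifactTemplate("blink", np.array([1.0, -1, 1, -1, 1, -1, 1]))
        assert flag_stereotyped_artifacts(dec, [tpl]).rejected == {}

    def test_cardiac_periodicity_gate(self):
        topo = np.linspace(0.2, 1.0, 7)
        period = 1.0 / 1.2
        n = 10000
        src = np.zeros(n)
        beats = (np.arange(0.3, 9.5, period) * 1000).astype(int)
        src[beats] = 1.0  # ~1.2 Hz impulse train
        other = np.sin(2 * np.pi * 3.0 * np.arange(n) / 1000.0)  # periodic, wrong rate
        mixing = np.stack([topo, topo], axis=1)
        dec = _manual_decomposition(mixing, np.vstack([src, other]))
        tpl = ArtifactTemplate("cardiac", topo, period_s=period)
        dec = flag_stereotyped_artifacts(dec, [tpl])
        assert dec.rejected == {0: "cardiac"}


class TestReconstruction:
    def test_flagging_the_artifact_removes_its_energy(self):
        rng = np.random.default_rng(5)
        t = np.arange(12000) / 1000.0
        artifact_src = np.exp(-(((t % 1.5) - 0.75) / 0.1) ** 2)  # slow burst train
        artifact_src -= artifact_src.mean()  # channel means are not part of any component
        neural = rng.laplace(size=(2, 12000))
        mixing = rng.normal(size=(7, 3))
        artifact_signal = np.outer(mixing[:, 0], 30 * artifact_src)
        x = artifact_signal + mixing[:, 1:] @ neural
        ep = _epochset_from_matrix(x)
        dec = decompose_ica(ep, n_components=3, rng_seed=0)
        dec = flag_stereotyped_artifacts(dec, [ArtifactTemplate("blink", mixing[:, 0])])
        assert len(dec.rejected) >= 1
        clean = reconstruct_clean(dec, ep)
        removed = ep.epochs - clean.epochs
        art_ep = _epochset_from_matrix(artifact_signal).epochs
        residual = art_ep - removed
        assert (residual**2).sum() <= 0.1 * (art_ep**2).sum()

    def test_flagging_everything_errors(self):
        rng = np.random.default_rng(6)
        ep = _epochset_from_matrix(rng.normal(size=(7, 4000)))
        dec = decompose_ica(ep, n_components=2, rng_seed=0)
        dec.flag(0, "manual")
        dec.flag(1, "manual")
        with pytest.raises(ValueError, match="no neural components"):
            reconstruct_clean(dec, ep)


def test_pipeline_order_recorded_in_provenance():
    rec = white_recording(4000, scale=5.0)
    ep = clean_pipeline(rec, PreprocessConfig(ica=False))
    text = " ".join(ep.provenance)
    assert "lowpass_hz=50.0" in text
    assert "reference=average" in text
    assert "detrend=linear" in text
    assert "amp_reject_uv=100.0" in text
    assert "ica=skipped" in text


def test_epoch_export_writes_csv_and_sidecar(tmp_path):
    rec = white_recording(3000, scale=5.0)
    ep = clean_pipeline(rec, PreprocessConfig(ica=False))
    path = tmp_path / "epochs.csv"
    ep.export_csv(path)
    import json

    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == list(rec.montage.lead_ids)
    assert len(df) == ep.n_kept * 1000
    sidecar = json.loads((tmp_path / "epochs.csv.json").read_text())
    assert sidecar["fs"] == 1000.0
    assert len(sidecar["kept_mask"]) == 3
    assert any("lowpass" in step for step in sidecar["provenance"])
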