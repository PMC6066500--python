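"""Shared fixtures: small montages, reduced ROI sets, chain helpers."""

from __future__ import annotations

import numpy as np
import pytest

from eegtrack.montage import (
    Montage,
    RoiSet,
    build_synthetic_montage,
    default_roi_config,
    seed_roi_from_neighbors,
)
from eegtrack.preprocess import Recording, epoch_and_detrend, lowpass, rereference_average


@pytest.fixture(scope="session")
def hex5():
    return build_synthetic_montage(5, "C3")


@pytest.fixture(scope="session")
def hex4():
    return build_synthetic_montage(4, "C3")


@pytest.fixture(scope="session")
def hex3():
    return build_synthetic_montage(3, "C3")


@pytest.fixture(scope="session")
def rois5(hex5):
    return default_roi_config(hex5)


@pytest.fixture(scope="session")
def rois4(hex4):
    return default_roi_config(hex4)


def reduced_rois(montage: Montage, n_par: int = 6, n_ctrl: int = 3) -> RoiSet:
    """Minimal ROI set (iM1 seed + posterior-lateral iPAR + one control) for
    montages too small for the shipped default layout."""
    im1 = seed_roi_from_neighbors(montage, "C3")
    others = [l for l in montage.lead_ids if l not in im1]
    pos = {l: montage.position_of(l) for l in others}
    ipar = sorted(others, key=lambda l: (pos[l][0] * 0.5 + pos[l][1]))[:n_par]
    rest = [l for l in others if l not in ipar]
    iv1 = sorted(rest, key=lambda l: pos[l][1])[:n_ctrl]
    return RoiSet(
        {"iM1": tuple(im1), "iPAR": tuple(ipar), "iV1": tuple(iv1)},
        primary_pair=("iM1", "iPAR"),
        control_pairs=(("iM1", "iV1"),),
    )


@pytest.fixture(scope="session")
def rois3(hex3):
    return reduced_rois(hex3)


def linear_chain_epochs(data: np.ndarray, fs: float, montage: Montage):
    """Project a lead-space signal through the (linear) pre-ICA chain:
    average reference -> low-pass -> 1-s epochs with detrend."""
    rec = Recording(data=data, fs=fs, montage=montage, reference="Cz")
    return epoch_and_detrend(lowpass(rereference_average(rec)))
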