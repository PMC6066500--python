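"""Electrode layouts, neighbor relations, and named ROI lead sets.

A :class:`Montage` is a set of labelled leads with 2-D (or 3-D) positions and a
symmetric, irreflexive neighbor graph.  ROI membership (which leads overlie
which cortical region) is configuration, not geometry: it is carried by a
:class:`RoiSet` that is validated against the montage.  The dense synthetic
layout used throughout the test-bench is a centered hexagonal grid whose
interior leads have exactly six neighbors, mirroring the "seed lead plus the
six immediately surrounding electrodes" rule used to define the primary motor
seed region.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "RoiSet",
    "build_synthetic_montage",
    "seed_roi_from_neighbors",
    "load_roi_config",
    "default_roi_config",
    "mirror_x",
]


@dataclass(frozen=True)
class Montage:
    """Electrode montage: unique lead labels, positions, neighbor graph.

    Parameters
    ----------
    lead_ids
        Unique text labels, one per lead.
    positions
        ``(n_leads, 2)`` or ``(n_leads, 3)`` array of coordinates in
        arbitrary head units, aligned with ``lead_ids``.
    neighbors
        Mapping lead label -> frozenset of neighboring labels.  Must be
        symmetric and irreflexive.
    """

    lead_ids: tuple[str, ...]
    positions: np.ndarray
    neighbors: dict[str, frozenset[str]] = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.lead_ids
        if len(set(ids)) != len(ids):
            raise ValueError("lead labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape[0] != len(ids) or pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise ValueError("positions must be (n_leads, 2|3) aligned with lead_ids")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        for lead, nbrs in self.neighbors.items():
            if lead not in self._index:
                raise ValueError(f"neighbor graph names unknown lead {lead!r}")
            if lead in nbrs:
                raise ValueError(f"neighbor graph is reflexive at {lead!r}")
            for other in nbrs:
                if lead not in self.neighbors.get(other, frozenset()):
                    raise ValueError(f"neighbor graph not symmetric: {lead!r}<->{other!r}")

    @property
    def _index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.lead_ids)}

    @property
    def n_leads(self) -> int:
        return len(self.lead_ids)

    def position_of(self, lead: str) -> np.ndarray:
        return self.positions[self._index[lead]]

    def index_of(self, leads) -> np.ndarray:
        """Integer row indices for a sequence of lead labels."""
        idx = self._index
        return np.array([idx[l] for l in leads], dtype=int)

    # ---- I/O -----------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, neighbor_scale: float = 1.5) -> "Montage":
        """Read a montage from CSV with columns lead_id,x,y(,z).

        Neighbor relations for user-supplied montages fall back to a distance
        rule: two leads are neighbors when their separation is at most
        ``neighbor_scale`` times the global minimum inter-lead distance.
        """
        df = pd.read_csv(path, dtype={"lead_id": str})
        cols = [c for c in ("x", "y", "z") if c in df.columns]
        if "lead_id" not in df.columns or len(cols) < 2:
            raise ValueError("montage CSV needs columns lead_id,x,y(,z)")
        ids = tuple(df["lead_id"].tolist())
        pos = df[cols].to_numpy(dtype=float)
        return cls(ids, pos, _distance_neighbors(ids, pos, neighbor_scale))

    def to_csv(self, path: str | Path) -> None:
        cols = ["x", "y", "z"][: self.positions.shape[1]]
        df = pd.DataFrame(self.positions, columns=cols)
        df.insert(0, "lead_id", self.lead_ids)
        df.to_csv(path, index=False)


def _distance_neighbors(ids, pos, scale: float) -> dict[str, frozenset[str]]:
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    cutoff = scale * d.min()
    nbrs: dict[str, frozenset[str]] = {}
    for i, lab in enumerate(ids):
        nbrs[lab] = frozenset(ids[j] for j in np.nonzero(d[i] <= cutoff)[0])
    return nbrs


def build_synthetic_montage(n_rings: int, seed_label: str = "C3") -> Montage:
    """Centered hexagonal grid with ``1 + 3*r*(r-1)`` leads for ``r = n_rings``.

    The center lead is labelled ``seed_label``; all other leads are labelled
    ``E001`` ... in a deterministic (ring, angle) order.  Interior leads have
    exactly 6 neighbors (unit-distance adjacency); edge leads fewer.
    """
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    # axial hex coordinates -> cartesian, unit spacing
    coords = [(0, 0)]
    for ring in range(1, n_rings):
        q, r = ring, 0
        directions = [(-1, 1), (-1, 0), (0, -1), (1, -1), (1, 0), (0, 1)]
        for dq, dr in directions:
            for _ in range(ring):
                coords.append((q, r))
                q, r = q + dq, r + dr
    pos = np.array([(q + r / 2.0, r * math.sqrt(3) / 2.0) for q, r in coords])
    ids = [seed_label] + [f"E{k:03d}" for k in range(1, len(coords))]
    nbrs: dict[str, set[str]] = {lab: set() for lab in ids}
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    for i, j in zip(*np.nonzero(np.abs(d - 1.0) < 1e-9)):
        if i < j:
            nbrs[ids[i]].add(ids[j])
            nbrs[ids[j]].add(ids[i])
    return Montage(tuple(ids), pos, {k: frozenset(v) for k, v in nbrs.items()})


def mirror_x(montage: Montage) -> Montage:
    """Montage reflected across the midline (x -> -x); labels unchanged.

    Used to express ipsilesional lead sets for right-hemisphere lesions as
    mirror images of the left-hemisphere configuration.
    """
    pos = montage.positions.copy()
    pos[:, 0] = -pos[:, 0]
    return Montage(montage.lead_ids, pos, montage.neighbors)


def seed_roi_from_neighbors(montage: Montage, center: str) -> list[str]:
    """Seed ROI: ``center`` plus its six nearest neighbors (7 leads total).

    Neighbors come from the montage graph; if more than six are adjacent the
    six nearest by Euclidean distance are kept, with residual ties broken by
    label order.
    """
    if center not in montage.neighbors:
        raise KeyError(f"lead {center!r} not in montage")
    nbrs = sorted(montage.neighbors[center])
    if len(nbrs) < 6:
        raise ValueError(
            f"lead {center!r} has only {len(nbrs)} neighbors; 6 required for the seed ROI"
        )
    c = montage.position_of(center)
    ranked = sorted(nbrs, key=lambda l: (round(float(np.linalg.norm(montage.position_of(l) - c)), 12), l))
    return [center] + ranked[:6]


@dataclass(frozen=True)
class RoiSet:
    """Named ROI lead sets plus the primary and control circuit pairs.

    The same lead may belong to several ROIs (boundary cortex) but never
    twice within one ROI.
    """

    rois: dict[str, tuple[str, ...]]
    primary_pair: tuple[str, str] = ("iM1", "iPAR")
    control_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for name, leads in self.rois.items():
            if len(leads) == 0:
                raise ValueError(f"ROI {name!r} is empty")
            if len(set(leads)) != len(leads):
                raise ValueError(f"ROI {name!r} lists a lead twice")
        for pair in [self.primary_pair, *self.control_pairs]:
            for name in pair:
                if name not in self.rois:
                    raise ValueError(f"circuit pair references unknown ROI {name!r}")

    @property
    def circuits(self) -> list[tuple[str, str]]:
        """Primary pair first, then control pairs, duplicates removed."""
        seen, out = set(), []
        for pair in [tuple(self.primary_pair), *map(tuple, self.control_pairs)]:
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
        return out

    def validate_against(self, montage: Montage) -> None:
        known = set(montage.lead_ids)
        bad = sorted({l for leads in self.rois.values() for l in leads if l not in known})
        if bad:
            raise ValueError(f"ROI config names leads absent from the montage: {bad}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rois": {k: list(v) for k, v in self.rois.items()},
            "primary_pair": list(self.primary_pair),
            "control_pairs": [list(p) for p in self.control_pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def load_roi_config(path: str | Path, montage: Montage) -> RoiSet:
    """Load and validate a JSON ROI configuration against a montage."""
    payload = json.loads(Path(path).read_text())
    rois = {str(k): tuple(map(str, v)) for k, v in payload["rois"].items()}
    primary = tuple(payload.get("primary_pair", ("iM1", "iPAR")))
    controls = tuple(tuple(p) for p in payload.get("control_pairs", ()))
    rs = RoiSet(rois=rois, primary_pair=primary, control_pairs=controls)
    rs.validate_against(montage)
    return rs


# Anchor points for the default synthetic ROI layout, in units of the montage
# radius, with the seed (ipsilesional M1) at the origin, +y anterior, and the
# midline lying toward +x.
_ROI_ANCHORS = {
    "iPAR": (-0.45, -0.70),
    "cM1": (0.90, 0.05),
    "cPAR": (0.80, -0.50),
    "iPMd": (-0.35, 0.50),
    "iPf": (-0.50, 0.85),
    "iMedPr": (0.40, -0.70),
    "iV1": (0.05, -0.95),
}

_DEFAULT_CONTROL_PAIRS = (
    ("iM1", "cPAR"),
    ("iM1", "cM1"),
    ("iM1", "iPMd"),
    ("iM1", "iPf"),
    ("iM1", "iMedPr"),
    ("iM1", "iV1"),
)


def default_roi_config(montage: Montage, seed: str = "C3") -> RoiSet:
    """Default ROI lead sets for the synthetic hexagonal montage.

    iM1 is the seed rule (center + 6 neighbors, 7 leads).  iPAR takes 21
    leads on montages with >= 61 leads, scaled down on smaller grids.  Six
    control regions (contralesional M1/PAR, ipsilesional dorsal premotor,
    prefrontal, medial parietal, and primary visual) are greedy
    nearest-to-anchor patches, all mutually disjoint.
    """
    im1 = seed_roi_from_neighbors(montage, seed)
    n = montage.n_leads
    ipar_n = 21 if n >= 61 else max(3, (n - 7) // 4)
    ctrl_n = min(7, max(3, (n - 7 - ipar_n) // 8))
    taken = set(im1)
    pos = montage.positions[:, :2]
    radius = float(np.linalg.norm(pos - montage.position_of(seed)[:2], axis=1).max())
    rois: dict[str, tuple[str, ...]] = {"iM1": tuple(im1)}

    def grab(anchor_xy, count) -> tuple[str, ...]:
        ax = montage.position_of(seed)[:2] + radius * np.asarray(anchor_xy)
        order = np.argsort(np.linalg.norm(pos - ax, axis=1), kind="stable")
        picked = []
        for i in order:
            lab = montage.lead_ids[i]
            if lab not in taken:
                picked.append(lab)
                taken.add(lab)
            if len(picked) == count:
                break
        if len(picked) < count:
            raise ValueError("montage too small for the default ROI layout")
        return tuple(picked)

    rois["iPAR"] = grab(_ROI_ANCHORS["iPAR"], ipar_n)
    for name in ("cM1", "cPAR", "iPMd", "iPf", "iMedPr", "iV1"):
        rois[name] = grab(_ROI_ANCHORS[name], ctrl_n)
    rs = RoiSet(rois=rois, primary_pair=("iM1", "iPAR"), control_pairs=_DEFAULT_CONTROL_PAIRS)
    rs.validate_against(montage)
    return rs
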