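"""Kyte–Doolittle hydropathy mapped onto the exposed surface and spatially
smoothed over a fixed-radius neighborhood.

Each surface residue gets the KD index of its type (raw value) and the
unweighted arithmetic mean of the raw values of all surface residues whose
Cα lies within ``radius`` Å of its own Cα, itself included (smoothed value).
A 6 Å radius reproduces the surface-coloring quantity used for solenoid
repeat proteins such as huntingtin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .constants import KD_SCALE
from .errors import EmptyInputError
from .sasa import SurfaceSet
from .structure import ResidueKey, StructureModel

logger = logging.getLogger(__name__)


@dataclass
class ResidueHydropathy:
    raw_kd: float
    smoothed_kd: float
    n_neighbors: int


@dataclass
class HydropathyMap:
    entries: dict[ResidueKey, ResidueHydropathy]
    radius: float

    def __getitem__(self, key: ResidueKey) -> ResidueHydropathy:
        return self.entries[key]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def smoothed(self) -> dict[ResidueKey, float]:
        return {k: e.smoothed_kd for k, e in self.entries.items()}

    def write_tsv(self, path: str | Path) -> None:
        lines = ["chain\tauth_number\ticode\traw_kd\tsmoothed_kd\tn_neighbors"]
        for key, e in self.entries.items():
            lines.append(
                f"{key.chain_id}\t{key.auth_number}\t{key.insertion_code}\t"
                f"{e.raw_kd:.2f}\t{e.smoothed_kd:.4f}\t{e.n_neighbors}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class HydropathySummary:
    smoothed_min: float
    smoothed_mean: float
    smoothed_max: float
    raw_min: float
    raw_max: float
    n: int

    def to_dict(self) -> dict:
        return {
            "smoothed_min": self.smoothed_min,
            "smoothed_mean": self.smoothed_mean,
            "smoothed_max": self.smoothed_max,
            "raw_min": self.raw_min,
            "raw_max": self.raw_max,
            "n": self.n,
        }


def smooth_kd(
    surface: SurfaceSet,
    model: StructureModel,
    scale: Mapping[str, float] = KD_SCALE,
    radius: float = 6.0,
) -> HydropathyMap:
    """Spatially smoothed KD hydropathy over the surface residues.

    Surface residues lacking a Cα atom or with a type outside the scale are
    skipped with a warning. Neighborhood membership is Cα–Cα distance
    <= radius, self included; the mean is unweighted.
    """
    if len(surface) == 0:
        raise EmptyInputError("surface set is empty; nothing to smooth")
    keys: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    raw: list[float] = []
    for key in surface:
        res = model.get_residue(key)
        ca = res.ca
        if ca is None:
            logger.warning("surface residue %s has no CA atom; skipped", key)
            continue
        if not res.is_standard or res.res_type not in scale:
            logger.warning("surface residue %s type %s not on the hydropathy scale; skipped", key, res.res_type)
            continue
        keys.append(key)
        coords.append(ca.coord)
        raw.append(float(scale[res.res_type]))
    if not keys:
        raise EmptyInputError("no surface residue has a usable CA atom")
    xyz = np.asarray(coords)
    raw_arr = np.asarray(raw)
    tree = cKDTree(xyz)
    neighbors = tree.query_ball_point(xyz, r=radius)
    entries: dict[ResidueKey, ResidueHydropathy] = {}
    for i, key in enumerate(keys):
        idx = neighbors[i]
        entries[key] = ResidueHydropathy(
            raw_kd=raw_arr[i],
            smoothed_kd=float(raw_arr[idx].mean()),
            n_neighbors=len(idx),
        )
    return HydropathyMap(entries=entries, radius=radius)


def hydropathy_summary(hmap: HydropathyMap) -> HydropathySummary:
    """Extremes and unweighted mean of the smoothed values (raw extremes kept
    alongside, since an isolated residue makes the two coincide)."""
    if len(hmap) == 0:
        raise EmptyInputError("hydropathy map is empty")
    smoothed = np.array([e.smoothed_kd for e in hmap.entries.values()])
    raw = np.array([e.raw_kd for e in hmap.entries.values()])
    return HydropathySummary(
        smoothed_min=float(smoothed.min()),
        smoothed_mean=float(smoothed.mean()),
        smoothed_max=float(smoothed.max()),
        raw_min=float(raw.min()),
        raw_max=float(raw.max()),
        n=len(hmap),
    )
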