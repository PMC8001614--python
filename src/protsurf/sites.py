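"""Externally predicted annotation tracks and their spatial analysis.

Two track classes are consumed, never computed here: residue-level
protein–protein interaction-site predictions (tabular: chain, author number,
insertion code, type, score) and metal-ion site predictions (tabular: x, y,
z, label). The module clusters interaction residues into spatial patches
(connected components of the Cα–Cα contact graph below a cutoff, strictly
"<" at 6 Å by default), extracts residues whose heavy atoms fall within a
coordination-shell radius of an ion center (inclusive "<=" at 3.5 Å by
default), and reports overlap and domain assignment between residue sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ParameterError, ValidationError
from .structure import ResidueKey, StructureModel

logger = logging.getLogger(__name__)

_SITE_COLUMNS = ["chain", "auth_number", "icode", "res_type", "score"]
_ION_COLUMNS = ["x", "y", "z", "label"]


@dataclass
class InteractionSiteSet:
    """Residues predicted to sit in protein–protein interfaces."""

    scores: dict[ResidueKey, float]
    score_threshold: float | None = None
    source: str = ""

    @property
    def residues(self) -> frozenset[ResidueKey]:
        return frozenset(self.scores)

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)


@dataclass
class IonSiteSet:
    """Predicted metal-ion centers (Å coordinates) with confidence labels."""

    points: np.ndarray  # (n, 3)
    labels: list[str]
    neighborhood_radius: float = 3.5
    source: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ParameterError("ion coordinates must be finite")
        if not self.neighborhood_radius > 0:
            raise ParameterError("neighborhood radius must be positive")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PatchSet:
    """Partition of interaction residues into spatially connected patches."""

    patches: list[frozenset[ResidueKey]]
    cutoff: float

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def sizes(self) -> list[int]:
        return sorted((len(p) for p in self.patches), reverse=True)

    def membership(self) -> dict[ResidueKey, int]:
        return {key: i for i, patch in enumerate(self.patches) for key in patch}

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_patches": self.n_patches,
            "sizes": self.sizes(),
            "patches": [sorted([list(k) for k in p]) for p in self.patches],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    intersection: list[ResidueKey]
    n_intersection: int
    n_union: int
    jaccard: float

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_intersection": self.n_intersection,
            "n_union": self.n_union,
            "jaccard": self.jaccard,
            "intersection": [list(k) for k in self.intersection],
        }


@dataclass
class DomainMap:
    """Named author-numbering intervals (inclusive); residues may be unassigned."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        for name, start, end in self.intervals:
            if start > end:
                raise ConfigurationError(f"domain {name!r}: start {start} > end {end}")

    @classmethod
    def from_file(cls, path: str | Path) -> "DomainMap":
        """TSV with columns name, start, end."""
        df = pd.read_csv(path, sep="\t", dtype={"name": str, "start": int, "end": int})
        missing = {"name", "start", "end"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"domain map {path}: missing columns {sorted(missing)}")
        return cls([(r["name"], int(r["start"]), int(r["end"])) for _, r in df.iterrows()])


def load_site_track(
    path: str | Path,
    model: StructureModel,
    score_threshold: float | None = None,
) -> InteractionSiteSet:
    """Read an interaction-site track (TSV with header
    chain/auth_number/icode/res_type/score) and validate it against the model.

    Unresolvable keys raise :class:`ValidationError` listing every offender;
    residue-type mismatches are reported as warnings. By default every listed
    residue is kept; a ``score_threshold`` filters raw probability tracks.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"chain": str, "icode": str}, keep_default_na=False
    )
    if df.empty and not set(_SITE_COLUMNS) <= set(df.columns):
        return InteractionSiteSet({}, score_threshold, source=str(path))
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"site track {path}: missing columns {sorted(missing)}")
    scores: dict[ResidueKey, float] = {}
    offenders: list[ResidueKey] = []
    for _, row in df.iterrows():
        score = float(row["score"])
        if not 0.0 <= score <= 1.0:
            raise ConfigurationError(
                f"site track {path}: score {score} outside [0, 1]"
            )
        key = ResidueKey(str(row["chain"]), int(row["auth_number"]), str(row["icode"]).strip())
        if key not in model:
            offenders.append(key)
            continue
        res = model.get_residue(key)
        if str(row["res_type"]).upper() not in (res.res_type, res.original_type):
            logger.warning(
                "site track %s: residue %s listed as %s but model has %s",
                path, key, row["res_type"], res.res_type,
            )
        if score_threshold is None or score >= score_threshold:
            scores[key] = score
    if offenders:
        raise ValidationError(
            f"site track {path}: {len(offenders)} residues not in model: "
            + ", ".join(map(str, offenders[:10])),
            offenders=offenders,
        )
    return InteractionSiteSet(scores, score_threshold, source=str(path))


def load_ion_track(path: str | Path, neighborhood_radius: float = 3.5) -> IonSiteSet:
    """Read an ion-site track: TSV with header x/y/z/label."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"label": str}, keep_default_na=False)
    if df.empty:
        return IonSiteSet(np.empty((0, 3)), [], neighborhood_radius, source=str(path))
    missing = set(_ION_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"ion track {path}: missing columns {sorted(missing)}")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    return IonSiteSet(pts, list(df["label"]), neighborhood_radius, source=str(path))


def cluster_patches(
    sites: InteractionSiteSet,
    model: StructureModel,
    cutoff: float = 6.0,
) -> PatchSet:
    """Connected components of the site-residue graph with an edge wherever
    the Cα–Cα distance is strictly below ``cutoff``.

    Singleton components are patches. Site residues without a Cα are skipped
    with a warning. Patches are ordered by their lowest residue key.
    """
    if not cutoff > 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    keys: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    for key in sorted(sites.scores):
        ca = model.get_residue(key).ca
        if ca is None:
            logger.warning("site residue %s has no CA atom; skipped", key)
            continue
        keys.append(key)
        coords.append(ca.coord)
    graph = nx.Graph()
    graph.add_nodes_from(keys)
    if keys:
        xyz = np.asarray(coords)
        tree = cKDTree(xyz)
        for i, j in tree.query_pairs(r=cutoff):
            if np.linalg.norm(xyz[i] - xyz[j]) < cutoff:  # strict "<"
                graph.add_edge(keys[i], keys[j])
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda p: min(p))
    return PatchSet(patches=comps, cutoff=cutoff)


def ion_neighborhood(
    ions: IonSiteSet,
    model: StructureModel,
    radius: float | None = None,
    atom_mode: str = "heavy",
) -> frozenset[ResidueKey]:
    """Residues with any heavy atom within ``radius`` Å (inclusive) of any ion
    center, deduplicated across ions.

    ``atom_mode="ca"`` restricts the distance test to Cα atoms — a 3.5 Å
    coordination shell is normally unreachable from Cα, so the default is all
    heavy atoms.
    """
    if radius is None:
        radius = ions.neighborhood_radius
    if not radius > 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if atom_mode not in ("heavy", "ca"):
        raise ConfigurationError(f"unknown atom_mode {atom_mode!r}")
    if len(ions) == 0:
        return frozenset()
    coords: list[np.ndarray] = []
    owner: list[ResidueKey] = []
    for res in model.residues():
        for atom in res.atoms:
            if atom_mode == "ca" and atom.name != "CA":
                continue
            coords.append(atom.coord)
            owner.append(res.key)
    if not coords:
        return frozenset()
    tree = cKDTree(np.asarray(coords))
    hits: set[ResidueKey] = set()
    for idx_list in tree.query_ball_point(ions.points, r=radius):
        hits.update(owner[i] for i in idx_list)
    return frozenset(hits)


def overlap(a: Iterable[ResidueKey], b: Iterable[ResidueKey]) -> OverlapReport:
    """Set overlap between two residue-key sets, with Jaccard index."""
    sa, sb = set(a), set(b)
    inter = sa & sb
    union = sa | sb
    return OverlapReport(
        n_a=len(sa),
        n_b=len(sb),
        intersection=sorted(inter),
        n_intersection=len(inter),
        n_union=len(union),
        jaccard=len(inter) / len(union) if union else 0.0,
    )


def assign_domains(
    residues: Iterable[ResidueKey],
    domains: DomainMap,
) -> dict[str, int]:
    """Count residues per named interval; first matching interval wins.

    Returns counts per domain name plus an ``"unassigned"`` bucket.
    Overlapping intervals trigger a configuration warning.
    """
    ivs = domains.intervals
    for i, (n1, s1, e1) in enumerate(ivs):
        for n2, s2, e2 in ivs[i + 1 :]:
            if s1 <= e2 and s2 <= e1:
                logger.warning(
                    "domain intervals %r and %r overlap; first-match rule applies", n1, n2
                )
    counts = {name: 0 for name, _, _ in ivs}
    counts["unassigned"] = 0
    for key in residues:
        for name, start, end in ivs:
            if start <= key.auth_number <= end:
                counts[name] += 1
                break
        else:
            counts["unassigned"] += 1
    return counts


def site_annotation_values(
    interaction: Iterable[ResidueKey],
    ion_neighbors: Iterable[ResidueKey],
) -> dict[ResidueKey, float]:
    """Per-residue code for annotated-PDB export: interaction-only = 1,
    ion-neighbor-only = 2, both = 3."""
    si, sn = set(interaction), set(ion_neighbors)
    values: dict[ResidueKey, float] = {}
    for key in si | sn:
        values[key] = 3.0 if (key in si and key in sn) else (1.0 if key in si else 2.0)
    return values
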