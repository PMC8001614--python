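"""Structural model: reading PDB/mmCIF coordinates, chain coverage and
backbone-gap accounting, and writing B-factor-annotated PDB files.

The residue identity key used throughout the package is
``ResidueKey(chain_id, auth_number, insertion_code)`` with author (deposited)
numbering, so intervals quoted in the literature map directly onto model
residues.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import gemmi
import numpy as np

from .constants import VDW_RADII, standardize_res_type
from .errors import (
    ConfigurationError,
    EmptyStructureError,
    FormattingError,
    LookupError_,
    ParameterError,
    ParseError,
)

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ResidueKey(NamedTuple):
    """Unique residue identity: chain, author number, insertion code ('' if none)."""

    chain_id: str
    auth_number: int
    insertion_code: str = ""


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    vdw_radius: float
    is_hetero: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise ValueError(f"atom {self.name}: vdw radius must be positive")


@dataclass
class ResidueRecord:
    chain_id: str
    auth_number: int
    insertion_code: str
    res_type: str  # standardized 3-letter code (MSE -> MET etc.)
    atoms: list[AtomRecord]
    is_standard: bool = True
    original_type: str = ""

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.auth_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class StructureModel:
    """Parsed atomic coordinates: ordered chains of residues in author numbering."""

    entry_id: str
    chains: dict[str, list[ResidueRecord]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for cid, residues in self.chains.items():
            order = [(r.auth_number, r.insertion_code) for r in residues]
            if any(b <= a for a, b in zip(order, order[1:])):
                raise ValueError(f"chain {cid}: residues not strictly increasing")

    def residues(self, chain_id: str | None = None) -> Iterator[ResidueRecord]:
        if chain_id is not None:
            if chain_id not in self.chains:
                raise LookupError_(f"chain {chain_id!r} not in model {self.entry_id}")
            yield from self.chains[chain_id]
        else:
            for residues in self.chains.values():
                yield from residues

    def get_residue(self, key: ResidueKey) -> ResidueRecord:
        index = self._index()
        if key not in index:
            raise LookupError_(f"residue {key} not in model {self.entry_id}")
        return index[key]

    def _index(self) -> dict[ResidueKey, ResidueRecord]:
        if not hasattr(self, "_key_index"):
            self._key_index = {r.key: r for r in self.residues()}
        return self._key_index

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index()

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def longest_polymer_chain(self) -> str:
        """Chain id with the most standard residues (the analysis default)."""
        best = max(
            self.chains,
            key=lambda c: sum(1 for r in self.chains[c] if r.is_standard),
        )
        return best


@dataclass
class GapReport:
    chain_id: str
    region: tuple[int, int]
    n_solved: int
    gaps: list[tuple[int, int]]
    n_gaps: int
    longest_gap: tuple[int, int] | None
    coverage_fraction: float

    def to_dict(self) -> dict:
        return {
            "chain_id": self.chain_id,
            "region": list(self.region),
            "n_solved": self.n_solved,
            "gaps": [list(g) for g in self.gaps],
            "n_gaps": self.n_gaps,
            "longest_gap": list(self.longest_gap) if self.longest_gap else None,
            "coverage_fraction": self.coverage_fraction,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        lines = ["gap_start\tgap_end\tlength"]
        for a, b in self.gaps:
            lines.append(f"{a}\t{b}\t{b - a + 1}")
        Path(path).write_text("\n".join(lines) + "\n")


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties by first altloc label."""
    chosen: dict[str, gemmi.Atom] = {}
    order: dict[str, int] = {}
    for i, atom in enumerate(res):
        prev = chosen.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            if prev is None:
                order[atom.name] = i
            chosen[atom.name] = atom
    return [chosen[name] for name in sorted(chosen, key=lambda n: order[n])]


def load_structure(
    path: str | Path,
    format: str = "auto",
    include_hydrogens: bool = False,
    radius_overrides: Mapping[str, float] | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model of multi-model files is used; waters are excluded;
    alternate locations resolve to the highest-occupancy conformer (ties by
    first label). Hydrogens are dropped unless ``include_hydrogens``.

    Raises :class:`ParseError` for unreadable files and
    :class:`EmptyStructureError` when no polymer residue survives filtering.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt_map = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if format not in fmt_map:
        raise ConfigurationError(f"unknown format {format!r} (use pdb/mmcif/auto)")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no coordinate model")
    st.setup_entities()
    model = st[0]

    radii = dict(VDW_RADII)
    if radius_overrides:
        radii.update({k.upper(): v for k, v in radius_overrides.items()})

    chains: dict[str, list[ResidueRecord]] = {}
    n_polymer = 0
    for chain in model:
        records: list[ResidueRecord] = []
        for res in chain:
            if res.name in _WATER_NAMES or res.is_water():
                continue
            res_type, is_std = standardize_res_type(res.name)
            is_het = res.het_flag == "H"
            atoms: list[AtomRecord] = []
            for atom in _pick_altlocs(res):
                element = atom.element.name.upper()
                if not include_hydrogens and element in ("H", "D"):
                    continue
                if element not in radii:
                    raise ConfigurationError(
                        f"no van der Waals radius for element {element!r} "
                        f"(atom {atom.name} in {chain.name} {res.seqid.num}); "
                        "provide radius_overrides"
                    )
                atoms.append(
                    AtomRecord(
                        name=atom.name,
                        element=element,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        vdw_radius=radii[element],
                        is_hetero=is_het,
                    )
                )
            if not atoms:
                continue
            if is_std:
                n_polymer += 1
            records.append(
                ResidueRecord(
                    chain_id=chain.name,
                    auth_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    res_type=res_type,
                    atoms=atoms,
                    is_standard=is_std,
                    original_type=res.name,
                )
            )
        if records:
            records.sort(key=lambda r: (r.auth_number, r.insertion_code))
            chains[chain.name] = records
    if n_polymer == 0:
        raise EmptyStructureError(f"{path}: no polymer residues with resolved atoms")
    entry_id = st.name or path.stem
    return StructureModel(
        entry_id=entry_id,
        chains=chains,
        provenance={"path": str(path), "format": format},
    )


def detect_gaps(
    model: StructureModel, chain_id: str, full_region: tuple[int, int]
) -> GapReport:
    """Find maximal runs of author numbers in ``full_region`` absent from a chain.

    Both interior and terminal gaps within the declared region count. Residues
    differing only by insertion code contribute a single author number, so
    ``n_solved + Σ gap lengths`` always equals the region length.
    """
    start, end = full_region
    if start > end:
        raise ParameterError(f"invalid region: start {start} > end {end}")
    if chain_id not in model.chains:
        raise LookupError_(f"chain {chain_id!r} not in model {model.entry_id}")
    present = {
        r.auth_number
        for r in model.chains[chain_id]
        if start <= r.auth_number <= end
    }
    gaps: list[tuple[int, int]] = []
    run_start: int | None = None
    for num in range(start, end + 1):
        if num not in present:
            if run_start is None:
                run_start = num
        elif run_start is not None:
            gaps.append((run_start, num - 1))
            run_start = None
    if run_start is not None:
        gaps.append((run_start, end))
    longest = max(gaps, key=lambda g: g[1] - g[0] + 1) if gaps else None
    region_len = end - start + 1
    return GapReport(
        chain_id=chain_id,
        region=(start, end),
        n_solved=len(present),
        gaps=gaps,
        n_gaps=len(gaps),
        longest_gap=longest,
        coverage_fraction=len(present) / region_len,
    )


def write_annotated_pdb(
    model: StructureModel,
    values: Mapping[ResidueKey, float],
    path: str | Path,
) -> None:
    """Write the model as PDB with each atom's B-factor set to its residue's
    value from ``values`` (0.0 where undefined).

    The PDB B-factor column holds %6.2f, so values must lie in [-99.99, 999.99].
    """
    for key, v in values.items():
        if not math.isfinite(v) or not (-99.99 <= v <= 999.99):
            raise FormattingError(
                f"value {v} for {key} does not fit the PDB B-factor column"
            )
    st = gemmi.Structure()
    st.name = model.entry_id
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.original_type or res.res_type
            gres.seqid = gemmi.SeqId(res.auth_number, res.insertion_code or " ")
            gres.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
            b = float(values.get(res.key, 0.0))
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = 1.0
                ga.b_iso = b
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def read_bfactor_map(path: str | Path) -> dict[ResidueKey, float]:
    """Recover the per-residue B-factor annotation from an annotated PDB."""
    model = load_structure(path, format="pdb")
    st = gemmi.read_structure(str(path))
    out: dict[ResidueKey, float] = {}
    for chain in st[0]:
        for res in chain:
            if res.is_water():
                continue
            key = ResidueKey(chain.name, res.seqid.num, (res.seqid.icode or "").strip())
            if len(res) > 0 and key in model:
                out[key] = res[0].b_iso
    return out
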