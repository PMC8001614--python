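"""Synthetic structures and prediction tracks with known ground truth.

The generator emulates the α-helical solenoid architecture of HEAT-repeat
proteins at the level the pipeline needs: each chain is an ideal α-helix
(φ = −57°, ψ = −47°, ω = 180°, ideal bond lengths and angles, so consecutive
Cα atoms sit ≈ 3.8 Å apart with a 1.5 Å rise per residue), helix axes are
parallel and separated by a configurable spacing, and each non-glycine
residue carries a single Cβ pseudo-atom in ideal geometry instead of a full
rotamer. Interaction-site tracks are planted as runs of consecutive residues
whose mutual Cα separation is verified against the clustering cutoff, and
ion points are placed at an exact offset from a chosen atom of each target
residue, so patch counts and neighborhoods are known by construction.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import ONE_TO_THREE, STANDARD_AA, VDW_RADII
from .errors import GenerationError
from .sites import InteractionSiteSet, IonSiteSet
from .structure import AtomRecord, ResidueKey, ResidueRecord, StructureModel

# ideal backbone internal coordinates (Engh–Huber-style values)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_BOND_CA_CB = 1.530
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_ANG_CA_C_O = 120.8
_ANG_N_CA_CB = 110.4
_PHI_HELIX = -57.0
_PSI_HELIX = -47.0
_PHI_EXT = -139.0
_PSI_EXT = 135.0

_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class BundleSpec:
    """Recipe for a multi-helix bundle.

    ``sequence`` fixes the per-helix sequence (1-letter string, recycled per
    helix); otherwise residue types are drawn from ``composition`` (3-letter
    code -> fraction summing to 1) with the given seed.
    """

    n_helices: int = 1
    residues_per_helix: int = 20
    inter_helix_spacing: float = 20.0
    sequence: str | None = None
    composition: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_helices < 1 or self.residues_per_helix < 1:
            raise GenerationError("n_helices and residues_per_helix must be positive")
        if self.n_helices > len(_CHAIN_IDS):
            raise GenerationError(f"at most {len(_CHAIN_IDS)} helices supported")
        if self.composition is not None:
            if abs(sum(self.composition.values()) - 1.0) > 1e-6:
                raise GenerationError("composition fractions must sum to 1")
            unknown = set(self.composition) - STANDARD_AA
            if unknown:
                raise GenerationError(f"unknown residue types in composition: {unknown}")


@dataclass
class PlantedTruth:
    """Ground truth carried alongside generated structures and tracks."""

    seed: int
    patches: list[list[ResidueKey]] = field(default_factory=list)
    expected_n_patches: int = 0
    ion_points: list[list[float]] = field(default_factory=list)
    ion_targets: list[ResidueKey] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "expected_n_patches": self.expected_n_patches,
            "patches": [[list(k) for k in p] for p in self.patches],
            "ion_points": self.ion_points,
            "ion_targets": [list(k) for k in self.ion_targets],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A-B-C."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O/CB-direction backbone for a chain with uniform (phi, psi)."""
    # seed triad for residue 1
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    coords.append(prev)
    for _ in range(1, n_res):
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANG_CA_C_N, psi)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i, _BOND_N_CA, _ANG_C_N_CA, 180.0)
        c_i = _place_atom(prev["C"], n_i, ca_i, _BOND_CA_C, _ANG_N_CA_C, phi)
        cur = {"N": n_i, "CA": ca_i, "C": c_i}
        coords.append(cur)
        prev = cur
    # carbonyl O: trans to the next N (dihedral psi+180 about CA-C); last O planar
    for i, res in enumerate(coords):
        res["O"] = _place_atom(
            res["N"], res["CA"], res["C"], _BOND_C_O, _ANG_CA_C_O, psi + 180.0
        )
    return coords


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ from the backbone triad (tetrahedral, correct chirality)."""
    b = ca - n
    c_v = c - ca
    a = np.cross(b, c_v)
    return ca + (-0.58273431 * a + 0.56802827 * b - 0.54067466 * c_v)


def _sequence_for(spec: BundleSpec, rng: np.random.Generator) -> list[str]:
    n = spec.residues_per_helix
    if spec.sequence is not None:
        seq3 = []
        for ch in spec.sequence:
            if ch.upper() not in ONE_TO_THREE:
                raise GenerationError(f"unknown 1-letter code {ch!r} in sequence")
            seq3.append(ONE_TO_THREE[ch.upper()])
        return [seq3[i % len(seq3)] for i in range(n)]
    if spec.composition is not None:
        types = sorted(spec.composition)
        probs = np.array([spec.composition[t] for t in types])
        return list(rng.choice(types, size=n, p=probs / probs.sum()))
    return ["ALA"] * n


def _make_residue(
    chain_id: str, number: int, res_type: str, bb: dict[str, np.ndarray]
) -> ResidueRecord:
    atoms = [
        AtomRecord("N", "N", bb["N"], VDW_RADII["N"]),
        AtomRecord("CA", "C", bb["CA"], VDW_RADII["C"]),
        AtomRecord("C", "C", bb["C"], VDW_RADII["C"]),
        AtomRecord("O", "O", bb["O"], VDW_RADII["O"]),
    ]
    if res_type != "GLY":
        atoms.append(
            AtomRecord("CB", "C", _cb_position(bb["N"], bb["CA"], bb["C"]), VDW_RADII["C"])
        )
    return ResidueRecord(
        chain_id=chain_id,
        auth_number=number,
        insertion_code="",
        res_type=res_type,
        atoms=atoms,
        is_standard=True,
        original_type=res_type,
    )


def build_helix_bundle(spec: BundleSpec) -> tuple[StructureModel, PlantedTruth]:
    """Generate a bundle of parallel ideal α-helices, one chain per helix.

    Helix k is translated by ``k * inter_helix_spacing`` along x after
    aligning its principal axis with z. Deterministic under ``spec.seed``
    (randomness enters only through composition sampling).
    """
    rng = np.random.default_rng(spec.seed)
    chains: dict[str, list[ResidueRecord]] = {}
    for h in range(spec.n_helices):
        chain_id = _CHAIN_IDS[h]
        bb = _backbone(spec.residues_per_helix, _PHI_HELIX, _PSI_HELIX)
        # align helix axis (first principal component of CA trace) with z
        cas = np.array([r["CA"] for r in bb])
        center = cas.mean(axis=0)
        if len(cas) > 1:
            _, _, vt = np.linalg.svd(cas - center)
            axis = vt[0]
            rot = _rotation_onto(axis, np.array([0.0, 0.0, 1.0]))
        else:
            rot = np.eye(3)
        offset = np.array([h * spec.inter_helix_spacing, 0.0, 0.0])
        seq = _sequence_for(spec, rng)
        residues = []
        for i, res_bb in enumerate(bb):
            placed = {k: (rot @ (v - center)) + offset for k, v in res_bb.items()}
            residues.append(_make_residue(chain_id, i + 1, seq[i], placed))
        chains[chain_id] = residues
    model = StructureModel(
        entry_id=f"SYNTH-{spec.seed}",
        chains=chains,
        provenance={"generator": "build_helix_bundle", "seed": spec.seed},
    )
    _check_clashes(model)
    return model, PlantedTruth(seed=spec.seed)


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    a, b = _unit(a), _unit(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _check_clashes(model: StructureModel, min_dist: float = 2.0) -> None:
    """Reject generated structures with severe inter-chain vdW overlap."""
    per_chain = {}
    for cid, residues in model.chains.items():
        per_chain[cid] = np.array([a.coord for r in residues for a in r.atoms])
    ids = list(per_chain)
    for i, c1 in enumerate(ids):
        t1 = cKDTree(per_chain[c1])
        for c2 in ids[i + 1 :]:
            d = t1.query(per_chain[c2], k=1)[0].min() if len(per_chain[c2]) else np.inf
            if d < min_dist:
                raise GenerationError(
                    f"chains {c1} and {c2} clash (min inter-atom distance {d:.2f} Å "
                    f"< {min_dist} Å); increase inter_helix_spacing"
                )


def build_extended_peptide(sequence: str, chain_id: str = "A") -> StructureModel:
    """Single extended (β-strand-like) chain; used for near-maximal-exposure
    reference geometries such as Ala-X-Ala tripeptides."""
    seq3 = []
    for ch in sequence:
        if ch.upper() not in ONE_TO_THREE:
            raise GenerationError(f"unknown 1-letter code {ch!r} in sequence")
        seq3.append(ONE_TO_THREE[ch.upper()])
    bb = _backbone(len(seq3), _PHI_EXT, _PSI_EXT)
    residues = [
        _make_residue(chain_id, i + 1, seq3[i], bb[i]) for i in range(len(seq3))
    ]
    return StructureModel(
        entry_id="SYNTH-EXT",
        chains={chain_id: residues},
        provenance={"generator": "build_extended_peptide"},
    )


def _min_inter_run_distance(
    model: StructureModel, runs: list[list[ResidueKey]]
) -> float:
    """Smallest Cα–Cα distance between residues of different runs."""
    best = np.inf
    cas = [
        np.array([model.get_residue(k).ca.coord for k in run]) for run in runs
    ]
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            d = np.linalg.norm(cas[i][:, None, :] - cas[j][None, :, :], axis=-1).min()
            best = min(best, float(d))
    return best


def _run_is_connected(model: StructureModel, run: list[ResidueKey], cutoff: float) -> bool:
    """A run hosts one patch only if every consecutive Cα pair is below the
    cutoff (a chain break inside the run would split it)."""
    cas = []
    for k in run:
        ca = model.get_residue(k).ca
        if ca is None:
            return False
        cas.append(ca.coord)
    return all(
        np.linalg.norm(b - a) < cutoff for a, b in zip(cas, cas[1:])
    )


def plant_sites(
    model: StructureModel,
    k_patches: int,
    patch_size: int,
    cutoff: float = 6.0,
    seed: int = 0,
) -> tuple[InteractionSiteSet, PlantedTruth]:
    """Plant ``k_patches`` runs of ``patch_size`` consecutive residues as
    interaction sites, mutually separated by more than ``cutoff`` Å.

    Consecutive Cα atoms sit ≈ 3.8 Å apart (< cutoff), so each run forms one
    connected patch; run placement is verified numerically against the cutoff
    and a :class:`GenerationError` is raised when the request cannot be
    hosted. Scores are drawn uniformly from [0.5, 1.0] under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if k_patches < 0 or patch_size < 1:
        raise GenerationError("k_patches must be >= 0 and patch_size >= 1")
    if k_patches == 0:
        return (
            InteractionSiteSet({}, source="planted"),
            PlantedTruth(seed=seed, patches=[], expected_n_patches=0),
        )
    # candidate run starts: walk chains, leaving a separation gap that grows
    # until the realized geometry clears the cutoff
    chain_res = {cid: [r.key for r in res] for cid, res in model.chains.items()}
    for gap in range(5, 12):
        runs: list[list[ResidueKey]] = []
        for cid, keys in chain_res.items():
            pos = 0
            while pos + patch_size <= len(keys) and len(runs) < k_patches:
                run = keys[pos : pos + patch_size]
                if _run_is_connected(model, run, cutoff):
                    runs.append(run)
                    pos += patch_size + gap
                else:
                    pos += 1
            if len(runs) >= k_patches:
                break
        if len(runs) < k_patches:
            raise GenerationError(
                f"model cannot host {k_patches} patches of {patch_size} residues"
            )
        if len(runs) == 1 or _min_inter_run_distance(model, runs) > cutoff:
            break
    else:
        raise GenerationError(
            f"could not separate {k_patches} runs by more than {cutoff} Å"
        )
    scores = {
        key: float(rng.uniform(0.5, 1.0)) for run in runs for key in run
    }
    truth = PlantedTruth(
        seed=seed,
        patches=[list(run) for run in runs],
        expected_n_patches=len(runs),
    )
    return InteractionSiteSet(scores, source="planted"), truth


def plant_ions(
    model: StructureModel,
    targets: list[ResidueKey],
    offset: float = 3.0,
    seed: int = 0,
    clearance: float = 5.0,
) -> tuple[IonSiteSet, PlantedTruth]:
    """Place one ion per target residue at exactly ``offset`` Å from one of
    its atoms (Cβ preferred), at least ``clearance`` Å from every atom of any
    non-target residue.

    Candidate directions are seeded-random unit vectors; the direction
    maximizing the clearance to non-target atoms is kept. Duplicate targets
    are deduplicated. Raises :class:`GenerationError` naming the residue when
    no direction achieves the clearance.
    """
    rng = np.random.default_rng(seed)
    unique_targets = list(dict.fromkeys(targets))
    all_coords = []
    all_owner = []
    for res in model.residues():
        for atom in res.atoms:
            all_coords.append(atom.coord)
            all_owner.append(res.key)
    all_coords = np.asarray(all_coords)
    points: list[list[float]] = []
    labels: list[str] = []
    for key in unique_targets:
        res = model.get_residue(key)
        anchor = res.atom("CB") or res.ca or res.atoms[0]
        other_mask = np.array([o != key for o in all_owner])
        others = all_coords[other_mask]
        dirs = rng.normal(size=(256, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        candidates = anchor.coord + offset * dirs
        if len(others):
            clear = np.min(
                np.linalg.norm(candidates[:, None, :] - others[None, :, :], axis=-1),
                axis=1,
            )
        else:
            clear = np.full(len(candidates), np.inf)
        best = int(np.argmax(clear))
        if clear[best] < clearance:
            raise GenerationError(
                f"cannot place ion near {key}: best clearance {clear[best]:.2f} Å "
                f"< {clearance} Å"
            )
        points.append([float(x) for x in candidates[best]])
        labels.append(f"planted:{key.chain_id}{key.auth_number}")
    truth = PlantedTruth(
        seed=seed,
        ion_points=points,
        ion_targets=unique_targets,
    )
    ions = IonSiteSet(np.asarray(points).reshape(-1, 3), labels, source="planted")
    return ions, truth


def write_site_track(sites: InteractionSiteSet, model: StructureModel, path: str | Path) -> None:
    """Write an interaction-site set in the track TSV format."""
    lines = ["chain\tauth_number\ticode\tres_type\tscore"]
    for key in sorted(sites.scores):
        res = model.get_residue(key)
        lines.append(
            f"{key.chain_id}\t{key.auth_number}\t{key.insertion_code}\t"
            f"{res.res_type}\t{sites.scores[key]:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ion_track(ions: IonSiteSet, path: str | Path) -> None:
    """Write an ion-site set in the track TSV format."""
    lines = ["x\ty\tz\tlabel"]
    for pt, label in zip(ions.points, ions.labels):
        lines.append(f"{pt[0]:.3f}\t{pt[1]:.3f}\t{pt[2]:.3f}\t{label}")
    Path(path).write_text("\n".join(lines) + "\n")
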