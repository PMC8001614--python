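"""End-to-end surface-annotation pipeline.

Stages, in order: load structure -> backbone-gap accounting -> SASA -> RSA ->
surface selection -> smoothed hydropathy -> surface composition ->
interaction-site patches -> ion neighborhoods -> overlap -> domain
assignment. Stages whose optional inputs (site/ion tracks, domain map) are
absent are skipped and marked as such in the report. Every stage writes its
table next to the machine-readable ``report.json`` so any number in the
report is traceable to one config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .composition import CompositionSummary, PolarityScheme, composition
from .errors import ConfigurationError
from .hydropathy import hydropathy_summary, smooth_kd
from .sasa import compute_rsa, compute_sasa, select_surface
from .sites import (
    DomainMap,
    assign_domains,
    cluster_patches,
    ion_neighborhood,
    load_ion_track,
    load_site_track,
    overlap,
    site_annotation_values,
)
from .structure import detect_gaps, load_structure, write_annotated_pdb

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    structure_path: str = ""
    structure_format: str = "auto"
    chain: str | None = None  # None -> longest polymer chain
    full_region: tuple[int, int] | None = None  # None -> chain's own extent
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    occluder_scope: str = "complex"
    rsa_threshold: float = 0.20
    max_asa_table: str = "RostSander1994"
    kd_radius: float = 6.0
    patch_cutoff: float = 6.0
    ion_radius: float = 3.5
    ion_atom_mode: str = "heavy"
    score_threshold: float | None = None
    polarity_scheme: str = "default"
    site_track: str | None = None
    ion_track: str | None = None
    domain_map: str | None = None
    output_dir: str = "protsurf_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.full_region is not None:
            d["full_region"] = list(self.full_region)
        return d


_POSITIVE_KEYS = ("probe_radius", "kd_radius", "patch_cutoff", "ion_radius")


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (or dict), checking
    every constraint before any computation. Errors are aggregated into one
    :class:`ConfigurationError` naming each offending key."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
        if raw is None:
            raw = {}
    else:
        raw = dict(source)
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if cfg.full_region is not None:
        cfg.full_region = tuple(int(x) for x in cfg.full_region)  # type: ignore[assignment]
        if len(cfg.full_region) != 2 or cfg.full_region[0] > cfg.full_region[1]:
            errors.append("full_region: must be [start, end] with start <= end")
    if not cfg.structure_path:
        errors.append("structure_path: required")
    elif not Path(cfg.structure_path).exists():
        errors.append(f"structure_path: no such file {cfg.structure_path!r}")
    for key in _POSITIVE_KEYS:
        if not getattr(cfg, key) > 0:
            errors.append(f"{key}: must be positive, got {getattr(cfg, key)}")
    if cfg.n_sphere_points < 32:
        errors.append(f"n_sphere_points: must be >= 32, got {cfg.n_sphere_points}")
    if not 0.0 <= cfg.rsa_threshold <= 1.0:
        errors.append(f"rsa_threshold: must be in [0, 1], got {cfg.rsa_threshold}")
    if cfg.occluder_scope not in ("complex", "chain_only"):
        errors.append(f"occluder_scope: unknown value {cfg.occluder_scope!r}")
    if cfg.ion_atom_mode not in ("heavy", "ca"):
        errors.append(f"ion_atom_mode: unknown value {cfg.ion_atom_mode!r}")
    try:
        PolarityScheme.named(cfg.polarity_scheme)
    except ConfigurationError as exc:
        errors.append(f"polarity_scheme: {exc}")
    for key in ("site_track", "ion_track", "domain_map"):
        p = getattr(cfg, key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key}: no such file {p!r}")
    if errors:
        raise ConfigurationError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


@dataclass
class ReportBundle:
    """Aggregated machine-readable results of one pipeline run."""

    config: dict
    gap_report: dict
    surface_stats: dict
    hydropathy: dict
    composition: dict
    patch_stats: dict | None = None
    ion_stats: dict | None = None
    overlap_report: dict | None = None
    domain_counts: dict | None = None
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order and write the report bundle plus
    per-stage files into ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage load: %s (format=%s)", config.structure_path, config.structure_format)
    model = load_structure(config.structure_path, format=config.structure_format)
    chain = config.chain or model.longest_polymer_chain()
    if chain not in model.chains:
        raise ConfigurationError(f"chain {chain!r} not in structure")
    region = config.full_region
    if region is None:
        nums = [r.auth_number for r in model.chains[chain]]
        region = (min(nums), max(nums))

    logger.info("stage gaps: chain %s region %s", chain, region)
    gaps = detect_gaps(model, chain, region)
    gaps.write_json(out / "gap_report.json")
    gaps.write_tsv(out / "gap_report.tsv")

    logger.info(
        "stage sasa: probe=%.2f points=%d scope=%s",
        config.probe_radius, config.n_sphere_points, config.occluder_scope,
    )
    sasa = compute_sasa(
        model,
        probe_radius=config.probe_radius,
        n_sphere_points=config.n_sphere_points,
        occluder_scope=config.occluder_scope,
        target_chain=chain,
    )
    sasa = compute_rsa(sasa, model, ref=config.max_asa_table)
    surface = select_surface(sasa, threshold=config.rsa_threshold)
    sasa.write_tsv(out / "sasa.tsv", surface=surface)
    surface_stats = {
        "chain": chain,
        "n_residues_reported": len(sasa),
        "n_exposed": len(surface),
        "surface_area": surface.total_area,
        "total_chain_sasa": sasa.total_sasa(),
        "rsa_threshold": config.rsa_threshold,
    }

    logger.info("stage hydropathy: radius=%.1f", config.kd_radius)
    hmap = smooth_kd(surface, model, radius=config.kd_radius)
    hmap.write_tsv(out / "hydropathy.tsv")
    clamped = {
        k: max(-4.5, min(4.5, v)) for k, v in hmap.smoothed().items()
    }
    write_annotated_pdb(model, clamped, out / "hydropathy_annotated.pdb")
    hyd = hydropathy_summary(hmap).to_dict()

    scheme = PolarityScheme.named(config.polarity_scheme)
    comp = composition(surface.members, model, scheme=scheme)
    comp.write_json(out / "composition.json")
    comp.write_tsv(out / "composition.tsv")

    skipped: list[str] = []
    patch_stats = ion_stats = overlap_report = domain_counts = None
    site_set = ion_neighbors = None

    if config.site_track:
        logger.info("stage patches: cutoff=%.1f", config.patch_cutoff)
        site_set = load_site_track(config.site_track, model, config.score_threshold)
        patches = cluster_patches(site_set, model, cutoff=config.patch_cutoff)
        patches.write_json(out / "patches.json")
        patch_stats = {
            "n_sites": len(site_set),
            "n_patches": patches.n_patches,
            "sizes": patches.sizes(),
            "cutoff": config.patch_cutoff,
        }
        assert set().union(*patches.patches, frozenset()) <= site_set.residues
    else:
        skipped.append("patches")

    if config.ion_track:
        logger.info("stage ions: radius=%.1f mode=%s", config.ion_radius, config.ion_atom_mode)
        ions = load_ion_track(config.ion_track, config.ion_radius)
        ion_neighbors = ion_neighborhood(
            ions, model, radius=config.ion_radius, atom_mode=config.ion_atom_mode
        )
        ion_stats = {
            "n_ions": len(ions),
            "n_neighbor_residues": len(ion_neighbors),
            "radius": config.ion_radius,
            "neighbors": sorted([list(k) for k in ion_neighbors]),
        }
        (out / "ion_neighbors.json").write_text(json.dumps(ion_stats, indent=2) + "\n")
    else:
        skipped.append("ions")

    if site_set is not None and ion_neighbors is not None:
        rep = overlap(site_set.residues, ion_neighbors)
        overlap_report = rep.to_dict()
        (out / "overlap.json").write_text(json.dumps(overlap_report, indent=2) + "\n")
        write_annotated_pdb(
            model,
            site_annotation_values(site_set.residues, ion_neighbors),
            out / "sites_annotated.pdb",
        )
    else:
        skipped.append("overlap")

    if config.domain_map:
        dmap = DomainMap.from_file(config.domain_map)
        annotated = set()
        if site_set is not None:
            annotated |= site_set.residues
        if ion_neighbors is not None:
            annotated |= ion_neighbors
        domain_counts = {
            "interaction_sites": assign_domains(site_set.residues, dmap) if site_set else None,
            "ion_neighbors": assign_domains(ion_neighbors, dmap) if ion_neighbors else None,
            "surface": assign_domains(surface.members, dmap),
        }
        (out / "domains.json").write_text(json.dumps(domain_counts, indent=2) + "\n")
    else:
        skipped.append("domains")

    bundle = ReportBundle(
        config=config.to_dict(),
        gap_report=gaps.to_dict(),
        surface_stats=surface_stats,
        hydropathy=hyd,
        composition=comp.to_dict(),
        patch_stats=patch_stats,
        ion_stats=ion_stats,
        overlap_report=overlap_report,
        domain_counts=domain_counts,
        skipped=skipped,
        provenance={
            "protsurf_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    # post-stage self-checks: the report must agree with the module outputs
    assert bundle.surface_stats["n_exposed"] == len(surface)
    assert bundle.gap_report["n_gaps"] == len(bundle.gap_report["gaps"])
    if patch_stats is not None:
        assert sum(patch_stats["sizes"]) <= patch_stats["n_sites"]
    bundle.write_json(out / "report.json")
    return bundle
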