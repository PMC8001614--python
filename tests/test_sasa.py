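"""Shrake–Rupley SASA against closed forms, Monte-Carlo and an independent
implementation, plus RSA normalization and surface selection."""

import math

import numpy as np
import pytest

from protsurf import ResidueKey, compute_rsa, compute_sasa, select_surface
from protsurf.errors import ConfigurationError, ParameterError
from protsurf.sasa import fibonacci_sphere
from protsurf.structure import AtomRecord, ResidueRecord, StructureModel
from protsurf.synthetic import BundleSpec, build_extended_peptide, build_helix_bundle

KEY = ResidueKey("A", 1, "")


def atom_model(coords, radii, chain="A"):
    atoms = [
        AtomRecord(f"C{i+1}", "C", np.asarray(c, dtype=float), r)
        for i, (c, r) in enumerate(zip(coords, radii))
    ]
    res = ResidueRecord(chain, 1, "", "ALA", atoms)
    return StructureModel("TOY", {chain: [res]})


def two_sphere_exact(r1, r2, d):
    """Total exposed area of two intersecting spheres (spherical-cap formula)."""
    a1, a2 = 4 * math.pi * r1**2, 4 * math.pi * r2**2
    if d >= r1 + r2:
        return a1 + a2
    h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
    h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
    return a1 - 2 * math.pi * r1 * h1 + a2 - 2 * math.pi * r2 * h2


class TestSasaClosedForms:
    def test_isolated_atom_equals_sphere_area(self):
        model = atom_model([[0, 0, 0]], [1.70])
        table = compute_sasa(model, probe_radius=1.4, n_sphere_points=960)
        exact = 4 * math.pi * 3.1**2  # ~120.76 Å²
        assert table[KEY].sasa == pytest.approx(exact, rel=0.01)

    @pytest.mark.parametrize("d", [1.0, 2.0, 3.0, 4.5])
    def test_two_spheres_match_cap_formula(self, d):
        model = atom_model([[0, 0, 0], [d, 0, 0]], [1.70, 1.70])
        table = compute_sasa(model, n_sphere_points=960)
        exact = two_sphere_exact(3.1, 3.1, d)
        assert table[KEY].sasa == pytest.approx(exact, rel=0.02)

    def test_caged_atom_is_fully_buried(self):
        # icosahedron of fat atoms around a small one
        phi = (1 + 5**0.5) / 2
        verts = []
        for a in (-1, 1):
            for b in (-phi, phi):
                verts += [[0, a, b], [a, b, 0], [b, 0, a]]
        verts = 2.0 * np.array(verts) / np.linalg.norm(verts[0])
        model = atom_model([[0, 0, 0]] + verts.tolist(), [0.4] + [2.5] * len(verts))
        table = compute_sasa(model, probe_radius=1.4)
        # central atom contributes nothing; per-atom check via a 1-atom report
        central_only = atom_model([[0, 0, 0]], [0.4])
        solo = compute_sasa(central_only)[KEY].sasa
        assert solo > 0
        buried_total = table[KEY].sasa
        cage_only = atom_model(verts.tolist(), [2.5] * len(verts))
        cage_total = compute_sasa(cage_only)[KEY].sasa
        assert buried_total == pytest.approx(cage_total, rel=1e-6)


class TestSasaProperties:
    def test_probe_radius_monotone_for_isolated_atom(self):
        areas = [
            compute_sasa(atom_model([[0, 0, 0]], [1.70]), probe_radius=p)[KEY].sasa
            for p in (0.5, 1.0, 1.4, 2.0)
        ]
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_convergence_960_vs_10000_points(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            coords = rng.uniform(-2.5, 2.5, size=(5, 3))
            model = atom_model(coords, [1.70] * 5)
            coarse = compute_sasa(model, n_sphere_points=960)[KEY].sasa
            fine = compute_sasa(model, n_sphere_points=10000)[KEY].sasa
            assert coarse == pytest.approx(fine, rel=0.03)

    def test_monte_carlo_oracle_random_configurations(self):
        """Per-configuration SASA matches an independent Monte-Carlo
        estimator (uniform random directions) within 3 sigma."""
        rng = np.random.default_rng(23)
        n_mc = 20000
        for _ in range(3):
            n_atoms = int(rng.integers(2, 20))
            coords = rng.uniform(-4, 4, size=(n_atoms, 3))
            radii = rng.uniform(1.2, 2.0, size=n_atoms)
            model = atom_model(coords, radii)
            got = compute_sasa(model, n_sphere_points=960)[KEY].sasa
            ext = radii + 1.4
            total, var = 0.0, 0.0
            for i in range(n_atoms):
                dirs = rng.normal(size=(n_mc, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                pts = coords[i] + ext[i] * dirs
                free = np.ones(n_mc, dtype=bool)
                for j in range(n_atoms):
                    if j == i:
                        continue
                    free &= np.sum((pts - coords[j]) ** 2, axis=1) >= ext[j] ** 2
                p = free.mean()
                area = 4 * math.pi * ext[i] ** 2
                total += p * area
                var += area**2 * p * (1 - p) / n_mc
            assert abs(got - total) <= max(3 * math.sqrt(var), 0.02 * total + 1e-6)

    def test_added_occluder_chain_never_increases_sasa(self, small_bundle):
        solo = compute_sasa(small_bundle, target_chain="A")
        spec = BundleSpec(n_helices=2, residues_per_helix=20, inter_helix_spacing=9.0, seed=7)
        pair, _ = build_helix_bundle(spec)
        occluded = compute_sasa(pair, occluder_scope="complex", target_chain="A")
        for key in solo:
            assert occluded[key].sasa <= solo[key].sasa + 1e-9

    def test_distant_chains_do_not_occlude(self):
        spec = BundleSpec(n_helices=2, residues_per_helix=20, inter_helix_spacing=100.0, seed=7)
        pair, _ = build_helix_bundle(spec)
        single, _ = build_helix_bundle(BundleSpec(n_helices=1, residues_per_helix=20, seed=7))
        far = compute_sasa(pair, target_chain="A")
        alone = compute_sasa(single, target_chain="A")
        for key in alone:
            assert far[key].sasa == pytest.approx(alone[key].sasa, abs=1e-6)

    def test_parameter_validation(self, small_bundle):
        with pytest.raises(ParameterError):
            compute_sasa(small_bundle, probe_radius=-1.0)
        with pytest.raises(ParameterError):
            compute_sasa(small_bundle, n_sphere_points=8)
        with pytest.raises(ConfigurationError):
            compute_sasa(small_bundle, occluder_scope="nonsense")

    def test_fibonacci_lattice_is_uniform_unit(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestAgainstIndependentImplementation:
    def test_matches_biotite_on_helix_bundle(self, small_bundle):
        """Per-residue SASA agrees with biotite's Shrake–Rupley (same radii,
        same probe) within 2%: two independent point sets, one quantity."""
        struc = pytest.importorskip("biotite.structure")
        import biotite.structure as bst

        atoms = [(r, a) for r in small_bundle.residues() for a in r.atoms]
        arr = bst.AtomArray(len(atoms))
        arr.coord = np.array([a.coord for _, a in atoms], dtype=np.float32)
        arr.chain_id = np.array([r.chain_id for r, _ in atoms])
        arr.res_id = np.array([r.auth_number for r, _ in atoms])
        arr.res_name = np.array([r.res_type for r, _ in atoms])
        arr.atom_name = np.array([a.name for _, a in atoms])
        arr.element = np.array([a.element for _, a in atoms])
        radii = np.array([a.vdw_radius for _, a in atoms], dtype=np.float32)
        per_atom = bst.sasa(arr, probe_radius=1.4, point_number=2000, vdw_radii=radii)
        mine = compute_sasa(small_bundle, n_sphere_points=2000)
        for res in small_bundle.residues():
            idx = [i for i, (r, _) in enumerate(atoms) if r.key == res.key]
            assert mine[res.key].sasa == pytest.approx(per_atom[idx].sum(), rel=0.02, abs=0.5)


class TestRsaAndSurface:
    def test_rsa_identity_and_zero(self, small_bundle):
        table = compute_sasa(small_bundle)
        table = compute_rsa(table, small_bundle)
        key = next(iter(table))
        entry = table[key]
        assert entry.rsa == pytest.approx(entry.sasa / 106.0)  # ALA reference
        entry.sasa = 0.0
        table2 = compute_rsa(table, small_bundle)
        assert table2[key].rsa == 0.0

    def test_extended_tripeptide_center_near_max_exposure(self):
        model = build_extended_peptide("AAA")
        table = compute_rsa(compute_sasa(model), model)
        center = ResidueKey("A", 2, "")
        assert 0.8 <= table[center].rsa <= 1.2

    def test_missing_reference_entry_names_type(self, small_bundle):
        table = compute_sasa(small_bundle)
        with pytest.raises(ConfigurationError, match="ALA"):
            compute_rsa(table, small_bundle, ref={"GLY": 84.0})

    def test_threshold_zero_selects_everything(self, small_bundle):
        table = compute_rsa(compute_sasa(small_bundle), small_bundle)
        surface = select_surface(table, threshold=0.0)
        assert len(surface) == len(table)
        assert surface.total_area == pytest.approx(table.total_sasa())

    def test_raising_threshold_never_grows_surface(self, mixed_bundle):
        table = compute_rsa(compute_sasa(mixed_bundle, target_chain="A"), mixed_bundle)
        sizes = [len(select_surface(table, t)) for t in (0.0, 0.2, 0.5, 0.9)]
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))

    def test_threshold_out_of_range_raises(self, small_bundle):
        table = compute_rsa(compute_sasa(small_bundle), small_bundle)
        with pytest.raises(ParameterError):
            select_surface(table, threshold=1.5)
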