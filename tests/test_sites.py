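"""Annotation tracks: patch clustering, ion neighborhoods, overlap, domains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protsurf import (
    DomainMap,
    InteractionSiteSet,
    IonSiteSet,
    ResidueKey,
    assign_domains,
    cluster_patches,
    ion_neighborhood,
    load_ion_track,
    load_site_track,
    overlap,
)
from protsurf.errors import ValidationError
from protsurf.structure import AtomRecord, ResidueRecord, StructureModel
from protsurf.synthetic import (
    BundleSpec,
    build_helix_bundle,
    plant_ions,
    plant_sites,
    write_ion_track,
    write_site_track,
)


def ca_model(positions):
    """CA-only chain with residue i+1 at positions[i]."""
    residues = [
        ResidueRecord(
            "A", i + 1, "", "ALA",
            [AtomRecord("CA", "C", np.asarray(p, dtype=float), 1.7)],
        )
        for i, p in enumerate(positions)
    ]
    return StructureModel("CA", {"A": residues})


def site_set(model, numbers):
    return InteractionSiteSet({ResidueKey("A", n, ""): 1.0 for n in numbers})


def union_find_components(keys, coords, cutoff):
    """Brute-force O(n^2) union-find oracle for the patch partition."""
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if np.linalg.norm(coords[a] - coords[b]) < cutoff:
                parent[find(a)] = find(b)
    comps = {}
    for k in keys:
        comps.setdefault(find(k), set()).add(k)
    return {frozenset(c) for c in comps.values()}


class TestTrackLoading:
    def test_empty_site_file(self, small_bundle, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("chain\tauth_number\ticode\tres_type\tscore\n")
        assert len(load_site_track(path, small_bundle)) == 0

    def test_planted_track_round_trips(self, mixed_bundle, tmp_path):
        sites, truth = plant_sites(mixed_bundle, 5, 5, seed=4)
        path = tmp_path / "sites.tsv"
        write_site_track(sites, mixed_bundle, path)
        loaded = load_site_track(path, mixed_bundle)
        assert loaded.residues == sites.residues
        assert len(loaded) == 25

    def test_unresolvable_keys_listed(self, small_bundle, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chain\tauth_number\ticode\tres_type\tscore\n"
            "A\t1\t\tALA\t0.9\nZ\t99\t\tGLY\t0.8\n"
        )
        with pytest.raises(ValidationError) as exc:
            load_site_track(path, small_bundle)
        assert ResidueKey("Z", 99, "") in exc.value.offenders

    def test_score_threshold_filters(self, small_bundle, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "chain\tauth_number\ticode\tres_type\tscore\n"
            "A\t1\t\tALA\t0.9\nA\t2\t\tALA\t0.3\n"
        )
        assert len(load_site_track(path, small_bundle)) == 2
        assert len(load_site_track(path, small_bundle, score_threshold=0.5)) == 1

    def test_ion_track_round_trip(self, tmp_path):
        ions = IonSiteSet(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]), ["a", "b"])
        path = tmp_path / "ions.tsv"
        write_ion_track(ions, path)
        loaded = load_ion_track(path)
        assert np.allclose(loaded.points, ions.points)
        assert loaded.labels == ["a", "b"]


class TestClusterPatches:
    def test_no_sites_no_patches(self, small_bundle):
        result = cluster_patches(InteractionSiteSet({}), small_bundle)
        assert result.n_patches == 0

    def test_boundary_is_strictly_below_cutoff(self):
        model = ca_model([[0, 0, 0], [5.0, 0, 0]])
        assert cluster_patches(site_set(model, [1, 2]), model, cutoff=6.0).n_patches == 1
        model_exact = ca_model([[0, 0, 0], [6.0, 0, 0]])
        assert (
            cluster_patches(site_set(model_exact, [1, 2]), model_exact, cutoff=6.0).n_patches
            == 2
        )

    @pytest.mark.parametrize("k,size", [(0, 3), (1, 3), (5, 4), (20, 3)])
    def test_recovers_planted_patch_count(self, mixed_bundle, k, size):
        sites, truth = plant_sites(mixed_bundle, k, size, seed=9)
        result = cluster_patches(sites, mixed_bundle, cutoff=6.0)
        assert result.n_patches == truth.expected_n_patches == k
        assert {frozenset(p) for p in result.patches} == {
            frozenset(p) for p in truth.patches
        }

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), cutoff=st.floats(2.0, 15.0))
    def test_matches_union_find_oracle(self, seed, cutoff):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        positions = rng.uniform(0, 25, size=(n, 3))
        model = ca_model(positions)
        sites = site_set(model, range(1, n + 1))
        result = cluster_patches(sites, model, cutoff=cutoff)
        coords = {r.key: r.ca.coord for r in model.residues()}
        expected = union_find_components(sorted(sites.residues), coords, cutoff)
        assert {frozenset(p) for p in result.patches} == expected

    def test_patch_count_monotone_in_cutoff(self, mixed_bundle):
        sites, _ = plant_sites(mixed_bundle, 5, 4, seed=2)
        counts = [
            cluster_patches(sites, mixed_bundle, cutoff=c).n_patches
            for c in (0.5, 3.9, 6.0, 12.0, 1e5)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[0] == len(sites)  # below bond distance: all singletons
        assert counts[-1] == 1  # one giant component


class TestIonNeighborhood:
    def test_distant_ion_sees_nothing(self, small_bundle):
        ions = IonSiteSet(np.array([[1000.0, 0, 0]]), ["far"])
        assert ion_neighborhood(ions, small_bundle, radius=3.5) == frozenset()

    def test_planted_ion_recovers_exact_targets(self, mixed_bundle):
        targets = [ResidueKey("A", 5, ""), ResidueKey("B", 12, ""), ResidueKey("C", 40, "")]
        ions, truth = plant_ions(mixed_bundle, targets, offset=3.0, seed=5)
        assert ion_neighborhood(ions, mixed_bundle, radius=3.5) == frozenset(targets)

    def test_offset_beyond_radius_is_empty(self, mixed_bundle):
        targets = [ResidueKey("A", 5, "")]
        ions, _ = plant_ions(mixed_bundle, targets, offset=4.0, seed=5)
        assert ion_neighborhood(ions, mixed_bundle, radius=3.5) == frozenset()

    def test_duplicate_targets_deduplicated(self, mixed_bundle):
        key = ResidueKey("A", 10, "")
        ions, truth = plant_ions(mixed_bundle, [key, key], offset=3.0, seed=6)
        assert len(ions) == 1 and truth.ion_targets == [key]
        assert ion_neighborhood(ions, mixed_bundle) == frozenset({key})

    def test_monotone_in_radius(self, mixed_bundle):
        targets = [ResidueKey("B", 20, "")]
        ions, _ = plant_ions(mixed_bundle, targets, offset=3.0, seed=7)
        sizes = [
            len(ion_neighborhood(ions, mixed_bundle, radius=r))
            for r in (0.5, 3.5, 6.0, 10.0)
        ]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] == 0

    def test_ca_mode_is_more_restrictive(self, mixed_bundle):
        targets = [ResidueKey("A", 30, "")]
        ions, _ = plant_ions(mixed_bundle, targets, offset=3.0, seed=8)
        heavy = ion_neighborhood(ions, mixed_bundle, radius=3.5, atom_mode="heavy")
        ca_only = ion_neighborhood(ions, mixed_bundle, radius=3.5, atom_mode="ca")
        assert ca_only <= heavy


class TestOverlapAndDomains:
    def test_disjoint_and_identical_sets(self):
        a = {ResidueKey("A", i, "") for i in range(5)}
        b = {ResidueKey("A", i, "") for i in range(10, 15)}
        rep = overlap(a, b)
        assert rep.n_intersection == 0 and rep.jaccard == 0.0
        rep2 = overlap(a, a)
        assert rep2.n_intersection == 5 and rep2.jaccard == 1.0

    def test_membrane_region_assignment(self):
        domains = DomainMap([("membrane-binding", 166, 443)])
        counts = assign_domains([ResidueKey("A", 200, "")], domains)
        assert counts["membrane-binding"] == 1 and counts["unassigned"] == 0

    def test_empty_set_all_zero(self):
        domains = DomainMap([("N-HEAT", 1, 100), ("C-HEAT", 101, 200)])
        counts = assign_domains([], domains)
        assert counts == {"N-HEAT": 0, "C-HEAT": 0, "unassigned": 0}

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_interval_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        intervals = []
        for i in range(rng.integers(1, 5)):
            s = int(rng.integers(1, 200))
            intervals.append((f"D{i}", s, s + int(rng.integers(0, 80))))
        residues = [ResidueKey("A", int(n), "") for n in rng.integers(1, 300, size=40)]
        counts = assign_domains(residues, DomainMap(intervals))
        expected = {name: 0 for name, _, _ in intervals}
        expected["unassigned"] = 0
        for key in residues:
            for name, s, e in intervals:
                if s <= key.auth_number <= e:
                    expected[name] += 1
                    break
            else:
                expected["unassigned"] += 1
        assert counts == expected

    def test_overlapping_intervals_first_match_and_warn(self, caplog):
        domains = DomainMap([("first", 1, 100), ("second", 50, 150)])
        import logging

        with caplog.at_level(logging.WARNING, logger="protsurf.sites"):
            counts = assign_domains([ResidueKey("A", 75, "")], domains)
        assert counts["first"] == 1 and counts["second"] == 0
        assert any("overlap" in r.message for r in caplog.records)
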