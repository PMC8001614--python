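import pytest

from protsurf.synthetic import BundleSpec, build_helix_bundle

MIXED_COMPOSITION = {"ALA": 0.3, "SER": 0.2, "GLU": 0.2, "LEU": 0.2, "ARG": 0.1}


@pytest.fixture(scope="session")
def small_bundle():
    """Single 20-residue poly-Ala helix."""
    model, _ = build_helix_bundle(BundleSpec(n_helices=1, residues_per_helix=20, seed=7))
    return model


@pytest.fixture(scope="session")
def mixed_bundle():
    """Three 60-residue helices, mixed polar/non-polar composition, 20 Å apart."""
    spec = BundleSpec(
        n_helices=3,
        residues_per_helix=60,
        inter_helix_spacing=20.0,
        composition=MIXED_COMPOSITION,
        seed=1,
    )
    model, _ = build_helix_bundle(spec)
    return model
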