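"""Shared fixtures: every structural/sequence/assay input is generated by
the synthetic-data module at test time."""

import pytest

from cadkit import synthetic as syn
from cadkit.structures import read_repeat_table, read_structure


@pytest.fixture(scope="session")
def toy_dimer(tmp_path_factory):
    """Antiparallel four-repeat toy dimer with full contact register."""
    d = tmp_path_factory.mktemp("dimer")
    bundle = syn.make_toy_dimer(str(d), n_repeats=4, residues_per_repeat=5)
    structure = read_structure(bundle.files["dimer"])
    annotations = read_repeat_table(bundle.files["repeats"])
    return bundle, structure, annotations


@pytest.fixture(scope="session")
def single_contact_dimer(tmp_path_factory):
    """Two-repeat toy dimer touching only at residue 3 (partner residue 8)."""
    d = tmp_path_factory.mktemp("dimer1")
    bundle = syn.make_toy_dimer(
        str(d), n_repeats=2, residues_per_repeat=5, contact_residues=[3]
    )
    structure = read_structure(bundle.files["dimer"])
    annotations = read_repeat_table(bundle.files["repeats"])
    return bundle, structure, annotations


@pytest.fixture(scope="session")
def twist_rod(tmp_path_factory):
    """Four-repeat rod with twists 30, 120, -45 plus zero-twist reference."""
    d = tmp_path_factory.mktemp("rod")
    bundle = syn.make_repeat_rod(
        str(d), 4, twist_list=[30.0, 120.0, -45.0], tilt=15.0, seed=11
    )
    return bundle
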