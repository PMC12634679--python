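import numpy as np
import pytest

from hybridfep import (
    PlacedResidue, get_template, place_mutant_side_chain,
)
from hybridfep.residue_templates import build_ideal_chain


@pytest.fixture(scope="session")
def ideal_chain():
    """Template-built MET-LYS-TYR-THR-GLY model peptide."""
    return build_ideal_chain(["MET", "LYS", "TYR", "THR", "GLY"])


@pytest.fixture(scope="session")
def leu_chain():
    return build_ideal_chain(["ALA", "LEU", "THR"])


def place_pair(structure, chain, resnum, mut_name):
    """(wt, mut) PlacedResidue pair sharing the site's backbone frame."""
    wt_name = structure.residue_name(chain, resnum)
    site = structure.residue_atoms(chain, resnum)
    mut_coords = place_mutant_side_chain(structure, chain, resnum, mut_name)
    frame = {k: site[k] for k in ("N", "CA", "C") if k in site}
    wt = PlacedResidue(get_template(wt_name), site)
    mut = PlacedResidue(get_template(mut_name), {**frame, **mut_coords})
    return wt, mut


@pytest.fixture
def pair_factory(ideal_chain):
    """Build a (wt, mut) placed pair for any wt/mut residue combination
    on a fresh ideal backbone."""
    def factory(wt_name, mut_name):
        chain = build_ideal_chain(["ALA", wt_name, "THR"])
        return place_pair(chain, "A", 2, mut_name)
    return factory
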