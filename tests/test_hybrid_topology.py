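import itertools

import numpy as np
import pytest

from hybridfep import (
    map_analogous_atoms, assign_restraints, build_hybrid_topology,
    ChargeChangeError, SoftCoreSpec, get_template, build_protocol,
    build_reference_peptide, emit_job_spec, PlacedResidue,
)
from hybridfep.hybrid_topology import AtomMapping, AtomPair
from hybridfep.residue_templates import build_ideal_chain
from conftest import place_pair

# residues eligible as both wild type and mutation target under the
# default scan rules: neutral, non-proline, non-Trp/Cys targets
SCAN_RESIDUES = ("ALA", "GLY", "ILE", "LEU", "MET", "PHE", "SER",
                 "THR", "TYR", "VAL", "ASN", "GLN", "HIS")


class TestMapping:
    def test_leu_to_ile(self, pair_factory):
        """The branch with more descendants continues the chain: CG pairs
        with CG1 (not the terminal CG2), then CD1 with CD1."""
        m = map_analogous_atoms(*pair_factory("LEU", "ILE"))
        assert [(p.wt, p.mut) for p in m.pairs] == \
            [("CB", "CB"), ("CG", "CG1"), ("CD1", "CD1")]
        assert m.unmatched_wt == ("CD2",)
        assert m.unmatched_mut == ("CG2",)

    def test_tyr_to_phe_spans_ring(self, pair_factory):
        m = map_analogous_atoms(*pair_factory("TYR", "PHE"))
        assert [(p.wt, p.mut) for p in m.pairs] == [
            ("CB", "CB"), ("CG", "CG"), ("CD1", "CD1"), ("CD2", "CD2"),
            ("CE1", "CE1"), ("CE2", "CE2"), ("CZ", "CZ")]
        assert m.unmatched_wt == ("OH",)

    def test_ala_to_ser_single_level(self, pair_factory):
        m = map_analogous_atoms(*pair_factory("ALA", "SER"))
        assert [(p.wt, p.mut) for p in m.pairs] == [("CB", "CB")]
        assert m.unmatched_mut == ("OG",)

    @pytest.mark.parametrize("other", ["ALA", "LEU", "TRP"])
    def test_glycine_yields_empty_mapping(self, pair_factory, other):
        m = map_analogous_atoms(*pair_factory("GLY", other))
        assert m.pairs == ()
        m = map_analogous_atoms(*pair_factory(other, "GLY"))
        assert m.pairs == ()

    def test_levels_are_nondecreasing_and_unique(self, pair_factory):
        for wt, mut in (("TRP", "TYR"), ("GLN", "MET"), ("ILE", "THR")):
            m = map_analogous_atoms(*pair_factory(wt, mut))
            levels = [p.level for p in m.pairs]
            assert levels == sorted(levels)
            assert len({p.wt for p in m.pairs}) == len(m.pairs)
            assert len({p.mut for p in m.pairs}) == len(m.pairs)
            if m.pairs:
                assert (m.pairs[0].wt, m.pairs[0].mut) == ("CB", "CB")

    def test_symmetry_over_supported_pairs(self, pair_factory):
        """map(wt, mut) reversed equals map(mut, wt), pair for pair."""
        for wt, mut in itertools.combinations(SCAN_RESIDUES, 2):
            a, b = pair_factory(wt, mut)
            fwd = map_analogous_atoms(a, b)
            rev = map_analogous_atoms(b, a)
            assert fwd.reversed().pairs == rev.pairs, (wt, mut)


class TestRestraints:
    def test_tyr_phe_stops_at_type_mismatch(self, pair_factory):
        m = map_analogous_atoms(*pair_factory("TYR", "PHE"))
        r = assign_restraints(m)
        assert [p.wt for p in r.pairs] == ["CB", "CG", "CD1", "CD2", "CE1", "CE2"]
        assert r.stop_reason == "type-mismatch"
        assert r.k == 10.0
        assert r.cutoff == 0.5

    def test_distance_stop(self):
        pairs = (
            AtomPair("CB", "CB", 1, True, 0.0),
            AtomPair("CG", "CG", 2, True, 0.6),
            AtomPair("CD", "CD", 3, True, 0.0),
        )
        r = assign_restraints(AtomMapping(pairs, (), ()))
        assert [p.wt for p in r.pairs] == ["CB"]
        assert r.stop_reason == "distance"

    def test_glycine_empty_scheme(self, pair_factory):
        m = map_analogous_atoms(*pair_factory("GLY", "LEU"))
        r = assign_restraints(m)
        assert r.pairs == ()
        assert r.stop_reason == "exhausted"

    def test_prefix_property_over_all_supported_pairs(self, pair_factory):
        """For every supported wt/mut combination the restrained pairs are
        a contiguous prefix of the mapping, and each satisfies the type
        and 0.5 Å criteria."""
        for wt, mut in itertools.product(SCAN_RESIDUES, repeat=2):
            if wt == mut:
                continue
            m = map_analogous_atoms(*pair_factory(wt, mut))
            r = assign_restraints(m)
            assert m.pairs[:len(r.pairs)] == r.pairs, (wt, mut)
            for p in r.pairs:
                assert p.type_equal and p.distance <= 0.5
            if len(r.pairs) < len(m.pairs):
                nxt = m.pairs[len(r.pairs)]
                assert (not nxt.type_equal) or nxt.distance > 0.5


class TestBuildTopology:
    def test_leu_ile_exclusion_count(self, pair_factory):
        wt, mut = pair_factory("LEU", "ILE")
        topo = build_hybrid_topology(wt, mut, map_analogous_atoms(wt, mut))
        # 13 side-chain atoms (incl. hydrogens) on each side
        assert len(topo.wt_sidechain) == 13
        assert len(topo.mut_sidechain) == 13
        assert topo.n_exclusions == 169

    @pytest.mark.parametrize("wt,mut", [("LEU", "ILE"), ("TYR", "PHE"),
                                        ("GLY", "TRP"), ("SER", "GLN")])
    def test_exclusions_are_full_cross_product(self, pair_factory, wt, mut):
        a, b = pair_factory(wt, mut)
        topo = build_hybrid_topology(a, b, map_analogous_atoms(a, b))
        assert topo.n_exclusions == \
            len(topo.wt_sidechain) * len(topo.mut_sidechain)
        assert len(set(topo.exclusions)) == topo.n_exclusions

    def test_deactivated_terms(self, pair_factory):
        """Exactly one angle (root-CA-root) plus every torsion through it:
        one per additional bond on either side-chain root."""
        wt, mut = pair_factory("LEU", "ILE")
        topo = build_hybrid_topology(wt, mut, map_analogous_atoms(wt, mut))
        assert topo.deactivated_angle == ("CB", "CA", "CB")
        deg_wt = len([n for n in wt.template.neighbors("CB") if n != "CA"])
        deg_mut = len([n for n in mut.template.neighbors("CB") if n != "CA"])
        assert len(topo.deactivated_torsions) == deg_wt + deg_mut
        for t in topo.deactivated_torsions:
            assert ("CB", "CA", "CB") in (t[:3], t[1:])

    def test_end_state_charge_neutrality(self, pair_factory):
        for wt, mut in (("LEU", "ILE"), ("ASN", "HIS"), ("GLY", "GLN")):
            a, b = pair_factory(wt, mut)
            topo = build_hybrid_topology(a, b, map_analogous_atoms(a, b))
            assert topo.state_charge(0) == pytest.approx(topo.state_charge(1),
                                                         abs=1e-9)
            assert topo.state_charge(0) == pytest.approx(0.0, abs=1e-9)

    def test_wt_dummy_in_state1_and_vice_versa(self, pair_factory):
        a, b = pair_factory("SER", "THR")
        topo = build_hybrid_topology(a, b, map_analogous_atoms(a, b))
        for (side, name), (q0, q1) in topo.end_state_charges.items():
            if side == "wt":
                assert q1 == 0.0
            elif side == "mut":
                assert q0 == 0.0
            else:
                assert q0 == q1  # backbone untouched

    def test_charge_changing_mutation_rejected(self):
        chain = build_ideal_chain(["ALA", "ASP", "THR"])
        wt, mut = place_pair(chain, "A", 2, "ALA")
        with pytest.raises(ChargeChangeError):
            build_hybrid_topology(wt, mut, map_analogous_atoms(wt, mut))

    def test_stage_markers(self, pair_factory):
        a, b = pair_factory("ALA", "VAL")
        topo = build_hybrid_topology(a, b, map_analogous_atoms(a, b))
        assert topo.stages == (("discharge-wt", "softcore-on"),
                               ("charge-mut", "softcore-off"))

    def test_softcore_validation(self):
        with pytest.raises(ValueError):
            SoftCoreSpec(alpha=0.0)
        assert SoftCoreSpec().alpha == 0.5


class TestLegConsistency:
    def test_protein_and_peptide_legs_share_restraints(self):
        """The restraint scheme computed at the protein site and the one
        computed on the reference peptide's central residue coincide —
        both legs must run under identical conditions."""
        chain = build_ideal_chain(["MET", "LYS", "TYR", "THR", "GLY"])
        wt, mut = place_pair(chain, "A", 3, "PHE")
        protein_r = assign_restraints(map_analogous_atoms(wt, mut))

        peptide = build_reference_peptide(chain, "A", 3, "ZXZ")
        pep_site = peptide.mutable.atoms
        wt_p = PlacedResidue(get_template("TYR"), pep_site)
        from hybridfep import place_mutant_side_chain
        mut_coords = place_mutant_side_chain(chain, "A", 3, "PHE")
        mut_p = PlacedResidue(get_template("PHE"),
                              {**{k: pep_site[k] for k in ("N", "CA", "C")},
                               **mut_coords})
        pep_r = assign_restraints(map_analogous_atoms(wt_p, mut_p))
        assert protein_r.table() == pep_r.table()

    def test_job_spec_restraint_tables_byte_identical(self):
        import json
        chain = build_ideal_chain(["MET", "LYS", "TYR", "THR", "GLY"])
        wt, mut = place_pair(chain, "A", 3, "PHE")
        mapping = map_analogous_atoms(wt, mut)
        restraints = assign_restraints(mapping)
        topo = build_hybrid_topology(wt, mut, mapping)
        legs = emit_job_spec(topo, build_protocol("H"), restraints)
        docs = {leg: json.loads(text) for leg, text in legs.items()}
        assert docs["protein"]["restraints"] == docs["reference"]["restraints"]

        def restraint_block(text):
            start = text.index('"restraints"')
            end = text.index('"softcore"')
            return text[start:end]

        assert restraint_block(legs["protein"]) == \
            restraint_block(legs["reference"])
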