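"""Macrolactone ring census and substructure presence annotation."""

import itertools

import networkx as nx
import pytest
from rdkit import Chem

from npclust.network import SimilarityEdge
from npclust.records import CompoundError, CompoundRecord, CompoundSet
from npclust.rings import (
    RingMatch,
    annotate_substructure_presence,
    find_macrolactones,
    group_matches,
    molecule_macrolactone_rings,
)
from npclust.synthetic import SCAFFOLD_LIBRARY, generate_dataset

HEXADECANOLIDE = "O=C1CCCCCCCCCCCCCCO1"   # 16-membered ring
PENTADECANOLIDE = "O=C1CCCCCCCCCCCCCO1"   # 15-membered ring


def _set_of(smiles_list):
    return CompoundSet(
        [
            CompoundRecord.from_fields(f"m{i}", smi)
            for i, smi in enumerate(smiles_list)
        ]
    )


def oracle_ester_cycles(mol, size):
    """Exhaustive simple-cycle enumeration oracle (small molecules only)."""
    graph = nx.Graph()
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    ester = Chem.MolFromSmarts("[OX2][CX3]=[OX1]")
    ester_bonds = {frozenset((o, c)) for o, c, _ in mol.GetSubstructMatches(ester)}
    cycles = set()
    for cyc in nx.simple_cycles(graph, length_bound=size):
        if len(cyc) != size:
            continue
        ring = set(cyc)
        ring_bonds = {
            frozenset((cyc[i], cyc[(i + 1) % len(cyc)])) for i in range(len(cyc))
        }
        if any(eb <= ring and eb in ring_bonds for eb in ester_bonds):
            cycles.add(frozenset(ring))
    return cycles


class TestFindMacrolactones:
    def test_16_membered_lactone_matches(self):
        matches = find_macrolactones(_set_of([HEXADECANOLIDE]), ring_size=16)
        assert len(matches) == 1
        assert matches[0].n_matching_rings == 1
        assert matches[0].is_macrolactone

    def test_15_membered_lactone_does_not_match_at_16(self):
        assert find_macrolactones(_set_of([PENTADECANOLIDE]), ring_size=16) == []
        # but it does match its own size
        assert len(find_macrolactones(_set_of([PENTADECANOLIDE]), ring_size=15)) == 1

    def test_benzene_never_matches(self):
        assert find_macrolactones(_set_of(["c1ccccc1"]), ring_size=16) == []

    def test_macrocyclic_ketone_is_not_a_lactone(self):
        # 16-ring with an in-ring C=O but no ester oxygen
        cyclohexadecanone = "O=C1CCCCCCCCCCCCCCC1"
        assert find_macrolactones(_set_of([cyclohexadecanone]), ring_size=16) == []

    def test_macrolactam_is_not_a_lactone(self):
        lactam = "O=C1CCCCCCCCCCCCCCN1"
        assert find_macrolactones(_set_of([lactam]), ring_size=16) == []

    def test_bridged_macrocycle_found_beyond_sssr(self):
        # 16-membered lactone bridged across the ring: the smallest-ring basis
        # decomposes it into two smaller rings, but the 16-cycle is still there
        mol = Chem.MolFromSmiles("O=C1CCCC2CCCC(CCCCCCO1)C2")
        assert mol is not None
        rings = molecule_macrolactone_rings(mol, 16)
        sssr_sizes = {len(r) for r in Chem.GetSymmSSSR(mol)}
        assert 16 not in sssr_sizes  # invisible to a smallest-rings treatment
        assert any(len(r) == 16 for r in rings)
        # the oracle agrees
        assert rings == oracle_ester_cycles(mol, 16)

    def test_ring_size_bounds_validated(self):
        with pytest.raises(ValueError):
            find_macrolactones(_set_of([HEXADECANOLIDE]), ring_size=100)

    @pytest.mark.parametrize("size", [14, 15, 16, 17])
    def test_agrees_with_exhaustive_cycle_oracle_on_small_molecules(self, size):
        small = [s for s in SCAFFOLD_LIBRARY if Chem.MolFromSmiles(s).GetNumAtoms() <= 30]
        for smi in small + [HEXADECANOLIDE, PENTADECANOLIDE]:
            mol = Chem.MolFromSmiles(smi)
            assert molecule_macrolactone_rings(mol, size) == oracle_ester_cycles(
                mol, size
            ), smi


class TestAnnotateSubstructure:
    def test_benzene_ring_present_in_toluene(self):
        ann = annotate_substructure_presence(_set_of(["Cc1ccccc1"]), "c1ccccc1", "phenyl")
        assert ann.presence == {"m0": True}

    def test_benzene_ring_absent_in_cyclohexane(self):
        ann = annotate_substructure_presence(_set_of(["C1CCCCC1"]), "c1ccccc1", "phenyl")
        assert ann.presence == {"m0": False}

    def test_invalid_pattern_fatal(self):
        with pytest.raises(CompoundError, match="not-a-smarts"):
            annotate_substructure_presence(_set_of(["CCO"]), "not-a-smarts", "bad")

    def test_decoration_flags_match_generator_ground_truth(self):
        compounds, truth = generate_dataset(
            n_families=4, family_size_distribution=(6,), n_singletons=0, seed=5
        )
        ann = annotate_substructure_presence(compounds, "[Cl]", "chloro")
        for cid, present in ann.presence.items():
            assert present == ("chloro" in truth.decorations[cid]), cid


class TestGroupMatches:
    def _matches(self, ids):
        return [RingMatch(cid, 16, 1) for cid in ids]

    def test_hand_partition_into_classes_and_minor_groups(self):
        # matched subgraph components of sizes {4, 2, 1}
        edges = [
            SimilarityEdge("a", "b", 0.8),
            SimilarityEdge("b", "c", 0.8),
            SimilarityEdge("c", "d", 0.8),
            SimilarityEdge("e", "f", 0.8),
            SimilarityEdge("f", "zz", 0.8),  # zz did not match: edge excluded
        ]
        result = group_matches(
            self._matches(["a", "b", "c", "d", "e", "f", "g"]), edges, min_class_size=3
        )
        assert result.classes == [["a", "b", "c", "d"]]
        assert sorted(map(tuple, result.minor_groups)) == [("e", "f"), ("g",)]

    def test_no_matches_empty(self):
        result = group_matches([], [], min_class_size=3)
        assert result.classes == [] and result.minor_groups == []

    def test_fully_connected_matches_one_class(self):
        ids = ["a", "b", "c", "d"]
        edges = [
            SimilarityEdge(*sorted(p), score=0.9)
            for p in itertools.combinations(ids, 2)
        ]
        result = group_matches(self._matches(ids), edges, min_class_size=3)
        assert result.classes == [ids]
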