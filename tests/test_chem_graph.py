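"""Encoding of SMILES into labeled rooted DAGs."""

import pytest

from gmri import (
    DisconnectedGraphError,
    MixtureError,
    MolGraph,
    SmilesError,
    UnknownElementWarning,
    assign_stereo_labels,
    canonical_serialization,
    parse_smiles,
    smiles_to_dag,
    strip_single_stereocenter,
    to_rooted_dag,
)
from gmri.chem_graph import AtomNode
from gmri.synthdata import generate_stereo_pairs, mirror_smiles

from conftest import SMALL_ALPHABET


def labels(graph):
    return [sorted(n.stereo_labels) for n in graph.nodes]


class TestParse:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            # degree label = sum of kekulized bond orders to heavy atoms
            ("Cl/C=C\\Cl", [("Cl", 1), ("C", 3), ("C", 3), ("Cl", 1)]),
            ("C", [("C", 0)]),
            ("CCO", [("C", 1), ("C", 2), ("O", 1)]),
            ("CC#N", [("C", 1), ("C", 4), ("N", 3)]),
        ],
    )
    def test_atom_and_degree_labels(self, smiles, expected):
        g = parse_smiles(smiles)
        assert [(n.atom_type, n.degree_label) for n in g.nodes] == expected

    def test_epoxide_ring(self):
        g = parse_smiles("CC1OC1C")
        assert g.n_nodes == 5
        assert len(g.edges) == 5
        ring_c = [n for n in g.nodes if n.atom_type == "C" and n.degree_label == 3]
        assert len(ring_c) == 2

    def test_aromatics_are_kekulized(self):
        g = parse_smiles("c1ccccc1")
        assert all(n.degree_label == 3 for n in g.nodes)

    def test_mixture_rejected(self):
        with pytest.raises(MixtureError):
            parse_smiles("CCO.CC")

    def test_syntax_error(self):
        with pytest.raises(SmilesError):
            parse_smiles("C1CC")

    def test_unknown_element_warns_and_is_recorded(self):
        with pytest.warns(UnknownElementWarning):
            g = parse_smiles("[AsH3]")
        assert g.unknown_elements == ("As",)

    def test_degree_sum_is_twice_bond_orders(self):
        for smi in ["CCO", "c1ccccc1", "CC1OC1C", "O=C=O", "CC#N"]:
            g = parse_smiles(smi)
            assert g.degree_sum() == 2 * sum(o for _, _, o in g.edges)


class TestStereoLabels:
    def test_z_bond_gets_iso1_iso2(self):
        g = assign_stereo_labels(parse_smiles("Cl/C=C\\Cl"))
        assert sorted(map(tuple, labels(g))) == [(), (), ("iso1",), ("iso2",)]

    def test_e_bond_gets_iso1_iso1(self):
        g = assign_stereo_labels(parse_smiles("Cl/C=C/Cl"))
        assert sorted(map(tuple, labels(g))) == [(), (), ("iso1",), ("iso1",)]

    def test_trans_dimethyloxirane_like_pair(self):
        # (2R,3R): both centres "like" -> {chi1, chi1}
        g = assign_stereo_labels(parse_smiles("C[C@H]1O[C@@H]1C"))
        chi = [tuple(l) for l in labels(g) if l]
        assert chi == [("chi1",), ("chi1",)]

    def test_meso_dimethyloxirane_unlike_pair(self):
        g = assign_stereo_labels(parse_smiles("C[C@H]1O[C@H]1C"))
        chi = sorted(tuple(l) for l in labels(g) if l)
        assert chi == [("chi1",), ("chi2",)]

    def test_unspecified_stereo_yields_no_labels(self):
        g = assign_stereo_labels(parse_smiles("CC=CC"))
        assert all(not n.stereo_labels for n in g.nodes)


class TestStripSingleStereocenter:
    def test_single_centre_equals_racemate(self):
        enantiomer = smiles_to_dag("CC[C@@H]1CO1")
        racemate = smiles_to_dag("CCC1CO1")
        assert canonical_serialization(enantiomer) == canonical_serialization(
            racemate
        )

    def test_two_centres_unchanged(self):
        g = assign_stereo_labels(parse_smiles("C[C@H]1O[C@@H]1C"))
        assert strip_single_stereocenter(g) is g

    def test_achiral_unchanged(self):
        g = assign_stereo_labels(parse_smiles("CCO"))
        assert strip_single_stereocenter(g) is g

    def test_stereo_double_bond_blocks_stripping(self):
        g = assign_stereo_labels(parse_smiles("C/C=C/[C@@H](C)O"))
        stripped = strip_single_stereocenter(g)
        assert any(
            n.stereo_labels & {"chi1", "chi2"} for n in stripped.nodes
        )


class TestRootedDAG:
    def test_oxirane_roots_at_oxygen_and_breaks_ring_cc(self):
        dag = smiles_to_dag("C[C@H]1O[C@@H]1C")
        assert dag.nodes[dag.root].atom_type == "O"
        assert len(dag.broken_edges) == 1
        u, v = dag.broken_edges[0]
        assert {dag.nodes[u].atom_type, dag.nodes[v].atom_type} == {"C"}
        # degree labels frozen: the disconnected ring carbons keep degree 3
        assert dag.nodes[u].degree_label == 3
        assert dag.nodes[v].degree_label == 3

    def test_atom_map_forces_root(self):
        dag = smiles_to_dag("[C:1]1=NN=CC=C1")
        assert dag.nodes[dag.root].atom_type == "C"

    def test_acyclic_molecule_has_no_broken_edges(self):
        dag = smiles_to_dag("CCO")
        assert dag.broken_edges == ()
        assert sum(1 for p in dag.parent if p == -1) == 1

    def test_broken_edge_count_equals_cyclomatic_number(self):
        for smi, mu in [("CCO", 0), ("C1CC1", 1), ("c1ccc2ccccc2c1", 2),
                        ("C1CC2(CC1)CCC2", 2)]:
            dag = smiles_to_dag(smi)
            assert len(dag.broken_edges) == mu

    def test_node_count_equals_heavy_atoms(self):
        for smi in ["C", "CCO", "c1ccccc1", "CC(F)(F)C#N"]:
            g = parse_smiles(smi)
            assert to_rooted_dag(g).n_nodes == g.n_nodes

    def test_disconnected_graph_rejected(self):
        g = MolGraph(
            nodes=[AtomNode("C", 0), AtomNode("C", 0)],
            edges=[],
            source_smiles="<synthetic>",
        )
        with pytest.raises(DisconnectedGraphError):
            to_rooted_dag(g)

    def test_root_override_argument(self):
        g = assign_stereo_labels(parse_smiles("CCO"))
        dag = to_rooted_dag(g, root_override=2)
        assert dag.root == 2

    def test_serialization_is_deterministic(self):
        a = canonical_serialization(smiles_to_dag("CC1OC1C"))
        b = canonical_serialization(smiles_to_dag("CC1OC1C"))
        assert a == b


class TestStereoInvariance:
    def test_enantiomers_encode_identically(self):
        pairs = generate_stereo_pairs(6, seed=101)
        for smi, mirror, dia in pairs:
            d1 = canonical_serialization(smiles_to_dag(smi))
            d2 = canonical_serialization(smiles_to_dag(mirror))
            d3 = canonical_serialization(smiles_to_dag(dia))
            assert d1 == d2, (smi, mirror)
            assert d1 != d3, (smi, dia)

    def test_mirror_of_single_centre_molecule(self):
        smi = "CC[C@@H](O)C"
        assert canonical_serialization(
            smiles_to_dag(smi)
        ) == canonical_serialization(smiles_to_dag(mirror_smiles(smi)))

    def test_degree_labels_unchanged_by_cycle_opening(self):
        for smi in ["C1CC1", "c1ccc2ccccc2c1", "CC1OC1C"]:
            g = parse_smiles(smi, alphabet=SMALL_ALPHABET)
            dag = to_rooted_dag(g)
            assert [n.degree_label for n in dag.nodes] == [
                n.degree_label for n in g.nodes
            ]
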