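"""Compound class mapping, Tanimoto and graph descriptors."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

from bindscape import annotation
from bindscape.core_io import CompoundRecord, Fingerprint, compute_fingerprint


def fp(bits, size=16):
    return Fingerprint(frozenset(bits), size)


def record(cid, mw, bits, size=16):
    return CompoundRecord(cid, None, mw, None, fp(bits, size))


def mol_record(cid, smiles):
    mol = Chem.MolFromSmiles(smiles)
    return CompoundRecord(cid, mol, Descriptors.MolWt(mol), smiles,
                          compute_fingerprint(mol))


class TestTanimoto:
    def test_identical(self):
        assert annotation.tanimoto(fp({1, 2, 3}), fp({1, 2, 3})) == 1.0

    def test_disjoint(self):
        assert annotation.tanimoto(fp({1, 2}), fp({3, 4})) == 0.0

    def test_worked_example(self):
        assert annotation.tanimoto(fp({1, 2, 3}), fp({2, 3, 4})) == 0.5

    def test_empty_pair_warns(self):
        with pytest.warns(UserWarning):
            assert annotation.tanimoto(fp(set()), fp(set())) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            annotation.tanimoto(fp({1}, 16), fp({1}, 32))

    def test_symmetric_and_identity(self, rng):
        for _ in range(200):
            a = fp(set(rng.choice(64, rng.integers(1, 20), replace=False)), 64)
            b = fp(set(rng.choice(64, rng.integers(1, 20), replace=False)), 64)
            tab = annotation.tanimoto(a, b)
            assert tab == annotation.tanimoto(b, a)
            assert (tab == 1.0) == (a.bits == b.bits)


class TestMapCompound:
    def test_drug_only(self):
        pdb = record("X", 100.0, {1, 2, 3})
        out = annotation.map_compound(pdb, [record("D1", 100.2, {1, 2, 3})],
                                      [[record("M1", 300.0, {9, 10, 11})]])
        assert out.compound_class == "drug"
        assert out.drug_matches == ("D1",)

    def test_overlapping(self):
        pdb = record("X", 100.0, {1, 2, 3})
        out = annotation.map_compound(pdb, [record("D1", 100.0, {1, 2, 3})],
                                      [[record("M1", 100.5, {1, 2, 3})]])
        assert out.compound_class == "overlapping"

    def test_mw_gate(self):
        pdb = record("X", 100.0, {1, 2, 3})
        out = annotation.map_compound(pdb, [record("D1", 101.5, {1, 2, 3})],
                                      [[]])
        assert out.compound_class == "unassigned"

    def test_tanimoto_strictly_greater(self):
        # T exactly 0.95: 19 shared bits of a 20-bit union
        a = set(range(20))
        b = set(range(19))
        assert annotation.tanimoto(fp(a, 32), fp(b, 32)) == 0.95
        pdb = record("X", 100.0, a, 32)
        out = annotation.map_compound(pdb, [record("D1", 100.0, b, 32)], [[]])
        assert out.compound_class == "unassigned"

    def test_library_order_invariance(self):
        pdb = record("X", 100.0, {1, 2, 3})
        m1 = [record("M1", 100.0, {1, 2, 3})]
        m2 = [record("M2", 100.0, {1, 2, 3})]
        a = annotation.map_compound(pdb, [], [m1, m2])
        b = annotation.map_compound(pdb, [], [m2, m1])
        assert a.metabolite_matches == b.metabolite_matches


def oracle_wiener(g):
    return nx.wiener_index(g)


def oracle_platt(g):
    return sum(g.degree[u] + g.degree[v] - 2 for u, v in g.edges)


def oracle_balaban(g):
    n, m = g.number_of_nodes(), g.number_of_edges()
    dist = dict(nx.all_pairs_shortest_path_length(g))
    s = {v: sum(dist[v].values()) for v in g}
    mu = m - n + 1
    return m / (mu + 1) * sum(1 / math.sqrt(s[u] * s[v]) for u, v in g.edges)


class TestGraphDescriptors:
    def test_nbutane_wiener(self):
        rec = mol_record("butane", "CCCC")
        vec = annotation.compute_graph_descriptors(rec)
        assert vec.wiener_index == 10  # 1+2+3+1+2+1

    def test_cyclohexane_rings(self):
        vec = annotation.compute_graph_descriptors(mol_record("chx", "C1CCCCC1"))
        assert vec.ring_atom_count == 6
        assert vec.relative_ring_atom_count == 1.0

    def test_methane(self):
        vec = annotation.compute_graph_descriptors(mol_record("methane", "C"))
        assert vec.relative_rotatable_bond_count == 0.0
        assert vec.relative_sp3_carbons == 1.0

    def test_graph_indices_match_oracles_on_all_small_trees(self):
        for n in range(2, 9):
            for g in nx.nonisomorphic_trees(n):
                edges = list(g.edges)
                deg = np.zeros(n, int)
                for u, v in edges:
                    deg[u] += 1
                    deg[v] += 1
                assert annotation.wiener_index(n, edges) == pytest.approx(
                    oracle_wiener(g))
                assert annotation.platt_index(edges, deg) == pytest.approx(
                    oracle_platt(g))
                assert annotation.balaban_index(n, edges) == pytest.approx(
                    oracle_balaban(g))

    def test_balaban_on_cycles(self):
        for n in (3, 5, 8):
            g = nx.cycle_graph(n)
            assert annotation.balaban_index(n, list(g.edges)) == pytest.approx(
                oracle_balaban(g))

    def test_vertex_adjacency_information(self):
        assert annotation.vertex_adjacency_information(
            [(0, 1), (1, 2)]) == pytest.approx(2.0)  # 1 + log2(2)

    def test_disconnected_uses_largest_fragment(self):
        with pytest.warns(UserWarning):
            vec = annotation.compute_graph_descriptors(
                mol_record("salt", "CCCC.[Na+]"))
        assert vec.atom_count == 4


class TestDescriptorTable:
    def test_override_and_unknown(self, tmp_path):
        vectors = {"X": annotation.DescriptorVector(molecular_weight=100.0)}
        table = tmp_path / "d.tsv"
        pd.DataFrame([{"compound_id": "X", "logp": 1.5},
                      {"compound_id": "Z", "logp": 0.0}]).to_csv(
            table, sep="\t", index=False)
        out = annotation.load_descriptor_table(table, vectors)
        assert out["X"].logp == 1.5
        assert "Z" not in out

    def test_mw_conflict_warns(self, tmp_path):
        vectors = {"X": annotation.DescriptorVector(molecular_weight=100.0)}
        table = tmp_path / "d.tsv"
        pd.DataFrame([{"compound_id": "X", "molecular_weight": 150.0}]
                     ).to_csv(table, sep="\t", index=False)
        with pytest.warns(UserWarning):
            annotation.load_descriptor_table(table, vectors)

    def test_missing_key_column(self, tmp_path):
        table = tmp_path / "d.tsv"
        pd.DataFrame([{"id": "X"}]).to_csv(table, sep="\t", index=False)
        with pytest.raises(ValueError):
            annotation.load_descriptor_table(table, {})
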