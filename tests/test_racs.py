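"""Autocorrelation descriptors against an independent brute-force oracle."""

import numpy as np
import pytest

from irphos.core import AtomNode, MolecularGraph
from irphos.racs import (
    PROPERTIES,
    autocorrelation,
    cd_racs,
    complex_racs,
    ligand_racs,
    property_values,
    assign_ligand_planes,
)

from conftest import random_graph


def bfs_distances(graph, src):
    """Plain breadth-first search, independent of the library path."""
    dist = {src: 0}
    frontier = [src]
    adj = {i: set() for i in range(graph.n_atoms)}
    for i, j in graph.bonds:
        adj[i].add(j)
        adj[j].add(i)
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_force_ac(graph, start_set, operation, prop, depth, decay=False):
    """Double loop over ordered pairs with hand-rolled BFS distances."""
    p = property_values(graph, prop)
    total = 0.0
    for i in start_set:
        dist = bfs_distances(graph, i)
        for j in range(graph.n_atoms):
            if dist.get(j, -1) != depth:
                continue
            term = p[i] * p[j] if operation == "product" else p[i] - p[j]
            if decay and i != j:
                r = float(np.linalg.norm(graph.coordinates[i] - graph.coordinates[j]))
                term /= r
            total += term
    return total


class TestOracleEquivalence:
    @pytest.mark.parametrize("operation", ["product", "difference"])
    def test_random_graphs_match_brute_force(self, operation):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            g = random_graph(rng)
            prop = str(rng.choice(PROPERTIES))
            depth = int(rng.integers(0, 5))
            start = [int(i) for i in
                     rng.choice(g.n_atoms, size=rng.integers(1, g.n_atoms + 1),
                                replace=False)]
            expected = brute_force_ac(g, start, operation, prop, depth)
            got = autocorrelation(g, start, operation, prop, depth)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_decayed_values_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g = random_graph(rng)
            prop = str(rng.choice(PROPERTIES))
            depth = int(rng.integers(0, 4))
            start = list(range(g.n_atoms))
            expected = brute_force_ac(g, start, "product", prop, depth, decay=True)
            got = autocorrelation(g, start, "product", prop, depth, decay=True)
            assert got == pytest.approx(expected, abs=1e-10)


class TestWorkedExamples:
    def water(self):
        return MolecularGraph(
            [AtomNode("H"), AtomNode("O"), AtomNode("H")], [(0, 1), (1, 2)]
        )

    def test_depth0_identity_product_counts_atoms(self):
        g = self.water()
        assert autocorrelation(g, range(3), "product", "I", 0) == 3

    def test_depth0_difference_is_zero(self):
        g = self.water()
        for prop in PROPERTIES:
            assert autocorrelation(g, range(3), "difference", prop, 0) == 0

    def test_water_depth1_nuclear_charge_product(self):
        # ordered pairs (H,O),(O,H),(O,H),(H,O), each 1*8
        assert autocorrelation(self.water(), range(3), "product", "Z", 1) == 32

    def test_two_atom_decayed_product(self):
        g = MolecularGraph(
            [AtomNode("H"), AtomNode("O")],
            [(0, 1)],
            coordinates=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        )
        got = autocorrelation(g, range(2), "product", "Z", 1, decay=True)
        assert got == pytest.approx(16.0)

    def test_identity_products_count_ordered_pairs_at_distance(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng)
        dist = g.distance_matrix()
        for d in range(4):
            expected = int((dist == d).sum())
            got = autocorrelation(g, range(g.n_atoms), "product", "I", d)
            assert got == expected


class TestFeatureSets:
    def test_ligand_rac_dimensions(self, small_dataset):
        lib = small_dataset.library
        fv = ligand_racs(lib.cn_ligands[0], lib.nn_ligands[0])
        assert len(fv) == 70
        fv0 = ligand_racs(lib.cn_ligands[0], lib.nn_ligands[0], d_max=0)
        assert len(fv0) == 14

    def test_ligand_rac_identity_depth0_counts_atoms(self, small_dataset):
        lib = small_dataset.library
        cn, nn = lib.cn_ligands[0], lib.nn_ligands[0]
        s = ligand_racs(cn, nn).to_series()
        assert s["lrac_CN_prod_I_0"] == cn.graph.n_atoms
        assert s["lrac_NN_prod_I_0"] == nn.graph.n_atoms

    def test_complex_rac_dimensions_and_metal_terms(self, toy_complex):
        fv = complex_racs(toy_complex)
        assert len(fv) == 196
        s = fv.to_series()
        assert s["rac_mc_prod_Z_0"] == 77**2  # Ir self-pair
        for prop in PROPERTIES:
            assert s[f"rac_mc_diff_{prop}_0"] == 0

    def test_cd_rac_dimensions(self, toy_complex):
        assert len(cd_racs(toy_complex)) == 222

    def test_cd_rac_scaling_with_geometry(self, toy_complex):
        fv1 = cd_racs(toy_complex).to_series()
        g = toy_complex.whole_graph
        saved = g.coordinates
        try:
            g.coordinates = saved * 2.0
            fv2 = cd_racs(toy_complex).to_series()
        finally:
            g.coordinates = saved
        for name in fv1.index:
            if name.endswith("_0") or "_diff_" in name:
                continue
            assert fv2[name] == pytest.approx(fv1[name] / 2.0, rel=1e-9)

    def test_cd_rac_equals_rac_at_unit_distances(self):
        # equilateral triangle, all pairwise distances 1
        coords = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]]
        )
        g = MolecularGraph(
            [AtomNode("C"), AtomNode("N"), AtomNode("O")],
            [(0, 1), (1, 2), (0, 2)],
            coordinates=coords,
        )
        for prop in PROPERTIES:
            plain = autocorrelation(g, range(3), "product", prop, 1)
            decayed = autocorrelation(g, range(3), "product", prop, 1, decay=True)
            assert decayed == pytest.approx(plain)

    def test_permutation_invariance(self, small_dataset):
        rng = np.random.default_rng(0)
        lib = small_dataset.library
        cn, nn = lib.cn_ligands[1], lib.nn_ligands[1]
        base = ligand_racs(cn, nn).values
        g = cn.graph
        perm = rng.permutation(g.n_atoms)
        inv = np.argsort(perm)
        permuted = MolecularGraph(
            [g.atoms[i] for i in perm],
            [(int(inv[i]), int(inv[j])) for i, j in g.bonds],
        )
        from irphos.core import LigandRecord

        cn_p = LigandRecord(
            "perm", "CN", permuted,
            (int(inv[cn.coordinating_atoms[0]]), int(inv[cn.coordinating_atoms[1]])),
        )
        assert ligand_racs(cn_p, nn).values == pytest.approx(base)

    def test_feature_names_stable_across_runs(self, toy_complex):
        assert complex_racs(toy_complex).names == complex_racs(toy_complex).names
        n1 = cd_racs(toy_complex).names
        n2 = cd_racs(toy_complex).names
        assert n1 == n2


class TestLigandPlanes:
    def test_weights_normalized_and_split(self, toy_complex):
        planes = assign_ligand_planes(toy_complex)
        assert sum(planes["equatorial"].values()) == pytest.approx(1.0)
        assert sum(planes["axial"].values()) == pytest.approx(1.0)
        # NN (instance 2) fully equatorial; CN copies appear in both classes
        assert 2 not in planes["axial"]
        assert set(planes["axial"]) == {0, 1}
        assert planes["equatorial"][2] == pytest.approx(0.5)


def test_missing_coordinates_error(small_dataset):
    from irphos.core import assemble_complex, LigandRecord, MolecularGraph as MG

    lib = small_dataset.library
    cn = lib.cn_ligands[0]
    bare_graph = MG(cn.graph.atoms, cn.graph.bonds)  # no coordinates
    cn_bare = LigandRecord("bare", "CN", bare_graph, cn.coordinating_atoms)
    nn = lib.nn_ligands[0]
    nn_bare = LigandRecord(
        "nbare", "NN", MG(nn.graph.atoms, nn.graph.bonds), nn.coordinating_atoms
    )
    c = assemble_complex(cn_bare, nn_bare)
    assert len(complex_racs(c)) == 196  # connectivity set works without geometry
    with pytest.raises(ValueError, match="coordinates"):
        cd_racs(c)
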