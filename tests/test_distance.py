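"""Distances, neighbour joining, PCA and Evanno ΔK."""

import itertools
import math

import numpy as np
import pytest

from radfp import (DistanceMatrix, StructureRuns, p_distance, p_distance_matrix,
                   nei1972_distance, nj_tree, pca_coordinates, evanno_delta_k,
                   structure_pseudo_likelihood, SimulationConfig, simulate_genotypes)
from .conftest import make_matrix


class TestPDistance:
    def test_definitional_values(self):
        m = make_matrix([["AA", "AA", "AA"],
                         ["GG", "AG", "AA"]])
        assert p_distance(m, 0, 0) == 0.0
        assert p_distance(m, 0, 1) == pytest.approx((1 + 0.5 + 0) / 3)

    def test_identical_modulo_missing_is_zero(self):
        m = make_matrix([["AA", "AG", "NN"],
                         ["AA", "NN", "CC"]])
        assert p_distance(m, 0, 1) == 0.0

    def test_no_shared_loci_error(self):
        m = make_matrix([["AA", "NN"], ["NN", "CC"]])
        with pytest.raises(ValueError, match="no mutually called"):
            p_distance(m, 0, 1)

    def test_matrix_matches_pairwise_and_brute_force(self, random_matrix):
        dm = p_distance_matrix(random_matrix)
        n = random_matrix.n_accessions
        rng = np.random.default_rng(2)
        for i, j in zip(rng.integers(0, n, 15), rng.integers(0, n, 15)):
            if i == j:
                continue
            # brute-force per-locus tally
            num = den = 0
            for a, b in zip(random_matrix.calls[i], random_matrix.calls[j]):
                if a == "NN" or b == "NN":
                    continue
                den += 1
                shared = sum(min(a.count(x), b.count(x)) for x in set(a + b))
                num += 1 - shared / 2
            assert dm.values[i, j] == pytest.approx(num / den)
            assert dm.values[i, j] == pytest.approx(p_distance(random_matrix, int(i), int(j)))


class TestNei1972:
    def test_identical_profiles_zero(self):
        m = make_matrix([["AA", "AG", "CC"], ["AA", "AG", "CC"], ["GG", "GG", "CC"]])
        d = nei1972_distance(m)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_fixation_infinite_flagged(self):
        m = make_matrix([["AA", "CC"], ["GG", "TT"], ["AA", "CC"]])
        d = nei1972_distance(m)
        assert math.isinf(d.values[0, 1])
        assert ("a0", "a1") in d.flagged_pairs

    def test_three_accession_hand_computation(self):
        # accessions x: AA,AG  y: AG,GG  over two loci
        # locus freq vectors: x = (1,0),(0.5,0.5); y = (0.5,0.5),(0,1)
        # Jxy per locus: 0.5, 0.5 -> mean 0.5
        # Jx: 1, 0.5 -> 0.75 ; Jy: 0.5, 1 -> 0.75
        # I = 0.5/0.75 = 2/3 ; D = -ln(2/3)
        m = make_matrix([["AA", "AG"], ["AG", "GG"]])
        d = nei1972_distance(m)
        assert d.values[0, 1] == pytest.approx(-math.log(2 / 3), abs=1e-10)

    def test_symmetry_zero_diagonal_permutation(self, random_matrix):
        d = nei1972_distance(random_matrix)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        perm = np.random.default_rng(3).permutation(random_matrix.n_accessions)
        m2 = make_matrix(random_matrix.calls[perm].tolist(),
                         accession_ids=[random_matrix.accession_ids[i] for i in perm],
                         marker_ids=list(random_matrix.marker_ids))
        d2 = nei1972_distance(m2)
        for a, b in itertools.combinations(range(5), 2):
            ia, ib = list(perm).index(a), list(perm).index(b)
            assert d2.values[ia, ib] == pytest.approx(d.values[a, b])


def additive_distance_from_tree(edges, leaves):
    """Path-length matrix of a tree given as {(u,v): length}."""
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    out = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(leaves):
            out[i, j] = lengths[b]
    return out


def enumerate_topologies(n_leaves):
    """All unrooted binary topologies over leaves 0..n-1 as edge lists."""
    trees = [[(0, 1), (1, 2), (0, 2)]]  # star on 3 leaves with center = node "-1"?
    # represent as list of edges over nodes; internal nodes get ids >= 100
    base = [[(0, 100), (1, 100), (2, 100)]]
    nxt = 101
    for leaf in range(3, n_leaves):
        new = []
        for edges in base:
            for k, (u, v) in enumerate(edges):
                internal = 100 + (leaf - 2) * 100  # unique per level
                e2 = [e for m, e in enumerate(edges) if m != k]
                e2 += [(u, internal), (internal, v), (leaf, internal)]
                new.append(e2)
        base = new
    return base


class TestNJTree:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5))
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float)
        t = nj_tree(DistanceMatrix(labels, D, "test"))
        assert t.negative_branches_clamped == 0
        tt = t.to_skbio().tip_tip_distances()
        for a, b in itertools.combinations(labels, 2):
            assert tt[a, b] == pytest.approx(D[labels.index(a), labels.index(b)], abs=1e-9)

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_tree(DistanceMatrix(labels, D, "test"))
        # la = (3+4-5)/2 = 1, lb = (3+5-4)/2 = 2, lc = (4+5-3)/2 = 3
        tt = t.to_skbio().tip_tip_distances()
        assert tt["A", "B"] == pytest.approx(3)
        assert tt["A", "C"] == pytest.approx(4)
        assert tt["B", "C"] == pytest.approx(5)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 1), (6, 2), (7, 3), (8, 4)])
    def test_random_additive_matrices_recovered(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        # random caterpillar-ish tree over n taxa
        edges = {}
        internal = 100
        edges[(0, internal)] = rng.uniform(0.5, 3)
        edges[(1, internal)] = rng.uniform(0.5, 3)
        prev = internal
        for leaf in range(2, n_taxa - 1):
            internal += 1
            edges[(prev, internal)] = rng.uniform(0.5, 3)
            edges[(leaf, internal)] = rng.uniform(0.5, 3)
            prev = internal
        edges[(n_taxa - 1, prev)] = rng.uniform(0.5, 3)
        leaves = list(range(n_taxa))
        D = additive_distance_from_tree(edges, leaves)
        labels = [f"t{i}" for i in leaves]
        t = nj_tree(DistanceMatrix(labels, D, "test"))
        tt = t.to_skbio().tip_tip_distances()
        for i, j in itertools.combinations(range(n_taxa), 2):
            assert tt[f"t{i}", f"t{j}"] == pytest.approx(D[i, j], abs=1e-9)

    def test_seven_taxa_matches_minimum_evolution_oracle(self):
        """NJ topology equals the exhaustive minimum-evolution optimum on
        additive input (all 945 seven-leaf topologies, OLS branch lengths)."""
        rng = np.random.default_rng(9)
        n = 7
        edges = {(0, 100): 1.2, (1, 100): 0.7, (100, 101): 0.6, (2, 101): 1.9,
                 (101, 102): 0.8, (3, 102): 0.9, (102, 103): 0.5, (4, 103): 1.1,
                 (103, 104): 0.7, (5, 104): 1.4, (6, 104): 2.0}
        D = additive_distance_from_tree(edges, list(range(n)))
        labels = [f"t{i}" for i in range(n)]
        t = nj_tree(DistanceMatrix(labels, D, "test"))

        def bipartitions(edge_list, leaves):
            import networkx as nx
            g = nx.Graph(edge_list)
            bips = set()
            for u, v in edge_list:
                g.remove_edge(u, v)
                side = {x for x in nx.node_connected_component(g, u) if x in leaves}
                g.add_edge(u, v)
                if 1 < len(side) < len(leaves) - 1:
                    bips.add(frozenset(side) if 0 in side
                             else frozenset(set(leaves) - side))
            return bips

        best_len, best_top = None, None
        leaves = list(range(n))
        for edge_list in enumerate_topologies(n):
            # OLS branch lengths on the path design matrix
            nodes = sorted({x for e in edge_list for x in e})
            eidx = {tuple(sorted(e)): k for k, e in enumerate(edge_list)}
            import networkx as nx
            g = nx.Graph(edge_list)
            rows, y = [], []
            for i, j in itertools.combinations(leaves, 2):
                path = nx.shortest_path(g, i, j)
                row = np.zeros(len(edge_list))
                for u, v in zip(path, path[1:]):
                    row[eidx[tuple(sorted((u, v)))]] = 1
                rows.append(row)
                y.append(D[i, j])
            lens, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
            tree_len = lens.sum()
            if best_len is None or tree_len < best_len - 1e-9:
                best_len, best_top = tree_len, bipartitions(edge_list, set(leaves))

        # NJ tree bipartitions (via skbio) must equal the ME-optimal topology
        sk = t.to_skbio()
        nj_bips = set()
        for node in sk.non_tips(include_self=False):
            side = {int(tip.name[1:]) for tip in node.tips()}
            if 1 < len(side) < n - 1:
                nj_bips.add(frozenset(side) if 0 in side
                            else frozenset(set(leaves) - side))
        assert nj_bips == best_top

    def test_cross_check_against_skbio(self):
        import skbio
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(4)
        x = rng.uniform(0.1, 1, size=(6, 6))
        D = (x + x.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(6)]
        ours = nj_tree(DistanceMatrix(labels, D, "test")).to_skbio()
        theirs = sknj(skbio.DistanceMatrix(D, labels))
        assert ours.compare_rfd(theirs) == 0

    def test_nonfinite_entries_error(self):
        D = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(DistanceMatrix(["a", "b", "c"], D, "test"))


class TestPCA:
    def test_duplicated_rows_identical_coordinates(self):
        m = make_matrix([["AA", "AG", "GG"], ["AA", "AG", "GG"], ["GG", "GG", "AA"],
                         ["AG", "AA", "AG"]])
        coords, _ = pca_coordinates(m, 2)
        assert np.allclose(coords.iloc[0], coords.iloc[1])

    def test_explained_variance_properties(self, random_matrix):
        coords, explained = pca_coordinates(random_matrix, 5)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1 + 1e-9

    def test_too_many_components_error(self, random_matrix):
        with pytest.raises(ValueError):
            pca_coordinates(random_matrix, 1000)

    def test_separates_well_differentiated_subpops(self):
        cfg = SimulationConfig(n_accessions=200, n_markers=32, fst=0.25,
                               admixture_alpha=0.05, n_duplicate_groups=0, seed=21)
        m, truth = simulate_genotypes(cfg)
        coords, _ = pca_coordinates(m, 2)
        lab = np.array(truth.subpop_assignment)
        pc1 = coords["PC1"].to_numpy()
        # best single threshold on PC1
        order = np.argsort(pc1)
        sorted_lab = lab[order]
        best = max(
            max((sorted_lab[:cut] == 0).sum() + (sorted_lab[cut:] == 1).sum(),
                (sorted_lab[:cut] == 1).sum() + (sorted_lab[cut:] == 0).sum())
            for cut in range(len(lab) + 1))
        assert best / len(lab) >= 0.95


class TestEvannoDeltaK:
    def test_printed_formula_arithmetic(self):
        runs = StructureRuns({
            1: [-1000 + d for d in (-2, 0, 2)],
            2: [-900 + d for d in (-2, 0, 2)],
            3: [-890 + d for d in (-2, 0, 2)],
            4: [-885 + d for d in (-2, 0, 2)],
        })
        table, best = evanno_delta_k(runs)
        assert best == 2
        dk = dict(zip(table["K"], table["delta_K"]))
        assert dk[2] == pytest.approx(90 / 2)
        assert dk[3] == pytest.approx(5 / 2)

    def test_linear_profile_zero_curvature(self):
        runs = StructureRuns({k: [-100.0 * k + r for r in (-1, 0, 1)]
                              for k in range(1, 6)})
        table, _ = evanno_delta_k(runs)
        interior = table.dropna(subset=["delta_K"])
        assert np.allclose(interior["delta_K"], 0)

    def test_zero_sd_infinite_flagged(self):
        runs = StructureRuns({1: [-100, -100], 2: [-50, -50], 3: [-49, -49]})
        with pytest.warns(UserWarning, match="zero replicate sd"):
            table, best = evanno_delta_k(runs)
        assert best == 2
        assert math.isinf(table.loc[table["K"] == 2, "delta_K"].iloc[0])

    def test_insufficient_replicates_error(self):
        with pytest.raises(ValueError, match="replicates"):
            StructureRuns({1: [-1.0], 2: [-2.0], 3: [-3.0]})

    def test_non_consecutive_k_error(self):
        with pytest.raises(ValueError):
            StructureRuns({1: [-1.0, -2.0], 3: [-1.0, -2.0], 5: [-1.0, -2.0]})

    def test_two_subpop_profile_recovers_k2(self):
        cfg = SimulationConfig(n_accessions=200, n_markers=32, fst=0.25,
                               admixture_alpha=0.05, n_duplicate_groups=0, seed=13)
        m, _ = simulate_genotypes(cfg)
        runs = structure_pseudo_likelihood(m, range(1, 6), seed=13)
        _, best = evanno_delta_k(runs)
        assert best == 2


class TestDuplicateGroupDistances:
    def test_planted_duplicates_zero_distance(self, panel_scale):
        matrix, truth = panel_scale
        (group,) = truth.duplicate_groups
        idx = [matrix.accession_ids.index(a) for a in group]
        nei = nei1972_distance(matrix)
        pd_ = p_distance_matrix(matrix)
        for a in idx:
            for b in idx:
                assert nei.values[a, b] == pytest.approx(0.0, abs=1e-12)
                assert pd_.values[a, b] == pytest.approx(0.0, abs=1e-12)
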