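import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from phenoplate import (
    ValidationError,
    centred_pearson_distance,
    cophenetic_matrix,
    cut,
    leaf_order,
    to_newick,
    upgma,
    write_cdt_gtr,
    write_newick,
)
from phenoplate.clustering import DistanceMatrix
from phenoplate.scoring import ToleranceScore, log_ratio_matrix
from phenoplate.synthetic import simulate_logratio_blocks


def brute_force_upgma(ids, dist):
    """Independent oracle: clusters as frozensets, inter-cluster distance
    recomputed each step as the plain average of all original pairwise
    distances between members (the defining property of average linkage)."""
    index = {s: i for i, s in enumerate(ids)}
    clusters = [frozenset([s]) for s in ids]
    merges = []
    while len(clusters) > 1:
        best = None
        best_d = np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [
                        dist[index[x], index[y]]
                        for x in clusters[a]
                        for y in clusters[b]
                    ]
                )
                if d < best_d:
                    best_d = d
                    best = (a, b)
        a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], best_d))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return merges


def members_of(dend):
    """Leaf-id sets of every internal node of a Dendrogram."""
    n = dend.n_leaves
    sets = {i: frozenset([dend.leaf_ids[i]]) for i in range(n)}
    out = []
    for k, m in enumerate(dend.merges):
        sets[n + k] = sets[m.left] | sets[m.right]
        out.append((sets[m.left], sets[m.right], m.height))
    return out


def random_distance_matrix(rng, n):
    d = rng.uniform(0.05, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=[f"s{i}" for i in range(n)], values=d)


class TestCentredPearsonDistance:
    def test_self_negation_and_hand_value(self):
        df = pd.DataFrame(
            [[1.0, 2, 3], [1.0, 2, 3], [-1.0, -2, -3], [2.0, 1, 3]],
            index=["a", "a2", "neg", "perm"],
        )
        dm = centred_pearson_distance(df)
        i = {s: k for k, s in enumerate(dm.ids)}
        assert dm.values[i["a"], i["a2"]] == pytest.approx(0.0, abs=1e-12)
        assert dm.values[i["a"], i["neg"]] == pytest.approx(2.0, abs=1e-12)
        assert dm.values[i["a"], i["perm"]] == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_row_flagged_at_distance_one(self):
        df = pd.DataFrame([[1.0, 2, 3], [5.0, 5, 5]], index=["a", "flat"])
        dm = centred_pearson_distance(df)
        assert dm.zero_variance == {"flat"}
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_pairwise_complete_with_missing_cells(self):
        df = pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 4, 6, np.nan]], index=["a", "b"]
        )
        dm = centred_pearson_distance(df)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_shared_columns_rejected(self):
        df = pd.DataFrame(
            [[1.0, 2, np.nan, np.nan], [np.nan, np.nan, 1.0, 2]], index=["a", "b"]
        )
        with pytest.raises(ValidationError):
            centred_pearson_distance(df)

    def test_distance_matrix_invariants_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestUpgma:
    def test_two_leaves_base_case(self):
        dm = DistanceMatrix(ids=["A", "B"], values=np.array([[0, 0.8], [0.8, 0]]))
        dend = upgma(dm)
        assert len(dend.merges) == 1
        assert dend.merges[0].height == pytest.approx(0.8)
        assert leaf_order(dend) == ["A", "B"]

    def test_four_item_hand_agglomeration(self):
        ids = ["A", "B", "C", "D"]
        d = np.full((4, 4), 0.9)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.2
        dend = upgma(DistanceMatrix(ids=ids, values=d))
        got = members_of(dend)
        assert got[0] == (frozenset("A"), frozenset("B"), pytest.approx(0.1))
        assert got[1] == (frozenset("C"), frozenset("D"), pytest.approx(0.2))
        assert got[2][2] == pytest.approx(0.9)
        assert leaf_order(dend) == ["A", "B", "C", "D"]

    @pytest.mark.parametrize("n", range(3, 9))
    def test_matches_brute_force_oracle(self, rng, n):
        for _ in range(10):
            dm = random_distance_matrix(rng, n)
            dend = upgma(dm)
            expected = brute_force_upgma(dm.ids, dm.values)
            got = members_of(dend)
            for (el, er, eh), (gl, gr, gh) in zip(expected, got):
                assert {el, er} == {gl, gr}
                assert gh == pytest.approx(eh, abs=1e-12)

    def test_heights_nondecreasing_on_random_matrices(self, rng):
        for _ in range(30):
            dend = upgma(random_distance_matrix(rng, int(rng.integers(3, 11))))
            heights = [m.height for m in dend.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_agrees_with_scipy_average_linkage_cophenetic(self, rng):
        for _ in range(10):
            dm = random_distance_matrix(rng, 9)
            ours = cophenetic_matrix(upgma(dm))
            Z = hierarchy.linkage(squareform(dm.values, checks=False), method="average")
            theirs = squareform(hierarchy.cophenet(Z))
            np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_ultrametric_input_reproduced_by_cophenetic_distances(self, rng):
        dm = random_distance_matrix(rng, 8)
        ultra = cophenetic_matrix(upgma(dm))
        dend2 = upgma(DistanceMatrix(ids=dm.ids, values=ultra))
        np.testing.assert_allclose(cophenetic_matrix(dend2), ultra, atol=1e-12)

    def test_determinism_under_ties(self):
        # identical profiles: every pairwise distance ties; creation-index
        # tie-break makes the result reproducible
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        dend = upgma(DistanceMatrix(ids=list("ABCD"), values=d))
        assert members_of(dend)[0] == (
            frozenset("A"),
            frozenset("B"),
            pytest.approx(0.5),
        )


class TestCut:
    def test_recovers_two_obvious_blocks(self):
        ids = ["a1", "a2", "b1", "b2"]
        d = np.array(
            [
                [0.0, 0.1, 1.8, 1.9],
                [0.1, 0.0, 1.7, 1.8],
                [1.8, 1.7, 0.0, 0.2],
                [1.9, 1.8, 0.2, 0.0],
            ]
        )
        labels = cut(upgma(DistanceMatrix(ids=ids, values=d)), 2)
        assert labels["a1"] == labels["a2"] != labels["b1"] == labels["b2"]

    def test_k_bounds(self):
        dm = DistanceMatrix(ids=["A", "B"], values=np.array([[0, 1.0], [1.0, 0]]))
        dend = upgma(dm)
        assert set(cut(dend, 1).values()) == {0}
        with pytest.raises(ValidationError):
            cut(dend, 3)


# ---------------------------------------------------------------------------
# export formats


def parse_gtr(path):
    """Minimal TreeView-compatible GTR reader: returns node -> (children, sim)."""
    nodes = {}
    for line in open(path):
        node, c1, c2, sim = line.rstrip("\n").split("\t")
        assert node.startswith("NODE") and node.endswith("X")
        nodes[node] = ((c1, c2), float(sim))
    return nodes


def _two_strain_matrix():
    scores = [
        ToleranceScore("S288C", "c1", 50, 100, 50.0),
        ToleranceScore("S288C", "c2", 40, 100, 40.0),
        ToleranceScore("A", "c1", 25, 100, 25.0),
        ToleranceScore("A", "c2", 80, 100, 80.0),
    ]
    return log_ratio_matrix(scores)


class TestCdtGtr:
    def test_two_leaf_gtr_line(self, tmp_path):
        matrix = _two_strain_matrix()
        dm = DistanceMatrix(
            ids=matrix.strain_ids, values=np.array([[0, 0.8], [0.8, 0]])
        )
        dend = upgma(dm)
        cdt, gtr = write_cdt_gtr(dend, matrix, tmp_path / "out")
        assert gtr.read_text() == "NODE1X\tGENE0X\tGENE1X\t0.2\n"

    def test_cdt_structure_and_reference_zeros(self, tmp_path, rng):
        scores = []
        ids = ["S288C"] + [f"s{i}" for i in range(5)]
        for cond in ("c1", "c2", "c3"):
            for s in ids:
                p = 50.0 if s == "S288C" else float(rng.uniform(10, 200))
                scores.append(ToleranceScore(s, cond, p, 100, p))
        matrix = log_ratio_matrix(scores)
        dend = upgma(centred_pearson_distance(matrix))
        cdt, gtr = write_cdt_gtr(dend, matrix, tmp_path / "clustered")
        lines = cdt.read_text().splitlines()
        assert len(lines) == len(ids) + 1
        assert lines[0].split("\t") == ["GID", "UNIQID", "NAME", "c1", "c2", "c3"]
        rows = {l.split("\t")[1]: l.split("\t") for l in lines[1:]}
        assert rows["S288C"][3:] == ["0", "0", "0"]
        assert [l.split("\t")[1] for l in lines[1:]] == leaf_order(dend)

    def test_gtr_parses_and_is_internally_consistent(self, tmp_path, rng):
        dm = random_distance_matrix(rng, 7)
        dend = upgma(dm)
        scores = [
            ToleranceScore(s, c, 50, 100, float(rng.uniform(20, 200)))
            for s in dm.ids
            for c in ("c1", "c2", "c3")
        ] + [ToleranceScore("S288C", c, 50, 100, 50.0) for c in ("c1", "c2", "c3")]
        matrix = log_ratio_matrix(
            [s for s in scores if s.strain_id in dm.ids or s.strain_id == "S288C"]
        )
        matrix.values = matrix.values.loc[dm.ids]
        dend = upgma(DistanceMatrix(ids=dm.ids, values=dm.values))
        cdt, gtr = write_cdt_gtr(dend, matrix, tmp_path / "t")
        nodes = parse_gtr(gtr)
        assert len(nodes) == len(dm.ids) - 1
        defined = set(nodes)
        used = [c for (children, _) in nodes.values() for c in children]
        assert len(used) == len(set(used))  # every node used once as a child
        for (children, sim) in nodes.values():
            for c in children:
                assert c in defined or (c.startswith("GENE") and c.endswith("X"))
        sims = [nodes[f"NODE{k}X"][1] for k in range(1, len(nodes) + 1)]
        assert all(b <= a + 1e-12 for a, b in zip(sims, sims[1:]))

    def test_mismatched_rows_rejected(self, tmp_path):
        matrix = _two_strain_matrix()
        dm = DistanceMatrix(ids=["X", "Y"], values=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValidationError):
            write_cdt_gtr(upgma(dm), matrix, tmp_path / "bad")


class TestNewick:
    def test_two_leaves_ultrametric_halving(self):
        dm = DistanceMatrix(ids=["A", "B"], values=np.array([[0, 0.8], [0.8, 0]]))
        assert to_newick(upgma(dm)) == "(A:0.4,B:0.4);"

    def test_round_trip_preserves_topology(self, tmp_path, rng):
        from io import StringIO

        from Bio import Phylo

        dm = random_distance_matrix(rng, 8)
        dend = upgma(dm)
        path = write_newick(dend, tmp_path / "t.nwk")
        tree = Phylo.read(str(path), "newick")
        leaves = [t.name for t in tree.get_terminals()]
        assert sorted(leaves) == sorted(dm.ids)
        # clades of the parsed tree match the dendrogram's internal nodes
        parsed_clades = {
            frozenset(t.name for t in c.get_terminals())
            for c in tree.get_nonterminals()
        }
        ours = {l | r for l, r, _ in members_of(dend)}
        assert parsed_clades == ours

    def test_leaf_depths_equal_half_root_height(self, tmp_path, rng):
        from Bio import Phylo

        dm = random_distance_matrix(rng, 6)
        dend = upgma(dm)
        path = write_newick(dend, tmp_path / "t.nwk")
        tree = Phylo.read(str(path), "newick")
        root_h = dend.merges[-1].height
        for leaf in tree.get_terminals():
            assert tree.distance(leaf) == pytest.approx(root_h / 2, abs=1e-9)


def test_cluster_recovery_on_planted_blocks():
    from sklearn.metrics import adjusted_rand_score

    matrix, truth = simulate_logratio_blocks(
        n_strains=40, n_conditions=9, sigma=0.3, seed=11
    )
    dend = upgma(centred_pearson_distance(matrix))
    labels = cut(dend, 2)
    ari = adjusted_rand_score(
        [truth[s] for s in matrix.index], [labels[s] for s in matrix.index]
    )
    assert ari >= 0.9
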