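"""Spectrum distances, neighbor joining and OP-group extraction."""

from io import StringIO

import numpy as np
import pytest
import scipy.stats
from skbio.tree import TreeNode

from compspec.clustering import (
    DistanceMatrix,
    cs_distance,
    distance_matrix,
    extract_op_groups,
    neighbor_joining,
    spearman_rho,
    tree_to_newick,
)
from compspec.spectra import SpectrumParams, generate_word_set, compute_spectrum
from compspec.synthetic import SyntheticSpec, emit_background, make_signature_words, plant_words


class FakeSpectrum:
    def __init__(self, segment_id, frequencies):
        self.segment_id = segment_id
        self.frequencies = np.asarray(frequencies, dtype=float)


class TestSpearmanRho:
    def test_identity(self):
        assert spearman_rho([0.5, 0.3, 0.2], [0.5, 0.3, 0.2]) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        assert spearman_rho([0.5, 0.3, 0.2], [0.2, 0.3, 0.5]) == pytest.approx(-1.0)

    def test_tied_ranks_hand_computed(self):
        # ranks (2.5, 2.5, 1) vs (1, 3, 2): rank-Pearson = 0 exactly
        assert spearman_rho([0.4, 0.4, 0.2], [0.1, 0.6, 0.3]) == pytest.approx(0.0)

    def test_matches_scipy_on_random_vectors(self, rng):
        for _ in range(25):
            x = rng.choice(np.arange(10) / 10.0, size=12)  # ties likely
            y = rng.random(12)
            if np.ptp(x) == 0:
                continue
            expected = scipy.stats.spearmanr(x, y).statistic
            assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestCsDistance:
    def test_identical_spectra(self):
        a = FakeSpectrum("a", [0.5, 0.3, 0.2])
        assert cs_distance(a, a) == 0.0

    def test_anti_ranked_spectra(self):
        a = FakeSpectrum("a", [0.5, 0.3, 0.2])
        b = FakeSpectrum("b", [0.2, 0.3, 0.5])
        assert cs_distance(a, b) == pytest.approx(2.0)

    def test_symmetry_on_random_spectra(self, rng):
        for _ in range(20):
            a = FakeSpectrum("a", rng.random(15))
            b = FakeSpectrum("b", rng.random(15))
            assert cs_distance(a, b) == pytest.approx(cs_distance(b, a), abs=1e-14)
            assert cs_distance(a, b) >= 0.0

    def test_word_set_size_mismatch(self):
        with pytest.raises(ValueError):
            cs_distance(FakeSpectrum("a", [0.5, 0.5]), FakeSpectrum("b", [0.3, 0.3, 0.4]))

    def test_same_op_class_pairs_are_closer(self, rng):
        """Segments planted with the same signature set have smaller
        spectrum distances than cross-class pairs, on average."""
        spec = SyntheticSpec(classes=("op1", "op2"), segment_len=4_000, seed=7)
        sigs = make_signature_words(spec, seed=11)
        ws = generate_word_set(60, 10, "ACGT", seed=2)
        params = SpectrumParams(r=2)
        spectra = {}
        for cls in spec.classes:
            for i in range(6):
                bg = emit_background(spec.segment_len, 0.45, seed=1000 + 100 * i + ord(cls[-1]))
                seq = plant_words(bg, sigs[cls], spec.planting_rate, seed=i)
                spectra[f"{cls}-{i}"] = compute_spectrum(seq, ws, params, f"{cls}-{i}")
        within, cross = [], []
        keys = sorted(spectra)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = cs_distance(spectra[a], spectra[b])
                (within if a[:3] == b[:3] else cross).append(d)
        assert np.mean(within) < np.mean(cross)


class TestDistanceMatrix:
    def test_identical_spectra_give_zero_matrix(self):
        a = FakeSpectrum("a", [0.1, 0.5, 0.4])
        b = FakeSpectrum("b", [0.1, 0.5, 0.4])
        dm = distance_matrix([a, b])
        np.testing.assert_array_equal(dm.values, np.zeros((2, 2)))

    def test_entries_match_pairwise_distance(self, rng):
        spectra = [FakeSpectrum(f"s{i}", rng.random(20)) for i in range(4)]
        dm = distance_matrix(spectra)
        for i in range(4):
            for j in range(4):
                expected = cs_distance(spectra[i], spectra[j]) if i != j else 0.0
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_input_order(self, rng):
        spectra = [FakeSpectrum(f"s{i}", rng.random(12)) for i in range(5)]
        dm = distance_matrix(spectra)
        perm = [3, 1, 4, 0, 2]
        dm_perm = distance_matrix([spectra[i] for i in perm])
        lookup = {sid: k for k, sid in enumerate(dm_perm.ids)}
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                assert dm.values[i, j] == pytest.approx(
                    dm_perm.values[lookup[a], lookup[b]], abs=1e-12
                )

    def test_requires_two_spectra(self):
        with pytest.raises(ValueError):
            distance_matrix([FakeSpectrum("a", [0.1, 0.2, 0.7])])


def random_additive_tree(n_leaves, rng):
    """Independent oracle: a random positively-weighted binary tree and its
    exact path-length (additive) distance matrix, built with plain graph
    bookkeeping."""
    adj = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    leaves = ["A", "B"]
    connect("A", "B", float(rng.uniform(0.2, 2.0)))
    next_internal = 0
    for k in range(2, n_leaves):
        leaf = chr(ord("A") + k)
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(0, len(edges))]
        w = adj[u][v]
        t = float(rng.uniform(0.2, 0.8))
        m = f"int{next_internal}"
        next_internal += 1
        disconnect(u, v)
        connect(u, m, w * t)
        connect(m, v, w * (1 - t))
        connect(m, leaf, float(rng.uniform(0.2, 2.0)))
        leaves.append(leaf)

    def path_lengths(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nbr, w in adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        return dist

    leaves = sorted(leaves)
    mat = np.zeros((len(leaves), len(leaves)))
    for i, leaf in enumerate(leaves):
        dist = path_lengths(leaf)
        for j, other in enumerate(leaves):
            mat[i, j] = dist[other]
    np.fill_diagonal(mat, 0.0)
    return leaves, (mat + mat.T) / 2.0


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = {tip.name: tip.length for tip in tree.tips()}
        # b_A = (d_AB + d_AC - d_BC) / 2 etc.
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n_leaves,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_recovers_additive_trees(self, n_leaves, seed):
        rng = np.random.default_rng(seed)
        ids, mat = random_additive_tree(n_leaves, rng)
        tree = neighbor_joining(DistanceMatrix(tuple(ids), mat))
        patristic = tree.tip_tip_distances()
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i != j:
                    assert patristic[a, b] == pytest.approx(mat[i, j], abs=1e-9)

    def test_equidistant_matrix_is_deterministic(self):
        values = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(tuple("ABCDE"), values)
        assert tree_to_newick(neighbor_joining(dm)) == tree_to_newick(neighbor_joining(dm))

    def test_branch_lengths_non_negative(self, rng):
        spectra = [FakeSpectrum(f"s{i}", rng.random(10)) for i in range(8)]
        tree = neighbor_joining(distance_matrix(spectra))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0.0

    def test_needs_three_leaves(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)


def _tree(newick):
    return TreeNode.read(StringIO(newick))


class TestExtractOpGroups:
    def test_two_clades_split_by_dominant_edge(self):
        a = ",".join(f"a{i}:0.1" for i in range(10))
        b = ",".join(f"b{i}:0.1" for i in range(8))
        tree = _tree(f"(({a}):2.0,({b}):2.0);")
        groups, unassigned = extract_op_groups(tree, "L2", min_size=5, n_groups=2)
        assert sorted(g.size for g in groups) == [8, 10]
        assert not unassigned
        assert groups[0].group_id == "L2-a" and groups[0].size == 10

    def test_small_component_goes_unassigned(self):
        tree = _tree("((a:0.1,b:0.1,c:0.1):5.0,(d:0.1,e:0.1,f:0.1,g:0.1,h:0.1):5.0);")
        groups, unassigned = extract_op_groups(tree, "H1", min_size=5, n_groups=2)
        assert [g.size for g in groups] == [5]
        assert unassigned == {"a", "b", "c"}

    def test_threshold_mode(self):
        tree = _tree("((a:0.1,b:0.1,c:0.1):5.0,(d:0.1,e:0.1,f:0.1):5.0);")
        groups, unassigned = extract_op_groups(tree, "H1", min_size=2, threshold=1.0)
        assert sorted(g.size for g in groups) == [3, 3]

    def test_output_is_a_partition(self, rng):
        spectra = [FakeSpectrum(f"s{i:02d}", rng.random(12)) for i in range(15)]
        tree = neighbor_joining(distance_matrix(spectra))
        groups, unassigned = extract_op_groups(tree, "H2", min_size=1, n_groups=4)
        seen = set(unassigned)
        for g in groups:
            assert not (g.segment_ids & seen)
            seen |= g.segment_ids
        assert seen == {s.segment_id for s in spectra}

    def test_n_groups_cannot_exceed_leaves(self):
        tree = _tree("(a:1,b:1,c:1);")
        with pytest.raises(ValueError):
            extract_op_groups(tree, "L1", min_size=1, n_groups=4)
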