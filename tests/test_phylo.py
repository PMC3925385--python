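import math

import numpy as np
import pytest

from barcode_diet.phylo import (BootstrapConfig, DistanceMatrix, SaturationError,
                                align_star, bootstrap_supports, distance_matrix,
                                k2p_distance, nj_tree, p_distance)
from barcode_diet.synthdata import SimParams, evolve_sequence


# --- independent oracle: random additive trees ------------------------------

def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random unrooted binary tree; returns (leaf-pair distances, bipartitions).

    Built edge-by-edge with its own bookkeeping (no code shared with the NJ
    implementation): distances are path sums, bipartitions are tracked as the
    leaf set on one side of each internal edge.
    """
    labels = [f"T{i:02d}" for i in range(n_leaves)]
    # adjacency: node -> list of (neighbor, length); leaves are labels,
    # internal nodes are ints
    adj: dict = {labels[0]: [], labels[1]: [], labels[2]: [], 0: []}
    nxt = 1

    def connect(a, b, w):
        adj[a].append((b, w))
        adj[b].append((a, w))

    for leaf in labels[:3]:
        connect(0, leaf, rng.uniform(0.1, 1.0))
    edges = [(0, leaf) for leaf in labels[:3]]
    for leaf in labels[3:]:
        a, b = edges[rng.integers(0, len(edges))]
        w = next(w for nb, w in adj[a] if nb == b)
        adj[a] = [(nb, ww) for nb, ww in adj[a] if nb != b]
        adj[b] = [(nb, ww) for nb, ww in adj[b] if nb != a]
        mid = nxt
        nxt += 1
        adj[mid] = []
        adj[leaf] = []
        w1 = w * rng.uniform(0.25, 0.75)
        connect(a, mid, w1)
        connect(mid, b, w - w1)
        connect(mid, leaf, rng.uniform(0.1, 1.0))
        edges.remove((a, b))
        edges += [(a, mid), (mid, b), (mid, leaf)]

    def paths_from(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    d = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(labels):
        dist = paths_from(a)
        for j, b in enumerate(labels):
            d[i, j] = dist[b]
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2

    anchor = min(labels)
    bips = set()
    for a, b in edges:
        if isinstance(a, str) or isinstance(b, str):
            continue  # pendant edge
        # leaves on a's side of edge (a, b)
        seen = {b, a}
        stack = [a]
        side = set()
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if v in seen:
                    continue
                seen.add(v)
                if isinstance(v, str):
                    side.add(v)
                else:
                    stack.append(v)
        full = set(labels)
        norm = frozenset(side) if anchor not in side else frozenset(full - side)
        if 2 <= len(norm) <= n_leaves - 2:
            bips.add(norm)
    return labels, d, bips


def assert_nj_recovers(labels, d, bips):
    tree = nj_tree(DistanceMatrix(labels, d))
    assert tree.bipartitions() == bips
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            assert tree.path_distance(a, labels[j]) == pytest.approx(
                d[i, j], abs=1e-9)
    assert tree.clamped_deficit == 0.0


# --- distances ---------------------------------------------------------------

class TestDistances:
    def test_p_distance_definition(self):
        assert p_distance("A" * 100, "A" * 99 + "C") == 0.01
        assert p_distance("ACGT", "ACGT") == 0.0

    def test_p_distance_masks_gaps_and_n(self):
        assert p_distance("AC-TN", "ACGTA") == 0.0

    def test_k2p_identical_is_zero(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_k2p_single_transition_closed_form(self):
        d = k2p_distance("A" * 99 + "G", "A" * 100)
        assert d == pytest.approx(-0.5 * math.log(0.98), abs=1e-9)

    def test_k2p_single_transversion_closed_form(self):
        # P=0, Q=0.01: d = -ln(1-Q)/2 - ln(1-2Q)/4
        d = k2p_distance("A" * 99 + "C", "A" * 100)
        assert d == pytest.approx(
            -0.5 * math.log(0.99) - 0.25 * math.log(0.98), abs=1e-9)

    def test_k2p_saturation_error_names_pair(self):
        with pytest.raises(SaturationError, match="x.*y"):
            k2p_distance("AG" * 20, "GA" * 20, labels=("x", "y"))

    def test_k2p_dominates_p_distance(self):
        params = SimParams(seed=0)
        rng = np.random.default_rng(1)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 658)])
        for k, div in enumerate((0.02, 0.1, 0.3)):
            other = evolve_sequence(base, div, params, rng=100 + k)
            assert k2p_distance(base, other) >= p_distance(base, other)

    def test_distance_matrix_models(self):
        seqs = {"a": "ACGT" * 5, "b": "ACGT" * 5, "c": "ACGA" * 5}
        for model in ("k2p", "p"):
            dm = distance_matrix(seqs, model=model)
            assert dm.data[0, 1] == 0.0 and dm.data[0, 2] > 0
        with pytest.raises(ValueError):
            distance_matrix(seqs, model="jc")


# --- neighbor joining --------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, .2, .3], [.2, 0, .4], [.3, .4, 0]]))
        tree = nj_tree(dm)
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    def test_four_taxon_additive(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> unique AB|CD topology
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                     dtype=float)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        assert tree.path_distance("A", "D") == pytest.approx(6.0)

    def test_all_zero_matrix_gives_star(self):
        tree = nj_tree(DistanceMatrix(list("ABCD"), np.zeros((4, 4))))
        assert all(l.length == 0 for l in tree.root.leaves())
        assert tree.bipartitions() <= {frozenset({"A", "B"}), frozenset({"C", "D"}),
                                       frozenset({"B", "C"}), frozenset({"B", "D"}),
                                       frozenset({"C", "B"}), frozenset({"A", "C"})}

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    @pytest.mark.parametrize("n_leaves", [4, 6, 9, 12])
    def test_recovers_random_additive_trees(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            assert_nj_recovers(*random_additive_tree(n_leaves, rng))

    def test_matches_scikit_bio_on_random_matrices(self):
        import io

        import skbio

        rng = np.random.default_rng(77)
        for trial in range(5):
            n = 6
            labels = [f"L{i}" for i in range(n)]
            m = rng.uniform(0.1, 1.0, (n, n))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            mine = nj_tree(DistanceMatrix(labels, d))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
            parsed = skbio.TreeNode.read(io.StringIO(mine.to_newick()))
            assert parsed.compare_rfd(theirs) == 0.0

    def test_negative_branch_lengths_clamped(self):
        # d(B,C) > d(A,B) + d(A,C) forces a negative pendant length for A
        d = np.array([[0, 1, 1], [1, 0, 3], [1, 3, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(list("ABC"), d))
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths["A"] == 0.0
        assert tree.clamped_deficit == pytest.approx(0.5)


# --- bootstrap ---------------------------------------------------------------

def _fake_alignment():
    # 200 columns; every 5th site separates AB from CD, none conflict
    base = "ACGT" * 50
    flipped = "".join(
        {"A": "G", "G": "A", "C": "T", "T": "C"}[c] if i % 5 == 0 else c
        for i, c in enumerate(base))
    return {"A": base, "B": base, "C": flipped, "D": flipped}


class TestBootstrap:
    def test_unanimous_split_gets_full_support(self):
        tree = bootstrap_supports(_fake_alignment(),
                                  BootstrapConfig(n_replicates=200, seed=1))
        assert tree.support_of({"A", "B"}) == pytest.approx(100.0, abs=1.0)

    def test_seed_determinism(self):
        cfg = BootstrapConfig(n_replicates=100, seed=9)
        t1 = bootstrap_supports(_fake_alignment(), cfg)
        t2 = bootstrap_supports(_fake_alignment(), cfg)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_supports_bounded_and_permutation_invariant(self):
        params = SimParams(seed=0)
        rng = np.random.default_rng(5)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        seqs = {f"s{i}": evolve_sequence(base, 0.05 + 0.03 * i, params, rng=i)
                for i in range(6)}
        cfg = BootstrapConfig(n_replicates=100, seed=3)
        t1 = bootstrap_supports(seqs, cfg)
        order = list(seqs)[::-1]
        t2 = bootstrap_supports({k: seqs[k] for k in order}, cfg)
        assert all(0 <= v <= 100 for v in t1.supports.values())
        assert set(t1.supports) == set(t2.supports)

    def test_replicate_count_guard(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_replicates=0)

    def test_needs_four_sequences(self):
        with pytest.raises(ValueError):
            bootstrap_supports({"a": "AC", "b": "AC", "c": "AC"},
                               BootstrapConfig(n_replicates=10))


# --- newick / star alignment -------------------------------------------------

class TestNewickAndStar:
    def test_newick_readable_by_dendropy(self):
        import dendropy

        tree = bootstrap_supports(_fake_alignment(),
                                  BootstrapConfig(n_replicates=50, seed=2))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == \
               {"A", "B", "C", "D"}

    def test_same_unrooted_topology_under_input_permutation(self):
        import io

        import skbio

        t1 = bootstrap_supports(_fake_alignment(), BootstrapConfig(50, 2))
        t2 = bootstrap_supports(dict(reversed(_fake_alignment().items())),
                                BootstrapConfig(50, 2))
        p1 = skbio.TreeNode.read(io.StringIO(t1.to_newick(with_supports=False)))
        p2 = skbio.TreeNode.read(io.StringIO(t2.to_newick(with_supports=False)))
        assert p1.compare_rfd(p2) == 0.0
        assert t1.supports == t2.supports

    def test_star_alignment_passthrough_when_equal_length(self):
        seqs = {"r": "ACGTACGT", "q1": "ACGTACGA", "q2": "TCGTACGT"}
        assert align_star(seqs) == seqs

    def test_star_alignment_pads_insertions(self):
        seqs = {"r": "AAATTTGGG", "q1": "AAATTTCCGGG", "q2": "AAAGGG"}
        msa = align_star(seqs)
        lens = {len(s) for s in msa.values()}
        assert len(lens) == 1
        assert msa["r"].replace("-", "") == seqs["r"]
        assert msa["q1"].replace("-", "") == seqs["q1"]
        assert msa["q2"].replace("-", "") == seqs["q2"]
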