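import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from barcodevar import (
    AlignedSeqSet,
    correlation_matrix,
    indicator_encode,
    klee_diagram,
    order_sequences,
    pdistance_matrix,
    render_klee,
)
from barcodevar.errors import AlphabetError, DegenerateInputError, MatrixError
from barcodevar.seqio import read_matrix

from conftest import random_alignment


def make_set(seqs):
    return AlignedSeqSet(names=[f"s{i}" for i in range(len(seqs))], seqs=list(seqs))


class TestIndicatorEncode:
    @pytest.mark.parametrize(
        "seq,vec",
        [
            ("A", [1, 0, 0, 0]),
            ("N", [0, 0, 0, 0]),
            ("-", [0, 0, 0, 0]),
            ("R", [0, 0, 0, 0]),  # ambiguity -> missing
            ("CT", [0, 1, 0, 0, 0, 0, 0, 1]),
        ],
    )
    def test_encoding(self, seq, vec):
        assert indicator_encode(seq).tolist() == vec

    def test_length_is_4L(self):
        assert indicator_encode("A" * 648).size == 2592

    def test_illegal_character(self):
        with pytest.raises(AlphabetError):
            indicator_encode("ACXG")


class TestCorrelationMatrix:
    def test_identical_sequences_correlate_fully(self):
        v = np.stack([indicator_encode("ACGT")] * 3)
        c = correlation_matrix(v)
        np.testing.assert_allclose(c, 1.0)

    def test_homopolymer_pair_hand_value(self):
        # (1,0,0,0)x4 vs (0,1,0,0)x4: Pearson r = -1/3
        v = np.stack([indicator_encode("AAAA"), indicator_encode("CCCC")])
        assert correlation_matrix(v)[0, 1] == pytest.approx(-1 / 3)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(0)
        v = np.stack([indicator_encode(s) for s in random_alignment(rng, 6, 50)])
        c = correlation_matrix(v)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-9)

    def test_all_missing_sequence_is_degenerate(self):
        v = np.stack([indicator_encode("ACGT"), indicator_encode("NNNN")])
        with pytest.raises(DegenerateInputError, match="nnn|index 1"):
            correlation_matrix(v, names=["ok", "nnn"])

    def test_correlation_decreases_with_p_distance(self):
        # without missing data, indicator correlation is a strictly
        # decreasing function of the fraction of differing columns
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=300))
        seqs = [base]
        for k in (3, 10, 30, 90, 200):
            mutated = list(base)
            for pos in rng.choice(300, size=k, replace=False):
                mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            seqs.append("".join(mutated))
        s = make_set(seqs)
        c = correlation_matrix(np.stack([indicator_encode(q) for q in s.seqs]))
        d = pdistance_matrix(s)
        order = np.argsort(d[0, 1:])
        corr_row = c[0, 1:][order]
        assert np.all(np.diff(corr_row) < 0)


class TestOrderSequences:
    def test_single_sequence(self):
        order, tree = order_sequences(np.zeros((1, 1)))
        assert order == [0]
        assert tree.leaf == 0

    def test_bad_matrices_rejected(self):
        with pytest.raises(MatrixError):
            order_sequences(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(MatrixError):
            order_sequences(np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_duplicate_sequence_placed_adjacent(self):
        rng = np.random.default_rng(1)
        seqs = random_alignment(rng, 6, 100)
        seqs.append(seqs[2])  # exact twin of s2
        s = make_set(seqs)
        order, _ = order_sequences(pdistance_matrix(s))
        pos = {i: k for k, i in enumerate(order)}
        assert abs(pos[2] - pos[6]) == 1

    def test_two_planted_clusters_are_contiguous(self):
        rng = np.random.default_rng(2)
        n, L = 12, 400
        a = "".join(rng.choice(list("ACGT"), size=L))
        b = list(a)
        for pos in rng.choice(L, size=20, replace=False):  # 5% divergence
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        seqs = []
        for anc in (a, b):
            for _ in range(n // 2):
                child = list(anc)
                for pos in rng.choice(L, size=1, replace=False):
                    child[pos] = rng.choice(list("ACGT"))
                seqs.append("".join(child))
        order, _ = order_sequences(pdistance_matrix(make_set(seqs)))
        labels = [0 if i < n // 2 else 1 for i in order]
        assert sum(x != y for x, y in zip(labels, labels[1:])) == 1

    def test_merge_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(3)
        d = pdistance_matrix(make_set(random_alignment(rng, 10, 500)))
        _, tree = order_sequences(d)

        def heights(node, acc):
            if node.children:
                acc.append(node.height)
                for c in node.children:
                    heights(c, acc)
            return acc

        ours = sorted(2 * h for h in heights(tree, []))
        Z = hierarchy.linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(ours, sorted(Z[:, 2]), atol=1e-12)

    def test_topology_invariant_under_input_permutation(self):
        rng = np.random.default_rng(4)
        s = make_set(random_alignment(rng, 9, 300))
        d = pdistance_matrix(s)
        _, t1 = order_sequences(d)
        perm = rng.permutation(9)
        d2 = d[np.ix_(perm, perm)]
        _, t2 = order_sequences(d2)

        def clades(node, relabel):
            out = set()

            def rec(nd):
                leaves = frozenset(relabel[i] for i in nd.leaves())
                out.add(leaves)
                for c in nd.children:
                    rec(c)

            rec(node)
            return out

        ident = {i: i for i in range(9)}
        back = {k: int(perm[k]) for k in range(9)}
        assert clades(t1, ident) == clades(t2, back)


class TestKleeDiagram:
    def test_result_invariants(self, chimp_like_sim):
        s = chimp_like_sim.seqs.subset(range(20))
        k = klee_diagram(s)
        assert sorted(k.order) == list(range(20))
        np.testing.assert_allclose(np.diag(k.corr), 1.0, atol=1e-9)
        np.testing.assert_allclose(k.corr, k.corr.T, atol=1e-12)
        assert k.labels == [s.names[i] for i in k.order]
        assert k.tree.leaves() == k.order

    def test_render_roundtrip_and_block_structure(self, tmp_path, chimp_like_sim):
        s = chimp_like_sim.seqs.subset(range(30))
        k = klee_diagram(s)
        paths = render_klee(k, tmp_path / "klee")
        assert paths["image"].exists()
        mat, labels = read_matrix(paths["matrix"])
        assert labels == k.labels
        np.testing.assert_allclose(mat, k.corr, atol=1e-10)
        # newick is parseable and keeps leaf order
        import dendropy

        tree = dendropy.Tree.get(path=str(paths["tree"]), schema="newick")
        taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        assert taxa == k.labels
        # cluster blocks: within-cluster correlation exceeds between
        groups = [s.groups[name] for name in k.labels]
        same = np.equal.outer(groups, groups)
        iu = np.triu_indices(len(groups), k=1)
        within = mat[iu][same[iu]]
        between = mat[iu][~same[iu]]
        assert within.mean() > between.mean()
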