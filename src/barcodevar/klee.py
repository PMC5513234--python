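"""Klee diagrams: indicator-vector correlation heat maps with tree ordering.

Each aligned sequence is encoded as a binary indicator vector — every column
contributes a length-4 sub-vector with a 1 at the observed base (A,C,G,T
order) — and every pair of sequences is scored by the Pearson correlation of
their vectors. The display order of sequences is chosen objectively, without
any species labels, by UPGMA agglomeration of the p-distance matrix with
fully deterministic tie-breaking; reproductively isolated clusters then show
up as contiguous high-correlation blocks along the diagonal.

Missing data (gap/N/ambiguity) encode as an all-zero sub-vector; excluded
columns are not renormalised. A sequence with no callable base at all has a
zero-variance vector and is rejected as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .diversity import pdistance_matrix
from .errors import AlphabetError, DegenerateInputError, MatrixError
from .seqio import ALPHABET, AlignedSeqSet, write_matrix


def indicator_encode(seq: str) -> np.ndarray:
    """Binary indicator vector of length 4L for one aligned sequence."""
    bad = set(seq.upper()) - ALPHABET
    if bad:
        raise AlphabetError(f"illegal characters in sequence: {sorted(bad)!r}")
    from .seqio import _CODE_LUT  # A=0 C=1 G=2 T=3, missing -1

    codes = _CODE_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    out = np.zeros((codes.size, 4), dtype=np.float64)
    ok = codes >= 0
    out[np.nonzero(ok)[0], codes[ok]] = 1.0
    return out.ravel()


def encode_set(s: AlignedSeqSet) -> np.ndarray:
    """(n, 4L) indicator matrix for a whole sequence set."""
    codes = s.codes()
    n, L = codes.shape
    out = np.zeros((n, L, 4), dtype=np.float64)
    ok = codes >= 0
    rows, cols = np.nonzero(ok)
    out[rows, cols, codes[rows, cols]] = 1.0
    return out.reshape(n, 4 * L)


def correlation_matrix(
    vectors: np.ndarray, names: list[str] | None = None
) -> np.ndarray:
    """Pearson correlation between every pair of indicator vectors."""
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim != 2 or v.shape[0] < 2:
        raise MatrixError("need >= 2 equal-length vectors")
    sd = v.std(axis=1)
    if (sd == 0).any():
        i = int(np.nonzero(sd == 0)[0][0])
        who = names[i] if names else f"index {i}"
        raise DegenerateInputError(
            f"zero-variance indicator vector for sequence {who} "
            "(no callable base)"
        )
    c = np.corrcoef(v)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# UPGMA ordering
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of the rooted ultrametric UPGMA tree."""

    height: float
    children: tuple["TreeNode", ...] = ()
    leaf: int = -1  # original sequence index; -1 for internal nodes

    @property
    def min_leaf(self) -> int:
        if self.leaf >= 0:
            return self.leaf
        return min(c.min_leaf for c in self.children)

    def leaves(self) -> list[int]:
        if self.leaf >= 0:
            return [self.leaf]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, names: list[str] | None = None) -> str:
        def fmt(node: TreeNode, parent_h: float) -> str:
            bl = parent_h - node.height
            if node.leaf >= 0:
                label = names[node.leaf] if names else f"s{node.leaf}"
                return f"{label}:{bl:.8g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.8g}"

        if self.leaf >= 0:
            label = names[self.leaf] if names else f"s{self.leaf}"
            return f"{label}:0;"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def order_sequences(dist: np.ndarray) -> tuple[list[int], TreeNode]:
    """UPGMA leaf ordering of a distance matrix, fully deterministic.

    Tie-breaking: at each agglomeration step the minimum-distance pair with
    the lexicographically smallest (row, col) index pair in the current
    working matrix is merged; at each internal node the child whose subtree
    contains the smallest original index is placed first. Returns the
    left-to-right leaf order and the rooted tree.
    """
    d = np.asarray(dist, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise MatrixError("distance matrix must be square")
    n = d.shape[0]
    if n == 0:
        raise MatrixError("empty distance matrix")
    if (d < 0).any():
        raise MatrixError("distance matrix has negative entries")
    if not np.allclose(d, d.T, atol=1e-9):
        raise MatrixError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise MatrixError("distance matrix diagonal is not zero")

    nodes: list[TreeNode] = [TreeNode(height=0.0, leaf=i) for i in range(n)]
    sizes = [1] * n
    w = d.copy()
    np.fill_diagonal(w, np.inf)
    while len(nodes) > 1:
        m = len(nodes)
        flat = int(np.argmin(w))  # row-major => smallest (row, col) among ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        h = w[i, j] / 2.0
        a, b = nodes[i], nodes[j]
        first, second = (a, b) if a.min_leaf <= b.min_leaf else (b, a)
        merged = TreeNode(height=h, children=(first, second))
        # average-linkage update into row i, drop row j
        si, sj = sizes[i], sizes[j]
        new_row = (si * w[i] + sj * w[j]) / (si + sj)
        w[i, :] = new_row
        w[:, i] = new_row
        w[i, i] = np.inf
        keep = [k for k in range(m) if k != j]
        w = w[np.ix_(keep, keep)]
        nodes[i] = merged
        sizes[i] = si + sj
        del nodes[j], sizes[j]
    root = nodes[0]
    return root.leaves(), root


# ---------------------------------------------------------------------------
# Assembly and rendering
# ---------------------------------------------------------------------------

@dataclass
class KleeResult:
    """Ordered indicator-correlation matrix with the tree that ordered it."""

    order: list[int]
    corr: np.ndarray  # re-indexed by `order`
    tree: TreeNode
    labels: list[str]  # sequence names in display order

    def newick(self) -> str:
        return self.tree.newick(names=self._orig_names)

    _orig_names: list[str] | None = None


def klee_diagram(s: AlignedSeqSet) -> KleeResult:
    """Build a Klee diagram: encode, correlate, order by UPGMA on p-distance."""
    vectors = encode_set(s)
    corr = correlation_matrix(vectors, names=list(s.names))
    dist = pdistance_matrix(s)
    order, tree = order_sequences(dist)
    res = KleeResult(
        order=order,
        corr=corr[np.ix_(order, order)],
        tree=tree,
        labels=[s.names[i] for i in order],
    )
    res._orig_names = list(s.names)
    return res


def render_klee(
    k: KleeResult,
    out_prefix: str | Path,
    cmap: str = "viridis",
    vmin: float = -0.2,
    vmax: float = 1.0,
    image_format: str = "png",
) -> dict[str, Path]:
    """Write the heat-map image plus its testable text artifacts.

    Produces ``<prefix>.<fmt>`` (image), ``<prefix>.matrix.tsv`` (ordered
    correlation matrix), ``<prefix>.order.txt`` and ``<prefix>.tree.nwk``.
    The TSV, not the image, is the bit-exact artifact.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": prefix.with_suffix(prefix.suffix + f".{image_format}"),
        "matrix": prefix.with_suffix(prefix.suffix + ".matrix.tsv"),
        "order": prefix.with_suffix(prefix.suffix + ".order.txt"),
        "tree": prefix.with_suffix(prefix.suffix + ".tree.nwk"),
    }
    write_matrix(k.corr, k.labels, paths["matrix"])
    paths["order"].write_text("".join(f"{name}\n" for name in k.labels))
    paths["tree"].write_text(k.newick() + "\n")

    fig, ax = plt.subplots(figsize=(6.0, 5.0))
    im = ax.imshow(
        k.corr, cmap=cmap, vmin=vmin, vmax=vmax, interpolation="nearest"
    )
    ax.set_title("Klee diagram (indicator-vector correlation)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="Pearson r")
    meta = {"Software": None} if image_format == "png" else None
    fig.savefig(paths["image"], dpi=150, metadata=meta)
    plt.close(fig)
    return paths
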