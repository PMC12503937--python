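"""Phylogenetic substrate: tree I/O, pruning, shared-ancestry covariance,
whitening, phylogenetic means and effective sample sizes.

Trees are thin wrappers around :class:`dendropy.Tree`.  All downstream
numerics work on the *ancestry matrix* ``C`` whose entry ``C[i, j]`` is the
root-to-MRCA path length shared by tips ``i`` and ``j`` (in Myr for dated
trees); under Brownian motion ``C`` is proportional to the expected
covariance among tip values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg

__all__ = [
    "Phylogeny",
    "AncestryMatrix",
    "WhiteningTransform",
    "read_newick",
    "parse_newick",
    "prune_to",
    "vcv",
    "whitening",
    "phylo_mean",
    "effective_n",
]

#: relative tolerance (fraction of tree height) for ultrametricity checks
ULTRAMETRIC_RTOL = 1e-6

#: ridge added to near-singular ancestry matrices, as a fraction of height
RIDGE_FRACTION = 1e-10


class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Wraps a :class:`dendropy.Tree` and exposes flat per-node arrays used by
    the numerical routines.  Node indices are assigned in preorder (root =
    0); every non-root node identifies the edge above it, which is how
    regime maps refer to branches.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._index()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip labels in Newick input: {exc}") from exc
        return cls(tree)

    def _index(self) -> None:
        tree = self._tree
        nodes = list(tree.preorder_node_iter())
        if len(nodes) < 2:
            raise ValueError("tree must have at least two nodes")
        self._nodes = nodes
        n_nodes = len(nodes)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        elen = np.zeros(n_nodes)
        for i, nd in enumerate(nodes):
            nd._wl_index = i
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = nd.parent_node._wl_index
                if nd.edge.length is None:
                    raise ValueError(
                        f"edge above node {nd.taxon.label if nd.taxon else i} "
                        "has no branch length"
                    )
                if nd.edge.length < 0:
                    raise ValueError("negative branch length")
                elen[i] = nd.edge.length
        # a root (stem) edge arises when pruning leaves the original root
        # with a single retained subtree; it carries shared history
        root_edge = tree.seed_node.edge.length or 0.0
        if root_edge < 0:
            raise ValueError("negative root edge length")
        elen[0] = root_edge
        depth = np.zeros(n_nodes)
        depth[0] = root_edge
        for i in range(1, n_nodes):
            depth[i] = depth[parent[i]] + elen[i]
        tip_ids = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
        labels = []
        for i in tip_ids:
            tx = nodes[i].taxon
            if tx is None or tx.label is None:
                raise ValueError("unlabeled tip")
            labels.append(tx.label)
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")
        self.parent = parent
        self.edge_length = elen
        self.depth = depth
        self.tip_ids = np.asarray(tip_ids, dtype=np.int64)
        self.tips = labels
        self.children: list[list[int]] = [[] for _ in range(n_nodes)]
        for i in range(1, n_nodes):
            self.children[parent[i]].append(i)

    # -- basic queries ------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def height(self) -> float:
        return float(self.depth[self.tip_ids].max())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depth[self.tip_ids]
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    def is_tip(self, node_id: int) -> bool:
        return not self.children[node_id]

    def tip_label(self, node_id: int) -> str:
        return self._nodes[node_id].taxon.label

    def to_newick(self) -> str:
        """Serialize to Newick, writing the stem (root edge) if nonzero."""
        def rec(nid: int) -> str:
            if self.is_tip(nid):
                return f"{self.tip_label(nid)}:{self.edge_length[nid]:.17g}"
            inner = ",".join(rec(c) for c in self.children[nid])
            if nid == 0:
                stem = self.edge_length[0]
                tail = f":{stem:.17g}" if stem > 0 else ""
                return f"({inner}){tail};"
            return f"({inner}):{self.edge_length[nid]:.17g}"

        return rec(0)

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    def postorder(self) -> list[int]:
        """Node ids, children before parents (reverse preorder works for
        trees indexed in preorder)."""
        return list(range(self.n_nodes - 1, -1, -1))

    def mrca_fill(self, node_values: np.ndarray) -> np.ndarray:
        """Tips x tips matrix whose (i, j) entry is ``node_values[mrca(i, j)]``
        and whose diagonal is ``node_values`` at the tips.

        With ``node_values = depth`` this is the ancestry matrix; with the
        per-node time spent in one regime it is a regime path-length matrix.
        """
        node_values = np.asarray(node_values, dtype=float)
        n = self.n_tips
        out = np.zeros((n, n))
        tip_pos = {int(t): k for k, t in enumerate(self.tip_ids)}
        below: dict[int, np.ndarray] = {}
        for nid in self.postorder():
            if self.is_tip(nid):
                k = tip_pos[nid]
                out[k, k] = node_values[nid]
                below[nid] = np.asarray([k], dtype=np.int64)
            else:
                groups = [below.pop(c) for c in self.children[nid]]
                v = node_values[nid]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        out[np.ix_(groups[a], groups[b])] = v
                        out[np.ix_(groups[b], groups[a])] = v
                below[nid] = np.concatenate(groups)
        return out


@dataclass
class AncestryMatrix:
    """Shared-ancestry (phylogenetic) covariance structure ``C``."""

    C: np.ndarray
    tips: list[str]
    height: float = field(default=0.0)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if self.C.shape[0] != len(self.tips):
            raise ValueError("tip labels do not match C")
        if not self.height:
            self.height = float(self.C.diagonal().max())

    @property
    def n(self) -> int:
        return self.C.shape[0]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.C.diagonal()
        return bool(np.ptp(d) <= rtol * max(self.height, 1e-300))

    def subset(self, labels: list[str]) -> "AncestryMatrix":
        pos = {t: i for i, t in enumerate(self.tips)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels not in ancestry matrix: {missing}")
        idx = np.asarray([pos[l] for l in labels])
        return AncestryMatrix(self.C[np.ix_(idx, idx)], list(labels), self.height)

    def cho_factor(self):
        return _factor(self.C, self.height)

    def solve(self, b: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self.cho_factor(), b)


@dataclass
class WhiteningTransform:
    """Eigendecomposition-based whitener, ``W C W' = I``."""

    U: np.ndarray
    eigenvalues: np.ndarray
    W: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.W @ X


def _factor(C: np.ndarray, scale: float):
    """Cholesky factor of C, ridging near-singular matrices."""
    try:
        return linalg.cho_factor(C)
    except linalg.LinAlgError:
        ridge = RIDGE_FRACTION * max(scale, 1.0)
        warnings.warn(
            f"ancestry matrix near-singular; adding ridge {ridge:.3g} to diagonal"
        )
        try:
            return linalg.cho_factor(C + ridge * np.eye(C.shape[0]))
        except linalg.LinAlgError as exc:
            raise ValueError("ancestry matrix is singular") from exc


# -- module-level operations ------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required)."""
    return Phylogeny.from_newick(text)


def read_newick(path) -> Phylogeny:
    """Read a rooted tree with branch lengths from a Newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def prune_to(phy: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on ``keep``, collapsing unbranched internals.

    Collapsed edges sum, so root-to-tip depths are preserved exactly; if
    every retained tip sits in one subtree of the root, the shared path
    down to that subtree is kept as a stem (root edge).
    """
    keep = list(dict.fromkeys(keep))
    unknown = sorted(set(keep) - set(phy.tips))
    if unknown:
        raise KeyError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to prune to")
    keep_set = set(keep)

    has_kept = np.zeros(phy.n_nodes, dtype=bool)
    for nid in phy.postorder():
        if phy.is_tip(nid):
            has_kept[nid] = phy.tip_label(nid) in keep_set
        else:
            has_kept[nid] = any(has_kept[c] for c in phy.children[nid])

    def rec(nid: int) -> tuple[str, float]:
        """Return (newick fragment without length, accumulated edge length)."""
        if phy.is_tip(nid):
            return phy.tip_label(nid), float(phy.edge_length[nid])
        kids = [c for c in phy.children[nid] if has_kept[c]]
        if len(kids) == 1:
            text, extra = rec(kids[0])
            return text, extra + float(phy.edge_length[nid])
        parts = [f"{t}:{l:.17g}" for t, l in (rec(k) for k in kids)]
        return "(" + ",".join(parts) + ")", float(phy.edge_length[nid])

    text, stem = rec(0)
    tail = f":{stem:.17g}" if stem > 0 else ""
    return Phylogeny.from_newick(f"{text}{tail};")


def vcv(phy: Phylogeny) -> AncestryMatrix:
    """Ancestry matrix: ``C[i, j]`` = depth of MRCA(i, j), diag = tip depths."""
    C = phy.mrca_fill(phy.depth)
    return AncestryMatrix(C, list(phy.tips), phy.height)


def whitening(A: AncestryMatrix) -> WhiteningTransform:
    """Whitener ``W = diag(eigenvalues)**-1/2 @ U.T`` so ``W C W' = I``.

    Any transform with that property serves; correlations of whitened data
    are invariant to the particular square root chosen.
    """
    C = A.C
    evals, U = linalg.eigh(C)
    scale = max(A.height, float(evals[-1]), 1.0)
    if evals[0] < -1e-10 * scale:
        raise ValueError("ancestry matrix is not positive semi-definite")
    evals = evals[::-1].copy()
    U = U[:, ::-1].copy()
    tiny = evals < 1e-12 * scale
    if tiny.any():
        ridge = RIDGE_FRACTION * max(A.height, 1.0)
        warnings.warn(
            f"near-zero eigenvalues in ancestry matrix; ridging by {ridge:.3g}"
        )
        evals = evals + ridge
    W = (U / np.sqrt(evals)).T
    return WhiteningTransform(U=U, eigenvalues=evals, W=W)


def phylo_mean(A: AncestryMatrix, y: np.ndarray) -> np.ndarray | float:
    """GLS intercept-only estimate ``(1' C^-1 y) / (1' C^-1 1)``.

    For 2-D ``y`` the mean is taken column-wise.  This is the maximum
    likelihood root-state estimate under Brownian motion.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != A.n:
        raise ValueError("y length does not match ancestry matrix")
    factor = A.cho_factor()
    ones = np.ones(A.n)
    Ci1 = linalg.cho_solve(factor, ones)
    denom = ones @ Ci1
    out = (Ci1 @ y) / denom
    return float(out) if np.ndim(out) == 0 else out


def effective_n(A: AncestryMatrix) -> float:
    """Phylogenetic effective sample size ``n_eff = T * (1' C^-1 1)``.

    The number of independent observations that would estimate a Brownian
    motion mean with the same precision as the ``n`` correlated tips;
    equals ``n`` on a star phylogeny and tends to 1 as all tips collapse
    onto a single lineage.  Requires an ultrametric tree.
    """
    if not A.is_ultrametric():
        raise ValueError("effective_n requires an ultrametric tree "
                         "(unequal tip depths)")
    factor = A.cho_factor()
    ones = np.ones(A.n)
    n_eff = A.height * float(ones @ linalg.cho_solve(factor, ones))
    return n_eff
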