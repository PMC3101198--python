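"""Rooted ultrametric trees, newick I/O, independent contrasts, and Blomberg's K.

Trees are stored as flat parent/length arrays in preorder for fast repeated
traversal (null-model simulation, tip randomization).  Newick parsing and
serialization are delegated to :mod:`dendropy`.

Branch lengths are interpreted as time in millions of years (my) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "independent_contrasts",
    "blomberg_k",
    "k_randomization_p",
]

#: relative tolerance on tip-height spread for ultrametricity checks
ULTRAMETRIC_RTOL = 1e-6


class NotUltrametricError(ValueError):
    """Raised when an operation requires an ultrametric tree but tip heights differ."""


@dataclass
class PhyloTree:
    """Rooted phylogenetic tree with branch lengths in my.

    Nodes are indexed 0..n_nodes-1 in preorder (root first, index 0).
    ``parent[i]`` is the preorder index of node i's parent (-1 for the root)
    and ``length[i]`` the length of the branch subtending node i (0 for the
    root).  Tips carry labels; internal nodes do not need them.
    """

    parent: np.ndarray  # (n_nodes,) int
    length: np.ndarray  # (n_nodes,) float
    children: list[list[int]]  # adjacency, preorder indices
    tip_labels: dict[int, str]  # node index -> label, tips only
    _heights: np.ndarray | None = field(default=None, repr=False, compare=False)

    # ---------------------------------------------------------------- basics
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> list[int]:
        return sorted(self.tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def labels(self) -> list[str]:
        """Tip labels in preorder-index order."""
        return [self.tip_labels[i] for i in self.tip_indices]

    def node_heights(self) -> np.ndarray:
        """Depth of every node measured from the root (root = 0)."""
        if self._heights is None:
            h = np.zeros(self.n_nodes)
            for i in range(1, self.n_nodes):  # preorder: parent precedes child
                h[i] = h[self.parent[i]] + self.length[i]
            self._heights = h
        return self._heights

    def crown_age(self) -> float:
        """Root-to-tip height in my; requires an ultrametric tree."""
        self.require_ultrametric()
        return float(self.node_heights()[self.tip_indices].mean())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        h = self.node_heights()[self.tip_indices]
        span = h.max()
        return span == 0 or (h.max() - h.min()) <= rtol * span

    def require_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> None:
        if not self.is_ultrametric(rtol):
            h = self.node_heights()[self.tip_indices]
            raise NotUltrametricError(
                f"tree is not ultrametric: tip heights span "
                f"[{h.min():.6g}, {h.max():.6g}]"
            )

    def is_bifurcating(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    # ------------------------------------------------------------- structure
    def postorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1)) if self._preorder_sorted else \
            self._postorder_generic()

    @property
    def _preorder_sorted(self) -> bool:
        # construction guarantees preorder indexing, so reversed order is a
        # valid postorder
        return True

    def _postorder_generic(self) -> list[int]:  # pragma: no cover - safety net
        order, stack = [], [0]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(self.children[n])
        return order[::-1]

    def subtree_tips(self, node: int) -> list[int]:
        """Preorder tip indices descending from ``node`` (inclusive if a tip)."""
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            if not self.children[n]:
                out.append(n)
            else:
                stack.extend(self.children[n])
        return out

    def resolve_polytomies(self, epsilon_frac: float = 1e-8) -> "PhyloTree":
        """Return a bifurcating copy; multifurcations are split arbitrarily.

        New internal branches get length ``epsilon_frac`` times tree height so
        contrast standardization stays defined.  A warning is emitted when any
        polytomy is resolved.
        """
        if self.is_bifurcating():
            return self
        eps = epsilon_frac * max(self.node_heights().max(), 1.0)
        warnings.warn(
            "polytomies resolved arbitrarily; new internal branches of length "
            f"{eps:g} inserted",
            stacklevel=2,
        )
        # rebuild via a nested structure, then re-index in preorder
        def build(n: int):
            ch = [build(c) for c in self.children[n]]
            while len(ch) > 2:
                a = ch.pop()
                b = ch.pop()
                ch.append(("", eps, [a, b]))
            label = self.tip_labels.get(n, "")
            return (label, float(self.length[n]), ch)

        return _from_nested(build(0))

    def scale_branches(self, factor: float) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.length * factor,
                         [list(c) for c in self.children], dict(self.tip_labels))

    # ------------------------------------------------------------- distances
    def distance_matrix(self, transform: str = "identity") -> tuple[np.ndarray, list[str]]:
        """Pairwise patristic distances between tips.

        transform ``"sqrt"`` takes the element-wise square root (the √my
        distances used for phylogenetic Mantel tests).  Returns the matrix and
        the tip-label order of its rows.
        """
        if transform not in ("identity", "sqrt"):
            raise ValueError(f"unknown transform {transform!r}")
        tips = self.tip_indices
        h = self.node_heights()
        k = len(tips)
        # d(i,j) = h_i + h_j - 2*h_mrca ; mrca via per-tip ancestor paths
        anc_sets = []
        for t in tips:
            path = {}
            n = t
            while n != -1:
                path[n] = h[n]
                n = self.parent[n]
            anc_sets.append(path)
        d = np.zeros((k, k))
        for a in range(k):
            for b in range(a + 1, k):
                pa = anc_sets[a]
                n = tips[b]
                while n not in pa:
                    n = self.parent[n]
                d[a, b] = d[b, a] = h[tips[a]] + h[tips[b]] - 2 * h[n]
        if transform == "sqrt":
            d = np.sqrt(d)
        return d, [self.tip_labels[t] for t in tips]

    def vcv(self) -> tuple[np.ndarray, list[str]]:
        """Brownian covariance matrix V among tips: shared root-to-MRCA depth."""
        d, labels = self.distance_matrix()
        h = self.node_heights()[self.tip_indices]
        # V_ij = (h_i + h_j - d_ij)/2
        v = (h[:, None] + h[None, :] - d) / 2.0
        return v, labels


# --------------------------------------------------------------------- I/O

def _from_nested(nested) -> PhyloTree:
    """Build a PhyloTree from (label, length, children) nests in preorder."""
    parent, length, children, tips = [], [], [], {}
    stack = [(nested, -1)]
    order = []
    while stack:
        (label, ln, ch), par = stack.pop()
        idx = len(parent)
        parent.append(par)
        length.append(ln)
        children.append([])
        if par >= 0:
            children[par].append(idx)
        if not ch:
            tips[idx] = label
        order.append((idx, ch))
        for c in reversed(ch):
            stack.append((c, idx))
    return PhyloTree(np.asarray(parent, dtype=int), np.asarray(length, dtype=float),
                     children, tips)


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    seen = set()

    def conv(node):
        ch = [conv(c) for c in node.child_nodes()]
        if not ch:
            if node.taxon is None or not node.taxon.label:
                raise ValueError("tip without a label")
            label = node.taxon.label
            if label in seen:
                raise ValueError(f"duplicate tip label {label!r}")
            seen.add(label)
        else:
            label = ""
        ln = node.edge.length
        if node.parent_node is None:
            ln = 0.0 if ln is None else float(ln)
        elif ln is None:
            where = label or "an internal node"
            raise ValueError(f"missing branch length on the edge above {where}")
        if ln < 0:
            raise ValueError("negative branch length")
        return (label, float(ln), ch)

    tree = _from_nested(conv(dtree.seed_node))
    if tree.n_tips < 2:
        raise ValueError("tree must have at least 2 tips")
    return tree


def read_newick(text: str) -> PhyloTree:
    """Parse a single newick string (branch lengths required on all edges)."""
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip label: {exc.message}") from exc
    return _from_dendropy(dtree)


def read_newick_file(path) -> list[PhyloTree]:
    """Read a newick file; multi-tree files come back as a list."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    return [_from_dendropy(t) for t in trees]


def write_newick(tree: PhyloTree) -> str:
    def quote(label: str) -> str:
        if any(c in label for c in " ()[]:;,'\""):
            return "'" + label.replace("'", "''") + "'"
        return label

    def render(n: int) -> str:
        if not tree.children[n]:
            body = quote(tree.tip_labels[n])
        else:
            body = "(" + ",".join(render(c) for c in tree.children[n]) + ")"
        if tree.parent[n] == -1:
            return body + ";"
        return f"{body}:{tree.length[n]:.12g}"

    return render(0)


def prune_to_tips(tree: PhyloTree, keep) -> PhyloTree:
    """Restrict a tree to the tip labels in ``keep`` (dendropy does the
    pruning; unifurcations left behind are suppressed)."""
    keep = set(keep)
    missing = keep - set(tree.labels)
    if missing:
        raise ValueError(f"labels not on the tree: {sorted(missing)[:5]}")
    if keep == set(tree.labels):
        return tree
    if len(keep) < 2:
        raise ValueError("cannot prune below 2 tips")
    d = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                          suppress_internal_node_taxa=True,
                          preserve_underscores=True)
    d.retain_taxa_with_labels(sorted(keep))
    return _from_dendropy(d)


# ------------------------------------------------------- trait housekeeping

def align_trait(tree: PhyloTree, trait: dict[str, float]) -> np.ndarray:
    """Map a {tip label: value} dict onto preorder tip order; strict matching."""
    labels = set(tree.labels)
    extra = set(trait) - labels
    missing = labels - set(trait)
    if extra or missing:
        raise ValueError(
            f"trait labels do not match tree tips (missing={sorted(missing)[:5]}, "
            f"extra={sorted(extra)[:5]})"
        )
    x = np.array([trait[tree.tip_labels[i]] for i in tree.tip_indices], float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite trait values")
    return x


# --------------------------------------------------- Felsenstein contrasts

def _pic_engine(tree: PhyloTree, x: np.ndarray):
    """Run the pruning algorithm; ``x`` may be (n_tips,) or (n_tips, k).

    Returns (contrasts, contrast_vars, root_value, root_var) where contrasts
    is (n_internal, k)-shaped standardized contrasts in postorder of internal
    nodes.
    """
    x = np.atleast_2d(np.asarray(x, float).T).T  # (n_tips, k)
    if not tree.is_bifurcating():
        raise ValueError("tree must be fully bifurcating; resolve polytomies first")
    n_nodes = tree.n_nodes
    k = x.shape[1]
    val = np.zeros((n_nodes, k))
    vlen = tree.length.astype(float).copy()  # working branch lengths
    tips = tree.tip_indices
    for j, t in enumerate(tips):
        val[t] = x[j]
    contrasts, cvars = [], []
    for n in tree.postorder():
        ch = tree.children[n]
        if not ch:
            continue
        c1, c2 = ch
        v1, v2 = vlen[c1], vlen[c2]
        if v1 + v2 <= 0:
            raise ValueError(
                "zero-length sister pair encountered; add a small epsilon to "
                "zero branches (see resolve_polytomies) before computing contrasts"
            )
        contrasts.append((val[c1] - val[c2]) / np.sqrt(v1 + v2))
        cvars.append(v1 + v2)
        val[n] = (v2 * val[c1] + v1 * val[c2]) / (v1 + v2)
        vlen[n] += v1 * v2 / (v1 + v2)
    return (np.array(contrasts), np.array(cvars), val[0], vlen[0])


def independent_contrasts(tree: PhyloTree, trait: dict[str, float]) -> np.ndarray:
    """Standardized phylogenetically independent contrasts (one per internal node).

    Classic pruning: contrast = (x1 - x2)/sqrt(v1 + v2), ancestral value the
    variance-weighted average, parent branch extended by v1*v2/(v1+v2).
    """
    x = align_trait(tree, trait)
    contrasts, _, _, _ = _pic_engine(tree, x)
    return contrasts[:, 0]


# ------------------------------------------------------------- Blomberg's K

def _k_expected_ratio(tree: PhyloTree) -> float:
    """(tr(V) - n/(1'V^-1 1)) / (n - 1) without forming dense V.

    tr(V) is the sum of tip depths; 1'V^-1 1 is the reciprocal of the root
    value's variance from the pruning algorithm.
    """
    n = tree.n_tips
    tr_v = float(tree.node_heights()[tree.tip_indices].sum())
    _, _, _, root_var = _pic_engine(tree, np.zeros(n))
    return (tr_v - n * root_var) / (n - 1)


def blomberg_k(tree: PhyloTree, trait: dict[str, float] | np.ndarray) -> float:
    """Blomberg's K statistic of phylogenetic signal (Brownian expectation 1).

    K = (MSE0/MSE)_obs / (MSE0/MSE)_Brownian, with MSE0 the trait variance
    about the phylogenetically weighted (GLS) mean and MSE the mean squared
    standardized contrast; the denominator depends only on the tree.
    Computed via the pruning algorithm in O(n).
    """
    x = trait if isinstance(trait, np.ndarray) else align_trait(tree, trait)
    if x.ndim == 1 and np.ptp(x) == 0:
        raise ValueError("phylogenetic signal undefined for a constant trait")
    if tree.n_tips < 4:
        raise ValueError("K requires at least 4 tips")
    tree.require_ultrametric()
    btree = tree.resolve_polytomies()
    n = btree.n_tips
    if isinstance(trait, np.ndarray):
        if btree is not tree:
            raise ValueError(
                "array traits are only accepted on bifurcating trees; "
                "resolve polytomies first and align to the resolved tip order"
            )
    else:
        x = align_trait(btree, trait)
    contrasts, _, root_val, _ = _pic_engine(btree, x)
    mse = (contrasts ** 2).sum(axis=0) / (n - 1)
    dev = np.atleast_2d(x.T).T - root_val[None, :]
    mse0 = (dev ** 2).sum(axis=0) / (n - 1)
    k = (mse0 / mse) / _k_expected_ratio(btree)
    return float(k[0]) if k.size == 1 else k


def k_randomization_p(tree: PhyloTree, trait: dict[str, float],
                      n_rand: int = 1000, seed: int | None = None) -> dict:
    """Tip-randomization significance for K.

    Trait values are shuffled across tips ``n_rand`` times and K recomputed;
    p = (1 + #{K_rand >= K_obs}) / (n_rand + 1).
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    x = align_trait(tree, trait)
    btree = tree.resolve_polytomies()
    k_obs = blomberg_k(btree, x)
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(x) for _ in range(n_rand)])
    k_rand = blomberg_k(btree, perms)
    p = (1 + int(np.sum(k_rand >= k_obs))) / (n_rand + 1)
    return {"K": k_obs, "p": p, "n_rand": n_rand}
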