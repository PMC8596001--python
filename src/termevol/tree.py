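"""Rooted phylogenies with branch lengths, possibly non-ultrametric.

The central container is :class:`Phylogeny`, a light array-backed rooted
tree.  Trees are parsed from Newick or Nexus via dendropy and converted to
index arrays once, so that the phylogenetic covariance matrix, branch-length
transforms and pruning are cheap vectorized operations.

Tips may terminate before the present (fossil taxa), so tip depths are not
assumed equal anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_tree", "RegimePainting", "paint_clade"]


class TreeError(ValueError):
    """Raised for malformed trees (duplicate labels, missing lengths...)."""


class Phylogeny:
    """A rooted tree with branch lengths, indexed in preorder.

    Node 0 is the root.  Every non-root node ``v`` has ``parent[v] < v`` and
    carries the length of the branch above it in ``blen[v]``; ``blen[0]`` is
    0.  Tips are the nodes without children; their labels are unique.

    Parameters
    ----------
    parent : array of int
        Parent index per node; -1 for the root.
    blen : array of float
        Branch length above each node (>= 0); ignored for the root.
    labels : dict int -> str
        Labels for tips (required) and optionally internal nodes.
    """

    def __init__(self, parent, blen, labels):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.blen = np.asarray(blen, dtype=float)
        n = self.parent.size
        if n < 2:
            raise TreeError("tree needs at least 2 nodes")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise TreeError("nodes must be in preorder with root first")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("parent index must precede child (preorder)")
        self.blen = self.blen.copy()
        self.blen[0] = 0.0
        bad = np.where(~np.isfinite(self.blen[1:]) | (self.blen[1:] < 0))[0]
        if bad.size:
            v = int(bad[0]) + 1
            raise TreeError(
                f"node {labels.get(v, v)!r} has missing or negative branch length"
            )
        self.n_nodes = n
        counts = np.zeros(n, dtype=np.intp)
        np.add.at(counts, self.parent[1:], 1)
        self.tips = np.where(counts == 0)[0]
        if self.tips.size < 2:
            raise TreeError("tree must have at least 2 tips")
        self.labels = {int(k): str(v) for k, v in labels.items()}
        tip_labels = [self.labels.get(int(t)) for t in self.tips]
        if any(l is None for l in tip_labels):
            raise TreeError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dups = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dups}")
        self.tip_labels = tip_labels
        self._children = [[] for _ in range(n)]
        for v in range(1, n):
            self._children[self.parent[v]].append(v)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        seed = dtree.seed_node
        order = []
        index = {}
        stack = [seed]
        while stack:
            nd = stack.pop()
            index[id(nd)] = len(order)
            order.append(nd)
            stack.extend(reversed(nd.child_nodes()))
        n = len(order)
        parent = np.full(n, -1, dtype=np.intp)
        blen = np.zeros(n)
        labels = {}
        for i, nd in enumerate(order):
            if nd is not seed:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    who = nd.taxon.label if nd.taxon else f"internal node {i}"
                    raise TreeError(f"missing branch length above {who!r}")
                blen[i] = nd.edge.length
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except (dendropy.utility.error.DataParseError, ValueError) as err:
            raise TreeError(f"unparseable newick: {err}") from err
        return cls.from_dendropy(dtree)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.blen.copy(), dict(self.labels))

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return int(self.tips.size)

    def children(self, v: int):
        return tuple(self._children[v])

    def postorder(self):
        return range(self.n_nodes - 1, -1, -1)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.blen[v]
        return d

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order."""
        return self.node_depths()[self.tips]

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"no tip labelled {label!r}") from None

    def incidence(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): node v lies on the root path of tip j.

        The root row is all False; row v marks the tips that descend from
        (or are) node v, i.e. whose root path crosses the branch above v.
        """
        n, tips = self.n_nodes, self.tips
        M = np.zeros((n, tips.size), dtype=bool)
        M[tips, np.arange(tips.size)] = True
        for v in range(n - 1, 0, -1):
            M[self.parent[v]] |= M[v]
        M[0] = False
        return M

    def vcv(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Phylogenetic covariance matrix C.

        ``C[i, j]`` is the summed length of the branches shared by the root
        paths of tips i and j (the depth of their MRCA); ``C[i, i]`` is the
        depth of tip i.  With ``weights`` given, per-branch lengths are
        replaced by those weights (used by the kappa/delta transforms).
        """
        M = self.incidence()
        w = self.blen if weights is None else np.asarray(weights, dtype=float)
        return (M.T * w) @ M

    def mrca(self, tip_indices) -> int:
        paths = []
        for i in tip_indices:
            v = int(self.tips[i])
            path = {v}
            while self.parent[v] != -1:
                v = int(self.parent[v])
                path.add(v)
            paths.append(path)
        shared = set.intersection(*paths)
        return max(shared)  # deepest shared node has the largest preorder index

    def clade_nodes(self, node: int) -> np.ndarray:
        """All strict descendants of ``node`` (crown branches), preorder."""
        out = []
        stack = list(self._children[node])
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._children[v])
        return np.array(sorted(out), dtype=np.intp)

    # ------------------------------------------------------------------
    # editing
    # ------------------------------------------------------------------
    def prune_to(self, keep_labels) -> "Phylogeny":
        """Restrict to the given tips, suppressing unifurcations.

        Branch lengths along collapsed paths are summed, so shared path
        lengths between retained tips are preserved exactly.
        """
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise TreeError("cannot prune to fewer than 2 tips")
        retain = np.zeros(self.n_nodes, dtype=bool)
        for j, t in enumerate(self.tips):
            if self.tip_labels[j] in keep:
                v = int(t)
                while v != -1 and not retain[v]:
                    retain[v] = True
                    v = int(self.parent[v])
        nchild = np.zeros(self.n_nodes, dtype=np.intp)
        for v in range(1, self.n_nodes):
            if retain[v]:
                nchild[self.parent[v]] += 1
        is_tip = retain & (nchild == 0)
        # the root is always kept (possibly with a single child) so shared
        # basal path lengths — and hence the covariance — are preserved
        parent_out = [-1]
        blen_out = [0.0]
        labels_out = {}
        stack = [(c, 0, self.blen[c]) for c in reversed(self._children[0]) if retain[c]]
        while stack:
            v, pa_new, acc = stack.pop()
            kids = [c for c in self._children[v] if retain[c]]
            if len(kids) == 1 and not is_tip[v]:
                # unifurcation: fold this branch into the child's
                c = kids[0]
                stack.append((c, pa_new, acc + self.blen[c]))
                continue
            idx = len(parent_out)
            parent_out.append(pa_new)
            blen_out.append(acc)
            if v in self.labels:
                labels_out[idx] = self.labels[v]
            for c in reversed(kids):
                stack.append((c, idx, self.blen[c]))
        return Phylogeny(parent_out, blen_out, labels_out)

    def with_branch_lengths(self, blen: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(blen, float), dict(self.labels))

    # ------------------------------------------------------------------
    # output
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        def label(v):
            lab = self.labels.get(v, "")
            if any(ch in lab for ch in " ():,;'"):
                lab = "'" + lab.replace("'", "''") + "'"
            return lab

        def rec(v):
            kids = self._children[v]
            inner = (
                "(" + ",".join(rec(c) for c in kids) + ")" if kids else ""
            )
            br = "" if v == 0 else f":{self.blen[v]:.12g}"
            return f"{inner}{label(v)}{br}"

        return rec(0) + ";"

    def write(self, path, schema: str = "newick") -> None:
        text = self.to_newick()
        if schema == "nexus":
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
            text = dtree.as_string(schema="nexus")
        with open(path, "w") as fh:
            fh.write(text if text.endswith("\n") else text + "\n")

    def __repr__(self):
        kind = "ultrametric" if self.is_ultrametric() else "non-ultrametric"
        return f"<Phylogeny: {self.n_tips} tips, {kind}>"


def read_tree(path, schema: str = "newick") -> Phylogeny:
    """Read a rooted tree with branch lengths from Newick or Nexus.

    Tip labels are preserved verbatim (underscores are not converted to
    spaces).  Missing branch lengths or duplicate tip labels raise
    :class:`TreeError` naming the offending node.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"schema must be 'newick' or 'nexus', got {schema!r}")
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True
        )
    except (dendropy.utility.error.DataParseError, ValueError) as err:
        raise TreeError(f"unparseable {schema} file {path}: {err}") from err
    return Phylogeny.from_dendropy(dtree)


# ----------------------------------------------------------------------
# regime paintings for the clade-mixed trend/BM model
# ----------------------------------------------------------------------
@dataclass
class RegimePainting:
    """Assignment of every branch to the 'trend' or 'bm' regime.

    ``regimes[v]`` labels the branch above node v; the root entry is unused
    but kept so the array aligns with the tree's node indexing.
    """

    tree: Phylogeny
    regimes: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.regimes is None:
            self.regimes = np.array(["trend"] * self.tree.n_nodes, dtype=object)
        self.regimes = np.asarray(self.regimes, dtype=object)
        if self.regimes.size != self.tree.n_nodes:
            raise ValueError("painting must label every branch")
        bad = set(self.regimes[1:]) - {"trend", "bm"}
        if bad:
            raise ValueError(f"unknown regime labels: {sorted(bad)}")

    def trend_exposure(self) -> np.ndarray:
        """Per-tip total time spent on trend-regime branches (root->tip)."""
        w = np.where(self.regimes == "trend", self.tree.blen, 0.0)
        w[0] = 0.0
        M = self.tree.incidence()
        return w @ M

    def to_table(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for v in range(1, self.tree.n_nodes):
            rows.append(
                {
                    "node": v,
                    "label": self.tree.labels.get(v, ""),
                    "regime": self.regimes[v],
                }
            )
        return pd.DataFrame(rows)


def paint_clade(tree: Phylogeny, clade_tips, include_stem: bool = False) -> RegimePainting:
    """Paint the crown group of the MRCA of ``clade_tips`` as 'bm'.

    Everything else is 'trend'.  By default the clade's stem branch stays in
    the trend regime (the directional size reduction runs up to the origin
    of the clade); ``include_stem=True`` flips that convention.
    """
    idx = [tree.tip_index(l) if isinstance(l, str) else int(l) for l in clade_tips]
    node = tree.mrca(idx)
    regimes = np.array(["trend"] * tree.n_nodes, dtype=object)
    regimes[tree.clade_nodes(node)] = "bm"
    if include_stem and node != 0:
        regimes[node] = "bm"
    return RegimePainting(tree, regimes)
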