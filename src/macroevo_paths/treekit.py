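"""Time-calibrated tree container, newick I/O, and tree utilities.

All downstream likelihoods share one convention: node ages are measured
backward from the present in Ma, so extant tips sit at age 0 and the crown
node sits at the crown age.  Trees are stored as flat parent/branch-length
arrays; the branch "belonging" to a node is the edge connecting it to its
parent, which gives every non-root node a branch index usable by the
rate-regression and regime-painting machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["TimeTree", "CladeDef", "read_newick", "write_newick"]

#: relative (to crown age) tolerance for declaring a tree ultrametric
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed trees or inconsistent tree queries."""


@dataclass(frozen=True)
class CladeDef:
    """A named clade: a set of tip labels plus its sampling fraction f."""

    name: str
    tips: frozenset
    sampling_fraction: float = 1.0

    def __post_init__(self):
        if not self.tips:
            raise TreeError(f"clade {self.name!r}: empty tip set")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise TreeError(
                f"clade {self.name!r}: sampling fraction must be in (0, 1]"
            )


class TimeTree:
    """Rooted tree with branch lengths in Myr and node ages in Ma.

    Nodes are integers ``0 .. n_nodes-1``; tips occupy ``0 .. n_tips-1`` in
    the order of ``tip_labels``.  ``parent[root] == -1`` and
    ``branch_lengths[root] == 0``.
    """

    def __init__(self, parent, branch_lengths, tip_labels,
                 annotations=None, _validate=True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_lengths = np.asarray(branch_lengths, dtype=np.float64)
        self.tip_labels = [str(x).strip() for x in tip_labels]
        #: free-form per-branch / per-node annotations (true rates, regimes)
        self.annotations = dict(annotations or {})
        if _validate:
            self._validate()
        self._children = None
        self._ages = None
        self._postorder = None

    # -- construction / validation -------------------------------------

    def _validate(self):
        n = self.parent.size
        if self.branch_lengths.size != n:
            raise TreeError("parent and branch_lengths length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"expected exactly one root, found {roots.size}")
        if np.any(self.branch_lengths[self.parent >= 0] < 0):
            raise TreeError("negative branch length")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeError("duplicate tip labels")
        # every node reaches the root (no cycles / orphans)
        seen = np.zeros(n, dtype=bool)
        for i in range(n):
            j, steps = i, 0
            while j >= 0 and not seen[j]:
                seen[j] = True
                j = self.parent[j]
                steps += 1
                if steps > n:
                    raise TreeError("cycle detected in parent map")
        if not seen.all():
            raise TreeError("disconnected nodes")

    # -- basic structure -----------------------------------------------

    @property
    def n_nodes(self):
        return self.parent.size

    @property
    def n_tips(self):
        return len(self.tip_labels)

    @property
    def root(self):
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def children(self):
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = [tuple(c) for c in ch]
        return self._children

    @property
    def tips(self):
        return np.arange(self.n_tips)

    def is_tip(self, node):
        return node < self.n_tips

    @property
    def internal_nodes(self):
        return np.arange(self.n_tips, self.n_nodes)

    def postorder(self):
        """Node indices, children before parents."""
        if self._postorder is None:
            order, stack = [], [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self):
        return self.postorder()[::-1]

    # -- ages ------------------------------------------------------------

    @property
    def depths(self):
        """Root-to-node path lengths (root at 0)."""
        d = np.zeros(self.n_nodes)
        for node in self.preorder():
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.branch_lengths[node]
        return d

    @property
    def ages(self):
        """Node ages in Ma before present (tips at ~0 for ultrametric trees)."""
        if self._ages is None:
            d = self.depths
            self._ages = d[: self.n_tips].max() - d
        return self._ages

    @property
    def crown_age(self):
        return float(self.ages[self.root])

    def is_ultrametric(self, rtol=ULTRAMETRIC_RTOL):
        tip_ages = self.ages[: self.n_tips]
        scale = max(self.crown_age, 1e-300)
        return bool(np.all(np.abs(tip_ages) <= rtol * scale))

    def is_bifurcating(self):
        return all(
            len(c) == 2 for n, c in enumerate(self.children) if not self.is_tip(n)
        )

    def require_ultrametric(self, rtol=ULTRAMETRIC_RTOL):
        if not self.is_ultrametric(rtol):
            raise TreeError("tree is not ultrametric within tolerance")

    def require_bifurcating(self):
        if not self.is_bifurcating():
            raise TreeError("tree has non-bifurcating internal nodes")

    def branching_times(self):
        """Internal-node ages, descending (crown age first)."""
        self.require_ultrametric()
        ages = self.ages[self.n_tips:]
        return np.sort(ages)[::-1]

    # -- queries ---------------------------------------------------------

    def tip_index(self, label):
        try:
            return self.tip_labels.index(str(label).strip())
        except ValueError:
            raise TreeError(f"unknown tip label {label!r}") from None

    def mrca(self, labels):
        """Most recent common ancestor node of a set of tip labels."""
        nodes = [self.tip_index(x) for x in labels]
        if not nodes:
            raise TreeError("mrca of empty set")
        common = None
        for node in nodes:
            path = self._path_to_root_set(node)
            common = path if common is None else (common & path)
        # the shallowest (youngest) common ancestor covers the subset
        ages = self.ages
        return min(common, key=lambda k: ages[k])

    def _path_to_root_set(self, node):
        out = set()
        j = node
        while j >= 0:
            out.add(j)
            j = self.parent[j]
        return out

    def clade_tips(self, node):
        """Labels of all tips descending from (and including) ``node``."""
        out, stack = [], [node]
        while stack:
            k = stack.pop()
            if self.is_tip(k):
                out.append(self.tip_labels[k])
            else:
                stack.extend(self.children[k])
        return sorted(out)

    def clade_mrca_tips(self, labels):
        """All tips descending from the MRCA of the given tip subset."""
        return self.clade_tips(self.mrca(labels))

    def tip_path_edges(self, tip):
        """Branch lengths from the tip toward the root (terminal edge first)."""
        out, j = [], tip
        while self.parent[j] >= 0:
            out.append(self.branch_lengths[j])
            j = self.parent[j]
        return np.asarray(out)

    # -- pruning ---------------------------------------------------------

    def keep_tips(self, labels):
        """Prune to the given tips, suppressing degree-2 internal nodes."""
        keep = {str(x).strip() for x in labels}
        unknown = keep - set(self.tip_labels)
        if unknown:
            raise TreeError(f"unknown tip labels: {sorted(unknown)}")
        if len(keep) < 2:
            raise TreeError("pruned tree must retain >= 2 tips")
        # number of retained tips below each node
        n_below = np.zeros(self.n_nodes, dtype=np.int64)
        for node in self.postorder():
            if self.is_tip(node):
                n_below[node] = 1 if self.tip_labels[node] in keep else 0
            else:
                n_below[node] = sum(n_below[c] for c in self.children[node])
        # new root: shallowest node with all retained tips below
        new_root = self.root
        total = n_below[self.root]
        while True:
            nxt = [c for c in self.children[new_root] if n_below[c] == total]
            if not nxt or self.is_tip(new_root):
                break
            new_root = nxt[0]
        # build new arrays; suppress unifurcations
        new_parent, new_blen, new_labels = [], [], []
        idx_map = {}

        def add_node(label):
            idx_map_len = len(new_parent)
            new_parent.append(-1)
            new_blen.append(0.0)
            new_labels.append(label)
            return idx_map_len

        # collect surviving tips then internal nodes (postorder style build)
        tips_new = [t for t in range(self.n_tips) if n_below[t] == 1]
        for t in tips_new:
            idx_map[t] = add_node(self.tip_labels[t])
        # walk original tree: for every surviving node, find its surviving
        # ancestor (nearest ancestor with >= 2 surviving children or root)
        surviving_internal = []
        for node in self.postorder():
            if self.is_tip(node) or n_below[node] == 0 or node == new_root:
                continue
            kids = [c for c in self.children[node] if n_below[c] > 0]
            if len(kids) >= 2:
                surviving_internal.append(node)
        surviving_internal.append(new_root)
        for node in surviving_internal:
            if node not in idx_map:
                idx_map[node] = add_node(None)
        surviving = set(idx_map)
        for node in idx_map:
            if node == new_root:
                continue
            # climb to nearest surviving ancestor, accumulating length
            length = self.branch_lengths[node]
            j = self.parent[node]
            while j not in surviving:
                length += self.branch_lengths[j]
                j = self.parent[j]
            new_parent[idx_map[node]] = idx_map[j]
            new_blen[idx_map[node]] = length
        tree = TimeTree(new_parent, new_blen, [l for l in new_labels if l])
        return tree

    def subsample_tips(self, fraction, seed):
        """Keep a uniformly sampled tip subset (round half up)."""
        if not (0 < fraction <= 1):
            raise TreeError("fraction must be in (0, 1]")
        if fraction == 1:
            return self
        n_keep = int(np.floor(self.n_tips * fraction + 0.5))
        if n_keep < 2:
            raise TreeError("subsample would leave fewer than 2 tips")
        rng = np.random.default_rng(seed)
        keep = rng.choice(self.n_tips, size=n_keep, replace=False)
        return self.keep_tips([self.tip_labels[i] for i in keep])

    # -- newick ----------------------------------------------------------

    @classmethod
    def from_newick(cls, text):
        return read_newick(text)

    def to_newick(self):
        return write_newick(self)

    def __repr__(self):
        return (f"TimeTree(n_tips={self.n_tips}, "
                f"crown_age={self.crown_age:.4g})")


def read_newick(text):
    """Parse a newick string (branch lengths required) into a TimeTree."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"newick parse error: {exc}") from exc

    dnodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in dnodes if nd.is_leaf()]
    labels = []
    for nd in tips:
        lab = nd.taxon.label if nd.taxon else nd.label
        if lab is None:
            raise TreeError("tip without label")
        labels.append(str(lab).strip())
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate tip labels")

    index = {}
    for i, nd in enumerate(tips):
        index[id(nd)] = i
    nxt = len(tips)
    for nd in dnodes:
        if not nd.is_leaf():
            index[id(nd)] = nxt
            nxt += 1

    parent = np.full(nxt, -1, dtype=np.int64)
    blen = np.zeros(nxt)
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeError("branch length missing")
            if nd.edge.length < 0:
                raise TreeError("negative branch length")
            blen[i] = float(nd.edge.length)
    return TimeTree(parent, blen, labels)


def write_newick(tree):
    """Serialize a TimeTree to a newick string with branch lengths."""
    def fmt(node):
        if tree.is_tip(node):
            core = tree.tip_labels[node]
        else:
            core = "(" + ",".join(fmt(c) for c in tree.children[node]) + ")"
        if tree.parent[node] >= 0:
            return f"{core}:{tree.branch_lengths[node]:.12g}"
        return core

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        return fmt(tree.root) + ";"
    finally:
        sys.setrecursionlimit(old)


def read_clade_tsv(path_or_buf):
    """Read clade definitions from TSV (columns: clade, tip, sampling_fraction)."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep="\t")
    clades = []
    for name, grp in df.groupby("clade", sort=True):
        f = float(grp["sampling_fraction"].iloc[0])
        clades.append(CladeDef(str(name), frozenset(grp["tip"].astype(str)), f))
    return clades


def shared_path_matrix(tree, tips_only=True):
    """Matrix of shared root-to-node path lengths (the BM covariance V).

    V[i, j] = depth of the MRCA of tips i and j; V[i, i] = tip depth.
    """
    tree.require_ultrametric()
    n = tree.n_tips
    depths = tree.depths
    V = np.zeros((n, n))
    # postorder accumulation of descendant tip sets
    below = [None] * tree.n_nodes
    for node in tree.postorder():
        if tree.is_tip(node):
            below[node] = [node]
            V[node, node] = depths[node]
        else:
            kids = tree.children[node]
            merged = []
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in below[kids[a]]:
                        for j in below[kids[b]]:
                            V[i, j] = V[j, i] = depths[node]
            for c in kids:
                merged.extend(below[c])
            below[node] = merged
    return V
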