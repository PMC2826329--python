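"""Rooted time trees: Newick I/O, age calibration, phylogenetic covariance.

Trees are stored in a flat array representation (parent pointers, child
lists, one branch length per non-root node).  Branch lengths are in the
same units as node ages (Myr for calibrated trees).  Newick parsing is
delegated to dendropy; the calibration and covariance algorithms operate
on the flat representation directly.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCov",
    "NewickError",
    "CalibrationError",
    "parse_newick",
    "write_newick",
    "bladj_calibrate",
    "phylo_covariance",
    "resolve_polytomies",
    "read_age_constraints",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class CalibrationError(ValueError):
    """Inconsistent or insufficient age constraints."""


@dataclass
class PhyloTree:
    """Rooted tree with optional branch lengths.

    Attributes
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent node id of node ``i``; the root has
        parent ``-1``.
    children : list of list of int
        Child ids per node (empty list for tips).
    branch_length : ndarray of float
        Length of the branch above each node (NaN if unknown; NaN at the
        root is conventional).
    labels : list of str or None
        Node labels.  Every tip must carry a unique label; internal
        labels are optional (used for age constraints).
    root : int
        Root node id.
    """

    parent: np.ndarray
    children: list
    branch_length: np.ndarray
    labels: list
    root: int = 0

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_length = np.asarray(self.branch_length, dtype=float)
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        n = len(self.parent)
        if n == 0:
            raise NewickError("empty tree")
        if len(self.children) != n or len(self.branch_length) != n:
            raise ValueError("inconsistent array lengths")
        if self.parent[self.root] != -1:
            raise ValueError("root must have parent -1")
        if int(np.sum(self.parent == -1)) != 1:
            raise ValueError("tree must have a single root")
        # connectivity / acyclicity: every node reachable from root once
        seen = np.zeros(n, dtype=bool)
        for node in self.preorder():
            if seen[node]:
                raise ValueError("cycle detected")
            seen[node] = True
        if not seen.all():
            raise ValueError("tree is not connected")
        tips = [self.labels[i] for i in self.tips()]
        if any(lbl is None or lbl == "" for lbl in tips):
            raise NewickError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            raise NewickError("duplicate tip labels")
        with np.errstate(invalid="ignore"):
            if np.any(self.branch_length < 0):
                raise ValueError("negative branch length")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tips(self) -> list:
        """Tip node ids in a stable (preorder) order."""
        return [i for i in self.preorder() if not self.children[i]]

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def preorder(self) -> list:
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self.children[node]))
        return order

    def postorder(self) -> list:
        return self.preorder()[::-1]

    def is_bifurcating(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children if c is not None)

    def has_branch_lengths(self) -> bool:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return not np.any(np.isnan(self.branch_length[mask]))

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (root depth 0)."""
        if not self.has_branch_lengths():
            raise ValueError("tree has missing branch lengths")
        depth = np.zeros(self.n_nodes)
        for node in self.preorder():
            if node == self.root:
                continue
            depth[node] = depth[self.parent[node]] + self.branch_length[node]
        return depth

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.node_depths()[self.tips()]
        dmax = d.max()
        if dmax == 0:
            return True
        return (d.max() - d.min()) / dmax <= rtol

    def find(self, label: str) -> int:
        for i, lbl in enumerate(self.labels):
            if lbl == label:
                return i
        raise KeyError(f"no node labelled {label!r}")

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            branch_length=self.branch_length.copy(),
            labels=list(self.labels),
            root=self.root,
        )

    def descendant_tips(self) -> list:
        """For each node, the list of tip ids below it (postorder fill)."""
        desc = [None] * self.n_nodes
        for node in self.postorder():
            if not self.children[node]:
                desc[node] = [node]
            else:
                acc = []
                for c in self.children[node]:
                    acc.extend(desc[c])
                desc[node] = acc
        return desc

    def prune_to_tips(self, keep: set) -> "PhyloTree":
        """Subtree spanning the given tip labels, unifurcations suppressed."""
        keep = set(keep)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        keep_node = np.zeros(self.n_nodes, dtype=bool)
        for node in self.postorder():
            if not self.children[node]:
                keep_node[node] = self.labels[node] in keep
            else:
                keep_node[node] = any(keep_node[c] for c in self.children[node])
        # rebuild, suppressing nodes with a single kept child
        new_parent, new_children, new_bl, new_labels = [], [], [], []

        def build(node, parent_new, bl_acc):
            kept_children = [c for c in (self.children[node] or []) if keep_node[c]]
            bl = self.branch_length[node]
            bl = 0.0 if np.isnan(bl) else bl
            if len(kept_children) == 1 and parent_new is not None:
                return build(kept_children[0], parent_new, bl_acc + bl)
            nid = len(new_parent)
            new_parent.append(-1 if parent_new is None else parent_new)
            new_children.append([])
            new_bl.append(np.nan if parent_new is None else bl_acc + bl)
            new_labels.append(self.labels[node])
            if parent_new is not None:
                new_children[parent_new].append(nid)
            for c in kept_children:
                build(c, nid, 0.0)
            return nid

        # descend past unifurcations at the root
        start = self.root
        while True:
            kc = [c for c in self.children[start] if keep_node[c]]
            if len(kc) == 1:
                start = kc[0]
            else:
                break
        build(start, None, 0.0)
        return PhyloTree(
            parent=np.array(new_parent),
            children=new_children,
            branch_length=np.array(new_bl, dtype=float),
            labels=new_labels,
            root=0,
        )


@dataclass
class PhyloCov:
    """Phylogenetic covariance matrix under Brownian motion.

    ``V[i, j]`` is the root-to-MRCA depth of tips ``i`` and ``j`` (shared
    branch length, in time units); the diagonal holds root-to-tip depths.
    """

    V: np.ndarray
    tip_labels: list
    _rtol: float = field(default=1e-6, repr=False)

    def correlation(self) -> np.ndarray:
        """V scaled to unit diagonal; only defined for ultrametric trees."""
        d = np.diag(self.V)
        dmax = d.max()
        if dmax <= 0 or (d.max() - d.min()) / dmax > self._rtol:
            raise ValueError(
                "correlation matrix requires an ultrametric tree "
                f"(relative depth spread {(d.max() - d.min()) / dmax:.2e})"
            )
        return self.V / dmax


# -- Newick I/O -------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    children: list = [[] for _ in range(n)]
    bl = np.full(n, np.nan)
    labels: list = [None] * n
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
        if nd.edge.length is not None and nd.parent_node is not None:
            bl[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return PhyloTree(parent=parent, children=children, branch_length=bl,
                     labels=labels, root=0)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths may be absent (NaN) before calibration.  Raises
    :class:`NewickError` on malformed input, duplicate tip labels or an
    empty tree.
    """
    text = text.strip()
    if not text or text == ";":
        raise NewickError("empty tree")
    if not text.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    if text.count("(") != text.count(")"):
        raise NewickError("unbalanced parentheses")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.leaf_nodes():
        raise NewickError("empty tree")
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick; inverse of :func:`parse_newick`."""

    def fmt(node: int) -> str:
        lbl = tree.labels[node] or ""
        if tree.children[node]:
            inner = ",".join(fmt(c) for c in tree.children[node])
            s = f"({inner}){lbl}"
        else:
            s = lbl
        bl = tree.branch_length[node]
        if node != tree.root and not np.isnan(bl):
            s += f":{float(bl)!r}"
        return s

    return fmt(tree.root) + ";"


def read_age_constraints(path) -> dict:
    """Two-column delimited text (node_label, age in Myr) -> dict."""
    ages = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ValueError(f"bad age-constraint line: {line!r}")
            ages[parts[0]] = float(parts[1])
    return ages


# -- BLADJ-style age calibration -------------------------------------------

def bladj_calibrate(tree: PhyloTree, ages: dict) -> PhyloTree:
    """Assign node ages by even interpolation between dated nodes.

    Dated nodes keep their constrained ages exactly.  Every undated node
    receives an age by linear interpolation along the path from its
    nearest dated ancestor (age tA) to its nearest dated descendant
    (age tD, fewest intervening edges): with the node k edges below the
    ancestor on a path of m edges, its age is ``tA - (tA - tD) * k / m``.
    Tips default to age 0 unless constrained.  Branch lengths of the
    returned tree are parent age minus child age.

    When several dated descendants are equally near, the one reached
    through the child subtree with the lexicographically smallest leading
    tip label wins (a deterministic tie-break; the choice is ours, not a
    published convention).
    """
    label_to_node = {}
    for i, lbl in enumerate(tree.labels):
        if lbl:
            label_to_node.setdefault(lbl, i)
    for lbl in ages:
        if lbl not in label_to_node:
            raise CalibrationError(f"constrained label {lbl!r} not in tree")
    n = tree.n_nodes
    age = np.full(n, np.nan)
    for lbl, a in ages.items():
        if a < 0:
            raise CalibrationError(f"negative age for {lbl!r}")
        age[label_to_node[lbl]] = float(a)
    for t in tree.tips():
        if np.isnan(age[t]):
            age[t] = 0.0
    if np.isnan(age[tree.root]):
        raise CalibrationError("root age must be constrained")

    dated = ~np.isnan(age)
    # smallest leading tip label per subtree, for the tie-break
    min_tip = [None] * n
    for node in tree.postorder():
        if not tree.children[node]:
            min_tip[node] = tree.labels[node]
        else:
            min_tip[node] = min(min_tip[c] for c in tree.children[node])

    # nearest dated ancestor (and edge distance) per node
    anc = np.full(n, -1, dtype=np.int64)
    anc_dist = np.zeros(n, dtype=np.int64)
    for node in tree.preorder():
        if node == tree.root:
            continue
        p = tree.parent[node]
        if dated[p]:
            anc[node], anc_dist[node] = p, 1
        else:
            anc[node], anc_dist[node] = anc[p], anc_dist[p] + 1

    for a_node in range(n):
        if dated[a_node] and a_node != tree.root:
            ref = anc[a_node]
            if ref >= 0 and age[a_node] >= age[ref]:
                raise CalibrationError(
                    f"descendant age {age[a_node]} >= ancestor age {age[ref]}"
                )

    def interpolate(u: int) -> float:
        """Age of undated node u, interpolated between the nearest dated
        ancestor and the nearest dated descendant (BFS; tie-break on the
        leading tip label of the first-step child subtree)."""
        best = None
        queue = deque()
        for c in tree.children[u]:
            queue.append((c, 1, min_tip[c]))
        while queue:
            node, dist, via = queue.popleft()
            if dated[node]:
                key = (dist, via, tree.labels[node] or "", age[node])
                if best is None or key[:3] < best[:3]:
                    best = key
                continue
            for c in tree.children[node]:
                queue.append((c, dist + 1, via))
        d_down, _, _, t_down = best
        t_up = age[anc[u]]
        d_up = anc_dist[u]
        return t_up - (t_up - t_down) * d_up / (d_up + d_down)

    new_age = age.copy()
    for u in range(n):
        if not dated[u]:
            new_age[u] = interpolate(u)

    out = tree.copy()
    for node in out.preorder():
        if node == out.root:
            out.branch_length[node] = np.nan
            continue
        bl = new_age[out.parent[node]] - new_age[node]
        if bl < -1e-9:
            raise CalibrationError(
                "age constraints imply a negative branch "
                f"above node {out.labels[node] or node}"
            )
        out.branch_length[node] = max(bl, 0.0)
    return out


# -- covariance -------------------------------------------------------------

def phylo_covariance(tree: PhyloTree) -> PhyloCov:
    """Brownian-motion covariance matrix V (tips x tips).

    ``V[i, j]`` is the depth (from the root) of the MRCA of tips i and j;
    the diagonal holds total root-to-tip depths.
    """
    depth = tree.node_depths()
    tips = tree.tips()
    tip_index = {t: k for k, t in enumerate(tips)}
    m = len(tips)
    V = np.zeros((m, m))
    desc = tree.descendant_tips()
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            V[tip_index[node], tip_index[node]] = depth[node]
            continue
        d = depth[node]
        for a in range(len(kids)):
            ta = np.array([tip_index[t] for t in desc[kids[a]]])
            for b in range(a + 1, len(kids)):
                tb = np.array([tip_index[t] for t in desc[kids[b]]])
                V[np.ix_(ta, tb)] = d
                V[np.ix_(tb, ta)] = d
    return PhyloCov(V=V, tip_labels=[tree.labels[t] for t in tips])


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Resolve every polytomy into bifurcations with zero-length branches.

    Children are ordered by the lexicographically smallest tip label of
    their subtree and folded left-to-right, so the output is
    deterministic.  Path lengths between tips (hence V) are unchanged.
    """
    out = tree.copy()
    min_tip = [None] * out.n_nodes
    for node in out.postorder():
        if not out.children[node]:
            min_tip[node] = out.labels[node]
        else:
            min_tip[node] = min(min_tip[c] for c in out.children[node])

    parent = list(out.parent)
    children = [list(c) for c in out.children]
    bl = list(out.branch_length)
    labels = list(out.labels)

    for node in list(range(len(parent))):
        kids = children[node]
        if len(kids) <= 2:
            continue
        kids = sorted(kids, key=lambda c: min_tip[c])
        # fold: ((k0,k1),k2),k3 ... with zero-length connector branches
        left = kids[0]
        for k in kids[1:-1]:
            new = len(parent)
            parent.append(node)
            children.append([left, k])
            bl.append(0.0)
            labels.append(None)
            min_tip.append(min(min_tip[left], min_tip[k]))
            parent[left] = new
            parent[k] = new
            left = new
        children[node] = [left, kids[-1]]
        parent[kids[-1]] = node

    return PhyloTree(
        parent=np.array(parent),
        children=children,
        branch_length=np.array(bl, dtype=float),
        labels=labels,
        root=out.root,
    )
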