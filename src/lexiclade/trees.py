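"""Rooted, dated binary trees with per-branch clock rates.

The MCMC machinery needs cheap copies and in-place topology surgery, so trees
are stored as flat arrays: tips are nodes ``0..n-1``, internals
``n..2n-2``; ``heights`` are in years BP (tips at their declared ages) and
``rates`` hold the clock rate of the branch above each node (unused at the
root).  Conversion to and from newick goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class Tree:
    labels: list[str]                 # tip labels, index = node id
    parent: np.ndarray                # int, -1 at root
    children: np.ndarray              # (n_nodes, 2), -1 at tips
    heights: np.ndarray               # years BP
    rates: np.ndarray                 # clock rate of branch above node
    root: int

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.children = np.asarray(self.children, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)

    # -- basics ------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def copy(self) -> "Tree":
        return Tree(list(self.labels), self.parent.copy(), self.children.copy(),
                    self.heights.copy(), self.rates.copy(), self.root)

    def is_tip(self, i: int) -> bool:
        return i < self.n_tips

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            if not self.is_tip(node):
                stack.extend(self.children[node])
        return order[::-1]

    def validate(self) -> None:
        for i in range(self.n_nodes):
            if i != self.root:
                p = self.parent[i]
                if self.heights[p] <= self.heights[i] - 1e-9:
                    raise ValueError(f"parent {p} not older than child {i}")
        if np.any(self.rates <= 0):
            raise ValueError("branch rates must be positive")

    def branch_durations(self) -> np.ndarray:
        """Years on the branch above each node (0 at the root)."""
        d = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            if i != self.root:
                d[i] = self.heights[self.parent[i]] - self.heights[i]
        return d

    # -- clades ------------------------------------------------------------
    def tipsets(self) -> dict[int, frozenset]:
        """Node -> frozenset of tip labels below it (tips included)."""
        out: dict[int, frozenset] = {}
        for node in self.postorder():
            if self.is_tip(node):
                out[node] = frozenset([self.labels[node]])
            else:
                a, b = self.children[node]
                out[node] = out[a] | out[b]
        return out

    def clades(self) -> dict[frozenset, int]:
        """Clade tip-set -> internal node, for all internal nodes."""
        return {s: n for n, s in self.tipsets().items() if not self.is_tip(n)}

    def mrca_height(self, taxa: frozenset) -> float:
        """Height of the most recent common ancestor of a label set."""
        sets = self.tipsets()
        best = None
        for node in self.postorder():
            if taxa <= sets[node]:
                best = node
                break  # postorder: first superset is the MRCA
        if best is None:
            raise ValueError("taxa not all present in tree")
        return float(self.heights[best])

    def is_monophyletic(self, taxa: frozenset) -> bool:
        return taxa in self.clades() or len(taxa) == 1

    # -- newick ------------------------------------------------------------
    def to_newick(self, with_rates: bool = False) -> str:
        def rec(i: int) -> str:
            blen = 0.0 if i == self.root else self.heights[self.parent[i]] - self.heights[i]
            meta = f"[&rate={self.rates[i]:.8g}]" if with_rates and i != self.root else ""
            if self.is_tip(i):
                return f"{self.labels[i]}{meta}:{blen:.8g}"
            a, b = self.children[i]
            inner = f"({rec(a)},{rec(b)})"
            if i == self.root:
                return inner
            return f"{inner}{meta}:{blen:.8g}"

        return rec(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(), schema="newick",
            taxon_namespace=taxon_namespace, rooting="force-rooted",
        )

    @classmethod
    def from_newick(cls, newick: str, tip_ages: dict[str, float] | None = None) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
        return cls.from_dendropy(dt, tip_ages)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree, tip_ages: dict[str, float] | None = None) -> "Tree":
        tip_ages = tip_ages or {}
        leaves = [lf for lf in dt.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        n = len(labels)
        n_nodes = 2 * n - 1
        parent = np.full(n_nodes, -1, dtype=int)
        children = np.full((n_nodes, 2), -1, dtype=int)
        heights = np.zeros(n_nodes)
        rates = np.ones(n_nodes)
        index: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        nxt = n
        for node in dt.postorder_node_iter():
            if node.is_leaf():
                continue
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("tree must be binary")
            index[id(node)] = nxt
            nxt += 1
        # depths from root along branch lengths
        depth: dict[int, float] = {id(dt.seed_node): 0.0}
        for node in dt.preorder_node_iter():
            for ch in node.child_nodes():
                depth[id(ch)] = depth[id(node)] + (ch.edge.length or 0.0)
        maxd = max(depth[id(lf)] + tip_ages.get(lf.taxon.label, 0.0) for lf in leaves)
        for node in dt.postorder_node_iter():
            i = index[id(node)]
            heights[i] = maxd - depth[id(node)]
            for ch in node.child_nodes():
                j = index[id(ch)]
                parent[j] = i
                slot = 0 if children[i, 0] == -1 else 1
                children[i, slot] = j
        root = index[id(dt.seed_node)]
        t = cls(labels, parent, children, heights, rates, root)
        return t


def random_coalescent_tree(
    labels: list[str], root_age: float, rng: np.random.Generator,
    tip_ages: dict[str, float] | None = None,
) -> Tree:
    """A random dated topology (uniform joins, quantile-spaced heights).

    Used for MCMC starting states; not a draw from any particular prior.
    """
    tip_ages = tip_ages or {}
    n = len(labels)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    children = np.full((n_nodes, 2), -1, dtype=int)
    heights = np.zeros(n_nodes)
    for i, lb in enumerate(labels):
        heights[i] = tip_ages.get(lb, 0.0)
    max_tip = float(heights[:n].max()) if n else 0.0
    hs = np.sort(rng.uniform(max_tip + 1e-6, root_age, size=n - 2)) if n > 2 else np.array([])
    active = list(range(n))
    nxt = n
    floor = max_tip
    for k in range(n - 1):
        h = root_age if k == n - 2 else float(hs[k])
        # join two active nodes younger than h; with old serial tips the
        # quantile height may undercut them, so lift it just above
        ok = [a for a in active if heights[a] < h]
        if len(ok) < 2:
            youngest = sorted(active, key=lambda x: heights[x])[:2]
            h = max(h, floor, heights[youngest[1]] + 1e-6)
            ok = [a for a in active if heights[a] < h]
        floor = max(floor, h)
        pair = rng.choice(len(ok), size=2, replace=False)
        a, b = ok[pair[0]], ok[pair[1]]
        parent[a] = parent[b] = nxt
        children[nxt] = (a, b)
        heights[nxt] = h
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Tree(list(labels), parent, children, heights, np.ones(n_nodes), n_nodes - 1)


def rf_distance(a: Tree, b: Tree, unrooted: bool = True) -> int:
    """Robinson-Foulds distance via dendropy (shared taxon namespace).

    Compared unrooted by default: a reversible substitution model cannot
    identify the root position, so topology recovery is an unrooted claim
    (root placement comes from priors and constraints, not the data).
    """
    ns = dendropy.TaxonNamespace()
    rooting = "force-rooted" if not unrooted else "force-unrooted"
    ta = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                           taxon_namespace=ns, rooting=rooting)
    tb = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                           taxon_namespace=ns, rooting=rooting)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
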