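"""Distance-based reticulation analysis.

From a matrix of pairwise lexical distances this module computes the two
standard quartet diagnostics of tree-likeness (δ-scores and Q-residuals) and
a NeighborNet circular split system.  A distance matrix is additive (fits a
tree exactly) iff every quartet satisfies the four-point condition; δ and Q
quantify the per-quartet violation, while the NeighborNet displays the
conflicting signal as a weighted circular split system.

The NeighborNet here follows the classic agglomerative scheme: clusters of
one or two linked nodes are merged under a neighbor-joining-style criterion,
three-node paths are reduced to two replacement nodes with weighted average
distances, and the reductions are expanded in reverse at the end to yield a
circular ordering of the taxa.  Split weights are then estimated by
nonnegative least squares over all splits compatible with that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import nnls

from .cognacy import CognacyMatrix


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("nonzero diagonal")


@dataclass
class SplitSystem:
    """Weighted splits compatible with a circular ordering of the taxa."""

    taxa: list[str]
    ordering: list[int]  # permutation of range(len(taxa))
    splits: list[tuple[frozenset, float]]  # (one side as taxon indices, weight)

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if sorted(self.ordering) != list(range(n)):
            raise ValueError("ordering is not a permutation of the taxa")
        pos = {t: i for i, t in enumerate(self.ordering)}
        for side, w in self.splits:
            if w < 0:
                raise ValueError("negative split weight")
            if not self._contiguous(sorted(pos[t] for t in side), n):
                raise ValueError(f"split {sorted(side)} not circular-contiguous")

    @staticmethod
    def _contiguous(positions: list[int], n: int) -> bool:
        k = len(positions)
        if k in (0, n):
            return True
        s = set(positions)
        # an arc on the circle: some rotation makes the positions consecutive
        for start in positions:
            if all((start + i) % n in s for i in range(k)):
                return True
        return False

    def induced_distances(self) -> np.ndarray:
        n = len(self.taxa)
        d = np.zeros((n, n))
        for side, w in self.splits:
            mask = np.zeros(n, dtype=bool)
            mask[list(side)] = True
            d[np.ix_(mask, ~mask)] += w
            d[np.ix_(~mask, mask)] += w
        return d


@dataclass
class QuartetScores:
    taxa: list[str]
    delta_overall: float
    delta_per_taxon: np.ndarray
    q_overall: float
    q_per_taxon: np.ndarray
    n_quartets: int


def cognacy_distance(cm: CognacyMatrix) -> DistanceMatrix:
    """d = 1 - shared cognacy.  Undefined pairs are a hard error."""
    und = cm.undefined_pairs()
    if und:
        bad = sorted({t for pair in und for t in pair})
        raise ValueError(f"cognacy undefined for pairs {und}; drop taxa {bad}")
    vals = 1.0 - cm.values
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, None)
    return DistanceMatrix(list(cm.taxa), vals)


# ---------------------------------------------------------------------------
# quartet diagnostics


def _quartet_indices(n: int, max_exhaustive: int, n_sample: int, seed: int):
    if n <= max_exhaustive:
        return np.array(list(combinations(range(n), 4)), dtype=int)
    rng = np.random.default_rng(seed)
    picks = set()
    while len(picks) < n_sample:
        q = rng.choice(n, size=4, replace=False)
        picks.add(tuple(sorted(int(x) for x in q)))
    return np.array(sorted(picks), dtype=int)


def delta_scores(
    d: DistanceMatrix,
    max_exhaustive: int = 45,
    n_sample: int = 100_000,
    seed: int = 0,
) -> QuartetScores:
    """δ-scores and Q-residuals over quartets.

    For a quartet let m1 >= m2 >= m3 be the three pairwise-sum pairings
    d(i,j)+d(k,l), d(i,k)+d(j,l), d(i,l)+d(j,k).  δ = (m1-m2)/(m1-m3)
    (0 when m1 == m3); the Q-residual is (m1-m2)^2 computed on a copy of the
    matrix rescaled to mean off-diagonal distance 1.  Exhaustive enumeration
    up to ``max_exhaustive`` taxa, seeded subsampling above.
    """
    n = len(d.taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    D = d.values
    off = D[np.triu_indices(n, 1)]
    mean_off = off.mean()
    Dq = D / mean_off if mean_off > 0 else D.copy()

    quart = _quartet_indices(n, max_exhaustive, n_sample, seed)
    i, j, k, l = quart.T
    sums = np.stack([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]], axis=1)
    sums_sorted = np.sort(sums, axis=1)[:, ::-1]
    m1, m2, m3 = sums_sorted.T
    span = m1 - m3
    delta = np.where(span > 0, (m1 - m2) / np.where(span > 0, span, 1.0), 0.0)

    qs = np.stack([Dq[i, j] + Dq[k, l], Dq[i, k] + Dq[j, l], Dq[i, l] + Dq[j, k]], axis=1)
    qs_sorted = np.sort(qs, axis=1)[:, ::-1]
    qres = (qs_sorted[:, 0] - qs_sorted[:, 1]) ** 2

    per_d = np.zeros(n)
    per_q = np.zeros(n)
    counts = np.zeros(n)
    for col in (i, j, k, l):
        np.add.at(per_d, col, delta)
        np.add.at(per_q, col, qres)
        np.add.at(counts, col, 1.0)
    counts[counts == 0] = 1.0
    return QuartetScores(
        list(d.taxa),
        float(delta.mean()),
        per_d / counts,
        float(qres.mean()),
        per_q / counts,
        len(quart),
    )


# ---------------------------------------------------------------------------
# NeighborNet


def neighbor_net(d: DistanceMatrix, weight_threshold: float = 1e-6) -> SplitSystem:
    """Build a circular split system by NeighborNet agglomeration + NNLS."""
    n = len(d.taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    ordering = _neighbor_net_ordering(d.values)
    splits = _circular_split_weights(d.values, ordering, weight_threshold)
    return SplitSystem(list(d.taxa), ordering, splits)


def _neighbor_net_ordering(D0: np.ndarray) -> list[int]:
    n = D0.shape[0]
    # distances between all nodes ever created, grown as reductions add nodes
    size = 3 * n + 4
    D = np.zeros((size, size))
    D[:n, :n] = D0
    next_id = n
    nbr: dict[int, int] = {}  # within-cluster link (paths of <=2 active nodes)
    clusters: list[list[int]] = [[i] for i in range(n)]
    stack: list[tuple[int, int, int, int, int]] = []  # (a, b, c, u, v)

    def cluster_dist(c1: list[int], c2: list[int]) -> float:
        return float(np.mean([D[x, y] for x in c1 for y in c2]))

    def active_nodes() -> list[int]:
        return [x for c in clusters for x in c]

    while len(active_nodes()) > 3 and len(clusters) > 1:
        m = len(clusters)
        # step 1: choose the cluster pair by the NJ criterion on averages
        if m > 2:
            cd = np.zeros((m, m))
            for a, b in combinations(range(m), 2):
                cd[a, b] = cd[b, a] = cluster_dist(clusters[a], clusters[b])
            r = cd.sum(axis=1)
            best, best_pair = np.inf, (0, 1)
            for a, b in combinations(range(m), 2):
                q = (m - 2) * cd[a, b] - r[a] - r[b]
                if q < best - 1e-14:
                    best, best_pair = q, (a, b)
            ia, ib = best_pair
        else:
            ia, ib = 0, 1
        C1, C2 = clusters[ia], clusters[ib]
        others = [c for t, c in enumerate(clusters) if t not in (ia, ib)]

        # step 2: choose the node pair, treating the nodes of the two chosen
        # clusters as singleton clusters alongside the remaining clusters
        mhat = len(others) + len(C1) + len(C2)
        local = C1 + C2

        def rsum(x: int) -> float:
            s = sum(cluster_dist([x], c) for c in others)
            s += sum(D[x, z] for z in local if z != x)
            return s

        best, bx, by = np.inf, C1[0], C2[0]
        for x in C1:
            for y in C2:
                q = (mhat - 2) * D[x, y] - rsum(x) - rsum(y)
                if q < best - 1e-14:
                    best, bx, by = q, x, y

        # agglomerate: link bx -- by; reduce any 3-node path immediately
        path: list[int] = []
        if len(C1) == 2:
            path.append([z for z in C1 if z != bx][0])
        path += [bx, by]
        if len(C2) == 2:
            path.append([z for z in C2 if z != by][0])

        clusters = [c for t, c in enumerate(clusters) if t not in (ia, ib)]
        while len(path) > 2:
            a, b, c = path[0], path[1], path[2]
            u, v = next_id, next_id + 1
            next_id += 2
            if next_id > size:
                raise RuntimeError("node budget exceeded")
            act = [x for cl in clusters for x in cl] + path[3:]
            for z in act:
                D[u, z] = D[z, u] = (2.0 * D[a, z] + D[b, z]) / 3.0
                D[v, z] = D[z, v] = (2.0 * D[c, z] + D[b, z]) / 3.0
            D[u, v] = D[v, u] = (D[a, b] + D[b, c] + D[a, c]) / 3.0
            stack.append((a, b, c, u, v))
            path = [u, v] + path[3:]
        nbr[path[0]], nbr[path[1]] = path[1], path[0]
        clusters.append(path)

    # close the remaining paths into a cycle (cluster paths stay contiguous)
    cycle: list[int] = [x for c in clusters for x in c]

    # expand reductions in reverse: replace adjacent (u, v) by (a, b, c)
    for a, b, c, u, v in reversed(stack):
        iu = cycle.index(u)
        iv = cycle.index(v)
        k = len(cycle)
        if (iu + 1) % k == iv:
            cycle = cycle[:iu] + [a, b, c] + cycle[iv + 1:]
        elif (iv + 1) % k == iu:
            cycle = cycle[:iv] + [c, b, a] + cycle[iu + 1:]
        else:  # u, v wrap around the ends of the list
            if iu == k - 1 and iv == 0:
                cycle = [b, c] + cycle[1:-1] + [a]
            elif iv == k - 1 and iu == 0:
                cycle = [b, a] + cycle[1:-1] + [c]
            else:
                raise RuntimeError("expansion lost adjacency")
    assert sorted(cycle) == list(range(n))
    return cycle


def _circular_split_weights(
    D: np.ndarray, ordering: list[int], threshold: float
) -> list[tuple[frozenset, float]]:
    """NNLS estimate of the weights of all splits of the circular ordering."""
    n = len(ordering)
    pairs = list(combinations(range(n), 2))
    pidx = {p: r for r, p in enumerate(pairs)}
    # splits are arcs ordering[i..j-1], 0 <= i < j <= n-1 (one side)
    split_sides: list[list[int]] = []
    for i in range(n):
        for j in range(i + 1, n + (1 if i > 0 else 0)):
            arc = ordering[i:j]
            if 0 < len(arc) < n:
                split_sides.append(arc)
    # deduplicate complements: keep side not containing ordering[0], else smaller
    seen: set[frozenset] = set()
    sides: list[list[int]] = []
    for arc in split_sides:
        key = frozenset(arc)
        comp = frozenset(set(range(n)) - key)
        if key in seen or comp in seen:
            continue
        seen.add(key)
        sides.append(arc)

    A = np.zeros((len(pairs), len(sides)))
    for c, arc in enumerate(sides):
        inside = np.zeros(n, dtype=bool)
        inside[arc] = True
        for (p, q), r in pidx.items():
            if inside[p] != inside[q]:
                A[r, c] = 1.0
    y = np.array([D[p, q] for p, q in pairs])
    w, _ = nnls(A, y)
    out = []
    for c, arc in enumerate(sides):
        if w[c] > threshold:
            out.append((frozenset(arc), float(w[c])))
    return out
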