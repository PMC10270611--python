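"""Metropolis-Hastings sampler over dated trees and model parameters.

The state is (dated topology, per-branch clock rates, covarion parameters,
clock mean/sd, birth-death parameters).  Proposals are the standard tree
moves — uniform node-height slide, whole-tree and root scaling, narrow and
wide exchange — plus multiplier (scale) moves on the scalars.  Constraint
violations are rejected through a -inf prior rather than by restricting the
proposal set, which keeps every move symmetric or with a simple Hastings
term.  Chains are fully reproducible from the configured seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .covarion import CovarionParams, tree_log_likelihood
from .priors import NEG_INF, BirthDeathParams, ClockModel, MCMCConfig, log_prior
from .trees import Tree, random_coalescent_tree
from .wordlist import BinaryMatrix

logger = logging.getLogger(__name__)


@dataclass
class PosteriorTrace:
    iterations: list[int] = field(default_factory=list)
    scalars: dict[str, list[float]] = field(default_factory=dict)
    trees: list[Tree] = field(default_factory=list)
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)

    def record(self, it: int, values: dict[str, float], tree: Tree) -> None:
        if self.iterations and it <= self.iterations[-1]:
            raise ValueError("iterations must be strictly increasing")
        self.iterations.append(it)
        for k, v in values.items():
            self.scalars.setdefault(k, []).append(float(v))
        self.trees.append(tree.copy())

    def array(self, name: str) -> np.ndarray:
        return np.asarray(self.scalars[name])

    def post_burn_in(self, burn_in: float) -> "PosteriorTrace":
        k = int(len(self.iterations) * burn_in)
        out = PosteriorTrace(
            self.iterations[k:],
            {n: v[k:] for n, v in self.scalars.items()},
            self.trees[k:],
            dict(self.acceptance),
        )
        return out


@dataclass
class State:
    tree: Tree
    covarion: CovarionParams
    clock: ClockModel
    bd: BirthDeathParams


def _posterior(state: State, m: BinaryMatrix | None, cfg: MCMCConfig) -> float:
    lp = log_prior(state.tree, state.covarion, state.clock, state.bd, cfg)
    if lp == NEG_INF:
        return NEG_INF
    if m is not None and cfg.use_likelihood:
        strict = state.clock.strict_rate if state.clock.kind == "strict" else None
        lp += tree_log_likelihood(m, state.tree, state.covarion, strict_rate=strict)
    return lp


DEFAULT_WEIGHTS = {
    "node_height": 8.0,
    "root_scale": 2.0,
    "tree_scale": 2.0,
    "up_down": 4.0,
    "narrow_exchange": 6.0,
    "wide_exchange": 2.0,
    "branch_rate": 6.0,
    "clock_mean": 2.0,
    "ucln_sd": 1.0,
    "alpha": 1.5,
    "switch_rate": 1.5,
    "net_div": 1.0,
    "turnover": 1.0,
}


def mcmc_sample(
    m: BinaryMatrix | None,
    cfg: MCMCConfig,
    init: State | None = None,
) -> PosteriorTrace:
    """Run the chain; with ``m`` None (or use_likelihood False) samples the prior."""
    rng = np.random.default_rng(cfg.seed)
    if init is None:
        init = default_init(m, cfg, rng)
    state = State(init.tree.copy(), init.covarion, init.clock, init.bd)
    state.tree.validate()
    logpost = _posterior(state, m, cfg)
    if not np.isfinite(logpost):
        raise ValueError("no valid starting state under the constraints/priors")

    weights = dict(DEFAULT_WEIGHTS)
    weights.update(cfg.operator_weights)
    if not cfg.sample_topology:
        weights["narrow_exchange"] = weights["wide_exchange"] = 0.0
    if cfg.clock_kind == "strict":
        weights["branch_rate"] = weights["ucln_sd"] = 0.0
    names = [k for k, w in weights.items() if w > 0]
    probs = np.array([weights[k] for k in names])
    probs = probs / probs.sum()
    accept = {k: [0, 0] for k in names}

    trace = PosteriorTrace()
    for it in range(cfg.iterations + 1):
        if it % cfg.thinning == 0:
            vals = {
                "posterior": logpost,
                "root_height": float(state.tree.heights[state.tree.root]),
                "alpha": state.covarion.alpha,
                "switch_rate": state.covarion.switch_rate,
                "clock_mean": state.clock.strict_rate if state.clock.kind == "strict" else state.clock.ucln_mean,
                "ucln_sd": state.clock.ucln_stdev,
                "net_div": state.bd.net_diversification,
                "turnover": state.bd.turnover,
            }
            trace.record(it, vals, state.tree)
        if it == cfg.iterations:
            break
        op = names[rng.choice(len(names), p=probs)]
        new_state, log_hastings = _propose(op, state, cfg, rng)
        accept[op][1] += 1
        if new_state is None:
            continue
        new_post = _posterior(new_state, m, cfg)
        if np.isfinite(new_post) and math.log(rng.random()) < new_post - logpost + log_hastings:
            state, logpost = new_state, new_post
            accept[op][0] += 1

    trace.acceptance = {k: (a, n) for k, (a, n) in accept.items()}
    for k, (a, n) in trace.acceptance.items():
        if n:
            logger.info("operator %-16s acceptance %.2f (%d/%d)", k, a / n, a, n)
    return trace


def default_init(m: BinaryMatrix | None, cfg: MCMCConfig, rng: np.random.Generator) -> State:
    if m is None:
        raise ValueError("default initialisation needs a data matrix")
    lo, hi = cfg.root_prior
    root0 = 0.5 * (lo + hi)
    tree = _constrained_start(m, cfg, root0, rng)
    rate0 = 2.0 / root0  # a couple of expected changes root-to-tip
    tree.rates[:] = rate0
    clock = ClockModel(cfg.clock_kind, strict_rate=rate0, ucln_mean=rate0, ucln_stdev=0.3)
    bd = BirthDeathParams(math.log(max(m.n_taxa, 2)) / root0, 0.2)
    return State(tree, CovarionParams(0.5, 0.5), clock, bd)


def _constrained_start(m: BinaryMatrix, cfg: MCMCConfig, root0: float, rng) -> Tree:
    """Random start tree honouring nested monophyly constraints."""
    for _ in range(200):
        tree = random_coalescent_tree(list(m.taxa), root0, rng, m.tip_ages)
        tree = _enforce_constraints(tree, cfg, rng)
        if tree is not None:
            return tree
    raise ValueError("could not build a valid starting tree under the constraints")


def _enforce_constraints(tree: Tree, cfg: MCMCConfig, rng) -> Tree | None:
    if all(tree.is_monophyletic(c.taxa) for c in cfg.constraints):
        ok = True
        for c in cfg.constraints:
            if c.height_range and len(c.taxa) > 1:
                h = tree.mrca_height(c.taxa)
                if not c.height_range[0] <= h <= c.height_range[1]:
                    ok = False
        if ok:
            return tree
    if not cfg.constraints:
        return tree
    # rebuild respecting nesting: join constrained groups bottom-up
    labels = list(tree.labels)
    root_h = float(tree.heights[tree.root])
    groups = sorted([c.taxa for c in cfg.constraints], key=len)
    newick = _grouped_newick(labels, groups, root_h, rng)
    t = Tree.from_newick(newick)
    t.rates[:] = 1.0
    if all(t.is_monophyletic(c.taxa) for c in cfg.constraints):
        # push constrained node heights into their ranges when needed
        clades = t.clades()
        for c in cfg.constraints:
            if c.height_range and len(c.taxa) > 1:
                node = clades[c.taxa]
                lo, hi = c.height_range
                h = t.heights[node]
                if not lo <= h <= hi:
                    _rescale_clade(t, node, 0.5 * (lo + hi))
        try:
            t.validate()
            return t
        except ValueError:
            return None
    return None


def _rescale_clade(t: Tree, node: int, target: float) -> None:
    """Scale heights inside a clade so its MRCA sits at ``target``."""
    h = t.heights[node]
    if h <= 0:
        return
    f = target / h
    stack = [node]
    while stack:
        i = stack.pop()
        if not t.is_tip(i):
            t.heights[i] *= f
            stack.extend(t.children[i])


def _grouped_newick(labels, groups, root_h, rng) -> str:
    # nest each constrained group as a caterpillar, then the remainder
    remaining = set(labels)
    parts: list[tuple[set, str]] = []
    for g in groups:
        sub = [p for p in parts if p[0] <= g]
        used = set().union(*(p[0] for p in sub)) if sub else set()
        loose = sorted(g - used)
        items = [p[1] for p in sub] + loose
        parts = [p for p in parts if not p[0] <= g]
        parts.append((set(g), _caterpillar(items)))
        remaining -= g
    items = [p[1] for p in parts] + sorted(remaining)
    newick = _caterpillar(items)
    # assign depths via unit branch lengths, then rescale: parse & rescale
    t = Tree.from_newick(newick + ";")
    t.heights *= root_h / max(t.heights[t.root], 1e-12)
    return t.to_newick()


def _caterpillar(items: list[str]) -> str:
    out = items[0]
    for it in items[1:]:
        out = f"({out},{it}):1"
    return out.rsplit(":", 1)[0] if len(items) > 1 else out


# ---------------------------------------------------------------------------
# proposals


def _propose(op: str, state: State, cfg: MCMCConfig, rng) -> tuple[State | None, float]:
    t = state.tree
    scale = math.exp(cfg.tuning * (rng.random() - 0.5) * 2)
    # scalar parameters are weakly informed; give them a wide multiplier
    if op in ("branch_rate", "clock_mean", "ucln_sd", "switch_rate", "net_div"):
        scale = math.exp(4.0 * cfg.tuning * (rng.random() - 0.5) * 2)

    if op == "node_height":
        internals = [i for i in range(t.n_nodes) if not t.is_tip(i) and i != t.root]
        if not internals:
            return None, 0.0
        node = internals[rng.integers(len(internals))]
        lo = max(t.heights[c] for c in t.children[node])
        hi = t.heights[t.parent[node]]
        nt = t.copy()
        nt.heights[node] = rng.uniform(lo, hi)
        return State(nt, state.covarion, state.clock, state.bd), 0.0

    if op == "root_scale":
        nt = t.copy()
        lo = max(nt.heights[c] for c in nt.children[nt.root])
        nt.heights[nt.root] = lo + (nt.heights[nt.root] - lo) * scale
        return State(nt, state.covarion, state.clock, state.bd), math.log(scale)

    if op == "tree_scale":
        nt = t.copy()
        internals = [i for i in range(t.n_nodes) if not t.is_tip(i)]
        nt.heights[internals] *= scale
        for i in range(nt.n_nodes):
            if i != nt.root and nt.heights[nt.parent[i]] < nt.heights[i]:
                return None, 0.0
        return State(nt, state.covarion, state.clock, state.bd), len(internals) * math.log(scale)

    if op == "up_down":
        # joint ridge move: stretch time, shrink rates — essential for
        # mixing along the rate-time confounding direction
        nt = t.copy()
        internals = [i for i in range(t.n_nodes) if not t.is_tip(i)]
        nt.heights[internals] *= scale
        for i in range(nt.n_nodes):
            if i != nt.root and nt.heights[nt.parent[i]] < nt.heights[i]:
                return None, 0.0
        nt.rates /= scale
        c = state.clock
        if c.kind == "strict":
            nc = ClockModel("strict", c.strict_rate / scale, c.ucln_mean, c.ucln_stdev)
        else:
            nc = ClockModel(c.kind, c.strict_rate, c.ucln_mean / scale, c.ucln_stdev)
        n_rates = 0 if c.kind == "strict" else t.n_nodes - 1
        log_j = (len(internals) - n_rates - 1) * math.log(scale)
        return State(nt, state.covarion, nc, state.bd), log_j

    if op in ("narrow_exchange", "wide_exchange"):
        nt = t.copy()
        ok = _exchange(nt, rng, wide=(op == "wide_exchange"))
        if not ok:
            return None, 0.0
        return State(nt, state.covarion, state.clock, state.bd), 0.0

    if op == "branch_rate":
        nt = t.copy()
        cand = [i for i in range(t.n_nodes) if i != t.root]
        i = cand[rng.integers(len(cand))]
        nt.rates[i] *= scale
        return State(nt, state.covarion, state.clock, state.bd), math.log(scale)

    if op == "clock_mean":
        c = state.clock
        if c.kind == "strict":
            nc = ClockModel("strict", strict_rate=c.strict_rate * scale,
                            ucln_mean=c.ucln_mean, ucln_stdev=c.ucln_stdev)
        else:
            nc = ClockModel(c.kind, strict_rate=c.strict_rate,
                            ucln_mean=c.ucln_mean * scale, ucln_stdev=c.ucln_stdev)
        return State(t, state.covarion, nc, state.bd), math.log(scale)

    if op == "ucln_sd":
        c = state.clock
        nc = ClockModel(c.kind, c.strict_rate, c.ucln_mean, max(c.ucln_stdev, 1e-3) * scale)
        return State(t, state.covarion, nc, state.bd), math.log(scale)

    if op == "alpha":
        # reflected random walk on (0, 1]
        a = state.covarion.alpha + cfg.tuning * 1.6 * (rng.random() - 0.5) * 2
        a = abs(a)
        if a > 1:
            a = 2 - a
        if not 0 < a <= 1:
            return None, 0.0
        p = state.covarion
        np_ = CovarionParams(a, p.switch_rate, p.visible_freqs, p.hidden_freqs, p.freq_weighted)
        return State(t, np_, state.clock, state.bd), 0.0

    if op == "switch_rate":
        p = state.covarion
        np_ = CovarionParams(p.alpha, max(p.switch_rate, 1e-6) * scale,
                             p.visible_freqs, p.hidden_freqs, p.freq_weighted)
        return State(t, np_, state.clock, state.bd), math.log(scale)

    if op == "net_div":
        bd = BirthDeathParams(state.bd.net_diversification * scale, state.bd.turnover)
        return State(t, state.covarion, state.clock, bd), math.log(scale)

    if op == "turnover":
        v = state.bd.turnover + 0.2 * (rng.random() - 0.5)
        v = abs(v)
        if v >= 1:
            v = 2 - v - 1e-9
        bd = BirthDeathParams(state.bd.net_diversification, min(max(v, 0.0), 1 - 1e-9))
        return State(t, state.covarion, state.clock, bd), 0.0

    raise ValueError(f"unknown operator {op}")


def _exchange(t: Tree, rng, wide: bool) -> bool:
    """Swap two subtrees in place; returns False when no valid move drawn."""
    if wide:
        a = int(rng.integers(t.n_nodes))
        b = int(rng.integers(t.n_nodes))
        if a == b or a == t.root or b == t.root:
            return False
        pa, pb = t.parent[a], t.parent[b]
        if pa == pb:
            return False
        # no ancestor/descendant pairs
        if _is_ancestor(t, a, b) or _is_ancestor(t, b, a):
            return False
        if t.heights[pa] <= t.heights[b] or t.heights[pb] <= t.heights[a]:
            return False
    else:
        # narrow: swap a grandchild with its uncle
        internals = [i for i in range(t.n_nodes)
                     if not t.is_tip(i) and i != t.root and not t.is_tip(t.parent[i])]
        if not internals:
            return False
        c = internals[rng.integers(len(internals))]
        p = t.parent[c]
        uncle = [x for x in t.children[p] if x != c][0]
        g = t.children[c][rng.integers(2)]
        a, b = g, uncle
        pa, pb = c, p
        if t.heights[pa] <= t.heights[b]:
            return False
    # swap
    for par, old, new in ((pa, a, b), (pb, b, a)):
        slot = 0 if t.children[par][0] == old else 1
        t.children[par][slot] = new
    t.parent[a], t.parent[b] = pb, pa
    return True


def _is_ancestor(t: Tree, a: int, b: int) -> bool:
    x = b
    while x != -1:
        if x == a:
            return True
        x = t.parent[x]
    return False
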