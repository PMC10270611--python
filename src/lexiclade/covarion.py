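"""Binary covarion substitution model and tree likelihood.

Cognate presence/absence evolves by a two-state (0 = absent, 1 = present)
process whose speed is governed by a hidden regime: each character is either
"fast" or "slow" and toggles between the regimes at rate ``s``.  The visible
process is symmetric up to the stationary state frequencies; the slow regime
runs at a fraction ``alpha`` of the fast rate.  The full chain therefore has
four states, ordered (0 fast, 1 fast, 0 slow, 1 slow), and its stationary
distribution is the outer product of the visible and hidden frequencies.

The generator is rescaled so that one unit of branch length equals one
expected *visible* substitution at stationarity, which makes clock rates
comparable across parameter values.

Likelihoods use Felsenstein pruning with per-node rescaling; at the tips the
visible state is observed and the hidden regime marginalised; missing cells
contribute a partial of one in every state.  Ascertainment corrects, per
character partition, for the patterns a wordlist can never contain: cognate
sets absent from every language.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig, inv

from .trees import Tree
from .wordlist import ABSENT, MISSING, PRESENT, BinaryMatrix

logger = logging.getLogger(__name__)

N_STATES = 4


@dataclass(frozen=True)
class CovarionParams:
    alpha: float                    # slow/fast rate ratio in (0, 1]
    switch_rate: float              # regime switch rate s > 0 (per unit time)
    visible_freqs: tuple[float, float] = (0.5, 0.5)   # (f0, f1)
    hidden_freqs: tuple[float, float] = (0.5, 0.5)    # (p_fast, p_slow)
    freq_weighted: bool = True      # weight visible moves by target frequency

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        for pair, name in ((self.visible_freqs, "visible"), (self.hidden_freqs, "hidden")):
            if abs(sum(pair) - 1) > 1e-9 or min(pair) < 0:
                raise ValueError(f"{name} frequencies must be nonnegative and sum to 1")
        if not self.freq_weighted and abs(self.visible_freqs[0] - 0.5) > 1e-12:
            raise ValueError("the unweighted dialect requires visible_freqs (0.5, 0.5)")

    @property
    def stationary(self) -> np.ndarray:
        f0, f1 = self.visible_freqs
        pf, ps = self.hidden_freqs
        return np.array([f0 * pf, f1 * pf, f0 * ps, f1 * ps])


def covarion_rate_matrix(p: CovarionParams) -> np.ndarray:
    """4x4 generator, states (0fast, 1fast, 0slow, 1slow), rows sum to 0.

    Rescaled so the expected visible substitution rate at stationarity is 1.
    """
    f0, f1 = p.visible_freqs
    pf, ps = p.hidden_freqs
    s = p.switch_rate
    a = p.alpha
    g01, g10 = (f1, f0) if p.freq_weighted else (1.0, 1.0)
    Q = np.zeros((N_STATES, N_STATES))
    Q[0, 1], Q[1, 0] = g01, g10                 # fast class
    Q[2, 3], Q[3, 2] = a * g01, a * g10         # slow class
    Q[0, 2] = Q[1, 3] = s * ps                  # fast -> slow
    Q[2, 0] = Q[3, 1] = s * pf                  # slow -> fast
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = p.stationary
    visible_rate = pi[0] * Q[0, 1] + pi[1] * Q[1, 0] + pi[2] * Q[2, 3] + pi[3] * Q[3, 2]
    if visible_rate <= 0:
        raise ValueError("degenerate covarion parameters")
    return Q / visible_rate


class TransitionKernel:
    """Eigendecomposition of Q, reused for all branches of one evaluation."""

    def __init__(self, Q: np.ndarray):
        w, U = eig(Q)
        self.w = w
        self.U = U
        self.Uinv = inv(U)

    def probs(self, lengths: np.ndarray) -> np.ndarray:
        """Transition matrices for an array of branch lengths, shape (k,4,4)."""
        lengths = np.asarray(lengths, dtype=float)
        ew = np.exp(np.outer(lengths, self.w))           # (k, 4)
        P = np.einsum("ij,kj,jl->kil", self.U, ew, self.Uinv).real
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


_TIP_PARTIAL = {
    PRESENT: np.array([0.0, 1.0, 0.0, 1.0]),
    ABSENT: np.array([1.0, 0.0, 1.0, 0.0]),
    MISSING: np.ones(4),
}


def _prune(tree: Tree, P: np.ndarray, tip_cells: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Per-character log-likelihoods; tip_cells shape (n_tips, n_chars)."""
    n_chars = tip_cells.shape[1]
    partials = np.empty((tree.n_nodes, n_chars, N_STATES))
    scale = np.zeros(n_chars)
    for node in tree.postorder():
        if tree.is_tip(node):
            cells = tip_cells[node]
            part = np.ones((n_chars, N_STATES))
            part[cells == PRESENT] = _TIP_PARTIAL[PRESENT]
            part[cells == ABSENT] = _TIP_PARTIAL[ABSENT]
            partials[node] = part
        else:
            a, b = tree.children[node]
            part = (partials[a] @ P[a].T) * (partials[b] @ P[b].T)
            mx = part.max(axis=1)
            mx[mx == 0] = 1.0
            partials[node] = part / mx[:, None]
            scale += np.log(mx)
    like = partials[tree.root] @ pi
    return np.log(np.maximum(like, 1e-300)) + scale


def tree_log_likelihood(
    m: BinaryMatrix,
    tree: Tree,
    p: CovarionParams,
    strict_rate: float | None = None,
    ascertainment: bool = True,
) -> float:
    """Ascertainment-corrected covarion log-likelihood of a binary matrix.

    Branch lengths in expected substitutions are (parent height - child
    height) x branch clock rate; ``strict_rate`` overrides the tree's
    per-branch rates with a single value.  The correction conditions, per
    partition, on characters being observable (not absent everywhere):
    log L - N_chars * log(1 - L(all-absent)).
    """
    order = [tree.labels.index(t) for t in m.taxa]
    if sorted(set(order)) != sorted(order) or len(order) != len(m.taxa):
        raise ValueError("matrix taxa must match tree tips one-to-one")
    tip_cells = np.full((tree.n_tips, m.n_chars), MISSING, dtype=np.int8)
    for row, node in enumerate(order):
        tip_cells[node] = m.cells[row]

    all_missing = np.all(tip_cells == MISSING, axis=0)
    if all_missing.any():
        logger.warning("excluding %d all-missing characters", int(all_missing.sum()))
        tip_cells = tip_cells[:, ~all_missing]
    partitions = [p_ for p_, keep in zip(m.partitions, ~all_missing) if keep]

    Q = covarion_rate_matrix(p)
    kernel = TransitionKernel(Q)
    rates = np.full(tree.n_nodes, strict_rate) if strict_rate is not None else tree.rates
    lengths = tree.branch_durations() * rates
    P = kernel.probs(lengths)
    pi = p.stationary

    logL = _prune(tree, P, tip_cells, pi)
    total = float(logL.sum())
    if ascertainment:
        absent = np.full((tree.n_tips, 1), ABSENT, dtype=np.int8)
        log_l0 = float(_prune(tree, P, absent, pi)[0])
        l0 = np.exp(log_l0)
        for label in dict.fromkeys(partitions):
            n_chars = sum(1 for q in partitions if q == label)
            total -= n_chars * np.log1p(-l0)
    return total


def brute_force_log_likelihood(
    m: BinaryMatrix, tree: Tree, p: CovarionParams,
    strict_rate: float | None = None, ascertainment: bool = False,
) -> float:
    """Oracle: enumerate all internal-state assignments (tiny trees only)."""
    from itertools import product

    Q = covarion_rate_matrix(p)
    kernel = TransitionKernel(Q)
    rates = np.full(tree.n_nodes, strict_rate) if strict_rate is not None else tree.rates
    P = kernel.probs(tree.branch_durations() * rates)
    pi = p.stationary
    order = [tree.labels.index(t) for t in m.taxa]
    internals = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]

    def char_like(col: np.ndarray) -> float:
        tipstates: dict[int, list[int]] = {}
        for row, node in enumerate(order):
            c = col[row]
            tipstates[node] = {PRESENT: [1, 3], ABSENT: [0, 2], MISSING: [0, 1, 2, 3]}[c]
        total = 0.0
        for assign in product(range(N_STATES), repeat=len(internals)):
            st = dict(zip(internals, assign))
            for tipchoice in product(*(tipstates[t] for t in range(tree.n_tips))):
                states = dict(st)
                states.update({t: s for t, s in enumerate(tipchoice)})
                pr = pi[states[tree.root]]
                for i in range(tree.n_nodes):
                    if i != tree.root:
                        pr *= P[i][states[tree.parent[i]], states[i]]
                total += pr
        return total

    total = sum(np.log(char_like(m.cells[:, j])) for j in range(m.n_chars))
    if ascertainment:
        absent_col = np.full(m.n_taxa, ABSENT, dtype=np.int8)
        l0 = char_like(absent_col)
        total -= m.n_chars * np.log1p(-l0)
    return float(total)
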