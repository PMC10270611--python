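"""Priors for the dated-tree model.

The joint prior combines: a birth-death density over the dated topology
(conditioned on the number of tips and the root age, complete sampling), a
uniform root-age prior on user-supplied bounds, monophyly constraints
(optionally with uniform height ranges), a lognormal density over branch
clock rates (the uncorrelated relaxed clock), and weakly informative
defaults over the scalar parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import expon, lognorm

from .covarion import CovarionParams
from .trees import Tree

NEG_INF = float("-inf")


@dataclass(frozen=True)
class BirthDeathParams:
    net_diversification: float      # lambda - mu > 0, per year
    turnover: float = 0.0           # mu / lambda in [0, 1)

    def __post_init__(self) -> None:
        if self.net_diversification <= 0:
            raise ValueError("net diversification must be > 0")
        if not 0 <= self.turnover < 1:
            raise ValueError("turnover must be in [0, 1)")

    @property
    def birth(self) -> float:
        return self.net_diversification / (1.0 - self.turnover)

    @property
    def death(self) -> float:
        return self.birth * self.turnover


@dataclass(frozen=True)
class ClockModel:
    kind: str = "ucln"              # "strict" | "ucln"
    strict_rate: float = 1.0
    ucln_mean: float = 1.0
    ucln_stdev: float = 0.5         # stdev of log rate

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "ucln"):
            raise ValueError("clock kind must be 'strict' or 'ucln'")
        if self.strict_rate <= 0 or self.ucln_mean <= 0 or self.ucln_stdev < 0:
            raise ValueError("invalid clock parameters")


@dataclass
class Constraint:
    taxa: frozenset
    height_range: Optional[tuple[float, float]] = None  # (younger, older) BP


@dataclass
class MCMCConfig:
    iterations: int = 200_000
    thinning: int = 100
    seed: int = 1
    burn_in: float = 0.5
    root_prior: tuple[float, float] = (1500.0, 5000.0)
    constraints: list[Constraint] = field(default_factory=list)
    operator_weights: dict[str, float] = field(default_factory=dict)
    sample_topology: bool = True
    clock_kind: str = "ucln"
    use_likelihood: bool = True
    tuning: float = 0.25            # log-scale window of scale moves
    # lognormal prior (median, log-sd) on the mean clock rate; None = flat
    clock_mean_prior: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")
        lo, hi = self.root_prior
        if not lo < hi:
            raise ValueError("root prior lower bound must be below upper")
        self.validate_constraints()

    def validate_constraints(self) -> None:
        sets = [c.taxa for c in self.constraints]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                a, b = sets[i], sets[j]
                if a & b and not (a <= b or b <= a):
                    raise ValueError(
                        f"constraints {sorted(a)} and {sorted(b)} overlap without nesting"
                    )


def birth_death_log_density(tree: Tree, bd: BirthDeathParams) -> float:
    """Log density of the non-root node heights given n tips and root age.

    Conditioned reconstructed birth-death process with complete sampling:
    the interior speciation times are iid on (0, T) with density
    g(t) = v'(t) / V(T),  v'(t) = r (1-a) e^{-rt} / (1 - a e^{-rt})^2,
    where r is the net diversification and a the turnover.  Reduces to the
    truncated exponential pure-birth density when a = 0.
    """
    r, a = bd.net_diversification, bd.turnover
    T = tree.heights[tree.root]
    internal = [i for i in range(tree.n_nodes)
                if not tree.is_tip(i) and i != tree.root]
    if not internal:
        return 0.0
    t = tree.heights[internal]
    if np.any(t >= T) or np.any(t < 0):
        return NEG_INF
    ert = np.exp(-r * t)
    num = np.log(r * (1 - a)) - r * t - 2 * np.log1p(-a * ert)
    V = (1 - math.exp(-r * T)) / (1 - a * math.exp(-r * T))
    return float(num.sum() - len(internal) * math.log(V))


def clock_log_density(tree: Tree, clock: ClockModel) -> float:
    """Lognormal branch-rate density (ucln); 0 for a strict clock."""
    if clock.kind == "strict":
        return 0.0
    rates = np.delete(tree.rates, tree.root)
    if np.any(rates <= 0):
        return NEG_INF
    if clock.ucln_stdev == 0:
        return 0.0 if np.allclose(rates, clock.ucln_mean) else NEG_INF
    sd = clock.ucln_stdev
    mu = math.log(clock.ucln_mean) - 0.5 * sd * sd   # E[rate] = ucln_mean
    return float(lognorm.logpdf(rates, s=sd, scale=math.exp(mu)).sum())


def log_prior(
    tree: Tree,
    p: CovarionParams,
    clock: ClockModel,
    bd: BirthDeathParams,
    cfg: MCMCConfig,
) -> float:
    """Joint log prior; -inf when bounds or constraints are violated."""
    lo, hi = cfg.root_prior
    root_h = tree.heights[tree.root]
    if not lo <= root_h <= hi:
        return NEG_INF
    total = -math.log(hi - lo)
    clades = tree.clades()
    for c in cfg.constraints:
        if len(c.taxa) > 1 and c.taxa not in clades:
            return NEG_INF
        if c.height_range is not None:
            node = clades[c.taxa] if len(c.taxa) > 1 else None
            h = tree.heights[node] if node is not None else 0.0
            ylo, yhi = c.height_range
            if not ylo <= h <= yhi:
                return NEG_INF
            total -= math.log(yhi - ylo)
    total += birth_death_log_density(tree, bd)
    total += clock_log_density(tree, clock)
    # scalar parameter defaults: alpha ~ U(0,1]; s ~ Exp(1);
    # ucln sd ~ Exp(mean 1/3); net diversification ~ Exp anchored at the
    # root-prior midpoint; turnover ~ U[0,1); optional lognormal prior on
    # the mean clock rate via cfg.clock_mean_prior
    total += float(expon.logpdf(p.switch_rate, scale=1.0))
    total += float(expon.logpdf(clock.ucln_stdev, scale=1.0 / 3.0))
    n = tree.n_tips
    # anchor the diversification prior at the root-prior midpoint so the
    # scalar priors stay independent of the sampled heights
    div_scale = max(math.log(n) / (0.5 * (lo + hi)), 1e-12)
    total += float(expon.logpdf(bd.net_diversification, scale=div_scale))
    if cfg.clock_mean_prior is not None:
        med, lsd = cfg.clock_mean_prior
        mean_rate = clock.strict_rate if clock.kind == "strict" else clock.ucln_mean
        total += float(lognorm.logpdf(mean_rate, s=lsd, scale=med))
    return total
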