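"""Posterior summaries: MCC tree with common-ancestor heights, HPD, ESS."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .mcmc import PosteriorTrace
from .trees import Tree

logger = logging.getLogger(__name__)


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = max(int(np.ceil(mass * n)), 1)  # points inside the interval
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass
class CladeSummary:
    taxa: frozenset
    support: float
    mean_height: float
    hpd: tuple[float, float]


@dataclass
class MCCResult:
    tree: Tree
    clades: list[CladeSummary]

    def support_of(self, taxa: frozenset) -> float:
        for c in self.clades:
            if c.taxa == taxa:
                return c.support
        return 0.0


def mcc_tree(trace: PosteriorTrace, burn_in: float = 0.5) -> MCCResult:
    """Maximum clade credibility tree with common-ancestor heights.

    Clade posterior = fraction of post-burn-in trees containing the clade;
    the MCC topology maximises the product of its clades' posteriors among
    the sampled topologies.  Node heights are common-ancestor heights: for
    each clade of the MCC tree, the mean over ALL post-burn-in trees of the
    MRCA height of that clade's taxon set, with a 95% HPD alongside.
    """
    post = trace.post_burn_in(burn_in)
    trees = post.trees
    if not trees:
        raise ValueError("no post-burn-in trees in trace")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for clade in t.clades():
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)

    best, best_score = None, -np.inf
    for t in trees:
        score = sum(np.log(counts[c] / n) for c in t.clades())
        if score > best_score:
            best, best_score = t, score

    mcc = best.copy()
    clades_nodes = mcc.clades()
    summaries = []
    for clade, node in clades_nodes.items():
        heights = np.array([t.mrca_height(clade) for t in trees])
        mean_h = float(heights.mean())
        mcc.heights[node] = mean_h
        summaries.append(
            CladeSummary(clade, counts.get(clade, 0) / n, mean_h, hpd_interval(heights, 0.95))
        )
    # common-ancestor heights can invert parent/child order; flatten gently
    for node in mcc.postorder():
        if node != mcc.root and not mcc.is_tip(node):
            p = mcc.parent[node]
            if mcc.heights[p] <= mcc.heights[node]:
                mcc.heights[p] = mcc.heights[node] + 1e-9
    summaries.sort(key=lambda c: -len(c.taxa))
    return MCCResult(mcc, summaries)


def ess(trace_or_samples, statistic: str | None = None) -> float:
    """Autocorrelation-time effective sample size of one scalar series.

    Accepts either a PosteriorTrace plus the statistic name, or a bare
    sequence of samples.  A constant series has no information about mixing
    and is reported as 1 with a warning.
    """
    import arviz

    if statistic is not None:
        x = np.asarray(trace_or_samples.scalars[statistic], dtype=float)
    else:
        x = np.asarray(trace_or_samples, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if np.allclose(x, x[0]):
        logger.warning("constant series: ESS reported as 1")
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        val = float(arviz.ess(arviz.convert_to_dataset(x[None, :]))["x"])
    if not np.isfinite(val):
        return 1.0
    return val
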