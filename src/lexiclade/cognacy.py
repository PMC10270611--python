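"""Descriptive statistics of cognate-coded data.

Three quantities characterise how tree-like and how diverse a cognate-coded
wordlist is before any phylogenetic inference:

* pairwise shared cognacy — for two languages, the fraction of mutually
  attested concepts on which they share at least one cognate set;
* cognacy diversity — D = (C - M) / (W - M), with C distinct cognate sets,
  M concepts and W distinct coded words; 0 when every concept is fully
  cognate across the sample, 1 when every word is an isolate;
* TIGER rates — per-concept agreement between the taxon partition induced
  by a concept's cognate sets and the partitions induced by every other
  concept; low values flag homoplasy or borrowing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .wordlist import Wordlist

logger = logging.getLogger(__name__)

#: marker for statistics that are undefined on the given input
UNDEFINED = float("nan")


@dataclass
class CognacyMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, diagonal 1, NaN where undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape mismatch")

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in combinations(range(len(self.taxa)), 2):
            if math.isnan(self.values[i, j]):
                out.append((self.taxa[i], self.taxa[j]))
        return out


@dataclass
class TigerReport:
    concepts: list[str]
    scores: np.ndarray
    excluded: list[str]

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores)) if len(self.scores) else UNDEFINED

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else 0.0


def _sets_by_concept(w: Wordlist) -> dict[str, dict[str, set[int]]]:
    out: dict[str, dict[str, set[int]]] = {c: {} for c in w.concepts}
    for e in w.entries:
        out[e.concept_id].setdefault(e.doculect_id, set()).add(e.cognate_set_id)
    return out


def pairwise_cognacy(w: Wordlist, a: str, b: str) -> float:
    """Fraction of mutually attested concepts on which a and b share a set.

    Returns NaN (undefined) when the two doculects attest no common concept.
    """
    ids = set(w.doculect_ids)
    for x in (a, b):
        if x not in ids:
            raise KeyError(f"unknown doculect {x!r}")
    shared = 0
    common = 0
    for concept, bysets in _sets_by_concept(w).items():
        if a in bysets and b in bysets:
            common += 1
            if bysets[a] & bysets[b]:
                shared += 1
    if common == 0:
        return UNDEFINED
    return shared / common


def cognacy_matrix(w: Wordlist) -> CognacyMatrix:
    taxa = w.doculect_ids
    n = len(taxa)
    vals = np.ones((n, n))
    by_concept = _sets_by_concept(w)
    for i, j in combinations(range(n), 2):
        a, b = taxa[i], taxa[j]
        shared = common = 0
        for bysets in by_concept.values():
            if a in bysets and b in bysets:
                common += 1
                if bysets[a] & bysets[b]:
                    shared += 1
        v = shared / common if common else UNDEFINED
        vals[i, j] = vals[j, i] = v
    cm = CognacyMatrix(taxa, vals)
    und = cm.undefined_pairs()
    if und:
        logger.warning("pairwise cognacy undefined for %d pairs (no shared concepts)", len(und))
    return cm


def cognacy_diversity(w: Wordlist) -> float:
    """D = (C - M) / (W - M).

    C = distinct cognate sets, M = concepts, W = distinct (doculect, concept,
    set) coded words.  Undefined (NaN) when W == M.
    """
    if len(w.doculects) < 2:
        raise ValueError("need at least 2 doculects")
    coded = {(e.doculect_id, e.concept_id, e.cognate_set_id) for e in w.entries}
    C = len({e.cognate_set_id for e in w.entries})
    M = len({e.concept_id for e in w.entries})
    W = len(coded)
    if W == M:
        return UNDEFINED
    return (C - M) / (W - M)


# ---------------------------------------------------------------------------
# TIGER rates


def _state_sets(w: Wordlist, soft_synonyms: bool = True) -> dict[str, list[set[str]]]:
    """Concept -> list of taxon sets, one per cognate set (the 'states').

    With ``soft_synonyms`` a taxon holding several sets of one concept is a
    member of each corresponding state set; otherwise only the first-listed
    entry counts.
    """
    out: dict[str, list[set[str]]] = {}
    for concept, bysets in _sets_by_concept(w).items():
        per_state: dict[int, set[str]] = {}
        for taxon, sets in bysets.items():
            chosen = sorted(sets) if soft_synonyms else sorted(sets)[:1]
            for s in chosen:
                per_state.setdefault(s, set()).add(taxon)
        if per_state:
            out[concept] = [per_state[k] for k in sorted(per_state)]
    return out


def _pa(states_i: list[set[str]], states_j: list[set[str]]) -> float:
    """Partition agreement of character i with character j, pa(i -> j).

    Restricted to taxa non-missing in both characters; mean over j's states
    of the best overlap fraction with any of i's states.
    """
    taxa_i = set().union(*states_i)
    taxa_j = set().union(*states_j)
    both = taxa_i & taxa_j
    if not both:
        return float("nan")
    vals = []
    for s in states_j:
        s_b = s & both
        if not s_b:
            continue
        best = max(len(s_b & (t & both)) / len(s_b) for t in states_i)
        vals.append(best)
    return float(np.mean(vals)) if vals else float("nan")


def tiger_rates(w: Wordlist, soft_synonyms: bool = True) -> TigerReport:
    """Per-concept TIGER rates: rate(j) = mean over i != j of pa(i -> j)."""
    if len(w.doculects) < 3:
        raise ValueError("need at least 3 doculects")
    states = _state_sets(w, soft_synonyms)
    excluded = []
    usable: dict[str, list[set[str]]] = {}
    for c, st in states.items():
        if len(set().union(*st)) < 2:
            excluded.append(c)
            logger.info("TIGER: concept %s excluded (<2 non-missing taxa)", c)
        else:
            usable[c] = st
    concepts = sorted(usable)
    if len(concepts) < 2:
        raise ValueError("need at least 2 usable concepts")
    scores = []
    for j in concepts:
        pas = [p for i in concepts if i != j
               for p in [_pa(usable[i], usable[j])] if not math.isnan(p)]
        scores.append(float(np.mean(pas)) if pas else float("nan"))
    arr = np.array(scores)
    keep = ~np.isnan(arr)
    return TigerReport([c for c, k in zip(concepts, keep) if k], arr[keep], excluded)
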