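"""Cognate-coded wordlists and their binary encoding.

A wordlist is a set of (doculect, concept, form, cognate-set) records, the
standard "root-meaning" coding of comparative lexical data: each cognate set
groups the reflexes of one ancestral root *within one concept*, so the same
set id never appears under two concepts.  The binary encoding turns every
cognate set into a presence/absence character, with three-valued cells:
present, absent (the doculect attests the concept but with other roots) and
missing (the concept is unattested for the doculect).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# cell codes of a BinaryMatrix
ABSENT = 0
PRESENT = 1
MISSING = -1


@dataclass(frozen=True)
class Doculect:
    """A documented language variety treated as a taxon."""

    id: str
    glottocode: Optional[str] = None
    coverage: float = 1.0
    tip_age: float = 0.0
    location: Optional[tuple[float, float]] = None  # (lat, lon) degrees

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must be in [0,1], got {self.coverage}")
        if self.tip_age < 0:
            raise ValueError("tip_age must be >= 0 years BP")
        if self.location is not None:
            lat, lon = self.location
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"invalid location {self.location}")


@dataclass(frozen=True)
class LexicalEntry:
    doculect_id: str
    concept_id: str
    form: str
    cognate_set_id: int


@dataclass
class Wordlist:
    """Validated collection of doculects, concepts and coded entries."""

    doculects: list[Doculect]
    concepts: list[str]
    entries: list[LexicalEntry]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [d.id for d in self.doculects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doculect ids")
        known_d, known_c = set(ids), set(self.concepts)
        set2concept: dict[int, str] = {}
        for e in self.entries:
            if e.doculect_id not in known_d:
                raise ValueError(f"entry references unknown doculect {e.doculect_id!r}")
            if e.concept_id not in known_c:
                raise ValueError(f"entry references unknown concept {e.concept_id!r}")
            prev = set2concept.setdefault(e.cognate_set_id, e.concept_id)
            if prev != e.concept_id:
                raise ValueError(
                    f"cognate set {e.cognate_set_id} appears under two concepts "
                    f"({prev!r} and {e.concept_id!r}); root-meaning coding requires "
                    "set ids scoped to a single concept"
                )

    # -- convenience views -------------------------------------------------
    @property
    def doculect_ids(self) -> list[str]:
        return [d.id for d in self.doculects]

    def attested_concepts(self, doculect_id: str) -> set[str]:
        return {e.concept_id for e in self.entries if e.doculect_id == doculect_id}

    def concept_sets(self, concept_id: str) -> dict[str, set[int]]:
        """doculect -> cognate sets attested for one concept."""
        out: dict[str, set[int]] = {}
        for e in self.entries:
            if e.concept_id == concept_id:
                out.setdefault(e.doculect_id, set()).add(e.cognate_set_id)
        return out

    def recompute_coverages(self) -> "Wordlist":
        """Return a copy whose doculect coverages match the entries."""
        total = max(len(self.concepts), 1)
        att = {d.id: len(self.attested_concepts(d.id)) for d in self.doculects}
        docs = [replace(d, coverage=att[d.id] / total) for d in self.doculects]
        return Wordlist(docs, list(self.concepts), list(self.entries))


@dataclass
class BinaryMatrix:
    """Taxa x cognate-set presence/absence matrix with missing mask.

    ``cells`` uses the codes ABSENT=0, PRESENT=1, MISSING=-1.  Characters are
    cognate sets, ordered; ``char_concepts`` maps each character to its
    concept and ``partitions`` to a partition label.
    """

    taxa: list[str]
    characters: list[int]
    char_concepts: list[str]
    cells: np.ndarray  # int8, shape (n_taxa, n_chars)
    partitions: list[str] = field(default_factory=list)
    tip_ages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("cells shape mismatch")
        if not self.partitions:
            self.partitions = ["all"] * len(self.characters)
        bad = ~np.isin(self.cells, (ABSENT, PRESENT, MISSING))
        if bad.any():
            raise ValueError("cells must be 0, 1 or -1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.characters)

    def partition_labels(self) -> list[str]:
        seen: "OrderedDict[str, None]" = OrderedDict()
        for p in self.partitions:
            seen.setdefault(p)
        return list(seen)

    def partition_columns(self, label: str) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.partitions) if p == label])

    def drop_singletons(self) -> "BinaryMatrix":
        """Remove characters present in exactly one taxon."""
        keep = (self.cells == PRESENT).sum(axis=0) > 1
        return BinaryMatrix(
            list(self.taxa),
            [c for c, k in zip(self.characters, keep) if k],
            [c for c, k in zip(self.char_concepts, keep) if k],
            self.cells[:, keep],
            [p for p, k in zip(self.partitions, keep) if k],
            dict(self.tip_ages),
        )


# ---------------------------------------------------------------------------
# reading


def read_wordlist(path, metadata=None) -> Wordlist:
    """Read a tab-separated cognate-coded wordlist.

    The file must have a header row with columns for the doculect, the
    concept, the phonetic form and the cognate-set id (case-insensitive
    matching on common column names).  Rows with an empty cognate id are
    dropped and counted in the log; exact duplicate (doculect, concept, set)
    triples are deduplicated with a warning.  ``metadata`` is an optional TSV
    with per-doculect columns (glottocode, tip_age, lat, lon) joined on id.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return Wordlist([], [], [])
    if df.empty and len(df.columns) == 0:
        return Wordlist([], [], [])

    cols = {c.lower().strip(): c for c in df.columns}

    def pick(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"missing required column (one of {names}) in {path}")

    c_doc = pick("doculect", "language", "doculect_id", "language_id")
    c_con = pick("concept", "parameter", "concept_id", "meaning")
    c_cog = pick("cognate set", "cognacy", "cognate_set", "cognateset_id", "cogid")
    try:
        c_form = pick("phonetic form", "form", "value", "segments")
    except ValueError:
        c_form = None

    n_dropped = (df[c_cog].str.strip() == "").sum()
    if n_dropped:
        logger.info("dropped %d rows with empty cognate id", n_dropped)
    df = df[df[c_cog].str.strip() != ""]

    entries: list[LexicalEntry] = []
    seen: set[tuple[str, str, int]] = set()
    n_dup = 0
    for _, row in df.iterrows():
        cid = int(str(row[c_cog]).strip())
        key = (row[c_doc].strip(), row[c_con].strip(), cid)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        entries.append(
            LexicalEntry(key[0], key[1], str(row[c_form]).strip() if c_form else "", cid)
        )
    if n_dup:
        logger.warning("deduplicated %d repeated (doculect, concept, cognate) rows", n_dup)

    doc_ids = sorted({e.doculect_id for e in entries})
    concepts = sorted({e.concept_id for e in entries})

    meta: dict[str, dict] = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata, sep="\t", dtype=str, keep_default_na=False)
        mcols = {c.lower().strip(): c for c in mdf.columns}
        idcol = next(mcols[k] for k in ("doculect", "id", "language") if k in mcols)
        for _, row in mdf.iterrows():
            rec: dict = {}
            if "glottocode" in mcols and row[mcols["glottocode"]].strip():
                rec["glottocode"] = row[mcols["glottocode"]].strip()
            if "tip_age" in mcols and row[mcols["tip_age"]].strip():
                rec["tip_age"] = float(row[mcols["tip_age"]])
            if "lat" in mcols and "lon" in mcols and row[mcols["lat"]].strip():
                rec["location"] = (float(row[mcols["lat"]]), float(row[mcols["lon"]]))
            meta[row[idcol].strip()] = rec

    docs = [Doculect(d, **meta.get(d, {})) for d in doc_ids]
    wl = Wordlist(docs, concepts, entries)
    return wl.recompute_coverages()


# ---------------------------------------------------------------------------
# filtering / encoding


def filter_by_missingness(w: Wordlist, max_missing: float) -> Wordlist:
    """Keep concepts attested in at least (1 - max_missing) of the doculects.

    Matches the study design of filtering the full concept pool so that each
    retained concept is missing in at most ``max_missing`` of the languages.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0,1]")
    n = len(w.doculects)
    if n == 0:
        return Wordlist([], [], [])
    need = (1.0 - max_missing) * n
    att: dict[str, set[str]] = {c: set() for c in w.concepts}
    for e in w.entries:
        att[e.concept_id].add(e.doculect_id)
    # tolerance guards the exact-boundary case (e.g. 8 of 10 at 20%)
    kept = [c for c in w.concepts if len(att[c]) >= need - 1e-9]
    kset = set(kept)
    entries = [e for e in w.entries if e.concept_id in kset]
    return Wordlist(list(w.doculects), kept, entries).recompute_coverages()


def filter_concepts(w: Wordlist, concepts: Sequence[str]) -> Wordlist:
    """Restrict to a named concept list (e.g. a Swadesh subset)."""
    missing = [c for c in concepts if c not in set(w.concepts)]
    if missing:
        raise ValueError(f"concepts not in wordlist: {missing}")
    kset = set(concepts)
    entries = [e for e in w.entries if e.concept_id in kset]
    return Wordlist(list(w.doculects), [c for c in w.concepts if c in kset], entries).recompute_coverages()


def encode_binary(w: Wordlist, drop_singletons: bool = False) -> BinaryMatrix:
    """Encode a wordlist as presence/absence characters, one per cognate set.

    A doculect with synonyms in several sets of one concept is PRESENT on all
    of them; a doculect that does not attest a concept at all is MISSING on
    every character of that concept.
    """
    taxa = w.doculect_ids
    tindex = {t: i for i, t in enumerate(taxa)}
    # characters grouped by concept, sets sorted within concept
    chars: list[int] = []
    char_concepts: list[str] = []
    for concept in w.concepts:
        sets = sorted({e.cognate_set_id for e in w.entries if e.concept_id == concept})
        chars.extend(sets)
        char_concepts.extend([concept] * len(sets))
    cindex = {c: j for j, c in enumerate(chars)}

    cells = np.full((len(taxa), len(chars)), MISSING, dtype=np.int8)
    # attested concept => absent baseline on its characters
    for e in w.entries:
        i = tindex[e.doculect_id]
        for j, cc in enumerate(char_concepts):
            if cc == e.concept_id and cells[i, j] == MISSING:
                cells[i, j] = ABSENT
    for e in w.entries:
        cells[tindex[e.doculect_id], cindex[e.cognate_set_id]] = PRESENT

    tip_ages = {d.id: d.tip_age for d in w.doculects}
    m = BinaryMatrix(taxa, chars, char_concepts, cells, tip_ages=tip_ages)
    return m.drop_singletons() if drop_singletons else m


def partition_characters(m: BinaryMatrix, k: int = 2) -> BinaryMatrix:
    """Assign whole concepts to k partitions balancing character counts.

    Greedy descending-size bin balancing: concepts sorted by (character
    count desc, concept id) each go to the currently lightest partition.
    Deterministic; never splits a concept across partitions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    concepts = list(dict.fromkeys(m.char_concepts))
    if k > len(concepts):
        raise ValueError(f"cannot make {k} partitions from {len(concepts)} concepts")
    sizes = {c: m.char_concepts.count(c) for c in concepts}
    order = sorted(concepts, key=lambda c: (-sizes[c], c))
    loads = [0] * k
    assign: dict[str, int] = {}
    for c in order:
        b = min(range(k), key=lambda i: (loads[i], i))
        assign[c] = b
        loads[b] += sizes[c]
    partitions = [f"p{assign[c] + 1}" for c in m.char_concepts]
    return BinaryMatrix(
        list(m.taxa), list(m.characters), list(m.char_concepts), m.cells.copy(),
        partitions, dict(m.tip_ages),
    )
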