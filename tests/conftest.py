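import numpy as np
import pytest

from lexiclade.trees import Tree
from lexiclade.wordlist import Doculect, LexicalEntry, Wordlist


@pytest.fixture
def bat_wordlist() -> Wordlist:
    """The five-row cognacy sample: one concept (BAT), three cognate sets."""
    rows = [
        ("Tupinamba", "BAT", "anɨra", 171),
        ("Wayampi", "BAT", "anɨla", 171),
        ("Guarani", "BAT", "mopi", 172),
        ("Kaiowa", "BAT", "bopiri", 172),
        ("Mawe", "BAT", "hakiʔi", 4513),
    ]
    docs = sorted({r[0] for r in rows})
    return Wordlist(
        [Doculect(d) for d in docs],
        ["BAT"],
        [LexicalEntry(*r) for r in rows],
    )


@pytest.fixture
def toy3_wordlist() -> Wordlist:
    """3 languages, 2 concepts: pairwise cognacy (A,B)=0.5 (B,C)=0.5 (A,C)=0."""
    entries = [
        LexicalEntry("A", "C1", "", 1),
        LexicalEntry("B", "C1", "", 1),
        LexicalEntry("C", "C1", "", 2),
        LexicalEntry("A", "C2", "", 3),
        LexicalEntry("B", "C2", "", 4),
        LexicalEntry("C", "C2", "", 4),
    ]
    return Wordlist([Doculect(x) for x in "ABC"], ["C1", "C2"], entries)


@pytest.fixture
def tree5() -> Tree:
    """Ultrametric 5-taxon tree with known branch lengths."""
    t = Tree.from_newick("((A:1,B:1):2,((C:0.5,D:0.5):1.5,E:2):1);")
    t.rates[:] = 1.0
    return t


@pytest.fixture
def tree4() -> Tree:
    t = Tree.from_newick("((A:0.3,B:0.5):0.4,(C:0.2,D:0.9):0.1);")
    t.rates[:] = 1.0
    return t


def tree_metric(tree: Tree) -> np.ndarray:
    """Additive (path-length) distances between the tips of a dated tree."""
    n = tree.n_tips
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset([tree.labels[i], tree.labels[j]])
            h = tree.mrca_height(pair)
            d[i, j] = d[j, i] = 2 * h - tree.heights[i] - tree.heights[j]
    return d
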