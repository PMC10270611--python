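import numpy as np
import pytest

from lexiclade.wordlist import (
    ABSENT,
    MISSING,
    PRESENT,
    Doculect,
    LexicalEntry,
    Wordlist,
    encode_binary,
    filter_by_missingness,
    partition_characters,
    read_wordlist,
)


def write_tsv(path, rows, header="doculect\tconcept\tform\tcognate set"):
    path.write_text(header + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")


class TestReadWordlist:
    def test_cognacy_sample_rows(self, tmp_path, bat_wordlist):
        f = tmp_path / "w.tsv"
        write_tsv(f, [(e.doculect_id, e.concept_id, e.form, e.cognate_set_id)
                      for e in bat_wordlist.entries])
        w = read_wordlist(f)
        assert len(w.entries) == 5
        assert w.concepts == ["BAT"]
        assert {e.cognate_set_id for e in w.entries} == {171, 172, 4513}

    def test_empty_file(self, tmp_path):
        f = tmp_path / "e.tsv"
        f.write_text("")
        w = read_wordlist(f)
        assert w.doculects == [] and w.entries == []

    def test_set_under_two_concepts_is_hard_error(self, tmp_path):
        f = tmp_path / "bad.tsv"
        write_tsv(f, [("A", "BAT", "x", 171), ("A", "LEG", "y", 171)])
        with pytest.raises(ValueError, match="171"):
            read_wordlist(f)

    def test_rows_with_empty_cognate_id_dropped_and_duplicates_merged(self, tmp_path):
        f = tmp_path / "w.tsv"
        write_tsv(f, [("A", "BAT", "x", 171), ("A", "BAT", "x2", 171),
                      ("B", "BAT", "y", ""), ("B", "BAT", "z", 172)])
        w = read_wordlist(f)
        assert len(w.entries) == 2

    def test_metadata_join(self, tmp_path):
        f = tmp_path / "w.tsv"
        write_tsv(f, [("A", "BAT", "x", 1), ("B", "BAT", "y", 2)])
        meta = tmp_path / "m.tsv"
        meta.write_text("doculect\tglottocode\ttip_age\tlat\tlon\n"
                        "A\taaaa1234\t350\t-10.5\t-55.0\n")
        w = read_wordlist(f, meta)
        a = next(d for d in w.doculects if d.id == "A")
        assert a.glottocode == "aaaa1234"
        assert a.tip_age == 350
        assert a.location == (-10.5, -55.0)


class TestFilterByMissingness:
    @staticmethod
    def staircase(n_docs=5):
        """Concept Ck attested in the first (n_docs - k) doculects."""
        docs = [f"D{i}" for i in range(n_docs)]
        entries = []
        sid = 1
        for k in range(n_docs):
            for i in range(n_docs - k):
                entries.append(LexicalEntry(docs[i], f"C{k}", "", sid))
            sid += 1
        return Wordlist([Doculect(d) for d in docs], [f"C{k}" for k in range(n_docs)], entries)

    def test_boundary_kept(self):
        docs = [f"D{i}" for i in range(10)]
        entries = [LexicalEntry(d, "C", "", 1) for d in docs[:8]]
        w = Wordlist([Doculect(d) for d in docs], ["C"], entries)
        assert filter_by_missingness(w, 0.2).concepts == ["C"]   # 8 >= 8
        assert filter_by_missingness(w, 0.1).concepts == []      # 8 < 9

    def test_staircase_counts(self):
        w = self.staircase(5)  # attested in 5,4,3,2,1 of 5
        kept = filter_by_missingness(w, 0.3).concepts
        assert len(kept) == 2  # need >= 3.5 attestations

    def test_identity_and_full_strictness(self):
        w = self.staircase(5)
        assert filter_by_missingness(w, 1.0).concepts == w.concepts
        assert filter_by_missingness(w, 0.0).concepts == ["C0"]

    def test_coverage_recomputed(self):
        w = self.staircase(5)
        w2 = filter_by_missingness(w, 0.3)  # 2 concepts remain
        d0 = next(d for d in w2.doculects if d.id == "D0")
        assert d0.coverage == 1.0
        d4 = next(d for d in w2.doculects if d.id == "D4")
        assert d4.coverage == 0.5  # attests C0 only of {C0, C1}


class TestEncodeBinary:
    def test_cognacy_sample_cells(self, bat_wordlist):
        m = encode_binary(bat_wordlist)
        j171 = m.characters.index(171)
        j172 = m.characters.index(172)
        j4513 = m.characters.index(4513)
        for taxon, present in (("Tupinamba", j171), ("Wayampi", j171)):
            i = m.taxa.index(taxon)
            assert m.cells[i, present] == PRESENT
            assert m.cells[i, j172] == ABSENT and m.cells[i, j4513] == ABSENT

    def test_unattested_concept_missing_on_all_its_characters(self, bat_wordlist):
        w = Wordlist(bat_wordlist.doculects + [Doculect("Xeta")],
                     ["BAT"], bat_wordlist.entries)
        m = encode_binary(w)
        i = m.taxa.index("Xeta")
        assert (m.cells[i] == MISSING).all()

    def test_synonyms_present_on_both(self, bat_wordlist):
        extra = bat_wordlist.entries + [LexicalEntry("Tupinamba", "BAT", "syn", 172)]
        w = Wordlist(bat_wordlist.doculects, ["BAT"], extra)
        m = encode_binary(w)
        i = m.taxa.index("Tupinamba")
        assert m.cells[i, m.characters.index(171)] == PRESENT
        assert m.cells[i, m.characters.index(172)] == PRESENT

    def test_present_plus_absent_counts_match_attested_concepts(self, toy3_wordlist):
        m = encode_binary(toy3_wordlist)
        for i, taxon in enumerate(m.taxa):
            attested = toy3_wordlist.attested_concepts(taxon)
            expect = sum(1 for c in m.char_concepts if c in attested)
            assert ((m.cells[i] == PRESENT) | (m.cells[i] == ABSENT)).sum() == expect

    def test_drop_singletons(self, bat_wordlist):
        m = encode_binary(bat_wordlist, drop_singletons=True)
        assert 4513 not in m.characters  # only Mawe has it
        assert set(m.characters) == {171, 172}


class TestPartitionCharacters:
    @staticmethod
    def wl_with_sizes(sizes):
        docs = [Doculect("A"), Doculect("B")]
        entries, sid = [], 1
        for k, size in enumerate(sizes):
            for _ in range(size):
                entries.append(LexicalEntry("A", f"C{k}", "", sid))
                entries.append(LexicalEntry("B", f"C{k}", "", sid + 1))
                sid += 2
        # each 'size' contributes 2 characters; halve by using one doculect set
        return Wordlist(docs, [f"C{k}" for k in range(len(sizes))], entries)

    def test_greedy_balance(self):
        # concepts with 4,3,2,1 characters -> partitions {4,1} and {3,2}
        docs = [Doculect("A")]
        entries, sid = [], 1
        for k, size in enumerate([4, 3, 2, 1]):
            for _ in range(size):
                entries.append(LexicalEntry("A", f"C{k}", "", sid))
                sid += 1
        w = Wordlist(docs, [f"C{k}" for k in range(4)], entries)
        m = partition_characters(encode_binary(w), 2)
        sizes = {label: len(m.partition_columns(label)) for label in m.partition_labels()}
        assert sorted(sizes.values()) == [5, 5]
        # concepts are never split
        for label in m.partition_labels():
            cols = m.partition_columns(label)
            for concept in {m.char_concepts[j] for j in cols}:
                js = [j for j, c in enumerate(m.char_concepts) if c == concept]
                assert set(js) <= set(cols.tolist())

    def test_k1_identity(self, bat_wordlist):
        m = partition_characters(encode_binary(bat_wordlist), 1)
        assert len(m.partition_labels()) == 1

    def test_too_many_partitions(self, bat_wordlist):
        with pytest.raises(ValueError):
            partition_characters(encode_binary(bat_wordlist), 4)

    def test_deterministic(self, toy3_wordlist):
        m1 = partition_characters(encode_binary(toy3_wordlist), 2)
        m2 = partition_characters(encode_binary(toy3_wordlist), 2)
        assert m1.partitions == m2.partitions
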