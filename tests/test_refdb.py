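"""Reference DB I/O, label index, split sampling, tag manifest."""

import json

import pytest

from ednacnn.refdb import (
    ReferenceDB,
    ReferenceRecord,
    TagEntry,
    TagManifest,
    eligible_species_for_split,
    load_label_index,
    read_reference_fasta,
    read_tag_manifest,
    save_label_index,
    split_train_holdout,
    write_reference_fasta,
    write_tag_manifest,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestReferenceFasta:
    def test_read_counts_species_and_records(self, tmp_path):
        fa = _write(
            tmp_path / "ref.fasta",
            ">r1 Genus alpha\nACGTACGT\n>r2 Genus alpha\nACGTACGA\n"
            ">r3 Genus beta\nTTTTACGT\n",
        )
        db = read_reference_fasta(fa)
        assert db.n_classes == 2
        assert len(db) == 3
        assert set(db.label_index) == {"Genus alpha", "Genus beta"}

    def test_duplicate_entries_collapse_with_multiplicity(self, tmp_path):
        fa = _write(
            tmp_path / "dup.fasta",
            ">r1 sp A\nACGT\n>r2 sp A\nACGT\n>r3 sp A\nACGA\n",
        )
        db = read_reference_fasta(fa)
        assert len(db) == 2
        assert db.total_copies() == 3
        mult = {r.sequence: r.multiplicity for r in db.records}
        assert mult == {"ACGT": 2, "ACGA": 1}

    def test_empty_file_and_bad_header_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            read_reference_fasta(_write(tmp_path / "e.fasta", ""))
        with pytest.raises(ValueError, match="entry 1"):
            read_reference_fasta(_write(tmp_path / "h.fasta", ">nolabel\nACGT\n"))

    def test_roundtrip(self, tmp_path):
        db = ReferenceDB(
            [ReferenceRecord("a", "sp X", "ACGT", 2), ReferenceRecord("b", "sp Y", "GGGG")]
        )
        write_reference_fasta(db, tmp_path / "out.fasta")
        back = read_reference_fasta(tmp_path / "out.fasta")
        assert back.total_copies() == 3
        assert back.label_index == db.label_index


class TestLabelIndex:
    def test_dense_and_stable_under_json(self, tmp_path):
        db = ReferenceDB(
            [ReferenceRecord(f"r{i}", sp, "ACGT" + "A" * i)
             for i, sp in enumerate(["b", "a", "c"])]
        )
        assert sorted(db.label_index.values()) == [0, 1, 2]
        save_label_index(db.label_index, tmp_path / "idx.json")
        assert load_label_index(tmp_path / "idx.json") == db.label_index

    def test_non_dense_index_rejected(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps({"a": 0, "b": 2}))
        with pytest.raises(ValueError, match="dense"):
            load_label_index(tmp_path / "bad.json")


class TestSplitSampling:
    @staticmethod
    def _db():
        recs = [
            ReferenceRecord("a1", "A", "AAAA"),
            ReferenceRecord("a2", "A", "AAAA"),
            ReferenceRecord("a3", "A", "AAAT"),
            ReferenceRecord("b1", "B", "CCCC"),
            ReferenceRecord("b2", "B", "CCCC"),
            ReferenceRecord("c1", "C", "GGGG"),
            ReferenceRecord("c2", "C", "GGGT"),
            ReferenceRecord("c3", "C", "GGTT"),
        ]
        return ReferenceDB(recs)

    def test_eligibility_counts_unique_sequences(self):
        db = self._db()
        # brute force: distinct strings per species
        assert eligible_species_for_split(db, 2) == {"A", "C"}
        assert eligible_species_for_split(db, 1) == {"A", "B", "C"}
        assert eligible_species_for_split(db, 3) == {"C"}

    def test_split_partitions_unique_sequences(self):
        db = self._db().filter_species({"A", "C"})
        train, hold = split_train_holdout(db, seed=0)
        for sp in ("A", "C"):
            tr = {r.sequence for r in train.records if r.species == sp}
            ho = {r.sequence for r in hold.records if r.species == sp}
            assert len(ho) == 1
            assert tr.isdisjoint(ho)
            all_seqs = {r.sequence for r in db.records if r.species == sp}
            assert tr | ho == all_seqs
        assert set(train.label_index) == set(hold.label_index) == {"A", "C"}

    def test_split_deterministic_given_seed(self):
        db = self._db().filter_species({"A", "C"})
        s1 = split_train_holdout(db, seed=42)
        s2 = split_train_holdout(db, seed=42)
        for a, b in zip(s1, s2):
            assert [r.record_id for r in a.records] == [r.record_id for r in b.records]

    def test_ineligible_species_rejected(self):
        with pytest.raises(ValueError, match="unique sequences"):
            split_train_holdout(self._db(), seed=0)


class TestTagManifest:
    @staticmethod
    def _manifest_text():
        return (
            "# experiment\tsample\ttags\tforward_primer\treverse_primer\tmetadata\n"
            "exp\tS1\tAACCGGTT:AACCGGTT\tACACCGCCCGTCACTCT\tCTTCCGGTACACTTACCATG\t"
            "filter=F1\triver=R1\n"
            "exp\tS2\tTTGGCCAA:TTGGCCAA\tACACCGCCCGTCACTCT\tCTTCCGGTACACTTACCATG\t"
            "filter=F1\triver=R1\n"
        )

    def test_read_and_fields(self, tmp_path):
        p = _write(tmp_path / "m.tsv", self._manifest_text())
        m = read_tag_manifest(p)
        assert m.sample_ids == ["S1", "S2"]
        assert m.tag_len == 8
        assert m.entries["S1"].forward_tag == "AACCGGTT"
        assert m.hierarchy()["S2"] == ("F1", "R1")

    def test_roundtrip_preserves_all_fields(self, tmp_path):
        m = read_tag_manifest(_write(tmp_path / "m.tsv", self._manifest_text()))
        write_tag_manifest(m, tmp_path / "out.tsv")
        back = read_tag_manifest(tmp_path / "out.tsv")
        assert back.entries == m.entries

    def test_duplicate_tag_pair_rejected(self):
        e1 = TagEntry("S1", "AACCGGTT", "AACCGGTT", "ACGT", "ACGT")
        e2 = TagEntry("S2", "AACCGGTT", "AACCGGTT", "ACGT", "ACGT")
        with pytest.raises(ValueError, match="duplicate tag pair"):
            TagManifest({"S1": e1, "S2": e2})

    def test_ragged_row_and_wrong_tag_length_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="line 1"):
            read_tag_manifest(_write(tmp_path / "r.tsv", "exp\tS1\tAACC:AACC\n"))
        p = _write(tmp_path / "m.tsv", self._manifest_text())
        with pytest.raises(ValueError, match="tag length"):
            read_tag_manifest(p, tag_len=10)
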