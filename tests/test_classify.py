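"""Seed-and-extend classification vs exhaustive Smith-Waterman oracles."""

import numpy as np
import pytest
from Bio import Align

from gmocap.classify import (
    align_read, classify_read_pairs, classify_reads,
    index_database,
)
from gmocap.dna import mutate_fraction, random_dna, revcomp
from gmocap.simulate import ReadPair, Fragment


def _sw_aligner():
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def _oracle_best(read, db):
    """Exhaustive local alignment of a read against every element, both strands."""
    aligner = _sw_aligner()
    best = {}
    for el in db:
        s = max(aligner.score(el.sequence, read),
                aligner.score(el.sequence, revcomp(read)))
        best[el.element_id] = int(s)
    top = max(best.values())
    return top, {e for e, s in best.items() if s == top}


class TestIndex:
    def test_key_count_for_single_element(self):
        from gmocap.element_db import (
            ElementCategory, ElementDatabase, StructuralElement,
        )
        rng = np.random.default_rng(0)
        db = ElementDatabase([
            StructuralElement("e", ElementCategory.GENE, random_dna(100, rng)),
        ])
        idx = index_database(db, k=15)
        assert idx.n_forward_positions == 86  # 100 - 15 + 1

    def test_absent_kmer_empty(self, toy_index):
        assert toy_index.lookup("N" * 15) == []

    def test_k_larger_than_shortest_element_rejected(self, toy_db):
        with pytest.raises(ValueError, match="shortest"):
            index_database(toy_db, k=151)

    def test_all_kmers_located_by_brute_force_scan(self, toy_db, toy_index):
        el = toy_db["beta"]
        k = toy_index.k
        for i in range(0, len(el.sequence) - k + 1, 7):
            kmer = el.sequence[i : i + k]
            hits = [(e, o) for e, o, s in toy_index.lookup(kmer) if s == "+"]
            # brute force: scan every element for the substring
            expected = []
            for other in toy_db:
                off = 0
                while True:
                    j = other.sequence.find(kmer, off)
                    if j < 0:
                        break
                    expected.append((other.element_id, j))
                    off = j + 1
            assert sorted(hits) == sorted(expected)


class TestAlignRead:
    def test_exact_substring_assigned(self, panel_db, kindex):
        el = panel_db["p35S"]
        read = el.sequence[100:175]
        a = align_read(read, kindex, panel_db)
        assert a.element_id == "p35S"
        assert a.identity == 1.0
        assert a.strand == "+"
        assert (a.element_start, a.element_end) == (100, 175)

    def test_reverse_complement_flips_strand(self, panel_db, kindex):
        el = panel_db["p35S"]
        read = revcomp(el.sequence[100:175])
        a = align_read(read, kindex, panel_db)
        assert a.element_id == "p35S"
        assert a.strand == "-"
        assert (a.element_start, a.element_end) == (100, 175)

    def test_unalignable_read_unassigned(self, panel_db, kindex):
        rng = np.random.default_rng(99)
        a = align_read(random_dna(75, rng), kindex, panel_db)
        assert not a.assigned
        assert a.element_start is None

    def test_matches_exhaustive_smith_waterman(self, toy_db, toy_index):
        """Seed-and-extend best hit equals full SW on 50 noisy reads."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            el = toy_db.elements[rng.integers(0, 3)]
            L = len(el.sequence)
            start = int(rng.integers(0, L - 75 + 1))
            read = el.sequence[start : start + 75]
            read = mutate_fraction(read, 0.03, rng)
            if trial % 5 == 0:  # occasional 1-2 bp indel
                p = int(rng.integers(10, 60))
                read = read[:p] + read[p + int(rng.integers(1, 3)):]
            if trial % 2 == 0:
                read = revcomp(read)
            a = align_read(read, toy_index, toy_db)
            top, top_set = _oracle_best(read, toy_db)
            assert a.assigned
            assert a.alignment_score == top
            assert a.element_id in top_set

    def test_strand_symmetry(self, panel_db, kindex):
        rng = np.random.default_rng(21)
        for eid in ("tNOS", "EPSPS1", "gox"):
            seq = panel_db[eid].sequence
            start = int(rng.integers(0, len(seq) - 75))
            read = mutate_fraction(seq[start : start + 75], 0.02, rng)
            a_fwd = align_read(read, kindex, panel_db)
            a_rev = align_read(revcomp(read), kindex, panel_db)
            assert a_fwd.element_id == a_rev.element_id == eid
            assert {a_fwd.strand, a_rev.strand} == {"+", "-"}
            assert a_fwd.alignment_score == a_rev.alignment_score


class TestVariantDisambiguation:
    @pytest.mark.parametrize("source", ["cry1Ab_c", "cry1Ac"])
    def test_paralog_majority_assignment(self, panel_db, kindex, source):
        """Reads from one ~92 %-identical cry variant mostly map to it."""
        rng = np.random.default_rng(31)
        seq = panel_db[source].sequence
        hits = {"cry1Ab_c": 0, "cry1Ac": 0}
        n = 80
        for _ in range(n):
            start = int(rng.integers(0, len(seq) - 75))
            read = mutate_fraction(seq[start : start + 75], 0.01, rng)
            a = align_read(read, kindex, panel_db)
            if a.element_id in hits:
                hits[a.element_id] += 1
        assert hits[source] > n / 2
        assert hits[source] > hits[{"cry1Ab_c": "cry1Ac",
                                    "cry1Ac": "cry1Ab_c"}[source]]


class TestClassifyReads:
    def test_counts_match_simulator_truth(self, panel_db, kindex, probes):
        """Error-free reads from a single element all assign to it."""
        el = panel_db["tNOS"]
        pairs = []
        for i in range(0, len(el.sequence) - 150, 10):
            frag = el.sequence[i : i + 150]
            pairs.append(ReadPair(
                read_id=f"r{i}", mate1=frag[:75], mate2=revcomp(frag)[:75],
                truth=Fragment("g", 0, i, i + 150, "insert"),
            ))
        df, summary = classify_read_pairs(pairs, kindex, panel_db)
        assert summary["total_reads"] == 2 * len(pairs)
        assert summary["reads_aligned"] == summary["total_reads"]
        assert set(df["element_id"]) == {"tNOS"}
        assert summary["pct_aligned"] == 100.0

    def test_malformed_fastq_reports_record(self, panel_db, kindex, tmp_path):
        bad = tmp_path / "bad.fastq"
        bad.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGTACGT\n+\nII\n")
        with pytest.raises(ValueError, match="record 2"):
            classify_reads(bad, None, kindex, panel_db)

    def test_fastq_classification_matches_in_memory(self, panel_db, kindex, tmp_path):
        from gmocap.simulate import write_fastq_pair

        el = panel_db["p35S"]
        pairs = [
            ReadPair("r0", el.sequence[0:75], revcomp(el.sequence[80:155]),
                     Fragment("g", 0, 0, 155, "insert")),
        ]
        write_fastq_pair(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        df, summary = classify_reads(tmp_path / "r1.fq", tmp_path / "r2.fq",
                                     kindex, panel_db)
        assert summary["reads_aligned"] == 2
        assert list(df["element_id"]) == ["p35S", "p35S"]
        assert list(df["strand"]) == ["+", "-"]

    def test_sam_export_readable_by_pysam(self, panel_db, kindex, tmp_path):
        import pysam

        from gmocap.classify import write_sam

        el = panel_db["tNOS"]
        reads = {"r0/1": el.sequence[10:85], "r1/1": "ACGT" * 19}
        pairs = [
            ReadPair("r0", reads["r0/1"], revcomp(el.sequence[100:175]),
                     Fragment("g", 0, 10, 175, "insert")),
        ]
        df, _summary = classify_read_pairs(pairs, kindex, panel_db)
        out = tmp_path / "a.sam"
        write_sam(df, panel_db, {"r0/1": pairs[0].mate1, "r0/2": pairs[0].mate2},
                  out)
        with pysam.AlignmentFile(str(out)) as fh:
            recs = list(fh)
        assert len(recs) == 2
        assert recs[0].reference_name == "tNOS"
        assert recs[0].reference_start == 10
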