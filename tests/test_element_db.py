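"""Element database construction, checksum, and probe tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmocap.dna import random_dna
from gmocap.element_db import (
    ElementCategory, ElementDatabase, StructuralElement, build_database,
    covered_intervals, database_checksum, design_probes,
    expected_probe_count, read_probe_bed, write_probe_bed,
)
from gmocap.panel import PANEL, PANEL_TOTAL_BP


def _write_fixture(tmp_path, records, meta_rows):
    fasta = tmp_path / "el.fasta"
    meta = tmp_path / "el.tsv"
    with open(fasta, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
    with open(meta, "w") as fh:
        fh.write("element_id\tcategory\tsize_bp\tsource\n")
        for row in meta_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return fasta, meta


class TestBuildDatabase:
    def test_total_length_is_sum_of_inputs(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = [("a", random_dna(100, rng)), ("b", random_dna(200, rng))]
        fasta, meta = _write_fixture(
            tmp_path, recs,
            [("a", "promoter", 100, "src"), ("b", "gene", 200, "src")],
        )
        db = build_database(fasta, meta)
        assert db.total_length_bp == 300
        assert database_checksum(db) == 300

    def test_duplicate_id_rejected(self, tmp_path):
        rng = np.random.default_rng(0)
        seq = random_dna(50, rng)
        fasta, meta = _write_fixture(
            tmp_path, [("dup", seq), ("dup", seq)],
            [("dup", "gene", 50, "src")],
        )
        with pytest.raises(ValueError, match="dup"):
            build_database(fasta, meta)

    def test_missing_metadata_row_names_id(self, tmp_path):
        fasta, meta = _write_fixture(
            tmp_path, [("a", "ACGT" * 10), ("orphan", "ACGT" * 10)],
            [("a", "gene", 40, "src")],
        )
        with pytest.raises(ValueError, match="orphan"):
            build_database(fasta, meta)

    def test_non_dna_character_reports_position(self, tmp_path):
        fasta, meta = _write_fixture(
            tmp_path, [("a", "ACGTXACGT")], [("a", "gene", 9, "src")],
        )
        with pytest.raises(ValueError, match="position 4"):
            build_database(fasta, meta)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            StructuralElement("e", ElementCategory.GENE, "")


class TestPanelChecksum:
    def test_panel_total_is_52534(self, panel_db):
        assert panel_db.total_length_bp == 52534
        assert len(panel_db) == 40

    def test_panel_roundtrips_through_files(self, panel_db, tmp_path):
        panel_db.to_fasta(tmp_path / "db.fasta")
        panel_db.to_metadata(tmp_path / "db.tsv")
        db2 = build_database(tmp_path / "db.fasta", tmp_path / "db.tsv")
        assert database_checksum(db2) == 52534
        assert db2.element_ids == panel_db.element_ids

    def test_category_breakdown(self):
        cats = [c for _e, c, _l, _s in PANEL]
        assert cats.count("promoter") == 11
        assert cats.count("terminator") == 6
        assert cats.count("gene") == 22
        assert cats.count("miscellaneous") == 1
        assert PANEL_TOTAL_BP == 52534

    def test_single_element_checksum(self, panel_db):
        db = ElementDatabase([panel_db["p35S"]])
        assert database_checksum(db) == 867

    def test_two_element_checksum(self, panel_db):
        db = ElementDatabase([panel_db["pNOS"], panel_db["tNOS"]])
        assert database_checksum(db) == 698


class TestProbeDesign:
    def test_exact_tiling(self, panel_db):
        rng = np.random.default_rng(1)
        db = ElementDatabase([
            StructuralElement("e240", ElementCategory.GENE, random_dna(240, rng)),
        ])
        ps = design_probes(db, probe_length_bp=120, step_bp=120)
        assert [(p.start, p.end) for p in ps.probes] == [(0, 120), (120, 240)]

    def test_short_element_single_probe(self):
        rng = np.random.default_rng(1)
        db = ElementDatabase([
            StructuralElement("e80", ElementCategory.GENE, random_dna(80, rng)),
        ])
        ps = design_probes(db, probe_length_bp=120, step_bp=110)
        assert len(ps) == 1
        assert (ps.probes[0].start, ps.probes[0].end) == (0, 80)

    def test_step_exceeding_probe_length_rejected(self, panel_db):
        with pytest.raises(ValueError, match="gaps"):
            design_probes(panel_db, probe_length_bp=120, step_bp=130)

    def test_probe_count_matches_brute_force_oracle(self):
        # brute-force tiling over positions, independently of design_probes
        rng = np.random.default_rng(2)
        db = ElementDatabase([
            StructuralElement("e867", ElementCategory.PROMOTER, random_dna(867, rng)),
        ])
        ps = design_probes(db, probe_length_bp=120, step_bp=110)
        starts = list(range(0, 867 - 120 + 1, 110))
        if starts[-1] + 120 < 867:
            starts.append(867 - 120)
        assert len(ps) == len(starts)
        assert len(ps) == expected_probe_count(867, 120, 110)

    def test_probes_are_verbatim_substrings(self, panel_db, probes):
        for p in probes.probes[:50]:
            assert p.sequence == panel_db[p.element_id].sequence[p.start:p.end]

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        length=st.integers(min_value=1, max_value=600),
        probe_len=st.integers(min_value=1, max_value=150),
        data=st.data(),
    )
    def test_full_coverage_property(self, length, probe_len, data):
        """Union of probe intervals always equals [0, element length)."""
        step = data.draw(st.integers(min_value=1, max_value=probe_len))
        db = ElementDatabase([
            StructuralElement("e", ElementCategory.GENE, "A" * length),
        ])
        ps = design_probes(db, probe_length_bp=probe_len, step_bp=step)
        assert covered_intervals(ps, "e") == [(0, length)]

    def test_panel_full_coverage(self, panel_db, probes):
        for el in panel_db:
            assert covered_intervals(probes, el.element_id) == [(0, el.length_bp)]


class TestProbeBed:
    def test_bed_roundtrip_and_determinism(self, panel_db, probes, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_probe_bed(probes, p1)
        write_probe_bed(probes, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_probe_bed(p1, panel_db)
        assert back.probes == probes.probes

    def test_bed_coordinate_convention(self, tmp_path):
        rng = np.random.default_rng(3)
        db = ElementDatabase([
            StructuralElement("elem", ElementCategory.GENE, random_dna(120, rng)),
        ])
        ps = design_probes(db, probe_length_bp=120, step_bp=110)
        out = tmp_path / "p.bed"
        write_probe_bed(ps, out)
        assert out.read_text() == "elem\t0\t120\telem_p000\n"
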