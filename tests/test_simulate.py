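"""Genome construction, capture rule, and read sequencing."""

import numpy as np
import pytest

from gmocap.dna import revcomp
from gmocap.scenarios import make_gts_like
from gmocap.simulate import (
    GMConstruct, SampleSpec, SimulatedGenome,
    build_gm_genome, capture_mask, draw_fragments, fragment_and_capture,
    make_read_pairs, probe_cover_mask, random_host, simulate_sample,
)


class TestBuildGMGenome:
    def test_empty_insert_is_identity(self, panel_db):
        host = random_host("h", 500, seed=0)
        c = GMConstruct("empty", parts=(), host_id="h", insertion_pos=100)
        gm = build_gm_genome(host, c, panel_db)
        assert gm.sequence == host.sequence
        assert gm.insert_start == gm.insert_end == 100

    def test_insert_coordinates(self, panel_db):
        host = random_host("h", 100, seed=0)
        insert = "A" * 50
        c = GMConstruct("c", parts=(("filler", insert),), host_id="h",
                        insertion_pos=40)
        gm = build_gm_genome(host, c, panel_db)
        assert len(gm.sequence) == 150
        assert gm.sequence[:40] == host.sequence[:40]
        assert gm.sequence[40:90] == insert
        assert gm.sequence[90:] == host.sequence[40:]
        assert (gm.insert_start, gm.insert_end) == (40, 90)

    def test_insertion_pos_out_of_range(self, panel_db):
        host = random_host("h", 100, seed=0)
        c = GMConstruct("c", parts=(), host_id="h", insertion_pos=101)
        with pytest.raises(ValueError, match="out of range"):
            build_gm_genome(host, c, panel_db)

    def test_gts_like_truth_coordinates(self, panel_db, probes):
        sc = make_gts_like(panel_db, probes, 0.1, 1000, seed=3)
        gm = sc.gm_genomes[0]
        c = sc.constructs[0]
        assert gm.insert_start == c.insertion_pos
        assert gm.insert_end == c.insertion_pos + len(c.insert_sequence(panel_db))
        # parts tile the insert contiguously
        assert gm.part_intervals[0][0] == gm.insert_start
        assert gm.part_intervals[-1][1] == gm.insert_end
        for (s1, e1, _k, _r), (s2, e2, _k2, _r2) in zip(
                gm.part_intervals, gm.part_intervals[1:]):
            assert e1 == s2

    def test_wrong_host_rejected(self, panel_db):
        host = random_host("other", 100, seed=0)
        c = GMConstruct("c", parts=(), host_id="h", insertion_pos=0)
        with pytest.raises(ValueError, match="host"):
            build_gm_genome(host, c, panel_db)


class TestCapture:
    def test_no_probe_homology_no_fragments(self, panel_db, probes):
        host = SimulatedGenome.from_host(random_host("h", 5000, seed=1))
        spec = SampleSpec(components=[(host, 1.0)], n_fragments=2000,
                          off_target_rate=0.0, seed=5)
        assert fragment_and_capture(spec, probes) == []

    def test_off_target_rate_one_retains_all(self, panel_db, probes):
        host = SimulatedGenome.from_host(random_host("h", 5000, seed=1))
        spec = SampleSpec(components=[(host, 1.0)], n_fragments=500,
                          off_target_rate=1.0, seed=5)
        frags = fragment_and_capture(spec, probes)
        assert len(frags) == 500

    def test_fragment_lengths_within_range(self, panel_db, probes):
        sc = make_gts_like(panel_db, probes, 0.5, 20_000, seed=7)
        frags = fragment_and_capture(sc.spec, probes)
        lo, hi = sc.spec.fragment_len_range
        assert frags
        for f in frags:
            assert lo <= f.end - f.start <= hi <= sc.spec.max_capture_len

    def test_capture_rule_matches_brute_force_oracle(self, panel_db, probes):
        """Re-apply the retention rule per fragment from merged probe intervals."""
        sc = make_gts_like(panel_db, probes, 0.2, 5000, seed=11)
        spec = sc.spec
        comp, start, end = draw_fragments(spec)
        keep = capture_mask(spec, probes, comp, start, end)
        # independent oracle: merged covered intervals per genome, overlap sum
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        off = rng.random(len(comp)) < spec.off_target_rate
        for i in range(len(comp)):
            g = spec.components[comp[i]][0]
            cover = probe_cover_mask(g, probes)
            ov = int(cover[start[i]:end[i]].sum())
            expected = (ov >= spec.min_overlap) or off[i]
            assert keep[i] == expected

    def test_origin_labels(self, panel_db, probes):
        sc = make_gts_like(panel_db, probes, 1.0, 30_000, seed=13)
        gm = sc.gm_genomes[0]
        frags = fragment_and_capture(sc.spec, probes)
        origins = {f.origin for f in frags}
        assert origins >= {"insert", "junction"}
        for f in frags:
            if f.origin == "insert":
                assert f.start >= gm.insert_start and f.end <= gm.insert_end
            elif f.origin == "junction":
                assert f.start < gm.insert_start or f.end > gm.insert_end


class TestSequencing:
    def test_error_free_reads_are_substrings(self, panel_db, probes):
        sc = make_gts_like(panel_db, probes, 1.0, 5000, seed=17,
                           error_rate=0.0)
        frags = fragment_and_capture(sc.spec, probes)
        pairs = make_read_pairs(frags, sc.spec)
        assert len(pairs) == len(frags)
        gm = sc.gm_genomes[0]
        for p in pairs[:100]:
            frag_seq = gm.sequence[p.truth.start:p.truth.end]
            assert p.mate1 == frag_seq[: sc.spec.read_len]
            assert p.mate2 == revcomp(frag_seq)[: sc.spec.read_len]

    def test_substitution_count_within_binomial_expectation(self, panel_db, probes):
        err = 0.01
        sc = make_gts_like(panel_db, probes, 1.0, 30_000, seed=19,
                           error_rate=err)
        frags = fragment_and_capture(sc.spec, probes)
        pairs = make_read_pairs(frags, sc.spec)
        gm = sc.gm_genomes[0]
        mismatches = 0
        bases = 0
        for p in pairs:
            frag_seq = gm.sequence[p.truth.start:p.truth.end]
            for obs, exp in ((p.mate1, frag_seq[: len(p.mate1)]),
                             (p.mate2, revcomp(frag_seq)[: len(p.mate2)])):
                mismatches += sum(a != b for a, b in zip(obs, exp))
                bases += len(obs)
        assert bases > 100_000
        mu = bases * err
        sigma = np.sqrt(bases * err * (1 - err))
        assert abs(mismatches - mu) < 3 * sigma

    def test_zero_gm_sample_has_no_insert_reads(self, panel_db, probes):
        sc = make_gts_like(panel_db, probes, 0.0, 50_000, seed=23)
        frags = fragment_and_capture(sc.spec, probes)
        assert all(f.origin == "host" for f in frags)

    def test_seed_determinism_byte_identical_fastq(self, panel_db, probes, tmp_path):
        sc = make_gts_like(panel_db, probes, 0.1, 20_000, seed=29)
        r1 = simulate_sample(sc.spec, probes, tmp_path / "a")
        r2 = simulate_sample(sc.spec, probes, tmp_path / "b")
        assert (tmp_path / "a/sample_R1.fastq").read_bytes() == \
               (tmp_path / "b/sample_R1.fastq").read_bytes()
        assert (tmp_path / "a/sample_R2.fastq").read_bytes() == \
               (tmp_path / "b/sample_R2.fastq").read_bytes()
        assert r1["n_pairs"] == r2["n_pairs"]

    def test_pair_count_equals_retained_fragments(self, panel_db, probes):
        sc = make_gts_like(panel_db, probes, 0.1, 20_000, seed=29)
        frags = fragment_and_capture(sc.spec, probes)
        pairs = make_read_pairs(frags, sc.spec)
        assert len(pairs) == len(frags)


class TestSampleSpecValidation:
    def test_fractions_must_sum_to_one(self, panel_db):
        host = SimulatedGenome.from_host(random_host("h", 1000, seed=0))
        with pytest.raises(ValueError, match="sum"):
            SampleSpec(components=[(host, 0.5)], n_fragments=10)

    def test_fragment_range_within_capture_reach(self, panel_db):
        host = SimulatedGenome.from_host(random_host("h", 1000, seed=0))
        with pytest.raises(ValueError, match="max_capture_len"):
            SampleSpec(components=[(host, 1.0)], n_fragments=10,
                       fragment_len_range=(150, 600))
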