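"""Exhaustive scanning, the hexad retention rule, conservation classes,
flank extraction and locus co-localization."""

import numpy as np
import pytest

from cnrescan.genome_scan import (
    GeneLocus,
    MotifHit,
    classify_conservation,
    colocalize,
    extract_flanks,
    hexad_filter,
    hits_to_frame,
    read_bed_loci,
    reduce_overlaps,
    scan_sequence,
    write_bed_loci,
)
from cnrescan.seqcore import NucSequence, hamming, revcomp, revcomp_str
from cnrescan.synthetic_data import CopySpec, DecoySpec, PlantSpec, gen_genome


def _full(hits):
    return [h for h in hits if h.is_full_length]


class TestScanSequence:
    def test_consensus_is_single_plus_hit(self, motif):
        hits = _full(scan_sequence(motif.consensus, motif, 0))
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.total_mismatches) == (1, 32, "+", 0)
        assert h.passes_filter

    def test_revcomp_consensus_is_minus_hit(self, motif):
        hits = _full(scan_sequence(revcomp(motif.consensus), motif, 0))
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (1, 32, "-")
        assert h.oriented_sequence == motif.bases

    def test_short_target_empty(self, motif):
        assert scan_sequence(NucSequence("t", "ACGTA"), motif, 11) == []

    def test_matches_window_oracle(self, motif):
        # every (position, strand) window's mismatch count equals a direct
        # per-window Hamming computation
        rng = np.random.default_rng(4)
        target = NucSequence("t", "".join(rng.choice(list("ACGT"), 3000)))
        max_mm = 18
        got = {
            (h.start, h.strand): h.total_mismatches
            for h in _full(scan_sequence(target, motif, max_mm))
        }
        expected = {}
        for off in range(len(target) - 31):
            win = target.bases[off : off + 32]
            for strand, oriented in (("+", win), ("-", revcomp_str(win))):
                mm = hamming(oriented, motif.bases)
                if mm <= max_mm:
                    expected[(off + 1, strand)] = mm
        assert got == expected

    def test_revcomp_target_mirrors_hits(self, motif):
        spec = PlantSpec(
            length=5000,
            copies=(CopySpec(strand="+"), CopySpec(strand="-", spacer_mismatches=2)),
            seed=9,
        )
        target, _, _ = gen_genome(spec, motif)
        fwd = _full(scan_sequence(target, motif, 5))
        rev = _full(scan_sequence(revcomp(target), motif, 5))
        L = len(target)
        mirrored = {
            (L - h.end + 1, L - h.start + 1, "-" if h.strand == "+" else "+",
             h.total_mismatches)
            for h in fwd
        }
        assert {
            (h.start, h.end, h.strand, h.total_mismatches) for h in rev
        } == mirrored

    def test_planted_copies_recovered_exactly(self, motif):
        # seeded 100-kb genome with seven planted copies across mismatch
        # classes: all recovered at the planted coordinates and counts
        copies = tuple(
            CopySpec(strand=s, hexad_mismatches=hx, spacer_mismatches=sp)
            for s, hx, sp in [
                ("+", (0, 0, 0), 0), ("-", (0, 0, 0), 0), ("+", (1, 0, 0), 0),
                ("-", (0, 1, 0), 2), ("+", (1, 1, 1), 3), ("-", (2, 0, 0), 0),
                ("+", (0, 0, 1), 4),
            ]
        )
        genome, truth, _ = gen_genome(PlantSpec(length=100_000, copies=copies, seed=21), motif)
        hits = {
            (h.start, h.end, h.strand): h
            for h in _full(scan_sequence(genome, motif, 11))
        }
        assert len(truth) == 7
        for row in truth.itertuples():
            h = hits[(row.start, row.end, row.strand)]
            assert h.total_mismatches == row.total_mm
            assert h.hexad_mismatches == (row.hexA_mm, row.hexB_mm, row.hexC_mm)
            assert h.passes_filter == row.passes_filter

    def test_truncated_edge_window_can_pass_when_core_covered(self, motif):
        # clipping positions 1-2 leaves the 3-29 core intact
        target = NucSequence("t", motif.bases[2:])
        hits = scan_sequence(target, motif, 0)
        passing = [h for h in hits if h.passes_filter]
        assert len(passing) == 1
        assert passing[0].covered_query_range == (3, 32)

    def test_truncated_window_missing_core_never_passes(self, motif):
        target = NucSequence("t", motif.bases[5:])  # clips into Hexad A
        for h in scan_sequence(target, motif, 0):
            if h.covered_query_range[0] > 3:
                assert not h.passes_filter


class TestHexadFilter:
    def test_exact_hit_passes(self, motif):
        (h,) = _full(scan_sequence(motif.consensus, motif, 0))
        assert h.hexad_mismatches == (0, 0, 0) and h.passes_filter

    def test_printed_viral_sequence_fails_on_hexad_a(self, motif):
        gahv1 = "GAACAGCGGCGAGACGAAAAAGAAGCGGAGGA"
        hit = MotifHit("GaHV1", 1, 32, "+", gahv1, hamming(gahv1, motif.bases))
        out = hexad_filter(hit, motif)
        assert out.hexad_mismatches[0] >= 2
        assert not out.passes_filter

    def test_spacer_mismatches_unrestricted(self, motif):
        seq = list(motif.bases)
        for pos in (1, 9, 19, 30, 31):  # spacer positions, 1-based
            seq[pos - 1] = {"A": "C"}.get(seq[pos - 1], "A")
        s = "".join(seq)
        hit = MotifHit("t", 1, 32, "+", s, hamming(s, motif.bases))
        out = hexad_filter(hit, motif)
        assert out.total_mismatches == 5
        assert out.hexad_mismatches == (0, 0, 0) and out.passes_filter


class TestConservation:
    @pytest.mark.parametrize("mm,label", [(0, "conserved"), (3, "conserved"),
                                          (4, "divergent"), (11, "divergent")])
    def test_threshold(self, mm, label):
        hit = MotifHit("t", 1, 32, "+", "A" * 32, mm)
        assert classify_conservation(hit) == label

    def test_truncated_undefined(self):
        hit = MotifHit("t", 1, 30, "+", "A" * 30, 2, covered_query_range=(3, 32))
        with pytest.raises(ValueError):
            classify_conservation(hit)


class TestFlanks:
    def test_standard_windows(self, motif):
        genome, truth, _ = gen_genome(
            PlantSpec(length=20_000, copies=(CopySpec(position=10_000),), seed=3), motif
        )
        (h,) = [x for x in _full(scan_sequence(genome, motif, 0)) if x.passes_filter]
        up, down = extract_flanks(genome, h, near=5000, far=6000)
        assert len(up.sequence) == 1000 and len(down.sequence) == 1000
        assert not up.clipped and not down.clipped
        assert up.end == h.start - 5001 and down.start == h.end + 5001

    def test_clipping_flagged(self, motif):
        target = NucSequence("t", "A" * 300)
        hit = MotifHit("t", 50, 81, "+", "A" * 32, 0)
        up, down = extract_flanks(target, hit, near=0, far=100)
        assert up.clipped and len(up.sequence) == 49
        assert not down.clipped and len(down.sequence) == 100

    def test_unplanted_flanks_contain_no_motif(self, motif):
        genome, _, _ = gen_genome(
            PlantSpec(length=30_000, copies=(CopySpec(position=15_000),), seed=8), motif
        )
        (h,) = [x for x in _full(scan_sequence(genome, motif, 0)) if x.passes_filter]
        up, down = extract_flanks(genome, h, near=1000, far=6000)
        for seg in (up, down):
            assert not any(
                x.passes_filter for x in scan_sequence(seg.sequence, motif, 11)
            )

    def test_errors(self, motif):
        target = NucSequence("t", "A" * 100)
        hit = MotifHit("t", 50, 81, "+", "A" * 32, 0)
        with pytest.raises(ValueError):
            extract_flanks(target, hit, near=100, far=50)
        with pytest.raises(ValueError):
            extract_flanks(target, MotifHit("t", 90, 121, "+", "A" * 32, 0), 0, 10)


class TestColocalize:
    def test_five_prime_flanking(self):
        hit = MotifHit("chr1", 1000, 1031, "+", "A" * 32, 0)
        locus = GeneLocus("chr1", 5000, 15000, "+", "myh")
        (out,) = colocalize([hit], [locus])
        assert out.locus_label == "myh:5_flanking"
        assert out.locus_distance == 5000 - 1031

    def test_different_scaffold(self):
        hit = MotifHit("chr2", 1000, 1031, "+", "A" * 32, 0)
        (out,) = colocalize([hit], [GeneLocus("chr1", 5000, 15000, "+", "myh")])
        assert out.locus_label == "different_scaffold"

    def test_planted_flanking_configuration(self, motif):
        # one copy 5' and one copy 3' of a planted locus: the primitive
        # single-gene arrangement
        genome, truth, _ = gen_genome(
            PlantSpec(
                length=60_000,
                copies=(CopySpec(position=10_000), CopySpec(position=50_000, strand="-")),
                seed=12,
            ),
            motif,
        )
        locus = GeneLocus(genome.id, 20_000, 40_000, "+", "smyhc3")
        hits = [h for h in _full(scan_sequence(genome, motif, 0)) if h.passes_filter]
        out = {h.start: h.locus_label for h in colocalize(hits, [locus])}
        assert out[10_000] == "smyhc3:5_flanking"
        assert out[50_000] == "smyhc3:3_flanking"

    def test_intragenic(self):
        hit = MotifHit("chr1", 7000, 7031, "+", "A" * 32, 0)
        (out,) = colocalize([hit], [GeneLocus("chr1", 5000, 15000, "+", "myh")])
        assert out.locus_label == "myh:intragenic" and out.locus_distance == 0


class TestUtilities:
    def test_reduce_overlaps_prefers_fewest_mismatches(self):
        hits = [
            MotifHit("t", 10, 41, "+", "A" * 32, 3),
            MotifHit("t", 12, 43, "+", "A" * 32, 1),
            MotifHit("t", 50, 81, "+", "A" * 32, 0),
        ]
        reduced = reduce_overlaps(hits)
        assert [(h.start, h.total_mismatches) for h in reduced] == [(12, 1), (50, 0)]

    def test_bed_round_trip(self, tmp_path):
        loci = [GeneLocus("chr1", 101, 200, "+", "a"), GeneLocus("s2", 5, 10, "-", "b")]
        p = tmp_path / "loci.bed"
        write_bed_loci(loci, p)
        assert read_bed_loci(p) == loci

    def test_hits_frame_columns(self, motif):
        hits = scan_sequence(motif.consensus, motif, 0)
        df = hits_to_frame(hits)
        assert list(df.columns)[:6] == [
            "target_id", "start", "end", "strand", "sequence", "total_mismatches",
        ]
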