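"""Segment alignment, CDR3 extraction, productivity and SHM counting."""

import numpy as np
import pytest

from igrecon.annotate import (
    AnnotationError,
    align_to_segments,
    annotate_contig,
    count_shm,
)
from igrecon.assemble import Contig
from igrecon.dna import random_dna, revcomp, STOP_CODONS
from igrecon.simulate import apply_shm, simulate_recombination


def _contig(seq):
    return Contig("c1", seq, 1.0)


class TestAlignToSegments:
    def test_self_alignment_is_top_hit_at_full_identity(self, db):
        seg = db.segments("IGH", "V")[2]
        hits = align_to_segments(_contig(seg.sequence), db, "IGH", "V")
        assert hits[0].allele_id == seg.allele_id
        assert hits[0].identity == 100.0
        assert hits[0].strand == "+"
        assert (hits[0].contig_start, hits[0].contig_end) == (0, len(seg.sequence))

    def test_reverse_complement_reports_minus_strand(self, db):
        seg = db.segments("IGH", "V")[2]
        hits = align_to_segments(_contig(revcomp(seg.sequence)), db, "IGH", "V")
        assert hits[0].allele_id == seg.allele_id
        assert hits[0].strand == "-"

    def test_planted_substitutions_are_reported_positionally(self, db):
        """Five planted substitutions come back as exactly those mismatch
        positions (planted-mutation oracle)."""
        seg = db.segments("IGK", "V")[0]
        rng = np.random.default_rng(6)
        planted = sorted(rng.choice(range(20, 280), size=5, replace=False))
        seq = list(seg.sequence)
        for pos in planted:
            seq[pos] = next(b for b in "ACGT" if b != seq[pos])
        hits = align_to_segments(_contig("".join(seq)), db, "IGK", "V")
        assert hits[0].allele_id == seg.allele_id
        assert sorted(m[0] for m in hits[0].mismatches) == planted


class TestAnnotateContig:
    def test_simulated_transcript_matches_truth(self, db):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            chain = ("IGH", "IGK", "IGL")[seed % 3]
            t = simulate_recombination(db, chain, rng)
            ann = annotate_contig(_contig(t.transcript), db)
            assert ann is not None
            assert (ann.chain, ann.v_call, ann.j_call) == (chain, t.v_id, t.j_id)
            assert ann.c_call == t.c_id
            assert ann.cdr3_nt == t.cdr3_nt
            assert ann.productive

    def test_strand_symmetry(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(200))
        fwd = annotate_contig(_contig(t.transcript), db)
        rev = annotate_contig(_contig(revcomp(t.transcript)), db)
        assert (fwd.v_call, fwd.j_call, fwd.cdr3_nt, fwd.productive) == (
            rev.v_call, rev.j_call, rev.cdr3_nt, rev.productive
        )
        assert (fwd.strand, rev.strand) == ("+", "-")

    def test_forced_stop_in_cdr3_kills_productivity(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(201))
        # overwrite the codon after the conserved Cys with an in-frame stop
        pos = t.cys_pos + 3
        seq = t.transcript[:pos] + "TAA" + t.transcript[pos + 3 :]
        ann = annotate_contig(_contig(seq), db)
        assert ann is not None
        assert ann.stop_codon
        assert not ann.productive

    def test_random_contig_is_no_call(self, db):
        ann = annotate_contig(_contig(random_dna(np.random.default_rng(7), 1000)), db)
        assert ann is None

    def test_missing_anchor_raises_named_error(self, db):
        from igrecon.germline import GermlineDatabase, GermlineSegment
        t = simulate_recombination(db, "IGH", np.random.default_rng(202))
        bare = GermlineDatabase()
        v = db.get(t.v_id)
        j = db.get(t.j_id)
        bare.add(GermlineSegment("IGHVx*01", "IGH", "V", v.sequence))  # no anchor
        bare.add(GermlineSegment(j.allele_id, "IGH", "J", j.sequence,
                                 jtrp_offset=j.jtrp_offset, reading_frame=j.reading_frame))
        with pytest.raises(AnnotationError, match="IGHVx"):
            annotate_contig(_contig(t.transcript), bare)


class TestCountShm:
    def test_unmutated_chain_counts_zero(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(300))
        ann = annotate_contig(_contig(t.transcript), db)
        assert count_shm(ann, db) == 0

    @pytest.mark.parametrize("chain,n", [("IGL", 16), ("IGH", 23)])
    def test_planted_mutation_count_recovered_exactly(self, db, chain, n):
        rng = np.random.default_rng(301)
        t = apply_shm(simulate_recombination(db, chain, rng), n, rng)
        ann = annotate_contig(_contig(t.transcript), db)
        assert ann.productive
        assert count_shm(ann, db) == n

    def test_mutations_in_n_inserts_never_counted(self, db):
        """Differences planted only inside junctional N inserts contribute 0
        (truth-position oracle for the N-diversity exclusion)."""
        rng = np.random.default_rng(302)
        t = None
        while t is None or not t.n1_insert:
            t = simulate_recombination(db, "IGH", rng)
        start = t.v_end  # N1 insert spans [v_end, v_end + |n1|)
        seq = list(t.transcript)
        for i, base in enumerate(t.n1_insert):
            seq[start + i] = next(b for b in "ACGT" if b != base)
        ann = annotate_contig(_contig("".join(seq)), db)
        assert ann is not None
        assert count_shm(ann, db) == 0

    def test_edge_position_mutations_are_counted(self, db):
        """A substitution at the very first base of V must still be counted
        (flank extension past the local-alignment trim)."""
        t = simulate_recombination(db, "IGK", np.random.default_rng(303))
        seq = t.transcript
        seq = ("A" if seq[0] != "A" else "C") + seq[1:]
        ann = annotate_contig(_contig(seq), db)
        assert count_shm(ann, db) == 1
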