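"""Simulator contracts: recombination, SHM planting, read generation."""

import numpy as np
import pytest
from scipy import stats

from igrecon.dna import revcomp, STOP_CODONS
from igrecon.simulate import (
    BCELL_IG_FRACTION,
    PLASMABLAST_IG_FRACTION,
    ReadConfig,
    SimulationError,
    apply_shm,
    simulate_cell,
    simulate_cell_reads,
    simulate_cohort,
    simulate_recombination,
    synthetic_germline_db,
)


class TestRecombination:
    def test_zero_diversity_is_exact_germline_concatenation(self, db):
        rng = np.random.default_rng(5)
        t = simulate_recombination(db, "IGH", rng, force_zero_diversity=True)
        parts = [db.get(t.v_id).sequence, db.get(t.d_id).sequence,
                 db.get(t.j_id).sequence, db.get(t.c_id).sequence]
        assert t.transcript == "".join(parts)

    def test_same_seed_is_deterministic(self, db):
        t1 = simulate_recombination(db, "IGH", np.random.default_rng(9))
        t2 = simulate_recombination(db, "IGH", np.random.default_rng(9))
        assert t1 == t2

    @pytest.mark.parametrize("chain", ["IGH", "IGK", "IGL"])
    def test_junction_is_productive(self, db, chain):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = simulate_recombination(db, chain, rng)
            assert t.cdr3_nt in t.transcript
            assert len(t.cdr3_nt) % 3 == 0
            # no stop codon in the CDR3 frame through the J end
            for i in range(t.cys_pos % 3, t.j_end - 2, 3):
                assert t.transcript[i : i + 3] not in STOP_CODONS

    def test_trim_distribution_uniform(self, db):
        """Empirical V-trim distribution over 1,000 draws stays within
        3-sigma multinomial bounds of uniform on [0, 5]."""
        rng = np.random.default_rng(123)
        draws = [simulate_recombination(db, "IGK", rng).v_trim for _ in range(1000)]
        counts = np.bincount(draws, minlength=6)
        n, p = 1000, 1 / 6
        sigma = np.sqrt(n * p * (1 - p))
        assert all(abs(c - n * p) <= 3 * sigma for c in counts), counts
        # and a chi-square sanity check
        assert stats.chisquare(counts).pvalue > 1e-4


class TestShm:
    def test_zero_mutations_is_identity(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(2))
        assert apply_shm(t, 0, np.random.default_rng(0)).transcript == t.transcript

    def test_planted_count_and_v_span(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(2))
        mutated = apply_shm(t, 23, np.random.default_rng(3))
        assert len(mutated.shm_positions) == 23
        assert all(0 <= pos < t.v_end for pos, _r, _a in mutated.shm_positions)
        # mutations stay clear of the junction (N-diversity exclusion well-posed)
        assert all(pos < t.cys_pos for pos, _r, _a in mutated.shm_positions)

    def test_replay_oracle(self, db):
        """Applying the recorded substitutions to the pre-SHM transcript
        reproduces the post-SHM transcript."""
        t = simulate_recombination(db, "IGL", np.random.default_rng(4))
        mutated = apply_shm(t, 16, np.random.default_rng(5))
        replay = list(t.transcript)
        for pos, ref, alt in mutated.shm_positions:
            assert replay[pos] == ref
            replay[pos] = alt
        assert "".join(replay) == mutated.transcript

    def test_excess_mutations_rejected(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(2))
        with pytest.raises(ValueError):
            apply_shm(t, t.cys_pos + 1, np.random.default_rng(0))


class TestReads:
    def test_rounding_contract(self, db, background):
        cell = simulate_cell(db, "c1", np.random.default_rng(1))
        cell.ig_fraction = 0.30
        rs = simulate_cell_reads(cell, background, ReadConfig(total_reads=10_000),
                                 np.random.default_rng(0))
        n_ig = sum(1 for r in rs if r.origin != "background")
        assert n_ig == 3000

    def test_error_free_reads_are_transcript_substrings(self, db, background):
        cell = simulate_cell(db, "c1", np.random.default_rng(1))
        cell.ig_fraction = 0.9999  # effectively all-Ig
        rs = simulate_cell_reads(cell, background,
                                 ReadConfig(total_reads=1000, error_rate=0.0),
                                 np.random.default_rng(0))
        sources = {"ig_heavy": cell.heavy.transcript, "ig_light": cell.light.transcript}
        for r in rs:
            if r.origin == "background":
                continue
            src = sources[r.origin]
            assert r.seq1 in src or revcomp(r.seq1) in src

    def test_pe_layout_has_both_mates(self, db, background):
        cell = simulate_cell(db, "c1", np.random.default_rng(1))
        rs = simulate_cell_reads(cell, background,
                                 ReadConfig(layout="PE", read_length=75, total_reads=1000),
                                 np.random.default_rng(0))
        assert all(r.seq2 is not None and len(r.seq2) == 75 for r in rs)

    def test_reproducible_from_seed(self, db, background):
        cell = simulate_cell(db, "c1", np.random.default_rng(1))
        cfg = ReadConfig(total_reads=2000)
        a = simulate_cell_reads(cell, background, cfg, np.random.default_rng(7))
        b = simulate_cell_reads(cell, background, cfg, np.random.default_rng(7))
        assert [(r.read_id, r.seq1) for r in a] == [(r.read_id, r.seq1) for r in b]

    def test_plasmablast_ig_fractions_in_range(self, db):
        rng = np.random.default_rng(42)
        lo, hi = PLASMABLAST_IG_FRACTION
        for i in range(100):
            cell = simulate_cell(db, f"c{i}", rng)
            assert lo <= cell.ig_fraction <= hi

    def test_bcell_ig_fractions_in_range(self, db):
        rng = np.random.default_rng(42)
        lo, hi = BCELL_IG_FRACTION
        for i in range(50):
            cell = simulate_cell(db, f"c{i}", rng, cell_type="b_cell")
            assert lo <= cell.ig_fraction <= hi


class TestCohort:
    def test_planted_families_share_clonotype_keys(self, db):
        cells = simulate_cohort(db, 8, seed=1, family_sizes=[3, 2])
        def key(c):
            return (c.heavy.v_gene, c.heavy.j_gene, len(c.heavy.cdr3_nt),
                    c.light.v_gene, c.light.j_gene, len(c.light.cdr3_nt))
        keys = [key(c) for c in cells]
        assert keys[0] == keys[1] == keys[2]
        assert keys[3] == keys[4]
        assert len({keys[0], keys[3], *keys[5:]}) == 1 + 1 + 3

    def test_oversized_families_rejected(self, db):
        with pytest.raises(SimulationError):
            simulate_cohort(db, 3, seed=1, family_sizes=[4])
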