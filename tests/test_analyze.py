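"""Reference concordance, accuracy summaries, clonal families."""

import numpy as np
import pytest

from igrecon.analyze import (
    ClonalFamily,
    ValidationRecord,
    assign_clonal_families,
    compare_to_reference,
    summarize_accuracy,
)
from igrecon.annotate import annotate_contig
from igrecon.assemble import Contig
from igrecon.dna import revcomp
from igrecon.select import ChainCall, RankedModel
from igrecon.simulate import simulate_recombination, simulate_cohort


def _call(db, transcript, cell_id="cell1", chain=None, count=100):
    contig = Contig("m1", transcript, 10.0)
    ann = annotate_contig(contig, db)
    assert ann is not None
    return ChainCall(cell_id, chain or ann.chain,
                     RankedModel(contig, ann, count, 1), 0, float(count), False)


class TestCompareToReference:
    def test_identical_sequences_are_accurate(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(1))
        rec = compare_to_reference(_call(db, t.transcript), t.transcript, db)
        assert rec.evaluable and rec.accurate
        assert rec.nt_identity == 100.0
        assert rec.coverage == 100.0

    def test_single_cdr3_edit_breaks_accuracy(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(2))
        pos = t.cys_pos + 4
        ref = t.transcript[:pos] + ("A" if t.transcript[pos] != "A" else "G") + t.transcript[pos + 1:]
        rec = compare_to_reference(_call(db, t.transcript), ref, db)
        assert rec.evaluable
        assert rec.v_match and rec.j_match
        assert not rec.cdr3_match
        assert not rec.accurate

    def test_truncated_reference_still_accurate_with_full_coverage(self, db):
        """A 5'-truncated reference (as amplicon references are) is covered
        end-to-end by the full-length reconstruction."""
        t = simulate_recombination(db, "IGK", np.random.default_rng(3))
        ref = t.transcript[150:]  # drop half the V
        rec = compare_to_reference(_call(db, t.transcript), ref, db)
        assert rec.evaluable and rec.accurate
        assert rec.coverage == 100.0

    def test_unannotatable_reference_is_non_evaluable(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(4))
        rec = compare_to_reference(_call(db, t.transcript), "ACGT" * 100, db)
        assert not rec.evaluable and not rec.accurate

    def test_reverse_complement_reference_same_verdict(self, db):
        t = simulate_recombination(db, "IGH", np.random.default_rng(5))
        fwd = compare_to_reference(_call(db, t.transcript), t.transcript, db)
        rev = compare_to_reference(_call(db, t.transcript), revcomp(t.transcript), db)
        assert fwd.accurate == rev.accurate is True


def _vr(cell, chain, accurate, evaluable=True):
    return ValidationRecord(cell, chain, evaluable=evaluable,
                            accurate=accurate, cdr3_match=accurate,
                            v_match=accurate, j_match=accurate, d_match=True)


class TestSummarizeAccuracy:
    def test_simple_ratio(self):
        records = [_vr(f"c{i}", "IGH", i != 0) for i in range(10)]
        s = summarize_accuracy(records)
        assert s.per_chain["IGH"] == (10, 9, 0.9)

    def test_paired_definition(self):
        records = []
        for i in range(3):
            records += [_vr(f"c{i}", "IGH", True), _vr(f"c{i}", "IGK", True)]
        records += [_vr("c3", "IGH", True), _vr("c3", "IGK", False)]
        s = summarize_accuracy(records)
        assert (s.paired_evaluable, s.paired_accurate) == (4, 3)
        assert s.paired_accuracy == 0.75

    def test_clonotype_collapsed_accuracy(self):
        """4 accurate cells in one family + 1 wrong singleton -> 50%."""
        records = []
        for i in range(4):
            records += [_vr(f"f{i}", "IGH", True), _vr(f"f{i}", "IGL", True)]
        records += [_vr("s0", "IGH", False), _vr("s0", "IGL", True)]
        fam = ClonalFamily("CF01", ("V", "J", 9, "V", "J", 9), [f"f{i}" for i in range(4)])
        s = summarize_accuracy(records, families=[fam])
        assert s.clonotype_collapsed_accuracy == 0.5

    def test_order_invariance(self):
        records = [_vr(f"c{i}", "IGH", i % 3 != 0) for i in range(9)]
        records += [_vr(f"c{i}", "IGL", True) for i in range(9)]
        a = summarize_accuracy(records)
        b = summarize_accuracy(list(reversed(records)))
        assert a == b

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_accuracy([])


class TestClonalFamilies:
    def test_identical_keys_merge(self, db):
        t_h = simulate_recombination(db, "IGH", np.random.default_rng(10))
        t_l = simulate_recombination(db, "IGK", np.random.default_rng(11))
        cells = {
            "a": (_call(db, t_h.transcript, "a"), _call(db, t_l.transcript, "a")),
            "b": (_call(db, t_h.transcript, "b"), _call(db, t_l.transcript, "b")),
        }
        families, excluded = assign_clonal_families(cells)
        assert len(families) == 1
        assert families[0].members == ["a", "b"]
        assert excluded == []

    def test_missing_chain_excluded_and_reported(self, db):
        t_h = simulate_recombination(db, "IGH", np.random.default_rng(12))
        t_l = simulate_recombination(db, "IGL", np.random.default_rng(13))
        cells = {
            "ok": (_call(db, t_h.transcript, "ok"), _call(db, t_l.transcript, "ok")),
            "noheavy": (None, _call(db, t_l.transcript, "noheavy")),
        }
        families, excluded = assign_clonal_families(cells)
        assert excluded == ["noheavy"]
        assert [f.members for f in families] == [["ok"]]

    def test_cdr3_length_sensitivity(self, db):
        """Two cells differing only in light CDR3 length form two families."""
        rng = np.random.default_rng(14)
        t_h = simulate_recombination(db, "IGH", rng)
        while True:
            l1 = simulate_recombination(db, "IGK", rng)
            l2 = simulate_recombination(db, "IGK", rng)
            if (l1.v_id, l1.j_id) == (l2.v_id, l2.j_id) and len(l1.cdr3_nt) != len(l2.cdr3_nt):
                break
        cells = {
            "a": (_call(db, t_h.transcript, "a"), _call(db, l1.transcript, "a")),
            "b": (_call(db, t_h.transcript, "b"), _call(db, l2.transcript, "b")),
        }
        families, _ = assign_clonal_families(cells)
        assert len(families) == 2

    def test_partition_property(self, db):
        """Families are disjoint and cover every eligible cell."""
        cohort = simulate_cohort(db, 12, seed=3, family_sizes=[4, 3])
        cells = {
            c.cell_id: (_call(db, c.heavy.transcript, c.cell_id),
                        _call(db, c.light.transcript, c.cell_id))
            for c in cohort
        }
        families, excluded = assign_clonal_families(cells)
        assert excluded == []
        members = [cid for f in families for cid in f.members]
        assert sorted(members) == sorted(cells)
        assert len(members) == len(set(members))
        sizes = sorted((len(f.members) for f in families), reverse=True)
        assert sizes[:2] == [4, 3]
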