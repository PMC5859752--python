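"""Germline database loading, recombinome construction, V/J/C references."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from igrecon.germline import (
    GermlineDatabase,
    GermlineError,
    GermlineSegment,
    build_recombinome,
    load_anchor_tsv,
    load_germline_fasta,
    make_vjc_reference,
    write_segments_fasta,
)


def _mini_db(nv=1, nj=1, nc=1, chain="IGH", vseq="AAA", jseq="CCC", cseq="GGG"):
    db = GermlineDatabase()
    for i in range(nv):
        db.add(GermlineSegment(f"{chain}V{i}*01", chain, "V", vseq + "ACGT"[i % 4]))
    for i in range(nj):
        db.add(GermlineSegment(f"{chain}J{i}*01", chain, "J", jseq + "ACGT"[i % 4]))
    for i in range(nc):
        db.add(GermlineSegment(f"{chain}C{i}*01", chain, "C", cseq + "ACGT"[i % 4]))
    return db


class TestLoadFasta:
    def test_count_and_canonicalization(self, tmp_path):
        path = tmp_path / "v.fasta"
        path.write_text(">IGHV1*01\nacgtacgt\n>IGHV2*01 cys104=3 frame=0\nAAACCCGGG\n>IGHV3*01\nTTTT\n")
        db = load_germline_fasta(path, "IGH", "V")
        assert len(db.segments("IGH", "V")) == 3
        assert db.get("IGHV1*01").sequence == "ACGTACGT"
        assert db.get("IGHV2*01").cys104_offset == 3

    def test_duplicate_id_rejected_by_name(self, tmp_path):
        path = tmp_path / "v.fasta"
        path.write_text(">IGHV1*01\nACGT\n>IGHV1*01\nACGT\n")
        with pytest.raises(GermlineError, match="IGHV1\\*01"):
            load_germline_fasta(path, "IGH", "V")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(GermlineError):
            load_germline_fasta(path, "IGH", "V")

    def test_roundtrip_with_anchor_sidecar(self, tmp_path, db):
        write_segments_fasta(db, tmp_path / "IGH_V.fasta", "IGH", "V")
        loaded = load_germline_fasta(tmp_path / "IGH_V.fasta", "IGH", "V")
        seg = db.segments("IGH", "V")[0]
        assert loaded.get(seg.allele_id).sequence == seg.sequence
        assert loaded.get(seg.allele_id).cys104_offset == seg.cys104_offset
        # anchors can also arrive via sidecar TSV
        sidecar = tmp_path / "anchors.tsv"
        sidecar.write_text(
            "allele_id\tanchor_type\toffset\n" + f"{seg.allele_id}\tcys104\t12\n"
        )
        load_anchor_tsv(sidecar, loaded)
        assert loaded.get(seg.allele_id).cys104_offset == 12


class TestRecombinome:
    def test_single_triple_layout(self):
        db = GermlineDatabase()
        db.add(GermlineSegment("V1*01", "IGH", "V", "AAA"))
        db.add(GermlineSegment("J1*01", "IGH", "J", "CCC"))
        db.add(GermlineSegment("C1*01", "IGH", "C", "GGG"))
        entries = build_recombinome(db, "IGH")
        assert len(entries) == 1
        assert entries[0].sequence == "N" * 20 + "AAA" + "N" * 10 + "CCC" + "GGG"
        assert entries[0].allele_ids == ("V1*01", "J1*01", "C1*01")

    def test_matches_bruteforce_enumeration(self):
        db = _mini_db(nv=2, nj=2, nc=2)
        entries = build_recombinome(db, "IGH")
        expected = set()
        for v, j, c in itertools.product(
            db.segments("IGH", "V"), db.segments("IGH", "J"), db.segments("IGH", "C")
        ):
            expected.add(
                "N" * 20 + v.sequence + "N" * 10 + j.sequence + c.sequence
            )
        assert len(entries) == 8
        assert {e.sequence for e in entries} == expected

    def test_light_chain_has_no_junction_pad_by_default(self):
        db = _mini_db(chain="IGK")
        (entry,) = build_recombinome(db, "IGK")
        assert "N" * 20 in entry.sequence
        v = db.segments("IGK", "V")[0].sequence
        j = db.segments("IGK", "J")[0].sequence
        assert v + j in entry.sequence

    def test_missing_class_rejected(self):
        db = GermlineDatabase()
        db.add(GermlineSegment("V1*01", "IGH", "V", "AAA"))
        db.add(GermlineSegment("J1*01", "IGH", "J", "CCC"))
        with pytest.raises(GermlineError, match="no C"):
            build_recombinome(db, "IGH")

    @settings(max_examples=25, deadline=None)
    @given(nv=st.integers(1, 4), nj=st.integers(1, 3), nc=st.integers(1, 3))
    def test_cardinality_and_substring_order(self, nv, nj, nc):
        db = _mini_db(nv=nv, nj=nj, nc=nc, vseq="ACGTAC", jseq="TTGGCC", cseq="GATCGA")
        entries = build_recombinome(db, "IGH")
        assert len(entries) == nv * nj * nc
        assert entries == build_recombinome(db, "IGH")  # deterministic
        for e in entries:
            v_id, j_id, c_id = e.allele_ids
            v, j, c = (db.get(x).sequence for x in (v_id, j_id, c_id))
            iv = e.sequence.find(v)
            ij = e.sequence.find(j, iv + len(v))
            ic = e.sequence.find(c, ij + len(j))
            assert 0 <= iv < ij < ic


class TestVjcReference:
    def test_count_and_no_d(self, db):
        refs = make_vjc_reference(db, "IGH")
        n_expected = sum(
            len(db.segments("IGH", cls)) for cls in ("V", "J", "C")
        )
        assert len(refs) == n_expected
        d_ids = {s.allele_id for s in db.segments("IGH", "D")}
        assert not d_ids & {rid for rid, _ in refs}

    def test_heavy_and_light_disjoint(self, db):
        igh = {rid for rid, _ in make_vjc_reference(db, "IGH")}
        igl = {rid for rid, _ in make_vjc_reference(db, "IGL")}
        assert not igh & igl

    def test_empty_chain_rejected(self):
        db = GermlineDatabase()
        db.add(GermlineSegment("V1*01", "IGH", "V", "AAA"))
        with pytest.raises(GermlineError):
            make_vjc_reference(db, "IGK")
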