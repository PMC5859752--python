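"""Filtering strategies, locus adjudication and SAM interop."""

import numpy as np
import pytest

from igrecon.filterreads import (
    FilterConfig,
    FilterConfigError,
    FilterResources,
    LocusTable,
    filter_reads,
    read_gff3,
    read_sam_hits,
    write_gff3,
    write_sam_hits,
)
from igrecon.reads import Read, ReadSet
from igrecon.simulate import ReadConfig, simulate_cell, simulate_cell_reads


def _config(strategy):
    return FilterConfig(strategy=strategy)


class TestStrategies:
    def test_unfiltered_is_identity(self, small_readset, resources):
        out = filter_reads(small_readset, _config("unfiltered"), resources)
        assert [r.read_id for r in out] == [r.read_id for r in small_readset]

    @pytest.mark.parametrize("strategy", [
        "ig_mapped", "ig_mapped_plus_unmapped", "recombinome_mapped",
        "imgt_mapped", "filter_non_ig",
    ])
    def test_retained_is_ordered_subset(self, small_readset, resources, strategy):
        out = filter_reads(small_readset, _config(strategy), resources)
        ids_in = [r.read_id for r in small_readset]
        ids_out = [r.read_id for r in out]
        assert set(ids_out) <= set(ids_in)
        assert ids_out == [i for i in ids_in if i in set(ids_out)]

    def test_monotone_containment(self, small_readset, resources):
        a = {r.read_id for r in filter_reads(small_readset, _config("ig_mapped"), resources)}
        b = {r.read_id for r in filter_reads(
            small_readset, _config("ig_mapped_plus_unmapped"), resources)}
        assert a <= b

    def test_ig_plus_unmapped_recalls_ig_truth_reads(self, db, background, resources):
        """Truth-label oracle: every Ig-origin read is either locus-mapped or
        genome-unmapped, so the combined strategy retains all of them."""
        cell = simulate_cell(db, "cF", np.random.default_rng(21))
        rs = simulate_cell_reads(cell, background, ReadConfig(total_reads=6000),
                                 np.random.default_rng(3))
        out = filter_reads(rs, _config("ig_mapped_plus_unmapped"), resources)
        kept = {r.read_id for r in out}
        ig_ids = {r.read_id for r in rs if r.origin != "background"}
        assert ig_ids <= kept
        # and the retained set is strongly enriched
        bg_kept = len(kept - ig_ids)
        assert bg_kept < 0.02 * (len(rs) - len(ig_ids))

    def test_filter_non_ig_drops_annotated_background(self, db, background, resources):
        cell = simulate_cell(db, "cG", np.random.default_rng(22))
        rs = simulate_cell_reads(cell, background, ReadConfig(total_reads=6000),
                                 np.random.default_rng(4))
        out = filter_reads(rs, _config("filter_non_ig"), resources)
        kept = {r.read_id for r in out}
        ig_ids = {r.read_id for r in rs if r.origin != "background"}
        assert ig_ids <= kept
        bg_kept = len(kept - ig_ids)
        assert bg_kept < 0.02 * (len(rs) - len(ig_ids))

    def test_recombinome_mapped_recall_within_segments(self, db, resources):
        """Error-free reads lying wholly inside V or C map to the recombinome."""
        from igrecon.simulate import simulate_recombination
        rng = np.random.default_rng(8)
        t = simulate_recombination(db, "IGH", rng)
        v = db.get(t.v_id).sequence
        c = db.get(t.c_id).sequence
        reads = [Read(f"v{i}", v[i : i + 50]) for i in range(0, 240, 40)]
        reads += [Read(f"c{i}", c[i : i + 50]) for i in range(0, 240, 40)]
        rs = ReadSet(reads, layout="SE", read_length=50)
        out = filter_reads(rs, _config("recombinome_mapped"), resources, chain_group="heavy")
        assert len(out) == len(rs)

    def test_missing_resource_raises_named_error(self, small_readset, db):
        bare = FilterResources.from_germline(db)
        with pytest.raises(FilterConfigError, match="genome"):
            filter_reads(small_readset, _config("ig_mapped"), bare)

    def test_mate_policy_keeps_pairs_together(self, db, background, resources):
        cell = simulate_cell(db, "cH", np.random.default_rng(23))
        rs = simulate_cell_reads(cell, background,
                                 ReadConfig(layout="PE", read_length=75, total_reads=4000),
                                 np.random.default_rng(5))
        out = filter_reads(rs, _config("ig_mapped"), resources)
        assert all(r.seq2 is not None for r in out)


class TestLocusTable:
    def test_coordinates_are_one_based_closed(self):
        from igrecon.filterreads import LocusRow
        lt = LocusTable(rows=[LocusRow("chr14", 101, 200, "IGH")])
        assert lt.overlaps("chr14", 100, 101)   # 0-based [100,101) == base 101
        assert not lt.overlaps("chr14", 99, 100)  # base 100 is outside
        assert lt.overlaps("chr14", 199, 205)
        assert not lt.overlaps("chr14", 200, 205)  # starts past base 200
        assert not lt.overlaps("chr2", 100, 200)

    def test_tsv_roundtrip(self, tmp_path, bundle):
        _genome, loci, _genes = bundle
        path = tmp_path / "loci.tsv"
        loci.to_tsv(path)
        again = LocusTable.from_tsv(path)
        assert again.rows == loci.rows


class TestGff3:
    def test_roundtrip_gene_spans(self, tmp_path, bundle):
        _genome, _loci, genes = bundle
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        again = read_gff3(path)
        assert again == genes


class TestSamInterop:
    def test_flag_partition_and_coordinate_conversion(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:refA\tLN:500\n"
            "readM\t0\trefA\t100\t60\t50M\t*\t0\t0\t*\t*\tAS:i:48\n"
            "readU\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"
        )
        result = read_sam_hits(sam)
        assert set(result.hits) == {("readM", 1)}
        assert result.unmapped == {("readU", 1)}
        hit = result.best(("readM", 1))
        assert hit.reference_start == 99  # SAM POS=100 -> 0-based 99
        assert hit.reference_end == 149

    def test_write_read_roundtrip_preserves_partition(self, tmp_path, small_readset, resources):
        from igrecon.mapper import map_units
        units = list(small_readset.units())[:500]
        index = resources.genome_index(21)
        result = map_units(units, index, mode="local", report="best")
        path = tmp_path / "hits.sam"
        write_sam_hits(result, resources.genome, path)
        again = read_sam_hits(path)
        assert set(again.hits) == set(result.hits)
        assert again.unmapped == result.unmapped
        for key in result.hits:
            assert again.best(key).reference_start == result.best(key).reference_start
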