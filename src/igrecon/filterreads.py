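"""Ig-read enrichment strategies applied before assembly.

Five strategies from the human pipeline plus the rhesus variant:

* ``unfiltered`` — identity;
* ``ig_mapped`` — keep fragments whose best genome hit overlaps an Ig locus
  interval by at least 1 nt;
* ``ig_mapped_plus_unmapped`` — the above plus all genome-unmapped fragments;
* ``recombinome_mapped`` — keep fragments mapping (local) to the in-silico
  V-J-C recombinome;
* ``imgt_mapped`` — keep fragments mapping (local) to the pooled germline
  V/J/C reference;
* ``filter_non_ig`` — discard fragments whose best genome hit lies wholly
  within an annotated non-Ig gene (rhesus-style negative filter).

Mate policy: a paired fragment is retained whenever either mate qualifies.
Locus coordinates are 1-based fully-closed, as printed in genome-browser
style locus tables (note: unlike BED).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .germline import (
    GermlineDatabase,
    RecombinomeEntry,
    build_recombinome,
    make_vjc_reference,
)
from .mapper import (
    DEFAULT_K,
    DEFAULT_MIN_SCORE,
    MappingError,
    MappingHit,
    MappingResult,
    ReferenceIndex,
    map_units,
)
from .reads import ReadSet

STRATEGIES = (
    "unfiltered",
    "ig_mapped",
    "ig_mapped_plus_unmapped",
    "recombinome_mapped",
    "imgt_mapped",
    "filter_non_ig",
)

CHAIN_GROUPS = {"heavy": ("IGH",), "light": ("IGK", "IGL")}


class FilterConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LocusRow:
    chromosome: str
    start: int  # 1-based, closed
    end: int  # 1-based, closed
    chain: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FilterConfigError(
                f"locus {self.chromosome}:{self.start}-{self.end}: start > end"
            )


@dataclass
class LocusTable:
    rows: list[LocusRow] = field(default_factory=list)

    def overlaps(self, chromosome: str, start0: int, end0: int, chains: Iterable[str] | None = None) -> bool:
        """Does the 0-based half-open span overlap any locus interval (>= 1 nt)?"""
        chains = set(chains) if chains is not None else None
        for row in self.rows:
            if row.chromosome != chromosome:
                continue
            if chains is not None and row.chain not in chains:
                continue
            if start0 < row.end and end0 > row.start - 1:  # closed -> half-open
                return True
        return False

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LocusTable":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["chromosome", "start", "end", "chain"], dtype={"chromosome": str})
        return cls([LocusRow(r.chromosome, int(r.start), int(r.end), r.chain) for r in df.itertuples()])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# 1-based, fully-closed intervals\n")
            for r in self.rows:
                fh.write(f"{r.chromosome}\t{r.start}\t{r.end}\t{r.chain}\n")


@dataclass(frozen=True)
class GeneFeature:
    chromosome: str
    start: int  # 1-based, closed (GFF3 convention)
    end: int
    gene_id: str

    def contains(self, chromosome: str, start0: int, end0: int) -> bool:
        """Is the 0-based half-open span wholly inside this gene?"""
        return (
            chromosome == self.chromosome
            and start0 >= self.start - 1
            and end0 <= self.end
        )


def write_gff3(genes: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tigrecon\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read gene-span features from a GFF3 file (only type == 'gene' rows used)."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols, dtype={"seqid": str})
    out = []
    for r in df.itertuples():
        if r.type != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv)
        out.append(GeneFeature(r.seqid, int(r.start), int(r.end), attrs.get("ID", f"{r.seqid}:{r.start}")))
    return out


@dataclass
class FilterConfig:
    strategy: str = "ig_mapped_plus_unmapped"
    k: int = DEFAULT_K
    min_seed_count: int = 1
    min_score: float = DEFAULT_MIN_SCORE

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise FilterConfigError(f"unknown strategy {self.strategy!r}")
        if not 11 <= self.k <= 31:
            raise FilterConfigError(f"k must be in [11, 31], got {self.k}")
        if self.min_score <= 0 or self.min_seed_count <= 0:
            raise FilterConfigError("thresholds must be positive")


@dataclass
class FilterResources:
    """Reference material the strategies may need; indexes are built lazily."""

    germline_db: GermlineDatabase | None = None
    recombinome: dict[str, list[RecombinomeEntry]] | None = None  # chain -> entries
    genome: dict[str, str] | None = None
    locus_table: LocusTable | None = None
    gene_annotation: list[GeneFeature] | None = None
    _genome_index: ReferenceIndex | None = field(default=None, repr=False)
    _group_indexes: dict[tuple[str, str], ReferenceIndex] = field(default_factory=dict, repr=False)

    def genome_index(self, k: int) -> ReferenceIndex:
        if self.genome is None:
            raise FilterConfigError("strategy requires resource 'genome'")
        if self._genome_index is None or self._genome_index.k != k:
            self._genome_index = ReferenceIndex(self.genome, k=k)
        return self._genome_index

    def recombinome_index(self, chain_group: str, k: int) -> ReferenceIndex:
        if self.recombinome is None:
            raise FilterConfigError("strategy requires resource 'recombinome'")
        key = ("recombinome", chain_group)
        if key not in self._group_indexes or self._group_indexes[key].k != k:
            refs = []
            for chain in CHAIN_GROUPS[chain_group]:
                refs.extend((e.name, e.sequence) for e in self.recombinome.get(chain, []))
            if not refs:
                raise FilterConfigError(f"recombinome has no entries for group {chain_group!r}")
            self._group_indexes[key] = ReferenceIndex(refs, k=k)
        return self._group_indexes[key]

    def vjc_index(self, chain_group: str, k: int) -> ReferenceIndex:
        if self.germline_db is None:
            raise FilterConfigError("strategy requires resource 'germline_db'")
        key = ("vjc", chain_group)
        if key not in self._group_indexes or self._group_indexes[key].k != k:
            refs = []
            for chain in CHAIN_GROUPS[chain_group]:
                try:
                    refs.extend(make_vjc_reference(self.germline_db, chain))
                except Exception:
                    continue
            if not refs:
                raise FilterConfigError(f"no V/J/C references for group {chain_group!r}")
            self._group_indexes[key] = ReferenceIndex(refs, k=k)
        return self._group_indexes[key]

    @classmethod
    def from_germline(cls, db: GermlineDatabase, **kwargs) -> "FilterResources":
        recombinome = {
            chain: build_recombinome(db, chain) for chain in db.chains
            if db.segments(chain, "V") and db.segments(chain, "J") and db.segments(chain, "C")
        }
        return cls(germline_db=db, recombinome=recombinome, **kwargs)


def map_reads(
    reads: ReadSet,
    references: ReferenceIndex | dict[str, str] | Iterable[tuple[str, str]],
    mode: str = "local",
    report: str = "best",
    **params,
) -> MappingResult:
    """Map a ReadSet against a reference set (see :mod:`igrecon.mapper`)."""
    if not isinstance(references, ReferenceIndex):
        references = ReferenceIndex(references, k=params.pop("k", DEFAULT_K))
    else:
        params.pop("k", None)
    return map_units(reads.units(), references, mode=mode, report=report, **params)


def filter_reads(
    reads: ReadSet,
    config: FilterConfig,
    resources: FilterResources,
    chain_group: str | None = None,
    genome_mapping: MappingResult | None = None,
) -> ReadSet:
    """Apply one enrichment strategy; the retained set preserves input order.

    ``chain_group`` ('heavy' / 'light' / None=both) restricts the reference
    side for the recombinome / V-J-C strategies and the locus set for
    ``ig_mapped``; genome-wide strategies may share a precomputed
    ``genome_mapping`` across chain passes.
    """
    strategy = config.strategy
    if strategy == "unfiltered":
        return ReadSet(list(reads.reads), layout=reads.layout, read_length=reads.read_length)

    chains = CHAIN_GROUPS[chain_group] if chain_group else ("IGH", "IGK", "IGL")

    if strategy in ("ig_mapped", "ig_mapped_plus_unmapped", "filter_non_ig"):
        if genome_mapping is None:
            index = resources.genome_index(config.k)
            # substitution-only placement suffices to adjudicate locus overlap
            genome_mapping = map_units(
                reads.units(), index, mode="local", report="best",
                min_seed_count=config.min_seed_count, min_score=config.min_score,
                dp_fallback=False,
            )
        if strategy in ("ig_mapped", "ig_mapped_plus_unmapped"):
            if resources.locus_table is None:
                raise FilterConfigError("strategy requires resource 'locus_table'")
            keep = set()
            for read in reads:
                units = read.units()
                in_locus = False
                all_unmapped = True
                for _id, mate, _seq in units:
                    best = genome_mapping.best((read.read_id, mate))
                    if best is None:
                        continue
                    all_unmapped = False
                    if resources.locus_table.overlaps(
                        best.reference_id, best.reference_start, best.reference_end, chains=chains
                    ):
                        in_locus = True
                if in_locus or (strategy == "ig_mapped_plus_unmapped" and all_unmapped):
                    keep.add(read.read_id)
        else:  # filter_non_ig
            if resources.gene_annotation is None:
                raise FilterConfigError("strategy requires resource 'gene_annotation'")
            genes = resources.gene_annotation
            keep = set()
            for read in reads:
                drop = True
                for _id, mate, _seq in read.units():
                    best = genome_mapping.best((read.read_id, mate))
                    if best is None:
                        drop = False  # unmapped mate: fragment survives
                        break
                    if not any(
                        g.contains(best.reference_id, best.reference_start, best.reference_end)
                        for g in genes
                    ):
                        drop = False
                        break
                if not drop:
                    keep.add(read.read_id)
        return reads.subset(keep)

    if strategy in ("recombinome_mapped", "imgt_mapped"):
        group = chain_group or "heavy"
        if chain_group is None:
            # both groups: union of the two reference sets
            keep: set[str] = set()
            for grp in ("heavy", "light"):
                try:
                    sub = filter_reads(reads, config, resources, chain_group=grp)
                except FilterConfigError:
                    continue
                keep |= {r.read_id for r in sub}
            return reads.subset(keep)
        if strategy == "recombinome_mapped":
            index = resources.recombinome_index(group, config.k)
        else:
            index = resources.vjc_index(group, config.k)
        result = map_units(
            reads.units(), index, mode="local", report="best",
            min_seed_count=config.min_seed_count, min_score=config.min_score,
        )
        keep = {
            read.read_id
            for read in reads
            if any(result.best((read.read_id, m)) is not None for _i, m, _s in read.units())
        }
        return reads.subset(keep)

    raise FilterConfigError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# SAM interop: externally produced alignments can drive the same filters.

def read_sam_hits(path: str | Path) -> MappingResult:
    """Load a SAM file into the internal hit/unmapped representation.

    Only primary records are used; coordinates become 0-based half-open.
    """
    hits: dict[tuple[str, int], list[MappingHit]] = {}
    unmapped: set[tuple[str, int]] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = 2 if rec.is_read2 else 1
            key = (rec.query_name, mate)
            if rec.is_unmapped:
                unmapped.add(key)
                continue
            hit = MappingHit(
                read_id=rec.query_name,
                mate=mate,
                reference_id=rec.reference_name,
                reference_start=rec.reference_start,
                reference_end=rec.reference_end if rec.reference_end is not None else rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                score=float(rec.get_tag("AS")) if rec.has_tag("AS") else float(rec.query_length or 0),
                mode="local",
            )
            hits.setdefault(key, []).append(hit)
    return MappingResult(hits, unmapped)


def write_sam_hits(
    result: MappingResult,
    references: dict[str, str],
    path: str | Path,
    read_lengths: dict[tuple[str, int], int] | None = None,
) -> None:
    """Serialize a mapping result to SAM (sequence-less records)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in references.items()],
    }
    ref_ids = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for key in sorted(result.hits):
            for hit in result.hits[key]:
                rec = pysam.AlignedSegment(fh.header)
                rec.query_name = hit.read_id
                rec.reference_id = ref_ids[hit.reference_id]
                rec.reference_start = hit.reference_start
                rec.flag = (16 if hit.strand == "-" else 0) | (0 if hit.mate == 1 else 128 | 1)
                if hit.mate == 2:
                    rec.flag |= 1
                span = hit.reference_end - hit.reference_start
                rec.cigarstring = f"{span}M" if span > 0 else None
                rec.mapping_quality = 255
                rec.set_tag("AS", int(hit.score))
                fh.write(rec)
        for read_id, mate in sorted(result.unmapped):
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = read_id
            rec.flag = 4 | (0 if mate == 1 else 128 | 1)
            rec.mapping_quality = 0
            fh.write(rec)
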