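"""Germline immunoglobulin segment databases and derived filter references.

A :class:`GermlineDatabase` holds V/D/J/C alleles per chain (IGH, IGK, IGL),
loaded from FASTA with IMGT-style allele names.  From it we derive the two
reference sets used for Ig-read enrichment:

* the *recombinome* — every ordered (V, J, C) combination, with 20 leading N
  bases standing in for the leader sequence and, on the heavy chain, 10 N
  bases replacing the D segment;
* the combined V/J/C reference — the raw segment sequences pooled per
  heavy/light chain group.

CDR3 anchor positions (second conserved cysteine on V, J-TRP/PHE on J) are
carried on the segments themselves; plain FASTA headers may embed them as
``key=value`` pairs, or they can be supplied in a sidecar TSV.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import DNA_ALPHABET

CHAINS = ("IGH", "IGK", "IGL")
SEGMENT_CLASSES = ("V", "D", "J", "C")
LIGHT_CHAINS = ("IGK", "IGL")

#: Default N padding: leader placeholder and (heavy chain) D placeholder.
LEADER_PAD = 20
HEAVY_JUNCTION_PAD = 10


class GermlineError(ValueError):
    """Raised for malformed or incomplete germline databases."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D, J or C allele.

    ``cys104_offset`` (V only) and ``jtrp_offset`` (J only) are 0-based
    offsets of the first base of the conserved anchor codon, in-frame with
    ``reading_frame``.
    """

    allele_id: str
    chain: str
    segment_class: str
    sequence: str
    cys104_offset: int | None = None
    jtrp_offset: int | None = None
    reading_frame: int = 0

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise GermlineError(f"unknown chain {self.chain!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise GermlineError(f"unknown segment class {self.segment_class!r}")
        if not self.sequence or not set(self.sequence) <= DNA_ALPHABET:
            raise GermlineError(
                f"segment {self.allele_id}: sequence empty or not over ACGTN"
            )
        if self.reading_frame not in (0, 1, 2):
            raise GermlineError(f"segment {self.allele_id}: bad reading frame")
        for name, off in (("cys104", self.cys104_offset), ("jtrp", self.jtrp_offset)):
            if off is None:
                continue
            if not 0 <= off <= len(self.sequence) - 3:
                raise GermlineError(
                    f"segment {self.allele_id}: {name} offset {off} outside sequence"
                )
            if (off - self.reading_frame) % 3 != 0:
                raise GermlineError(
                    f"segment {self.allele_id}: {name} offset {off} out of frame"
                )

    @property
    def gene(self) -> str:
        """Gene name with the allele designation stripped (IGHV1-69*01 -> IGHV1-69)."""
        return self.allele_id.split("*")[0]


class GermlineDatabase:
    """Segments indexed by (chain, segment_class) and by allele_id."""

    def __init__(self, species: str = "human") -> None:
        self.species = species
        self._by_class: dict[tuple[str, str], list[GermlineSegment]] = {}
        self._by_id: dict[str, GermlineSegment] = {}

    def add(self, segment: GermlineSegment) -> None:
        if segment.allele_id in self._by_id:
            raise GermlineError(f"duplicate allele_id {segment.allele_id!r}")
        self._by_id[segment.allele_id] = segment
        self._by_class.setdefault((segment.chain, segment.segment_class), []).append(
            segment
        )

    def segments(self, chain: str, segment_class: str) -> list[GermlineSegment]:
        return list(self._by_class.get((chain, segment_class), []))

    def get(self, allele_id: str) -> GermlineSegment:
        try:
            return self._by_id[allele_id]
        except KeyError:
            raise GermlineError(f"unknown allele_id {allele_id!r}") from None

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self._by_id

    def __iter__(self) -> Iterator[GermlineSegment]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def chains(self) -> list[str]:
        return sorted({c for (c, _s) in self._by_class})

    def validate(self, chains: Iterable[str] | None = None) -> None:
        """Check that every (requested) chain has at least one V and one J."""
        for chain in chains if chains is not None else self.chains:
            for cls in ("V", "J"):
                if not self._by_class.get((chain, cls)):
                    raise GermlineError(f"no {cls} segments for chain {chain}")

    def set_anchor(self, allele_id: str, anchor_type: str, offset: int) -> None:
        seg = self.get(allele_id)
        if anchor_type == "cys104":
            updated = GermlineSegment(
                seg.allele_id, seg.chain, seg.segment_class, seg.sequence,
                cys104_offset=offset, jtrp_offset=seg.jtrp_offset,
                reading_frame=seg.reading_frame,
            )
        elif anchor_type == "jtrp":
            updated = GermlineSegment(
                seg.allele_id, seg.chain, seg.segment_class, seg.sequence,
                cys104_offset=seg.cys104_offset, jtrp_offset=offset,
                reading_frame=seg.reading_frame,
            )
        else:
            raise GermlineError(f"unknown anchor type {anchor_type!r}")
        self._by_id[allele_id] = updated
        lst = self._by_class[(seg.chain, seg.segment_class)]
        lst[lst.index(seg)] = updated


@dataclass(frozen=True)
class RecombinomeEntry:
    """One in-silico V-J-C recombination with N padding."""

    name: str  # "V|J|C"
    chain: str
    sequence: str

    @property
    def allele_ids(self) -> tuple[str, str, str]:
        parts = self.name.split("|")
        if len(parts) != 3:
            raise GermlineError(f"recombinome name {self.name!r} is not V|J|C")
        return tuple(parts)  # type: ignore[return-value]


def _parse_header(description: str) -> tuple[str, dict[str, str]]:
    """Split a '>allele_id key=value ...' FASTA description."""
    fields = description.split()
    allele_id = fields[0]
    meta = {}
    for tok in fields[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            meta[key] = value
    return allele_id, meta


def load_germline_fasta(
    path: str | Path,
    chain: str,
    segment_class: str,
    db: GermlineDatabase | None = None,
    species: str = "human",
) -> GermlineDatabase:
    """Load one FASTA of segments into a (possibly pre-existing) database.

    Headers are ``>allele_id [key=value ...]``; recognized keys are
    ``cys104``, ``jtrp`` and ``frame``.  Sequences are uppercased; duplicate
    allele ids and empty files are rejected.
    """
    if db is None:
        db = GermlineDatabase(species=species)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        allele_id, meta = _parse_header(rec.description)
        seq = str(rec.seq).upper()
        db.add(
            GermlineSegment(
                allele_id=allele_id,
                chain=chain,
                segment_class=segment_class,
                sequence=seq,
                cys104_offset=int(meta["cys104"]) if "cys104" in meta else None,
                jtrp_offset=int(meta["jtrp"]) if "jtrp" in meta else None,
                reading_frame=int(meta.get("frame", 0)),
            )
        )
        n += 1
    if n == 0:
        raise GermlineError(f"no FASTA records in {path}")
    return db


def load_anchor_tsv(path: str | Path, db: GermlineDatabase) -> None:
    """Apply a sidecar anchor table (columns: allele_id, anchor_type, offset)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            db.set_anchor(row["allele_id"], row["anchor_type"], int(row["offset"]))


def build_recombinome(
    db: GermlineDatabase,
    chain: str,
    leader_pad: int = LEADER_PAD,
    junction_pad: int | None = None,
) -> list[RecombinomeEntry]:
    """Enumerate every ordered (V, J, C) triple for *chain*.

    Each entry is ``N*leader_pad + V + N*junction_pad + J + C``.  The heavy
    chain replaces the D segment with 10 N bases by default; light chains
    default to no junction pad (their V-J junctions carry only a few
    nucleotides, which the k-mer mapper tolerates).
    """
    if junction_pad is None:
        junction_pad = HEAVY_JUNCTION_PAD if chain == "IGH" else 0
    if leader_pad < 0 or junction_pad < 0:
        raise GermlineError("pads must be >= 0")
    groups = {}
    for cls in ("V", "J", "C"):
        segs = db.segments(chain, cls)
        if not segs:
            raise GermlineError(f"no {cls} segments for chain {chain}")
        groups[cls] = sorted(segs, key=lambda s: s.allele_id)
    lead = "N" * leader_pad
    junc = "N" * junction_pad
    entries = []
    for v, j, c in itertools.product(groups["V"], groups["J"], groups["C"]):
        entries.append(
            RecombinomeEntry(
                name=f"{v.allele_id}|{j.allele_id}|{c.allele_id}",
                chain=chain,
                sequence=lead + v.sequence + junc + j.sequence + c.sequence,
            )
        )
    return entries


def make_vjc_reference(db: GermlineDatabase, chain: str) -> list[tuple[str, str]]:
    """Pool the raw V, J and C sequences (no D) for one chain.

    Returns (allele_id, sequence) pairs, V then J then C, each class sorted
    by allele id.
    """
    out = []
    for cls in ("V", "J", "C"):
        segs = db.segments(chain, cls)
        out.extend(
            (s.allele_id, s.sequence) for s in sorted(segs, key=lambda s: s.allele_id)
        )
    if not out:
        raise GermlineError(f"no V/J/C segments for chain {chain}")
    return out


def write_recombinome_fasta(entries: Iterable[RecombinomeEntry], path: str | Path) -> None:
    records = (
        SeqRecord(Seq(e.sequence), id=e.name, description="") for e in entries
    )
    SeqIO.write(records, str(path), "fasta")


def write_segments_fasta(db: GermlineDatabase, path: str | Path, chain: str, segment_class: str) -> None:
    """Write one chain/class slice back to FASTA with anchor metadata in headers."""
    records = []
    for seg in sorted(db.segments(chain, segment_class), key=lambda s: s.allele_id):
        meta = [f"frame={seg.reading_frame}"]
        if seg.cys104_offset is not None:
            meta.append(f"cys104={seg.cys104_offset}")
        if seg.jtrp_offset is not None:
            meta.append(f"jtrp={seg.jtrp_offset}")
        records.append(
            SeqRecord(Seq(seg.sequence), id=seg.allele_id, description=" ".join(meta))
        )
    SeqIO.write(records, str(path), "fasta")
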