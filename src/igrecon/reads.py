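"""Read-set container and FASTQ I/O.

Reads are carried in memory as plain records; per-read origin labels
(``ig_heavy`` / ``ig_light`` / ``background``) are attached by the simulator
and used only by tests and validation code, never by the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

ORIGINS = ("ig_heavy", "ig_light", "background")


@dataclass
class Read:
    read_id: str
    seq1: str
    seq2: str | None = None
    qual1: str | None = None
    qual2: str | None = None
    origin: str | None = None

    def units(self) -> list[tuple[str, int, str]]:
        """Mate-level view: (read_id, mate, sequence)."""
        out = [(self.read_id, 1, self.seq1)]
        if self.seq2 is not None:
            out.append((self.read_id, 2, self.seq2))
        return out


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    layout: str = "SE"  # SE | PE
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("SE", "PE"):
            raise ValueError(f"layout must be SE or PE, got {self.layout!r}")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def units(self) -> Iterator[tuple[str, int, str]]:
        for read in self.reads:
            yield from read.units()

    def n_units(self) -> int:
        return sum(2 if r.seq2 is not None else 1 for r in self.reads)

    def subset(self, read_ids: set[str]) -> "ReadSet":
        """Retain the listed fragments, preserving input order."""
        return ReadSet(
            reads=[r for r in self.reads if r.read_id in read_ids],
            layout=self.layout,
            read_length=self.read_length,
        )

    def sequences(self) -> list[str]:
        return [seq for _id, _m, seq in self.units()]


def write_fastq(readset: ReadSet, prefix: str | Path) -> list[Path]:
    """Write SE as <prefix>.fastq, PE as <prefix>_1.fastq / <prefix>_2.fastq."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    def _dump(path: Path, mate: int) -> None:
        with open(path, "w") as fh:
            for read in readset:
                seq = read.seq1 if mate == 1 else read.seq2
                qual = (read.qual1 if mate == 1 else read.qual2) or "I" * len(seq)
                fh.write(f"@{read.read_id}\n{seq}\n+\n{qual}\n")

    if readset.layout == "SE":
        path = prefix.with_suffix(".fastq")
        _dump(path, 1)
        return [path]
    p1 = prefix.parent / f"{prefix.name}_1.fastq"
    p2 = prefix.parent / f"{prefix.name}_2.fastq"
    _dump(p1, 1)
    _dump(p2, 2)
    return [p1, p2]


def read_fastq(path1: str | Path, path2: str | Path | None = None) -> ReadSet:
    """Load one (SE) or two (PE) FASTQ files into a ReadSet."""
    reads: dict[str, Read] = {}
    with pysam.FastxFile(str(path1)) as fh:
        for entry in fh:
            reads[entry.name] = Read(
                read_id=entry.name, seq1=entry.sequence.upper(), qual1=entry.quality
            )
    if not reads and Path(path1).stat().st_size > 0:
        raise ValueError(f"{path1}: no FASTQ records parsed from non-empty file")
    layout = "SE"
    if path2 is not None:
        layout = "PE"
        with pysam.FastxFile(str(path2)) as fh:
            for entry in fh:
                try:
                    read = reads[entry.name]
                except KeyError:
                    raise ValueError(
                        f"read {entry.name} present in mate-2 file only"
                    ) from None
                read.seq2 = entry.sequence.upper()
                read.qual2 = entry.quality
    out = list(reads.values())
    read_length = max((len(r.seq1) for r in out), default=0)
    return ReadSet(reads=out, layout=layout, read_length=read_length)
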