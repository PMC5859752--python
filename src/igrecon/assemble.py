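"""Single-k De Bruijn assembly of filtered reads into transcript models.

Per-cell Ig read sets are small and each chain has one dominant isoform, so
a single-k assembler with tip and bubble cleanup suffices in the role a
general-purpose transcriptome assembler plays at scale.  Contigs are walks
over canonical k-mers: tips shorter than 2k are clipped, bubbles resolved
toward the higher-coverage branch (ties: lexicographically smaller
sequence), and remaining branch points crossed by a greedy max-coverage
walk consuming each k-mer at most once per contig.  Output is deterministic
for fixed input and k.

An external-assembler adapter (:func:`load_contigs_fasta`) lets contigs from
any other assembler enter the downstream stages unchanged.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import revcomp
from .mapper import _codes_matrix, _encode_matrix
from .reads import ReadSet


class AssemblyError(RuntimeError):
    pass


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)


_RC16 = None


def _rc16_table() -> np.ndarray:
    """Reverse complement of every 8-base (16-bit) 2-bit-packed chunk."""
    global _RC16
    if _RC16 is None:
        t = np.empty(65536, dtype=np.uint64)
        for x in range(65536):
            y = 0
            v = x
            for _ in range(8):
                y = (y << 2) | (3 - (v & 3))
                v >>= 2
            t[x] = y
        _RC16 = t
    return _RC16


def _revcomp_code(code: int, k: int) -> int:
    t = _rc16_table()
    nchunks = (k + 7) // 8
    out = 0
    v = code
    for _ in range(nchunks):
        out = (out << 16) | int(t[v & 0xFFFF])
        v >>= 16
    return out >> (2 * (8 * nchunks - k))


_BASES = "ACGT"


def _decode(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(_BASES[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def _count_canonical_kmers(seqs: list[str], k: int, chunk: int = 50000) -> dict[int, int]:
    counts: dict[int, int] = {}
    usable = [s for s in seqs if len(s) >= k]
    if not usable:
        raise AssemblyError("no usable k-mers")
    for lo in range(0, len(usable), chunk):
        batch = usable[lo : lo + chunk]
        lengths = np.array([len(s) for s in batch], dtype=np.int64)
        maxlen = int(lengths.max())
        fwd = _encode_matrix(batch, maxlen)
        codes, valid = _codes_matrix(fwd, lengths, k)
        rc_batch = [revcomp(s) for s in batch]
        rc = _encode_matrix(rc_batch, maxlen)
        rc_codes, _rc_valid = _codes_matrix(rc, lengths, k)
        # window j of the forward read is window (len-k-j) of its reverse complement
        rc_aligned = np.zeros_like(rc_codes)
        for length in np.unique(lengths):
            rows = np.flatnonzero(lengths == length)
            ncol = int(length) - k + 1
            rc_aligned[np.ix_(rows, range(ncol))] = rc_codes[np.ix_(rows, range(ncol))][:, ::-1]
        canon = np.minimum(codes, rc_aligned)
        vals, cnts = np.unique(canon[valid], return_counts=True)
        for v, c in zip(vals.tolist(), cnts.tolist()):
            counts[v] = counts.get(v, 0) + c
    if not counts:
        raise AssemblyError("no usable k-mers")
    return counts


class _Graph:
    """Implicit De Bruijn graph over canonical k-mer counts."""

    def __init__(self, counts: dict[int, int], k: int) -> None:
        self.counts = counts
        self.k = k
        self.mask = (1 << (2 * k)) - 1
        self._canon_cache: dict[int, int] = {}

    def canon(self, code: int) -> int:
        cached = self._canon_cache.get(code)
        if cached is None:
            rc = _revcomp_code(code, self.k)
            cached = code if code <= rc else rc
            self._canon_cache[code] = cached
        return cached

    def succs(self, code: int) -> list[int]:
        out = []
        base = (code << 2) & self.mask
        for b in range(4):
            nxt = base | b
            if self.canon(nxt) in self.counts:
                out.append(nxt)
        return out

    def preds(self, code: int) -> list[int]:
        out = []
        base = code >> 2
        shift = 2 * (self.k - 1)
        for b in range(4):
            prv = (b << shift) | base
            if self.canon(prv) in self.counts:
                out.append(prv)
        return out

    def remove(self, codes: Iterable[int]) -> None:
        for c in codes:
            self.counts.pop(self.canon(c), None)


@dataclass
class _Unitig:
    codes: list[int]  # oriented
    seq: str
    cov: float


def _build_unitigs(graph: _Graph) -> list[_Unitig]:
    visited: set[int] = set()
    unitigs = []
    k = graph.k
    for start in sorted(graph.counts):
        if start in visited:
            continue
        visited.add(start)
        path = deque([start])
        cur = start
        while True:
            ss = graph.succs(cur)
            if len(ss) != 1 or len(graph.preds(ss[0])) != 1:
                break
            nxt = ss[0]
            if graph.canon(nxt) in visited:
                break
            visited.add(graph.canon(nxt))
            path.append(nxt)
            cur = nxt
        cur = start
        while True:
            ps = graph.preds(cur)
            if len(ps) != 1 or len(graph.succs(ps[0])) != 1:
                break
            prv = ps[0]
            if graph.canon(prv) in visited:
                break
            visited.add(graph.canon(prv))
            path.appendleft(prv)
            cur = prv
        codes = list(path)
        seq = _decode(codes[0], k) + "".join(_BASES[c & 3] for c in codes[1:])
        cov = float(np.mean([graph.counts[graph.canon(c)] for c in codes]))
        unitigs.append(_Unitig(codes, seq, cov))
    return unitigs


def _clip_tips(graph: _Graph, max_rounds: int = 5) -> None:
    """Remove short dead-end side branches.

    A tip is clipped only when a clearly better-supported sibling leaves the
    same junction; a transcript's true terminus is also a dead end, and must
    survive even when errors fragment the path around it.
    """
    k = graph.k
    for _ in range(max_rounds):
        unitigs = _build_unitigs(graph)
        endmap: dict[int, _Unitig] = {}
        for u in unitigs:
            endmap[graph.canon(u.codes[0])] = u
            endmap[graph.canon(u.codes[-1])] = u

        def _outcompeted(u: _Unitig, junction_nodes: list[int], own_end: int) -> bool:
            own = graph.canon(own_end)
            for node in junction_nodes:
                for child in graph.succs(node) + graph.preds(node):
                    sib = endmap.get(graph.canon(child))
                    if sib is None or sib is u:
                        continue
                    if graph.canon(child) != own and sib.cov >= 2 * u.cov:
                        return True
            return False

        removed = False
        for u in unitigs:
            if len(u.seq) >= 2 * k:
                continue
            out_deg = len(graph.succs(u.codes[-1]))
            in_deg = len(graph.preds(u.codes[0]))
            if out_deg == 0 and in_deg > 0:
                if _outcompeted(u, graph.preds(u.codes[0]), u.codes[0]):
                    graph.remove(u.codes)
                    removed = True
            elif in_deg == 0 and out_deg > 0:
                if _outcompeted(u, graph.succs(u.codes[-1]), u.codes[-1]):
                    graph.remove(u.codes)
                    removed = True
        if not removed:
            break


def _prune_low_coverage_branches(graph: _Graph, rel_frac: float = 0.2) -> bool:
    """Remove branches far below their siblings' coverage at a shared fork.

    Sequencing errors at high per-cell coverage recur on multiple reads, so
    a fixed count cutoff cannot separate them from signal; their branches
    are instead pruned relative to the dominant branch at each fork.
    """
    unitigs = _build_unitigs(graph)
    start_groups: dict[int, list[_Unitig]] = {}
    end_groups: dict[int, list[_Unitig]] = {}
    for u in unitigs:
        for p in graph.preds(u.codes[0]):
            start_groups.setdefault(graph.canon(p), []).append(u)
        for s in graph.succs(u.codes[-1]):
            end_groups.setdefault(graph.canon(s), []).append(u)
    doomed: set[int] = set()
    for groups in (start_groups, end_groups):
        for members in groups.values():
            if len(members) < 2:
                continue
            top = max(m.cov for m in members)
            for m in members:
                if m.cov < rel_frac * top:
                    doomed.add(id(m))
    removed = False
    for u in unitigs:
        if id(u) in doomed:
            graph.remove(u.codes)
            removed = True
    return removed


def _pop_bubbles(graph: _Graph, max_rounds: int = 5) -> None:
    for _ in range(max_rounds):
        groups: dict[tuple, list[_Unitig]] = {}
        for u in _build_unitigs(graph):
            ps = frozenset(graph.canon(p) for p in graph.preds(u.codes[0]))
            ss = frozenset(graph.canon(s) for s in graph.succs(u.codes[-1]))
            if ps and ss:
                groups.setdefault((ps, ss), []).append(u)
        removed = False
        for members in groups.values():
            if len(members) < 2:
                continue
            members.sort(key=lambda u: (-u.cov, min(u.seq, revcomp(u.seq))))
            for loser in members[1:]:
                graph.remove(loser.codes)
                removed = True
        if not removed:
            break


def assemble_reads(
    reads: ReadSet | Iterable[str],
    k: int = 25,
    min_contig_len: int = 300,
    min_kmer_count: int = 2,
) -> list[Contig]:
    """Assemble reads (mates treated as independent sequences) into contigs.

    ``min_kmer_count`` drops singleton k-mers, which at typical per-cell
    coverage removes sequencing-error artifacts before graph cleanup.
    """
    if k % 2 == 0 or not 15 <= k <= 31:
        raise AssemblyError(f"k must be odd and in [15, 31], got {k}")
    seqs = reads.sequences() if isinstance(reads, ReadSet) else list(reads)
    if not seqs:
        raise AssemblyError("no usable k-mers")
    counts = _count_canonical_kmers(seqs, k)
    counts = {c: n for c, n in counts.items() if n >= min_kmer_count}
    if not counts:
        raise AssemblyError("no usable k-mers")
    graph = _Graph(counts, k)
    for _ in range(5):
        changed = _prune_low_coverage_branches(graph)
        _clip_tips(graph)
        _pop_bubbles(graph)
        if not changed:
            break

    unitigs = _build_unitigs(graph)
    unitigs.sort(key=lambda u: (-u.cov, -len(u.seq), min(u.seq, revcomp(u.seq))))
    global_used: set[int] = set()
    raw: list[tuple[str, float]] = []
    for seed in unitigs:
        canons = {graph.canon(c) for c in seed.codes}
        if canons <= global_used:
            continue
        path = deque(seed.codes)
        used = set(canons)
        cur = path[-1]
        while True:
            options = [s for s in graph.succs(cur) if graph.canon(s) not in used]
            if not options:
                break
            options.sort(key=lambda s: (-graph.counts[graph.canon(s)], s & 3))
            nxt = options[0]
            used.add(graph.canon(nxt))
            path.append(nxt)
            cur = nxt
        cur = path[0]
        while True:
            options = [p for p in graph.preds(cur) if graph.canon(p) not in used]
            if not options:
                break
            options.sort(key=lambda p: (-graph.counts[graph.canon(p)], p >> (2 * (k - 1))))
            prv = options[0]
            used.add(graph.canon(prv))
            path.appendleft(prv)
            cur = prv
        codes = list(path)
        # a walk that mostly re-treads k-mers of an earlier (higher-coverage)
        # contig is a duplicate through a residual error branch, not a new model
        reused = sum(1 for c in codes if graph.canon(c) in global_used)
        global_used |= used
        if reused > 0.5 * len(codes):
            continue
        seq = _decode(codes[0], k) + "".join(_BASES[c & 3] for c in codes[1:])
        cov = float(np.mean([graph.counts[graph.canon(c)] for c in codes]))
        seq = min(seq, revcomp(seq))
        raw.append((seq, cov))

    raw = [(s, c) for s, c in raw if len(s) >= min_contig_len]
    raw.sort(key=lambda sc: (-sc[1], -len(sc[0]), sc[0]))
    return [
        Contig(contig_id=f"contig_{i + 1}", sequence=seq, coverage=cov)
        for i, (seq, cov) in enumerate(raw)
    ]


def write_contigs_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    records = (
        SeqRecord(Seq(c.sequence), id=c.contig_id, description=f"cov={c.coverage:.1f}")
        for c in contigs
    )
    SeqIO.write(records, str(path), "fasta")


def load_contigs_fasta(path: str | Path) -> list[Contig]:
    """External-assembler adapter: read contigs from FASTA."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cov = 0.0
        for tok in rec.description.split():
            if tok.startswith("cov="):
                cov = float(tok[4:])
        out.append(Contig(rec.id, str(rec.seq).upper(), cov))
    if not out:
        raise AssemblyError(f"no contigs in {path}")
    return out


def trim_adapters(readset: ReadSet, adapters: list[str]) -> ReadSet:
    """Literal adapter prefix/suffix clipping (no-op for adapter-free reads)."""
    if not adapters:
        return readset

    def _clip(seq: str) -> str:
        for ad in adapters:
            if seq.startswith(ad):
                seq = seq[len(ad):]
            if seq.endswith(ad):
                seq = seq[: -len(ad)]
        return seq

    from .reads import Read

    clipped = [
        Read(r.read_id, _clip(r.seq1), _clip(r.seq2) if r.seq2 else None,
             r.qual1, r.qual2, r.origin)
        for r in readset
    ]
    return ReadSet(clipped, layout=readset.layout, read_length=readset.read_length)
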