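"""Internal k-mer seed-and-extend read mapper.

Replaces the external aligners a production pipeline would call for read
*enrichment* (local mode) and model *quantification* (end-to-end mode) at
desk scale.  A read is considered mapped iff it shares at least
``min_seed_count`` k-mers with some reference and its extended alignment
meets the score threshold.  Scoring is +1 match / -1 mismatch / -2 per gap
position; positions where either base is N contribute 0 ("N is free"), so
reads can span the N pads of recombinome entries.

Extension is a two-stage affair: an exact diagonal score (substitution-only
alignments, the overwhelming case for short-read data) followed by an exact
dynamic-programming fallback in a window around the seed diagonal when the
diagonal score misses the threshold (gapped alignments, ragged N pads).

k-mers containing N never seed.  Strand is handled by also seeding the
reverse-complemented read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dna import encode

DEFAULT_K = 21
DEFAULT_MIN_SCORE = 30
DEFAULT_E2E_MIN_FRACTION = 0.9

_POSTING_CAP = 256  # repetitive k-mers: cap postings to bound worst-case work


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class MappingHit:
    read_id: str
    mate: int
    reference_id: str
    reference_start: int  # 0-based, start of the aligned reference span
    reference_end: int  # half-open
    strand: str  # '+' or '-'
    score: float
    mode: str  # 'local' | 'end_to_end'


class MappingResult:
    """Hits per (read_id, mate) unit plus the unmapped complement."""

    def __init__(
        self,
        hits: dict[tuple[str, int], list[MappingHit]],
        unmapped: set[tuple[str, int]],
    ) -> None:
        self.hits = hits
        self.unmapped = unmapped

    def best(self, key: tuple[str, int]) -> MappingHit | None:
        lst = self.hits.get(key)
        return lst[0] if lst else None

    def mapped_keys(self) -> set[tuple[str, int]]:
        return set(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def _rolling_codes_1d(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for every k-window of a 1-D uint8 base-code array."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    a = (arr & 3).astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    codes = np.zeros(n, np.uint64)
    for i in range(k):
        codes = ((codes << np.uint64(2)) | a[i : i + n]) & mask
    isn = np.concatenate(([0], np.cumsum(arr == 4)))
    valid = (isn[k:] - isn[:-k]) == 0
    return codes, valid


class ReferenceIndex:
    """k-mer index over a named reference sequence set."""

    def __init__(
        self,
        references: dict[str, str] | Sequence[tuple[str, str]],
        k: int = DEFAULT_K,
    ) -> None:
        if isinstance(references, dict):
            items = list(references.items())
        else:
            items = list(references)
        if not items:
            raise MappingError("reference set is empty")
        if not 11 <= k <= 31:
            raise MappingError(f"k must be in [11, 31], got {k}")
        self.k = k
        self.names = [name for name, _ in items]
        self.seqs = [seq.upper() for _, seq in items]
        self.arrs = [encode(seq) for seq in self.seqs]
        postings: dict[int, list[tuple[int, int]]] = {}
        for ri, arr in enumerate(self.arrs):
            codes, valid = _rolling_codes_1d(arr, k)
            for pos in np.flatnonzero(valid):
                code = int(codes[pos])
                lst = postings.setdefault(code, [])
                if len(lst) < _POSTING_CAP:
                    lst.append((ri, int(pos)))
        self.postings = postings
        self.sorted_codes = np.sort(np.fromiter(postings.keys(), dtype=np.uint64, count=len(postings)))

    def __len__(self) -> int:
        return len(self.names)


def _encode_matrix(seqs: list[str], maxlen: int) -> np.ndarray:
    mat = np.full((len(seqs), maxlen), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = encode(s)
    return mat


def _codes_matrix(mat: np.ndarray, lengths: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer codes for every row; invalid windows (N or out of row) masked."""
    n, maxlen = mat.shape
    ncol = maxlen - k + 1
    if ncol <= 0:
        return np.zeros((n, 0), np.uint64), np.zeros((n, 0), bool)
    a = (mat & 3).astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    codes = np.zeros((n, ncol), np.uint64)
    c = np.zeros(n, np.uint64)
    for j in range(k - 1):
        c = ((c << np.uint64(2)) | a[:, j]) & mask
    for j in range(ncol):
        c = ((c << np.uint64(2)) | a[:, j + k - 1]) & mask
        codes[:, j] = c
    isn = np.zeros((n, maxlen + 1), np.int32)
    np.cumsum(mat == 4, axis=1, out=isn[:, 1:])
    valid = (isn[:, k:] - isn[:, :-k]) == 0
    valid &= np.arange(ncol)[None, :] <= (lengths - k)[:, None]
    return codes, valid


def _membership(sorted_codes: np.ndarray, codes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(sorted_codes, codes.ravel())
    idx[idx >= sorted_codes.size] = 0
    found = sorted_codes[idx] == codes.ravel()
    return found.reshape(codes.shape)


def _diag_scores(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    free = (q == 4) | (r == 4)
    return np.where(free, 0, np.where(q == r, 1, -1)).astype(np.int32)


def _kadane(s: np.ndarray) -> tuple[int, int, int]:
    """Best-scoring contiguous subarray: (score, start, stop)."""
    c = np.concatenate(([0], np.cumsum(s)))
    runmin = np.minimum.accumulate(c[:-1])
    diffs = c[1:] - runmin
    j = int(np.argmax(diffs))
    score = int(diffs[j])
    start = int(np.argmin(c[: j + 1]))
    return score, start, j + 1


_NFREE_MATRIX = None


def nfree_substitution_matrix():
    """ACGTN substitution matrix: +1 match, -1 mismatch, 0 anything-vs-N."""
    global _NFREE_MATRIX
    if _NFREE_MATRIX is None:
        from skbio.sequence import SubstitutionMatrix

        data = np.full((5, 5), -1.0)
        np.fill_diagonal(data, 1.0)
        data[4, :] = 0.0
        data[:, 4] = 0.0
        _NFREE_MATRIX = SubstitutionMatrix("ACGTN", data)
    return _NFREE_MATRIX


def _dp_extend(
    seq: str, ref_seq: str, diag: int, mode: str, band: int
) -> tuple[float, int, int] | None:
    """Exact DP alignment of the read against a reference window around *diag*.

    Returns (score, ref_start, ref_end) or None when no alignment exists.
    """
    from skbio.alignment import pair_align

    w0 = max(0, diag - band)
    w1 = min(len(ref_seq), diag + len(seq) + band)
    window = ref_seq[w0:w1]
    if not window:
        return None
    mat = nfree_substitution_matrix()
    if mode == "local":
        res = pair_align(seq, window, mode="local", sub_score=mat, gap_cost=2, max_paths=1)
        if not res.paths:
            return None
        t0, t1 = (int(x) for x in res.paths[0].ranges[1])
    else:
        res = pair_align(
            seq,
            window,
            mode="global",
            sub_score=mat,
            gap_cost=2,
            free_ends=(False, False, True, True),
            trim_ends=True,
            max_paths=1,
        )
        if not res.paths:
            return None
        t0, t1 = (int(x) for x in res.paths[0].ranges[1])
    return float(res.score), w0 + t0, w0 + t1


def map_units(
    units: Iterable[tuple[str, int, str]],
    index: ReferenceIndex,
    mode: str = "local",
    report: str = "best",
    min_seed_count: int = 1,
    min_score: float = DEFAULT_MIN_SCORE,
    e2e_min_fraction: float = DEFAULT_E2E_MIN_FRACTION,
    band: int = 8,
    max_candidates: int = 4,
    dp_fallback: bool = True,
    chunk_size: int = 32768,
) -> MappingResult:
    """Map (read_id, mate, sequence) units against an indexed reference set."""
    if mode not in ("local", "end_to_end"):
        raise MappingError(f"unknown mode {mode!r}")
    if report not in ("best", "all"):
        raise MappingError(f"unknown report {report!r}")
    units = list(units)
    k = index.k
    for _id, _m, seq in units:
        if k > len(seq):
            raise MappingError(f"k={k} exceeds read length {len(seq)} ({_id})")

    hits: dict[tuple[str, int], list[MappingHit]] = {}
    unmapped: set[tuple[str, int]] = set()
    for lo in range(0, len(units), chunk_size):
        chunk = units[lo : lo + chunk_size]
        _map_chunk(
            chunk, index, mode, report, min_seed_count, min_score,
            e2e_min_fraction, band, max_candidates, dp_fallback, hits, unmapped,
        )
    return MappingResult(hits, unmapped)


def _revcomp_matrix(mat: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Per-row reverse complement, keeping sequences left-aligned."""
    n, maxlen = mat.shape
    out = np.full_like(mat, 4)
    comp = np.where(mat == 4, 4, 3 - mat)
    for length in np.unique(lengths):
        rows = np.flatnonzero(lengths == length)
        out[rows, :length] = comp[rows, :length][:, ::-1]
    return out


def _map_chunk(
    chunk, index, mode, report, min_seed_count, min_score, e2e_min_fraction,
    band, max_candidates, dp_fallback, hits, unmapped,
) -> None:
    k = index.k
    seqs = [seq for _i, _m, seq in chunk]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    maxlen = int(lengths.max())
    fwd = _encode_matrix(seqs, maxlen)
    rc = _revcomp_matrix(fwd, lengths)
    n = len(chunk)
    ncol = maxlen - k + 1

    strands = {}
    for label, mat in (("+", fwd), ("-", rc)):
        codes, valid = _codes_matrix(mat, lengths, k)
        strands[label] = (mat, codes, valid)

    # Tier 1: probe first / middle / last k-mer of each strand.
    need_full = min_seed_count > 1 or report == "all"
    t1_member = {}
    if not need_full:
        last = np.maximum(lengths - k, 0)
        cols = np.stack([np.zeros(n, np.int64), last // 2, last], axis=1)
        rows = np.arange(n)[:, None]
        for label, (_mat, codes, valid) in strands.items():
            sub = codes[rows, cols]
            ok = valid[rows, cols] & _membership(index.sorted_codes, sub)
            t1_member[label] = (cols, ok)
        t1_any = t1_member["+"][1].any(axis=1) | t1_member["-"][1].any(axis=1)
        full_rows = np.flatnonzero(~t1_any)
    else:
        full_rows = np.arange(n)

    full_member = {}
    if full_rows.size:
        for label, (_mat, codes, valid) in strands.items():
            sub = codes[full_rows]
            member = valid[full_rows] & _membership(index.sorted_codes, sub)
            full_member[label] = member
    full_row_pos = {int(r): i for i, r in enumerate(full_rows)}

    e2e = mode == "end_to_end"
    for r in range(n):
        read_id, mate, _seq = chunk[r]
        key = (read_id, mate)
        L = int(lengths[r])
        # gather matched (strand, col, code) seeds
        seeds: list[tuple[str, int, int]] = []
        seed_count_by_ref: dict[int, int] = {}
        if r in full_row_pos:
            i = full_row_pos[r]
            for label in ("+", "-"):
                member = full_member[label][i]
                cols_hit = np.flatnonzero(member)
                if cols_hit.size == 0:
                    continue
                codes_row = strands[label][1][r]
                if min_seed_count > 1:
                    for col in cols_hit:
                        code = int(codes_row[col])
                        for ri in {ri for ri, _p in index.postings.get(code, ())}:
                            seed_count_by_ref[ri] = seed_count_by_ref.get(ri, 0) + 1
                if report == "all":
                    # sample matched columns at a stride; a shared k-mer's
                    # postings name every reference containing it, so refs
                    # supported across the read are reached without probing
                    # every column
                    step = max(1, cols_hit.size // 48)
                    picked = cols_hit[::step]
                else:
                    picked = cols_hit[[0, cols_hit.size // 2, cols_hit.size - 1]]
                last_col = -1
                for col in picked:
                    col = int(col)
                    if col != last_col:
                        seeds.append((label, col, int(codes_row[col])))
                        last_col = col
        else:
            for label in ("+", "-"):
                cols, ok = t1_member[label]
                codes_row = strands[label][1][r]
                for j in range(cols.shape[1]):
                    if ok[r, j]:
                        col = int(cols[r, j])
                        seeds.append((label, col, int(codes_row[col])))
        if not seeds:
            unmapped.add(key)
            continue

        # candidate (ref, diag, strand) set
        candidates: list[tuple[int, int, str]] = []
        seen = set()
        for label, col, code in seeds:
            for ri, pos in index.postings.get(code, ()):
                if min_seed_count > 1 and seed_count_by_ref.get(ri, 0) < min_seed_count:
                    continue
                cand = (ri, pos - col, label)
                if cand not in seen:
                    seen.add(cand)
                    candidates.append(cand)
            if report == "best" and len(candidates) >= max_candidates:
                break

        threshold = e2e_min_fraction * L if e2e else min_score
        row_hits: list[MappingHit] = []
        best_per_ref: dict[tuple[int, str], MappingHit] = {}
        for ri, diag, label in candidates:
            ref_arr = index.arrs[ri]
            q = strands[label][0][r, :L]
            result = None
            if e2e:
                if 0 <= diag and diag + L <= ref_arr.size:
                    ref_slice = ref_arr[diag : diag + L]
                    # exact-match fast path (N-free: N would score 0, not +1)
                    if np.array_equal(q, ref_slice) and not (q == 4).any():
                        result = (float(L), diag, diag + L)
                    else:
                        s = _diag_scores(q, ref_slice)
                        result = (float(s.sum()), diag, diag + L)
            else:
                qoff = max(0, -diag)
                rstart = max(0, diag)
                rstop = min(ref_arr.size, diag + L)
                if rstop > rstart:
                    ref_slice = ref_arr[rstart:rstop]
                    q_slice = q[qoff : qoff + rstop - rstart]
                    if (
                        q_slice.size == L
                        and np.array_equal(q_slice, ref_slice)
                        and not (q_slice == 4).any()
                    ):
                        result = (float(L), rstart, rstop)
                    else:
                        s = _diag_scores(q_slice, ref_slice)
                        score, a, b = _kadane(s)
                        result = (float(score), rstart + a, rstart + b)
            if (result is None or result[0] < threshold) and dp_fallback:
                strand_seq = _decode_row(q)
                dp = _dp_extend(strand_seq, index.seqs[ri], diag, "end_to_end" if e2e else "local", band)
                if dp is not None and (result is None or dp[0] > result[0]):
                    result = dp
            if result is None or result[0] < threshold:
                continue
            hit = MappingHit(
                read_id=read_id, mate=mate, reference_id=index.names[ri],
                reference_start=result[1], reference_end=result[2],
                strand=label, score=result[0], mode=mode,
            )
            ref_key = (ri, label) if report == "all" else (ri, label)
            prev = best_per_ref.get(ref_key)
            if prev is None or hit.score > prev.score or (
                hit.score == prev.score and hit.reference_start < prev.reference_start
            ):
                best_per_ref[ref_key] = hit
        row_hits = sorted(
            best_per_ref.values(),
            key=lambda h: (-h.score, h.reference_id, h.reference_start, h.strand),
        )
        if not row_hits:
            unmapped.add(key)
        elif report == "best":
            hits[key] = [row_hits[0]]
        else:
            # one best hit per reference
            per_ref: dict[str, MappingHit] = {}
            for h in row_hits:
                if h.reference_id not in per_ref:
                    per_ref[h.reference_id] = h
            hits[key] = sorted(
                per_ref.values(),
                key=lambda h: (-h.score, h.reference_id, h.reference_start),
            )


_DECODE = np.array(list("ACGTN"))


def _decode_row(arr: np.ndarray) -> str:
    return "".join(_DECODE[arr])
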