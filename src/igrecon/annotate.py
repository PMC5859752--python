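"""V(D)J/C annotation of assembled contigs, CDR3 extraction and productivity.

Each contig is annotated by exact local alignment (match +1 / mismatch -1 /
gap -2, N scores 0) of germline segments: the best V hit over both strands
fixes chain and orientation, J is searched downstream of V, D (heavy only)
inside the V-J window, and C downstream of J.  The CDR3 spans the conserved
V second-cysteine codon through the J-TRP/PHE codon inclusive, projected
onto the contig through the alignments.  A model is productive iff the two
anchors are in frame, no stop codon lies between the V start and the J end
in that frame, and the CDR3 is non-empty with length divisible by 3.

Class-specific minimum alignment scores (V 50, J 18, D 10, C 30) play the
role an e-value threshold plays in database search: germline-length matches
pass while random contigs of desk scale fail with negligible probability.
Annotation alignments use a gap penalty of 5 per position, steeper than the
read mapper's, because runs of adjacent point mutations must not be
reinterpreted as indels.

V alignments are extended ungapped to the sequence ends ("flank extension")
so substitutions at the first/last aligned positions — which a purely local
alignment would trim — are still recorded; mutation counting depends on it.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

from skbio.alignment import pair_align

from .assemble import Contig
from .dna import has_stop_in_frame, revcomp, translate
from .germline import GermlineDatabase
from .mapper import nfree_substitution_matrix

DEFAULT_MIN_SCORES = {"V": 50, "J": 18, "D": 10, "C": 30}


class AnnotationError(RuntimeError):
    pass


@dataclass
class SegmentAlignment:
    allele_id: str
    segment_class: str
    contig_start: int  # 0-based half-open, on the strand-oriented contig
    contig_end: int
    segment_start: int
    segment_end: int
    score: float
    identity: float  # percent over alignment columns
    strand: str = "+"
    # aligned (segment_pos, contig_pos) for substitution columns only
    pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)
    mismatches: list[tuple[int, int, str, str]] = field(default_factory=list)

    def project(self, segment_pos: int) -> int | None:
        """Contig position aligned to *segment_pos*, or None if gapped/outside."""
        i = bisect_left(self.pairs, (segment_pos, -1))
        if i < len(self.pairs) and self.pairs[i][0] == segment_pos:
            return self.pairs[i][1]
        return None

    @property
    def gene(self) -> str:
        return self.allele_id.split("*")[0]


@dataclass
class IgAnnotation:
    contig_id: str
    chain: str
    v_call: str
    j_call: str
    d_call: str | None = None
    c_call: str | None = None
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    productive: bool = False
    frame_ok: bool = False
    stop_codon: bool = False
    strand: str = "+"
    cdr3_start: int | None = None  # on the oriented contig
    v_alignment: SegmentAlignment | None = None
    j_alignment: SegmentAlignment | None = None
    d_alignment: SegmentAlignment | None = None
    c_alignment: SegmentAlignment | None = None

    @property
    def v_gene(self) -> str:
        return self.v_call.split("*")[0]

    @property
    def j_gene(self) -> str:
        return self.j_call.split("*")[0]

    @property
    def d_gene(self) -> str | None:
        return self.d_call.split("*")[0] if self.d_call else None


def _align_one(
    segment_seq: str,
    target: str,
    offset: int,
    extend_flanks: bool,
) -> tuple[float, dict] | None:
    """Local alignment of one segment against target[offset:...]; raw pieces."""
    # gaps cost more than mismatch runs: somatic hypermutation is
    # substitution-dominated, and a cheap gap can misattribute adjacent
    # substitutions to indels (corrupting both anchors and mutation counts)
    res = pair_align(
        segment_seq, target, mode="local",
        sub_score=nfree_substitution_matrix(), gap_cost=5, max_paths=1,
    )
    if not res.paths:
        return None
    path = res.paths[0]
    (q0, q1), (t0, t1) = (tuple(int(x) for x in r) for r in path.ranges)
    aligned_q, aligned_t = path.to_aligned((segment_seq, target))
    pairs: list[tuple[int, int]] = []
    mismatches: list[tuple[int, int, str, str]] = []
    columns = 0
    matches = 0
    qpos, tpos = q0, t0
    for cq, ct in zip(aligned_q, aligned_t):
        columns += 1
        if cq != "-" and ct != "-":
            pairs.append((qpos, tpos + offset))
            if cq == ct:
                matches += 1
            elif cq != "N" and ct != "N":
                mismatches.append((qpos, tpos + offset, cq, ct))
            qpos += 1
            tpos += 1
        elif cq == "-":
            tpos += 1
        else:
            qpos += 1
    if extend_flanks:
        while q0 > 0 and t0 > 0:
            q0 -= 1
            t0 -= 1
            cq, ct = segment_seq[q0], target[t0]
            pairs.insert(0, (q0, t0 + offset))
            columns += 1
            if cq == ct:
                matches += 1
            elif cq != "N" and ct != "N":
                mismatches.insert(0, (q0, t0 + offset, cq, ct))
        while q1 < len(segment_seq) and t1 < len(target):
            cq, ct = segment_seq[q1], target[t1]
            pairs.append((q1, t1 + offset))
            columns += 1
            if cq == ct:
                matches += 1
            elif cq != "N" and ct != "N":
                mismatches.append((q1, t1 + offset, cq, ct))
            q1 += 1
            t1 += 1
    return float(res.score), {
        "segment_start": q0, "segment_end": q1,
        "contig_start": t0 + offset, "contig_end": t1 + offset,
        "identity": 100.0 * matches / columns if columns else 0.0,
        "pairs": pairs, "mismatches": mismatches,
    }


def align_to_segments(
    contig: Contig | str,
    db: GermlineDatabase,
    chain: str,
    segment_class: str,
    search_window: tuple[int, int] | None = None,
    min_score: float | None = None,
    strand: str = "+",
    both_strands: bool | None = None,
    extend_flanks: bool = False,
) -> list[SegmentAlignment]:
    """Rank local alignments of every (chain, class) segment against a contig.

    V searches both strands by default; coordinates always refer to the
    strand-oriented contig.  Results are sorted score desc, then identity
    desc, then allele_id; alignments under ``min_score`` are dropped.
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    segments = db.segments(chain, segment_class)
    if not segments:
        raise AnnotationError(f"no {segment_class} segments for chain {chain}")
    if min_score is None:
        min_score = DEFAULT_MIN_SCORES[segment_class]
    if both_strands is None:
        both_strands = segment_class == "V" and strand == "+"
    out: list[SegmentAlignment] = []
    strands = [("+", seq), ("-", revcomp(seq))] if both_strands else [(strand, seq)]
    for label, oriented in strands:
        lo, hi = search_window if search_window else (0, len(oriented))
        window = oriented[lo:hi]
        if not window:
            continue
        for seg in segments:
            res = _align_one(seg.sequence, window, lo, extend_flanks)
            if res is None or res[0] < min_score:
                continue
            score, parts = res
            out.append(SegmentAlignment(
                allele_id=seg.allele_id, segment_class=segment_class,
                score=score, strand=label, **parts,
            ))
    out.sort(key=lambda a: (-a.score, -a.identity, a.allele_id, a.strand))
    return out


def annotate_contig(
    contig: Contig,
    db: GermlineDatabase,
    min_scores: dict[str, float] | None = None,
) -> IgAnnotation | None:
    """Full V(D)J/C annotation of one contig, or None when no V/J call passes."""
    scores = dict(DEFAULT_MIN_SCORES)
    if min_scores:
        scores.update(min_scores)

    best_v: SegmentAlignment | None = None
    best_chain: str | None = None
    for chain in db.chains:
        if not db.segments(chain, "V"):
            continue
        hits = align_to_segments(
            contig, db, chain, "V", min_score=scores["V"], extend_flanks=True
        )
        if hits and (best_v is None or hits[0].score > best_v.score):
            best_v, best_chain = hits[0], chain
    if best_v is None:
        return None
    chain = best_chain
    strand = best_v.strand
    oriented = contig.sequence if strand == "+" else revcomp(contig.sequence)

    v_seg = db.get(best_v.allele_id)
    if v_seg.cys104_offset is None:
        raise AnnotationError(f"anchor cys104 missing for {best_v.allele_id}")

    j_hits = align_to_segments(
        oriented, db, chain, "J",
        search_window=(best_v.contig_end, len(oriented)),
        min_score=scores["J"], strand=strand, both_strands=False,
    )
    if not j_hits:
        return None
    best_j = j_hits[0]
    j_seg = db.get(best_j.allele_id)
    if j_seg.jtrp_offset is None:
        raise AnnotationError(f"anchor jtrp missing for {best_j.allele_id}")

    d_aln = None
    if chain == "IGH" and db.segments(chain, "D"):
        window = (best_v.contig_end, best_j.contig_start)
        if window[1] - window[0] >= 5:
            d_hits = align_to_segments(
                oriented, db, chain, "D", search_window=window,
                min_score=scores["D"], strand=strand, both_strands=False,
            )
            d_aln = d_hits[0] if d_hits else None

    c_aln = None
    if db.segments(chain, "C") and best_j.contig_end < len(oriented):
        c_hits = align_to_segments(
            oriented, db, chain, "C",
            search_window=(best_j.contig_end, len(oriented)),
            min_score=scores["C"], strand=strand, both_strands=False,
        )
        c_aln = c_hits[0] if c_hits else None

    cys_pos = best_v.project(v_seg.cys104_offset)
    j_anchor = best_j.project(j_seg.jtrp_offset)
    cdr3 = ""
    frame_ok = False
    stop = False
    cdr3_start = None
    if cys_pos is not None and j_anchor is not None and j_anchor + 3 <= len(oriented):
        frame_ok = (j_anchor - cys_pos) % 3 == 0
        if j_anchor >= cys_pos:
            cdr3 = oriented[cys_pos : j_anchor + 3]
            cdr3_start = cys_pos
        scan_start = best_v.contig_start + ((cys_pos - best_v.contig_start) % 3)
        stop = has_stop_in_frame(oriented, scan_start, best_j.contig_end)
    productive = bool(frame_ok and not stop and cdr3 and len(cdr3) % 3 == 0)
    return IgAnnotation(
        contig_id=contig.contig_id, chain=chain,
        v_call=best_v.allele_id, j_call=best_j.allele_id,
        d_call=d_aln.allele_id if d_aln else None,
        c_call=c_aln.allele_id if c_aln else None,
        cdr3_nt=cdr3,
        cdr3_aa=translate(cdr3) if cdr3 and len(cdr3) % 3 == 0 else "",
        productive=productive, frame_ok=frame_ok, stop_codon=stop,
        strand=strand, cdr3_start=cdr3_start,
        v_alignment=best_v, j_alignment=best_j,
        d_alignment=d_aln, c_alignment=c_aln,
    )


def count_shm(annotation: IgAnnotation, db: GermlineDatabase) -> int:
    """Substitutions in the V region upstream of the CDR3 start.

    Differences arising from junctional N diversity are never counted: the
    count stops at the conserved cysteine codon that opens the CDR3, and
    alignment gaps are not counted as mutations.
    """
    if annotation.v_alignment is None:
        raise AnnotationError("annotation has no V alignment")
    v_seg = db.get(annotation.v_call)
    cutoff = v_seg.cys104_offset
    if cutoff is None:
        cutoff = len(v_seg.sequence)
    return sum(1 for seg_pos, _c, _a, _b in annotation.v_alignment.mismatches if seg_pos < cutoff)
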