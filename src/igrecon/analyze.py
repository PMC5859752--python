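"""Downstream analyses: concordance validation, accuracy summaries and
clonal-family assignment.

A reconstruction is *accurate* for a chain when its V(D)J gene annotations
and exact CDR3 nucleotide sequence agree with an independently obtained
reference sequence (e.g. RT-PCR/Sanger) for the same cell.  Gene-level
comparison strips allele designations (IGHV1-69*01 -> IGHV1-69) because
amplicon references cannot always resolve alleles; allele-exact mode is
available.  Clonal families group cells sharing V gene, J gene and CDR3
length on both chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from skbio.alignment import pair_align

from .annotate import annotate_contig
from .assemble import Contig
from .dna import revcomp
from .germline import GermlineDatabase
from .mapper import nfree_substitution_matrix
from .select import ChainCall


@dataclass
class ValidationRecord:
    cell_id: str
    chain: str
    evaluable: bool
    v_match: bool = False
    d_match: bool = False
    j_match: bool = False
    cdr3_match: bool = False
    accurate: bool = False
    nt_identity: float = 0.0  # percent over aligned columns
    coverage: float = 0.0  # percent of reference length aligned


@dataclass
class ClonalFamily:
    family_id: str
    key: tuple  # (hV, hJ, h CDR3 len, lV, lJ, l CDR3 len)
    members: list[str]


def _identity_and_coverage(query: str, reference: str) -> tuple[float, float]:
    """Best-strand local alignment identity (%) and reference coverage (%)."""
    best = (0.0, 0.0)
    for q in (query, revcomp(query)):
        res = pair_align(
            q, reference, mode="local",
            sub_score=nfree_substitution_matrix(), gap_cost=2, max_paths=1,
        )
        if not res.paths:
            continue
        path = res.paths[0]
        a_q, a_r = path.to_aligned((q, reference))
        columns = len(a_q)
        matches = sum(1 for x, y in zip(a_q, a_r) if x == y and x != "-")
        r0, r1 = (int(x) for x in path.ranges[1])
        identity = 100.0 * matches / columns if columns else 0.0
        coverage = 100.0 * (r1 - r0) / len(reference) if reference else 0.0
        if (coverage, identity) > (best[1], best[0]):
            best = (identity, coverage)
    return best


def compare_to_reference(
    call: ChainCall,
    reference_seq: str,
    db: GermlineDatabase,
    allele_level: bool = False,
) -> ValidationRecord:
    """Adjudicate one chain call against a matched reference sequence.

    The reference is annotated with the same machinery; a reference that is
    not annotatable/productive yields a non-evaluable record.  CDR3 match is
    exact nucleotide equality; D match is vacuously true when either side
    lacks a confident D call.
    """
    ref_ann = annotate_contig(Contig("reference", reference_seq.upper(), 0.0), db)
    if ref_ann is None or not ref_ann.productive:
        return ValidationRecord(call.cell_id, call.chain, evaluable=False)
    rec_ann = call.selected.annotation

    def _name(callname: str | None) -> str | None:
        if callname is None:
            return None
        return callname if allele_level else callname.split("*")[0]

    v_match = _name(rec_ann.v_call) == _name(ref_ann.v_call)
    j_match = _name(rec_ann.j_call) == _name(ref_ann.j_call)
    if rec_ann.d_call is None or ref_ann.d_call is None:
        d_match = True
    else:
        d_match = _name(rec_ann.d_call) == _name(ref_ann.d_call)
    cdr3_match = rec_ann.cdr3_nt == ref_ann.cdr3_nt
    accurate = bool(v_match and j_match and cdr3_match and (call.chain != "IGH" or d_match))
    identity, coverage = _identity_and_coverage(
        call.selected.contig.sequence, reference_seq.upper()
    )
    return ValidationRecord(
        cell_id=call.cell_id, chain=call.chain, evaluable=True,
        v_match=v_match, d_match=d_match, j_match=j_match,
        cdr3_match=cdr3_match, accurate=accurate,
        nt_identity=identity, coverage=coverage,
    )


@dataclass
class AccuracySummary:
    per_chain: dict[str, tuple[int, int, float | None]]  # chain -> (eval, accurate, frac)
    paired_evaluable: int
    paired_accurate: int
    paired_accuracy: float | None
    clonotype_collapsed_accuracy: float | None = None


def _chain_group(chain: str) -> str:
    return "IGH" if chain == "IGH" else "IGL"


def summarize_accuracy(
    records: Sequence[ValidationRecord],
    families: Sequence[ClonalFamily] | None = None,
) -> AccuracySummary:
    """Per-chain and paired accuracy over evaluable records.

    Light-chain records (IGK/IGL) are pooled under "IGL".  Paired accuracy
    is computed over cells with both a heavy and a light evaluable record,
    requiring both to be accurate.  When clonal families are supplied, a
    clonotype-collapsed paired accuracy is added: one vote per family,
    accurate iff every evaluable member pair is accurate.
    """
    if not records:
        raise ValueError("no validation records")
    per_chain: dict[str, list[ValidationRecord]] = {}
    for rec in records:
        per_chain.setdefault(_chain_group(rec.chain), []).append(rec)
    chain_stats = {}
    for grp, recs in sorted(per_chain.items()):
        ev = [r for r in recs if r.evaluable]
        acc = sum(1 for r in ev if r.accurate)
        chain_stats[grp] = (len(ev), acc, acc / len(ev) if ev else None)

    by_cell: dict[str, dict[str, ValidationRecord]] = {}
    for rec in records:
        if rec.evaluable:
            by_cell.setdefault(rec.cell_id, {})[_chain_group(rec.chain)] = rec
    paired = {
        cid: chains for cid, chains in by_cell.items() if {"IGH", "IGL"} <= set(chains)
    }
    paired_acc = {
        cid for cid, chains in paired.items()
        if chains["IGH"].accurate and chains["IGL"].accurate
    }
    collapsed = None
    if families is not None and paired:
        assigned = {cid for fam in families for cid in fam.members}
        votes = []
        for fam in families:
            members = [cid for cid in fam.members if cid in paired]
            if members:
                votes.append(all(cid in paired_acc for cid in members))
        for cid in paired:
            if cid not in assigned:
                votes.append(cid in paired_acc)
        if votes:
            collapsed = sum(votes) / len(votes)
    return AccuracySummary(
        per_chain=chain_stats,
        paired_evaluable=len(paired),
        paired_accurate=len(paired_acc),
        paired_accuracy=len(paired_acc) / len(paired) if paired else None,
        clonotype_collapsed_accuracy=collapsed,
    )


def clonotype_key(heavy: ChainCall, light: ChainCall) -> tuple:
    h = heavy.selected.annotation
    l = light.selected.annotation
    return (
        h.v_gene, h.j_gene, len(h.cdr3_nt),
        l.v_gene, l.j_gene, len(l.cdr3_nt),
    )


def assign_clonal_families(
    cells: Mapping[str, tuple[ChainCall | None, ChainCall | None]],
) -> tuple[list[ClonalFamily], list[str]]:
    """Partition cells with both chains called by the 6-tuple clonotype key.

    Returns (families, excluded_cell_ids); families are sorted by size desc
    then key, and ids are CF01, CF02, ...
    """
    excluded = sorted(
        cid for cid, (h, l) in cells.items() if h is None or l is None
    )
    groups: dict[tuple, list[str]] = {}
    for cid, (h, l) in cells.items():
        if h is None or l is None:
            continue
        groups.setdefault(clonotype_key(h, l), []).append(cid)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    families = [
        ClonalFamily(family_id=f"CF{i + 1:02d}", key=key, members=sorted(members))
        for i, (key, members) in enumerate(ordered)
    ]
    return families, excluded
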