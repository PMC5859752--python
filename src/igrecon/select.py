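"""Read-support quantification, model ranking/filtering and top-model choice.

Transcript models are ranked by the number of reads mapping end-to-end
(report-all semantics: a read increments every model it aligns to);
unproductive models and models repeating the (V, D, J, CDR3 nt) of a
higher-ranked survivor are removed, and the top survivor becomes the
per-chain call.  A call whose read support is under twice the surviving
runner-up's is flagged ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotate import IgAnnotation
from .assemble import Contig
from .mapper import (
    DEFAULT_E2E_MIN_FRACTION,
    DEFAULT_K,
    MappingResult,
    ReferenceIndex,
    map_units,
)
from .reads import ReadSet

AMBIGUITY_RATIO = 2.0


@dataclass
class RankedModel:
    contig: Contig
    annotation: IgAnnotation | None
    read_count: int
    rank: int = 0

    @property
    def redundancy_key(self) -> tuple | None:
        a = self.annotation
        if a is None:
            return None
        return (a.v_call, a.d_call, a.j_call, a.cdr3_nt)


@dataclass
class ChainCall:
    cell_id: str
    chain: str
    selected: RankedModel
    runner_up_count: int
    ambiguity_ratio: float
    ambiguous: bool


def quantify_models(
    contigs: Sequence[Contig],
    reads: ReadSet,
    k: int = DEFAULT_K,
    e2e_min_fraction: float = DEFAULT_E2E_MIN_FRACTION,
    dp_fallback: bool = False,
) -> dict[str, int]:
    """End-to-end read counts per contig (each mate counts individually).

    Extension is substitution-only by default (models are assembled from the
    same reads, so gapped placements do not arise); set ``dp_fallback`` for
    exact-DP rescue of gapped alignments.
    """
    if not contigs:
        raise ValueError("no contigs to quantify")
    index = ReferenceIndex([(c.contig_id, c.sequence) for c in contigs], k=k)
    units = [(rid, mate, seq) for rid, mate, seq in reads.units() if len(seq) >= k]
    result = map_units(
        units, index, mode="end_to_end", report="all",
        e2e_min_fraction=e2e_min_fraction, dp_fallback=dp_fallback,
    )
    counts = {c.contig_id: 0 for c in contigs}
    for hits in result.hits.values():
        for hit in hits:
            counts[hit.reference_id] += 1
    return counts


def rank_and_filter_models(
    models: Iterable[RankedModel], chain: str | None = None
) -> list[RankedModel]:
    """Order by read support and drop unproductive / redundant models.

    Sort: read count desc, contig length desc, contig_id asc.  A model whose
    (V, D, J, CDR3 nt) equals a surviving higher-ranked model's is dropped;
    no-call annotations are treated as unproductive.
    """
    pool = [
        m for m in models
        if chain is None or (m.annotation is not None and m.annotation.chain == chain)
    ]
    pool.sort(key=lambda m: (-m.read_count, -m.contig.length, m.contig.contig_id))
    survivors: list[RankedModel] = []
    seen_keys: set[tuple] = set()
    for m in pool:
        if m.annotation is None or not m.annotation.productive:
            continue
        key = m.redundancy_key
        if key in seen_keys:
            continue
        seen_keys.add(key)
        survivors.append(
            RankedModel(m.contig, m.annotation, m.read_count, rank=len(survivors) + 1)
        )
    return survivors


def select_top_model(
    survivors: Sequence[RankedModel], cell_id: str, chain: str
) -> ChainCall | None:
    """First survivor becomes the chain call; None when no survivor exists."""
    if not survivors:
        return None
    selected = survivors[0]
    runner_up = survivors[1].read_count if len(survivors) > 1 else 0
    ratio = selected.read_count / max(runner_up, 1)
    return ChainCall(
        cell_id=cell_id, chain=chain, selected=selected,
        runner_up_count=runner_up, ambiguity_ratio=ratio,
        ambiguous=len(survivors) > 1 and ratio < AMBIGUITY_RATIO,
    )
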