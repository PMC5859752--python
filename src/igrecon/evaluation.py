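"""Canned simulation-based evaluation protocols.

Each protocol builds its own synthetic repertoire, genome bundle and cells
from a single integer seed, runs the relevant part of the pipeline, and
returns plain result records.  They are the package's reproducible
self-checks: a scaled-down round-trip of the reconstruction accuracy study,
the dominant-model (top vs runner-up) property, exact somatic-hypermutation
recovery, filter containment, assembler reconstruction oracles, and
clonal-family recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analyze import assign_clonal_families
from .annotate import annotate_contig, count_shm
from .assemble import Contig, assemble_reads
from .dna import random_dna, revcomp
from .filterreads import FilterConfig, FilterResources, filter_reads
from .pipeline import PipelineConfig, run_cell
from .reads import Read, ReadSet
from .select import ChainCall, RankedModel
from .simulate import (
    BackgroundTranscriptome,
    ReadConfig,
    build_reference_bundle,
    simulate_cell_reads,
    simulate_cohort,
    synthetic_germline_db,
)


def _derive(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31 - 1))


def _study_setup(seed: int):
    rng = np.random.default_rng(seed)
    db = synthetic_germline_db(rng)
    background = BackgroundTranscriptome.generate(rng)
    genome, loci, genes = build_reference_bundle(db, background, rng)
    resources = FilterResources.from_germline(
        db, genome=genome, locus_table=loci, gene_annotation=genes
    )
    return db, background, resources


@dataclass
class CellRoundTrip:
    cell_id: str
    heavy_recovered: bool
    light_recovered: bool
    chain_ratios: list[float] = field(default_factory=list)
    shm: list[tuple[int, int]] = field(default_factory=list)  # (planted, counted)

    @property
    def both_recovered(self) -> bool:
        return self.heavy_recovered and self.light_recovered


@dataclass
class RoundTripResult:
    cells: list[CellRoundTrip]

    @property
    def recovery_fraction(self) -> float:
        return sum(c.both_recovered for c in self.cells) / len(self.cells)

    @property
    def dominant_fraction(self) -> float:
        ratios = [r for c in self.cells for r in c.chain_ratios]
        return sum(r >= 2.0 for r in ratios) / len(ratios) if ratios else 0.0

    @property
    def shm_exact_fraction(self) -> float:
        pairs = [p for c in self.cells for p in c.shm]
        return sum(a == b for a, b in pairs) / len(pairs) if pairs else 0.0


def _recovered(call: ChainCall | None, truth) -> bool:
    if call is None:
        return False
    ann = call.selected.annotation
    return (
        ann.v_gene == truth.v_gene
        and ann.j_gene == truth.j_gene
        and ann.cdr3_nt == truth.cdr3_nt
    )


def roundtrip_study(
    seed: int,
    n_cells: int = 20,
    total_reads: int = 100_000,
    read_length: int = 151,
    error_rate: float = 0.001,
    strategy: str = "ig_mapped_plus_unmapped",
    count_mutations: bool = False,
) -> RoundTripResult:
    """Scaled-down reconstruction round-trip on simulated plasmablasts.

    Simulates ``n_cells`` SE-``read_length`` plasmablasts carrying
    Poisson-distributed mutation loads around the observed medians, runs the
    full pipeline with the chosen strategy, and records per cell whether the
    selected models reproduce the true (V gene, J gene, CDR3 nt) for both
    chains, plus the top:runner-up read-support ratio of every call.
    """
    db, background, resources = _study_setup(_derive(seed, 1))
    cells = simulate_cohort(db, n_cells, seed=_derive(seed, 2))
    read_config = ReadConfig(
        layout="SE", read_length=read_length,
        total_reads=total_reads, error_rate=error_rate,
    )
    pipe_config = PipelineConfig(strategy=strategy, seed=seed)
    out = []
    for cell in cells:
        reads = simulate_cell_reads(
            cell, background, read_config, np.random.default_rng(cell.seed)
        )
        result = run_cell(cell.cell_id, reads, pipe_config, resources)
        ratios = [
            c.ambiguity_ratio if c.runner_up_count else float("inf")
            for c in (result.heavy, result.light) if c is not None
        ]
        shm_pairs = []
        if count_mutations:
            for call, truth in ((result.heavy, cell.heavy), (result.light, cell.light)):
                if call is not None and _recovered(call, truth):
                    shm_pairs.append(
                        (len(truth.shm_positions),
                         count_shm(call.selected.annotation, db))
                    )
        out.append(CellRoundTrip(
            cell_id=cell.cell_id,
            heavy_recovered=_recovered(result.heavy, cell.heavy),
            light_recovered=_recovered(result.light, cell.light),
            chain_ratios=ratios,
            shm=shm_pairs,
        ))
    return RoundTripResult(out)


def shm_exactness_study(
    seed: int, n_cells: int = 8, total_reads: int = 30_000
) -> RoundTripResult:
    """Error-free cells: planted V-region mutation counts must be recovered
    exactly by count_shm on the selected models."""
    return roundtrip_study(
        seed, n_cells=n_cells, total_reads=total_reads,
        error_rate=0.0, count_mutations=True,
    )


@dataclass
class ContainmentResult:
    n_readsets: int
    violations: int
    unfiltered_identity: bool


def containment_study(seed: int, n_cells: int = 3, total_reads: int = 5_000) -> ContainmentResult:
    """ig_mapped retained must be a subset of ig_mapped_plus_unmapped
    retained, and unfiltered must be the identity, on every read set."""
    db, background, resources = _study_setup(_derive(seed, 3))
    cells = simulate_cohort(db, n_cells, seed=_derive(seed, 4))
    violations = 0
    identity_ok = True
    for cell in cells:
        reads = simulate_cell_reads(
            cell, background, ReadConfig(total_reads=total_reads),
            np.random.default_rng(cell.seed),
        )
        ids = lambda strategy: {
            r.read_id for r in filter_reads(reads, FilterConfig(strategy=strategy), resources)
        }
        if not ids("ig_mapped") <= ids("ig_mapped_plus_unmapped"):
            violations += 1
        kept = filter_reads(reads, FilterConfig(strategy="unfiltered"), resources)
        if [r.read_id for r in kept] != [r.read_id for r in reads]:
            identity_ok = False
    return ContainmentResult(n_cells, violations, identity_ok)


@dataclass
class AssemblerOracleResult:
    single_exact: bool
    two_transcripts_exact: bool


def assembler_oracle_study(seed: int, transcript_len: int = 1400) -> AssemblerOracleResult:
    """Error-free tiling reads of known transcripts must reassemble them
    exactly (up to reverse complement)."""
    rng = np.random.default_rng(_derive(seed, 5))

    def _tile(transcript: str, tag: str) -> list[Read]:
        reads = []
        for d in range(30):
            for start in range(0, len(transcript) - 100 + 1, 37):
                seq = transcript[start : start + 100]
                reads.append(Read(f"{tag}_{d}_{start}", seq))
            reads.append(Read(f"{tag}_{d}_end", transcript[-100:]))
        return reads

    def _exact(contigs: list[Contig], transcript: str) -> bool:
        return any(
            c.sequence == transcript or c.sequence == revcomp(transcript)
            for c in contigs
        )

    t1 = random_dna(rng, transcript_len)
    contigs1 = assemble_reads(
        ReadSet(_tile(t1, "a"), layout="SE", read_length=100), k=25
    )
    single = len(contigs1) == 1 and _exact(contigs1, t1)

    t2 = random_dna(rng, 900)
    t3 = random_dna(rng, 700)
    contigs2 = assemble_reads(
        ReadSet(_tile(t2, "b") + _tile(t3, "c"), layout="SE", read_length=100), k=25
    )
    double = len(contigs2) == 2 and _exact(contigs2, t2) and _exact(contigs2, t3)
    return AssemblerOracleResult(single, double)


@dataclass
class ClonalPartitionResult:
    n_cells: int
    planted_sizes: list[int]
    recovered_sizes: list[int]
    exact: bool


def clonal_partition_study(
    seed: int, family_sizes: tuple[int, ...] = (17, 9, 5)
) -> ClonalPartitionResult:
    """Annotate the true transcripts of a planted-family cohort and check the
    clonal partition is recovered exactly."""
    rng = np.random.default_rng(_derive(seed, 6))
    db = synthetic_germline_db(rng)
    n_cells = sum(family_sizes)
    cohort = simulate_cohort(db, n_cells, seed=_derive(seed, 7), family_sizes=list(family_sizes))
    planted: dict[str, set[str]] = {}
    calls = {}
    for i, cell in enumerate(cohort):
        fam_idx = 0
        consumed = 0
        for j, size in enumerate(family_sizes):
            if i < consumed + size:
                fam_idx = j
                break
            consumed += size
        planted.setdefault(str(fam_idx), set()).add(cell.cell_id)
        pair = []
        for truth in (cell.heavy, cell.light):
            contig = Contig(f"{cell.cell_id}_{truth.chain}", truth.transcript, 10.0)
            ann = annotate_contig(contig, db)
            pair.append(
                ChainCall(cell.cell_id, truth.chain, RankedModel(contig, ann, 100, 1),
                          0, 100.0, False)
                if ann is not None else None
            )
        calls[cell.cell_id] = (pair[0], pair[1])
    families, excluded = assign_clonal_families(calls)
    recovered = {frozenset(f.members) for f in families}
    expected = {frozenset(m) for m in planted.values()}
    return ClonalPartitionResult(
        n_cells=n_cells,
        planted_sizes=sorted(family_sizes, reverse=True),
        recovered_sizes=sorted((len(f.members) for f in families), reverse=True),
        exact=not excluded and recovered == expected,
    )
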