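"""Per-cell and batch orchestration of the reconstruction pipeline.

One cell runs trim -> filter -> assemble -> annotate -> quantify ->
rank/filter -> select.  Genome-based strategies (unfiltered, ig_mapped,
ig_mapped_plus_unmapped, filter_non_ig) produce one chain-agnostic read set
and a single assembly whose contigs are adjudicated per locus; the
reference-based strategies (recombinome_mapped, imgt_mapped) run the heavy
and light passes independently against their own reference sets.  The light
chain call is the best surviving model across IGK and IGL by read count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate import IgAnnotation, annotate_contig
from .assemble import Contig, assemble_reads, trim_adapters, write_contigs_fasta, AssemblyError
from .filterreads import (
    CHAIN_GROUPS,
    FilterConfig,
    FilterResources,
    filter_reads,
)
from .mapper import DEFAULT_E2E_MIN_FRACTION, DEFAULT_K, DEFAULT_MIN_SCORE, map_units
from .reads import ReadSet, read_fastq
from .select import ChainCall, RankedModel, quantify_models, rank_and_filter_models, select_top_model

GENOME_WIDE_STRATEGIES = ("unfiltered", "ig_mapped", "ig_mapped_plus_unmapped", "filter_non_ig")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    species: str = "human"
    strategy: str = "ig_mapped_plus_unmapped"
    seed: int = 0
    adapters: list[str] = field(default_factory=list)
    filter_k: int = DEFAULT_K
    filter_min_score: float = DEFAULT_MIN_SCORE
    min_seed_count: int = 1
    assembly_k: int = 25
    min_contig_len: int = 300
    min_kmer_count: int = 2
    e2e_min_fraction: float = DEFAULT_E2E_MIN_FRACTION
    annotation_min_scores: dict[str, float] = field(default_factory=dict)
    allele_level: bool = False
    output_dir: str | None = None

    def validate(self, resources: FilterResources) -> None:
        if self.species == "human" and self.strategy == "filter_non_ig":
            raise PipelineConfigError(
                "filter_non_ig is the rhesus-preset strategy; species must be 'rhesus'"
            )
        if self.strategy == "filter_non_ig" and resources.gene_annotation is None:
            raise PipelineConfigError("filter_non_ig requires a gene annotation")
        FilterConfig(strategy=self.strategy, k=self.filter_k,
                     min_seed_count=self.min_seed_count, min_score=self.filter_min_score)

    def digest(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir", None)  # where results land is not what they are
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class CellResult:
    cell_id: str
    status: str  # 'ok' | 'no_call' | 'failed'
    heavy: ChainCall | None = None
    light: ChainCall | None = None
    models: dict[str, list[RankedModel]] = field(default_factory=dict)  # locus -> survivors
    annotations: list[IgAnnotation] = field(default_factory=list)
    counters: dict[str, int] = field(default_factory=dict)
    error: str | None = None

    @property
    def calls(self) -> dict[str, ChainCall | None]:
        return {"IGH": self.heavy, "light": self.light}


def _filter_config(config: PipelineConfig) -> FilterConfig:
    return FilterConfig(
        strategy=config.strategy, k=config.filter_k,
        min_seed_count=config.min_seed_count, min_score=config.filter_min_score,
    )


def _build_models(
    contigs: Sequence[Contig],
    reads: ReadSet,
    resources: FilterResources,
    config: PipelineConfig,
) -> tuple[list[RankedModel], list[IgAnnotation]]:
    counts = quantify_models(
        contigs, reads, k=min(config.filter_k, config.assembly_k),
        e2e_min_fraction=config.e2e_min_fraction,
    ) if contigs else {}
    models = []
    annotations = []
    for contig in contigs:
        ann = annotate_contig(contig, resources.germline_db, config.annotation_min_scores or None)
        if ann is not None:
            annotations.append(ann)
        models.append(RankedModel(contig, ann, counts.get(contig.contig_id, 0)))
    return models, annotations


def run_cell(
    cell_id: str,
    reads: ReadSet | str | Path | Sequence[str | Path],
    config: PipelineConfig,
    resources: FilterResources,
) -> CellResult:
    """Run the full pipeline for one cell.

    ``reads`` may be a ReadSet or FASTQ path(s).  'no_call' status means the
    pipeline ran but no productive model survived for any chain; failures
    carry the error message instead of raising.
    """
    config.validate(resources)
    if not isinstance(reads, ReadSet):
        paths = [reads] if isinstance(reads, (str, Path)) else list(reads)
        reads = read_fastq(*paths)
    reads = trim_adapters(reads, config.adapters)
    counters = {"reads_in": len(reads)}
    fconfig = _filter_config(config)

    models_by_locus: dict[str, list[RankedModel]] = {}
    annotations: list[IgAnnotation] = []

    def _assemble(readset: ReadSet) -> list[Contig]:
        try:
            return assemble_reads(
                readset, k=config.assembly_k,
                min_contig_len=config.min_contig_len,
                min_kmer_count=config.min_kmer_count,
            )
        except AssemblyError:
            return []

    if config.strategy in GENOME_WIDE_STRATEGIES:
        retained = filter_reads(reads, fconfig, resources)
        counters["reads_retained"] = len(retained)
        contigs = _assemble(retained)
        counters["contigs"] = len(contigs)
        models, annotations = _build_models(contigs, retained, resources, config)
        for locus in ("IGH", "IGK", "IGL"):
            models_by_locus[locus] = rank_and_filter_models(models, locus)
    else:
        for group, loci in CHAIN_GROUPS.items():
            retained = filter_reads(reads, fconfig, resources, chain_group=group)
            counters[f"reads_retained_{group}"] = len(retained)
            contigs = _assemble(retained)
            counters[f"contigs_{group}"] = len(contigs)
            models, anns = _build_models(contigs, retained, resources, config)
            annotations.extend(anns)
            for locus in loci:
                models_by_locus[locus] = rank_and_filter_models(models, locus)

    heavy = select_top_model(models_by_locus.get("IGH", []), cell_id, "IGH")
    light_calls = [
        call
        for locus in ("IGK", "IGL")
        if (call := select_top_model(models_by_locus.get(locus, []), cell_id, locus))
    ]
    light = max(light_calls, key=lambda c: c.selected.read_count, default=None)

    counters["survivors"] = sum(len(v) for v in models_by_locus.values())
    status = "ok" if (heavy or light) else "no_call"
    result = CellResult(
        cell_id=cell_id, status=status, heavy=heavy, light=light,
        models=models_by_locus, annotations=annotations, counters=counters,
    )
    if config.output_dir:
        _write_cell_outputs(result, config)
    return result


def airr_table(results: Sequence[CellResult]) -> pd.DataFrame:
    """AIRR Rearrangement-style table of the selected chain calls."""
    rows = []
    for res in sorted(results, key=lambda r: r.cell_id):
        for call in (res.heavy, res.light):
            if call is None:
                continue
            ann = call.selected.annotation
            rows.append({
                "cell_id": call.cell_id,
                "locus": call.chain,
                "v_call": ann.v_call,
                "d_call": ann.d_call or "",
                "j_call": ann.j_call,
                "c_call": ann.c_call or "",
                "cdr3": ann.cdr3_nt,
                "cdr3_aa": ann.cdr3_aa,
                "productive": ann.productive,
                "consensus_count": call.selected.read_count,
            })
    return pd.DataFrame(
        rows,
        columns=["cell_id", "locus", "v_call", "d_call", "j_call", "c_call",
                 "cdr3", "cdr3_aa", "productive", "consensus_count"],
    )


def ranked_model_table(results: Sequence[CellResult]) -> pd.DataFrame:
    rows = []
    for res in sorted(results, key=lambda r: r.cell_id):
        for locus, survivors in sorted(res.models.items()):
            for m in survivors:
                ann = m.annotation
                rows.append({
                    "cell_id": res.cell_id, "locus": locus,
                    "contig_id": m.contig.contig_id, "rank": m.rank,
                    "read_count": m.read_count, "length": m.contig.length,
                    "v_call": ann.v_call if ann else "",
                    "d_call": (ann.d_call or "") if ann else "",
                    "j_call": ann.j_call if ann else "",
                    "cdr3": ann.cdr3_nt if ann else "",
                    "productive": ann.productive if ann else False,
                })
    return pd.DataFrame(
        rows,
        columns=["cell_id", "locus", "contig_id", "rank", "read_count", "length",
                 "v_call", "d_call", "j_call", "cdr3", "productive"],
    )


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# igrecon seed={config.seed} config={config.digest()}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_cell_outputs(result: CellResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir) / result.cell_id
    out.mkdir(parents=True, exist_ok=True)
    contigs = [m.contig for models in result.models.values() for m in models]
    seen = set()
    unique = [c for c in contigs if not (c.contig_id in seen or seen.add(c.contig_id))]
    if unique:
        write_contigs_fasta(unique, out / "models.fasta")
    _write_tsv(airr_table([result]), out / "chain_calls.tsv", config)
    _write_tsv(ranked_model_table([result]), out / "ranked_models.tsv", config)
    with open(out / "counters.json", "w") as fh:
        json.dump({"status": result.status, **result.counters}, fh, indent=1)


@dataclass
class BatchResult:
    results: list[CellResult]
    airr: pd.DataFrame
    failures: dict[str, str]

    @property
    def calls(self) -> dict[str, tuple[ChainCall | None, ChainCall | None]]:
        return {r.cell_id: (r.heavy, r.light) for r in self.results if r.status != "failed"}


def run_batch(
    manifest: Mapping[str, "ReadSet | str | Path | Sequence[str | Path]"],
    config: PipelineConfig,
    resources: FilterResources,
) -> BatchResult:
    """Run cells independently; one failing cell never aborts the batch."""
    results = []
    failures = {}
    for cell_id in sorted(manifest):
        try:
            results.append(run_cell(cell_id, manifest[cell_id], config, resources))
        except Exception as exc:  # noqa: BLE001 - per-cell isolation contract
            failures[cell_id] = str(exc)
            results.append(CellResult(cell_id=cell_id, status="failed", error=str(exc)))
    table = airr_table([r for r in results if r.status != "failed"])
    if config.output_dir:
        _write_tsv(table, Path(config.output_dir) / "combined_airr.tsv", config)
        summary = pd.DataFrame(
            [{"cell_id": r.cell_id, "status": r.status, "error": r.error or ""} for r in results]
        )
        _write_tsv(summary, Path(config.output_dir) / "batch_summary.tsv", config)
    return BatchResult(results=results, airr=table, failures=failures)


def read_manifest(path: str | Path) -> dict[str, list[Path]]:
    """TSV manifest: cell_id <tab> fastq1 [<tab> fastq2]; unique cell ids."""
    manifest: dict[str, list[Path]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PipelineConfigError(f"manifest line {line_no}: expected >= 2 columns")
            cell_id = parts[0]
            if cell_id in manifest:
                raise PipelineConfigError(f"manifest: duplicate cell_id {cell_id!r}")
            manifest[cell_id] = [Path(p) for p in parts[1:3]]
    return manifest
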