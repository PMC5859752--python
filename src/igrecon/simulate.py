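"""Truth-labeled synthetic single-cell B-cell read simulator.

The simulator emulates the statistical structure the reconstruction pipeline
assumes about plasmablast / B-cell transcriptomes:

* V(D)J recombination with exonucleolytic trimming (uniform 0-5 nt per
  junction side) and non-templated N nucleotides (uniform 0-10 nt per
  junction), retried until the junction is productive;
* somatic hypermutation as point substitutions in the V region upstream of
  the CDR3 (so mutation counting that excludes junctional N diversity is
  exactly recoverable), at Poisson-distributed loads around the observed
  medians of 23 (heavy) / 16 (light) changes;
* an Ig mRNA fraction of the cell's transcriptome drawn per cell type:
  plasmablasts 5-50%, conventional B cells 0.2-7.9% (log-uniform);
* a background transcriptome of non-Ig "genes" with log-normal abundance;
* SE/PE sequencing at read lengths 50/75/101/151 with uniform substitution
  errors.

Everything is reproducible from (config, seed), and every read carries a
truth origin label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dna import has_stop_in_frame, random_dna, revcomp, STOP_CODONS
from .filterreads import GeneFeature, LocusTable, LocusRow
from .germline import GermlineDatabase, GermlineSegment
from .reads import Read, ReadSet

MAX_TRIM = 5
MAX_N_INSERT = 10
SHM_MEAN_HEAVY = 23  # median V-region nt changes observed for IgH
SHM_MEAN_LIGHT = 16  # and for IgL

PLASMABLAST_IG_FRACTION = (0.05, 0.50)
BCELL_IG_FRACTION = (0.002, 0.079)
HEAVY_LIGHT_RATIO = 1.2  # light-chain transcripts per heavy-chain transcript

_NONSTOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS
)


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Synthetic germline database

_DB_SIZES = {
    "IGH": {"V": 8, "D": 6, "J": 4, "C": 3},
    "IGK": {"V": 6, "D": 0, "J": 3, "C": 1},
    "IGL": {"V": 5, "D": 0, "J": 3, "C": 2},
}
_V_LEN = 300  # 100 codons; second conserved cysteine at codon 97
_CYS_OFFSET = 288
_D_LEN = 15
_J_LEN = {"IGH": 48, "IGK": 39, "IGL": 39}
_JTRP_OFFSET = {"IGH": 30, "IGK": 27, "IGL": 27}
_C_LEN = 300


def _nonstop_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def synthetic_germline_db(
    seed_or_rng: int | np.random.Generator,
    sizes: dict[str, dict[str, int]] | None = None,
    species: str = "human",
) -> GermlineDatabase:
    """Generate a random germline database with CDR3 anchors.

    V alleles are stop-free in frame 0 with a TGT (Cys) anchor codon near the
    3' end; J alleles are stop-free in the anchor frame with a TGG (Trp,
    heavy) or TTT (Phe, light) anchor.  Segment counts default to a small
    desk-scale repertoire.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, int) else seed_or_rng
    sizes = sizes or _DB_SIZES
    db = GermlineDatabase(species=species)
    for chain, counts in sizes.items():
        for i in range(counts.get("V", 0)):
            seq = _nonstop_codons(rng, _V_LEN // 3)
            seq = seq[:_CYS_OFFSET] + "TGT" + seq[_CYS_OFFSET + 3 :]
            db.add(GermlineSegment(
                f"{chain}V1-{i + 1}*01", chain, "V", seq,
                cys104_offset=_CYS_OFFSET, reading_frame=0,
            ))
        for i in range(counts.get("D", 0)):
            # stop-free codons keep the zero-diversity junction productive
            db.add(GermlineSegment(
                f"{chain}D{i + 1}-1*01", chain, "D", _nonstop_codons(rng, _D_LEN // 3)
            ))
        anchor = "TGG" if chain == "IGH" else "TTT"
        jlen, joff = _J_LEN[chain], _JTRP_OFFSET[chain]
        for i in range(counts.get("J", 0)):
            seq = _nonstop_codons(rng, jlen // 3)
            seq = seq[:joff] + anchor + seq[joff + 3 :]
            db.add(GermlineSegment(
                f"{chain}J{i + 1}*01", chain, "J", seq,
                jtrp_offset=joff, reading_frame=joff % 3,
            ))
        for i in range(counts.get("C", 0)):
            db.add(GermlineSegment(f"{chain}C{i + 1}*01", chain, "C", random_dna(rng, _C_LEN)))
    return db


# ---------------------------------------------------------------------------
# Recombination and SHM

@dataclass
class RecombinationTruth:
    chain: str
    v_id: str
    d_id: str | None
    j_id: str
    c_id: str
    v_trim: int
    j_trim: int
    d_trim5: int
    d_trim3: int
    n1_insert: str
    n2_insert: str
    transcript: str
    cdr3_nt: str
    shm_positions: list[tuple[int, str, str]] = field(default_factory=list)
    # derived coordinates on the transcript (0-based)
    v_end: int = 0
    j_start: int = 0
    j_end: int = 0
    cys_pos: int = 0
    j_anchor_pos: int = 0

    @property
    def v_gene(self) -> str:
        return self.v_id.split("*")[0]

    @property
    def j_gene(self) -> str:
        return self.j_id.split("*")[0]


def simulate_recombination(
    db: GermlineDatabase,
    chain: str,
    rng: np.random.Generator,
    max_trim: int = MAX_TRIM,
    max_n_insert: int = MAX_N_INSERT,
    max_retries: int = 100,
    force_zero_diversity: bool = False,
) -> RecombinationTruth:
    """Draw one productive recombination for *chain*.

    Segments are drawn uniformly; trims are uniform on [0, max_trim] and
    junctional insert lengths uniform on [0, max_n_insert] with uniform
    bases.  The junction is redrawn until the V and J anchors are in frame
    and no stop codon lies between the transcript start and the J end.
    """
    db.validate([chain])
    vs = sorted(db.segments(chain, "V"), key=lambda s: s.allele_id)
    js = sorted(db.segments(chain, "J"), key=lambda s: s.allele_id)
    cs = sorted(db.segments(chain, "C"), key=lambda s: s.allele_id)
    ds = sorted(db.segments(chain, "D"), key=lambda s: s.allele_id)
    if chain == "IGH" and not ds:
        raise SimulationError("heavy chain requires at least one D segment")
    if not cs:
        raise SimulationError(f"no C segments for chain {chain}")
    v = vs[rng.integers(0, len(vs))]
    j = js[rng.integers(0, len(js))]
    c = cs[rng.integers(0, len(cs))]
    d = ds[rng.integers(0, len(ds))] if chain == "IGH" else None
    if v.cys104_offset is None or j.jtrp_offset is None:
        raise SimulationError(f"anchors missing for {v.allele_id} / {j.allele_id}")

    for _ in range(max_retries):
        if force_zero_diversity:
            v_trim = j_trim = d5 = d3 = 0
            n1 = n2 = ""
        else:
            v_trim = int(rng.integers(0, max_trim + 1))
            j_trim = int(rng.integers(0, max_trim + 1))
            d5 = int(rng.integers(0, max_trim + 1)) if d else 0
            d3 = int(rng.integers(0, max_trim + 1)) if d else 0
            n1 = random_dna(rng, int(rng.integers(0, max_n_insert + 1)))
            n2 = random_dna(rng, int(rng.integers(0, max_n_insert + 1))) if d else ""
        v_part = v.sequence[: len(v.sequence) - v_trim]
        d_part = d.sequence[d5 : len(d.sequence) - d3] if d else ""
        j_part = j.sequence[j_trim:]
        transcript = v_part + n1 + d_part + n2 + j_part + c.sequence
        j_start = len(v_part) + len(n1) + len(d_part) + len(n2)
        j_end = j_start + len(j_part)
        cys = v.cys104_offset
        j_anchor = j_start + (j.jtrp_offset - j_trim)
        if cys + 3 > len(v_part) or j.jtrp_offset < j_trim:
            continue
        if (j_anchor - cys) % 3 != 0:
            continue
        if has_stop_in_frame(transcript, cys % 3, j_end):
            continue
        return RecombinationTruth(
            chain=chain, v_id=v.allele_id, d_id=d.allele_id if d else None,
            j_id=j.allele_id, c_id=c.allele_id,
            v_trim=v_trim, j_trim=j_trim, d_trim5=d5, d_trim3=d3,
            n1_insert=n1, n2_insert=n2, transcript=transcript,
            cdr3_nt=transcript[cys : j_anchor + 3],
            v_end=len(v_part), j_start=j_start, j_end=j_end,
            cys_pos=cys, j_anchor_pos=j_anchor,
        )
    raise SimulationError(
        f"no productive junction for {v.allele_id}/{j.allele_id} in {max_retries} tries"
    )


def apply_shm(
    truth: RecombinationTruth, n_mutations: int, rng: np.random.Generator
) -> RecombinationTruth:
    """Plant point substitutions in the V region upstream of the CDR3.

    Mutations never fall in N inserts or the junction (so mutation counting
    that excludes N diversity recovers the count exactly), and substitutions
    that would create an in-frame stop codon are resampled, preserving
    productivity.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    eligible = truth.cys_pos  # positions [0, cys_pos)
    if n_mutations > eligible:
        raise ValueError(f"n_mutations={n_mutations} exceeds {eligible} eligible positions")
    seq = list(truth.transcript)
    positions = rng.choice(eligible, size=n_mutations, replace=False)
    shm: list[tuple[int, str, str]] = []
    for pos in sorted(int(p) for p in positions):
        ref = seq[pos]
        codon_start = pos - pos % 3
        alts = [b for b in "ACGT" if b != ref]
        order = rng.permutation(len(alts))
        placed = False
        for oi in order:
            alt = alts[oi]
            codon = "".join(seq[codon_start : codon_start + 3])
            new_codon = codon[: pos - codon_start] + alt + codon[pos - codon_start + 1 :]
            if new_codon not in STOP_CODONS:
                seq[pos] = alt
                shm.append((pos, ref, alt))
                placed = True
                break
        if not placed:  # every substitution makes a stop; cannot happen for ACGT codons
            raise SimulationError(f"no stop-free substitution at position {pos}")
    transcript = "".join(seq)
    return RecombinationTruth(
        chain=truth.chain, v_id=truth.v_id, d_id=truth.d_id, j_id=truth.j_id,
        c_id=truth.c_id, v_trim=truth.v_trim, j_trim=truth.j_trim,
        d_trim5=truth.d_trim5, d_trim3=truth.d_trim3,
        n1_insert=truth.n1_insert, n2_insert=truth.n2_insert,
        transcript=transcript,
        cdr3_nt=transcript[truth.cys_pos : truth.j_anchor_pos + 3],
        shm_positions=truth.shm_positions + shm,
        v_end=truth.v_end, j_start=truth.j_start, j_end=truth.j_end,
        cys_pos=truth.cys_pos, j_anchor_pos=truth.j_anchor_pos,
    )


# ---------------------------------------------------------------------------
# Background transcriptome and cells

@dataclass
class BackgroundGene:
    gene_id: str
    sequence: str
    abundance: float


@dataclass
class BackgroundTranscriptome:
    genes: list[BackgroundGene]

    @classmethod
    def generate(
        cls,
        rng: np.random.Generator,
        n_genes: int = 200,
        length_range: tuple[int, int] = (500, 3000),
        lognormal_sigma: float = 1.0,
    ) -> "BackgroundTranscriptome":
        genes = []
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_genes)
        abund = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_genes)
        for i in range(n_genes):
            genes.append(BackgroundGene(
                gene_id=f"BG{i + 1:04d}",
                sequence=random_dna(rng, int(lengths[i])),
                abundance=float(abund[i]),
            ))
        return cls(genes)

    def probabilities(self) -> np.ndarray:
        w = np.array([g.abundance for g in self.genes])
        return w / w.sum()


@dataclass
class SimulatedCell:
    cell_id: str
    cell_type: str  # plasmablast | b_cell
    heavy: RecombinationTruth
    light: RecombinationTruth
    ig_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.ig_fraction < 1:
            raise SimulationError(f"ig_fraction {self.ig_fraction} outside (0, 1)")


@dataclass
class ReadConfig:
    layout: str = "SE"  # SE | PE
    read_length: int = 151
    total_reads: int = 100_000
    error_rate: float = 0.001
    fragment_length: int = 350
    fragment_sd: int = 25
    base_quality: int = 30

    def __post_init__(self) -> None:
        if self.layout not in ("SE", "PE"):
            raise SimulationError(f"layout must be SE or PE, got {self.layout!r}")
        if self.read_length not in (50, 75, 101, 151):
            raise SimulationError(f"read_length must be one of 50/75/101/151")
        if not 0 <= self.error_rate <= 0.05:
            raise SimulationError("error rate must be in [0, 0.05]")
        if self.total_reads < 1000:
            raise SimulationError("total_reads must be >= 1000")


def _draw_ig_fraction(cell_type: str, rng: np.random.Generator) -> float:
    if cell_type == "plasmablast":
        lo, hi = PLASMABLAST_IG_FRACTION
        return float(rng.uniform(lo, hi))
    if cell_type == "b_cell":
        lo, hi = BCELL_IG_FRACTION
        return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    raise SimulationError(f"unknown cell type {cell_type!r}")


def simulate_cell(
    db: GermlineDatabase,
    cell_id: str,
    rng: np.random.Generator,
    cell_type: str = "plasmablast",
    shm_mean_heavy: float = SHM_MEAN_HEAVY,
    shm_mean_light: float = SHM_MEAN_LIGHT,
    base_heavy: RecombinationTruth | None = None,
    base_light: RecombinationTruth | None = None,
) -> SimulatedCell:
    """One cell: a heavy and a light productive rearrangement plus SHM.

    ``base_heavy``/``base_light`` let a caller share the pre-SHM
    rearrangement across cells (clonal families); SHM is always drawn
    independently.
    """
    heavy = base_heavy or simulate_recombination(db, "IGH", rng)
    if base_light is None:
        light_chain = "IGK" if rng.random() < 0.5 else "IGL"
        light = simulate_recombination(db, light_chain, rng)
    else:
        light = base_light
    heavy = apply_shm(heavy, int(rng.poisson(shm_mean_heavy)), rng)
    light = apply_shm(light, int(rng.poisson(shm_mean_light)), rng)
    return SimulatedCell(
        cell_id=cell_id, cell_type=cell_type, heavy=heavy, light=light,
        ig_fraction=_draw_ig_fraction(cell_type, rng),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _sample_reads_from(
    transcript: str, n: int, config: ReadConfig, rng: np.random.Generator
) -> list[tuple[str, str | None]]:
    """(mate1, mate2) windows; antisense fragments are reverse-complemented."""
    L = config.read_length
    if len(transcript) < L:
        raise SimulationError(
            f"read_length {L} exceeds transcript length {len(transcript)}"
        )
    out = []
    for _ in range(n):
        if config.layout == "SE":
            start = int(rng.integers(0, len(transcript) - L + 1))
            frag = transcript[start : start + L]
            if rng.random() < 0.5:
                out.append((frag, None))
            else:
                out.append((revcomp(frag), None))
        else:
            flen = int(round(rng.normal(config.fragment_length, config.fragment_sd)))
            flen = max(L, min(flen, len(transcript)))
            start = int(rng.integers(0, len(transcript) - flen + 1))
            frag = transcript[start : start + flen]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            out.append((frag[:L], revcomp(frag[-L:])))
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for pos in positions:
        alts = [b for b in "ACGT" if b != s[pos]]
        s[pos] = alts[int(rng.integers(0, 3))]
    return "".join(s)


def simulate_cell_reads(
    cell: SimulatedCell,
    background: BackgroundTranscriptome,
    config: ReadConfig,
    rng: np.random.Generator | None = None,
    heavy_light_ratio: float = HEAVY_LIGHT_RATIO,
) -> ReadSet:
    """Draw the cell's read set with truth origin labels.

    Ig reads number round(ig_fraction * total), split heavy:light as
    1:heavy_light_ratio; the rest come from the background transcriptome
    with abundance-weighted gene choice.
    """
    rng = rng if rng is not None else np.random.default_rng(cell.seed)
    n_ig = round(cell.ig_fraction * config.total_reads)
    n_heavy = round(n_ig / (1.0 + heavy_light_ratio))
    n_light = n_ig - n_heavy
    n_bg = config.total_reads - n_ig

    qual = chr(config.base_quality + 33) * config.read_length
    reads: list[Read] = []

    def _emit(pairs, origin):
        for m1, m2 in pairs:
            i = len(reads)
            reads.append(Read(
                read_id=f"{cell.cell_id}_r{i:07d}",
                seq1=_apply_errors(m1, config.error_rate, rng),
                seq2=_apply_errors(m2, config.error_rate, rng) if m2 is not None else None,
                qual1=qual, qual2=qual if m2 is not None else None,
                origin=origin,
            ))

    _emit(_sample_reads_from(cell.heavy.transcript, n_heavy, config, rng), "ig_heavy")
    _emit(_sample_reads_from(cell.light.transcript, n_light, config, rng), "ig_light")
    if n_bg:
        probs = background.probabilities()
        gene_idx = rng.choice(len(background.genes), size=n_bg, p=probs)
        counts = np.bincount(gene_idx, minlength=len(background.genes))
        for gi, cnt in enumerate(counts):
            if cnt:
                _emit(
                    _sample_reads_from(background.genes[gi].sequence, int(cnt), config, rng),
                    "background",
                )
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return ReadSet(reads=reads, layout=config.layout, read_length=config.read_length)


def simulate_cohort(
    db: GermlineDatabase,
    n_cells: int,
    seed: int,
    cell_type: str = "plasmablast",
    family_sizes: Sequence[int] | None = None,
    shm_mean_heavy: float = SHM_MEAN_HEAVY,
    shm_mean_light: float = SHM_MEAN_LIGHT,
) -> list[SimulatedCell]:
    """A cohort of cells, optionally with planted clonal-family structure.

    ``family_sizes`` plants families sharing the pre-SHM heavy and light
    rearrangements; remaining cells are singletons.  Distinct families are
    redrawn until their (V gene, J gene, CDR3 length) x2 keys differ.
    """
    rng = np.random.default_rng(seed)
    family_sizes = list(family_sizes or [])
    if sum(family_sizes) > n_cells:
        raise SimulationError("family sizes exceed cohort size")
    sizes = family_sizes + [1] * (n_cells - sum(family_sizes))
    cells = []
    used_keys: set[tuple] = set()
    idx = 1
    for fam_size in sizes:
        for _attempt in range(100):
            heavy = simulate_recombination(db, "IGH", rng)
            light_chain = "IGK" if rng.random() < 0.5 else "IGL"
            light = simulate_recombination(db, light_chain, rng)
            key = (
                heavy.v_gene, heavy.j_gene, len(heavy.cdr3_nt),
                light.v_gene, light.j_gene, len(light.cdr3_nt),
            )
            if key not in used_keys:
                used_keys.add(key)
                break
        else:
            raise SimulationError("could not draw a distinct clonal-family key")
        for _member in range(fam_size):
            cells.append(simulate_cell(
                db, f"cell{idx:03d}", rng, cell_type=cell_type,
                shm_mean_heavy=shm_mean_heavy, shm_mean_light=shm_mean_light,
                base_heavy=heavy, base_light=light,
            ))
            idx += 1
    return cells


# ---------------------------------------------------------------------------
# Synthetic genome bundle for the locus / annotation based filters

def build_reference_bundle(
    db: GermlineDatabase,
    background: BackgroundTranscriptome,
    rng: np.random.Generator,
    spacer: int = 200,
) -> tuple[dict[str, str], LocusTable, list[GeneFeature]]:
    """Synthetic genome + Ig locus table + non-Ig gene annotation.

    Each Ig chain's germline segments are laid out on its own chromosome
    (chr14/chr2/chr22 for IGH/IGK/IGL) separated by random spacers, with one
    locus interval spanning all of them (1-based, closed).  Background genes
    sit on chr1 and are annotated as (non-Ig) gene features.
    """
    genome: dict[str, str] = {}
    locus_rows: list[LocusRow] = []
    chrom_of = {"IGH": "chr14", "IGK": "chr2", "IGL": "chr22"}
    for chain, chrom in chrom_of.items():
        segs = sorted(
            (s for s in db if s.chain == chain),
            key=lambda s: (s.segment_class, s.allele_id),
        )
        if not segs:
            continue
        parts = [random_dna(rng, spacer)]
        locus_start = spacer + 1  # 1-based
        for seg in segs:
            parts.append(seg.sequence)
            parts.append(random_dna(rng, spacer))
        seq = "".join(parts)
        locus_end = len(seq) - spacer
        genome[chrom] = seq
        locus_rows.append(LocusRow(chrom, locus_start, locus_end, chain))
    parts = []
    genes: list[GeneFeature] = []
    pos = 0
    for gene in background.genes:
        parts.append(random_dna(rng, spacer))
        pos += spacer
        start = pos + 1
        parts.append(gene.sequence)
        pos += len(gene.sequence)
        genes.append(GeneFeature("chr1", start, pos, gene.gene_id))
    parts.append(random_dna(rng, spacer))
    genome["chr1"] = "".join(parts)
    return genome, LocusTable(locus_rows), genes


# ---------------------------------------------------------------------------
# Truth serialization

def truth_record(cell: SimulatedCell) -> dict:
    rec = {
        "cell_id": cell.cell_id,
        "cell_type": cell.cell_type,
        "ig_fraction": cell.ig_fraction,
        "seed": cell.seed,
    }
    for name, truth in (("heavy", cell.heavy), ("light", cell.light)):
        rec[name] = asdict(truth)
    return rec


def write_truth_jsonl(cells: Iterable[SimulatedCell], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cell in cells:
            fh.write(json.dumps(truth_record(cell)) + "\n")


def write_origin_tsv(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\torigin\n")
        for read in readset:
            fh.write(f"{read.read_id}\t{read.origin}\n")
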