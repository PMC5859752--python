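# Methods

This note documents the models, algorithms and numerical choices behind
`igrecon`, and what its simulation-based tests do and do not establish.

## Problem setting

A single B cell expresses one productive heavy-chain (IGH) and one
productive light-chain (IGK or IGL) rearrangement. In full-length
single-cell RNA-seq libraries these transcripts are abundant — in
plasmablasts on the order of 5–50% of mRNA, in conventional B cells
0.2–8% — so both chains can be assembled de novo from the cell's reads.
The reconstruction problem is: given one cell's reads and a germline
segment database, return the cell's paired chain sequences with V(D)J/C
gene calls, the CDR3 junction, a productivity verdict, read-support
evidence, and derived quantities (somatic hypermutation load, clonal
family membership).

## Germline model and derived references

A `GermlineSegment` is one V, D, J or C allele. V segments carry the
0-based offset of the conserved second-cysteine codon (`cys104`), J
segments the offset of the conserved TRP/PHE codon (`jtrp`); both are
in-frame with the segment's declared reading frame. Anchors may be read
from `key=value` FASTA headers or a sidecar TSV, because public FASTA
header dialects vary.

Two filter references derive from the database:

* **Recombinome** — all ordered (V, J, C) triples per chain, each entry
  `N*20 + V + N*pad + J + C`. The 20 leading N bases stand in for the
  leader sequence; on the heavy chain `pad = 10` replaces the D segment.
  Light chains default to `pad = 0`: their V–J junctions carry only a few
  nucleotides and the k-mer mapper tolerates small junction gaps. The pad
  is configurable since real junction lengths vary.
* **Pooled V/J/C reference** — raw segment sequences per heavy/light
  group (no D; D segments are too short to capture reads on their own).

Constant regions may be truncated (e.g. first exon only): annotation uses
top-scoring local alignment, never full-length match.

## Internal read mapper

Filtering and quantification need an aligner; `igrecon` ships a small
exact one rather than shelling out to external binaries. References are
indexed by 2-bit-packed k-mers (default k = 21; k-mers containing N never
seed). A read is **mapped** iff it shares at least `min_seed_count`
(default 1) k-mers with some reference and its extension meets the score
threshold. Scoring is +1 match / −1 mismatch / −2 per gap position, with
any position involving N scoring 0, so reads span the recombinome's N
pads freely.

Extension is two-stage. The seed diagonal is scored directly (best
contiguous segment for local mode, full-read sum for end-to-end mode);
this is exact for substitution-only alignments, which dominate short-read
data. When the diagonal misses the threshold, an exact
dynamic-programming alignment (scikit-bio `pair_align`, same scoring) is
run in a window around the diagonal to rescue gapped placements.
Default thresholds: local score ≥ 30; end-to-end score ≥ 0.9 × read
length. Membership tests probe the first/middle/last k-mer first and fall
back to a full k-mer scan only for reads those probes miss, which keeps
per-cell mapping in seconds without changing the mapped/unmapped
partition. For report-all quantification, matched k-mer columns are
sampled at a stride; since one k-mer's posting list names every reference
containing it, every supported reference is still reached.

The genome prefilter runs without the DP fallback: a junction or
heavily mutated read that fails diagonal placement is exactly the read
the `+Unmapped` strategies are designed to retain. Spliced alignment is
not implemented; for real genomes, externally produced SAM can drive the
same filters through `read_sam_hits`.

## Filtering strategies

* `unfiltered` — identity.
* `ig_mapped` — keep fragments whose best genome hit overlaps an Ig locus
  interval by ≥ 1 nt. Locus tables are 1-based fully-closed, as printed
  in genome-database locus listings (unlike BED).
* `ig_mapped_plus_unmapped` — the above plus fragments with no genome hit
  on any mate.
* `recombinome_mapped`, `imgt_mapped` — keep fragments with a local hit
  to the respective reference set, heavy and light groups handled
  independently.
* `filter_non_ig` — drop fragments whose every mate's best hit lies
  wholly within an annotated non-Ig gene (the rhesus-style negative
  filter for genomes with poorly annotated Ig loci).

Mate policy throughout: if either mate qualifies, the whole fragment is
retained — junction evidence is too valuable to discard half a pair.

## Assembly

Per-cell Ig read sets are small and each chain has one dominant isoform,
so a single-k De Bruijn assembler (default k = 25, canonical k-mers,
singleton k-mers dropped) suffices in the role a general transcriptome
assembler plays at scale. Cleanup matters more than size here: at
per-cell coverages of 10²–10³×, sequencing errors recur on multiple reads
and no fixed count cutoff separates them from signal. Cleanup therefore
interleaves three coverage-aware passes until stable:

1. **Relative branch pruning** — at any fork, branches below 0.2× the
   best sibling's mean coverage are removed. Within one cell no true
   alternative haplotype exists inside a connected component, so the
   threshold can be generous.
2. **Tip clipping** — dead-end unitigs shorter than 2k are removed only
   when a sibling with ≥ 2× their coverage leaves the same junction. The
   sibling condition is essential: a transcript's true terminus is also a
   dead end, and an unconditional clip erodes real sequence whenever
   errors fragment the path near an end.
3. **Bubble popping** — of two unitigs sharing both endpoints, the
   lower-coverage one is removed (ties: keep the lexicographically
   smaller sequence).

Contigs are maximal unambiguous paths extended through remaining branch
points by a greedy max-coverage walk, each k-mer consumed at most once
per contig. A walk that re-treads more than half its k-mers from an
earlier (higher-coverage) contig is a duplicate through a residual error
branch and is suppressed. Output is deterministic: contigs are
strand-normalized (lexicographic minimum of the two orientations) and
sorted by coverage, then length, then sequence. Default minimum contig
length is 300 nt — this package's choice, below full-length Ig
transcripts (~0.6–1 kb in the simulator) but above junk fragments.

In-silico read normalization is deliberately absent. An adapter accepts
externally assembled contig FASTA so any other assembler can feed the
downstream stages.

## Annotation, CDR3 and productivity

The best local V alignment across chains and strands (match +1, mismatch
−1, gap −5) fixes chain and orientation; J is searched downstream of V, D
(heavy only) inside the V–J window with a reduced threshold, C downstream
of J. Class minimum scores V 50 / J 18 / D 10 / C 30 play the role of a
database-search significance threshold: germline-length matches pass, and
the chance of a random ~1 kb contig reaching them is negligible (a score
of 50 requires a ≥ 50-nt net-matching local segment against a 300-nt
segment set). The steeper gap penalty (−5 here vs −2 in the mapper) is
deliberate: somatic hypermutation is substitution-dominated, and a cheap
gap lets an optimal aligner reinterpret runs of adjacent substitutions as
balanced indels, which corrupts anchor projection and mutation counts.

The CDR3 runs from the V 2nd-CYS codon through the J-TRP/PHE codon
inclusive, projected onto the contig through the alignments. A model is
productive iff both anchors project, they are in frame, no stop codon
lies between the V alignment start and the J end in the CDR3 frame, and
the CDR3 length is a multiple of 3. Missing anchors on a winning allele
raise an error naming the allele — distinct from a no-call, which means
no V or J hit met its threshold.

V alignments are extended ungapped to the sequence ends ("flank
extension"): a purely local alignment trims a substitution sitting at the
first or last aligned position, which would silently drop edge mutations
from SHM counts. On this package's data nothing but V context flanks the
V alignment, so the extension is safe; on real data with chimeric contigs
it could add spurious flank mismatches (a known limitation).

**SHM counting**: substitutions within the V alignment at germline
offsets before the 2nd-CYS codon. Junctional/N-region differences are
structurally excluded; alignment gaps are not counted.

## Model selection

Reads used for assembly are mapped end-to-end against every model with
report-all semantics, so a read supports every model it fits — the
quantification mirror of reporting all alignments. Models are ranked by
read count (ties: longer contig, then contig id), unproductive and
redundant models — same (V, D, J, CDR3 nt) as a surviving higher-ranked
model — are dropped, and the top survivor is the call. The ambiguity flag
marks calls whose support is under 2× the surviving runner-up's; the
runner-up is taken after filtering, since ratios are only meaningful
between genuinely distinct surviving models. The light-chain call is the
better of the IGK and IGL survivors by read count.

## Validation and clonality

Reference (e.g. RT-PCR/Sanger) sequences are annotated with the same
machinery; non-annotatable or unproductive references yield non-evaluable
records rather than errors. A chain is *accurate* when V and J gene calls
(allele designation stripped, since amplicons rarely resolve alleles;
allele-exact mode available) and the exact CDR3 nucleotide sequence
agree; the D call participates only when both sides call one confidently.
Nucleotide identity is percent matches over alignment columns and
coverage is percent of the reference length aligned, both from a
best-strand local alignment. Paired accuracy requires both chains of a
cell; the clonotype-collapsed variant gives each clonal family one vote
(accurate iff all its evaluable members are), so large accurate clones
cannot mask errors elsewhere.

Clonal families partition cells by (heavy V gene, heavy J gene, heavy
CDR3 length, light V gene, light J gene, light CDR3 length).

## Simulator

The simulator is the package's study-conditions generator, not a fixture:

* **Repertoire**: a random germline database (8/6/4/3 IGH V/D/J/C, 6/3/1
  IGK, 5/3/2 IGL by default) with 300-nt V segments (stop-free in frame,
  TGT anchor at offset 288), 15-nt D, 48- or 39-nt J with TGG/TTT
  anchors, 300-nt C.
* **Recombination**: segments uniform; exonuclease trims uniform on
  [0, 5] nt per junction side; N-insert lengths uniform on [0, 10] with
  uniform bases. Junctions are redrawn (≤ 100 tries) until the anchors
  are in frame and the V-through-J span is stop-free, because validation
  data consists of productive chains. No published trim/insert length
  distributions back these uniform defaults; they are documented config,
  not claims of realism.
* **SHM**: Poisson loads around the observed medians (23 heavy, 16
  light), planted as substitutions at distinct positions uniformly in the
  V region upstream of the CDR3 start, resampled if they would create an
  in-frame stop. Restricting to upstream-of-CDR3 keeps "mutation count
  excluding N diversity" exactly recoverable; mutations inside the
  junction would be indistinguishable from N diversity by construction.
* **Cell**: one heavy + one light truth; Ig mRNA fraction uniform on
  [0.05, 0.50] for plasmablasts and log-uniform on [0.002, 0.079] for B
  cells; heavy:light expression 1:1.2 (unreported in the literature this
  emulates; exposed in config).
* **Background**: 200 random "genes" of 500–3000 nt with log-normal
  abundance — only their non-Ig-ness matters to the filters.
* **Reads**: SE/PE at 50/75/101/151 nt, uniform start positions, both
  strands, uniform substitution errors (default 0.1%), constant Q30
  qualities (carried, never used). PE fragments are Normal(350, 25)
  clamped to the transcript.
* **Genome bundle**: per-chain chromosomes carrying the germline segments
  with random spacers plus one locus interval each; background genes on a
  separate chromosome with GFF3 gene annotation. Clonal families are
  planted by sharing the pre-SHM rearrangement across members.

What passing simulations do **not** show about real data: no indel
sequencing errors, no empirical quality models, no splicing (real
genome mapping should come through SAM interop), no allelic diversity
within genes, no class-switch structure beyond C-allele choice, random
rather than homologous germline families (real V genes share ~80%
identity, making gene-call confusion harder than simulated), and no
library-preparation coverage bias.

## Evaluation protocols and problem sizes

`igrecon.evaluation` fixes the self-check protocols, all seeded:

* Round-trip: 20 simulated plasmablasts, SE 151, 100,000 reads/cell,
  0.1% error, default SHM; full pipeline with
  `ig_mapped_plus_unmapped`; measures the fraction of cells with both
  chains' (V gene, J gene, CDR3 nt) equal to truth and the fraction of
  calls whose support is ≥ 2× the surviving runner-up.
* SHM exactness: 8 error-free cells at 30,000 reads; every recovered
  chain's `count_shm` must equal the planted count.
* Containment: per read set, `ig_mapped` ⊆ `ig_mapped_plus_unmapped` and
  `unfiltered` is the identity.
* Assembler oracles: error-free tiling reads of a known 1.4 kb transcript
  reassemble it exactly; two k-mer-disjoint transcripts stay separate.
* Clonal partition: a planted 17/9/5 family structure over 31 cells is
  recovered exactly from annotated true transcripts.

These sizes are the package's documented defaults; `scripts/acceptance.py`
runs exactly these protocols from a single seed.

## Known limitations

* One productive rearrangement per chain is assumed; double-light-chain
  cells and secondary chains are out of scope.
* The internal genome mapper is contiguous-only; use SAM interop for
  spliced real-genome alignments.
* Allele-level calls are only as good as the database; with truncated C
  references, isotype subclass resolution is approximate.
* `quantify_models` defaults to substitution-only end-to-end extension;
  enable its DP fallback for data with indels.
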