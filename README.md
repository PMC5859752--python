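# igrecon

Reconstruction of paired immunoglobulin heavy- and light-chain transcripts
from per-cell RNA-seq reads.

Antibody-secreting B cells (plasmablasts) devote a large share of their
transcriptome — roughly 5–50% of mRNA — to their rearranged immunoglobulin
genes, and conventional B cells a smaller share (≈0.2–8%). Full-length
single-cell RNA-seq libraries therefore contain enough reads to assemble
each cell's heavy (IGH) and light (IGK/IGL) chain de novo, recovering the
V(D)J gene usage, the CDR3 junction, and the somatic hypermutation load
without targeted amplification. `igrecon` implements that reconstruction
pipeline end to end for people who work with plate-based (SMART-Seq-style)
single B cell data: immunologists pairing antibody sequences with
transcriptional state, and tool builders who need a fully testable,
self-contained reference pipeline.

## The pipeline

For each cell, reads go through six stages:

1. **Adapter trimming** (literal prefix/suffix clipping).
2. **Ig-read filtering** — one of five enrichment strategies:
   `unfiltered`, `ig_mapped` (reads whose best genome hit overlaps an Ig
   locus interval), `ig_mapped_plus_unmapped` (adds all genome-unmapped
   reads, catching highly mutated and junction-spanning reads),
   `recombinome_mapped` (reads mapping to an in-silico database of every
   V–J–C combination, with 20 N bases standing in for the leader and 10 N
   bases for the heavy-chain D segment), `imgt_mapped` (reads mapping to
   the pooled germline V/J/C sequences), and the rhesus-style
   `filter_non_ig` (discard reads wholly inside annotated non-Ig genes).
3. **De novo assembly** of the retained reads (single-k De Bruijn graph
   with coverage-aware cleanup).
4. **Annotation** of each contig: best local alignments of germline V,
   (D,) J and C alleles fix the chain and strand; the CDR3 spans the
   conserved V 2nd-CYS codon through the J-TRP/PHE codon; a model is
   *productive* iff the anchors are in frame, no stop codon intervenes,
   and the CDR3 length is a multiple of 3.
5. **Quantification** — every read used for assembly is mapped end-to-end
   against every model (report-all), and models are ranked by read count.
6. **Selection** — unproductive models and models repeating the
   (V, D, J, CDR3) of a higher-ranked survivor are dropped; the top
   survivor is the chain call, flagged *ambiguous* when its read support
   is under twice the runner-up's.

Somatic hypermutation is counted as substitutions in the V region upstream
of the CDR3, so junctional N-diversity never inflates the count. Cells are
grouped into clonal families by shared V gene, J gene and CDR3 length on
both chains.

A truth-labeled simulator (`igrecon.simulate`) generates the whole study
in miniature — V(D)J recombination with exonuclease trimming and N
insertions, SHM, realistic Ig mRNA fractions, background transcripts, a
synthetic genome with locus table and gene annotation — so every stage is
testable without external data.

## Worked example

```python
import numpy as np
from igrecon.simulate import (synthetic_germline_db, BackgroundTranscriptome,
                              build_reference_bundle, simulate_cell,
                              simulate_cell_reads, ReadConfig)
from igrecon.filterreads import FilterResources
from igrecon.pipeline import PipelineConfig, run_cell
from igrecon.annotate import count_shm

rng = np.random.default_rng(7)
db = synthetic_germline_db(42)
bg = BackgroundTranscriptome.generate(rng)
genome, loci, genes = build_reference_bundle(db, bg, rng)
res = FilterResources.from_germline(db, genome=genome, locus_table=loci,
                                    gene_annotation=genes)

cell = simulate_cell(db, "cellA", rng)                      # one plasmablast
reads = simulate_cell_reads(cell, bg, ReadConfig(total_reads=20_000),
                            np.random.default_rng(cell.seed))
out = run_cell("cellA", reads, PipelineConfig(strategy="ig_mapped_plus_unmapped"), res)

for name, call, truth in [("heavy", out.heavy, cell.heavy),
                          ("light", out.light, cell.light)]:
    ann = call.selected.annotation
    print(name, call.chain, ann.v_call, ann.j_call,
          "cdr3==truth:", ann.cdr3_nt == truth.cdr3_nt,
          "reads:", call.selected.read_count,
          "shm:", count_shm(ann, db))
```

prints

```
heavy IGH IGHV1-3*01 IGHJ1*01 cdr3==truth: True reads: 4150 shm: 25
light IGK IGKV1-3*01 IGKJ1*01 cdr3==truth: True reads: 4979 shm: 13
```

i.e. both chains were reconstructed with the correct germline gene calls
and CDR3 nucleotide sequence, supported by thousands of reads each, and
the somatic hypermutation count equals the number of mutations the
simulator planted.

The same pipeline is available from the shell:

```bash
igrecon simulate cells --n-cells 3 --total-reads 20000 --seed 5 --out sim/
igrecon reconstruct batch sim/manifest.tsv --germline-dir sim/ \
    --strategy recombinome_mapped --out recon/
igrecon germline build-recombinome --germline-dir sim/ --chain IGH --out igh.fasta
```

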