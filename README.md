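# lncprobe

**Discovery and regulation analysis of long non-coding RNAs from repurposed
expression-microarray probes.**

Most expression microarrays were designed for protein-coding genes, yet a
substantial fraction of their probes align inside long non-coding RNA
(lncRNA) loci. `lncprobe` turns this into a discovery pipeline for systems
like LPS-stimulated mouse bone marrow-derived macrophages (TLR4 signaling),
where abundant public array data exist but lncRNAs were never annotated on
the platforms. It is a Python library for computational biologists: the
importable API is the interface, `examples/` holds one narrative script per
capability, and a synthetic-data generator with planted truth makes every
stage testable without downloads.

## What the pipeline computes

1. **Probe reannotation** — probe alignments (BED6) are intersected,
   strand-aware, with the exons of noncoding transcripts (spliced length
   ≥ 200 nt) and coding genes; probes hitting more than one gene of the same
   kind are removed to avoid cross-hybridization ambiguity.
2. **TSS inference** — the 5′ end of each TSS-seq read is a tag; same-strand
   tags within 20 bp chain into clusters, clusters within 400 bp into TSS
   regions, and regions with fewer than 20 supporting tags are discarded.
3. **Catalog validation** — a lncRNA enters the catalog only if a same-strand
   TSS region lies within ±30 kb of its span, that region carries a peak of
   H3K4me3, H3K4me1 or PolII, and it does not overlap a coding-gene TSS
   region (ambiguity filter). Survivors are classified as exonic sense /
   intronic sense / antisense / bidirectional / intergenic relative to the
   neighboring coding gene, and renamed `lncRNA-<neighbor>`.
4. **Chromatin signatures** — mean normalized read density over
   TSS ± 2 kb; the H3K4me1:H3K4me3 ratio separates enhancer-like (elncRNA)
   from promoter-associated (plncRNA) loci.
5. **Expression integration** — per-dataset probe matrices are KNN-imputed,
   collapsed to transcripts (mean over probes), reduced to
   log2FC = mean(LPS) − mean(unstim), and integrated across datasets by
   **robust rank aggregation**: with sorted normalized ranks
   r(1) ≤ … ≤ r(n) over the n datasets where a transcript is measured,

   ρ = min₍k₎ P( Binomial(n, r(k)) ≥ k ),  p = min(1, ρ·n),

   Bonferroni-adjusted over the transcripts tested per direction; calls use
   adjusted p < 0.05.
6. **Neighbors and TF binding** — nearest/longest-overlap coding neighbors,
   co-expression shift tests (one-sided KS), and TF peak association within
   TSS ± 10 kb (p65, IRF3, JunB, cJun, Bcl6) with co-binding summaries.

## Worked example

`examples/03_rank_aggregation.py` plants one up- and one down-regulated
transcript among 40 across 8 simulated datasets and integrates them:

```
top of the upregulated ranking (rho, p, p_adj):
  t00  rho=1.53e-13  p=1.22e-12  p_adj=4.88e-11
  t02  rho=0.00709  p=0.0567  p_adj=1
  t11  rho=0.0113  p=0.0903  p_adj=1

called up:   ['t00']
called down: ['t01']
```

`t00` sits at the top of every dataset's ranking, so the probability of its
rank vector under the uniform null (ρ) is astronomically small and it alone
clears the Bonferroni cutoff; the best null transcript (`t02`) does not.
`examples/01_simulate_and_run.py` runs the full funnel — probes → candidates
→ TSS-validated catalog → classes → regulated calls — and prints the stage
counts next to the planted truth.

## Layout

```
src/lncprobe/
  annotations.py   transcript ingestion (BED12/GTF), merging, interval index
  probes.py        probe-to-transcript assignment and ambiguity removal
  tss.py           tag extraction and two-level TSS clustering
  catalog.py       TSS/chromatin/ambiguity filters, positional classes, naming
  expression.py    imputation, collapsing, fold changes, robust rank aggregation
  chromatin.py     TSS-window densities, elncRNA/plncRNA, mark-change KS tests
  neighbors.py     neighbor genes, co-expression, TF peak association
  simulate.py      synthetic universe with planted truth; worked toy
  pipeline.py      manifest-driven orchestration and funnel report
```
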