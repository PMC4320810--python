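# Methods

This note records the models, parameter choices and numerical conventions
behind `lncprobe`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Probe reannotation

Probes arrive as one best genomic alignment per platform (BED6). Assignment
intersects the probe interval with *exonic* intervals of lncRNA candidates
and coding transcripts — a probe lying only in a coding intron is
unassigned, since it may interrogate an intronic lncRNA rather than the
mRNA. Matching is strand-aware by default (`require_same_strand=True`)
because expression arrays carry strand information; the flag exists because
strandedness conventions differ across manufacturers. The minimum overlap is
1 bp (`min_overlap_bp`), i.e. any exonic overlap counts; no overlap
threshold is asserted beyond that. Ambiguity is judged at **gene** level: a
probe covering two isoforms of one gene is kept (and attributed to the
longest-overlap isoform), while a probe covering two distinct genes of the
same kind (two lncRNA genes, or two coding genes) is removed for that kind.
A probe may legitimately carry one lncRNA and one coding assignment — e.g.
over an exonic-sense lncRNA that shares sequence with a coding exon — and
then contributes to both targets' expression.

## TSS regions

The 5′ end of each aligned TSS-seq read is a tag (start for `+` reads,
end − 1 for `-` reads; coordinates 0-based half-open throughout). Two-level
single-linkage chaining builds regions:

* tags: same strand, adjacent gap ≤ `cluster_gap` (default 20 bp);
* clusters: same strand, nearest-edge gap ≤ `group_gap` (default 400 bp);
* regions with fewer than `min_tags` (default 20) supporting tags are
  discarded.

"Closer than 20 bp" is implemented **inclusively** (gap ≤ 20 joins); the
boundary convention is configurable since the original clustering script is
not available to consult. Inter-cluster distance is measured between nearest
cluster edges — the conventional BED merge semantics — not centers.
Duplicate tags at one position all count; no deduplication is applied.
Region coordinates are min/max member tag positions exported half-open as
`[start, end + 1)`.

## Catalog filters

A candidate lncRNA (noncoding, spliced length ≥ 200 nt — the mature
transcript length, not the genomic span; exactly 200 is included) is
validated in three steps:

1. **Association**: same-strand TSS regions intersecting the span extended
   by `flank` = 30 kb on both sides. Association is same-strand only: the
   TSS of an antisense transcript must not validate the sense lncRNA. A
   strand-agnostic flag is provided since the original pipeline's behaviour
   is not documented.
2. **Chromatin**: at least one peak of H3K4me3, H3K4me1 or PolII (either
   condition) overlapping the region. H3K27Ac is deliberately excluded from
   the filter set (it marks activity, not TSS identity).
3. **Ambiguity**: regions intersecting a coding-gene TSS interval are
   removed; those intervals are coding 5′ ends ± `ambiguity_window` (default
   500 bp per side — no value is prescribed by the source procedure, so a
   half-kilobase promoter-scale window is used and exposed as a parameter).

A lncRNA survives if any region survives; `primary_tss` is the midpoint of
the surviving region with the highest tag count (ties broken toward the
leftmost region). Keeping a single anchor per lncRNA is a deliberate
simplification: windowed chromatin and TF analyses need one position, while
the catalog still stores every validated region.

## Positional classes

The neighbor coding gene is the longest-overlap gene when any gene overlaps,
else the nearest-gap gene (ties: smaller start). The class rule table,
applied to that neighbor: overlapping + same strand → `exonic_sense` if any
exon base overlaps else `intronic_sense`; overlapping + opposite strand →
`antisense`; non-overlapping + opposite strand + distance < 1 kb →
`bidirectional`; otherwise `intergenic`. Distance is the gap between nearest
feature ends; a `bidirectional_metric="tss"` variant measures TSS-to-TSS
instead, since the two phrasings of the 1 kb rule differ in the source
material — the gene-distance reading is the default. Exonic-sense lncRNAs
are flagged and excluded from expression analyses by default (they largely
represent UTR fragments or NMD isoforms of the host mRNA). Display names are
`lncRNA-<neighbor symbol>`, with `-2`, `-3`… suffixes on collisions in
genomic order.

## Expression integration

KNN imputation (k = 10, uniform weights, nan-Euclidean distances over shared
observed columns — delegated to scikit-learn's `KNNImputer`) fills missing
probe-level cells; a fully missing column is an error and oversized k is
truncated with a warning. Probes collapse to transcripts by arithmetic mean
per sample; fold change is mean(LPS) − mean(unstim) on log2 intensities.

Robust rank aggregation ranks transcripts per dataset (descending fold
change for the up direction, ascending for down; ties by average rank —
unbiased under the uniform null), normalizes by that dataset's list length,
and scores the sorted rank vector r(1) ≤ … ≤ r(n) with
βₖ = P(Binomial(n, r(k)) ≥ k), ρ = minₖ βₖ, p = min(1, ρ·n). Transcripts
absent from a dataset simply contribute no rank (n is per-transcript), which
matches the cross-platform overlap structure of array compendia. The
binomial tail uses `scipy.stats.binom.sf`; tests verify agreement with exact
summation to 1e−12 for n ≤ 12. Bonferroni multiplies by the number of
transcripts tested **per direction** (not ×2); a flag doubles m for the
stricter reading. Calls use adjusted p strictly below α = 0.05; a transcript
significant in both directions is assigned to the smaller-p direction with a
warning. ρ is the "aggregation rank score" and is reported as ±log10 for
plotting conventions.

## Chromatin signatures

Density = (window signal sum) × (10⁷ / library size) / window width, over
TSS ± 2 kb (truncated widths at chromosome starts). Classification:
elncRNA iff (me1 + ε)/(me3 + ε) > 1, computed on **unstimulated** densities
(stimulation barely moves the ratio; a pooled-condition flag exists). The
threshold 1.0 and ε = 0.1 × median nonzero cohort density are declared
defaults, not inferred values — the upstream literature states only
"high"/"low" — and both are configurable and echoed in output metadata.
Ties at the threshold go to plncRNA; both densities zero → `unclassified`.
With ε proportional to cohort density the label is invariant to common
rescaling, which the tests check directly.

Mark-change analysis splits lncRNAs by log2(density_LPS/density_unstim)
beyond ±log2(1.5) (default; unprescribed upstream) into increased/decreased
groups per mark and chromatin class, and compares each group's expression
fold-change ECDF against all lncRNAs of that class with a **one-sided**
two-sample KS test (increased → right shift, decreased → left shift; all
four marks are activity marks). Groups under 5 members are reported with a
low-n flag. The up/down × elnc/plnc contingency table is tested by
chi-square without continuity correction (Yates flag available).

## Neighbors and TF binding

Gene-level fold change is the mean over a gene's transcripts' integrated
fold changes. Co-expression compares neighbor-gene fold changes of
LPS-changed lncRNAs (per class and direction) against all coding genes by
one-sided KS; elncRNA vs plncRNA neighbor distances are compared by Welch's
t-test restricted to intergenic + bidirectional lncRNAs (elsewhere distance
is 0 by construction). Pairwise dataset consistency uses Pearson correlation
on ≥ 10 shared transcripts.

TF association is strand-agnostic (peaks carry no strand): bound iff ≥ 1
peak inside `primary_tss` ± 10 kb. Summaries report Venn cells over
p65/IRF3/JunB/cJun in the LPS condition, the count bound by ≥ 1 and by all
four, the mean pairwise distance between different TFs' nearest peak
**summits** on co-bound lncRNAs (summit-to-summit mean; the summary statistic
is not precisely defined upstream, so the most common convention is used),
and the fraction of Bcl6-bound lncRNAs colocalizing with ≥ 1 core factor
after stimulation.

## Synthetic universe

The generator's defaults are the study conditions: 560 lncRNAs (30 exonic
sense, 30 intronic sense, 160 antisense, 160 bidirectional, 180 intergenic),
12 datasets on 3 pseudo-platforms, 3 samples per condition, planted effects
+2/−2 log2 units on 15 up / 12 down loci, noise σ = 0.5, TSS tag bundles
Poisson(80) within ±10 bp of each true TSS over a 10⁻⁶/bp background,
enhancer loci at 4:1 and promoter loci at 1:4 me1:me3 density, and 5
regulated lncRNAs bound by all four core TFs with summits staggered within
2 kb. Each 60 kb genome block holds one coding gene and one lncRNA placed so
its class is geometrically unambiguous; block spacing guarantees a lncRNA's
±30 kb TSS scan never reaches another block's lncRNA TSS. Decoy blocks with
two overlapping coding genes plant ambiguous probes.

Deliberate generator choices:

* Baselines U(4, 12) per transcript with N(0, 0.3) platform offsets mimic
  the observed cross-platform fold-change consistency without modeling real
  array chemistry.
* Each platform omits a random 20% of lncRNAs, but the omission sets are
  adjusted so every lncRNA survives on ≥ 1 platform: the catalog is the
  union over platforms, and total dropout would make a locus unrecoverable
  by construction rather than by method failure.
* Regulated loci are planted among antisense and intergenic classes.
  Bidirectional TSS regions sit ~800 bp from the coding promoter, where a
  rare background-tag chain can bridge into the coding ambiguity window and
  remove the locus for reasons unrelated to the expression method; exonic
  sense loci are excluded from expression analysis by design.
* Coding promoters contribute H3K4me3/PolII **peaks** (exercising the
  chromatin filter) but no coverage, because their 2 kb coverage windows
  would bleed into bidirectional/intronic lncRNA TSS windows and contaminate
  the planted density ratios.
* Neighbor genes of regulated lncRNAs receive the lncRNA's effect
  + N(0, 0.3), planting the co-expression signal.

What passing tests show — and don't. Recovery of planted regulation,
classes, chromatin labels and TF sets demonstrates that the implementation
executes its stated rules exactly and that the statistics are calibrated
(RRA's null P(p < 0.05) ≈ 0.03 ≤ 0.05; one-sided KS type-I error ≈ 0.05).
The generator does not emulate sequence-driven cross-hybridization, platform
normalization artifacts, overlapping transcription units beyond the planted
geometries, unbalanced replicate designs, or mark colocalization structure;
perfect recovery here therefore bounds implementation error, not real-data
performance, where the upstream filters exist precisely because these
nuisances are common.

## Problem sizes and numerics

The default simulation (560 lncRNAs, ~1,100 coding transcripts, ~90k TSS
tags, ~6,000 probes, 12 matrices) runs the full pipeline in a few seconds;
test-suite Monte-Carlo sizes (10,000 null transcripts for RRA, 2,000 KS
simulations, 200 clustering instances, 1,000 rule-table configurations) were
chosen to give stable empirical rates at interactive runtimes. All
coordinates are 0-based half-open internally; GTF input is converted at the
reader boundary. Degenerate inputs have defined behaviour: empty rank
vectors, all-missing columns and inconsistent configurations raise;
unknown chromosomes in coverage lookups yield density 0 with a warning;
probes on chromosomes absent from the annotation are unassigned, not errors.
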