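# Methods notes

## Coordinate conventions

All intervals are 0-based half-open (BED convention) everywhere inside the
package; peaks, motifs, protospacers and genes share the single
`GenomicInterval` type so no stage re-derives coordinates. 1-based
coordinates appear only in human-readable reports. `N` bases are legal in a
genome, but no motif match, protospacer or PAM may overlap one: guides are
never designed against unknown sequence, and skipped windows are counted in
the log rather than silently dropped.

## Motif scanning

The scanner matches a dyad consensus `ARM1[N]{a,b}ARM2` (IUPAC arms, an
unconstrained spacer of a–b bp). Every (offset, spacer length) combination
is reported; overlapping hits are **not** collapsed, because any collapsing
convention is a lossy choice — a greedy leftmost/shortest-spacer collapse is
available but off by default. Pattern `N` matches A/C/G/T but never a
sequence `N`.

Scanning is single-strand (+). The default p53 dyad CWWG[N]{2,12}CWWG is
its own reverse complement, so a + strand scan is exhaustive for it; for
non-palindromic patterns a both-strands mode scans the reverse complement
and mirrors coordinates, deduplicating identical intervals. Motif ids are
`<peak>.<k>` with k numbering hits 5'→3' within the peak.

## Guide enumeration

"Within 16 bp of the motif" is anchored on the PAM: a candidate is emitted
when its full 3-bp PAM lies inside the motif interval extended by `window`
(16) bp on each side. The alternative anchor (cut site in window) is a
switch (`anchor="cut"`); the PAM reading is the default because the design
criterion is phrased around PAM-containing sites. PAM defaults to NGG
(SpCas9); the blunt cut is placed between protospacer positions 17/18
(3 bp 5' of the PAM), and `cut_pos` records the + strand base immediately
5' of the cut, which is what TSS distances are measured from.

No on-target efficacy score is applied — efficacy models trained on
coding-sequence knockouts do not transfer to regulatory-element targeting —
so every PAM-admissible candidate survives to the off-target filter.
Duplicate spacer sequences at different loci are retained at design time;
a second perfect site is exactly a CFD = 1 off-target and is handled by the
filter, keeping design and filtering concerns separate. Guide ids follow
`<peak>.<motif index>-<running index>` (e.g. `peak_2319.1-1`), using the
5'-most motif when a guide's window spans several.

## Off-target model

The CFD score of a site is the product over spacer positions 1–20 of a
(position, guide-RNA base, site base) mismatch penalty, times a PAM 2-mer
penalty; matches contribute 1.0, so the score is 1 iff every factor is
fully tolerated. Scores live in [0, 1] and can only fall as mismatches are
added (product of factors ≤ 1).

Filtering applies two rules, with "potential off-target" meaning CFD = 1
within 1e-9: (A) any such site overlapping a protein-coding gene **body**
(not exon-resolved — the exclusion criterion is phrased at the gene level)
rejects the guide; (B) more than one such site in noncoding sequence
rejects it. "Unrelated noncoding" is read strictly: a CFD = 1 site inside
another *targeted* peak still counts under rule B by default
(`exempt_targeted_peaks` relaxes this), because a guide that also cuts a
second screened element confounds attribution either way.

The search enumerates NGG and NAG PAMs (NAG discounted by its PAM penalty)
up to `max_mm = 3` mismatches. At table load the positions carrying any
fully tolerated (penalty 1.0) mismatch entry are collected; since a CFD = 1
site can only mismatch at those positions, `max_mm` ≥ that count provably
contains every CFD = 1 site, and `filter_guides` asserts this. The search
itself is a direct vectorized scan: all PAM-adjacent 20-mers of the genome
are packed once into a byte matrix and each guide is compared in one numpy
pass. At the desk scale this package targets (≤ ~1 Mb genomes) this is a
few milliseconds per guide and is tested bit-exact against a
position-by-position oracle; no heuristic aligner is involved.

**The packaged penalty table is synthetic.** The empirically measured CFD
tables are not redistributed here; `data/cfd_weights_synthetic.tsv` has the
same schema (240 mismatch entries + 16 PAM 2-mers) and the same structural
invariants — matches and the GG PAM score 1.0, penalties in [0, 1],
tolerance decaying toward the PAM, wobble-like pairs (rG:dA site, rU:dC
site) most tolerated, full tolerance confined to PAM-distal positions 1–2 —
but its numeric values are constructed, not measured. Every property the
package's logic relies on is invariant to the exact numbers; pass
`CfdTable.load(path)` a measured table for production use.

## Controls

Intergenic controls are real NGG sites ≥ `min_gene_distance` (default
5 kb) from every gene body and outside all targeted peaks, each required to
pass the same off-target filter as library guides. Non-targeting controls
are random 20-mers verified to have no PAM-adjacent genomic site within
`max_mm_clearance` (default 2) mismatches. Both are deterministic in their
seed.

## Screen statistics

The analysis preserves the reported quantities of pooled-screen practice —
log2FC relative to the plasmid (pDNA) pool, median-based peak aggregation,
BH FDR — with a deliberately simple, fully specified, control-anchored
statistic instead of a negative-binomial model:

* **Normalization**: DESeq-style median-of-ratios over guides nonzero in
  all samples, falling back to total-count scaling when fewer than 100 such
  guides exist.
* **log2FC**: per replicate, `log2((n_s + c) / (n_pdna + c))` on normalized
  counts with pseudocount c = 0.5; `mean_lfc` averages replicates. A day-0
  reference instead of pDNA is a configuration choice.
* **Guide significance**: two-sided add-one-smoothed empirical p of
  `mean_lfc` against the non-targeting-control distribution,
  `p = (1 + #{|ctrl| ≥ |obs|}) / (1 + n_ctrl)`; BH across targeting guides.
* **Peak aggregation**: the peak statistic is the exact median of member
  guides' `mean_lfc` (over *all* member guides — no trimming threshold);
  its p-value compares it against medians of `n_perm` (default 10,000)
  random same-size draws from the control pool, two-sided and add-one
  smoothed, so p ∈ (0, 1]; BH across peaks. Guides whose motifs span
  several peaks are assigned to the peak whose motif lies closest to the
  cut site, ties to the lower peak id, so aggregation is over a partition.
* **Replicate concordance**: Pearson correlation of per-replicate log2FC
  vectors by default, Spearman as an option; zero-variance vectors are
  flagged undefined instead of propagating NaN.

Spacer counting is alignment-free: the 20-mer after a vector anchor (or at
a fixed offset) is matched exactly against the library; reads with a
missing anchor, a short extract, or an unknown 20-mer are counted
unassigned, and spacer sequences shared by multiple library entries go to
an ambiguity bin rather than being split. Assigned + unassigned + ambiguous
always equals total reads.

## Synthetic data

The generator emulates the study design at its stated scale: background
sequence at GC 0.41; non-overlapping 300-bp peaks; each peak seeded with
1 + Poisson(1.4) dyad instances (mean ≈ 2.4 motifs/peak, matching the
observed motif-per-peak ratio of the reference screen), W drawn uniformly
from {A,T} and spacer length uniform on 2–12; genes with TSSs in both a
proximal (< 10 kb) and a distal (> 100 kb) stratum. To make the distal
stratum exist, peaks occupy the left ~35% of each contig, proximal genes
anchor only to peaks in the leftmost 15%, and "distal" genes start
≥ 100 kb right of the last peak (contigs shorter than that simply lack the
distal stratum).

Counts: per guide a pDNA abundance ~ LogNormal(0, 0.5²) scaled to the mean
depth (default 500 reads/guide). The pDNA sample is that abundance with
**Poisson** noise only — a plasmid pool is sequenced DNA and carries no
biological overdispersion — while each screen replicate draws from a
negative binomial (variance μ + αμ², default α = 0.1, the overdispersion
contributed by cell sampling and infection bottlenecks) around
`pdna_mean × 2^(true_lfc × efficiency)`. Modelling the pDNA column as NB
with the screen dispersion would inject a shared reference noise
(sd ≈ 0.5 log2 units) into every guide's fold change that no replication
can average away, which matches neither real screens nor the noise scale
the statistic's own calibration examples assume. Guide efficiency
multipliers are Beta(2, 1) (mean 2/3) for targeting guides — regulatory-
element screens show markedly more guide-to-guide variability than coding
knockouts — so a planted ±1.5 peak yields guide-level effects around ±1.0;
recovery tests account for this rather than assuming the nominal effect.
All generators are pure functions of (config, seed).

`make_screen_library` builds a statistics-only library (random spacers,
4 guides/peak + controls) without a genome, used where only the count model
matters; genome-backed libraries come from the design pipeline.

What passing tests on synthetic data do **not** show: real chromatin
context (accessibility, CRISPRi window effects), guide-position effects
within an element, copy-number artifacts, or fitness-mediated
normalization shifts. The generator's conditions are the package's test
bed, not a claim about any particular biological dataset.

## Problem sizes and numerical choices

The default test and acceptance runs use a 400-kb genome with 60 peaks on
the design side (every stage exercised, oracle-checkable in seconds) and
the full stated screen conditions (200 peaks, 10+10 effects, 20 seeds) on
the statistics side; these sizes are the package's choice of a thorough
but quick default. Tolerances: CFD = 1 is tested at 1e-9 on the product;
empirical p-values are add-one smoothed so they are never 0; BH uses the
standard step-up. Degenerate inputs are errors, not guesses: empty null
sets, all-zero samples, zero pseudocount with zero counts, peaks outside
contig bounds.

## Known limitations

* Guide-level p-values share one null (the control distribution) across
  all guides; depth-dependent variance is not modelled.
* The peak permutation null draws guides independently, ignoring any
  within-peak correlation beyond what controls carry.
* No bulge (indel) off-targets; no genome-scale (GB-range) search
  performance claims.
* The gene annotation is a minimal TSV (id, span, strand, coding flag) —
  deliberately not a GFF/GTF parser.
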