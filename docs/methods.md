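# Methods

## Scope and data model

The package analyses sparse CpG methylomes of the kind seen in
Lepidoptera: a single pooled WGBS sample summarised as per-cytosine
counts (Bismark cytosine-report dialect: chrom, 1-based position,
strand, methylated count, unmethylated count, context, trinucleotide),
a genome FASTA, a GFF3 gene annotation with exons, an expression table
of TMM-normalised FPKM per gene, a gene→term mapping for enrichment,
and per-individual targeted-amplicon count tables with two phenotype
labels.

All coordinates are 1-based inclusive internally (the convention of the
cytosine report and GFF3); BED6 output converts to 0-based half-open at
the boundary and scales methylation levels to a 0–1000 score. The two
cytosines of a symmetric CpG are kept as separate sites, matching the
granularity of the input report.

## Site calling

Bisulfite conversion is imperfect: a fraction *e* of truly
unmethylated cytosines read as methylated. With conversion > 99%, *e*
defaults to 0.01 and can be estimated as pooled
Σ methylated / Σ total over CHG/CHH cytosines, which insect genomes
leave essentially unmethylated. The estimator is a simple pooled
binomial proportion; at ≥ 10⁶ non-CpG observations its standard error
is below 10⁻⁴.

Each CpG site with at least `min_reads` total reads (default 2;
a stricter 10 is common for per-site reporting) is tested one-sided
against that error rate: `p_raw = P[X ≥ n_meth]`,
`X ~ Binomial(n_total, e)`. A two-sided test has no meaning against an
error-rate null. Sites below the coverage floor are excluded *before*
adjustment, so the Benjamini–Hochberg family is exactly the tested
set; `is_methylated = (p_adj < 0.05)`. Because the binomial test is
discrete and every null site has true level 0, BH keeps the realised
false-discovery proportion conservative; on the default synthetic
genome it runs at ~2% of calls.

The coverage filter interacts with BH: moving from a 2-read to a
10-read floor changes the family, so adjusted p-values at shared sites
are not mathematically guaranteed to nest. Empirically the two call
sets disagree only at the BH boundary (< 0.1% of shared sites), which
is what the tests assert.

## Feature assignment and methylation ratios

A called site inside any exon interval of a gene is exonic for that
gene; inside the gene span but no exon, intronic; within the 2 kb
window 5′ of the annotated gene start (strand-aware, clipped at contig
edges), upstream. A site may be assigned to several overlapping genes
and is counted in each — per-gene statistics stay self-contained, and
no deduplication rule is imposed. Within one gene, exon takes
precedence over intron, so genic detected CpGs partition exactly.

Ratios use detected CpGs (sites passing the coverage floor) as the
denominator, not all genomic CpGs: the measure is over sequenced sites.
A gene with zero detected CpGs in a feature class has an undefined
(NaN) ratio, never a silent zero, and is excluded from classification
with its count reported. Classification is strict: exon ratio > 0.10
⇒ methylated; ≤ 0.10 ⇒ nonmethylated.

## CpG observed/expected

For a sequence with C, G and CG counts and N-free length L,
`CpG O/E = n_CG · L / (n_C · n_G)`. N bases drop out of every count
(an N interrupts any CG it touches). The region defaults to the
genomic gene span (exons + introns); a flag switches to concatenated
exons. Sequence is taken on the annotated strand (reverse complement
for − genes) and counted once — CG counts are strand-symmetric, so
this only swaps C and G, leaving the statistic unchanged. On an i.i.d.
sequence the statistic is ~1 regardless of GC content; historical
methylation drives it below 1 via 5mC→T deamination. Class comparison
reports per-class means, an F variance-ratio with (n₁−1, n₂−1) df and
a Welch mean comparison (the class-difference claim is not tied to one
of them), plus the Spearman correlation of exon ratio with CpG O/E.

## Dip statistic

Hartigan & Hartigan's dip — `min over unimodal CDFs U of
sup_x |F_n(x) − U(x)|` — is implemented from first principles as the
iterative greatest-convex-minorant / least-concave-majorant algorithm
on the sorted sample: compute both envelopes on the current interval,
find the largest separation between their fits, shrink the candidate
modal interval, and accumulate the largest ECDF deviation outside it;
the result is floored at 1/(2n) (any n-point sample admits a unimodal
fit that close). Reference behaviours: an equispaced sample gives
exactly 1/(2n); a balanced two-point mixture gives the maximal 0.25.

The implementation is validated against an independent oracle
(`methylome_kit._reference.dip_oracle`) that minimises the defining
sup-distance directly: for each admissible mode position — at a data
value with an atom allowed, or inside a gap, swept over a refined grid
— the best piecewise-linear unimodal CDF is found by linear
programming with explicit convex/concave slope-ordering constraints.
Agreement is within 10⁻⁹ for samples of n ≤ 8, including ties.

P-values are Monte Carlo: the fraction of uniform(0,1) samples of the
same n (the least favourable unimodal null, the convention of the
standard dip-test implementations) with dip at least the observed,
with a plus-one correction; default 2000 draws, seeded.

## Enrichment and rank statistics

Term enrichment is a one-sided ("greater") Fisher exact test per term
on the 2×2 table target/non-target × in-term/not-in-term, BH across
terms, flagged at FDR < 0.05. GO DAG propagation is out of scope — the
mapping file is taken as-is. Highly methylated means exon ratio > 0.5;
the methylation-free set is genes with zero methylated-called CpGs.

The expression comparison between the two gene classes is an
independent-samples design, so the Mann–Whitney U (rank-sum) test is
the default; a signed-rank variant exists but requires genuinely
paired samples of equal size and refuses anything else. FPKM = 0
genes participate in rank statistics (ranks handle zeros) but are
excluded from log-scale bin summaries; bins are [0,0.1), …, [0.9,1.0]
with the top edge closed, and empty bins are retained.

## Amplicon comparisons

Per sample and site, fractional methylation = methylated / total
reads. A site is retained when ≥ 1 sample reaches `min_reads`
(default 10); retained sites keep sub-threshold samples as missing and
each site is analysed complete-case. Group means average per-sample
fractions (not pooled reads), the difference is first group minus
second (long − short in the motivating design), and the default test
is the pooled-variance Student's t (Welch by flag), two-sided. No
multiple-testing correction is applied by default — per-site raw
p-values are the primary report for a small targeted panel — but a BH
column is emitted alongside. Degenerate all-constant sites get p = 1
(no difference) or p = 0 (a difference with zero variance).
WGBS-vs-amplicon concordance is an ordinary least-squares fit with R²,
slope and p; a negative slope is flagged rather than hidden inside R².

## Synthetic-data generator

The generator exists so every stage is testable against known ground
truth; its defaults are the study conditions the pipeline assumes.

- **Genome**: 4 contigs × 500 kb of i.i.d. sequence at GC 0.37
  (typical noctuid composition); 400 genes with 2–6 exons
  (150–400 bp) and introns of 200–800 bp, placed without overlap with
  ≥ 300 bp gaps, random strands.
- **Gene classes**: methylated with probability 0.2 (the minority
  class implied by genome-wide insect methylomes).
- **Methylation states**: each gene draws a propensity π — the
  fraction of its CpGs truly methylated — from Beta(8, 2) (methylated
  class, mean 0.8) or Beta(0.5, 40) (nonmethylated class, mean 0.012).
  Sites are then binary, the sparse-methylome regime: truly methylated
  with probability π in exons and 0.2·π in introns (exon bias), at a
  per-site level drawn from Beta(20, 3) (mean 0.87, the high levels
  seen at genuinely methylated insect CpGs); all other sites have
  level exactly 0. Intergenic CpGs are methylated with probability
  0.002 (a free parameter; background methylation outside genes is not
  well characterised). The two strand cytosines of a CpG share their
  state, mirroring symmetric maintenance methylation. The gene-level
  Beta mixture is what makes the exon-ratio distribution bimodal; the
  binary site layer is what lets a binomial caller recover classes at
  any coverage (a model in which "lowly methylated" sites carry
  intermediate true levels of a few percent would be called methylated
  wholesale at high coverage, which is neither the biology nor the
  behaviour of real sparse methylomes).
- **CpG depletion**: inside methylated-class genes each CG is
  rewritten to TG or CA with probability 0.4 at genome construction,
  so low CpG O/E in methylated genes *emerges from sequence* rather
  than being painted onto a statistic.
- **Observation model**: coverage ~ NegativeBinomial(mean 28,
  dispersion 8); methylated reads ~ Binomial(coverage,
  m·(1 − ε_over) + (1 − m)·e) with non-conversion e = 0.01 and
  over-conversion ε_over = 0 by default. A 10% subsample of non-CpG
  cytosines (truly unmethylated) is emitted for error-rate estimation.
- **Expression**: log₁₀ FPKM = 0.8 + 0.8·1[methylated] + N(0, 0.55);
  12% of nonmethylated and 1% of methylated genes are silenced to
  FPKM = 0, reproducing the silent-gene / methylation-free overlap.
- **Amplicon panels**: per-site group means (short-group mean plus a
  planted difference, validated to stay in [0, 1]), 8 samples per
  group, coverage ~ NB(500, 8), binomial counts with the same error
  model.

Identical config and seed give byte-identical files; each stage draws
from a child stream of the config seed.

What the generator does **not** emulate: read-level artefacts (mapping
bias, PCR duplicates, M-bias), chromosome-scale methylation domains or
correlation between neighbouring CpGs beyond strand pairing,
annotation error, expression dispersion structure beyond a log-normal,
and biological between-individual variance in amplicon panels (counts
are binomial around group means, so the amplicon t-test calibration
checks the statistics, not over-dispersed biology). Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not performance on any particular real genome.

## Problem sizes and numerical choices

The validation suites run the default study (~2 Mb, ~130k CpG
cytosines, 400 genes) for error-control and structure checks, a
6.4 Mb / 2000-gene study at 100× for class-fraction recovery, 500
replicate null amplicon panels for t-test calibration, and n ≤ 8
samples for the LP dip oracle — sizes chosen so the full suite
completes in a few minutes while keeping every Monte-Carlo margin wide
(e.g. the recovery check has expected bias ~0.01 against its ±0.03
band; the low-class Beta(0.5, 40) was chosen over a heavier-tailed
low class precisely so that misclassification of genuinely
high-propensity "low" genes stays a ~1% effect rather than sitting on
the band).

Ties in the dip statistic are handled by the ECDF itself (the oracle
groups tied values and constrains left/right plateaus separately).
BH uses a mergesort argsort for deterministic tie order.
`p_raw = scipy.stats.binom.sf(k−1, n, e)` avoids summation error.
Fisher tables are built from exact set intersections. Undefined
quantities (ratios with empty denominators, CpG O/E without C or G,
silent-gene fractions without silent genes) are NaN with an explicit
flag or count, never silently zero.

## Known limitations

- The 2 kb upstream window is a TSS proxy from the gene start; UTRs
  are not modelled separately.
- The dip oracle's gap-mode search refines a grid; its 10⁻⁹ agreement
  is demonstrated for n ≤ 8, not proven for all inputs.
- Enrichment treats terms independently (no DAG structure).
- The amplicon module assumes two groups; multi-group designs are out
  of scope.
- Genome-scale percentage summaries take the genomic CpG total as
  given (per-cytosine vs per-dinucleotide conventions differ between
  studies; both counts are exposed).
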