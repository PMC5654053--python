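# Methods

`ernalink` implements a CAGE-based transcribed-enhancer analysis for
macrophage activation studies: enhancer calling from divergent tag
clusters, eRNA/promoter quantification, TAD-constrained enhancer–promoter
linking, z-score classification, and enrichment testing, together with a
seeded synthetic-data generator that plants ground truth for every stage.
This note records the models, conventions and parameter choices, and what
the synthetic benchmark does and does not demonstrate.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention).
Region strings of the form `chr10:25119065…25119466` are parsed as 0-based
start and half-open end, so such regions have width 401 nt — consistent
with the fixed enhancer-region width below.  CAGE tag clusters are always
stranded; enhancer regions and TADs are unstranded.  Distances between a
feature and a point or interval follow the `bedtools closest -d`
convention: 0 for overlap, 1 for adjacency.

## Tag clustering and promoter annotation

`cluster_tss` is a deliberately simple single-linkage clustering of
same-strand TSS positions (gap ≤ 20 bp, summit = highest pooled count,
leftmost on ties).  It is plumbing: production FANTOM-style analyses
decompose tag clusters with ICA-based methods whose reimplementation is
out of scope here, and one clustered peak set serves both enhancer calling
and promoter annotation.

A tag cluster is a promoter of a transcript when its 5′ end (cluster start
on `+`, last base on `−`) lies within 500 bp of the transcript 5′ end on
the same strand; gene-level promoter sets are unions over the gene's
transcripts.  Gene expression is the per-sample sum of the gene's promoter
expression.

## Normalization

Promoter raw counts are TMM-normalized (trimmed mean of M-values) and
expressed as tags per million over the effective library size
(`count / (library × factor) × 1e6`); CAGE tags get no length
normalization.  The TMM implementation follows the published defaults:
reference sample = upper-quartile of nonzero relative counts closest to
the mean; per sample, features positive in both sample and reference
contribute M (log2 ratio of relative counts) and A (mean log2 abundance);
30% of each M tail and 5% of each A tail are trimmed by rank; the factor
is 2 to the inverse-delta-method-variance weighted mean of retained M;
factors are rescaled to geometric mean 1.  Because the precision weights
depend on absolute depth, factors are only approximately (within a few
percent) invariant to a global rescale of one library; the M-values
themselves are exactly invariant.

Enhancer eRNA counts are converted to TPM using the *promoter* matrix's
TMM factors and library sizes.  Promoter tags dominate library
composition, and a standalone TMM on the sparse enhancer matrix would be
undefined for samples in which no enhancer is transcribed at all.

Expression filters use "at least one TPM in at least ⌈0.10·N⌉ macrophage
samples".  The ceiling is computed on a value rounded to 9 decimals first,
so that 0.10 × 40 is 4 and not ⌈4.000000000000001⌉ = 5.

## Enhancer calling

Tag clusters within 500 bp of a protein-coding transcript TSS or within
200 bp of an exon are masked (strand-agnostic).  A minus-strand cluster m
and a plus-strand cluster p on one chromosome form a divergent candidate
when m.summit < p.summit and the summit separation is at most 400 bp.  The
candidate region is fixed-width: midpoint = ⌊(m.summit + p.summit)/2⌋,
interval = [midpoint − 200, midpoint + 201), i.e. 401 nt.  The
directionality score D = (P − M)/(P + M) pools plus-strand tags in
[midpoint, end) and minus-strand tags in [start, midpoint), each cluster's
pooled count attributed to its summit; candidates with |D| ≥ 0.8 or no
window tags are discarded.  Overlapping surviving candidates are resolved
deterministically by keeping the strongest (largest P + M; ties broken by
coordinate).  The 400-bp gap, 200-bp halfwidth and 0.8 cutoff are the
published parameters of the bidirectional-pairing strategy this caller
follows, and all three are `Config` fields.

Per-sample eRNA counts sum minus-strand tags in the left half-window and
plus-strand tags in the right half-window (the divergent configuration
only).  A region is *transcribed* with nonzero eRNA in at least ⌈0.10·N⌉
macrophage samples, and *chromatin-supported* when it overlaps (≥ 1 bp,
strand-ignoring) a ChIP-derived enhancer interval; the region's chromatin
state is `active` if any overlapped interval carries H3K4me1+H3K27ac,
otherwise `poised` (H3K4me1 only).

## Enhancer–promoter linking

Candidate pairs are transcribed, chromatin-supported enhancers and
expression-filtered promoter clusters entirely contained in the same TAD.
Each pair is scored by Spearman correlation (mean ranks for ties,
two-sided p from the t-approximation) of eRNA and promoter TPM across
macrophage samples; constant vectors are dropped with a log entry.
Benjamini–Hochberg correction is applied once across all TAD-based pairs
(one family, matching the single reported FDR threshold), and links with
rho > 0 and q < 1e-4 are retained.  An enhancer regulates a gene when it
links to at least one of the gene's promoters; link distance is enhancer
midpoint to promoter 5′ end.  Every run verifies that no selected link
crosses a TAD boundary.

## Specificity and markers

z-scores are (x − mean_bg)/sd_bg with the n−1 sd.  A zero-variance
background gives z = +∞ above the mean and 0 otherwise, so features silent
everywhere are never classified.  Macrophage-specific: z > 3 (strict)
versus the non-macrophage panel in at least ⌈0.10·N_mac⌉ macrophage
samples.  Stimulus-responsive: z > 3 versus the 10 untreated macrophages
in strictly more than 25% of the 16 stimulated samples (≥ 5 of 16); "at
least 10%" maps to a ceiling, "more than 25%" to a strict inequality —
the two readings are kept distinct deliberately and are configurable.

State-restricted links keep previously selected links whose endpoints are
both responsive in that state and whose Spearman rho over the state's
samples is strictly positive (sign only).  A marker enhancer for a state
is responsive in that state only, linked in-state to a known marker gene,
and has z > 3 versus the opposite state's samples in more than 25% of the
state's samples.  The packaged marker panel
(`ernalink/data/marker_genes.tsv`) lists classical (IFN-γ) and alternative
(IL-4/IL-13) activation markers with described enhancer regulation; it is
data, not code, and can be replaced by any two-column TSV.

### Null calibration of the responsive rule

The responsive rule's false-call rate depends strongly on the background
panel size.  With z computed against effectively known population
parameters (a large background panel), the per-feature null rate is the
binomial tail of P(Z > 3) ≈ 0.00135 at ≥ 5 of 16, about 3e-7 — zero calls
are expected in a 10,000-feature null panel, and the calibration test
asserts exactly that using a 744-sample background (the size of the
non-macrophage panel).  With the 10-sample untreated background the 16
z-scores share one noisy mean/sd estimate and the measured null rate rises
to ~1.2e-3 per feature (direct simulation, 2×10⁶ replicates).  Generator
runs with the condition effect switched off therefore show occasional
(order 1 per state) responsive calls among hundreds of features; the
corresponding test bounds them at that rate rather than asserting zero.
This is a property of the published rule at the study's background size,
not of the implementation.

## Enrichment

Gene sets are tested with the upper-tail hypergeometric probability of the
observed-or-larger overlap against a fixed universe, BH-corrected across
the collection's terms.  TFBS over-representation uses the fraction of
query enhancers containing ≥ 1 ChIP summit (point-in-interval, half-open;
summits pre-filtered at q < 1e-4) and Monte-Carlo resampling with 1000
trials against three backgrounds: the whole called enhancer set and the
not-transcribed subset (drawn without replacement), and width-matched
random regions placed uniformly inside TADs excluding assembly gaps,
repeats, coding exons and called enhancers (regenerated fresh each trial).
The random placement enumerates all exclusion-free legal start positions
exactly, so no rejection sampling is involved and the
never-touches-an-exclusion guarantee is checked exhaustively in tests.
Empirical p uses the plus-one estimator (1 + #{trial ≥ observed})/(trials
+ 1) and never returns 0.  A factor is significant when p < 0.01 against
all three backgrounds and the factor itself is expressed (mean TPM > 0).
Trial draws are shared across factors, which matches drawing random region
sets first and scoring every factor against them.

## Synthetic data

The generator emulates the study's data structure at desk scale (the
defaults keep a full run under ten seconds on one CPU):

- **Genome**: 2 chromosomes × 1.44 Mb, 8 equal TADs per chromosome.
  Features (genes, enhancer anchors, decoy cluster pairs, exclusion
  intervals) occupy anchors spaced 6 kb apart, which keeps planted
  enhancers structurally clear of the TSS/exon masking windows.
- **Samples**: 10 untreated + 16 IFN-γ + 16 IL-4/IL-13 macrophages
  (mirroring the study design) and 80 non-macrophage background samples
  (a scaled-down stand-in for the 744-sample panel).
- **Counts**: negative-binomial per TSS position (dispersion 0.1,
  baseline mean 60 tags split over 3 positions per feature and strand).
- **Links**: each of 60 planted enhancers targets a distinct gene in the
  same TAD; both share a per-sample log-normal activity factor whose log
  sd is set from the target Spearman rho (0.8) via
  σ² = ρ/(1−ρ)·(dispersion/2 + 1/mean), the effective noise variance of a
  position-summed NB feature.  The log-latent is clipped at ±2σ (activity
  saturation), which stabilizes the realized correlation (median ≈ 0.86)
  and avoids single-sample blowups.
- **Condition effects**: 10 links per state are up-scaled in the state's
  samples by exp(5·σ_total), i.e. a five-SD shift on the log scale, on
  both the eRNA and the target promoter.
- **Chromatin and TFBS**: ChIP intervals cover all planted enhancers
  (90% active / 10% poised) plus decoy intervals; planted factors
  (Spi1, Cebpb, Rela at the default count of 3) receive low-q summits in
  50% of planted enhancers plus above-cutoff summits that the q filter
  must remove; 20 decoy factors receive uniform summits, one of them with
  zero expression to exercise the expression rule.
- **Non-macrophage enhancers** (80) are expressed only in background
  samples, giving the caller real but untranscribed regions that form the
  "not expressed in macrophages" background pool.  Off-state leak is
  0.002 tags/position — silent enhancers are essentially zero-count, as
  inactive-tissue eRNA is.
- **Decoys**: 60 convergent or too-distant (> 400 bp) cluster pairs that
  the caller must reject.

Everything derives from a single seeded generator, so datasets and truth
tables are byte-identical across runs with the same seed.

What the synthetic benchmark shows: the calling, linking, classification
and enrichment machinery recovers planted structure at the configured
effect sizes and respects its invariants (fixed width, TAD containment,
FDR direction, exclusion-free backgrounds).  What it does not show:
performance on real CAGE data with mappability artefacts, overlapping
genes, promoter-proximal eRNA, unbalanced library sizes across platforms,
or correlated biological replicates — none of which are modelled.

## Problem sizes used in checks

Oracle-equivalence checks run the caller against brute-force enumeration
on 200 random configurations of ≤ 50 peaks; hypergeometric p-values are
enumerated exhaustively for every universe up to N = 12; BH q-values are
compared with the direct step-up formula on 1000 random vectors; the TMM
factor is compared with a hand-computed weighted mean on a 6-feature toy
at 1e-9; Monte-Carlo p on an enumeration-sized toy (pool of 5, draws of 3)
must land within 3 MC standard deviations of the exact draw probability;
the background sampler is checked exhaustively on 10,000 draws.  The full
recovery benchmark uses the default generator scale above.

## Known limitations

- The caller attributes each cluster's pooled count to its summit when
  scoring directionality; sub-cluster tag shape is ignored.
- One tag-cluster set serves both promoter annotation and enhancer
  calling; there is no "robust subset" distinction.
- BH is applied globally across all TAD pairs; per-enhancer correction
  would change q-values for enhancers with many candidate promoters.
- The generator plants at most one enhancer per gene; many-to-one
  regulation appears only through chance double-links.
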