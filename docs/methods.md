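# Methods

## Scope and coordinate conventions

The package re-implements, as a tested library, the analysis chain used to
characterize a transposable-element landscape from standard annotation
inputs: a repeat-consensus library (FASTA with `name#Class/Superfamily`
headers), RepeatMasker `.out` hits, tandem-repeat intervals (BED), gene
models (GFF3), a compartment map (autosome / PAR / SDR / centromere /
subtelomere anchor), small-RNA alignments (SAM/BAM or BED6), broad peaks,
and binned signal (bedGraph). All coordinates are normalized to 0-based
half-open intervals at the I/O boundary and every internal operation uses
that single convention; interval set algebra (union, subtraction,
intersection, windowed coverage) is implemented on sorted integer arrays
and audited in the tests against brute-force per-base labellings, which
must agree exactly.

## Copy annotation

Hits sharing a link id merge into one copy spanning [min start, max end);
copy divergence is the fragment-length-weighted mean and consensus
coverage is the union of fragment consensus spans over the consensus
length. Coverage is measured on consensus coordinates rather than genomic
length so that nested insertions of other families do not inflate it.
LTR terminus–internal–terminus chains of paired families on one strand
merge into full-length copies when inter-copy gaps are at most `max_gap`
(default 500 bp, boundary inclusive); the assembled consensus length is
2·LTR + internal. A copy is intact iff divergence < 20% and coverage
> 0.8, strict on both sides — the boundary behaviour is pinned by tests.
Where TE and tandem annotations overlap, TEs take precedence: tandem
intervals are clipped, never TE intervals, and afterwards no base carries
both labels (checked per-base).

Mechanism classes: DNA → cut-and-paste; LTR, LINE, DIRS, PLE and Helitron
→ copy-and-paste; anything else → unknown, excluded from cut:copy ratios
and reported separately. The cut:copy ratio defaults to covered bases
(`unit="bp"`); a copy-count mode is available since "abundance" admits
both readings.

## Landscape statistics

Windows are non-overlapping, tiled from zero (or from a subtelomere anchor
toward the centromere in anchored mode); terminal partial windows are kept
and flagged, and excluded from between-group tests by default because
their density denominators differ. Window densities use a cumulative
coverage function so that the per-window TE bp sums to the annotation
total exactly. Window compartment labels follow the majority-bp rule.
Between-compartment comparisons use Kruskal–Wallis (scipy, tie-corrected;
all-identical input is reported as H = 0, p = 1) followed by Dunn's
tie-corrected z tests with Bonferroni adjustment, or the Wilcoxon
rank-sum test with continuity correction for two groups (the asymptotic
Mann–Whitney U, matching R's `wilcox.test` default). Dunn's test is
implemented in-package (no post-hoc library in the dependency set); the
tests check it against a hand-written rank-formula oracle. Superfamily
enrichment uses per-Mb densities with log2FC = log2((d + ε)/(d_ref + ε)),
ε = 1 bp/Mb, and an enrichment call at log2FC > 1 (strict).

## Gene context

Transcripts with > 70% (strict) of CDS bp covered by TE are removed before
any gene-context analysis. The site-class partition labels every base
exactly once via the precedence ladder CDS > 5′UTR > 3′UTR > intron >
intergenic, with intergenic bases proximal iff within 500 bp of any gene
span boundary, else distal; overlapping transcripts are collapsed by the
same ladder (a base is CDS if CDS in any transcript). Individual copies
overlapping genic bases take the majority genic label; fully intergenic
copies are proximal iff strictly more than 1% of their length lies in the
proximal zone. Gene–TE distances are gaps between gene spans and
intergenic copies, binned [0,500], (500,1000], (1000,2000], (2000,∞).
The genic TE:CDS ratio divides TE bp in the non-CDS gene body (introns +
UTRs) by CDS bp; mono-exonic genes are excluded. Expression relationships
use Spearman correlation on log2(TPM+1) (the pseudo-count is echoed in
output headers), and the gene-age analysis is a superfamily × phylostratum
Pearson chi-square with adjusted standardized residuals and expected-<5
flags — a formal surrogate for what is usually shown as a mosaic plot.

## Regulation association

Read-length filtering is inclusive (20–24 nt by default). Counting over
copies requires full containment of the alignment interval; a read is
counted for every containing copy, and every alignment of a multi-mapped
read counts. CPM normalizes by the number of distinct filtered mapped
reads (not alignments, not feature-assigned reads). The ≥10-read
prefilter (row sums across samples by default; a per-sample mode covers
the stricter reading) prepares count matrices for external differential
modelling, which is deliberately not reimplemented. The all-stage sRNA
association flag requires CPM > 0 in every stage; per-stage flags are also
emitted so the union reading stays recoverable. Peak association is ≥1 bp
overlap; the overlap fraction is the per-copy peak-union coverage.
The scale-regions metaprofile rescales each region body to 100 bins
(1000 bp body / 10 bp bins) with 10-kb native-bin flanks, reverses
minus-strand regions, and ignores missing-data bins; an all-ones track
yields an exactly flat profile. ChIP/sRNA signal is lifted to consensus
coordinates linearly within each fragment's consensus span (the signal
could alternatively be obtained by mapping reads directly to consensus
sequences; the lift route works from genomic alignments alone).
Feature-level coverage tests use Kruskal–Wallis across consensus features
with family as the unit and Benjamini–Hochberg-adjusted Dunn post hocs;
the autonomous vs non-autonomous comparison uses the Wilcoxon rank-sum
test. The descriptive expression trend uses LOESS (statsmodels lowess,
span 0.75), skipped with a warning below 10 families.

## Library curation

Pairwise comparison is a Smith–Waterman local alignment (match +1,
mismatch −1, gap −2, configurable), numba-accelerated, with deterministic
tie-breaks (diagonal > up > left; first maximal cell in row-major order)
so a naive quadratic DP oracle in the tests reproduces it exactly.
Both orientations are tried because consensus strand is arbitrary.
Identity is matches over alignment columns; coverage is the aligned span
on the shorter sequence over its length. Clustering is greedy and
longest-first (ties by id): a sequence joins the first cluster whose
representative passes identity ≥ 0.8 and coverage ≥ 0.8 (0.95/0.95 for
the redundancy pass) — a defined, reproducible stand-in for the usual
clustering heuristic, idempotent on representatives. Reclassification
propagates a curated (else any classified) member's label to unclassified
cluster mates, preferring curated donors and breaking ties by donor
length; clusters with conflicting curated labels are left unchanged and
flagged, since the right resolution is genuinely ambiguous.  Families
whose genomic copies overlap tandem-repeat intervals by strictly more
than 60% of their cumulative length are relabelled as tandem repeats.
Deduplication keeps one record per 95% cluster, never discarding a
curated record. Majority consensus from an alignment drops gap-majority
columns and resolves base ties alphabetically.

## The synthetic mobilome

The generator produces genomes, libraries, hits, gene models, compartment
maps, reads and peaks whose true parameters are recorded per copy, so
every downstream stage can be validated without external data. Defaults
are the study conditions this package models:

| parameter | default | meaning |
|---|---|---|
| compartment TE densities | 0.22 / 0.39 / 0.51 / 0.65 | autosome / PAR / male SDR / female SDR TE fraction |
| cut:copy ratios | 0.48 / 0.71 / 0.79 / 0.52 | per-compartment cut bp over copy bp |
| divergence mixture | 53% uniform [0,5)%, rest uniform [5,30)% | ~53% of TE bp below 5% divergence |
| truncation | P = 0.3, exponential mean 0.3·L, cap 0.9·L | 5′ truncation of copies |
| genes | exons ~230 bp, introns median 524 bp, intergenic median 1302 bp, 10% mono-exonic | compact gene space |
| island gaps | P = 0.10, median 10 kb | occasional gene-free tracts hosting giant elements |
| sRNA | P(target\|intact) = 0.647, P(target\|non-intact) = 0.218, 21-nt mode, 5′-U 0.8 | per-copy sRNA targeting |
| peaks | P(peak\|intact) = 0.302, P(peak\|non-intact) = 0.231, body-covering | broad-mark association |
| coupling | P(sRNA\|intact, peak) = 0.736 | conditional sRNA on peak-marked intact copies |

Planting is budgeted: each compartment segment receives a TE bp budget
split by mechanism to its cut:copy target; copies are drawn family by
family and placed into free space (intergenic tracts and introns, never
exons), with a drawn copy 5′-truncated to the largest available slot when
nothing larger fits, so realized densities and ratios land within a few
hundred bp of their targets. Introns attract insertions threefold beyond
their size share, emulating high intronic TE content. Divergence is
substitution-only (uniform over the three alternative bases) so the
realized value has a closed binomial form; an emitted copy's genomic
sequence differs from its truncated consensus at exactly the recorded
mismatch fraction. A copy is emitted as one hit or, with probability 0.1,
as two abutting fragments sharing a link id (for minus-strand copies the
genomic-left fragment carries the consensus-right span), exercising
defragmentation. sRNA targeting is drawn once per copy — a targeted copy
produces reads in every stage — because the association definition
requires CPM > 0 in all stages; when the conditional coupling is active
the probability for peak-free intact copies is adjusted so the intact
marginal is preserved. Reads fall fully inside their source copy with a
20–24 nt distribution peaking at 21 nt, and positions are
rejection-sampled so the 5′ genomic base is T-equivalent with probability
0.8. Peaks cover the whole copy body with zero flanks by default so a
peak never touches a neighbouring copy and the planted association
probabilities stay identifiable. Identical configuration and seed give
byte-identical outputs.

A lightweight `simulate_copy_set` lays out copies on a coordinate-only
chromosome for regulation-parameter recovery at n = 5000, where sequence
content is irrelevant; background (copy-independent) reads default to 5%
of the total in full simulations but are disabled in parameter-recovery
runs, since off-target reads perturb the estimand itself rather than the
estimator.

### What the generator does not emulate

Realistic base composition and GC structure, indels and sequencing error,
nested insertions (an optional fragmenting mode exercises defragmentation
but copies never interleave), TE-derived genes, exonic TE fractions
(placement avoids exons entirely, so CDS/UTR TE densities are ~0 rather
than the small real-world values), centromere-specific element structure,
and read mapping itself (alignments are emitted directly). Passing tests
therefore demonstrate correctness of the measurement chain under planted
truth, not robustness to alignment artefacts or assembly error.

## Problem sizes and numerical choices

The default synthetic genome is 5 Mb over three chromosomes (two
autosomes and a PAR/SDR/PAR sex chromosome), which gives 50 100-kb
windows and ~400–500 copies — enough for the compartment contrasts to be
declared at p < 0.01 by Kruskal–Wallis + Dunn while keeping a full run
under a second. Regulation parameters are recovered on 5000 copies, where
binomial standard errors are below 0.01. Between-compartment tests run on
50-kb windows when any compartment has fewer than four full 100-kb
windows, mirroring the usual finer-window treatment of small regions.
Degenerate inputs are defined, not exceptional: all-identical groups give
H = 0, a region with zero copy-mechanism bp gives an undefined (NaN)
cut:copy ratio with a flag, empty divergence tables and annotations
propagate as empty outputs, and zero-copy families are skipped with a
warning during tandem reclassification.

## Design choices made where the design was open

- "Spanned more than 80% of the consensus" is measured on the union of
  consensus coordinates, not genomic length (robust to nested insertions).
- The cut:copy ratio is cut bp / copy bp in bases, with a copy-count mode
  behind a flag.
- Cluster-based reclassification treats "association with curated
  elements" as cluster co-membership; conflicting curated labels flag the
  cluster rather than guessing.
- The ≥10-read prefilter sums counts across samples; a per-sample switch
  implements the stricter reading.
- The all-stage sRNA flag is the intersection reading (CPM > 0 in every
  stage); per-stage flags allow the union reading.
- Copies straddling genic and intergenic space take the majority genic
  label; the paper-style per-copy "proximal" call uses the strict >1%
  rule.
- Library size for CPM is total filtered mapped reads; stated in output
  metadata.
- LOESS span 0.75 for descriptive trends.

## Known limitations

Greedy longest-first clustering approximates, but is not, CD-HIT; the
simplified defragmentation (link-id join plus the LTR chain rule) covers
the behaviour relied upon — fragment rejoining and full-length LTR
assembly — not every heuristic of the original defragmenter. Intronic TE
density in the default simulation (~5% of intron bp) is lower than in the
real system because large copies rarely fit inside introns; the planted
intron bias raises copy counts, not bp share. The female SDR chromosome is
off by default (enable with `default_chromosomes(include_female_sdr=True)`).
Statistical engines are asymptotic; at very small window counts (n < 4
per compartment) the pipeline switches to finer windows or skips the test
with a note rather than reporting an underpowered comparison.
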