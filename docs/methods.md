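# Methods

## Scope and model

`regulonkit` implements the downstream half of an integrative
repressor-regulon study: it starts from called ChIP-seq peak summits,
a genome annotation/sequence, and per-gene FPKM expression values, and
ends at a per-gene regulatory classification with supporting motif,
occupancy, cluster and cobinding analyses. Upstream steps — read
alignment, peak calling, count-based differential-expression modelling,
de novo motif discovery, pathway-database lookups — are deliberately out
of scope; their products are inputs (summit BEDs, external DE tables,
IUPAC motif patterns, category label tables).

## Coordinate and window conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted on read, BED is native. The ATG is the first base of the
start codon, taken as the 5′-most CDS start in transcription direction
when a gene has several CDS records.

The promoter-proximal window runs from `upstream` (default 2,000) bp 5′ of
the ATG to `downstream` (default 200) bp 3′ of it, inclusive at both ends,
so an unclipped window spans upstream + downstream + 1 bases. Windows are
clipped to the chromosome and are *not* truncated at neighbouring genes: a
summit between two divergently transcribed genes is assigned to both.

Genomic locations are reported with fixed priority
promoter > gene body > 3′ end > distal upstream > other. "3′ end" is the
500 bp past a gene span (configurable; the underlying convention in the
source analyses is unstated). "Distal upstream" covers signed ATG
distances from −2,001 out to a −10 kb cap (configurable; only "beyond
−2,000 bp" is defined by convention).

## Summit reconciliation and peak-set union

Reproducibility is positional: replicate summits within `max_dist`
(default 100 bp) are paired one-to-one, greedily by increasing distance
with ties broken toward the lower coordinate, and merged at
floor((posA+posB)/2); unpaired summits are reported and excluded. The same
greedy matcher unions the two epitope peak sets, recording per-peak
provenance and the shared fraction |shared| / |smaller set|. Greedy
matching was chosen over optimal bipartite matching for transparency;
tests bound its behaviour against a brute-force all-pairs oracle, and at
realistic summit spacing (≥300 bp between true sites, jitter clipped to
half the pairing threshold) the two coincide. Interactive browser-based
rescue of marginal peaks is replaced by explicit allowlist/denylist BED
inputs.

## Occupancy quantification

Reads are single 5′ positions, extended to `extsize` (default 200 bp)
fragments strand-appropriately. The FPKM track is a per-base density:
each fragment contributes 10^9 / (total_mapped × fragment_length) to each
base it covers, and bins store per-base means. This makes the track
independent of bin size, reproduces region FPKM exactly when a region is
tiled by fragments of its own length (10 fragments over 1 kb at 10^6
mapped reads → 10.0), and conserves mass: mean depth × bin length summed
over bins equals total fragment–genome overlap, which the tests verify
against a per-base oracle. Window signals are length-weighted bin means;
at bin size 1 they equal per-base means exactly, at the default 10 bp they
are an approximation adequate for windows ≥100 bp. Group occupancy
comparisons use Welch's t (the unequal-variance form, since group
variances are not assumed equal); zero-variance degenerate groups resolve
to p = 1 (equal means) or p = 0 (different means) with an explicit flag.

## Motif scanning

IUPAC patterns compile to regular-expression character classes wrapped in
a lookahead so overlapping matches are all reported. Minus-strand matches
come from scanning the reverse-complement pattern on the forward sequence,
reported in plus-strand coordinates. An `N` in the sequence matches only
an `N` motif position. The summit window for counting is
[summit − w/2, summit − w/2 + w) with w = 100 by default; a hit belongs to
the window of its start coordinate, so a motif straddling the right edge
with its start inside still counts. Correctness is established against an
exhaustive word-set-expansion oracle and an analytic background rate
(2 × 8/4^6 per position for `SYGGRG` on uniform DNA). The secondary
CGGG-core motifs exist publicly only as sequence logos; the shipped
`motif2`/`motif4` entries (`YCGGGG`, `CGGGWR`) are synthetic IUPAC
stand-ins and should be replaced by user-supplied consensus strings when
available.

## Differential expression

The low-expression filter removes genes with FPKM < 1 in at least two of
three replicates in both genotypes — low expression in only one genotype
is a signal, not noise, and is kept. Fold changes are
log2((mean_mut + c)/(mean_wt + c)) with pseudocount c = 1 (FPKMs are not
counts; the pseudocount bounds ratios at low expression). Classification
thresholds are inclusive: |log2 FC| ≥ 1 and adjusted p ≤ 0.05. "Adjusted"
means Benjamini–Hochberg (the usual default of count-based DE tools),
implemented via `statsmodels` and verified against the textbook step-up
definition. The consistency rescue formalizes a manual-inspection rule:
a non-significant gene is rescued when all per-replicate-pair log2 ratios
share a sign and their mean magnitude reaches the fold-change threshold.

The internal per-gene test is Welch's t on log2(FPKM + 1). It exists so
synthetic data can run end-to-end without external tools; real datasets
should supply a DESeq2-style external table. At r = 3 the
Welch–Satterthwaite approximation is conservative (measured size ≈ 0.036
at nominal 0.05), which costs a little power and is acceptable for a
validity-first stand-in; the test suite asserts the size never exceeds
nominal.

## Regulatory classification

`assign_regulatory_class` is a pure table over (bound, DE status):
bound∧up → class1, bound∧unchanged → class2, unbound∧up/down →
class3_up/class3_down, bound∧down → class4, everything else (including
filtered genes) → none. Rescued statuses count as their direction by
default (toggleable). "Bound" means ≥1 reconciled summit in the promoter
window after optional allow/deny edits. Pathway summaries emit
percentages under both candidate denominators (per category and per
class) because the natural one is ambiguous; enrichment is a one-sided
hypergeometric tail with BH adjustment across categories.

## Cobinding

The per-promoter distance between two factors is the minimum |posA−posB|
over all their summit pairs at that promoter (the multi-summit convention
is a package choice). Labels are cobound at distance ≤ 50 bp — inclusive,
"within 50 bp" — else distinct. `calibrate_threshold` picks the smallest
multiple of the granularity (10 bp) whose empirical coverage of the
heterodimer reference distances reaches the target (0.8 default);
coverage is reported alongside. Occupancy-change correlation is Pearson's
r on per-promoter signal differences (log-ratio mode available, since the
appropriate scale is condition-dependent); zero-variance inputs yield a
flagged NaN.

## Synthetic data

The generator plants, under one mandatory seed (numpy `SeedSequence`
children for the annotation / regulon / cobinding stages): gene layouts
with ≥5 kb spacing and a configurable fraction of divergent pairs sharing
a <2.2 kb intergenic gap; binding sites at ≥300 bp spacing within
promoter windows for genes of bound classes, with homotypic clusters at
probability 0.35 (0.6 for TF-flagged genes, echoing the observed
multi-site excess at regulator promoters); per-epitope site detection at
0.9; per-replicate summit jitter N(0, 20 bp) clipped at ±50 bp so a
replicate pair can never exceed the 100 bp reconciliation threshold;
motifs written into the random genome at the site (background occurrences
still arise by chance, so motif-presence truth is a lower bound);
reads around each site plus uniform background; and lognormal FPKM
baselines (floored at 2) with mean-preserving 20% replicate CV and planted
|log2 FC| = 3 for DE classes. Class 2 genes split into low- and
high-expression subgroups, mirroring the two regulatory situations that
produce bound-but-unchanged targets. Class proportions default to
2/10/4/8/2/74% over class1/class2/class3_up/class3_down/class4/none,
echoing the relative magnitudes reported for a real repressor regulon.

Binding *truth* is geometric: after site placement, a gene is truly bound
iff some planted site lies in its promoter window — so a shared
bidirectional-promoter site marks both genes bound — and the truth class
is recomputed from (bound, planted DE direction). Under zero noise the
pipeline output equals the truth exactly; under the standard-noise preset
the expected disagreement is dominated by double-epitope site misses
(~1% per site) and is well inside the ≥95% agreement the end-to-end test
asserts.

What the generator does not emulate: mappability and GC bias, peak-caller
artefacts, correlated replicate noise, overdispersed counts, isoform
structure, or real motif position-weight matrices. Passing tests
demonstrate the correctness of the downstream logic, not robustness to
those upstream artefacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: 200–1,000
genes on 2–4 chromosomes of 0.8–2 Mb, 1 Mb analytic motif backgrounds,
500-pair cobinding panels. Statistical checks use 3-standard-error bands
around analytic or Monte-Carlo expectations; deterministic checks are
exact. Ties in greedy matching break toward lower coordinates; merged
positions round down; BH outputs are clipped at 1; empty intervals,
empty references and invalid probabilities raise rather than propagate.

## Known limitations

- The replicate-reconciliation rule is applied genome-wide by coordinate
  distance; the original phrasing ("for the same gene") is a per-gene
  superset of this and can differ for summits near window boundaries.
- Greedy distance matching is not globally optimal for pathological
  summit configurations (near-equidistant chains); tests quantify
  agreement with the brute-force matching on random instances.
- The internal DE test is not a substitute for count-based models on real
  data (no dispersion sharing, conservative at r = 3).
- Motif hits are binary presence calls; no PWM scoring or E-values.
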