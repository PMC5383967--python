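# Methods

This note documents the models, conventions and numerical choices behind
`pancscan`.  The package analyses promoter-associated non-coding RNA
(pancRNA): antisense transcription arising from the 2 kb immediately
upstream of a protein-coding gene's transcription start site (TSS), on
the strand opposite the gene.  Its core question is whether a gene's
pancRNA expression tracks the gene's own mRNA across tissues, and how
that pairing behaves across species.

## Coordinates and promoter construction

All internal coordinates are 0-based, half-open; GTF input (1-based,
closed) is converted on read.  For a gene with TSS at `t`, the promoter
is `[t-2000, t)` on the plus strand and `[t+1, t+2001)` on the minus
strand, clipped at chromosome bounds.  The pancRNA strand is always the
opposite of the gene strand.

Promoter filtering has to guarantee that antisense reads counted for a
promoter really are promoter-derived.  For every gene, one candidate
promoter is built per alternative TSS.  A candidate that overlaps
another gene's span or another gene's candidate promoter is discarded;
among the survivors the most distal candidate (TSS farthest upstream of
the gene body) is selected and labelled CLEAN.  A gene with no surviving
candidate keeps its most distal candidate but is labelled CONTAMINATED
when that candidate overlaps another gene's span (such genes remain in
gene-level analyses but are excluded from pancRNA counting) or EXCLUDED
otherwise.  Finally, CLEAN promoters closer than `min_gap = 500` bp
(edge to edge, strand-blind) are resolved in favour of the more distal
one — distality measured as the upstream shift of the selected TSS
relative to the gene's most proximal TSS, with ties broken by promoter
length and then gene id — and the loser becomes EXCLUDED.  The outcome
is a deterministic function of the gene *set*, so input order never
matters, and CLEAN/CONTAMINATED/EXCLUDED partitions the genes.

Two points in this procedure were genuinely open and are package
decisions: the `< 500 bp` proximity rule is applied promoter-to-promoter
(edge to edge), and overlap tests ignore strand because contaminating
transcription can come from either strand.

## Counting and strandedness

Counting is union-style with an ambiguity rule: a uniquely mapped read
increments a feature when it overlaps the feature's interval by at least
one base on the required strand (gene strand for mRNA, antisense strand
for pancRNA); a read compatible with more than one feature of the same
kind is discarded and tallied.  Uniqueness is decided upstream (MAPQ >=
20 by default when reading SAM/BAM).  Paired-end data are expected to be
reduced upstream to the upstream-side mate as single-end evidence.
Strandedness QC reports the fraction of unique, single-gene-overlapping
reads whose strand matches the gene — a library-preparation sanity check
that should be near 1 for a directional protocol.

## Normalization: TMM inside a DEG-elimination loop

Scaling normalization is the trimmed mean of M-values (TMM).  The
reference sample is the one whose 75th-percentile count fraction is
closest to the across-sample mean.  For each sample, M (log2 expression
ratio versus the reference) and A (average log intensity) are computed
over genes positive in both; the M distribution is trimmed at 30% each
side and A at 5% each side, and the surviving M values are combined with
delta-method precision weights.  The reported factor for sample *j* is
the *effective* size factor — library size times the TMM scaling —
rescaled so the factors have geometric mean exactly 1.

The DEG-elimination wrapper (DEGES) iterates: (1) estimate factors, (2)
flag the top `deg_fraction` (default 0.25) of genes ranked by the
maximum absolute pairwise log2 fold change of factor-adjusted tissue
means (a 0.5-count offset keeps zero means finite), (3) re-estimate the
factors on the unflagged genes; the default is one iteration.  The flag
statistic is a deliberate simplification: it keeps the three-step
structure testable without re-implementing an exact-test DE caller, and
it reduces exactly to plain TMM when `deg_fraction = 0` or
`iterations = 0`.  Normalized output is counts per million on the
effective-library scale, anchored on the geometric-mean library size.
mRNA and pancRNA counts from the same libraries are normalized jointly
(stacked into one matrix) before being split for downstream use.

## Pairing classification

Replicates are averaged to tissue means first, so correlations are
computed on one point per tissue (five by default).  For each gene with
a CLEAN promoter, the Pearson correlation r between the mRNA and pancRNA
tissue-mean vectors decides the class:

* `r > 0.7` — PARTNERED (pancRNA-partnered gene);
* `r < 0.4`, or pancRNA identically zero — LACKING;
* otherwise INTERMEDIATE; incomputable r with nonzero pancRNA —
  UNDEFINED.

Thresholds are strict inequalities; exact ties fall to INTERMEDIATE.
Treating an all-zero pancRNA vector as LACKING is a deliberate choice:
absence of antisense signal is the biological meaning of "lacking", and
leaving it undefined would silently shrink that class.  Two-sided
p-values from the t transform (n-2 df) are reported but never gate the
classification — at n = 5 tissues an r of 0.7 is not significant at
0.05, so the thresholds and a p filter cannot both be active.
Correlations use untransformed normalized means.  Negative correlations
(r < -0.7) are tallied separately in summaries.

## Tissue specificity

The tissue-specificity index is tau = sum_i (1 - x_i / x_max) / (N - 1)
over the N tissue means: 0 for uniform expression, 1 for single-tissue
expression, invariant under positive scaling, undefined for an all-zero
vector.  Group comparisons (all genes; genes with CONTAMINATED
promoters; partnered; lacking) use the Steel-Dwass all-pairs test.

## Species-level calls

One-to-one ortholog pairs are assembled into groups by connected
components; only *complete singleton* groups (exactly one gene per
species) are used.  A species-specific pancRNA-partnered gene is
PARTNERED in exactly one species with all orthologs LACKING — strict on
both sides, so an INTERMEDIATE ortholog blocks the call.  The loss-side
set (LACKING in one species, PARTNERED in all others) and the conserved
set (PARTNERED everywhere) are computed the same way.

## Cross-species clustering

Joint matrices hold one row per complete ortholog group and one column
per (species, tissue) sample, with each species contributing its own
tissue means.  Three feature universes: all complete groups (`mrna`),
groups PARTNERED in at least one species (`panc_any` — "encodes a
pancRNA in any species" is operationalized through the pairing calls),
and groups PARTNERED everywhere (`panc_conserved`).  Samples are
compared by mid-rank Spearman correlation; clustering is hand-rolled
UPGMA on d = 1 - rho with deterministic tie-breaking (smallest pair of
minimal leaf labels), node heights equal to the average-linkage
distance, and newick export.  The segregation score condenses the
heat-map claim into a number: the fraction of samples whose nearest
neighbour (highest rho, self excluded) shares the species, and likewise
for tissue.  The dendrogram remains the primary output; the score exists
so the species-versus-tissue clustering claim is assertable.

## Conservation

Per-base conservation scores (phastCons-style, consumed from fixedStep
wiggle or bedGraph) are averaged per gene over the promoter interval and
over the merged union of coding exons.  Missing positions mean
"unalignable", not "unconserved", and are excluded from means; a fully
missing region is undefined.  The Steel-Dwass procedure compares groups:
each pair is tested with a mid-rank, tie-variance-corrected rank sum,
and sqrt(2)|t| is referred to the studentized-range distribution with
infinite degrees of freedom (evaluated numerically via scipy), which at
k = 2 reduces exactly to the two-sided normal-approximation
Mann-Whitney test.

## Motif scanning

PWMs are position probability matrices (MEME minimal format reader
included; discovery itself is delegated to external tools).  A window
hits when its relative score — (s - s_min) / (s_max - s_min), with
s_min/s_max the sums of per-column minima/maxima — reaches `min_frac`
(default 0.70, the "70% identity" convention).  Windows containing N are
skipped; a degenerate matrix with s_max = s_min hits everywhere (the
relative score is taken as 1).  Sequences are pre-oriented 5'->3' on the
gene strand, so scanning is single-strand.  The frequency profile tiles
-2000..+2000 around the TSS in 50-bp windows (labelled by their 5' edge)
and reports, per window, the fraction of sequences with at least one hit
*starting* there — counting hit-bearing sequences, not hits, because the
quantity of interest is how many promoters carry the motif.  Windows not
fully covered by a sequence are missing for that sequence.
Co-occurrence of a C-skewed and a G-skewed motif in the -200..-1 region
is reported as four fractions (only C, only G, both, neither) summing
to 1.

## The synthetic data generator

The generator emulates a five-species (chimpanzee/macaque/marmoset/
mouse/rat-like), five-tissue (cortex, cerebellum, heart, kidney, liver)
directional RNA-seq comparison with planted ground truth.  Defaults are
the study conditions: 5 species x 5 tissues x 2 replicates, 2000 genes,
15% of genes pancRNA-partnered (the published per-species range is
roughly 10-19%), 8% of the partnered repertoire species-private
(published range roughly 4-10%), negative-binomial dispersion 0.1,
baseline log2 expression uniform on [4, 10], latent pancRNA-mRNA
correlation 0.95, pancRNA at 10% of the partner's expression.

Structure per ortholog group: one baseline expression level and one
tissue program shared by all species (mRNA tissue programs are
conserved, which is what makes mRNA profiles cluster by tissue).
Partnered genes get a restricted program — dominant tissue weight 1,
other tissues 0.05, giving tau near 0.95 — and their pancRNA follows the
same program with latent log-scale correlation 0.95 at 10% expression.
Species-specific gain is modelled as promoter activation in one species
only: the pancRNA exists (and the mRNA becomes tissue-restricted) in the
gained species and is absent in the others, matching an expression-level
rather than sequence-level definition of gain.  Most lacking genes have
no pancRNA at all; a small planted subset (1% of lacking genes, a
*group-level* property shared by orthologs, reflecting the view that
antisense propensity is a promoter-sequence property) carries flat,
uncorrelated low-level antisense noise.  That fraction is deliberately
small: with only five tissue points, the null distribution of Pearson r
puts ~9% of truly uncorrelated expressed pairs above 0.7, so uncorrelated
antisense is the dominant false-positive channel for both pair
classification and species-specific calling.  Per-sample library
factors are lognormal (sigma = 0.25 log2 units) and planted for
normalization recovery.

Gene layout guarantees non-violating genes a free 2 kb upstream window
and >= 1.5 kb spacing, so they come out CLEAN; a 4% minority of
lacking-category genes is laid out to exercise the filters (parasite
promoters reaching 1 kb into a host gene's body -> CONTAMINATED;
divergent pairs with a 300 bp promoter gap -> one EXCLUDED).  Ortholog
groups are complete except for a configurable drop rate applied to
lacking-category groups only, so planted gains and conserved pairs stay
well-defined.  Sequences are uniform-random ACGT with C- or G-skewed
width-16 motif instances (rejection-sampled to at least 0.75 relative
score) planted uniformly within -200..-1 of partnered promoters at rate
0.6 (both motifs in 16.4% of planted cases) and at rate 0.02 in lacking
promoters.  Conservation is per-base Beta noise with planted means 0.85
(CDS), 0.42 (partnered promoters), 0.35 (lacking promoters) at
concentration 10; infinite concentration gives constant tracks.

What the generator does *not* emulate: splice isoforms, 3'/5' coverage
bias, mappability, GC effects, sequence-level promoter evolution,
realistic genome sizes, or correlated noise between tissues.  Passing
recovery tests therefore shows the pipeline's logic is correct under the
declared statistical model, not that real libraries meet that model.

## Problem sizes used in validation

The recovery experiments run at the default 2000 genes (three
simulations each for classifier and species-specific recovery).  The
segregation property uses 100 simulations of 800 genes with 40% of the
partnered repertoire species-private — the property is stated for
species-private shares of 30% or more, and 800 genes keeps each of the
100 replicates light while leaving hundreds of features per matrix.  The
conservation comparison sizes the simulation so each compared group
holds 1000 genes.  These sizes are the package's validation conditions;
scaling any of them up changes nothing qualitatively.

## Known limitations

* `run_all` currently orchestrates simulated inputs end-to-end; on real
  data the stages are driven individually (CLI subcommands or library
  calls), with the user supplying alignments, orthologs, scores and
  sequences.
* The DEG flag inside DEGES is a rank cut on fold change, not a
  dispersion-aware test; with fewer than two tissues it degenerates to
  plain TMM.
* The Steel-Dwass implementation uses the asymptotic studentized-range
  reference, adequate for the group sizes used here (hundreds to
  thousands) but approximate for very small groups.
* Pearson classification at five tissue points is intrinsically noisy
  (see the null-distribution remark above); this mirrors the analysed
  design rather than a removable implementation choice.
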