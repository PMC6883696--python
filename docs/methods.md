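# Methods

This note documents the statistical models, the conventions chosen where
the design was genuinely open, the synthetic-data generator that the test
suite runs against, and the known limitations.

## Variant geometry

Inputs use the standard 1-based inclusive conventions (VCF, GTF/GFF3);
internally every interval is 0-based half-open, and outputs revert to
1-based. Intron positions are numbered without a position 0: +1 is the
first intronic base after a donor junction and −1 the last before an
acceptor junction, in transcript orientation, so donor distance plus
|acceptor distance| equals intron length + 1. A variant is *on-ss* iff its
donor distance is in +1..+7 or its acceptor distance in −13..−1; the
splice-site windows are therefore 7 and 13 intronic bases, and variants on
an exon boundary base are exonic and excluded. When several transcripts
host a variant, the reported context minimises the junction distance, with
ties broken by longest CDS and then lexicographic transcript id — an
arbitrary but deterministic rule, needed because multi-transcript genes
can legitimately disagree.

## Junction scores

Donor and acceptor PWMs are tallied from annotated internal introns at
run time (strand-aware; junctions shared between transcripts counted
once). The scored windows are −3..+7 around donors (3 exonic + 7 intronic
bases) and −13..+1 around acceptors (13 intronic + 1 exonic); with no
position 0 these are 10- and 14-base windows. Window bounds are module
constants rather than data, because the standard splice-site windows are a
fixed convention of the field.

Scoring uses the same pseudo-counted log2-odds as RBP motifs,
`s_ij = log2(((n_ij + √N)/(N + 4√N))/0.25)`, summed over the window. We
read "information content of a position" in the operational sense of the
log-odds contribution of the observed base — a per-column Shannon
information would be sequence-independent and could not produce
allele-specific scores. The allele-induced score change is defined only
for on-ss variants (the variant must lie inside a scored window); both
the donor and the acceptor scores of the nearest exon are emitted as
features, so exon-level splice strength is visible in both directions.

## RBP binding change (M) and switch probability (P)

For a motif of length k, matching scores of the reference and alternative
local sequences are the maxima over the k windows covering the variant,
maximised independently per allele (best-binding-site convention; a
shared-window variant selected on the reference allele is available via
`RbpScorer(window="best_of_ref")`). Score distributions under the binding
background (pseudo-counted PWM frequencies) and the non-binding background
(uniform 0.25) are Gaussian with moments

    M_p = Σ_ij f_ij s_ij
    V_p = Σ_ij ( f_ij s_ij² − (f_ij s_ij)² )

The variance is implemented cell-wise exactly as written above, which is
the source formulation of this statistic; it differs from the variance of
the score sum under independent per-position draws (available via
`variance="per_position"`). Consequently only the *mean* is asserted
against sampling in the tests.

Ω(S) = Φ(S,B)/(1 − Φ(S,NB)) is evaluated in log space with
`logcdf`/`logsf` (the naive ratio overflows for strong motifs) and floored
at 1e−300; M = log2 Ω(S_alt) − log2 Ω(S_ref) is computed directly from
the log quantities, which makes allele antisymmetry exact in floating
point.

P(Switch) integrates the closed-form conditional

    P(Switch|x) = x(1−x)[Φ_R^B Φ_A^NB + Φ_R^NB Φ_A^B] /
                  ([xΦ_R^B + (1−x)Φ_R^NB][xΦ_A^B + (1−x)Φ_A^NB])

over a Beta(α, β) prior on the binding base rate x, by adaptive quadrature
to absolute tolerance 1e−6 (fixed-grid Simpson fallback on
non-convergence). The prior solves three constraints: α, β > 1; mode
(α−1)/(α+β−2) = 1/2^IC; CDF(mode/10) = 0.005. Eliminating β through the
mode identity leaves a 1-D root-finding problem in α. Along this curve
the tail CDF rises to a single maximum (≈0.0088 as IC grows) and then
decreases monotonically; the solver brackets the decreasing branch
(coarse log-spaced scan for the maximum, then Brent's method), where the
root is unique for every IC in at least 1..20. The motif information
content uses pseudo-counted binding frequencies (Σ_i [2 + Σ_j f log2 f]),
which keeps IC finite for degenerate columns. RNA alphabets (U) are
transliterated to DNA on load; minus-strand variants are scored in
transcript orientation. Motif files lacking the number of source sites
default to N = 100 (configurable) — N only enters through the √N
pseudo-count, so the scores are insensitive to its exact value.

## Protein-structure and conservation features

An exon maps to the residues with ≥1 encoding nucleotide inside it, so a
split codon belongs to both flanking exons. Eight features summarise the
segment: mean disorder; longest run of residues with disorder < 0.5 (the
"structured" threshold, configurable — the cutoff at 0.5 is the usual
binary disorder call); helix/sheet/coil fractions (8-state inputs are
collapsed by the standard DSSP reduction); mean ASA (unit-agnostic
passthrough, absolute or relative as supplied); percent residues inside
any domain; PTM sites per 100 residues. Missing tracks yield *absent*
features, never zeros — zero disorder is a strong structural statement.

Conservation features are the locus score and means over locus-centred
windows of 7 and 15 bases (3-bp and 7-bp flanks, locus included by
default; `include_locus=False` gives the locus-exclusive reading).
Windows truncate at contig edges and missing bases are ignored; a fully
missing window is absent. Tracks are read from bedGraph or wiggle text
(bigWig when pyBigWig is importable), keeping the test fixtures
plain-text.

## Datasets, screening and the classifier

Neutral variants must have MAF strictly greater than 0.10. Off-ss
neutrals are subsampled without replacement to match the pathogenic
distance-to-junction histogram in 10-bp bins (bin width configurable),
capped at per-bin availability with a warning; this removes the gross
distance confound between the classes. The train/validation split is
2/3–1/3, stratified by label, from a seeded RNG.

Feature screening is a two-sided Wilcoxon rank-sum test per feature
(exact enumeration for small samples without ties, normal approximation
otherwise), Benjamini–Hochberg adjusted across features, with delta
medians (pathogenic minus neutral) min-max rescaled to [−1, 1] across
features; constant features are flagged with p = 1.

`FprCalibratedForest` follows the scikit-learn estimator contract.
Hyperparameters (trees ∈ {25,…,200} step 25; depth ∈ {5,…,25} step 5) are
selected by 3-fold stratified CV on mean AUROC with ties broken toward
fewer trees, then shallower depth — an explicit loop rather than
`GridSearchCV` so the tie-break order is under our control. Missing
values are imputed with training-set medians, and one absence-indicator
column per feature family (splicing / structural / conservation) records
what was imputed. Separate estimators are trained for on-ss and off-ss
variants; applying one to the other's variants is a hard error.
Calibration stores the sorted predicted probabilities of validation-set
neutrals; the FPR of a probability p is the fraction of those neutrals
scoring ≥ p (a conservative, monotone step lookup), and categories are
Damaging (FPR < 0.05), Possibly Damaging (< 0.1), Benign (≥ 0.1).
Evaluation reports AUROC, step-interpolated AUPR (average precision) and
MCC at probability 0.5.

## Reporter-count interaction model

Counts per (replicate, allele, splice class) are modelled as negative
binomial (NB2, Var = μ + αμ²) with log mean
β0 + β1·allele + β2·splice + β3·allele:splice + u_rep, u_rep ~ N(0, σ²).
The replicate random intercept is integrated out with 25-node
Gauss–Hermite quadrature and (β, log α, log σ) maximised by L-BFGS-B,
started from cell-mean log ratios. The Wald covariance comes from a
central-difference Hessian. Because ML underestimates the variance
parameters at a handful of replicates, standard errors are inflated by
√(n/(n−p)) (p counting all six parameters) and the interaction is tested
against a between-within t reference with df = n − 4 − (replicates − 1);
under the generator's null this test rejects at ≈3–8% at nominal 5%,
where the uncorrected z-test rejected at 15%. If the random-intercept
variance collapses (σ̂ below 1e−3) the model falls back to an NB GLM with
replicate fixed effects (Poisson GLM in the equidispersed limit where the
NB optimiser stalls at the α→0 boundary); fallbacks are recorded per
result. Fewer than two replicates or a missing allele×class cell is an
error; an all-zero cell adds 0.5 continuity counts, flagged. The count
table is canonicalised (sorted) before fitting, so results are exactly
invariant to row order.

The per-assay effect summary is the pooled log2 odds ratio
log2[(ref spliced/ref aberrant)/(alt spliced/alt aberrant)] with +0.5
continuity when any pooled cell is zero; its sign agrees with β3 (both
measure the aberrant shift under the alternative allele). Experiment
summaries apply BH-FDR within each cell line, call significance at
FDR ≤ 0.1 (configurable), report the validation rate
(significant/evaluable) and pairwise Pearson correlations of log2 odds
ratios between cell lines on jointly evaluable assays.

Read classification for raw reporter reads replaces spliced alignment
with direct reference matching — appropriate because the constructs are
~113 bp with known spliced and unspliced sequences: a 6-nt sample barcode
is matched exactly, then the read body is assigned to the closest
construct reference by edit distance within a configurable budget
(default 2); everything else is counted as discarded.

## Synthetic data: what it emulates and what it does not

The generator produces a single contig of multi-exon genes on both
strands. Exons are 90 bp (a codon multiple; every exon coding), introns
140 bp, all starting GT and ending AG inside consensus-profiled splice
windows (donor MAG|GTAAGT-like, acceptor polypyrimidine + AG|G).
Pathogenic variants (1000 by default, half on-ss) disrupt splice windows
or planted RBP motif consensus sites; neutral variants (1000) are placed
uniformly in introns with MAF drawn so that a configurable fraction
(default 25%) fails the 10% filter. Off-ss pathogenic distances decay
exponentially from the junction (scale 25 bp), so distance matching has
real work to do. Conservation is N(0, 0.7) background with N(2.5, 0.5)
in a ±7 bp halo around pathogenic loci; neutral variants are never placed
inside such a halo, reflecting the depletion of common variants from
conserved elements (without this exclusion the planted truth leaks across
labels and the task becomes artificially ambiguous rather than
realistically hard). Exons nearest to pathogenic variants get low
disorder, low ASA, helix/sheet-rich structure, a covering domain and a
couple of PTMs. Reporter counts are drawn from exactly the NB
random-intercept model above (5 replicates, mean depth 100, dispersion
0.1, intercept SD 0.3); the calibration studies use equal cell means of
~100, the bundle default keeps a realistic spliced:aberrant imbalance
(log ratio −1).

Every output file has its own RNG stream derived from the master seed via
CRC-32 of the stream name, so regeneration of any single artifact is
byte-identical and independent of generation order.

What passing on these fixtures shows: the feature mathematics, the
plumbing between formats, the calibration machinery and the mixed model
behave correctly when their modelled signals are present. What it cannot
show: performance on real genomes, where effects are weaker and
correlated, conservation is not conditionally independent of class,
splice-site usage is context-dependent, and label noise is substantial.
Held-out AUROC near 1.0 on the bundle is a property of the planted effect
sizes, not a performance claim for real data.

## Problem sizes and numerical conventions

The default test suite and the acceptance script run the full bundle at
1000+1000 variants with 8 RBP motifs, the null calibration at 200
simulated assays and the power/bias study at 500 — sizes chosen so a
complete run stays within a few minutes on one CPU while keeping the
Monte-Carlo error of the measured rates small. Switch-probability
quadrature tolerance is 1e−6; the beta-prior root is solved to ~1e−12;
Ω underflow floors at 1e−300; degenerate zero-variance Gaussians use a
step-function Φ with Φ = 0.5 at the mean. Forests, splits and all
simulations take explicit seeds and are reproducible bit-for-bit.

## Limitations

- The feature registry is configuration-driven; the exact historical
  inventory of several hundred RBP-feature columns depends on which motif
  collection is supplied.
- No branch-point or higher-order (maximum-entropy) splice models; no RNA
  secondary-structure accessibility for RBP binding.
- The mixed model treats "aberrant" as one class; partially spliced
  isoforms are not modelled separately.
- MCC is thresholded at probability 0.5, not at an FPR cutpoint; both
  conventions exist and the threshold is an argument.
- The small-sample correction for the interaction test is a convention,
  not an exact theory; its measured null rejection on the generator's
  conditions is ≈3–8% at nominal 5%.
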