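# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic-data generator's assumptions, and the numerical and
design choices that were genuinely open.

## Differential expression

**Model.** Counts for feature *i*, sample *j* are modelled
NB(μ_ij, α_i) with Var = μ + αμ² and

    log μ_ij = log s_j + β0 + β_L·[group_j = L] + β_sex·[sex_j = M] + Σ_b β_b·[batch_j = b]

where s_j is the sample's size factor. The H group is the reference, so
β_L > 0 (log2FC > 0) means higher expression in L. The group coefficient is
tested with a two-sided Wald z = β̂_L / se(β̂_L) against the standard
normal; p-values are BH-adjusted within each layer (mRNAs and miRNAs are
analysed separately). A feature is called DE when p_adj < α (default 0.05)
and |log2FC| exceeds log2 of the layer's linear fold-change threshold —
1.5 for mRNAs, 1.2 for miRNAs. The fold-change cut is interpreted on the
linear scale (|log2FC| > log2 1.5 ≈ 0.585); threshold comparisons are
strict throughout.

**Filtering.** Features with total count ≤ 20 across all samples are
removed before normalization and testing (strictly-greater-than-20 kept).

**Size factors.** Median-of-ratios: for each feature positive in every
sample, the per-sample ratio to the feature's geometric mean; the
per-sample median of those ratios. The ratio definition leaves a global
scale free; it is fixed by normalizing the factors to geometric mean 1.

**Dispersion.** Per-feature method-of-moments on normalized counts,
α̂ = max(1e−8, (s² − m̄)/m̄²). No empirical-Bayes shrinkage is applied: the
package's accuracy claims rest on calibration and recovery studies against
simulated truth, not on value-matching any particular shrinkage estimator.
At the design's sample size (10 + 10) the plug-in Wald test is close to
nominal: under a global simulated null the raw type-I rate at p < 0.05 is
≈ 0.044 (the acceptance script recomputes this).

**Degenerate features.** A non-converged GLM fit is reported with
p_value = 1 and `converged = False` rather than dropped. A feature with all
zeros in one group has an unbounded coefficient; its fold change is
reported from pseudo-counted group means, log2((mean_L + 0.5)/(mean_H + 0.5)),
without altering the test outcome.

## Co-expression and PCIT

Correlation is computed on log2(count/size-factor + 1), a variance-
stabilising transform that is invariant to rescaling counts and factors
together. Constant features are dropped with a warning; fewer than 3
samples is an error.

The PCIT filter sweeps every unordered trio (x, y, z). The three
first-order partial correlations

    r_xy.z = (r_xy − r_xz r_yz) / √((1 − r_xz²)(1 − r_yz²))   (and rotations)

define the tolerance ε̄ = mean of |partial/raw| over the trio's edges, and
edge (x, y) is knocked out when |r_xy| < |ε̄·r_xz| and |r_xy| < |ε̄·r_yz|.
An edge is significant iff no trio knocks it out. The full O(n³) sweep is
always performed (one vectorised pass per conditioning node), so the result
does not depend on node order.

Numerical guards: a ratio whose raw correlation is exactly 0, or whose
partial denominator is ≤ 1e−12 (legs at ±1), is excluded from ε̄'s average;
a trio with no valid ratio is skipped entirely. Skipping keeps edges — the
conservative direction. Knockout comparisons are strict, so a perfectly
symmetric trio (all ratios equal) keeps all edges deterministically.

One behaviour worth knowing: when r_xy exactly equals r_xz·r_yz (pure
common-driver structure) the x–y partial is 0, which pulls ε̄ down far
enough that even the fully-explained direct edge survives. Knockouts occur
when the direct edge is *weak relative to* ε̄-scaled legs, e.g.
r_xy = 0.2 with legs 0.9/0.3. Both behaviours are frozen as regression
tests against a straight-from-definition triple-loop oracle.

In pipeline use PCIT runs once on the joint expression matrix of DE mRNAs
plus DE miRNAs (PCIT is defined on one full correlation matrix, not
per-pair). The co-expression count without the PCIT requirement is
available through `require_pcit=False` / `--no-pcit`, since a
threshold-only reading of the workflow is also defensible.

## Seed matching

The 7mer-m8 site is the reverse complement of mature miRNA nucleotides 2–8
(1-based), U→T. Scanning is exact substring search on the UTR sense strand
only; overlapping occurrences all count; `N` never matches; sequences are
uppercased and U→T-normalized on load. UTR isoforms (`GENE.1`, `GENE.2`)
pool to the parent gene: a gene is targeted if any isoform matches, and its
offsets are the sorted union over isoforms. Gene-level targeting is binary
(≥ 1 site), which makes the overlap-counting question immaterial for the
summary table. No G:U wobble, no mismatches, no 6mer/8mer classes, no
thermodynamic scoring. Percentages in the targeting summary are rounded
half-up to 2 decimals.

## Network assembly

miRNA→mRNA edges are the conjunction of four conditions: miRNA DE (its
layer's thresholds), gene DE, r < −0.50, PCIT-significant, and ≥ 1 seed
site; mRNA–mRNA edges connect targeted genes to other DE genes at
|r| > 0.7 plus PCIT, stored undirected with lexicographic endpoints. The
asymmetric thresholds reflect that mRNA–mRNA expression correlations
typically run larger in magnitude than miRNA–mRNA ones. All thresholds are
strict; lowering r_max or raising the |r| floor can only remove edges
(tested). Both subnetworks are emitted in one TSV with an `edge_type`
column, ordered deterministically (edge_type, source, target; r printed to
6 decimals) so identical inputs give byte-identical files.

## Enrichment

For a term annotating K genes of the N-gene universe, with k of the n
selected genes annotated, p = P(X ≥ k) under Hypergeometric(N, K, n),
BH-corrected across tested terms. The universe is the expressed-gene set
after the count filter, not the whole annotation — the standard choice for
expression studies. Terms with K < 3 in the universe are skipped as
degenerate. The implementation (scipy's survival function) is cross-checked
in tests against exact combinatorial enumeration.

## Synthetic-data generator

**What it emulates.** A 20-sample two-group design (10 H + 10 L), sex
alternating sample-by-sample and two batches alternating pair-by-pair
within each group — balanced, and neither covariate confounded with group
or with the other. Counts are NB with a single run-level dispersion
(default α = 0.05) around per-sample means assembled on the log2 scale
from: a feature baseline (uniform in (3, 9) log2 units), the planted group
effect, N(0, 0.1) sex and batch effects, and a per-sample library size
factor (uniform in (0.7, 1.4) — library-size variation is exposed as
config because it is design-dependent).

**Planted effects.** `n_de_mrna`/`n_de_mirna` features receive signed
log2 effects with magnitudes uniform in `de_log2fc_range`; the default
(0.2, 2.0) deliberately straddles the 1.5/1.2 calling thresholds so that
threshold behaviour is exercised. Each planted DE miRNA represses
`n_targets_per_de_mirna` genes drawn from the planted DE mRNAs (disjoint
while capacity allows). Repression enters through a shared latent: the
regulator's per-sample log2 abundance (group/sex/batch effects plus
N(0, 0.4) latent noise) is standardised and added to each target as
−strength × 2.0 log2-units × latent. Two consequences are intentional: the
target inherits an anti-correlated group response (its planted effect sign
is set opposite the regulator's, as repression implies), and targets of a
regulator are negatively correlated with it *within* groups as well. The
latent noise sd of 0.4 keeps a planted miRNA's own group effect detectable
at the design's sample size while still carrying the coupling.

**Sequences.** Mature miRNAs are 22-nt RNA (ACGU) with pairwise-distinct
seeds; UTRs are DNA (ACGT) — the alphabet split forces the pipeline's U→T
normalization to be exercised. Every UTR is rejection-sampled (up to 1000
attempts, then a loud error naming the site and length) to contain no
simulated miRNA's seed site; sites are then planted only at recorded
offsets in true-target UTRs, and the result is re-scanned to confirm
nothing uninvited appeared. Non-target genes are therefore clean negative
controls against the *entire* simulated miRNA panel, not just the planted
regulators — a deliberate strengthening, since a miRNA falsely called DE
by the multiple-testing procedure would otherwise carry chance seed
matches and contaminate precision measurements.

**Annotation.** 25 terms of 10–30 genes; the first 3 are planted enriched
by drawing ~70% of members from the planted DE genes, the rest uniformly.

**What it does not emulate.** Read-level artifacts (FASTQ, alignment, GC
bias), isoform structure, correlated baseline programs between genes
(co-expression beyond the planted couplings), empirical mean–dispersion
trends, or miRNA families with shared seeds. Passing recovery tests
therefore shows the pipeline is correct and well-calibrated under its own
model family — not that its thresholds are optimal for any real tissue.

## Problem sizes and evaluation studies

The evaluation module runs two standing studies, sized for desk-scale
reproduction: null calibration (20 replicates × 200 features × 10+10
samples, nothing planted; reports the pooled raw-p and BH positive rates)
and edge recovery (10 seeds of 200 genes/20 miRNAs with 3 regulators × 5
targets at |log2FC| = 2, repression 0.9; reports pooled precision and
recall of planted miRNA→target edges). At these settings precision is 1.0
by construction of the clean negative controls, and recall is limited only
by DE detection (≈ 0.97–1.0 across seed sets).

## Known limitations

- The Wald test with plug-in method-of-moments dispersion is slightly
  liberal at very small sample sizes and has no shrinkage across features;
  results will not numerically match shrinkage-based DE tools, by design.
- PCIT is O(n³) time with an O(n²) working set per conditioning node; it is
  intended for node sets of DE features (hundreds), not whole
  transcriptomes.
- Exact seed matching ignores wobble pairing, site context and conservation;
  it reproduces the interrogation step of the workflow, not a full target
  predictor.
- The pipeline treats the two layers' libraries as independently normalized;
  no cross-layer normalization is attempted.
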