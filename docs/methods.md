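# Methods

## The splicing ratio

The alternative splicing ratio treats a genome's annotation as a map from
genomic positions to the set of isoform coding sequences (CDSs) that
contain them. Writing *f(i, j)* for the number of CDSs containing both
positions *i* and *j*, the co-occurrence matrix *M* (*M<sub>ij</sub> =
f(i, j)*) and its binarization *A* give

ρ = tr(*M*) / tr(*A*),

the average number of isoforms a coding nucleotide participates in. Both
traces have closed forms that avoid the matrix entirely:

* tr(*M*) = Σ over isoforms of the isoform's CDS length (each isoform's
  segments are merged first, so a position claimed twice by one isoform —
  which a well-formed annotation should not contain — counts once);
* tr(*A*) = length of the union of all CDS intervals (the projection of
  coding DNA onto the genome).

The implementation computes both as exact integers and returns a reduced
`fractions.Fraction`, so ρ carries no floating-point accumulation error
and equality tests (ρ = 1 exactly in the single-isoform limit) are
meaningful. The dense matrix is retained as a brute-force oracle
(`build_transcription_matrix`), refused above a configurable position
budget because it is O(L²); the test suite asserts exact equality between
the two routes on randomized annotations.

**Strand handling.** Coding and gene unions are positional — computed per
(sequence, position) ignoring strand — so antisense-overlapping CDSs
share positions. A `per_strand` switch computes unions per (sequence,
strand) instead. Overlap of this kind is rare in real annotations; both
conventions are exposed because the choice is not forced by the metric's
definition.

**Gene content** is the union of retained gene spans, not their sum, so
overlapping genes are not double-counted; coding content ≤ gene content ≤
genome size holds by construction in the default (positional) mode.

## Annotation input and filters

GFF3 rows are parsed with `gffutils` (attribute percent-decoding
included); the gene → mRNA → CDS hierarchy is resolved from `ID`/`Parent`
links in a second pass, so feature order in the file is irrelevant.
Filters, each tallied and logged:

* **Pseudogenes** (feature type `pseudogene` or `pseudo=true`) are
  excluded together with their children.
* **Duplicated genes** — two or more gene records sharing one gene
  identity (`Dbxref=GeneID:`, falling back to `gene`/`Name`/`ID`) — are
  all excluded by default; a `keep-first` policy is available. The
  conservative default reflects that a duplicated identity leaves it
  ambiguous which record carries the real isoform complement.
* **Orphan CDSs** (`Parent` absent from the file) are dropped and
  counted; CDSs under deliberately ignored feature types (non-mRNA
  transcripts, by default) are dropped silently since their exclusion is
  a policy, not a data defect.
* **Isoforms spanning multiple sequences** are excluded (the genome
  projection is per-sequence).
* **Genes left without a valid coding isoform** are excluded (`no_cds`).

Only `mRNA`-typed transcripts contribute isoforms by default
(configurable allowlist): the ratio counts protein-isoform CDS reuse.
CDS nucleotide counting ignores frame/phase; annotated stop codons inside
CDS features count.

Genome size is resolved per sequence with precedence
`##sequence-region` pragma → `region` feature span → maximum feature end
(with a warning, since that is only a lower bound). Coordinates are
converted to 0-based half-open form internally and all reported lengths
are end − start + 1 in GFF3 terms.

## Support-bias normalization (ASR\*)

Isoform counts in public annotations scale with the experimental evidence
available to the annotation pipeline. The correction fits, across
species, a polynomial least-squares trend f̂ of ASR on the fraction of
fully supported CDSs (optionally all three support fractions as additive
polynomial terms) and subtracts it, re-centering at a reference covariate
value c\*:

ASR\* = ASR − f̂(c) + f̂(c\*),  c\* = cohort mean by default.

Properties enforced by tests: exact identity at the reference, exact
rank/spacing preservation within equal-covariate strata, degree 0 is a
no-op, and on cohorts where ASR varies only through the covariate the
corrected values are uncorrelated with it. The degree defaults to 2 and
may be selected by minimum AIC over degrees 1–4; saturated
(interpolating) fits are permitted at n = degree + 1. Support fractions
arrive as a TSV side table; the package does not re-derive them from raw
RNA-Seq. Corrected values are standardized estimates for comparability,
not absolute measurements.

## Group comparisons

Pairwise group differences are tested with Monte Carlo permutation tests
on the mean and on the median: group labels are shuffled (10,000
permutations by default) and the empirical p-value is the plain
proportion of shuffles with |statistic difference| ≥ the observed one.
The two-sided (absolute-difference) form is the default because the
cross-taxa comparisons are direction-agnostic; a one-sided switch and a
(k+1)/(n+1) correction are available. An exhaustive mode enumerates all
label assignments for small groups and anchors the Monte Carlo mode in
tests. Batteries of pairwise tests are Bonferroni-corrected. Welch's
t-test (and a k-group Welch ANOVA omnibus, cross-checked against
`pingouin`) covers the parametric route; for zero variance in both groups
the test returns t = 0, p = 1 at equal means and raises otherwise.

Relative variability uses the coefficient of variation (sample sd over
sample mean; exactly 0 for a constant vector) and the ratio
CV<sub>x</sub>/CV<sub>y</sub>. Summary tables report mean, 5th/95th
percentiles (linear interpolation between order statistics — ranges
depend on this choice, so it is fixed and documented) and sample sd,
with singleton groups flagged and reported as sd 0.

## PGLS with Pagel's λ

The tip covariance under Brownian motion is C<sub>ij</sub> = shared
root-to-MRCA branch length (C<sub>ii</sub> = root-to-tip length); Pagel's
λ multiplies the off-diagonal entries. λ is estimated by maximum
likelihood (profile over the GLS fit, σ² concentrated out) with a bounded
scalar search on [0, 1] at tolerance 1e-6; both endpoints are evaluated
explicitly so boundary optima are returned exactly. The slope's p-value
comes from its t statistic with n − 2 degrees of freedom; adjusted R² is
computed against the intercept-only GLS model under the same fitted
covariance. Fits are invariant to rescaling all branch lengths and to tip
order; λ = 0 on an ultrametric tree reproduces OLS to machine precision
(tested at 1e-8). Species present in the trait table but absent from the
tree are dropped with a logged count; non-ultrametric trees are accepted
unchanged. Measurement error in traits is not modeled.

## Synthetic data

Generators compute their ground truths during construction — from the
exon layout, the drawn group means, or the simulating covariance — never
by running the analysis pipeline, so they serve as independent oracles.

* **Random annotations**: genes laid left-to-right on one scaffold with
  intergenic gaps; each gene is a chain of exons with intron gaps; each
  isoform keeps each exon with probability 0.6 by default (1.0 forces
  full reuse, giving ASR = number of isoforms per gene). Defaults
  (1–4 isoforms and 1–6 exons per gene, exons 10–300 nt, introns
  10–500 nt, intergenic 50–2000 nt) give compact gene-dense toy genomes —
  deliberately small so the quadratic matrix oracle stays cheap. Switches
  inject pseudogenes and orphan CDSs for filter testing. The generator
  does not emulate UTRs, overlapping or nested genes, trans-splicing, or
  realistic length distributions; passing tests demonstrate correctness
  of the computation on well-formed hierarchies, not robustness to every
  pathology of real RefSeq files (the filter tests cover the specific
  defect classes the pipeline claims to handle).
* **Group tables**: Gaussian draws per group with stated n, mean, sd —
  matching the study design of ~20+ species per compared taxon; used for
  calibration (type-I error within the 95% binomial band around 5% at
  n = 30/group) and power checks.
* **Trees and traits**: Yule (pure-birth) trees via dendropy; the
  sampler's zero-length terminal sister branches (an artifact of stopping
  at the target tip count) are padded by a constant 10% of tree depth on
  every terminal edge, preserving ultrametricity while keeping the λ = 1
  covariance non-singular. x is Brownian on the tree; y = βx + ε with
  ε ~ N(0, σ²C(λ)).

## Problem sizes in the checks

The oracle-equivalence suite uses ~100 annotations of 1–4 genes with
≤ 200 gene positions (the dense matrix is quadratic); permutation
calibration uses 500 replicates of n = 30 per group at 2,000
permutations, with the 10,000-vs-20,000-permutation stability check run
on 20 seeds (the longer run extends the shorter run's permutation
stream, which is what increasing the permutation count means
operationally); PGLS recovery uses 100 replicates of 64-tip trees with
β = 0.5, λ = 1, σ = 1. These sizes make every distributional claim
testable in seconds while keeping the binomial acceptance bands
meaningful.

## Known limitations

* Duplicate-gene detection relies on the `GeneID`/`gene` attribute; files
  lacking any identity attribute fall back to record `ID`s and cannot
  detect cross-record duplication.
* The support-bias correction is additive in ASR; a multiplicative bias
  would be mis-specified (degree > 1 absorbs mild curvature).
* PGLS supports a single predictor with intercept, matching the reported
  bivariate fits; no multiple regression or measurement-error model.
* GTF input is out of scope; convert to GFF3 first.
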