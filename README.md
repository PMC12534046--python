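# spliceratio

Genome-scale quantification of alternative splicing from GFF3 genome
annotations.

Alternative splicing lets one gene produce several mRNA isoforms by
combining exons and introns differently, but there has been no standard
way to compare splicing activity between distantly related species.
`spliceratio` computes the **alternative splicing ratio (ASR)** — a single
number per genome that measures how intensively coding DNA is reused
across isoforms — directly from the gene → mRNA → CDS hierarchy of a
standard annotation file, plus the statistics needed to compare it across
taxa: an annotation-support bias correction (ASR\*), Monte Carlo
permutation tests, coefficient-of-variation ratios, and phylogenetic
generalized least squares (PGLS) with Pagel's λ.

## The metric

For genomic positions *i*, *j* inside genes, let *f(i, j)* be the number
of CDSs (isoform coding sequences) containing both nucleotides. The
symmetric matrix *M* with *M<sub>ij</sub> = f(i, j)* encodes nucleotide
co-occurrence across isoforms, and *A* is its binarization
(*A<sub>ij</sub> = 1* iff *M<sub>ij</sub> > 0*). The ASR is the trace
ratio

&nbsp;&nbsp;&nbsp;&nbsp;ρ = tr(*M*) / tr(*A*)

— equivalently, the total number of coding nucleotides summed over all
isoforms divided by the number of genomic positions covered by at least
one CDS. ρ = 1 means no coding nucleotide is reused by a second isoform;
ρ = 2 means the average coding position appears in two isoforms. The
package never materializes *M* for real genomes (it is quadratic in gene
length); the production path evaluates both traces with exact integer
interval arithmetic, and the dense matrix survives as a small-instance
test oracle.

Because isoform counts in public annotations depend on how much
experimental evidence backed the annotation run, the package also fits a
cross-species polynomial trend of ASR on the fraction of fully supported
CDSs and removes it additively (re-centered at the cohort mean), giving
the normalized ASR\* used for fair cross-taxon comparison.

## Worked example

A 33 nt gene with three isoforms — CDS segments `[1,9]+[27,33]` (16 nt),
`[5,13]` (9 nt) and `[1,13]+[22,27]` (19 nt) — has a coding union of
25 nt, so ρ = (16 + 9 + 19) / 25 = 44/25 = 1.76:

```python
>>> from spliceratio import load_annotation, make_worked_example, asr_genomewide
>>> ann = load_annotation(make_worked_example())
>>> asr_genomewide(ann)
Fraction(44, 25)
>>> float(asr_genomewide(ann))
1.76
```

The same computation from the shell:

```sh
$ spliceratio synth --preset worked-example --out example.gff3
wrote example.gff3 (worked example, true ASR 1.76)
$ spliceratio compute example.gff3 --out profile.tsv
wrote profile.tsv (1 species)
```

`profile.tsv` then contains one row per species with the genome size
(33), gene content (33 nt of the genome covered by gene spans), coding
content (25 nt covered by at least one CDS), the three composition
percentages (here gene/genome = 100.0, coding/gene ≈ 75.76), isoform and
gene counts, and `asr` = 1.76.

The other subcommands cover the rest of a comparative analysis:

```sh
spliceratio normalize profile.tsv support.tsv --degree 2 --out profile_star.tsv
spliceratio compare profile_star.tsv --groups groups.tsv --n-perm 10000 --seed 42 --out comparisons.tsv
spliceratio pgls profile_star.tsv tree.nwk --x coding_over_gene --y asr_star --out pgls.tsv
```

`support.tsv` holds per-species fractions of fully supported / known /
model-derived CDSs, `groups.tsv` maps species to taxonomic groups, and
`tree.nwk` is a Newick phylogeny whose tip labels match the species ids
(species absent from the tree are dropped with a logged count).

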