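"""Synthetic data generators with construction-time ground truth.

Every generator records the quantity of interest *while building* the
data — isoform CDS totals, coding unions, group effect sizes, simulated
slopes and phylogenetic signal — using its own bookkeeping rather than
the analysis pipeline, so generated fixtures double as independent
oracles for the pipeline.

Includes the worked single-gene example used throughout the docs: a 33 nt
scaffold carrying one gene with three isoforms of 16, 9 and 19 coding
nucleotides over a coding union of 25, hence ASR = 44/25 = 1.76.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .phylo import phylo_covariance


# -- the worked single-gene example -----------------------------------------

def make_worked_example() -> str:
    """One 33 nt scaffold, one gene, three isoforms; ASR = 44/25 = 1.76.

    CDS segments (1-based inclusive): isoform A = [1, 9] + [27, 33]
    (16 nt); isoform B = [5, 13] (9 nt); isoform C = [1, 13] + [22, 27]
    (19 nt).  The coding union is [1, 13] + [22, 33] = 25 nt.
    """
    rows = [
        "##gff-version 3",
        "##sequence-region chr1 1 33",
        "chr1\tsynthetic\tregion\t1\t33\t.\t+\t.\tID=chr1",
        "chr1\tsynthetic\tgene\t1\t33\t.\t+\t.\tID=gene1;Dbxref=GeneID:1",
        "chr1\tsynthetic\tmRNA\t1\t33\t.\t+\t.\tID=mrna1;Parent=gene1",
        "chr1\tsynthetic\tCDS\t1\t9\t.\t+\t0\tID=cds1;Parent=mrna1",
        "chr1\tsynthetic\tCDS\t27\t33\t.\t+\t0\tID=cds1;Parent=mrna1",
        "chr1\tsynthetic\tmRNA\t5\t13\t.\t+\t.\tID=mrna2;Parent=gene1",
        "chr1\tsynthetic\tCDS\t5\t13\t.\t+\t0\tID=cds2;Parent=mrna2",
        "chr1\tsynthetic\tmRNA\t1\t27\t.\t+\t.\tID=mrna3;Parent=gene1",
        "chr1\tsynthetic\tCDS\t1\t13\t.\t+\t0\tID=cds3;Parent=mrna3",
        "chr1\tsynthetic\tCDS\t22\t27\t.\t+\t0\tID=cds3;Parent=mrna3",
    ]
    return "\n".join(rows) + "\n"


# -- random annotations ------------------------------------------------------

@dataclass(frozen=True)
class AnnotationSpec:
    """Parameters of a random multi-isoform annotation.

    Ranges are inclusive (low, high) bounds for uniform integer draws.
    Genes are laid out left to right on one scaffold with intergenic gaps;
    each gene is a chain of candidate exons separated by introns, and each
    isoform selects a non-empty subset of the exons.
    """

    n_genes: int = 10
    isoforms_per_gene: tuple[int, int] = (1, 4)
    exons_per_gene: tuple[int, int] = (1, 6)
    exon_length: tuple[int, int] = (10, 300)
    intron_length: tuple[int, int] = (10, 500)
    intergenic_length: tuple[int, int] = (50, 2000)
    exon_inclusion_prob: float = 0.6  # chance an isoform keeps each exon
    scaffold_length: int | None = None  # derived from content when None
    seed: int = 0
    inject_pseudogenes: int = 0
    inject_orphan_cds: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in (
            "isoforms_per_gene",
            "exons_per_gene",
            "exon_length",
            "intron_length",
            "intergenic_length",
        ):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 < self.exon_inclusion_prob <= 1.0:
            raise ValueError("exon_inclusion_prob must lie in (0, 1]")


@dataclass
class SyntheticAnnotation:
    """A generated GFF3 with its construction-time truths."""

    gff3: str
    true_asr: Fraction
    truth: dict = field(default_factory=dict)


def make_annotation(spec: AnnotationSpec) -> SyntheticAnnotation:
    """Generate a GFF3 annotation and its ground-truth statistics.

    The truths (isoform totals, coding union, gene content) are tallied
    from the exon layout during generation, independently of the parsing
    and interval machinery that will later analyze the file.  Deterministic
    given ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    rows = ["##gff-version 3"]
    body: list[str] = []
    cursor = 1  # next free 1-based position
    numerator = 0
    denominator = 0
    gene_content = 0
    n_isoforms = 0

    for gi in range(1, spec.n_genes + 1):
        cursor += rng.randint(*spec.intergenic_length)
        n_exons = rng.randint(*spec.exons_per_gene)
        exons: list[tuple[int, int]] = []
        pos = cursor
        for k in range(n_exons):
            length = rng.randint(*spec.exon_length)
            exons.append((pos, pos + length - 1))
            pos += length
            if k < n_exons - 1:
                pos += rng.randint(*spec.intron_length)
        gene_start, gene_end = exons[0][0], exons[-1][1]
        cursor = gene_end + 1
        gene_content += gene_end - gene_start + 1

        n_iso = rng.randint(*spec.isoforms_per_gene)
        subsets: list[list[int]] = []
        for _ in range(n_iso):
            mask = [
                rng.random() < spec.exon_inclusion_prob for _ in range(n_exons)
            ]
            if not any(mask):
                mask[rng.randrange(n_exons)] = True
            subsets.append([k for k, m in enumerate(mask) if m])

        used = sorted({k for sub in subsets for k in sub})
        exon_len = [e - s + 1 for s, e in exons]
        denominator += sum(exon_len[k] for k in used)
        for sub in subsets:
            numerator += sum(exon_len[k] for k in sub)
        n_isoforms += n_iso

        body.append(
            f"scaf1\tsynthetic\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\t"
            f"ID=gene{gi};Dbxref=GeneID:{gi}"
        )
        for ii, sub in enumerate(subsets, start=1):
            m_start = exons[sub[0]][0]
            m_end = exons[sub[-1]][1]
            mid = f"mrna{gi}.{ii}"
            body.append(
                f"scaf1\tsynthetic\tmRNA\t{m_start}\t{m_end}\t.\t+\t.\t"
                f"ID={mid};Parent=gene{gi}"
            )
            for k in sub:
                s, e = exons[k]
                body.append(
                    f"scaf1\tsynthetic\tCDS\t{s}\t{e}\t.\t+\t0\t"
                    f"ID=cds{gi}.{ii};Parent={mid}"
                )

    # optional defect injection for filter testing
    for pi in range(1, spec.inject_pseudogenes + 1):
        start = cursor + rng.randint(*spec.intergenic_length)
        end = start + rng.randint(*spec.exon_length) - 1
        cursor = end + 1
        body.append(
            f"scaf1\tsynthetic\tpseudogene\t{start}\t{end}\t.\t+\t.\t"
            f"ID=pseudo{pi};pseudo=true"
        )
        body.append(
            f"scaf1\tsynthetic\tCDS\t{start}\t{end}\t.\t+\t0\t"
            f"ID=cds-pseudo{pi};Parent=pseudo{pi}"
        )
    for oi in range(1, spec.inject_orphan_cds + 1):
        start = cursor + rng.randint(*spec.intergenic_length)
        end = start + rng.randint(*spec.exon_length) - 1
        cursor = end + 1
        body.append(
            f"scaf1\tsynthetic\tCDS\t{start}\t{end}\t.\t+\t0\t"
            f"ID=cds-orphan{oi};Parent=mrna-missing{oi}"
        )

    scaffold = spec.scaffold_length or cursor + rng.randint(
        *spec.intergenic_length
    )
    if scaffold < cursor - 1:
        raise ValueError(
            f"scaffold_length {scaffold} too small for generated features "
            f"(need >= {cursor - 1})"
        )
    rows.append(f"##sequence-region scaf1 1 {scaffold}")
    rows.extend(body)

    truth = {
        "genome_size": scaffold,
        "gene_content": gene_content,
        "coding_content": denominator,
        "numerator": numerator,
        "n_genes": spec.n_genes,
        "n_isoforms": n_isoforms,
    }
    return SyntheticAnnotation(
        gff3="\n".join(rows) + "\n",
        true_asr=Fraction(numerator, denominator),
        truth=truth,
    )


# -- grouped species tables ---------------------------------------------------

def simulate_group_table(
    groups: dict[str, tuple[int, float, float]], seed: int | None = None
) -> pd.DataFrame:
    """Gaussian per-group species values.

    ``groups`` maps a group label to (n, mean, sd).  Returns a frame with
    columns ``species_id``, ``group``, ``value``; deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(groups):
        n, mean, sd = groups[label]
        if n < 2:
            raise ValueError(f"group {label!r}: n must be >= 2")
        if sd < 0:
            raise ValueError(f"group {label!r}: sd must be >= 0")
        values = rng.normal(mean, sd, size=n)
        for i, v in enumerate(values):
            rows.append(
                {"species_id": f"{label}_{i}", "group": label, "value": float(v)}
            )
    return pd.DataFrame(rows)


# -- trees and traits ---------------------------------------------------------

def simulate_tree_traits(
    n_tips: int,
    beta: float,
    lam: float,
    sigma: float = 1.0,
    seed: int | None = None,
) -> tuple[dendropy.Tree, np.ndarray, np.ndarray, list[str]]:
    """Yule tree plus correlated traits with known slope and lambda.

    The predictor x evolves by Brownian motion on the tree (unit rate);
    the response is y = beta * x + eps with eps multivariate normal of
    covariance sigma^2 * C(lambda), C the Brownian tip covariance.
    Terminal branches are extended by a constant (10% of tree depth) so
    the final speciation events do not leave zero-length sister pairs;
    the extension is uniform across tips, so the tree stays ultrametric.

    Returns (tree, x, y, tip_labels) with traits aligned to the labels.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    pad = 0.1 * depth if depth > 0 else 1.0
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + pad

    C1, labels = phylo_covariance(tree, lam=1.0)
    Clam, _ = phylo_covariance(tree, lam=lam)
    L1 = np.linalg.cholesky(C1)
    Ll = np.linalg.cholesky(Clam)
    rng = np.random.default_rng(seed)
    x = L1 @ rng.standard_normal(n_tips)
    eps = sigma * (Ll @ rng.standard_normal(n_tips))
    y = beta * x + eps
    return tree, x, y, labels
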