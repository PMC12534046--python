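"""The alternative splicing ratio (ASR) and genomic-composition variables.

The ASR quantifies how intensively coding DNA is reused across mRNA
isoforms.  Conceptually it is defined through a nucleotide co-occurrence
("transcription") matrix ``M`` over the genomic positions inside genes:
``M[i][j]`` counts the CDSs (isoforms) that contain both positions ``i``
and ``j``, and ``A`` is its binarization.  The ratio

    rho = tr(M) / tr(A)

is the average number of isoforms each coding nucleotide participates in:
``tr(M)`` sums, over isoforms, the number of coding nucleotides each
contains, while ``tr(A)`` is the number of genomic positions covered by at
least one CDS (the projection of coding DNA onto the genome).

The dense matrix is quadratic in gene length and is kept only as a
small-instance oracle (:func:`build_transcription_matrix`); the production
path (:func:`asr_genomewide`) evaluates the two traces directly with
interval arithmetic, in exact integer arithmetic, and returns a reduced
:class:`fractions.Fraction`.  A genome of single-isoform genes with no
shared coding positions has ASR exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .annotation import (
    AnnotationSet,
    cds_intervals,
    gene_span_intervals,
    genome_length,
)
from .errors import OracleSizeError, UndefinedASRError
from .intervals import IntervalSet, interval_union_length  # noqa: F401  (re-export)


@dataclass
class TranscriptionMatrix:
    """Dense nucleotide co-occurrence matrix (oracle for small inputs).

    ``positions`` lists the (seqid, position) pairs inside retained gene
    spans, in genomic order; ``M[i, j]`` counts isoforms containing both
    positions; ``A`` is the binarized matrix.
    """

    positions: list[tuple[str, int]]
    M: np.ndarray
    A: np.ndarray

    @property
    def trace_m(self) -> int:
        return int(np.trace(self.M))

    @property
    def trace_a(self) -> int:
        return int(np.trace(self.A))


def build_transcription_matrix(
    annotation: AnnotationSet, max_positions: int = 2000
) -> TranscriptionMatrix:
    """Materialize the co-occurrence matrix by direct position enumeration.

    Refuses inputs whose gene spans cover more than ``max_positions``
    positions: the construction is O(L^2) and exists to cross-check the
    interval implementation, not to process genomes — use
    :func:`asr_genomewide` for those.
    """
    spans = gene_span_intervals(annotation)
    total = spans.union_length()
    if total > max_positions:
        raise OracleSizeError(
            f"gene spans cover {total} positions > max_positions="
            f"{max_positions}; the dense matrix is an oracle for small "
            "inputs only — use asr_genomewide instead"
        )
    positions: list[tuple[str, int]] = []
    for sid in spans.seqids():
        positions.extend((sid, p) for p in spans.positions(sid))
    index = {pos: k for k, pos in enumerate(positions)}

    n = len(positions)
    M = np.zeros((n, n), dtype=np.int64)
    for gene in annotation.genes:
        for iso in gene.isoforms:
            idx = [
                index[(gene.seqid, p)]
                for s, e in iso.cds
                for p in range(s - 1, e)
                if (gene.seqid, p) in index
            ]
            v = np.zeros(n, dtype=np.int64)
            v[idx] = 1
            M += np.outer(v, v)
    A = (M > 0).astype(np.int64)
    return TranscriptionMatrix(positions=positions, M=M, A=A)


def asr_from_matrix(tm: TranscriptionMatrix) -> Fraction:
    """ASR as the ratio of the two matrix traces, tr(M)/tr(A)."""
    tra = tm.trace_a
    if tra == 0:
        raise UndefinedASRError("no coding positions: ASR is undefined")
    return Fraction(tm.trace_m, tra)


def asr_genomewide(annotation: AnnotationSet, per_strand: bool = False) -> Fraction:
    """Genome-wide ASR via the trace identities (exact rational).

    Numerator: total CDS nucleotides summed over all isoforms (each isoform
    counts its own positions once).  Denominator: length of the genomic
    union of all CDS intervals.  Equals :func:`asr_from_matrix` on the
    co-occurrence matrix of the same annotation.
    """
    numerator = sum(
        iso.cds_length for g in annotation.genes for iso in g.isoforms
    )
    denominator = cds_intervals(annotation, per_strand=per_strand).union_length()
    if denominator == 0:
        raise UndefinedASRError("no coding positions: ASR is undefined")
    return Fraction(numerator, denominator)


def asr_per_gene(
    annotation: AnnotationSet, per_strand: bool = False
) -> dict[str, Fraction]:
    """ASR restricted to each gene's own CDS set."""
    out: dict[str, Fraction] = {}
    for g in annotation.genes:
        num = sum(iso.cds_length for iso in g.isoforms)
        ivs = IntervalSet()
        for iso in g.isoforms:
            key = f"{g.seqid}|{g.strand}" if per_strand else g.seqid
            for s, e in iso.cds:
                ivs.add_gff3(key, s, e)
        den = ivs.union_length()
        if den == 0:
            raise UndefinedASRError(f"gene {g.gene_id} has no coding positions")
        out[g.gene_id] = Fraction(num, den)
    return out


@dataclass
class GenomeProfile:
    """Per-species genomic composition record.

    Contents (nt) are unions: ``gene_content`` counts positions inside at
    least one retained gene span, ``coding_content`` positions inside at
    least one CDS.  Percentages are the three composition ratios commonly
    tabulated alongside the splicing ratio.  ``asr_star`` is filled in by
    the support normalization step when available.
    """

    species_id: str
    genome_size: int
    gene_content: int
    coding_content: int
    gene_over_genome: float
    coding_over_gene: float
    coding_over_genome: float
    asr: float
    n_genes: int
    n_isoforms: int
    asr_star: float | None = None

    def as_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "genome_size": self.genome_size,
            "gene_content": self.gene_content,
            "coding_content": self.coding_content,
            "gene_over_genome": self.gene_over_genome,
            "coding_over_gene": self.coding_over_gene,
            "coding_over_genome": self.coding_over_genome,
            "n_genes": self.n_genes,
            "n_isoforms": self.n_isoforms,
            "asr": self.asr,
            "asr_star": self.asr_star,
        }


def genome_profile(
    annotation: AnnotationSet,
    species_id: str = "species",
    per_strand: bool = False,
) -> GenomeProfile:
    """Genomic-composition summary plus ASR for one annotation.

    With zero retained genes the contents are 0 and ``asr`` is reported as
    ``nan`` (undefined, not 1).
    """
    gsize = genome_length(annotation)
    gene_content = gene_span_intervals(annotation).union_length()
    coding_content = cds_intervals(annotation, per_strand=per_strand).union_length()
    try:
        asr = float(asr_genomewide(annotation, per_strand=per_strand))
    except UndefinedASRError:
        asr = float("nan")
    return GenomeProfile(
        species_id=species_id,
        genome_size=gsize,
        gene_content=gene_content,
        coding_content=coding_content,
        gene_over_genome=100.0 * gene_content / gsize if gsize else float("nan"),
        coding_over_gene=(
            100.0 * coding_content / gene_content if gene_content else float("nan")
        ),
        coding_over_genome=(
            100.0 * coding_content / gsize if gsize else float("nan")
        ),
        asr=asr,
        n_genes=annotation.n_genes,
        n_isoforms=annotation.n_isoforms,
    )
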