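"""GFF3 annotation input: hierarchy reconstruction and inclusion filters.

Reads GFF3 files in the NCBI RefSeq dialect, reconstructs the
gene → mRNA → CDS parent–child hierarchy via ``ID``/``Parent`` attributes,
and applies the inclusion rules used for splicing-ratio analysis:

* pseudogenes are excluded;
* duplicated genes (same gene identity annotated more than once) are
  excluded (configurable to keep the first record);
* CDS rows whose ``Parent`` cannot be traced to a retained mRNA are
  dropped as orphans;
* isoforms whose CDS segments span multiple sequences are excluded;
* genes left with no valid coding isoform are excluded.

Coordinates are stored in GFF3 convention (1-based inclusive); interval
arithmetic converts to 0-based half-open internally (:mod:`.intervals`).
Line-level record parsing (column splitting, attribute percent-decoding)
is delegated to :func:`gffutils.feature.feature_from_line`.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, TextIO

from gffutils.feature import feature_from_line

from .errors import GFF3ParseError, GenomeLengthError
from .intervals import IntervalSet, merge, to_internal

logger = logging.getLogger(__name__)

#: Exclusion reasons tracked per annotation set.  ``pseudogene``,
#: ``duplicated_gene`` and ``no_cds`` count whole genes; ``orphan_cds``
#: counts CDS rows; ``multi_seqid`` counts mRNA isoforms.
EXCLUSION_REASONS = (
    "pseudogene",
    "orphan_cds",
    "duplicated_gene",
    "no_cds",
    "multi_seqid",
)


@dataclass(frozen=True)
class ParserConfig:
    """Options controlling GFF3 record parsing.

    Parameters
    ----------
    on_record_error:
        ``"skip"`` logs malformed feature rows and continues; ``"raise"``
        aborts with :class:`GFF3ParseError` naming the line.
    transcript_types:
        Feature types that contribute protein isoforms.  Only ``mRNA`` by
        default; other transcript classes (``transcript``, ncRNAs) carry no
        protein isoform and are ignored together with their children.
    """

    on_record_error: str = "skip"
    transcript_types: frozenset[str] = frozenset({"mRNA"})


@dataclass(frozen=True)
class FilterConfig:
    """Options controlling gene-level inclusion filters.

    ``duplicate_policy`` is ``"drop-all"`` (every record of a gene identity
    seen more than once is excluded) or ``"keep-first"``.
    """

    duplicate_policy: str = "drop-all"


@dataclass
class Isoform:
    """One mRNA and its ordered CDS segments (GFF3 coordinates).

    Segments are merged at book-ended or overlapping junctions, so
    ``cds_length`` counts each genomic position claimed by this isoform
    exactly once.
    """

    mrna_id: str
    cds: list[tuple[int, int]]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass
class GeneModel:
    """A gene with its validated coding isoforms."""

    gene_id: str
    gene_key: str  # identity used for duplicate detection (GeneID when present)
    seqid: str
    start: int
    end: int
    strand: str
    isoforms: list[Isoform] = field(default_factory=list)

    @property
    def n_isoforms(self) -> int:
        return len(self.isoforms)


@dataclass
class AnnotationSet:
    """Parsed annotation: retained genes, sequence lengths, exclusion tallies."""

    genes: list[GeneModel] = field(default_factory=list)
    excluded: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )
    n_gene_features: int = 0
    pragma_lengths: dict[str, int] = field(default_factory=dict)
    region_lengths: dict[str, int] = field(default_factory=dict)
    max_feature_end: dict[str, int] = field(default_factory=dict)
    filtered: bool = False

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_isoforms(self) -> int:
        return sum(g.n_isoforms for g in self.genes)

    def sequence_lengths(self) -> dict[str, int]:
        """Resolved per-sequence lengths.

        Precedence: ``##sequence-region`` pragma, then ``region`` feature
        span, then the maximum feature end coordinate (with a warning —
        a lower bound only).
        """
        seqids = (
            set(self.pragma_lengths)
            | set(self.region_lengths)
            | set(self.max_feature_end)
        )
        out: dict[str, int] = {}
        for sid in sorted(seqids):
            if sid in self.pragma_lengths:
                out[sid] = self.pragma_lengths[sid]
            elif sid in self.region_lengths:
                out[sid] = self.region_lengths[sid]
            elif sid in self.max_feature_end:
                warnings.warn(
                    f"no ##sequence-region pragma or region feature for "
                    f"{sid!r}; using max feature end as its length",
                    stacklevel=2,
                )
                out[sid] = self.max_feature_end[sid]
            else:  # pragma: no cover - seqids set is built from these maps
                raise GenomeLengthError(f"no length derivable for {sid!r}")
        return out


def _open_source(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, Path):
        return open(source)
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            return io.StringIO(source)
        p = Path(source)
        if p.exists():
            return open(p)
        return io.StringIO(source)
    raise TypeError(f"cannot read GFF3 from {type(source).__name__}")


def _gene_key(attrs) -> str | None:
    for x in attrs.get("Dbxref", []):
        for part in x.split(","):
            if part.startswith("GeneID:"):
                return part
    for key in ("gene", "Name", "ID"):
        if attrs.get(key):
            return f"{key}={attrs[key][0]}"
    return None


def parse_gff3(
    source: str | Path | TextIO, config: ParserConfig | None = None
) -> AnnotationSet:
    """Parse GFF3 text into an :class:`AnnotationSet` with resolved hierarchy.

    Pseudogene records (feature type ``pseudogene`` or ``pseudo=true``) and
    CDS rows with unresolvable parents are tallied here; the remaining
    gene-level filters are applied by :func:`apply_filters`.

    Parameters
    ----------
    source:
        GFF3 text, a path, or an open text stream.
    config:
        Parsing options; see :class:`ParserConfig`.
    """
    cfg = config or ParserConfig()
    if cfg.on_record_error not in ("skip", "raise"):
        raise ValueError(f"unknown on_record_error {cfg.on_record_error!r}")

    ann = AnnotationSet()
    # collected first, resolved after the scan: GFF3 does not guarantee
    # that parents precede children, so hierarchy is order-independent
    gene_rows: list[tuple[int, object]] = []
    transcript_rows: list[tuple[int, object]] = []
    cds_rows: list[tuple[int, object]] = []
    other_ids: set[str] = set()  # IDs of features outside the hierarchy
    saw_version = False

    stream = _open_source(source)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("##"):
            if line.startswith("##gff-version"):
                saw_version = True
            elif line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    try:
                        ann.pragma_lengths[parts[1]] = int(parts[3])
                    except ValueError:
                        pass
            elif line.startswith("##FASTA"):
                break
            continue
        if line.startswith("#"):
            continue

        try:
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"expected 9 columns, found {len(cols)}")
            start, end = int(cols[3]), int(cols[4])
            if start > end or start < 1:
                raise ValueError(f"invalid coordinates {start}..{end}")
            feat = feature_from_line(line)
        except Exception as exc:
            if cfg.on_record_error == "raise":
                raise GFF3ParseError(str(exc), lineno) from exc
            logger.warning("skipping malformed record at line %d: %s", lineno, exc)
            continue

        ftype = feat.featuretype
        seqid = feat.seqid
        ann.max_feature_end[seqid] = max(
            ann.max_feature_end.get(seqid, 0), feat.end
        )

        if ftype == "region":
            # NCBI emits one region row per sequence spanning 1..length
            ann.region_lengths.setdefault(seqid, feat.end)
        elif ftype in ("gene", "pseudogene"):
            gene_rows.append((lineno, feat))
        elif ftype in cfg.transcript_types:
            transcript_rows.append((lineno, feat))
        elif ftype == "CDS":
            cds_rows.append((lineno, feat))
        else:
            # exon/UTR/ncRNA/... contribute no isoforms, but their IDs are
            # remembered so CDSs under them count as deliberately ignored,
            # not as orphans (orphan = parent absent from the file)
            fid = feat.attributes.get("ID", [None])[0]
            if fid is not None:
                other_ids.add(fid)

    if not saw_version:
        warnings.warn("missing ##gff-version pragma; proceeding", stacklevel=2)

    # -- resolve hierarchy (order-independent) ------------------------------
    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    pseudo_ids: set[str] = set()

    for lineno, feat in gene_rows:
        attrs = feat.attributes
        fid = attrs.get("ID", [None])[0]
        ann.n_gene_features += 1
        is_pseudo = feat.featuretype == "pseudogene" or attrs.get(
            "pseudo", ["false"]
        )[0].lower() in ("true", "1")
        if is_pseudo:
            ann.excluded["pseudogene"] += 1
            if fid is not None:
                pseudo_ids.add(fid)
            logger.info("excluded pseudogene %s", fid or "<no ID>")
            continue
        gid = fid or f"gene@line{lineno}"
        genes[gid] = GeneModel(
            gene_id=gid,
            gene_key=_gene_key(attrs) or gid,
            seqid=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand,
        )
        gene_order.append(gid)

    mrna_parent: dict[str, str] = {}  # mRNA ID -> gene ID
    ignored_transcripts: set[str] = set()
    for lineno, feat in transcript_rows:
        attrs = feat.attributes
        fid = attrs.get("ID", [None])[0]
        parents = attrs.get("Parent", [])
        parent = parents[0] if parents else None
        if fid is None:
            logger.warning("mRNA without ID at line %d ignored", lineno)
            continue
        if parent is None or parent in pseudo_ids or parent not in genes:
            # children of pseudogenes follow their parent out; an mRNA with
            # an unknown parent cannot anchor a gene model
            ignored_transcripts.add(fid)
            continue
        mrna_parent[fid] = parent

    cds_segments: dict[str, list[tuple[int, int, str]]] = {}
    for lineno, feat in cds_rows:
        parents = feat.attributes.get("Parent", [])
        hit = False
        for parent in parents:
            if parent in mrna_parent:
                cds_segments.setdefault(parent, []).append(
                    (feat.start, feat.end, feat.seqid)
                )
                hit = True
            elif (
                parent in ignored_transcripts
                or parent in pseudo_ids
                or parent in other_ids
                or parent in genes
            ):
                hit = True  # deliberately dropped with its parent
        if not hit:
            ann.excluded["orphan_cds"] += 1
            logger.info(
                "orphan CDS at line %d (Parent=%s)", lineno, ",".join(parents)
            )

    # assemble isoforms onto their genes, in stable (mRNA ID) order
    for mrna_id in sorted(mrna_parent):
        gid = mrna_parent[mrna_id]
        segs = cds_segments.get(mrna_id)
        if not segs:
            continue
        seqids = {s[2] for s in segs}
        gene = genes[gid]
        if len(seqids) > 1 or seqids != {gene.seqid}:
            ann.excluded["multi_seqid"] += 1
            warnings.warn(
                f"isoform {mrna_id} spans sequences {sorted(seqids)}; excluded",
                stacklevel=2,
            )
            continue
        internal = [to_internal(s, e) for s, e, _ in segs]
        merged = [(s0 + 1, e0) for s0, e0 in merge(internal)]
        gene.isoforms.append(Isoform(mrna_id=mrna_id, cds=merged))

    ann.genes = [genes[g] for g in gene_order]
    return ann


def apply_filters(
    raw: AnnotationSet, config: FilterConfig | None = None
) -> AnnotationSet:
    """Apply gene-level inclusion filters; total and idempotent.

    Drops duplicated gene identities per ``config.duplicate_policy`` and
    genes without any valid coding isoform.  Every drop is logged and
    tallied in ``excluded``.
    """
    cfg = config or FilterConfig()
    if cfg.duplicate_policy not in ("drop-all", "keep-first"):
        raise ValueError(f"unknown duplicate_policy {cfg.duplicate_policy!r}")

    key_counts: dict[str, int] = {}
    for g in raw.genes:
        key_counts[g.gene_key] = key_counts.get(g.gene_key, 0) + 1

    excluded = dict(raw.excluded)
    kept: list[GeneModel] = []
    seen_keys: set[str] = set()
    for g in raw.genes:
        if key_counts[g.gene_key] > 1:
            if cfg.duplicate_policy == "drop-all" or g.gene_key in seen_keys:
                excluded["duplicated_gene"] += 1
                logger.info("excluded duplicated gene %s (%s)", g.gene_id, g.gene_key)
                continue
        seen_keys.add(g.gene_key)
        if not g.isoforms:
            excluded["no_cds"] += 1
            logger.info("excluded gene %s: no valid coding isoform", g.gene_id)
            continue
        kept.append(g)

    return replace(raw, genes=kept, excluded=excluded, filtered=True)


def load_annotation(
    source: str | Path | TextIO,
    parser_config: ParserConfig | None = None,
    filter_config: FilterConfig | None = None,
) -> AnnotationSet:
    """Parse and filter in one step."""
    return apply_filters(parse_gff3(source, parser_config), filter_config)


def genome_length(annotation: AnnotationSet) -> int:
    """Total genome length in nucleotides, summed over all sequences.

    Uses the precedence documented on
    :meth:`AnnotationSet.sequence_lengths`.
    """
    lengths = annotation.sequence_lengths()
    if not lengths:
        raise GenomeLengthError("no sequence length derivable from annotation")
    return sum(lengths.values())


def gene_span_intervals(annotation: AnnotationSet) -> IntervalSet:
    """Union of retained gene spans."""
    ivs = IntervalSet()
    for g in annotation.genes:
        ivs.add_gff3(g.seqid, g.start, g.end)
    return ivs


def cds_intervals(annotation: AnnotationSet, per_strand: bool = False) -> IntervalSet:
    """Union of all retained CDS segments (the coding projection).

    With ``per_strand`` the union is kept separately per (sequence, strand),
    so antisense-overlapping CDSs do not share positions.
    """
    ivs = IntervalSet()
    for g in annotation.genes:
        key = f"{g.seqid}|{g.strand}" if per_strand else g.seqid
        for iso in g.isoforms:
            for s, e in iso.cds:
                ivs.add_gff3(key, s, e)
    return ivs


def write_gff3(annotation: AnnotationSet) -> str:
    """Serialize retained genes back to GFF3 text (round-trip safe)."""
    out = ["##gff-version 3"]
    for sid, length in sorted(annotation.sequence_lengths().items()):
        out.append(f"##sequence-region {sid} 1 {length}")
    for g in annotation.genes:
        out.append(
            f"{g.seqid}\tspliceratio\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        for iso in g.isoforms:
            s = min(x for x, _ in iso.cds)
            e = max(x for _, x in iso.cds)
            out.append(
                f"{g.seqid}\tspliceratio\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={iso.mrna_id};Parent={g.gene_id}"
            )
            for i, (cs, ce) in enumerate(iso.cds):
                out.append(
                    f"{g.seqid}\tspliceratio\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t"
                    f"ID=cds-{iso.mrna_id};Parent={iso.mrna_id}"
                )
    return "\n".join(out) + "\n"


def exclusion_summary(annotation: AnnotationSet) -> dict[str, int]:
    """Retained/excluded tallies, suitable for a one-row TSV report."""
    return {
        "retained_genes": annotation.n_genes,
        "retained_isoforms": annotation.n_isoforms,
        "gene_features_parsed": annotation.n_gene_features,
        **{f"excluded_{k}": v for k, v in annotation.excluded.items()},
    }
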