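"""GFF3 parsing, hierarchy resolution and inclusion filters."""

import random

import pytest

from spliceratio import (
    AnnotationSpec,
    FilterConfig,
    GFF3ParseError,
    ParserConfig,
    apply_filters,
    genome_length,
    load_annotation,
    make_annotation,
    parse_gff3,
    write_gff3,
)

GFF = "\t".join


def row(seqid, ftype, start, end, attrs, strand="+"):
    return GFF([seqid, "t", ftype, str(start), str(end), ".", strand, ".", attrs])


HEADER = "##gff-version 3\n##sequence-region chr1 1 1000\n"


def test_parse_clean_hierarchy(worked_example_ann):
    assert worked_example_ann.n_genes == 1
    assert worked_example_ann.n_isoforms == 3
    assert all(v == 0 for v in worked_example_ann.excluded.values())
    lengths = sorted(i.cds_length for i in worked_example_ann.genes[0].isoforms)
    assert lengths == [9, 16, 19]


def test_empty_input():
    ann = parse_gff3("##gff-version 3\n")
    assert ann.n_genes == 0 and ann.n_gene_features == 0


def test_missing_version_pragma_warns():
    with pytest.warns(UserWarning, match="gff-version"):
        parse_gff3(row("chr1", "gene", 1, 10, "ID=g1") + "\n")


def test_pseudogene_with_child_cds_excluded():
    text = HEADER + "\n".join(
        [
            row("chr1", "pseudogene", 1, 100, "ID=pg1"),
            row("chr1", "mRNA", 1, 100, "ID=m1;Parent=pg1"),
            row("chr1", "CDS", 1, 100, "ID=c1;Parent=m1"),
        ]
    )
    ann = load_annotation(text)
    assert ann.n_genes == 0
    assert ann.excluded["pseudogene"] == 1
    assert ann.excluded["orphan_cds"] == 0  # followed its parent out


def test_pseudo_attribute_excludes_gene():
    text = HEADER + row("chr1", "gene", 1, 100, "ID=g1;pseudo=true")
    ann = load_annotation(text)
    assert ann.excluded["pseudogene"] == 1 and ann.n_genes == 0


def test_gene_without_cds_dropped():
    text = HEADER + "\n".join(
        [
            row("chr1", "gene", 1, 100, "ID=g1"),
            row("chr1", "mRNA", 1, 100, "ID=m1;Parent=g1"),
        ]
    )
    ann = load_annotation(text)
    assert ann.n_genes == 0
    assert ann.excluded["no_cds"] == 1


def test_dangling_cds_parent_is_orphan_but_gene_survives():
    text = HEADER + "\n".join(
        [
            row("chr1", "gene", 1, 100, "ID=g1"),
            row("chr1", "mRNA", 1, 100, "ID=m1;Parent=g1"),
            row("chr1", "CDS", 1, 50, "ID=c1;Parent=m1"),
            row("chr1", "CDS", 60, 90, "ID=cX;Parent=m-missing"),
        ]
    )
    ann = load_annotation(text)
    assert ann.n_genes == 1
    assert ann.excluded["orphan_cds"] == 1


def _dup_text():
    return (
        "##gff-version 3\n"
        "##sequence-region chr1 1 500\n"
        "##sequence-region chr2 1 500\n"
        + "\n".join(
            [
                row("chr1", "gene", 1, 100, "ID=g1;Dbxref=GeneID:7"),
                row("chr1", "mRNA", 1, 100, "ID=m1;Parent=g1"),
                row("chr1", "CDS", 1, 50, "ID=c1;Parent=m1"),
                row("chr2", "gene", 1, 100, "ID=g2;Dbxref=GeneID:7"),
                row("chr2", "mRNA", 1, 100, "ID=m2;Parent=g2"),
                row("chr2", "CDS", 1, 50, "ID=c2;Parent=m2"),
            ]
        )
    )


def test_duplicated_gene_identity_dropped_by_default():
    ann = load_annotation(_dup_text())
    assert ann.n_genes == 0
    assert ann.excluded["duplicated_gene"] == 2


def test_duplicated_gene_keep_first_policy():
    ann = load_annotation(
        _dup_text(), filter_config=FilterConfig(duplicate_policy="keep-first")
    )
    assert ann.n_genes == 1
    assert ann.genes[0].gene_id == "g1"
    assert ann.excluded["duplicated_gene"] == 1


def test_multi_seqid_isoform_excluded():
    text = (
        "##gff-version 3\n"
        "##sequence-region chr1 1 500\n"
        "##sequence-region chr2 1 500\n"
        + "\n".join(
            [
                row("chr1", "gene", 1, 100, "ID=g1"),
                row("chr1", "mRNA", 1, 100, "ID=m1;Parent=g1"),
                row("chr1", "CDS", 1, 50, "ID=c1;Parent=m1"),
                row("chr2", "CDS", 1, 50, "ID=c1;Parent=m1"),
            ]
        )
    )
    with pytest.warns(UserWarning, match="spans sequences"):
        ann = load_annotation(text)
    assert ann.n_genes == 0
    assert ann.excluded["multi_seqid"] == 1
    assert ann.excluded["no_cds"] == 1  # the gene lost its only isoform


def test_non_mrna_transcripts_ignored():
    text = HEADER + "\n".join(
        [
            row("chr1", "gene", 1, 100, "ID=g1"),
            row("chr1", "transcript", 1, 100, "ID=t1;Parent=g1"),
            row("chr1", "CDS", 1, 50, "ID=c1;Parent=t1"),
        ]
    )
    ann = load_annotation(text)
    assert ann.n_genes == 0
    assert ann.excluded["orphan_cds"] == 0  # dropped with its ignored parent
    # with an allowlist including `transcript` the isoform counts
    ann2 = load_annotation(
        text, ParserConfig(transcript_types=frozenset({"mRNA", "transcript"}))
    )
    assert ann2.n_genes == 1 and ann2.n_isoforms == 1


def test_attribute_percent_decoding():
    text = HEADER + row("chr1", "gene", 1, 100, "ID=g%2C1")
    ann = parse_gff3(text)
    assert ann.genes[0].gene_id == "g,1"


class TestMalformedRecords:
    BAD = HEADER + "\n".join(
        [
            row("chr1", "gene", 1, 100, "ID=g1"),
            GFF(["chr1", "t", "mRNA", "x", "100", ".", "+", ".", "ID=m1;Parent=g1"]),
        ]
    )

    def test_skip_mode_drops_record(self):
        ann = parse_gff3(self.BAD)
        assert ann.n_genes == 1 and ann.n_isoforms == 0

    def test_strict_mode_raises_with_line_number(self):
        with pytest.raises(GFF3ParseError, match="line 4"):
            parse_gff3(self.BAD, ParserConfig(on_record_error="raise"))

    def test_start_greater_than_end_rejected(self):
        bad = HEADER + row("chr1", "gene", 50, 10, "ID=g1")
        with pytest.raises(GFF3ParseError):
            parse_gff3(bad, ParserConfig(on_record_error="raise"))


class TestGenomeLength:
    def test_pragma_only(self):
        assert genome_length(parse_gff3("##gff-version 3\n##sequence-region chr1 1 33\n")) == 33

    def test_two_scaffolds_additive(self):
        text = (
            "##gff-version 3\n"
            "##sequence-region s1 1 100\n"
            "##sequence-region s2 1 50\n"
        )
        assert genome_length(parse_gff3(text)) == 150

    def test_region_feature_fallback(self):
        text = "##gff-version 3\n" + row("chr1", "region", 1, 500, "ID=chr1")
        assert genome_length(parse_gff3(text)) == 500

    def test_max_end_fallback_warns(self):
        text = "##gff-version 3\n" + row("chr1", "gene", 1, 250, "ID=g1")
        ann = parse_gff3(text)
        with pytest.warns(UserWarning, match="max feature end"):
            assert genome_length(ann) == 250

    def test_pragma_beats_region(self):
        text = (
            "##gff-version 3\n##sequence-region chr1 1 600\n"
            + row("chr1", "region", 1, 500, "ID=chr1")
        )
        assert genome_length(parse_gff3(text)) == 600


def test_round_trip_preserves_gene_models(worked_example_ann):
    reparsed = load_annotation(write_gff3(worked_example_ann))
    assert reparsed.n_genes == worked_example_ann.n_genes
    for a, b in zip(worked_example_ann.genes, reparsed.genes):
        assert (a.gene_id, a.seqid, a.start, a.end) == (
            b.gene_id,
            b.seqid,
            b.start,
            b.end,
        )
        assert [i.cds for i in a.isoforms] == [i.cds for i in b.isoforms]


def test_filter_idempotence():
    syn = make_annotation(
        AnnotationSpec(n_genes=8, seed=11, inject_pseudogenes=2, inject_orphan_cds=1)
    )
    once = load_annotation(syn.gff3)
    twice = apply_filters(once)
    assert twice.n_genes == once.n_genes
    assert twice.excluded == once.excluded


@pytest.mark.parametrize("seed", range(5))
def test_gene_count_conservation(seed):
    """Retained + gene-level exclusions equals gene-like features parsed."""
    rng = random.Random(seed)
    syn = make_annotation(
        AnnotationSpec(
            n_genes=rng.randint(1, 12),
            seed=seed,
            inject_pseudogenes=rng.randint(0, 3),
            inject_orphan_cds=rng.randint(0, 2),
        )
    )
    ann = load_annotation(syn.gff3)
    gene_level = (
        ann.excluded["pseudogene"]
        + ann.excluded["duplicated_gene"]
        + ann.excluded["no_cds"]
    )
    assert ann.n_genes + gene_level == ann.n_gene_features
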