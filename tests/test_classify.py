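"""Novelty classification against a reference annotation."""

from collections import Counter

from isocurate import (
    AnnotationSet,
    IsoformModel,
    JunctionCode,
    annotation_code_set,
    classify,
    cluster_new_gene_regions,
    collapse,
    find_novel_exons,
    summarize,
)
from conftest import make_alignment


def _annot(transcripts, gene_of):
    return AnnotationSet(list(transcripts), dict(gene_of))


def _model(introns, start, end, chrom="chr1", strand="+", support=1, mid=None):
    return IsoformModel(
        code=JunctionCode(chrom, strand, tuple(introns)),
        start=start,
        end=end,
        support=support,
        member_ids=(mid or f"m{start}",),
    )


REF = _annot(
    [
        make_alignment([(100, 200), (300, 400)], id="t1", source="annotation"),
        make_alignment([(100, 200), (300, 400), (500, 600)], id="t2", source="annotation"),
        make_alignment([(5000, 5400)], id="t3", chrom="chr2", source="annotation"),
    ],
    {"t1": "g1", "t2": "g1", "t3": "g2"},
)


class TestAnnotationCodeSet:
    def test_one_code_per_multi_exon_transcript(self):
        assert len(annotation_code_set(REF)) == 2

    def test_identical_intron_chains_collapse_to_one_code(self):
        annot = _annot(
            [
                make_alignment([(100, 200), (300, 400)], id="a", source="annotation"),
                make_alignment([(80, 200), (300, 450)], id="b", source="annotation"),
            ],
            {"a": "g1", "b": "g1"},
        )
        assert len(annotation_code_set(annot)) == 1

    def test_single_exon_transcripts_contribute_no_code(self):
        annot = _annot(
            [make_alignment([(100, 400)], id="a", source="annotation")], {"a": "g1"}
        )
        assert annotation_code_set(annot) == set()


class TestClassify:
    def test_known_code_is_annotated(self):
        model = _model([(200, 300)], 100, 400)
        (c,) = classify([model], REF)
        assert c.category == "annotated"

    def test_unknown_code_overlapping_a_gene_is_a_novel_isoform(self):
        model = _model([(250, 350)], 150, 550)  # novel chain inside g1's span
        (c,) = classify([model], REF)
        assert c.category == "novel_isoform_known_gene"
        assert c.overlapping_gene_ids == ["g1"]

    def test_unknown_code_outside_all_genes_is_a_novel_gene(self):
        model = _model([(10200, 10300)], 10000, 10500, chrom="chr3")
        (c,) = classify([model], REF)
        assert c.category == "novel_gene" and c.overlapping_gene_ids == []

    def test_categories_partition_the_models(self, hidden_gene_dataset):
        ds = hidden_gene_dataset
        models = collapse([r for r in ds.reads if r.n_exons >= 2])
        classifications = classify(models, ds.emitted_annotation)
        counts = Counter(c.category for c in classifications)
        assert sum(counts.values()) == len(models)
        assert set(counts) <= {"annotated", "novel_isoform_known_gene", "novel_gene"}

    def test_annotation_classified_against_itself_is_fully_annotated(self, clean_dataset):
        """Self-test: the annotation's own multi-exon transcripts are never novel."""
        annot = clean_dataset.true_annotation
        models = collapse([t for t in annot.transcripts if t.n_exons >= 2])
        classifications = classify(models, annot)
        assert {c.category for c in classifications} == {"annotated"}

    def test_hidden_genes_are_recovered_as_novel_gene_regions(self, hidden_gene_dataset):
        ds = hidden_gene_dataset
        models = collapse([r for r in ds.reads if r.n_exons >= 2])
        classifications = classify(models, ds.emitted_annotation)
        category_of = {c.code_text: c.category for c in classifications}
        for code, expected in ds.truth.expected_classification.items():
            assert category_of[code] == expected, code
        novel_gene = [
            m for m in models
            if next(c for c in classifications if c.model_id == m.id).category == "novel_gene"
        ]
        regions = cluster_new_gene_regions(novel_gene)
        assert len(regions) == len(ds.truth.hidden_gene_ids)


class TestFindNovelExons:
    def test_exact_match_is_not_novel(self):
        model = _model([(250, 350)], 150, 400)
        novel = find_novel_exons(_model([(200, 300)], 100, 400), REF)
        assert novel == []

    def test_partial_overlap_is_not_novel(self):
        # exon (395, 500) overlaps annotated (300,400) by 5 bp
        model = _model([(250, 395)], 150, 500)
        assert find_novel_exons(model, REF) == []

    def test_disjoint_exon_is_novel(self):
        model = _model([(250, 700)], 150, 800)  # second exon (700,800) is unannotated
        assert find_novel_exons(model, REF) == [("chr1", 700, 800)]


class TestClusterRegions:
    def test_transitive_overlap_forms_one_region(self):
        models = [
            _model([(200, 300)], 100, 500, mid="a"),
            _model([(600, 700)], 400, 900, mid="b"),
        ]
        (region,) = cluster_new_gene_regions(models)
        assert (region.start, region.end) == (100, 900)
        assert len(region.model_ids) == 2

    def test_disjoint_spans_form_separate_regions(self):
        models = [
            _model([(200, 300)], 100, 500, mid="a"),
            _model([(700, 800)], 600, 900, mid="b"),
        ]
        assert len(cluster_new_gene_regions(models)) == 2

    def test_distinct_exons_counted_by_exact_coordinates(self):
        models = [
            _model([(200, 300)], 100, 500, mid="a"),
            _model([(250, 300)], 100, 500, mid="b"),
        ]
        (region,) = cluster_new_gene_regions(models)
        # brute-force distinct exon set over member models
        exon_set = {e for m in models for e in m.exons}
        assert region.n_distinct_exons == len(exon_set) == 3


class TestSummarize:
    def test_counts_over_a_mixed_classification(self):
        novel_gene_models = [
            _model([(10200, 10300)], 10000, 10500, chrom="chr3", mid="n1"),
            _model([(10250, 10350)], 10100, 10600, chrom="chr3", mid="n2"),
        ]
        models = [
            _model([(250, 350)], 150, 550, mid="k1"),
            _model([(255, 355)], 150, 550, mid="k2"),
            _model([(260, 360)], 150, 550, mid="k3"),
        ] + novel_gene_models
        classifications = classify(models, REF)
        regions = cluster_new_gene_regions(novel_gene_models)
        s = summarize(classifications, regions)
        assert s.n_new_annotations == 5
        assert s.n_new_genes == 1
        assert s.n_isoforms_for_new_genes == 2
        assert s.n_genes_with_new_annotations == 2  # g1 plus one new region
        exon_set = {e for m in novel_gene_models for e in m.exons}
        assert s.n_exons_in_new_genes == len(exon_set)

    def test_no_novel_models_gives_all_zero_counts(self):
        model = _model([(200, 300)], 100, 400)
        s = summarize(classify([model], REF), [])
        assert (
            s.n_new_annotations,
            s.n_new_genes,
            s.n_isoforms_for_new_genes,
            s.n_exons_in_new_genes,
            s.n_new_exons_in_known_genes,
        ) == (0, 0, 0, 0, 0)

    def test_hidden_gene_count_matches_simulator_ground_truth(self, hidden_gene_dataset):
        ds = hidden_gene_dataset
        models = collapse([r for r in ds.reads if r.n_exons >= 2])
        classifications = classify(models, ds.emitted_annotation)
        novel_gene = [
            m for m in models
            if next(c for c in classifications if c.model_id == m.id).category == "novel_gene"
        ]
        regions = cluster_new_gene_regions(novel_gene)
        s = summarize(classifications, regions)
        assert s.n_new_genes == len(ds.truth.hidden_gene_ids)
        # brute-force exon-count consistency
        exon_set = {(m.chrom, e) for m in novel_gene for e in m.exons}
        assert s.n_exons_in_new_genes == len(exon_set)
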