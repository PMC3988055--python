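"""Classify collapsed isoform models against a reference annotation.

Every model falls into exactly one category:

* ``annotated`` — its junction code equals that of some multi-exon
  annotated transcript;
* ``novel_isoform_known_gene`` — unannotated code, but the model span
  overlaps at least one annotated genic region by >=1 bp;
* ``novel_gene`` — unannotated code overlapping no genic region.

Novel-gene models are clustered into candidate new gene regions by
single-linkage any-overlap of their spans, and a bookkeeping summary of
new annotations, genes and exons is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .collapse import IsoformModel, JunctionCode, make_code
from .io import AnnotationSet

CATEGORIES = ("annotated", "novel_isoform_known_gene", "novel_gene")


@dataclass
class Classification:
    model_id: str
    code_text: str
    category: str
    overlapping_gene_ids: list[str] = field(default_factory=list)
    novel_exons: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class NewGeneRegion:
    """One single-linkage cluster of novel-gene isoform model spans."""

    chrom: str
    start: int
    end: int
    model_ids: tuple[str, ...]
    n_distinct_exons: int


@dataclass(frozen=True)
class NoveltySummary:
    """Bookkeeping counts over all novel isoform models."""

    n_new_annotations: int
    n_genes_with_new_annotations: int
    n_new_genes: int
    n_isoforms_for_new_genes: int
    n_exons_in_new_genes: int
    n_new_exons_in_known_genes: int


def annotation_code_set(annot: AnnotationSet) -> set[JunctionCode]:
    """Junction codes of every multi-exon annotated transcript."""
    return {make_code(t) for t in annot.transcripts if t.n_exons >= 2}


def _gene_trees(annot: AnnotationSet, strand_specific: bool):
    """Per (chrom[, strand]) interval trees of genic regions -> gene ids."""
    trees: dict[tuple, IntervalTree] = {}
    strand_of_gene = {}
    for t in annot.transcripts:
        strand_of_gene[annot.gene_of[t.id]] = t.strand
    for gene_id, (chrom, start, end) in annot.gene_spans.items():
        key = (chrom, strand_of_gene[gene_id]) if strand_specific else (chrom,)
        trees.setdefault(key, IntervalTree()).addi(start, end, gene_id)
    return trees


def _exon_trees(annot: AnnotationSet, strand_specific: bool):
    trees: dict[tuple, IntervalTree] = {}
    for t in annot.transcripts:
        key = (t.chrom, t.strand) if strand_specific else (t.chrom,)
        tree = trees.setdefault(key, IntervalTree())
        for s, e in t.exons:
            tree.addi(s, e)
    return trees


def find_novel_exons(
    model: IsoformModel,
    annot: AnnotationSet,
    strand_specific: bool = False,
    _exon_tree_cache: dict | None = None,
) -> list[tuple[str, int, int]]:
    """Model exons sharing zero bases with any annotated exon.

    Any overlap at all (>=1 shared base) makes an exon "known"; only exons
    completely outside the annotated exon space are reported.
    """
    trees = _exon_tree_cache if _exon_tree_cache is not None else _exon_trees(
        annot, strand_specific
    )
    key = (model.chrom, model.strand) if strand_specific else (model.chrom,)
    tree = trees.get(key, IntervalTree())
    return [
        (model.chrom, s, e) for s, e in model.exons if not tree.overlap(s, e)
    ]


def classify(
    models: Sequence[IsoformModel],
    annot: AnnotationSet,
    strand_specific: bool = False,
) -> list[Classification]:
    """Assign each model to annotated / novel isoform / novel gene.

    Genic overlap is >=1 bp intersection between the model span and a
    gene's span (union of its transcript spans, introns included),
    strand-agnostic unless ``strand_specific``.
    """
    known_codes = {c.text for c in annotation_code_set(annot)}
    gene_trees = _gene_trees(annot, strand_specific)
    exon_trees = _exon_trees(annot, strand_specific)
    out = []
    for model in models:
        key = (model.chrom, model.strand) if strand_specific else (model.chrom,)
        if model.code.text in known_codes:
            out.append(
                Classification(model.id, model.code.text, "annotated")
            )
            continue
        hits = gene_trees.get(key, IntervalTree()).overlap(model.start, model.end)
        genes = sorted({iv.data for iv in hits})
        category = "novel_isoform_known_gene" if genes else "novel_gene"
        out.append(
            Classification(
                model.id,
                model.code.text,
                category,
                overlapping_gene_ids=genes,
                novel_exons=find_novel_exons(
                    model, annot, strand_specific, _exon_tree_cache=exon_trees
                ),
            )
        )
    return out


def cluster_new_gene_regions(
    models: Sequence[IsoformModel],
) -> list[NewGeneRegion]:
    """Single-linkage clustering of novel-gene model spans by any-overlap.

    Models whose spans share >=1 bp on the same chromosome (directly or
    transitively) form one candidate new gene region.  Strand-agnostic:
    the region is a genomic locus, not a stranded transcript.
    """
    by_chrom: dict[str, list[IsoformModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    regions = []
    for chrom in sorted(by_chrom):
        cluster: list[IsoformModel] = []
        cluster_end = -1
        for m in sorted(by_chrom[chrom], key=lambda m: (m.start, m.end, m.code.text)):
            if cluster and m.start < cluster_end:
                cluster.append(m)
                cluster_end = max(cluster_end, m.end)
            else:
                if cluster:
                    regions.append(_make_region(chrom, cluster))
                cluster = [m]
                cluster_end = m.end
        if cluster:
            regions.append(_make_region(chrom, cluster))
    return regions


def _make_region(chrom: str, members: list[IsoformModel]) -> NewGeneRegion:
    exons = {(chrom, s, e) for m in members for s, e in m.exons}
    return NewGeneRegion(
        chrom=chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        model_ids=tuple(sorted(m.id for m in members)),
        n_distinct_exons=len(exons),
    )


def summarize(
    classifications: Iterable[Classification],
    regions: Sequence[NewGeneRegion],
) -> NoveltySummary:
    """Table-style bookkeeping over the classification output.

    Distinct exons are counted by exact (chrom, start, end) coordinates;
    alternative 5'/3' ends of the same internal exon count separately.
    "Genes with new annotations" counts distinct annotated genes that
    received at least one novel isoform, plus the new gene regions.
    """
    classifications = list(classifications)
    novel_iso = [c for c in classifications if c.category == "novel_isoform_known_gene"]
    novel_gene = [c for c in classifications if c.category == "novel_gene"]
    known_genes_touched = {g for c in novel_iso for g in c.overlapping_gene_ids}
    exons_in_new_genes = sum(r.n_distinct_exons for r in regions)
    new_exons_known = {e for c in novel_iso for e in c.novel_exons}
    return NoveltySummary(
        n_new_annotations=len(novel_iso) + len(novel_gene),
        n_genes_with_new_annotations=len(known_genes_touched) + len(regions),
        n_new_genes=len(regions),
        n_isoforms_for_new_genes=len(novel_gene),
        n_exons_in_new_genes=exons_in_new_genes,
        n_new_exons_in_known_genes=len(new_exons_known),
    )
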