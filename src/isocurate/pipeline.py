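"""End-to-end orchestration: validate -> collapse -> classify -> metrics.

One :func:`run_pipeline` call reads the four inputs (genome FASTA, long
reads BED12, short-read junction evidence, reference GTF), runs every
stage, and writes all reports plus a ``manifest.json`` recording the
configuration, input checksums and per-stage record counts.  The pipeline
is deterministic: rerunning on identical inputs produces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .classify import classify, cluster_new_gene_regions, summarize
from .collapse import collapse, subset_collapse
from .errors import ConfigError
from .io import (
    read_bed12,
    read_fasta,
    read_gtf,
    read_junction_bed,
    write_bed12,
)
from .metrics import coverage_profile, overlap_matrix, splice_distance_profile
from .validation import build_junction_db, extract_junctions, validate_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, knobs and output location for one pipeline run."""

    genome: str
    reads: str
    junctions: str
    annotation: str
    outdir: str
    junction_dialect: str = "tophat_bed"
    min_support: int = 1
    subset_collapse: bool = False
    strand_specific: bool = False
    strand_aware_db: bool = False
    window: int = 50
    bins: str = "0:6000:250"
    seed: int = 0

    def validate(self) -> None:
        for name in ("genome", "reads", "junctions", "annotation"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigError(f"{name} file does not exist: {path}")
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        parse_bins(self.bins)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def parse_bins(expr: str) -> np.ndarray:
    """Parse ``start:stop:step`` into inclusive bin edges."""
    try:
        start, stop, step = (int(x) for x in expr.split(":"))
    except ValueError as exc:
        raise ConfigError(f"bins must be start:stop:step, got {expr!r}") from exc
    if step <= 0 or stop <= start:
        raise ConfigError(f"invalid bins {expr!r}")
    return np.arange(start, stop + 1, step)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all outputs; returns the manifest dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "isocurate",
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
            for name in ("genome", "reads", "junctions", "annotation")
        },
        "stages": {},
        "outputs": [],
    }

    genomes = {g.name: g for g in read_fasta(config.genome)}
    reads = read_bed12(config.reads)
    junction_records = read_junction_bed(config.junctions, config.junction_dialect)
    annot = read_gtf(config.annotation)
    logger.info(
        "loaded %d chromosomes, %d reads, %d junction records, %d annotated transcripts",
        len(genomes), len(reads), len(junction_records), len(annot.transcripts),
    )

    # --- validation -------------------------------------------------------
    db = build_junction_db(
        junction_records, config.min_support, config.strand_aware_db
    )
    results, retained = validate_all(reads, genomes, db)
    _write_tsv(
        outdir / "validation.tsv",
        ["read_id", "n_exons", "n_junctions", "n_motif_fail", "n_evidence_fail", "retained"],
        (
            [
                res.alignment_id,
                len(res.junctions) + 1,
                len(res.junctions),
                res.n_motif_fail,
                res.n_evidence_fail,
                int(res.retained),
            ]
            for res, _aln in zip(results, reads)
        ),
    )
    write_bed12(retained, outdir / "validated.bed12")
    manifest["stages"]["validation"] = {
        "reads_in": len(reads),
        "retained": len(retained),
        "dropped": len(reads) - len(retained),
        "junction_db_size": len(db),
    }
    logger.info("validation: %d/%d reads retained", len(retained), len(reads))

    # --- collapse ---------------------------------------------------------
    models = collapse(retained, genomes)
    models = subset_collapse(models, enabled=config.subset_collapse)
    write_bed12(models, outdir / "models.bed12")
    manifest["stages"]["collapse"] = {
        "models": len(models),
        "support_total": sum(m.support for m in models),
    }
    logger.info("collapse: %d isoform models", len(models))

    # --- classification ---------------------------------------------------
    classifications = classify(models, annot, config.strand_specific)
    category_of = {c.model_id: c for c in classifications}
    novel_iso = [m for m in models if category_of[m.id].category == "novel_isoform_known_gene"]
    novel_gene = [m for m in models if category_of[m.id].category == "novel_gene"]
    write_bed12(novel_iso, outdir / "novel_isoforms.bed12")
    write_bed12(novel_gene, outdir / "new_gene_isoforms.bed12")
    regions = cluster_new_gene_regions(novel_gene)
    summary = summarize(classifications, regions)
    _write_tsv(
        outdir / "summary.tsv",
        ["metric", "value"],
        [
            ["all new annotations", summary.n_new_annotations],
            ["genes with new annotations", summary.n_genes_with_new_annotations],
            ["new genes (not in annotation)", summary.n_new_genes],
            ["isoforms for new genes", summary.n_isoforms_for_new_genes],
            ["exons in new genes", summary.n_exons_in_new_genes],
            ["new exons in known genes", summary.n_new_exons_in_known_genes],
        ],
    )
    manifest["stages"]["classification"] = {
        "annotated": sum(1 for c in classifications if c.category == "annotated"),
        "novel_isoform_known_gene": len(novel_iso),
        "novel_gene": len(novel_gene),
        "new_gene_regions": len(regions),
        "summary": asdict(summary),
    }
    logger.info(
        "classification: %d annotated, %d novel isoforms, %d novel-gene models in %d regions",
        manifest["stages"]["classification"]["annotated"],
        len(novel_iso), len(novel_gene), len(regions),
    )

    # --- metrics ----------------------------------------------------------
    matrix = overlap_matrix(
        {
            "annotation": annot.transcripts,
            "reads": reads,
            "models": [m.as_alignment() for m in models],
        }
    )
    df = matrix.to_dataframe()
    df.index.name = "set"
    df.to_csv(outdir / "matrix.tsv", sep="\t", float_format="%.2f", na_rep="NA")

    edges = parse_bins(config.bins)
    cov = coverage_profile(annot.transcripts, retained, edges)
    bin_labels = [
        f"{edges[i]}-{edges[i + 1]}" for i in range(len(edges) - 1)
    ] + [f">={edges[-1]}"]
    _write_tsv(
        outdir / "covhist.tsv",
        ["length_bin", "all_transcripts", "any_overlap", "gt90_covered"],
        (
            [lab, int(a), int(b), int(c)]
            for lab, a, b, c in zip(bin_labels, cov.hist_all, cov.hist_any, cov.hist_90)
        ),
    )

    observed = [j for aln in retained for j in extract_junctions(aln)]
    annotated_j = [
        j for t in annot.transcripts for j in extract_junctions(t)
    ]
    profiles = splice_distance_profile(observed, annotated_j, config.window)
    rows = []
    for kind in ("donor", "acceptor"):
        prof = profiles[kind]
        for dist in sorted(prof.histogram):
            rows.append([kind, dist, prof.histogram[dist]])
        rows.append([kind, "overflow", prof.overflow])
    _write_tsv(outdir / "dist.tsv", ["site_kind", "distance", "count"], rows)
    manifest["stages"]["metrics"] = {
        "observed_junction_sites": sum(p.total for p in profiles.values()),
        "donor_nonzero_fraction": round(profiles["donor"].nonzero_fraction, 6),
    }

    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.name != "manifest.json"
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
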