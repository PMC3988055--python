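"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are normalised to 0-based half-open intervals at the
boundary.  GTF (1-based closed) is converted on read and on write; BED12 is
already half-open.  Strand is one of ``"+"``, ``"-"`` or ``"."`` (unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import FormatError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: nucleotides kept verbatim by FASTA normalisation
_CANONICAL_BASES = frozenset("ACGTN")
#: IUPAC ambiguity codes collapsed to N with a warning
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: an identifier plus its uppercase base string."""

    name: str
    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> str:
        """Return bases[start:end); raises on out-of-bounds coordinates."""
        if start < 0 or end > self.length or start > end:
            raise IndexError(
                f"slice [{start},{end}) outside chromosome {self.name} "
                f"of length {self.length}"
            )
        return self.bases[start:end]


@dataclass(frozen=True)
class TranscriptAlignment:
    """A spliced alignment (or annotated transcript) as ordered exon blocks.

    Exons are ``(start, end)`` pairs in 0-based half-open genomic
    coordinates, sorted ascending, non-overlapping, with at least one
    intronic base between consecutive blocks.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "long_read"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"{self.id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"{self.id}: alignment with no exon blocks")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise FormatError(f"{self.id}: empty exon block ({start},{end})")
            if prev_end is not None and start <= prev_end:
                raise FormatError(
                    f"{self.id}: exon blocks overlap or touch at {start} "
                    f"(previous block ends {prev_end}); introns need >=1 base"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class AnnotationSet:
    """A reference annotation: transcripts plus gene-level bookkeeping."""

    transcripts: list[TranscriptAlignment]
    gene_of: dict[str, str]
    gene_spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_spans:
            self.gene_spans = _gene_spans(self.transcripts, self.gene_of)

    @property
    def genic_regions(self) -> dict[str, list[tuple[int, int, str]]]:
        """Per chromosome, sorted (start, end, gene_id) spans."""
        regions: dict[str, list[tuple[int, int, str]]] = {}
        for gene_id, (chrom, start, end) in self.gene_spans.items():
            regions.setdefault(chrom, []).append((start, end, gene_id))
        for spans in regions.values():
            spans.sort()
        return regions

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptAlignment]:
        return [t for t in self.transcripts if self.gene_of[t.id] == gene_id]


def _gene_spans(
    transcripts: Sequence[TranscriptAlignment], gene_of: Mapping[str, str]
) -> dict[str, tuple[str, int, int]]:
    spans: dict[str, tuple[str, int, int]] = {}
    for t in transcripts:
        gene = gene_of[t.id]
        if gene in spans:
            chrom, start, end = spans[gene]
            if chrom != t.chrom:
                raise FormatError(f"gene {gene} spans chromosomes {chrom} and {t.chrom}")
            spans[gene] = (chrom, min(start, t.start), max(end, t.end))
        else:
            spans[gene] = (t.chrom, t.start, t.end)
    return spans


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence objects.

    Sequence is uppercased; IUPAC ambiguity codes are collapsed to ``N``
    with a logged warning; any other character is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        if not bases:
            raise FormatError(f"FASTA record {rec.id!r} is empty")
        bad = set(bases) - _CANONICAL_BASES
        if bad:
            ambiguous = bad & _IUPAC_AMBIGUOUS
            illegal = bad - _IUPAC_AMBIGUOUS
            if illegal:
                raise FormatError(
                    f"FASTA record {rec.id!r} contains non-nucleotide "
                    f"characters: {sorted(illegal)}"
                )
            logger.warning(
                "FASTA record %s: IUPAC ambiguity codes %s collapsed to N",
                rec.id,
                sorted(ambiguous),
            )
            bases = "".join("N" if b in ambiguous else b for b in bases)
        records.append(GenomeSequence(rec.id, bases))
    if not records:
        raise FormatError(f"no records in FASTA file {path}")
    return records


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, width):
                fh.write(g.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED12


def read_bed12(path: str | Path, source: str = "long_read") -> list[TranscriptAlignment]:
    """Read 12-column BED into TranscriptAlignment objects.

    blockStarts are relative to chromStart; thickStart/thickEnd and itemRgb
    are ignored.  Strand ``.`` is kept as unknown.
    """
    alignments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(cols)}")
            chrom, chrom_start, name, strand = cols[0], int(cols[1]), cols[3], cols[5]
            block_count = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={block_count} but "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                alignments.append(
                    TranscriptAlignment(name, chrom, strand, exons, source=source)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return alignments


def write_bed12(features, path: str | Path) -> None:
    """Write features (IsoformModel or TranscriptAlignment) as BED12.

    Score column is the supporting-read count (``support`` attribute if
    present, else 0), capped at 1000.  Round-tripping through
    :func:`read_bed12` reproduces (chrom, strand, exons) exactly.
    """
    with open(path, "w") as fh:
        for feat in features:
            exons = list(feat.exons)
            start, end = exons[0][0], exons[-1][1]
            support = getattr(feat, "support", 0)
            name = getattr(feat, "id", None) or getattr(feat, "name")
            sizes = ",".join(str(e - s) for s, e in exons) + ","
            offsets = ",".join(str(s - start) for s, e in exons) + ","
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            feat.chrom,
                            start,
                            end,
                            name,
                            min(int(support), 1000),
                            feat.strand,
                            start,
                            end,
                            0,
                            len(exons),
                            sizes,
                            offsets,
                        ],
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read exon features from a GTF file into an AnnotationSet.

    Exons are grouped by ``transcript_id``; GTF's 1-based closed coordinates
    become 0-based half-open.  Overlapping exons within one transcript are a
    malformed gene model and raise FormatError.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"cannot parse GTF {path}: {exc}") from exc

    by_transcript: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene)
    for feat in db.features_of_type("exon"):
        if "transcript_id" not in feat.attributes or not feat.attributes["transcript_id"]:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} lacks transcript_id")
        if "gene_id" not in feat.attributes or not feat.attributes["gene_id"]:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} lacks gene_id")
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        by_transcript.setdefault(tid, []).append((feat.start - 1, feat.end))
        meta.setdefault(tid, (feat.seqid, strand, gid))
    if not by_transcript:
        raise FormatError(f"no exon features in GTF {path}")

    transcripts = []
    gene_of = {}
    for tid in sorted(by_transcript):
        chrom, strand, gid = meta[tid]
        exons = tuple(sorted(by_transcript[tid]))
        try:
            transcripts.append(
                TranscriptAlignment(tid, chrom, strand, exons, source="annotation")
            )
        except FormatError as exc:
            raise FormatError(f"{path}: malformed transcript model {tid}: {exc}") from exc
        gene_of[tid] = gid
    return AnnotationSet(transcripts, gene_of)


def write_gtf(annot: AnnotationSet, path: str | Path, source: str = "isocurate") -> None:
    """Write an AnnotationSet as exon-only GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for t in sorted(annot.transcripts, key=lambda t: (t.chrom, t.start, t.id)):
            gene = annot.gene_of[t.id]
            for i, (s, e) in enumerate(t.exons, 1):
                attrs = (
                    f'gene_id "{gene}"; transcript_id "{t.id}"; exon_number "{i}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            source,
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            t.strand if t.strand != "." else ".",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Junction evidence

JUNCTION_DIALECTS = ("tophat_bed", "plain_tab")


def read_junction_bed(
    path: str | Path, dialect: str = "tophat_bed"
) -> list[tuple["Junction", int]]:
    """Read short-read junction evidence with per-junction read counts.

    ``tophat_bed``: TopHat2 ``junctions.bed`` — BED12 records with exactly two
    blocks flanking the intron; the score column is the supporting read count.
    ``plain_tab``: chrom, intronStart (0-based), intronEnd (exclusive),
    strand, count.

    Duplicate junctions have their counts summed.
    """
    from .validation import Junction

    if dialect not in JUNCTION_DIALECTS:
        raise FormatError(f"unknown junction dialect {dialect!r}")
    counts: dict[tuple[str, int, int, str], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split()
            if dialect == "tophat_bed":
                if len(cols) < 12:
                    raise FormatError(f"{path}:{lineno}: expected 12 columns")
                chrom, chrom_start = cols[0], int(cols[1])
                count, strand = int(cols[4]), cols[5]
                if int(cols[9]) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: tophat_bed junction must have "
                        f"exactly 2 blocks, got {cols[9]}"
                    )
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
                start = chrom_start + sizes[0]
                end = chrom_start + offsets[1]
            else:
                if len(cols) < 5:
                    raise FormatError(f"{path}:{lineno}: expected 5 columns")
                chrom, start, end, strand, count = (
                    cols[0],
                    int(cols[1]),
                    int(cols[2]),
                    cols[3],
                    int(cols[4]),
                )
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative junction count {count}")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            key = (chrom, start, end, strand)
            counts[key] = counts.get(key, 0) + count
    return [
        (Junction(chrom=c, strand=st, start=s, end=e), n)
        for (c, s, e, st), n in sorted(counts.items())
    ]


def write_junction_tab(records, path: str | Path) -> None:
    """Write (Junction, count) records in the plain 5-column tab dialect."""
    with open(path, "w") as fh:
        for junc, count in sorted(
            records, key=lambda jc: (jc[0].chrom, jc[0].start, jc[0].end, jc[0].strand)
        ):
            fh.write(
                f"{junc.chrom}\t{junc.start}\t{junc.end}\t{junc.strand}\t{count}\n"
            )
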