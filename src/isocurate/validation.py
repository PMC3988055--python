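"""Splice-junction validation of spliced alignments.

Each intron implied by an alignment's exon blocks is checked twice:

1. *Motif check* — the intron must begin with the canonical donor
   dinucleotide GT and end with the acceptor AG in transcript orientation
   (on the minus strand the genomic text reads CT...AC).
2. *Evidence check* — the intron must be present, at exact coordinates, in
   a database of junctions observed in orthogonal short-read data.

Multi-exon alignments in which every junction passes both checks are
retained; everything else (including all single-exon alignments) is
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import InvariantError
from .io import GenomeSequence, TranscriptAlignment

logger = logging.getLogger(__name__)

#: canonical splice dinucleotides on the genomic plus strand
DONOR_PLUS, ACCEPTOR_PLUS = "GT", "AG"
#: their reverse complements, seen when the transcript runs on the minus strand
DONOR_MINUS, ACCEPTOR_MINUS = "AC", "CT"  # genomic text at intron end / start


@dataclass(frozen=True)
class Junction:
    """A single intron: genomic interval [start, end), 0-based half-open."""

    chrom: str
    strand: str
    start: int
    end: int
    motif_valid: bool | None = None
    evidence_valid: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 4:
            raise InvariantError(
                f"intron [{self.start},{self.end}) on {self.chrom} shorter "
                "than 4 bases: no room for donor and acceptor dinucleotides"
            )

    @property
    def coords(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class JunctionDB:
    """Short-read-supported junctions with aggregated read counts.

    Lookup is strand-agnostic on (chrom, start, end) by default: aligners
    infer junction strand from the motif anyway, so coordinates alone
    identify an intron.  ``strand_aware=True`` keys on strand too.
    """

    entries: dict[tuple, int] = field(default_factory=dict)
    min_support: int = 1
    strand_aware: bool = False

    def _key(self, chrom: str, start: int, end: int, strand: str = "."):
        if self.strand_aware:
            return (chrom, start, end, strand)
        return (chrom, start, end)

    def supports(self, junction: Junction) -> bool:
        return self._key(junction.chrom, junction.start, junction.end, junction.strand) in self.entries

    def count(self, junction: Junction) -> int:
        return self.entries.get(
            self._key(junction.chrom, junction.start, junction.end, junction.strand), 0
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ValidationResult:
    """Per-alignment validation outcome."""

    alignment_id: str
    junctions: list[Junction]
    retained: bool
    inferred_strand: str = "."

    @property
    def n_motif_fail(self) -> int:
        return sum(1 for j in self.junctions if not j.motif_valid)

    @property
    def n_evidence_fail(self) -> int:
        return sum(1 for j in self.junctions if not j.evidence_valid)


def extract_junctions(aln: TranscriptAlignment) -> list[Junction]:
    """The introns implied by consecutive exon blocks.

    A single-exon alignment yields an empty list.  Intron shorter than four
    bases (no room for both splice dinucleotides) raises InvariantError.
    """
    return [
        Junction(chrom=aln.chrom, strand=aln.strand, start=left[1], end=right[0])
        for left, right in zip(aln.exons, aln.exons[1:])
    ]


def check_splice_motifs(
    junction: Junction, genome: GenomeSequence
) -> tuple[bool, str]:
    """Test a junction for canonical GT...AG splice dinucleotides.

    Returns ``(motif_valid, inferred_strand)``.  If the junction's strand is
    known only that orientation is tested; if unknown, both are tried and
    the passing orientation is reported.  When both orientations pass (a
    palindromic-like boundary) the motif is accepted but the strand stays
    unknown, with a warning.  Out-of-bounds junctions are motif-invalid.
    """
    if junction.start < 0 or junction.end > genome.length:
        logger.warning(
            "junction %s:[%d,%d) outside chromosome bounds (length %d)",
            junction.chrom,
            junction.start,
            junction.end,
            genome.length,
        )
        return False, junction.strand
    left = genome.slice(junction.start, junction.start + 2)
    right = genome.slice(junction.end - 2, junction.end)
    plus_ok = left == DONOR_PLUS and right == ACCEPTOR_PLUS
    minus_ok = left == ACCEPTOR_MINUS and right == DONOR_MINUS
    if junction.strand == "+":
        return plus_ok, "+"
    if junction.strand == "-":
        return minus_ok, "-"
    if plus_ok and minus_ok:
        logger.warning(
            "junction %s:[%d,%d): motif canonical on both strands; "
            "strand left unknown",
            junction.chrom,
            junction.start,
            junction.end,
        )
        return True, "."
    if plus_ok:
        return True, "+"
    if minus_ok:
        return True, "-"
    return False, "."


def build_junction_db(
    junction_records: Iterable[tuple[Junction, int]],
    min_support: int = 1,
    strand_aware: bool = False,
) -> JunctionDB:
    """Aggregate (junction, count) records and keep those meeting min_support."""
    totals: dict[tuple, int] = {}
    for junction, count in junction_records:
        if count < 0:
            raise InvariantError(f"negative junction count {count}")
        key = (
            (junction.chrom, junction.start, junction.end, junction.strand)
            if strand_aware
            else junction.coords
        )
        totals[key] = totals.get(key, 0) + count
    entries = {k: n for k, n in totals.items() if n >= max(min_support, 1)}
    return JunctionDB(entries=entries, min_support=min_support, strand_aware=strand_aware)


def validate_alignment(
    aln: TranscriptAlignment,
    genomes: Mapping[str, GenomeSequence] | GenomeSequence,
    db: JunctionDB,
) -> ValidationResult:
    """Run both validation checks on one alignment.

    Retained iff the alignment is multi-exon and every junction is both
    motif-valid and evidence-valid.  Single-exon alignments are never
    retained.  The alignment-level inferred strand is the consensus of
    per-junction motif inference (unknown if junctions disagree).
    """
    if isinstance(genomes, GenomeSequence):
        genomes = {genomes.name: genomes}
    genome = genomes.get(aln.chrom)
    checked: list[Junction] = []
    strands: set[str] = set()
    for junction in extract_junctions(aln):
        if genome is None:
            motif_ok, inferred = False, junction.strand
            logger.warning("no genome sequence for chromosome %s", aln.chrom)
        else:
            motif_ok, inferred = check_splice_motifs(junction, genome)
        evidence_ok = db.supports(junction)
        checked.append(
            replace(
                junction,
                strand=inferred if inferred != "." else junction.strand,
                motif_valid=motif_ok,
                evidence_valid=evidence_ok,
            )
        )
        if motif_ok and inferred != ".":
            strands.add(inferred)
    retained = (
        aln.n_exons >= 2
        and all(j.motif_valid and j.evidence_valid for j in checked)
    )
    inferred_strand = strands.pop() if len(strands) == 1 else "."
    return ValidationResult(
        alignment_id=aln.id,
        junctions=checked,
        retained=retained,
        inferred_strand=inferred_strand,
    )


def validate_all(
    alignments: Iterable[TranscriptAlignment],
    genomes: Mapping[str, GenomeSequence],
    db: JunctionDB,
) -> tuple[list[ValidationResult], list[TranscriptAlignment]]:
    """Validate every alignment; also return retained alignments with
    unknown strands replaced by the motif-inferred strand."""
    results = []
    retained = []
    for aln in alignments:
        res = validate_alignment(aln, genomes, db)
        results.append(res)
        if res.retained:
            if aln.strand == "." and res.inferred_strand != ".":
                aln = replace(aln, strand=res.inferred_strand)
            retained.append(aln)
    return results, retained
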