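"""Synthetic genomes, gene models, long reads and junction evidence.

The generator builds random chromosomes carrying non-overlapping multi-exon
genes with alternative (exon-skipping) isoforms.  Every planted intron gets
canonical GT...AG boundaries in gene orientation.  Long reads are sampled
per isoform and corrupted with the two error modes seen in real long-read
cDNA data:

* **truncation** — reads lose whole 5' and/or 3' terminal exons and part of
  the new terminal exon, as happens with RNA degradation, shearing,
  incomplete amplification or sequencer loading bias.  Internal junction
  coordinates are never altered, so a truncated read is an exact sub-chain
  of its source isoform.
* **donor shift** — with some probability a junction's splice donor is
  moved to the nearest downstream GT within ``max_shift`` bases, imitating
  an aligner placing the exon boundary at the wrong one of several nearby
  candidate donors.  So that the artifact always has a target, every
  planted intron also carries a decoy GT dinucleotide a few bases
  downstream of the true donor.

Short-read junction evidence is simulated at junction level: every true
junction is emitted with a read count (optionally dropped with probability
``p_junction_unsupported``); artifact junctions are never emitted, making
short reads the clean orthogonal oracle.

Ground truth (source isoform per read, every applied modification, the
expected retained codes and expected classification per code) is recorded
machine-readably so each pipeline stage can be tested against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .collapse import make_code
from .errors import ConfigError
from .io import (
    AnnotationSet,
    GenomeSequence,
    TranscriptAlignment,
    write_fasta,
    write_gtf,
    write_junction_tab,
)
from .io import write_bed12
from .validation import Junction, extract_junctions

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Ranges are inclusive ``(low, high)`` pairs.  Gene geometry defaults
    give ~20 genes of 3-6 exons on two 100 kb chromosomes; read counts and
    truncation rates reflect long-read cDNA libraries in which roughly
    half the reads fail to cover their full source transcript.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 20
    isoforms_per_gene: tuple[int, int] = (2, 4)
    exons_per_isoform: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 400)
    n_hidden_genes: int = 0
    n_hidden_isoforms: int = 0
    reads_per_isoform: tuple[int, int] = (5, 20)
    p_truncate_5p: float = 0.4
    p_truncate_3p: float = 0.2
    p_donor_shift: float = 0.0
    max_shift: int = 10
    short_read_coverage_per_junction: tuple[int, int] = (5, 50)
    p_junction_unsupported: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_truncate_5p", "p_truncate_3p", "p_donor_shift", "p_junction_unsupported"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0,1]")
        for name in (
            "isoforms_per_gene",
            "exons_per_isoform",
            "exon_length",
            "intron_length",
            "reads_per_isoform",
            "short_read_coverage_per_junction",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"{name}=({lo},{hi}) is not a valid range")
        if self.exons_per_isoform[0] < 2:
            raise ConfigError("genes need >=2 exons to carry junctions")
        if self.intron_length[0] < self.max_shift + 8:
            raise ConfigError(
                "intron_length lower bound must exceed max_shift + 8 so the "
                "decoy donor fits inside the intron"
            )
        if self.n_hidden_genes > self.n_genes:
            raise ConfigError("cannot hide more genes than are generated")


@dataclass(frozen=True)
class Isoform:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def as_alignment(self) -> TranscriptAlignment:
        return TranscriptAlignment(self.id, self.chrom, self.strand, self.exons, "annotation")

    @property
    def code_text(self) -> str:
        return make_code(self.as_alignment()).text


@dataclass(frozen=True)
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    isoforms: tuple[Isoform, ...]


@dataclass
class SyntheticGenome:
    """Chromosome sequences plus the gene models planted in them."""

    chromosomes: dict[str, GenomeSequence]
    genes: list[Gene]
    config: SimulationConfig

    @property
    def isoforms(self) -> list[Isoform]:
        return [iso for g in self.genes for iso in g.isoforms]

    def annotation(self, hidden_gene_ids: set[str] = frozenset(),
                   hidden_isoform_ids: set[str] = frozenset()) -> AnnotationSet:
        transcripts = []
        gene_of = {}
        for gene in self.genes:
            if gene.id in hidden_gene_ids:
                continue
            for iso in gene.isoforms:
                if iso.id in hidden_isoform_ids:
                    continue
                transcripts.append(iso.as_alignment())
                gene_of[iso.id] = gene.id
        return AnnotationSet(transcripts, gene_of)


@dataclass
class ReadRecord:
    """Ground truth for one simulated long read."""

    read_id: str
    isoform_id: str
    gene_id: str
    truncated_5p: bool
    truncated_3p: bool
    shifted_junctions: list[tuple[int, int]]  # (junction index in read, offset bases)


@dataclass
class GroundTruth:
    """Machine-readable record of everything the simulator did."""

    hidden_gene_ids: list[str]
    hidden_isoform_ids: list[str]
    reads: list[ReadRecord]
    expressed_codes: dict[str, str]  # isoform code text -> isoform id
    expected_retained_codes: set[str] = field(default_factory=set)
    expected_classification: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "hidden_gene_ids": self.hidden_gene_ids,
            "hidden_isoform_ids": self.hidden_isoform_ids,
            "reads": [dataclasses.asdict(r) for r in self.reads],
            "expressed_codes": self.expressed_codes,
            "expected_retained_codes": sorted(self.expected_retained_codes),
            "expected_classification": dict(sorted(self.expected_classification.items())),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _draw(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Random chromosomes with planted multi-exon genes.

    Genes are laid out left to right, round-robin across chromosomes, with
    random intergenic gaps.  Isoforms of one gene share a master exon
    chain; alternatives skip internal exons, so all isoforms of a gene
    share exon boundaries but differ in intron chain.  Every intron gets
    canonical splice dinucleotides in gene orientation plus one decoy
    donor GT at a random offset in [4, max_shift] downstream of the true
    donor.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {
        name: rng.choice(_BASES, size=config.chrom_length)
        for name in chrom_names
    }
    cursors = {name: 0 for name in chrom_names}
    genes: list[Gene] = []
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = _draw(rng, config.exons_per_isoform)
        exon_lens = [_draw(rng, config.exon_length) for _ in range(n_exons)]
        intron_lens = [_draw(rng, config.intron_length) for _ in range(n_exons - 1)]
        gap = int(rng.integers(200, 1001))
        start = cursors[chrom] + gap
        # master exon chain in genomic coordinates
        exons = []
        pos = start
        for i, elen in enumerate(exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_exons - 1:
                pos += intron_lens[i]
        end = pos
        if end > config.chrom_length:
            raise ConfigError(
                f"gene geometry infeasible: gene {gi} would end at {end} on "
                f"{chrom} of length {config.chrom_length}; reduce n_genes or "
                "gene size, or enlarge chromosomes"
            )
        cursors[chrom] = end
        gene_id = f"g{gi + 1:03d}"
        isoforms = _make_isoforms(rng, gene_id, chrom, strand, tuple(exons), config)
        _plant_motifs(seqs[chrom], isoforms, strand, rng, config.max_shift)
        genes.append(
            Gene(gene_id, chrom, strand, start, end, tuple(isoforms))
        )
    chromosomes = {
        name: GenomeSequence(name, seqs[name].tobytes().decode())
        for name in chrom_names
    }
    return SyntheticGenome(chromosomes=chromosomes, genes=genes, config=config)


def _make_isoforms(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    master: tuple[tuple[int, int], ...],
    config: SimulationConfig,
) -> list[Isoform]:
    n_iso = _draw(rng, config.isoforms_per_gene)
    chains: list[tuple[tuple[int, int], ...]] = [master]
    n_internal = len(master) - 2
    attempts = 0
    while len(chains) < n_iso and attempts < 50:
        attempts += 1
        if n_internal == 0:
            break
        n_skip = _draw(rng, (1, n_internal))
        skip = set(rng.choice(n_internal, size=n_skip, replace=False) + 1)
        chain = tuple(e for i, e in enumerate(master) if i not in skip)
        if len(chain) >= 2 and chain not in chains:
            chains.append(chain)
    return [
        Isoform(f"{gene_id}.i{k + 1}", gene_id, chrom, strand, chain)
        for k, chain in enumerate(chains)
    ]


def _plant_motifs(
    seq: np.ndarray,
    isoforms: Iterable[Isoform],
    strand: str,
    rng: np.random.Generator,
    max_shift: int,
) -> None:
    """Write canonical splice dinucleotides (and a decoy donor) per intron."""
    introns = sorted(
        {
            (left[1], right[0])
            for iso in isoforms
            for left, right in zip(iso.exons, iso.exons[1:])
        }
    )
    for s, e in introns:
        if strand == "+":
            seq[s : s + 2] = np.frombuffer(b"GT", dtype="S1")
            seq[e - 2 : e] = np.frombuffer(b"AG", dtype="S1")
            d = int(rng.integers(4, max_shift + 1))
            seq[s + d : s + d + 2] = np.frombuffer(b"GT", dtype="S1")
        else:
            # gene on minus strand: genomic text reads CT ... AC
            seq[s : s + 2] = np.frombuffer(b"CT", dtype="S1")
            seq[e - 2 : e] = np.frombuffer(b"AC", dtype="S1")
            d = int(rng.integers(4, max_shift + 1))
            seq[e - d - 2 : e - d] = np.frombuffer(b"AC", dtype="S1")


def _truncate(
    rng: np.random.Generator,
    exons: list[tuple[int, int]],
    strand: str,
    p5: float,
    p3: float,
) -> tuple[list[tuple[int, int]], bool, bool]:
    """Drop terminal exons / trim terminal exon ends, transcript-oriented.

    Internal junction coordinates are preserved; only the outermost exon
    edge on the truncated side moves.
    """
    t5 = rng.random() < p5
    t3 = rng.random() < p3
    # map transcript 5'/3' onto genomic left/right
    drop_left = t5 if strand != "-" else t3
    drop_right = t3 if strand != "-" else t5
    if drop_left and len(exons) > 1:
        k = int(rng.integers(0, len(exons)))  # may truncate down to one exon
        exons = exons[k:]
    if drop_right and len(exons) > 1:
        k = int(rng.integers(0, len(exons)))
        exons = exons[: len(exons) - k]
    if drop_left:
        s, e = exons[0]
        trim = int(rng.integers(0, max(e - s - 20, 1)))
        exons[0] = (s + trim, e)
    if drop_right:
        s, e = exons[-1]
        trim = int(rng.integers(0, max(e - s - 20, 1)))
        exons[-1] = (s, e - trim)
    return exons, t5, t3


def _find_downstream_gt(
    seq: str, s: int, e: int, strand: str, max_shift: int
) -> int | None:
    """Offset (in transcript direction) of the nearest downstream donor
    dinucleotide within max_shift bases, or None."""
    for d in range(1, max_shift + 1):
        if strand == "+":
            if seq[s + d : s + d + 2] == "GT":
                return d
        else:
            if seq[e - d - 2 : e - d] == "AC":
                return d
    return None


def simulate_long_reads(
    genome: SyntheticGenome, config: SimulationConfig | None = None
) -> tuple[list[TranscriptAlignment], GroundTruth]:
    """Sample truncated, optionally donor-shifted long reads per isoform."""
    config = config or genome.config
    rng = np.random.default_rng([config.seed, 1])
    hidden_genes, hidden_isoforms = _pick_hidden(genome, config)
    reads: list[TranscriptAlignment] = []
    records: list[ReadRecord] = []
    expressed: dict[str, str] = {}
    counter = 0
    for gene in genome.genes:
        for iso in gene.isoforms:
            n_reads = _draw(rng, config.reads_per_isoform)
            if n_reads > 0:
                expressed[iso.code_text] = iso.id
            for _ in range(n_reads):
                counter += 1
                read_id = f"r{counter:06d}"
                exons, t5, t3 = _truncate(
                    rng,
                    list(iso.exons),
                    iso.strand,
                    config.p_truncate_5p,
                    config.p_truncate_3p,
                )
                shifted: list[tuple[int, int]] = []
                if config.p_donor_shift > 0 and len(exons) > 1:
                    seq = genome.chromosomes[iso.chrom].bases
                    for ji in range(len(exons) - 1):
                        if rng.random() >= config.p_donor_shift:
                            continue
                        s, e = exons[ji][1], exons[ji + 1][0]
                        d = _find_downstream_gt(seq, s, e, iso.strand, config.max_shift)
                        if d is None:
                            continue  # no candidate donor: shift impossible, recorded as unshifted
                        if iso.strand == "+":
                            exons[ji] = (exons[ji][0], s + d)  # exon grows into intron
                        else:
                            exons[ji + 1] = (e - d, exons[ji + 1][1])
                        shifted.append((ji, d))
                reads.append(
                    TranscriptAlignment(
                        read_id, iso.chrom, iso.strand, tuple(exons), "long_read"
                    )
                )
                records.append(
                    ReadRecord(read_id, iso.id, gene.id, t5, t3, shifted)
                )
    truth = GroundTruth(
        hidden_gene_ids=sorted(hidden_genes),
        hidden_isoform_ids=sorted(hidden_isoforms),
        reads=records,
        expressed_codes=expressed,
    )
    _fill_expectations(genome, config, reads, truth)
    return reads, truth


def _pick_hidden(
    genome: SyntheticGenome, config: SimulationConfig
) -> tuple[set[str], set[str]]:
    rng = np.random.default_rng([config.seed, 2])
    gene_ids = [g.id for g in genome.genes]
    hidden_genes = set(
        rng.choice(gene_ids, size=config.n_hidden_genes, replace=False).tolist()
        if config.n_hidden_genes
        else []
    )
    candidates = [
        iso.id
        for g in genome.genes
        if g.id not in hidden_genes and len(g.isoforms) > 1
        for iso in g.isoforms[1:]  # keep each gene's first isoform visible
    ]
    n_hide = min(config.n_hidden_isoforms, len(candidates))
    hidden_isoforms = set(
        rng.choice(candidates, size=n_hide, replace=False).tolist() if n_hide else []
    )
    return hidden_genes, hidden_isoforms


def _fill_expectations(
    genome: SyntheticGenome,
    config: SimulationConfig,
    reads: list[TranscriptAlignment],
    truth: GroundTruth,
) -> None:
    """Expected retained codes (assuming complete junction evidence) and
    expected classification per expressed isoform code."""
    shifted_ids = {r.read_id for r in truth.reads if r.shifted_junctions}
    for read in reads:
        if read.n_exons < 2 or read.id in shifted_ids:
            continue
        truth.expected_retained_codes.add(make_code(read).text)
    gene_of_iso = {iso.id: g.id for g in genome.genes for iso in g.isoforms}
    for code_text, iso_id in truth.expressed_codes.items():
        gene = gene_of_iso[iso_id]
        if gene in truth.hidden_gene_ids:
            truth.expected_classification[code_text] = "novel_gene"
        elif iso_id in truth.hidden_isoform_ids:
            truth.expected_classification[code_text] = "novel_isoform_known_gene"
        else:
            truth.expected_classification[code_text] = "annotated"


def simulate_short_read_junctions(
    genome: SyntheticGenome, config: SimulationConfig | None = None
) -> list[tuple[Junction, int]]:
    """Junction-level short-read evidence over all true junctions.

    Every junction of every isoform (hidden genes included — short reads
    see the transcriptome, not the annotation) is emitted with a count
    drawn from ``short_read_coverage_per_junction``, unless dropped with
    probability ``p_junction_unsupported``.  Artifact junctions are never
    emitted.
    """
    config = config or genome.config
    rng = np.random.default_rng([config.seed, 3])
    records = []
    seen = set()
    for gene in genome.genes:
        for iso in gene.isoforms:
            for j in extract_junctions(iso.as_alignment()):
                if j.coords in seen:
                    continue
                seen.add(j.coords)
                if rng.random() < config.p_junction_unsupported:
                    continue
                count = _draw(rng, config.short_read_coverage_per_junction)
                records.append((j, count))
    records.sort(key=lambda jc: (jc[0].chrom, jc[0].start, jc[0].end))
    return records


@dataclass
class SimulatedDataset:
    genome: SyntheticGenome
    reads: list[TranscriptAlignment]
    truth: GroundTruth
    junction_records: list[tuple[Junction, int]]

    @property
    def true_annotation(self) -> AnnotationSet:
        return self.genome.annotation()

    @property
    def emitted_annotation(self) -> AnnotationSet:
        return self.genome.annotation(
            set(self.truth.hidden_gene_ids), set(self.truth.hidden_isoform_ids)
        )

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write genome.fa, truth.gtf, emitted.gtf, reads.bed12,
        junctions.tab and truth.json; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "truth_gtf": outdir / "truth.gtf",
            "emitted_gtf": outdir / "emitted.gtf",
            "reads": outdir / "reads.bed12",
            "junctions": outdir / "junctions.tab",
            "truth_json": outdir / "truth.json",
        }
        write_fasta(self.genome.chromosomes.values(), paths["genome"])
        write_gtf(self.true_annotation, paths["truth_gtf"])
        write_gtf(self.emitted_annotation, paths["emitted_gtf"])
        write_bed12(self.reads, paths["reads"])
        write_junction_tab(self.junction_records, paths["junctions"])
        paths["truth_json"].write_text(self.truth.to_json())
        return {k: str(v) for k, v in paths.items()}


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genome, reads and junction evidence."""
    genome = generate_genome(config)
    reads, truth = simulate_long_reads(genome, config)
    junctions = simulate_short_read_junctions(genome, config)
    return SimulatedDataset(genome, reads, truth, junctions)
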