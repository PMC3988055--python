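"""Collapse validated spliced alignments into isoform models.

Two reads represent the same isoform when they share the same *junction
code* — the ordered chain of their intron coordinates on one chromosome and
strand.  Exact 5'/3' ends vary between reads of one isoform (truncation,
degradation), so after merging reads by code, each model is assigned the
furthest observed transcription start and end over its members.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InvariantError
from .io import GenomeSequence, TranscriptAlignment
from .validation import check_splice_motifs, extract_junctions


@dataclass(frozen=True)
class JunctionCode:
    """Canonical identity of a multi-exon isoform: its ordered intron chain."""

    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.introns:
            raise InvariantError("junction code requires at least one intron")
        prev_end = -1
        for s, e in self.introns:
            if s <= prev_end or e <= s:
                raise InvariantError(f"introns not sorted/disjoint: {self.introns}")
            prev_end = e

    @property
    def text(self) -> str:
        chain = ",".join(f"{s}-{e}" for s, e in self.introns)
        return f"{self.chrom}:{self.strand}:{chain}"

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class IsoformModel:
    """A collapsed isoform: junction code plus furthest observed extent."""

    code: JunctionCode
    start: int
    end: int
    support: int
    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start >= self.code.introns[0][0]:
            raise InvariantError(
                f"model start {self.start} not left of first intron "
                f"{self.code.introns[0]}"
            )
        if self.end <= self.code.introns[-1][1]:
            raise InvariantError(
                f"model end {self.end} not right of last intron "
                f"{self.code.introns[-1]}"
            )

    @property
    def id(self) -> str:
        digest = hashlib.sha1(self.code.text.encode()).hexdigest()[:10]
        return f"iso_{digest}_{self.support}"

    @property
    def chrom(self) -> str:
        return self.code.chrom

    @property
    def strand(self) -> str:
        return self.code.strand

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        """Exon blocks implied by (start, intron chain, end)."""
        bounds = [self.start]
        for s, e in self.code.introns:
            bounds.extend([s, e])
        bounds.append(self.end)
        return tuple((bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2))

    def as_alignment(self, source: str = "long_read") -> TranscriptAlignment:
        return TranscriptAlignment(self.id, self.chrom, self.strand, self.exons, source)


def make_code(
    aln: TranscriptAlignment,
    genomes: Mapping[str, GenomeSequence] | None = None,
) -> JunctionCode:
    """Build the junction code of a multi-exon alignment.

    Strand comes from the alignment; if unknown and a genome is supplied,
    it is inferred from the splice motifs (and stays unknown when the
    junctions disagree or none is canonical).
    """
    junctions = extract_junctions(aln)
    if not junctions:
        raise InvariantError(f"{aln.id}: junction code requires >=2 exons")
    strand = aln.strand
    if strand == "." and genomes is not None:
        genome = genomes.get(aln.chrom) if not isinstance(genomes, GenomeSequence) else genomes
        if genome is not None:
            inferred = {
                s
                for ok, s in (check_splice_motifs(j, genome) for j in junctions)
                if ok and s != "."
            }
            if len(inferred) == 1:
                strand = inferred.pop()
    return JunctionCode(
        chrom=aln.chrom,
        strand=strand,
        introns=tuple((j.start, j.end) for j in junctions),
    )


def collapse(
    alignments: Iterable[TranscriptAlignment],
    genomes: Mapping[str, GenomeSequence] | None = None,
) -> list[IsoformModel]:
    """Merge alignments sharing a junction code into one model each.

    Support counts the merged alignments; the model extent is the furthest
    observed start/end over members.  Output is sorted by (chrom, start,
    code text) so runs are reproducible regardless of input order.
    """
    groups: dict[JunctionCode, list[TranscriptAlignment]] = {}
    for aln in alignments:
        groups.setdefault(make_code(aln, genomes), []).append(aln)
    models = [
        IsoformModel(
            code=code,
            start=min(a.start for a in members),
            end=max(a.end for a in members),
            support=len(members),
            member_ids=tuple(sorted(a.id for a in members)),
        )
        for code, members in groups.items()
    ]
    models.sort(key=lambda m: (m.chrom, m.start, m.code.text))
    return models


def _subchain_offset(
    short: Sequence[tuple[int, int]], long: Sequence[tuple[int, int]]
) -> int | None:
    """Index at which ``short`` occurs as a contiguous run in ``long``."""
    n, m = len(short), len(long)
    for i in range(m - n + 1):
        if tuple(long[i : i + n]) == tuple(short):
            return i
    return None


def subset_collapse(models: Sequence[IsoformModel], enabled: bool = True) -> list[IsoformModel]:
    """Optionally absorb fragment models into longer compatible models.

    A model is absorbed when its intron chain is a contiguous sub-chain of
    another model's chain on the same chromosome and strand, and its extent
    is compatible with the longer model's exon structure: the fragment's
    terminal exons must not reach into introns of the longer chain that
    flank the matched sub-chain.  Supports are summed and extents extended
    when the match sits at the boundary of the longer chain.  When disabled
    (the default pipeline setting) the input is returned unchanged.
    """
    if not enabled:
        return list(models)
    ordered = sorted(
        models, key=lambda m: (-len(m.code.introns), m.chrom, m.start, m.code.text)
    )
    kept: list[IsoformModel] = []
    for model in ordered:
        absorber_idx = None
        for idx, host in enumerate(kept):
            if host.chrom != model.chrom or host.strand != model.strand:
                continue
            if len(host.code.introns) <= len(model.code.introns):
                continue
            off = _subchain_offset(model.code.introns, host.code.introns)
            if off is None:
                continue
            last = off + len(model.code.introns) - 1
            if off > 0 and model.start < host.code.introns[off - 1][1]:
                continue  # fragment's first exon reaches into a host intron
            if last < len(host.code.introns) - 1 and model.end > host.code.introns[last + 1][0]:
                continue  # fragment's last exon reaches into a host intron
            absorber_idx = idx
            break
        if absorber_idx is None:
            kept.append(model)
        else:
            host = kept[absorber_idx]
            off = _subchain_offset(model.code.introns, host.code.introns)
            last = off + len(model.code.introns) - 1
            new_start = min(host.start, model.start) if off == 0 else host.start
            new_end = (
                max(host.end, model.end)
                if last == len(host.code.introns) - 1
                else host.end
            )
            kept[absorber_idx] = IsoformModel(
                code=host.code,
                start=new_start,
                end=new_end,
                support=host.support + model.support,
                member_ids=tuple(sorted(host.member_ids + model.member_ids)),
            )
    kept.sort(key=lambda m: (m.chrom, m.start, m.code.text))
    return kept
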