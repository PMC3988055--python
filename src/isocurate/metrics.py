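"""Descriptive analytics: overlap matrices, coverage profiles and
splice-site distance histograms.

These reproduce the bulk comparisons a curation study reports: what
fraction of one feature set is touched by another (any-overlap, at the
span level), how completely each annotated transcript's exonic bases are
covered by read exons, and how far observed splice donor/acceptor sites
fall from the nearest annotated site of the same kind.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptAlignment
from .validation import Junction

#: default half-width of the splice-distance window, in bases
DEFAULT_WINDOW = 50


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _union_overlap(intervals: list[tuple[int, int]], start: int, end: int) -> int:
    """Bases of [start,end) covered by a sorted, merged interval list."""
    i = bisect.bisect_left(intervals, (start, -1)) - 1
    covered = 0
    if i >= 0 and intervals[i][1] > start:
        covered += min(intervals[i][1], end) - start
    for s, e in intervals[max(i + 1, 0) :]:
        if s >= end:
            break
        covered += min(e, end) - max(s, start)
    return covered


@dataclass
class OverlapMatrix:
    set_names: list[str]
    counts: dict[str, int]
    percent: dict[str, dict[str, float | None]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                [self.percent[r][c] for c in self.set_names]
                for r in self.set_names
            ],
            index=self.set_names,
            columns=self.set_names,
            dtype=object,
        )
        df.insert(0, "total", [self.counts[r] for r in self.set_names])
        return df


def overlap_matrix(
    feature_sets: Mapping[str, Sequence[TranscriptAlignment]]
) -> OverlapMatrix:
    """Any-overlap percentage matrix between named feature sets.

    Cell (row, col) is the percentage of row elements whose span shares at
    least one base with some column element's span (strand-agnostic).  The
    matrix is asymmetric in general; the diagonal is 100% for non-empty
    sets.  Empty rows get count 0 and ``None`` percentages.
    """
    names = list(feature_sets)
    unions = {
        name: {
            chrom: _merge_intervals(
                (f.start, f.end) for f in feats if f.chrom == chrom
            )
            for chrom in {f.chrom for f in feats}
        }
        for name, feats in feature_sets.items()
    }
    counts = {name: len(feature_sets[name]) for name in names}
    percent: dict[str, dict[str, float | None]] = {}
    for row in names:
        percent[row] = {}
        feats = feature_sets[row]
        for col in names:
            if not feats:
                percent[row][col] = None
                continue
            col_union = unions[col]
            hit = sum(
                1
                for f in feats
                if _union_overlap(col_union.get(f.chrom, []), f.start, f.end) > 0
            )
            percent[row][col] = 100.0 * hit / len(feats)
    return OverlapMatrix(set_names=names, counts=counts, percent=percent)


@dataclass
class CoverageProfile:
    """Per-transcript exonic coverage plus length-binned histograms.

    ``table`` has one row per annotated transcript: exonic length, covered
    bases and coverage fraction.  The three histograms share ``bin_edges``
    (last bin is an open overflow bin): all transcripts, transcripts
    overlapped by any amount, and transcripts covered over more than 90%
    of their exonic length (strictly greater).
    """

    table: pd.DataFrame
    bin_edges: np.ndarray
    hist_all: np.ndarray
    hist_any: np.ndarray
    hist_90: np.ndarray


def coverage_profile(
    transcripts: Sequence[TranscriptAlignment],
    reads: Sequence[TranscriptAlignment],
    bin_edges: Sequence[int] | np.ndarray = tuple(range(0, 6250, 250)),
) -> CoverageProfile:
    """Exonic coverage of each annotated transcript by the union of read exons."""
    edges = np.asarray(bin_edges, dtype=int)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >=2 values")
    read_union = {
        chrom: _merge_intervals(
            (s, e) for r in reads if r.chrom == chrom for s, e in r.exons
        )
        for chrom in {r.chrom for r in reads}
    }
    rows = []
    for t in transcripts:
        union = read_union.get(t.chrom, [])
        covered = sum(_union_overlap(union, s, e) for s, e in t.exons)
        length = t.exonic_length
        rows.append(
            {
                "transcript_id": t.id,
                "length": length,
                "covered_bases": covered,
                "fraction": covered / length,
            }
        )
    table = pd.DataFrame(rows, columns=["transcript_id", "length", "covered_bases", "fraction"])

    def hist(lengths: np.ndarray) -> np.ndarray:
        n_bins = len(edges) - 1
        idx = np.searchsorted(edges, lengths, side="right") - 1
        idx = np.clip(idx, 0, n_bins)  # overflow bin at index n_bins
        counts = np.bincount(idx, minlength=n_bins + 1)
        return counts

    lengths = table["length"].to_numpy() if len(table) else np.array([], dtype=int)
    fractions = table["fraction"].to_numpy() if len(table) else np.array([])
    return CoverageProfile(
        table=table,
        bin_edges=edges,
        hist_all=hist(lengths),
        hist_any=hist(lengths[fractions > 0]),
        hist_90=hist(lengths[fractions > 0.90]),
    )


@dataclass
class SpliceDistanceProfile:
    """Signed distances from observed splice sites to the nearest annotated
    site of the same kind, orientation-corrected so positive means
    downstream in transcript direction."""

    site_kind: str  # "donor" or "acceptor"
    window: int
    histogram: Counter = field(default_factory=Counter)
    overflow: int = 0

    @property
    def total(self) -> int:
        return sum(self.histogram.values()) + self.overflow

    @property
    def nonzero_fraction(self) -> float:
        """Fraction of in-window sites at a nonzero offset."""
        in_window = sum(self.histogram.values())
        if in_window == 0:
            return 0.0
        return (in_window - self.histogram.get(0, 0)) / in_window


def _site_positions(junction: Junction) -> dict[str, int]:
    """Genomic coordinate of the donor and acceptor site of a junction.

    The donor is the transcript-5' end of the intron: intron start on the
    plus strand, intron end on the minus strand.  Coordinates follow the
    half-open convention of the intron interval itself.
    """
    if junction.strand == "+":
        return {"donor": junction.start, "acceptor": junction.end}
    if junction.strand == "-":
        return {"donor": junction.end, "acceptor": junction.start}
    raise ValueError("cannot orient a junction with unknown strand")


def splice_distance_profile(
    observed: Iterable[Junction],
    annotated: Iterable[Junction],
    window: int = DEFAULT_WINDOW,
) -> dict[str, SpliceDistanceProfile]:
    """Distance histograms of observed donor/acceptor sites vs annotation.

    For each observed site the nearest annotated site of the same kind on
    the same chromosome is found; the signed offset (observed - annotated)
    is flipped on the minus strand so that positive always means
    downstream in transcript direction.  Sites farther than ``window``
    from any annotated site land in the overflow bucket; ties in absolute
    distance resolve toward the lower-coordinate annotated site.  Observed
    junctions with unknown strand are skipped (they cannot be oriented).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ann_sites: dict[tuple[str, str], list[int]] = {}
    for j in annotated:
        if j.strand == ".":
            continue
        for kind, pos in _site_positions(j).items():
            ann_sites.setdefault((kind, j.chrom), []).append(pos)
    for positions in ann_sites.values():
        positions.sort()

    profiles = {
        kind: SpliceDistanceProfile(site_kind=kind, window=window)
        for kind in ("donor", "acceptor")
    }
    for j in observed:
        if j.strand == ".":
            continue
        for kind, pos in _site_positions(j).items():
            positions = ann_sites.get((kind, j.chrom), [])
            prof = profiles[kind]
            if not positions:
                prof.overflow += 1
                continue
            i = bisect.bisect_left(positions, pos)
            candidates = positions[max(i - 1, 0) : i + 1]
            nearest = min(candidates, key=lambda p: (abs(pos - p), p))
            delta = pos - nearest
            if j.strand == "-":
                delta = -delta
            if abs(delta) > window:
                prof.overflow += 1
            else:
                prof.histogram[delta] += 1
    return profiles
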