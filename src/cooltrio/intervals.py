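"""Genomic interval algebra shared by every analysis stage.

All coordinates are 0-based, half-open ``[start, end)``.  Interval algebra is
strand-blind; strand only matters for strand-relative definitions (promoters,
metagene windows), which live on :class:`GeneModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional BED6-style annotation."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end <= start"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other`` (<= 0 means disjoint; negative = gap)."""
        if self.chrom != other.chrom:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)


@dataclass(frozen=True)
class MergedInterval:
    """A merged interval carrying the ids of its source intervals.

    Provenance is kept because merged-NDR support counting needs distinct
    contributing *cells*, not counts of source intervals.
    """

    chrom: str
    start: int
    end: int
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end <= start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def support(self) -> int:
        return len(self.sources)

    def to_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, score=self.support)


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates with strand-oriented promoter and body derivations.

    ``tss``/``tes`` are 0-based.  On the minus strand the gene body occupies
    ``[tes, tss)`` so the body length is exactly ``|tss - tes|`` on both
    strands; the promoter covers 1 kb upstream and 0.5 kb downstream of the
    TSS in transcription orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and self.tes <= self.tss:
            raise ValueError(f"gene {self.gene_id}: + strand requires tes > tss")
        if self.strand == "-" and self.tss <= self.tes:
            raise ValueError(f"gene {self.gene_id}: - strand requires tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    def promoter(self, upstream: int = 1000, downstream: int = 500) -> GenomicInterval:
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream, self.tss + upstream
        return GenomicInterval(self.chrom, max(0, start), end, name=self.gene_id,
                               strand=self.strand)

    def body(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi, name=self.gene_id, strand=self.strand)


def _validate(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    out = []
    for i, iv in enumerate(intervals):
        if not isinstance(iv, GenomicInterval):
            raise TypeError(f"record {i} is not a GenomicInterval: {iv!r}")
        out.append(iv)
    return out


def merge_intervals(
    intervals: Sequence[GenomicInterval], min_overlap: int = 0
) -> list[MergedInterval]:
    """Merge intervals that overlap by ``min_overlap`` or more bases.

    Implements the negative-gap semantics of ``bedtools merge -d -<min_overlap>``:
    scanning intervals sorted by start, an interval joins the running cluster
    when ``start <= cluster_end - min_overlap``; merging is therefore
    transitive (chained).  With ``min_overlap=0`` touching intervals merge;
    with ``min_overlap=1`` this is the classical union of overlapping
    intervals.  Each merged interval carries the set of source interval ids
    (``name`` when set, else the coordinate string).
    """
    if min_overlap < 0:
        raise ValueError("min_overlap must be >= 0")
    ivs = _validate(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    merged: list[MergedInterval] = []
    for chrom in sorted(by_chrom):
        chunk = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = chunk[0].start, chunk[0].end
        cur_sources = {chunk[0].id}
        for iv in chunk[1:]:
            if iv.start <= cur_end - min_overlap:
                cur_end = max(cur_end, iv.end)
                cur_sources.add(iv.id)
            else:
                merged.append(MergedInterval(chrom, cur_start, cur_end,
                                             frozenset(cur_sources)))
                cur_start, cur_end, cur_sources = iv.start, iv.end, {iv.id}
        merged.append(MergedInterval(chrom, cur_start, cur_end, frozenset(cur_sources)))
    return merged


@dataclass(frozen=True)
class IntersectResult:
    n_query: int
    n_overlapping: int

    @property
    def fraction(self) -> float:
        return self.n_overlapping / self.n_query


def build_tree(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def max_single_overlap(
    iv: GenomicInterval, trees: dict[str, IntervalTree]
) -> int:
    """Largest bp overlap between ``iv`` and any single interval in ``trees``."""
    tree = trees.get(iv.chrom)
    if tree is None:
        return 0
    best = 0
    for hit in tree.overlap(iv.start, iv.end):
        best = max(best, min(iv.end, hit.end) - max(iv.start, hit.begin))
    return best


def intersect_fraction(
    query: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> IntersectResult:
    """Fraction of query intervals overlapping the reference by >= ``min_overlap`` bp.

    Overlap is evaluated against a single reference partner (the best one),
    not cumulatively across partners; each query counts at most once.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    q = _validate(query)
    if not q:
        raise ValueError("intersect_fraction is undefined for an empty query")
    trees = build_tree(_validate(reference))
    n_hit = sum(1 for iv in q if max_single_overlap(iv, trees) >= min_overlap)
    return IntersectResult(n_query=len(q), n_overlapping=n_hit)


def tile_genome(chrom_sizes: dict[str, int], width: int) -> list[GenomicInterval]:
    """Consecutive fixed-width windows per chromosome.

    The terminal partial window is retained with its true length.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    tiles = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        starts = np.arange(0, size, width)
        for s in starts:
            tiles.append(GenomicInterval(chrom, int(s), int(min(s + width, size))))
    return tiles
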