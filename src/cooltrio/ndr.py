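"""Nucleosome-depleted region (NDR) calling from binary GCH accessibility.

Per cell, 100-bp windows sliding by 20 bp are tested (2x2 chi-square, 1 df, no
continuity correction) for accessibility enrichment over the same cell's
genome-wide background; significant windows (p < 1e-15 and window rate above
background) are unioned into candidate regions, which become single-cell NDRs
(scNDRs) when they span > 140 bp and contain >= 5 covered GCH sites.  scNDRs
are merged across cells into mNDRs when they overlap by >= 100 bp, support is
counted as distinct contributing cells, and group-specific mNDRs are those
with zero overlap with the other group's mNDRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (GenomicInterval, MergedInterval, build_tree,
                        max_single_overlap, merge_intervals)
from .io import SiteCallTable, write_bed
from .methylome import _binary_arrays

P_THRESHOLD = 1e-15
WINDOW = 100
STEP = 20
MIN_LENGTH = 140  # NDR span must exceed this
MIN_SITES = 5
MERGE_OVERLAP = 100


@dataclass(frozen=True)
class NDR:
    """Single-cell nucleosome-depleted region."""

    cell_id: str
    chrom: str
    start: int
    end: int
    n_gch: int
    min_p: float

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.cell_id)


@dataclass(frozen=True)
class MergedNDR:
    chrom: str
    start: int
    end: int
    cells: frozenset
    group: str = ""

    @property
    def support(self) -> int:
        return len(self.cells)

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=f"{self.chrom}:{self.start}-{self.end}",
                               score=self.support)


def chi2_enrichment(acc_in, n_in, acc_total, n_total):
    """Vectorised 2x2 chi-square (no Yates correction) of window vs rest of genome.

    Cells: (accessible, inaccessible) x (in window, out of window).  Returns
    (chi2, p).  Degenerate tables (a zero margin) give chi2 = 0, p = 1.
    """
    a = np.asarray(acc_in, dtype=np.float64)
    n_in = np.asarray(n_in, dtype=np.float64)
    b = n_in - a
    c = acc_total - a
    d = (n_total - n_in) - c
    n = np.float64(n_total)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def scan_cell(
    table: SiteCallTable,
    chrom_sizes: Mapping[str, int] | None = None,
    window: int = WINDOW,
    step: int = STEP,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Significant accessibility-enriched windows for one cell.

    The background is this cell's genome-wide binary GCH calls.  A window is
    kept iff its chi-square p-value is below ``p_threshold`` *and* its
    accessible-call rate exceeds the background rate (the test is two-sided,
    so depleted windows must be excluded explicitly).
    """
    arrays = _binary_arrays(table, "GCH")
    n_total = sum(len(pos) for pos, _ in arrays.values())
    if n_total == 0:
        raise ValueError(f"cell {table.cell_id}: no GCH calls for background")
    acc_total = sum(float(calls.sum()) for _, calls in arrays.values())
    bg_rate = acc_total / n_total

    frames = []
    for chrom, (pos, calls) in arrays.items():
        size = chrom_sizes[chrom] if chrom_sizes else int(pos[-1]) + 1
        starts = np.arange(0, max(size - window, 0) + 1, step, dtype=np.int64)
        csum = np.concatenate([[0.0], np.cumsum(calls)])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n_in = (hi - lo).astype(np.float64)
        acc_in = csum[hi] - csum[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(n_in > 0, acc_in / n_in, 0.0)
        cand = (n_in > 0) & (rate > bg_rate)
        if not cand.any():
            continue
        chi2, p = chi2_enrichment(acc_in[cand], n_in[cand], acc_total, n_total)
        keep = p < p_threshold
        if not keep.any():
            continue
        sel = np.flatnonzero(cand)[keep]
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts[sel],
            "end": starts[sel] + window,
            "n_gch": n_in[sel].astype(int),
            "n_accessible": acc_in[sel].astype(int),
            "chi2": chi2[keep],
            "p": p[keep],
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_gch",
                                     "n_accessible", "chi2", "p"])
    return pd.concat(frames, ignore_index=True)


def windows_to_scndrs(
    windows: pd.DataFrame,
    table: SiteCallTable,
    min_length: int = MIN_LENGTH,
    min_sites: int = MIN_SITES,
) -> list[NDR]:
    """Union overlapping/adjacent significant windows into scNDRs.

    Candidates are kept iff their span exceeds ``min_length`` bp and they
    contain >= ``min_sites`` covered GCH calls; the minimum window p is kept.
    """
    if len(windows) == 0:
        return []
    arrays = _binary_arrays(table, "GCH")
    ndrs: list[NDR] = []
    for chrom, sub in windows.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        pos = arrays[chrom][0] if chrom in arrays else np.empty(0, dtype=np.int64)
        cur_start = cur_end = None
        cur_p = np.inf
        def flush(start, end, min_p):
            n = int(np.searchsorted(pos, end, side="left")
                    - np.searchsorted(pos, start, side="left"))
            if end - start > min_length and n >= min_sites:
                ndrs.append(NDR(table.cell_id, chrom, int(start), int(end), n, min_p))
        for r in sub.itertuples():
            if cur_start is None:
                cur_start, cur_end, cur_p = r.start, r.end, r.p
            elif r.start <= cur_end:  # share >=1 bp or touch
                cur_end = max(cur_end, r.end)
                cur_p = min(cur_p, r.p)
            else:
                flush(cur_start, cur_end, cur_p)
                cur_start, cur_end, cur_p = r.start, r.end, r.p
        flush(cur_start, cur_end, cur_p)
    return ndrs


def call_cell_ndrs(
    table: SiteCallTable,
    chrom_sizes: Mapping[str, int] | None = None,
    **params,
) -> list[NDR]:
    """Scan one cell and assemble its scNDRs."""
    scan_kw = {k: params[k] for k in ("window", "step", "p_threshold") if k in params}
    asm_kw = {k: params[k] for k in ("min_length", "min_sites") if k in params}
    windows = scan_cell(table, chrom_sizes, **scan_kw)
    return windows_to_scndrs(windows, table, **asm_kw)


def merge_to_mndrs(
    scndrs: Sequence[NDR],
    min_support: int = 1,
    min_overlap: int = MERGE_OVERLAP,
    group: str = "",
) -> list[MergedNDR]:
    """Merge scNDRs (>= ``min_overlap`` bp overlap, transitive) into mNDRs.

    Support counts *distinct contributing cells*; mNDR coordinates are the
    union span of the contributing scNDRs.  mNDRs with support below
    ``min_support`` are dropped.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    ivs = [GenomicInterval(n.chrom, n.start, n.end, name=f"{n.cell_id}|{i}")
           for i, n in enumerate(scndrs)]
    merged = merge_intervals(ivs, min_overlap=min_overlap)
    out = []
    for m in merged:
        cells = frozenset(src.split("|")[0] for src in m.sources)
        if len(cells) >= min_support:
            out.append(MergedNDR(m.chrom, m.start, m.end, cells, group))
    return out


def support_threshold(n_cells: int, fraction: float = 0.05, floor: int = 1) -> int:
    """Per-group mNDR support threshold as a fraction of group size."""
    return max(floor, round(n_cells * fraction))


def expected_covered_cells(n_cells: int, site_coverage: float) -> int:
    """Expected number of cells in which any one GCH site is detected.

    With per-cell site coverage c, a site is seen in about ``n_cells * c``
    cells; a support threshold of 5% of all cells therefore corresponds to
    roughly ``0.05 / c`` of the cells actually covering the site.
    """
    return round(n_cells * site_coverage)


@dataclass
class GroupSpecificResult:
    a_specific: list[MergedNDR]
    b_specific: list[MergedNDR]
    shared_a: list[MergedNDR]
    shared_b: list[MergedNDR]
    ambiguous_a: list[MergedNDR]
    ambiguous_b: list[MergedNDR]


def group_specific_mndrs(
    group_a: Sequence[MergedNDR],
    group_b: Sequence[MergedNDR],
    shared_min_overlap: int = 100,
) -> GroupSpecificResult:
    """Partition two groups' mNDRs into specific / shared / ambiguous.

    Shared requires >= ``shared_min_overlap`` bp overlap with some mNDR of the
    other group; specific requires *zero* overlap; mNDRs overlapping by 1 to
    ``shared_min_overlap - 1`` bp fall in neither bucket and are reported as
    ambiguous.
    """
    def classify(query, other):
        trees = build_tree([m.to_interval() for m in other])
        specific, shared, ambiguous = [], [], []
        for m in query:
            ov = max_single_overlap(m.to_interval(), trees)
            if ov == 0:
                specific.append(m)
            elif ov >= shared_min_overlap:
                shared.append(m)
            else:
                ambiguous.append(m)
        return specific, shared, ambiguous

    a_spec, a_shared, a_amb = classify(group_a, group_b)
    b_spec, b_shared, b_amb = classify(group_b, group_a)
    return GroupSpecificResult(a_spec, b_spec, a_shared, b_shared, a_amb, b_amb)


def export_for_motif_search(mndrs: Sequence[MergedNDR], path) -> None:
    """BED6 export of mNDRs (support in the score column) for motif tools."""
    ivs = [m.to_interval() for m in
           sorted(mndrs, key=lambda m: (m.chrom, m.start, m.end))]
    write_bed(ivs, path, header="chrom\tstart\tend\tname\tsupport\tstrand")
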