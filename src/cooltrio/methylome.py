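"""Cell QC, usable-site filtering, feature/tile-level quantification, global
levels, accessibility normalization, and classical MDS of promoter profiles.

The quantification convention follows single-cell bisulfite practice: site
fractions are first reduced to confident binary states (>0.9 -> methylated,
<0.1 -> unmethylated, intermediates discarded), element and tile levels are
means of those binary calls and are reported only when backed by >= 3 covered
sites, and per-cell global levels are the *tile-weighted* (not site-weighted)
mean over qualifying 1-kb tiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .io import SiteCallTable

# DNA-library QC thresholds (scCOOL-seq style)
DNA_MIN_COVERAGE = 0.04
DNA_MIN_WCG_SITES = 800_000
DNA_MIN_GCH_SITES = 5_000_000
DNA_MIN_MAPPING = 0.05
DNA_MIN_CONVERSION = 0.98
# RNA-library QC thresholds
RNA_MIN_GENES = 1_500
RNA_MAX_GENES = 9_000
RNA_MAX_UMIS = 400_000


@dataclass
class CellQCRecord:
    cell_id: str
    genome_coverage: float | None = None
    n_wcg_sites: int | None = None
    n_gch_sites: int | None = None
    mapping_ratio: float | None = None
    conversion_rate: float | None = None
    n_detected_genes: int | None = None
    n_umis: int | None = None


def filter_cells(records: Sequence[CellQCRecord], mode: str) -> list[str]:
    """Return ids of cells passing QC for ``mode`` ('dna' or 'rna').

    All >=/<= comparisons are boundary-inclusive; for RNA, cells with more
    than 400,000 UMIs fail.
    """
    passing = []
    for rec in records:
        if mode == "dna":
            fields = (rec.genome_coverage, rec.n_wcg_sites, rec.n_gch_sites,
                      rec.mapping_ratio, rec.conversion_rate)
            if any(f is None for f in fields):
                raise ValueError(f"cell {rec.cell_id}: missing DNA QC fields")
            ok = (rec.genome_coverage >= DNA_MIN_COVERAGE
                  and rec.n_wcg_sites >= DNA_MIN_WCG_SITES
                  and rec.n_gch_sites >= DNA_MIN_GCH_SITES
                  and rec.mapping_ratio >= DNA_MIN_MAPPING
                  and rec.conversion_rate >= DNA_MIN_CONVERSION)
        elif mode == "rna":
            if rec.n_detected_genes is None or rec.n_umis is None:
                raise ValueError(f"cell {rec.cell_id}: missing RNA QC fields")
            ok = (RNA_MIN_GENES <= rec.n_detected_genes <= RNA_MAX_GENES
                  and rec.n_umis <= RNA_MAX_UMIS)
        else:
            raise ValueError(f"unknown QC mode {mode!r}")
        if ok:
            passing.append(rec.cell_id)
    return passing


def qc_records_from_frame(df: pd.DataFrame) -> list[CellQCRecord]:
    cols = set(df.columns)
    recs = []
    for r in df.itertuples():
        kwargs = {c: getattr(r, c) for c in
                  ("genome_coverage", "n_wcg_sites", "n_gch_sites", "mapping_ratio",
                   "conversion_rate", "n_detected_genes", "n_umis") if c in cols}
        recs.append(CellQCRecord(cell_id=str(r.cell_id), **kwargs))
    return recs


def usable_sites(table: SiteCallTable, high: float = 0.9, low: float = 0.1) -> SiteCallTable:
    """Keep confident sites only and binarize them.

    Sites with ``meth_fraction > high`` become ``call=1``, ``< low`` become
    ``call=0``; intermediates are dropped (strict inequalities on both sides).
    """
    df = table.data
    frac = df["meth_fraction"].to_numpy()
    keep = (frac > high) | (frac < low)
    out = df.loc[keep].copy()
    out["call"] = (out["meth_fraction"].to_numpy() > high).astype(np.int8)
    return SiteCallTable(table.cell_id, out.reset_index(drop=True))


def _binary_arrays(table: SiteCallTable, context: str):
    """Per-chromosome sorted positions and call values for one context."""
    if "call" not in table.data.columns:
        raise ValueError("site table is not binarized; run usable_sites first")
    df = table.data[table.data["context"] == context]
    out = {}
    for chrom, sub in df.groupby("chrom", observed=True, sort=False):
        pos = sub["pos"].to_numpy(np.int64)
        calls = sub["call"].to_numpy(np.float64)
        out[str(chrom)] = (pos, calls)
    return out


def feature_level(
    table: SiteCallTable,
    features: Sequence[GenomicInterval],
    context: str,
    min_sites: int = 3,
) -> tuple[pd.Series, pd.Series]:
    """Mean binary call per feature for one cell; NA when < ``min_sites`` sites.

    Returns ``(levels, counts)`` indexed by feature id.
    """
    arrays = _binary_arrays(table, context)
    ids = [f.id for f in features]
    levels = np.full(len(features), np.nan)
    counts = np.zeros(len(features), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, f in enumerate(features):
        by_chrom.setdefault(f.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        if chrom not in arrays:
            continue
        pos, calls = arrays[chrom]
        csum = np.concatenate([[0.0], np.cumsum(calls)])
        starts = np.array([features[i].start for i in idxs])
        ends = np.array([features[i].end for i in idxs])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n = hi - lo
        total = csum[hi] - csum[lo]
        idx_arr = np.asarray(idxs)
        counts[idx_arr] = n
        ok = n >= min_sites
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(ok, total / np.maximum(n, 1), np.nan)
        levels[idx_arr] = vals
    return (pd.Series(levels, index=ids, name=table.cell_id),
            pd.Series(counts, index=ids, name=table.cell_id))


@dataclass
class LevelMatrix:
    """Features x cells mean-level matrix with the matching covered-site counts."""

    levels: pd.DataFrame
    counts: pd.DataFrame
    context: str

    def __post_init__(self) -> None:
        if not self.levels.index.equals(self.counts.index) or \
                not self.levels.columns.equals(self.counts.columns):
            raise ValueError("levels and counts must share index and columns")


def feature_level_matrix(
    tables: Mapping[str, SiteCallTable],
    features: Sequence[GenomicInterval],
    context: str,
    min_sites: int = 3,
) -> LevelMatrix:
    levels, counts = {}, {}
    for cell, table in tables.items():
        lv, ct = feature_level(table, features, context, min_sites)
        levels[cell] = lv
        counts[cell] = ct
    return LevelMatrix(pd.DataFrame(levels), pd.DataFrame(counts), context)


@dataclass(frozen=True)
class GlobalLevel:
    cell_id: str
    context: str
    level: float
    n_tiles: int


def global_level(
    table: SiteCallTable,
    context: str,
    tile_size: int = 1000,
    min_sites: int = 3,
) -> GlobalLevel:
    """Per-cell global level: unweighted mean over qualifying 1-kb tile means.

    Tiles are consecutive fixed-size windows; a tile qualifies when it holds
    >= ``min_sites`` covered sites of the requested context.  Tiles are
    equally weighted regardless of how many sites they contain.
    """
    if "call" not in table.data.columns:
        raise ValueError("site table is not binarized; run usable_sites first")
    df = table.data[table.data["context"] == context]
    if len(df) == 0:
        raise ValueError(f"cell {table.cell_id}: no {context} calls")
    tile = df["pos"].to_numpy(np.int64) // tile_size
    grouped = pd.DataFrame({
        "chrom": df["chrom"].to_numpy(), "tile": tile,
        "call": df["call"].to_numpy(np.float64),
    }).groupby(["chrom", "tile"], observed=True)["call"].agg(["mean", "size"])
    qual = grouped[grouped["size"] >= min_sites]
    if len(qual) == 0:
        raise ValueError(f"cell {table.cell_id}: no tile holds >= {min_sites} "
                         f"{context} sites; global level undefined")
    return GlobalLevel(table.cell_id, context, float(qual["mean"].mean()), len(qual))


def normalize_accessibility(
    matrix: LevelMatrix, globals_: Mapping[str, GlobalLevel | float]
) -> LevelMatrix:
    """Divide each cell's GCH levels by that cell's global accessibility."""
    if matrix.context != "GCH":
        raise ValueError("accessibility normalization applies to GCH matrices")
    scaled = matrix.levels.copy()
    for cell in scaled.columns:
        if cell not in globals_:
            raise ValueError(f"no global accessibility for cell {cell}")
        g = globals_[cell]
        g = g.level if isinstance(g, GlobalLevel) else float(g)
        if not g > 0:
            raise ValueError(f"cell {cell}: global accessibility must be > 0")
        scaled[cell] = scaled[cell] / g
    return LevelMatrix(scaled, matrix.counts.copy(), matrix.context)


def classical_mds(dist: np.ndarray, n_components: int = 2):
    """Torgerson MDS: eigendecomposition of the double-centred squared
    distance matrix.  Returns (coords, eigenvalues sorted descending)."""
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :n_components] * np.sqrt(np.clip(evals[:n_components], 0, None))
    return coords, evals


def promoter_mds(
    levels: pd.DataFrame,
    min_cell_fraction: float = 0.5,
    n_components: int = 2,
):
    """Classical MDS of cells from a promoter-level matrix.

    Features are restricted to those observed (non-NA) in at least
    ``min_cell_fraction`` of the cells; remaining NAs are imputed with the
    feature mean; cells are embedded from pairwise Euclidean distances.
    Returns ``(coords: cells x k DataFrame, eigenvalues)``.
    """
    if levels.shape[1] < 3:
        raise ValueError("MDS needs at least 3 cells")
    frac = levels.notna().mean(axis=1)
    kept = levels.loc[frac >= min_cell_fraction]
    if kept.shape[0] < 3:
        raise ValueError(
            f"only {kept.shape[0]} promoters covered in >= "
            f"{min_cell_fraction:.0%} of cells; need >= 3")
    filled = kept.apply(lambda row: row.fillna(row.mean()), axis=1)
    x = filled.to_numpy().T  # cells x features
    diff = x[:, None, :] - x[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    coords, evals = classical_mds(dist, n_components)
    cols = [f"MDS{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=levels.columns, columns=cols), evals
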