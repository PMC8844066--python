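"""Relative DNA methylation degree / demethylation degree of cancer cells and
its multi-resolution rank correlation with genomic feature densities.

For cancer cell i and genomic window j, the relative methylation degree is
``R_DMeD[i, j] = level[i, j] / baseline[j]`` where ``baseline[j]`` is the
median level of the normal cells in window j, and the demethylation degree is
``DDemeD[i, j] = 1 - R_DMeD[i, j]``.  Negative DDemeD values (cancer more
methylated than the normal baseline) are retained, not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crossomics import spearman
from .dmr import rank_sum_test
from .intervals import GenomicInterval, merge_intervals, tile_genome
from .methylome import GlobalLevel

RESOLUTIONS = (250_000, 500_000, 1_000_000, 2_500_000, 5_000_000, 10_000_000)


def window_genome(chrom_sizes: Mapping[str, int], resolution: int) -> list[GenomicInterval]:
    """Equal-length windows per chromosome; the terminal partial window is
    retained with its true length."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return tile_genome(dict(chrom_sizes), resolution)


def feature_density(
    track: Sequence[GenomicInterval],
    windows: Sequence[GenomicInterval],
    name: str = "",
) -> pd.Series:
    """Per-window density: merged-track overlap length / true window length."""
    merged = merge_intervals(track, min_overlap=1) if track else []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {m.chrom for m in merged}:
        sub = sorted((m for m in merged if m.chrom == chrom), key=lambda m: m.start)
        by_chrom[chrom] = (np.array([m.start for m in sub]),
                           np.array([m.end for m in sub]))
    dens = np.zeros(len(windows))
    for i, w in enumerate(windows):
        if w.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[w.chrom]
        ov = np.minimum(ends, w.end) - np.maximum(starts, w.start)
        dens[i] = float(np.clip(ov, 0, None).sum()) / w.length
    return pd.Series(dens, index=[w.id for w in windows], name=name or "density")


@dataclass
class DemethylationMap:
    """Cancer-cells x windows demethylation degrees at one resolution."""

    resolution: int
    windows: list[GenomicInterval]
    r_dmed: pd.DataFrame   # windows x cancer cells
    ddemed: pd.DataFrame   # 1 - r_dmed, same shape
    baseline: pd.Series    # per-window median of normal cells


def compute_ddemed(
    normal_levels: pd.DataFrame,
    cancer_levels: pd.DataFrame,
    windows: Sequence[GenomicInterval],
    resolution: int,
    min_normal_cells: int = 3,
) -> DemethylationMap:
    """Demethylation map from windowed WCG level matrices (windows x cells).

    The per-window baseline is the median over informative (non-NA) normal
    cells and is left undefined (NA) when fewer than ``min_normal_cells``
    normal cells are informative or the median is 0; entries inherit NA from
    the baseline or from the cancer cell's own coverage.
    """
    if not normal_levels.index.equals(cancer_levels.index):
        raise ValueError("normal and cancer matrices must share the window index")
    informative = normal_levels.notna().sum(axis=1)
    baseline = normal_levels.median(axis=1, skipna=True)
    baseline[informative < min_normal_cells] = np.nan
    if baseline.isna().all():
        raise ValueError("baseline undefined in every window")
    denom = baseline.replace(0.0, np.nan)
    r = cancer_levels.div(denom, axis=0)
    return DemethylationMap(resolution=resolution, windows=list(windows),
                            r_dmed=r, ddemed=1.0 - r, baseline=baseline)


def correlate_ddemed(
    dmap: DemethylationMap,
    tracks: Mapping[str, pd.Series],
    min_windows: int = 3,
) -> pd.DataFrame:
    """Per-cancer-cell Spearman of DDemeD against each feature-density track.

    Tracks must be indexed by the same window ids as the map.  Returns a
    cells x features frame of rho values (NaN when fewer than ``min_windows``
    shared non-NA windows or zero rank variance).
    """
    out = {}
    for feat, dens in tracks.items():
        dens = dens.reindex(dmap.ddemed.index)
        if dens.isna().all():
            raise ValueError(f"track {feat!r} shares no windows with the map")
        rhos = {}
        for cell in dmap.ddemed.columns:
            d = dmap.ddemed[cell].to_numpy(float)
            t = dens.to_numpy(float)
            ok = ~(np.isnan(d) | np.isnan(t))
            if ok.sum() < min_windows:
                rhos[cell] = float("nan")
            else:
                rhos[cell] = spearman(d[ok], t[ok])
        out[feat] = pd.Series(rhos)
    return pd.DataFrame(out)


def multi_resolution_correlations(
    chrom_sizes: Mapping[str, int],
    level_fn,
    tracks: Mapping[str, Sequence[GenomicInterval]],
    resolutions: Sequence[int] = RESOLUTIONS,
    min_normal_cells: int = 3,
) -> pd.DataFrame:
    """Demethylation-density correlations across resolutions.

    ``level_fn(windows)`` must return ``(normal_levels, cancer_levels)``
    window x cell matrices for a given window list.  Returns a tidy frame
    (resolution, cell, feature, rho).
    """
    rows = []
    for res in resolutions:
        windows = window_genome(chrom_sizes, res)
        normal_lv, cancer_lv = level_fn(windows)
        dmap = compute_ddemed(normal_lv, cancer_lv, windows, res, min_normal_cells)
        dens = {name: feature_density(track, windows, name)
                for name, track in tracks.items()}
        rhos = correlate_ddemed(dmap, dens)
        for cell in rhos.index:
            for feat in rhos.columns:
                rows.append({"resolution": res, "cell": cell,
                             "feature": feat, "rho": rhos.loc[cell, feat]})
    return pd.DataFrame(rows)


def subclone_demethylation_summary(
    global_levels: Mapping[str, GlobalLevel | float],
    subclones: Mapping[str, str] | pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subclone global-methylation summary and pairwise rank-sum p-values.

    Returns ``(summary, pairwise_p)``; a subclone with a single cell yields NA
    p-values against every other subclone.
    """
    subclones = pd.Series(subclones)
    levels = pd.Series({c: (g.level if isinstance(g, GlobalLevel) else float(g))
                        for c, g in global_levels.items()})
    labels = sorted(subclones.unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 subclones")
    values = {}
    rows = []
    for lab in labels:
        cells = subclones.index[subclones == lab]
        v = levels.reindex(cells).dropna().to_numpy()
        if len(v) == 0:
            raise ValueError(f"subclone {lab!r} is empty")
        values[lab] = v
        rows.append({"subclone": lab, "n_cells": len(v),
                     "mean": float(v.mean()), "median": float(np.median(v))})
    summary = pd.DataFrame(rows).set_index("subclone")
    pw = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if len(values[a]) >= 2 and len(values[b]) >= 2:
                p = rank_sum_test(values[a], values[b])
                pw.loc[a, b] = pw.loc[b, a] = p
    return summary, pw
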