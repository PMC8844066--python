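"""Bin-level somatic copy-number profiles, sex-chromosome adjustment,
aneuploidy calling, subclone clustering, and the methylation / copy-number
correlation.

Bins are an input (any interval set); the module implements the normalization
convention: per-cell counts are turned into frequencies, divided by the median
control (normal) profile, and scaled to a diploid baseline of 2.  The X and Y
values of *all* cells are halved afterwards, matching the convention of using
male normal cells (one X, one Y) as controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .intervals import GenomicInterval

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}
ANEUPLOID_DEVIATION = 0.5
ANEUPLOID_BIN_FRACTION = 0.05


@dataclass
class CNVProfile:
    """Bins x cells copy-number values on the diploid scale."""

    bins: list[GenomicInterval]
    values: pd.DataFrame  # index = bin ids, columns = cells
    sex_adjusted: bool = False
    control_cells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [b.id for b in self.bins]
        if list(self.values.index) != ids:
            raise ValueError("values index must match the bin list")

    @property
    def autosomal_mask(self) -> np.ndarray:
        return np.array([b.chrom not in SEX_CHROMS for b in self.bins])


def estimate_cnv(
    counts: pd.DataFrame,
    bins: Sequence[GenomicInterval],
    control_cells: Sequence[str],
) -> CNVProfile:
    """Copy-number profile from raw bin read counts.

    Per cell: counts normalized by the cell total (scale invariance), divided
    by the median control-cell profile, times 2 (diploid scale).  No
    segmentation is performed; values stay bin-wise.  Bins where the control
    median is 0 become NA.
    """
    if len(control_cells) < 2:
        raise ValueError("need >= 2 control cells")
    missing = set(control_cells) - set(counts.columns)
    if missing:
        raise ValueError(f"control cells absent from the count matrix: {sorted(missing)}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-count cell(s): {list(zero.index)}")
    freq = counts / totals
    control = freq[list(control_cells)].median(axis=1)
    control = control.replace(0.0, np.nan)
    values = freq.div(control, axis=0) * 2.0
    values.index = [b.id for b in bins]
    return CNVProfile(list(bins), values, control_cells=list(control_cells))


def adjust_sex_chromosomes(profile: CNVProfile, force: bool = False) -> CNVProfile:
    """Halve X/Y bin values for all cells regardless of patient sex.

    Male normal cells carry one X and one Y, so against male controls a
    one-copy X reads as 2; halving renders it 1 (and a female diploid X as 2
    reads 4 -> 2).  The operation is not idempotent, so re-application is
    refused unless ``force=True``.
    """
    if profile.sex_adjusted and not force:
        raise ValueError("profile is already sex-adjusted (pass force=True to repeat)")
    chroms = np.array([b.chrom for b in profile.bins])
    if not len(chroms):
        raise ValueError("profile has no bins")
    sex_mask = np.isin(chroms, list(SEX_CHROMS))
    values = profile.values.copy()
    values.iloc[sex_mask] = values.iloc[sex_mask] / 2.0
    return CNVProfile(profile.bins, values, sex_adjusted=True,
                      control_cells=profile.control_cells)


def call_aneuploid(
    profile: CNVProfile,
    deviation: float = ANEUPLOID_DEVIATION,
    max_bin_fraction: float = ANEUPLOID_BIN_FRACTION,
) -> pd.Series:
    """Flag cells whose autosomal profile shows obvious copy-number change.

    A cell is aneuploid iff the fraction of autosomal bins with
    ``|value - 2| > deviation`` exceeds ``max_bin_fraction``.  Both parameters
    operationalize 'obvious SCNA' and are deliberately exposed.
    """
    auto = profile.values.loc[profile.autosomal_mask]
    dev_frac = (auto.sub(2.0).abs() > deviation).sum(axis=0) / auto.notna().sum(axis=0)
    return dev_frac > max_bin_fraction


def cluster_subclones(
    profile: CNVProfile,
    cells: Sequence[str] | None = None,
    k: int | None = None,
    k_range: Sequence[int] = (2, 3, 4, 5, 6),
    identical_tol: float = 1e-9,
) -> pd.Series:
    """Subclone labels by Ward hierarchical clustering of bin profiles.

    ``k=None`` selects k over ``k_range`` by silhouette score (Euclidean).
    Identical cells collapse to a single cluster.  Deterministic given the
    input ordering.  NA bins are dropped column-wise before clustering.
    """
    cells = list(cells) if cells is not None else list(profile.values.columns)
    if len(cells) < 2:
        raise ValueError("need >= 2 cells to cluster")
    x = profile.values[cells].dropna(axis=0).to_numpy().T  # cells x bins
    spread = np.abs(x - x[0]).max() if len(x) else 0.0
    if spread <= identical_tol:
        return pd.Series(1, index=cells, name="subclone")
    z = linkage(x, method="ward")
    if k is not None:
        if k > len(cells):
            raise ValueError("k exceeds the number of cells")
        labels = fcluster(z, t=k, criterion="maxclust")
    else:
        best_labels, best_score = None, -np.inf
        for kk in k_range:
            if kk >= len(cells):
                continue
            lab = fcluster(z, t=kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(x, lab, metric="euclidean")
            if score > best_score:
                best_labels, best_score = lab, score
        if best_labels is None or best_score <= 0:
            return pd.Series(1, index=cells, name="subclone")
        labels = best_labels
    return pd.Series(labels, index=cells, name="subclone")


def methylation_cnv_correlation(
    profile: CNVProfile,
    meth_levels: pd.DataFrame,
    subclones: Mapping[str, str | int] | pd.Series,
) -> pd.DataFrame:
    """Per-subclone Pearson correlation of methylation vs copy number.

    Both modalities are first averaged across the cells of each subclone per
    bin; the Pearson coefficient is computed across bins with pairwise NA
    deletion.  Zero variance in either averaged profile yields NA.
    """
    if list(meth_levels.index) != list(profile.values.index):
        raise ValueError("methylation matrix must use the same bins as the CNV profile")
    subclones = pd.Series(subclones)
    rows = []
    for lab in sorted(subclones.unique()):
        cells = [c for c in subclones.index[subclones == lab]
                 if c in profile.values.columns and c in meth_levels.columns]
        if not cells:
            raise ValueError(f"subclone {lab!r} has no cells in both matrices")
        cn = profile.values[cells].mean(axis=1)
        me = meth_levels[cells].mean(axis=1)
        ok = cn.notna() & me.notna()
        n = int(ok.sum())
        if n < 3 or cn[ok].nunique() == 1 or me[ok].nunique() == 1:
            r = float("nan")
        else:
            r = float(np.corrcoef(me[ok], cn[ok])[0, 1])
        rows.append({"subclone": lab, "pearson_r": r, "n_bins": n,
                     "n_cells": len(cells)})
    return pd.DataFrame(rows).set_index("subclone")
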