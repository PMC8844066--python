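"""Metagene windowing and per-cell Spearman correlation profiles among RNA
expression, endogenous methylation (WCG), and chromatin accessibility (GCH).

Each gene >= 2.5 kb is cut into 20 equal body windows (TSS to TES) flanked by
5 upstream and 5 downstream 3-kb windows, all strand-oriented (window 1 is the
most upstream).  Within each cell, the correlation for window k is computed
*across genes* between the expression vector and the window-k level vector;
this is the reading under which every cell yields a coefficient that can be
compared between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import normalize_expression, rank_sum_test
from .intervals import GeneModel, GenomicInterval

N_BODY = 20
N_FLANK = 5
FLANK_BP = 15_000
MIN_GENE_LENGTH = 2_500
MAJOR_BODY_OFFSET = 2_000
MIN_GENES = 20
PAIRS = ("rna-wcg", "rna-gch", "wcg-gch")
REGIONS = [f"w{k:02d}" for k in range(1, 31)] + ["promoter", "major_body"]


@dataclass
class MetageneWindows:
    """Strand-oriented metagene windows per gene.

    ``windows[gene]`` holds 30 intervals (5 upstream, 20 body, 5 downstream,
    in transcription order); ``promoter`` and ``major_body`` hold one interval
    per gene.
    """

    windows: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    promoter: dict[str, GenomicInterval] = field(default_factory=dict)
    major_body: dict[str, GenomicInterval] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.windows)

    def all_features(self) -> list[GenomicInterval]:
        feats = []
        for gene, wins in self.windows.items():
            for k, iv in enumerate(wins, start=1):
                feats.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                             name=f"{gene}|w{k:02d}"))
            p = self.promoter[gene]
            feats.append(GenomicInterval(p.chrom, p.start, p.end,
                                         name=f"{gene}|promoter"))
            b = self.major_body[gene]
            feats.append(GenomicInterval(b.chrom, b.start, b.end,
                                         name=f"{gene}|major_body"))
        return feats


def _body_edges(tss: int, tes: int, n: int) -> np.ndarray:
    """Integer window edges partitioning [tss, tes) (plus strand) exactly."""
    length = tes - tss
    return tss + np.round(np.arange(n + 1) * length / n).astype(np.int64)


def build_windows(genes: Sequence[GeneModel],
                  min_length: int = MIN_GENE_LENGTH) -> MetageneWindows:
    """Metagene windows for all genes of length >= ``min_length``.

    Body windows partition [TSS, TES) exactly (integer rounding, cumulative
    length exact); minus-strand genes are mirrored so window 1 lies at
    coordinates above the TSS.  Flank windows extending past the chromosome
    start are clipped out of existence only if fully negative.
    """
    out = MetageneWindows()
    flank_w = FLANK_BP // N_FLANK
    for g in genes:
        if g.length < min_length:
            continue
        wins: list[GenomicInterval] = []
        if g.strand == "+":
            up = [(g.tss - FLANK_BP + i * flank_w, g.tss - FLANK_BP + (i + 1) * flank_w)
                  for i in range(N_FLANK)]
            edges = _body_edges(g.tss, g.tes, N_BODY)
            body = [(int(edges[i]), int(edges[i + 1])) for i in range(N_BODY)]
            down = [(g.tes + i * flank_w, g.tes + (i + 1) * flank_w)
                    for i in range(N_FLANK)]
            ordered = up + body + down
            major = (g.tss + MAJOR_BODY_OFFSET, g.tes)
        else:
            # transcription runs towards lower coordinates; gene body = [tes, tss)
            up = [(g.tss + FLANK_BP - (i + 1) * flank_w, g.tss + FLANK_BP - i * flank_w)
                  for i in range(N_FLANK)]
            edges = _body_edges(g.tes, g.tss, N_BODY)[::-1]
            body = [(int(edges[i + 1]), int(edges[i])) for i in range(N_BODY)]
            down = [(g.tes - i * flank_w, g.tes - (i - 1) * flank_w)
                    for i in range(1, N_FLANK + 1)]
            ordered = up + body + down
            major = (g.tes, g.tss - MAJOR_BODY_OFFSET)
        for start, end in ordered:
            start = max(0, start)
            if end <= start:
                end = start + 1  # degenerate clipped flank; keeps 30 slots
            wins.append(GenomicInterval(g.chrom, start, end, strand=g.strand))
        out.windows[g.gene_id] = wins
        out.promoter[g.gene_id] = g.promoter()
        out.major_body[g.gene_id] = GenomicInterval(g.chrom, major[0], major[1],
                                                    name=g.gene_id, strand=g.strand)
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho with midrank ties and pairwise NA deletion; NaN if < 3
    complete pairs or zero rank variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan")
    rho, _ = stats.spearmanr(xs, ys)
    return float(rho)


def per_cell_profiles(
    expr: pd.DataFrame,
    wcg_levels: pd.DataFrame | None,
    gch_levels: pd.DataFrame | None,
    windows: MetageneWindows,
    min_genes: int = MIN_GENES,
) -> pd.DataFrame:
    """Per-cell Spearman profiles across metagene regions.

    ``wcg_levels``/``gch_levels`` are (gene|region) x cell matrices as produced
    by :func:`cooltrio.methylome.feature_level_matrix` over
    :meth:`MetageneWindows.all_features`.  Expression is normalized per cell
    (counts-per-total x 1e4, log1p) -- irrelevant to the rank correlation
    beyond monotonicity.  Returns a tidy frame with columns
    (cell, pair, region, rho, n_genes); rho is NA when fewer than
    ``min_genes`` genes are informative for both variables.
    """
    genes = windows.genes
    logexpr = normalize_expression(expr.loc[expr.index.intersection(genes)])

    def level_block(levels: pd.DataFrame, region: str) -> pd.DataFrame:
        idx = [f"{g}|{region}" for g in genes]
        block = levels.reindex(idx)
        block.index = genes
        return block

    cells = None
    for m in (logexpr, wcg_levels, gch_levels):
        if m is not None:
            cells = m.columns if cells is None else cells
            if not set(cells) <= set(m.columns):
                raise ValueError("cell sets of the input matrices disagree")

    records = []
    for region in REGIONS:
        blocks: dict[str, pd.DataFrame | None] = {
            "rna": logexpr.reindex(genes),
            "wcg": level_block(wcg_levels, region) if wcg_levels is not None else None,
            "gch": level_block(gch_levels, region) if gch_levels is not None else None,
        }
        for pair in PAIRS:
            a_name, b_name = pair.split("-")
            a, b = blocks[a_name], blocks[b_name]
            if a is None or b is None:
                continue
            for cell in cells:
                xa = a[cell].to_numpy(float)
                xb = b[cell].to_numpy(float)
                ok = ~(np.isnan(xa) | np.isnan(xb))
                n = int(ok.sum())
                rho = spearman(xa, xb) if n >= min_genes else float("nan")
                records.append({"cell": cell, "pair": pair, "region": region,
                                "rho": rho, "n_genes": n})
    return pd.DataFrame.from_records(records)


def group_compare(
    profiles: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Rank-sum comparison of per-cell coefficients between the two groups,
    per omics pair and region."""
    groups = pd.Series(groups)
    for g in ("normal", "cancer"):
        if (groups.reindex(profiles["cell"].unique()) == g).sum() < 3:
            raise ValueError(f"need >= 3 cells in group {g!r}")
    rows = []
    for (pair, region), sub in profiles.groupby(["pair", "region"], sort=False):
        vals = {g: sub.loc[[groups.get(c) == g for c in sub["cell"]], "rho"]
                .dropna().to_numpy() for g in ("normal", "cancer")}
        # regions informative in too few cells get an NA p, not an error
        if len(vals["normal"]) < 3 or len(vals["cancer"]) < 3:
            p = float("nan")
        else:
            p = rank_sum_test(vals["normal"], vals["cancer"])
        rows.append({"pair": pair, "region": region, "p_value": p,
                     "mean_rho_normal": float(vals["normal"].mean())
                     if len(vals["normal"]) else float("nan"),
                     "mean_rho_cancer": float(vals["cancer"].mean())
                     if len(vals["cancer"]) else float("nan")})
    return pd.DataFrame(rows)
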