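"""Synthetic multi-patient triple-omics dataset with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated against known truth:

* sparse per-cell site coverage (independent Bernoulli subsampling, default
  14.8% of sites per cell);
* bimodal site-level methylation (Beta mixtures near 0 and 1 plus a minority
  intermediate component, so the >0.9/<0.1 usable-site filter is exercised);
* a heterochromatin score field on 250-kb blocks (with distinct per-chromosome
  baselines) that drives LINE-1 density up and active histone-mark densities
  down, and concentrates cancer demethylation in LINE-1-dense regions;
* CpG-dense promoters (CGI-like) that resist global demethylation, with
  planted hyper- and hypomethylated promoter sets coupled to expression;
* extra gene-body demethylation in cancer inversely proportional to the
  gene's expression in normal cells;
* planted nucleosome-depleted regions (GC-dense loci) that are accessible in
  one or both groups against a low NOMe-style background;
* subclonal copy-number segments and mean-zero between-subclone methylation
  offsets (so the group-level demethylation delta is preserved).

Identical seed and config give identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GeneModel, GenomicInterval, build_tree, max_single_overlap, tile_genome
from .io import (SiteCallTable, write_bed, write_gene_models, write_matrix,
                 write_site_calls)

TRACK_NAMES = ("LINE1", "H3K4me3", "H3K27Ac", "H3K36me3")


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000,
            "chrX": 5_000_000}


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the analysed regime: a 35-Mb toy genome (3 autosomes of
    10 Mb plus a 5-Mb chrX), 800 genes, per-cell site coverage 14.8%, normal
    global methylation 0.80, cancer demethylation 5-20% below normal (default
    0.10) concentrated in LINE-1-dense blocks, more hypermethylated than
    hypomethylated promoters, planted group-specific accessible regions, and
    three CNV subclones per patient.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    block_size: int = 250_000

    # cohort
    n_patients: int = 2
    patient_sexes: tuple[str, ...] = ("male", "female")
    n_normal_cells: int = 20
    n_cancer_cells: int = 40
    n_subclones: int = 3

    # methylome
    global_meth_normal: float = 0.80
    cancer_demeth_delta: float = 0.10
    subclone_demeth_offsets: tuple[float, ...] = (0.05, -0.05, 0.0)
    intermediate_site_rate: float = 0.10
    site_coverage: float = 0.148
    wcg_spacing: int = 50
    wcg_promoter_spacing: int = 15

    # genes / expression
    n_genes: int = 800
    gene_length_range: tuple[int, int] = (3_000, 8_000)
    short_gene_fraction: float = 0.05
    n_promoter_hyper: int = 40
    n_promoter_hypo: int = 15
    promoter_meth_low: float = 0.10
    promoter_meth_high: float = 0.85
    expr_meth_coupling: float = 2.0
    body_demeth_expression_max: float = 0.10
    umis_per_cell: int = 20_000

    # accessibility / NDRs
    gch_spacing: int = 15
    gch_ndr_spacing: int = 4
    gch_background_accessibility: float = 0.04
    ndr_accessibility: float = 0.90
    n_shared_ndrs: int = 120
    n_cancer_ndrs: int = 60
    n_normal_ndrs: int = 60
    ndr_length_range: tuple[int, int] = (300, 800)

    # feature tracks
    line1_base: float = 0.05
    line1_het_gain: float = 0.55
    mark_base: float = 0.02
    mark_het_gain: float = 0.30

    # CNV
    cnv_bin_size: int = 500_000
    cnv_reads_per_cell: int = 500_000
    scna_segments_per_subclone: int = 3
    scna_segment_bins: tuple[int, int] = (4, 10)

    # which modalities to generate
    include_gch: bool = True
    include_rna: bool = True
    include_cnv: bool = True

    def validate(self) -> None:
        for name in ("global_meth_normal", "cancer_demeth_delta", "site_coverage",
                     "intermediate_site_rate", "gch_background_accessibility",
                     "ndr_accessibility", "promoter_meth_low", "promoter_meth_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_normal_cells < 2 or self.n_cancer_cells < 2:
            raise ValueError("need >= 2 cells per group")
        if self.n_patients < 1:
            raise ValueError("need >= 1 patient")
        if len(self.subclone_demeth_offsets) < self.n_subclones:
            raise ValueError("one demethylation offset per subclone required")
        if self.n_promoter_hyper + self.n_promoter_hypo > self.n_genes:
            raise ValueError("promoter classes exceed the number of genes")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in raw.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class GroundTruth:
    promoter_class: pd.Series          # gene -> hyper | hypo | neutral
    ndrs: list[tuple[GenomicInterval, str]]  # (interval, shared|cancer|normal)
    subclones: pd.Series               # cancer cell -> 1..k
    scna: pd.DataFrame                 # patient, subclone, chrom, start, end, copy
    expression_quartile: pd.Series     # gene -> 1..4 (1 = lowest expression)
    block_weights: pd.DataFrame        # chrom, start, end, het, line1_target


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    chrom_sizes: dict[str, int]
    gene_models: list[GeneModel]
    groups: pd.Series                  # cell -> normal | cancer
    patients: pd.Series                # cell -> patient id
    sexes: dict[str, str]              # patient -> male | female
    wcg: dict[str, SiteCallTable]
    gch: dict[str, SiteCallTable]
    expression: pd.DataFrame | None    # genes x cells UMI counts
    cnv_counts: pd.DataFrame | None    # bins x cells read counts
    cnv_bins: list[GenomicInterval]
    tracks: dict[str, list[GenomicInterval]]
    qc: pd.DataFrame
    truth: GroundTruth

    @property
    def cells(self) -> list[str]:
        return list(self.groups.index)

    def cells_of(self, group: str, patient: str | None = None) -> list[str]:
        sel = self.groups == group
        if patient is not None:
            sel &= self.patients == patient
        return list(self.groups.index[sel])


# ---------------------------------------------------------------------------
# building blocks

def _het_field(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-block heterochromatin score with distinct per-chromosome baselines."""
    chroms = list(cfg.chrom_sizes)
    bases = np.linspace(0.25, 0.75, len(chroms))
    rows = []
    for chrom, base in zip(chroms, bases):
        size = cfg.chrom_sizes[chrom]
        n_blocks = int(np.ceil(size / cfg.block_size))
        het = np.clip(base + rng.normal(0.0, 0.12, n_blocks), 0.02, 0.98)
        for i in range(n_blocks):
            start = i * cfg.block_size
            rows.append({"chrom": chrom, "start": start,
                         "end": min(start + cfg.block_size, size),
                         "het": het[i]})
    df = pd.DataFrame(rows)
    df["line1_target"] = np.clip(cfg.line1_base + cfg.line1_het_gain * df["het"], 0, 0.9)
    return df


def _make_tracks(cfg: SyntheticConfig, blocks: pd.DataFrame,
                 rng: np.random.Generator) -> dict[str, list[GenomicInterval]]:
    tracks: dict[str, list[GenomicInterval]] = {name: [] for name in TRACK_NAMES}
    specs = [("LINE1", "line1", 1500), ("H3K4me3", "mark", 800),
             ("H3K27Ac", "mark", 800), ("H3K36me3", "mark", 800)]
    for row in blocks.itertuples():
        blen = row.end - row.start
        for name, kind, elem_len in specs:
            if kind == "line1":
                cov = row.line1_target
            else:
                cov = np.clip(cfg.mark_base + cfg.mark_het_gain * (1.0 - row.het)
                              + rng.normal(0.0, 0.01), 0.0, 0.6)
            n_elem = int(round(cov * blen / elem_len))
            if n_elem == 0:
                continue
            starts = rng.integers(row.start, max(row.start + 1, row.end - elem_len),
                                  size=n_elem)
            for s in np.sort(starts):
                tracks[name].append(
                    GenomicInterval(row.chrom, int(s), int(min(s + elem_len, row.end)),
                                    name=name))
    return tracks


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Place genes on autosomes with non-overlapping loci.

    Loci (gene body plus promoter footprint and a small gap) never overlap so
    the planted promoter classes stay disjoint on the genome.
    """
    autosomes = [c for c in cfg.chrom_sizes if c not in ("chrX", "chrY", "X", "Y")]
    sizes = np.array([cfg.chrom_sizes[c] for c in autosomes], dtype=float)
    probs = sizes / sizes.sum()
    genes = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in autosomes}
    pad = 20_000
    footprint = 1_500  # promoter reach + spacing between loci
    for i in range(cfg.n_genes):
        for attempt in range(1_000):
            chrom = autosomes[rng.choice(len(autosomes), p=probs)]
            if rng.random() < cfg.short_gene_fraction:
                length = int(rng.integers(1_200, 2_400))
            else:
                length = int(rng.integers(*cfg.gene_length_range))
            start = int(rng.integers(pad, cfg.chrom_sizes[chrom] - length - pad))
            lo, hi = start - footprint, start + length + footprint
            if not any(lo < e and hi > s for s, e in occupied[chrom]):
                occupied[chrom].append((lo, hi))
                break
        else:
            raise RuntimeError("could not place non-overlapping genes; "
                               "genome too small for n_genes")
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i + 1:04d}"
        if strand == "+":
            genes.append(GeneModel(gid, chrom, "+", start, start + length))
        else:
            genes.append(GeneModel(gid, chrom, "-", start + length, start))
    return genes


def _assign_promoter_classes(cfg: SyntheticConfig, genes: list[GeneModel],
                             rng: np.random.Generator) -> pd.Series:
    eligible = [g.gene_id for g in genes if g.length >= 2_500]
    need = cfg.n_promoter_hyper + cfg.n_promoter_hypo
    if need > len(eligible):
        raise ValueError("not enough genes >= 2.5 kb for the planted promoter sets")
    chosen = rng.choice(len(eligible), size=need, replace=False)
    classes = pd.Series("neutral", index=[g.gene_id for g in genes], name="class")
    classes.loc[[eligible[i] for i in chosen[:cfg.n_promoter_hyper]]] = "hyper"
    classes.loc[[eligible[i] for i in chosen[cfg.n_promoter_hyper:]]] = "hypo"
    return classes


def _place_ndrs(cfg: SyntheticConfig, rng: np.random.Generator
                ) -> list[tuple[GenomicInterval, str]]:
    """Non-overlapping planted NDR loci with group labels."""
    wanted = ([("shared", cfg.n_shared_ndrs), ("cancer", cfg.n_cancer_ndrs),
               ("normal", cfg.n_normal_ndrs)])
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    placed: list[tuple[GenomicInterval, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for label, count in wanted:
        done = 0
        attempts = 0
        while done < count:
            attempts += 1
            if attempts > 100 * max(count, 1):
                raise RuntimeError("could not place non-overlapping NDRs; "
                                   "genome too small for the requested counts")
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            length = int(rng.integers(*cfg.ndr_length_range))
            start = int(rng.integers(1_000, cfg.chrom_sizes[chrom] - length - 1_000))
            end = start + length
            clash = any(start < e + 1_000 and end > s - 1_000
                        for s, e in occupied[chrom])
            if clash:
                continue
            occupied[chrom].append((start, end))
            placed.append((GenomicInterval(chrom, start, end,
                                           name=f"ndr_{label}_{done + 1:03d}"),
                           label))
            done += 1
    return placed


class _SiteUniverse:
    """Genome-wide site positions with per-state emission probabilities.

    ``probs`` maps a state key (e.g. 'normal' or 'cancer_sc1') to the per-site
    probability of the high (methylated / accessible) component.
    """

    def __init__(self, chroms: Sequence[str], pos_by_chrom: Mapping[str, np.ndarray]):
        self.chroms = list(chroms)
        self.pos_by_chrom = {c: pos_by_chrom[c] for c in self.chroms}
        lengths = [len(self.pos_by_chrom[c]) for c in self.chroms]
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.pos = np.concatenate([self.pos_by_chrom[c] for c in self.chroms]) \
            if lengths else np.empty(0, dtype=np.int64)
        self.n = len(self.pos)
        codes = np.concatenate([np.full(n, i, dtype=np.int16)
                                for i, n in enumerate(lengths)]) \
            if lengths else np.empty(0, dtype=np.int16)
        self.chrom_values = pd.Categorical.from_codes(codes, categories=self.chroms)
        self.probs: dict[str, np.ndarray] = {}

    def chrom_slice(self, chrom: str) -> slice:
        i = self.chroms.index(chrom)
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    def mark_interval(self, key: str, iv: GenomicInterval, value: float) -> None:
        sl = self.chrom_slice(iv.chrom)
        pos = self.pos_by_chrom[iv.chrom]
        lo = np.searchsorted(pos, iv.start, side="left") + sl.start
        hi = np.searchsorted(pos, iv.end, side="left") + sl.start
        self.probs[key][lo:hi] = value


def _wcg_universe(cfg: SyntheticConfig, genes: list[GeneModel],
                  classes: pd.Series, blocks: pd.DataFrame,
                  mu_normal: pd.Series | None) -> _SiteUniverse:
    chroms = sorted(cfg.chrom_sizes)
    pos_by_chrom = {}
    promoters = {g.gene_id: g.promoter() for g in genes}
    for chrom in chroms:
        parts = [np.arange(25, cfg.chrom_sizes[chrom], cfg.wcg_spacing, dtype=np.int64)]
        for g in genes:
            p = promoters[g.gene_id]
            if p.chrom == chrom:
                parts.append(np.arange(p.start + 3, min(p.end, cfg.chrom_sizes[chrom]),
                                       cfg.wcg_promoter_spacing, dtype=np.int64))
        pos_by_chrom[chrom] = np.unique(np.concatenate(parts))
    uni = _SiteUniverse(chroms, pos_by_chrom)

    # demethylation weight: per-block LINE-1 density, normalised to mean 1 over
    # non-promoter sites; CpG-dense promoters resist demethylation (weight 0)
    weight = np.empty(uni.n)
    block_lookup = {(r.chrom, r.start // cfg.block_size): r.line1_target
                    for r in blocks.itertuples()}
    for chrom in chroms:
        sl = uni.chrom_slice(chrom)
        bidx = uni.pos_by_chrom[chrom] // cfg.block_size
        weight[sl] = [block_lookup[(chrom, int(b))] for b in bidx]
    promoter_site = np.zeros(uni.n, dtype=bool)
    uni.probs["_promoter"] = promoter_site.astype(float)
    for g in genes:
        uni.mark_interval("_promoter", promoters[g.gene_id], 1.0)
    promoter_site = uni.probs.pop("_promoter").astype(bool)
    nonprom = ~promoter_site
    weight = weight / weight[nonprom].mean()
    weight[promoter_site] = 0.0

    # extra gene-body demethylation, inversely proportional to expression rank
    extra = np.zeros(uni.n)
    if cfg.body_demeth_expression_max > 0 and mu_normal is not None and len(genes) > 1:
        rank = mu_normal.rank(method="first") - 1
        rank = rank / max(len(mu_normal) - 1, 1)
        uni.probs["_extra"] = extra
        for g in genes:
            uni.mark_interval("_extra", g.body(),
                              cfg.body_demeth_expression_max * (1.0 - rank[g.gene_id]))
        extra = uni.probs.pop("_extra")
        extra[promoter_site] = 0.0

    # normal-cell high-component probability
    m_normal = np.full(uni.n, cfg.global_meth_normal)
    uni.probs["normal"] = m_normal
    for g in genes:
        level = (cfg.global_meth_normal if classes[g.gene_id] == "hypo"
                 else cfg.promoter_meth_low)
        uni.mark_interval("normal", promoters[g.gene_id], level)

    # cancer, per subclone
    for s in range(cfg.n_subclones):
        d = cfg.cancer_demeth_delta + cfg.subclone_demeth_offsets[s]
        m = np.clip(uni.probs["normal"] - d * weight - extra, 0.0, 1.0)
        uni.probs[f"cancer_sc{s + 1}"] = m
        for g in genes:
            if classes[g.gene_id] == "hyper":
                uni.mark_interval(f"cancer_sc{s + 1}", promoters[g.gene_id],
                                  cfg.promoter_meth_high)
            elif classes[g.gene_id] == "hypo":
                uni.mark_interval(f"cancer_sc{s + 1}", promoters[g.gene_id],
                                  cfg.promoter_meth_low)
    return uni


def _gch_universe(cfg: SyntheticConfig,
                  ndrs: list[tuple[GenomicInterval, str]]) -> _SiteUniverse:
    chroms = sorted(cfg.chrom_sizes)
    pos_by_chrom = {}
    for chrom in chroms:
        parts = [np.arange(7, cfg.chrom_sizes[chrom], cfg.gch_spacing, dtype=np.int64)]
        for iv, _label in ndrs:
            if iv.chrom == chrom:
                parts.append(np.arange(iv.start + 1, iv.end, cfg.gch_ndr_spacing,
                                       dtype=np.int64))
        pos_by_chrom[chrom] = np.unique(np.concatenate(parts))
    uni = _SiteUniverse(chroms, pos_by_chrom)
    bg = cfg.gch_background_accessibility
    uni.probs["normal"] = np.full(uni.n, bg)
    uni.probs["cancer"] = np.full(uni.n, bg)
    for iv, label in ndrs:
        if label in ("shared", "normal"):
            uni.mark_interval("normal", iv, cfg.ndr_accessibility)
        if label in ("shared", "cancer"):
            uni.mark_interval("cancer", iv, cfg.ndr_accessibility)
    return uni


def _draw_cell_table(cell_id: str, context: str, uni: _SiteUniverse, state: str,
                     cfg: SyntheticConfig, rng: np.random.Generator) -> SiteCallTable:
    covered = rng.random(uni.n) < cfg.site_coverage
    idx = np.flatnonzero(covered)
    n = len(idx)
    m = uni.probs[state][idx]
    inter = rng.random(n) < cfg.intermediate_site_rate
    high = rng.random(n) < m
    frac = np.where(inter, rng.beta(2.0, 2.0, n),
                    np.where(high, rng.beta(100.0, 1.0, n), rng.beta(1.0, 100.0, n)))
    df = pd.DataFrame({
        "chrom": uni.chrom_values[idx],
        "pos": uni.pos[idx],
        "context": context,
        "meth_fraction": frac,
        "depth": rng.poisson(1.5, n).astype(np.int64) + 1,
    })
    df["chrom"] = df["chrom"].astype(str)
    return SiteCallTable(cell_id, df)


def _expression(cfg: SyntheticConfig, genes: list[GeneModel], classes: pd.Series,
                rng: np.random.Generator) -> tuple[pd.Series, pd.Series]:
    """Per-gene expected expression in (normal, cancer) cells."""
    gids = [g.gene_id for g in genes]
    lam = pd.Series(rng.lognormal(1.0, 1.0, len(genes)), index=gids)
    m_norm = pd.Series(cfg.promoter_meth_low, index=gids)
    m_norm[classes == "hypo"] = cfg.global_meth_normal
    m_can = pd.Series(cfg.promoter_meth_low, index=gids)
    m_can[classes == "hyper"] = cfg.promoter_meth_high
    c = cfg.expr_meth_coupling
    mu_norm = lam * np.exp(-c * (m_norm - cfg.promoter_meth_low))
    mu_can = lam * np.exp(-c * (m_can - cfg.promoter_meth_low))
    return mu_norm, mu_can


def _cnv_truth_and_counts(cfg: SyntheticConfig, bins: list[GenomicInterval],
                          cells: pd.DataFrame, sexes: Mapping[str, str],
                          rng: np.random.Generator
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    bin_ids = [b.id for b in bins]
    autosomal = np.array([b.chrom not in ("chrX", "chrY", "X", "Y") for b in bins])
    lengths = np.array([b.length for b in bins], dtype=float)
    scna_rows = []
    copy_by_cell = {}
    # per-patient truncal + per-subclone segments on autosomal bins
    seg_plans: dict[str, list[tuple[str | int, np.ndarray, int]]] = {}
    auto_idx = np.flatnonzero(autosomal)
    for patient in cells["patient"].unique():
        plans = []
        global_used = np.zeros(len(bins), dtype=bool)
        used = np.zeros(len(bins), dtype=bool)  # rebound per subclone below

        def free_runs(blocked_idx):
            """Contiguous unblocked autosomal bin runs on a single chromosome."""
            blocked = np.zeros(len(bins), dtype=bool)
            blocked[blocked_idx] = True
            runs, cur = [], []
            for i in auto_idx:
                if blocked[i]:
                    if len(cur) >= 2:
                        runs.append(cur)
                    cur = []
                elif cur and bins[i].chrom != bins[cur[-1]].chrom:
                    if len(cur) >= 2:
                        runs.append(cur)
                    cur = [i]
                else:
                    cur.append(i)
            if len(cur) >= 2:
                runs.append(cur)
            return runs

        def pick_segment():
            # prefer bins unused by any subclone (distinct segment sets);
            # fall back to per-subclone disjointness on small genomes, where
            # cross-subclone overlaps mimic convergent SCNAs
            runs = free_runs(np.flatnonzero(used | global_used))
            if not runs:
                runs = free_runs(np.flatnonzero(used))
            if not runs:
                raise RuntimeError(
                    "could not place non-overlapping SCNA segments; too few "
                    "autosomal bins for the requested subclone structure")
            run = runs[int(rng.integers(len(runs)))]
            nbins = min(int(rng.integers(*cfg.scna_segment_bins)), len(run))
            nbins = max(nbins, 2)
            start = int(rng.integers(0, len(run) - nbins + 1))
            seg = np.array(run[start:start + nbins])
            used[seg] = True
            global_used[seg] = True
            return seg

        seg = pick_segment()
        truncal_used = used.copy()
        plans.append(("truncal", seg, 3))
        # segments of different subclones may overlap (convergent SCNAs);
        # within a subclone, and with the truncal segment, they stay disjoint
        for s in range(cfg.n_subclones):
            used = truncal_used.copy()
            for _ in range(cfg.scna_segments_per_subclone):
                seg = pick_segment()
                copy = int(rng.choice([1, 3]))
                plans.append((s + 1, seg, copy))
        seg_plans[patient] = plans
        for label, seg, copy in plans:
            scna_rows.append({"patient": patient, "subclone": label,
                              "chrom": bins[seg[0]].chrom,
                              "start": bins[seg[0]].start,
                              "end": bins[seg[-1]].end, "copy": copy})

    for row in cells.itertuples():
        copy = np.full(len(bins), 2.0)
        if sexes[row.patient] == "male":
            copy[~autosomal] = 1.0
        if row.group == "cancer":
            for label, seg, cval in seg_plans[row.patient]:
                if label == "truncal" or label == row.subclone:
                    copy[seg] = cval
        copy_by_cell[row.Index] = copy

    counts = {}
    for cell, copy in copy_by_cell.items():
        w = copy * lengths
        expected = cfg.cnv_reads_per_cell * w / w.sum()
        counts[cell] = rng.poisson(expected)
    counts_df = pd.DataFrame(counts, index=bin_ids)
    return pd.DataFrame(scna_rows), counts_df


def _qc_frame(cells: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(cells)
    return pd.DataFrame({
        "cell_id": cells.index,
        "genome_coverage": rng.uniform(0.05, 0.12, n),
        "n_wcg_sites": rng.integers(900_000, 2_500_000, n),
        "n_gch_sites": rng.integers(5_500_000, 15_000_000, n),
        "mapping_ratio": rng.uniform(0.2, 0.5, n),
        "conversion_rate": rng.uniform(0.985, 0.999, n),
        "n_detected_genes": rng.integers(2_000, 7_000, n),
        "n_umis": rng.integers(30_000, 300_000, n),
    }).set_index("cell_id")


# ---------------------------------------------------------------------------

def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic cohort (deterministic given seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    blocks = _het_field(config, rng)
    tracks = _make_tracks(config, blocks, rng)
    genes = _place_genes(config, rng)
    classes = _assign_promoter_classes(config, genes, rng)
    ndrs = _place_ndrs(config, rng)
    mu_norm, mu_can = _expression(config, genes, classes, rng)
    rank = mu_norm.rank(method="first")
    quartile = pd.Series(np.ceil(rank / len(rank) * 4).astype(int),
                         index=mu_norm.index, name="quartile")

    # cohort layout
    sexes = {}
    rows = []
    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        sexes[patient] = config.patient_sexes[p % len(config.patient_sexes)]
        for i in range(config.n_normal_cells):
            rows.append({"cell": f"{patient}_norm_{i + 1:03d}", "patient": patient,
                         "group": "normal", "subclone": 0})
        for i in range(config.n_cancer_cells):
            rows.append({"cell": f"{patient}_tumor_{i + 1:03d}", "patient": patient,
                         "group": "cancer", "subclone": i % config.n_subclones + 1})
    cells = pd.DataFrame(rows).set_index("cell")

    wcg_uni = _wcg_universe(config, genes, classes, blocks,
                            mu_norm if config.include_rna else None)
    gch_uni = _gch_universe(config, ndrs) if config.include_gch else None

    wcg_tables, gch_tables = {}, {}
    for row in cells.itertuples():
        state = "normal" if row.group == "normal" else f"cancer_sc{row.subclone}"
        wcg_tables[row.Index] = _draw_cell_table(row.Index, "WCG", wcg_uni, state,
                                                 config, rng)
        if gch_uni is not None:
            gch_state = "normal" if row.group == "normal" else "cancer"
            gch_tables[row.Index] = _draw_cell_table(row.Index, "GCH", gch_uni,
                                                     gch_state, config, rng)

    expression = None
    if config.include_rna:
        mats = {}
        for row in cells.itertuples():
            mu = mu_norm if row.group == "normal" else mu_can
            lib = config.umis_per_cell * rng.lognormal(0.0, 0.2)
            p = (mu / mu.sum()).to_numpy()
            mats[row.Index] = rng.poisson(lib * p)
        expression = pd.DataFrame(mats, index=mu_norm.index)

    bins = tile_genome(config.chrom_sizes, config.cnv_bin_size)
    if config.include_cnv:
        scna, cnv_counts = _cnv_truth_and_counts(config, bins, cells, sexes, rng)
    else:
        scna, cnv_counts = pd.DataFrame(), None

    qc = _qc_frame(cells, rng)
    subclones = cells.loc[cells["group"] == "cancer", "subclone"]

    truth = GroundTruth(promoter_class=classes, ndrs=ndrs, subclones=subclones,
                        scna=scna, expression_quartile=quartile,
                        block_weights=blocks)
    return SyntheticDataset(
        config=config, chrom_sizes=dict(config.chrom_sizes), gene_models=genes,
        groups=cells["group"], patients=cells["patient"], sexes=sexes,
        wcg=wcg_tables, gch=gch_tables, expression=expression,
        cnv_counts=cnv_counts, cnv_bins=bins, tracks=tracks, qc=qc, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset in the formats the I/O layer reads back."""
    out = Path(outdir)
    (out / "cells").mkdir(parents=True, exist_ok=True)
    ds.config.to_yaml(out / "config.yaml")
    write_gene_models(ds.gene_models, out / "genes.tsv")
    for cell in ds.cells:
        parts = [ds.wcg[cell].data]
        if cell in ds.gch:
            parts.append(ds.gch[cell].data)
        combined = SiteCallTable(cell, pd.concat(parts, ignore_index=True))
        write_site_calls(combined, out / "cells" / f"{cell}.tsv")
    if ds.expression is not None:
        write_matrix(ds.expression, out / "expression.tsv")
    if ds.cnv_counts is not None:
        write_matrix(ds.cnv_counts, out / "cnv_counts.tsv")
    write_bed(ds.cnv_bins, out / "cnv_bins.bed")
    for name, track in ds.tracks.items():
        write_bed(track, out / f"track_{name}.bed")
    groups = pd.DataFrame({"group": ds.groups, "patient": ds.patients})
    groups.to_csv(out / "groups.tsv", sep="\t")
    ds.qc.to_csv(out / "qc.tsv", sep="\t")
    ds.truth.promoter_class.to_csv(out / "truth_promoters.tsv", sep="\t")
    write_bed([iv for iv, _ in ds.truth.ndrs], out / "truth_ndrs.bed")
    ds.truth.subclones.to_csv(out / "truth_subclones.tsv", sep="\t")
    if len(ds.truth.scna):
        ds.truth.scna.to_csv(out / "truth_scna.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# truth comparison

@dataclass(frozen=True)
class PrecisionRecall:
    n_truth: int
    n_called: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        """None (undefined) when nothing was called."""
        return None if self.n_called == 0 else self.tp / self.n_called

    @property
    def recall(self) -> float:
        return 0.0 if self.n_truth == 0 else (self.n_truth - self.fn) / self.n_truth


def truth_report_intervals(
    planted: Sequence[GenomicInterval],
    called: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> PrecisionRecall:
    """Interval-set precision/recall with >= ``min_overlap`` bp matching."""
    called_trees = build_tree(list(called))
    planted_trees = build_tree(list(planted))
    fn = sum(1 for iv in planted
             if max_single_overlap(iv, called_trees) < min_overlap)
    tp = sum(1 for iv in called
             if max_single_overlap(iv, planted_trees) >= min_overlap)
    return PrecisionRecall(n_truth=len(planted), n_called=len(called),
                           tp=tp, fp=len(called) - tp, fn=fn)


def truth_report_labels(
    truth_positive: Sequence[str],
    called_positive: Sequence[str],
    universe: Sequence[str],
) -> PrecisionRecall:
    """Label-set precision/recall (e.g. planted vs called DMR genes)."""
    t = set(truth_positive)
    c = set(called_positive)
    u = set(universe)
    if not c <= u or not t <= u:
        raise ValueError("truth/called labels outside the stated universe")
    tp = len(t & c)
    return PrecisionRecall(n_truth=len(t), n_called=len(c), tp=tp,
                           fp=len(c - t), fn=len(t - c))


def truth_report(truth: GroundTruth, called, kind: str,
                 group: str | None = None, min_overlap: int = 1) -> PrecisionRecall:
    """Compare a stage's output against the planted ground truth.

    kind='ndr': ``called`` is a list of intervals; ``group`` restricts the
    planted set to NDRs active in that group (shared + group-specific).
    kind='dmr_hyper'/'dmr_hypo': ``called`` is an iterable of gene ids.
    """
    if kind == "ndr":
        labels = {"shared", group} if group else {"shared", "cancer", "normal"}
        planted = [iv for iv, lab in truth.ndrs if lab in labels]
        return truth_report_intervals(planted, called, min_overlap)
    if kind in ("dmr_hyper", "dmr_hypo"):
        cls = kind.split("_")[1]
        planted = list(truth.promoter_class.index[truth.promoter_class == cls])
        return truth_report_labels(planted, list(called),
                                   list(truth.promoter_class.index))
    raise ValueError(f"unknown truth kind {kind!r}")
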