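"""End-to-end orchestration of the analysis stages with a single seed, a
config whose defaults are the analysis' canonical thresholds, and a manifest
from which every output is re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cnv, crossomics, demethylation, dmr, methylome, ndr
from .intervals import GenomicInterval
from .io import write_bed, write_matrix
from .simulate import SyntheticConfig, generate_dataset, truth_report

log = logging.getLogger("cooltrio")


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out (stage-level reproducibility)."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """All stage parameters, pre-filled with the canonical defaults:
    0.9/0.1 usable-site filter, >=3 sites per element, 1-kb tiles, promoter
    -1 kb/+0.5 kb, the four-part differential filter, NDR scan
    100 bp / 20 bp / p<1e-15 / >140 bp / >=5 sites, 100-bp merge overlap, and
    multi-megabase demethylation resolutions."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    usable_high: float = 0.9
    usable_low: float = 0.1
    min_sites: int = 3
    tile_size: int = 1000
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    mds_min_cell_fraction: float = 0.5
    dmr_coverage_fraction: float = 0.3
    ndr_window: int = 100
    ndr_step: int = 20
    ndr_p_threshold: float = 1e-15
    ndr_min_length: int = 140
    ndr_min_sites: int = 5
    ndr_merge_overlap: int = 100
    ndr_support_fraction: float = 0.05
    ndr_support_floor: int = 2
    resolutions: tuple[int, ...] = (250_000, 500_000, 1_000_000)
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("synthetic", {}).items()})
        defaults = cls(synthetic=syn)
        overrides = {}
        for key, value in raw.items():
            if not hasattr(defaults, key):
                raise ValueError(f"unknown pipeline parameter {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            if getattr(defaults, key) != value:
                overrides[key] = value
            setattr(defaults, key, value)
        defaults.overrides = overrides
        return defaults


def demo_config(seed: int = 0) -> PipelineConfig:
    """Reduced-scale cohort for the one-command demo (two patients on a
    10.5-Mb genome) so the full pipeline runs in minutes."""
    syn = SyntheticConfig(
        seed=seed,
        chrom_sizes={"chr1": 3_000_000, "chr2": 3_000_000, "chr3": 3_000_000,
                     "chrX": 1_500_000},
        n_patients=2, n_normal_cells=8, n_cancer_cells=16,
        n_genes=300, n_promoter_hyper=20, n_promoter_hypo=8,
        n_shared_ndrs=40, n_cancer_ndrs=20, n_normal_ndrs=20,
        cnv_bin_size=250_000,
    )
    return PipelineConfig(synthetic=syn, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic cohort and write the artifact directory.

    Deterministic given ``config.seed``; returns the manifest (also written as
    ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    syn = dataclasses.replace(config.synthetic,
                              seed=child_seed(config.seed, "synthetic"))
    log.info("generating synthetic cohort (seed %d)", syn.seed)
    ds = generate_dataset(syn)

    # --- QC ------------------------------------------------------------
    records = methylome.qc_records_from_frame(ds.qc.reset_index())
    dna_pass = set(methylome.filter_cells(records, "dna"))
    rna_pass = set(methylome.filter_cells(records, "rna"))
    qc_table = ds.qc.copy()
    qc_table["dna_pass"] = [c in dna_pass for c in qc_table.index]
    qc_table["rna_pass"] = [c in rna_pass for c in qc_table.index]
    qc_table.to_csv(out / "qc.tsv", sep="\t")
    cells = [c for c in ds.cells if c in dna_pass]
    log.info("%d/%d cells pass DNA QC", len(cells), len(ds.cells))

    # --- usable sites & global levels -----------------------------------
    wcg = {c: methylome.usable_sites(ds.wcg[c], config.usable_high, config.usable_low)
           for c in cells}
    gch = {c: methylome.usable_sites(ds.gch[c], config.usable_high, config.usable_low)
           for c in cells} if ds.gch else {}
    glob_rows = []
    wcg_globals, gch_globals = {}, {}
    for c in cells:
        g = methylome.global_level(wcg[c], "WCG", config.tile_size, config.min_sites)
        wcg_globals[c] = g
        glob_rows.append(g.__dict__)
        if gch:
            g = methylome.global_level(gch[c], "GCH", config.tile_size, config.min_sites)
            gch_globals[c] = g
            glob_rows.append(g.__dict__)
    pd.DataFrame(glob_rows).to_csv(out / "global_levels.tsv", sep="\t", index=False)

    # --- promoter quantification & MDS ----------------------------------
    promoters = [g.promoter(config.promoter_upstream, config.promoter_downstream)
                 for g in ds.gene_models]
    prom_wcg = methylome.feature_level_matrix(wcg, promoters, "WCG", config.min_sites)
    write_matrix(prom_wcg.levels, out / "promoter_wcg.tsv")
    coords, _ = methylome.promoter_mds(prom_wcg.levels, config.mds_min_cell_fraction)
    coords.to_csv(out / "mds.tsv", sep="\t")

    manifest_metrics: dict = {}

    # --- NDR calling -----------------------------------------------------
    if gch:
        scndrs = {c: ndr.call_cell_ndrs(
            gch[c], ds.chrom_sizes, window=config.ndr_window, step=config.ndr_step,
            p_threshold=config.ndr_p_threshold, min_length=config.ndr_min_length,
            min_sites=config.ndr_min_sites) for c in cells}
        mndrs = {}
        for group in ("normal", "cancer"):
            gcells = [c for c in ds.cells_of(group) if c in dna_pass]
            support = ndr.support_threshold(len(gcells), config.ndr_support_fraction,
                                            config.ndr_support_floor)
            flat = [n for c in gcells for n in scndrs[c]]
            mndrs[group] = ndr.merge_to_mndrs(flat, support,
                                              config.ndr_merge_overlap, group)
            ndr.export_for_motif_search(mndrs[group], out / f"mndr_{group}.bed")
            log.info("%s: %d mNDRs (support >= %d)", group, len(mndrs[group]), support)
        spec = ndr.group_specific_mndrs(mndrs["normal"], mndrs["cancer"])
        ndr.export_for_motif_search(spec.a_specific, out / "mndr_normal_specific.bed")
        ndr.export_for_motif_search(spec.b_specific, out / "mndr_cancer_specific.bed")
        rep = truth_report(ds.truth, [m.to_interval() for m in mndrs["cancer"]],
                           kind="ndr", group="cancer")
        manifest_metrics["ndr_cancer_recall"] = rep.recall
        manifest_metrics["ndr_cancer_precision"] = rep.precision

    # --- differential promoter methylation -------------------------------
    per_patient = {}
    for patient in sorted(ds.patients.unique()):
        pcells = [c for c in cells if ds.patients[c] == patient]
        sub = prom_wcg.levels[pcells]
        kept = dmr.coverage_filter(sub, config.dmr_coverage_fraction)
        results, _skipped = dmr.call_dmrs(sub.loc[kept], ds.groups[pcells])
        per_patient[patient] = results
        dmr.results_frame(results).to_csv(out / f"dmr_{patient}.tsv", sep="\t")
    if len(per_patient) >= 2:
        rec = dmr.recurrence_summary(per_patient, min_patients=2)
        rec.to_csv(out / "dmr_recurrence.tsv", sep="\t")

    # --- cross-omics profiles --------------------------------------------
    if ds.expression is not None:
        windows = crossomics.build_windows(ds.gene_models)
        feats = windows.all_features()
        wcg_win = methylome.feature_level_matrix(wcg, feats, "WCG", config.min_sites)
        gch_win = (methylome.feature_level_matrix(gch, feats, "GCH", config.min_sites)
                   if gch else None)
        profiles = crossomics.per_cell_profiles(
            ds.expression[cells], wcg_win.levels,
            gch_win.levels if gch_win else None, windows)
        profiles.to_csv(out / "xomics_profiles.tsv", sep="\t", index=False)
        comp = crossomics.group_compare(profiles, ds.groups)
        comp.to_csv(out / "xomics_group_compare.tsv", sep="\t", index=False)

        body_feats = [g.body() for g in ds.gene_models]
        body = methylome.feature_level_matrix(wcg, body_feats, "WCG", config.min_sites)
        quart = dmr.expression_quartile_demethylation(
            ds.expression[cells], body.levels, ds.groups[cells])
        quart.to_csv(out / "expression_quartile_demethylation.tsv", sep="\t")

    # --- demethylation map -------------------------------------------------
    normal_cells = [c for c in ds.cells_of("normal") if c in dna_pass]
    cancer_cells = [c for c in ds.cells_of("cancer") if c in dna_pass]

    def level_fn(wins: list[GenomicInterval]):
        lm = methylome.feature_level_matrix(wcg, wins, "WCG", config.min_sites)
        return lm.levels[normal_cells], lm.levels[cancer_cells]

    corr = demethylation.multi_resolution_correlations(
        ds.chrom_sizes, level_fn, ds.tracks, config.resolutions)
    corr.to_csv(out / "ddemed_correlations.tsv", sep="\t", index=False)
    line1 = corr[corr["feature"] == "LINE1"]
    manifest_metrics["ddemed_line1_positive_fraction"] = float(
        (line1["rho"] > 0).mean())

    # --- CNV / subclones ---------------------------------------------------
    if ds.cnv_counts is not None:
        male_controls = [c for c in normal_cells
                         if ds.sexes[ds.patients[c]] == "male"]
        profile = cnv.estimate_cnv(ds.cnv_counts, ds.cnv_bins, male_controls)
        profile = cnv.adjust_sex_chromosomes(profile)
        write_matrix(profile.values, out / "cnv_profile.tsv")
        aneuploid = cnv.call_aneuploid(profile)
        sub_rows = []
        meth_bins = methylome.feature_level_matrix(wcg, ds.cnv_bins, "WCG",
                                                   config.min_sites)
        for patient in sorted(ds.patients.unique()):
            pcancer = [c for c in cancer_cells
                       if ds.patients[c] == patient and aneuploid.get(c, False)]
            if len(pcancer) < 2:
                continue
            labels = cnv.cluster_subclones(profile, pcancer)
            mc = cnv.methylation_cnv_correlation(profile, meth_bins.levels, labels)
            mc.insert(0, "patient", patient)
            for cell, lab in labels.items():
                sub_rows.append({"cell": cell, "patient": patient, "subclone": lab})
            mc.to_csv(out / f"meth_cnv_corr_{patient}.tsv", sep="\t")
        pd.DataFrame(sub_rows).to_csv(out / "subclones.tsv", sep="\t", index=False)

        glw = {c: wcg_globals[c] for c in cancer_cells}
        if sub_rows:
            sub_series = pd.Series({r["cell"]: f"{r['patient']}_sc{r['subclone']}"
                                    for r in sub_rows})
            common = [c for c in sub_series.index if c in glw]
            if len(set(sub_series[common])) >= 2:
                summary, pw = demethylation.subclone_demethylation_summary(
                    {c: glw[c] for c in common}, sub_series[common])
                summary.to_csv(out / "subclone_methylation.tsv", sep="\t")

    # --- manifest ----------------------------------------------------------
    params = dataclasses.asdict(config)
    params["synthetic"] = dataclasses.asdict(syn)
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package": "cooltrio",
        "version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": config.seed,
        "parameters": params,
        "overrides": config.overrides,
        "metrics": manifest_metrics,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
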