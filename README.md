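# cooltrio

Analysis of single-cell **triple-omics** data — endogenous DNA methylation
(WCG sites), chromatin accessibility from a GpC methyltransferase assay
(GCH sites), and the transcriptome — as produced by scCOOL-seq-style
protocols in tumor studies that compare normal epithelial cells with cancer
cells. The package is written for computational biologists who have per-cell
cytosine call tables, a UMI count matrix, and per-cell binned read counts,
and want the downstream statistics: who is demethylated where, which
promoters flip, where chromatin opens, and how copy-number subclones relate
to the methylome.

## What it computes

* **Quantification** (`cooltrio.methylome`). Site calls are reduced to
  confident binary states (fraction > 0.9 → methylated/accessible, < 0.1 →
  un-; intermediates discarded). Element and tile levels are means of binary
  calls, reported only with ≥ 3 covered sites. Per-cell global levels are the
  *tile-weighted* mean over qualifying 1-kb tiles. Accessibility of elements
  is normalized by each cell's global accessibility. Cells are QC-filtered
  (genome coverage ≥ 4%, ≥ 8×10⁵ WCG and ≥ 5×10⁶ GCH sites, mapping ≥ 5%,
  CT conversion ≥ 98%; RNA: 1500–9000 genes, ≤ 4×10⁵ UMIs), and cells are
  embedded by classical (Torgerson) MDS of promoter profiles.
* **NDR calling** (`cooltrio.ndr`). Per cell, 100-bp windows sliding by 20 bp
  are χ²-tested (1 df, no continuity correction) for accessibility enrichment
  over that cell's genome-wide background; windows with p < 10⁻¹⁵ and
  above-background rate are unioned, and candidates spanning > 140 bp with
  ≥ 5 GCH calls become single-cell NDRs. scNDRs merge across cells at
  ≥ 100 bp overlap into mNDRs whose support counts *distinct cells*;
  group-specific mNDRs have zero overlap with the other group's set.
* **Differential promoters** (`cooltrio.dmr`). Promoters (−1 kb/+0.5 kb of
  the TSS) covered in ≥ 30% of cells are tested with a stringent four-part
  filter: rank-sum p < 0.05, fold change > 2 or < 0.5, absolute difference
  > 0.5, and within-group SD < 0.25 — plus cross-patient recurrence tables
  and the expression-quartile gene-body demethylation comparison.
* **Cross-omics profiles** (`cooltrio.crossomics`). Genes ≥ 2.5 kb are cut
  into 20 equal body windows plus 5 upstream / 5 downstream 3-kb windows;
  per cell and window, Spearman correlations across genes between RNA, WCG,
  and GCH levels, with promoter and major-gene-body (TSS+2 kb → TES)
  summaries and group comparisons.
* **Demethylation mapping** (`cooltrio.demethylation`). Per cancer cell i and
  genomic window j, the relative methylation degree
  `R_DMeD[i,j] = level[i,j] / median(normal levels in j)` and the
  demethylation degree `DDemeD = 1 − R_DMeD`, rank-correlated per cell with
  LINE-1 and histone-mark densities across 0.25–10 Mb resolutions.
* **Copy number** (`cooltrio.cnv`). Bin read counts normalized per cell,
  divided by the median control (male normal) profile and scaled to a diploid
  baseline; X/Y values halved for all cells; aneuploidy calling, Ward
  subclone clustering, and the subclone-averaged methylation/copy-number
  Pearson correlation.
* **Synthetic cohorts** (`cooltrio.simulate`). A generator that plants all of
  the above structure (sparse bimodal site calls, LINE-1-biased
  demethylation, promoter classes coupled to expression, accessible regions,
  subclonal SCNAs) with full ground truth, so every stage is testable.

## Worked example

```python
import numpy as np
from cooltrio import methylome, dmr
from cooltrio.simulate import SyntheticConfig, generate_dataset, truth_report

cfg = SyntheticConfig(
    seed=7,
    chrom_sizes={"chr1": 3_000_000, "chr2": 3_000_000, "chr3": 3_000_000},
    n_patients=1, n_normal_cells=20, n_cancer_cells=40,
    n_genes=200, n_promoter_hyper=12, n_promoter_hypo=5,
    cancer_demeth_delta=0.10,
    include_gch=False, include_rna=False, include_cnv=False)
ds = generate_dataset(cfg)

wcg = {c: methylome.usable_sites(ds.wcg[c]) for c in ds.cells}
levels = {c: methylome.global_level(wcg[c], "WCG").level for c in ds.cells}
normal = np.mean([levels[c] for c in ds.cells_of("normal")])
cancer = np.mean([levels[c] for c in ds.cells_of("cancer")])
print(f"global WCG methylation: normal {normal:.3f}, cancer {cancer:.3f} "
      f"(difference {normal - cancer:.3f})")

promoters = [g.promoter() for g in ds.gene_models]
matrix = methylome.feature_level_matrix(wcg, promoters, "WCG")
kept = dmr.coverage_filter(matrix.levels)
results, _ = dmr.call_dmrs(matrix.levels.loc[kept], ds.groups)
hyper = [r.gene_id for r in results if r.passed and r.direction == "hyper"]
rep = truth_report(ds.truth, hyper, kind="dmr_hyper")
print(f"promoters tested: {len(kept)}; hypermethylated: {len(hyper)}")
print(f"recovery of planted hypermethylated promoters: "
      f"recall {rep.recall:.2f}, false positives {rep.fp}")
```

Output:

```
global WCG methylation: normal 0.745, cancer 0.654 (difference 0.090)
promoters tested: 200; hypermethylated: 12
recovery of planted hypermethylated promoters: recall 1.00, false positives 0
```

The 60 cancer cells were generated 0.10 lower in global methylation,
concentrated in LINE-1-dense blocks; the tile-weighted estimator recovers
0.090 (CpG-island promoter tiles resist demethylation and slightly shrink the
group difference — see `docs/methods.md`). All 12 planted hypermethylated
promoters pass the four-part filter; no neutral promoter does.

## Command line

`cooltrio demo --seed 7 --out demo/` runs every stage on a reduced-scale
two-patient synthetic cohort and writes QC tables, methylation matrices,
mNDR BED files, differential-promoter tables, correlation profiles,
demethylation-degree correlations, CNV profiles with subclones, and a
`manifest.json` recording parameters and output hashes (identical seeds give
identical manifests). `cooltrio run --config cfg.yaml` does the same from a
YAML config; `qc`, `quantify`, `mds`, `ndr`, `dmr`, `ddemed`, and `cnv`
operate on files for stage-by-stage use.

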