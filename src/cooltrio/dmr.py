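"""Differential promoter methylation between normal-epithelial and cancer
cells, with the stringent four-part filter (rank-sum p < 0.05, fold change
> 2 or < 0.5, absolute difference > 0.5, within-group SD < 0.25), cross-patient
recurrence summaries, and the expression-quartile gene-body demethylation
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

P_CUTOFF = 0.05
FC_HIGH = 2.0
FC_LOW = 0.5
DIFF_CUTOFF = 0.5
SD_CUTOFF = 0.25
COVERAGE_FRACTION = 0.3


@dataclass(frozen=True)
class DMRResult:
    gene_id: str
    n_normal: int
    n_cancer: int
    mean_normal: float
    mean_cancer: float
    p_value: float
    fold_change: float
    abs_difference: float
    sd_normal: float
    sd_cancer: float
    direction: str  # hyper = higher methylation in cancer
    passed: bool


def coverage_filter(levels: pd.DataFrame,
                    min_cell_fraction: float = COVERAGE_FRACTION) -> list[str]:
    """Genes (rows) observed in at least ``min_cell_fraction`` of all cells.

    The denominator pools both groups; the boundary is inclusive (a gene
    covered in exactly 30% of cells is retained).
    """
    if levels.shape[0] == 0 or levels.shape[1] == 0:
        raise ValueError("empty methylation matrix")
    frac = levels.notna().mean(axis=1)
    return list(levels.index[frac >= min_cell_fraction])


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples are small (min(n, m) <= 8) and free of
    ties; normal approximation with midrank tie handling and continuity
    correction otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test needs non-NA values in both samples")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and min(len(x), len(y)) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def _passes(p: float, fc: float, diff: float, sd_n: float, sd_c: float) -> bool:
    return (p < P_CUTOFF and (fc > FC_HIGH or fc < FC_LOW)
            and diff > DIFF_CUTOFF and sd_n < SD_CUTOFF and sd_c < SD_CUTOFF)


def call_dmrs(
    levels: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    min_cells: int = 2,
    fdr: bool = False,
) -> tuple[list[DMRResult], list[str]]:
    """Evaluate the four-part differential-methylation filter per gene.

    ``levels`` is a promoter x cell WCG matrix (apply :func:`coverage_filter`
    first); ``groups`` maps cell -> 'normal' | 'cancer'.  Fold change is
    cancer/normal (+inf when the normal mean is 0 and cancer is positive,
    which satisfies the FC > 2 arm).  No multiple-testing correction is
    applied by default, matching the stringent-filter design; ``fdr=True``
    additionally requires Benjamini-Hochberg q < 0.05.

    Returns ``(results, skipped_gene_ids)`` where skipped genes had fewer than
    ``min_cells`` covered cells in either group.
    """
    groups = pd.Series(groups)
    normal_cells = [c for c in levels.columns if groups.get(c) == "normal"]
    cancer_cells = [c for c in levels.columns if groups.get(c) == "cancer"]
    if not normal_cells or not cancer_cells:
        raise ValueError("both 'normal' and 'cancer' groups must be present")

    results: list[DMRResult] = []
    skipped: list[str] = []
    for gene in levels.index:
        vn = levels.loc[gene, normal_cells].dropna().to_numpy(float)
        vc = levels.loc[gene, cancer_cells].dropna().to_numpy(float)
        if len(vn) < min_cells or len(vc) < min_cells:
            skipped.append(gene)
            continue
        mean_n, mean_c = float(vn.mean()), float(vc.mean())
        sd_n, sd_c = float(vn.std(ddof=1)), float(vc.std(ddof=1))
        if mean_n == 0:
            fc = math.inf if mean_c > 0 else math.nan
        else:
            fc = mean_c / mean_n
        diff = abs(mean_c - mean_n)
        p = rank_sum_test(vn, vc)
        passed = False if math.isnan(fc) else _passes(p, fc, diff, sd_n, sd_c)
        results.append(DMRResult(
            gene_id=gene, n_normal=len(vn), n_cancer=len(vc),
            mean_normal=mean_n, mean_cancer=mean_c, p_value=p,
            fold_change=fc, abs_difference=diff, sd_normal=sd_n, sd_cancer=sd_c,
            direction="hyper" if mean_c > mean_n else "hypo", passed=passed,
        ))
    if fdr and results:
        ps = np.array([r.p_value for r in results])
        q = _benjamini_hochberg(ps)
        results = [
            DMRResult(**{**r.__dict__, "passed": r.passed and q[i] < P_CUTOFF})
            for i, r in enumerate(results)
        ]
    return results, skipped


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def results_frame(results: Sequence[DMRResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("gene_id") \
        if results else pd.DataFrame(
            columns=["n_normal", "n_cancer", "mean_normal", "mean_cancer",
                     "p_value", "fold_change", "abs_difference", "sd_normal",
                     "sd_cancer", "direction", "passed"])


def recurrence_summary(
    per_patient: Mapping[str, Sequence[DMRResult]],
    min_patients: int = 3,
) -> pd.DataFrame:
    """Gene x patient incidence of passing calls, split by direction.

    Gene universes are aligned by intersection (with a warning column is not
    emitted; genes absent from a patient simply do not count for it).
    Returns genes with >= ``min_patients`` passing patients in one direction,
    with columns ``n_patients_hyper``, ``n_patients_hypo`` and per-patient
    flags.
    """
    if len(per_patient) < 2:
        raise ValueError("recurrence summary needs >= 2 patients")
    rows: dict[str, dict[str, object]] = {}
    for patient, results in per_patient.items():
        for r in results:
            if not r.passed:
                continue
            d = rows.setdefault(r.gene_id, {"n_patients_hyper": 0, "n_patients_hypo": 0})
            d[f"n_patients_{r.direction}"] += 1
            d[patient] = r.direction
    if not rows:
        return pd.DataFrame(columns=["n_patients_hyper", "n_patients_hypo"])
    df = pd.DataFrame.from_dict(rows, orient="index")
    keep = (df["n_patients_hyper"] >= min_patients) | \
           (df["n_patients_hypo"] >= min_patients)
    return df[keep].sort_values(["n_patients_hyper", "n_patients_hypo"],
                                ascending=False)


def normalize_expression(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """log1p of counts-per-cell-total x ``scale`` (genes x cells)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every cell needs a positive UMI total")
    return np.log1p(counts / totals * scale)


def expression_quartile_demethylation(
    expr: pd.DataFrame,
    body_levels: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
) -> pd.Series:
    """Gene-body methylation change (cancer - normal) by expression quartile.

    Genes are split into four equal groups by their mean normalized expression
    across normal cells (Q1 = lowest).  Per gene, the delta is the difference
    of group means of gene-body WCG levels (NA-aware); per quartile, deltas
    are averaged.
    """
    groups = pd.Series(groups)
    common = expr.index.intersection(body_levels.index)
    if len(common) < 8:
        raise ValueError("need >= 8 genes shared by expression and methylation")
    expr = expr.loc[common]
    body = body_levels.loc[common]
    normal_cells = [c for c in expr.columns if groups.get(c) == "normal"]
    cancer_cells = [c for c in body.columns if groups.get(c) == "cancer"]
    body_normal = [c for c in body.columns if groups.get(c) == "normal"]
    mean_expr = normalize_expression(expr)[normal_cells].mean(axis=1)
    order = mean_expr.sort_values(kind="mergesort").index
    quartiles = np.array_split(np.asarray(order), 4)
    delta = body[cancer_cells].mean(axis=1) - body[body_normal].mean(axis=1)
    out = {f"Q{i + 1}": float(delta.loc[list(q)].mean())
           for i, q in enumerate(quartiles)}
    return pd.Series(out, name="delta_methylation")
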