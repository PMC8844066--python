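import itertools

import numpy as np
import pandas as pd
import pytest

from cooltrio.dmr import (DMRResult, _passes, call_dmrs, coverage_filter,
                          expression_quartile_demethylation, rank_sum_test,
                          recurrence_summary)


class TestCoverageFilter:
    def test_boundary_30_percent_retained(self):
        vals = [[0.5] * 3 + [np.nan] * 7,   # exactly 30% -> kept
                [0.5] * 2 + [np.nan] * 8]   # 20% -> dropped
        levels = pd.DataFrame(vals, index=["g1", "g2"],
                              columns=[f"c{i}" for i in range(10)])
        assert coverage_filter(levels) == ["g1"]

    def test_sparse_gene_dropped(self):
        levels = pd.DataFrame([[0.5] + [np.nan] * 99], index=["g"],
                              columns=[f"c{i}" for i in range(100)])
        assert coverage_filter(levels) == []

    def test_matches_counting_oracle(self, rng):
        levels = pd.DataFrame(rng.random((50, 40)),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"c{i}" for i in range(40)])
        levels = levels.mask(rng.random((50, 40)) < 0.7)
        kept = coverage_filter(levels, 0.3)
        expected = [g for g in levels.index
                    if levels.loc[g].notna().sum() >= 0.3 * 40]
        assert kept == expected

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coverage_filter(pd.DataFrame())


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_small_samples_exact(self):
        # one-sided tail 1/C(6,3) = 1/20, two-sided p = 0.1
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_equals_full_enumeration(self, rng):
        """Exact p at n=m<=8 equals enumeration of all rank assignments."""
        for n, m in [(3, 3), (4, 6), (8, 8)]:
            vals = rng.permutation(100)[: n + m].astype(float)
            a, b = vals[:n], vals[n:]
            p = rank_sum_test(a, b)
            ranks = pd.Series(np.concatenate([a, b])).rank().to_numpy()
            w_obs = ranks[:n].sum()
            mu = n * (n + m + 1) / 2
            count = sum(1 for comb in itertools.combinations(range(n + m), n)
                        if abs(sum(ranks[list(comb)]) - mu) >= abs(w_obs - mu) - 1e-9)
            from math import comb as ncomb
            assert p == pytest.approx(count / ncomb(n + m, n), abs=1e-12)

    def test_asymptotic_close_to_exact_at_n8(self, rng):
        vals = rng.permutation(1_000)[:16].astype(float)
        a, b = vals[:8], vals[8:]
        p_exact = rank_sum_test(a, b)
        from scipy.stats import mannwhitneyu
        p_asym = mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.01

    def test_all_na_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([np.nan], [1.0, 2.0])


def build_matrix(normal, cancer, gene="g1"):
    cols = [f"n{i}" for i in range(len(normal))] + \
           [f"t{i}" for i in range(len(cancer))]
    levels = pd.DataFrame([list(normal) + list(cancer)], index=[gene], columns=cols)
    groups = pd.Series(["normal"] * len(normal) + ["cancer"] * len(cancer),
                       index=cols)
    return levels, groups


class TestCallDmrs:
    def test_constructed_hypermethylated_promoter_passes(self, rng):
        normal = rng.normal(0.10, 0.02, 20).clip(0, 1)
        cancer = rng.normal(0.80, 0.05, 20).clip(0, 1)
        levels, groups = build_matrix(normal, cancer)
        [r], _ = call_dmrs(levels, groups)
        assert r.passed and r.direction == "hyper"
        assert r.fold_change == pytest.approx(cancer.mean() / normal.mean())
        assert r.abs_difference > 0.5

    def test_single_criterion_knockout_on_difference(self, rng):
        normal = rng.normal(0.10, 0.02, 20).clip(0, 1)
        cancer = rng.normal(0.55, 0.02, 20).clip(0, 1)  # FC >> 2 but delta < 0.5
        levels, groups = build_matrix(normal, cancer)
        [r], _ = call_dmrs(levels, groups)
        assert not r.passed and r.abs_difference < 0.5
        assert r.p_value < 0.05 and r.fold_change > 2

    def test_zero_normal_mean_gives_infinite_fold_change(self):
        levels, groups = build_matrix([0.0] * 5, [0.8] * 5)
        [r], _ = call_dmrs(levels, groups)
        assert np.isinf(r.fold_change) and r.passed

    def test_sparse_gene_skipped_and_reported(self):
        levels, groups = build_matrix([0.1, np.nan, np.nan], [0.8, 0.9, 0.7])
        results, skipped = call_dmrs(levels, groups)
        assert results == [] and skipped == ["g1"]

    def test_pass_flag_is_exact_conjunction(self):
        """The pass flag equals the four-criterion conjunction on a grid of
        boundary and non-boundary values."""
        for p in (0.049, 0.05):
            for fc in (0.4, 0.5, 1.0, 2.0, 2.1):
                for diff in (0.45, 0.5, 0.55):
                    for sd in (0.2, 0.25, 0.3):
                        expected = (p < 0.05 and (fc > 2 or fc < 0.5)
                                    and diff > 0.5 and sd < 0.25 and sd < 0.25)
                        assert _passes(p, fc, diff, sd, sd) == expected

    def test_group_swap_inverts_fold_change_and_direction(self, rng):
        levels = pd.DataFrame(rng.random((10, 24)),
                              index=[f"g{i}" for i in range(10)],
                              columns=[f"c{i}" for i in range(24)])
        groups = pd.Series(["normal"] * 12 + ["cancer"] * 12, index=levels.columns)
        swapped = groups.map({"normal": "cancer", "cancer": "normal"})
        res1, _ = call_dmrs(levels, groups)
        res2, _ = call_dmrs(levels, swapped)
        for a, b in zip(res1, res2):
            assert a.fold_change == pytest.approx(1 / b.fold_change)
            assert {a.direction, b.direction} in ({"hyper", "hypo"},
                                                  {a.direction})
            assert a.p_value == pytest.approx(b.p_value)

    def test_null_data_yields_at_most_one_pass(self, rng):
        """200 genes, 30+30 cells, no planted effect: the delta and SD filters
        keep the expected pass count near zero."""
        n_genes, n = 200, 60
        levels = pd.DataFrame(
            np.clip(rng.normal(0.1, 0.05, (n_genes, n)), 0, 1),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"c{i}" for i in range(n)])
        groups = pd.Series(["normal"] * 30 + ["cancer"] * 30,
                           index=levels.columns)
        results, _ = call_dmrs(levels, groups)
        assert sum(r.passed for r in results) <= 1


def result(gene, direction="hyper", passed=True):
    return DMRResult(gene_id=gene, n_normal=10, n_cancer=10, mean_normal=0.1,
                     mean_cancer=0.8, p_value=0.001, fold_change=8.0,
                     abs_difference=0.7, sd_normal=0.05, sd_cancer=0.05,
                     direction=direction, passed=passed)


class TestRecurrence:
    def test_gene_passing_in_three_patients_included(self):
        per_patient = {f"P{i}": [result("gA")] for i in range(3)}
        per_patient["P3"] = [result("gB")]
        table = recurrence_summary(per_patient, min_patients=3)
        assert list(table.index) == ["gA"]
        assert table.loc["gA", "n_patients_hyper"] == 3

    def test_threshold_one_equals_union(self):
        per_patient = {"P1": [result("gA")], "P2": [result("gB", "hypo")]}
        table = recurrence_summary(per_patient, min_patients=1)
        assert set(table.index) == {"gA", "gB"}

    def test_counts_match_bruteforce_tally(self, rng):
        genes = [f"g{i}" for i in range(30)]
        per_patient = {}
        for p in range(5):
            per_patient[f"P{p}"] = [result(g, passed=bool(rng.random() < 0.3))
                                    for g in genes]
        table = recurrence_summary(per_patient, min_patients=1)
        for g in genes:
            expected = sum(1 for res in per_patient.values()
                           for r in res if r.gene_id == g and r.passed)
            got = (int(table.loc[g, "n_patients_hyper"])
                   if g in table.index else 0)
            assert got == expected

    def test_needs_two_patients(self):
        with pytest.raises(ValueError):
            recurrence_summary({"P1": [result("g")]})


class TestExpressionQuartiles:
    def test_eight_genes_split_two_per_quartile(self):
        genes = [f"g{i}" for i in range(8)]
        cells = ["n1", "n2", "t1", "t2"]
        expr = pd.DataFrame(
            np.array([[2 ** i] * 4 for i in range(8)], dtype=float),
            index=genes, columns=cells)
        # plant body delta proportional to expression rank: -0.8 ... -0.1
        body = pd.DataFrame(0.8, index=genes, columns=cells)
        for i, g in enumerate(genes):
            body.loc[g, ["t1", "t2"]] = 0.8 - max(0.8 - 0.1 * i, 0.0)
        groups = pd.Series(["normal", "normal", "cancer", "cancer"], index=cells)
        deltas = expression_quartile_demethylation(expr, body, groups)
        assert list(deltas.index) == ["Q1", "Q2", "Q3", "Q4"]
        # two genes per quartile: Q1 mean of planted deltas for the two
        # lowest-expression genes
        assert deltas["Q1"] == pytest.approx(-(0.8 + 0.7) / 2)
        assert (deltas.diff().dropna() > 0).all()

    def test_no_difference_gives_near_zero_deltas(self, rng):
        genes = [f"g{i}" for i in range(40)]
        cells = [f"c{i}" for i in range(20)]
        expr = pd.DataFrame(rng.poisson(20, (40, 20)).astype(float) + 1,
                            index=genes, columns=cells)
        body = pd.DataFrame(0.8 + rng.normal(0, 0.001, (40, 20)),
                            index=genes, columns=cells)
        groups = pd.Series(["normal"] * 10 + ["cancer"] * 10, index=cells)
        deltas = expression_quartile_demethylation(expr, body, groups)
        assert (deltas.abs() < 0.01).all()

    def test_fewer_than_eight_genes_rejected(self):
        expr = pd.DataFrame(np.ones((5, 4)), index=list("abcde"),
                            columns=["n1", "n2", "t1", "t2"])
        groups = pd.Series(["normal", "normal", "cancer", "cancer"],
                           index=expr.columns)
        with pytest.raises(ValueError, match=">= 8"):
            expression_quartile_demethylation(expr, expr, groups)
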