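import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cooltrio.intervals import GenomicInterval
from cooltrio.io import SiteCallTable
from cooltrio.methylome import (CellQCRecord, classical_mds, feature_level,
                                filter_cells, global_level,
                                normalize_accessibility, promoter_mds,
                                usable_sites, LevelMatrix)


def make_table(pos, frac, context="WCG", chrom="chr1", cell="c1"):
    return SiteCallTable(cell, pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
        "context": context, "meth_fraction": np.asarray(frac, dtype=float),
        "depth": 1}))


def passing_dna_record(cell="c", **over):
    base = dict(genome_coverage=0.05, n_wcg_sites=1_000_000,
                n_gch_sites=6_000_000, mapping_ratio=0.3, conversion_rate=0.99)
    base.update(over)
    return CellQCRecord(cell_id=cell, **base)


class TestFilterCells:
    def test_rna_boundaries_inclusive(self):
        recs = [CellQCRecord("a", n_detected_genes=1_500, n_umis=400_000),
                CellQCRecord("b", n_detected_genes=1_499, n_umis=100_000),
                CellQCRecord("c", n_detected_genes=9_001, n_umis=100_000),
                CellQCRecord("d", n_detected_genes=5_000, n_umis=400_001)]
        assert filter_cells(recs, "rna") == ["a"]

    @pytest.mark.parametrize("field,bad", [
        ("genome_coverage", 0.039), ("n_wcg_sites", 799_999),
        ("n_gch_sites", 4_999_999), ("mapping_ratio", 0.049),
        ("conversion_rate", 0.979),
    ])
    def test_dna_single_criterion_knockout(self, field, bad):
        recs = [passing_dna_record("ok"), passing_dna_record("bad", **{field: bad})]
        assert filter_cells(recs, "dna") == ["ok"]

    def test_dna_boundaries_inclusive(self):
        rec = passing_dna_record("edge", genome_coverage=0.04,
                                 n_wcg_sites=800_000, n_gch_sites=5_000_000,
                                 mapping_ratio=0.05, conversion_rate=0.98)
        assert filter_cells([rec], "dna") == ["edge"]

    def test_missing_field_for_mode_raises(self):
        with pytest.raises(ValueError, match="missing RNA"):
            filter_cells([passing_dna_record()], "rna")

    def test_survivor_count_matches_violation_count(self):
        recs = [passing_dna_record(f"ok{i}") for i in range(15)]
        recs += [passing_dna_record("k1", genome_coverage=0.01),
                 passing_dna_record("k2", n_wcg_sites=10),
                 passing_dna_record("k3", conversion_rate=0.5)]
        assert len(filter_cells(recs, "dna")) == 15


class TestUsableSites:
    def test_binarization_and_intermediate_removal(self):
        t = make_table([10, 20, 30], [0.95, 0.5, 0.05])
        out = usable_sites(t)
        assert list(out.data["call"]) == [1, 0]
        assert list(out.data["pos"]) == [10, 30]

    def test_strict_inequality_at_both_bounds(self):
        t = make_table([10, 20], [0.9, 0.1])
        assert len(usable_sites(t)) == 0

    def test_retained_fraction_matches_mixture_expectation(self, rng):
        """10% intermediate Beta(2,2) sites: analytic retention 0.9056."""
        n = 100_000
        inter = rng.random(n) < 0.1
        frac = np.where(inter, rng.beta(2, 2, n),
                        np.where(rng.random(n) < 0.8, rng.beta(100, 1, n),
                                 rng.beta(1, 100, n)))
        t = make_table(np.arange(10, 10 * n + 10, 10), frac)
        observed = len(usable_sites(t)) / n
        beta_tail = stats.beta(2, 2).cdf(0.1) + stats.beta(2, 2).sf(0.9)
        expected = 0.9 + 0.1 * beta_tail
        assert observed == pytest.approx(expected, abs=0.01)


class TestFeatureLevel:
    def test_mean_and_min_sites_rule(self):
        t = usable_sites(make_table([10, 20, 30, 100, 110],
                                    [0.95, 0.95, 0.05, 0.95, 0.05]))
        feats = [GenomicInterval("chr1", 0, 50, name="a"),
                 GenomicInterval("chr1", 90, 200, name="b")]
        levels, counts = feature_level(t, feats, "WCG")
        assert levels["a"] == pytest.approx(2 / 3)
        assert np.isnan(levels["b"]) and counts["b"] == 2

    def test_all_methylated_gives_one(self):
        t = usable_sites(make_table([10, 20, 30], [0.95, 0.99, 0.96]))
        levels, _ = feature_level(t, [GenomicInterval("chr1", 0, 50, name="a")], "WCG")
        assert levels["a"] == 1.0

    def test_matches_bruteforce_scan(self, rng):
        n = 5_000
        pos = np.sort(rng.choice(np.arange(0, 500_000), n, replace=False))
        frac = np.where(rng.random(n) < 0.7, 0.99, 0.01)
        t = usable_sites(make_table(pos, frac))
        feats = [GenomicInterval("chr1", int(s), int(s) + int(l), name=f"f{i}")
                 for i, (s, l) in enumerate(zip(rng.integers(0, 490_000, 100),
                                                rng.integers(100, 10_000, 100)))]
        levels, counts = feature_level(t, feats, "WCG")
        df = t.data
        for f in feats:
            sub = df[(df["pos"] >= f.start) & (df["pos"] < f.end)]
            assert counts[f.name] == len(sub)
            if len(sub) >= 3:
                assert levels[f.name] == pytest.approx(sub["call"].mean())
            else:
                assert np.isnan(levels[f.name])

    def test_requires_binarized_table(self):
        with pytest.raises(ValueError, match="binarized"):
            feature_level(make_table([10], [0.5]),
                          [GenomicInterval("chr1", 0, 50)], "WCG")

    def test_values_stay_in_unit_interval(self, tiny_wcg, tiny_ds):
        from cooltrio.methylome import feature_level_matrix
        proms = [g.promoter() for g in tiny_ds.gene_models[:30]]
        m = feature_level_matrix(tiny_wcg, proms, "WCG")
        vals = m.levels.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
        # NA exactly where < 3 covered sites
        assert ((m.counts < 3) == m.levels.isna()).all().all()


class TestGlobalLevel:
    def test_tiles_weighted_equally_not_by_sites(self):
        # tile 1: 3 sites all methylated; tile 2: 300 sites all unmethylated
        pos = np.concatenate([[100, 200, 300],
                              np.arange(1_000, 1_900, 3)])
        frac = np.concatenate([[0.99] * 3, [0.01] * 300])
        t = usable_sites(make_table(pos, frac))
        g = global_level(t, "WCG")
        assert g.level == pytest.approx(0.5)
        assert g.n_tiles == 2

    def test_single_qualifying_tile(self):
        t = usable_sites(make_table([10, 20, 30, 5_000], [0.99, 0.99, 0.01, 0.99]))
        assert global_level(t, "WCG").level == pytest.approx(2 / 3)

    def test_invariant_to_row_order(self, rng):
        n = 2_000
        pos = np.sort(rng.choice(np.arange(0, 100_000), n, replace=False))
        frac = np.where(rng.random(n) < 0.6, 0.99, 0.01)
        t1 = usable_sites(make_table(pos, frac))
        perm = rng.permutation(n)
        t2 = usable_sites(make_table(pos[perm], frac[perm]))
        assert global_level(t1, "WCG").level == global_level(t2, "WCG").level

    def test_no_qualifying_tile_is_undefined(self):
        t = usable_sites(make_table([10, 2_000], [0.99, 0.99]))
        with pytest.raises(ValueError, match="undefined"):
            global_level(t, "WCG")


class TestNormalizeAccessibility:
    def make_matrix(self, values):
        levels = pd.DataFrame(values, index=["f1"], columns=["c1"])
        counts = pd.DataFrame(5, index=["f1"], columns=["c1"])
        return LevelMatrix(levels, counts, "GCH")

    def test_division_by_global(self):
        m = normalize_accessibility(self.make_matrix([[0.30]]), {"c1": 0.15})
        assert m.levels.loc["f1", "c1"] == pytest.approx(2.0)

    def test_entry_equal_to_global_gives_one(self):
        m = normalize_accessibility(self.make_matrix([[0.15]]), {"c1": 0.15})
        assert m.levels.loc["f1", "c1"] == pytest.approx(1.0)

    def test_na_preserved_and_zero_global_rejected(self):
        m = normalize_accessibility(self.make_matrix([[np.nan]]), {"c1": 0.2})
        assert m.levels.isna().all().all()
        with pytest.raises(ValueError, match="> 0"):
            normalize_accessibility(self.make_matrix([[0.3]]), {"c1": 0.0})


class TestMDS:
    def test_equilateral_triangle_recovered(self):
        # three cells at mutual distance sqrt(2) in feature space
        levels = pd.DataFrame(np.eye(3), index=["f1", "f2", "f3"],
                              columns=["a", "b", "c"])
        coords, _ = promoter_mds(levels, min_cell_fraction=0.0)
        d = np.linalg.norm(coords.loc["a"] - coords.loc["b"])
        for pair in (("a", "c"), ("b", "c")):
            dd = np.linalg.norm(coords.loc[pair[0]] - coords.loc[pair[1]])
            assert dd == pytest.approx(d, abs=1e-9)
        assert d == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_duplicate_cells_embed_at_distance_zero(self):
        levels = pd.DataFrame({"a": [0.1, 0.9, 0.4], "b": [0.1, 0.9, 0.4],
                               "c": [0.8, 0.2, 0.6]},
                              index=["f1", "f2", "f3"])
        coords, _ = promoter_mds(levels, min_cell_fraction=0.0)
        assert np.linalg.norm(coords.loc["a"] - coords.loc["b"]) < 1e-6

    def test_feature_coverage_restriction_and_imputation(self):
        levels = pd.DataFrame({"a": [0.1, np.nan, np.nan],
                               "b": [0.2, 0.5, np.nan],
                               "c": [0.3, 0.6, np.nan],
                               "d": [0.4, 0.7, 0.9]},
                              index=["f1", "f2", "f3"])
        # f3 observed in 25% of cells -> dropped at the 50% rule; needs >=3 feats
        with pytest.raises(ValueError, match=">= 3"):
            promoter_mds(levels, min_cell_fraction=0.5)

    def test_matches_eigendecomposition_oracle(self, rng):
        x = rng.random((8, 20))
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        coords, evals = classical_mds(dist, n_components=7)
        # oracle: reconstructed pairwise distances from the full embedding
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        assert np.allclose(rec, dist, atol=1e-8)

    def test_separates_planted_groups(self, tiny_wcg, tiny_ds):
        from cooltrio.methylome import feature_level_matrix
        proms = [g.promoter() for g in tiny_ds.gene_models]
        m = feature_level_matrix(tiny_wcg, proms, "WCG")
        coords, _ = promoter_mds(m.levels)
        from sklearn.metrics import silhouette_score
        labels = [tiny_ds.groups[c] for c in coords.index]
        assert silhouette_score(coords.to_numpy(), labels) > 0
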