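"""Linkage mapping: dedup, t tests, FDR, loci, histograms, cis,
heritability, variance explained, avoidance test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_traits
from segnet import linkage, simulate
from segnet.types import ConstantTraitError, ExpressionSet, GenotypeMatrix, TraitMatrix


class TestDedupeMarkers:
    def test_identical_markers_collapse(self, tiny_map):
        calls = np.zeros((9, 6), dtype=np.uint8)
        calls[:, :3] = 1  # all nine markers share one pattern
        geno = GenotypeMatrix(tiny_map, [f"s{i}" for i in range(6)], calls)
        red, groups = linkage.dedupe_markers(geno)
        assert red.n_markers == 1
        assert len(groups["1_10"]) == 9

    def test_complementary_patterns_group_together(self, tiny_map):
        rng = np.random.default_rng(1)
        base = (rng.random(6) < 0.5).astype(np.uint8)
        base[0], base[1] = 0, 1  # polymorphic
        calls = np.vstack([base if i % 2 == 0 else 1 - base for i in range(9)])
        geno = GenotypeMatrix(tiny_map, [f"s{i}" for i in range(6)], calls)
        red, groups = linkage.dedupe_markers(geno)
        assert red.n_markers == 1

    def test_group_count_matches_pattern_string_oracle(self, small_genotypes):
        red, groups = linkage.dedupe_markers(small_genotypes)
        # oracle: distinct canonical pattern strings
        seen = set()
        for row in small_genotypes.calls:
            s = "".join(map(str, row if row[0] == 0 else 1 - row))
            seen.add(s)
        assert red.n_markers == len(seen)
        assert sum(len(v) for v in groups.values()) == small_genotypes.n_markers

    def test_representative_preserves_t_tests(self, small_genotypes):
        red, groups = linkage.dedupe_markers(small_genotypes)
        rng = np.random.default_rng(2)
        trait = rng.normal(size=small_genotypes.n_segregants)
        for rep, members in groups.items():
            t_rep, _ = linkage.marker_t_test(trait, red.marker_calls(rep))
            for m in members:
                t_m, _ = linkage.marker_t_test(trait, small_genotypes.marker_calls(m))
                assert abs(t_m) == pytest.approx(abs(t_rep), rel=1e-9)


class TestMarkerTTest:
    def test_identical_groups_give_t_zero(self):
        trait = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        marker = np.array([0, 0, 0, 1, 1, 1])
        t, p = linkage.marker_t_test(trait, marker)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        trait = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0])
        marker = np.array([0, 0, 0, 1, 1, 1])
        t, p = linkage.marker_t_test(trait, marker, equal_var=True)
        # textbook pooled two-sample t oracle
        a, b = trait[3:], trait[:3]
        sp = np.sqrt(((a.var(ddof=1)) * 2 + (b.var(ddof=1)) * 2) / 4)
        t_direct = (a.mean() - b.mean()) / (sp * np.sqrt(2 / 3))
        assert t == pytest.approx(t_direct, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_direct), 4), rel=1e-12)

    def test_small_group_rejected_with_marker_name(self):
        with pytest.raises(ValueError, match="mk7"):
            linkage.marker_t_test(np.arange(5.0), np.array([0, 0, 0, 0, 1]), marker_id="mk7")

    def test_vectorised_scan_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(4, 40))
        G = (rng.random((6, 40)) < 0.5).astype(np.uint8)
        G[:, 0], G[:, 1] = 0, 1
        G[:, 2], G[:, 3] = 0, 1
        t, p = linkage.t_scan(Y, G)
        for i in range(4):
            for j in range(6):
                ref = stats.ttest_ind(Y[i, G[j] == 1], Y[i, G[j] == 0], equal_var=False)
                assert t[i, j] == pytest.approx(ref.statistic, rel=1e-9)
                assert p[i, j] == pytest.approx(ref.pvalue, rel=1e-9)


class TestVarianceExplained:
    def test_trait_equal_to_indicator_explains_everything(self):
        marker = np.array([0, 1, 0, 1, 1, 0])
        assert linkage.variance_explained(marker.astype(float), marker) == pytest.approx(1.0)

    def test_equal_group_means_explain_nothing(self):
        trait = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        marker = np.array([0, 0, 0, 1, 1, 1])
        assert linkage.variance_explained(trait, marker) == pytest.approx(0.0)

    def test_equals_squared_point_biserial(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(6, 60)
            trait = rng.normal(size=n)
            marker = (rng.random(n) < 0.5).astype(int)
            marker[:2] = [0, 1]
            r = np.corrcoef(trait, marker)[0, 1]
            assert linkage.variance_explained(trait, marker) == pytest.approx(r**2, rel=1e-9)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        trait = rng.normal(size=30)
        marker = (rng.random(30) < 0.5).astype(int)
        marker[:2] = [0, 1]
        v = linkage.variance_explained(trait, marker)
        assert linkage.variance_explained(3.7 * trait + 11.0, marker) == pytest.approx(v)

    def test_constant_trait_rejected(self):
        with pytest.raises(ConstantTraitError):
            linkage.variance_explained(np.ones(6), np.array([0, 0, 0, 1, 1, 1]))


def _expr_from_matrix(values: np.ndarray) -> ExpressionSet:
    """strains x measurements -> ExpressionSet with a 1x(m) replicate layout."""
    n_strain, m = values.shape
    return ExpressionSet(
        ["G1"], [f"s{i}" for i in range(n_strain)], values.reshape(1, n_strain, 1, m)
    )


class TestHeritability:
    def test_pure_strain_differences_give_one(self):
        vals = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert linkage.heritability(_expr_from_matrix(vals), "G1")["H"] == pytest.approx(1.0)

    def test_within_strain_noise_only_is_near_zero(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(40, 50))  # many replicates, one true mean
        h = linkage.heritability(_expr_from_matrix(vals), "G1")["H"]
        assert h < 0.1

    def test_equals_anova_between_over_total(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            vals = rng.normal(rng.normal(0, 1, size=(10, 1)), 0.5, size=(10, 4))
            h = linkage.heritability(_expr_from_matrix(vals), "G1")["H"]
            gm = vals.mean()
            between = (4 * (vals.mean(axis=1) - gm) ** 2).sum()
            total = ((vals - gm) ** 2).sum()
            assert h == pytest.approx(between / total, rel=1e-9)

    def test_unbalanced_weights_by_measurement_count(self):
        vals = np.array(
            [[1.0, 1.2, 0.8, np.nan], [2.0, np.nan, np.nan, np.nan], [3.0, 3.1, np.nan, np.nan]]
        )
        expr = _expr_from_matrix(vals)
        rec = linkage.heritability(expr, "G1")
        flat = vals[~np.isnan(vals)]
        gm = flat.mean()
        x = [np.nanmean(vals[i]) for i in range(3)]
        between = sum(n * (xi - gm) ** 2 for n, xi in zip((3, 1, 2), x))
        assert rec["H"] == pytest.approx(between / ((flat - gm) ** 2).sum(), rel=1e-12)
        assert rec["N"] == 6

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, size=(8, 3)) + rng.normal(0, 2, size=(8, 1))
        h1 = linkage.heritability(_expr_from_matrix(vals), "G1")["H"]
        h2 = linkage.heritability(_expr_from_matrix(vals + 100.0), "G1")["H"]
        assert 0.0 <= h1 <= 1.0
        assert h1 == pytest.approx(h2, rel=1e-9)


class TestPermutationFdr:
    def test_null_traits_yield_almost_no_linkages(self, small_genotypes):
        traits = make_traits(20, small_genotypes.n_segregants, seed=9)
        traits = TraitMatrix(traits.gene_ids, small_genotypes.segregant_ids, traits.values)
        red, _ = linkage.dedupe_markers(small_genotypes)
        rec = linkage.permutation_fdr(traits, red, n_perm=50, seed=10)
        peaks = rec[(rec["fdr_tier"] != "none") & rec["is_peak"]]
        assert len(peaks) <= 2  # ~0 expected under the null
        assert set(rec["trait"]) == set(traits.gene_ids)  # every trait reported

    def test_planted_effect_recovered_at_marker(self, small_genotypes):
        red, _ = linkage.dedupe_markers(small_genotypes)
        rng = np.random.default_rng(11)
        target = red.calls[3].astype(float)
        vals = np.vstack([1.5 * target + rng.normal(0, 1, red.n_segregants) for _ in range(5)])
        traits = TraitMatrix([f"g{i}" for i in range(5)], red.segregant_ids, vals)
        rec = linkage.permutation_fdr(traits, red, n_perm=60, seed=12)
        hit_marker = str(red.markers.marker_id[3])
        hits = rec[(rec["marker"] == hit_marker) & (rec["fdr_tier"] != "none")]
        assert hits["trait"].nunique() >= 4

    def test_both_tiers_reported_and_nested(self, small_genotypes):
        red, _ = linkage.dedupe_markers(small_genotypes)
        rng = np.random.default_rng(13)
        target = red.calls[2].astype(float)
        vals = np.vstack([2.0 * target + rng.normal(0, 1, red.n_segregants) for _ in range(4)])
        traits = TraitMatrix([f"g{i}" for i in range(4)], red.segregant_ids, vals)
        rec = linkage.permutation_fdr(traits, red, n_perm=60, seed=14)
        tiers = set(rec["fdr_tier"]) - {"none"}
        assert tiers <= {"0.05", "0.01"}
        # a 1% marker is by construction also below the 5% cutoff
        assert (rec.loc[rec["fdr_tier"] == "0.01", "p"].max() or 0) <= (
            rec.loc[rec["fdr_tier"] != "none", "p"].max()
        )

    def test_max_stat_method_recovers_signal_and_silences_null(self, small_genotypes):
        red, _ = linkage.dedupe_markers(small_genotypes)
        rng = np.random.default_rng(31)
        target = red.calls[3].astype(float)
        vals = np.vstack(
            [2.0 * target + rng.normal(0, 1, red.n_segregants) for _ in range(3)]
            + [rng.normal(0, 1, red.n_segregants) for _ in range(10)]
        )
        traits = TraitMatrix([f"g{i}" for i in range(13)], red.segregant_ids, vals)
        rec = linkage.permutation_fdr(
            traits, red, n_perm=60, seed=32, fdr_method="max_stat"
        )
        sig = rec[rec["fdr_tier"] != "none"]
        assert set(sig["trait"]) <= {"g0", "g1", "g2"}
        assert sig["trait"].nunique() >= 2

    def test_low_n_perm_warns(self, small_genotypes):
        traits = make_traits(2, small_genotypes.n_segregants, seed=15)
        traits = TraitMatrix(traits.gene_ids, small_genotypes.segregant_ids, traits.values)
        red, _ = linkage.dedupe_markers(small_genotypes)
        with pytest.warns(UserWarning, match="FDR resolution"):
            linkage.permutation_fdr(traits, red, n_perm=10, seed=16)


class TestCollapseToLoci:
    @staticmethod
    def _records(positions, chroms, ps, tier="0.05"):
        return pd.DataFrame(
            {
                "trait": ["g1"] * len(positions),
                "layer": ["protein"] * len(positions),
                "marker": [f"m{i}" for i in range(len(positions))],
                "chrom": chroms,
                "pos": positions,
                "t": [1.0] * len(positions),
                "p": ps,
                "var_explained": [0.1] * len(positions),
                "fdr_tier": [tier] * len(positions),
                "locus_id": [""] * len(positions),
            }
        )

    def test_adjacent_markers_form_one_locus_with_min_p_peak(self):
        rec = self._records([1000, 2000, 3000], [1, 1, 1], [0.01, 0.001, 0.01])
        out = linkage.collapse_to_loci(rec, min_gap=100_000)
        assert out["locus_id"].nunique() == 1
        assert out.loc[out["is_peak"], "marker"].tolist() == ["m1"]

    def test_distinct_chromosomes_never_merge(self):
        rec = self._records([1000, 1000], [3, 13], [0.01, 0.01])
        out = linkage.collapse_to_loci(rec, min_gap=10**9)
        assert out["locus_id"].nunique() == 2

    def test_matches_gap_scan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            chroms = np.sort(rng.integers(1, 4, n))
            pos = np.sort(rng.integers(1, 10**6, n))
            rec = self._records(pos, chroms, rng.uniform(0.0001, 0.04, n))
            rec = rec.sort_values(["chrom", "pos"]).reset_index(drop=True)
            out = linkage.collapse_to_loci(rec, min_gap=100_000)
            # oracle: walk sorted markers, break on chrom change or gap >= min_gap
            breaks = 1
            for i in range(1, len(rec)):
                if (
                    rec.loc[i, "chrom"] != rec.loc[i - 1, "chrom"]
                    or rec.loc[i, "pos"] - rec.loc[i - 1, "pos"] >= 100_000
                ):
                    breaks += 1
            assert out["locus_id"].nunique() == breaks
            assert out["is_peak"].sum() == breaks


class TestHotspotHistogram:
    def test_empty_records_all_zero(self, tiny_map):
        rec = pd.DataFrame(columns=["trait", "chrom", "pos", "fdr_tier", "is_peak"])
        hist = linkage.hotspot_histogram(rec, tiny_map, bin_size=20)
        assert hist["count"].sum() == 0

    def test_boundary_position_lands_in_second_bin(self, tiny_map):
        rec = pd.DataFrame(
            {"trait": ["g"], "chrom": [1], "pos": [20], "fdr_tier": ["0.05"], "is_peak": [True]}
        )
        hist = linkage.hotspot_histogram(rec, tiny_map, bin_size=20)
        row = hist[(hist["chrom"] == 1) & (hist["start"] == 20)]
        assert int(row["count"].iloc[0]) == 1
        assert hist["count"].sum() == 1

    def test_counts_conserved(self, tiny_map):
        rng = np.random.default_rng(18)
        n = 25
        rec = pd.DataFrame(
            {
                "trait": [f"g{i}" for i in range(n)],
                "chrom": rng.choice([1, 2], n),
                "pos": rng.integers(1, 39, n),
                "fdr_tier": ["0.05"] * n,
                "is_peak": [True] * n,
            }
        )
        hist = linkage.hotspot_histogram(rec, tiny_map, bin_size=10)
        assert hist["count"].sum() == n

    def test_position_beyond_chromosome_rejected(self, tiny_map):
        rec = pd.DataFrame(
            {"trait": ["g"], "chrom": [2], "pos": [90], "fdr_tier": ["0.05"], "is_peak": [True]}
        )
        with pytest.raises(ValueError, match="beyond declared"):
            linkage.hotspot_histogram(rec, tiny_map, bin_size=20)


class TestCisScan:
    def test_expected_false_positive_arithmetic(self, small_genotypes):
        traits = make_traits(10, small_genotypes.n_segregants, seed=19)
        traits = TraitMatrix(traits.gene_ids, small_genotypes.segregant_ids, traits.values)
        pos = pd.DataFrame(
            {"gene_id": traits.gene_ids, "chromosome": [1] * 10, "position": range(10, 60, 5)}
        )
        tab, exp_fp = linkage.cis_scan(traits, small_genotypes, pos, alpha=0.01)
        assert exp_fp == pytest.approx(0.1)
        assert len(tab) == 10

    def test_planted_cis_effect_detected(self, default_map):
        geno = simulate.simulate_genotypes(95, default_map, seed=20)
        rng = np.random.default_rng(21)
        midx = [100, 500, 1200, 2000, 2400]
        gene_pos = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(5)],
                "chromosome": [int(default_map.chromosome[m]) for m in midx],
                "position": [int(default_map.position[m]) for m in midx],
            }
        )
        vals = np.vstack(
            [1.5 * geno.calls[m] + rng.normal(0, 1, 95) for m in midx]
        )
        traits = TraitMatrix(gene_pos["gene_id"].tolist(), geno.segregant_ids, vals)
        tab, _ = linkage.cis_scan(traits, geno, gene_pos, alpha=0.01)
        assert tab["cis"].all()

    def test_null_cis_rate_calibrated(self, default_map):
        geno = simulate.simulate_genotypes(60, default_map, seed=22)
        n = 400
        rng = np.random.default_rng(23)
        gene_pos = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chromosome": rng.integers(1, 17, n),
                "position": rng.integers(1, 200_000, n),
            }
        )
        traits = TraitMatrix(
            gene_pos["gene_id"].tolist(), geno.segregant_ids, rng.normal(size=(n, 60))
        )
        tab, _ = linkage.cis_scan(traits, geno, gene_pos, alpha=0.05)
        frac = tab["cis"].mean()
        half = 2.807 * np.sqrt(0.05 * 0.95 / n)  # 99.5% band
        assert abs(frac - 0.05) < half


class TestSharedLocusAvoidance:
    @staticmethod
    def _records(bins, trait_ids, chrom=1):
        return pd.DataFrame(
            {
                "trait": trait_ids,
                "chrom": [chrom] * len(bins),
                "pos": [b * 20_000 + 7 for b in bins],
                "fdr_tier": ["0.05"] * len(bins),
                "is_peak": [True] * len(bins),
            }
        )

    def test_identical_maps_cannot_avoid(self):
        bins = list(range(12))
        traits = [f"g{i}" for i in range(12)]
        rec = self._records(bins, traits)
        res = linkage.shared_locus_avoidance(rec, rec.copy(), set(traits), n_perm=300, seed=24)
        assert res["p_low"] == pytest.approx(1.0)

    def test_disjoint_subset_maps_show_avoidance(self):
        rng = np.random.default_rng(25)
        sub = [f"g{i}" for i in range(30)]
        other = [f"x{i}" for i in range(70)]
        # subset linkages occupy disjoint bin ranges; full pools overlap
        rec_p = self._records(list(range(0, 30)) + list(rng.integers(0, 200, 70)), sub + other)
        rec_t = self._records(list(range(100, 130)) + list(rng.integers(0, 200, 70)), sub + other)
        res = linkage.shared_locus_avoidance(rec_p, rec_t, set(sub), n_perm=500, seed=26)
        assert res["observed_shared_bins"] == 0
        assert res["p_low"] < 0.1

    def test_resolution_floor_is_one_over_n_perm(self):
        bins = list(range(12))
        traits = [f"g{i}" for i in range(12)]
        rec = self._records(bins, traits)
        res = linkage.shared_locus_avoidance(rec, rec.copy(), set(traits), n_perm=400, seed=27)
        assert res["p_high"] >= 1.0 / 400

    def test_empty_subset_rejected(self):
        rec = self._records([1, 2], ["a", "b"])
        with pytest.raises(ValueError):
            linkage.shared_locus_avoidance(rec, rec, {"zzz"}, n_perm=10, seed=0)
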