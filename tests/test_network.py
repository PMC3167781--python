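"""Correlation networks: Pearson, permutation cutoffs, degree stats,
protein-transcript significance, abundance-binned correlations."""

import numpy as np
import networkx as nx
import pytest
from scipy import stats

from conftest import make_traits
from segnet import network
from segnet.types import ConstantTraitError, TraitMatrix


class TestPearson:
    def test_identity_and_sign_flip(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert network.pearson(x, x) == pytest.approx(1.0)
        assert network.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        # direct covariance / SD oracle
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert network.pearson(x, y) == pytest.approx(expected, rel=1e-12)
        assert network.pearson(x, y) == pytest.approx(network.pearson(y, x))

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantTraitError):
            network.pearson(np.ones(5), np.arange(5.0))


class TestPairPermutationCutoff:
    def test_rank_convention_tenth_highest_of_1000(self):
        # with a tiny n_perm the k-th highest is directly checkable
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        cut = network.pair_permutation_cutoff(x, y, n_perm=100, fpr=0.05, seed=1)
        # recompute the permuted distribution with the same seed
        perms = network._permutations(50, 100, "random", np.random.default_rng(1))
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        r = yc[perms] @ xc / 50
        assert cut == pytest.approx(np.sort(r)[-5])

    def test_null_cutoff_matches_analytic_student_quantile(self):
        # analytic oracle: one-sided 99th percentile of null r at n=95
        # is t_0.99 / sqrt(t_0.99^2 + 93)
        t99 = stats.t.ppf(0.99, df=93)
        expected = t99 / np.sqrt(t99**2 + 93)
        rng = np.random.default_rng(42)
        cut = network.pair_permutation_cutoff(
            rng.normal(size=95), rng.normal(size=95), n_perm=1000, fpr=0.01, seed=7
        )
        assert cut == pytest.approx(expected, abs=0.03)

    def test_tied_vector_raises(self):
        with pytest.raises(ConstantTraitError):
            network.pair_permutation_cutoff(np.ones(10), np.arange(10.0))

    def test_cyclic_scheme_uses_rotations(self):
        x = np.arange(6.0)
        perms = network._permutations(6, 10, "cyclic", np.random.default_rng(0))
        assert np.array_equal(perms[0], np.roll(np.arange(6), -1))
        # shifts wrap after n-1 distinct rotations
        assert np.array_equal(perms[5], perms[0])


class TestBuildConnectivity:
    def test_pair_count_is_all_unordered_pairs(self):
        tm = make_traits(5, 20, seed=3)
        res = network.build_connectivity(tm, n_perm=50, fpr=0.1, seed=4)
        assert res.n_pairs == 10
        tm2 = make_traits(2, 20, seed=3)
        assert network.build_connectivity(tm2, n_perm=50, fpr=0.1, seed=4).n_pairs == 1

    def test_study_design_pair_count(self):
        # 354 genes -> 62,481 unordered pairs (no need to permute to know it)
        assert 354 * 353 // 2 == 62_481

    def test_perfectly_correlated_pair_connects(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=30)
        tm = TraitMatrix(
            ["a", "b", "c"],
            [f"s{i}" for i in range(30)],
            np.vstack([base, base + 1e-6 * rng.normal(size=30), rng.normal(size=30)]),
        )
        res = network.build_connectivity(tm, n_perm=200, fpr=0.01, seed=6)
        assert res.graph.has_edge("a", "b")

    def test_null_edge_rate_matches_nominal_fpr(self):
        # calibration: 3,000+ null pairs, 99% binomial band around fpr
        tm = make_traits(80, 60, seed=8)
        res = network.build_connectivity(tm, n_perm=500, fpr=0.02, seed=9)
        frac = res.pairs["connected"].mean()
        n = res.n_pairs
        half = 2.576 * np.sqrt(0.02 * 0.98 / n)
        assert abs(frac - 0.02) < half

    def test_lowering_fpr_never_adds_edges(self):
        tm = make_traits(30, 40, seed=10)
        loose = network.build_connectivity(tm, n_perm=400, fpr=0.05, seed=11)
        tight = network.build_connectivity(tm, n_perm=400, fpr=0.01, seed=11)
        assert set(tight.graph.edges) <= set(loose.graph.edges)

    def test_deterministic_under_fixed_seed(self):
        tm = make_traits(12, 25, seed=12)
        a = network.build_connectivity(tm, n_perm=100, fpr=0.05, seed=13)
        b = network.build_connectivity(tm, n_perm=100, fpr=0.05, seed=13)
        assert a.pairs.equals(b.pairs)

    def test_constant_gene_named_in_error(self):
        vals = np.vstack([np.ones(10), np.arange(10.0)])
        tm = TraitMatrix(["flat", "ok"], [f"s{i}" for i in range(10)], vals)
        with pytest.raises(ConstantTraitError, match="flat"):
            network.build_connectivity(tm, n_perm=50, fpr=0.1, seed=1)


class TestDegreeSummary:
    def test_empty_graph(self):
        g = nx.empty_graph(5)
        s = network.degree_summary(g)
        assert s == {"min": 0.0, "max": 0.0, "mean": 0.0, "median": 0.0, "edges": 0}

    def test_star_graph_closed_form(self):
        s = network.degree_summary(nx.star_graph(4))  # degrees 4,1,1,1,1
        assert (s["min"], s["max"], s["mean"]) == (1.0, 4.0, 1.6)

    def test_handshake_identity(self):
        g = nx.gnp_random_graph(40, 0.2, seed=7)
        s = network.degree_summary(g)
        assert s["mean"] * g.number_of_nodes() == pytest.approx(2 * s["edges"])


class TestGeneCorrelationSignificance:
    def test_identical_layers_fully_significant(self):
        tm = make_traits(6, 30, seed=20)
        tab, _ = network.gene_correlation_significance(tm, tm, n_perm=200, seed=21)
        assert np.allclose(tab["r"], 1.0)
        assert tab["sig05"].all() and tab["sig01"].all()

    def test_sig01_implies_sig05(self):
        p = make_traits(40, 50, seed=22)
        t = make_traits(40, 50, seed=23)
        tab, _ = network.gene_correlation_significance(p, t, n_perm=400, seed=24)
        assert (~tab["sig01"] | tab["sig05"]).all()

    def test_null_significant_fraction_calibrated(self):
        p = make_traits(354, 95, seed=25)
        t = make_traits(354, 95, seed=26)
        tab, avg = network.gene_correlation_significance(p, t, n_perm=1000, seed=27)
        frac = tab["sig05"].mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / 354)
        assert abs(frac - 0.05) < half
        # two-sided null cutoffs at n=95 sit near the Student critical values
        t975 = stats.t.ppf(0.975, 93)
        assert avg["avg_cutoff05"] == pytest.approx(t975 / np.sqrt(t975**2 + 93), abs=0.02)

    def test_mismatched_gene_sets_listed(self):
        p = make_traits(3, 10, seed=28)
        t = make_traits(4, 10, seed=29)
        with pytest.raises(ValueError, match="g3"):
            network.gene_correlation_significance(p, t)


class TestSlidingWindowCorrelation:
    def test_single_bin_when_abundances_equal_spread(self):
        rng = np.random.default_rng(30)
        t = np.full(50, 10.0) * np.exp(rng.normal(0, 0.01, 50))
        p = t * np.exp(rng.normal(0, 0.1, 50))
        bins, mean_r, global_r = network.sliding_window_correlation(t, p)
        assert len(bins) == 1
        assert mean_r == pytest.approx(global_r)

    def test_abundance_driven_correlation_vanishes_within_bins(self):
        # genes span 1000-fold abundance; within any 3.5-fold window the
        # protein is independent noise, so binned r must fall below global r
        rng = np.random.default_rng(31)
        t = np.exp(rng.uniform(0, np.log(1000), 400))
        p = t * np.exp(rng.normal(0, 1.0, 400))
        bins, mean_r, global_r = network.sliding_window_correlation(t, p)
        assert len(bins) >= 3
        assert mean_r < global_r

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(ValueError):
            network.sliding_window_correlation(np.array([1.0, -2.0, 3.0]), np.ones(3))
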