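import numpy as np
import pytest
from scipy.special import expit

from tsskit.du import (
    DuDesign,
    bh_adjust,
    filter_genes,
    fit_du_bulk,
    fit_du_cell,
    ideas_modified_du,
    wilcoxon_du,
)


@pytest.fixture
def design10():
    return DuDesign({f"s{i}": 1 if i < 5 else 2 for i in range(10)})


@pytest.fixture
def samples10():
    return [f"s{i}" for i in range(10)]


class TestGlmmBulk:
    def test_symmetric_data_has_null_effect(self, design10, samples10):
        r = fit_du_bulk(np.full(10, 50.0), np.full(10, 100.0),
                        samples10, design10)
        assert abs(r.beta[0]) < 1e-3
        assert r.p_value > 0.5
        assert r.lrt_stat >= 0

    def test_large_effect_is_detected(self, design10, samples10, rng):
        x = np.r_[rng.binomial(100, 0.1, 5), rng.binomial(100, 0.9, 5)]
        r = fit_du_bulk(x.astype(float), np.full(10, 100.0),
                        samples10, design10)
        assert r.p_value < 1e-6

    def test_extreme_separation_small_j_stays_finite(self):
        design = DuDesign({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
        r = fit_du_bulk([0.0, 0.0, 50.0, 50.0], [50.0] * 4,
                        ["a1", "a2", "b1", "b2"], design)
        assert np.isfinite(r.p_value) and r.converged

    def test_x_exceeding_y_rejected(self, design10, samples10):
        with pytest.raises(ValueError):
            fit_du_bulk([10.0] * 10, [5.0] * 10, samples10, design10)

    def test_single_condition_rejected(self, samples10):
        design = DuDesign({s: 1 for s in samples10})
        with pytest.raises(ValueError):
            fit_du_bulk([5.0] * 10, [10.0] * 10, samples10, design)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_sigma_zero_reproduces_plain_binomial_glm(self, design10,
                                                      samples10, seed):
        """With the variance fixed at 0 the model is an ordinary GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        y = rng.integers(50, 200, 10).astype(float)
        x = rng.binomial(y.astype(int), rng.uniform(0.2, 0.8)).astype(float)
        r = fit_du_bulk(x, y, samples10, design10, fixed_sigma2=0.0)
        Z = np.column_stack([np.ones(10), np.r_[np.zeros(5), np.ones(5)]])
        glm = sm.GLM(np.column_stack([x, y - x]), Z,
                     family=sm.families.Binomial()).fit()
        assert r.beta0 == pytest.approx(glm.params[0], rel=1e-4)
        assert r.beta[0] == pytest.approx(glm.params[1], rel=1e-4, abs=1e-6)

    def test_null_rejection_rate_calibrated(self):
        """Monte-Carlo: at 10 samples per group the nominal 0.05 level holds
        within sampling error (the chi-square LRT is asymptotic in the number
        of samples, so very small J is expectedly anti-conservative)."""
        rng = np.random.default_rng(123)
        design = DuDesign({f"s{i}": 1 if i < 10 else 2 for i in range(20)})
        samples = [f"s{i}" for i in range(20)]
        n = 400
        rej = 0
        for _ in range(n):
            phi = rng.normal(0, 0.3, 20)
            theta = expit(-0.5 + phi)
            y = rng.poisson(150, 20) + 1
            x = rng.binomial(y, theta)
            p = fit_du_bulk(x.astype(float), y.astype(float),
                            samples, design).p_value
            rej += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n)
        assert rej / n <= 0.05 + 3 * se


class TestCellBulkEquivalence:
    def test_aggregation_identity(self, design10, samples10, rng):
        """Cells sharing theta_j aggregate: identical estimates and p."""
        cells_per_sample = 30
        cell_sample = np.repeat(samples10, cells_per_sample)
        y = rng.poisson(5, 300).astype(float)
        theta = np.repeat(expit(rng.normal(-0.5, 0.4, 10)), cells_per_sample)
        x = rng.binomial(y.astype(int), theta).astype(float)
        rc = fit_du_cell(x, y, cell_sample, design10)
        keep = y > 0
        xb = [x[keep][cell_sample[keep] == s].sum() for s in samples10]
        yb = [y[keep][cell_sample[keep] == s].sum() for s in samples10]
        rb = fit_du_bulk(xb, yb, samples10, design10)
        assert rc.p_value == pytest.approx(rb.p_value, abs=1e-12)
        assert rc.beta[0] == pytest.approx(rb.beta[0], abs=1e-9)
        # cell-level loglik differs only by the combinatorial constant
        assert (rc.loglik_full - rc.loglik_null) == pytest.approx(
            rb.loglik_full - rb.loglik_null, abs=1e-6
        )

    def test_zero_count_cells_are_ignored(self, design10, samples10, rng):
        cell_sample = np.repeat(samples10, 10)
        y = rng.poisson(5, 100).astype(float) + 1
        x = rng.binomial(y.astype(int), 0.4).astype(float)
        r1 = fit_du_cell(x, y, cell_sample, design10)
        x2 = np.r_[x, [0.0] * 10]
        y2 = np.r_[y, [0.0] * 10]
        cs2 = np.r_[cell_sample, [samples10[0]] * 10]
        r2 = fit_du_cell(x2, y2, cs2, design10)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


class TestBhAdjust:
    def _brute_force(self, p):
        """Textbook step-up: p(i) * m / i, cumulative minimum from the top."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.03], [0.03]),
            ([0.5, 1.0], [1.0, 1.0]),
        ],
    )
    def test_known_vectors(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), self._brute_force(p))

    def test_missing_values_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.02])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        assert np.allclose(adj[[0, 2]], self._brute_force([0.01, 0.02]))


class TestWilcoxon:
    def test_identical_usage_gives_p_one(self, design10, samples10):
        x = np.full(100, 5.0)
        y = np.full(100, 10.0)
        cs = np.repeat(samples10, 10)
        assert wilcoxon_du(x, y, cs, design10, level="cell") == 1.0

    def test_bulk_complete_separation_exact_minimum(self, design10, samples10):
        # 5 vs 5 samples, non-overlapping usages: two-sided exact p = 2/252
        cs = np.array(samples10)
        x = np.array([10, 11, 12, 13, 14, 80, 81, 82, 83, 84], float)
        y = np.full(10, 100.0)
        p = wilcoxon_du(x, y, cs, design10, level="bulk")
        assert p == pytest.approx(2 / 252)

    def test_cell_level_matches_exact_permutation_oracle(self, rng):
        """4 vs 4 untied cells: scipy's exact rank-sum equals enumeration."""
        from itertools import combinations

        from scipy.stats import mannwhitneyu

        design = DuDesign({"a": 1, "b": 2})
        usage = rng.permutation([0.11, 0.23, 0.35, 0.47, 0.59, 0.61, 0.73, 0.85])
        x = usage * 100
        y = np.full(8, 100.0)
        cs = np.array(["a"] * 4 + ["b"] * 4)
        p = wilcoxon_du(x, y, cs, design, level="cell")
        # enumerate all label assignments of 4 cells to group a
        obs = mannwhitneyu(usage[:4], usage[4:],
                           alternative="two-sided").statistic
        n_extreme = 0
        half = 4 * 4 / 2
        for idx in combinations(range(8), 4):
            grp = usage[list(idx)]
            rest = np.delete(usage, list(idx))
            u = mannwhitneyu(grp, rest, alternative="two-sided").statistic
            if abs(u - half) >= abs(obs - half) - 1e-12:
                n_extreme += 1
        assert p == pytest.approx(n_extreme / 70)

    def test_empty_group_gives_missing(self, design10, samples10):
        x = np.full(10, 3.0)
        y = np.r_[np.full(5, 10.0), np.zeros(5)]
        cs = np.array(samples10)
        assert np.isnan(wilcoxon_du(x, y, cs, design10, level="bulk"))


class TestIdeasModified:
    def test_identical_distributions_p_near_one(self, design10):
        usages = {f"s{i}": np.full(20, 0.5) for i in range(10)}
        p = ideas_modified_du(usages, design10, n_perm=200,
                              rng=np.random.default_rng(0))
        assert p == 1.0

    def test_wasserstein_point_masses(self):
        from scipy.stats import wasserstein_distance

        assert wasserstein_distance([0.2], [0.7]) == pytest.approx(0.5)

    def test_large_shift_detected(self):
        # 5 samples per group: 126 distinct label splits, so the permutation
        # p-value can resolve below 0.05 (3 per group cannot: only 10 splits)
        rng = np.random.default_rng(5)
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        design = DuDesign({**{s: 1 for s in a}, **{s: 2 for s in b}})
        usages = {s: rng.beta(2, 8, 100) for s in a}    # mean 0.2
        usages.update({s: rng.beta(8, 2, 100) for s in b})  # mean 0.8
        p = ideas_modified_du(usages, design, n_perm=2000,
                              rng=np.random.default_rng(6))
        assert p < 0.05

    def test_too_few_samples_missing(self):
        design = DuDesign({"a": 1, "b": 2})
        p = ideas_modified_du({"a": [0.5], "b": [0.6]}, design, n_perm=100)
        assert np.isnan(p)


class TestFilterGenes:
    def _matrix(self, sample_id, detections, n_cells=20):
        """One cluster pair per gene; gene g detected in detections[g] cells."""
        import scipy.sparse as sp

        from tsskit.genomic import GenomicInterval
        from tsskit.quantification import CellClusterMatrix

        genes = list(detections)
        rows = []
        gene_of_cluster = {}
        data = np.zeros((2 * len(genes), n_cells))
        for gi, g in enumerate(genes):
            gene_of_cluster[2 * gi] = g
            gene_of_cluster[2 * gi + 1] = g
            data[2 * gi, : detections[g]] = 1
        clusters = [
            GenomicInterval("chr1", 100 * (i + 1), 100 * (i + 1) + 10, "+")
            for i in range(2 * len(genes))
        ]
        return CellClusterMatrix(
            sample_id, clusters, [f"bc{i}" for i in range(n_cells)],
            sp.csr_matrix(data), gene_of_cluster,
        )

    def test_detection_threshold_is_inclusive(self):
        m1 = self._matrix("s1", {"G1": 2, "G2": 1})  # 10% and 5% of 20 cells
        m2 = self._matrix("s2", {"G1": 3, "G2": 4})
        kept = filter_genes([m1, m2], min_detection_fraction=0.1)
        assert kept == {"G1"}

    def test_single_cluster_genes_dropped(self):
        import scipy.sparse as sp

        from tsskit.genomic import GenomicInterval
        from tsskit.quantification import CellClusterMatrix

        m = CellClusterMatrix(
            "s1", [GenomicInterval("chr1", 100, 110, "+")], ["bc0", "bc1"],
            sp.csr_matrix(np.array([[1.0, 1.0]])), {0: "G1"},
        )
        assert filter_genes([m], min_detection_fraction=0.1) == set()
        assert filter_genes([m], min_detection_fraction=0.1,
                            require_multicluster=False) == {"G1"}
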