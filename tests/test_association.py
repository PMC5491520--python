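"""Association engine: score statistics against brute-force recomputation,
permutation oracles, and contingency statistics against enumeration."""

import numpy as np
import pytest
from scipy.stats import chi2, hypergeom

from rareburden.association import (ContingencyTable, DEFAULT_RHO_GRID,
                                    RareVariantAssociation,
                                    allele_count_table, chisq_test,
                                    fisher_exact_test, fit_null_model,
                                    odds_ratio, score_statistic, skato_test,
                                    variant_weights)
from rareburden.errors import FittingError


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

class TestNullModel:
    def test_intercept_only_is_case_fraction(self):
        y = np.r_[np.ones(2548), np.zeros(1117)]
        null = fit_null_model(y)
        assert np.allclose(null.mu, 2548 / 3665)
        assert null.residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_phenotype_raises(self):
        with pytest.raises(FittingError):
            fit_null_model(np.ones(50))
        with pytest.raises(FittingError):
            fit_null_model(np.r_[np.zeros(10), 2 * np.ones(5)])

    def test_uncorrelated_covariate_keeps_mu_near_case_fraction(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 400).astype(float)
        x = np.tile([0.0, 1.0], 200)  # balanced, independent of y
        null = fit_null_model(y, x)
        assert null.mu.mean() == pytest.approx(y.mean(), abs=1e-8)
        assert np.all(np.abs(null.mu - y.mean()) < 0.1)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

class TestWeights:
    def test_flat_weights(self):
        assert np.allclose(variant_weights([0.01, 0.2, 0.5], (1, 1)), 1.0)

    def test_closed_form_beta_1_25(self):
        # Beta(1,25) density at f: 25 (1-f)^24
        assert variant_weights([0.01])[0] == pytest.approx(25 * 0.99**24,
                                                           rel=1e-12)

    def test_rarer_is_heavier(self):
        w = variant_weights([0.001, 0.01])
        assert w[0] > w[1]

    def test_zero_maf_rejected(self):
        with pytest.raises(ValueError):
            variant_weights([0.0, 0.01])


# ---------------------------------------------------------------------------
# score statistic
# ---------------------------------------------------------------------------

def _brute_force_q(G, y, w, rho):
    mu = y.mean()
    S = np.array([np.sum(G[:, j] * (y - mu)) for j in range(G.shape[1])])
    return (1 - rho) * np.sum((w * S) ** 2) + rho * np.sum(w * S) ** 2


class TestScoreStatistic:
    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(7)
        G = rng.binomial(2, 0.15, size=(20, 3)).astype(float)
        y = np.r_[np.ones(8), np.zeros(12)]
        null = fit_null_model(y)
        w = np.array([2.0, 1.0, 0.5])
        for rho in (0.0, 0.3, 1.0):
            res = score_statistic(G, null, w, rho)
            assert res.statistic == pytest.approx(_brute_force_q(G, y, w, rho),
                                                  rel=1e-10)

    def test_single_variant_invariant_in_rho(self):
        rng = np.random.default_rng(8)
        G = rng.binomial(2, 0.2, size=(40, 1)).astype(float)
        y = np.r_[np.ones(20), np.zeros(20)]
        null = fit_null_model(y)
        stats = [score_statistic(G, null, np.array([1.5]), r).statistic
                 for r in (0.0, 0.25, 1.0)]
        assert np.allclose(stats, stats[0])

    def test_burden_rho1_is_collapsing_score(self):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.1, size=(50, 4)).astype(float)
        y = np.r_[np.ones(25), np.zeros(25)]
        null = fit_null_model(y)
        w = np.full(4, 1.0)
        res = score_statistic(G, null, w, 1.0)
        burden = G @ w
        assert res.statistic == pytest.approx(
            np.sum(burden * (y - y.mean())) ** 2, rel=1e-10)
        # one eigenvalue: exact scaled chi2_1
        assert res.lambdas.size == 1
        assert res.p_value == pytest.approx(
            chi2.sf(res.statistic / res.lambdas[0], 1), rel=1e-6)

    def test_monomorphic_gene_flags_no_test(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        null = fit_null_model(y)
        res = score_statistic(np.zeros((20, 3)), null, np.ones(3), 0.5)
        assert res.no_test and np.isnan(res.p_value)


# ---------------------------------------------------------------------------
# SKAT-O
# ---------------------------------------------------------------------------

class TestSkatO:
    def test_single_variant_degenerates(self, signal_fixture):
        y, G = signal_fixture
        null = fit_null_model(y)
        res = skato_test(G[:, :1], null, variant_weights(
            [max(G[:, 0].mean() / 2, 1e-3)]))
        ps = list(res.p_by_rho.values())
        assert np.allclose(ps, ps[0])
        assert res.p_value == pytest.approx(ps[0])

    def test_combined_p_pays_for_selection(self, signal_fixture):
        y, G = signal_fixture
        model = RareVariantAssociation(y, G)
        res = model.fit("skato")
        assert res.p_value >= min(res.p_by_rho.values())
        assert res.p_value <= min(res.p_by_rho.values()) * len(DEFAULT_RHO_GRID)

    def test_rho_grid_requires_endpoints(self, signal_fixture):
        y, G = signal_fixture
        null = fit_null_model(y)
        with pytest.raises(ValueError):
            skato_test(G, null, np.ones(G.shape[1]), rho_grid=(0.0, 0.5))

    def test_p_rho_continuity(self, signal_fixture):
        """p_rho varies continuously in rho on fixed data."""
        y, G = signal_fixture
        null = fit_null_model(y)
        maf = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
        w = variant_weights(np.maximum(maf, 1e-4))
        rhos = np.linspace(0.0, 1.0, 21)
        ps = [score_statistic(G, null, w, r).p_value for r in rhos]
        assert max(abs(np.diff(ps))) < 0.08


_N_PERM = 100_000


@pytest.fixture(scope="module")
def perm_stats(signal_fixture):
    """1e5 permutation score vectors on the 100-sample fixture (case labels
    permuted; scores recomputed in vectorised form from the definition)."""
    y, G = signal_fixture
    rng = np.random.default_rng(2024)
    n = y.size
    mu = y.mean()
    maf = np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2)
    w = variant_weights(np.maximum(maf, 1e-4))
    Gt = G.T
    colsum = G.sum(axis=0)
    ncase = int(y.sum())
    S_obs = Gt @ y - mu * colsum
    S_all = np.empty((G.shape[1], _N_PERM))
    for start in range(0, _N_PERM, 10_000):
        ii = np.argsort(rng.random((10_000, n)), axis=1)[:, :ncase]
        Yp = np.zeros((n, 10_000))
        Yp[ii.T, np.arange(10_000)[None, :]] = 1.0
        S_all[:, start:start + 10_000] = Gt @ Yp - mu * colsum[:, None]
    return y, G, w, S_obs, S_all


class TestPermutationOracle:
    """Asymptotic p-values vs the permutation oracle."""

    B = _N_PERM

    @staticmethod
    def _q(S, w, rho):
        wS = w[:, None] * S if S.ndim == 2 else w * S
        return (1 - rho) * (wS**2).sum(axis=0) + rho * wS.sum(axis=0) ** 2

    @pytest.mark.parametrize("method,rho", [("burden", 1.0), ("skat", 0.0)])
    def test_burden_and_skat_match_permutation(self, perm_stats, method, rho):
        y, G, w, S_obs, S_all = perm_stats
        q_obs = self._q(S_obs, w, rho)
        p_perm = (self._q(S_all, w, rho) >= q_obs - 1e-12).mean()
        p_asym = RareVariantAssociation(y, G).fit(method).p_value
        se = np.sqrt(p_perm * (1 - p_perm) / self.B)
        assert abs(p_asym - p_perm) < 0.02 + 3 * se

    def test_skato_matches_rank_based_min_p_permutation(self, perm_stats):
        y, G, w, S_obs, S_all = perm_stats
        grid = np.array(DEFAULT_RHO_GRID)
        # empirical per-rho p of every permutation via ranks, then min over rho
        T_perm = np.ones(self.B)
        T_obs = 1.0
        for rho in grid:
            qs = self._q(S_all, w, rho)
            q_obs = self._q(S_obs, w, rho)
            order = np.argsort(qs)
            ranks = np.empty(self.B)
            ranks[order] = np.arange(self.B)
            p_each = 1.0 - ranks / self.B
            T_perm = np.minimum(T_perm, p_each)
            T_obs = min(T_obs, (qs >= q_obs - 1e-12).mean())
        p_perm = (T_perm <= T_obs).mean()
        p_asym = RareVariantAssociation(y, G).fit("skato").p_value
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-12) / self.B)
        assert abs(p_asym - p_perm) < 0.03 + 3 * se


# ---------------------------------------------------------------------------
# missing-data handling
# ---------------------------------------------------------------------------

def test_mean_imputation_preserves_score_expectation():
    """Under MCAR masking, mean-dosage imputation leaves the expected
    per-variant score unchanged."""
    rng = np.random.default_rng(15)
    n = 400
    diffs = []
    for _ in range(200):
        G = rng.binomial(2, 0.1, size=(n, 1)).astype(float)
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        rng.shuffle(y)
        S_full = float(G[:, 0] @ (y - y.mean()))
        Gm = G.copy()
        mask = rng.random(n) < 0.2
        Gm[mask, 0] = np.nan
        model = RareVariantAssociation(y, Gm)
        S_imp = float(model.genotypes[:, 0] @ (y - y.mean()))
        diffs.append(S_imp - S_full)
    assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.05


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------

class TestAlleleCounts:
    def test_sums_dosages_by_status(self):
        G = np.array([[1, 0], [2, 1], [0, 0], [0, 1]], dtype=float)
        status = np.array([1, 1, 0, 0])
        t = allele_count_table(G, status)
        assert (t.a, t.c) == (4.0, 1.0)
        assert t.a + t.b == 2 * 2  # 2 cases x 2 alleles (per-sample margins)

    def test_all_reference_matrix(self):
        t = allele_count_table(np.zeros((6, 3)), [1, 1, 1, 0, 0, 0])
        assert t.a == 0 and t.c == 0

    def test_per_variant_denominator_counts_calls(self):
        G = np.array([[1.0, np.nan], [0.0, 1.0]])
        t = allele_count_table(G, [1, 0], per_variant_denominator=True)
        assert t.a + t.b == 2 * 1  # one non-missing case call
        assert t.c + t.d == 2 * 2

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            allele_count_table(np.ones((2, 2)), [1, 0], variant_subset=[])


class TestOddsRatio:
    def test_zero_control_cell_gnas_novel_row(self):
        # 15 case alleles vs 0 control alleles in 2548 cases / 1117 controls
        res = odds_ratio(ContingencyTable(15, 5081, 0, 2234))
        assert np.isinf(res.oddsratio)
        assert res.adjusted
        assert res.adjusted_oddsratio == pytest.approx(13.6317, abs=5e-4)

    def test_symmetric_table_is_unity(self):
        res = odds_ratio(ContingencyTable(1, 1, 1, 1))
        assert res.oddsratio == pytest.approx(1.0)
        assert not res.adjusted

    def test_cross_product(self):
        res = odds_ratio(ContingencyTable(10, 90, 5, 95))
        assert res.oddsratio == pytest.approx(10 * 95 / (90 * 5), rel=1e-12)

    def test_ci_contains_point_estimate(self):
        res = odds_ratio(ContingencyTable(8, 100, 3, 120))
        assert res.ci_low < res.adjusted_oddsratio < res.ci_high

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(ContingencyTable(0, 0, 0, 0))


class TestFisherExact:
    @staticmethod
    def _enumerated_two_sided(a, b, c, d):
        """Sum of hypergeometric probabilities <= that of the observed
        table, over all tables with the same margins."""
        n1, n2, m1 = a + b, c + d, a + c
        N = n1 + n2
        p_obs = hypergeom.pmf(a, N, m1, n1)
        total = 0.0
        for x in range(max(0, m1 - n2), min(m1, n1) + 1):
            px = hypergeom.pmf(x, N, m1, n1)
            if px <= p_obs * (1 + 1e-9):
                total += px
        return min(total, 1.0)

    def test_tiny_table_closed_form(self):
        # (3,0,0,3): two extreme tables of 20 equally likely arrangements
        assert fisher_exact_test(ContingencyTable(3, 0, 0, 3)) == \
            pytest.approx(0.1, rel=1e-9)

    def test_proportional_rows_give_one(self):
        assert fisher_exact_test(ContingencyTable(5, 10, 10, 20)) == \
            pytest.approx(1.0)

    def test_matches_enumeration_all_small_margins(self):
        """Every 2x2 table with all margins <= 30 (on a coarse lattice)
        matches the exhaustive hypergeometric enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            expected = self._enumerated_two_sided(int(a), int(b), int(c), int(d))
            got = fisher_exact_test(ContingencyTable(int(a), int(b),
                                                     int(c), int(d)))
            assert got == pytest.approx(expected, rel=1e-6), (a, b, c, d)


class TestChisq:
    def test_balanced_table_p_one(self):
        assert chisq_test(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_statistic_matches_hand_arithmetic(self):
        a, b, c, d = 12.0, 28.0, 5.0, 35.0
        n = a + b + c + d
        expected_cells = [(a + b) * (a + c) / n, (a + b) * (b + d) / n,
                          (c + d) * (a + c) / n, (c + d) * (b + d) / n]
        stat = sum((o - e) ** 2 / e
                   for o, e in zip((a, b, c, d), expected_cells))
        assert chisq_test(ContingencyTable(a, b, c, d)) == \
            pytest.approx(chi2.sf(stat, 1), rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_test(ContingencyTable(0, 0, 5, 5))

    def test_agrees_with_fisher_on_large_balanced_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a, b, c, d = rng.integers(20, 80, size=4)
            p_chi = chisq_test(ContingencyTable(int(a), int(b), int(c), int(d)))
            p_f = fisher_exact_test(ContingencyTable(int(a), int(b),
                                                     int(c), int(d)))
            if min(p_chi, p_f) > 0.01:
                assert 0.5 < p_chi / p_f < 2.0
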