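import math

import numpy as np
import pytest
from scipy.stats import chi2

from dytburden.burden import (
    BurdenConfig,
    BurdenResult,
    NullModel,
    beta_maf_weights,
    fit_null,
    impute_mean,
    run_burden_scan,
    score_statistic,
    significance_flags,
    skat_o,
    skat_o_permutation,
)
from dytburden.exceptions import ConvergenceError, NoTestError, ValidationError
from dytburden.io import ExonicFunction as EF
from dytburden.panel import GenePanel, Inheritance, PanelGene

from conftest import make_annotation, make_cohort


class TestFitNull:
    def test_intercept_only_balanced(self):
        y = np.array([0, 1] * 25)
        null = fit_null(y)
        assert np.allclose(null.mu, 0.5)
        assert abs(null.residuals.sum()) < 1e-6

    def test_intercept_only_thirty_percent_cases(self):
        y = np.array([1] * 30 + [0] * 70)
        assert np.allclose(fit_null(y).mu, 0.3)

    def test_perfect_predictor_raises_separation_error(self):
        y = np.array([0] * 20 + [1] * 20, dtype=float)
        X = y.copy()[:, None]
        with pytest.raises(ConvergenceError):
            fit_null(y, X)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_null(np.ones(10))

    def test_missing_covariates_rejected(self):
        y = np.array([0, 1] * 10, dtype=float)
        X = np.ones((20, 1))
        X[3, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_null(y, X)


def _null_with_residuals():
    """Intercept-only null with mu = 0.5: residuals are +/-0.5."""
    y = np.array([1.0] * 4 + [0.0] * 4)
    return fit_null(y)


class TestScoreStatistic:
    def test_single_variant_identical_across_rho(self):
        null = _null_with_residuals()
        G = np.arange(8.0)[:, None]
        qs = {rho: score_statistic(G, null, [0.7], rho) for rho in (0.0, 0.3, 1.0)}
        assert len({round(v, 12) for v in qs.values()}) == 1

    def test_hand_computed_two_variant_case(self):
        # G chosen so the per-variant scores are S = (2, -2); with equal
        # weights w the kernel statistic is 8 w^2 at rho=0 and 0 at rho=1
        null = _null_with_residuals()
        G = np.zeros((8, 2))
        G[:4, 0] = 1.0  # variant 1 carried by cases only: S1 = 4 * 0.5
        G[4:, 1] = 1.0  # variant 2 carried by controls only: S2 = -2
        w = 0.7
        assert score_statistic(G, null, [w, w], 0.0) == pytest.approx(8 * w**2)
        assert score_statistic(G, null, [w, w], 1.0) == pytest.approx(0.0)

    def test_rho_one_is_squared_weighted_burden(self):
        rng = np.random.default_rng(3)
        null = _null_with_residuals()
        G = rng.integers(0, 3, size=(8, 4)).astype(float)
        w = rng.uniform(0.5, 2.0, 4)
        expected = float((w @ (G.T @ null.residuals)) ** 2)
        assert score_statistic(G, null, w, 1.0) == pytest.approx(expected)

    def test_zero_variants_is_no_test(self):
        with pytest.raises(NoTestError):
            score_statistic(np.empty((8, 0)), _null_with_residuals(), [], 0.0)

    def test_mean_imputation_fills_column_mean(self):
        G = np.array([[0.0], [2.0], [np.nan]])
        assert impute_mean(G)[2, 0] == pytest.approx(1.0)


def _sim_cohort(rng, n=200, m=6, maf_lo=0.05, maf_hi=0.2):
    maf = rng.uniform(maf_lo, maf_hi, m)
    G = rng.binomial(2, maf, size=(n, m)).astype(float)
    y = rng.binomial(1, 0.5, n).astype(float)
    return G, y


class TestSkatO:
    def test_grid_endpoints_reproduce_pure_skat_and_burden(self):
        rng = np.random.default_rng(11)
        G, y = _sim_cohort(rng)
        null = fit_null(y)
        full = skat_o(G, null)
        assert skat_o(G, null, rho_grid=(0.0,)).p_value == pytest.approx(
            full.p_per_rho[0.0]
        )
        assert skat_o(G, null, rho_grid=(1.0,)).p_value == pytest.approx(
            full.p_per_rho[1.0]
        )

    def test_single_variant_equals_score_test(self):
        rng = np.random.default_rng(12)
        G, y = _sim_cohort(rng, m=1)
        null = fit_null(y)
        res = skat_o(G, null)
        g = G[:, 0]
        v = null.variance
        g_c = g - g @ v / v.sum()  # intercept-only projection
        score = float(g @ null.residuals) ** 2 / float(g_c @ (v * g_c))
        assert res.p_value == pytest.approx(chi2.sf(score, 1))

    def test_combined_p_bounded_by_minimum_and_bonferroni(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            G, y = _sim_cohort(rng, n=150, m=int(rng.integers(2, 9)))
            null = fit_null(y)
            res = skat_o(G, null)
            t = min(res.p_per_rho.values())
            assert t <= res.p_value <= min(1.0, t * len(res.p_per_rho)) + 1e-12

    @pytest.mark.parametrize("beta", [0.0, 1.0])
    def test_agrees_with_permutation_oracle(self, beta):
        rng = np.random.default_rng(21)
        n, m = 180, 8
        maf = rng.uniform(0.05, 0.2, m)
        G = rng.binomial(2, maf, size=(n, m)).astype(float)
        eta = -0.2 + beta * (G[:, : m // 2].sum(axis=1) > 0)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        null = fit_null(y)
        n_perm = 4000
        p_perm = skat_o_permutation(
            G, null, n_perm=n_perm, rng=np.random.default_rng(99)
        )
        se = math.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert skat_o(G, null).p_value == pytest.approx(p_perm, abs=3 * se)

    def test_all_zero_genotypes_is_no_test(self):
        null = _null_with_residuals()
        with pytest.raises(NoTestError):
            skat_o(np.zeros((8, 2)), null)

    def test_power_nondecreasing_in_effect_size(self):
        # common random numbers across a 3-point effect grid
        rates = []
        for beta in (0.0, 1.25, 2.5):
            hits = 0
            for rep in range(40):
                rng = np.random.default_rng(500 + rep)
                n, m = 250, 5
                maf = rng.uniform(0.02, 0.08, m)
                G = rng.binomial(2, maf, size=(n, m)).astype(float)
                carrier = (G >= 1).any(axis=1)
                eta = -0.2 + beta * carrier
                y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
                if len(np.unique(y)) < 2:
                    continue
                hits += skat_o(G, fit_null(y)).p_value < 0.05
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 30  # strong effect detected most of the time


class TestSignificanceFlags:
    def _res(self, p):
        return BurdenResult(
            gene="TH", cohort="Cohort 1", patient_subgroup="sEOPD",
            variant_subgroup="LoF", maf_threshold=0.001, n_variants=1,
            case_carriers=1, control_carriers=0, p_value=p, tested=p is not None,
        )

    def test_bonferroni_threshold_over_47_genes(self):
        assert round(0.05 / 47, 3) == 0.001
        (r,) = significance_flags([self._res(0.0009)], 47)
        assert r.significant and not r.suggestive

    def test_suggestive_band(self):
        (r,) = significance_flags([self._res(0.0022)], 47)
        assert r.suggestive and not r.significant

    def test_boundary_is_strict(self):
        (r,) = significance_flags([self._res(0.05)], 47)
        assert not r.suggestive and not r.significant

    def test_untested_cells_carry_no_flags(self):
        (r,) = significance_flags([self._res(None)], 47)
        assert not r.suggestive and not r.significant


def _scan_cohort(rng, n_cases=60, n_controls=60, m=8, gene="TH"):
    anns = [
        make_annotation(
            vid=f"chr1:{100 + j}:A:G", gene=gene, func=EF.MISSENSE,
            reve=0.9 if j % 2 else 0.3, maf=(0.002, None),
        )
        for j in range(m)
    ]
    dos = rng.binomial(2, 0.08, size=(n_cases + n_controls, m)).astype(float)
    return make_cohort(dos, anns, n_cases=n_cases)


class TestRunBurdenScan:
    PANEL = GenePanel(genes=[PanelGene("TH", Inheritance.AR), PanelGene("ANO3", Inheritance.AD)])

    def test_empty_gene_cells_reported_untested(self):
        rng = np.random.default_rng(31)
        cohort = _scan_cohort(rng)
        results = run_burden_scan(cohort, self.PANEL)
        ano3 = [r for r in results if r.gene == "ANO3"]
        assert ano3 and all(not r.tested and r.p_value is None for r in ano3)
        missense = {
            r.maf_threshold: r
            for r in results
            if r.gene == "TH" and r.variant_subgroup == "missense"
        }
        assert missense[0.01].tested  # variants at MAF 0.002 populate this cell
        assert not missense[0.001].tested  # but fail the stricter threshold

    def test_carrier_counts_invariant_to_variant_order_and_extras(self):
        rng = np.random.default_rng(32)
        cohort = _scan_cohort(rng)
        base = {
            (r.variant_subgroup, r.maf_threshold): (r.case_carriers, r.control_carriers)
            for r in run_burden_scan(cohort, self.PANEL)
            if r.tested
        }
        perm = rng.permutation(cohort.n_variants)
        shuffled = make_cohort(
            cohort.dosages[:, perm],
            [cohort.annotations[cohort.variants[j].id] for j in perm],
            n_cases=60,
        )
        after = {
            (r.variant_subgroup, r.maf_threshold): (r.case_carriers, r.control_carriers)
            for r in run_burden_scan(shuffled, self.PANEL)
            if r.tested
        }
        assert base == after

    def test_mixed_case_subgroups_rejected(self):
        from dytburden.io import Status, Subgroup

        rng = np.random.default_rng(33)
        cohort = _scan_cohort(rng, n_cases=4, n_controls=4)
        cohort.samples[0].subgroup = Subgroup.SLOPD
        with pytest.raises(ValidationError, match="subgroup"):
            run_burden_scan(cohort, self.PANEL)

    def test_samples_with_missing_covariates_are_dropped(self):
        rng = np.random.default_rng(34)
        cohort = _scan_cohort(rng)
        cohort.samples[0].age = None
        results = run_burden_scan(cohort, self.PANEL)
        tested = [r for r in results if r.tested]
        assert tested  # scan still runs on the remaining samples

    def test_beta_weights_favor_rare_variants(self):
        w = beta_maf_weights(np.array([0.0, 0.001, 0.01, 0.1]))
        assert np.all(np.diff(w) < 0) and w[0] == pytest.approx(25.0)
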