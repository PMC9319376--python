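"""Univariable MR estimators: arithmetic cases, oracles, invariances."""

import numpy as np
import pytest
import statsmodels.api as sm

from netmr.errors import InsufficientInstrumentsError, ValidationError
from netmr.simulate import SimulationParams, simulate_system
from netmr.uvmr import (egger, ivw, mr_presso, wald_ratio, weighted_median)


def _data(rng, j=30, theta=0.4, sey=0.02, sex=0.001, alpha=0.0):
    bx_true = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
    bx = rng.normal(bx_true, sex)
    by = rng.normal(alpha + theta * bx_true, sey)
    return bx, np.full(j, sex), by, np.full(j, sey)


class TestWald:
    @pytest.mark.parametrize("bx,by,sey,beta,se", [
        (0.1, 0.2, 0.01, 2.0, 0.1),
        (0.2, 0.0, 0.01, 0.0, 0.05),
        (-0.1, 0.05, 0.01, -0.5, 0.1),
    ])
    def test_arithmetic(self, bx, by, sey, beta, se):
        est = wald_ratio(bx, by, 0.01, sey)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValidationError, match="rs9"):
            wald_ratio(0.0, 0.1, 0.01, 0.01, snp="rs9")


class TestIVW:
    def test_exact_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.3 * bx
        est, rep = ivw((bx, bx * 0 + 0.01, by, bx * 0 + 0.02))
        assert est.beta == pytest.approx(0.3)
        assert rep.cochran_q == pytest.approx(0.0, abs=1e-20)

    def test_single_snp_reduces_to_wald(self):
        est, _ = ivw((np.r_[0.1], np.r_[0.01], np.r_[0.05], np.r_[0.02]))
        wald = wald_ratio(0.1, 0.05, 0.01, 0.02)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_matches_statsmodels_wls(self, rng):
        bx, sex, by, sey = _data(rng)
        est, rep = ivw((bx, sex, by, sey))
        w = 1 / sey ** 2
        fit = sm.WLS(by, bx, weights=w).fit()
        assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
        # statsmodels scales by RSS/(n-1): exactly the multiplicative-RE SE
        assert est.se == pytest.approx(fit.bse[0], rel=1e-10)
        assert rep.cochran_q == pytest.approx(
            float(np.sum(w * fit.resid ** 2)), rel=1e-10)

    def test_sign_flip_invariance(self, rng):
        bx, sex, by, sey = _data(rng)
        est1, _ = ivw((bx, sex, by, sey))
        flip = rng.choice([-1.0, 1.0], len(bx))
        est2, _ = ivw((bx * flip, sex, by * flip, sey))
        assert est2.beta == pytest.approx(est1.beta)
        assert est2.se == pytest.approx(est1.se)

    def test_scaling_equivariance(self, rng):
        bx, sex, by, sey = _data(rng)
        est1, _ = ivw((bx, sex, by, sey))
        est2, _ = ivw((2 * bx, 2 * sex, by, sey))
        assert est2.beta == pytest.approx(est1.beta / 2)

    def test_floored_variance_never_smaller(self, rng):
        bx, sex, by, sey = _data(rng, sey=0.2)
        plain, _ = ivw((bx, sex, by, sey))
        floored, _ = ivw((bx, sex, by, sey), floor_variance=True)
        assert floored.se >= plain.se - 1e-15


class TestEgger:
    def test_exact_fit_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.4 * bx
        slope, intercept = egger((bx, bx * 0 + 0.01, by, bx * 0 + 0.02))
        assert slope.beta == pytest.approx(0.4)
        assert intercept.estimate == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_directional_pleiotropy(self, rng):
        # constant pleiotropic offset on the oriented (bx >= 0) scale
        j = 100
        bx_true = rng.uniform(0.05, 0.3, j)
        bx = rng.normal(bx_true, 0.001)
        by = rng.normal(0.05 + 0.4 * bx_true, 0.005)
        slope, intercept = egger((bx, np.full(j, 0.001), by,
                                  np.full(j, 0.005)))
        assert intercept.estimate == pytest.approx(0.05, abs=0.01)
        assert intercept.pval < 0.05
        assert intercept.directional_pleiotropy

    def test_matches_statsmodels_wls(self, rng):
        bx, sex, by, sey = _data(rng)
        flip = np.where(bx < 0, -1.0, 1.0)
        slope, intercept = egger((bx, sex, by, sey))
        w = 1 / sey ** 2
        x = sm.add_constant(bx * flip)
        fit = sm.WLS(by * flip, x, weights=w).fit()
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert slope.se == pytest.approx(fit.bse[1], rel=1e-10)
        assert intercept.pval == pytest.approx(fit.pvalues[0], rel=1e-8)

    def test_requires_three_snps(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger((np.r_[0.1, 0.2], np.r_[0.01, 0.01],
                   np.r_[0.1, 0.2], np.r_[0.01, 0.01]))


class TestWeightedMedian:
    def test_equal_weights_odd_count(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([1.0, 2.0, 9.0])
        est = weighted_median((bx, bx * 0.001, by, bx * 0 + 1.0),
                              n_boot=100, seed=1)
        assert est.beta == pytest.approx(2.0)

    @pytest.mark.parametrize("j", [3, 5, 7, 9])
    def test_equal_weights_match_plain_median(self, rng, j):
        bx = np.ones(j)
        by = rng.normal(0.5, 0.3, j)
        est = weighted_median((bx, bx * 1e-4, by, np.ones(j)),
                              n_boot=100, seed=2)
        assert est.beta == pytest.approx(float(np.median(by)))

    def test_majority_weight_snp_dominates(self):
        # interior SNP carrying >50% of total weight pins the estimate
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.7, 5.0])
        sey = np.array([1.0, 0.1, 1.0])  # middle ratio has weight 100 vs 1
        est = weighted_median((bx, bx * 1e-4, by, sey), n_boot=100, seed=3)
        assert est.beta == pytest.approx(0.7)

    def test_seed_is_mandatory(self):
        bx = np.ones(3)
        with pytest.raises(ValidationError, match="seed"):
            weighted_median((bx, bx * 0.001, bx, bx), n_boot=100, seed=None)

    def test_more_robust_than_ivw_to_invalid_instruments(self, rng):
        # 30% of instruments get a large pleiotropic offset: the weighted
        # median should track the truth better than IVW, seed after seed
        theta = 0.5
        wins = 0
        n_rep = 60
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            j = 30
            bx_true = r.uniform(0.1, 0.3, j)
            bx = r.normal(bx_true, 0.001)
            offset = np.where(np.arange(j) < 9, 0.08, 0.0)
            by = r.normal(theta * bx_true + offset, 0.01)
            data = (bx, np.full(j, 0.001), by, np.full(j, 0.01))
            wm = weighted_median(data, n_boot=100, seed=rep)
            iv, _ = ivw(data)
            if abs(wm.beta - theta) < abs(iv.beta - theta):
                wins += 1
        assert wins / n_rep > 0.9


class TestPresso:
    def test_degenerate_exact_fit_global_p_one(self):
        bx = np.linspace(0.1, 0.5, 20)
        by = 0.3 * bx
        res = mr_presso((bx, bx * 0 + 1e-6, by, bx * 0 + 0.01),
                        n_sim=1000, seed=4)
        assert res.rss_observed == pytest.approx(0.0, abs=1e-12)
        assert res.global_p == pytest.approx(1.0)
        assert res.outliers == []

    def test_null_calibration(self):
        # homogeneous data: global p roughly uniform across seeds
        pvals = []
        for seed in range(40):
            r = np.random.default_rng(1000 + seed)
            j = 20
            bx = r.uniform(0.1, 0.3, j)
            by = r.normal(0.3 * bx, 0.01)
            res = mr_presso((bx, np.full(j, 1e-6), by, np.full(j, 0.01)),
                            n_sim=1000, seed=seed)
            pvals.append(res.global_p)
        pvals = np.array(pvals)
        assert np.mean(pvals < 0.05) <= 0.15
        assert 0.3 < pvals.mean() < 0.7

    def test_planted_outlier_flagged_and_corrected(self):
        sys = simulate_system(
            SimulationParams(n_exposure_snps=20, n_mediator_snps=0,
                             n_outlier_snps=1), seed=9)
        from netmr.gwas_io import harmonize
        from netmr.instruments import select_candidates
        cand = select_candidates(sys.exposure, 5e-8)
        h = harmonize(sys.exposure, sys.outcome, snps=cand["snp"])
        res = mr_presso(h, n_sim=1000, seed=10)
        assert set(sys.truth.outlier_snps) <= set(res.outliers)
        assert res.global_p < 0.05
        assert res.corrected.n_snps == h.n_snps - len(res.outliers)

    def test_requires_four_snps(self):
        bx = np.ones(3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso((bx, bx * 0.001, bx, bx), n_sim=1000, seed=0)
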