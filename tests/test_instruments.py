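"""Instrument selection, clumping, strength diagnostics, Steiger filter."""

import numpy as np
import pandas as pd
import pytest

from netmr.errors import ValidationError
from netmr.gwas_io import HarmonizedSet, harmonize
from netmr.instruments import (BlockLDProvider, MatrixLDProvider, clump,
                               f_statistic, instrument_strength, is_weak,
                               select_candidates, snp_r2, steiger_filter)
from netmr.simulate import SimulationParams, simulate_system
from tests.conftest import make_sumstats


class TestSelectCandidates:
    def test_filters_and_sorts(self):
        ss = make_sumstats([
            {"snp": f"rs{i}", "ea": "A", "oa": "G", "beta": 0.1,
             "pval": p}
            for i, p in enumerate([0.5, 1e-6, 1e-7, 0.2, 1e-9, 0.9, 0.3,
                                   0.4, 0.6, 0.7])
        ])
        out = select_candidates(ss, 1e-5)
        assert list(out["snp"]) == ["rs4", "rs2", "rs1"]
        assert out["pval"].is_monotonic_increasing

    def test_all_null_gives_empty(self):
        ss = make_sumstats([{"snp": "rs1", "ea": "A", "oa": "G", "beta": 0,
                             "pval": 1.0}])
        assert select_candidates(ss, 5e-8).empty

    def test_null_simulation_yields_few_hits(self, rng):
        # 1000 uniform p-values at 5e-8: expected hits 1000*5e-8 ~ 0
        ss = make_sumstats([
            {"snp": f"rs{i}", "ea": "A", "oa": "G", "beta": 0.0,
             "pval": p, "pos": i + 1}
            for i, p in enumerate(rng.uniform(size=1000))
        ])
        assert len(select_candidates(ss, 5e-8)) == 0


def _cand(rows):
    return pd.DataFrame(rows)


class TestClump:
    def test_correlated_pair_keeps_lower_p(self):
        cand = _cand([
            {"snp": "a", "chrom": "1", "pos": 100_000, "pval": 1e-10},
            {"snp": "b", "chrom": "1", "pos": 105_000, "pval": 1e-8},
        ])
        ld = MatrixLDProvider({("a", "b"): 0.9})
        out = clump(cand, ld)
        assert list(out["snp"]) == ["a"]

    def test_different_chromosomes_all_kept(self):
        cand = _cand([
            {"snp": "a", "chrom": "1", "pos": 1000, "pval": 1e-10},
            {"snp": "b", "chrom": "2", "pos": 1000, "pval": 1e-8},
        ])
        ld = MatrixLDProvider({("a", "b"): 0.99})
        assert len(clump(cand, ld)) == 2

    def test_outside_window_kept(self):
        cand = _cand([
            {"snp": "a", "chrom": "1", "pos": 1, "pval": 1e-10},
            {"snp": "b", "chrom": "1", "pos": 20_000_001, "pval": 1e-8},
        ])
        ld = MatrixLDProvider({("a", "b"): 0.99})
        assert len(clump(cand, ld, window_kb=10_000)) == 2

    def test_block_panel_keeps_block_minima(self):
        # 4 blocks x 10 SNPs, within-block r2 = 0.8: one survivor per block,
        # each the block's p-minimum
        sys = simulate_system(
            SimulationParams(n_exposure_snps=40, n_mediator_snps=0,
                             block_size=10, within_block_r2=0.8),
            seed=5,
        )
        cand = select_candidates(sys.exposure, 5e-8)
        out = clump(cand, sys.ld)
        assert len(out) == 4
        truth = sys.truth
        recs = sys.exposure.records.set_index("snp")
        for snp in out["snp"]:
            block = truth.block_of[snp]
            members = [s for s, b in truth.block_of.items() if b == block]
            assert recs.loc[snp, "pval"] == recs.loc[members, "pval"].min()

    def test_input_order_invariance(self, rng):
        rows = [{"snp": f"rs{i}", "chrom": str(1 + i % 3),
                 "pos": 1000 * (i + 1),
                 "pval": float(rng.uniform(1e-12, 1e-6))} for i in range(30)]
        ld = MatrixLDProvider({
            (f"rs{i}", f"rs{j}"): 0.5
            for i in range(30) for j in range(i + 1, 30) if j - i <= 2
        })
        a = clump(_cand(rows), ld)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        b = clump(_cand(shuffled), ld)
        assert list(a["snp"]) == list(b["snp"])


class TestSnpR2:
    @pytest.mark.parametrize("beta,se,n,expected", [
        (0.0, 0.02, 5000, 0.0),
        (0.1, 0.01, 1000, 0.01 / 0.11),        # = 0.0909...
    ])
    def test_arithmetic(self, beta, se, n, expected):
        assert snp_r2(beta, se, n) == pytest.approx(expected)

    def test_balance_point(self):
        # beta = se * sqrt(N) sits exactly at r2 = 1/2
        assert snp_r2(0.02 * np.sqrt(400.0), 0.02, 400) == pytest.approx(0.5)

    def test_requires_n_above_one(self):
        with pytest.raises(ValidationError):
            snp_r2(0.1, 0.01, 1)

    def test_matches_individual_level_regression(self, rng):
        # independent oracle: squared correlation from simulated genotypes
        n, f, beta = 20_000, 0.3, 0.15
        x = rng.binomial(2, f, size=n).astype(float)
        y = beta * x + rng.normal(0, 1, size=n)
        xc = x - x.mean()
        bhat = float(xc @ y / (xc @ xc))
        resid = y - y.mean() - bhat * xc
        se = float(np.sqrt(resid @ resid / (n - 2) / (xc @ xc)))
        r2_formula = snp_r2(bhat, se, n)
        r2_corr = float(np.corrcoef(x, y)[0, 1] ** 2)
        assert r2_formula == pytest.approx(r2_corr, rel=0.02)


class TestFStatistic:
    @pytest.mark.parametrize("r2,n,k,expected", [
        (0.0, 1000, 5, 0.0),
        (0.5, 103, 1, 101.0),
        (0.01, 7824, 15, (7824 - 16) * 0.01 / (15 * 0.99)),
    ])
    def test_arithmetic(self, r2, n, k, expected):
        assert f_statistic(r2, n, k) == pytest.approx(expected)

    def test_study_scale_value_is_weak(self):
        f = f_statistic(0.01, 7824, 15)
        assert f == pytest.approx(5.258, abs=0.01)
        assert is_weak(f)

    def test_aberrant_r2_rejected(self):
        with pytest.raises(ValidationError, match="aberrant"):
            f_statistic(1.0, 1000, 5)

    def test_monotone_in_r2(self):
        fs = [f_statistic(r2, 10_000, 10) for r2 in (0.01, 0.05, 0.2, 0.5)]
        assert fs == sorted(fs)


def _hset(bx, sex, by, sey, nx, ny):
    k = len(bx)
    return HarmonizedSet(
        exposure_ids=["X"], outcome_id="Y",
        snps=[f"rs{i}" for i in range(k)],
        ea=["A"] * k, oa=["G"] * k,
        bx=np.asarray(bx, float), sex=np.asarray(sex, float),
        by=np.asarray(by, float), sey=np.asarray(sey, float),
        nx=np.full(k, float(nx)), n_outcome=float(ny),
    )


class TestSteiger:
    def test_correct_direction_retained(self):
        # r2_exp = 0.01 >> r2_out = 0.0001
        h = _hset([0.1], [0.01], [0.01], [0.01], 10_000, 10_000)
        assert steiger_filter(h).n_snps == 1

    def test_marginal_excess_not_significant_retained(self):
        # Fisher-z oracle: r_exp=0.02, r_out=0.022, N=10,000 both sides
        # z = (atanh(.022)-atanh(.02)) / sqrt(2/9997) = 0.1415 -> p = 0.444
        n, se = 10_000, 0.01
        b_exp = np.sqrt(4e-4 / (1 - 4e-4)) * se * np.sqrt(n)
        b_out = np.sqrt(4.84e-4 / (1 - 4.84e-4)) * se * np.sqrt(n)
        h = _hset([b_exp], [se], [b_out], [se], n, n)
        assert steiger_filter(h, alpha=0.05).n_snps == 1

    def test_reverse_causal_plants_dropped(self):
        # planted effect only in the outcome layer, N = 20,000 both sides
        params = SimulationParams(
            n_exposure_snps=20, n_mediator_snps=0, n_reverse_snps=5,
            exposure_n_case=10_000, exposure_n_control=10_000,
            outcome_n_case=10_000, outcome_n_control=10_000,
        )
        detected = total = 0
        for seed in range(20):
            sys = simulate_system(params, seed=seed)
            cand = select_candidates(sys.exposure, 5e-8)
            snps = list(cand["snp"]) + sys.truth.reverse_snps
            h = harmonize(sys.exposure, sys.outcome, snps=snps)
            filt = steiger_filter(h)
            dropped = {s for s, r in filt.dropped.items() if r == "steiger"}
            detected += len(dropped & set(sys.truth.reverse_snps))
            total += len(set(h.snps) & set(sys.truth.reverse_snps))
        assert detected / total > 0.9

    def test_type_i_control_on_well_behaved_snps(self):
        # over >= 500 honest instruments, <= 5% are discarded
        dropped = total = 0
        for seed in range(6):
            sys = simulate_system(SimulationParams(), seed=100 + seed)
            cand = select_candidates(sys.exposure, 5e-8)
            h = harmonize(sys.exposure, sys.outcome, snps=cand["snp"])
            filt = steiger_filter(h)
            total += h.n_snps
            dropped += h.n_snps - filt.n_snps
        assert total >= 500
        assert dropped / total <= 0.05


def test_instrument_strength_aggregates(valid_system):
    cand = select_candidates(valid_system.exposure, 5e-8)
    s = instrument_strength("exposure", cand)
    assert 0 < s.r2_total < 0.9
    assert s.f_statistic > 10
    assert not s.aberrant
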