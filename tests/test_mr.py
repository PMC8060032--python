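"""Mendelian randomisation estimators and sensitivity diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pharmagenic as pg
from pharmagenic.mr import (IvSet, mr_egger, mr_ivw, mr_leave_one_out,
                            mr_steiger, mr_weighted_median, presso_global,
                            select_instruments)


def make_iv(bx, by, se_y, se_x=None, n_x=100_000, n_y=100_000):
    k = len(bx)
    return IvSet(pd.DataFrame({
        "snp": [f"iv{i}" for i in range(k)], "bx": bx,
        "se_x": se_x if se_x is not None else [0.01] * k,
        "by": by, "se_y": se_y, "n_x": n_x, "n_y": n_y}))


@pytest.fixture
def random_iv():
    rng = np.random.default_rng(3)
    k = 10
    bx = rng.uniform(0.05, 0.3, k)
    se_y = rng.uniform(0.02, 0.08, k)
    by = 0.4 * bx + se_y * rng.standard_normal(k)
    return make_iv(bx, by, se_y, se_x=rng.uniform(0.005, 0.02, k))


class TestIvw:
    def test_identical_ratios_equal_weights(self):
        est = mr_ivw(make_iv([0.2, 0.4], [0.1, 0.2], [0.05, 0.05]))
        assert est.beta == pytest.approx(0.5)
        assert est.Q == pytest.approx(0.0, abs=1e-12)
        # Q = 0: multiplicative random effects may not deflate the SE
        fixed = mr_ivw(make_iv([0.2, 0.4], [0.1, 0.2], [0.05, 0.05]), random_effects=False)
        assert est.se == fixed.se

    def test_matches_wls_through_origin_oracle(self):
        bx = np.array([1.0, 2.0, 3.0])
        by = np.array([0.9, 2.1, 3.3])
        se_y = np.array([0.1, 0.1, 0.1])
        # independent oracle: weighted least squares via lstsq on sqrt(w)-scaled data
        w = 1 / se_y ** 2
        oracle = np.linalg.lstsq((np.sqrt(w) * bx)[:, None], np.sqrt(w) * by, rcond=None)[0][0]
        est = mr_ivw(make_iv(bx, by, se_y))
        assert est.beta == pytest.approx(oracle, abs=1e-10)

    def test_equals_weighted_mean_of_wald_ratios(self, random_iv):
        # algebraic identity with weights bx^2 / se_y^2
        bx, _, by, se_y = random_iv.arrays()
        wr = by / bx
        w = bx ** 2 / se_y ** 2
        assert mr_ivw(random_iv).beta == pytest.approx((w * wr).sum() / w.sum(), abs=1e-10)

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError, match=">= 2"):
            mr_ivw(make_iv([0.2], [0.1], [0.05]))

    def test_units_contract_scaling(self, random_iv):
        # doubling exposure units halves the causal effect
        df = random_iv.df.copy()
        df["bx"] *= 2
        assert mr_ivw(IvSet(df)).beta == pytest.approx(mr_ivw(random_iv).beta / 2)

    def test_sign_flip_invariance(self, random_iv):
        df = random_iv.df.copy()
        df.loc[3, ["bx", "by"]] *= -1
        flipped = IvSet(df)
        for fn in (mr_ivw, mr_egger):
            assert fn(flipped).beta == pytest.approx(fn(random_iv).beta, abs=1e-12)
        wm0 = mr_weighted_median(random_iv, seed=5)
        wm1 = mr_weighted_median(flipped, seed=5)
        assert wm1.beta == pytest.approx(wm0.beta, abs=1e-12)


class TestWeightedMedian:
    def test_equal_ratios_return_that_ratio(self):
        est = mr_weighted_median(make_iv([0.1, 0.2, 0.3], [0.05, 0.1, 0.15],
                                         [0.01, 0.05, 0.02]), seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_robust_to_single_outlier(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        by = 0.5 * bx
        by[4] = 0.25 * 5.0  # gross pleiotropic outlier (ratio 5 vs 0.5)
        iv = make_iv(bx, by, [0.02] * 5)
        wm = mr_weighted_median(iv, seed=1)
        ivw = mr_ivw(iv)
        assert wm.beta == pytest.approx(0.5, rel=0.10)
        assert abs(ivw.beta - 0.5) > abs(wm.beta - 0.5)

    def test_bootstrap_reproducible(self, random_iv):
        a = mr_weighted_median(random_iv, seed=7)
        b = mr_weighted_median(random_iv, seed=7)
        assert a.se == b.se

    def test_zero_bx_dropped_with_warning(self):
        iv = make_iv([0.0, 0.2, 0.3, 0.1], [0.1, 0.1, 0.15, 0.05], [0.02] * 4)
        with pytest.warns(UserWarning, match="bx = 0"):
            est = mr_weighted_median(iv, seed=1)
        assert est.k == 3


class TestEgger:
    def test_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr_egger(make_iv(bx, 0.5 * bx, [0.02] * 4))
        ivw_fe = mr_ivw(make_iv(bx, 0.5 * bx, [0.02] * 4), random_effects=False)
        assert est.beta == pytest.approx(ivw_fe.beta, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constant_pleiotropy(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.1, 0.5, 20)
        se_y = np.full(20, 0.02)
        by = 0.1 + 0.3 * bx + se_y * rng.standard_normal(20)
        est = mr_egger(make_iv(bx, by, se_y))
        # independent WLS-with-intercept oracle
        X = np.column_stack([np.ones(20), bx])
        sw = np.sqrt(1 / se_y ** 2)
        oracle = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)[0]
        assert est.intercept == pytest.approx(oracle[0], abs=1e-10)
        assert est.beta == pytest.approx(oracle[1], abs=1e-10)
        assert est.intercept == pytest.approx(0.1, abs=0.05)

    def test_no_spread_error(self):
        with pytest.raises(ValueError, match="spread"):
            mr_egger(make_iv([0.2, 0.2, -0.2], [0.1, 0.1, -0.1], [0.02] * 3))


class TestSteiger:
    def test_direction_verdict(self):
        iv = make_iv([0.1] * 4, [0.01] * 4, se_y=[0.01] * 4, se_x=[0.01] * 4)
        res = mr_steiger(iv)  # z_x = 10, z_y = 1, equal n
        assert res["verdict"] == "exposure->outcome"

    def test_swap_flips_verdict_same_p(self):
        iv = make_iv([0.1, 0.12, 0.09], [0.01, 0.02, 0.015],
                     se_y=[0.01] * 3, se_x=[0.01] * 3)
        swapped = IvSet(iv.df.rename(columns={
            "bx": "by", "by": "bx", "se_x": "se_y", "se_y": "se_x",
            "n_x": "n_y", "n_y": "n_x"}))
        a, b = mr_steiger(iv), mr_steiger(swapped)
        assert a["verdict"] != b["verdict"]
        assert a["p"] == pytest.approx(b["p"])

    def test_correct_on_simulated_causal_data(self, ldsc_panel):
        p = pg.LcvSimParams(h2_1=0.4, h2_2=0.3, rg=0.5, gcp=1.0,
                            frac_causal=0.01, n1=200_000, n2=200_000, seed=17)
        a, b = pg.simulate_sumstats_pair(p, ldsc_panel)
        iv = select_instruments(a, b, ldsc_panel)
        assert mr_steiger(iv)["correct_direction"]


class TestLeaveOneOut:
    def test_bookkeeping(self, random_iv):
        loo = mr_leave_one_out(random_iv)
        assert len(loo) == len(random_iv)
        assert (loo["k"] == len(random_iv) - 1).all()

    def test_homogeneous_instruments_stay_within_one_se(self):
        bx = np.linspace(0.1, 0.4, 8)
        iv = make_iv(bx, 0.5 * bx, [0.02] * 8)
        full = mr_ivw(iv)
        loo = mr_leave_one_out(iv)
        assert (np.abs(loo["beta"] - full.beta) <= full.se).all()

    def test_high_leverage_instrument_flagged(self):
        rng = np.random.default_rng(2)
        bx = np.concatenate([rng.uniform(0.1, 0.2, 6), [0.5]])
        se_y = np.full(7, 0.05)
        by = 0.08 * bx + se_y * 0.1 * rng.standard_normal(7)
        by[6] = 0.5 * 0.5  # one instrument carries the signal
        iv = make_iv(bx, by, se_y)
        loo = mr_leave_one_out(iv)
        full_sig = mr_ivw(iv).p < 0.05
        # removing the leveraged IV must change the significance verdict
        row = loo[loo["snp"] == "iv6"].iloc[0]
        assert row["significance_changed"] == ((row["p"] < 0.05) != full_sig)
        assert loo["significance_changed"].any()


class TestPresso:
    def test_reproducible_with_seed(self, random_iv):
        assert presso_global(random_iv, seed=9)["p"] == presso_global(random_iv, seed=9)["p"]

    def test_requires_four_instruments(self):
        with pytest.raises(ValueError, match=">= 4"):
            presso_global(make_iv([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.02] * 3))

    def test_detects_injected_outlier(self):
        rng = np.random.default_rng(4)
        hits = 0
        for rep in range(25):
            k = 12
            bx = rng.uniform(0.05, 0.3, k)
            se_y = rng.uniform(0.02, 0.05, k)
            by = 0.4 * bx + se_y * rng.standard_normal(k)
            by[0] += 0.5  # large pleiotropic outlier
            iv = make_iv(bx, by, se_y)
            hits += presso_global(iv, n_sim=500, seed=int(rng.integers(2 ** 31)))["p"] < 0.05
        assert hits >= 20  # >= 80% detection


class TestSelectInstruments:
    def _exposure(self, extra=None):
        rows = [
            {"snp": "a", "chrom": "1", "pos": 1000, "a1": "A", "a2": "G",
             "beta": 0.3, "se": 0.03, "p": 1e-23, "n": 1e5, "maf": 0.3},
            {"snp": "b", "chrom": "1", "pos": 500_000, "a1": "C", "a2": "T",
             "beta": 0.25, "se": 0.03, "p": 1e-16, "n": 1e5, "maf": 0.3},
            {"snp": "c", "chrom": "2", "pos": 1000, "a1": "G", "a2": "A",
             "beta": -0.2, "se": 0.03, "p": 1e-11, "n": 1e5, "maf": 0.3},
        ]
        if extra:
            rows += extra
        return pg.SumStats(pd.DataFrame(rows))

    def _outcome(self, exposure):
        df = exposure.df.copy()
        df["beta"] = 0.1 * df["beta"]
        df["z"] = np.nan  # recomputed from beta/se
        df["p"] = 0.01
        return pg.SumStats(df)

    def _panel(self, snps, r=None):
        from pharmagenic.core import LdBlock, LdPanel
        k = len(snps)
        mat = np.eye(k) if r is None else r
        return LdPanel([LdBlock(snps, mat)])

    def test_three_independent_significant(self):
        exp = self._exposure()
        iv = select_instruments(exp, self._outcome(exp), self._panel(["a", "b", "c"]))
        assert len(iv) == 3

    def test_weak_ld_still_excluded_at_strict_threshold(self):
        extra = [{"snp": "d", "chrom": "1", "pos": 2000, "a1": "A", "a2": "G",
                  "beta": 0.28, "se": 0.03, "p": 1e-20, "n": 1e5, "maf": 0.3}]
        exp = self._exposure(extra)
        r = np.eye(4)
        r[0, 3] = r[3, 0] = 0.1  # r^2 = 0.01 with the top SNP: above 0.001
        iv = select_instruments(exp, self._outcome(exp), self._panel(["a", "b", "c", "d"], r))
        assert len(iv) == 3
        assert "d" not in set(iv.df["snp"])

    def test_palindromic_excluded(self):
        extra = [{"snp": "e", "chrom": "3", "pos": 1000, "a1": "A", "a2": "T",
                  "beta": 0.3, "se": 0.03, "p": 1e-30, "n": 1e5, "maf": 0.3}]
        exp = self._exposure(extra)
        iv = select_instruments(exp, self._outcome(exp), self._panel(["a", "b", "c", "e"]))
        assert "e" not in set(iv.df["snp"])
        assert len(iv) == 3


def test_iv_table_round_trip(tmp_path, random_iv):
    path = tmp_path / "ivs.tsv"
    random_iv.df.to_csv(path, sep="\t", index=False)
    loaded = IvSet.from_table(path)
    assert mr_ivw(loaded).beta == pytest.approx(mr_ivw(random_iv).beta, rel=1e-12)
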