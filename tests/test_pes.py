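"""Pathway polygenic scores: construction, scoring, association, drugs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pharmagenic as pg
from pharmagenic.core import GeneAnnotation, GeneSet, GenotypeMatrix
from pharmagenic.pes import (ClumpParams, PesDefinition, associate_profile,
                             build_pes_definition, decile_depletion,
                             drug_overrepresentation, pes_pgs_overlap,
                             prepare_phenotype, score_profiles)


def _definition(snps, weights, a1=None, a2=None):
    k = len(snps)
    return PesDefinition(
        "toy", 1.0, "conservative",
        pd.DataFrame({"snp": snps, "a1": a1 or ["A"] * k, "a2": a2 or ["G"] * k,
                      "weight": weights, "p": [0.01] * k}))


def _geno(snps, dosage, a1=None, a2=None):
    d = np.asarray(dosage, float)
    k = d.shape[1]
    return GenotypeMatrix([f"i{j}" for j in range(d.shape[0])], list(snps),
                          a1 or ["A"] * k, a2 or ["G"] * k, d)


class TestBuildDefinition:
    def _inputs(self):
        ann = [GeneAnnotation("GENE1", "1", 10_000, 30_000, "+")]
        gs = GeneSet("SET", ["GENE1"])
        df = pd.DataFrame({
            "snp": [f"s{i}" for i in range(6)],
            "chrom": "1",
            "pos": [10_100, 10_200, 12_000, 20_000, 25_000, 29_000],
            "a1": "A", "a2": "G",
            "maf": [0.3, 0.005, 0.008, 0.2, 0.4, 0.25],
            "beta": [0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
            "se": [0.02] * 6,
            "p": [1e-6, 1e-6, 1e-6, 0.2, 1e-4, 1e-5],
            "n": 1e5})
        ss = pg.SumStats(df)
        from pharmagenic.core import LdBlock, LdPanel
        r = np.eye(6)
        r[4, 5] = r[5, 4] = 0.9  # s4-s5 clump together
        panel = LdPanel([LdBlock(list(df["snp"]), r)])
        return ss, gs, ann, panel

    def test_filters_applied_by_hand(self):
        # 6 SNPs: 2 fail MAF, 1 fails P_T, one of the s4/s5 pair clumped away
        ss, gs, ann, panel = self._inputs()
        d = build_pes_definition(ss, gs, ann, panel, p_t=0.05, boundary="conservative",
                                 clump_params=ClumpParams(r2=0.1))
        assert d.m == 2
        assert set(d.snps["snp"]) == {"s0", "s5"}  # s5 beats s4 on p

    def test_all_snps_threshold_skips_p_filter(self):
        ss, gs, ann, panel = self._inputs()
        d = build_pes_definition(ss, gs, ann, panel, p_t=1.0, clump_params=ClumpParams(r2=0.1))
        assert set(d.snps["snp"]) == {"s0", "s3", "s5"}

    def test_genome_wide_pgs_degenerate_set(self):
        ss, _, ann, panel = self._inputs()
        d = build_pes_definition(ss, None, ann, panel, p_t=1.0, boundary=None,
                                 clump_params=ClumpParams(r2=0.1))
        assert d.set_name == "genome-wide"
        assert d.m == 3  # only MAF + clump filters

    def test_zero_survivors_error(self):
        ss, gs, ann, panel = self._inputs()
        with pytest.raises(ValueError, match="no SNPs"):
            build_pes_definition(ss, gs, ann, panel, p_t=1e-12)


class TestScoring:
    def test_worked_two_snp_average(self):
        d = _definition(["s1", "s2"], [0.2, -0.1])
        prof = score_profiles(d, _geno(["s1", "s2"], [[2, 1], [0, 0], [1, 2]]))
        assert prof["raw"].iloc[0] == pytest.approx(0.15)

    def test_prestandardization_linearity(self):
        d = _definition(["s1", "s2"], [0.2, -0.1])
        g1 = _geno(["s1", "s2"], [[2, 1], [0.5, 0.25], [1, 0.5]])
        g2 = _geno(["s1", "s2"], [[1, 0.5], [0.25, 0.125], [0.5, 0.25]])
        p1, p2 = score_profiles(d, g1), score_profiles(d, g2)
        assert np.allclose(p1["raw"], 2 * p2["raw"])

    def test_standardization_matches_oracle(self):
        rng = np.random.default_rng(0)
        d = _definition(["s1", "s2", "s3"], [0.2, -0.1, 0.05])
        g = _geno(["s1", "s2", "s3"], rng.integers(0, 3, (20, 3)))
        prof = score_profiles(d, g)
        raw = prof["raw"].to_numpy()
        assert np.allclose(prof["pes"], (raw - raw.mean()) / raw.std(ddof=0))
        assert abs(prof["pes"].mean()) < 1e-10
        assert abs(prof["pes"].std(ddof=0) - 1) < 1e-10

    def test_snp_order_invariance(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (15, 3)).astype(float)
        d1 = _definition(["a", "b", "c"], [0.2, -0.1, 0.3])
        d2 = _definition(["c", "a", "b"], [0.3, 0.2, -0.1])
        g = _geno(["a", "b", "c"], dos)
        assert np.allclose(score_profiles(d1, g)["pes"], score_profiles(d2, g)["pes"])

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, (15, 2)).astype(float)
        d = _definition(["a", "b"], [0.2, -0.1])
        g = _geno(["a", "b"], dos)
        # recode SNP b on the other allele in the genotype file
        g_flip = _geno(["a", "b"], np.column_stack([dos[:, 0], 2 - dos[:, 1]]),
                       a1=["A", "G"], a2=["G", "A"])
        assert np.allclose(score_profiles(d, g)["pes"], score_profiles(d, g_flip)["pes"])

    def test_missing_dosages_drop_from_average(self):
        d = _definition(["s1", "s2"], [0.2, -0.1])
        dos = np.array([[2, np.nan], [1, 1], [np.nan, np.nan]])
        with pytest.warns(UserWarning, match="zero scored"):
            prof = score_profiles(d, _geno(["s1", "s2"], dos))
        assert prof["raw"].iloc[0] == pytest.approx(0.4)  # only s1 counted
        assert prof["snps_counted"].tolist() == [1, 2, 0]
        assert np.isnan(prof["raw"].iloc[2])


class TestPhenotype:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "y": rng.normal(2.5, 0.6, n), "sex": rng.integers(0, 2, n).astype(float),
            "age": rng.uniform(55, 85, n)})

    def test_orthogonal_covariates_reduce_to_blom(self):
        tab = self._table()
        out = prepare_phenotype(tab, "y", ["sex", "age"])
        resid = tab["y"] - np.column_stack(
            [np.ones(len(tab)), tab[["sex", "age"]]]) @ np.linalg.lstsq(
            np.column_stack([np.ones(len(tab)), tab[["sex", "age"]]]), tab["y"], rcond=None)[0]
        assert stats.spearmanr(out, resid).statistic == pytest.approx(1.0)

    def test_output_sd_near_one(self):
        out = prepare_phenotype(self._table(n=500), "y", ["sex", "age"])
        assert 0.95 <= out.std() <= 1.05

    def test_row_permutation_consistency(self):
        tab = self._table()
        out = prepare_phenotype(tab, "y", ["sex", "age"])
        perm = np.random.default_rng(3).permutation(len(tab))
        out_perm = prepare_phenotype(tab.iloc[perm].reset_index(drop=True), "y", ["sex", "age"])
        assert np.allclose(out.to_numpy()[perm], out_perm.to_numpy())

    def test_max_of_attempts(self):
        tab = self._table()
        tab["y2"] = tab["y"] - 0.1
        out_max = prepare_phenotype(tab, ["y", "y2"], ["sex", "age"])
        out_single = prepare_phenotype(tab, "y", ["sex", "age"])
        assert np.allclose(out_max, out_single)

    def test_collinear_design_names_column(self):
        tab = self._table()
        tab["age_copy"] = tab["age"]
        with pytest.raises(ValueError, match="age"):
            prepare_phenotype(tab, "y", ["sex", "age", "age_copy"])


class TestAssociation:
    def test_collinear_pgs_raises(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame({"pes": rng.standard_normal(100)})
        pheno = pd.Series(rng.standard_normal(100))
        with pytest.raises(ValueError, match="collinear"):
            associate_profile(prof, pheno, adjust_pgs=prof)

    def test_small_n_refused(self):
        prof = pd.DataFrame({"pes": np.arange(10.0)})
        with pytest.raises(ValueError, match="n < 30"):
            associate_profile(prof, pd.Series(np.arange(10.0)))

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        score = rng.standard_normal(n)
        pheno = pd.Series(0.1 * score + rng.standard_normal(n))
        res = associate_profile(pd.DataFrame({"pes": score}), pheno)
        assert res.p < 1e-3
        assert res.delta_r2 == pytest.approx(0.01, abs=0.01)


class TestDecile:
    def test_bottom_decile_size(self):
        rng = np.random.default_rng(6)
        prof = pd.DataFrame({"pes": rng.standard_normal(505)})
        res = decile_depletion(prof, pd.Series(rng.standard_normal(505)))
        assert res["n_bottom_decile"] == 50

    def test_negative_dependence_gives_or_below_one(self):
        rng = np.random.default_rng(7)
        n = 2000
        score = rng.standard_normal(n)
        pheno = pd.Series(0.8 * score + 0.6 * rng.standard_normal(n))
        res = decile_depletion(pd.DataFrame({"pes": score}), pheno)
        assert res["odds_ratio"] < 1
        assert res["ci95"][1] < 1

    def test_null_ci_covers_one(self):
        rng = np.random.default_rng(8)
        covered = 0
        for _ in range(20):
            prof = pd.DataFrame({"pes": rng.standard_normal(500)})
            res = decile_depletion(prof, pd.Series(rng.standard_normal(500)))
            lo, hi = res["ci95"]
            covered += lo <= 1.0 <= hi
        assert covered >= 17


class TestDrugs:
    def test_exact_hypergeometric_oracle(self):
        universe = [f"G{i}" for i in range(100)]
        gs = GeneSet("S", universe[:10])
        targets = {"drugA": universe[7:12]}  # 3 of 5 targets in the set
        res = drug_overrepresentation(gs, targets, universe)
        # enumerate the upper tail by hand: P(X >= 3), X ~ Hypergeom(100, 10, 5)
        from math import comb
        tail = sum(comb(10, k) * comb(90, 5 - k) for k in (3, 4, 5)) / comb(100, 5)
        assert res["p"].iloc[0] == pytest.approx(tail, rel=1e-12)

    def test_overlap_two_excluded(self):
        universe = [f"G{i}" for i in range(50)]
        gs = GeneSet("S", universe[:10])
        res = drug_overrepresentation(gs, {"d": universe[8:11]}, universe)  # overlap 2
        assert res.empty

    def test_perfect_drug_most_significant(self):
        universe = [f"G{i}" for i in range(60)]
        gs = GeneSet("S", universe[:8])
        targets = {"perfect": universe[:8], "random": universe[4:12], "off": universe[30:38]}
        res = drug_overrepresentation(gs, targets, universe)
        assert res["drug"].iloc[0] == "perfect"


def test_pes_pgs_overlap_diagnostics():
    rng = np.random.default_rng(9)
    pes = pd.DataFrame({"pes": rng.standard_normal(1000)})
    pgs = pd.DataFrame({"pes": rng.standard_normal(1000)})
    d = pes_pgs_overlap(pes, pgs)
    assert abs(d["correlation"]) < 0.15
    assert 0 <= d["top_pgs_bottom_pes_fraction"] <= 1
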