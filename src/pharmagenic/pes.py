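"""Pathway-specific polygenic scores (pharmagenic enrichment scores).

A PES is an ordinary additive polygenic score restricted to the
boundary-extended gene bodies of one druggable gene-set, built at the
p-value threshold where that set showed its strongest competitive
association.  For individual i over the m scored SNPs,

    PES_i = sum_j beta_j * G_ij,

averaged by the number of non-missing scored SNPs the individual carries
and standardized across the cohort (mean 0, SD 1).  The same machinery with
"all genes, no boundary restriction" yields the genome-wide PGS used as an
adjustment covariate.  Downstream: Blom-normalised residual phenotypes,
association with delta-R^2, decile-depletion odds, and hypergeometric
drug-target overrepresentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core import (GeneSet, GenotypeMatrix, LdPanel, SumStats,
                   annotate_snps_to_genes, blom_transform, ld_clump)

__all__ = [
    "PesDefinition",
    "build_pes_definition",
    "score_profiles",
    "prepare_phenotype",
    "associate_profile",
    "decile_depletion",
    "drug_overrepresentation",
    "pes_pgs_overlap",
]

#: PGS thresholds used when scoring genome-wide at several P_T.
PGS_THRESHOLDS = (1.0, 0.5, 0.05, 0.005, 5e-5, 5e-8)


@dataclass
class ClumpParams:
    r2: float = 0.1
    window_kb: float = 250.0


@dataclass
class PesDefinition:
    """SNP-weight recipe for one gene-set at one threshold."""

    set_name: str
    p_t: float
    boundary: str | None
    snps: pd.DataFrame  # snp, a1, a2, weight, p
    clump: ClumpParams = field(default_factory=ClumpParams)
    maf_floor: float = 0.01

    @property
    def m(self) -> int:
        return len(self.snps)


def build_pes_definition(
    ss: SumStats,
    gene_set: GeneSet | None,
    annotations,
    ld: LdPanel,
    p_t: float,
    boundary: str | None = "conservative",
    clump_params: ClumpParams | None = None,
    maf_floor: float = 0.01,
) -> PesDefinition:
    """Filter, restrict, clump: the score recipe.

    Common variants (MAF > ``maf_floor``) inside the set's extended gene
    bodies with p below ``p_t`` are LD-clumped; the surviving effect sizes
    are the weights.  ``gene_set=None`` with ``boundary=None`` skips the
    genic restriction entirely, producing a genome-wide PGS definition.
    """
    clump_params = clump_params or ClumpParams()
    df = ss.df
    keep = df["maf"].to_numpy(float) > maf_floor
    if p_t < 1.0:
        keep &= df["p"].to_numpy(float) < p_t
    if gene_set is not None and boundary is not None:
        gene_map = annotate_snps_to_genes(ss, annotations, boundary=boundary)
        in_set = set()
        for gene in gene_set.members:
            in_set.update(gene_map.get(gene, []))
        keep &= df["snp"].isin(in_set).to_numpy()
    sub = ss.subset(keep)
    if len(sub) == 0:
        raise ValueError("no SNPs survive the MAF/threshold/gene-body filters")
    kept = ld_clump(sub, ld, p_thresh=np.inf, r2_thresh=clump_params.r2,
                    window_kb=clump_params.window_kb)
    if not kept:
        raise ValueError("no SNPs survive LD clumping")
    out = sub.df[sub.df["snp"].isin(kept)][["snp", "a1", "a2", "beta", "p"]]
    out = out.rename(columns={"beta": "weight"})
    return PesDefinition(gene_set.name if gene_set else "genome-wide", p_t, boundary,
                         out.reset_index(drop=True), clump_params, maf_floor)


def score_profiles(definition: PesDefinition, geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual scores: raw sum, SNP-count average, standardized PES.

    Dosages coded on the other allele are flipped (d -> 2 - d) before
    weighting; missing dosages drop out of both the sum and the averaging
    denominator.  Returns columns id, raw, snps_counted, pes.
    """
    idx = {s: j for j, s in enumerate(geno.snps)}
    weights, cols = [], []
    for row in definition.snps.itertuples(index=False):
        j = idx.get(row.snp)
        if j is None:
            continue
        if geno.a1[j] == row.a1:
            cols.append((j, False))
        elif geno.a1[j] == row.a2 and geno.a2[j] == row.a1:
            cols.append((j, True))
        else:
            warnings.warn(f"{row.snp}: genotype alleles irreconcilable with score; skipped")
            continue
        weights.append(row.weight)
    if not cols:
        raise ValueError("no scored SNPs present in the genotype matrix")
    D = np.empty((len(geno.individuals), len(cols)))
    for c, (j, flipped) in enumerate(cols):
        D[:, c] = 2.0 - geno.dosage[:, j] if flipped else geno.dosage[:, j]
    W = np.asarray(weights)
    present = np.isfinite(D)
    counted = present.sum(axis=1)
    raw_sum = np.nansum(D * W[None, :], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = raw_sum / counted
    none = counted == 0
    if none.any():
        warnings.warn(f"{int(none.sum())} individuals with zero scored genotypes; score missing")
        raw[none] = np.nan
    ok = np.isfinite(raw)
    mu, sd = raw[ok].mean(), raw[ok].std(ddof=0)
    pes = (raw - mu) / sd
    return pd.DataFrame({"id": geno.individuals, "raw": raw,
                         "snps_counted": counted, "pes": pes})


def prepare_phenotype(
    table: pd.DataFrame,
    phenotype: str | list[str],
    covariates: list[str],
) -> pd.Series:
    """Covariate-residualised, Blom-normalised phenotype.

    ``phenotype`` may name several columns (e.g. repeated spirometry
    attempts); the per-row maximum is used.  The linear model must be full
    rank; collinear columns are named in the error.
    """
    pheno_cols = [phenotype] if isinstance(phenotype, str) else list(phenotype)
    y = table[pheno_cols].max(axis=1).to_numpy(float)
    X = table[covariates].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values")
    X1 = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        bad = []
        cols = ["intercept"] + list(covariates)
        for j in range(1, X1.shape[1]):
            sub = np.delete(X1, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X1):
                bad.append(cols[j])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    return pd.Series(blom_transform(resid), index=table.index, name="phenotype")


@dataclass
class AssociationResult:
    term: str
    beta: float
    se: float
    z: float
    p: float
    delta_r2: float
    n: int
    df_model: int


def associate_profile(
    profile: pd.DataFrame,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
    adjust_pgs: pd.DataFrame | None = None,
) -> AssociationResult:
    """OLS of the phenotype on the standardized score (+ covariates, + PGS).

    delta_r2 is the full-model R^2 minus the same model without the score.
    A score collinear with the adjustment PGS raises rather than silently
    double-counting.
    """
    y = np.asarray(phenotype, float)
    n = len(y)
    if n < 30:
        raise ValueError("refusing association with n < 30 (unstable R^2)")
    parts = [np.asarray(profile["pes"], float)[:, None]]
    names = ["pes"]
    if covariates is not None:
        parts.append(np.asarray(covariates, float))
        names += list(covariates.columns)
    if adjust_pgs is not None:
        parts.append(np.asarray(adjust_pgs["pes"], float)[:, None])
        names.append("pgs")
    X = np.column_stack([np.ones(n)] + parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design (is the PGS identical to the profile?)")
    full = sm.OLS(y, X).fit()
    null = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
    beta, se = full.params[1], full.bse[1]
    return AssociationResult("pes", float(beta), float(se), float(beta / se),
                             float(full.pvalues[1]),
                             float(max(full.rsquared - null.rsquared, 0.0)),
                             n, int(X.shape[1]))


def decile_depletion(profile: pd.DataFrame, phenotype: pd.Series) -> dict:
    """Odds of sitting in the bottom score decile per SD of phenotype.

    Logistic regression of indicator(bottom 10% of the standardized score)
    on the standardized phenotype.  Complete separation falls back to an
    L2-penalised fit, flagged in the output.
    """
    pes = np.asarray(profile["pes"], float)
    y_pheno = np.asarray(phenotype, float)
    ok = np.isfinite(pes) & np.isfinite(y_pheno)
    pes, y_pheno = pes[ok], y_pheno[ok]
    n = len(pes)
    if n < 100:
        raise ValueError("decile depletion requires n >= 100")
    n_bottom = n // 10
    order = np.argsort(pes, kind="stable")
    indicator = np.zeros(n)
    indicator[order[:n_bottom]] = 1.0
    x = (y_pheno - y_pheno.mean()) / y_pheno.std(ddof=0)
    X = sm.add_constant(x)
    flagged = False
    try:
        from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("error", RuntimeWarning)
            fit = sm.Logit(indicator, X).fit(disp=0)
        coef, se = fit.params[1], fit.bse[1]
    except (PerfectSeparationError, Warning, np.linalg.LinAlgError):
        flagged = True
        fit = sm.Logit(indicator, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        coef = fit.params[1]
        se = np.nan
    or_ = float(np.exp(coef))
    ci = (float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))) if np.isfinite(se) else (np.nan, np.nan)
    return {"odds_ratio": or_, "ci95": ci, "n_bottom_decile": int(n_bottom),
            "separation_fallback": flagged}


def drug_overrepresentation(
    gene_set: GeneSet,
    drug_targets: dict[str, list[str]],
    universe: list[str],
    min_overlap: int = 3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each drug's targets in the set.

    Only drugs hitting >= ``min_overlap`` set members are reported;
    Benjamini-Hochberg q across all tested drugs; ``approved`` flags
    q < ``fdr``.
    """
    uni = set(universe)
    members = set(gene_set.members) & uni
    if not set(gene_set.members) <= uni:
        warnings.warn("set members outside the gene universe are ignored")
    rows = []
    for drug, targets in drug_targets.items():
        t_in_uni = set(targets) & uni
        if not t_in_uni:
            continue
        overlap = len(t_in_uni & members)
        # P(X >= overlap), X ~ Hypergeom(|universe|, |members|, |targets|)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(t_in_uni)))
        rows.append({"drug": drug, "n_overlap": overlap, "n_targets": len(t_in_uni), "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df[df["n_overlap"] >= min_overlap].reset_index(drop=True)
    df["enriched"] = df["q"] < fdr
    return df.sort_values("p", ignore_index=True)


def pes_pgs_overlap(pes_profile: pd.DataFrame, pgs_profile: pd.DataFrame) -> dict:
    """Diagnostics relating a pathway score to the genome-wide score.

    Reports their Pearson correlation and the fraction of top-decile-PGS
    individuals who fall in the bottom PES decile (individuals a
    genome-wide score would call protected but the pathway flags).
    """
    pes = np.asarray(pes_profile["pes"], float)
    pgs = np.asarray(pgs_profile["pes"], float)
    n = len(pes)
    r = float(np.corrcoef(pes, pgs)[0, 1])
    n_dec = n // 10
    top_pgs = set(np.argsort(pgs, kind="stable")[-n_dec:])
    bottom_pes = set(np.argsort(pes, kind="stable")[:n_dec])
    frac = len(top_pgs & bottom_pes) / max(len(top_pgs), 1)
    return {"correlation": r, "top_pgs_bottom_pes_fraction": float(frac)}
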