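"""Synthetic GWAS inputs with known ground truth.

Everything downstream is exercisable without any external download:

* AR(1)-block LD panels, with genotype draws whose realized dosage
  correlations match the panel (Gaussian-copula haplotypes with
  tetrachorically calibrated latent correlation);
* paired summary statistics under a latent-factor architecture with chosen
  SNP heritabilities, genetic correlation and genetic causality proportion
  (loadings q1 = |rg|^((1-gcp)/2), q2 = |rg|^((1+gcp)/2), so gcp is the
  analytic ground truth); the sparse (spike-and-slab) latent factor supplies
  the positive excess kurtosis that moment-based causality estimation
  requires — a Gaussian architecture is a designed failure case;
* genotyped cohorts with a stated fraction of phenotypic variance planted
  inside a designated gene-set's gene bodies;
* TWAS loci with known causal genes.

Summary statistics are simulated at the z level (multivariate normal with
LD covariance, E[chi^2_j] = N*h2*l_j/M + 1) rather than via individual-level
GWAS, for speed; effect sizes are in per-standardized-genotype units.
Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (GeneAnnotation, GeneSet, GenotypeMatrix, LdBlock, LdPanel,
                   SumStats)
from .finemap import TwasLocus

__all__ = [
    "LcvSimParams",
    "CohortSimParams",
    "make_ld_panel",
    "draw_genotypes",
    "simulate_sumstats_pair",
    "simulate_sumstats",
    "sumstats_from_true_effects",
    "simulate_cohort",
    "simulate_twas_locus",
    "make_gene_annotations",
    "make_gene_sets",
    "make_drug_target_map",
]

_ALLELES = ("A", "G")  # non-palindromic pair used for synthetic variants
_SPACING_BP = 5_000
_BLOCK_GAP_BP = 500_000


def ar1_matrix(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def make_ld_panel(
    n_blocks: int = 10,
    block_size: int = 50,
    ar1_rho: float | tuple = 0.5,
    seed: int = 0,
    maf_range: tuple = (0.1, 0.5),
    chrom: str = "1",
) -> LdPanel:
    """AR(1)-correlation LD blocks with synthetic variant metadata.

    ``ar1_rho`` may be a scalar (every block identical) or a ``(lo, hi)``
    range from which each block draws its own correlation strength —
    heterogeneous LD across blocks mirrors the genome and gives LD scores
    the spread that LD-score regression needs for identification.

    MAF is drawn once per block (shared within the block): variants in
    tight LD cannot hold discrepant allele frequencies, and a shared MAF
    keeps the target dosage correlation attainable for the genotype draw.
    The panel gains a ``variants`` DataFrame (snp, chrom, pos, a1, a2, maf).
    """
    rho_range = ar1_rho if isinstance(ar1_rho, (tuple, list)) else (ar1_rho, ar1_rho)
    if not all(abs(r) < 1 for r in rho_range):
        raise ValueError("|ar1_rho| must be < 1")
    rng = np.random.default_rng(seed)
    blocks, rows = [], []
    pos = 1
    for b in range(n_blocks):
        rho_b = float(rng.uniform(*rho_range))
        ids = [f"rs{b}_{i}" for i in range(block_size)]
        blocks.append(LdBlock(ids, ar1_matrix(block_size, rho_b)))
        maf = float(rng.uniform(*maf_range))
        for vid in ids:
            rows.append({"snp": vid, "chrom": chrom, "pos": pos,
                         "a1": _ALLELES[0], "a2": _ALLELES[1], "maf": maf})
            pos += _SPACING_BP
        pos += _BLOCK_GAP_BP
    panel = LdPanel(blocks, provenance=f"synthetic ar1={ar1_rho} seed={seed}")
    panel.variants = pd.DataFrame(rows)
    return panel


# ---------------------------------------------------------------------------
# genotype draws


def _binary_corr(latent_r: float, t1: float, t2: float, f1: float, f2: float) -> float:
    p11 = stats.multivariate_normal(cov=[[1.0, latent_r], [latent_r, 1.0]]).cdf([t1, t2])
    return (p11 - f1 * f2) / np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))


def _latent_r(target: float, f1: float, f2: float, cache: dict) -> float:
    """Latent Gaussian correlation giving dosage correlation ``target``."""
    key = (round(target, 4), round(min(f1, f2), 4), round(max(f1, f2), 4))
    if key in cache:
        return cache[key]
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    hi = _binary_corr(0.999, t1, t2, f1, f2)
    lo = _binary_corr(-0.999, t1, t2, f1, f2)
    if target >= hi:
        warnings.warn(f"target correlation {target:.3f} above attainable {hi:.3f}; clamped")
        val = 0.999
    elif target <= lo:
        val = -0.999
    else:
        val = optimize.brentq(
            lambda r: _binary_corr(r, t1, t2, f1, f2) - target, -0.999, 0.999, xtol=1e-4)
    cache[key] = float(val)
    return cache[key]


def _nearest_corr(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 1e-6, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


def draw_genotypes(panel: LdPanel, n: int, seed: int = 0) -> GenotypeMatrix:
    """Draw dosages whose correlation structure matches the panel.

    Two haplotypes per individual: latent MVN vectors thresholded at the
    allele-frequency quantile, summed to a 0/1/2 dosage.  The latent
    correlation is calibrated per SNP pair so the *dosage* correlation hits
    the panel's r (tetrachoric inversion), cached on the panel.
    """
    if not hasattr(panel, "variants"):
        raise ValueError("panel lacks variant metadata (build it with make_ld_panel)")
    rng = np.random.default_rng(seed)
    cache = getattr(panel, "_latent_cache", None)
    if cache is None:
        cache = panel._latent_cache = {"pairs": {}, "chol": {}}
    maf = panel.variants.set_index("snp")["maf"]
    cols = []
    for bi, blk in enumerate(panel.blocks):
        k = len(blk.ids)
        if bi not in cache["chol"]:
            f = maf.loc[blk.ids].to_numpy(float)
            lat = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    lat[i, j] = lat[j, i] = _latent_r(blk.r[i, j], f[i], f[j], cache["pairs"])
            cache["chol"][bi] = np.linalg.cholesky(_nearest_corr(lat))
        L = cache["chol"][bi]
        f = maf.loc[blk.ids].to_numpy(float)
        thresh = stats.norm.ppf(f)
        h1 = rng.standard_normal((n, k)) @ L.T < thresh
        h2 = rng.standard_normal((n, k)) @ L.T < thresh
        cols.append((h1.astype(float) + h2.astype(float)))
    dosage = np.concatenate(cols, axis=1)
    ids = [f"ind{i}" for i in range(n)]
    v = panel.variants
    return GenotypeMatrix(ids, list(v["snp"]), list(v["a1"]), list(v["a2"]), dosage)


# ---------------------------------------------------------------------------
# paired summary statistics under the latent-factor architecture


@dataclass
class LcvSimParams:
    """Generative parameters for a trait pair with known causal asymmetry."""

    h2_1: float = 0.3
    h2_2: float = 0.3
    rg: float = 0.5
    gcp: float = 0.0
    frac_causal: float = 0.05
    n1: int = 50_000
    n2: int = 50_000
    seed: int = 0

    def __post_init__(self):
        for h in (self.h2_1, self.h2_2):
            if not 0 <= h <= 1:
                raise ValueError("heritabilities must lie in [0, 1]")
        if not -1 <= self.rg <= 1:
            raise ValueError("rg must lie in [-1, 1]")
        if not -1 <= self.gcp <= 1:
            raise ValueError("gcp must lie in [-1, 1]")
        if not 0 < self.frac_causal <= 1:
            raise ValueError("frac_causal must lie in (0, 1]")

    @property
    def loadings(self) -> tuple[float, float]:
        """(q1, q2) with q1*q2 = |rg| and gcp = (ln q2 - ln q1)/ln|rg|."""
        a = abs(self.rg)
        if a == 0:
            return 0.0, 0.0
        q1 = a ** ((1 - self.gcp) / 2.0)
        q2 = a ** ((1 + self.gcp) / 2.0)
        assert abs(q1 * q2 - a) < 1e-12
        return q1, float(np.sign(self.rg)) * q2


def _spike_slab(rng, m: int, frac: float) -> np.ndarray:
    """Unit-variance sparse effects: Bernoulli(frac) x N(0, 1/frac)."""
    mask = rng.random(m) < frac
    return np.where(mask, rng.standard_normal(m) / np.sqrt(frac), 0.0)


def _true_effect_pair(params: LcvSimParams, m: int, rng) -> tuple[np.ndarray, np.ndarray]:
    q1, q2 = params.loadings
    pi = _spike_slab(rng, m, params.frac_causal)
    g1 = _spike_slab(rng, m, params.frac_causal)
    g2 = _spike_slab(rng, m, params.frac_causal)
    a1 = q1 * pi + np.sqrt(max(1 - q1 ** 2, 0.0)) * g1
    a2 = q2 * pi + np.sqrt(max(1 - q2 ** 2, 0.0)) * g2
    b1 = np.sqrt(params.h2_1 / m) * a1
    b2 = np.sqrt(params.h2_2 / m) * a2
    return b1, b2


def _marginal_z(beta: np.ndarray, panel: LdPanel, n: float, rng) -> np.ndarray:
    """z = sqrt(N) R beta + MVN(0, R), block by block."""
    out = np.empty(len(beta))
    off = 0
    for blk in panel.blocks:
        k = len(blk.ids)
        L = _block_chol(panel, blk)
        b = beta[off:off + k]
        out[off:off + k] = np.sqrt(n) * blk.r @ b + L @ rng.standard_normal(k)
        off += k
    return out


def _block_chol(panel: LdPanel, blk: LdBlock) -> np.ndarray:
    cache = getattr(panel, "_r_chol", None)
    if cache is None:
        cache = panel._r_chol = {}
    key = id(blk)
    if key not in cache:
        cache[key] = np.linalg.cholesky(blk.r + 1e-10 * np.eye(len(blk.ids)))
    return cache[key]


def _to_sumstats(panel: LdPanel, z: np.ndarray, n: float, trait: str) -> SumStats:
    v = panel.variants.copy()
    se = np.full(len(z), 1.0 / np.sqrt(n))
    v["z"] = z
    v["se"] = se
    v["beta"] = z * se
    v["p"] = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    v["n"] = n
    return SumStats(v, trait=trait)


def simulate_sumstats_pair(params: LcvSimParams, panel: LdPanel) -> tuple[SumStats, SumStats]:
    """Paired, pre-harmonized summary statistics with the requested
    h2 / rg / gcp structure.  gcp = 1 yields a fully causal
    exposure -> outcome pair usable for Mendelian randomisation."""
    if not hasattr(panel, "variants"):
        raise ValueError("panel lacks variant metadata (build it with make_ld_panel)")
    m = len(panel)
    rng = np.random.default_rng(params.seed)
    b1, b2 = _true_effect_pair(params, m, rng)
    z1 = _marginal_z(b1, panel, params.n1, rng)
    z2 = _marginal_z(b2, panel, params.n2, rng)
    ss1 = _to_sumstats(panel, z1, params.n1, "trait1")
    ss2 = _to_sumstats(panel, z2, params.n2, "trait2")
    ss1.true_beta, ss2.true_beta = b1, b2
    return ss1, ss2


def simulate_sumstats(panel: LdPanel, h2: float = 0.3, n: int = 50_000,
                      frac_causal: float = 0.05, seed: int = 0) -> SumStats:
    """Single-trait convenience wrapper."""
    params = LcvSimParams(h2_1=h2, h2_2=0.0, rg=0.0, gcp=0.0,
                          frac_causal=frac_causal, n1=n, n2=n, seed=seed)
    ss, _ = simulate_sumstats_pair(params, panel)
    return ss


def sumstats_from_true_effects(beta: np.ndarray, panel: LdPanel, n: float,
                               seed: int = 0, trait: str = "") -> SumStats:
    """Discovery-GWAS summary statistics for given true per-SNP effects
    (per-standardized-genotype units)."""
    rng = np.random.default_rng(seed)
    z = _marginal_z(np.asarray(beta, float), panel, n, rng)
    return _to_sumstats(panel, z, n, trait)


# ---------------------------------------------------------------------------
# cohorts with planted pathway effects


@dataclass
class CohortSimParams:
    n: int = 5_000
    planted_fraction: float = 0.01
    background_fraction: float = 0.0  # polygenic variance outside the planted set
    covariate_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for f in (self.planted_fraction, self.background_fraction,
                  self.covariate_fraction):
            if not 0 <= f < 1:
                raise ValueError("variance fractions must lie in [0, 1)")
        if self.planted_fraction + self.background_fraction + self.covariate_fraction >= 1:
            raise ValueError("variance fractions must sum below 1")


def simulate_cohort(
    params: CohortSimParams,
    panel: LdPanel,
    annotations: list[GeneAnnotation],
    planted_set: GeneSet | None,
):
    """Genotyped cohort whose phenotype hides a stated variance fraction
    inside the planted set's gene bodies.

    Phenotype = planted genetic value + optional polygenic background
    (variance ``background_fraction`` spread over all other SNPs) +
    sex/age covariate effects + noise; the planted component explains
    exactly ``planted_fraction`` of the phenotypic variance in this
    cohort.  Returns (GenotypeMatrix, PhenotypeTable, truth dict with the
    causal effects).
    """
    rng = np.random.default_rng(params.seed)
    geno = draw_genotypes(panel, params.n, seed=int(rng.integers(2 ** 31)))
    v = panel.variants
    if planted_set is not None:
        ann = {a.gene: a for a in annotations}
        chosen = set()
        for gene in planted_set.members:
            a = ann.get(gene)
            if a is None:
                raise ValueError(f"planted gene {gene} missing from annotations")
            mask = (v["chrom"].astype(str) == a.chrom) & v["pos"].between(a.start, a.end)
            chosen.update(v.loc[mask, "snp"])
        causal_idx = np.array([j for j, s in enumerate(geno.snps) if s in chosen])
        if len(causal_idx) == 0:
            raise ValueError("planted set covers no panel variants")
    else:
        causal_idx = np.array([], int)

    d = geno.dosage
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    d_std = (d - mu) / sd

    def _scaled_component(idx, target_var):
        b = np.zeros(d.shape[1])
        if target_var <= 0 or len(idx) == 0:
            return b, np.zeros(params.n)
        b[idx] = rng.standard_normal(len(idx))
        g = d_std @ b
        g_sd = g.std(ddof=0)
        if g_sd > 0:
            b *= np.sqrt(target_var) / g_sd
            g *= np.sqrt(target_var) / g_sd
        return b, g

    beta, g = _scaled_component(causal_idx, params.planted_fraction)
    bg_idx = np.setdiff1d(np.arange(d.shape[1]), causal_idx)
    beta_bg, g_bg = _scaled_component(bg_idx, params.background_fraction)
    beta = beta + beta_bg
    g = g + g_bg

    sex = rng.integers(0, 2, params.n).astype(float)
    age = rng.uniform(55, 85, params.n)
    height = rng.normal(170, 10, params.n)
    smoking = rng.integers(0, 2, params.n).astype(float)
    planted_g = d_std[:, causal_idx] @ beta[causal_idx] if len(causal_idx) else np.zeros(params.n)
    cov_lin = np.sqrt(params.covariate_fraction) * (
        (sex - sex.mean()) / max(sex.std(), 1e-9) * 0.6
        + (age - age.mean()) / age.std() * 0.6
        + (height - height.mean()) / height.std() * 0.5)
    noise_var = 1.0 - params.planted_fraction - params.background_fraction - cov_lin.var()
    pheno = g + cov_lin + rng.normal(0, np.sqrt(max(noise_var, 1e-9)), params.n)
    table = pd.DataFrame({
        "id": geno.individuals, "phenotype": pheno, "sex": sex, "age": age,
        "age2": age ** 2, "height": height, "height2": height ** 2,
        "smoking": smoking,
    })
    truth = {"beta_std": beta, "causal_idx": causal_idx,
             "genetic_variance": float(np.var(planted_g)),
             "total_genetic_variance": float(np.var(g))}
    return geno, table, truth


# ---------------------------------------------------------------------------
# TWAS loci


def simulate_twas_locus(
    m: int = 10,
    omega_rho: float = 0.4,
    causal_genes: tuple = (0,),
    prior_var: float = 40.0,
    seed: int = 0,
    label: str = "",
) -> TwasLocus:
    """Locus with known causal genes: lambda_c ~ N(0, prior_var) at causal
    genes and z ~ MVN(Omega lambda, Omega)."""
    rng = np.random.default_rng(seed)
    omega = ar1_matrix(m, omega_rho)
    lam = np.zeros(m)
    for g in causal_genes:
        lam[g] = rng.normal(0, np.sqrt(prior_var))
    L = np.linalg.cholesky(omega + 1e-10 * np.eye(m))
    z = omega @ lam + L @ rng.standard_normal(m)
    locus = TwasLocus([f"GENE{i}" for i in range(m)], z, omega, label=label)
    locus.causal_genes = [f"GENE{i}" for i in causal_genes]
    return locus


# ---------------------------------------------------------------------------
# annotations, gene-sets and drug maps over a synthetic panel


def make_gene_annotations(panel: LdPanel, snps_per_gene: int = 10) -> list[GeneAnnotation]:
    """Tile genes along the panel: consecutive runs of ``snps_per_gene``
    variants per gene, alternating strand."""
    v = panel.variants
    out = []
    gi = 0
    for _, grp in v.groupby(v.index // snps_per_gene, sort=True):
        out.append(GeneAnnotation(
            gene=f"G{gi:04d}", chrom=str(grp["chrom"].iloc[0]),
            start=int(grp["pos"].min()), end=int(grp["pos"].max()),
            strand="+" if gi % 2 == 0 else "-"))
        gi += 1
    return out


def make_gene_sets(genes: list[str], n_sets: int, set_size: int, seed: int = 0,
                   druggable: bool = True) -> list[GeneSet]:
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        members = list(rng.choice(genes, size=min(set_size, len(genes)), replace=False))
        sets.append(GeneSet(f"SET{i:04d}", members, source="synthetic", druggable=druggable))
    return sets


def make_drug_target_map(genes: list[str], n_drugs: int = 20,
                         targets_per_drug: int = 5, seed: int = 0,
                         focused_set: GeneSet | None = None) -> dict[str, list[str]]:
    """Random drug -> target maps; one optional drug aimed at a given set."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_drugs):
        out[f"drug{i:03d}"] = list(rng.choice(genes, size=min(targets_per_drug, len(genes)),
                                              replace=False))
    if focused_set is not None:
        k = min(targets_per_drug, len(focused_set.members))
        out["drug_focused"] = list(rng.choice(focused_set.members, size=k, replace=False))
    return out
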