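"""Shared GWAS data model and plumbing.

Summary statistics, LD reference panels, genotype dosages, gene annotations
and gene-sets, plus the operations every downstream stage leans on:
munging/reading, allele harmonization between two studies, greedy LD
clumping, SNP-to-gene annotation with strand-aware boundary extension, and
the Blom (inverse-rank normal) transformation.

All genomic spans are held internally as 1-based inclusive intervals; BED
input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: Conventional MHC exclusion interval on chromosome 6 (hg19-ish, configurable).
DEFAULT_MHC_SPAN = ("6", 25_000_000, 35_000_000)

#: Default column-name synonyms recognised when reading summary statistics.
COLUMN_SYNONYMS = {
    "snp": ["snp", "id", "rsid", "markername", "variant_id"],
    "chrom": ["chr", "chrom", "chromosome"],
    "pos": ["bp", "pos", "position", "base_pair_location"],
    "a1": ["a1", "ea", "effect_allele", "allele1"],
    "a2": ["a2", "oa", "nea", "other_allele", "allele2", "a0"],
    "beta": ["beta", "b", "effect", "effect_size"],
    "se": ["se", "stderr", "standard_error"],
    "z": ["z", "zscore", "z_score", "stat"],
    "p": ["p", "pval", "pvalue", "p_value"],
    "n": ["n", "nobs", "sample_size", "neff"],
    "maf": ["maf", "frq", "freq", "eaf", "af"],
}

SUMSTAT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf", "beta", "se", "z", "p", "n"]


class FormatError(ValueError):
    """Raised when an input file is missing mandatory columns or malformed."""


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP; ``a1`` is the effect allele."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    maf: float = np.nan

    def __post_init__(self):
        if self.a1 == self.a2:
            raise ValueError(f"{self.id}: effect and other allele identical")
        if self.a1 not in VALID_ALLELES or self.a2 not in VALID_ALLELES:
            raise ValueError(f"{self.id}: alleles must be in {{A,C,G,T}}")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")

    @property
    def palindromic(self) -> bool:
        return (self.a1, self.a2) in PALINDROMIC_PAIRS


class SumStats:
    """Per-SNP marginal GWAS results for one trait.

    Thin wrapper over a DataFrame with columns ``snp, chrom, pos, a1, a2,
    maf, beta, se, z, p, n``.  ``z`` is filled from ``beta/se`` when absent
    and checked for consistency when both are present.
    """

    def __init__(self, df: pd.DataFrame, trait: str = ""):
        df = df.copy().reset_index(drop=True)
        for col in SUMSTAT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        if df["z"].isna().all() and df[["beta", "se"]].notna().all(axis=None):
            df["z"] = df["beta"] / df["se"]
        both = df["z"].notna() & df["beta"].notna() & df["se"].notna()
        if both.any():
            dev = np.abs(df.loc[both, "z"] - df.loc[both, "beta"] / df.loc[both, "se"])
            if (dev > 1e-6).any():
                raise ValueError("z inconsistent with beta/se")
        if df["snp"].duplicated().any():
            raise ValueError("duplicate variant ids in summary statistics")
        p = df["p"].dropna()
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        n = df["n"].dropna()
        if (n <= 0).any():
            raise ValueError("sample sizes must be positive")
        self.df = df[SUMSTAT_COLUMNS]
        self.trait = trait

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SumStats({self.trait or 'unnamed'}, {len(self)} variants)"

    @property
    def snp(self) -> pd.Series:
        return self.df["snp"]

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.df["n"].to_numpy(float)

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(float)

    def subset(self, mask) -> "SumStats":
        return SumStats(self.df[mask], trait=self.trait)


@dataclass
class LdBlock:
    """One LD block: variant ids plus their correlation matrix r."""

    ids: list
    r: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r, float)
        if r.shape != (len(self.ids), len(self.ids)):
            raise ValueError("correlation matrix shape does not match id list")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-6):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.abs(r).max() > 1 + 1e-8:
            raise ValueError("|r| entries must be <= 1")
        self.r = r


class LdPanel:
    """Block-diagonal SNP correlation reference.

    Correlation between variants in different blocks is defined as zero.
    A small ridge is applied to each block diagonal before any inversion
    elsewhere; the stored matrices are the raw correlations.
    """

    def __init__(self, blocks: list[LdBlock], provenance: str = ""):
        self.blocks = list(blocks)
        self.provenance = provenance
        self._index: dict[str, tuple[int, int]] = {}
        for bi, blk in enumerate(self.blocks):
            for vi, vid in enumerate(blk.ids):
                if vid in self._index:
                    raise ValueError(f"variant {vid} appears in more than one block")
                self._index[vid] = (bi, vi)

    @property
    def variant_ids(self) -> list[str]:
        return [vid for blk in self.blocks for vid in blk.ids]

    def __contains__(self, vid: str) -> bool:
        return vid in self._index

    def __len__(self) -> int:
        return len(self._index)

    def r(self, id_a: str, id_b: str) -> float:
        """Pairwise correlation; 0 across blocks, error for unknown ids."""
        ba, ia = self._index[id_a]
        bb, ib = self._index[id_b]
        if ba != bb:
            return 0.0
        return float(self.blocks[ba].r[ia, ib])

    def r2(self, id_a: str, id_b: str) -> float:
        return self.r(id_a, id_b) ** 2

    def block_of(self, vid: str) -> int:
        return self._index[vid][0]

    def submatrix(self, ids: list[str], missing: str = "error") -> np.ndarray:
        """Correlation matrix for ``ids`` (block-diagonal fill, 0 across blocks).

        ``missing='independent'`` treats ids absent from the panel as
        uncorrelated with everything (with a warning), mirroring the
        behaviour downstream gene statistics need.
        """
        k = len(ids)
        out = np.eye(k)
        locs = []
        for vid in ids:
            if vid in self._index:
                locs.append(self._index[vid])
            elif missing == "independent":
                warnings.warn(f"variant {vid} absent from LD panel; treated as independent")
                locs.append(None)
            else:
                raise KeyError(f"variant {vid} absent from LD panel")
        for i in range(k):
            for j in range(i + 1, k):
                if locs[i] is None or locs[j] is None:
                    continue
                bi, vi = locs[i]
                bj, vj = locs[j]
                if bi == bj:
                    out[i, j] = out[j, i] = self.blocks[bi].r[vi, vj]
        return out


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x variants), values in [0, 2], NaN = missing.

    ``a1`` records the counted (effect) allele per SNP so scores can
    reconcile orientation; ``a2`` the other allele.
    """

    individuals: list
    snps: list
    a1: list
    a2: list
    dosage: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dosage, float)
        if d.shape != (len(self.individuals), len(self.snps)):
            raise ValueError("dosage shape does not match id lists")
        with np.errstate(invalid="ignore"):
            bad = (d < 0) | (d > 2)
        if np.nansum(bad) > 0:
            raise ValueError("dosages must lie in [0, 2] or be NaN")
        self.dosage = d


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's span, 1-based inclusive. Strand drives asymmetric extension."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be '+' or '-'")


def read_gene_annotations_bed(path) -> list[GeneAnnotation]:
    """Read gene spans from BED (chrom, start, end, name, score, strand).

    BED is 0-based half-open; converted to 1-based inclusive.
    Genes with unknown strand are skipped with a warning.
    """
    out = []
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    for row in df.itertuples(index=False):
        strand = str(row[5]) if len(row) > 5 else "?"
        if strand not in ("+", "-"):
            warnings.warn(f"gene {row[3]}: unknown strand; skipped")
            continue
        out.append(GeneAnnotation(str(row[3]), str(row[0]).removeprefix("chr"),
                                  int(row[1]) + 1, int(row[2]), strand))
    return out


@dataclass
class GeneSet:
    name: str
    members: list
    source: str = ""
    druggable: bool = False

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene-set {self.name}: empty member list")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene-set {self.name}: duplicate members")


def read_gene_sets_gmt(path, tclin_genes=None) -> list[GeneSet]:
    """Read GMT gene-sets; flag druggable sets (>= 1 T_Clin member)."""
    tclin = set(tclin_genes or [])
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            members = [g for g in parts[2:] if g]
            # de-duplicate preserving order
            members = list(dict.fromkeys(members))
            sets.append(GeneSet(parts[0], members, source=parts[1],
                                druggable=bool(tclin & set(members))))
    return sets


# ---------------------------------------------------------------------------
# munging


def _resolve_columns(columns, synonyms) -> dict:
    lower = {c.lower(): c for c in columns}
    mapping = {}
    for canon, alts in synonyms.items():
        for alt in alts:
            if alt in lower:
                mapping[canon] = lower[alt]
                break
    return mapping


def read_sumstats(
    path,
    maf_min: float | None = 0.01,
    mhc_exclude: bool = False,
    mhc_span: tuple = DEFAULT_MHC_SPAN,
    synonyms: dict | None = None,
    trait: str = "",
) -> SumStats:
    """Read and munge a whitespace/tab-delimited summary-statistics file.

    Cleaning mirrors standard practice for LD-score-regression inputs:
    rows with invalid alleles are rejected (and counted), rare variants
    below ``maf_min`` dropped, the MHC region optionally excluded, and z
    computed from beta/se when absent.
    """
    syn = dict(COLUMN_SYNONYMS)
    if synonyms:
        for k, v in synonyms.items():
            syn[k] = list(v) + syn.get(k, [])
    raw = pd.read_csv(path, sep=r"\s+")
    mapping = _resolve_columns(raw.columns, syn)
    missing = {"snp", "a1", "a2", "p"} - set(mapping)
    if missing:
        raise FormatError(f"missing mandatory columns: {sorted(missing)}")
    df = pd.DataFrame({canon: raw[col] for canon, col in mapping.items()})
    n0 = len(df)
    drops: dict[str, int] = {}

    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
    ok = df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES) & (df["a1"] != df["a2"])
    drops["invalid_alleles"] = int((~ok).sum())
    df = df[ok]

    if maf_min is not None and "maf" in df.columns and df["maf"].notna().any():
        maf = np.minimum(df["maf"].astype(float), 1 - df["maf"].astype(float))
        df = df.assign(maf=maf)
        keep = df["maf"] > maf_min
        drops["maf"] = int((~keep).sum())
        df = df[keep]

    if mhc_exclude:
        chrom, lo, hi = mhc_span
        if {"chrom", "pos"} <= set(df.columns):
            in_mhc = (df["chrom"].astype(str).str.removeprefix("chr") == str(chrom)) & \
                df["pos"].astype(float).between(lo, hi)
            drops["mhc"] = int(in_mhc.sum())
            df = df[~in_mhc]

    log.info("read_sumstats(%s): %d rows in, %d retained, drops=%s", path, n0, len(df), drops)
    ss = SumStats(df, trait=trait)
    ss.munge_report = {"rows_in": n0, "rows_out": len(df), "drops": drops}
    return ss


# ---------------------------------------------------------------------------
# harmonization


def harmonize_pair(a: SumStats, b: SumStats, drop_palindromic: bool = False):
    """Align two studies to a common effect allele on shared variants.

    b's effects are sign-flipped where its effect allele equals a's other
    allele; A/T and C/G (strand-ambiguous) variants optionally dropped;
    variants with irreconcilable allele sets dropped and counted.

    Returns ``(a_shared, b_aligned, report)``.
    """
    da = a.df.set_index("snp")
    db = b.df.set_index("snp")
    shared = da.index.intersection(db.index)
    if len(shared) == 0:
        warnings.warn("harmonize_pair: no shared variants")
    flips = drops_pal = drops_mismatch = 0
    keep, flip_mask = [], []
    for vid in shared:
        a1a, a2a = da.at[vid, "a1"], da.at[vid, "a2"]
        a1b, a2b = db.at[vid, "a1"], db.at[vid, "a2"]
        if drop_palindromic and (a1a, a2a) in PALINDROMIC_PAIRS:
            drops_pal += 1
            continue
        if (a1b, a2b) == (a1a, a2a):
            keep.append(vid)
            flip_mask.append(False)
        elif (a1b, a2b) == (a2a, a1a):
            keep.append(vid)
            flip_mask.append(True)
            flips += 1
        else:
            drops_mismatch += 1
    out_a = da.loc[keep].reset_index()
    out_b = db.loc[keep].reset_index()
    flip = np.asarray(flip_mask, bool) if keep else np.zeros(0, bool)
    for col in ("beta", "z"):
        vals = out_b[col].to_numpy(float)
        vals[flip] = -vals[flip]
        out_b[col] = vals
    out_b.loc[flip, ["a1", "a2"]] = out_a.loc[flip, ["a1", "a2"]].to_numpy()
    mafb = out_b["maf"].to_numpy(float)
    mafb[flip] = 1 - mafb[flip]
    out_b["maf"] = np.minimum(mafb, 1 - mafb) if np.isfinite(mafb).any() else mafb
    report = {"shared": len(shared), "kept": len(keep), "flipped": flips,
              "dropped_palindromic": drops_pal, "dropped_mismatch": drops_mismatch}
    return SumStats(out_a, trait=a.trait), SumStats(out_b, trait=b.trait), report


# ---------------------------------------------------------------------------
# LD clumping


def ld_clump(
    ss: SumStats,
    ld: LdPanel,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy p-value-ordered LD clumping.

    Variants are visited in ascending p; a variant is accepted iff its r^2
    with every previously accepted variant within ``window_kb`` is below
    ``r2_thresh``.  Variants absent from the panel are dropped with a
    warning.  Output is guaranteed pairwise r^2 < threshold (cross-block
    r is 0 by construction).
    """
    df = ss.df[ss.df["p"] < p_thresh].copy()
    absent = ~df["snp"].isin(ld._index)
    if absent.any():
        warnings.warn(f"ld_clump: {int(absent.sum())} variants absent from LD panel; dropped")
        df = df[~absent]
    if df.empty:
        return []
    df = df.sort_values(["p", "snp"], kind="mergesort")
    accepted: list[str] = []
    acc_pos: list[tuple[str, float]] = []
    win = window_kb * 1000.0
    for row in df.itertuples(index=False):
        rchrom, rpos = str(row.chrom), float(row.pos)
        ok = True
        for prev, (pchrom, ppos) in zip(accepted, acc_pos):
            if np.isfinite(ppos) and np.isfinite(rpos):
                # outside the window (or other chromosome): exempt from the r2 check
                if pchrom != rchrom or abs(ppos - rpos) > win:
                    continue
            if ld.r2(prev, row.snp) >= r2_thresh:
                ok = False
                break
        if ok:
            accepted.append(row.snp)
            acc_pos.append((rchrom, rpos))
    return accepted


# ---------------------------------------------------------------------------
# SNP-to-gene annotation

#: (upstream, downstream) boundary extensions in bp, 5' / 3' of the strand.
BOUNDARY_EXTENSIONS = {"conservative": (5_000, 1_500), "liberal": (35_000, 10_000)}


def annotate_snps_to_genes(
    ss: SumStats,
    annotations: list[GeneAnnotation],
    boundary: str = "conservative",
) -> dict[str, list[str]]:
    """Map SNPs to genes within strand-aware extended gene bodies.

    "Upstream" means 5' of the coding strand, so for minus-strand genes the
    numeric directions swap (the upstream extension grows the ``end``
    coordinate).  Extended intervals are closed; a SNP may map to several
    genes.  Returns gene -> list of variant ids.
    """
    if boundary not in BOUNDARY_EXTENSIONS:
        raise ValueError(f"boundary must be one of {sorted(BOUNDARY_EXTENSIONS)}")
    up, down = BOUNDARY_EXTENSIONS[boundary]
    df = ss.df
    chroms = df["chrom"].astype(str).to_numpy()
    pos = df["pos"].to_numpy(float)
    snps = df["snp"].to_numpy()
    out: dict[str, list[str]] = {}
    for g in annotations:
        if g.strand == "+":
            lo, hi = g.start - up, g.end + down
        else:
            lo, hi = g.start - down, g.end + up
        mask = (chroms == g.chrom) & (pos >= lo) & (pos <= hi)
        if mask.any():
            out[g.gene] = list(snps[mask])
    return out


# ---------------------------------------------------------------------------
# rank-based normalisation


def blom_transform(values) -> np.ndarray:
    """Inverse-rank normal (Blom) transformation.

    Maps ranks to normal quantiles via ``Phi^-1((rank - 3/8) / (n + 1/4))``.
    Ties receive their average rank; missing values propagate as NaN.
    """
    x = np.asarray(values, float)
    out = np.full_like(x, np.nan)
    mask = np.isfinite(x)
    v = x[mask]
    if len(v) < 3:
        raise ValueError("blom_transform requires >= 3 non-missing values")
    if np.ptp(v) == 0:
        raise ValueError("blom_transform undefined for constant input")
    ranks = stats.rankdata(v, method="average")
    out[mask] = stats.norm.ppf((ranks - 3.0 / 8.0) / (len(v) + 0.25))
    return out
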