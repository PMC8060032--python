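"""Two-sample Mendelian randomisation with a full sensitivity suite.

Instruments are genome-wide-significant, mutually independent variants for
the exposure (p < 5e-8, r^2 < 0.001, palindromic SNPs removed), harmonized
against the outcome study.  Estimators: inverse-variance-weighted with
multiplicative random effects (the primary model), the weighted median
(robust to <50% invalid instruments), and MR-Egger (intercept = average
directional pleiotropy).  Diagnostics: Cochran's Q heterogeneity, the
Steiger directionality test, leave-one-out re-estimation, and a
simulation-based global pleiotropy test in the spirit of MR-PRESSO.

Causal effects are in outcome SD units per unit of exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import LdPanel, SumStats, harmonize_pair, ld_clump

__all__ = [
    "IvSet",
    "MrEstimate",
    "select_instruments",
    "mr_ivw",
    "mr_weighted_median",
    "mr_egger",
    "mr_steiger",
    "mr_leave_one_out",
    "presso_global",
]


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    p: float
    k: int
    Q: float = np.nan
    Q_df: int = 0
    Q_p: float = np.nan
    intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_p: float = np.nan

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


class IvSet:
    """Harmonized instruments: exposure (bx, se_x) and outcome (by, se_y) effects."""

    COLUMNS = ["snp", "bx", "se_x", "by", "se_y", "n_x", "n_y"]

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        for col in ("n_x", "n_y"):
            if col not in df:
                df[col] = np.nan
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"IvSet missing columns: {sorted(missing)}")
        if len(df) < 1:
            raise ValueError("IvSet requires at least one instrument")
        if (df["se_x"].dropna() <= 0).any() or (df["se_y"] <= 0).any():
            raise ValueError("standard errors must be positive")
        self.df = df[self.COLUMNS]

    def __len__(self):
        return len(self.df)

    @classmethod
    def from_table(cls, path) -> "IvSet":
        """Load a pre-harmonized instrument table (TSV with snp, bx, se_x, by, se_y[, n_x, n_y]).

        Lets published per-instrument tables be re-analysed directly.
        """
        return cls(pd.read_csv(path, sep="\t"))

    def arrays(self):
        d = self.df
        return (d["bx"].to_numpy(float), d["se_x"].to_numpy(float),
                d["by"].to_numpy(float), d["se_y"].to_numpy(float))

    def drop(self, i: int) -> "IvSet":
        return IvSet(self.df.drop(self.df.index[i]))


def select_instruments(
    exposure: SumStats,
    outcome: SumStats,
    ld: LdPanel,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.001,
    window_kb: float = 250.0,
) -> IvSet:
    """Build the instrument set: clump the exposure, drop palindromic SNPs,
    and harmonize outcome effects to the exposure's effect alleles."""
    keep = ld_clump(exposure, ld, p_thresh=p_thresh, r2_thresh=r2_thresh, window_kb=window_kb)
    if not keep:
        raise ValueError("no instruments survive the significance threshold")
    exp_sub = exposure.subset(exposure.df["snp"].isin(keep))
    ex, out, _ = harmonize_pair(exp_sub, outcome, drop_palindromic=True)
    if len(ex) == 0:
        raise ValueError("no instruments survive harmonization")
    df = pd.DataFrame({
        "snp": ex.df["snp"], "bx": ex.df["beta"], "se_x": ex.df["se"],
        "by": out.df["beta"], "se_y": out.df["se"],
        "n_x": ex.df["n"], "n_y": out.df["n"],
    })
    return IvSet(df)


def mr_ivw(iv: IvSet, random_effects: bool = True) -> MrEstimate:
    """Inverse-variance-weighted estimate (weighted regression through the
    origin); multiplicative random effects scale the SE by
    max(1, sqrt(Q/(k-1))), never deflating below the fixed-effect SE."""
    k = len(iv)
    if k < 2:
        raise ValueError("IVW requires >= 2 instruments")
    bx, _, by, se_y = iv.arrays()
    w = 1.0 / se_y ** 2
    sxx = (w * bx * bx).sum()
    beta = (w * bx * by).sum() / sxx
    var_fixed = 1.0 / sxx
    Q = float((w * (by - beta * bx) ** 2).sum())
    q_df = k - 1
    scale = max(1.0, np.sqrt(Q / q_df)) if random_effects else 1.0
    se = float(np.sqrt(var_fixed) * scale)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MrEstimate("IVW-MRE" if random_effects else "IVW-FE", float(beta), se, p, k,
                      Q=Q, Q_df=q_df, Q_p=float(stats.chi2.sf(Q, q_df)))


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight midpoint interpolation at probability 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def mr_weighted_median(iv: IvSet, n_boot: int = 1000, seed: int | np.random.Generator = 0) -> MrEstimate:
    """Weighted median of per-instrument Wald ratios; precision upweights
    the ratios, and the SE comes from a seeded parametric bootstrap."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bx, se_x, by, se_y = iv.arrays()
    nonzero = bx != 0
    if not nonzero.all():
        import warnings
        warnings.warn(f"{int((~nonzero).sum())} instruments with bx = 0 dropped")
    bx, se_x, by, se_y = bx[nonzero], se_x[nonzero], by[nonzero], se_y[nonzero]
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median requires >= 3 usable instruments")
    if np.isnan(se_x).any():
        se_x = np.zeros_like(bx)

    def wm(bx_, by_):
        ratios = by_ / bx_
        var = se_y ** 2 / bx_ ** 2 + by_ ** 2 * se_x ** 2 / bx_ ** 4  # delta method
        return _weighted_median(ratios, 1.0 / var)

    beta = wm(bx, by)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_s = bx + se_x * rng.standard_normal(k)
        by_s = by + se_y * rng.standard_normal(k)
        bx_s[bx_s == 0] = np.finfo(float).tiny
        boots[i] = wm(bx_s, by_s)
    se = float(boots.std(ddof=1))
    p = float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else (0.0 if beta else 1.0)
    return MrEstimate("weighted-median", float(beta), se, p, k)


def mr_egger(iv: IvSet) -> MrEstimate:
    """MR-Egger: WLS of by on bx with an intercept capturing average
    directional pleiotropy.  Instruments are oriented so bx > 0; inference
    is t with k-2 df; residual SD floored at 1 (random-effects convention)."""
    k = len(iv)
    if k < 3:
        raise ValueError("MR-Egger requires >= 3 instruments")
    bx, _, by, se_y = iv.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise ValueError("no spread in exposure effects after orientation")
    w = 1.0 / se_y ** 2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    df_resid = k - 2
    sigma2 = float((w * resid ** 2).sum() / df_resid)
    cov_unscaled = np.linalg.inv(xtx)
    ses = np.sqrt(np.diag(cov_unscaled) * sigma2)
    ses = ses / min(1.0, np.sqrt(sigma2))  # never report below the fixed-effect SE
    t_slope = coef[1] / ses[1]
    t_int = coef[0] / ses[0]
    return MrEstimate(
        "MR-Egger", float(coef[1]), float(ses[1]),
        float(2 * stats.t.sf(abs(t_slope), df_resid)), k,
        intercept=float(coef[0]), intercept_se=float(ses[0]),
        intercept_p=float(2 * stats.t.sf(abs(t_int), df_resid)),
    )


def mr_steiger(iv: IvSet) -> dict:
    """Directionality check: do the instruments explain more variance in
    the exposure than in the outcome?

    Per-instrument variance explained uses r^2 ~ z^2/(z^2 + n) (an
    approximation needing no allele frequencies); the difference of the
    Fisher-transformed aggregate correlations gives the p-value.
    """
    d = iv.df
    if d["n_x"].isna().any() or d["n_y"].isna().any():
        raise ValueError("Steiger test requires per-instrument sample sizes")
    bx, se_x, by, se_y = iv.arrays()
    if np.isnan(se_x).any():
        raise ValueError("Steiger test requires exposure standard errors")
    zx = bx / se_x
    zy = by / se_y
    nx = d["n_x"].to_numpy(float)
    ny = d["n_y"].to_numpy(float)
    r2x = float((zx ** 2 / (zx ** 2 + nx)).sum())
    r2y = float((zy ** 2 / (zy ** 2 + ny)).sum())
    rx = np.sqrt(min(r2x, 1 - 1e-12))
    ry = np.sqrt(min(r2y, 1 - 1e-12))
    se_diff = np.sqrt(1.0 / (nx.mean() - 3) + 1.0 / (ny.mean() - 3))
    zdiff = (np.arctanh(rx) - np.arctanh(ry)) / se_diff
    return {
        "verdict": "exposure->outcome" if r2x > r2y else "outcome->exposure",
        "correct_direction": r2x > r2y,
        "r2_exposure": r2x,
        "r2_outcome": r2y,
        "p": float(2 * stats.norm.sf(abs(zdiff))),
    }


def mr_leave_one_out(iv: IvSet, alpha: float = 0.05) -> pd.DataFrame:
    """Recompute IVW-MRE k times, each omitting one instrument.

    Flags instruments whose removal changes significance at ``alpha``.
    """
    if len(iv) < 3:
        raise ValueError("leave-one-out requires >= 3 instruments")
    full = mr_ivw(iv)
    rows = []
    for i in range(len(iv)):
        est = mr_ivw(iv.drop(i))
        rows.append({
            "snp": iv.df["snp"].iloc[i], "beta": est.beta, "se": est.se, "p": est.p,
            "k": est.k, "significance_changed": (est.p < alpha) != (full.p < alpha),
        })
    return pd.DataFrame(rows)


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes via sufficient-statistic downdates."""
    sxy = (w * bx * by).sum()
    sxx = (w * bx * bx).sum()
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def presso_global(iv: IvSet, n_sim: int = 1000, seed: int | np.random.Generator = 0) -> dict:
    """Global pleiotropy test (MR-PRESSO style).

    The observed residual sum of squares uses leave-one-out slopes so each
    instrument is compared with a fit that excludes it; the null
    distribution comes from parametric simulation of the outcome effects
    under the fitted IVW model with the reported se_y noise.
    """
    k = len(iv)
    if k < 4:
        raise ValueError("global pleiotropy test requires >= 4 instruments")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bx, _, by, se_y = iv.arrays()
    w = 1.0 / se_y ** 2
    slopes = _loo_slopes(bx, by, w)
    rss_obs = float((w * (by - slopes * bx) ** 2).sum())

    beta_full = (w * bx * by).sum() / (w * bx * bx).sum()
    expected = beta_full * bx  # simulate under the fitted IVW model
    sims = expected[None, :] + se_y[None, :] * rng.standard_normal((n_sim, k))
    sxy = (w * bx * sims).sum(axis=1, keepdims=True)
    sxx = (w * bx * bx).sum()
    loo_sl = (sxy - w * bx * sims) / (sxx - w * bx * bx)
    rss_sim = ((sims - loo_sl * bx) ** 2 * w).sum(axis=1)
    p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))
    return {"rss_obs": rss_obs, "p": p, "n_sim": n_sim}
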