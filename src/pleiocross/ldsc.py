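"""LD score regression: SNP heritability and cross-trait genetic correlation.

The regression model: for variant j with LD score l_j,

    E[chi2_j]      = 1 + N h2 l_j / M           (single trait)
    E[z1_j z2_j]   = rho_n + sqrt(N1 N2) gencov l_j / M   (trait pair)

where rho_n — the cross-trait intercept — absorbs sample overlap.  The
slope is estimated by weighted least squares with plug-in
heteroscedasticity weights refined over two iterations, and standard
errors come from a delete-one block jackknife over contiguous variant
blocks (contiguity respects LD).  Genetic correlation is
rg = gencov / sqrt(h2_1 h2_2), jackknifed as a ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference, liability_factor

logger = logging.getLogger(__name__)


def compute_ld_scores(
    panel: LDReference, window: int | None = None, positions: dict[str, int] | None = None
) -> pd.DataFrame:
    """Per-variant LD scores from a reference panel.

    l_j = sum over variants k in the same block (within ``window`` bp when
    positions are supplied) of the unbiased r-squared estimate
    r2_adj = r2 - (1 - r2) / (n_ref - 2); the self term is included.
    """
    if panel.n_ref <= 2:
        raise ValueError("LD score adjustment requires n_ref > 2")
    rows = []
    adj = 1.0 / (panel.n_ref - 2)
    for ids, R in panel.blocks:
        r2 = R**2
        r2_adj = r2 - (1.0 - r2) * adj
        if window is not None and positions is not None:
            pos = np.array([positions[v] for v in ids])
            mask = np.abs(pos[:, None] - pos[None, :]) <= window
            r2_adj = np.where(mask, r2_adj, 0.0)
        l = r2_adj.sum(axis=1)
        rows.append(pd.DataFrame({"snp": ids, "ld_score": l}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class H2Estimate:
    h2_obs: float
    h2_obs_se: float
    intercept: float
    intercept_se: float
    h2_liab: float | None
    z: float
    p: float
    n_snps: int
    constrained: bool

    @property
    def h2(self) -> float:
        return self.h2_liab if self.h2_liab is not None else self.h2_obs


@dataclass
class RgEstimate:
    rg: float
    se: float
    z: float
    p: float
    gencov: float
    gencov_se: float
    gencov_intercept: float
    gencov_intercept_se: float
    h2_1: float
    h2_2: float
    n_valid_snps: int
    constrained_intercept: bool
    flag: str = ""


def _block_edges(n: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, n, n_blocks + 1).astype(int)


def _wls_jackknife(x, y, w, n_blocks, constrain_intercept=None):
    """Weighted slope/intercept with delete-one-block jackknife.

    Returns (slope, slope_se, intercept, intercept_se, slopes_i, intercepts_i)
    where *_i are the delete-one estimates, computed from per-block
    sufficient statistics in O(n_blocks).
    """
    n = len(x)
    edges = _block_edges(n, n_blocks)
    labels = np.searchsorted(edges, np.arange(n), side="right") - 1
    g = n_blocks

    def sums(v):
        return np.bincount(labels, weights=v, minlength=g)

    if constrain_intercept is None:
        Sw, Sx, Sy = sums(w), sums(w * x), sums(w * y)
        Sxx, Sxy = sums(w * x * x), sums(w * x * y)
        tw, tx, ty, txx, txy = Sw.sum(), Sx.sum(), Sy.sum(), Sxx.sum(), Sxy.sum()

        def solve(a_w, a_x, a_y, a_xx, a_xy):
            den = a_w * a_xx - a_x**2
            slope = (a_w * a_xy - a_x * a_y) / den
            inter = (a_y - slope * a_x) / a_w
            return slope, inter

        slope, inter = solve(tw, tx, ty, txx, txy)
        slopes_i, inters_i = solve(tw - Sw, tx - Sx, ty - Sy, txx - Sxx, txy - Sxy)
    else:
        c = constrain_intercept
        Sxx, Sxy = sums(w * x * x), sums(w * x * (y - c))
        txx, txy = Sxx.sum(), Sxy.sum()
        slope = txy / txx
        slopes_i = (txy - Sxy) / (txx - Sxx)
        inter = c
        inters_i = np.full(g, c)

    def jk_se(theta_i):
        return np.sqrt((g - 1) / g * np.sum((theta_i - theta_i.mean()) ** 2))

    return slope, jk_se(slopes_i), inter, jk_se(inters_i), slopes_i, inters_i


def _filter_outliers(chi2, N):
    lim = max(80.0, 0.001 * float(np.median(N)))
    keep = chi2 <= lim
    n_out = int((~keep).sum())
    if n_out:
        logger.info("ldsc: excluded %d variants with chi2 > %.1f", n_out, lim)
    return keep


def estimate_h2(
    ss: pd.DataFrame,
    ld: pd.DataFrame,
    M: int | None = None,
    n_blocks: int = 200,
    constrain_intercept: float | None = None,
    prevalence: float | None = None,
) -> H2Estimate:
    """SNP heritability by LD score regression of chi-square on N l / M.

    Heteroscedasticity weights 1/(1 + N h2 l / M)^2 are refined over two
    iterations from an initial unweighted fit.  When the table carries
    case/control counts, the estimate is also reported on the liability
    scale using the sample case proportion and ``prevalence`` (defaulting,
    with a warning, to the sample proportion).
    """
    df = ss.merge(ld, on="snp")
    if len(df) < 200:
        raise ValueError("need at least 200 variants overlapping the LD scores")
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if M is None:
        M = len(df)
    df = df.sort_values(["chr", "pos"]).reset_index(drop=True)
    chi2 = df["z"].to_numpy() ** 2
    N = df["n"].to_numpy().astype(float)
    keep = _filter_outliers(chi2, N)
    chi2, N = chi2[keep], N[keep]
    l = df["ld_score"].to_numpy()[keep]
    if np.ptp(l) < 1e-12:
        raise ValueError("LD scores are constant; regression design is degenerate")
    x = N * l / M

    w = np.ones_like(x)
    for _ in range(2):
        slope = _wls_jackknife(x, chi2, w, n_blocks, constrain_intercept)[0]
        h2_hat = max(slope, 0.0)
        w = 1.0 / (1.0 + N * h2_hat * l / M) ** 2
    slope, slope_se, inter, inter_se, _, _ = _wls_jackknife(
        x, chi2, w, n_blocks, constrain_intercept
    )

    h2_liab = None
    if "n_cases" in ss.columns and ss["n_cases"].notna().any():
        n_cases = float(ss["n_cases"].iloc[0])
        n_controls = float(ss["n_controls"].iloc[0])
        P = n_cases / (n_cases + n_controls)
        K = prevalence
        if K is None:
            K = P
            logger.warning("estimate_h2: population prevalence not given; using sample P=%.3g", P)
        h2_liab = slope * liability_factor(P, K)

    z = slope / slope_se if slope_se > 0 else np.nan
    return H2Estimate(
        h2_obs=slope,
        h2_obs_se=slope_se,
        intercept=inter,
        intercept_se=inter_se,
        h2_liab=h2_liab,
        z=z,
        p=2 * stats.norm.sf(abs(z)),
        n_snps=int(keep.sum()),
        constrained=constrain_intercept is not None,
    )


def estimate_rg(
    pair: pd.DataFrame,
    ld: pd.DataFrame,
    M: int | None = None,
    n_blocks: int = 200,
    constrain_gencov_intercept: bool = False,
    constrain_h2_intercepts: bool = False,
) -> RgEstimate:
    """Cross-trait genetic correlation from a harmonized pair table.

    Regresses z1 z2 on sqrt(N1 N2) l / M; the slope is the genetic
    covariance and the free intercept absorbs sample-overlap confounding
    (it can be constrained to 0 for non-overlapping cohorts).  The rg
    ratio and its standard error come from a joint delete-one block
    jackknife over the two heritability slopes and the covariance slope.
    """
    df = pair.merge(ld, on="snp")
    if len(df) < 200:
        raise ValueError("need at least 200 variants overlapping the LD scores")
    if M is None:
        M = len(df)
    df = df.sort_values(["chr", "pos"]).reset_index(drop=True)
    z1 = df["z_1"].to_numpy()
    z2 = df["z_2"].to_numpy()
    N1 = df["n_1"].to_numpy().astype(float)
    N2 = df["n_2"].to_numpy().astype(float)
    keep = _filter_outliers(z1**2, N1) & _filter_outliers(z2**2, N2)
    z1, z2, N1, N2 = z1[keep], z2[keep], N1[keep], N2[keep]
    l = df["ld_score"].to_numpy()[keep]
    n = len(l)

    h2_c = 1.0 if constrain_h2_intercepts else None
    x1 = N1 * l / M
    x2 = N2 * l / M
    xg = np.sqrt(N1 * N2) * l / M

    # two-step weights for each of the three regressions
    def refit(x, y, constrain):
        w = np.ones(n)
        est = 0.0
        for _ in range(2):
            s = _wls_jackknife(x, y, w, n_blocks, constrain)[0]
            est = max(s, 0.0)
            w = 1.0 / (1.0 + x * est) ** 2
        return w

    w1 = refit(x1, z1**2, h2_c)
    w2 = refit(x2, z2**2, h2_c)
    h1_s, _, _, _, h1_i, _ = _wls_jackknife(x1, z1**2, w1, n_blocks, h2_c)
    h2_s, _, _, _, h2_i, _ = _wls_jackknife(x2, z2**2, w2, n_blocks, h2_c)

    gc_c = 0.0 if constrain_gencov_intercept else None
    y = z1 * z2
    wg = np.ones(n)
    for _ in range(2):
        g_s, _, g_int, _, _, _ = _wls_jackknife(xg, y, wg, n_blocks, gc_c)
        het1 = 1.0 + x1 * max(h1_s, 0.0)
        het2 = 1.0 + x2 * max(h2_s, 0.0)
        wg = 1.0 / (het1 * het2 + (xg * g_s + g_int) ** 2)
    g_s, g_se, g_int, g_int_se, g_i, _ = _wls_jackknife(xg, y, wg, n_blocks, gc_c)

    flag = ""
    if h1_s <= 0 or h2_s <= 0:
        flag = "nonpositive h2 point estimate; rg undefined"
        rg = np.nan
        rg_se = np.nan
    else:
        rg = g_s / np.sqrt(h1_s * h2_s)
        ok = (h1_i > 0) & (h2_i > 0)
        rg_i = g_i[ok] / np.sqrt(h1_i[ok] * h2_i[ok])
        g = len(rg_i)
        rg_se = np.sqrt((g - 1) / g * np.sum((rg_i - rg_i.mean()) ** 2))
        if abs(rg) > 1:
            logger.warning("estimate_rg: |rg| = %.3f exceeds 1", rg)
    z = rg / rg_se if rg_se and np.isfinite(rg_se) and rg_se > 0 else np.nan
    return RgEstimate(
        rg=rg,
        se=rg_se,
        z=z,
        p=2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
        gencov=g_s,
        gencov_se=g_se,
        gencov_intercept=g_int,
        gencov_intercept_se=g_int_se,
        h2_1=h1_s,
        h2_2=h2_s,
        n_valid_snps=n,
        constrained_intercept=constrain_gencov_intercept,
        flag=flag,
    )
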