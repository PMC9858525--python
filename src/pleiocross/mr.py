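"""Two-sample Mendelian randomisation estimators and diagnostics.

Instruments are LD-independent (r^2 < 0.1) genome-wide-significant
variants for the exposure, harmonized against the outcome GWAS; when too
few reach 5e-8 a configurable fallback threshold (1e-5) is used.  The
estimators: inverse-variance-weighted (IVW) regression through the
origin with multiplicative random-effects inflation, weighted median
with bootstrap standard error, MR-Egger with its intercept as the
directional-pleiotropy test, a PRESSO-style residual-sum global/outlier
test, leave-one-out IVW, and a HEIDI-filtered exposure-error-aware IVW
in the spirit of GSMR.  Running both trait orderings gives the
bidirectional analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .meta import ld_clump
from .sumstats import LDReference

logger = logging.getLogger(__name__)


class InstrumentError(ValueError):
    """Raised when an estimator cannot run on the available instruments."""


@dataclass
class InstrumentSet:
    """Harmonized instrument effects: exposure (zx) and outcome (zy) sides."""

    snp: np.ndarray
    b_zx: np.ndarray
    se_zx: np.ndarray
    b_zy: np.ndarray
    se_zy: np.ndarray
    fallback_used: bool = False

    def __post_init__(self):
        for arr in (self.b_zx, self.se_zx, self.b_zy, self.se_zy):
            if len(arr) != len(self.snp):
                raise ValueError("instrument arrays must be aligned")
        if np.any(self.se_zx <= 0) or np.any(self.se_zy <= 0):
            raise ValueError("instrument standard errors must be positive")

    def __len__(self):
        return len(self.snp)

    def oriented(self) -> "InstrumentSet":
        """Copy with alleles oriented so every exposure effect is >= 0."""
        s = np.where(self.b_zx < 0, -1.0, 1.0)
        return InstrumentSet(
            self.snp, self.b_zx * s, self.se_zx, self.b_zy * s, self.se_zy, self.fallback_used
        )

    def drop(self, idx) -> "InstrumentSet":
        keep = np.ones(len(self), bool)
        keep[np.asarray(idx, int)] = False
        return InstrumentSet(
            self.snp[keep], self.b_zx[keep], self.se_zx[keep],
            self.b_zy[keep], self.se_zy[keep], self.fallback_used,
        )


@dataclass
class MRResult:
    method: str
    beta: float
    se: float
    p: float
    n_instruments: int
    q: float | None = None
    q_p: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    global_p: float | None = None
    global_p_at_floor: bool = False
    outliers: list[int] = field(default_factory=list)
    corrected_beta: float | None = None
    corrected_se: float | None = None
    corrected_p: float | None = None
    extra: dict = field(default_factory=dict)

    def format_p(self) -> str:
        """PRESSO-style display: '< floor' when the global p sits at its floor."""
        if self.global_p is None:
            return ""
        if self.global_p_at_floor:
            return f"< {self.global_p:.2e}"
        return f"{self.global_p:.3g}"


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDReference,
    p_thresh: float = 5e-8,
    fallback_p: float | None = 1e-5,
    min_instruments: int = 3,
    r2_lead: float = 0.1,
) -> InstrumentSet:
    """LD-independent exposure-significant instruments present in both GWAS.

    ``exposure``/``outcome`` are *harmonized* single-trait tables sharing
    variant keys (use :func:`pleiocross.sumstats.harmonize_pair` and split,
    or pass the suffixed pair columns via :func:`instruments_from_pair`).
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))

    def pick(log_thresh):
        cand = merged.loc[merged["log_p_x"] < log_thresh]
        if len(cand) == 0:
            return cand
        clump = ld_clump(
            cand.rename(columns={"log_p_x": "log_p", "pos_x": "pos"})[["snp", "pos", "log_p"]],
            ld,
            r2_lead=r2_lead,
        )
        return cand.loc[cand["snp"].isin(clump.leads)]

    sel = pick(np.log(p_thresh))
    fallback_used = False
    if len(sel) < min_instruments and fallback_p is not None:
        sel = pick(np.log(fallback_p))
        fallback_used = True
        logger.info("select_instruments: fallback threshold %.1e used (%d instruments)", fallback_p, len(sel))
    if len(sel) < 2:
        raise InstrumentError(
            f"only {len(sel)} LD-independent instrument(s) available "
            f"(p < {p_thresh:g}, fallback {fallback_p}); need at least 2"
        )
    return InstrumentSet(
        snp=sel["snp"].to_numpy(),
        b_zx=sel["beta_x"].to_numpy(float),
        se_zx=sel["se_x"].to_numpy(float),
        b_zy=sel["beta_y"].to_numpy(float),
        se_zy=sel["se_y"].to_numpy(float),
        fallback_used=fallback_used,
    )


def instruments_from_pair(
    pair: pd.DataFrame, ld: LDReference, exposure: int = 1, **kwargs
) -> InstrumentSet:
    """Instrument selection from a harmonized pair table; ``exposure`` is 1 or 2."""
    x, y = (1, 2) if exposure == 1 else (2, 1)
    expo = pd.DataFrame(
        {"snp": pair["snp"], "pos": pair["pos"], "beta": pair[f"beta_{x}"],
         "se": pair[f"se_{x}"], "log_p": pair[f"log_p_{x}"]}
    )
    outc = pd.DataFrame(
        {"snp": pair["snp"], "pos": pair["pos"], "beta": pair[f"beta_{y}"],
         "se": pair[f"se_{y}"], "log_p": pair[f"log_p_{y}"]}
    )
    return select_instruments(expo, outc, ld, **kwargs)


def wald_ratio(b_zx, se_zx, b_zy, se_zy):
    """Single-instrument causal estimate b_zy / b_zx with first-order se."""
    if b_zx == 0:
        raise InstrumentError("Wald ratio undefined for a null exposure effect")
    return b_zy / b_zx, se_zy / abs(b_zx)


def _ivw_fit(b_zx, se_zx, b_zy, se_zy):
    """Core IVW: slope through the origin, weights 1/se_zy^2."""
    w = 1.0 / se_zy**2
    beta = np.sum(w * b_zx * b_zy) / np.sum(w * b_zx**2)
    se_fixed = 1.0 / np.sqrt(np.sum(w * b_zx**2))
    k = len(b_zx)
    Q = float(np.sum(w * (b_zy - beta * b_zx) ** 2))
    if k > 1:
        se = se_fixed * max(1.0, np.sqrt(Q / (k - 1)))
    else:
        se = se_fixed
    return beta, se, Q


def mr_ivw(instr: InstrumentSet) -> MRResult:
    """Inverse-variance-weighted estimate (multiplicative random effects)."""
    if len(instr) < 2:
        raise InstrumentError("IVW needs at least 2 instruments")
    beta, se, Q = _ivw_fit(instr.b_zx, instr.se_zx, instr.b_zy, instr.se_zy)
    k = len(instr)
    z = beta / se
    return MRResult(
        method="ivw", beta=beta, se=se, p=2 * stats.norm.sf(abs(z)),
        n_instruments=k, q=Q, q_p=stats.chi2.sf(Q, k - 1),
    )


def mr_weighted_median(
    instr: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted median of Wald ratios; breakdown point 50% invalid weight."""
    if len(instr) < 3:
        raise InstrumentError("weighted median needs at least 3 instruments")

    def wmedian(ratios, weights):
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order]
        cum = np.cumsum(w) - 0.5 * w
        cum /= w.sum()
        return float(np.interp(0.5, cum, r))

    ratios = instr.b_zy / instr.b_zx
    weights = instr.b_zx**2 / instr.se_zy**2  # inverse variance of the ratio
    beta = wmedian(ratios, weights)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx = instr.b_zx + rng.standard_normal(len(instr)) * instr.se_zx
        by = instr.b_zy + rng.standard_normal(len(instr)) * instr.se_zy
        boots[b] = wmedian(by / bx, bx**2 / instr.se_zy**2)
    se = float(np.std(boots, ddof=1))
    z = beta / se
    return MRResult(
        method="weighted_median", beta=beta, se=se,
        p=2 * stats.norm.sf(abs(z)), n_instruments=len(instr),
    )


def mr_egger(instr: InstrumentSet) -> MRResult:
    """MR-Egger: weighted regression with a free intercept.

    Instruments are oriented to nonnegative exposure effects first; the
    intercept estimates directional pleiotropy and its t-test (k-2 df) is
    the pleiotropy diagnostic.
    """
    if len(instr) < 3:
        raise InstrumentError("MR-Egger needs at least 3 instruments")
    import statsmodels.api as sm

    o = instr.oriented()
    w = 1.0 / o.se_zy**2
    X = sm.add_constant(o.b_zx)
    fit = sm.WLS(o.b_zy, X, weights=w).fit()
    k = len(o)
    # multiplicative over-dispersion, floored at 1 as in the IVW estimator
    sigma = max(1.0, np.sqrt(fit.scale))
    se_slope = fit.bse[1] / np.sqrt(fit.scale) * sigma
    se_int = fit.bse[0] / np.sqrt(fit.scale) * sigma
    beta, intercept = fit.params[1], fit.params[0]
    t_slope = beta / se_slope
    t_int = intercept / se_int
    df = k - 2
    return MRResult(
        method="egger", beta=beta, se=se_slope,
        p=2 * stats.t.sf(abs(t_slope), df), n_instruments=k,
        intercept=intercept, intercept_se=se_int,
        intercept_p=2 * stats.t.sf(abs(t_int), df),
    )


def leave_one_out(instr: InstrumentSet) -> pd.DataFrame:
    """IVW re-estimated k times, each excluding one instrument."""
    if len(instr) < 3:
        raise InstrumentError("leave-one-out needs at least 3 instruments")
    rows = []
    for i in range(len(instr)):
        sub = instr.drop([i])
        beta, se, _ = _ivw_fit(sub.b_zx, sub.se_zx, sub.b_zy, sub.se_zy)
        rows.append({"excluded": instr.snp[i], "beta": beta, "se": se,
                     "p": 2 * stats.norm.sf(abs(beta / se))})
    return pd.DataFrame(rows)


def mr_presso(instr: InstrumentSet, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> MRResult:
    """PRESSO-style global residual-sum test with outlier correction.

    The observed statistic is the sum over instruments of the squared
    outcome residual from the IVW fit that excludes that instrument; its
    null distribution is simulated by redrawing outcome effects from the
    fitted model with the stated standard errors.  The global p is
    rank-based with floor 1/(n_sim+1) (reported as an inequality at the
    floor); per-instrument outlier p-values are Bonferroni-compared to
    ``outlier_alpha`` and the corrected estimate is IVW on non-outliers.
    """
    k = len(instr)
    if k < 4:
        raise InstrumentError("PRESSO global test needs at least 4 instruments")
    rng = np.random.default_rng(seed)

    def loo_rss(b_zy):
        w = 1.0 / instr.se_zy**2
        swxy = np.sum(w * instr.b_zx * b_zy)
        swxx = np.sum(w * instr.b_zx**2)
        beta_i = (swxy - w * instr.b_zx * b_zy) / (swxx - w * instr.b_zx**2)
        resid2 = (b_zy - beta_i * instr.b_zx) ** 2 / instr.se_zy**2
        return resid2

    obs_resid2 = loo_rss(instr.b_zy)
    obs = float(obs_resid2.sum())
    beta_full, _, _ = _ivw_fit(instr.b_zx, instr.se_zx, instr.b_zy, instr.se_zy)

    sim_stats = np.empty(n_sim)
    exceed = np.zeros(k)
    for s in range(n_sim):
        b_sim = beta_full * instr.b_zx + rng.standard_normal(k) * instr.se_zy
        r2 = loo_rss(b_sim)
        sim_stats[s] = r2.sum()
        exceed += r2 >= obs_resid2
    n_ge = int(np.sum(sim_stats >= obs))
    floor = 1.0 / (n_sim + 1)
    at_floor = n_ge == 0
    global_p = max(n_ge / n_sim, floor)

    outlier_p = exceed / n_sim  # unfloored: Bonferroni-compared below
    outliers = [int(i) for i in np.nonzero(outlier_p * k < outlier_alpha)[0]]

    res = MRResult(
        method="presso", beta=beta_full,
        se=_ivw_fit(instr.b_zx, instr.se_zx, instr.b_zy, instr.se_zy)[1],
        p=np.nan, n_instruments=k,
        global_p=global_p, global_p_at_floor=at_floor, outliers=outliers,
    )
    res.p = 2 * stats.norm.sf(abs(res.beta / res.se))
    if outliers and k - len(outliers) >= 2:
        sub = instr.drop(outliers)
        cb, cs, _ = _ivw_fit(sub.b_zx, sub.se_zx, sub.b_zy, sub.se_zy)
        res.corrected_beta, res.corrected_se = cb, cs
        res.corrected_p = 2 * stats.norm.sf(abs(cb / cs))
    return res


def _ratio_variances(instr: InstrumentSet):
    ratios = instr.b_zy / instr.b_zx
    var = instr.se_zy**2 / instr.b_zx**2 + instr.b_zy**2 * instr.se_zx**2 / instr.b_zx**4
    return ratios, var


def heidi_filtered_ivw(instr: InstrumentSet, heidi_p: float = 0.01) -> MRResult:
    """Exposure-error-aware IVW after HEIDI-style outlier removal.

    The reference causal estimate is the median Wald ratio among the
    low-variance half of the instruments; each instrument's deviation
    d_i = ratio_i - ratio_ref is tested with a delta-method standard
    error that includes the exposure-side error, and instruments with
    p(d_i) < ``heidi_p`` are removed before the weighted combination
    (weights 1 / var(ratio_i)).  ``heidi_p = 0`` disables the filter.
    """
    if len(instr) < 3:
        raise InstrumentError("HEIDI-filtered IVW needs at least 3 instruments")
    ratios, var = _ratio_variances(instr)
    order = np.argsort(var)
    low = order[: max(1, len(instr) // 2)]
    ref = float(np.median(ratios[low]))
    ref_var = float(np.median(var[low])) / len(low)
    d = ratios - ref
    se_d = np.sqrt(var + ref_var)
    p_d = 2 * stats.norm.sf(np.abs(d) / se_d)
    keep = p_d >= heidi_p
    removed = [int(i) for i in np.nonzero(~keep)[0]]
    if removed:
        logger.info("heidi_filtered_ivw: removed %d instrument(s)", len(removed))
    if keep.sum() < 2:
        raise InstrumentError("HEIDI filtering removed too many instruments")
    w = 1.0 / var[keep]
    beta = float(np.sum(w * ratios[keep]) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    return MRResult(
        method="heidi_ivw", beta=beta, se=se, p=2 * stats.norm.sf(abs(z)),
        n_instruments=int(keep.sum()), outliers=removed,
    )


METHODS = {
    "ivw": mr_ivw,
    "median": mr_weighted_median,
    "egger": mr_egger,
    "presso": mr_presso,
    "heidi-ivw": heidi_filtered_ivw,
}


def run_mr(
    pair: pd.DataFrame,
    ld: LDReference,
    methods=("ivw", "median", "egger", "presso", "heidi-ivw"),
    p_thresh: float = 5e-8,
    fallback_p: float | None = 1e-5,
    seed: int = 0,
    bidirectional: bool = True,
) -> pd.DataFrame:
    """Bidirectional MR over a harmonized pair; one row per method/direction."""
    rows = []
    directions = [(1, "1->2"), (2, "2->1")] if bidirectional else [(1, "1->2")]
    for expo, label in directions:
        try:
            instr = instruments_from_pair(
                pair, ld, exposure=expo, p_thresh=p_thresh, fallback_p=fallback_p
            )
        except InstrumentError as e:
            logger.warning("run_mr %s: %s", label, e)
            continue
        for name in methods:
            fn = METHODS[name]
            kwargs = {"seed": seed} if name in ("median", "presso") else {}
            try:
                r = fn(instr, **kwargs)
            except InstrumentError as e:
                logger.warning("run_mr %s/%s: %s", label, name, e)
                continue
            rows.append(
                {
                    "direction": label, "method": r.method, "beta": r.beta,
                    "se": r.se, "p": r.p, "n_instruments": r.n_instruments,
                    "q": r.q, "q_p": r.q_p, "egger_intercept": r.intercept,
                    "egger_intercept_p": r.intercept_p, "global_p": r.global_p,
                    "global_p_display": r.format_p(),
                    "n_outliers": len(r.outliers),
                    "corrected_beta": r.corrected_beta, "corrected_p": r.corrected_p,
                    "fallback_used": instr.fallback_used,
                }
            )
    return pd.DataFrame(rows)
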