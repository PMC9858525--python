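"""Cross-trait meta-analysis, LD clumping and novel-locus discovery.

A fixed-effect inverse-variance-weighted meta-analysis combines the two
traits' per-variant effects; Cochran's Q quantifies between-trait
heterogeneity.  Shared-signal candidates are variants that reach
genome-wide significance (p < 5e-8) in the meta-analysis while being
only nominally significant (5e-8 < p < 0.05) in each single trait.
Candidates are grouped into loci by greedy p-value-ordered LD clumping,
and a six-step masking procedure decides which lead variants are novel,
i.e. LD-independent (r^2 < 0.1) of every genome-wide-significant variant
of either single trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference, log_p_from_z

logger = logging.getLogger(__name__)

LOG_GWS = np.log(5e-8)
LOG_NOMINAL = np.log(0.05)


def ivw_fixed_meta(b1, s1, b2, s2):
    """Fixed-effect IVW combination of two effect estimates.

    Returns (beta_meta, se_meta, log_p_meta); weights are 1/se^2, so the
    combined precision is the sum of the per-trait precisions.
    """
    b1, s1, b2, s2 = (np.asarray(v, float) for v in (b1, s1, b2, s2))
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / s1**2, 1.0 / s2**2
    beta = (w1 * b1 + w2 * b2) / (w1 + w2)
    se = 1.0 / np.sqrt(w1 + w2)
    return beta, se, log_p_from_z(beta / se)


def heterogeneity(b1, s1, b2, s2):
    """Cochran's Q for a two-study meta-analysis and its chi2(1) p-value."""
    b1, s1, b2, s2 = (np.asarray(v, float) for v in (b1, s1, b2, s2))
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("standard errors must be positive")
    w1, w2 = 1.0 / s1**2, 1.0 / s2**2
    beta = (w1 * b1 + w2 * b2) / (w1 + w2)
    Q = w1 * (b1 - beta) ** 2 + w2 * (b2 - beta) ** 2
    return Q, stats.chi2.sf(Q, df=1)


def cross_trait_meta(pair: pd.DataFrame) -> pd.DataFrame:
    """Meta-analysis table for a harmonized pair (one row per variant)."""
    beta, se, log_p = ivw_fixed_meta(
        pair["beta_1"], pair["se_1"], pair["beta_2"], pair["se_2"]
    )
    Q, q_p = heterogeneity(pair["beta_1"], pair["se_1"], pair["beta_2"], pair["se_2"])
    out = pair.copy()
    out["beta_meta"] = beta
    out["se_meta"] = se
    out["log_p_meta"] = log_p
    out["p_meta"] = np.exp(np.maximum(log_p, -745.0))
    out["cochran_q"] = Q
    out["q_p"] = q_p
    return out


def filter_shared_candidates(meta: pd.DataFrame) -> pd.DataFrame:
    """Variants GWS in the meta-analysis but only nominal in each trait.

    Keeps rows with p_meta < 5e-8 and both single-trait p-values strictly
    inside (5e-8, 0.05); comparisons run on log p-values.
    """
    keep = (
        (meta["log_p_meta"] < LOG_GWS)
        & (meta["log_p_1"] > LOG_GWS)
        & (meta["log_p_1"] < LOG_NOMINAL)
        & (meta["log_p_2"] > LOG_GWS)
        & (meta["log_p_2"] < LOG_NOMINAL)
    )
    out = meta.loc[keep].reset_index(drop=True)
    logger.info("filter_shared_candidates: %d of %d variants kept", len(out), len(meta))
    return out


@dataclass
class Clump:
    lead: str
    members: list[str]
    span: tuple[int, int]  # merged span from r2 >= r2_merge members


@dataclass
class ClumpResult:
    clumps: list[Clump]
    assignment: dict[str, str] = field(default_factory=dict)  # variant -> lead
    n_missing_ld: int = 0

    @property
    def leads(self) -> list[str]:
        return [c.lead for c in self.clumps]


def ld_clump(
    variants: pd.DataFrame,
    ld: LDReference,
    r2_merge: float = 0.6,
    r2_lead: float = 0.1,
) -> ClumpResult:
    """Greedy p-value-ordered LD clumping (PLINK/FUMA style).

    The best remaining variant (smallest p, position tie-break) becomes a
    lead; remaining variants with r^2 >= ``r2_lead`` to it join its clump;
    members at r^2 >= ``r2_merge`` define the locus's merged span.
    Variants absent from the LD reference are treated as unlinked; their
    count is surfaced because it bears on novelty claims.
    """
    df = variants.sort_values(["log_p", "pos"], kind="mergesort").reset_index(drop=True)
    missing = ld.missing(df["snp"])
    if missing:
        logger.warning("ld_clump: %d variant(s) missing from LD reference, treated as unlinked", len(missing))
    remaining = list(df.index)
    clumps: list[Clump] = []
    assignment: dict[str, str] = {}
    snp = df["snp"].to_numpy()
    pos = df["pos"].to_numpy()
    while remaining:
        lead_i = remaining.pop(0)
        lead = snp[lead_i]
        member_idx = [lead_i]
        rest = []
        for i in remaining:
            r2 = ld.r2(lead, snp[i])
            if np.isnan(r2):
                r2 = 0.0
            if r2 >= r2_lead:
                member_idx.append(i)
            else:
                rest.append(i)
        remaining = rest
        span_idx = [lead_i]
        for i in member_idx[1:]:
            r2 = ld.r2(lead, snp[i])
            if not np.isnan(r2) and r2 >= r2_merge:
                span_idx.append(i)
        span = (int(pos[span_idx].min()), int(pos[span_idx].max()))
        members = [snp[i] for i in member_idx]
        for m in members:
            assignment[m] = lead
        clumps.append(Clump(lead=lead, members=members, span=span))
    return ClumpResult(clumps=clumps, assignment=assignment, n_missing_ld=len(missing))


def novel_loci_six_step(
    candidates: pd.DataFrame,
    gws_trait1: pd.DataFrame,
    gws_trait2: pd.DataFrame,
    ld: LDReference,
    r2_lead: float = 0.1,
) -> list[str]:
    """Lead variants of the shared-candidate loci that are LD-independent
    of every single-trait GWS variant.

    Steps: (1) clump the candidates; (2) carry the resulting leads forward
    with their p-values masked to a non-GWS sentinel (1.0); (3)+(4) collect
    each trait's GWS variants; (5) clump the union of (2)-(4); (6) return
    the masked leads that re-emerge as independent index variants.
    """
    if len(candidates) == 0:
        return []
    step1 = ld_clump(candidates, ld, r2_lead=r2_lead)
    leads = step1.leads
    lead_rows = candidates.set_index("snp").loc[leads].reset_index()
    masked = pd.DataFrame(
        {"snp": lead_rows["snp"], "pos": lead_rows["pos"], "log_p": 0.0}  # sentinel p = 1
    )
    union = [masked]
    for gws in (gws_trait1, gws_trait2):
        if len(gws):
            union.append(gws[["snp", "pos", "log_p"]])
    pool = pd.concat(union, ignore_index=True)
    # a masked lead can coincide with a GWS variant; the GWS row must win
    pool = pool.sort_values("log_p", kind="mergesort").drop_duplicates("snp", keep="first")
    step5 = ld_clump(pool, ld, r2_lead=r2_lead)
    novel = [s for s in leads if s in step5.leads]
    logger.info("novel_loci_six_step: %d of %d candidate leads novel", len(novel), len(leads))
    return novel


def annotate_nearest_gene(variants: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Nearest gene per variant: minimal distance to [tss, tes], 0 inside;
    ties broken by smaller gene span then identifier."""
    if len(genes) == 0:
        return pd.Series([""] * len(variants), index=variants.index)
    out = []
    for _, v in variants.iterrows():
        g = genes.loc[genes["chr"] == v["chr"]]
        if len(g) == 0:
            out.append("")
            continue
        dist = np.maximum(g["tss"] - v["pos"], 0) + np.maximum(v["pos"] - g["tes"], 0)
        span = g["tes"] - g["tss"]
        order = pd.DataFrame({"dist": dist, "span": span, "gene_id": g["gene_id"]})
        best = order.sort_values(["dist", "span", "gene_id"]).iloc[0]
        out.append(best["gene_id"])
    return pd.Series(out, index=variants.index)


def run_meta_stage(
    pair: pd.DataFrame,
    ld: LDReference,
    genes: pd.DataFrame | None = None,
    r2_merge: float = 0.6,
    r2_lead: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full meta stage: IVW table plus the novel-locus lead table."""
    meta = cross_trait_meta(pair)
    cand = filter_shared_candidates(meta)
    gws1 = meta.loc[meta["log_p_1"] < LOG_GWS, ["snp", "pos", "log_p_1"]].rename(
        columns={"log_p_1": "log_p"}
    )
    gws2 = meta.loc[meta["log_p_2"] < LOG_GWS, ["snp", "pos", "log_p_2"]].rename(
        columns={"log_p_2": "log_p"}
    )
    cand_for_clump = pd.DataFrame(
        {"snp": cand["snp"], "pos": cand["pos"], "log_p": cand["log_p_meta"]}
    )
    novel = novel_loci_six_step(cand_for_clump, gws1, gws2, ld, r2_lead=r2_lead)
    meta["shared_candidate"] = meta["snp"].isin(cand["snp"])
    meta["novel"] = meta["snp"].isin(novel)
    novel_table = meta.loc[meta["novel"]].copy()
    if genes is not None and len(novel_table):
        novel_table["nearest_gene"] = annotate_nearest_gene(novel_table, genes)
    return meta, novel_table
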