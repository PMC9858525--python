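"""Per-segment Bayesian pleiotropy model.

For each LD-independent genomic segment, five models compete: no
association (model 0), association with trait 1 only (1), trait 2 only
(2), both traits through one shared variant (3), and both traits through
two distinct variants (4).  Per-variant evidence is a Wakefield
approximate Bayes factor computed from the z-score and the standard
error; regional Bayes factors average the per-variant ABFs under a
one-causal-variant-per-model prior, and posteriors PPA0-4 follow from
model priors.  Segments with PPA3 above a threshold (default 0.5) are
called pleiotropic.

Sample overlap between the two GWAS makes the z-score pair correlated
even under the null; that correlation (``null_cor``, typically wired
from the LDSC genetic-covariance intercept or rg) enters the shared-SNP
model through a bivariate normal ABF.  All Bayes-factor arithmetic is in
log space and stable for z-scores of 40 and beyond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import assign_segments

logger = logging.getLogger(__name__)

#: prior variance of the standardized effect (sd 0.1)
DEFAULT_W = 0.01

#: fixed model priors (null, trait1, trait2, shared, distinct)
FIXED_PRIORS = (0.9, 0.025, 0.025, 0.025, 0.025)


def log_wakefield_abf(z, se, W: float = DEFAULT_W) -> np.ndarray:
    """Log approximate Bayes factor for one trait at each variant.

    With V = se^2 and shrinkage r = W / (V + W):
    ABF = sqrt(1 - r) * exp(z^2 r / 2).
    """
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or W <= 0:
        raise ValueError("se and W must be positive")
    V = se**2
    r = W / (V + W)
    return 0.5 * np.log1p(-r) + z**2 * r / 2.0


def wakefield_abf(z, se, W: float = DEFAULT_W):
    """Approximate Bayes factor (natural scale); see :func:`log_wakefield_abf`."""
    return np.exp(log_wakefield_abf(z, se, W))


def log_abf_bivariate(z1, se1, z2, se2, W: float = DEFAULT_W, null_cor: float = 0.0):
    """Log joint ABF for a shared causal variant affecting both traits.

    Under the null the z-pair is bivariate normal with correlation
    ``null_cor`` (sample-overlap induced); under the alternative each
    trait's marginal variance gains W / V_t, effects a priori independent.
    """
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    r1 = W / (np.asarray(se1, float) ** 2 + W)
    r2 = W / (np.asarray(se2, float) ** 2 + W)
    c = null_cor

    def log_mvn2(z1, z2, v1, v2, cov):
        det = v1 * v2 - cov**2
        quad = (v2 * z1**2 - 2 * cov * z1 * z2 + v1 * z2**2) / det
        return -0.5 * (np.log(det) + quad)

    # null: unit variances; alternative: variances 1/(1-r_t), same covariance c
    return log_mvn2(z1, z2, 1.0 / (1.0 - r1), 1.0 / (1.0 - r2), c) - log_mvn2(
        z1, z2, 1.0, 1.0, c
    )


def segment_model_bfs(labf1: np.ndarray, labf2: np.ndarray, labf2_adj: np.ndarray | None = None):
    """Log regional Bayes factors (RBF1..4) from per-variant log-ABFs.

    RBF1/RBF2 average single-trait ABFs; RBF3 averages the shared-variant
    joint evidence abf1 * abf2_adj (``labf2_adj`` defaults to ``labf2``,
    exact when the null correlation is 0); RBF4 averages abf1_i * abf2_j
    over ordered pairs of distinct variants.
    """
    k = len(labf1)
    if k < 2 or len(labf2) != k:
        raise ValueError("need aligned per-variant ABFs for at least 2 variants")
    if labf2_adj is None:
        labf2_adj = labf2
    logk = np.log(k)
    lrbf1 = logsumexp(labf1) - logk
    lrbf2 = logsumexp(labf2) - logk
    lrbf3 = logsumexp(labf1 + labf2_adj) - logk
    # sum over i != j of abf1_i abf2_j  =  (sum abf1)(sum abf2) - sum abf1_i abf2_i
    ls1, ls2 = logsumexp(labf1), logsumexp(labf2)
    lsd = logsumexp(labf1 + labf2)
    d = lsd - (ls1 + ls2)
    if d < -1e-12:
        lrbf4 = ls1 + ls2 + np.log1p(-np.exp(d)) - np.log(k * (k - 1))
    else:  # near-total diagonal mass: fall back to the masked outer sum
        outer = labf1[:, None] + labf2[None, :]
        np.fill_diagonal(outer, -np.inf)
        lrbf4 = logsumexp(outer) - np.log(k * (k - 1))
    return np.array([lrbf1, lrbf2, lrbf3, lrbf4])


def segment_posteriors(log_rbfs: np.ndarray, priors=FIXED_PRIORS) -> np.ndarray:
    """Posterior probabilities (PPA0..PPA4) from log RBFs and model priors."""
    priors = np.asarray(priors, float)
    if priors.shape != (5,) or np.any(priors < 0) or abs(priors.sum() - 1) > 1e-8:
        raise ValueError("priors must be 5 nonnegative numbers summing to 1")
    with np.errstate(divide="ignore"):
        log_post = np.log(priors) + np.concatenate([[0.0], log_rbfs])
    return np.exp(log_post - logsumexp(log_post))


def empirical_bayes_priors(log_rbf_matrix: np.ndarray, n_iter: int = 300) -> np.ndarray:
    """Model priors maximizing the marginal likelihood across segments (EM).

    Falls back to :data:`FIXED_PRIORS` when fewer than 10 segments are
    available or the optimization degenerates.
    """
    S = log_rbf_matrix.shape[0]
    if S < 10:
        logger.info("empirical_bayes_priors: %d segments < 10, using fixed priors", S)
        return np.array(FIXED_PRIORS)
    lbf = np.hstack([np.zeros((S, 1)), log_rbf_matrix])  # null column
    pi = np.array(FIXED_PRIORS)
    for _ in range(n_iter):
        with np.errstate(divide="ignore"):
            log_r = np.log(pi)[None, :] + lbf
        log_r -= logsumexp(log_r, axis=1, keepdims=True)
        new = np.exp(logsumexp(log_r, axis=0) - np.log(S))
        if np.max(np.abs(new - pi)) < 1e-10:
            pi = new
            break
        pi = new
    pi = np.clip(pi, 1e-6, None)
    return pi / pi.sum()


@dataclass
class SegmentScan:
    """Per-segment posteriors plus the priors that produced them."""

    table: pd.DataFrame
    priors: np.ndarray


def scan_segments(
    pair: pd.DataFrame,
    segments: pd.DataFrame,
    W: float = DEFAULT_W,
    null_cor: float = 0.0,
    priors="eb",
) -> SegmentScan:
    """Compute PPA1-4 for every segment of a harmonized pair table.

    ``priors``: "eb" for empirical-Bayes estimation across segments,
    "fixed" or an explicit 5-tuple otherwise.  Segments with fewer than 2
    variants are skipped with a log entry.
    """
    seg_idx = assign_segments(pair, segments)
    labf1 = log_wakefield_abf(pair["z_1"].to_numpy(), pair["se_1"].to_numpy(), W)
    labf2 = log_wakefield_abf(pair["z_2"].to_numpy(), pair["se_2"].to_numpy(), W)
    labf_joint = log_abf_bivariate(
        pair["z_1"].to_numpy(), pair["se_1"].to_numpy(),
        pair["z_2"].to_numpy(), pair["se_2"].to_numpy(), W, null_cor,
    )
    labf2_adj = labf_joint - labf1

    rows = []
    lrbfs = []
    for si in range(len(segments)):
        sel = seg_idx == si
        k = int(sel.sum())
        if k < 2:
            if k:
                logger.info("scan_segments: segment %d has %d variant(s); skipped", si, k)
            continue
        lrbf = segment_model_bfs(labf1[sel], labf2[sel], labf2_adj[sel])
        joint = labf1[sel] + labf2_adj[sel]
        lead_pos = int(np.argmax(joint))
        lead = pair.loc[sel].iloc[lead_pos]
        rows.append(
            {
                "segment": si,
                "chr": segments.loc[si, "chr"],
                "start": segments.loc[si, "start"],
                "end": segments.loc[si, "end"],
                "n_snps": k,
                "lead_snp": lead["snp"],
                "dir_1": "increase" if lead["beta_1"] > 0 else "decrease",
                "dir_2": "increase" if lead["beta_2"] > 0 else "decrease",
            }
        )
        lrbfs.append(lrbf)
    if not rows:
        return SegmentScan(pd.DataFrame(), np.array(FIXED_PRIORS))

    lrbf_matrix = np.vstack(lrbfs)
    if isinstance(priors, str) and priors == "eb":
        pi = empirical_bayes_priors(lrbf_matrix)
    elif isinstance(priors, str) and priors == "fixed":
        pi = np.array(FIXED_PRIORS)
    else:
        pi = np.asarray(priors, float)

    table = pd.DataFrame(rows)
    ppa = np.vstack([segment_posteriors(lr, pi) for lr in lrbf_matrix])
    for m in range(5):
        table[f"ppa{m}"] = ppa[:, m]
    return SegmentScan(table=table, priors=pi)


def call_pleiotropic_segments(scan: SegmentScan | pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Segments with PPA3 > threshold, sorted by PPA3 descending."""
    table = scan.table if isinstance(scan, SegmentScan) else scan
    if len(table) == 0:
        return table
    hits = table.loc[table["ppa3"] > threshold].sort_values("ppa3", ascending=False)
    return hits.reset_index(drop=True)
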