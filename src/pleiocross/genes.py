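"""Gene-based association and gene-level overlap between two GWAS.

The gene test is GATES: the best SNP p-value in a gene (SNPs mapped from
15 kb upstream of the TSS to 15 kb downstream of the TES) is adjusted by
the effective number of independent SNPs, estimated from the eigenvalues
of the SNP LD correlation matrix.  Effective numbers of independent
*genes* follow the same eigenvalue rule applied to the LD matrix of the
genes' best SNPs (neighbouring genes are correlated through LD of their
top variants).  Overlap between a discovery and a target GWAS at a gene
p-value threshold is tested with a one-sided binomial test on effective
counts, and individual shared genes are called with Fisher's combined
p-value at a Bonferroni threshold of 0.05 over the effective gene count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDReference

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 15_000


def assign_snps_to_genes(
    ss: pd.DataFrame, genes: pd.DataFrame, flank: int = DEFAULT_FLANK
) -> dict[str, list[str]]:
    """Map variants to genes within [tss - flank, tes + flank] (closed).

    A variant may belong to several genes; genes with no variants are
    dropped with a logged count.
    """
    out: dict[str, list[str]] = {}
    n_empty = 0
    for _, g in genes.iterrows():
        sel = (
            (ss["chr"] == g["chr"])
            & (ss["pos"] >= g["tss"] - flank)
            & (ss["pos"] <= g["tes"] + flank)
        )
        snps = ss.loc[sel, "snp"].tolist()
        if snps:
            out[g["gene_id"]] = snps
        else:
            n_empty += 1
    if n_empty:
        logger.info("assign_snps_to_genes: %d gene(s) had no variants", n_empty)
    return out


def effective_tests(R: np.ndarray) -> float:
    """Effective number of independent tests from a correlation matrix.

    Me = M - sum over eigenvalues above 1 of (eigenvalue - 1), clamped to
    [1, M]; equals M for independent variants and 1 under perfect LD.
    """
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    M = R.shape[0]
    if M == 0:
        raise ValueError("empty correlation matrix")
    lam = np.linalg.eigvalsh((R + R.T) / 2.0)
    me = M - float(np.sum(lam[lam > 1.0] - 1.0))
    return float(np.clip(me, 1.0, M))


def pvalue_correlation(r: np.ndarray) -> np.ndarray:
    """Correlation between two-sided association p-values from genotype r.

    Sixth-degree polynomial approximation (the GATES mapping), evaluated
    at |r| since two-sided p-values are sign-blind; perfectly linked
    variants (|r| = 1) have identical p-values, so that limit is pinned
    to exactly 1.  Applied elementwise.
    """
    r = np.abs(np.asarray(r, float))
    out = (
        0.2982 * r**6
        - 0.0127 * r**5
        + 0.0588 * r**4
        + 0.0099 * r**3
        + 0.6281 * r**2
        - 0.0009 * r
    )
    return np.where(r >= 1.0 - 1e-12, 1.0, out)


def gates_pvalue(p_sorted: np.ndarray, R_sorted: np.ndarray) -> float:
    """GATES gene p-value from ascending SNP p-values and their LD matrix.

    p_gates = min_j ( Me(all) * p_(j) / Me(top j) ), capped at 1, where
    Me is :func:`effective_tests` of the *p-value* correlation matrix
    (genotype LD mapped through :func:`pvalue_correlation`) of the j most
    significant SNPs.  ``R_sorted`` must be ordered like ``p_sorted``.
    Reduces to the Simes test for independent SNPs and to the best SNP
    p-value under perfect LD.
    """
    p_sorted = np.asarray(p_sorted, float)
    M = len(p_sorted)
    if M == 0:
        raise ValueError("gene without variants")
    if np.any(np.diff(p_sorted) < 0):
        raise ValueError("p-values must be sorted ascending")
    Rp = pvalue_correlation(R_sorted)
    np.fill_diagonal(Rp, 1.0)
    me_total = effective_tests(Rp)
    best = np.inf
    for j in range(1, M + 1):
        me_j = effective_tests(Rp[:j, :j])
        best = min(best, me_total * p_sorted[j - 1] / me_j)
    return float(min(best, 1.0))


def gene_scan(
    ss: pd.DataFrame,
    genes: pd.DataFrame,
    ld: LDReference,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """GATES p-value for every gene with assigned variants.

    Returns one row per gene: SNP count, effective SNP count, best
    variant and its p-value, and the GATES gene p-value.
    """
    assignment = assign_snps_to_genes(ss, genes, flank)
    by_snp = ss.set_index("snp")
    rows = []
    for gene_id, snps in assignment.items():
        sub = by_snp.loc[snps]
        order = np.argsort(sub["p"].to_numpy(), kind="mergesort")
        snps_sorted = [snps[i] for i in order]
        p_sorted = sub["p"].to_numpy()[order]
        R = ld.corr_submatrix(snps_sorted)
        p_g = gates_pvalue(p_sorted, R)
        rows.append(
            {
                "gene_id": gene_id,
                "n_snps": len(snps),
                "me": effective_tests(R),
                "best_snp": snps_sorted[0],
                "p_best": float(p_sorted[0]),
                "p_gates": p_g,
            }
        )
    return pd.DataFrame(rows)


def effective_gene_count(
    gene_results: pd.DataFrame,
    ss: pd.DataFrame,
    ld: LDReference,
    threshold: float | None = None,
) -> float:
    """Effective number of independent genes via best-SNP LD.

    Builds, per chromosome, the LD correlation matrix of the genes' best
    variants and applies the eigenvalue rule of :func:`effective_tests`,
    summing across chromosomes.  With ``threshold``, only genes with
    p_gates below it are counted.  Genes whose best variant is missing
    from the LD reference count as independent (logged).
    """
    df = gene_results
    if threshold is not None:
        df = df.loc[df["p_gates"] < threshold]
    if len(df) == 0:
        return 0.0
    chrom = ss.set_index("snp")["chr"]
    total = 0.0
    n_missing = 0
    for _, grp in df.groupby(df["best_snp"].map(chrom)):
        snps = grp["best_snp"].tolist()
        n_missing += len(ld.missing(snps))
        R = ld.corr_submatrix(snps)
        total += effective_tests(R)
    if n_missing:
        logger.warning("effective_gene_count: %d best variant(s) missing from LD reference", n_missing)
    return total


@dataclass
class OverlapResult:
    """Gene-level overlap between a discovery and a target GWAS at one threshold."""

    threshold: float
    raw_discovery: int
    eff_discovery: float
    raw_target: int
    eff_target: float
    eff_target_total: float
    raw_overlap: int
    eff_overlap: float
    expected_prop: float
    observed_prop: float
    binomial_p: float
    log10_binomial_p: float
    undefined: bool = False


def binomial_overlap_p(k: int, n: int, expected: float) -> tuple[float, float]:
    """One-sided upper-tail binomial P(X >= k), X ~ Binomial(n, expected).

    Returns (p, log10 p); the log10 value survives tails far below float
    underflow.
    """
    if not 0.0 < expected < 1.0:
        raise ValueError("expected proportion must lie in (0, 1)")
    log_p = stats.binom.logsf(k - 1, n, expected)
    return float(np.exp(log_p)), float(log_p / np.log(10.0))


def overlap_binomial(
    discovery: pd.DataFrame,
    target: pd.DataFrame,
    ss_discovery: pd.DataFrame,
    ss_target: pd.DataFrame,
    ld: LDReference,
    thresholds=(0.1, 0.05, 0.01),
) -> list[OverlapResult]:
    """One-sided binomial overlap tests at each gene p-value threshold.

    Expected proportion = effective target genes below the threshold over
    the total effective target genes; observed proportion = effective
    overlapping genes over effective discovery genes below the threshold.
    Effective counts are rounded to integers for the test.
    """
    eff_target_total = effective_gene_count(target, ss_target, ld)
    both = discovery.merge(target, on="gene_id", suffixes=("_d", "_t"))
    out = []
    for t in thresholds:
        disc_t = discovery.loc[discovery["p_gates"] < t]
        targ_t = target.loc[target["p_gates"] < t]
        overlap_genes = both.loc[(both["p_gates_d"] < t) & (both["p_gates_t"] < t), "gene_id"]
        eff_disc = effective_gene_count(discovery, ss_discovery, ld, threshold=t)
        eff_targ = effective_gene_count(target, ss_target, ld, threshold=t)
        ov = discovery.loc[discovery["gene_id"].isin(overlap_genes)]
        eff_ov = effective_gene_count(ov, ss_discovery, ld)

        n = int(round(eff_disc))
        k = int(round(eff_ov))
        if n == 0 or eff_target_total == 0:
            out.append(
                OverlapResult(t, len(disc_t), eff_disc, len(targ_t), eff_targ,
                              eff_target_total, len(overlap_genes), eff_ov,
                              np.nan, np.nan, np.nan, np.nan, undefined=True)
            )
            continue
        expected = eff_targ / eff_target_total
        observed = eff_ov / eff_disc
        p, log10p = binomial_overlap_p(k, n, expected)
        out.append(
            OverlapResult(
                threshold=t, raw_discovery=len(disc_t), eff_discovery=eff_disc,
                raw_target=len(targ_t), eff_target=eff_targ,
                eff_target_total=eff_target_total, raw_overlap=len(overlap_genes),
                eff_overlap=eff_ov, expected_prop=expected, observed_prop=observed,
                binomial_p=p, log10_binomial_p=log10p,
            )
        )
    return out


def fisher_combined(p1: float, p2: float) -> float:
    """Fisher's combined p for two p-values: chi-square(4 df) upper tail.

    X = -2 (ln p1 + ln p2); the tail has the closed form e^{-X/2}(1 + X/2).
    """
    if not (0.0 < p1 <= 1.0 and 0.0 < p2 <= 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    X = -2.0 * (np.log(p1) + np.log(p2))
    return float(np.exp(-X / 2.0) * (1.0 + X / 2.0))


def call_shared_genes(
    discovery: pd.DataFrame, target: pd.DataFrame, eff_total_genes: float
) -> pd.DataFrame:
    """Shared-gene calls by Fisher's combined p-value.

    Candidates are genes with both trait p-values below 0.05; a gene is
    genome-wide significant when its combined p falls below
    0.05 / ``eff_total_genes``.
    """
    threshold = 0.05 / eff_total_genes
    both = discovery.merge(target, on="gene_id", suffixes=("_1", "_2"))
    cand = both.loc[(both["p_gates_1"] < 0.05) & (both["p_gates_2"] < 0.05)].copy()
    if len(cand) == 0:
        return pd.DataFrame(columns=["gene_id", "p_1", "p_2", "fcp_p", "gws", "threshold"])
    cand["fcp_p"] = [
        fisher_combined(a, b) for a, b in zip(cand["p_gates_1"], cand["p_gates_2"])
    ]
    out = pd.DataFrame(
        {
            "gene_id": cand["gene_id"],
            "p_1": cand["p_gates_1"],
            "p_2": cand["p_gates_2"],
            "fcp_p": cand["fcp_p"],
            "gws": cand["fcp_p"] < threshold,
            "threshold": threshold,
        }
    )
    return out.sort_values("fcp_p").reset_index(drop=True)
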