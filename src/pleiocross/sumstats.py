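"""Summary-statistics data model, I/O and cross-trait harmonization.

A summary-statistics table is a :class:`pandas.DataFrame` with canonical
columns ``snp, chr, pos, a1, a2, beta, se, p, log_p, z, n`` and, for
case-control traits, ``n_cases``/``n_controls`` (optionally ``eaf``).
``a1`` is the effect allele; ``beta`` is the per-allele effect on the
observed scale (log-odds for binary traits, SD units for quantitative
traits).  ``log_p`` is the natural-log two-sided p-value and is the
authoritative copy: comparisons against significance thresholds go through
it so that associations far beyond float underflow (p < 1e-308) survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for a validated table
CANONICAL_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "beta", "se", "p", "log_p", "z", "n"]

#: default file-side column names, the common GWAS export convention
DEFAULT_COLUMN_MAP = {
    "snp": "SNP",
    "chr": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
    "n_cases": "N_CASES",
    "n_controls": "N_CONTROLS",
    "eaf": "EAF",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumStatsError(ValueError):
    """Raised for unusable summary-statistics input."""


class ConfigError(ValueError):
    """Raised for an invalid column map or analysis configuration."""


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return _complement(a1) == a2


def log_p_from_z(z: np.ndarray) -> np.ndarray:
    """Natural-log two-sided normal p-value, stable for very large ``|z|``."""
    z = np.asarray(z, dtype=float)
    return stats.norm.logsf(np.abs(z)) + np.log(2.0)


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Enforce table invariants, dropping rows that violate them.

    Requires ``se > 0``, ``p`` in (0, 1], chromosome in 1-22, finite beta,
    and a unique (chr, pos, allele-set) key.  Fills ``z`` from beta/se and
    ``log_p`` from ``z`` where absent.  Returns the clean table and the
    number of rows dropped.
    """
    n_in = len(df)
    df = df.copy()

    for col in ("beta", "se"):
        if col not in df.columns:
            raise ConfigError(f"mandatory column '{col}' missing from summary statistics")

    df["beta"] = pd.to_numeric(df["beta"], errors="coerce")
    df["se"] = pd.to_numeric(df["se"], errors="coerce")
    keep = np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0)
    if "chr" in df.columns:
        df["chr"] = pd.to_numeric(df["chr"], errors="coerce")
        keep &= df["chr"].between(1, 22)
    if "p" in df.columns:
        p = pd.to_numeric(df["p"], errors="coerce")
        keep &= (p > 0) & (p <= 1) | p.isna()
    df = df.loc[keep].copy()

    if "z" not in df.columns:
        df["z"] = df["beta"] / df["se"]
    else:
        df["z"] = df["z"].fillna(df["beta"] / df["se"])
    if "log_p" not in df.columns:
        df["log_p"] = log_p_from_z(df["z"].to_numpy())
    df["p"] = np.exp(np.maximum(df["log_p"], -745.0))

    if {"chr", "pos"}.issubset(df.columns):
        key = [df["chr"], df["pos"], df[["a1", "a2"]].apply(frozenset, axis=1)]
        dup = pd.Series(list(zip(*key)), index=df.index).duplicated()
        df = df.loc[~dup]

    dropped = n_in - len(df)
    if dropped:
        logger.info("validate_sumstats: dropped %d of %d rows", dropped, n_in)
    if len(df) == 0:
        raise SumStatsError("no rows survived validation")
    return df.reset_index(drop=True), dropped


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a whitespace/tab-delimited association file into a validated table.

    ``column_map`` maps canonical names (``snp, chr, pos, a1, a2, beta, se,
    p, n, n_cases, n_controls, eaf``) to the file's header names; defaults
    to the PLINK-style convention in :data:`DEFAULT_COLUMN_MAP`.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")

    mandatory = ["snp", "chr", "pos", "a1", "a2", "beta", "se"]
    missing = [cmap[k] for k in mandatory if cmap[k] not in raw.columns]
    if missing:
        raise ConfigError(f"missing mandatory column(s) {missing} in {path}")

    out = pd.DataFrame()
    for canon, name in cmap.items():
        if name in raw.columns:
            out[canon] = raw[name]
    out["a1"] = out["a1"].astype(str).str.upper()
    out["a2"] = out["a2"].astype(str).str.upper()
    table, dropped = validate_sumstats(out)
    logger.info("read_sumstats(%s): %d rows kept, %d dropped", path, len(table), dropped)
    return table


def write_sumstats(table: pd.DataFrame, path, column_map: dict | None = None) -> None:
    """Write a table back to delimited text using the file-side names."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = pd.DataFrame()
    for canon, name in cmap.items():
        if canon in table.columns:
            out[name] = table[canon]
    out.to_csv(path, sep="\t", index=False)


def harmonize_pair(
    a: pd.DataFrame, b: pd.DataFrame, drop_palindromic: bool = True
) -> pd.DataFrame:
    """Align two validated tables on shared variants with consistent alleles.

    Variants are matched on (chromosome, position).  Where ``b``'s effect
    allele equals ``a``'s other allele, ``b``'s effect sign is flipped;
    strand flips are resolved by complementing ``b``'s alleles before
    matching.  Unresolvable allele pairs are dropped, as are A/T and C/G
    palindromic variants when ``drop_palindromic``.

    Returns a table with ``a``'s variant columns plus suffixed effect
    columns ``beta_1/se_1/p_1/log_p_1/z_1/n_1`` and ``..._2``.
    """
    m = a.merge(b, on=["chr", "pos"], suffixes=("_1", "_2"))
    if len(m) == 0:
        raise SumStatsError("no shared variants between the two tables")

    a1_1, a2_1 = m["a1_1"].to_numpy(), m["a2_1"].to_numpy()
    a1_2, a2_2 = m["a1_2"].to_numpy(), m["a2_2"].to_numpy()
    c1_2 = np.array([_complement(x) for x in a1_2])
    c2_2 = np.array([_complement(x) for x in a2_2])

    same = (a1_2 == a1_1) & (a2_2 == a2_1)
    swap = (a1_2 == a2_1) & (a2_2 == a1_1)
    same_c = (c1_2 == a1_1) & (c2_2 == a2_1) & ~same & ~swap
    swap_c = (c1_2 == a2_1) & (c2_2 == a1_1) & ~same & ~swap
    flip = swap | swap_c
    ok = same | swap | same_c | swap_c

    palin = np.array([is_palindromic(x, y) for x, y in zip(a1_1, a2_1)])
    if drop_palindromic:
        ok &= ~palin

    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("harmonize_pair: dropped %d unresolvable/palindromic variants", n_drop)
    m = m.loc[ok].copy()
    flip = flip[ok]
    for col in ("beta_2", "z_2"):
        if col in m.columns:
            m.loc[flip, col] = -m.loc[flip, col]
    if "eaf_2" in m.columns:
        m.loc[flip, "eaf_2"] = 1.0 - m.loc[flip, "eaf_2"]
    m["a1_2"] = m["a1_1"]
    m["a2_2"] = m["a2_1"]

    if len(m) == 0:
        raise SumStatsError("no variants survived harmonization")
    keep = ["snp_1", "chr", "pos", "a1_1", "a2_1"]
    keep += [c for c in m.columns if c.endswith(("_1", "_2")) and c not in keep and not c.startswith(("snp_2", "a1", "a2"))]
    out = m[keep].rename(columns={"snp_1": "snp", "a1_1": "a1", "a2_1": "a2"})
    return out.reset_index(drop=True)


def liability_factor(P: float, K: float) -> float:
    """Observed-to-liability-scale conversion factor for heritability.

    Under the liability-threshold model a case-control trait with sample
    case proportion ``P`` and population prevalence ``K`` has

        h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) * phi(t)^2),

    where ``t = Phi^{-1}(1-K)`` is the liability threshold and ``phi`` the
    standard normal density.
    """
    if not (0.0 < P < 1.0 and 0.0 < K < 1.0):
        raise ValueError("P and K must lie strictly inside (0, 1)")
    t = stats.norm.isf(K)
    phi = stats.norm.pdf(t)
    return K**2 * (1 - K) ** 2 / (P * (1 - P) * phi**2)


# ---------------------------------------------------------------------------
# LD reference panel


@dataclass
class LDReference:
    """Block-diagonal LD reference: per-block variant lists and correlations.

    Every variant belongs to exactly one block; correlation between variants
    in different blocks is zero by construction.
    """

    blocks: list[tuple[np.ndarray, np.ndarray]]  # (variant_ids, R)
    n_ref: int
    maf: dict[str, float] = field(default_factory=dict)
    _index: dict[str, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for ids, R in self.blocks:
            if R.shape != (len(ids), len(ids)):
                raise ValueError("block correlation matrix does not match variant list")
            if not np.allclose(R, R.T, atol=1e-8):
                raise ValueError("block correlation matrix is not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-6):
                raise ValueError("block correlation matrix diagonal is not 1")
        if not self._index:
            for bi, (ids, _) in enumerate(self.blocks):
                for vi, v in enumerate(ids):
                    if v in self._index:
                        raise ValueError(f"variant {v} appears in more than one block")
                    self._index[v] = (bi, vi)

    @property
    def variant_ids(self) -> list[str]:
        return [v for ids, _ in self.blocks for v in ids]

    def __contains__(self, variant: str) -> bool:
        return variant in self._index

    def block_of(self, variant: str) -> int:
        return self._index[variant][0]

    def r2(self, v1: str, v2: str) -> float:
        """Squared correlation; 0 across blocks, NaN if either is absent."""
        if v1 not in self._index or v2 not in self._index:
            return float("nan")
        b1, i1 = self._index[v1]
        b2, i2 = self._index[v2]
        if b1 != b2:
            return 0.0
        return float(self.blocks[b1][1][i1, i2] ** 2)

    def corr_submatrix(self, variants: list[str]) -> np.ndarray:
        """Correlation matrix of a variant set (zeros across blocks).

        Variants absent from the panel are treated as unlinked (identity
        row/column) and counted by the caller via :meth:`missing`.
        """
        k = len(variants)
        R = np.eye(k)
        locs = [self._index.get(v) for v in variants]
        for i in range(k):
            if locs[i] is None:
                continue
            bi, ii = locs[i]
            for j in range(i + 1, k):
                if locs[j] is None or locs[j][0] != bi:
                    continue
                R[i, j] = R[j, i] = self.blocks[bi][1][ii, locs[j][1]]
        return R

    def missing(self, variants) -> list[str]:
        return [v for v in variants if v not in self._index]

    # -- text round trip ----------------------------------------------------

    def save(self, out_dir) -> None:
        """Write one whitespace-delimited matrix file per block plus an index."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "panel.index"), "w") as fh:
            fh.write(f"#n_ref\t{self.n_ref}\n")
            for bi, (ids, R) in enumerate(self.blocks):
                np.savetxt(os.path.join(out_dir, f"block{bi:05d}.ld"), R, fmt="%.6g")
                for v in ids:
                    fh.write(f"{v}\tblock{bi:05d}\t{self.maf.get(v, 0.5):.6g}\n")

    @classmethod
    def load(cls, in_dir) -> "LDReference":
        import os

        n_ref = None
        order: dict[str, list[str]] = {}
        maf = {}
        with open(os.path.join(in_dir, "panel.index")) as fh:
            for line in fh:
                if line.startswith("#n_ref"):
                    n_ref = int(line.split("\t")[1])
                    continue
                v, blk, m = line.split()
                order.setdefault(blk, []).append(v)
                maf[v] = float(m)
        blocks = []
        for blk in sorted(order):
            R = np.loadtxt(os.path.join(in_dir, f"{blk}.ld"))
            R = np.atleast_2d(R)
            blocks.append((np.array(order[blk]), R))
        return cls(blocks=blocks, n_ref=int(n_ref), maf=maf)


# ---------------------------------------------------------------------------
# Genes and segments


def read_genes(path) -> pd.DataFrame:
    """Read a BED-like gene file (chr, start, end, gene_id[, strand]).

    File intervals are half-open 0-based; converted to 1-based closed
    [tss, tes] coordinates on read, oriented so tss <= tes.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :5]
    df.columns = ["chr", "start", "end", "gene_id", "strand"][: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    genes = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "chr": df["chr"].astype(int),
            "tss": df["start"].astype(int) + 1,
            "tes": df["end"].astype(int),
            "strand": df["strand"],
        }
    )
    bad = genes["tss"] > genes["tes"]
    genes.loc[bad, ["tss", "tes"]] = genes.loc[bad, ["tes", "tss"]].to_numpy()
    if genes["gene_id"].duplicated().any():
        raise SumStatsError("duplicate gene identifiers in annotation")
    return genes


def write_genes(genes: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chr": genes["chr"],
            "start": genes["tss"] - 1,
            "end": genes["tes"],
            "gene_id": genes["gene_id"],
            "strand": genes.get("strand", "+"),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_segments(path) -> pd.DataFrame:
    """Read a 3-column BED of LD-independent segments (half-open, 0-based)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    seg = pd.DataFrame(
        {"chr": df.iloc[:, 0].astype(int), "start": df.iloc[:, 1].astype(int) + 1, "end": df.iloc[:, 2].astype(int) + 1}
    )
    seg = seg.sort_values(["chr", "start"]).reset_index(drop=True)
    for _, grp in seg.groupby("chr"):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise SumStatsError("segments overlap within a chromosome")
    return seg


def write_segments(segments: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {"chr": segments["chr"], "start": segments["start"] - 1, "end": segments["end"] - 1}
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def assign_segments(table: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """Segment index (row of ``segments``) for each variant; -1 if uncovered.

    Segment intervals are half-open [start, end) on 1-based positions.
    """
    seg_idx = np.full(len(table), -1, dtype=int)
    for ci, grp in segments.groupby("chr"):
        sel = table["chr"] == ci
        if not sel.any():
            continue
        pos = table.loc[sel, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        good = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        out = np.where(good, grp.index.to_numpy()[np.clip(j, 0, len(ends) - 1)], -1)
        seg_idx[sel.to_numpy()] = out
    return seg_idx
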