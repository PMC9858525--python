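"""Synthetic GWAS study generator.

Produces paired summary-statistics tables, a block-diagonal LD reference
panel, gene annotations and LD-independent segments under a bivariate
infinitesimal polygenic model: every variant is causal, per-variant
standardized effects (b1j, b2j) are bivariate normal with variances
h2_t / M and correlation rg_true, LD within blocks follows an AR(1)
profile, and the two traits' sampling noise is correlated within blocks
by rho_n = (n_overlap / sqrt(N1 N2)) * pheno_corr to emulate shared
cohort individuals.

Case-control traits are simulated on the liability scale: the requested
heritability is interpreted as liability-scale and deflated to the
observed scale for generation, and the output tables carry case/control
counts so that downstream liability conversion recovers the input value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LDReference, liability_factor, log_p_from_z, validate_sumstats


@dataclass
class TraitDesign:
    """Per-trait sampling design; case-control when case_fraction is set."""

    case_fraction: float | None = None  # sample case proportion P
    prevalence: float | None = None  # population prevalence K


@dataclass
class SimConfig:
    """Parameters of one simulated two-trait GWAS study."""

    M: int = 20_000
    block_sizes: tuple[int, ...] = (10, 25, 50, 100)
    within_block_r: float = 0.8
    h2_1: float = 0.2
    h2_2: float = 0.2
    rg_true: float = 0.2
    N1: int = 20_000
    N2: int = 20_000
    n_overlap: int = 0
    pheno_corr: float = 0.0
    trait1: TraitDesign = field(default_factory=TraitDesign)
    trait2: TraitDesign = field(default_factory=TraitDesign)
    n_genes: int = 200
    gene_span: int = 20_000  # bp
    bp_spacing: int = 1_000  # bp between adjacent variants
    chromosome: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.h2_1 <= 1.0 and 0.0 <= self.h2_2 <= 1.0):
            raise ValueError("heritabilities must lie in [0, 1]")
        if not -1.0 <= self.rg_true <= 1.0:
            raise ValueError("rg_true must lie in [-1, 1]")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.n_overlap > min(self.N1, self.N2):
            raise ValueError("n_overlap cannot exceed min(N1, N2)")

    @property
    def rho_n(self) -> float:
        """Cross-trait correlation of sampling noise induced by overlap."""
        return self.n_overlap / np.sqrt(self.N1 * self.N2) * self.pheno_corr

    def block_partition(self) -> list[int]:
        """Block sizes cycled to cover all M variants."""
        sizes, total, i = [], 0, 0
        while total < self.M:
            s = min(self.block_sizes[i % len(self.block_sizes)], self.M - total)
            sizes.append(s)
            total += s
            i += 1
        return sizes


def ar1_corr(size: int, r: float) -> np.ndarray:
    """AR(1) correlation matrix: entry (j, k) = r^|j-k|."""
    idx = np.arange(size)
    return r ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_panel(config: SimConfig, n_ref: int = 10_000) -> LDReference:
    """Block-diagonal AR(1) LD reference panel, deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    blocks = []
    maf = {}
    start = 0
    for size in config.block_partition():
        ids = np.array([f"snp{j:07d}" for j in range(start, start + size)])
        R = ar1_corr(size, config.within_block_r)
        blocks.append((ids, R))
        for v in ids:
            maf[v] = float(rng.uniform(0.05, 0.5))
        start += size
    return LDReference(blocks=blocks, n_ref=n_ref, maf=maf)


def simulate_joint_effects(config: SimConfig) -> np.ndarray:
    """Per-variant standardized causal effect pairs, shape (M, 2).

    Bivariate normal with per-variant variances h2_t / M and correlation
    rg_true; degenerate cases (zero heritability, |rg| = 1) handled exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    M = config.M
    s1 = np.sqrt(config.h2_1 / M)
    s2 = np.sqrt(config.h2_2 / M)
    u = rng.standard_normal(M)
    rho = config.rg_true
    if abs(rho) == 1.0:
        v = u * np.sign(rho)
    else:
        v = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal(M)
    return np.column_stack([s1 * u, s2 * v])


def _trait_columns(config: SimConfig, which: int) -> tuple[float, dict]:
    """(observed-scale h2, extra table columns) for one trait."""
    design = config.trait1 if which == 1 else config.trait2
    h2 = config.h2_1 if which == 1 else config.h2_2
    N = config.N1 if which == 1 else config.N2
    extra: dict = {}
    if design.case_fraction is not None:
        P = design.case_fraction
        K = design.prevalence if design.prevalence is not None else P
        h2 = h2 / liability_factor(P, K)
        extra["n_cases"] = int(round(P * N))
        extra["n_controls"] = N - int(round(P * N))
    return h2, extra


def simulate_sumstats_pair(
    effects: np.ndarray, panel: LDReference, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired GWAS z-score tables given true effects and an LD panel.

    Per block with correlation matrix R, the trait-t z-vector is drawn as
    N(sqrt(N_t) * R @ beta_t, R); the two traits' noise vectors share
    correlation rho_n.  beta = z / sqrt(N), se = 1 / sqrt(N) on the
    standardized scale.
    """
    if effects.shape[0] != sum(len(ids) for ids, _ in panel.blocks):
        raise ValueError("effects and panel cover different variant counts")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rho_n = config.rho_n

    h2o1, extra1 = _trait_columns(config, 1)
    h2o2, extra2 = _trait_columns(config, 2)
    # liability-scale designs rescale the generated effects to observed scale
    scale1 = np.sqrt(h2o1 / config.h2_1) if config.h2_1 > 0 else 1.0
    scale2 = np.sqrt(h2o2 / config.h2_2) if config.h2_2 > 0 else 1.0

    chol_cache: dict[int, np.ndarray] = {}
    z1 = np.empty(effects.shape[0])
    z2 = np.empty(effects.shape[0])
    start = 0
    for ids, R in panel.blocks:
        k = len(ids)
        if k not in chol_cache:
            chol_cache[k] = np.linalg.cholesky(R + 1e-10 * np.eye(k))
        L = chol_cache[k]
        b1 = effects[start : start + k, 0] * scale1
        b2 = effects[start : start + k, 1] * scale2
        e1 = L @ rng.standard_normal(k)
        ey = L @ rng.standard_normal(k)
        e2 = rho_n * e1 + np.sqrt(max(0.0, 1.0 - rho_n**2)) * ey
        z1[start : start + k] = np.sqrt(config.N1) * (R @ b1) + e1
        z2[start : start + k] = np.sqrt(config.N2) * (R @ b2) + e2
        start += k

    ids = np.array(panel.variant_ids)
    pos = (np.arange(len(ids)) + 1) * config.bp_spacing
    maf = np.array([panel.maf.get(v, 0.5) for v in ids])

    def build(z, N, extra):
        df = pd.DataFrame(
            {
                "snp": ids,
                "chr": config.chromosome,
                "pos": pos,
                "a1": "A",
                "a2": "G",
                "beta": z / np.sqrt(N),
                "se": 1.0 / np.sqrt(N),
                "z": z,
                "log_p": log_p_from_z(z),
                "n": N,
                "eaf": maf,
            }
        )
        for k, v in extra.items():
            df[k] = v
        table, _ = validate_sumstats(df)
        return table

    return build(z1, config.N1, extra1), build(z2, config.N2, extra2)


def simulate_annotation(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping genes tiled over the coordinate space, plus segments.

    Segments align with LD-block boundaries so they are LD-independent by
    construction; every variant falls in exactly one segment.
    """
    chrom_len = (config.M + 1) * config.bp_spacing
    if config.n_genes > 0 and config.gene_span >= chrom_len:
        raise ValueError("gene_span exceeds the simulated chromosome length")

    genes = []
    if config.n_genes > 0:
        stride = chrom_len // config.n_genes
        if stride <= config.gene_span:
            raise ValueError("n_genes * gene_span exceeds the chromosome; genes would overlap")
        for g in range(config.n_genes):
            tss = g * stride + 1
            genes.append(
                {
                    "gene_id": f"gene{g:05d}",
                    "chr": config.chromosome,
                    "tss": tss,
                    "tes": tss + config.gene_span - 1,
                    "strand": "+" if g % 2 == 0 else "-",
                }
            )
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chr", "tss", "tes", "strand"])

    bounds = np.cumsum([0] + config.block_partition())
    segs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        segs.append(
            {
                "chr": config.chromosome,
                "start": (lo + 1) * config.bp_spacing,  # position of first variant
                "end": (hi + 1) * config.bp_spacing,  # half-open
            }
        )
    seg_df = pd.DataFrame(segs)
    return gene_df, seg_df


def simulate_study(config: SimConfig, n_ref: int = 10_000):
    """Full study bundle: (ss1, ss2, panel, genes, segments, effects)."""
    panel = simulate_ld_panel(config, n_ref=n_ref)
    effects = simulate_joint_effects(config)
    ss1, ss2 = simulate_sumstats_pair(effects, panel, config)
    genes, segments = simulate_annotation(config)
    return ss1, ss2, panel, genes, segments, effects
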