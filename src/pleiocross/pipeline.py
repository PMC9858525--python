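"""End-to-end orchestration of the cross-trait analysis.

Stages run in a fixed order — harmonize, genetic correlation, regional
pleiotropy posteriors, cross-trait meta-analysis with novel loci,
bidirectional MR, gene-level overlap — each writing its table to the
output directory, followed by a plain-text report index.  Inputs come
either from files or from the synthetic generator; everything downstream
is a pure function of the configuration and seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import genes as genes_mod
from . import ldsc, meta, mr, regional, simulate
from .sumstats import (
    LDReference,
    harmonize_pair,
    read_genes,
    read_segments,
    read_sumstats,
)

logger = logging.getLogger(__name__)

STAGES = ("rg", "gwas-pw", "meta", "mr", "genes")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""


@dataclass
class PipelineConfig:
    out_dir: str = "pleiocross_out"
    seed: int = 0
    # input: either file paths ...
    sumstats_a: str | None = None
    sumstats_b: str | None = None
    ld_panel: str | None = None
    genes_file: str | None = None
    segments_file: str | None = None
    # ... or a simulation block
    sim: simulate.SimConfig | None = None
    stages: tuple[str, ...] = STAGES
    drop_palindromic: bool = True
    # stage parameters
    constrain_gencov_intercept: bool = False
    null_cor: float | str = 0.0  # "from-rg" wires the rg-stage intercept
    gwaspw_priors: str = "eb"
    r2_merge: float = 0.6
    r2_lead: float = 0.1
    mr_p_thresh: float = 5e-8
    mr_fallback_p: float = 1e-5
    gene_flank: int = 15_000
    overlap_thresholds: tuple[float, ...] = (0.1, 0.05, 0.01)

    def __post_init__(self):
        has_paths = self.sumstats_a is not None
        if has_paths == (self.sim is not None):
            raise ValueError("provide exactly one of input paths or a simulation block")
        if self.null_cor == "from-rg" and "rg" not in self.stages:
            raise ValueError("null_cor='from-rg' requires the rg stage to be enabled")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            for tkey in ("trait1", "trait2"):
                if tkey in sim_raw and sim_raw[tkey] is not None:
                    sim_raw[tkey] = simulate.TraitDesign(**sim_raw[tkey])
            if "block_sizes" in sim_raw:
                sim_raw["block_sizes"] = tuple(sim_raw["block_sizes"])
            raw["sim"] = simulate.SimConfig(**sim_raw)
        for key in ("stages", "overlap_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_inputs(cfg: PipelineConfig):
    if cfg.sim is not None:
        sim_cfg = cfg.sim
        ss1, ss2, panel, gene_df, seg_df, _ = simulate.simulate_study(sim_cfg)
        return ss1, ss2, panel, gene_df, seg_df
    ss1 = read_sumstats(cfg.sumstats_a)
    ss2 = read_sumstats(cfg.sumstats_b)
    panel = LDReference.load(cfg.ld_panel)
    gene_df = read_genes(cfg.genes_file) if cfg.genes_file else pd.DataFrame(
        columns=["gene_id", "chr", "tss", "tes", "strand"]
    )
    seg_df = read_segments(cfg.segments_file) if cfg.segments_file else None
    return ss1, ss2, panel, gene_df, seg_df


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the configured stages, writing one TSV per stage plus an index.

    Returns the in-memory stage tables keyed by stage name.  A stage
    failure raises :class:`PipelineError` naming the stage; downstream
    stages are skipped.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}

    ss1, ss2, panel, gene_df, seg_df = _load_inputs(cfg)
    pair = harmonize_pair(ss1, ss2, drop_palindromic=cfg.drop_palindromic)
    logger.info("pipeline: %d harmonized variants", len(pair))

    ld_scores = ldsc.compute_ld_scores(panel)
    null_cor = cfg.null_cor if not isinstance(cfg.null_cor, str) else 0.0

    for stage in cfg.stages:
        try:
            if stage == "rg":
                est = ldsc.estimate_rg(
                    pair, ld_scores,
                    constrain_gencov_intercept=cfg.constrain_gencov_intercept,
                )
                tbl = pd.DataFrame(
                    [{
                        "rg": est.rg, "se": est.se, "z": est.z, "p": est.p,
                        "gencov": est.gencov, "gencov_intercept": est.gencov_intercept,
                        "gencov_intercept_se": est.gencov_intercept_se,
                        "h2_obs_1": est.h2_1, "h2_obs_2": est.h2_2,
                        "n_snps": est.n_valid_snps,
                        "sig_0.05": est.p < 0.05 if np.isfinite(est.p) else False,
                        "sig_0.01": est.p < 0.01 if np.isfinite(est.p) else False,
                        "flag": est.flag,
                    }]
                )
                outputs["rg"] = tbl
                if cfg.null_cor == "from-rg" and np.isfinite(est.gencov_intercept):
                    null_cor = float(est.gencov_intercept)
            elif stage == "gwas-pw":
                if seg_df is None:
                    raise ValueError("segments are required for the gwas-pw stage")
                scan = regional.scan_segments(
                    pair, seg_df, null_cor=null_cor, priors=cfg.gwaspw_priors
                )
                outputs["gwas-pw"] = scan.table
                outputs["gwas-pw-calls"] = regional.call_pleiotropic_segments(scan)
            elif stage == "meta":
                meta_tbl, novel_tbl = meta.run_meta_stage(
                    pair, panel, gene_df, r2_merge=cfg.r2_merge, r2_lead=cfg.r2_lead
                )
                outputs["meta"] = meta_tbl
                outputs["meta-novel"] = novel_tbl
            elif stage == "mr":
                outputs["mr"] = mr.run_mr(
                    pair, panel, p_thresh=cfg.mr_p_thresh,
                    fallback_p=cfg.mr_fallback_p, seed=cfg.seed,
                )
            elif stage == "genes":
                if len(gene_df) == 0:
                    raise ValueError("gene annotation is required for the genes stage")
                s1 = _split_pair(pair, 1)
                s2 = _split_pair(pair, 2)
                g1 = genes_mod.gene_scan(s1, gene_df, panel, flank=cfg.gene_flank)
                g2 = genes_mod.gene_scan(s2, gene_df, panel, flank=cfg.gene_flank)
                outputs["genes-trait1"] = g1
                outputs["genes-trait2"] = g2
                ov = genes_mod.overlap_binomial(
                    g1, g2, s1, s2, panel, thresholds=cfg.overlap_thresholds
                )
                outputs["genes-overlap"] = pd.DataFrame([vars(o) for o in ov])
                eff_total = genes_mod.effective_gene_count(g1, s1, panel)
                outputs["genes-shared"] = genes_mod.call_shared_genes(g1, g2, max(eff_total, 1.0))
            else:
                raise ValueError(f"unknown stage '{stage}'")
        except Exception as e:  # halt with stage name; downstream skipped
            raise PipelineError(f"stage '{stage}' failed: {e}") from e

    for name, tbl in outputs.items():
        tbl.to_csv(os.path.join(cfg.out_dir, f"{name}.tsv"), sep="\t", index=False)
    make_report(outputs, cfg.out_dir)
    return outputs


def _split_pair(pair: pd.DataFrame, which: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": pair["snp"], "chr": pair["chr"], "pos": pair["pos"],
            "beta": pair[f"beta_{which}"], "se": pair[f"se_{which}"],
            "z": pair[f"z_{which}"], "log_p": pair[f"log_p_{which}"],
            "p": np.exp(np.maximum(pair[f"log_p_{which}"], -745.0)),
            "n": pair[f"n_{which}"],
        }
    )


def make_report(outputs: dict[str, pd.DataFrame], out_dir: str) -> str:
    """Plain-text index summarising every stage table that was produced."""
    lines = ["pleiocross report", "================="]
    for name, tbl in outputs.items():
        lines.append(f"\n[{name}] {len(tbl)} row(s) -> {name}.tsv")
        if name == "rg" and len(tbl):
            r = tbl.iloc[0]
            lines.append(
                f"  rg = {r['rg']:.4f} (se {r['se']:.4f}, p {r['p']:.3g}); "
                f"gencov intercept {r['gencov_intercept']:.4f}"
            )
        if name == "gwas-pw-calls":
            lines.append(f"  {len(tbl)} segment(s) with PPA3 > 0.5")
        if name == "meta-novel":
            lines.append(f"  {len(tbl)} novel loci" if len(tbl) else "  0 novel loci")
        if name == "genes-shared" and len(tbl):
            lines.append(f"  {int(tbl['gws'].sum())} shared gene(s) GWS at FCP threshold")
    text = "\n".join(lines) + "\n"
    path = os.path.join(out_dir, "report.txt")
    with open(path, "w") as fh:
        fh.write(text)
    return text
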