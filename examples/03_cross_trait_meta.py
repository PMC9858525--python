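"""Cross-trait meta-analysis with novel-locus discovery.

Simulates a genetically correlated trait pair, combines the per-variant
effects with a fixed-effect inverse-variance-weighted meta-analysis,
keeps variants that are genome-wide significant only in the combined
analysis, clumps them by LD, and applies the six-step masking procedure
that declares a lead variant novel when it is LD-independent (r^2 < 0.1)
of every single-trait genome-wide-significant variant.
"""

from pleiocross import harmonize_pair
from pleiocross.meta import run_meta_stage
from pleiocross.simulate import SimConfig, simulate_study

cfg = SimConfig(M=10_000, h2_1=0.3, h2_2=0.3, rg_true=0.5, N1=50_000, N2=50_000, seed=5)
ss1, ss2, panel, genes, _, _ = simulate_study(cfg)
pair = harmonize_pair(ss1, ss2)

meta, novel = run_meta_stage(pair, panel, genes)

n_gws_meta = int((meta["p_meta"] < 5e-8).sum())
n_cand = int(meta["shared_candidate"].sum())
print(f"variants GWS in meta-analysis        : {n_gws_meta}")
print(f"shared candidates (GWS meta only)    : {n_cand}")
print(f"novel lead variants after six steps  : {len(novel)}")
if len(novel):
    cols = ["snp", "pos", "p_meta", "p_1", "p_2"]
    print(novel[cols].to_string(index=False))
print()
print("Shared candidates reach p < 5e-8 only when the two traits are")
print("combined; the six-step procedure then removes any candidate that")
print("merely tags a known single-trait signal, so what remains are loci")
print("discoverable only through the cross-trait analysis.")
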