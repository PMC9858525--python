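"""Gene-based association and gene-level overlap between two GWAS.

Runs the GATES gene test for both traits of a simulated correlated
pair, then asks whether genes associated with trait 1 (discovery)
overlap genes associated with trait 2 (target) more often than chance,
using effective (LD-deflated) gene counts and a one-sided binomial
test, and finally calls individual shared genes with Fisher's combined
p-value.
"""

import pandas as pd

from pleiocross.genes import call_shared_genes, effective_gene_count, gene_scan, overlap_binomial
from pleiocross.pipeline import _split_pair
from pleiocross.simulate import SimConfig, simulate_study
from pleiocross.sumstats import harmonize_pair

cfg = SimConfig(M=10_000, h2_1=0.3, h2_2=0.3, rg_true=0.7, N1=15_000, N2=15_000,
                n_genes=300, gene_span=5_000, bp_spacing=3_000, seed=21)
ss1, ss2, panel, genes, _, _ = simulate_study(cfg)
pair = harmonize_pair(ss1, ss2)
s1, s2 = _split_pair(pair, 1), _split_pair(pair, 2)

g1 = gene_scan(s1, genes, panel)
g2 = gene_scan(s2, genes, panel)
print(f"genes tested: {len(g1)}; trait-1 genes with p < 0.05: {(g1.p_gates < 0.05).sum()}")

rows = overlap_binomial(g1, g2, s1, s2, panel)
tbl = pd.DataFrame([vars(r) for r in rows])
print(tbl[["threshold", "eff_discovery", "eff_overlap", "expected_prop",
           "observed_prop", "binomial_p"]].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

eff_total = effective_gene_count(g1, s1, panel)
shared = call_shared_genes(g1, g2, eff_total)
print(f"\nshared-gene calls (both p < 0.05): {len(shared)}, "
      f"of which {int(shared['gws'].sum())} pass the 0.05/{eff_total:.0f} cut")
print()
print("An observed overlap proportion above the expected one — here most")
print("clearly at the strictest threshold — is gene-level evidence of")
print("shared genetics; the Fisher-combined calls name the genes driving it.")
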