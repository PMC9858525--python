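"""GATES gene test, effective counts, overlap binomial, Fisher's combined p."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiocross.genes import (
    assign_snps_to_genes,
    binomial_overlap_p,
    call_shared_genes,
    effective_gene_count,
    effective_tests,
    fisher_combined,
    gates_pvalue,
    gene_scan,
)
from pleiocross.simulate import ar1_corr
from pleiocross.sumstats import LDReference


def _ss(positions, ps=None, chrom=1):
    n = len(positions)
    ps = np.full(n, 0.5) if ps is None else np.asarray(ps)
    z = stats.norm.isf(ps / 2)
    return pd.DataFrame(
        {
            "snp": [f"v{i}" for i in range(n)],
            "chr": chrom,
            "pos": positions,
            "p": ps,
            "log_p": np.log(ps),
            "z": z,
            "beta": z * 0.01,
            "se": 0.01,
            "n": 10_000,
        }
    )


class TestAssignment:
    GENES = pd.DataFrame(
        {"gene_id": ["g1"], "chr": [1], "tss": [50_000], "tes": [60_000], "strand": ["+"]}
    )

    def test_flank_boundary_closed(self):
        ss = _ss([35_000, 34_999, 75_000, 75_001])
        out = assign_snps_to_genes(ss, self.GENES, flank=15_000)
        assert out["g1"] == ["v0", "v2"]  # tss-15000 and tes+15000 in; one past out

    def test_brute_force_containment_oracle(self):
        rng = np.random.default_rng(2)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(4)],
                "chr": [1, 1, 1, 2],
                "tss": [10_000, 40_000, 41_000, 5_000],
                "tes": [20_000, 50_000, 90_000, 9_000],
                "strand": ["+"] * 4,
            }
        )
        pos = rng.integers(1, 120_000, size=20)
        ss = _ss(pos)
        out = assign_snps_to_genes(ss, genes, flank=15_000)
        for _, g in genes.iterrows():
            expected = [
                f"v{i}" for i, p in enumerate(pos)
                if g["tss"] - 15_000 <= p <= g["tes"] + 15_000 and 1 == g["chr"]
            ]
            assert out.get(g["gene_id"], []) == expected


class TestEffectiveTests:
    def test_identity(self):
        assert effective_tests(np.eye(5)) == pytest.approx(5.0)

    def test_perfect_pair(self):
        assert effective_tests(np.ones((2, 2))) == pytest.approx(1.0)

    def test_ar1_between_bounds_eigen_oracle(self):
        R = ar1_corr(10, 0.8)
        lam = np.linalg.eigvalsh(R)
        expected = 10 - np.sum(lam[lam > 1] - 1)
        me = effective_tests(R)
        assert me == pytest.approx(expected, rel=1e-12)
        assert 1.0 < me < 10.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            effective_tests(np.ones((2, 3)))


class TestGates:
    def test_single_variant_is_identity(self):
        assert gates_pvalue(np.array([0.03]), np.eye(1)) == pytest.approx(0.03)

    def test_two_independent_equals_simes(self):
        p = np.array([0.01, 0.5])
        # min(2*0.01/1, 2*0.5/2) = 0.02
        assert gates_pvalue(p, np.eye(2)) == pytest.approx(0.02)

    def test_perfect_ld_no_redundancy_penalty(self):
        p = np.array([0.01, 0.01])
        assert gates_pvalue(p, np.ones((2, 2))) == pytest.approx(0.01, rel=1e-6)

    def test_equals_simes_for_independent_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = np.sort(rng.uniform(size=8))
            simes = np.min(8 * p / np.arange(1, 9))
            assert gates_pvalue(p, np.eye(8)) == pytest.approx(min(simes, 1.0), rel=1e-9)

    def test_bounded_by_best_p_and_bonferroni(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            M = rng.integers(2, 12)
            R = ar1_corr(int(M), rng.uniform(0, 0.95))
            p = np.sort(rng.uniform(size=int(M)))
            g = gates_pvalue(p, R)
            assert p[0] - 1e-12 <= g <= min(1.0, M * p[0]) + 1e-9

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            gates_pvalue(np.array([0.5, 0.01]), np.eye(2))


class TestEffectiveGeneCount:
    def _results(self, best_snps, p=0.01):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(best_snps))],
                "best_snp": best_snps,
                "p_gates": p,
            }
        )

    def test_unlinked_best_variants_effective_equals_raw(self):
        panel = LDReference(
            blocks=[(np.array([f"v{i}"]), np.eye(1)) for i in range(4)], n_ref=1000
        )
        ss = _ss([100, 200, 300, 400])
        res = self._results(["v0", "v1", "v2", "v3"])
        assert effective_gene_count(res, ss, panel) == pytest.approx(4.0)

    def test_shared_best_variant_collapses(self):
        panel = LDReference(blocks=[(np.array(["v0"]), np.eye(1))], n_ref=1000)
        ss = _ss([100])
        res = self._results(["v0", "v0"])
        assert effective_gene_count(res, ss, panel) == pytest.approx(1.0)

    def test_toy_chromosome_eigen_oracle(self):
        """Six genes; two LD-duplicated best-SNP pairs give effective 4."""
        R = np.ones((2, 2))
        panel = LDReference(
            blocks=[
                (np.array(["a1", "a2"]), R.copy()),
                (np.array(["b1", "b2"]), R.copy()),
                (np.array(["c1"]), np.eye(1)),
                (np.array(["c2"]), np.eye(1)),
            ],
            n_ref=1000,
        )
        ss = _ss([100, 200, 300, 400, 500, 600])
        ss["snp"] = ["a1", "a2", "b1", "b2", "c1", "c2"]
        res = self._results(["a1", "a2", "b1", "b2", "c1", "c2"])
        assert effective_gene_count(res, ss, panel) == pytest.approx(4.0)

    def test_threshold_restricts_counts_monotonically(self):
        panel = LDReference(
            blocks=[(np.array([f"v{i}"]), np.eye(1)) for i in range(6)], n_ref=1000
        )
        ss = _ss([100 * (i + 1) for i in range(6)])
        res = self._results([f"v{i}" for i in range(6)])
        res["p_gates"] = [0.005, 0.02, 0.04, 0.08, 0.2, 0.9]
        counts = [effective_gene_count(res, ss, panel, threshold=t) for t in (0.01, 0.05, 0.1)]
        assert counts[0] <= counts[1] <= counts[2]


class TestOverlapBinomial:
    def test_null_behaviour_at_exact_expectation(self):
        # observed proportion equals expected: upper tail >= ~0.5
        p, _ = binomial_overlap_p(5, 10, 0.5)
        assert p >= 0.5

    def test_invalid_expected_rejected(self):
        with pytest.raises(ValueError):
            binomial_overlap_p(1, 10, 0.0)

    def test_log_tail_survives_underflow(self):
        p, log10p = binomial_overlap_p(5000, 5000, 1e-4)
        assert p == 0.0  # underflows on the natural scale
        assert log10p < -10_000  # but the log survives


class TestFisherCombined:
    def test_unit_pvalues(self):
        assert fisher_combined(1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form_example(self):
        X = -2 * (np.log(0.05) + np.log(0.05))
        expected = np.exp(-X / 2) * (1 + X / 2)
        assert expected == pytest.approx(0.0175, abs=0.0005)
        assert fisher_combined(0.05, 0.05) == pytest.approx(expected, rel=1e-12)

    def test_matches_chi2_4df(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p1, p2 = rng.uniform(size=2)
            X = -2 * (np.log(p1) + np.log(p2))
            assert fisher_combined(p1, p2) == pytest.approx(stats.chi2.sf(X, 4), rel=1e-9)

    def test_symmetry_and_monotonicity(self):
        assert fisher_combined(0.01, 0.3) == fisher_combined(0.3, 0.01)
        assert fisher_combined(0.01, 0.3) < fisher_combined(0.02, 0.3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fisher_combined(0.0, 0.5)


class TestSharedCalls:
    def test_threshold_rule(self):
        disc = pd.DataFrame({"gene_id": ["g1", "g2"], "p_gates": [1e-8, 0.04]})
        targ = pd.DataFrame({"gene_id": ["g1", "g2"], "p_gates": [1e-7, 0.3]})
        out = call_shared_genes(disc, targ, eff_total_genes=23_957)
        # g2 excluded (target p >= 0.05); g1 combined p far below 0.05/23957
        assert list(out["gene_id"]) == ["g1"]
        assert out.loc[0, "threshold"] == pytest.approx(0.05 / 23_957)
        assert bool(out.loc[0, "gws"])


class TestGeneScanIntegration:
    def test_scan_fields_and_invariants(self, small_study):
        g = gene_scan(
            small_study["ss1"], small_study["genes"], small_study["panel"]
        )
        assert len(g) > 0
        assert ((g["me"] >= 1) & (g["me"] <= g["n_snps"])).all()
        assert (g["p_gates"] >= g["p_best"] - 1e-12).all()
        assert (g["p_gates"] <= np.minimum(1.0, g["n_snps"] * g["p_best"]) + 1e-9).all()
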