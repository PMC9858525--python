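"""Two-sample MR estimators, pleiotropy diagnostics, instrument selection."""

import numpy as np
import pandas as pd
import pytest

from pleiocross.mr import (
    InstrumentError,
    InstrumentSet,
    heidi_filtered_ivw,
    instruments_from_pair,
    leave_one_out,
    mr_egger,
    mr_ivw,
    mr_presso,
    mr_weighted_median,
    wald_ratio,
)
from pleiocross.sumstats import LDReference


def make_instruments(b_zx, b_zy, se_zx=0.01, se_zy=0.01):
    k = len(b_zx)
    return InstrumentSet(
        snp=np.array([f"i{j}" for j in range(k)]),
        b_zx=np.asarray(b_zx, float),
        se_zx=np.full(k, se_zx) if np.isscalar(se_zx) else np.asarray(se_zx),
        b_zy=np.asarray(b_zy, float),
        se_zy=np.full(k, se_zy) if np.isscalar(se_zy) else np.asarray(se_zy),
    )


def simulate_instruments(k, true_effect, seed, pleio_offset=0.0, se_zx=0.005, se_zy=0.01):
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(0.05, 0.15, k) * rng.choice([-1, 1], k)
    bx = bx_true + rng.standard_normal(k) * se_zx
    by = true_effect * bx_true + pleio_offset * np.sign(bx_true) + rng.standard_normal(k) * se_zy
    return make_instruments(bx, by, se_zx, se_zy)


class TestWaldRatio:
    def test_basic_and_zero_outcome(self):
        beta, se = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert beta == pytest.approx(0.5) and se == pytest.approx(0.2)
        beta, se = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert beta == 0.0 and se == pytest.approx(0.2)

    def test_joint_sign_flip_invariant(self):
        assert wald_ratio(0.1, 0.01, 0.05, 0.02)[0] == wald_ratio(-0.1, 0.01, -0.05, 0.02)[0]

    def test_null_exposure_rejected(self):
        with pytest.raises(InstrumentError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_exact_ray(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        res = mr_ivw(make_instruments(bx, 0.3 * bx))
        assert res.beta == pytest.approx(0.3, rel=1e-10)
        assert res.q == pytest.approx(0.0, abs=1e-12)

    def test_two_instrument_precision_weighted_wald_oracle(self):
        bx, by = np.array([0.1, 0.2]), np.array([0.05, 0.02])
        se_y = np.array([0.01, 0.02])
        res = mr_ivw(make_instruments(bx, by, se_zy=se_y))
        ratios = by / bx
        w = bx**2 / se_y**2  # precision of each Wald ratio
        assert res.beta == pytest.approx(np.sum(w * ratios) / np.sum(w), rel=1e-10)

    def test_recovery_study(self):
        hits = 0
        for seed in range(50):
            instr = simulate_instruments(50, 0.2, seed)
            res = mr_ivw(instr)
            hits += abs(res.beta - 0.2) < 2 * res.se
        assert hits >= 45

    def test_orientation_invariance(self):
        instr = simulate_instruments(20, 0.2, 1)
        flipped = InstrumentSet(
            instr.snp, -instr.b_zx, instr.se_zx, -instr.b_zy, instr.se_zy
        )
        assert mr_ivw(flipped).beta == pytest.approx(mr_ivw(instr).beta, rel=1e-12)

    def test_minimum_instruments(self):
        with pytest.raises(InstrumentError):
            mr_ivw(make_instruments([0.1], [0.05]))


class TestWeightedMedian:
    def test_constant_ratios_exact(self):
        bx = np.array([0.05, 0.1, 0.2])
        res = mr_weighted_median(make_instruments(bx, 0.3 * bx), seed=0)
        assert res.beta == pytest.approx(0.3, rel=1e-9)

    def test_plain_median_for_equal_weights(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.02, 0.09])
        res = mr_weighted_median(make_instruments(bx, by), seed=0)
        assert res.beta == pytest.approx(0.2, rel=1e-9)

    def test_robust_to_minority_pleiotropy(self):
        """With 40% of instruments strongly pleiotropic, the weighted median
        stays nearer the truth than IVW in most replicates."""
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            instr = simulate_instruments(30, 0.2, seed)
            bad = rng.choice(30, size=12, replace=False)
            by = instr.b_zy.copy()
            by[bad] += 0.08
            dirty = InstrumentSet(instr.snp, instr.b_zx, instr.se_zx, by, instr.se_zy)
            med = mr_weighted_median(dirty, n_boot=50, seed=seed)
            ivw = mr_ivw(dirty)
            wins += abs(med.beta - 0.2) < abs(ivw.beta - 0.2)
        assert wins > 25


class TestEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        res = mr_egger(make_instruments(bx, 0.02 + 0.5 * bx))
        assert res.intercept == pytest.approx(0.02, rel=1e-8)
        assert res.beta == pytest.approx(0.5, rel=1e-8)

    def test_no_pleiotropy_null_intercept(self):
        instr = simulate_instruments(50, 0.2, 7)
        res = mr_egger(instr)
        assert abs(res.intercept) < 2 * res.intercept_se

    def test_directional_pleiotropy_recovered(self):
        hits_int = 0
        for seed in range(20):
            instr = simulate_instruments(50, 0.2, 2000 + seed, pleio_offset=0.05)
            res = mr_egger(instr)
            hits_int += abs(res.intercept - 0.05) < 2 * res.intercept_se
        assert hits_int >= 18


class TestLeaveOneOut:
    def test_matches_full_recompute_oracle(self):
        instr = simulate_instruments(10, 0.2, 3)
        loo = leave_one_out(instr)
        for i in range(10):
            sub = instr.drop([i])
            oracle = mr_ivw(sub)
            row = loo.iloc[i]
            assert row["beta"] == pytest.approx(oracle.beta, rel=1e-12)

    def test_outlier_shifts_exactly_one_row(self):
        instr = simulate_instruments(10, 0.2, 4, se_zy=0.001)
        by = instr.b_zy.copy()
        by[3] += 0.5
        dirty = InstrumentSet(instr.snp, instr.b_zx, instr.se_zx, by, instr.se_zy)
        loo = leave_one_out(dirty)
        full = mr_ivw(dirty).beta
        shifts = np.abs(loo["beta"] - full)
        assert shifts.idxmax() == 3


class TestPresso:
    def test_deterministic_given_seed(self):
        instr = simulate_instruments(20, 0.2, 5)
        a = mr_presso(instr, n_sim=200, seed=9)
        b = mr_presso(instr, n_sim=200, seed=9)
        assert a.global_p == b.global_p and a.outliers == b.outliers

    def test_spiked_outlier_flagged_and_corrected(self):
        flagged = 0
        closer = 0
        for seed in range(25):
            instr = simulate_instruments(30, 0.2, 3000 + seed)
            by = instr.b_zy.copy()
            by[7] += 0.3
            dirty = InstrumentSet(instr.snp, instr.b_zx, instr.se_zx, by, instr.se_zy)
            res = mr_presso(dirty, n_sim=300, seed=seed)
            flagged += 7 in res.outliers
            if res.corrected_beta is not None:
                closer += abs(res.corrected_beta - 0.2) < abs(res.beta - 0.2)
        assert flagged >= 22
        assert closer >= 20

    def test_minimum_instruments(self):
        with pytest.raises(InstrumentError):
            mr_presso(simulate_instruments(3, 0.2, 1))

    def test_floor_reported_as_inequality(self):
        instr = simulate_instruments(20, 0.2, 6)
        by = instr.b_zy.copy()
        by[::4] += 0.5
        res = mr_presso(
            InstrumentSet(instr.snp, instr.b_zx, instr.se_zx, by, instr.se_zy),
            n_sim=100, seed=1,
        )
        if res.global_p_at_floor:
            assert res.format_p().startswith("<")


class TestHeidi:
    def test_homogeneous_ratios_nothing_removed(self):
        bx = np.linspace(0.05, 0.2, 20)
        instr = make_instruments(bx, 0.2 * bx)  # every Wald ratio exactly 0.2
        res = heidi_filtered_ivw(instr)
        assert res.outliers == []
        ivw = mr_ivw(instr)
        assert abs(res.beta - ivw.beta) <= 0.1 * max(ivw.se, 1e-12) + 1e-9

    def test_gross_pleiotropic_instrument_removed(self):
        bx = np.full(10, 0.1)
        by = np.full(10, 0.02)
        by[0] = 0.10  # ratio 1.0 vs 0.2 elsewhere
        instr = make_instruments(bx, by, se_zx=0.002, se_zy=0.002)
        res = heidi_filtered_ivw(instr)
        assert 0 in res.outliers

    def test_disabled_filter_keeps_everything(self):
        instr = simulate_instruments(15, 0.2, 9)
        res = heidi_filtered_ivw(instr, heidi_p=0.0)
        assert res.outliers == []
        assert res.n_instruments == 15


class TestSelection:
    @pytest.fixture()
    def pair_with_hits(self, small_study):
        return small_study["pair"], small_study["panel"]

    def test_selection_respects_ld_independence(self, pair_with_hits):
        pair, panel = pair_with_hits
        try:
            instr = instruments_from_pair(pair, panel, exposure=1, fallback_p=1e-3)
        except InstrumentError:
            pytest.skip("no instruments at this seed")
        for i in range(len(instr)):
            for j in range(i + 1, len(instr)):
                assert panel.r2(instr.snp[i], instr.snp[j]) < 0.1

    def test_single_instrument_ivw_equals_wald(self):
        instr = make_instruments([0.1, 0.2], [0.05, 0.1])
        one = InstrumentSet(
            instr.snp[:1], instr.b_zx[:1], instr.se_zx[:1], instr.b_zy[:1], instr.se_zy[:1]
        )
        # IVW through the origin with a single point is the Wald ratio
        from pleiocross.mr import _ivw_fit

        beta, se, _ = _ivw_fit(one.b_zx, one.se_zx, one.b_zy, one.se_zy)
        wr, wr_se = wald_ratio(one.b_zx[0], one.se_zx[0], one.b_zy[0], one.se_zy[0])
        assert beta == pytest.approx(wr, rel=1e-12)
        assert se == pytest.approx(wr_se, rel=1e-12)
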