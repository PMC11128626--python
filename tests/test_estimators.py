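"""The five-estimator panel and the sensitivity suite."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrmediate.errors import InputError
from mrmediate.estimators import (
    _silverman_bandwidth,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mode_estimate,
    mr_presso,
    or_from_beta,
    wald_ratio,
    weighted_median,
)


def _flip(instruments, idx):
    out = []
    for k, inst in enumerate(instruments):
        if k in idx:
            inst = dataclasses.replace(
                inst,
                beta_exposure=-inst.beta_exposure,
                beta_outcome=-inst.beta_outcome,
                effect_allele=inst.other_allele,
                other_allele=inst.effect_allele,
            )
        out.append(inst)
    return out


class TestWaldRatio:
    def test_hand_arithmetic(self, make_instruments):
        (inst,) = make_instruments([0.02], [0.01], [-0.001], [0.004])
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(-0.05)
        assert est.se == pytest.approx(0.2)

    def test_flip_symmetry(self, make_instruments):
        (inst,) = make_instruments([1.0], [0.1], [0.5], [0.1])
        assert wald_ratio(inst).beta == pytest.approx(0.5)
        (flipped,) = _flip([inst], {0})
        assert wald_ratio(flipped).beta == pytest.approx(0.5)

    def test_zero_exposure_effect_rejected(self, make_instruments):
        (inst,) = make_instruments([0.0], [0.1], [0.5], [0.1])
        with pytest.raises(InputError):
            wald_ratio(inst)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self, make_instruments):
        insts = make_instruments([0.1], [0.01], [0.05], [0.02])
        assert ivw(insts).beta == pytest.approx(wald_ratio(insts[0]).beta)

    def test_consensus_ratio(self, make_instruments):
        insts = make_instruments([0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12], [0.02] * 3)
        est = ivw(insts)
        assert est.beta == pytest.approx(0.3)
        assert cochran_q(insts).Q == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_wls_through_origin_oracle(self, random_instruments, seed):
        insts = random_instruments(j=12, theta=0.25, seed=seed)
        bx = np.array([i.beta_exposure for i in insts])
        by = np.array([i.beta_outcome for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        fit = sm.WLS(by, bx, weights=sy**-2).fit()
        est = ivw(insts, model="fixed")
        assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales the variance by RSS/df; the fixed-effect IVW SE
        # divides that scale back out.
        assert est.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), abs=1e-10)

    def test_random_effects_never_tighter_than_fixed(self, random_instruments):
        insts = random_instruments(j=15, theta=0.1, seed=3, sy=0.1)
        assert ivw(insts, model="random").se >= ivw(insts, model="fixed").se

    def test_allele_flip_invariance(self, random_instruments):
        insts = random_instruments(j=8, theta=0.4, seed=7)
        est = ivw(insts)
        est_f = ivw(_flip(insts, {0, 3, 5}))
        assert est_f.beta == pytest.approx(est.beta, abs=1e-12)
        assert est_f.se == pytest.approx(est.se, abs=1e-12)


class TestEgger:
    def test_exact_line(self, make_instruments):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        insts = make_instruments(bx, [0.01] * 4, 0.3 * bx, [0.02, 0.03, 0.04, 0.05])
        res = egger(insts)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine_shift_moves_intercept_only(self, make_instruments):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.1, 0.5, 5)
        by = 0.2 * bx + rng.normal(0, 0.01, 5)
        sy = rng.uniform(0.01, 0.05, 5)
        base = egger(make_instruments(bx, [0.01] * 5, by, sy))
        shifted = egger(make_instruments(bx, [0.01] * 5, by + 0.07, sy))
        assert shifted.slope.beta == pytest.approx(base.slope.beta, abs=1e-12)
        assert shifted.intercept == pytest.approx(base.intercept + 0.07, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generic_wls_oracle(self, random_instruments, seed):
        insts = random_instruments(j=10, theta=0.3, seed=100 + seed)
        bx = np.array([i.beta_exposure for i in insts])
        by = np.array([i.beta_outcome for i in insts])
        sy = np.array([i.se_outcome for i in insts])
        flip = np.sign(bx)
        bx, by = bx * flip, by * flip
        fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2).fit()
        res = egger(insts)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        # SEs agree once both use the same variance scale (ours never drops
        # below the fixed-effect scale).
        expect_scale = max(1.0, fit.scale)
        assert res.slope.se == pytest.approx(
            fit.bse[1] * np.sqrt(expect_scale / fit.scale), abs=1e-10
        )

    def test_requires_three_instruments(self, make_instruments):
        with pytest.raises(InputError):
            egger(make_instruments([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.02] * 2))


class TestWeightedMedian:
    def test_equal_weight_interpolation(self, make_instruments):
        # equal weights, ratios {1, 2, 9}: cumulative midpoints {1/6, 1/2, 5/6}
        insts = make_instruments([0.1] * 3, [0.01] * 3, [0.1, 0.2, 0.9], [0.02] * 3)
        assert weighted_median(insts, n_boot=0).beta == pytest.approx(2.0)

    def test_consensus(self, make_instruments):
        insts = make_instruments([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.02] * 3)
        assert weighted_median(insts, n_boot=0).beta == pytest.approx(0.5)

    def test_bootstrap_determinism(self, random_instruments):
        insts = random_instruments(j=8, theta=0.2, seed=1)
        a = weighted_median(insts, n_boot=200, seed=11)
        b = weighted_median(insts, n_boot=200, seed=11)
        assert a.se == b.se

    def test_seed_required_for_bootstrap(self, random_instruments):
        with pytest.raises(InputError):
            weighted_median(random_instruments(j=5, seed=0), n_boot=100)


class TestModeEstimate:
    def test_majority_mode_ignores_outlier(self, make_instruments):
        insts = make_instruments([0.1] * 4, [0.01] * 4, [0.1, 0.1, 0.1, 5.0], [0.02] * 4)
        assert mode_estimate(insts, weighted=False, n_boot=0).beta == pytest.approx(1.0)

    def test_consensus(self, make_instruments):
        insts = make_instruments([0.1, 0.2, 0.5], [0.01] * 3, [0.07, 0.14, 0.35], [0.02] * 3)
        assert mode_estimate(insts, weighted=True, n_boot=0).beta == pytest.approx(0.7)

    def test_argmax_matches_grid_scan_oracle(self, make_instruments):
        bx = np.array([0.2, 0.3, 0.25, 0.4, 0.35, 0.28])
        by = np.array([0.05, 0.09, 0.06, 0.13, 0.10, 0.08])
        sy = np.array([0.02, 0.03, 0.02, 0.04, 0.03, 0.02])
        insts = make_instruments(bx, [0.01] * 6, by, sy)
        ratios = by / bx
        w = (bx / sy) ** 2
        w = w / w.sum()
        h = _silverman_bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 200_001)
        dens = (w[None, :] * stats.norm.pdf((grid[:, None] - ratios[None, :]) / h)).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        est = mode_estimate(insts, weighted=True, n_boot=0)
        tol = (grid[-1] - grid[0]) / 2048  # implementation grid resolution
        assert est.beta == pytest.approx(oracle, abs=tol)

    def test_bootstrap_determinism(self, random_instruments):
        insts = random_instruments(j=8, theta=0.2, seed=2)
        a = mode_estimate(insts, n_boot=100, seed=5)
        b = mode_estimate(insts, n_boot=100, seed=5)
        assert a.se == b.se


class TestCochranQ:
    def test_identical_ratios(self, make_instruments):
        insts = make_instruments([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        res = cochran_q(insts)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.pvalue == pytest.approx(1.0)

    def test_two_point_closed_form(self, make_instruments):
        # equal weights w, ratios differing by d: Q = w d^2 / 2
        bx, sy = 0.2, 0.04
        d = 0.3
        insts = make_instruments([bx, bx], [0.01] * 2, [0.5 * bx, (0.5 + d) * bx], [sy, sy])
        w = (bx / sy) ** 2
        assert cochran_q(insts).Q == pytest.approx(w * d**2 / 2)

    def test_null_mean_q_near_df(self, make_instruments):
        """On data simulated under the homogeneous model, E[Q] ~ J-1."""
        rng = np.random.default_rng(9)
        j, reps = 8, 500
        qs = []
        for _ in range(reps):
            gamma = rng.uniform(0.2, 0.5, j)
            sy = np.full(j, 0.05)
            by = rng.normal(0.3 * gamma, sy)
            qs.append(cochran_q(make_instruments(gamma, [0.0001] * j, by, sy)).Q)
        mean_ratio = np.mean(qs) / (j - 1)
        assert 0.9 < mean_ratio < 1.1


class TestLeaveOneOut:
    def test_output_length(self, random_instruments):
        insts = random_instruments(j=7, seed=4)
        assert len(leave_one_out(insts)) == 7

    def test_identical_instruments_leave_estimate_unchanged(self, make_instruments):
        insts = make_instruments([0.2] * 5, [0.01] * 5, [0.1] * 5, [0.02] * 5)
        full = ivw(insts).beta
        for _, est in leave_one_out(insts):
            assert est.beta == pytest.approx(full)

    def test_planted_outlier_moves_most(self, random_instruments, make_instruments):
        insts = random_instruments(j=9, theta=0.2, seed=6)
        bad = dataclasses.replace(insts[4], beta_outcome=insts[4].beta_outcome + 0.5)
        insts = insts[:4] + [bad] + insts[5:]
        full = ivw(insts).beta
        deltas = {vid: abs(est.beta - full) for vid, est in leave_one_out(insts)}
        assert max(deltas, key=deltas.get) == bad.variant_id


class TestMRPresso:
    def test_determinism(self, random_instruments):
        insts = random_instruments(j=10, theta=0.2, seed=8)
        a = mr_presso(insts, n_sim=1000, seed=3)
        b = mr_presso(insts, n_sim=1000, seed=3)
        assert a.global_pvalue == b.global_pvalue
        assert a.outlier_indices == b.outlier_indices
        assert np.array_equal(a.outlier_pvalues, b.outlier_pvalues)

    def test_planted_outlier_recovered(self, random_instruments):
        insts = random_instruments(j=10, theta=0.2, seed=12)
        shifted = dataclasses.replace(
            insts[6], beta_outcome=insts[6].beta_outcome + 10 * insts[6].se_outcome
        )
        insts = insts[:6] + [shifted] + insts[7:]
        res = mr_presso(insts, n_sim=2000, seed=21)
        assert 6 in res.outlier_indices
        assert res.distortion_pvalue is not None

    def test_minimum_instruments_enforced(self, random_instruments):
        with pytest.raises(InputError, match="4"):
            mr_presso(random_instruments(j=3, seed=0), n_sim=1000, seed=0)


class TestORScale:
    def test_log_odds_to_or(self):
        assert or_from_beta(0.0)[0] == pytest.approx(1.0)
        or_, lo, hi = or_from_beta(0.1, se=0.05)
        assert (lo, hi) == pytest.approx(
            (np.exp(0.1 - 1.959963984540054 * 0.05), np.exp(0.1 + 1.959963984540054 * 0.05))
        )

    def test_printed_ci_is_exp_transformed(self):
        or_, lo, hi = or_from_beta(-0.0171, ci=(-0.0277, -0.0065))
        assert or_ == pytest.approx(np.exp(-0.0171))
        assert lo == pytest.approx(np.exp(-0.0277))
        assert hi == pytest.approx(np.exp(-0.0065))


class TestPanelInvariance:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_all_estimators_flip_invariant(self, random_instruments, seed):
        insts = random_instruments(j=10, theta=0.3, seed=30 + seed)
        flipped = _flip(insts, {1, 4, 8})
        assert ivw(flipped).beta == pytest.approx(ivw(insts).beta, abs=1e-12)
        assert egger(flipped).slope.beta == pytest.approx(egger(insts).slope.beta, abs=1e-12)
        assert weighted_median(flipped, n_boot=0).beta == pytest.approx(
            weighted_median(insts, n_boot=0).beta, abs=1e-12
        )
        for weighted in (False, True):
            assert mode_estimate(flipped, weighted=weighted, n_boot=0).beta == pytest.approx(
                mode_estimate(insts, weighted=weighted, n_boot=0).beta, abs=1e-12
            )


class TestPleiotropyBehaviour:
    def test_egger_intercept_calibrated_under_balanced_pleiotropy(self, make_instruments):
        """Mean-zero direct effects inflate heterogeneity but should not
        trigger the directional-pleiotropy (intercept) alarm beyond its
        nominal rate."""
        from mrmediate.simulate import Pleiotropy, SimulationConfig, simulate_two_sample
        from mrmediate.summary_io import harmonize

        cfg = dict(
            n_variants=100, n_causal=60, n_causal_mediator=20, gamma_sd=0.15,
            theta_em=0.0, theta_mo=0.0, theta_direct=0.1,
            case_fraction=0.3, case_fraction_mediator=0.3,
            pleiotropy=Pleiotropy("balanced", sd=0.01),
        )
        rej, reps = 0, 500
        for s in range(reps):
            study = simulate_two_sample(SimulationConfig(seed=s, **cfg))
            gamma = np.abs(np.array(study.truth["gamma"]))
            se_x = np.array([r.se for r in study.exposure_stats])
            top = np.argsort(gamma / se_x)[-50:]
            harm = harmonize(
                [study.exposure_stats[i] for i in top], study.outcome_stats
            ).instruments
            rej += egger(harm).intercept_pvalue < 0.05
        assert 0.02 <= rej / reps <= 0.09, f"intercept rejection {rej / reps}"

    def test_directional_pleiotropy_biases_ivw_but_not_egger_slope(self, make_instruments):
        """With positive-oriented instruments and direct effects of constant
        sign drawn independently of instrument strength (InSIDE), IVW drifts
        in the planted direction while the Egger slope stays unbiased."""
        theta, reps, j = 0.2, 200, 30
        ivws, eggs = [], []
        for s in range(reps):
            rng = np.random.default_rng(s)
            gamma = rng.uniform(0.1, 0.4, j)
            sx, sy = np.full(j, 0.01), np.full(j, 0.03)
            alpha = rng.normal(0.02, 0.01, j)  # directional, independent of gamma
            bx = rng.normal(gamma, sx)
            by = rng.normal(theta * gamma + alpha, sy)
            insts = make_instruments(bx, sx, by, sy)
            ivws.append(ivw(insts).beta)
            eggs.append(egger(insts).slope.beta)
        ivws, eggs = np.asarray(ivws), np.asarray(eggs)
        mcse_i = ivws.std(ddof=1) / np.sqrt(reps)
        mcse_e = eggs.std(ddof=1) / np.sqrt(reps)
        assert ivws.mean() - theta > 3 * mcse_i  # biased upward, the planted sign
        assert abs(eggs.mean() - theta) < 3 * mcse_e
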