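import math

import numpy as np
import pytest

from hybridfep import (
    EstimatorConfig, EnergySamples, WindowSamples, AffinityPair,
    zwanzig_dg, bar_dg, estimate_leg, solve_cycle, ki_to_ddg,
    read_samples, write_samples, GaussianWorkSpec, gaussian_work_samples,
)
from hybridfep.estimators import EstimatorError, bar_residual

CFG = EstimatorConfig()
BETA = CFG.beta


def _single_interface(w_f, w_r=None):
    n = len(w_f)
    windows = [WindowSamples(stage=1, index=0, lam=0.0, u_self=np.zeros(n),
                             u_forward=np.asarray(w_f, dtype=float))]
    if w_r is not None:
        windows.append(WindowSamples(stage=1, index=1, lam=1.0,
                                     u_self=np.zeros(len(w_r)),
                                     u_reverse=np.asarray(w_r, dtype=float)))
    else:
        windows.append(WindowSamples(stage=1, index=1, lam=1.0,
                                     u_self=np.zeros(n)))
    return EnergySamples(windows=tuple(windows))


def _bar_fixed_point_oracle(w_f, w_r, beta, tol=1e-10):
    """Independent BAR solver: damped fixed-point iteration on the
    logarithmic form of the acceptance-ratio equation (no root
    bracketing, different algorithm from the implementation)."""
    w_f = np.asarray(w_f)
    w_r = np.asarray(w_r)
    m = math.log(len(w_f) / len(w_r))

    def log_mean_fermi(x):
        return -np.logaddexp.reduce(np.logaddexp(0.0, x)) \
            if False else np.log(np.mean(1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))))

    dg = float(np.mean(w_f))
    for _ in range(10_000):
        num = log_mean_fermi(-m + beta * (w_r + dg))
        den = log_mean_fermi(m + beta * (w_f - dg))
        step = (num - den) / beta
        dg_new = dg + 0.5 * step
        if abs(dg_new - dg) < tol:
            return dg_new
        dg = dg_new
    raise RuntimeError("oracle did not converge")


class TestZwanzig:
    def test_identity_perturbation_is_exactly_zero(self):
        es = _single_interface(np.zeros(100))
        per, total = zwanzig_dg(es, CFG)
        assert per == [0.0]
        assert total == 0.0

    def test_constant_difference(self):
        es = _single_interface(np.full(50, 2.5))
        _, total = zwanzig_dg(es, CFG)
        assert total == pytest.approx(2.5, abs=1e-12)

    def test_gaussian_cumulant_closed_form(self):
        """For Gaussian forward differences N(mu, sigma^2) the exact
        answer is mu - beta*sigma^2/2; the log-sum-exp path must also
        agree with a brute-force numeric average."""
        mu, sigma, n = 1.0, 0.5, 1_000_000
        rng = np.random.default_rng(5)
        w = rng.normal(mu, sigma, n)
        _, total = zwanzig_dg(_single_interface(w), CFG)
        brute = -np.log(np.mean(np.exp(-BETA * w))) / BETA
        assert total == pytest.approx(brute, abs=1e-9)
        closed = mu - BETA * sigma**2 / 2
        se = sigma / math.sqrt(n)  # conservative scale for the estimator error
        assert abs(total - closed) < 3 * se * 3

    def test_no_overflow_for_large_differences(self):
        es = _single_interface(np.array([1e4, 1e4 + 1, 1e4 - 1]))
        _, total = zwanzig_dg(es, CFG)
        assert np.isfinite(total)

    def test_empty_series_rejected(self):
        with pytest.raises(EstimatorError):
            WindowSamples(stage=1, index=0, lam=0.0, u_self=np.array([]))


class TestBar:
    def test_degenerate_overlap_fixed_point(self):
        es = _single_interface(np.full(40, 3.0), np.full(40, -3.0))
        per, total, consts, warnings = bar_dg(es, CFG)
        assert total == pytest.approx(3.0, abs=1e-6)
        assert consts[0] == pytest.approx(3.0, abs=1e-6)

    def test_crooks_consistent_gaussian_recovery(self):
        es = gaussian_work_samples(GaussianWorkSpec(dg_true=1.0, sigma=1.0,
                                                    n=100_000, seed=7))
        _, total, _, warnings = bar_dg(es, CFG)
        se = 1.0 / math.sqrt(100_000)
        assert abs(total - 1.0) < 3 * se * 3
        assert warnings == []

    def test_mirrored_distributions_give_zero(self):
        rng = np.random.default_rng(11)
        w = rng.normal(0.0, 1.0, 20_000)
        _, total, _, _ = bar_dg(_single_interface(w, -w), CFG)
        assert abs(total) < 0.05

    def test_agrees_with_independent_fixed_point_oracle(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            w_f = rng.normal(1.5, 0.8, 5000)
            w_r = rng.normal(-1.2, 0.8, 4000)  # unequal sample counts
            _, total, _, _ = bar_dg(_single_interface(w_f, w_r), CFG)
            oracle = _bar_fixed_point_oracle(w_f, w_r, BETA)
            assert total == pytest.approx(oracle, abs=1e-5)

    def test_fixed_point_residual_below_tolerance(self):
        es = gaussian_work_samples(GaussianWorkSpec(dg_true=0.7, sigma=1.2,
                                                    n=20_000, seed=3))
        per, _, _, _ = bar_dg(es, CFG)
        a, b = next(iter(es.interfaces()))
        w_f = a.u_forward - a.u_self
        w_r = b.u_reverse - b.u_self
        assert abs(bar_residual(w_f, w_r, per[0], BETA)) < 1e-6

    def test_zero_overlap_warning(self):
        es = _single_interface(np.full(30, 100.0), np.full(30, 100.0))
        _, _, _, warnings = bar_dg(es, CFG)
        assert warnings

    def test_missing_reverse_rejected(self):
        es = _single_interface(np.zeros(10))
        with pytest.raises(EstimatorError):
            bar_dg(es, CFG)


class TestGaugeInvariance:
    def test_uniform_energy_offset_leaves_estimates_unchanged(self):
        es = gaussian_work_samples(GaussianWorkSpec(dg_true=0.9, sigma=0.7,
                                                    n=5000, seed=9))
        shifted = EnergySamples(windows=tuple(
            WindowSamples(stage=w.stage, index=w.index, lam=w.lam,
                          u_self=w.u_self + 123.4,
                          u_forward=None if w.u_forward is None
                          else w.u_forward + 123.4,
                          u_reverse=None if w.u_reverse is None
                          else w.u_reverse + 123.4)
            for w in es.windows))
        assert zwanzig_dg(es, CFG)[1] == pytest.approx(
            zwanzig_dg(shifted, CFG)[1], abs=1e-9)
        assert bar_dg(es, CFG)[1] == pytest.approx(
            bar_dg(shifted, CFG)[1], abs=1e-6)


def _leg_from_values(values):
    reps = [_single_interface(np.full(10, v)) for v in values]
    return estimate_leg(reps, EstimatorConfig(method="zwanzig"))


class TestEstimateLeg:
    def test_mean_and_sem_arithmetic(self):
        leg = _leg_from_values([1.0, 2.0, 3.0])
        assert leg.mean_dg == pytest.approx(2.0)
        assert leg.sem == pytest.approx(1.0 / math.sqrt(3))

    def test_identical_replicas_have_zero_sem(self):
        leg = _leg_from_values([1.5] * 10)
        assert leg.sem == 0.0

    def test_per_replica_total_is_window_sum(self):
        spec = GaussianWorkSpec(dg_true=1.0, sigma=1.0, n=500, seed=2)
        leg = estimate_leg([gaussian_work_samples(spec)],
                           EstimatorConfig(method="bar"))
        assert leg.per_replica_dg[0] == pytest.approx(
            sum(leg.per_window_dg[0]), abs=1e-9)

    def test_mismatched_structure_rejected(self):
        a = _single_interface(np.zeros(5))
        b = EnergySamples(windows=(
            WindowSamples(stage=1, index=0, lam=0.0, u_self=np.zeros(5),
                          u_forward=np.zeros(5)),
            WindowSamples(stage=1, index=1, lam=0.5, u_self=np.zeros(5),
                          u_forward=np.zeros(5)),
            WindowSamples(stage=1, index=2, lam=1.0, u_self=np.zeros(5)),
        ))
        with pytest.raises(EstimatorError):
            estimate_leg([a, b], EstimatorConfig(method="zwanzig"))

    def test_three_sem_calibration_over_many_seeds(self):
        """Coverage of the analytic value at ±3 SEM over 200 seeded
        repetitions of 10 Gaussian replicas.  With 10 replicas the
        mean/SEM ratio follows Student's t with 9 dof, whose 3-sigma
        coverage is 98.6%, so the empirical rate must exceed ~96%."""
        for method in ("bar", "zwanzig"):
            hits = 0
            for rep in range(200):
                replicas = [gaussian_work_samples(
                    GaussianWorkSpec(dg_true=1.0, sigma=1.0, n=2000,
                                     seed=1000 * rep + k))
                    for k in range(10)]
                leg = estimate_leg(replicas, EstimatorConfig(method=method))
                if abs(leg.mean_dg - 1.0) <= 3 * leg.sem:
                    hits += 1
            assert hits >= 192, method


class TestSolveCycle:
    def test_arithmetic_and_quadrature(self):
        a = _leg_from_values([1.7, 2.0, 2.3])
        b = _leg_from_values([0.1, 0.5, 0.9])
        a = a.__class__(**{**a.__dict__, "mean_dg": 2.0, "sem": 0.3})
        b = b.__class__(**{**b.__dict__, "mean_dg": 0.5, "sem": 0.4})
        cy = solve_cycle(a, b)
        assert cy.ddg == pytest.approx(1.5)
        assert cy.sem == pytest.approx(0.5)

    def test_identical_legs_cancel(self):
        a = _leg_from_values([1.0, 2.0])
        cy = solve_cycle(a, a)
        assert cy.ddg == 0.0

    def test_antisymmetry_under_leg_swap(self):
        a = _leg_from_values([2.0, 2.2])
        b = _leg_from_values([0.4, 0.6])
        assert solve_cycle(a, b).ddg == pytest.approx(-solve_cycle(b, a).ddg)

    def test_protocol_mismatch_rejected(self):
        a = _leg_from_values([1.0, 2.0])
        b = estimate_leg(
            [EnergySamples(windows=(
                WindowSamples(stage=1, index=0, lam=0.0, u_self=np.zeros(5),
                              u_forward=np.zeros(5)),
                WindowSamples(stage=1, index=1, lam=0.4, u_self=np.zeros(5),
                              u_forward=np.zeros(5)),
                WindowSamples(stage=1, index=2, lam=1.0, u_self=np.zeros(5)),
            ))],
            EstimatorConfig(method="zwanzig"))
        with pytest.raises(EstimatorError):
            solve_cycle(a, b)

    def test_unknown_kind(self):
        a = _leg_from_values([1.0, 2.0])
        with pytest.raises(ValueError):
            solve_cycle(a, a, kind="osmosis")


class TestKiToDdg:
    def test_identity(self):
        assert ki_to_ddg(AffinityPair(3.0, 3.0)) == 0.0

    def test_tenfold_ratio_at_298(self):
        assert ki_to_ddg(AffinityPair(1.0, 10.0)) == pytest.approx(1.3634,
                                                                   abs=2e-4)

    def test_antisymmetry(self):
        fwd = ki_to_ddg(AffinityPair(2.0, 14.0))
        rev = ki_to_ddg(AffinityPair(14.0, 2.0))
        assert fwd == pytest.approx(-rev)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            AffinityPair(0.0, 1.0)


def test_sample_file_round_trip(tmp_path):
    es = gaussian_work_samples(GaussianWorkSpec(dg_true=0.5, sigma=0.8,
                                                n=100, seed=1))
    path = tmp_path / "replica.csv"
    write_samples(es, path)
    back = read_samples(path)
    assert back.structure_signature() == es.structure_signature()
    for a, b in zip(es.ordered(), back.ordered()):
        assert np.allclose(a.u_self, b.u_self)
        if a.u_forward is not None:
            assert np.allclose(a.u_forward, b.u_forward)
    # estimates agree after the round trip
    assert bar_dg(back, CFG)[1] == pytest.approx(bar_dg(es, CFG)[1], abs=1e-7)
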