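"""Synthetic fixture generators with known free energies.

Every estimator in this package can be validated without molecular
dynamics using two exactly solvable systems:

* **Gaussian work distributions** consistent with the Crooks fluctuation
  theorem: forward work ~ N(ΔG + βσ²/2, σ²) and reverse work
  ~ N(−ΔG + βσ²/2, σ²) share the true free-energy difference ΔG by
  construction.
* **A 1-D harmonic λ-coupled system**: U_A = ½k_A x², U_B = ½k_B(x−d)².
  The mixed potential U_λ = (1−λ)U_A + λU_B is sampled by Metropolis
  Monte Carlo per window; the exact answer ΔG = ln(k_B/k_A)/(2β) is
  independent of the displacement d, so a pure translation is a strong
  null test.

All sampling is seeded and reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimators import EnergySamples, WindowSamples, EstimatorConfig
from .fep_protocol import FepProtocol, LambdaSchedule, PerturbationStage, \
    sigmoidal_lambdas, linear_lambdas

__all__ = [
    "GaussianWorkSpec", "HarmonicToyModel", "ToyCycleFixture",
    "gaussian_work_samples", "harmonic_toy_fep", "analytic_dg",
    "cycle_fixture", "build_toy_protocol",
]


@dataclass(frozen=True)
class GaussianWorkSpec:
    dg_true: float = 1.0     # kcal·mol⁻¹
    sigma: float = 1.0       # kcal·mol⁻¹
    n: int = 100_000
    seed: int = 0
    temperature: float = 298.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def gaussian_work_samples(spec: GaussianWorkSpec) -> EnergySamples:
    """Single-interface energy samples with Crooks-consistent Gaussian
    work distributions (forward at window 0, reverse at window 1)."""
    beta = EstimatorConfig(temperature=spec.temperature).beta
    rng = np.random.default_rng(spec.seed)
    shift = beta * spec.sigma ** 2 / 2.0
    w_f = rng.normal(spec.dg_true + shift, spec.sigma, spec.n)
    w_r = rng.normal(-spec.dg_true + shift, spec.sigma, spec.n)
    zeros = np.zeros(spec.n)
    return EnergySamples(windows=(
        WindowSamples(stage=1, index=0, lam=0.0, u_self=zeros, u_forward=w_f),
        WindowSamples(stage=1, index=1, lam=1.0, u_self=zeros, u_reverse=w_r),
    ))


@dataclass(frozen=True)
class HarmonicToyModel:
    k_a: float = 1.0   # kcal·mol⁻¹·Å⁻²
    k_b: float = 4.0
    d: float = 0.0     # Å displacement of the B minimum

    def __post_init__(self):
        if self.k_a <= 0 or self.k_b <= 0:
            raise ValueError("force constants must be positive")

    def u_a(self, x: float) -> float:
        return 0.5 * self.k_a * x * x

    def u_b(self, x: float) -> float:
        return 0.5 * self.k_b * (x - self.d) ** 2

    def u_lambda(self, x: float, lam: float) -> float:
        return (1.0 - lam) * self.u_a(x) + lam * self.u_b(x)


def analytic_dg(model: HarmonicToyModel,
                config: EstimatorConfig | None = None) -> float:
    """Closed-form ΔG(A→B) = ln(k_B/k_A)/(2β); independent of d."""
    config = config or EstimatorConfig()
    return math.log(model.k_b / model.k_a) / (2.0 * config.beta)


def build_toy_protocol(windows: int = 50, samples_per_window: int = 200,
                       spacing: str = "sigmoidal",
                       replicas: int = 10) -> FepProtocol:
    """Reduced single-stage protocol for the toy system (the harmonic
    transformation has no separate charge/soft-core stages)."""
    make = sigmoidal_lambdas if spacing == "sigmoidal" else linear_lambdas
    stage = PerturbationStage(stage_id=1, schedule=make(windows),
                              steps_per_window=samples_per_window,
                              timestep_fs=2.0)
    return FepProtocol(stages=(stage,), replicas=replicas, preset="H-reduced")


def _metropolis_window(model: HarmonicToyModel, lam: float, x0: float,
                       n_samples: int, n_equil: int, rng) -> tuple[np.ndarray, float]:
    """Metropolis sampling of x under U_λ; the step size is adapted to an
    acceptance ratio in [0.3, 0.7] during equilibration only."""
    beta = _BETA
    x = x0
    step = 1.0
    u = model.u_lambda(x, lam)
    accepted = 0
    tried = 0
    xs = np.empty(n_samples)
    for it in range(n_equil + n_samples):
        trial = x + rng.uniform(-step, step)
        du = model.u_lambda(trial, lam) - u
        tried += 1
        if du <= 0 or rng.random() < math.exp(-beta * du):
            x = trial
            u += du
            accepted += 1
        if it < n_equil and tried == 25:
            acc = accepted / tried
            if acc < 0.3:
                step /= 1.3
            elif acc > 0.7:
                step *= 1.3
            accepted = tried = 0
        if it >= n_equil:
            xs[it - n_equil] = x
    return xs, x


_BETA = EstimatorConfig().beta  # toy sampling runs at the default 298 K


def harmonic_toy_fep(model: HarmonicToyModel,
                     protocol: FepProtocol | LambdaSchedule | None = None,
                     equilibration_steps: int = 100,
                     seed: int = 0) -> EnergySamples:
    """Sample the harmonic system along the λ path of ``protocol``.

    Records, for every window, U at its own λ plus re-evaluations at the
    neighboring λ values (forward/reverse), which is all the estimators
    need.  The per-window sample count is the protocol's
    ``steps_per_window``.
    """
    if protocol is None:
        protocol = build_toy_protocol()
    if isinstance(protocol, LambdaSchedule):
        stages = [(1, protocol, 200)]
    else:
        stages = [(s.stage_id, s.schedule, s.steps_per_window)
                  for s in protocol.stages]
    rng = np.random.default_rng(seed)
    windows = []
    for stage_id, schedule, n_samples in stages:
        lams = schedule.values
        x = model.d * lams[0]  # start near the window minimum
        for i, lam in enumerate(lams):
            xs, x = _metropolis_window(model, lam, x, n_samples,
                                       equilibration_steps, rng)
            ua = 0.5 * model.k_a * xs ** 2
            ub = 0.5 * model.k_b * (xs - model.d) ** 2
            u_at = lambda l: (1.0 - l) * ua + l * ub
            windows.append(WindowSamples(
                stage=stage_id, index=i, lam=lam,
                u_self=u_at(lam),
                u_forward=u_at(lams[i + 1]) if i + 1 < len(lams) else None,
                u_reverse=u_at(lams[i - 1]) if i > 0 else None))
    return EnergySamples(windows=tuple(windows))


@dataclass(frozen=True)
class ToyCycleFixture:
    leg_a: HarmonicToyModel
    leg_b: HarmonicToyModel
    exact_ddg: float
    samples_a: tuple[EnergySamples, ...]
    samples_b: tuple[EnergySamples, ...]


def cycle_fixture(leg_a: HarmonicToyModel, leg_b: HarmonicToyModel,
                  protocol: FepProtocol | None = None,
                  seed: int = 0) -> ToyCycleFixture:
    """Two independently sampled harmonic legs with the exact ΔΔG
    attached, exercising the full two-leg cycle end to end."""
    if protocol is None:
        protocol = build_toy_protocol()
    config = EstimatorConfig()
    exact = analytic_dg(leg_a, config) - analytic_dg(leg_b, config)
    seq = np.random.SeedSequence(seed)
    seeds = seq.generate_state(2 * protocol.replicas)
    samples_a = tuple(harmonic_toy_fep(leg_a, protocol, seed=int(s))
                      for s in seeds[:protocol.replicas])
    samples_b = tuple(harmonic_toy_fep(leg_b, protocol, seed=int(s))
                      for s in seeds[protocol.replicas:])
    return ToyCycleFixture(leg_a=leg_a, leg_b=leg_b, exact_ddg=exact,
                           samples_a=samples_a, samples_b=samples_b)
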