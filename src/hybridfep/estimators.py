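"""Free-energy estimation from per-window energy samples.

Two estimators are provided for the free-energy difference between
adjacent λ-windows:

* **Exponential averaging** (Zwanzig):
  ΔG_i = −β⁻¹ ln ⟨exp(−β(U_{i+1} − U_i))⟩_i, accumulated over windows.
* **Bennett's acceptance ratio** (BAR): the minimum-variance two-state
  estimator, using samples from both adjacent ensembles.  The implicit
  equation is solved per interface by bracketed root search on the
  (monotone) self-consistency residual; at the root the constant C_i
  equals the interface free energy ΔG_i (for equal sample counts; the
  general sample-size correction is handled internally).

A leg of the thermodynamic cycle is an average over independent
replicas, reported with the standard error of the mean (sample standard
deviation with n−1 denominator over replicas, divided by √n).  Two legs
combine into a ΔΔG with the SEMs propagated in quadrature.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

__all__ = [
    "GAS_CONSTANT_KCAL", "EstimatorConfig", "WindowSamples", "EnergySamples",
    "FepLegResult", "CycleResult", "AffinityPair", "EstimatorError",
    "zwanzig_dg", "bar_dg", "bar_residual", "estimate_leg", "solve_cycle",
    "ki_to_ddg", "write_samples", "read_samples",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal·mol⁻¹·K⁻¹


class EstimatorError(ValueError):
    pass


@dataclass(frozen=True)
class EstimatorConfig:
    temperature: float = 298.0
    gas_constant: float = GAS_CONSTANT_KCAL
    method: str = "bar"
    bar_tolerance: float = 1e-7     # kcal·mol⁻¹
    bar_max_iterations: int = 500

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (self.gas_constant * self.temperature)


@dataclass(frozen=True)
class WindowSamples:
    """Potential-energy evaluations collected in one λ-window.

    ``u_self`` is U_i evaluated on the window's own samples; ``u_forward``
    and ``u_reverse`` are the same configurations re-evaluated at the
    next/previous λ.  Forward is absent only for the last window of a
    stage, reverse only for the first.
    """

    stage: int
    index: int
    lam: float
    u_self: np.ndarray
    u_forward: np.ndarray | None = None
    u_reverse: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.u_self)
        if n == 0:
            raise EstimatorError("empty sample series")
        for arr in (self.u_forward, self.u_reverse):
            if arr is not None and len(arr) != n:
                raise EstimatorError("sample series lengths differ within a window")


@dataclass(frozen=True)
class EnergySamples:
    windows: tuple[WindowSamples, ...]

    def __post_init__(self):
        by_stage: dict[int, list[WindowSamples]] = {}
        for w in sorted(self.windows, key=lambda w: (w.stage, w.index)):
            by_stage.setdefault(w.stage, []).append(w)
        for ws in by_stage.values():
            for j, w in enumerate(ws):
                if j < len(ws) - 1 and w.u_forward is None:
                    raise EstimatorError(
                        f"window (stage {w.stage}, {w.index}) lacks forward "
                        "evaluations")

    def ordered(self) -> list[WindowSamples]:
        return sorted(self.windows, key=lambda w: (w.stage, w.index))

    def interfaces(self):
        """Consecutive window pairs within each stage."""
        ws = self.ordered()
        for a, b in zip(ws, ws[1:]):
            if a.stage == b.stage:
                yield a, b

    def structure_signature(self) -> tuple:
        return tuple((w.stage, w.index, round(w.lam, 12)) for w in self.ordered())


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def zwanzig_dg(samples: EnergySamples, config: EstimatorConfig | None = None):
    """Forward exponential-averaging estimate.

    Returns ``(per_interface, total)`` in kcal·mol⁻¹.  The exponential
    average is evaluated with log-sum-exp, so far-from-equilibrium work
    values cannot overflow (and are never clipped).
    """
    config = config or EstimatorConfig()
    beta = config.beta
    per = []
    for a, _b in samples.interfaces():
        if a.u_forward is None:
            raise EstimatorError("forward series required for Zwanzig")
        w = np.asarray(a.u_forward) - np.asarray(a.u_self)
        dg = -(logsumexp(-beta * w) - math.log(len(w))) / beta
        per.append(float(dg))
    return per, float(sum(per))


def _fermi_log(x: np.ndarray) -> np.ndarray:
    # log(1/(1+e^x)) evaluated stably
    return -np.logaddexp(0.0, x)


def bar_residual(w_f: np.ndarray, w_r: np.ndarray, dg: float, beta: float) -> float:
    """Self-consistency residual of the acceptance-ratio equation at a
    trial ΔG; zero at the solution.  Strictly increasing in ``dg``."""
    m = math.log(len(w_f) / len(w_r))
    lhs = np.exp(_fermi_log(m + beta * (w_f - dg))).mean()
    rhs = np.exp(_fermi_log(-m + beta * (w_r + dg))).mean()
    return float(lhs - rhs)


def _solve_bar_interface(w_f: np.ndarray, w_r: np.ndarray,
                         config: EstimatorConfig) -> float:
    beta = config.beta
    f = lambda dg: bar_residual(w_f, w_r, dg, beta)
    # bracket the unique root around a robust initial guess
    lo = min(float(np.min(w_f)), float(np.min(-w_r))) - 1.0
    hi = max(float(np.max(w_f)), float(np.max(-w_r))) + 1.0
    it = 0
    while f(lo) > 0:
        lo -= max(1.0, hi - lo)
        it += 1
        if it > config.bar_max_iterations:
            raise EstimatorError(f"BAR bracketing failed (residual {f(lo):.3e})")
    while f(hi) < 0:
        hi += max(1.0, hi - lo)
        it += 1
        if it > config.bar_max_iterations:
            raise EstimatorError(f"BAR bracketing failed (residual {f(hi):.3e})")
    return float(brentq(f, lo, hi, xtol=config.bar_tolerance,
                        maxiter=config.bar_max_iterations))


def bar_dg(samples: EnergySamples, config: EstimatorConfig | None = None):
    """Bennett acceptance ratio estimate per interface.

    Returns ``(per_interface, total, constants, warnings)``: the
    interface free energies ΔG_i, their sum, the converged constants C_i
    (equal to ΔG_i at self-consistency) and any zero-overlap warnings.
    """
    config = config or EstimatorConfig()
    per, consts, warnings = [], [], []
    for a, b in samples.interfaces():
        if a.u_forward is None or b.u_reverse is None:
            raise EstimatorError(
                "BAR needs forward samples at window i and reverse samples "
                f"at window i+1 (stage {a.stage}, interface {a.index})")
        w_f = np.asarray(a.u_forward) - np.asarray(a.u_self)
        w_r = np.asarray(b.u_reverse) - np.asarray(b.u_self)
        if np.max(-w_r) < np.min(w_f) or np.max(w_f) < np.min(-w_r):
            warnings.append(
                f"stage {a.stage} interface {a.index}: forward and reverse "
                "work distributions do not overlap; estimate is unreliable")
        dg = _solve_bar_interface(w_f, w_r, config)
        per.append(dg)
        consts.append(dg)
    return per, float(sum(per)), consts, warnings


@dataclass(frozen=True)
class FepLegResult:
    per_replica_dg: tuple[float, ...]
    mean_dg: float
    sem: float
    per_window_dg: tuple[tuple[float, ...], ...]   # one tuple per replica
    method: str
    bar_constants: tuple = ()
    warnings: tuple = ()
    signature: tuple = field(default=(), repr=False)

    @property
    def n_replicas(self) -> int:
        return len(self.per_replica_dg)


def estimate_leg(replica_samples, config: EstimatorConfig | None = None) -> FepLegResult:
    """Estimate one leg of the thermodynamic cycle from replica samples.

    Every replica must share the same window structure.  The leg value is
    the arithmetic mean of the per-replica totals; the SEM uses the n−1
    sample standard deviation (0 for a single replica).
    """
    config = config or EstimatorConfig()
    replicas = list(replica_samples)
    if not replicas:
        raise EstimatorError("at least one replica is required")
    sig = replicas[0].structure_signature()
    for r in replicas[1:]:
        if r.structure_signature() != sig:
            raise EstimatorError("replicas have mismatched window structure")

    totals, per_window, consts, warns = [], [], [], []
    for r in replicas:
        if config.method == "bar":
            per, total, c, w = bar_dg(r, config)
            consts.append(tuple(c))
            warns.extend(w)
        elif config.method == "zwanzig":
            per, total = zwanzig_dg(r, config)
        else:
            raise EstimatorError(f"unknown estimator {config.method!r}")
        totals.append(total)
        per_window.append(tuple(per))

    mean = float(np.mean(totals))
    sem = float(np.std(totals, ddof=1) / math.sqrt(len(totals))) \
        if len(totals) > 1 else 0.0
    return FepLegResult(
        per_replica_dg=tuple(totals), mean_dg=mean, sem=sem,
        per_window_dg=tuple(per_window), method=config.method,
        bar_constants=tuple(consts), warnings=tuple(warns), signature=sig)


@dataclass(frozen=True)
class CycleResult:
    """ΔΔG from two FEP legs with SEMs propagated in quadrature.

    Leg A is the bound/folded/complex environment (protein sphere); leg B
    the reference environment (tripeptide, apo protein, or monomer).
    """

    ddg: float
    sem: float
    leg_a: FepLegResult
    leg_b: FepLegResult
    kind: str = "stability"


def solve_cycle(leg_a: FepLegResult, leg_b: FepLegResult,
                kind: str = "stability") -> CycleResult:
    if kind not in ("stability", "ligand-binding", "ppi"):
        raise ValueError(f"unknown cycle kind {kind!r}")
    if leg_a.signature and leg_b.signature and leg_a.signature != leg_b.signature:
        raise EstimatorError(
            "legs were sampled with different protocols; the thermodynamic "
            "cycle requires identical conditions on both legs")
    return CycleResult(
        ddg=leg_a.mean_dg - leg_b.mean_dg,
        sem=math.hypot(leg_a.sem, leg_b.sem),
        leg_a=leg_a, leg_b=leg_b, kind=kind)


@dataclass(frozen=True)
class AffinityPair:
    ki_wt: float
    ki_mut: float
    temperature: float = 298.0

    def __post_init__(self):
        if self.ki_wt <= 0 or self.ki_mut <= 0:
            raise ValueError("inhibition constants must be positive")


def ki_to_ddg(pair: AffinityPair,
              gas_constant: float = GAS_CONSTANT_KCAL) -> float:
    """Experimental binding ΔΔG from an inhibition-constant ratio:
    ΔΔG = RT ln(Ki_mut / Ki_wt), in kcal·mol⁻¹."""
    return gas_constant * pair.temperature * math.log(pair.ki_mut / pair.ki_wt)


# ---------------------------------------------------------------------------
# tabular sample files
# ---------------------------------------------------------------------------

_HEADER = (
    "# hybridfep energy samples, one row per recorded configuration\n"
    "# columns: stage, window, lambda, u_self, u_forward, u_reverse\n"
    "# energies in kcal/mol; empty u_forward/u_reverse where not defined\n"
)


def write_samples(samples: EnergySamples, path) -> None:
    rows = []
    for w in samples.ordered():
        n = len(w.u_self)
        fwd = w.u_forward if w.u_forward is not None else [np.nan] * n
        rev = w.u_reverse if w.u_reverse is not None else [np.nan] * n
        for k in range(n):
            rows.append((w.stage, w.index, w.lam, w.u_self[k], fwd[k], rev[k]))
    df = pd.DataFrame(rows, columns=["stage", "window", "lambda",
                                     "u_self", "u_forward", "u_reverse"])
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False, float_format="%.10g")


def read_samples(path) -> EnergySamples:
    df = pd.read_csv(Path(path), comment="#")
    windows = []
    for (stage, idx), grp in df.groupby(["stage", "window"], sort=True):
        fwd = grp["u_forward"].to_numpy()
        rev = grp["u_reverse"].to_numpy()
        windows.append(WindowSamples(
            stage=int(stage), index=int(idx), lam=float(grp["lambda"].iloc[0]),
            u_self=grp["u_self"].to_numpy(),
            u_forward=None if np.all(np.isnan(fwd)) else fwd,
            u_reverse=None if np.all(np.isnan(rev)) else rev))
    return EnergySamples(windows=tuple(windows))
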