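"""λ schedules, two-stage perturbation protocols and sampling budgets.

The full wt→mut transformation is split into two consecutive stages:
(1) the wild-type side-chain charges are scaled off while a soft-core
van der Waals potential is active on both side chains, then (2) the
mutant charges are scaled on and the soft core is removed.  Each stage
is discretized into λ-windows spaced either evenly ("linear") or with a
higher density near the end points ("sigmoidal"), where the integrand
of an alchemical transformation usually varies fastest.

Two named presets are shipped:

=======  ===========================================================
H        2 stages × 50 sigmoidal windows × 10 000 MD steps of 2 fs
         (20 ps/window), 10 replicas — 1 M steps per replica per leg
J        as H but 100 windows per stage (doubled λ resolution)
=======  ===========================================================
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "LambdaSchedule", "PerturbationStage", "FepProtocol", "BudgetReport",
    "linear_lambdas", "sigmoidal_lambdas", "build_protocol",
    "sampling_budget", "emit_job_spec", "DEFAULT_EQUILIBRATION",
]

#: declarative pre-production stanza (the toolkit never runs protein MD)
DEFAULT_EQUILIBRATION = {
    "optimization_ps": 10,
    "heating_target_K": 298,
    "heating_ps": 150,
    "restraint_release_ps": 350,
    "free_equilibration_ns": 0.5,
}


@dataclass(frozen=True)
class LambdaSchedule:
    values: tuple[float, ...]
    mode: str  # 'linear' | 'sigmoidal'

    def __post_init__(self):
        v = self.values
        if len(v) < 2:
            raise ValueError("schedule needs at least 2 windows")
        if abs(v[0]) > 1e-12 or abs(v[-1] - 1) > 1e-12:
            raise ValueError("schedule must start at 0 and end at 1")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.values)


def linear_lambdas(n: int) -> LambdaSchedule:
    """Evenly spaced λ values, λ_i = i/(n−1)."""
    if n < 2:
        raise ValueError("need n >= 2 windows")
    vals = tuple(i / (n - 1) for i in range(n))
    return LambdaSchedule(values=vals, mode="linear")


def sigmoidal_lambdas(n: int, steepness: float = 1.0) -> LambdaSchedule:
    """λ values with a higher window density near the end points.

    Uses the symmetric sine map λ = ½(1 + sin(π s (x−½))/sin(π s/2)) on
    x = i/(n−1).  The default steepness s = 1 gives the plain sine
    profile; as s → 0 the schedule degenerates to linear spacing.  Only
    monotonicity, the λ_i + λ_{n−1−i} = 1 symmetry and end-point density
    are treated as contractual.
    """
    if n < 2:
        raise ValueError("need n >= 2 windows")
    if not (0 < steepness <= 1):
        raise ValueError("steepness must be in (0, 1]")
    x = np.linspace(0.0, 1.0, n)
    vals = 0.5 * (1.0 + np.sin(np.pi * steepness * (x - 0.5))
                  / np.sin(np.pi * steepness / 2.0))
    vals[0], vals[-1] = 0.0, 1.0
    return LambdaSchedule(values=tuple(float(v) for v in vals), mode="sigmoidal")


@dataclass(frozen=True)
class PerturbationStage:
    stage_id: int                 # 1: discharge wt, soft-core on; 2: charge mut, soft-core off
    schedule: LambdaSchedule
    steps_per_window: int
    timestep_fs: float

    def __post_init__(self):
        if self.steps_per_window < 1:
            raise ValueError("steps per window must be >= 1")
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")

    @property
    def sampling_ps_per_window(self) -> float:
        return self.steps_per_window * self.timestep_fs / 1000.0


@dataclass(frozen=True)
class FepProtocol:
    stages: tuple[PerturbationStage, ...]
    replicas: int = 10
    preset: str | None = None
    equilibration: dict = field(default_factory=lambda: dict(DEFAULT_EQUILIBRATION))

    def __post_init__(self):
        if not self.stages:
            raise ValueError("protocol needs at least one stage")
        if self.replicas < 1:
            raise ValueError("replicas must be >= 1")

    @property
    def total_windows(self) -> int:
        return sum(s.schedule.n for s in self.stages)


def build_protocol(preset: str | None = None, *,
                   windows: int | None = None,
                   spacing: str = "sigmoidal",
                   steps_per_window: int = 10_000,
                   timestep_fs: float = 2.0,
                   replicas: int = 10,
                   stages: int = 2) -> FepProtocol:
    """Named preset (``'H'`` or ``'J'``) or a custom protocol from
    explicit parameters."""
    if preset is not None:
        preset = preset.upper()
        if preset == "H":
            windows, spacing = 50, "sigmoidal"
        elif preset == "J":
            windows, spacing = 100, "sigmoidal"
        else:
            raise ValueError(
                f"unknown preset {preset!r}: only H and J ship as named "
                "presets; other parameter combinations are reachable via "
                "explicit arguments")
        steps_per_window, timestep_fs, replicas, stages = 10_000, 2.0, 10, 2
    if windows is None:
        raise ValueError("either a preset or an explicit window count is required")
    make = sigmoidal_lambdas if spacing == "sigmoidal" else linear_lambdas
    stage_list = tuple(
        PerturbationStage(stage_id=i + 1, schedule=make(windows),
                          steps_per_window=steps_per_window,
                          timestep_fs=timestep_fs)
        for i in range(stages))
    return FepProtocol(stages=stage_list, replicas=replicas, preset=preset)


@dataclass(frozen=True)
class BudgetReport:
    steps_per_replica_per_leg: int
    time_ns_per_replica_per_leg: float
    aggregate_ns_per_leg: float
    aggregate_ns_per_cycle: float
    replicas: int
    legacy: bool = False


def sampling_budget(protocol: FepProtocol, legacy: bool = False,
                    wt_annihilation_subperturbations: int = 0,
                    legacy_timestep_fs: float = 1.0) -> BudgetReport:
    """MD-step and sampling-time bookkeeping for one mutation.

    ``legacy`` reproduces the accounting of the single-topology
    annihilation approach, where a non-alanine mutation requires several
    subperturbations per leg at a shorter timestep.
    """
    if legacy:
        if wt_annihilation_subperturbations < 1:
            raise ValueError("legacy mode requires the subperturbation count")
        ref = protocol.stages[0]
        steps = (wt_annihilation_subperturbations * ref.schedule.n
                 * ref.steps_per_window)
        t_ns = steps * legacy_timestep_fs / 1e6
    else:
        steps = sum(s.schedule.n * s.steps_per_window for s in protocol.stages)
        t_ns = sum(s.schedule.n * s.steps_per_window * s.timestep_fs
                   for s in protocol.stages) / 1e6
    agg_leg = t_ns * protocol.replicas
    return BudgetReport(
        steps_per_replica_per_leg=steps,
        time_ns_per_replica_per_leg=t_ns,
        aggregate_ns_per_leg=agg_leg,
        aggregate_ns_per_cycle=2 * agg_leg,
        replicas=protocol.replicas,
        legacy=legacy,
    )


def _schedule_doc(protocol: FepProtocol) -> list[dict]:
    out = []
    for s in protocol.stages:
        for i, lam in enumerate(s.schedule.values):
            out.append({"stage": s.stage_id, "window": i,
                        "lambda": round(lam, 10),
                        "steps": s.steps_per_window,
                        "timestep_fs": s.timestep_fs})
    return out


def emit_job_spec(topology, protocol: FepProtocol, restraints,
                  selection=None, peptide=None,
                  reference_restraints=None) -> dict[str, str]:
    """Render both legs of the thermodynamic cycle as self-contained,
    deterministic JSON documents.

    The restraint table is rendered identically in both legs — both
    simulations must run under identical conditions for the cycle to
    close.  Passing a diverging ``reference_restraints`` is an error.
    """
    if reference_restraints is not None and \
            reference_restraints.table() != restraints.table():
        raise ValueError("protein and reference legs must share the same "
                         "restraint scheme")

    restraint_doc = [
        {"wt_atom": w, "mut_atom": m, "k": k, "initial_distance": d}
        for (w, m, k, d) in restraints.table()
    ]
    common = {
        "format": "hybridfep-jobspec-1",
        "backbone": list(topology.backbone),
        "wt_sidechain": list(topology.wt_sidechain),
        "mut_sidechain": list(topology.mut_sidechain),
        "exclusions": [list(p) for p in topology.exclusions],
        "deactivated_angle": list(topology.deactivated_angle),
        "deactivated_torsions": [list(t) for t in topology.deactivated_torsions],
        "end_state_charges": {
            f"{side}:{name}": list(q)
            for (side, name), q in sorted(topology.end_state_charges.items())},
        "softcore": asdict(topology.softcore),
        "restraints": restraint_doc,
        "windows": _schedule_doc(protocol),
        "replicas": protocol.replicas,
        "equilibration": protocol.equilibration,
    }
    legs = {}
    for leg in ("protein", "reference"):
        doc = dict(common)
        doc["leg"] = leg
        if leg == "protein" and selection is not None:
            doc["sphere"] = {
                "center": [round(float(c), 3) for c in selection.center],
                "radius": selection.radius,
                "k_out": selection.k_out,
                "n_free": int(len(selection.free_ids)),
                "n_restrained": int(len(selection.restrained_ids)),
                "n_excluded": int(len(selection.excluded_ids)),
            }
        if leg == "reference" and peptide is not None:
            doc["peptide"] = {
                "scheme": peptide.scheme,
                "residues": [
                    {"name": r.name, "resnum": r.resnum, "cap": r.is_cap,
                     "mutable": r.is_mutable}
                    for r in peptide.residues],
            }
        legs[leg] = json.dumps(doc, indent=1, sort_keys=True)
    return legs
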