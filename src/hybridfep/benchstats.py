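"""Figures of merit for benchmark tables, with bootstrap confidence
intervals.

Point statistics over paired experimental/calculated ΔΔG values:

* MAE — mean absolute error (kcal·mol⁻¹)
* R² — squared Pearson correlation
* ρ — Spearman rank correlation (average ranks on ties)
* τ — Kendall rank correlation, tie-corrected τ-b variant
* accuracy — % of records classified with the correct sign relative to
  a threshold (default 0: stabilizing vs destabilizing)
* MCC — Matthews correlation coefficient of the same 2×2 classification;
  undefined (reported as None / "n.a.") when the experimental data
  contain a single class

Interval estimates use a seeded case-resampling bootstrap with
percentile 95% bounds, the reporting convention used throughout the
benchmark tables this module reproduces.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mutation_scan import BenchmarkTable

__all__ = [
    "FiguresOfMerit", "BootstrapSpec", "BootstrapResult",
    "figures_of_merit", "bootstrap_ci", "matthews_corrcoef",
    "plot_benchmark", "load_hydration_benchmark", "STATISTICS",
]


def load_hydration_benchmark(method: str = "bar") -> BenchmarkTable:
    """Shipped benchmark of relative hydration free energies of
    amino-acid side-chain analogs (12 neutral side chains vs methane),
    a standard validation set for residue transformations.

    ``method`` selects the calculated column: ``'bar'`` (acceptance
    ratio) or ``'zwanzig'`` (exponential averaging).
    """
    from importlib import resources
    from .mutation_scan import assemble_benchmark

    if method not in ("bar", "zwanzig"):
        raise ValueError("method must be 'bar' or 'zwanzig'")
    ref = resources.files("hybridfep").joinpath(
        "data/hydration_sidechain_analogs.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    records = [
        {"mutation": f"{row.mutation}->ALA", "ddg_exp": row.ddg_exp,
         "ddg_calc": getattr(row, f"ddg_calc_{method}"),
         "sem": getattr(row, f"sem_{method}")}
        for row in df.itertuples()
    ]
    return assemble_benchmark(records, dataset=f"hydration-analogs-{method}")


@dataclass(frozen=True)
class FiguresOfMerit:
    mae: float
    r2: float
    rho: float
    tau: float
    accuracy_pct: float
    mcc: float | None
    n_quantitative: int
    n_classified: int

    def as_dict(self) -> dict:
        return {"MAE": self.mae, "R2": self.r2, "rho": self.rho,
                "tau": self.tau, "accuracy_pct": self.accuracy_pct,
                "MCC": self.mcc}


def matthews_corrcoef(tp: int, tn: int, fp: int, fn: int) -> float | None:
    """MCC from a 2×2 confusion matrix; None when undefined (a zero
    row/column, e.g. a single-class dataset)."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def _classes(table: BenchmarkTable, threshold: float, dead_zone: float):
    """Boolean 'destabilizing' calls for experiment and calculation over
    all classifiable records (quantitative plus labelled qualitative).
    Records whose calculated value falls inside the optional neutrality
    dead zone are dropped."""
    df = table.frame
    usable = df["exp_class"].notna()
    df = df[usable]
    if dead_zone > 0:
        df = df[np.abs(df["ddg_calc"] - threshold) > dead_zone]
    exp_pos = df["exp_class"].eq("destabilizing").to_numpy()
    calc_pos = (df["ddg_calc"] > threshold).to_numpy()
    return exp_pos, calc_pos


def figures_of_merit(table: BenchmarkTable, threshold: float = 0.0,
                     dead_zone: float = 0.0) -> FiguresOfMerit:
    """Point statistics for a benchmark table.

    Correlation/error statistics use the quantitative records only;
    classification statistics additionally use qualitative records that
    carry an experimental class label.
    """
    q = table.quantitative
    if len(q) < 2:
        raise ValueError("need at least 2 quantitative records")
    exp = q["ddg_exp"].to_numpy()
    calc = q["ddg_calc"].to_numpy()

    mae = float(np.mean(np.abs(calc - exp)))
    r = stats.pearsonr(exp, calc).statistic
    rho = stats.spearmanr(exp, calc).statistic
    tau = stats.kendalltau(exp, calc).statistic  # tau-b

    exp_pos, calc_pos = _classes(table, threshold, dead_zone)
    agree = exp_pos == calc_pos
    accuracy = 100.0 * float(np.mean(agree)) if len(agree) else np.nan
    tp = int(np.sum(exp_pos & calc_pos))
    tn = int(np.sum(~exp_pos & ~calc_pos))
    fp = int(np.sum(~exp_pos & calc_pos))
    fn = int(np.sum(exp_pos & ~calc_pos))
    mcc = matthews_corrcoef(tp, tn, fp, fn)

    return FiguresOfMerit(mae=mae, r2=float(r * r), rho=float(rho),
                          tau=float(tau), accuracy_pct=accuracy, mcc=mcc,
                          n_quantitative=len(q), n_classified=len(agree))


STATISTICS = ("MAE", "R2", "rho", "tau", "accuracy_pct", "MCC")


@dataclass(frozen=True)
class BootstrapSpec:
    n_resamples: int = 10_000
    seed: int = 0
    confidence: float = 95.0
    interval: str = "percentile"

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("need at least one resample")


@dataclass(frozen=True)
class BootstrapResult:
    statistic: str
    point: float | None
    mean: float
    low: float
    high: float
    n_resamples: int


def _subset(table: BenchmarkTable, idx) -> BenchmarkTable:
    return BenchmarkTable(frame=table.frame.iloc[idx].reset_index(drop=True),
                          dataset=table.dataset)


def _single_statistic(table: BenchmarkTable, statistic: str,
                      threshold: float) -> float | None:
    """One named statistic without computing the others (the bootstrap
    loop calls this thousands of times)."""
    if statistic in ("MAE", "R2", "rho", "tau"):
        q = table.quantitative
        if len(q) < 2:
            raise ValueError("need at least 2 quantitative records")
        exp = q["ddg_exp"].to_numpy()
        calc = q["ddg_calc"].to_numpy()
        if statistic == "MAE":
            return float(np.mean(np.abs(calc - exp)))
        import warnings
        with warnings.catch_warnings():
            # constant resamples yield NaN and are redrawn by the caller
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            if statistic == "R2":
                r = stats.pearsonr(exp, calc).statistic
                return float(r * r)
            if statistic == "rho":
                return float(stats.spearmanr(exp, calc).statistic)
            return float(stats.kendalltau(exp, calc).statistic)
    exp_pos, calc_pos = _classes(table, threshold, 0.0)
    if statistic == "accuracy_pct":
        return 100.0 * float(np.mean(exp_pos == calc_pos))
    tp = int(np.sum(exp_pos & calc_pos))
    tn = int(np.sum(~exp_pos & ~calc_pos))
    fp = int(np.sum(~exp_pos & calc_pos))
    fn = int(np.sum(exp_pos & ~calc_pos))
    return matthews_corrcoef(tp, tn, fp, fn)


def bootstrap_ci(table: BenchmarkTable, statistic: str,
                 spec: BootstrapSpec | None = None,
                 threshold: float = 0.0) -> BootstrapResult:
    """Case-resampling bootstrap of one named statistic.

    Resamples on which the statistic is undefined (e.g. MCC on a
    single-class draw, or a zero-variance correlation) are redrawn, up
    to a cap of 10× the requested resample count.
    """
    spec = spec or BootstrapSpec()
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    point = _single_statistic(table, statistic, threshold)

    rng = np.random.default_rng(spec.seed)
    n = len(table.frame)
    values = []
    attempts = 0
    cap = 10 * spec.n_resamples
    while len(values) < spec.n_resamples:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"statistic {statistic} undefined on too many bootstrap "
                f"resamples ({attempts - len(values)} redraws)")
        idx = rng.integers(0, n, size=n)
        try:
            v = _single_statistic(_subset(table, idx), statistic, threshold)
        except ValueError:
            continue
        if v is None or not np.isfinite(v):
            continue
        values.append(v)
    values = np.asarray(values)
    half = (100.0 - spec.confidence) / 2.0
    return BootstrapResult(
        statistic=statistic, point=point, mean=float(values.mean()),
        low=float(np.percentile(values, half)),
        high=float(np.percentile(values, 100.0 - half)),
        n_resamples=spec.n_resamples)


def plot_benchmark(table: BenchmarkTable, path) -> None:
    """Basic experimental-vs-calculated ΔΔG scatter with the identity
    line, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = table.quantitative
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.errorbar(q["ddg_exp"], q["ddg_calc"], yerr=q["sem"].fillna(0),
                fmt="o", ms=4, lw=0.8, alpha=0.8)
    lims = [min(q["ddg_exp"].min(), q["ddg_calc"].min()) - 0.5,
            max(q["ddg_exp"].max(), q["ddg_calc"].max()) + 0.5]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel(r"experimental $\Delta\Delta G$ (kcal/mol)")
    ax.set_ylabel(r"calculated $\Delta\Delta G$ (kcal/mol)")
    ax.set_title(table.dataset or "benchmark")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
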