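"""Systematic mutation-scan enumeration and benchmark-table assembly.

A domain-wide scan mutates every eligible sequence position to every
allowed target residue.  The default exclusion rules reflect what
residue-FEP mutational assays can meaningfully cover: no tryptophan
(interferes with fluorescence readouts) or cysteine (disulfide
oligomerization) targets, no proline (backbone-fused ring), no
titratable residues (charge-changing transformations), no terminal
positions (not comparable with the tripeptide reference state), and no
self-mutations.  With these defaults every eligible position has a
uniform wheel of 12 target side chains.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig", "MutationMatrix", "BenchmarkTable", "enumerate_scan",
    "assemble_benchmark", "GB1_SEQUENCE", "STANDARD_AA1",
]

STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: 56-residue B1 domain of streptococcal protein G, the classic
#: domain-wide mutagenesis benchmark sequence
GB1_SEQUENCE = "MTYKLILNGKTLKGETTTEAVDAATAEKVFKQYANDNGVDGEWTYDDATKTFTVTE"

#: residues never used as mutation targets (assay- and method-driven)
DEFAULT_EXCLUDED_TARGETS = frozenset("WCPRKDE")
#: wild-type position types excluded from scanning; the same seven types,
#: so every eligible position offers the same 12-residue target wheel
DEFAULT_EXCLUDED_WT = frozenset("PRKDEWC")


@dataclass(frozen=True)
class ScanConfig:
    excluded_targets: frozenset = DEFAULT_EXCLUDED_TARGETS
    excluded_wt_types: frozenset = DEFAULT_EXCLUDED_WT
    exclude_terminal: bool = True
    extra_excluded_positions: tuple[int, ...] = ()
    allow_self_mutations: bool = False


@dataclass(frozen=True)
class MutationMatrix:
    positions: tuple[tuple[int, str], ...]      # (1-based position, wt letter)
    targets: dict = field(repr=False)           # position -> tuple of targets
    entries: tuple[tuple[int, str, str], ...]   # (position, wt, mut)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["position", "wt", "mut"])


def enumerate_scan(sequence: str, config: ScanConfig | None = None) -> MutationMatrix:
    """Enumerate the mutation matrix of a sequence under the scan rules.

    Positions are 1-based.  The entry count equals the sum over eligible
    positions of the per-position target count.
    """
    config = config or ScanConfig()
    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted(set(sequence) - set(STANDARD_AA1))
    if bad:
        raise ValueError(f"unknown residue letters {bad}")

    positions = []
    targets = {}
    entries = []
    last = len(sequence)
    for pos, wt in enumerate(sequence, start=1):
        if config.exclude_terminal and pos in (1, last):
            continue
        if wt in config.excluded_wt_types:
            continue
        if pos in config.extra_excluded_positions:
            continue
        tgt = tuple(t for t in STANDARD_AA1
                    if t not in config.excluded_targets
                    and (config.allow_self_mutations or t != wt))
        positions.append((pos, wt))
        targets[pos] = tgt
        entries.extend((pos, wt, t) for t in tgt)
    return MutationMatrix(positions=tuple(positions), targets=targets,
                          entries=tuple(entries))


@dataclass(frozen=True)
class BenchmarkTable:
    """Paired experimental/calculated ΔΔG records.

    Qualitative records (e.g. "totally unstable", "no expression") have
    no numeric experimental ΔΔG but carry a class label
    ('stabilizing'/'destabilizing'); they are kept for classification
    statistics and excluded from quantitative ones.
    """

    frame: pd.DataFrame
    dataset: str = ""

    @property
    def quantitative(self) -> pd.DataFrame:
        return self.frame[~self.frame["qualitative"]]

    @property
    def n_records(self) -> int:
        return len(self.frame)


def assemble_benchmark(records, dataset: str = "") -> BenchmarkTable:
    """Build a benchmark table from per-mutation records.

    Each record is a mapping with keys ``mutation`` (unique id),
    ``ddg_exp`` (float, or None for qualitative records), ``ddg_calc``,
    ``sem``, and optionally ``exp_class`` for qualitative records.
    """
    rows = []
    seen = set()
    for rec in records:
        mid = rec["mutation"]
        if mid in seen:
            raise ValueError(f"duplicate mutation id {mid!r}")
        seen.add(mid)
        calc = rec.get("ddg_calc")
        if calc is None or (isinstance(calc, float) and np.isnan(calc)):
            raise ValueError(f"record {mid!r} lacks a calculated value")
        exp = rec.get("ddg_exp")
        qual = exp is None or (isinstance(exp, float) and np.isnan(exp))
        rows.append({
            "mutation": mid,
            "ddg_exp": np.nan if qual else float(exp),
            "ddg_calc": float(calc),
            "sem": float(rec.get("sem", np.nan)),
            "qualitative": qual,
            "exp_class": rec.get("exp_class") or (
                None if qual else
                ("destabilizing" if exp > 0 else "stabilizing")),
        })
    frame = pd.DataFrame(rows, columns=["mutation", "ddg_exp", "ddg_calc",
                                        "sem", "qualitative", "exp_class"])
    return BenchmarkTable(frame=frame, dataset=dataset)
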