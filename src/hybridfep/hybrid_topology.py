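"""Hybrid (dual-like) topology construction for a wt→mut side-chain
transformation.

The transformation shares a single backbone while the wild-type and
mutant side chains coexist as separate, mutually non-interacting atom
sets.  Three ingredients make this physically consistent:

* **Analogous-atom mapping** — heavy atoms of the two side chains are
  paired outward from CA by topological level, so the spatial overlap
  between the end states can be controlled.
* **Dynamic restraints** — analogous pairs are harmonically tied
  (k = 10.0 kcal·mol⁻¹·Å⁻²) as long as they have identical atom types
  and start within 0.5 Å of each other; the first failure of either
  criterion stops the restraint list.  This keeps phase-space overlap
  while preventing erroneous "flapping" onto non-equivalent neighbors.
* **Exclusions and deactivated bonded terms** — every wt/mut side-chain
  atom pair is excluded from non-bonded interactions, and the bonded
  terms that would couple the two side chains through CA (the
  CBwt-CA-CBmut angle and all torsions passing through it) are switched
  off, so neither side chain "feels" the other.

The transformation runs in two stages: stage 1 discharges the wild-type
side chain while a soft-core van der Waals potential is active on both
side chains; stage 2 charges the mutant side chain and removes the
soft core.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .residue_templates import ResidueTemplate

__all__ = [
    "PlacedResidue", "AtomPair", "AtomMapping", "RestraintScheme",
    "SoftCoreSpec", "HybridTopology", "ChargeChangeError",
    "map_analogous_atoms", "assign_restraints", "build_hybrid_topology",
    "RESTRAINT_K", "RESTRAINT_CUTOFF",
]

RESTRAINT_K = 10.0       # kcal·mol⁻¹·Å⁻², pairwise distance restraints
RESTRAINT_CUTOFF = 0.5   # Å, initial-distance criterion for restraining


class ChargeChangeError(ValueError):
    """Net charge differs between the end states (charge-changing
    mutations are unsupported by default)."""


@dataclass(frozen=True)
class PlacedResidue:
    """A residue template together with Cartesian coordinates for (at
    least) its side-chain atoms and the backbone frame."""

    template: ResidueTemplate
    coords: dict

    def coord(self, name: str) -> np.ndarray:
        return np.asarray(self.coords[name], dtype=float)


@dataclass(frozen=True)
class AtomPair:
    wt: str
    mut: str
    level: int
    type_equal: bool
    distance: float


@dataclass(frozen=True)
class AtomMapping:
    """Analogous heavy-atom pairs ordered by increasing level from CA."""

    pairs: tuple[AtomPair, ...]
    unmatched_wt: tuple[str, ...]
    unmatched_mut: tuple[str, ...]

    def reversed(self) -> "AtomMapping":
        return AtomMapping(
            pairs=tuple(AtomPair(p.mut, p.wt, p.level, p.type_equal, p.distance)
                        for p in self.pairs),
            unmatched_wt=self.unmatched_mut,
            unmatched_mut=self.unmatched_wt,
        )


@dataclass(frozen=True)
class RestraintScheme:
    pairs: tuple[AtomPair, ...]
    stop_reason: str                    # 'type-mismatch' | 'distance' | 'exhausted'
    k: float = RESTRAINT_K
    cutoff: float = RESTRAINT_CUTOFF

    def table(self) -> list[tuple[str, str, float, float]]:
        """(wt atom, mut atom, k, initial distance) rows."""
        return [(p.wt, p.mut, self.k, round(p.distance, 3)) for p in self.pairs]


@dataclass(frozen=True)
class SoftCoreSpec:
    """Declarative soft-core van der Waals description.

    The default functional form replaces r⁶ by r⁶ + α·σ⁶·(1−λ_vdw) on
    transforming atoms, removing the r→0 singularity during atom
    creation/annihilation.  Only the declarative content matters here;
    an MD engine consumes it.
    """

    form: str = "shifted-r6"
    alpha: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("soft-core alpha must be positive")


def _candidate_children(tpl: ResidueTemplate, atom: str, levels: dict,
                        matched: set) -> list[str]:
    lv = levels[atom]
    return sorted(nb for nb in tpl.neighbors(atom)
                  if nb in levels and levels[nb] == lv + 1 and nb not in matched)


def _match_children(wt: PlacedResidue, mut: PlacedResidue,
                    a_children: list[str], b_children: list[str],
                    wt_desc: dict, mut_desc: dict,
                    wt_levels: dict, mut_levels: dict,
                    matched_wt: set, matched_mut: set,
                    depth: int = 0):
    """Best injective assignment between two sibling groups.

    Candidates are ranked by atom-type agreement, then similarity of
    downstream heavy-atom counts, then total initial distance summed over
    the assignment *and its recursively matched descendants* (which
    resolves symmetric aromatic CD1/CD2 branches by whole-ring distance),
    with a final deterministic alphabetical tie-break.
    """
    if not a_children or not b_children:
        return []
    small, large, swap = (a_children, b_children, False)
    if len(b_children) < len(a_children):
        small, large, swap = (b_children, a_children, True)

    best = None
    best_key = None
    for perm in itertools.permutations(large, len(small)):
        assignment = list(zip(small, perm))
        if swap:
            assignment = [(b, a) for a, b in assignment]
        type_miss = 0
        desc_diff = 0
        total_dist = 0.0
        for a, b in assignment:
            ta = wt.template.atom(a).type_code
            tb = mut.template.atom(b).type_code
            type_miss += int(ta != tb)
            desc_diff += abs(wt_desc[a] - mut_desc[b])
            total_dist += float(np.linalg.norm(wt.coord(a) - mut.coord(b)))
        # look ahead: add descendant distances of a trial recursion so that
        # e.g. swapped ring branches are judged by the whole ring
        if depth < 8:
            trial_wt = set(matched_wt) | {a for a, _ in assignment}
            trial_mut = set(matched_mut) | {b for _, b in assignment}
            for a, b in assignment:
                sub = _match_children(
                    wt, mut,
                    _candidate_children(wt.template, a, wt_levels, trial_wt),
                    _candidate_children(mut.template, b, mut_levels, trial_mut),
                    wt_desc, mut_desc, wt_levels, mut_levels,
                    trial_wt, trial_mut, depth + 1)
                for x, y in sub:
                    trial_wt.add(x)
                    trial_mut.add(y)
                    total_dist += float(np.linalg.norm(wt.coord(x) - mut.coord(y)))
        names = tuple(sorted(tuple(sorted((a, b))) for a, b in assignment))
        key = (type_miss, desc_diff, round(total_dist, 9), names)
        if best_key is None or key < best_key:
            best_key = key
            best = assignment
    return best


def map_analogous_atoms(wt: PlacedResidue, mut: PlacedResidue) -> AtomMapping:
    """Enumerate analogous heavy atoms of two side chains sharing a
    backbone frame, pairing breadth-first from CA outward.

    Glycine on either side yields an empty mapping (no Cβ to seed the
    walk); this is not an error.
    """
    wt_levels = wt.template.heavy_levels()
    mut_levels = mut.template.heavy_levels()
    wt_desc = wt.template.descendant_counts()
    mut_desc = mut.template.descendant_counts()

    pairs: list[AtomPair] = []
    matched_wt: set[str] = set()
    matched_mut: set[str] = set()

    def add_pair(a: str, b: str):
        matched_wt.add(a)
        matched_mut.add(b)
        pairs.append(AtomPair(
            wt=a, mut=b, level=wt_levels[a],
            type_equal=(wt.template.atom(a).type_code
                        == mut.template.atom(b).type_code),
            distance=float(np.linalg.norm(wt.coord(a) - mut.coord(b))),
        ))

    if "CB" in wt_levels and "CB" in mut_levels:
        add_pair("CB", "CB")
        frontier = [("CB", "CB")]
        while frontier:
            nxt = []
            for a, b in frontier:
                ac = _candidate_children(wt.template, a, wt_levels, matched_wt)
                bc = _candidate_children(mut.template, b, mut_levels, matched_mut)
                assignment = _match_children(
                    wt, mut, ac, bc, wt_desc, mut_desc,
                    wt_levels, mut_levels, matched_wt, matched_mut)
                for x, y in assignment:
                    if x in matched_wt or y in matched_mut:
                        continue  # ring closure reached twice
                    add_pair(x, y)
                    nxt.append((x, y))
            frontier = nxt

    pairs.sort(key=lambda p: (p.level, tuple(sorted((p.wt, p.mut)))))
    return AtomMapping(
        pairs=tuple(pairs),
        unmatched_wt=tuple(n for n in sorted(wt_levels, key=lambda x: (wt_levels[x], x))
                           if n not in matched_wt),
        unmatched_mut=tuple(n for n in sorted(mut_levels, key=lambda x: (mut_levels[x], x))
                            if n not in matched_mut),
    )


def assign_restraints(mapping: AtomMapping,
                      cutoff: float = RESTRAINT_CUTOFF,
                      k: float = RESTRAINT_K) -> RestraintScheme:
    """Contiguous prefix of the mapping that is pairwise restrained.

    Walking the pairs in level order, a pair is restrained only if every
    preceding pair was restrained and the pair has equal atom types and
    an initial separation within ``cutoff``.  The uniform rule applies to
    the Cβ pair as well, so the Cβ-only scheme is the minimal non-empty
    outcome.
    """
    kept = []
    reason = "exhausted"
    for p in mapping.pairs:
        if not p.type_equal:
            reason = "type-mismatch"
            break
        if p.distance > cutoff:
            reason = "distance"
            break
        kept.append(p)
    return RestraintScheme(pairs=tuple(kept), stop_reason=reason, k=k, cutoff=cutoff)


@dataclass(frozen=True)
class HybridTopology:
    """Merged representation of the wt and mut residues on one backbone.

    ``wt_sidechain``/``mut_sidechain`` are the two coexisting atom sets
    (heavy atoms plus their hydrogens).  ``end_state_charges`` maps
    (side, atom name) to the (state 0, state 1) charges: the wild-type
    side chain carries its full charges in state 0 and is a dummy in
    state 1, and vice versa for the mutant.
    """

    backbone: tuple[str, ...]
    wt_sidechain: tuple[str, ...]
    mut_sidechain: tuple[str, ...]
    wt_root: str
    mut_root: str
    exclusions: tuple[tuple[str, str], ...]
    deactivated_angle: tuple[str, str, str]
    deactivated_torsions: tuple[tuple[str, str, str, str], ...]
    end_state_charges: dict = field(repr=False)
    stages: tuple = (
        ("discharge-wt", "softcore-on"),
        ("charge-mut", "softcore-off"),
    )
    softcore: SoftCoreSpec = SoftCoreSpec()

    @property
    def n_exclusions(self) -> int:
        return len(self.exclusions)

    def state_charge(self, state: int) -> float:
        """Net charge of backbone + active side chain in an end state."""
        total = sum(q[state] for q in self.end_state_charges.values())
        return total


def _sidechain_root(template: ResidueTemplate) -> str:
    # CB for everything except glycine, whose "side chain" is the
    # α-hydrogen occupying the Cβ position
    return "CB" if "CB" in {a.name for a in template.atoms} else \
        template.sidechain_atoms[0]


def build_hybrid_topology(wt: PlacedResidue, mut: PlacedResidue,
                          mapping: AtomMapping,
                          softcore: SoftCoreSpec | None = None) -> HybridTopology:
    """Assemble the hybrid topology for one mutation.

    Raises :class:`ChargeChangeError` if the two side chains carry
    different net charges (the thermodynamic cycle does not close for
    charge-changing mutations without special treatment).
    """
    if softcore is None:
        softcore = SoftCoreSpec()

    qa = wt.template.sidechain_charge
    qb = mut.template.sidechain_charge
    if abs(qa - qb) > 1e-9:
        raise ChargeChangeError(
            f"net side-chain charge changes ({wt.template.name} {qa:+.3f} -> "
            f"{mut.template.name} {qb:+.3f}); charge-changing mutations are "
            "unsupported by default")

    a_atoms = tuple(wt.template.sidechain_atoms)
    b_atoms = tuple(mut.template.sidechain_atoms)
    exclusions = tuple((a, b) for a in a_atoms for b in b_atoms)

    root_a = _sidechain_root(wt.template)
    root_b = _sidechain_root(mut.template)
    angle = (root_a, "CA", root_b)

    torsions = []
    for x in wt.template.neighbors(root_a):
        if x != "CA":
            torsions.append((x, root_a, "CA", root_b))
    for y in mut.template.neighbors(root_b):
        if y != "CA":
            torsions.append((root_a, "CA", root_b, y))

    charges: dict[tuple[str, str], tuple[float, float]] = {}
    for name in wt.template.backbone_atoms:
        q = wt.template.atom(name).charge
        charges[("bb", name)] = (q, q)
    for name in a_atoms:
        q = wt.template.atom(name).charge
        charges[("wt", name)] = (q, 0.0)
    for name in b_atoms:
        q = mut.template.atom(name).charge
        charges[("mut", name)] = (0.0, q)

    return HybridTopology(
        backbone=tuple(wt.template.backbone_atoms),
        wt_sidechain=a_atoms,
        mut_sidechain=b_atoms,
        wt_root=root_a,
        mut_root=root_b,
        exclusions=exclusions,
        deactivated_angle=angle,
        deactivated_torsions=tuple(torsions),
        end_state_charges=charges,
        softcore=softcore,
    )
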