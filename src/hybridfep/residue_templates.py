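"""Amino-acid topology templates, mutant side-chain building and capped
reference peptides.

The shipped template library (one JSON document per residue under
``data/templates/``) records, for the 20 standard residues and the
acetyl/N-methylamide caps: atom names and elements, self-consistent
partial charges (neutral side chains sum to exactly zero), atom type
codes used for restraint type-matching, the bond graph, and ideal
side-chain internal coordinates rooted in the N-CA-C(-CB) backbone
frame.  The charge/type set is intentionally minimal and internally
consistent; it does not claim fidelity to any published force field.

Mutant side chains are built deterministically from these internal
coordinates, copying the χ (side-chain) torsions the wild-type and
mutant residues share, so that topologically analogous atoms start the
transformation spatially superimposed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from ._geometry import dihedral, place_atom
from .structure_io import Structure, StructureError

__all__ = [
    "ResidueTemplate", "TemplateAtom", "ZMatrixEntry", "PeptideModel",
    "PeptideResidue", "UnknownResidueError", "UnsupportedResidueError",
    "get_template", "supported_residues", "place_mutant_side_chain",
    "build_reference_peptide", "build_ideal_chain", "PEPTIDE_SCHEMES",
]

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
CAPS = ("ACE", "NME")
PEPTIDE_SCHEMES = ("ZXZ", "AXA", "GXG", "X")

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


class UnknownResidueError(KeyError):
    pass


class UnsupportedResidueError(ValueError):
    """Raised for residues the transformation machinery cannot handle
    (proline, whose backbone-fused ring breaks the common-backbone
    assumption of the hybrid topology)."""


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    type_code: str
    charge: float


@dataclass(frozen=True)
class ZMatrixEntry:
    name: str
    refs: tuple[str, str, str]
    length: float
    angle: float
    torsion: float
    chi: int | None = None


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    formal_charge: int
    atoms: tuple[TemplateAtom, ...]
    bonds: tuple[tuple[str, str], ...]
    backbone_atoms: tuple[str, ...]
    sidechain_atoms: tuple[str, ...]
    zmatrix: tuple[ZMatrixEntry, ...]
    chi_atoms: dict = field(default_factory=dict)

    def atom(self, name: str) -> TemplateAtom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise UnknownResidueError(f"{self.name} has no atom {name}")

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.atoms)

    @property
    def sidechain_charge(self) -> float:
        sc = set(self.sidechain_atoms)
        return sum(a.charge for a in self.atoms if a.name in sc)

    @property
    def total_charge(self) -> float:
        return sum(a.charge for a in self.atoms)

    def sidechain_heavy_atoms(self) -> tuple[str, ...]:
        return tuple(n for n in self.sidechain_atoms
                     if self.atom(n).element != "H")

    def neighbors(self, name: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return sorted(out)

    def heavy_levels(self) -> dict[str, int]:
        """Graph distance from CA along bonds, restricted to side-chain
        heavy atoms (CB is level 1)."""
        heavy = set(self.sidechain_heavy_atoms())
        levels: dict[str, int] = {}
        frontier = ["CA"]
        dist = 0
        seen = {"CA"}
        while frontier:
            dist += 1
            nxt = []
            for node in frontier:
                for nb in self.neighbors(node):
                    if nb in heavy and nb not in seen:
                        levels[nb] = dist
                        seen.add(nb)
                        nxt.append(nb)
            frontier = nxt
        return levels

    def descendant_counts(self) -> dict[str, int]:
        """For each side-chain heavy atom, the number of heavy atoms that
        lie strictly further from CA and are reachable through it."""
        levels = self.heavy_levels()
        counts = {}
        for a in levels:
            seen = {a}
            frontier = [a]
            n = 0
            while frontier:
                nxt = []
                for node in frontier:
                    for nb in self.neighbors(node):
                        if nb in levels and nb not in seen and levels[nb] > levels[node]:
                            seen.add(nb)
                            nxt.append(nb)
                            n += 1
                frontier = nxt
            counts[a] = n
        return counts


@lru_cache(maxsize=None)
def get_template(residue_name: str) -> ResidueTemplate:
    """Immutable shipped template for a standard residue or cap.

    Proline is deliberately rejected: its side chain closes onto the
    backbone nitrogen, which is incompatible with the shared-backbone
    hybrid-topology construction.
    """
    name = residue_name.upper()
    if name == "PRO":
        raise UnsupportedResidueError(
            "proline is unsupported: its ring involves the backbone and "
            "cannot be represented as a detachable side chain")
    if name not in STANDARD_RESIDUES and name not in CAPS:
        raise UnknownResidueError(f"unknown residue {residue_name!r}")
    ref = resources.files("hybridfep").joinpath(f"data/templates/{name}.json")
    data = json.loads(ref.read_text())
    return ResidueTemplate(
        name=data["name"],
        formal_charge=data["formal_charge"],
        atoms=tuple(TemplateAtom(a["name"], a["element"], a["type"], a["charge"])
                    for a in data["atoms"]),
        bonds=tuple((a, b) for a, b in data["bonds"]),
        backbone_atoms=tuple(data["backbone_atoms"]),
        sidechain_atoms=tuple(data["sidechain_atoms"]),
        zmatrix=tuple(ZMatrixEntry(z["name"], tuple(z["refs"]), z["length"],
                                   z["angle"], z["torsion"], z["chi"])
                      for z in data["zmatrix"]),
        chi_atoms={int(k): tuple(v) for k, v in data["chi_atoms"].items()},
    )


def supported_residues() -> tuple[str, ...]:
    """Residues that can serve as mutation endpoints (no proline, no
    charged side chains)."""
    out = []
    for name in STANDARD_RESIDUES:
        if name == "PRO":
            continue
        if get_template(name).formal_charge != 0:
            continue
        out.append(name)
    return tuple(out)


def _build_from_zmatrix(template: ResidueTemplate,
                        coords: dict[str, np.ndarray],
                        chi_overrides: dict[int, float]) -> dict[str, np.ndarray]:
    built: dict[str, np.ndarray] = {}
    for entry in template.zmatrix:
        if entry.name in coords:
            built[entry.name] = coords[entry.name]
            continue
        torsion = entry.torsion
        if entry.chi is not None and entry.chi in chi_overrides:
            torsion = chi_overrides[entry.chi]
        refs = []
        for r in entry.refs:
            if r in coords:
                refs.append(coords[r])
            elif r in built:
                refs.append(built[r])
            else:
                raise StructureError(
                    f"z-matrix reference {r} unavailable while building "
                    f"{template.name}:{entry.name}")
        pos = place_atom(refs[0], refs[1], refs[2], entry.length, entry.angle, torsion)
        built[entry.name] = pos
        coords = {**coords, entry.name: pos}
    return built


def _measure_chis(template: ResidueTemplate,
                  coords: dict[str, np.ndarray]) -> dict[int, float]:
    chis = {}
    for k, quartet in template.chi_atoms.items():
        if all(a in coords for a in quartet):
            p = [coords[a] for a in quartet]
            chis[k] = dihedral(*p)
    return chis


def place_mutant_side_chain(structure: Structure, chain: str, resnum: int,
                            mut_name: str) -> dict[str, np.ndarray]:
    """Coordinates for the mutant side-chain atoms at a protein site.

    The side chain is constructed from the mutant template's internal
    coordinates in the frame defined by the wild-type N-CA-C backbone.
    The wild-type Cβ is reused directly when present, and every χ torsion
    defined in both residues is copied from the wild-type conformation,
    which maximizes the initial spatial overlap of analogous atoms.  The
    construction is fully deterministic.
    """
    mut = get_template(mut_name)
    wt_name = structure.residue_name(chain, resnum)
    wt = get_template(wt_name)  # raises for proline / unknown residues

    site = structure.residue_atoms(chain, resnum)
    missing = [a for a in ("N", "CA", "C") if a not in site]
    if missing:
        raise StructureError(
            f"residue {chain}/{resnum} is missing backbone atoms {missing}")
    if wt_name != "GLY" and "CB" not in site:
        raise StructureError(
            f"residue {chain}/{resnum} ({wt_name}) has no CB to anchor the "
            "mutant side chain")

    frame = {k: site[k] for k in ("N", "CA", "C")}
    if "CB" in site and mut.name != "GLY":
        frame["CB"] = site["CB"]

    wt_chis = _measure_chis(wt, site)
    shared = {k: wt_chis[k] for k in mut.chi_atoms if k in wt_chis}
    return _build_from_zmatrix(mut, frame, shared)


# ---------------------------------------------------------------------------
# reference (unfolded-state) peptides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptideResidue:
    name: str
    resnum: int
    atoms: dict
    is_cap: bool = False
    is_mutable: bool = False


@dataclass(frozen=True)
class PeptideModel:
    """A capped peptide standing in for the unfolded state.

    ``scheme`` selects the flanks: ZXZ keeps the natural neighbors with
    their crystal coordinates, AXA/GXG substitute alanine/glycine side
    chains on the natural backbone, and X keeps only the mutable residue.
    All schemes carry an N-terminal acetyl and a C-terminal N-methylamide
    cap.
    """

    scheme: str
    residues: tuple[PeptideResidue, ...]

    def __post_init__(self):
        if not (self.residues[0].is_cap and self.residues[-1].is_cap):
            raise ValueError("peptide must be capped at both termini")
        inner = [r for r in self.residues if not r.is_cap]
        if not inner[len(inner) // 2].is_mutable:
            raise ValueError("mutable residue must occupy the central position")

    @property
    def mutable(self) -> PeptideResidue:
        return next(r for r in self.residues if r.is_mutable)


def _ace_from_residue(atoms: dict[str, np.ndarray], resnum: int) -> PeptideResidue:
    # truncate the preceding residue: its CA becomes the acetyl methyl
    coords = {"CH3": atoms["CA"], "C": atoms["C"], "O": atoms["O"]}
    for i, t in enumerate((60.0, 180.0, -60.0), start=1):
        coords[f"HH3{i}"] = place_atom(coords["CH3"], coords["C"], coords["O"],
                                       1.09, 109.5, t)
    return PeptideResidue("ACE", resnum, coords, is_cap=True)


def _ace_built(first: dict[str, np.ndarray], resnum: int) -> PeptideResidue:
    c = place_atom(first["N"], first["CA"], first["C"], 1.33, 121.0, 180.0)
    o = place_atom(c, first["N"], first["CA"], 1.23, 123.0, 0.0)
    ch3 = place_atom(c, first["N"], first["CA"], 1.51, 116.5, 180.0)
    coords = {"C": c, "O": o, "CH3": ch3}
    for i, t in enumerate((60.0, 180.0, -60.0), start=1):
        coords[f"HH3{i}"] = place_atom(ch3, c, o, 1.09, 109.5, t)
    return PeptideResidue("ACE", resnum, coords, is_cap=True)


def _nme_from_residue(atoms: dict[str, np.ndarray], resnum: int) -> PeptideResidue:
    coords = {"N": atoms["N"], "CH3": atoms["CA"]}
    if "H" in atoms:
        coords["H"] = atoms["H"]
    else:
        coords["H"] = place_atom(coords["N"], coords["CH3"], atoms["C"],
                                 1.01, 119.0, 180.0)
    for i, t in enumerate((60.0, 180.0, -60.0), start=1):
        coords[f"HH3{i}"] = place_atom(coords["CH3"], coords["N"], coords["H"],
                                       1.09, 109.5, t)
    return PeptideResidue("NME", resnum, coords, is_cap=True)


def _nme_built(last: dict[str, np.ndarray], resnum: int) -> PeptideResidue:
    n = place_atom(last["C"], last["CA"], last["N"], 1.33, 116.5, 180.0)
    h = place_atom(n, last["C"], last["CA"], 1.01, 119.0, 0.0)
    ch3 = place_atom(n, last["C"], last["CA"], 1.45, 121.5, 180.0)
    coords = {"N": n, "H": h, "CH3": ch3}
    for i, t in enumerate((60.0, 180.0, -60.0), start=1):
        coords[f"HH3{i}"] = place_atom(ch3, n, h, 1.09, 109.5, t)
    return PeptideResidue("NME", resnum, coords, is_cap=True)


def _flank_residue(structure: Structure, chain: str, resnum: int,
                   scheme: str) -> PeptideResidue:
    name = structure.residue_name(chain, resnum)
    atoms = structure.residue_atoms(chain, resnum)
    if scheme == "ZXZ":
        return PeptideResidue(name, resnum, atoms)
    sub = "ALA" if scheme == "AXA" else "GLY"
    tpl = get_template(sub)
    backbone = {k: v for k, v in atoms.items() if k in tpl.backbone_atoms}
    frame = {k: atoms[k] for k in ("N", "CA", "C") if k in atoms}
    if len(frame) < 3:
        raise StructureError(
            f"flank {chain}/{resnum} lacks backbone atoms for {scheme}")
    side = _build_from_zmatrix(tpl, dict(frame), {})
    return PeptideResidue(sub, resnum, {**backbone, **side})


def build_reference_peptide(structure: Structure, chain: str, resnum: int,
                            scheme: str = "ZXZ") -> PeptideModel:
    """Build the capped reference peptide for a mutation site.

    Tripeptide schemes require both sequence neighbors to exist; terminal
    residues are rejected because their reference state would not be
    comparable across mutations.
    """
    if scheme not in PEPTIDE_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {PEPTIDE_SCHEMES}")
    resnums = structure.chain_residue_numbers(chain)
    protein_nums = [r for r in resnums
                    if structure.residue_name(chain, r) in STANDARD_RESIDUES]
    pos = protein_nums.index(resnum) if resnum in protein_nums else None
    if pos is None:
        raise StructureError(f"no protein residue {chain}/{resnum}")

    central = PeptideResidue(structure.residue_name(chain, resnum), resnum,
                             structure.residue_atoms(chain, resnum),
                             is_mutable=True)

    if scheme == "X":
        units = [central]
    else:
        if pos == 0 or pos == len(protein_nums) - 1:
            raise StructureError(
                f"residue {chain}/{resnum} is terminal; tripeptide scheme "
                f"{scheme} needs both sequence neighbors")
        units = [
            _flank_residue(structure, chain, protein_nums[pos - 1], scheme),
            central,
            _flank_residue(structure, chain, protein_nums[pos + 1], scheme),
        ]

    first_num, last_num = units[0].resnum, units[-1].resnum
    before = protein_nums[protein_nums.index(first_num) - 1] \
        if protein_nums.index(first_num) > 0 else None
    after_i = protein_nums.index(last_num) + 1
    after = protein_nums[after_i] if after_i < len(protein_nums) else None

    if before is not None:
        ace = _ace_from_residue(structure.residue_atoms(chain, before), before)
    else:
        ace = _ace_built(units[0].atoms, first_num - 1)
    if after is not None:
        nme = _nme_from_residue(structure.residue_atoms(chain, after), after)
    else:
        nme = _nme_built(units[-1].atoms, last_num + 1)

    return PeptideModel(scheme=scheme, residues=tuple([ace, *units, nme]))


# ---------------------------------------------------------------------------
# ideal chains (template-built model peptides)
# ---------------------------------------------------------------------------

def build_ideal_chain(sequence, chain_id: str = "A",
                      phi: float = -120.0, psi: float = 140.0) -> "Structure":
    """Build an idealized peptide chain entirely from the template library.

    ``sequence`` is an iterable of 3-letter residue names.  The backbone
    is generated with uniform (phi, psi) torsions (extended by default)
    and ideal bond geometry; side chains use the template default
    rotamers.  Useful as a self-contained model system for exercising
    the mutation machinery without an experimental structure.
    """
    import biotite.structure as struc

    sequence = [s.upper() for s in sequence]
    residues = []
    prev = None  # (N, CA, C) of previous residue
    for i, resname in enumerate(sequence):
        tpl = get_template(resname)
        coords: dict[str, np.ndarray] = {}
        if prev is None:
            coords["N"] = np.array([0.0, 0.0, 0.0])
            coords["CA"] = np.array([1.458, 0.0, 0.0])
            coords["C"] = place_atom(coords["CA"], coords["N"],
                                     np.array([0.0, 1.0, 0.0]),
                                     1.525, 111.0, 0.0)
        else:
            p_n, p_ca, p_c = prev
            coords["N"] = place_atom(p_c, p_ca, p_n, 1.33, 116.5, psi)
            coords["CA"] = place_atom(coords["N"], p_c, p_ca, 1.458, 121.5, 180.0)
            coords["C"] = place_atom(coords["CA"], coords["N"], p_c,
                                     1.525, 111.0, phi)
            coords["H"] = place_atom(coords["N"], p_c, coords["CA"],
                                     1.01, 119.0, 180.0)
        coords["O"] = place_atom(coords["C"], coords["CA"], coords["N"],
                                 1.23, 121.0, 45.0)
        coords["HA"] = place_atom(coords["CA"], coords["N"], coords["C"],
                                  1.09, 109.5, 120.0)
        side = _build_from_zmatrix(tpl, dict(coords), {})
        coords.update(side)
        prev = (coords["N"], coords["CA"], coords["C"])
        order = [a.name for a in tpl.atoms if a.name in coords]
        residues.append((resname, i + 1, [(n, coords[n]) for n in order]))

    n_atoms = sum(len(r[2]) for r in residues)
    arr = struc.AtomArray(n_atoms)
    arr.add_annotation("occupancy", dtype=float)
    arr.add_annotation("atom_id", dtype=int)
    k = 0
    for resname, resnum, atoms in residues:
        for name, xyz in atoms:
            arr.chain_id[k] = chain_id
            arr.res_id[k] = resnum
            arr.res_name[k] = resname
            arr.atom_name[k] = name
            arr.element[k] = "H" if name.startswith("H") else name[0]
            arr.hetero[k] = False
            arr.coord[k] = xyz
            arr.occupancy[k] = 1.0
            arr.atom_id[k] = k + 1
            k += 1
    from .structure_io import Structure
    return Structure(arr)
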