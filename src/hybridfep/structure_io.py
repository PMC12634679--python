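"""PDB structure input/output and spherical-system bookkeeping.

Simulation systems are built inside a solvated sphere (default 50 Å
diameter) centered on the mutation site: the Cβ atom of the mutable
residue, or its side-chain hydrogen for glycine.  Atoms inside the
sphere move freely; protein atoms outside it are harmonically pinned to
their crystal positions (k = 200 kcal·mol⁻¹·Å⁻²) and excluded from
non-bonded interactions.  Ionizable residues whose charged group sits
within a thin shell (< 3 Å) of the sphere surface are flagged for
neutralization, since the dielectric screening near the boundary is too
poor to support a bare charge.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from ._geometry import place_atom

__all__ = [
    "Structure", "SphereSelection", "StructureError", "PdbParseError",
    "read_structure", "write_structure", "mutation_center", "select_sphere",
    "outer_layer_ionizables",
    "AMINO_ACIDS", "WATER_NAMES", "IONIZABLE_REFERENCE_ATOMS",
    "DEFAULT_SPHERE_DIAMETER", "OUTER_RESTRAINT_K", "IONIZABLE_SHELL",
]

#: residue names treated as protein (20 standard residues plus peptide caps)
AMINO_ACIDS = frozenset([
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ACE", "NME",
])
WATER_NAMES = frozenset(["HOH", "WAT", "TIP", "TIP3", "SPC", "SOL"])

#: atom defining the position of the charged group of each ionizable residue
IONIZABLE_REFERENCE_ATOMS = {
    "ARG": "CZ", "LYS": "NZ", "ASP": "CG", "GLU": "CD", "HIS": "NE2",
}

DEFAULT_SPHERE_DIAMETER = 50.0   # Å
OUTER_RESTRAINT_K = 200.0        # kcal·mol⁻¹·Å⁻², positional pin outside sphere
IONIZABLE_SHELL = 3.0            # Å, neutralization shell below the surface

# ideal Cβ internal coordinates in the N-CA-C backbone frame (L-configuration)
_CB_LENGTH, _CB_ANGLE, _CB_TORSION = 1.53, 109.5, -120.0


class StructureError(ValueError):
    pass


class PdbParseError(StructureError):
    pass


@dataclass
class Structure:
    """A protein structure in author (1-based, as-printed) PDB numbering.

    Wraps a :class:`biotite.structure.AtomArray` whose alternate locations
    have already been resolved (one atom per site) and that contains only
    the first model of multi-model files.
    """

    atoms: struc.AtomArray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not np.all(np.isfinite(self.atoms.coord)):
            raise StructureError("non-finite coordinates")
        self._index = {}
        for i in range(self.atoms.array_length()):
            key = (str(self.atoms.chain_id[i]), int(self.atoms.res_id[i]))
            self._index.setdefault(key, []).append(i)

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    @property
    def residue_keys(self):
        return list(self._index)

    def residue_indices(self, chain: str, resnum: int) -> list[int]:
        try:
            return self._index[(chain, resnum)]
        except KeyError:
            raise StructureError(f"no residue {chain}/{resnum}") from None

    def residue_name(self, chain: str, resnum: int) -> str:
        return str(self.atoms.res_name[self.residue_indices(chain, resnum)[0]])

    def residue_atoms(self, chain: str, resnum: int) -> dict[str, np.ndarray]:
        """Mapping atom name -> coordinates for one residue."""
        idx = self.residue_indices(chain, resnum)
        return {str(self.atoms.atom_name[i]): self.atoms.coord[i].copy() for i in idx}

    def atom_coord(self, chain: str, resnum: int, atom_name: str) -> np.ndarray:
        for i in self.residue_indices(chain, resnum):
            if self.atoms.atom_name[i] == atom_name:
                return self.atoms.coord[i].copy()
        raise StructureError(f"no atom {atom_name} in {chain}/{resnum}")

    def has_atom(self, chain: str, resnum: int, atom_name: str) -> bool:
        try:
            self.atom_coord(chain, resnum, atom_name)
            return True
        except StructureError:
            return False

    def chain_residue_numbers(self, chain: str) -> list[int]:
        return sorted(r for c, r in self._index if c == chain)

    def is_protein_mask(self) -> np.ndarray:
        return np.isin(self.atoms.res_name, list(AMINO_ACIDS))


def _validate_records(text: str) -> None:
    """Pre-flight check of fixed-column records so parse failures can be
    reported with a line number."""
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n_records += 1
        if len(line) < 54:
            raise PdbParseError(
                f"line {lineno}: truncated ATOM/HETATM record ({len(line)} columns)")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PdbParseError(
                    f"line {lineno}: unparsable {what} coordinate "
                    f"{line[lo:hi]!r}") from None
    if n_records == 0:
        raise PdbParseError("no ATOM/HETATM records found")


def _resolve_altlocs(atoms: struc.AtomArray) -> struc.AtomArray:
    """Keep one conformer per atom site: prefer altloc 'A', then highest
    occupancy, then lowest serial number."""
    alt = atoms.altloc_id
    blank = (alt == "") | (alt == " ") | (alt == ".")
    keep = np.ones(atoms.array_length(), dtype=bool)
    groups: dict[tuple, list[int]] = {}
    for i in np.nonzero(~blank)[0]:
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]),
               str(atoms.ins_code[i]), str(atoms.atom_name[i]))
        groups.setdefault(key, []).append(int(i))
    for idx in groups.values():
        best = min(idx, key=lambda i: (atoms.altloc_id[i] != "A",
                                       -float(atoms.occupancy[i]),
                                       int(atoms.atom_id[i])))
        for i in idx:
            keep[i] = i == best
    return atoms[keep]


def read_structure(source) -> Structure:
    """Read a PDB structure from a string or text file handle.

    Only the first model of a multi-model file is retained, and alternate
    locations are resolved (code 'A' preferred, then occupancy).  Author
    residue numbering is preserved verbatim.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    _validate_records(text)
    try:
        pfile = pdb.PDBFile.read(io.StringIO(text))
        atoms = pfile.get_structure(
            model=1, altloc="all", extra_fields=["occupancy", "atom_id"])
    except Exception as exc:  # biotite reports its own context
        raise PdbParseError(f"PDB parsing failed: {exc}") from exc
    atoms = _resolve_altlocs(atoms)
    if atoms.array_length() == 0:
        raise PdbParseError("structure is empty after altloc resolution")
    return Structure(atoms)


def write_structure(structure: Structure) -> str:
    """Serialize back to PDB text (fixed columns, ATOM/HETATM/END)."""
    pfile = pdb.PDBFile()
    pfile.set_structure(structure.atoms)
    out = io.StringIO()
    pfile.write(out)
    return out.getvalue()


def mutation_center(structure: Structure, chain: str, resnum: int) -> np.ndarray:
    """Center of the simulation sphere for a mutation at the given residue.

    Returns the Cβ position, or the side-chain α-hydrogen for glycine.  If
    the required atom is absent (e.g. a hydrogen-free crystal structure of
    glycine), an ideal Cβ is reconstructed from the N-CA-C backbone frame.
    """
    resname = structure.residue_name(chain, resnum)
    names = structure.residue_atoms(chain, resnum)
    if resname == "GLY":
        for h in ("HA2", "2HA", "HA3"):
            if h in names:
                return names[h]
    elif "CB" in names:
        return names["CB"]
    if all(a in names for a in ("N", "CA", "C")):
        return place_atom(names["CA"], names["N"], names["C"],
                          _CB_LENGTH, _CB_ANGLE, _CB_TORSION)
    raise StructureError(
        f"residue {chain}/{resnum} ({resname}) has neither a side-chain "
        "center atom nor a complete N/CA/C backbone to reconstruct one")


@dataclass
class SphereSelection:
    """Partition of a structure relative to the simulation sphere.

    ``free`` atoms (inside the sphere) move during MD; ``restrained``
    protein atoms outside the sphere are pinned with force constant
    ``k_out`` and excluded from non-bonded interactions; ``excluded``
    atoms are non-protein atoms outside the sphere, which are dropped
    from the system entirely.
    """

    center: np.ndarray
    radius: float
    free_ids: np.ndarray
    restrained_ids: np.ndarray
    excluded_ids: np.ndarray
    k_out: float = OUTER_RESTRAINT_K

    @property
    def nonbonded_excluded_ids(self) -> np.ndarray:
        """Atoms removed from the non-bonded pair list (the restrained
        outer protein shell)."""
        return self.restrained_ids


def select_sphere(structure: Structure, center, diameter: float = DEFAULT_SPHERE_DIAMETER) -> SphereSelection:
    if diameter <= 0:
        raise ValueError("sphere diameter must be positive")
    center = np.asarray(center, dtype=float)
    radius = diameter / 2.0
    dist = np.linalg.norm(structure.atoms.coord - center, axis=1)
    inside = dist <= radius
    protein = structure.is_protein_mask()
    ids = np.arange(structure.n_atoms)
    return SphereSelection(
        center=center,
        radius=radius,
        free_ids=ids[inside],
        restrained_ids=ids[~inside & protein],
        excluded_ids=ids[~inside & ~protein],
    )


def outer_layer_ionizables(structure: Structure, selection: SphereSelection,
                           shell: float = IONIZABLE_SHELL) -> list[tuple[str, int]]:
    """Ionizable residues whose charged group lies inside the sphere but
    within ``shell`` Å of its surface; these are neutralized.

    The charged group is located by a fixed reference atom per residue
    type (ARG: CZ, LYS: NZ, ASP: CG, GLU: CD, HIS: NE2).
    """
    out = []
    for (chain, resnum) in structure.residue_keys:
        resname = structure.residue_name(chain, resnum)
        ref = IONIZABLE_REFERENCE_ATOMS.get(resname)
        if ref is None or not structure.has_atom(chain, resnum, ref):
            continue
        d = float(np.linalg.norm(
            structure.atom_coord(chain, resnum, ref) - selection.center))
        if selection.radius - shell < d <= selection.radius:
            out.append((chain, resnum))
    return out
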