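"""Protein-ligand complexes: PDB I/O, donor/acceptor fragments, contact detection.

A binding pose is reduced to a heavy-atom model.  Every nitrogen or oxygen
that sits in a three-atom environment (the center plus its two nearest heavy
neighbors) defines a *fragment* whose center is classified as a hydrogen-bond
donor or acceptor from its heavy-atom valence alone — no explicit hydrogens
are required.  A residue fragment and a ligand fragment whose roles are
complementary and whose centers lie within a distance cutoff form one
*contact*; contacts are the atoms of the binding language.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger("bindtext")

#: default center-to-center contact cutoff, Angstrom
DEFAULT_CUTOFF = 4.0

#: single-bond covalent radii (Angstrom) for the elements the model handles
COVALENT_RADII = {
    "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "H": 0.31,
}
BOND_TOLERANCE = 0.4  # added to the radius sum when inferring bonds

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    """One heavy atom: element symbol, PDB atom name, coordinates, owner id."""

    element: str
    name: str
    coords: tuple[float, float, float]
    owner: str

    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Residue:
    code: str          # one-letter amino-acid code
    number: int        # 1-based residue number
    atoms: tuple[Atom, ...]


@dataclass(frozen=True)
class Fragment:
    """Three-atom unit: a donor/acceptor center plus its two nearest heavy
    neighbors.  ``context`` is the next-nearest heavy atom beyond the two
    neighbors (used only for serialization context; it is not part of the
    three-atom unit and may be absent in minimal molecules)."""

    center: Atom
    neighbors: tuple[Atom, Atom]
    role: str                      # "donor" | "acceptor"
    context: Atom | None = None

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor"):
            raise ValueError(f"fragment role must be donor/acceptor, got {self.role!r}")
        atoms = {id(self.center), id(self.neighbors[0]), id(self.neighbors[1])}
        if len(atoms) != 3:
            raise ValueError("fragment requires 3 distinct atoms")


@dataclass(frozen=True)
class ContactPair:
    residue_fragment: Fragment
    ligand_fragment: Fragment
    residue_code: str
    distance: float
    ligand_fragment_index: int   # 1-based ordinal within the ligand
    residue_order: int = 0       # position of the residue in the complex

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        roles = {self.residue_fragment.role, self.ligand_fragment.role}
        if roles != {"donor", "acceptor"}:
            raise ValueError("contact roles must be complementary donor/acceptor")


@dataclass
class BindingComplex:
    """One pose of one protein-ligand complex (heavy atoms only)."""

    residues: list[Residue]
    ligand: list[Atom]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("complex needs at least one residue")
        if len(self.ligand) < 3:
            raise ValueError("complex needs a ligand with at least 3 atoms")

    @property
    def target(self) -> str:
        return self.metadata.get("target", "")

    @property
    def ligand_id(self) -> str:
        return self.metadata.get("ligand_id", "")

    @property
    def pose_id(self) -> str:
        return self.metadata.get("pose_id", "")


# ---------------------------------------------------------------------------
# bond inference and fragment assignment
# ---------------------------------------------------------------------------

def _bonded(a: Atom, b: Atom) -> bool:
    ra = COVALENT_RADII.get(a.element.upper(), 0.77)
    rb = COVALENT_RADII.get(b.element.upper(), 0.77)
    d = float(np.linalg.norm(a.xyz() - b.xyz()))
    return 0.0 < d <= ra + rb + BOND_TOLERANCE


def infer_bonds(atoms: list[Atom]) -> list[set[int]]:
    """Distance-based adjacency (covalent radii + 0.4 A); heavy atoms only."""
    n = len(atoms)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _bonded(atoms[i], atoms[j]):
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _role_for(element: str, degree: int) -> str | None:
    """Valence-based donor/acceptor call for an N/O center.

    N with heavy-atom degree < 3 carries an implicit hydrogen -> donor;
    fully substituted N -> acceptor.  O with degree 1 (carbonyl-like) has no
    hydrogen -> acceptor; O with degree 2 is hydroxyl/ether-like -> donor.
    """
    el = element.upper()
    if el == "N":
        return "donor" if degree < 3 else "acceptor"
    if el == "O":
        return "acceptor" if degree <= 1 else "donor"
    return None


def assign_fragments(atoms: list[Atom], adjacency: list[set[int]] | None = None) -> list[Fragment]:
    """Return one fragment per N/O heavy atom that has >= 2 near heavy atoms.

    The two fragment neighbors are the bonded heavy atoms nearest the center
    (padded with the nearest non-bonded atoms of the same molecule when the
    center has fewer than two bonds, e.g. a carbonyl oxygen); ties break on
    atom name.  Centers without two candidates are skipped and logged.
    """
    if adjacency is None:
        adjacency = infer_bonds(atoms)
    fragments: list[Fragment] = []
    for i, atom in enumerate(atoms):
        role = _role_for(atom.element, len(adjacency[i]))
        if role is None:
            continue
        center_xyz = atom.xyz()

        def _key(j: int) -> tuple[float, str]:
            return (float(np.linalg.norm(atoms[j].xyz() - center_xyz)), atoms[j].name)

        bonded = sorted(adjacency[i], key=_key)
        others = sorted((j for j in range(len(atoms)) if j != i and j not in adjacency[i]),
                        key=_key)
        ranked = bonded + others
        if len(ranked) < 2:
            logger.debug("fragment skipped: %s/%s has <2 heavy neighbors", atom.owner, atom.name)
            continue
        n1, n2 = atoms[ranked[0]], atoms[ranked[1]]
        context = atoms[ranked[2]] if len(ranked) > 2 else None
        fragments.append(Fragment(center=atom, neighbors=(n1, n2), role=role, context=context))
    return fragments


def residue_fragments(residue: Residue) -> list[Fragment]:
    return assign_fragments(list(residue.atoms))


def ligand_fragments(ligand: list[Atom]) -> list[Fragment]:
    return assign_fragments(ligand)


# ---------------------------------------------------------------------------
# contact detection
# ---------------------------------------------------------------------------

def detect_contacts(complex_: BindingComplex, cutoff: float = DEFAULT_CUTOFF) -> list[ContactPair]:
    """All complementary residue-fragment/ligand-fragment pairs within cutoff.

    Each discrete donor-acceptor pair is one contact; the list is sorted by
    (residue order in the complex, ligand fragment ordinal).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_frags = ligand_fragments(complex_.ligand)
    contacts: list[ContactPair] = []
    for r_idx, res in enumerate(complex_.residues):
        for rfrag in residue_fragments(res):
            for l_idx, lfrag in enumerate(lig_frags, start=1):
                if rfrag.role == lfrag.role:
                    continue
                d = float(np.linalg.norm(rfrag.center.xyz() - lfrag.center.xyz()))
                if 0.0 < d <= cutoff:
                    contacts.append(ContactPair(
                        residue_fragment=rfrag,
                        ligand_fragment=lfrag,
                        residue_code=res.code,
                        distance=d,
                        ligand_fragment_index=l_idx,
                        residue_order=r_idx,
                    ))
    contacts.sort(key=lambda c: (c.residue_order, c.ligand_fragment_index))
    return contacts


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _validate_pdb_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6].strip() in ("ATOM", "HETATM"):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ValueError(f"unparsable coordinate record at line {lineno}") from None


def load_complex(pdb_text: str) -> BindingComplex:
    """Parse a single-pose protein-ligand complex from PDB text.

    Waters, hydrogens and alternate locations are removed; the largest
    connected HETATM component is taken as the ligand; residue numbering is
    preserved.  Raises ``ValueError`` if no ligand is present or a coordinate
    record cannot be parsed (reported with its line number).
    """
    _validate_pdb_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("complex", io.StringIO(pdb_text))
    model = next(structure.get_models())

    residues: list[Residue] = []
    het_atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, _ = res.get_id()
            resname = res.get_resname().strip()
            if resname in WATER_NAMES or hetflag == "W":
                continue
            atoms = []
            for a in res.get_atoms():
                if a.is_disordered():
                    a = a.disordered_get()
                el = (a.element or a.get_name()[:1]).strip().upper()
                if el in ("H", "D"):
                    continue
                atoms.append((a.get_name().strip(), el, tuple(round(float(v), 3) for v in a.coord)))
            if not atoms:
                continue
            if hetflag.startswith("H"):
                owner = resname
                het_atoms.extend(Atom(el, nm, xyz, owner) for nm, el, xyz in atoms)
            else:
                code = THREE_TO_ONE.get(resname, "X")
                owner = f"{code}{resseq}"
                residues.append(Residue(
                    code=code, number=int(resseq),
                    atoms=tuple(Atom(el, nm, xyz, owner) for nm, el, xyz in atoms),
                ))

    if not het_atoms:
        raise ValueError("no ligand found (no non-water HETATM records)")

    # ligand = largest connected HETATM component (ties: earliest atom)
    adj = infer_bonds(het_atoms)
    seen: set[int] = set()
    components: list[list[int]] = []
    for start in range(len(het_atoms)):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in adj[i]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        components.append(sorted(comp))
    components.sort(key=lambda c: (-len(c), c[0]))
    ligand = [het_atoms[i] for i in components[0]]

    metadata = {"target": "", "ligand_id": ligand[0].owner.split(":")[0], "pose_id": ""}
    for line in pdb_text.splitlines():
        if line.startswith("REMARK 900"):
            parts = line.split(maxsplit=3)
            if len(parts) == 4 and parts[2] in ("TARGET", "LIGAND", "POSE"):
                key = {"TARGET": "target", "LIGAND": "ligand_id", "POSE": "pose_id"}[parts[2]]
                metadata[key] = parts[3].strip()
    return BindingComplex(residues=residues, ligand=ligand, metadata=metadata)


def write_complex_pdb(complex_: BindingComplex) -> str:
    """Serialize a complex as minimal standard PDB records (inverse of
    :func:`load_complex` for complexes produced by this package)."""
    lines: list[str] = []
    md = complex_.metadata
    for key, tag in (("target", "TARGET"), ("ligand_id", "LIGAND"), ("pose_id", "POSE")):
        if md.get(key):
            lines.append(f"REMARK 900 {tag} {md[key]}")
    serial = 1
    for res in complex_.residues:
        resname = ONE_TO_THREE.get(res.code, "UNK")
        for atom in res.atoms:
            lines.append(_pdb_record("ATOM", serial, atom.name, resname, "A",
                                     res.number, atom.coords, atom.element))
            serial += 1
    lines.append(f"TER   {serial:>5d}")
    serial += 1
    lig_name = (md.get("ligand_id") or "LIG")[:3].upper() or "LIG"
    for atom in complex_.ligand:
        lines.append(_pdb_record("HETATM", serial, atom.name, lig_name, "A",
                                 1, atom.coords, atom.element))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _pdb_record(kind: str, serial: int, name: str, resname: str, chain: str,
                resseq: int, coords: tuple[float, float, float], element: str) -> str:
    # PDB convention: atom names of <4 chars start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = coords
    return (f"{kind:<6s}{serial:>5d} {name_field} {resname:<3s} {chain}{resseq:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element.upper():>2s}")


def transform_complex(complex_: BindingComplex, rotation: np.ndarray,
                      translation: np.ndarray) -> BindingComplex:
    """Apply a rigid-body transform to every atom (used for invariance checks)."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)

    def _move(a: Atom) -> Atom:
        return replace(a, coords=tuple(np.round(R @ a.xyz() + t, 6)))

    residues = [Residue(r.code, r.number, tuple(_move(a) for a in r.atoms))
                for r in complex_.residues]
    ligand = [_move(a) for a in complex_.ligand]
    return BindingComplex(residues=residues, ligand=ligand, metadata=dict(complex_.metadata))
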