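"""Molecular data model, PDB/XYZ I/O, atom typing, and furanoside fixtures.

The packaged fixtures are the eight methyl D-pentofuranosides (arabino-,
lyxo-, ribo- and xylo-furanoside, alpha and beta anomers): 23 atoms, formula
C6H12O5, ring atoms C1, C2, C3, C4, O4. Geometries are idealized internal
coordinates (C-C 1.526 A, C-O 1.410 A, C-H 1.09 A, O-H 0.96 A, tetrahedral
angles; ring bond angles relax for closure), which is sufficient for
descriptor and pipeline work on these molecules.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io

from . import _ring
from .exceptions import ParseError, TypingError, ValidationError
from .geometry import dihedral, place_nerf

__all__ = [
    "AtomRecord",
    "MoleculeGraph",
    "TypingTemplate",
    "read_structure",
    "write_structure",
    "assign_atom_types",
    "dihedral",
    "build_furanoside_fixture",
    "load_typing_template",
    "infer_bonds",
    "RING_ATOM_NAMES",
    "SUGARS",
    "ANOMERS",
]

RING_ATOM_NAMES = ("C1", "C2", "C3", "C4", "O4")
SUGARS = ("ara", "lyx", "rib", "xyl")
ANOMERS = ("alpha", "beta")

# single-bond covalent radii (A), for distance-based bond inference
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}
BOND_INFERENCE_FACTOR = 1.25

# idealized internal coordinates (A / deg)
BOND_CC = 1.526
BOND_CO = 1.410
BOND_OH = 0.96
BOND_CH = 1.09
TETRAHEDRAL = 109.47


@dataclass
class AtomRecord:
    """One atom: stable 0-based index, element, unique name, optional
    force-field type, Cartesian position in Angstrom."""

    index: int
    element: str
    atom_name: str
    position: np.ndarray
    atom_type: str | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.atom_name}: position must be a finite 3-vector")


@dataclass
class MoleculeGraph:
    """Atoms + bond list + net charge. Bonds are unordered 0-based index pairs."""

    atoms: list[AtomRecord]
    bonds: set[tuple[int, int]]
    net_charge: int = 0
    label: str = ""

    def __post_init__(self):
        self.bonds = {tuple(sorted(b)) for b in self.bonds}
        names = [a.atom_name for a in self.atoms]
        if len(set(names)) != len(names):
            raise ValidationError("atom names must be unique within a molecule")
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValidationError(f"invalid bond ({i}, {j}) for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "MoleculeGraph":
        coords = np.asarray(coords, float)
        if coords.shape != (self.n_atoms, 3):
            raise ValidationError("coordinate array shape mismatch")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return MoleculeGraph(atoms, set(self.bonds), self.net_charge, self.label)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return {k: sorted(v) for k, v in adj.items()}

    def neighbors(self, i: int) -> list[int]:
        return self.adjacency()[i]

    def index_of(self, atom_name: str) -> int:
        for a in self.atoms:
            if a.atom_name == atom_name:
                return a.index
        raise KeyError(atom_name)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def atom_names(self) -> list[str]:
        return [a.atom_name for a in self.atoms]

    def atom_types(self) -> list[str]:
        types = []
        for a in self.atoms:
            if a.atom_type is None:
                raise TypingError(f"atom {a.atom_name} has no atom type assigned")
            types.append(a.atom_type)
        return types

    def validate_connected(self) -> None:
        if self.n_atoms == 0:
            raise ValidationError("empty molecule")
        if self.n_atoms == 1 or not nx.is_connected(self.graph()):
            raise ValidationError(
                f"bond graph of '{self.label or 'molecule'}' is not a single connected component"
            )

    def ring_indices(self) -> list[int]:
        """Indices of the (single) ring, in bond order starting from the
        lowest-index ring atom."""
        cycles = nx.cycle_basis(self.graph())
        if len(cycles) != 1:
            raise ValidationError(f"expected exactly one ring, found {len(cycles)}")
        cyc = cycles[0]
        start = cyc.index(min(cyc))
        ordered = cyc[start:] + cyc[:start]
        if len(ordered) > 2 and ordered[1] > ordered[-1]:
            ordered = [ordered[0]] + ordered[:0:-1]
        return ordered


@dataclass
class TypingTemplate:
    """atom_name -> force-field atom_type mapping for one residue class."""

    residue_class: str
    mapping: dict[str, str] = field(default_factory=dict)

    def type_of(self, atom_name: str) -> str:
        try:
            return self.mapping[atom_name]
        except KeyError:
            raise TypingError(
                f"atom name '{atom_name}' is not covered by typing template "
                f"'{self.residue_class}'"
            ) from None


def load_typing_template(residue_class: str = "methyl_pentofuranoside") -> TypingTemplate:
    """Load a packaged typing template (GLYCAM-style furanoside types)."""
    text = resources.files("atsf.data").joinpath("typing_templates.json").read_text()
    tables = json.loads(text)
    if residue_class not in tables:
        raise TypingError(f"no packaged typing template for '{residue_class}'")
    return TypingTemplate(residue_class, tables[residue_class])


def assign_atom_types(mol: MoleculeGraph, template: TypingTemplate) -> MoleculeGraph:
    """Return a copy of `mol` with atom types set from the template.

    Raises :class:`TypingError` naming the first atom whose name the template
    does not cover.
    """
    atoms = [replace(a, atom_type=template.type_of(a.atom_name)) for a in mol.atoms]
    return MoleculeGraph(atoms, set(mol.bonds), mol.net_charge, mol.label)


def infer_hydrogen_type(mol: MoleculeGraph, h_index: int) -> str:
    """GLYCAM hydrogen typing rule: a hydrogen on a carbon is H1 or H2
    according to whether that carbon is bonded to one or two
    electron-withdrawing (oxygen) atoms; a hydrogen on oxygen is Ho."""
    neigh = mol.neighbors(h_index)
    if len(neigh) != 1:
        raise TypingError("hydrogen must have exactly one bond")
    heavy = mol.atoms[neigh[0]]
    if heavy.element == "O":
        return "Ho"
    if heavy.element != "C":
        raise TypingError(f"unsupported hydrogen attachment: {heavy.element}")
    n_o = sum(1 for k in mol.neighbors(heavy.index) if mol.atoms[k].element == "O")
    if n_o == 1:
        return "H1"
    if n_o == 2:
        return "H2"
    raise TypingError(f"carbon {heavy.atom_name} bonded to {n_o} oxygens: rule undefined")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def infer_bonds(elements: list[str], coords: np.ndarray) -> set[tuple[int, int]]:
    """Distance-based bond inference: bond iff distance < 1.25 x sum of
    covalent radii."""
    coords = np.asarray(coords, float)
    n = len(elements)
    bonds = set()
    for i in range(n):
        for j in range(i + 1, n):
            try:
                cut = BOND_INFERENCE_FACTOR * (COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]])
            except KeyError as exc:
                raise ParseError(f"no covalent radius for element {exc}") from None
            if np.linalg.norm(coords[i] - coords[j]) < cut:
                bonds.add((i, j))
    return bonds


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ParseError(f"cannot derive element from atom name '{name}'")


def read_structure(path, fmt: str | None = None, model: int = 1) -> MoleculeGraph:
    """Read a PDB or XYZ file into a MoleculeGraph (coordinates in Angstrom).

    PDB atom names are preserved verbatim; bonds are inferred by covalent
    distance unless the file is one of ours with explicit CONECT records
    (biotite drops them; inference is the rule here). The graph must be
    connected.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        try:
            pfile = pdb_io.PDBFile.read(str(path))
            arr = pfile.get_structure(model=model)
        except Exception as exc:
            raise ParseError(f"failed to parse PDB file {path}: {exc}") from exc
        atoms = []
        for i in range(arr.array_length()):
            el = str(arr.element[i]).strip().capitalize()
            name = str(arr.atom_name[i]).strip()
            if not el:
                el = _element_from_name(name)
            atoms.append(AtomRecord(i, el, name, np.asarray(arr.coord[i], float)))
        label = path.stem
    elif fmt == "xyz":
        atoms = _read_xyz(path)
        label = path.stem
    else:
        raise ParseError(f"unsupported structure format '{fmt}'")
    elements = [a.element for a in atoms]
    coords = np.array([a.position for a in atoms]) if atoms else np.empty((0, 3))
    bonds = infer_bonds(elements, coords)
    mol = MoleculeGraph(atoms, bonds, net_charge=0, label=label)
    mol.validate_connected()
    return mol


def _read_xyz(path: Path) -> list[AtomRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}, line 1: expected atom count") from None
    atoms = []
    counts: dict[str, int] = {}
    for ln, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {ln}: expected 'element x y z'")
        el = parts[0].capitalize()
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}, line {ln}: non-numeric coordinate") from None
        counts[el] = counts.get(el, 0) + 1
        atoms.append(AtomRecord(len(atoms), el, f"{el}{counts[el]}", np.array(xyz)))
    if len(atoms) != n:
        raise ParseError(f"{path}: header promises {n} atoms, found {len(atoms)}")
    return atoms


def write_structure(
    mol: MoleculeGraph,
    path,
    fmt: str | None = None,
    conformers: list[np.ndarray] | None = None,
) -> None:
    """Write a molecule (optionally a conformer ensemble) as PDB or XYZ.

    PDB output uses HETATM records with 1-based serials; an ensemble becomes
    MODEL 1..n blocks. XYZ ensembles are concatenated frames.
    """
    if mol.n_atoms == 0:
        raise ValidationError("refusing to write an empty molecule")
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    frames = conformers if conformers is not None else [mol.coords]
    if fmt == "pdb":
        n = mol.n_atoms
        template = struc.AtomArray(n)
        template.coord = np.zeros((n, 3), dtype=np.float32)
        for i, a in enumerate(mol.atoms):
            template.atom_name[i] = a.atom_name
            template.element[i] = a.element.upper()
            template.res_id[i] = 1
            template.res_name[i] = (mol.label[:3].upper() or "LIG")
            template.hetero[i] = True
        if len(frames) == 1:
            arr = template.copy()
            arr.coord = np.asarray(frames[0], np.float32)
            pfile = pdb_io.PDBFile()
            pfile.set_structure(arr)
        else:
            stack = struc.stack([template] * len(frames))
            stack.coord = np.asarray(frames, np.float32)
            pfile = pdb_io.PDBFile()
            pfile.set_structure(stack)
        pfile.write(str(path))
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for fr in frames:
                fh.write(f"{mol.n_atoms}\n{mol.label}\n")
                for a, xyz in zip(mol.atoms, np.asarray(fr, float)):
                    fh.write(f"{a.element:2s} {xyz[0]:15.8f} {xyz[1]:15.8f} {xyz[2]:15.8f}\n")
    else:
        raise ParseError(f"unsupported structure format '{fmt}'")


# ---------------------------------------------------------------------------
# furanoside fixtures
# ---------------------------------------------------------------------------

# Haworth-style relative configuration: is the substituent oxygen on the same
# face as the C5 (hydroxymethyl) branch? C5 itself defines "up".
_SUGAR_FACES = {
    #        O2 up?   O3 up?
    "rib": (False, False),
    "ara": (True, False),
    "xyl": (False, True),
    "lyx": (True, True),
}

_FIXTURE_ATOM_ORDER = [
    "C1", "H1", "O1", "CH3", "H1M", "H2M", "H3M",
    "C2", "H2", "O2", "H2O",
    "C3", "H3", "O3", "H3O",
    "C4", "H4",
    "C5", "H51", "H52", "O5", "H5O",
    "O4",
]

_FIXTURE_ELEMENTS = {name: name.lstrip("H")[:1] if not name.startswith("H") else "H"
                     for name in _FIXTURE_ATOM_ORDER}

_FIXTURE_BONDS_BY_NAME = [
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "O4"), ("O4", "C1"),
    ("C1", "H1"), ("C1", "O1"), ("O1", "CH3"),
    ("CH3", "H1M"), ("CH3", "H2M"), ("CH3", "H3M"),
    ("C2", "H2"), ("C2", "O2"), ("O2", "H2O"),
    ("C3", "H3"), ("C3", "O3"), ("O3", "H3O"),
    ("C4", "H4"), ("C4", "C5"),
    ("C5", "H51"), ("C5", "H52"), ("C5", "O5"), ("O5", "H5O"),
]

DEFAULT_EXO_TORSIONS = {
    "C1-O1": 180.0,
    "O1-CH3": 180.0,
    "C2-O2": 180.0,
    "C3-O3": 180.0,
    "C4-C5": 180.0,
    "C5-O5": 180.0,
}

DEFAULT_PUCKER = (18.0, 39.0)  # (P, tau_m): a typical north twist


def _tetrahedral_pair(x, prev_pt, next_pt):
    """Unit directions for the two substituents of a ring atom `x` whose ring
    neighbors sit at prev_pt/next_pt. Returns (up, down) with 'up' on the
    +cross(u_prev, u_next) face, which is the same face for every ring atom."""
    u1 = prev_pt - x
    u1 /= np.linalg.norm(u1)
    u2 = next_pt - x
    u2 /= np.linalg.norm(u2)
    b = -(u1 + u2)
    b /= np.linalg.norm(b)
    p = np.cross(u1, u2)
    p /= np.linalg.norm(p)
    half = np.radians(TETRAHEDRAL / 2.0)
    up = b * np.cos(half) + p * np.sin(half)
    down = b * np.cos(half) - p * np.sin(half)
    return up, down


def build_furanoside_fixture(
    sugar: str,
    anomer: str,
    pucker: tuple[float, float] = DEFAULT_PUCKER,
    exo_torsions: dict[str, float] | None = None,
) -> MoleculeGraph:
    """Construct an idealized methyl D-pentofuranoside (23 atoms, C6H12O5).

    `sugar` selects the relative configuration at C2/C3 (ara, lyx, rib, xyl);
    `anomer` places the glycosidic oxygen cis (beta) or trans (alpha) to the
    C5 branch. The ring is embedded at the requested pseudorotation state and
    exo-cyclic torsions are driven to the requested values (default all
    anti). Atoms carry no types; see :func:`assign_atom_types`.
    """
    if sugar not in _SUGAR_FACES:
        raise ValueError(f"unknown sugar '{sugar}'; expected one of {SUGARS}")
    if anomer not in ANOMERS:
        raise ValueError(f"unknown anomer '{anomer}'; expected one of {ANOMERS}")
    exo = dict(DEFAULT_EXO_TORSIONS)
    if exo_torsions:
        unknown = set(exo_torsions) - set(exo)
        if unknown:
            raise ValueError(f"unknown exo-cyclic torsions: {sorted(unknown)}")
        exo.update(exo_torsions)

    pos: dict[str, np.ndarray] = {}
    ring = np.asarray(_ring.ring_coords_cached(float(pucker[0]), float(pucker[1])), float)
    for name, xyz in zip(RING_ATOM_NAMES, ring):
        pos[name] = np.array(xyz)

    o2_up, o3_up = _SUGAR_FACES[sugar]
    o1_up = anomer == "beta"

    ring_order = list(RING_ATOM_NAMES)

    def ring_neighbors(name):
        i = ring_order.index(name)
        return ring_order[i - 1], ring_order[(i + 1) % 5]

    # substituents on ring carbons (two per carbon, one face each)
    for carbon, sub_o, sub_h, o_up, r_o in (
        ("C1", "O1", "H1", o1_up, BOND_CO),
        ("C2", "O2", "H2", o2_up, BOND_CO),
        ("C3", "O3", "H3", o3_up, BOND_CO),
        ("C4", "C5", "H4", True, BOND_CC),  # D-configuration: C5 up
    ):
        prev_name, next_name = ring_neighbors(carbon)
        up, down = _tetrahedral_pair(pos[carbon], pos[prev_name], pos[next_name])
        d_o, d_h = (up, down) if o_up else (down, up)
        pos[sub_o] = pos[carbon] + r_o * d_o
        pos[sub_h] = pos[carbon] + BOND_CH * d_h

    # chain extension by Z-matrix placement (torsions driven afterwards)
    pos["CH3"] = place_nerf(pos["C2"], pos["C1"], pos["O1"], BOND_CO, TETRAHEDRAL, exo["C1-O1"])
    for hname, off in (("H1M", 0.0), ("H2M", 120.0), ("H3M", -120.0)):
        pos[hname] = place_nerf(
            pos["C1"], pos["O1"], pos["CH3"], BOND_CH, TETRAHEDRAL, exo["O1-CH3"] + off
        )
    pos["H2O"] = place_nerf(pos["C1"], pos["C2"], pos["O2"], BOND_OH, TETRAHEDRAL, exo["C2-O2"])
    pos["H3O"] = place_nerf(pos["C2"], pos["C3"], pos["O3"], BOND_OH, TETRAHEDRAL, exo["C3-O3"])
    pos["O5"] = place_nerf(pos["C3"], pos["C4"], pos["C5"], BOND_CO, TETRAHEDRAL, exo["C4-C5"])
    for hname, off in (("H51", 120.0), ("H52", -120.0)):
        pos[hname] = place_nerf(
            pos["C3"], pos["C4"], pos["C5"], BOND_CH, TETRAHEDRAL, exo["C4-C5"] + off
        )
    pos["H5O"] = place_nerf(pos["C4"], pos["C5"], pos["O5"], BOND_OH, TETRAHEDRAL, exo["C5-O5"])

    atoms = [
        AtomRecord(i, _FIXTURE_ELEMENTS[name], name, pos[name])
        for i, name in enumerate(_FIXTURE_ATOM_ORDER)
    ]
    name_to_idx = {name: i for i, name in enumerate(_FIXTURE_ATOM_ORDER)}
    bonds = {(name_to_idx[a], name_to_idx[b]) for a, b in _FIXTURE_BONDS_BY_NAME}
    mol = MoleculeGraph(atoms, bonds, net_charge=0, label=f"{sugar}_{anomer}")
    mol.validate_connected()
    return mol
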