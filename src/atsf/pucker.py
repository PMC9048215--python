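"""Furanose pseudorotation: phase/amplitude math, the ring-conformation grid,
conformer embedding, exo-cyclic torsion randomization, and dataset splitting.

A five-membered ring conformation is described by the pseudorotation phase
angle P (degrees, [0, 360)) and puckering amplitude tau_m (degrees): the five
endo-cyclic torsions follow theta_j = tau_m * cos(P + 144 deg * j), with
theta_0 = C1-C2-C3-C4, ..., theta_4 = O4-C1-C2-C3. The inverse uses the
discrete Fourier projections

    tau_m cos P =  (2/5) sum_j theta_j cos(144 j)
    tau_m sin P = -(2/5) sum_j theta_j sin(144 j)

which are algebraically exact for cosine-law torsion sets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _ring
from .exceptions import GeometryError, EmbeddingError, ValidationError
from .geometry import dihedral, set_torsion
from .molecule import MoleculeGraph, RING_ATOM_NAMES

__all__ = [
    "PuckerState",
    "RingTorsions",
    "ConformerSpec",
    "ConformerDataset",
    "torsions_from_pucker",
    "pucker_from_torsions",
    "ring_grid",
    "embed_conformer",
    "exocyclic_torsions",
    "randomize_exocyclic",
    "split_dataset",
    "generate_conformers",
    "ring_torsion_quads",
]

_J = np.arange(5)
_COS = np.cos(np.radians(144.0 * _J))
_SIN = np.sin(np.radians(144.0 * _J))


@dataclass(frozen=True)
class PuckerState:
    """Pseudorotation phase P (deg, normalized to [0, 360)) and amplitude
    tau_m (deg, > 0)."""

    P: float
    tau_m: float

    def __post_init__(self):
        object.__setattr__(self, "P", float(self.P) % 360.0)
        object.__setattr__(self, "tau_m", float(self.tau_m))
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")


@dataclass(frozen=True)
class RingTorsions:
    """The five signed ring torsions theta_0..theta_4 in degrees."""

    theta: tuple[float, float, float, float, float]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.theta, float)


@dataclass(frozen=True)
class ConformerSpec:
    """One target conformation: ring pucker + exo-cyclic torsion targets."""

    pucker: PuckerState
    exo_torsions: dict[str, float] = field(default_factory=dict)
    conformer_id: str = ""

    def __hash__(self):
        return hash((self.pucker, tuple(sorted(self.exo_torsions.items())), self.conformer_id))


@dataclass
class ConformerDataset:
    """Embedded conformers of one molecule with per-ring-conformation grouping
    and (after :func:`split_dataset`) train/test labels."""

    molecule: MoleculeGraph
    specs: list[ConformerSpec]
    coords: list[np.ndarray]
    ring_ids: list[int]  # index of the ring conformation each conformer samples
    split: list[str] | None = None  # "train"/"test" per conformer

    def __len__(self) -> int:
        return len(self.specs)


def torsions_from_pucker(p: PuckerState) -> RingTorsions:
    """Cosine law: theta_j = tau_m * cos(P + 144 deg * j)."""
    th = p.tau_m * np.cos(np.radians(p.P + 144.0 * _J))
    return RingTorsions(tuple(float(t) for t in th))


def pucker_from_torsions(t: RingTorsions) -> PuckerState:
    """Invert the cosine law via Fourier projections (exact for cosine-law
    torsions). Raises :class:`GeometryError` for an all-zero (planar) set,
    whose phase is undefined."""
    th = t.as_array()
    x = (2.0 / 5.0) * float(np.dot(th, _COS))  # tau_m cos P
    y = -(2.0 / 5.0) * float(np.dot(th, _SIN))  # tau_m sin P
    tau = float(np.hypot(x, y))
    if tau < 1e-12:
        raise GeometryError("planar ring: pseudorotation phase is undefined")
    P = float(np.degrees(np.arctan2(y, x))) % 360.0
    return PuckerState(P, tau)


def ring_grid(
    tau_start: float = 3.0,
    tau_stop: float = 45.0,
    tau_step: float = 3.0,
    p_step: float = 6.0,
) -> list[PuckerState]:
    """The ring-conformation sampling grid: tau_m from 3 to 45 deg in 3 deg
    steps, P from 0 deg in 6 deg steps with the redundant 360 deg endpoint
    excluded — 15 x 60 = 900 states at the defaults, tau_m-major order."""
    taus = np.arange(tau_start, tau_stop + 0.5 * tau_step, tau_step)
    ps = np.arange(0.0, 360.0, p_step)
    return [PuckerState(float(p), float(t)) for t in taus for p in ps]


def ring_torsion_quads(mol: MoleculeGraph) -> list[tuple[int, int, int, int]]:
    """Index quadruples for theta_0..theta_4 on this molecule's ring."""
    ring = mol.ring_indices()
    if len(ring) != 5:
        raise ValidationError("pseudorotation requires a five-membered ring")
    return [tuple(ring[(j + k) % 5] for k in range(4)) for j in range(5)]


def ring_torsions_of(mol: MoleculeGraph, coords: np.ndarray) -> RingTorsions:
    """Measure theta_0..theta_4 on a coordinate set."""
    coords = np.asarray(coords, float)
    th = tuple(
        dihedral(*(coords[i] for i in quad)) for quad in ring_torsion_quads(mol)
    )
    return RingTorsions(th)


# ---------------------------------------------------------------------------
# exo-cyclic torsions
# ---------------------------------------------------------------------------

def exocyclic_torsions(mol: MoleculeGraph) -> dict[str, tuple[int, int, int, int]]:
    """Discover rotatable exo-cyclic bonds and a deterministic reference
    quadruple for each.

    A bond is rotatable iff both atoms are heavy and the bond is not part of
    the ring. The reference atoms are the lowest-index heavy neighbor on each
    side (falling back to the lowest-index hydrogen)."""
    ring = set(mol.ring_indices())
    adj = mol.adjacency()

    def pick_ref(center: int, exclude: int) -> int:
        cands = [k for k in adj[center] if k != exclude]
        heavy = [k for k in cands if mol.atoms[k].element != "H"]
        pool = heavy or cands
        if not pool:
            raise GeometryError("terminal atom cannot anchor a torsion")
        return min(pool)

    quads: dict[str, tuple[int, int, int, int]] = {}
    for i, j in sorted(mol.bonds):
        if mol.atoms[i].element == "H" or mol.atoms[j].element == "H":
            continue
        if i in ring and j in ring:
            continue
        b, c = (i, j) if (i in ring or i < j) else (j, i)
        if j in ring:
            b, c = j, i
        if len(adj[c]) < 2 or len(adj[b]) < 2:
            continue
        name = f"{mol.atoms[b].atom_name}-{mol.atoms[c].atom_name}"
        quads[name] = (pick_ref(b, c), b, c, pick_ref(c, b))
    return quads


def randomize_exocyclic(
    mol: MoleculeGraph, n: int, rng_seed: int | np.random.Generator
) -> list[dict[str, float]]:
    """Draw `n` exo-cyclic torsion maps, each torsion i.i.d. uniform on
    [0, 360) degrees; reproducible under the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    names = sorted(exocyclic_torsions(mol))
    if not names:
        raise ValidationError("molecule has no rotatable exo-cyclic bonds")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    draws = rng.uniform(0.0, 360.0, size=(n, len(names)))
    return [dict(zip(names, map(float, row))) for row in draws]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def _pucker_tolerances(tau_m: float) -> tuple[float, float]:
    # phase is ill-conditioned as the ring flattens
    return (10.0, 1.0) if tau_m < 9.0 else (2.0, 1.0)


def embed_conformer(
    mol: MoleculeGraph, spec: ConformerSpec, validate: bool = True
) -> np.ndarray:
    """Build Cartesian coordinates for `mol` at the requested ring pucker and
    exo-cyclic torsions.

    The ring is solved by least-squares closure against the cosine-law
    torsions; every other atom is rebuilt by Z-matrix extension reusing the
    molecule's own internal coordinates, then the exo-cyclic torsions are
    driven to their targets. Deterministic given the spec.
    """
    from .geometry import bond_angle, bond_length, place_nerf

    ring_idx = mol.ring_indices()
    old = mol.coords
    new = np.full_like(old, np.nan)
    ring_xyz = np.asarray(
        _ring.ring_coords_cached(spec.pucker.P, spec.pucker.tau_m), float
    )
    for k, idx in enumerate(ring_idx):
        new[idx] = ring_xyz[k]

    adj = mol.adjacency()
    ring_set = set(ring_idx)
    pos_in_ring = {idx: k for k, idx in enumerate(ring_idx)}

    # reference chain (parent, grandparent, great-grandparent) per atom
    placed = set(ring_idx)
    parent: dict[int, int] = {}
    order: list[int] = []
    frontier = list(ring_idx)
    while frontier:
        nxt = []
        for b in frontier:
            for c in adj[b]:
                if c not in placed:
                    placed.add(c)
                    parent[c] = b
                    order.append(c)
                    nxt.append(c)
        frontier = nxt

    def refs(atom: int) -> tuple[int, int]:
        """(grandparent, great-grandparent) completing atom's Z-matrix row."""
        p = parent[atom]
        if p in ring_set:
            k = pos_in_ring[p]
            return ring_idx[k - 1], ring_idx[k - 2]
        g = parent[p]
        if g in ring_set:
            k = pos_in_ring[g]
            return g, ring_idx[k - 1]
        return g, parent[g]

    for atom in order:
        p = parent[atom]
        g, gg = refs(atom)
        r = bond_length(old[p], old[atom])
        ang = bond_angle(old[g], old[p], old[atom])
        tor = dihedral(old[gg], old[g], old[p], old[atom])
        new[atom] = place_nerf(new[gg], new[g], new[p], r, ang, tor)

    # drive exo-cyclic torsions to their targets
    quads = exocyclic_torsions(mol)
    for name in sorted(spec.exo_torsions):
        if name not in quads:
            raise ValidationError(f"unknown exo-cyclic torsion '{name}'")
        new = set_torsion(new, adj, quads[name], spec.exo_torsions[name])

    if validate:
        achieved = pucker_from_torsions(ring_torsions_of(mol, new))
        p_tol, t_tol = _pucker_tolerances(spec.pucker.tau_m)
        dp = abs((achieved.P - spec.pucker.P + 180.0) % 360.0 - 180.0)
        dt = abs(achieved.tau_m - spec.pucker.tau_m)
        if dp > p_tol or dt > t_tol:
            raise EmbeddingError(
                f"embedding residual too large: target (P={spec.pucker.P:.2f}, "
                f"tau_m={spec.pucker.tau_m:.2f}), achieved (P={achieved.P:.2f}, "
                f"tau_m={achieved.tau_m:.2f})"
            )
        for name, tgt in spec.exo_torsions.items():
            cur = dihedral(*(new[i] for i in quads[name]))
            if abs((cur - tgt + 180.0) % 360.0 - 180.0) > 0.1:
                raise EmbeddingError(
                    f"exo-cyclic torsion {name} missed target: {cur:.3f} vs {tgt:.3f}"
                )
    return new


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_conformers(
    mol: MoleculeGraph,
    grid: list[PuckerState] | None = None,
    n_exo: int = 30,
    rng_seed: int | np.random.Generator = 0,
) -> ConformerDataset:
    """Embed `n_exo` random exo-cyclic variants of every ring conformation in
    `grid` (defaults to the full 900-point grid)."""
    grid = grid if grid is not None else ring_grid()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    specs: list[ConformerSpec] = []
    coords: list[np.ndarray] = []
    ring_ids: list[int] = []
    for ridx, state in enumerate(grid):
        for eidx, exo in enumerate(randomize_exocyclic(mol, n_exo, rng)):
            spec = ConformerSpec(
                pucker=state,
                exo_torsions=exo,
                conformer_id=f"{mol.label}:r{ridx:04d}:e{eidx:02d}",
            )
            specs.append(spec)
            coords.append(embed_conformer(mol, spec))
            ring_ids.append(ridx)
    return ConformerDataset(mol, specs, coords, ring_ids)


def split_dataset(
    ds: ConformerDataset,
    train_per_ring: int = 24,
    rng_seed: int | np.random.Generator = 0,
) -> ConformerDataset:
    """Label conformers train/test, selecting `train_per_ring` training
    members uniformly at random within every ring conformation."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    by_ring: dict[int, list[int]] = {}
    for i, r in enumerate(ds.ring_ids):
        by_ring.setdefault(r, []).append(i)
    split = [""] * len(ds)
    for r in sorted(by_ring):
        members = by_ring[r]
        if len(members) < train_per_ring:
            raise ValidationError(
                f"ring conformation {r} has {len(members)} members; "
                f"need at least {train_per_ring}"
            )
        chosen = rng.choice(len(members), size=train_per_ring, replace=False)
        chosen_set = {members[int(c)] for c in chosen}
        for i in members:
            split[i] = "train" if i in chosen_set else "test"
    ds.split = split
    return ds
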