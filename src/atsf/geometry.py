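"""Low-level internal-coordinate geometry: angles, dihedrals, Z-matrix placement.

All distances are in Angstrom, all angles in degrees. Dihedrals follow the
IUPAC sign convention: cis = 0 deg, positive clockwise when sighting from the
second to the third atom, range (-180, 180].
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import GeometryError

_COLLINEAR_TOL = 1e-10


def bond_length(p1: np.ndarray, p2: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p2, float) - np.asarray(p1, float)))


def bond_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in degrees."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise GeometryError("coincident points in angle computation")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, IUPAC convention, (-180, 180].

    Raises :class:`GeometryError` when three consecutive points are collinear
    (the dihedral is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError("undefined dihedral: three consecutive points are collinear")
    b2u = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2u)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    # atan2 returns [-180, 180]; fold -180 onto +180 for the half-open range
    if ang <= -180.0:
        ang = 180.0
    return float(ang)


def place_nerf(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C such that |C-D| = bond, angle(B,C,D) = angle
    and dihedral(A,B,C,D) = torsion (degrees). Natural-extension reference
    frame construction.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _COLLINEAR_TOL:
        raise GeometryError("coincident reference atoms in NERF placement")
    bc_u = bc / nbc
    ab = b - a
    n = np.cross(ab, bc_u)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise GeometryError("collinear reference atoms in NERF placement")
    n_u = n / nn
    m_u = np.cross(n_u, bc_u)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            -bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc_u + d_local[1] * m_u + d_local[2] * n_u


def rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate points about the line through `origin` along `axis` (right-hand rule)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return rot.apply(np.asarray(points, float) - origin) + origin


def downstream_atoms(adjacency: dict[int, list[int]], b: int, c: int) -> set[int]:
    """Atoms on the c-side of bond (b, c), excluding b's side, including c.

    Assumes bond (b, c) is not part of a cycle (removing it disconnects c from b).
    """
    seen = {b, c}
    stack = [c]
    out = {c}
    while stack:
        cur = stack.pop()
        for nxt in adjacency[cur]:
            if nxt not in seen:
                seen.add(nxt)
                out.add(nxt)
                stack.append(nxt)
    if b in out:
        raise GeometryError("bond (%d, %d) lies on a cycle; torsion drive undefined" % (b, c))
    return out


def set_torsion(
    coords: np.ndarray,
    adjacency: dict[int, list[int]],
    quad: tuple[int, int, int, int],
    target: float,
) -> np.ndarray:
    """Return coordinates with dihedral over `quad` driven to `target` degrees.

    The subtree on the far side of the central bond is rotated rigidly; the
    central bond must be acyclic.
    """
    ia, ib, ic, idx = quad
    coords = np.array(coords, float)
    current = dihedral(coords[ia], coords[ib], coords[ic], coords[idx])
    delta = target - current
    moving = sorted(downstream_atoms(adjacency, ib, ic) - {ic})
    if not moving:
        raise GeometryError("no atoms to move for torsion drive")
    axis = coords[ic] - coords[ib]
    # right-hand rotation of the far subtree about b->c by -delta raises the
    # IUPAC dihedral by +delta
    coords[moving] = rotate_about_axis(coords[moving], coords[ic], axis, -delta)
    return coords
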