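"""Five-membered-ring construction from pseudorotation targets.

Builds Cartesian coordinates for the furanose ring (atom order C1, C2, C3,
C4, O4) whose five endo-cyclic torsions follow the cosine law
theta_j = tau_m * cos(P + 144 deg * j). Bond lengths are held at their ideal
values; ring bond angles are left free for closure, with a weak restraint
toward a regular-pentagon-like value to select the chemically sensible
solution.

The construction starts from a regular pentagon with an out-of-plane
displacement wave and refines all fifteen coordinates by nonlinear least
squares. Multiple phase-offset starts are screened cheaply and the best one
is refined, which keeps the solver on the correct mirror branch.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .exceptions import EmbeddingError
from .geometry import bond_angle, dihedral

# ring bond lengths: C1-C2, C2-C3, C3-C4 (C-C); C4-O4, O4-C1 (C-O)
RING_BOND_LENGTHS = (1.526, 1.526, 1.526, 1.410, 1.410)
_ANGLE_REST = 104.5  # deg, soft target for ring bond angles
_W_BOND = 100.0
_W_ANGLE = 0.02


def cosine_law_torsions(p_deg: float, tau_m: float) -> np.ndarray:
    """Target ring torsions theta_j = tau_m * cos(P + 144 j), degrees."""
    j = np.arange(5)
    return tau_m * np.cos(np.radians(p_deg + 144.0 * j))


def _torsion_rad_noraise(p1, p2, p3, p4) -> float:
    # guard-free variant for use inside the optimizer (finite differencing may
    # probe degenerate configurations transiently)
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0:
        return 0.0
    m1 = np.cross(n1, b2 / nb2)
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def _ring_torsions(coords: np.ndarray) -> np.ndarray:
    th = np.empty(5)
    for j in range(5):
        th[j] = dihedral(
            coords[j % 5], coords[(j + 1) % 5], coords[(j + 2) % 5], coords[(j + 3) % 5]
        )
    return th


def _build_chain(x: np.ndarray) -> np.ndarray:
    """Build the five ring atoms from (alpha1, alpha2, alpha3, theta0', theta1').

    Angles in degrees. Atoms 0..2 fix the frame; atoms 3 and 4 follow by
    Z-matrix extension with the trial torsions.
    """
    a1, a2, a3, t0, t1 = x
    L = RING_BOND_LENGTHS
    c = np.zeros((5, 3))
    c[1] = (L[0], 0.0, 0.0)
    ang = np.radians(a1)
    c[2] = c[1] + L[1] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    from .geometry import place_nerf  # local import avoids cycle at module load

    c[3] = place_nerf(c[0], c[1], c[2], L[2], a2, t0)
    c[4] = place_nerf(c[1], c[2], c[3], L[3], a3, t1)
    return c


def _residuals(x: np.ndarray, targets: np.ndarray) -> np.ndarray:
    c = _build_chain(x)
    L = RING_BOND_LENGTHS
    res = []
    # closure bond
    res.append(_W_BOND * (np.linalg.norm(c[0] - c[4]) - L[4]))
    # five torsion targets: theta0/theta1 are the trial values themselves,
    # theta2..theta4 are measured on the closed chain
    for j, trial in ((0, x[3]), (1, x[4])):
        res.append(np.radians((trial - targets[j] + 180.0) % 360.0 - 180.0))
    for j in (2, 3, 4):
        th = np.degrees(
            _torsion_rad_noraise(c[j % 5], c[(j + 1) % 5], c[(j + 2) % 5], c[(j + 3) % 5])
        )
        res.append(np.radians((th - targets[j] + 180.0) % 360.0 - 180.0))
    # soft restraint keeping ring bond angles near a sensible value
    for j in range(5):
        ang = bond_angle(c[(j - 1) % 5], c[j], c[(j + 1) % 5])
        res.append(_W_ANGLE * np.radians(ang - _ANGLE_REST))
    return np.asarray(res)


def ring_coords(p_deg: float, tau_m: float) -> np.ndarray:
    """Ring coordinates (5 x 3, Angstrom) realizing the cosine-law torsions.

    Raises :class:`EmbeddingError` if the closure refinement does not reach
    the targets (torsion residual reported in the message).
    """
    targets = cosine_law_torsions(p_deg, tau_m)

    # ring bond angles contract as the pucker amplitude grows
    a0 = _ANGLE_REST - 0.004 * tau_m**2 / 5.0
    x0 = np.array([a0, a0, a0, targets[0], targets[1]])
    sol = least_squares(
        _residuals,
        x0,
        args=(targets,),
        method="lm",
        xtol=1e-13,
        ftol=1e-13,
        max_nfev=2000,
    )
    coords = _build_chain(sol.x)
    th = _ring_torsions(coords)
    diff = (th - targets + 180.0) % 360.0 - 180.0
    bonds = np.array([np.linalg.norm(coords[(j + 1) % 5] - coords[j]) for j in range(5)])
    bond_err = np.abs(bonds - np.asarray(RING_BOND_LENGTHS))
    if np.max(np.abs(diff)) > 3.0 or np.max(bond_err) > 0.01:
        raise EmbeddingError(
            "ring closure did not converge for P=%.1f tau_m=%.1f: "
            "max torsion residual %.3f deg, max bond residual %.4f A"
            % (p_deg, tau_m, float(np.max(np.abs(diff))), float(np.max(bond_err)))
        )
    return coords


@lru_cache(maxsize=4096)
def ring_coords_cached(p_deg: float, tau_m: float) -> tuple[tuple[float, ...], ...]:
    c = ring_coords(p_deg, tau_m)
    return tuple(tuple(row) for row in c)
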