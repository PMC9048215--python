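"""Reference per-atom partial charges: a synthetic conformation-dependent
oracle, and a reader for user-supplied charge tables.

The oracle stands in for quantum-chemistry-derived electrostatic-potential
(RESP) charges: it is deterministic, smooth, depends on conformation only
through interatomic distances (hence is rotation/translation invariant), and
obeys the same charge conventions as the force-field philosophy the package
targets — aliphatic hydrogens carry exactly zero charge and the molecule is
exactly neutral. Its numeric constants are packaged artifact constants, not
values from any quantum calculation.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .molecule import MoleculeGraph

__all__ = ["ChargeSet", "OracleParams", "load_oracle_params", "synthetic_resp", "read_charges"]

PROVENANCES = ("reference", "predicted_raw", "predicted_corrected", "ensemble_averaged")


@dataclass
class ChargeSet:
    """Per-atom charges (elementary charge units) with provenance."""

    values: np.ndarray
    provenance: str
    molecule_label: str = ""
    conformer_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown charge provenance '{self.provenance}'")

    def total(self) -> float:
        return float(np.sum(self.values))


@dataclass(frozen=True)
class OracleParams:
    """Constants of the synthetic charge oracle.

    base: per-atom-type baseline charge (e). sensitivity: per-type coupling
    factor s; the pair weight is w(J, K) = s_J * s_K. rho: distance decay
    length (A). alpha: overall coupling scale. clamped_types: hydrogen types
    fixed at exactly zero.
    """

    base: dict[str, float]
    sensitivity: dict[str, float]
    rho: float = 2.5
    alpha: float = 0.35
    clamped_types: tuple[str, ...] = ("H1", "H2")
    version: int = 1

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive")


def load_oracle_params() -> OracleParams:
    """The packaged, versioned oracle constant table."""
    text = resources.files("atsf.data").joinpath("oracle_params.json").read_text()
    raw = json.loads(text)
    return OracleParams(
        base=raw["base"],
        sensitivity=raw["sensitivity"],
        rho=raw["rho"],
        alpha=raw["alpha"],
        clamped_types=tuple(raw["clamped_types"]),
        version=raw["version"],
    )


def clamped_mask(mol: MoleculeGraph, clamped_types: tuple[str, ...] = ("H1", "H2")) -> np.ndarray:
    """Boolean mask of atoms whose charge is fixed at zero (aliphatic H)."""
    return np.array([t in clamped_types for t in mol.atom_types()])


def synthetic_resp(
    coords: np.ndarray,
    mol: MoleculeGraph,
    params: OracleParams | None = None,
) -> ChargeSet:
    """Deterministic conformation-dependent reference charges.

    q_i = base(t_i) + alpha * sum_{j != i} s(t_i) s(t_j) exp(-R_ij / rho),
    then aliphatic hydrogens are clamped to exactly 0 and the net-charge
    residual is removed by a uniform shift over the non-clamped atoms.
    """
    params = params or load_oracle_params()
    types = mol.atom_types()
    missing = sorted({t for t in types if t not in params.base or t not in params.sensitivity})
    if missing:
        raise ValidationError(f"oracle table lacks atom types: {missing}")
    coords = np.asarray(coords, float)
    n = mol.n_atoms
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    s = np.array([params.sensitivity[t] for t in types])
    base = np.array([params.base[t] for t in types])
    decay = np.exp(-D / params.rho)
    np.fill_diagonal(decay, 0.0)
    q = base + params.alpha * s * (decay @ s)
    clamp = clamped_mask(mol, params.clamped_types)
    q[clamp] = 0.0
    free = ~clamp
    q[free] -= (q.sum() - mol.net_charge) / free.sum()
    return ChargeSet(q, "reference", mol.label)


def read_charges(path, mol: MoleculeGraph) -> ChargeSet:
    """Read a two-column delimited charge table (atom name or 0-based index,
    charge in e) as reference charges.

    Convention violations (nonzero aliphatic hydrogen, nonzero net charge)
    warn but do not fail: genuine externally fitted tables may break them
    slightly.
    """
    path = Path(path)
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) < 2:
            raise ValidationError(f"{path}, line {ln}: expected 'atom charge'")
        try:
            rows.append((parts[0], float(parts[1])))
        except ValueError:
            raise ValidationError(f"{path}, line {ln}: non-numeric charge '{parts[1]}'") from None
    if len(rows) != mol.n_atoms:
        raise ValidationError(
            f"{path}: {len(rows)} charge rows for a {mol.n_atoms}-atom molecule"
        )
    values = np.full(mol.n_atoms, np.nan)
    names = {a.atom_name: a.index for a in mol.atoms}
    for ident, q in rows:
        if ident in names:
            idx = names[ident]
        else:
            try:
                idx = int(ident)
            except ValueError:
                raise ValidationError(f"{path}: unresolvable atom identifier '{ident}'") from None
            if not 0 <= idx < mol.n_atoms:
                raise ValidationError(f"{path}: atom index {idx} out of range")
        if not np.isnan(values[idx]):
            raise ValidationError(f"{path}: duplicate entry for atom '{ident}'")
        values[idx] = q
    cs = ChargeSet(values, "reference", mol.label)
    try:
        clamp = clamped_mask(mol)
    except Exception:
        clamp = None
    if clamp is not None and np.any(np.abs(values[clamp]) > 1e-9):
        warnings.warn(
            "reference charges carry nonzero values on aliphatic hydrogens",
            stacklevel=2,
        )
    if abs(cs.total() - mol.net_charge) > 1e-6:
        warnings.warn(
            f"reference charges sum to {cs.total():.6f}, expected {mol.net_charge}",
            stacklevel=2,
        )
    return cs
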