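"""Evaluation metrics: per-atom-name Pearson correlation and linear fits of
predicted vs reference charges, and point-charge molecular dipole moments.

The dipole of a point-charge set is mu = k * sum_i q_i r_i with
k = 4.80320 D/(e*A); it is origin-independent exactly when the charges sum
to zero. Dipole agreement between two charge sets is summarized as the mean
and standard deviation over conformers of | |mu_A| - |mu_B| | (magnitude
difference; a vector-difference-norm mode is available since the scalar
convention is a reporting choice).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedCorrelationError, ValidationError
from .reference_charges import ChargeSet

__all__ = [
    "DEBYE_PER_E_ANGSTROM",
    "PearsonReport",
    "LinearFitResult",
    "DipoleReport",
    "pearson",
    "pearson_by_atom_name",
    "linear_fit_by_atom_name",
    "dipole",
    "mean_abs_dipole_diff",
]

DEBYE_PER_E_ANGSTROM = 4.80320


@dataclass
class PearsonReport:
    """Per-atom-name correlation; zero-variance names are flagged in
    `undefined` (value None) rather than silently NaN."""

    values: dict[str, float | None]
    undefined: set[str]


@dataclass(frozen=True)
class LinearFitResult:
    """Ordinary least squares y = a*x + b with x = reference, y = predicted."""

    a: float
    b: float


@dataclass(frozen=True)
class DipoleReport:
    mean: float
    sd: float
    convention: str  # "magnitude" or "vector"
    provenance: tuple[str, str]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("zero-variance series")
    return float(stats.pearsonr(x, y).statistic)


def _paired_series(
    predicted: list[ChargeSet], reference: list[ChargeSet], atom_names: list[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    if len(predicted) != len(reference):
        raise ValidationError("unpaired charge sets")
    n = len(atom_names)
    pred = np.stack([cs.values for cs in predicted])
    ref = np.stack([cs.values for cs in reference])
    if pred.shape[1] != n or ref.shape[1] != n:
        raise ValidationError("charge-set length does not match atom names")
    return {name: (ref[:, i], pred[:, i]) for i, name in enumerate(atom_names)}


def pearson_by_atom_name(
    predicted: list[ChargeSet], reference: list[ChargeSet], atom_names: list[str]
) -> PearsonReport:
    """Pearson r of predicted vs reference charge, per atom name, over all
    paired conformers."""
    series = _paired_series(predicted, reference, atom_names)
    values: dict[str, float | None] = {}
    undefined: set[str] = set()
    for name, (x, y) in series.items():
        try:
            values[name] = pearson(x, y)
        except UndefinedCorrelationError:
            values[name] = None
            undefined.add(name)
    return PearsonReport(values, undefined)


def linear_fit_by_atom_name(
    predicted: list[ChargeSet], reference: list[ChargeSet], atom_names: list[str]
) -> dict[str, LinearFitResult]:
    """OLS slope/intercept per atom name (x = reference, y = predicted).
    Zero-variance reference series are skipped (degenerate design)."""
    series = _paired_series(predicted, reference, atom_names)
    out = {}
    for name, (x, y) in series.items():
        if np.std(x) == 0.0:
            continue
        a, b = np.polyfit(x, y, 1)
        out[name] = LinearFitResult(float(a), float(b))
    return out


def dipole(coords: np.ndarray, charges: np.ndarray) -> np.ndarray:
    """Point-charge dipole vector in Debye; origin-independent for neutral
    charge sets."""
    coords = np.asarray(coords, float)
    charges = np.asarray(charges, float)
    if coords.shape[0] != charges.shape[0]:
        raise ValidationError("coords/charges length mismatch")
    return DEBYE_PER_E_ANGSTROM * charges @ coords


def mean_abs_dipole_diff(
    set_a: list[ChargeSet],
    set_b: list[ChargeSet],
    conformers: list[np.ndarray],
    convention: str = "magnitude",
) -> DipoleReport:
    """Mean +- sd over conformers of the dipole disagreement between two
    charge sets: | |mu_A| - |mu_B| | ("magnitude", default) or |mu_A - mu_B|
    ("vector")."""
    if not (len(set_a) == len(set_b) == len(conformers)):
        raise ValidationError("unpaired inputs")
    if convention not in ("magnitude", "vector"):
        raise ValueError("convention must be 'magnitude' or 'vector'")
    diffs = []
    for ca, cb, xyz in zip(set_a, set_b, conformers):
        mu_a = dipole(xyz, ca.values)
        mu_b = dipole(xyz, cb.values)
        if convention == "magnitude":
            diffs.append(abs(np.linalg.norm(mu_a) - np.linalg.norm(mu_b)))
        else:
            diffs.append(np.linalg.norm(mu_a - mu_b))
    diffs = np.asarray(diffs)
    prov = (set_a[0].provenance if set_a else "", set_b[0].provenance if set_b else "")
    return DipoleReport(float(diffs.mean()), float(diffs.std()), convention, prov)
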