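"""Per-element random-forest charge regression with a neutrality-spreading
correction, and the end-to-end conformational-adaptive charge pipeline.

One forest is trained per chemical element (C, O, H). The hydrogen model by
default sees only hydroxyl hydrogens: aliphatic hydrogens are clamped to
exactly zero by convention, so their rows are degenerate targets. Prediction
returns, per atom, the across-tree mean (raw charge) and across-tree standard
deviation sigma; the raw charges generally do not sum to the molecular net
charge, and the discrepancy is spread over the atoms proportionally to sigma
(atoms the forest is unsure about absorb more of the correction).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .exceptions import LayoutMismatchError, ValidationError
from .molecule import MoleculeGraph
from .pucker import ConformerDataset, PuckerState, generate_conformers, split_dataset
from .reference_charges import ChargeSet, OracleParams, clamped_mask, synthetic_resp
from .symfun import DescriptorLayout, DescriptorMatrix, SymFunParams, build_layout, featurize
from . import metrics as _metrics

__all__ = [
    "ForestHyperparams",
    "ModelBundle",
    "PredictionResult",
    "train",
    "predict",
    "neutralize",
    "run_pipeline",
]

ELEMENTS = ("C", "O", "H")


@dataclass(frozen=True)
class ForestHyperparams:
    """Random-forest settings: 200 trees, depth 6, and a minimum of 6 samples
    both to split a node and in every leaf."""

    n_trees: int = 200
    max_depth: int = 6
    min_samples_split: int = 6
    min_samples_leaf: int = 6
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_trees", "max_depth", "min_samples_split", "min_samples_leaf"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class ModelBundle:
    """Fitted per-element forests plus the layout/parameters they were
    trained with and a training manifest."""

    forests: dict[str, RandomForestRegressor]
    layout: DescriptorLayout
    params: SymFunParams
    hyperparams: ForestHyperparams
    manifest: dict = field(default_factory=dict)

    def check_layout(self, layout: DescriptorLayout) -> None:
        if layout != self.layout:
            raise LayoutMismatchError(
                "descriptor layout does not match the layout this model was trained with"
            )


@dataclass
class PredictionResult:
    """Raw forest charges, per-atom across-tree spread, and corrected charges."""

    raw: np.ndarray
    sigma: np.ndarray
    corrected: np.ndarray
    molecule_label: str = ""
    conformer_id: str = ""


def _element_rows(
    mols_rows: list[tuple[MoleculeGraph, DescriptorMatrix, ChargeSet]],
    include_clamped_hydrogens: bool,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Stack per-element training matrices across conformers."""
    by_el: dict[str, list] = {el: [] for el in ELEMENTS}
    for mol, dm, cs in mols_rows:
        clamp = clamped_mask(mol)
        for el in ELEMENTS:
            sel = np.array([a.element == el for a in mol.atoms])
            if el == "H" and not include_clamped_hydrogens:
                sel &= ~clamp
            if sel.any():
                by_el[el].append((dm.values[sel], cs.values[sel]))
    out = {}
    for el, chunks in by_el.items():
        if chunks:
            out[el] = (
                np.vstack([c[0] for c in chunks]),
                np.concatenate([c[1] for c in chunks]),
            )
    return out


def train(
    rows: list[tuple[MoleculeGraph, DescriptorMatrix, ChargeSet]],
    hp: ForestHyperparams = ForestHyperparams(),
    include_clamped_hydrogens: bool = False,
    manifest: dict | None = None,
) -> ModelBundle:
    """Fit one forest per element from (molecule, descriptors, charges)
    triples. All descriptor matrices must share one layout."""
    if not rows:
        raise ValidationError("no training rows")
    layout = rows[0][1].layout
    params = rows[0][1].params
    for _, dm, cs in rows:
        if dm.layout != layout:
            raise LayoutMismatchError("training descriptor matrices mix layouts")
        if len(cs.values) != dm.values.shape[0]:
            raise ValidationError("charge/descriptor row mismatch")
    data = _element_rows(rows, include_clamped_hydrogens)
    missing = [el for el in ELEMENTS if el not in data]
    if missing:
        raise ValidationError(f"no training rows for element(s): {missing}")
    forests = {}
    for el in ELEMENTS:
        X, y = data[el]
        forest = RandomForestRegressor(
            n_estimators=hp.n_trees,
            max_depth=hp.max_depth,
            min_samples_split=hp.min_samples_split,
            min_samples_leaf=hp.min_samples_leaf,
            random_state=hp.rng_seed,
            n_jobs=1,
        )
        forest.fit(X, y)
        forests[el] = forest
    return ModelBundle(forests, layout, params, hp, manifest or {})


def _forest_mean_sigma(forest: RandomForestRegressor, X: np.ndarray):
    per_tree = np.stack([t.predict(X) for t in forest.estimators_])
    return per_tree.mean(axis=0), per_tree.std(axis=0)


def predict(bundle: ModelBundle, features: DescriptorMatrix, mol: MoleculeGraph) -> PredictionResult:
    """Raw per-atom charges (across-tree mean) and spread sigma for one
    conformer. Clamped hydrogens get raw 0, sigma 0. The corrected field is
    filled by :func:`neutralize`."""
    bundle.check_layout(features.layout)
    clamp = clamped_mask(mol)
    raw = np.zeros(mol.n_atoms)
    sigma = np.zeros(mol.n_atoms)
    for el in ELEMENTS:
        sel = np.array([a.element == el for a in mol.atoms])
        if el == "H":
            sel &= ~clamp
        if sel.any():
            raw[sel], sigma[sel] = _forest_mean_sigma(bundle.forests[el], features.values[sel])
    corrected = neutralize(raw, sigma, mol.net_charge, clamp)
    return PredictionResult(raw, sigma, corrected, mol.label)


def neutralize(
    raw: np.ndarray,
    sigmas: np.ndarray,
    net_charge: float,
    clamped: np.ndarray | None = None,
    weight: str = "sigma",
) -> np.ndarray:
    """Spread the net-charge discrepancy over atoms by their prediction
    spread: corrected_i = raw_i - Delta * w_i / sum(w), with w = sigma
    (default) or sigma^2. Clamped atoms never move; if every weight is zero
    the discrepancy is spread uniformly over the non-clamped atoms.
    """
    raw = np.asarray(raw, float)
    sigmas = np.asarray(sigmas, float)
    if raw.shape != sigmas.shape:
        raise ValidationError("raw/sigma length mismatch")
    if clamped is None:
        clamped = np.zeros(raw.shape, bool)
    clamped = np.asarray(clamped, bool)
    delta = float(raw.sum() - net_charge)
    corrected = raw.copy()
    free = ~clamped
    if not free.any():
        if abs(delta) > 1e-12:
            raise ValidationError("all atoms clamped but net charge is off")
        return corrected
    w = sigmas**2 if weight == "sigma2" else sigmas
    w = np.where(free, w, 0.0)
    wsum = float(w.sum())
    if wsum > 0.0:
        corrected -= delta * w / wsum
    else:
        corrected[free] -= delta / free.sum()
    return corrected


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _predict_batch(
    bundle: ModelBundle,
    mols: list[MoleculeGraph],
    feats: list[DescriptorMatrix],
) -> list[PredictionResult]:
    """Batched prediction over many conformers (one estimator pass per
    element instead of one per conformer)."""
    for dm in feats:
        bundle.check_layout(dm.layout)
    results = [
        PredictionResult(
            np.zeros(m.n_atoms), np.zeros(m.n_atoms), np.zeros(m.n_atoms), m.label
        )
        for m in mols
    ]
    sel_cache: dict[int, dict[str, np.ndarray]] = {}
    for el in ELEMENTS:
        chunks, owners = [], []
        for ci, (m, dm) in enumerate(zip(mols, feats)):
            sels = sel_cache.setdefault(ci, {})
            sel = np.array([a.element == el for a in m.atoms])
            if el == "H":
                sel &= ~clamped_mask(m)
            sels[el] = sel
            if sel.any():
                chunks.append(dm.values[sel])
                owners.append(ci)
        if not chunks:
            continue
        X = np.vstack(chunks)
        mean, sigma = _forest_mean_sigma(bundle.forests[el], X)
        pos = 0
        for ci, chunk in zip(owners, chunks):
            k = chunk.shape[0]
            sel = sel_cache[ci][el]
            results[ci].raw[sel] = mean[pos : pos + k]
            results[ci].sigma[sel] = sigma[pos : pos + k]
            pos += k
    for ci, m in enumerate(mols):
        results[ci].corrected = neutralize(
            results[ci].raw, results[ci].sigma, m.net_charge, clamped_mask(m)
        )
    return results


def run_pipeline(
    mols: list[MoleculeGraph],
    grid: list[PuckerState],
    scheme: str = "atom_type",
    params: SymFunParams = SymFunParams(),
    hp: ForestHyperparams = ForestHyperparams(),
    oracle: OracleParams | None = None,
    n_exo: int = 30,
    train_per_ring: int = 24,
    seed: int = 0,
) -> dict:
    """Generate conformers, featurize, train on the per-ring training split,
    predict + neutralize on the test split, and evaluate.

    Returns a report dict with per-atom-name Pearson r and linear fits,
    per-element pooled Pearson r, dipole-difference statistics, a neutrality
    check, and the dataset/layout bookkeeping.
    """
    ss = np.random.SeedSequence(seed)
    mol_seeds = ss.spawn(len(mols))
    layout = build_layout(mols[0], scheme)

    train_rows = []
    test_entries = []  # (mol, features, reference ChargeSet, coords, conformer_id)
    n_train = n_test = 0
    for mol, mseed in zip(mols, mol_seeds):
        gen_rng, split_rng = (np.random.default_rng(s) for s in mseed.spawn(2))
        ds = generate_conformers(mol, grid, n_exo=n_exo, rng_seed=gen_rng)
        ds = split_dataset(ds, train_per_ring=train_per_ring, rng_seed=split_rng)
        mol_layout = build_layout(mol, scheme)
        if mol_layout != layout:
            raise LayoutMismatchError("molecules do not share a descriptor layout")
        for spec, coords, lab in zip(ds.specs, ds.coords, ds.split):
            dm = featurize(coords, mol, scheme, params, layout)
            ref = synthetic_resp(coords, mol, oracle)
            ref.conformer_id = spec.conformer_id
            if lab == "train":
                train_rows.append((mol, dm, ref))
                n_train += 1
            else:
                test_entries.append((mol, dm, ref, coords, spec.conformer_id))
                n_test += 1

    bundle = train(
        train_rows,
        hp,
        manifest={"seed": seed, "scheme": scheme, "n_molecules": len(mols)},
    )

    t_mols = [e[0] for e in test_entries]
    t_feats = [e[1] for e in test_entries]
    preds = _predict_batch(bundle, t_mols, t_feats)

    pred_sets = []
    ref_sets = []
    for (mol, _, ref, coords, cid), pr in zip(test_entries, preds):
        pr.conformer_id = cid
        pred_sets.append(ChargeSet(pr.corrected, "predicted_corrected", mol.label, cid))
        ref_sets.append(ref)

    names = t_mols[0].atom_names()
    pearson = _metrics.pearson_by_atom_name(pred_sets, ref_sets, names)
    fits = _metrics.linear_fit_by_atom_name(pred_sets, ref_sets, names)
    coords_list = [e[3] for e in test_entries]
    dip = _metrics.mean_abs_dipole_diff(pred_sets, ref_sets, coords_list)

    # pooled per-element correlation over non-clamped test atoms
    per_element = {}
    for el in ELEMENTS:
        xs, ys = [], []
        for (mol, _, ref, _, _), ps in zip(test_entries, pred_sets):
            sel = np.array([a.element == el for a in mol.atoms]) & ~clamped_mask(mol)
            xs.append(ref.values[sel])
            ys.append(ps.values[sel])
        per_element[el] = _metrics.pearson(np.concatenate(xs), np.concatenate(ys))

    neutrality = max(
        abs(float(ps.values.sum()) - m.net_charge) for ps, m in zip(pred_sets, t_mols)
    )
    defined = {k: v for k, v in pearson.values.items() if v is not None}
    return {
        "scheme": scheme,
        "layout_total": layout.total,
        "n_ring_conformations": len(grid),
        "n_train": n_train,
        "n_test": n_test,
        "train_per_ring": train_per_ring,
        "pearson_by_atom_name": pearson.values,
        "pearson_undefined": sorted(pearson.undefined),
        "mean_pearson": float(np.mean(list(defined.values()))),
        "pearson_by_element": per_element,
        "linear_fits": {k: {"a": v.a, "b": v.b} for k, v in fits.items()},
        "dipole_diff_mean": dip.mean,
        "dipole_diff_sd": dip.sd,
        "max_abs_net_charge_error": neutrality,
        "seed": seed,
    }
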