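"""Per-element forest regression, neutrality spreading, and the pipeline."""
import numpy as np
import pytest

from atsf.charge_model import (
    ForestHyperparams,
    _predict_batch,
    neutralize,
    predict,
    run_pipeline,
    train,
)
from atsf.exceptions import LayoutMismatchError, ValidationError
from atsf.pucker import generate_conformers, ring_grid, split_dataset
from atsf.reference_charges import clamped_mask, synthetic_resp
from atsf.symfun import build_layout, featurize
from scipy.stats import pearsonr


@pytest.fixture(scope="module")
def small_training_set(rib_beta):
    """A small embedded dataset with descriptors and oracle charges."""
    grid = ring_grid(21.0, 45.0, 12.0, 60.0)  # 3 tau x 6 P = 18 ring states
    ds = generate_conformers(rib_beta, grid, n_exo=4, rng_seed=21)
    layout = build_layout(rib_beta, "atom_type")
    rows = []
    for coords in ds.coords:
        dm = featurize(coords, rib_beta, "atom_type", layout=layout)
        rows.append((rib_beta, dm, synthetic_resp(coords, rib_beta)))
    return rows


class TestNeutralize:
    def test_sigma_weighted_hand_example(self):
        out = neutralize(np.array([0.3, -0.2]), np.array([0.1, 0.1]), 0.0)
        assert np.allclose(out, [0.25, -0.25], atol=1e-12)

    def test_all_discrepancy_on_uncertain_atom(self):
        out = neutralize(np.array([0.3, -0.2]), np.array([0.2, 0.0]), 0.0)
        assert np.allclose(out, [0.2, -0.2], atol=1e-12)

    def test_already_neutral_unchanged(self):
        raw = np.array([0.4, -0.1, -0.3])
        out = neutralize(raw, np.array([0.1, 0.2, 0.3]), 0.0)
        assert np.allclose(out, raw, atol=1e-15)

    def test_zero_sigma_spreads_uniformly_over_free_atoms(self):
        raw = np.array([0.2, 0.2, 0.1])
        clamp = np.array([False, False, True])
        out = neutralize(raw, np.zeros(3), 0.0, clamp)
        assert np.allclose(out, [-0.05, -0.05, 0.1], atol=1e-12)
        assert out.sum() == pytest.approx(0.0, abs=1e-12)

    def test_exactness_and_permutation_invariance(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 30))
            raw = rng.normal(size=n)
            sig = np.abs(rng.normal(size=n))
            net = float(rng.integers(-2, 3))
            out = neutralize(raw, sig, net)
            assert out.sum() == pytest.approx(net, abs=1e-12)
            perm = rng.permutation(n)
            out_p = neutralize(raw[perm], sig[perm], net)
            assert np.allclose(out_p, out[perm], atol=1e-12)

    def test_clamped_atoms_never_move(self):
        raw = np.array([0.5, 0.0, -0.2])
        clamp = np.array([False, True, False])
        out = neutralize(raw, np.array([0.1, 0.0, 0.3]), 0.0, clamp)
        assert out[1] == 0.0
        assert out.sum() == pytest.approx(0.0, abs=1e-12)

    def test_all_clamped_with_discrepancy_rejected(self):
        with pytest.raises(ValidationError):
            neutralize(np.array([0.1]), np.array([0.0]), 0.0, np.array([True]))

    def test_sigma2_weighting_mode(self):
        out = neutralize(np.array([0.3, -0.2]), np.array([0.2, 0.1]), 0.0, weight="sigma2")
        assert np.allclose(out, [0.3 - 0.1 * 0.8, -0.2 - 0.1 * 0.2], atol=1e-12)


class TestNeutralizeProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @given(
        raw=hnp.arrays(float, 8, elements=st.floats(-1, 1)),
        sig=hnp.arrays(float, 8, elements=st.floats(0, 0.5)),
        net=st.integers(-2, 2),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_corrected_sum_is_exact(self, raw, sig, net):
        out = neutralize(raw, sig, float(net))
        assert abs(out.sum() - net) < 1e-12


class TestTrainPredict:
    def test_in_sample_recovery(self, rib_beta, small_training_set):
        bundle = train(small_training_set, ForestHyperparams(rng_seed=0))
        preds = _predict_batch(
            bundle,
            [rib_beta] * len(small_training_set),
            [dm for _, dm, _ in small_training_set],
        )
        # depth-6 forests cannot interpolate arbitrarily well in-sample; the
        # hydroxyl-hydrogen channel has the least between-site variance and
        # sits lower than C/O
        floors = {"C": 0.99, "O": 0.99, "H": 0.95}
        for el in ("C", "O", "H"):
            sel = np.array([a.element == el for a in rib_beta.atoms]) & ~clamped_mask(rib_beta)
            x = np.concatenate([cs.values[sel] for _, _, cs in small_training_set])
            y = np.concatenate([p.raw[sel] for p in preds])
            assert pearsonr(x, y).statistic > floors[el]

    def test_deterministic_under_seed(self, rib_beta, small_training_set):
        b1 = train(small_training_set, ForestHyperparams(rng_seed=4))
        b2 = train(small_training_set, ForestHyperparams(rng_seed=4))
        dm = small_training_set[0][1]
        p1 = predict(b1, dm, rib_beta)
        p2 = predict(b2, dm, rib_beta)
        assert np.array_equal(p1.raw, p2.raw)
        assert np.array_equal(p1.corrected, p2.corrected)

    def test_prediction_contract(self, rib_beta, small_training_set):
        bundle = train(small_training_set, ForestHyperparams(rng_seed=0))
        res = predict(bundle, small_training_set[0][1], rib_beta)
        clamp = clamped_mask(rib_beta)
        assert np.all(res.sigma >= 0)
        assert np.all(res.raw[clamp] == 0.0)
        assert np.all(res.sigma[clamp] == 0.0)
        assert res.corrected.sum() == pytest.approx(0.0, abs=1e-12)

    def test_single_tree_has_zero_spread(self, rib_beta, small_training_set):
        bundle = train(small_training_set[:20], ForestHyperparams(n_trees=1, rng_seed=0))
        res = predict(bundle, small_training_set[0][1], rib_beta)
        assert np.all(res.sigma == 0.0)

    def test_layout_mismatch_rejected(self, rib_beta, small_training_set):
        bundle = train(small_training_set, ForestHyperparams(rng_seed=0))
        wrong = featurize(rib_beta.coords, rib_beta, "element")
        with pytest.raises(LayoutMismatchError):
            predict(bundle, wrong, rib_beta)

    def test_empty_training_rejected(self):
        with pytest.raises(ValidationError):
            train([], ForestHyperparams())

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            ForestHyperparams(n_trees=0)


class TestPipeline:
    def test_smoke_reduced_run_reports_all_metrics(self, all_fixtures):
        grid = ring_grid(30.0, 45.0, 15.0, 90.0)  # 2 x 4 = 8 ring states
        rep = run_pipeline(
            all_fixtures[:2], grid, scheme="atom_type", n_exo=4,
            train_per_ring=3, seed=11,
        )
        assert rep["layout_total"] == 41
        assert rep["n_train"] == 2 * 8 * 3
        assert rep["n_test"] == 2 * 8 * 1
        assert set(rep["pearson_by_element"]) == {"C", "O", "H"}
        assert rep["max_abs_net_charge_error"] < 1e-12
        assert rep["dipole_diff_mean"] >= 0.0
        assert set(rep["linear_fits"]) <= set(all_fixtures[0].atom_names())

    def test_pipeline_deterministic(self, all_fixtures):
        grid = ring_grid(30.0, 45.0, 15.0, 120.0)  # 2 x 3
        kw = dict(scheme="atom_type", n_exo=4, train_per_ring=3, seed=5)
        r1 = run_pipeline(all_fixtures[:1], grid, **kw)
        r2 = run_pipeline(all_fixtures[:1], grid, **kw)
        assert r1["pearson_by_element"] == r2["pearson_by_element"]
        assert r1["dipole_diff_mean"] == r2["dipole_diff_mean"]
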