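"""Pseudorotation math, the ring grid, embedding, and dataset assembly."""
import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from atsf.exceptions import GeometryError, ValidationError
from atsf.geometry import dihedral
from atsf.pucker import (
    ConformerDataset,
    ConformerSpec,
    PuckerState,
    RingTorsions,
    embed_conformer,
    exocyclic_torsions,
    generate_conformers,
    pucker_from_torsions,
    randomize_exocyclic,
    ring_grid,
    ring_torsions_of,
    split_dataset,
    torsions_from_pucker,
)


def angdiff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestPuckerMath:
    def test_cosine_law_at_phase_zero(self):
        th = torsions_from_pucker(PuckerState(0, 30)).as_array()
        expected = 30 * np.cos(np.radians(144.0 * np.arange(5)))
        assert np.allclose(th, expected, atol=1e-12)

    def test_theta0_vanishes_at_phase_90(self):
        th = torsions_from_pucker(PuckerState(90, 30)).as_array()
        assert th[0] == pytest.approx(0.0, abs=1e-12)
        # frozen from high-precision evaluation of 30*cos(90 + 144 j)
        assert th[1] == pytest.approx(-17.633557568774194, abs=1e-9)
        assert th[2] == pytest.approx(28.531695488854606, abs=1e-9)

    def test_round_trip_identity_on_grid(self):
        for state in ring_grid():
            back = pucker_from_torsions(torsions_from_pucker(state))
            assert angdiff(back.P, state.P) < 1e-9
            assert back.tau_m == pytest.approx(state.tau_m, abs=1e-9)

    def test_explicit_phase_zero_torsion_set(self):
        tau = 39.0
        th = RingTorsions(tuple(tau * np.cos(np.radians(144.0 * np.arange(5)))))
        st = pucker_from_torsions(th)
        assert st.P == pytest.approx(0.0, abs=1e-9)
        assert st.tau_m == pytest.approx(39.0, abs=1e-9)

    def test_planar_ring_phase_undefined(self):
        with pytest.raises(GeometryError):
            pucker_from_torsions(RingTorsions((0.0,) * 5))

    def test_noise_robust_recovery(self, rng):
        # +-0.5 deg torsion noise: the Fourier projection bounds the phase
        # error by ~(0.2 * sum|sin(144 j)|)/tau_m radians (about 3.9 deg at
        # tau_m = 9, under 2 deg from tau_m = 21) and the amplitude error by
        # ~0.65 deg
        p_bound = 0.2 * 0.5 * np.sum(np.abs(np.sin(np.radians(144.0 * np.arange(5)))))
        for tau in (9.0, 21.0, 33.0, 45.0):
            tol = np.degrees(2 * p_bound / tau) * 1.05
            for P in range(0, 360, 20):
                th = torsions_from_pucker(PuckerState(P, tau)).as_array()
                noisy = th + rng.uniform(-0.5, 0.5, 5)
                back = pucker_from_torsions(RingTorsions(tuple(noisy)))
                assert angdiff(back.P, P) < max(tol, 2.0)
                assert abs(back.tau_m - tau) < 1.0
                if tau >= 21.0:
                    assert angdiff(back.P, P) < 2.0


class TestPuckerProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        P=st.floats(0.0, 360.0, exclude_max=True),
        tau=st.floats(0.5, 60.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_any_state(self, P, tau):
        back = pucker_from_torsions(torsions_from_pucker(PuckerState(P, tau)))
        assert angdiff(back.P, P) < 1e-8
        assert back.tau_m == pytest.approx(tau, abs=1e-9)


class TestRingGrid:
    def test_size_and_extremes(self):
        grid = ring_grid()
        assert len(grid) == 900
        assert (grid[0].P, grid[0].tau_m) == (0.0, 3.0)
        assert (grid[-1].P, grid[-1].tau_m) == (354.0, 45.0)

    def test_no_duplicates_and_phase_coverage(self):
        grid = ring_grid()
        assert len({(g.P, g.tau_m) for g in grid}) == 900
        phases, counts = np.unique([g.P for g in grid], return_counts=True)
        assert len(phases) == 60
        assert np.all(counts == 15)


class TestEmbedding:
    def test_pucker_round_trip(self, rib_beta):
        spec = ConformerSpec(PuckerState(18, 39))
        coords = embed_conformer(rib_beta, spec)
        back = pucker_from_torsions(ring_torsions_of(rib_beta, coords))
        assert angdiff(back.P, 18) < 2.0
        assert abs(back.tau_m - 39) < 1.0

    def test_near_planar_ring_closure(self, rib_beta):
        # tau_m = 3: closure succeeds; phase tolerance is relaxed internally
        spec = ConformerSpec(PuckerState(120, 3))
        coords = embed_conformer(rib_beta, spec)
        back = pucker_from_torsions(ring_torsions_of(rib_beta, coords))
        assert abs(back.tau_m - 3) < 1.0
        assert angdiff(back.P, 120) < 10.0

    def test_exo_torsions_hit_targets(self, rib_beta):
        quads = exocyclic_torsions(rib_beta)
        targets = {name: 25.0 + 40.0 * k for k, name in enumerate(sorted(quads))}
        coords = embed_conformer(rib_beta, ConformerSpec(PuckerState(90, 30), targets))
        for name, tgt in targets.items():
            got = dihedral(*(coords[i] for i in quads[name]))
            assert angdiff(got, tgt) < 0.1

    def test_deterministic_and_phase_periodic(self, rib_beta):
        exo = {k: 60.0 for k in exocyclic_torsions(rib_beta)}
        a = embed_conformer(rib_beta, ConformerSpec(PuckerState(18, 30), exo))
        b = embed_conformer(rib_beta, ConformerSpec(PuckerState(18, 30), exo))
        c = embed_conformer(rib_beta, ConformerSpec(PuckerState(18 + 360, 30), exo))
        assert np.array_equal(a, b)
        assert np.array_equal(a, c)

    def test_invariant_under_rigid_motion_of_input(self, rib_beta):
        spec = ConformerSpec(PuckerState(200, 25), {"C2-O2": 45.0})
        a = embed_conformer(rib_beta, spec)
        R = Rotation.from_rotvec([0.4, -0.2, 1.1]).as_matrix()
        moved = rib_beta.with_coords(rib_beta.coords @ R.T + np.array([3.0, -7.0, 2.0]))
        b = embed_conformer(moved, spec)
        assert np.allclose(a, b, atol=1e-8)

    def test_bond_lengths_preserved(self, rib_beta):
        spec = ConformerSpec(PuckerState(306, 42))
        coords = embed_conformer(rib_beta, spec)
        old = rib_beta.coords
        for i, j in rib_beta.bonds:
            d_new = np.linalg.norm(coords[i] - coords[j])
            d_old = np.linalg.norm(old[i] - old[j])
            assert d_new == pytest.approx(d_old, abs=0.01)


class TestExoRandomization:
    def test_count_and_reproducibility(self, rib_beta):
        maps1 = randomize_exocyclic(rib_beta, 30, rng_seed=7)
        maps2 = randomize_exocyclic(rib_beta, 30, rng_seed=7)
        assert len(maps1) == 30
        assert maps1 == maps2
        assert set(maps1[0]) == set(exocyclic_torsions(rib_beta))

    def test_uniformity_by_ks(self, rib_beta):
        maps = randomize_exocyclic(rib_beta, 10_000, rng_seed=11)
        for name in maps[0]:
            vals = np.array([m[name] for m in maps]) / 360.0
            assert stats.kstest(vals, "uniform").pvalue > 0.01


class TestSplit:
    @staticmethod
    def _dummy_dataset(mol, n_ring, n_exo):
        specs, coords, ring_ids = [], [], []
        for r in range(n_ring):
            for e in range(n_exo):
                specs.append(ConformerSpec(PuckerState(6.0 * r + 1, 30), conformer_id=f"r{r}e{e}"))
                coords.append(np.zeros((mol.n_atoms, 3)))
                ring_ids.append(r)
        return ConformerDataset(mol, specs, coords, ring_ids)

    def test_full_protocol_counts(self, rib_beta):
        ds = self._dummy_dataset(rib_beta, 900, 30)
        ds = split_dataset(ds, train_per_ring=24, rng_seed=3)
        labels = np.array(ds.split)
        assert (labels == "train").sum() == 21_600
        assert (labels == "test").sum() == 5_400
        ring_ids = np.array(ds.ring_ids)
        for r in range(0, 900, 97):
            assert (labels[ring_ids == r] == "train").sum() == 24

    def test_split_reproducible(self, rib_beta):
        ds1 = split_dataset(self._dummy_dataset(rib_beta, 10, 30), 24, rng_seed=5)
        ds2 = split_dataset(self._dummy_dataset(rib_beta, 10, 30), 24, rng_seed=5)
        assert ds1.split == ds2.split

    def test_too_few_members_rejected(self, rib_beta):
        ds = self._dummy_dataset(rib_beta, 3, 10)
        with pytest.raises(ValidationError):
            split_dataset(ds, train_per_ring=24, rng_seed=0)


def test_generate_conformers_shape(rib_beta):
    grid = ring_grid(30.0, 45.0, 15.0, 120.0)  # 2 x 3 = 6 ring states
    ds = generate_conformers(rib_beta, grid, n_exo=4, rng_seed=9)
    assert len(ds) == 24
    assert ds.ring_ids == sorted(ds.ring_ids)
    ids = [s.conformer_id for s in ds.specs]
    assert len(set(ids)) == len(ids)
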