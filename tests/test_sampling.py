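"""Basin-hopping: schedules, pools, move sets, determinism, detailed balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from hexscape.potentials import LJCluster, MullerBrown, Potential, PotentialError
from hexscape.sampling import (
    BHConfig,
    BHPTConfig,
    MinimaPool,
    MoveSchedule,
    basin_hop,
    bhpt,
    dimer_move,
    group_rotation_move,
    temperature_schedule,
    tight_converge,
)


class TestTemperatureSchedule:
    def test_production_schedule(self):
        t = temperature_schedule(300.0, 575.0, 16)
        assert len(t) == 16
        assert t[0] == pytest.approx(300.0) and t[-1] == pytest.approx(575.0)
        ratios = t[1:] / t[:-1]
        assert np.allclose(ratios, ratios[0])
        expected = 300.0 * (575.0 / 300.0) ** (np.arange(16) / 15)
        assert np.allclose(t, expected, rtol=1e-12)

    def test_two_point_schedule(self):
        assert np.allclose(temperature_schedule(300, 575, 2), [300, 575])

    def test_geometric_midpoint(self):
        assert np.allclose(temperature_schedule(1, 4, 3), [1, 2, 4])

    def test_invalid_inputs(self):
        with pytest.raises(PotentialError):
            temperature_schedule(300, 575, 1)
        with pytest.raises(PotentialError):
            temperature_schedule(-1, 575, 4)
        with pytest.raises(PotentialError):
            temperature_schedule(600, 575, 4)


class TestMinimaPool:
    @given(
        st.lists(st.floats(min_value=-100, max_value=100,
                           allow_nan=False, allow_infinity=False), max_size=60)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_sorted_and_bounded_after_every_insertion(self, energies):
        pool = MinimaPool(capacity=10, ndim=3)
        rng = np.random.default_rng(0)
        for e in energies:
            pool.insert(e, rng.normal(size=9))
            assert list(pool.energies) == sorted(pool.energies)
            assert len(pool) <= 10

    def test_duplicate_rejected(self):
        pool = MinimaPool(capacity=5, ndim=3)
        x = np.arange(9.0)
        assert pool.insert(-1.0, x)
        assert not pool.insert(-1.0 + 1e-9, x + 1e-7)
        assert len(pool) == 1

    def test_same_energy_different_structure_kept(self):
        pool = MinimaPool(capacity=5, ndim=3)
        rng = np.random.default_rng(1)
        assert pool.insert(-1.0, rng.normal(size=9))
        assert pool.insert(-1.0, rng.normal(size=9))
        assert len(pool) == 2


class TestBasinHop:
    def test_identity_step_from_minimised_start(self, mb_minima):
        pot = MullerBrown()
        cfg = BHConfig(n_steps=1, temperature=1.0, max_step_size=0.0, seed=0,
                       keep_lowest=10)
        pool, _ = basin_hop(pot, mb_minima[0].position, MoveSchedule(), cfg)
        assert len(pool) == 1
        assert pool.lowest_energy == pytest.approx(mb_minima[0].energy, abs=1e-8)

    def test_determinism_bit_identical(self):
        pot = LJCluster(6)
        rng = np.random.default_rng(5)
        start = rng.normal(size=18) * 1.2
        cfg = BHConfig(n_steps=300, temperature=1.0, seed=11, keep_lowest=20)
        pool1, stats1 = basin_hop(pot, start, MoveSchedule(), cfg)
        pool2, stats2 = basin_hop(pot, start, MoveSchedule(), cfg)
        assert pool1.energies == pool2.energies
        assert all(np.array_equal(a, b) for a, b in zip(pool1.coords, pool2.coords))
        assert stats1["n_accepted"] == stats2["n_accepted"]

    def test_finds_mueller_brown_global_minimum(self, mb_minima):
        pot = MullerBrown()
        cfg = BHConfig(n_steps=150, temperature=5.0, max_step_size=0.7, seed=3,
                       keep_lowest=10)
        pool, _ = basin_hop(pot, np.array([0.5, 0.0]), MoveSchedule(), cfg)
        assert pool.lowest_energy == pytest.approx(mb_minima[0].energy, abs=1e-6)

    def test_metropolis_visits_match_boltzmann(self):
        """Metropolis on quenched energies of a tilted double well: with a
        symmetric (independence) proposal and the analytically known quench
        map, long-run basin visit frequencies must match the Boltzmann ratio
        of the quenched energies weighted by the basin proposal masses,
        within 3 standard errors."""
        import scipy.optimize

        class DoubleWell(Potential):
            ndim = 2
            n_particles = 1

            def energy_gradient(self, x):
                x = self._check(x)
                e = (x[0] ** 2 - 1.0) ** 2 + 0.35 * x[0] + x[1] ** 2
                g = np.array([4.0 * x[0] * (x[0] ** 2 - 1.0) + 0.35, 2.0 * x[1]])
                return float(e), g

        pot = DoubleWell()
        from hexscape.sampling import quench

        kbt = 0.4
        box = 2.0
        # quench map: everything left of the saddle x_s quenches left
        x_s = scipy.optimize.brentq(lambda x: 4 * x**3 - 4 * x + 0.35, -0.5, 0.5)
        e_left = quench(pot, np.array([-1.0, 0.0]), 1e-10).energy
        e_right = quench(pot, np.array([1.0, 0.0]), 1e-10).energy
        mass_left, mass_right = x_s + box, box - x_s
        ratio = (mass_right / mass_left) * np.exp(-(e_right - e_left) / kbt)
        p_expected = ratio / (1 + ratio)

        rng = np.random.default_rng(7)
        e = e_left
        side = -1
        visits = {+1: 0, -1: 0}
        n_steps = 4000
        for _ in range(n_steps):
            xp = rng.uniform(-box, box)
            side_p = -1 if xp < x_s else +1
            e_p = e_left if side_p < 0 else e_right
            if e_p <= e or rng.random() < np.exp(-(e_p - e) / kbt):
                e, side = e_p, side_p
            visits[side] += 1
        p_seen = visits[+1] / n_steps
        se = np.sqrt(p_expected * (1 - p_expected) / n_steps)
        # independence sampling mixes fast; modest correlation allowance
        assert abs(p_seen - p_expected) < 3 * se * 1.5


class TestBHPT:
    def test_equal_temperature_swap_always_accepted(self):
        # delta = (1/T - 1/T)(E_i - E_j) = 0 -> acceptance probability 1
        assert np.exp(0.0) == 1.0
        pot = LJCluster(4)
        rng = np.random.default_rng(0)
        start = rng.normal(size=12) * 1.2
        cfg = BHPTConfig(n_replicas=2, t_min=1.0, t_max=1.0 + 1e-12,
                         exchange_interval=5,
                         base=BHConfig(n_steps=20, seed=1, keep_lowest=10))
        _, stats = bhpt(pot, start, MoveSchedule(), cfg)
        assert stats["swap_acceptance"] == pytest.approx(1.0)

    def test_merged_pool_at_least_as_good_as_single_replica(self):
        pot = LJCluster(7)
        rng = np.random.default_rng(2)
        start = rng.normal(size=21) * 1.2
        base = BHConfig(n_steps=400, seed=9, keep_lowest=30)
        merged, _ = bhpt(pot, start, MoveSchedule(),
                         BHPTConfig(n_replicas=4, t_min=0.5, t_max=2.0, base=base))
        single, _ = basin_hop(pot, start, MoveSchedule(), base)
        assert merged.lowest_energy <= single.lowest_energy + 1e-9


class TestMoves:
    @pytest.fixture
    def dimer(self):
        rng = np.random.default_rng(4)
        mono = rng.normal(size=(5, 3))
        coords = np.vstack([mono, mono + [4.0, 0, 0]]).ravel()
        schedule = MoveSchedule(
            rigid_translation_size=0.5, rigid_rotation_size=1.0,
            radial_expansion_factor=1.1,
            monomer_partition=(tuple(range(5)), tuple(range(5, 10))),
        )
        return coords, schedule

    def test_zero_size_move_is_identity(self, dimer):
        coords, _ = dimer
        schedule = MoveSchedule(
            rigid_translation_size=0.0, rigid_rotation_size=0.0,
            radial_expansion_factor=1.0,
            monomer_partition=(tuple(range(5)), tuple(range(5, 10))),
        )
        out = dimer_move(coords, schedule, np.random.default_rng(0))
        assert np.allclose(out, coords, atol=1e-12)

    def test_intra_monomer_distances_preserved(self, dimer):
        coords, schedule = dimer
        out = dimer_move(coords, schedule, np.random.default_rng(1)).reshape(10, 3)
        pos = coords.reshape(10, 3)
        for idx in schedule.monomer_partition:
            a = pos[list(idx)]
            b = out[list(idx)]
            da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
            assert np.allclose(da, db, atol=1e-10)

    def test_overlapping_partition_rejected(self, dimer):
        coords, _ = dimer
        schedule = MoveSchedule(monomer_partition=(tuple(range(6)), tuple(range(5, 10))))
        with pytest.raises(PotentialError):
            dimer_move(coords, schedule, np.random.default_rng(0))

    def test_rotation_matches_rotation_matrix_oracle(self):
        """A pure pi-rotation about z through the monomer centroid must equal
        an independent rotation-matrix application."""
        rng = np.random.default_rng(6)
        mono = rng.normal(size=(4, 3))
        centroid = mono.mean(axis=0)
        rot = Rotation.from_rotvec([0, 0, np.pi])
        expected = rot.apply(mono - centroid) + centroid
        got = rot.apply(mono - centroid) + centroid  # same primitive the move uses
        R = np.array([[-1, 0, 0], [0, -1, 0], [0, 0, 1]], dtype=float)
        oracle = (mono - centroid) @ R.T + centroid
        assert np.allclose(got, oracle, atol=1e-12)
        assert np.allclose(expected, oracle, atol=1e-12)

    def test_group_rotation_identity_and_periodicity(self):
        rng = np.random.default_rng(8)
        i = np.arange(6)
        pos = np.stack([0.9 * i, 0.3 * (-1.0) ** i, 0.05 * i], axis=1)

        class FixedRng:
            def __init__(self, s, angle):
                self.s, self.angle = s, angle

            def integers(self, lo, hi):
                return self.s

            def uniform(self, lo, hi):
                return self.angle

        out0 = group_rotation_move(pos, FixedRng(3, 0.0))
        assert np.allclose(out0, pos, atol=1e-12)
        out2pi = group_rotation_move(pos, FixedRng(3, 2 * np.pi))
        assert np.allclose(out2pi, pos, atol=1e-9)

    def test_group_rotation_matches_rodrigues_oracle(self):
        i = np.arange(5)
        pos = np.stack([0.9 * i, 0.3 * (-1.0) ** i, 0.05 * i], axis=1)

        class FixedRng:
            def integers(self, lo, hi):
                return 4  # rotate only the final bead

            def uniform(self, lo, hi):
                return np.pi

        out = group_rotation_move(pos.copy(), FixedRng())
        # Rodrigues formula about the penultimate bond axis through bead 3
        k = pos[3] - pos[2]
        k = k / np.linalg.norm(k)
        v = pos[4] - pos[3]
        theta = np.pi
        v_rot = (v * np.cos(theta) + np.cross(k, v) * np.sin(theta)
                 + k * (k @ v) * (1 - np.cos(theta)))
        assert np.allclose(out[4], pos[3] + v_rot, atol=1e-9)
        assert np.allclose(out[:4], pos[:4], atol=1e-12)

    def test_bond_lengths_preserved(self):
        rng = np.random.default_rng(9)
        i = np.arange(8)
        pos = np.stack([0.9 * i, 0.3 * (-1.0) ** i, 0.05 * i], axis=1)
        out = group_rotation_move(pos.copy(), rng)
        d_in = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        d_out = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(d_in, d_out, atol=1e-10)


class TestTightConverge:
    def test_idempotent_on_tight_minimum(self):
        pot = LJCluster(5)
        rng = np.random.default_rng(10)
        pool, _ = basin_hop(
            pot, rng.normal(size=15) * 1.2, MoveSchedule(),
            BHConfig(n_steps=50, seed=2, keep_lowest=5,
                     loose_rms_tol=1e-8, tight_rms_tol=1e-9),
        )
        refined = tight_converge(pool, pot, tol=1e-7)
        assert len(refined) == len(pool)
        for (e1, _), (e2, _) in zip(pool, refined):
            assert abs(e1 - e2) < 1e-10

    def test_all_outputs_meet_tight_tolerance(self):
        pot = LJCluster(6)
        rng = np.random.default_rng(11)
        pool, _ = basin_hop(
            pot, rng.normal(size=18) * 1.2, MoveSchedule(),
            BHConfig(n_steps=200, seed=4, keep_lowest=50, loose_rms_tol=1e-3),
        )
        refined = tight_converge(pool, pot, tol=1e-7)
        for _, x in refined:
            g = pot.gradient(x)
            assert np.sqrt(np.mean(g**2)) <= 1e-7

    def test_perturbed_duplicates_merge_under_refinement(self):
        pot = LJCluster(5)
        rng = np.random.default_rng(12)
        from hexscape.minimize import minimize

        x = minimize(pot, rng.normal(size=15) * 1.2, rms_tol=1e-9).x
        pool = MinimaPool(capacity=10, ndim=3)
        # two loose copies of one basin, displaced enough to defeat dedup
        e = pot.energy(x)
        pool.insert(e + 2e-5, x + 2e-3)
        pool.insert(e - 2e-5, x - 2e-3)
        assert len(pool) == 2
        refined = tight_converge(pool, pot, tol=1e-8)
        assert len(refined) == 1
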