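import numpy as np
import pytest

from conjugate_release.engine import (
    SimConfig,
    SimState,
    mc_step,
    run_realization,
    single_particle_release_times,
)
from conjugate_release.lattice import build_spherical_lattice

from conftest import exact_mean_exit_steps


def _single_particle_state(R, site, bonded):
    lat = build_spherical_lattice(R)
    idx = lat.index_of(site)
    occ = np.full(lat.ms, -1, dtype=np.int64)
    occ[idx] = 0
    return SimState(
        lattice=lat,
        occupancy=occ,
        positions=np.array([idx], dtype=np.int64),
        bonded=np.array([bonded]),
        n=1,
        n_bonded=int(bonded),
    )


class TestMcStep:
    def test_certain_cleavage_at_kb_one(self):
        """A bonded particle picked with kb=1 detaches without moving."""
        state = _single_particle_state(2, (0, 0, 0), bonded=True)
        pos_before = state.positions[0]
        dt = mc_step(state, kb=1.0, rng=np.random.default_rng(0))
        assert dt == 1.0  # Nt=1 at pick time
        assert state.n_bonded == 0 and not state.bonded[0]
        assert state.positions[0] == pos_before

    def test_no_cleavage_at_vanishing_kb(self):
        state = _single_particle_state(2, (0, 0, 0), bonded=True)
        rng = np.random.default_rng(1)
        for _ in range(200):
            mc_step(state, kb=0.0, rng=rng)
        assert state.n_bonded == 1 and state.n == 1

    def test_boundary_step_releases_particle(self):
        """A free particle on the surface of R=1 leaves w.p. 5/6 per pick."""
        state = _single_particle_state(1, (1, 0, 0), bonded=False)
        rng = np.random.default_rng(2)
        steps = 0
        while state.n > 0:
            dt = mc_step(state, kb=0.0, rng=rng)
            assert dt == 1.0
            state.check_invariants()
            steps += 1
        assert state.n_released == 1
        assert np.all(state.occupancy == -1)
        assert steps >= 1

    def test_blocked_moves_preserve_excluded_volume(self):
        """With every site filled and all particles free, no two particles
        ever share a site while the matrix drains."""
        lat = build_spherical_lattice(1)
        rng = np.random.default_rng(5)
        state = SimState.initialize(lat, 1.0, rng, diffusion_only=True)
        assert state.n == 7
        while state.n > 0:
            mc_step(state, kb=0.0, rng=rng)
            state.check_invariants()  # asserts one particle per occupied site
        assert state.n_released == 7

    def test_empty_matrix_is_a_state_error(self):
        state = _single_particle_state(1, (0, 0, 0), bonded=False)
        state.n = 0
        with pytest.raises(RuntimeError):
            mc_step(state, kb=0.5, rng=np.random.default_rng(0))

    def test_time_increment_uses_population_at_pick(self):
        """dt = 1/Nt with the pre-release Nt: the pick that releases the last
        of two particles still advances the clock by 1/2."""
        lat = build_spherical_lattice(1)
        occ = np.full(lat.ms, -1, dtype=np.int64)
        i, j = lat.index_of((1, 0, 0)), lat.index_of((-1, 0, 0))
        occ[i], occ[j] = 0, 1
        state = SimState(
            lattice=lat,
            occupancy=occ,
            positions=np.array([i, j], dtype=np.int64),
            bonded=np.array([False, False]),
            n=2,
            n_bonded=0,
        )
        rng = np.random.default_rng(7)
        while state.n == 2:
            assert mc_step(state, kb=0.0, rng=rng) == 0.5
        # the releasing pick above returned 1/2, not 1/1
        while state.n == 1:
            assert mc_step(state, kb=0.0, rng=rng) == 1.0


class TestRunRealization:
    def test_trajectory_bookkeeping(self):
        cfg = SimConfig(R=4, C0=0.5, kb=0.2, n_realizations=1, seed=3)
        tr = run_realization(cfg, seed=3)
        assert tr.times[0] == 0.0
        assert tr.N[0] == tr.Nb[0] == tr.n0
        assert np.all(np.diff(tr.times) >= 0)
        assert np.all(np.diff(tr.N) <= 0) and np.all(np.diff(tr.Nb) <= 0)
        assert np.all(tr.Nf >= 0)
        assert not tr.truncated
        assert tr.N[-1] == 0 and tr.Nb[-1] == 0
        assert tr.times[-1] == tr.t_final
        assert len(tr.release_times()) == tr.n0

    def test_diffusion_only_initial_condition(self):
        tr = run_realization(SimConfig(R=3, C0=0.5, seed=0, diffusion_only=True), seed=1)
        assert tr.Nb[0] == 0 and tr.N[0] == tr.n0

    def test_no_cleavage_means_no_release(self):
        """With a negligible kb and a short horizon everything stays bonded."""
        cfg = SimConfig(R=3, C0=0.5, kb=1e-9, n_realizations=1, seed=0, max_time=20.0)
        tr = run_realization(cfg, seed=5)
        assert tr.truncated
        assert tr.Nb[-1] == tr.n0 and tr.N[-1] == tr.n0

    def test_seeded_runs_are_bit_reproducible(self):
        cfg = SimConfig(R=4, C0=0.5, kb=0.3, n_realizations=1, seed=9)
        a = run_realization(cfg, seed=42)
        b = run_realization(cfg, seed=42)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.N, b.N) and np.array_equal(a.Nb, b.Nb)

    def test_mean_release_time_equals_step_integral(self):
        """Average of individual release times == exact integral of N(t)/N0."""
        tr = run_realization(SimConfig(R=4, C0=0.5, kb=0.2, seed=1), seed=8)
        step_integral = float(np.sum(tr.N[:-1] * np.diff(tr.times))) / tr.n0
        assert tr.mean_release_time() == pytest.approx(step_integral, rel=1e-12)


class TestSingleParticleOracle:
    def test_center_release_time_r1(self):
        """Mean exit time from the centre of the R=1 sphere is 12/5 tu."""
        times = single_particle_release_times(1, (0, 0, 0), 10_000, seed=0)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 2.4) < 3 * se

    @pytest.mark.parametrize("R,site", [(1, (1, 0, 0)), (2, (0, 0, 0)), (2, (1, 1, 0))])
    def test_matches_absorbing_chain_expectation(self, R, site):
        lat = build_spherical_lattice(R)
        expected = exact_mean_exit_steps(lat)[lat.index_of(site)]
        times = single_particle_release_times(R, site, 10_000, seed=1)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - expected) < 3 * se

    def test_python_step_agrees_with_kernel(self):
        """The reference mc_step loop and the compiled kernel give the same
        single-particle mean exit time (two routes, one law)."""
        lat = build_spherical_lattice(2)
        rng = np.random.default_rng(13)
        py_times = []
        for _ in range(800):
            state = _single_particle_state(2, (0, 0, 0), bonded=False)
            t = 0.0
            while state.n > 0:
                t += mc_step(state, kb=0.0, rng=rng)
            py_times.append(t)
        py_times = np.asarray(py_times)
        kern = single_particle_release_times(2, (0, 0, 0), 10_000, seed=2)
        se = np.hypot(
            py_times.std(ddof=1) / np.sqrt(len(py_times)),
            kern.std(ddof=1) / np.sqrt(len(kern)),
        )
        assert abs(py_times.mean() - kern.mean()) < 3 * se


@pytest.mark.parametrize(
    "kwargs",
    [
        {"R": 0},
        {"R": 3, "C0": 0.0},
        {"R": 3, "C0": 1.2},
        {"R": 3, "kb": 0.0},
        {"R": 3, "kb": 1.5},
        {"R": 3, "n_realizations": 0},
        {"R": 3, "max_time": -1.0},
        {"R": 3, "grid_kind": "cubic"},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimConfig(**kwargs)
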