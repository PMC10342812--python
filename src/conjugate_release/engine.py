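"""Monte Carlo dynamics of one realization.

At every Monte Carlo step one of the ``Nt`` drug particles still inside the
matrix is picked uniformly at random and the clock advances by ``1/Nt``
(with the ``Nt`` in force at pick time), so each particle attempts on
average one event per time unit tu.  A bonded particle undergoes a cleavage
trial: with probability ``kb`` its covalent link breaks and it becomes free
(its position is unchanged in that step).  A free particle attempts a hop
to one of its six lattice neighbours chosen with probability 1/6 each; a
hop onto an occupied site is rejected (the particle stays), and a hop
outside the sphere releases the particle, which is removed from the
simulation (perfect-sink absorbing boundary).

Because each particle is picked at unit rate irrespective of ``Nt``, the
bonded population decays as ``Nb(t)/N0 = exp(-kb t)``: the cleavage
reaction exhibits first-order kinetics by construction.

The hot loop is compiled with numba; :func:`mc_step` is the equivalent
pure-Python single-step reference used by the unit tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .lattice import (
    SphericalLattice,
    build_spherical_lattice,
    initial_load,
    sample_initial_sites,
)

__all__ = [
    "SimConfig",
    "SimState",
    "Trajectory",
    "mc_step",
    "run_realization",
    "single_particle_release_times",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SimConfig:
    """All parameters of a simulation run.

    Parameters
    ----------
    R : int
        Sphere radius in lattice constants (lu); >= 1.
    C0 : float
        Initial drug load fraction in (0, 1]; N0 = round(C0 * MS) sites are
        occupied at t = 0.
    kb : float
        Relative bond cleavage rate constant in (0, 1], units 1/tu.  The
        per-pick detachment probability of a bonded particle; kb = 1 is the
        upper limit of the scheme.
    n_realizations : int
        Independent realizations to average over.
    seed : int
        Master seed; per-realization streams are spawned from it.
    max_time : float or None
        Safety cap in tu.  None runs every realization until the matrix is
        empty (Nt = 0).  A capped, unfinished run is flagged truncated.
    n_grid : int
        Number of points of the common recording grid (plus t = 0).
    grid_kind : {"log", "linear"}
        Spacing of the recording grid.
    diffusion_only : bool
        Start with every particle already detached (Nb(0) = 0).  This is the
        purely diffusional reference used to measure t_diff.
    """

    R: int
    C0: float = 0.5
    kb: float = 1.0
    n_realizations: int = 100
    seed: int = 0
    max_time: float | None = None
    n_grid: int = 512
    grid_kind: str = "log"
    diffusion_only: bool = False

    def __post_init__(self):
        if int(self.R) != self.R or self.R < 1:
            raise ValueError(f"R must be a positive integer, got {self.R!r}")
        if not 0.0 < self.C0 <= 1.0:
            raise ValueError(f"C0 must be in (0, 1], got {self.C0!r}")
        if not self.diffusion_only and not 0.0 < self.kb <= 1.0:
            raise ValueError(f"kb must be in (0, 1], got {self.kb!r}")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.max_time is not None and self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if self.grid_kind not in ("log", "linear"):
            raise ValueError(f"grid_kind must be 'log' or 'linear', got {self.grid_kind!r}")
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "R": self.R,
            "C0": self.C0,
            "kb": self.kb,
            "n_realizations": self.n_realizations,
            "seed": self.seed,
            "max_time": self.max_time,
            "n_grid": self.n_grid,
            "grid_kind": self.grid_kind,
            "diffusion_only": self.diffusion_only,
        }


@dataclass
class Trajectory:
    """Event record of one realization, as left-continuous step functions.

    ``times[0] = 0`` and a row is appended at every change of (Nt, Nb);
    values hold from one event time up to (and including) the next.
    """

    times: np.ndarray
    N: np.ndarray
    Nb: np.ndarray
    n0: int
    t_final: float
    truncated: bool

    @property
    def Nf(self) -> np.ndarray:
        """Free (detached but not yet released) particle count Nf = Nt - Nb."""
        return self.N - self.Nb

    def resample(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(N, Nb) on ``grid`` as left-continuous step functions."""
        pos = np.searchsorted(self.times, grid, side="right") - 1
        pos = np.clip(pos, 0, len(self.times) - 1)
        return self.N[pos], self.Nb[pos]

    def release_times(self) -> np.ndarray:
        """Times of the individual release events (decrements of Nt)."""
        drops = np.diff(self.N) < 0
        return self.times[1:][drops]

    def mean_release_time(self) -> float:
        """Exact average of the individual particles' release times.

        Identical to the integral of the step function N(t)/N0; only defined
        for completed (untruncated) runs.
        """
        if self.truncated:
            raise ValueError("mean release time undefined for a truncated trajectory")
        return float(self.release_times().sum()) / self.n0


# ---------------------------------------------------------------------------
# compiled hot loop

@njit(cache=True)
def _run_kernel(neighbors, ms, pos0, bonded0, kb, seed, max_time):  # pragma: no cover
    np.random.seed(seed)
    n0 = pos0.shape[0]
    occ = np.full(ms, -1, dtype=np.int64)
    pos = pos0.copy()
    bonded = bonded0.copy()
    for i in range(n0):
        occ[pos[i]] = i
    n = n0
    nb = 0
    for i in range(n0):
        if bonded[i]:
            nb += 1

    max_ev = 2 * n0 + 1
    ev_t = np.empty(max_ev)
    ev_n = np.empty(max_ev, dtype=np.int64)
    ev_nb = np.empty(max_ev, dtype=np.int64)
    ev_t[0] = 0.0
    ev_n[0] = n0
    ev_nb[0] = nb
    k = 1

    t = 0.0
    while n > 0 and t < max_time:
        j = np.random.randint(n)
        t += 1.0 / n  # Nt in force at pick time
        if bonded[j]:
            if np.random.random() < kb:
                bonded[j] = False
                nb -= 1
                ev_t[k] = t
                ev_n[k] = n
                ev_nb[k] = nb
                k += 1
        else:
            d = np.random.randint(6)
            target = neighbors[pos[j], d]
            if target == -1:
                # stepped outside the sphere: released, removed for good
                occ[pos[j]] = -1
                n -= 1
                if j != n:
                    pos[j] = pos[n]
                    bonded[j] = bonded[n]
                    occ[pos[j]] = j
                ev_t[k] = t
                ev_n[k] = n
                ev_nb[k] = nb
                k += 1
            elif occ[target] == -1:
                occ[pos[j]] = -1
                occ[target] = j
                pos[j] = target
            # occupied target: blocked move, particle stays
    return ev_t[:k], ev_n[:k], ev_nb[:k], t, n > 0


@njit(cache=True)
def _single_particle_batch(neighbors, ms, start, seeds):  # pragma: no cover
    pos0 = np.full(1, start, dtype=np.int64)
    bonded0 = np.zeros(1, dtype=np.bool_)
    out = np.empty(seeds.shape[0])
    for i in range(seeds.shape[0]):
        _, _, _, t_final, _ = _run_kernel(
            neighbors, ms, pos0, bonded0, 0.0, seeds[i], np.inf
        )
        out[i] = t_final
    return out


def _spawn(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def run_realization(config: SimConfig, seed, lattice: SphericalLattice | None = None) -> Trajectory:
    """Simulate one realization until the matrix empties (or ``max_time``).

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`; the
    placement stream and the dynamics stream are spawned from it, so a given
    (config, seed) pair is bit-reproducible.
    """
    if lattice is None:
        lattice = build_spherical_lattice(config.R)
    ss_place, ss_dyn = _spawn(seed).spawn(2)
    rng = np.random.default_rng(ss_place)
    pos0 = np.sort(sample_initial_sites(lattice, config.C0, rng)).astype(np.int64)
    bonded0 = np.full(pos0.shape[0], not config.diffusion_only, dtype=np.bool_)
    kernel_seed = int(ss_dyn.generate_state(1)[0]) % _SEED_MOD
    max_time = np.inf if config.max_time is None else float(config.max_time)
    kb = 0.0 if config.diffusion_only else config.kb
    ev_t, ev_n, ev_nb, t_final, truncated = _run_kernel(
        lattice.neighbors, lattice.ms, pos0, bonded0, kb, kernel_seed, max_time
    )
    return Trajectory(
        times=ev_t,
        N=ev_n,
        Nb=ev_nb,
        n0=pos0.shape[0],
        t_final=float(t_final),
        truncated=bool(truncated),
    )


def single_particle_release_times(
    R: int, start_site, n_runs: int, seed
) -> np.ndarray:
    """Release times of a lone free particle started at ``start_site``.

    Runs the full engine kernel ``n_runs`` times with a single detached
    particle.  With Nt = 1 every pick advances time by exactly 1 tu, so the
    returned times equal the step counts of the corresponding absorbing
    random walk — directly comparable with the exact Markov-chain
    expectation.
    """
    lattice = build_spherical_lattice(R)
    start = lattice.index_of(start_site) if np.ndim(start_site) else int(start_site)
    seeds = (_spawn(seed).generate_state(n_runs, dtype=np.uint64) % _SEED_MOD).astype(np.int64)
    return _single_particle_batch(lattice.neighbors, lattice.ms, start, seeds)


# ---------------------------------------------------------------------------
# pure-Python reference state + single step

@dataclass
class SimState:
    """Mutable in-memory state used by the reference :func:`mc_step`."""

    lattice: SphericalLattice
    occupancy: np.ndarray  # site index -> particle slot, -1 when empty
    positions: np.ndarray  # slot -> site index
    bonded: np.ndarray  # slot -> bool
    n: int
    n_bonded: int
    time: float = 0.0
    n_released: int = field(default=0)

    @classmethod
    def initialize(cls, lattice: SphericalLattice, C0: float, rng, diffusion_only: bool = False):
        pos = np.sort(sample_initial_sites(lattice, C0, rng)).astype(np.int64)
        occ = np.full(lattice.ms, -1, dtype=np.int64)
        occ[pos] = np.arange(pos.shape[0])
        bonded = np.full(pos.shape[0], not diffusion_only, dtype=bool)
        n = pos.shape[0]
        return cls(
            lattice=lattice,
            occupancy=occ,
            positions=pos,
            bonded=bonded,
            n=n,
            n_bonded=int(bonded.sum()),
        )

    def check_invariants(self):
        occupied = np.flatnonzero(self.occupancy >= 0)
        assert occupied.shape[0] == self.n, "occupancy count != particle count"
        assert np.array_equal(np.sort(self.positions[: self.n]), occupied), (
            "occupancy map inconsistent with particle positions"
        )
        assert self.n_bonded == int(self.bonded[: self.n].sum())
        assert self.n + self.n_released == self.positions.shape[0]


def mc_step(state: SimState, kb: float, rng: np.random.Generator) -> float:
    """One Monte Carlo pick; returns the time increment 1/Nt.

    Readable reference implementation of the kernel's step rule (same
    branches, same conventions; it does not share the kernel's random
    stream).
    """
    if state.n < 1:
        raise RuntimeError("mc_step called on an empty matrix")
    n_at_pick = state.n
    j = int(rng.integers(n_at_pick))
    dt = 1.0 / n_at_pick
    state.time += dt
    if state.bonded[j]:
        if rng.random() < kb:
            state.bonded[j] = False
            state.n_bonded -= 1
    else:
        d = int(rng.integers(6))
        target = state.lattice.neighbors[state.positions[j], d]
        if target == -1:
            state.occupancy[state.positions[j]] = -1
            state.n -= 1
            state.n_released += 1
            last = state.n
            if j != last:
                state.positions[j] = state.positions[last]
                state.bonded[j] = state.bonded[last]
                state.occupancy[state.positions[j]] = j
        elif state.occupancy[target] == -1:
            state.occupancy[state.positions[j]] = -1
            state.occupancy[target] = j
            state.positions[j] = target
    return dt
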