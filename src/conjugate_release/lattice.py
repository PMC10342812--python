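"""Spherical simulation domain on a cubic lattice.

The polymer matrix is the set of integer lattice sites ``(x, y, z)`` with
``x^2 + y^2 + z^2 <= R^2``, centred on a lattice site at the origin.  All
lengths are in lattice-constant units (lu).  Drug particles occupy sites
exclusively: double occupancy is forbidden (excluded volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DIRECTIONS",
    "SphericalLattice",
    "ParticleState",
    "build_spherical_lattice",
    "initialize_particles",
    "initial_load",
]

#: The six nearest-neighbour moves on the cubic lattice, in fixed order.
DIRECTIONS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class SphericalLattice:
    """All lattice sites of a sphere of radius ``R`` (lu), centre at the origin.

    Attributes
    ----------
    R : int
        Sphere radius in lattice constants.
    sites : ndarray of shape (MS, 3)
        Integer site coordinates in lexicographic order over (x, y, z).
        The deterministic ordering makes seeded runs bit-reproducible.
    site_index : ndarray of shape (2R+1, 2R+1, 2R+1)
        Dense lookup ``site_index[x+R, y+R, z+R]`` giving the row of a site
        in ``sites``, or -1 for points of the bounding cube outside the sphere.
    neighbors : ndarray of shape (MS, 6)
        Site index of each of the six nearest neighbours, or -1 when the
        neighbour lies outside the sphere (the absorbing boundary).
    """

    R: int
    sites: np.ndarray
    site_index: np.ndarray
    neighbors: np.ndarray = field(repr=False)

    @property
    def ms(self) -> int:
        """Number of lattice sites inside the sphere (the symbol MS)."""
        return self.sites.shape[0]

    def contains(self, point) -> bool:
        x, y, z = point
        return x * x + y * y + z * z <= self.R * self.R

    def index_of(self, point) -> int:
        """Row of ``point`` in ``sites``; raises for points outside."""
        if not self.contains(point):
            raise ValueError(f"point {tuple(point)} lies outside the sphere R={self.R}")
        x, y, z = point
        return int(self.site_index[x + self.R, y + self.R, z + self.R])

    def summary(self) -> dict:
        return {"R": self.R, "MS": self.ms}


@dataclass
class ParticleState:
    """One drug molecule: either covalently bonded or free to diffuse.

    Released particles are removed from the simulation state entirely, so a
    particle record is always inside the matrix.
    """

    id: int
    position: tuple[int, int, int]
    bonded: bool = True


def build_spherical_lattice(R: int) -> SphericalLattice:
    """Enumerate all integer sites with squared distance <= R^2 from the origin.

    Parameters
    ----------
    R : int
        Sphere radius in lattice constants; must be >= 0.
    """
    if R < 0 or int(R) != R:
        raise ValueError(f"radius R must be a nonnegative integer, got {R!r}")
    R = int(R)
    side = 2 * R + 1
    ax = np.arange(-R, R + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = X * X + Y * Y + Z * Z <= R * R
    sites = np.stack([X[inside], Y[inside], Z[inside]], axis=1).astype(np.int64)
    # meshgrid with indexing="ij" already yields lexicographic (x, y, z) order
    site_index = np.full((side, side, side), -1, dtype=np.int64)
    site_index[inside] = np.arange(sites.shape[0])

    neighbors = np.full((sites.shape[0], 6), -1, dtype=np.int64)
    for d, (dx, dy, dz) in enumerate(DIRECTIONS):
        nb = sites + (dx, dy, dz)
        ok = (nb * nb).sum(axis=1) <= R * R
        neighbors[ok, d] = site_index[
            nb[ok, 0] + R, nb[ok, 1] + R, nb[ok, 2] + R
        ]
    return SphericalLattice(R=R, sites=sites, site_index=site_index, neighbors=neighbors)


def initial_load(ms: int, C0: float) -> int:
    """Initial particle number N0 = round(C0 * MS).

    Rounds half away from zero and clamps to at least one particle so a
    simulation always has something to release.
    """
    if not 0.0 < C0 <= 1.0:
        raise ValueError(f"initial load fraction C0 must be in (0, 1], got {C0!r}")
    n0 = int(math.floor(C0 * ms + 0.5))
    return min(max(n0, 1), ms)


def sample_initial_sites(lattice: SphericalLattice, C0: float, rng: np.random.Generator) -> np.ndarray:
    """Site indices of the initial placement: N0 distinct sites, uniform."""
    n0 = initial_load(lattice.ms, C0)
    return rng.choice(lattice.ms, size=n0, replace=False)


def initialize_particles(
    lattice: SphericalLattice, C0: float, rng: np.random.Generator
) -> list[ParticleState]:
    """Place N0 = round(C0*MS) bonded particles on distinct random sites."""
    idx = sample_initial_sites(lattice, C0, rng)
    return [
        ParticleState(id=i, position=tuple(int(c) for c in lattice.sites[s]), bonded=True)
        for i, s in enumerate(idx)
    ]
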