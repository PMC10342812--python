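"""Realization averaging: the ensemble curves and the regime classifier.

All curves are recorded on one common time grid.  Positions on the grid
after a realization's terminal time contribute zero particles (the matrix
is empty), so ensemble means remain defined up to the last terminal time.
"""

from __future__ import annotations

import json
import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SimConfig, Trajectory, run_realization
from .lattice import build_spherical_lattice

__all__ = [
    "EnsembleResult",
    "run_ensemble",
    "free_fraction_curve",
    "classify_regime",
    "write_ensemble_csv",
    "read_ensemble_csv",
]


@dataclass
class EnsembleResult:
    """Realization-averaged release curves on a common time grid.

    ``release_frac`` is defined as ``1 - mean_N_frac`` so the two sum to one
    identically.  ``mean_free_frac`` is the mean of the per-realization
    ratio Nf/Nt over realizations that still contain particles; it is NaN
    once every realization has emptied.
    """

    grid: np.ndarray
    mean_N_frac: np.ndarray
    se_N_frac: np.ndarray
    mean_Nb_frac: np.ndarray
    se_Nb_frac: np.ndarray
    mean_Nf: np.ndarray
    se_Nf: np.ndarray
    mean_free_frac: np.ndarray
    se_free_frac: np.ndarray
    n_alive: np.ndarray
    n_realizations: int
    n0: int
    config: SimConfig | None
    t_finals: np.ndarray
    truncated: bool
    mean_release_times: np.ndarray | None = field(default=None, repr=False)

    @property
    def release_frac(self) -> np.ndarray:
        """Fractional release 1 - <Nt>/N0, the experimental release profile."""
        return 1.0 - self.mean_N_frac


def _build_grid(t_max: float, n_grid: int, kind: str) -> np.ndarray:
    """t = 0 plus ``n_grid`` points ending exactly at ``t_max``."""
    if kind == "linear":
        return np.linspace(0.0, t_max, n_grid + 1)
    lo = min(0.1, t_max / 1000.0)
    pts = np.geomspace(lo, t_max, n_grid)
    return np.concatenate([[0.0], pts])


def run_ensemble(config: SimConfig, progress: bool = False) -> EnsembleResult:
    """Simulate ``config.n_realizations`` independent realizations and average.

    Per-realization random streams are spawned deterministically from the
    master seed (``SeedSequence(seed).spawn``), so results are
    bit-reproducible for a given config.
    """
    lattice = build_spherical_lattice(config.R)
    children = np.random.SeedSequence(config.seed).spawn(config.n_realizations)
    trajectories: list[Trajectory] = []
    for i, child in enumerate(children):
        trajectories.append(run_realization(config, child, lattice=lattice))
        if progress and (i + 1) % 10 == 0:
            print(f"  realization {i + 1}/{config.n_realizations}", file=sys.stderr)
    return average_trajectories(trajectories, config)


def average_trajectories(trajectories: list[Trajectory], config: SimConfig | None = None) -> EnsembleResult:
    n_real = len(trajectories)
    n0 = trajectories[0].n0
    truncated = any(tr.truncated for tr in trajectories)
    if truncated:
        warnings.warn(
            "ensemble contains truncated realizations; averages cover the "
            "capped horizon only",
            stacklevel=2,
        )
    t_finals = np.array([tr.t_final for tr in trajectories])
    n_grid = config.n_grid if config is not None else 512
    kind = config.grid_kind if config is not None else "log"
    grid = _build_grid(float(t_finals.max()), n_grid, kind)

    N = np.empty((n_real, grid.shape[0]))
    Nb = np.empty_like(N)
    for i, tr in enumerate(trajectories):
        Ni, Nbi = tr.resample(grid)
        N[i] = Ni
        Nb[i] = Nbi
    Nf = N - Nb

    def _mean_se(a):
        m = a.mean(axis=0)
        se = a.std(axis=0, ddof=1) / np.sqrt(n_real) if n_real > 1 else np.full(a.shape[1], np.nan)
        return m, se

    mean_N_frac, se_N_frac = _mean_se(N / n0)
    mean_Nb_frac, se_Nb_frac = _mean_se(Nb / n0)
    mean_Nf, se_Nf = _mean_se(Nf)

    alive = N > 0
    n_alive = alive.sum(axis=0)
    ratio = np.where(alive, Nf, np.nan) / np.where(alive, N, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid tails
        mean_free_frac = np.nanmean(ratio, axis=0)
        sd = np.nanstd(ratio, axis=0, ddof=1)
    se_free_frac = np.where(n_alive > 1, sd / np.sqrt(np.maximum(n_alive, 1)), np.nan)

    mean_release_times = None
    if not truncated:
        mean_release_times = np.array([tr.mean_release_time() for tr in trajectories])

    return EnsembleResult(
        grid=grid,
        mean_N_frac=mean_N_frac,
        se_N_frac=se_N_frac,
        mean_Nb_frac=mean_Nb_frac,
        se_Nb_frac=se_Nb_frac,
        mean_Nf=mean_Nf,
        se_Nf=se_Nf,
        mean_free_frac=mean_free_frac,
        se_free_frac=se_free_frac,
        n_alive=n_alive,
        n_realizations=n_real,
        n0=n0,
        config=config,
        t_finals=t_finals,
        truncated=truncated,
        mean_release_times=mean_release_times,
    )


def free_fraction_curve(result: EnsembleResult) -> np.ndarray:
    """Mean detached fraction Nf/Nt over realizations still holding drug.

    NaN where no realization contains particles any more.
    """
    return result.mean_free_frac


def classify_regime(
    result: EnsembleResult,
    high: float = 0.99,
    low: float = 0.3,
    completion: float = 0.95,
) -> str:
    """Label the release as diffusion-controlled, reaction-controlled or crossover.

    The classifier inspects the free-drug fraction Nf/Nt over the part of
    the release before ``completion`` of the drug has left (the terminal
    tail, where only a handful of particles remain, is dominated by shot
    noise).  Diffusion-controlled: the curve reaches ``high`` and stays
    there for the rest of the inspected window (cleavage finishes early and
    escape limits release).  Reaction-controlled: the curve, transient peak
    included, never exceeds ``low`` (detachment limits release).  Anything
    else — the curve rises past ``low`` without settling at ``high`` — is
    the crossover regime.  Thresholds are heuristic stand-ins for the
    qualitative steady-state signatures and can be tuned.
    """
    if result.truncated:
        raise ValueError("cannot classify a truncated ensemble (release incomplete)")
    window = (result.release_frac <= completion) & np.isfinite(result.mean_free_frac)
    curve = result.mean_free_frac[window]
    if curve.size == 0:
        raise ValueError("no usable grid points before the completion cutoff")
    at_high = curve >= high
    if at_high.any() and at_high[np.argmax(at_high):].all():
        return "diffusion_controlled"
    if curve.max() <= low:
        return "reaction_controlled"
    return "crossover"


# ---------------------------------------------------------------------------
# persistence

_CSV_COLUMNS = [
    "time",
    "mean_N_frac",
    "se_N_frac",
    "mean_Nb_frac",
    "se_Nb_frac",
    "mean_Nf",
    "se_Nf",
    "mean_free_frac",
    "se_free_frac",
    "n_alive",
    "release_frac",
]


def write_ensemble_csv(result: EnsembleResult, csv_path, sidecar_path=None, extra: dict | None = None):
    """Write the curves as CSV plus a JSON sidecar (config echo, seeds, flags)."""
    df = pd.DataFrame(
        {
            "time": result.grid,
            "mean_N_frac": result.mean_N_frac,
            "se_N_frac": result.se_N_frac,
            "mean_Nb_frac": result.mean_Nb_frac,
            "se_Nb_frac": result.se_Nb_frac,
            "mean_Nf": result.mean_Nf,
            "se_Nf": result.se_Nf,
            "mean_free_frac": result.mean_free_frac,
            "se_free_frac": result.se_free_frac,
            "n_alive": result.n_alive,
            "release_frac": result.release_frac,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    if sidecar_path is not None:
        meta = {
            "config": result.config.to_dict() if result.config else None,
            "n_realizations": result.n_realizations,
            "n0": result.n0,
            "t_finals": result.t_finals.tolist(),
            "truncated": result.truncated,
        }
        if extra:
            meta.update(extra)
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_ensemble_csv(csv_path, sidecar_path=None) -> EnsembleResult:
    """Parse a written ensemble back; inverse of :func:`write_ensemble_csv`."""
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ensemble CSV missing columns: {missing}")
    config = None
    n_real, n0, t_finals, truncated = 0, 0, np.array([]), False
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        if meta.get("config"):
            config = SimConfig(**meta["config"])
        n_real = meta.get("n_realizations", 0)
        n0 = meta.get("n0", 0)
        t_finals = np.asarray(meta.get("t_finals", []))
        truncated = bool(meta.get("truncated", False))
    return EnsembleResult(
        grid=df["time"].to_numpy(),
        mean_N_frac=df["mean_N_frac"].to_numpy(),
        se_N_frac=df["se_N_frac"].to_numpy(),
        mean_Nb_frac=df["mean_Nb_frac"].to_numpy(),
        se_Nb_frac=df["se_Nb_frac"].to_numpy(),
        mean_Nf=df["mean_Nf"].to_numpy(),
        se_Nf=df["se_Nf"].to_numpy(),
        mean_free_frac=df["mean_free_frac"].to_numpy(),
        se_free_frac=df["se_free_frac"].to_numpy(),
        n_alive=df["n_alive"].to_numpy(),
        n_realizations=n_real,
        n0=n0,
        config=config,
        t_finals=t_finals,
        truncated=truncated,
    )
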