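"""Release-site placement, tonic/phasic cohort assignment and quantal events.

A release site is a dopaminergic bouton (~0.9 µm across) and occupies exactly
one 1-µm³ voxel.  Sites are placed uniformly at random without replacement
over the voxel lattice; release at each site is an independent Bernoulli
trial per time step with probability ``rate(t) * release_prob * dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .params import GridSpec, ParameterError, _round_half_up

__all__ = [
    "ReleaseSiteSet",
    "FiringSchedule",
    "place_sites",
    "assign_phasic_cohort",
    "nearest_neighbour_stats",
    "sample_events",
    "iter_events",
]

TONIC = "tonic"
PHASIC = "phasic"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ReleaseSiteSet:
    """Positions (voxel indices) and cohort labels of the release sites."""

    positions: np.ndarray          # (n, 3) int voxel indices
    cohort: np.ndarray             # (n,) str, "tonic" or "phasic"
    grid: GridSpec
    seed: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.intp).reshape(-1, 3)
        object.__setattr__(self, "positions", pos)
        coh = np.asarray(self.cohort)
        if coh.shape != (len(pos),):
            raise ParameterError("cohort must have one label per site")
        object.__setattr__(self, "cohort", coh)
        shape = np.asarray(self.grid.shape)
        if len(pos) and ((pos < 0) | (pos >= shape)).any():
            raise ParameterError("site positions outside the grid")
        flat = np.ravel_multi_index(pos.T, self.grid.shape) if len(pos) else np.array([], int)
        if len(np.unique(flat)) != len(pos):
            raise ParameterError("site positions must be distinct voxels")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def phasic_mask(self) -> np.ndarray:
        return self.cohort == PHASIC

    @property
    def n_phasic(self) -> int:
        return int(self.phasic_mask.sum())

    @property
    def centers(self) -> np.ndarray:
        """Site centre coordinates in µm (voxel centres)."""
        return (self.positions + 0.5) * self.grid.spacing

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"x": self.positions[:, 0], "y": self.positions[:, 1],
             "z": self.positions[:, 2], "cohort": self.cohort}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: GridSpec) -> "ReleaseSiteSet":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(), df["cohort"].to_numpy(), grid)


def place_sites(density: float, grid: GridSpec, rng_seed) -> ReleaseSiteSet:
    """Place ``round(density × volume)`` sites uniformly over distinct voxels.

    Deterministic for a given seed.  All sites start in the tonic cohort.
    """
    n = _round_half_up(density * grid.volume)
    if n < 1:
        raise ParameterError(f"density {density} yields no sites in {grid.volume} µm³")
    if n > grid.n_voxels:
        raise ParameterError("more sites than voxels: cannot place distinctly")
    rng = _as_rng(rng_seed)
    flat = rng.choice(grid.n_voxels, size=n, replace=False)
    positions = np.stack(np.unravel_index(flat, grid.shape), axis=1)
    seed = rng_seed if isinstance(rng_seed, int) else None
    return ReleaseSiteSet(positions, np.full(n, TONIC, dtype=object), grid, seed=seed)


def assign_phasic_cohort(sites: ReleaseSiteSet, fraction: float, rng_seed) -> ReleaseSiteSet:
    """Label a random subset of ``round(fraction × n)`` sites as phasic.

    Round-half-up on the cohort size (10% of 52 sites → 5 phasic).
    """
    if not 0 <= fraction <= 1:
        raise ParameterError("fraction must lie in [0, 1]")
    n_phasic = _round_half_up(fraction * len(sites))
    rng = _as_rng(rng_seed)
    chosen = rng.choice(len(sites), size=n_phasic, replace=False)
    cohort = np.full(len(sites), TONIC, dtype=object)
    cohort[chosen] = PHASIC
    return ReleaseSiteSet(sites.positions, cohort, sites.grid, seed=sites.seed)


def nearest_neighbour_stats(sites: ReleaseSiteSet) -> tuple[float, float]:
    """Mean and std (µm) of the nearest-neighbour distance between site centres.

    For a spatial Poisson process of intensity ρ the expected value is
    0.554·ρ^(−1/3); at ρ = 2e-4 /µm³ that is 9.5 µm, matching the measured
    inter-bouton spacing in area 10.
    """
    if len(sites) < 2:
        raise ParameterError("need at least two sites for nearest-neighbour stats")
    centers = sites.centers
    # minimum-image distances on a periodic grid, plain Euclidean otherwise
    boxsize = sites.grid.edge_lengths if sites.grid.boundary == "periodic" else None
    d, _ = cKDTree(centers, boxsize=boxsize).query(centers, k=2)
    nn = d[:, 1]
    return float(nn.mean()), float(nn.std())


@dataclass(frozen=True)
class FiringSchedule:
    """Piecewise-constant firing rate with a per-spike release probability."""

    segments: tuple[tuple[float, float, float], ...]  # (t_start, t_end, rate Hz)
    release_prob: float = 0.5

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(r)) for a, b, r in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ParameterError("schedule needs at least one segment")
        for (a, b, r) in segs:
            if b <= a:
                raise ParameterError(f"segment ({a}, {b}) is empty or reversed")
            if r < 0:
                raise ParameterError("firing rates must be non-negative")
        for (_, b0, _), (a1, _, _) in zip(segs, segs[1:]):
            if not np.isclose(a1, b0):
                raise ParameterError("segments must be contiguous and non-overlapping")
        if not 0 <= self.release_prob <= 1:
            raise ParameterError("release_prob must lie in [0, 1]")

    @classmethod
    def constant(cls, rate: float, t_end: float, p: float = 0.5,
                 t_start: float = 0.0) -> "FiringSchedule":
        return cls(((t_start, t_end, rate),), p)

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def rate_at(self, t: float) -> float:
        """Firing rate at time ``t`` (right-continuous; clamped outside)."""
        for a, b, r in self.segments:
            if a <= t < b:
                return r
        return self.segments[-1][2] if t >= self.t_end else self.segments[0][2]

    def max_rate(self) -> float:
        return max(r for _, _, r in self.segments)


def _event_probs(schedules: dict[str, FiringSchedule], t: float, dt: float) -> dict[str, float]:
    probs = {}
    for label, sched in schedules.items():
        p = sched.rate_at(t) * sched.release_prob * dt
        if p >= 1:
            raise ParameterError(
                f"rate × p × dt = {p:.3g} ≥ 1 for cohort {label!r}: dt too large "
                "for Bernoulli-per-step sampling"
            )
        probs[label] = p
    return probs


def iter_events(
    sites: ReleaseSiteSet,
    schedules: dict[str, FiringSchedule],
    dt: float,
    rng: np.random.Generator,
    n_steps: int,
    t_start: float = 0.0,
) -> Iterator[np.ndarray]:
    """Yield, per step, the indices of sites that release a vesicle.

    Each site is an independent Bernoulli trial with probability
    ``rate(t) · p · dt`` evaluated at the step's start time.
    """
    labels = np.asarray(sites.cohort)
    masks = {label: labels == label for label in schedules}
    unknown = set(np.unique(labels)) - set(schedules)
    if unknown:
        raise ParameterError(f"no schedule for cohort(s) {sorted(unknown)}")
    idx = {label: np.flatnonzero(m) for label, m in masks.items()}
    for step in range(n_steps):
        t = t_start + step * dt
        probs = _event_probs(schedules, t, dt)
        parts = []
        for label, p in probs.items():
            ids = idx[label]
            if p <= 0 or len(ids) == 0:
                continue
            hits = ids[rng.random(len(ids)) < p]
            if len(hits):
                parts.append(hits)
        yield np.concatenate(parts) if parts else np.empty(0, dtype=np.intp)


def sample_events(
    sites: ReleaseSiteSet,
    schedules: dict[str, FiringSchedule],
    dt: float,
    rng,
    n_steps: int,
    t_start: float = 0.0,
) -> list[np.ndarray]:
    """Materialized version of :func:`iter_events` (mostly for tests/analysis)."""
    return list(iter_events(sites, schedules, dt, _as_rng(rng), n_steps, t_start))
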