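"""Measurements on concentration fields and trajectories.

Everything the study reports is computed here: whole-volume statistics,
voxelwise difference maps between steady state and the post-burst field,
line samples through the volume, distance-resolved time courses around
phasic sites, equilibrium receptor occupancy, and the condition-by-condition
summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .engine import ConcentrationField, Trajectory
from .params import ParameterError
from .release import ReleaseSiteSet

__all__ = [
    "VolumeStats",
    "volume_stats",
    "difference_maps",
    "line_sample",
    "DistanceTrace",
    "distance_timeseries",
    "occupancy",
    "build_table1",
]

#: voxels with a baseline below this (nM) are excluded from relative-change means
MIN_BASELINE_NM = 0.01


class VolumeStats(NamedTuple):
    mean: float
    std: float
    min: float
    max: float


def volume_stats(field: ConcentrationField | np.ndarray) -> VolumeStats:
    """Mean/std/min/max over all voxels (1-µm³ resolution)."""
    v = field.values if isinstance(field, ConcentrationField) else np.asarray(field)
    if v.size == 0:
        raise ParameterError("empty field")
    return VolumeStats(float(v.mean()), float(v.std()), float(v.min()), float(v.max()))


def difference_maps(
    post: ConcentrationField | np.ndarray,
    pre: ConcentrationField | np.ndarray,
    min_baseline: float = MIN_BASELINE_NM,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise absolute (nM) and relative (%) change maps.

    ``abs = post − pre``; ``rel = 100·(post − pre)/pre``.  Voxels whose
    baseline is below ``min_baseline`` get NaN in the relative map (the
    ratio is degenerate there); use ``np.nanmean`` for summaries.
    """
    a = post.values if isinstance(post, ConcentrationField) else np.asarray(post, float)
    b = pre.values if isinstance(pre, ConcentrationField) else np.asarray(pre, float)
    if a.shape != b.shape:
        raise ParameterError("fields must share a grid")
    abs_map = a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_map = 100.0 * abs_map / b
    rel_map[b < min_baseline] = np.nan
    return abs_map, rel_map


def line_sample(
    field: ConcentrationField,
    start_voxel: Sequence[int],
    direction: Sequence[int],
    length: int | None = None,
) -> pd.DataFrame:
    """Concentration profile along a straight lattice line.

    ``direction`` is an integer step vector (axis-aligned or diagonal);
    samples are nearest-voxel values every step until the line leaves the
    grid (or after ``length`` samples).  Returns columns ``distance_um``
    and ``concentration_nM``.
    """
    start = np.asarray(start_voxel, dtype=int)
    step = np.asarray(direction, dtype=int)
    if start.shape != (3,) or step.shape != (3,) or not step.any():
        raise ParameterError("start_voxel and direction must be 3-vectors, direction non-zero")
    shape = np.asarray(field.grid.shape)
    if ((start < 0) | (start >= shape)).any():
        raise ParameterError("start voxel outside the grid")
    pts, dists = [], []
    pos = start.copy()
    step_len = float(np.linalg.norm(step)) * field.grid.spacing
    i = 0
    while ((pos >= 0) & (pos < shape)).all():
        pts.append(field.values[tuple(pos)])
        dists.append(i * step_len)
        i += 1
        if length is not None and i >= length:
            break
        pos = start + i * step
    if length is not None and i < length:
        raise ParameterError("line leaves the grid before the requested length")
    return pd.DataFrame({"distance_um": dists, "concentration_nM": pts})


@dataclass
class DistanceTrace:
    """Mean/std across phasic sites of the concentration at fixed radii."""

    times: np.ndarray                    # s
    radii: tuple[float, ...]             # µm
    mean: np.ndarray                     # (n_radii, n_times) nM
    std: np.ndarray                      # (n_radii, n_times) nM

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.radii):
            for j, t in enumerate(self.times):
                rows.append((t, r, self.mean[i, j], self.std[i, j]))
        return pd.DataFrame(rows, columns=["time_s", "radius_um", "mean_nM", "std_nM"])


def _shell_offsets(radius: float, spacing: float) -> np.ndarray:
    """Voxel offsets whose centre distance lies in [r−0.5, r+0.5) voxel units."""
    r_hi = radius / spacing + 0.5
    m = int(np.ceil(r_hi))
    ax = np.arange(-m, m + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt(dx**2 + dy**2 + dz**2) * spacing
    sel = (d >= radius - 0.5 * spacing) & (d < radius + 0.5 * spacing)
    return np.stack([dx[sel], dy[sel], dz[sel]], axis=1)


def distance_timeseries(
    trajectory: Trajectory,
    sites: ReleaseSiteSet,
    radii: Sequence[float] = (1.0, 2.0, 5.0),
    cohort: str = "phasic",
) -> DistanceTrace:
    """Shell-averaged concentration around each phasic site versus time.

    For each site of the requested cohort and each radius r the voxels whose
    centre lies within ±0.5 µm of r are averaged; the mean and standard
    deviation across sites are reported for every stored snapshot.
    """
    mask = sites.cohort == cohort
    if not mask.any():
        raise ParameterError(f"no sites in cohort {cohort!r}")
    centers = sites.positions[mask]
    grid = trajectory.snapshots[0].grid
    shape = np.asarray(grid.shape)
    periodic = grid.boundary == "periodic"

    per_radius_voxels = []
    for r in radii:
        offs = _shell_offsets(r, grid.spacing)
        vox_per_site = []
        for c in centers:
            v = c + offs
            if periodic:
                v = v % shape
            else:
                inside = ((v >= 0) & (v < shape)).all(axis=1)
                if not inside.all():
                    warnings.warn(
                        f"shell r={r} µm clipped at the boundary for site {tuple(c)}",
                        stacklevel=2,
                    )
                v = v[inside]
            vox_per_site.append(tuple(v.T))
        per_radius_voxels.append(vox_per_site)

    n_t = len(trajectory.snapshots)
    mean = np.empty((len(radii), n_t))
    std = np.empty((len(radii), n_t))
    for j, snap in enumerate(trajectory.snapshots):
        vals = snap.values
        for i, vox_per_site in enumerate(per_radius_voxels):
            site_means = np.array([vals[v].mean() for v in vox_per_site])
            mean[i, j] = site_means.mean()
            std[i, j] = site_means.std()
    return DistanceTrace(
        times=np.asarray(trajectory.snapshot_times, float),
        radii=tuple(float(r) for r in radii),
        mean=mean,
        std=std,
    )


def occupancy(field: ConcentrationField | np.ndarray, kd: float) -> np.ndarray:
    """Equilibrium receptor binding probability C/(C + Kd) per voxel.

    With the high-affinity Kd (~10 nM) the tonic baseline of ~26 nM occupies
    about 70% of receptors everywhere; with the low-affinity Kd (µM range)
    occupancy stays below 2%, which is why only the high-affinity state
    senses cortical dopamine levels.
    """
    if kd <= 0:
        raise ParameterError("Kd must be positive")
    v = field.values if isinstance(field, ConcentrationField) else np.asarray(field, float)
    return v / (v + kd)


def build_table1(
    params=None,
    n_seeds: int = 10,
    branch_reps: int = 10,
    base_seed: int = 0,
    conditions=None,
) -> pd.DataFrame:
    """Simulate every protocol condition and aggregate the summary table.

    Thin wrapper around :func:`dopadiff.reproduce.run_phasic_study` using
    the standard condition grid (15/26/0 Hz × 10/25/50% at normal density
    plus the depleted-density variants at 15 Hz).
    """
    from .params import default_params
    from .protocols import table1_conditions
    from .reproduce import run_phasic_study

    params = default_params() if params is None else params
    conditions = table1_conditions() if conditions is None else conditions
    study = run_phasic_study(params, conditions, n_seeds=n_seeds,
                             branch_reps=branch_reps, base_seed=base_seed)
    return study.table
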