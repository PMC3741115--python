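"""Ensemble studies over placement seeds: the machinery behind the headline
numbers (steady-state level, phasic-change table, depleted-density condition,
reuptake-block ramp, single-site profile check).

Every condition shares the identical 4-s tonic run-in, so for each placement
seed the run-in is simulated once and each phasic condition branches from
the stored steady-state field with fresh event randomness.  Branch
replicates per seed average away the Bernoulli event noise of the short
phasic window, which dominates the Monte-Carlo error of the change scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .analysis import MIN_BASELINE_NM, difference_maps, volume_stats
from .engine import ConcentrationField, blocked_uptake_variant, run_protocol
from .params import SimulationParams
from .protocols import ProtocolSpec, build_schedules, table1_conditions
from .release import FiringSchedule, assign_phasic_cohort, place_sites

__all__ = [
    "StudyResult",
    "run_phasic_study",
    "RampResult",
    "run_blocked_ramp",
    "single_site_profile",
]


def _rng(ss: np.random.SeedSequence) -> np.random.Generator:
    return np.random.default_rng(ss)


@dataclass
class StudyResult:
    """Pooled summary table plus per-seed traces for uncertainty estimates."""

    table: pd.DataFrame
    baselines: pd.DataFrame          # columns: density, seed, mean/std/min/max (nM)
    per_condition: dict[str, dict]   # name -> {"abs_mean": (n_seeds, reps), ...}
    n_seeds: int
    branch_reps: int

    def baseline_mean(self, density: float) -> float:
        """Seed-averaged steady-state volume mean (nM) at one site density."""
        sel = self.baselines[np.isclose(self.baselines["density"], density)]
        return float(sel["mean"].mean())

    def seed_means(self, name: str, key: str = "abs_mean") -> np.ndarray:
        """Per-seed means (averaged over branch replicates) of one score."""
        return self.per_condition[name][key].mean(axis=1)

    def sem(self, name: str, key: str = "abs_mean") -> float:
        """Standard error across placement seeds of the ensemble mean."""
        m = self.seed_means(name, key)
        return float(m.std(ddof=1) / math.sqrt(len(m)))


class _Pool:
    """Running pooled statistics over voxels of many branch fields."""

    def __init__(self) -> None:
        self.n = 0
        self.s = 0.0
        self.ss = 0.0
        self.lo = math.inf
        self.hi = -math.inf

    def add(self, arr: np.ndarray) -> None:
        a = arr[np.isfinite(arr)] if np.isnan(arr).any() else arr
        self.n += a.size
        self.s += float(a.sum())
        self.ss += float((a * a).sum())
        self.lo = min(self.lo, float(a.min()))
        self.hi = max(self.hi, float(a.max()))

    def stats(self) -> tuple[float, float, float, float]:
        mean = self.s / self.n
        var = max(self.ss / self.n - mean * mean, 0.0)
        return mean, math.sqrt(var), self.lo, self.hi


def run_phasic_study(
    params: SimulationParams,
    conditions: list[ProtocolSpec] | None = None,
    n_seeds: int = 10,
    branch_reps: int = 10,
    base_seed: int = 0,
    tonic_duration: float = 4.0,
) -> StudyResult:
    """Simulate the condition grid and pool the summary statistics.

    For every placement seed and site density: run the tonic prefix to
    steady state once, then branch ``branch_reps`` times per condition with
    independently drawn phasic cohorts and release events.  Scores per
    branch are the volume statistics of the post-window field, of the
    absolute difference map and of the relative (percent) difference map.
    """
    conditions = table1_conditions() if conditions is None else conditions
    densities: list[float] = []
    for c in conditions:
        if not any(np.isclose(c.site_density, d) for d in densities):
            densities.append(c.site_density)

    master = np.random.SeedSequence(base_seed)
    density_ss = master.spawn(len(densities))

    base_rows = []
    per_condition: dict[str, dict] = {
        c.name: {k: np.empty((n_seeds, branch_reps)) for k in
                 ("value_mean", "abs_mean", "rel_mean")}
        for c in conditions
    }
    pools = {c.name: {"value": _Pool(), "abs": _Pool(), "rel": _Pool()} for c in conditions}

    for d_idx, density in enumerate(densities):
        conds_here = [c for c in conditions if np.isclose(c.site_density, density)]
        run_params = params.with_(site_density=density)
        seed_ss = density_ss[d_idx].spawn(n_seeds)
        for s_idx in range(n_seeds):
            place_ss, tonic_ss, branch_root = seed_ss[s_idx].spawn(3)
            sites = place_sites(density, run_params.grid, _rng(place_ss))
            tonic_sched = {"tonic": FiringSchedule.constant(
                run_params.f_tonic, tonic_duration, run_params.release_prob)}
            traj = run_protocol(run_params, sites, tonic_sched,
                                rng_seed=_rng(tonic_ss), t_end=tonic_duration,
                                record_traces=False)
            f0 = traj.final
            vs = volume_stats(f0)
            base_rows.append((density, s_idx, *vs))

            branch_ss = iter(branch_root.spawn(len(conds_here) * branch_reps))
            for cond in conds_here:
                t1 = tonic_duration + cond.phasic_duration
                for rep in range(branch_reps):
                    b = next(branch_ss)
                    cohort_ss, events_ss = b.spawn(2)
                    branched = assign_phasic_cohort(
                        sites, cond.phasic_fraction, _rng(cohort_ss))
                    scheds = {
                        "tonic": FiringSchedule.constant(
                            run_params.f_tonic, t1, run_params.release_prob,
                            t_start=tonic_duration),
                        "phasic": FiringSchedule.constant(
                            cond.phasic_rate, t1, run_params.release_prob,
                            t_start=tonic_duration),
                    }
                    btraj = run_protocol(run_params, branched, scheds,
                                         rng_seed=_rng(events_ss), t_end=t1,
                                         initial=f0, record_traces=False)
                    post = btraj.final
                    abs_map, rel_map = difference_maps(post, f0,
                                                       min_baseline=MIN_BASELINE_NM)
                    rec = per_condition[cond.name]
                    rec["value_mean"][s_idx, rep] = float(post.values.mean())
                    rec["abs_mean"][s_idx, rep] = float(abs_map.mean())
                    rec["rel_mean"][s_idx, rep] = float(np.nanmean(rel_map))
                    pools[cond.name]["value"].add(post.values)
                    pools[cond.name]["abs"].add(abs_map)
                    pools[cond.name]["rel"].add(rel_map)

    rows = []
    for cond in conditions:
        p = pools[cond.name]
        v = p["value"].stats()
        a = p["abs"].stats()
        r = p["rel"].stats()
        rows.append({
            "condition": cond.name,
            "density": cond.site_density,
            "phasic_rate_hz": cond.phasic_rate,
            "phasic_fraction": cond.phasic_fraction,
            "n_branches": n_seeds * branch_reps,
            "value_mean": v[0], "value_std": v[1], "value_min": v[2], "value_max": v[3],
            "absdiff_mean": a[0], "absdiff_std": a[1], "absdiff_min": a[2], "absdiff_max": a[3],
            "reldiff_mean": r[0], "reldiff_std": r[1], "reldiff_min": r[2], "reldiff_max": r[3],
        })
    baselines = pd.DataFrame(base_rows,
                             columns=["density", "seed", "mean", "std", "min", "max"])
    return StudyResult(pd.DataFrame(rows), baselines, per_condition,
                       n_seeds, branch_reps)


@dataclass
class RampResult:
    """Fit of the linear accumulation ramp after a complete reuptake block."""

    slopes: np.ndarray       # nM/s per seed
    r_squared: np.ndarray    # per seed, post-switch linear fit
    times: np.ndarray        # s (post-switch)
    mean_trace: np.ndarray   # nM, averaged across seeds
    block_time: float

    @property
    def slope(self) -> float:
        return float(self.slopes.mean())

    @property
    def slope_sem(self) -> float:
        return float(self.slopes.std(ddof=1) / math.sqrt(len(self.slopes)))

    def time_to(self, target_nm: float, baseline_nm: float) -> float:
        return (target_nm - baseline_nm) / self.slope


def run_blocked_ramp(
    params: SimulationParams,
    n_seeds: int = 10,
    base_seed: int = 0,
    block_time: float = 1.0,
    t_end: float = 3.5,
) -> RampResult:
    """Protocol E: tonic firing throughout, reuptake set to zero at ``block_time``.

    Fits a line to each seed's post-switch volume-mean trace.
    """
    run_params = blocked_uptake_variant(params, block_time)
    master = np.random.SeedSequence(base_seed)
    seed_ss = master.spawn(n_seeds)
    slopes, r2s, traces = [], [], []
    times = None
    for s_idx in range(n_seeds):
        place_ss, events_ss = seed_ss[s_idx].spawn(2)
        sites = place_sites(run_params.site_density, run_params.grid, _rng(place_ss))
        sched = {"tonic": FiringSchedule.constant(
            run_params.f_tonic, t_end, run_params.release_prob)}
        traj = run_protocol(run_params, sites, sched, rng_seed=_rng(events_ss),
                            t_end=t_end)
        post = traj.trace_time >= block_time
        t = traj.trace_time[post]
        y = traj.trace_mean[post]
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        r2 = 1.0 - float(resid.var()) / float(y.var())
        slopes.append(slope)
        r2s.append(r2)
        traces.append(y)
        times = t
    return RampResult(np.asarray(slopes), np.asarray(r2s), times,
                      np.mean(traces, axis=0), block_time)


def single_site_profile(
    params: SimulationParams,
    t_end: float = 3.0,
    radii=tuple(range(1, 13)),
) -> pd.DataFrame:
    """Steady-state radial profile of one continuously releasing site.

    The site releases deterministically at its mean rate f·p·Q per second
    (the expected field of the stochastic process, by linearity).  The
    simulated shell averages are compared with the continuum screened
    point-source solution

        C(r) = f·p·Q / (4π·D_eff·α·r) · exp(−r/λ),   λ = sqrt(D_eff/k),

    summed over periodic images.  Columns: radius_um, simulated_nM,
    analytic_nM, ratio.
    """
    from .analysis import _shell_offsets
    from .engine import _KERNELS
    from .params import LITRE_PER_UM3

    grid = params.grid
    c = np.zeros(grid.shape)
    work = np.empty_like(c)
    center = tuple(n // 2 for n in grid.shape)
    dt = params.dt
    per_step = (params.f_tonic * params.release_prob * dt) * params.quantal_increment_nm
    kernel = _KERNELS[grid.boundary]
    ddt = params.d_eff * dt / grid.spacing**2
    g = math.exp(-params.uptake_rate * dt)
    for _ in range(int(round(t_end / dt))):
        c[center] += per_step
        kernel(c, work, ddt, g)
        c, work = work, c

    lam = params.uptake_length
    pref = (params.f_tonic * params.release_prob * params.quantal_moles
            / (4.0 * math.pi * params.d_eff * params.alpha * LITRE_PER_UM3) * 1e9)
    edges = np.asarray(grid.edge_lengths)

    def analytic(points_um: np.ndarray) -> np.ndarray:
        total = np.zeros(len(points_um))
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    if grid.boundary != "periodic" and (ox, oy, oz) != (0, 0, 0):
                        continue
                    shift = points_um + np.array([ox, oy, oz]) * edges
                    r = np.linalg.norm(shift, axis=1)
                    total += pref / r * np.exp(-r / lam)
        return total

    rows = []
    for r in radii:
        offs = _shell_offsets(r, grid.spacing)
        vox = (np.asarray(center) + offs) % np.asarray(grid.shape)
        sim = float(c[tuple(vox.T)].mean())
        ana = float(analytic(offs * grid.spacing).mean())
        rows.append({"radius_um": float(r), "simulated_nM": sim,
                     "analytic_nM": ana, "ratio": sim / ana})
    return pd.DataFrame(rows)
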