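import math

import numpy as np
import pytest

import dopadiff as dd
from dopadiff.engine import ConcentrationField
from dopadiff.params import ParameterError, StabilityError
from dopadiff.release import FiringSchedule

from conftest import roll_laplacian


def field_of(values, grid, t=0.0):
    return ConcentrationField(np.asarray(values, float), t, grid)


class TestDiffuseUptakeStep:
    def test_uniform_field_without_uptake_is_invariant(self, small_params):
        p = small_params.with_(uptake_rate=0.0)
        f = field_of(np.full(p.grid.shape, 37.0), p.grid)
        out = dd.diffuse_uptake_step(f, p)
        np.testing.assert_allclose(out.values, 37.0, rtol=1e-13)

    def test_uptake_only_decay_matches_exponential(self, small_params):
        # uniform 100 nM for 1 s at k = 1.5/s → 100·e^(−1.5) = 22.313 nM
        p = small_params
        f = field_of(np.full(p.grid.shape, 100.0), p.grid)
        n = int(round(1.0 / p.dt))
        for _ in range(n):
            f = dd.diffuse_uptake_step(f, p)
        expected = 100.0 * math.exp(-p.uptake_rate * 1.0)
        np.testing.assert_allclose(f.values, expected, rtol=1e-6)
        assert f.time == pytest.approx(1.0)

    def test_mass_conserved_without_uptake(self, small_params):
        p = small_params.with_(uptake_rate=0.0)
        vals = np.zeros(p.grid.shape)
        vals[3, 4, 5] = 1000.0
        f = field_of(vals, p.grid)
        total0 = f.values.sum()
        for _ in range(400):
            f = dd.diffuse_uptake_step(f, p)
        assert f.values.sum() == pytest.approx(total0, rel=1e-9)
        assert (f.values >= 0).all()

    def test_reflecting_boundary_also_conserves(self):
        grid = dd.GridSpec(shape=(12, 12, 12), boundary="reflecting")
        p = dd.default_params(uptake_rate=0.0, grid=grid)
        vals = np.zeros(grid.shape)
        vals[0, 0, 0] = 500.0  # corner: worst case for flux leakage
        f = field_of(vals, grid)
        for _ in range(300):
            f = dd.diffuse_uptake_step(f, p)
        assert f.values.sum() == pytest.approx(500.0, rel=1e-9)

    def test_kernel_matches_independent_roll_stencil(self, small_params):
        p = small_params
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 50, p.grid.shape)
        f = field_of(vals.copy(), p.grid)
        out = dd.diffuse_uptake_step(f, p)
        ddt = p.d_eff * p.dt / p.grid.spacing**2
        expected = math.exp(-p.uptake_rate * p.dt) * (vals + ddt * roll_laplacian(vals))
        np.testing.assert_allclose(out.values, expected, rtol=1e-12, atol=1e-12)

    def test_refuses_unstable_dt(self, small_params):
        f = ConcentrationField.zeros(small_params.grid)
        with pytest.raises(StabilityError):
            dd.diffuse_uptake_step(f, small_params, dt=1e-3)


class TestInjectQuanta:
    def test_single_event_increment(self, small_params):
        f = ConcentrationField.zeros(small_params.grid)
        out = dd.inject_quanta(f, [(2, 3, 4)], small_params)
        assert out.values[2, 3, 4] == pytest.approx(7.065e4, rel=1e-3)
        assert out.values.sum() == pytest.approx(out.values[2, 3, 4])

    def test_empty_event_list_noop(self, small_params):
        f = ConcentrationField.zeros(small_params.grid)
        out = dd.inject_quanta(f, np.empty((0, 3), int), small_params)
        assert not out.values.any()

    def test_repeated_voxel_accumulates(self, small_params):
        f = ConcentrationField.zeros(small_params.grid)
        out = dd.inject_quanta(f, [(1, 1, 1), (1, 1, 1)], small_params)
        assert out.values[1, 1, 1] == pytest.approx(1.413e5, rel=1e-3)

    def test_out_of_grid_rejected(self, small_params):
        f = ConcentrationField.zeros(small_params.grid)
        with pytest.raises(ParameterError):
            dd.inject_quanta(f, [(99, 0, 0)], small_params)


class TestRunProtocol:
    def _tonic(self, params, t_end, seed, **kw):
        sites = dd.place_sites(params.site_density, params.grid, seed)
        sched = {"tonic": FiringSchedule.constant(
            params.f_tonic, t_end, params.release_prob)}
        return dd.run_protocol(params, sites, sched, rng_seed=seed + 1,
                               t_end=t_end, **kw)

    def test_zero_sites_rate_zero_trajectory(self, small_params):
        sites = dd.place_sites(1 / small_params.grid.volume, small_params.grid, 0)
        sched = {"tonic": FiringSchedule.constant(0.0, 0.5, 0.5)}
        traj = dd.run_protocol(small_params, sites, sched, rng_seed=0, t_end=0.5)
        assert not traj.final.values.any()
        assert traj.trace_mean[-1] == 0.0

    def test_mass_ledger_closes(self, params):
        traj = self._tonic(params, 0.5, seed=3)
        err = traj.mass_balance_error(params.alpha, params.grid.voxel_volume)
        assert err < 1e-9

    def test_determinism_per_seed(self, small_params):
        a = self._tonic(small_params, 0.3, seed=5)
        b = self._tonic(small_params, 0.3, seed=5)
        assert np.array_equal(a.final.values, b.final.values)
        assert np.array_equal(a.trace_mean, b.trace_mean)

    def test_linearity_in_quantal_size(self, small_params):
        # doubling Q doubles every concentration exactly (same event stream)
        p2 = small_params.with_(vesicle_conc=0.5, quantal_moles=2 * 1.625e-20)
        a = self._tonic(small_params, 0.3, seed=9)
        b = self._tonic(p2, 0.3, seed=9)
        assert np.array_equal(b.final.values, 2.0 * a.final.values)

    def test_snapshots_at_requested_times(self, small_params):
        traj = self._tonic(small_params, 0.2, seed=1,
                           snapshot_times=(0.1, 0.2))
        assert list(traj.snapshot_times) == [0.1, 0.2]
        snap = traj.snapshot_at(0.2)
        assert np.array_equal(snap.values, traj.final.values)
        with pytest.raises(KeyError):
            traj.snapshot_at(0.15)

    def test_non_negative_everywhere(self, small_params):
        traj = self._tonic(small_params, 0.5, seed=13)
        assert (traj.final.values >= 0).all()


class TestBlockedUptake:
    def test_variant_sets_switch_time(self, params):
        blocked = dd.blocked_uptake_variant(params, 1.0)
        assert blocked.uptake_block_time == 1.0
        assert dd.blocked_uptake_variant(params, None).uptake_block_time is None

    def test_mean_ramps_linearly_after_switch(self, ramp):
        assert (ramp.r_squared > 0.99).all()

    def test_never_switched_reaches_ordinary_steady_state(self, small_params):
        # on the small grid the realized density is one site per 16-µm cube
        sites = dd.place_sites(1 / small_params.grid.volume, small_params.grid, 2)
        sched = {"tonic": FiringSchedule.constant(5.6, 4.0, 0.5)}
        traj = dd.run_protocol(small_params, sites, sched, rng_seed=4, t_end=4.0)
        from dopadiff.meanfield import MeanFieldInputs, steady_state_mean

        mf = MeanFieldInputs.from_params(
            small_params.with_(site_density=1 / small_params.grid.volume))
        expected = steady_state_mean(mf)
        # single site, short run: generous Monte-Carlo band (±40%)
        assert traj.trace_mean[-1] == pytest.approx(expected, rel=0.4)


class TestSingleSiteProfile:
    def test_matches_screened_point_source(self, site_profile):
        # continuum Green's function S/(4πDαr)·e^(−r/λ) within 15% at 2–10 µm
        sel = site_profile[(site_profile.radius_um >= 2)
                           & (site_profile.radius_um <= 10)]
        assert ((sel.ratio > 0.85) & (sel.ratio < 1.15)).all()

    def test_profile_decreases_with_distance(self, site_profile):
        assert site_profile.simulated_nM.is_monotonic_decreasing
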