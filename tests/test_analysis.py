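import numpy as np
import pytest

import dopadiff as dd
from dopadiff.analysis import distance_timeseries
from dopadiff.engine import ConcentrationField, Trajectory
from dopadiff.params import ParameterError
from dopadiff.release import ReleaseSiteSet


@pytest.fixture(scope="module")
def grid():
    return dd.GridSpec(shape=(32, 32, 32))


def const_field(grid, value, t=0.0):
    return ConcentrationField(np.full(grid.shape, float(value)), t, grid)


class TestVolumeStats:
    def test_constant_field(self, grid):
        assert dd.volume_stats(const_field(grid, 5.0)) == (5.0, 0.0, 5.0, 5.0)

    def test_single_hot_voxel(self, grid):
        f = const_field(grid, 0.0)
        f.values[1, 2, 3] = 10.0
        stats = dd.volume_stats(f)
        assert stats.max == 10.0 and stats.min == 0.0
        assert stats.mean == pytest.approx(10.0 / grid.n_voxels)


class TestDifferenceMaps:
    def test_identical_fields_zero_maps(self, grid):
        f = const_field(grid, 20.0)
        abs_map, rel_map = dd.difference_maps(f, f)
        assert not abs_map.any()
        assert not np.nanmax(np.abs(rel_map)) > 0

    def test_doubling_gives_plus_hundred_percent(self, grid):
        pre = const_field(grid, 13.0)
        post = const_field(grid, 26.0, t=1.0)
        abs_map, rel_map = dd.difference_maps(post, pre)
        np.testing.assert_allclose(abs_map, 13.0)
        np.testing.assert_allclose(rel_map, 100.0)

    def test_zero_baseline_voxels_flagged(self, grid):
        pre = const_field(grid, 20.0)
        pre.values[0, 0, 0] = 0.0
        post = const_field(grid, 25.0, t=1.0)
        _, rel_map = dd.difference_maps(post, pre)
        assert np.isnan(rel_map[0, 0, 0])
        assert np.nanmean(rel_map) == pytest.approx(25.0)

    def test_relative_map_scale_invariant(self, grid):
        rng = np.random.default_rng(1)
        pre = ConcentrationField(rng.uniform(5, 50, grid.shape), 0.0, grid)
        post = ConcentrationField(pre.values * rng.uniform(1, 2, grid.shape),
                                  1.0, grid)
        _, rel1 = dd.difference_maps(post, pre)
        scaled_pre = ConcentrationField(7.0 * pre.values, 0.0, grid)
        scaled_post = ConcentrationField(7.0 * post.values, 1.0, grid)
        _, rel2 = dd.difference_maps(scaled_post, scaled_pre)
        # atol absorbs cancellation round-off where post ≈ pre
        np.testing.assert_allclose(rel1, rel2, rtol=1e-9, atol=1e-9)


class TestLineSample:
    def test_constant_profile(self, grid):
        df = dd.line_sample(const_field(grid, 8.0), (0, 5, 5), (1, 0, 0))
        assert len(df) == grid.shape[0]
        assert (df.concentration_nM == 8.0).all()
        np.testing.assert_allclose(np.diff(df.distance_um), 1.0)

    def test_diagonal_step_length(self, grid):
        df = dd.line_sample(const_field(grid, 0.0), (0, 0, 0), (1, 1, 0))
        assert df.distance_um.iloc[1] == pytest.approx(np.sqrt(2))
        assert (df.concentration_nM == 0.0).all()

    def test_peak_at_release_site(self, grid):
        # radially decreasing bump centred on a voxel → maximum on the line
        f = const_field(grid, 0.0)
        center = np.array([16, 16, 16])
        ii = np.indices(grid.shape)
        r2 = sum((ii[k] - center[k]) ** 2 for k in range(3))
        f.values[:] = 100.0 * np.exp(-r2 / 18.0)
        df = dd.line_sample(f, (16, 0, 16), (0, 1, 0))
        assert df.concentration_nM.idxmax() == 16

    def test_out_of_grid_rejected(self, grid):
        with pytest.raises(ParameterError):
            dd.line_sample(const_field(grid, 0.0), (40, 0, 0), (1, 0, 0))
        with pytest.raises(ParameterError):
            dd.line_sample(const_field(grid, 0.0), (0, 0, 0), (1, 0, 0), length=64)


def _trajectory_of(fields, times, grid):
    e = np.empty(0)
    return Trajectory(np.asarray(times, float), fields, e, e, e, e,
                      final=fields[-1])


class TestDistanceTimeseries:
    def _sites(self, grid, positions, cohorts):
        return ReleaseSiteSet(np.asarray(positions),
                              np.asarray(cohorts, dtype=object), grid)

    def test_uniform_field_all_radii_equal(self, grid):
        sites = self._sites(grid, [[16, 16, 16], [4, 4, 4]], ["phasic", "tonic"])
        traj = _trajectory_of([const_field(grid, 12.0)], [0.0], grid)
        trace = distance_timeseries(traj, sites, radii=(1, 2, 5))
        np.testing.assert_allclose(trace.mean, 12.0)
        np.testing.assert_allclose(trace.std, 0.0)

    def test_point_source_profile_orders_radii(self, grid):
        sites = self._sites(grid, [[16, 16, 16]], ["phasic"])
        f = const_field(grid, 0.0)
        ii = np.indices(grid.shape)
        r = np.sqrt(sum((ii[k] - 16.0) ** 2 for k in range(3)))
        f.values[:] = 100.0 / np.maximum(r, 0.5)
        trace = distance_timeseries(_trajectory_of([f], [0.0], grid), sites)
        c1, c2, c5 = trace.mean[:, 0]
        assert c1 > c2 > c5

    def test_no_phasic_sites_rejected(self, grid):
        sites = self._sites(grid, [[1, 1, 1]], ["tonic"])
        traj = _trajectory_of([const_field(grid, 1.0)], [0.0], grid)
        with pytest.raises(ParameterError):
            distance_timeseries(traj, sites)

    def test_boundary_shell_clipped_with_warning(self):
        grid = dd.GridSpec(shape=(16, 16, 16), boundary="reflecting")
        sites = self._sites(grid, [[0, 0, 0]], ["phasic"])
        traj = _trajectory_of([const_field(grid, 3.0)], [0.0], grid)
        with pytest.warns(UserWarning, match="clipped"):
            trace = distance_timeseries(traj, sites, radii=(5,))
        np.testing.assert_allclose(trace.mean, 3.0)


class TestOccupancy:
    @pytest.mark.parametrize("conc, kd, expected", [
        (10.0, 10.0, 0.5),          # half-saturation
        (26.2, 10.0, 0.724),        # tonic baseline on high-affinity state
        (26.2, 1500.0, 0.017),      # low-affinity state barely engaged
    ])
    def test_equilibrium_binding(self, grid, conc, kd, expected):
        occ = dd.occupancy(const_field(grid, conc), kd)
        assert occ[0, 0, 0] == pytest.approx(expected, abs=5e-4)

    def test_monotone_and_bounded(self, grid):
        c = np.linspace(0, 1e4, 200)
        occ = dd.occupancy(c, 10.0)
        assert occ[0] == 0.0
        assert (np.diff(occ) > 0).all()
        assert (occ < 1.0).all()

    def test_rejects_bad_kd(self, grid):
        with pytest.raises(ParameterError):
            dd.occupancy(const_field(grid, 1.0), 0.0)
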