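import numpy as np
import pytest

from disolv.analysis import (block_average, coordination_number,
                             cylindrical_ndp, occupancy_grid_3d,
                             radial_distribution, self_diffusion_einstein,
                             shell_occupancy_residence)
from disolv.units import NM2_PER_PS_TO_M2_PER_S

BOX = (4.0, 4.0, 4.0)


def _uniform_frames(rng, n_frames=60, n_particles=120, box=BOX):
    return rng.random((n_frames, n_particles, 3)) * np.asarray(box)


class TestRDF:
    def test_ideal_gas_is_flat(self, rng, traj_factory):
        frames = _uniform_frames(rng, n_frames=120)
        traj = traj_factory(frames, ["Na"] * 60 + ["Cl"] * 60, BOX)
        rdf = radial_distribution(traj, "Na", "Cl", bin_width=0.05)
        sampled = rdf.r > 0.15  # innermost bins have near-zero shell volume
        assert np.all(np.abs(rdf.g[sampled] - 1.0) < 0.35)
        assert np.abs(np.mean(rdf.g[sampled]) - 1.0) < 0.02

    def test_two_fixed_particles_single_bin(self, traj_factory):
        traj = traj_factory([[[1, 1, 1], [1.733, 1, 1]]], ["Na", "Cl"], BOX)
        rdf = radial_distribution(traj, "Na", "Cl", bin_width=0.01)
        nz = np.flatnonzero(rdf.g)
        assert len(nz) == 1
        assert rdf.r[nz[0]] == pytest.approx(0.735)

    def test_matches_brute_force_histogram(self, rng, traj_factory):
        frames = _uniform_frames(rng, n_frames=4, n_particles=40)
        species = ["Na"] * 20 + ["Cl"] * 20
        traj = traj_factory(frames, species, BOX)
        bw = 0.02
        rdf = radial_distribution(traj, "Na", "Na", bin_width=bw)
        # independent O(N^2) histogram over ordered same-species pairs
        hist = np.zeros_like(rdf.g)
        for frame in frames:
            pos = frame[:20]
            for i in range(20):
                for j in range(20):
                    if i == j:
                        continue
                    d = pos[j] - pos[i]
                    d -= np.asarray(BOX) * np.floor(d / np.asarray(BOX) + 0.5)
                    r = np.linalg.norm(d)
                    k = int(r / bw)
                    if k < len(hist):
                        hist[k] += 1
        edges = np.arange(len(hist) + 1) * bw
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = hist / (4 * 20 * (19 / 64.0) * shell)
        np.testing.assert_allclose(rdf.g, expected, atol=1e-12)

    def test_empty_selection_rejected(self, traj_factory):
        traj = traj_factory([[[1, 1, 1]]], ["Na"], BOX)
        with pytest.raises(ValueError):
            radial_distribution(traj, "Na", "K")

    def test_relabeling_invariance(self, rng, traj_factory):
        frames = _uniform_frames(rng, n_frames=3, n_particles=30)
        species = ["Na"] * 30
        traj = traj_factory(frames, species, BOX)
        perm = rng.permutation(30)
        traj2 = traj_factory(frames[:, perm, :], species, BOX)
        a = radial_distribution(traj, "Na", "Na", bin_width=0.05)
        b = radial_distribution(traj2, "Na", "Na", bin_width=0.05)
        np.testing.assert_allclose(a.g, b.g, atol=1e-12)


class TestCoordinationNumber:
    def test_uniform_g_gives_ideal_volume_integral(self, traj_factory, rng):
        from disolv.analysis import RDFResult
        r = np.arange(0.005, 1.5, 0.01)
        rdf = RDFResult(r=r, g=np.ones_like(r), bin_width=0.01, n_frames=1,
                        n_a=1, n_b=1, rho=0.8)
        n = coordination_number(rdf)
        expected = 4 / 3 * np.pi * 0.8 * (r ** 3 - r[0] ** 3)
        np.testing.assert_allclose(n, expected, rtol=5e-3, atol=2e-5)
        assert np.all(np.diff(n) >= 0)

    def test_zero_g_gives_zero(self):
        from disolv.analysis import RDFResult
        r = np.arange(0.005, 1.0, 0.01)
        rdf = RDFResult(r=r, g=np.zeros_like(r), bin_width=0.01, n_frames=1,
                        n_a=1, n_b=1, rho=0.8)
        np.testing.assert_array_equal(coordination_number(rdf), 0.0)

    def test_matches_independent_quadrature(self, rng):
        from disolv.analysis import RDFResult
        r = np.arange(0.005, 1.0, 0.01)
        g = rng.random(len(r)) * 2
        rdf = RDFResult(r=r, g=g, bin_width=0.01, n_frames=1, n_a=1, n_b=1,
                        rho=0.6)
        got = coordination_number(rdf)
        integrand = 4 * np.pi * 0.6 * g * r ** 2
        expected = np.concatenate(
            [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1])
                              * np.diff(r))])
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestNDP:
    def test_uniform_system_is_flat(self, rng, traj_factory):
        frames = _uniform_frames(rng, n_frames=100, n_particles=200)
        traj = traj_factory(frames, ["Na"] * 200, BOX)
        ndp = cylindrical_ndp(traj, (2.0, 2.0), "Na", bin_width=0.1)
        assert np.all(np.abs(ndp.ndp - 1.0) < 0.25)

    def test_single_radius_single_bin(self, traj_factory):
        pos = [[[2.5, 2.0, 1.0], [1.5, 2.0, 3.0]]]
        traj = traj_factory(pos, ["Na", "Na"], BOX, times=[0.0])
        ndp = cylindrical_ndp(traj, (2.0, 2.0), "Na", bin_width=0.1)
        nz = np.flatnonzero(ndp.ndp)
        assert len(nz) == 1
        assert ndp.r[nz[0]] == pytest.approx(0.55)

    def test_block_std_of_static_profile_is_zero(self, traj_factory):
        frames = np.tile(np.array([[[2.5, 2.0, 1.0]]]), (40, 1, 1))
        traj = traj_factory(frames, ["Na"], BOX, times=np.arange(40.0))
        ndp = cylindrical_ndp(traj, (2.0, 2.0), "Na", bin_width=0.1,
                              block_ps=9.0)
        np.testing.assert_allclose(ndp.std, 0.0, atol=1e-12)

    def test_block_length_exceeding_span_rejected(self, traj_factory):
        frames = np.zeros((5, 1, 3)) + 1.0
        traj = traj_factory(frames, ["Na"], BOX, times=np.arange(5.0))
        with pytest.raises(ValueError):
            cylindrical_ndp(traj, (2.0, 2.0), "Na", block_ps=100.0)


class TestOccupancyGrid:
    def test_static_single_cation_single_voxel(self, traj_factory):
        traj = traj_factory([[[1.23, 2.34, 3.45]]], ["Na"], BOX, times=[0.0])
        grid = occupancy_grid_3d(traj, "Na", spacing=0.05)
        assert grid.values.max() == 1.0
        assert grid.values.sum() == 1.0

    def test_normalization_identity(self, rng, traj_factory):
        frames = _uniform_frames(rng, n_frames=7, n_particles=30)
        traj = traj_factory(frames, ["Na"] * 30, BOX)
        grid = occupancy_grid_3d(traj, "Na", spacing=0.05)
        assert grid.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert grid.values.shape == (80, 80, 80)

    def test_two_frames_split_half_half(self, traj_factory):
        frames = [[[0.51, 0.51, 0.51]], [[3.52, 3.52, 3.52]]]
        traj = traj_factory(frames, ["Na"], BOX, times=[0.0, 1.0])
        grid = occupancy_grid_3d(traj, "Na", spacing=0.05)
        vals = np.sort(grid.values.ravel())
        assert vals[-1] == 0.5 and vals[-2] == 0.5

    def test_bad_spacing(self, traj_factory):
        traj = traj_factory([[[1, 1, 1]]], ["Na"], BOX)
        with pytest.raises(ValueError):
            occupancy_grid_3d(traj, "Na", spacing=0.0)

    def test_grid_text_export(self, tmp_path, traj_factory):
        traj = traj_factory([[[1, 1, 1]]], ["Na"], BOX)
        grid = occupancy_grid_3d(traj, "Na", spacing=0.5)
        grid.save_text(tmp_path / "g.grid")
        lines = (tmp_path / "g.grid").read_text().splitlines()
        assert lines[3] == "shape 8 8 8"


class TestResidence:
    def _traj_from_occupancy(self, occ, traj_factory):
        """One ion stepping in/out of a shell around a fixed site."""
        frames = []
        for o in occ:
            frames.append([[2.0, 2.0, 2.0],
                           [2.2 if o else 3.5, 2.0, 2.0]])
        times = np.arange(len(occ), dtype=float)
        return traj_factory(frames, ["PH", "Na"], BOX, times=times,
                            mobile=[False, True])

    def test_one_stride_gap_closed_at_tolerance(self, traj_factory):
        # occupied 0-10 ps, one vacant sample, occupied 12-20 ps: the vacancy
        # is one frame stride (1 ps) and closes at tolerance 1 ps exactly
        occ = [True] * 11 + [False] + [True] * 9
        traj = self._traj_from_occupancy(occ, traj_factory)
        stats = shell_occupancy_residence(
            traj, {"site": np.array([[2.0, 2.0, 2.0]])}, {"site": 0.5},
            gap_tolerance=1.0)
        s = stats["site"]
        assert s.n_events == 1
        assert s.mean_residence == pytest.approx(20.0)

    def test_gap_beyond_tolerance_splits_events(self, traj_factory):
        # a two-stride vacancy (2 ps) stays open at tolerance 1 ps
        occ = [True] * 11 + [False, False] + [True] * 8
        traj = self._traj_from_occupancy(occ, traj_factory)
        stats = shell_occupancy_residence(
            traj, {"site": np.array([[2.0, 2.0, 2.0]])}, {"site": 0.5},
            gap_tolerance=1.0)
        s = stats["site"]
        assert s.n_events == 2
        assert sorted([s.mean_residence - s.residence_std,
                       s.mean_residence + s.residence_std]) == [7.0, 10.0]

    def test_hand_computed_occupancy(self, traj_factory):
        # 3 ions, 4 frames; shell of radius 0.5 around a fixed site
        site = [2.0, 2.0, 2.0]
        def ion(r):  # place at distance r along x
            return [2.0 + r, 2.0, 2.0]
        frames = [
            [site, ion(0.1), ion(0.3), ion(1.0)],   # 2 inside
            [site, ion(0.2), ion(0.9), ion(1.0)],   # 1 inside
            [site, ion(0.1), ion(0.2), ion(0.4)],   # 3 inside
            [site, ion(0.9), ion(0.9), ion(0.9)],   # 0 inside
        ]
        traj = traj_factory(frames, ["PH", "Na", "Na", "Na"], BOX,
                            times=np.arange(4.0), mobile=[False] + [True] * 3)
        stats = shell_occupancy_residence(
            traj, {"site": np.array([site])}, {"site": 0.5}, gap_tolerance=1.0)
        assert stats["site"].mean_occupancy == pytest.approx((2 + 1 + 3 + 0) / 4)

    def test_stride_must_not_exceed_tolerance(self, traj_factory):
        traj = self._traj_from_occupancy([True, True], traj_factory)
        with pytest.raises(ValueError):
            shell_occupancy_residence(traj, {"s": np.array([[2, 2, 2.0]])},
                                      {"s": 0.5}, gap_tolerance=0.5)


class TestDiffusion:
    def test_brownian_trajectory_recovers_d(self, rng, traj_factory):
        d0 = 0.05  # nm^2/ps
        n_p, n_f, dt = 200, 400, 0.5
        steps = rng.normal(0, np.sqrt(2 * d0 * dt), size=(n_f - 1, n_p, 3))
        pos = np.concatenate([np.zeros((1, n_p, 3)),
                              np.cumsum(steps, axis=0)]) + 50.0
        traj = traj_factory(pos, ["Na"] * n_p, (100, 100, 100),
                            times=np.arange(n_f) * dt)
        res = self_diffusion_einstein(traj, "Na")
        assert res.D == pytest.approx(d0, rel=0.05)
        assert res.diffusive
        assert res.D_si == pytest.approx(res.D * NM2_PER_PS_TO_M2_PER_S)

    def test_static_particles_give_zero(self, traj_factory):
        pos = np.tile(np.array([[[1.0, 1.0, 1.0]]]), (50, 1, 1))
        traj = traj_factory(pos, ["Na"], BOX, times=np.arange(50.0))
        res = self_diffusion_einstein(traj, "Na")
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_ballistic_flagged_non_diffusive(self, traj_factory):
        t = np.arange(100.0)
        pos = np.zeros((100, 1, 3))
        pos[:, 0, 0] = 0.3 * t
        traj = traj_factory(pos + 50.0, ["Na"], (200, 200, 200), times=t)
        res = self_diffusion_einstein(traj, "Na")
        assert not res.diffusive
        assert res.exponent == pytest.approx(2.0, abs=0.05)

    def test_missing_images_rejected(self, traj_factory):
        traj = traj_factory(np.zeros((10, 1, 3)) + 1, ["Na"], BOX,
                            times=np.arange(10.0))
        traj.images = None
        with pytest.raises(ValueError):
            self_diffusion_einstein(traj, "Na")


class TestBlockAverage:
    def test_constant_series(self):
        mean, std = block_average(np.full(100, 3.3), 10)
        assert mean == pytest.approx(3.3)
        assert std == 0.0

    def test_small_example(self):
        mean, std = block_average([1, 1, 2, 2], 2)
        assert mean == pytest.approx(1.5)
        assert std == pytest.approx(0.5)  # population std of {1, 2}

    def test_iid_normal_clt_scaling(self, rng):
        series = rng.normal(0.0, 2.0, size=100_000)
        _, std = block_average(series, 100)
        assert std == pytest.approx(2.0 / np.sqrt(100), rel=0.1)

    def test_requires_two_blocks(self):
        with pytest.raises(ValueError):
            block_average([1.0, 2.0, 3.0], 2)
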