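import numpy as np
import pytest

from fulmkit.config import AcquisitionConfig, GridSpec, StimulusProtocol
from fulmkit.maps import ULMMaps, accumulate_maps
from fulmkit.synth import PhenotypeParams, TreeLayout, build_vessel_tree, desk_grid, simulate_tracks
from fulmkit.tracking import Track, TrackSet, tracks_from_ground_truth
from fulmkit.vessels import (
    depth_profile,
    measure_diameter,
    roundness,
    segment_vessels,
    tortuosity,
)


def _zero_maps(grid):
    shape = (grid.n_z_fine, grid.n_x_fine)
    z = np.zeros(shape)
    return ULMMaps(mb_flow=z.copy(), vx=z.copy(), vz=z.copy(),
                   speed=z.copy(), backscatter=z.copy(),
                   window=(0.0, 1.0), grid=grid)


@pytest.fixture(scope="module")
def gt_scene(acq, protocol, grid):
    """Maps and tracks from ground truth (no rendering/localization noise)."""
    tree = build_vessel_tree(TreeLayout(), PhenotypeParams(), seed=9)
    gt = simulate_tracks(tree, protocol, PhenotypeParams(), acq, seed=10,
                         duration_s=10.0)
    ts = tracks_from_ground_truth(gt.tracks, acq.frame_rate_hz)
    maps = accumulate_maps(ts, grid, (0.0, 10.0))
    return maps, ts, tree


class TestSegmentation:
    def test_zero_maps_give_no_segments(self, grid):
        assert segment_vessels(_zero_maps(grid)) == []

    def test_all_vertical_vessels_found_with_correct_class(self, gt_scene,
                                                           grid):
        maps, _, tree = gt_scene
        segs = segment_vessels(maps, 500.0)
        arts = [s for s in segs if s.vessel_class == "arteriole"]
        vens = [s for s in segs if s.vessel_class == "venule"]
        n_art_paths = sum(1 for s in tree
                          if s.vessel_class == "penetrating_arteriole")
        n_ven = sum(1 for s in tree if s.vessel_class == "venule")
        assert len(arts) == n_art_paths
        assert len(vens) == n_ven

    def test_centerline_matches_truth_within_one_fine_pixel(self, gt_scene,
                                                            grid):
        maps, _, tree = gt_scene
        segs = segment_vessels(maps, 500.0)
        true_x = sorted(s.centerline[0, 0] for s in tree
                        if s.vessel_class == "penetrating_arteriole")
        art_x = sorted(s.centerline[len(s.centerline) // 4, 0]
                       for s in segs if s.vessel_class == "arteriole")
        for got, want in zip(art_x, true_x):
            assert abs(got - want) <= 1.5 * grid.fine_pitch_x

    def test_classification_by_vz_sign_is_exact(self, gt_scene):
        maps, _, _ = gt_scene
        for seg in segment_vessels(maps, 500.0):
            assert (seg.vessel_class == "arteriole") == (seg.mean_vz > 0)


class TestDepthProfile:
    def test_constant_speed_vessel_has_flat_profile(self, gt_scene, grid):
        maps, _, tree = gt_scene
        segs = [s for s in segment_vessels(maps, 500.0)
                if s.vessel_class == "venule"]
        prof = depth_profile(maps, segs[0], 60.0)
        speeds = prof.speed[(prof.depths_um > 250)
                            & (prof.depths_um < 1300) & (prof.speed > 0)]
        v = 5.0  # layout venule speed
        assert np.abs(speeds / v - 1).max() < 0.05

    def test_profile_of_empty_region_is_zero(self, grid):
        seg_mask = np.zeros((grid.n_z_fine, grid.n_x_fine), bool)
        seg_mask[:, 100] = True
        from fulmkit.vessels import VesselSegment

        seg = VesselSegment(
            mask=seg_mask,
            centerline=np.stack([np.full(50, 700.0),
                                 np.linspace(100, 1300, 50)], 1),
            vessel_class="arteriole", length_um=1200.0,
            depth_extent_um=(100.0, 1300.0))
        prof = depth_profile(_zero_maps(grid), seg, 100.0)
        assert (prof.mb_flow == 0).all() and (prof.speed == 0).all()

    def test_too_short_span_rejected(self, gt_scene):
        maps, _, _ = gt_scene
        seg = segment_vessels(maps, 500.0)[0]
        with pytest.raises(ValueError):
            depth_profile(maps, seg, depth_step_um=1e5)


class TestDiameter:
    def test_fwhm_recovers_true_diameter_within_one_fine_pixel(
            self, acq, protocol, grid):
        # oracle scene: ground-truth tracks only, so the lateral support of
        # the rasterized vessel equals the true lumen
        layout = TreeLayout(arteriole_diameter_um=28.0)
        tree = build_vessel_tree(layout, PhenotypeParams(), seed=2)
        gt = simulate_tracks(tree, protocol, PhenotypeParams(), acq, seed=3,
                             duration_s=20.0)
        ts = tracks_from_ground_truth(gt.tracks, acq.frame_rate_hz)
        maps = accumulate_maps(ts, grid, (0.0, 20.0))
        segs = [s for s in segment_vessels(maps, 500.0)
                if s.vessel_class == "arteriole"]
        vals = []
        for s in segs:
            for depth in (200.0, 300.0):
                r = measure_diameter(maps.backscatter, grid, s, depth)
                if not r.flagged:
                    vals.append(r.value_um)
        assert len(vals) >= 4
        assert abs(np.median(vals) - 28.0) <= grid.fine_pitch_x

    def test_flat_profile_is_flagged(self, grid):
        from fulmkit.vessels import VesselSegment

        seg = VesselSegment(
            mask=np.zeros((grid.n_z_fine, grid.n_x_fine), bool),
            centerline=np.stack([np.full(50, 700.0),
                                 np.linspace(100, 1300, 50)], 1),
            vessel_class="arteriole", length_um=1200.0,
            depth_extent_um=(100.0, 1300.0))
        r = measure_diameter(np.zeros((grid.n_z_fine, grid.n_x_fine)), grid,
                             seg, 500.0)
        assert r.flagged and r.value_um is None


class TestTortuosity:
    def _straight_track(self, angle_deg=0.0, n=40, step=15.0):
        th = np.deg2rad(angle_deg)
        return Track(0, np.arange(n),
                     500.0 + step * np.sin(th) * np.arange(n),
                     200.0 + step * np.cos(th) * np.arange(n))

    def _mask_segment(self, grid):
        from fulmkit.vessels import VesselSegment

        mask = np.ones((grid.n_z_fine, grid.n_x_fine), bool)
        return VesselSegment(mask=mask,
                             centerline=np.array([[500.0, 100.0],
                                                  [500.0, 900.0]]),
                             vessel_class="arteriole", length_um=800.0,
                             depth_extent_um=(100.0, 900.0))

    def test_straight_flow_has_zero_statistic(self, grid):
        ts = TrackSet([self._straight_track()], 500.0)
        res = tortuosity(self._mask_segment(grid), ts, grid)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariance(self, grid):
        rng = np.random.default_rng(5)
        base = []
        for i in range(8):
            n = 30
            x = 500 + np.cumsum(rng.uniform(5, 15, n))
            z = 300 + np.cumsum(rng.uniform(5, 15, n))
            base.append((x, z))
        def stat(theta):
            c, s = np.cos(theta), np.sin(theta)
            tracks = [Track(i, np.arange(len(x)),
                            c * x - s * z + 2000, s * x + c * z + 2000)
                      for i, (x, z) in enumerate(base)]
            seg = self._mask_segment(grid)
            return tortuosity(seg, TrackSet(tracks, 500.0), grid).statistic
        assert stat(0.0) == pytest.approx(stat(0.4), rel=1e-6)

    def test_sinusoidal_vessel_matches_tangent_angle_oracle(
            self, acq, protocol, grid):
        amp, wl = 30.0, 300.0
        phen = PhenotypeParams(tortuosity_amplitude=amp,
                               tortuosity_wavelength=wl)
        tree = build_vessel_tree(TreeLayout(), phen, seed=4)
        gt = simulate_tracks(tree, protocol, phen, acq, seed=5,
                             duration_s=10.0)
        art = [s for s in tree if s.vessel_class == "ACT"][0]
        sub = gt.tracks[gt.tracks.segment_id == art.id]
        ts = tracks_from_ground_truth(sub, acq.frame_rate_hz)
        from fulmkit.vessels import VesselSegment

        seg = VesselSegment(mask=np.ones((grid.n_z_fine, grid.n_x_fine), bool),
                            centerline=art.centerline,
                            vessel_class="arteriole",
                            length_um=art.length_um,
                            depth_extent_um=(float(art.centerline[:, 1].min()),
                                             float(art.centerline[:, 1].max())))
        res = tortuosity(seg, ts, grid, min_track_len_um=100.0)
        # oracle: circular std of tangent angles from numerical
        # differentiation of the perturbed centerline
        from scipy.stats import circstd

        d = np.diff(art.centerline, axis=0)
        angles = np.arctan2(d[:, 1], d[:, 0])
        oracle = circstd(angles, high=np.pi, low=-np.pi)
        assert res.statistic == pytest.approx(oracle, rel=0.10)

    def test_statistic_increases_with_perturbation_amplitude(
            self, acq, protocol, grid):
        stats = []
        for amp in (0.0, 15.0, 30.0):
            phen = PhenotypeParams(tortuosity_amplitude=amp,
                                   tortuosity_wavelength=300.0)
            tree = build_vessel_tree(TreeLayout(), phen, seed=6)
            gt = simulate_tracks(tree, protocol, phen, acq, seed=7,
                                 duration_s=6.0)
            act = [s for s in tree if s.vessel_class == "ACT"][0]
            sub = gt.tracks[gt.tracks.segment_id == act.id]
            ts = tracks_from_ground_truth(sub, acq.frame_rate_hz)
            seg = self._mask_segment(grid)
            stats.append(tortuosity(seg, ts, grid).statistic)
        assert stats[0] < stats[1] < stats[2]

    def test_short_tracks_are_excluded(self, grid):
        # 90 µm path length < 100 µm filter
        tr = Track(0, np.arange(7), 500.0 + 15.0 * np.arange(7),
                   np.full(7, 200.0))
        assert tr.path_length_um == pytest.approx(90.0)
        with pytest.raises(ValueError, match="100"):
            tortuosity(self._mask_segment(grid), TrackSet([tr], 500.0), grid)

    def test_dot_product_mode_zero_for_straight_flow(self, grid):
        ts = TrackSet([self._straight_track()], 500.0)
        res = tortuosity(self._mask_segment(grid), ts, grid, mode="dot")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)


class TestRoundness:
    def test_disc_has_roundness_one(self):
        r = 5.0
        assert roundness(np.pi * r ** 2, 2 * r) == pytest.approx(1.0)

    @pytest.mark.parametrize("a,b", [(10.0, 5.0), (8.0, 2.0), (7.0, 7.0)])
    def test_ellipse_roundness_is_axis_ratio(self, a, b):
        # full axes a >= b: area = pi*a*b/4, major axis = a
        area = np.pi * a * b / 4
        assert roundness(area, a) == pytest.approx(b / a)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            roundness(0.0, 5.0)
        with pytest.raises(ValueError):
            roundness(5.0, 0.0)
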