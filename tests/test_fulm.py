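import numpy as np
import pytest

from fulmkit.config import GridSpec, StimulusProtocol
from fulmkit.fulm import (
    activation_map,
    activation_signal,
    pattern_qc,
    track_windows,
)
from fulmkit.maps import (
    ULMMaps,
    pattern_average_from_tracks,
    split_baseline_stim,
)
from fulmkit.synth import PhenotypeParams, TreeLayout, build_vessel_tree, simulate_tracks
from fulmkit.tracking import Track, TrackSet, tracks_from_ground_truth


def _maps(grid, flow):
    z = np.zeros_like(flow)
    return ULMMaps(mb_flow=flow, vx=z, vz=z, speed=z, backscatter=z,
                   window=(0.0, 1.0), grid=grid)


@pytest.fixture
def tiny_grid():
    return GridSpec(n_x_native=2, n_z_native=2)


class TestActivationMap:
    def test_equal_maps_give_zero_everywhere_defined(self, tiny_grid):
        flow = np.random.default_rng(0).uniform(0, 2, (32, 32))
        am = activation_map(_maps(tiny_grid, flow), _maps(tiny_grid, flow))
        assert np.all(am.values[am.defined] == 0.0)
        assert (am.defined == (flow > 0)).all()

    def test_doubled_flow_gives_plus_100pc(self, tiny_grid):
        flow = np.random.default_rng(1).uniform(0.1, 2, (32, 32))
        am = activation_map(_maps(tiny_grid, flow), _maps(tiny_grid, 2 * flow))
        np.testing.assert_allclose(am.values[am.defined], 1.0)

    def test_zero_baseline_pixels_are_masked_not_infinite(self, tiny_grid):
        base = np.zeros((32, 32))
        stim = np.ones((32, 32))
        am = activation_map(_maps(tiny_grid, base), _maps(tiny_grid, stim))
        assert not am.defined.any()
        assert np.isfinite(am.values).all()

    def test_mismatched_grids_rejected(self, tiny_grid):
        big = GridSpec(n_x_native=3, n_z_native=3)
        with pytest.raises(ValueError):
            activation_map(_maps(tiny_grid, np.ones((32, 32))),
                           _maps(big, np.ones((48, 48))))

    def test_injected_gain_recovered_in_target_subtree(self, acq, grid,
                                                       gt_tracks_scene):
        gt, proto, tree = gt_tracks_scene
        ts = tracks_from_ground_truth(gt.tracks, acq.frame_rate_hz)
        base, stim = split_baseline_stim(ts, grid, proto,
                                         duration_s=proto.total_duration_s)
        am = activation_map(base, stim)
        target = np.zeros_like(am.values, bool)
        for seg in tree:
            if not seg.activated:
                continue
            cols = (seg.centerline[:, 0] / grid.fine_pitch_x).astype(int)
            rows = (seg.centerline[:, 1] / grid.fine_pitch_z).astype(int)
            for r, c in zip(rows, cols):
                target[r - 2:r + 3, c - 2:c + 3] = True
        inside = am.values[target & am.defined]
        outside = am.values[am.defined & ~target]
        # ramp (2 s of 30 s) trims the injected 0.5 slightly
        assert inside.mean() == pytest.approx(0.5, abs=0.12)
        assert abs(outside.mean()) < 0.12


class TestActivationSignal:
    def test_stationary_scene_signal_is_flat_100pc(self, acq, grid, protocol):
        phen = PhenotypeParams(activation_gain=0.0)
        proto = StimulusProtocol(n_patterns=2)
        tree = build_vessel_tree(TreeLayout(), phen, seed=12)
        gt = simulate_tracks(tree, proto, phen, acq, seed=13)
        ts = tracks_from_ground_truth(gt.tracks, acq.frame_rate_hz)
        stack = pattern_average_from_tracks(ts, grid, proto)
        mask = np.zeros((grid.n_z_fine, grid.n_x_fine), bool)
        for seg in tree:
            if seg.vessel_class not in ("penetrating_arteriole", "ACT"):
                continue
            cols = (seg.centerline[:, 0] / grid.fine_pitch_x).astype(int)
            rows = (seg.centerline[:, 1] / grid.fine_pitch_z).astype(int)
            for r, c in zip(rows, cols):
                mask[r - 2:r + 3, c - 2:c + 3] = True
        sig = activation_signal(stack, mask, proto, band="deep")
        assert sig.signal_percent.mean() == pytest.approx(100.0, abs=8.0)
        assert abs(sig.early_percent) < 10.0

    def test_act_confined_activation_is_deep_band_specific(self, acq, grid):
        proto = StimulusProtocol(n_patterns=3)
        layout = TreeLayout(activated_classes=("ACT",))
        phen = PhenotypeParams(activation_gain=0.6)
        tree = build_vessel_tree(layout, phen, seed=14)
        gt = simulate_tracks(tree, proto, phen, acq, seed=15)
        ts = tracks_from_ground_truth(gt.tracks, acq.frame_rate_hz)
        stack = pattern_average_from_tracks(ts, grid, proto)
        mask = np.zeros((grid.n_z_fine, grid.n_x_fine), bool)
        for seg in tree:
            if seg.vessel_class not in ("penetrating_arteriole", "ACT"):
                continue
            cols = (seg.centerline[:, 0] / grid.fine_pitch_x).astype(int)
            rows = (seg.centerline[:, 1] / grid.fine_pitch_z).astype(int)
            for r, c in zip(rows, cols):
                mask[r - 2:r + 3, c - 2:c + 3] = True
        deep = activation_signal(stack, mask, proto, band="deep")
        upper = activation_signal(stack, mask, proto, band="upper")
        assert deep.early_percent > upper.early_percent + 10.0

    def test_delayed_activation_blunts_early_mean(self, acq, grid):
        proto = StimulusProtocol(n_patterns=3)
        res = {}
        for delay in (0.0, 4.0):
            phen = PhenotypeParams(activation_gain=0.6,
                                   activation_delay_s=delay)
            tree = build_vessel_tree(TreeLayout(), phen, seed=16)
            gt = simulate_tracks(tree, proto, phen, acq, seed=17)
            ts = tracks_from_ground_truth(gt.tracks, acq.frame_rate_hz)
            stack = pattern_average_from_tracks(ts, grid, proto)
            mask = np.zeros((grid.n_z_fine, grid.n_x_fine), bool)
            for seg in tree:
                if not seg.activated:
                    continue
                cols = (seg.centerline[:, 0] / grid.fine_pitch_x).astype(int)
                rows = (seg.centerline[:, 1] / grid.fine_pitch_z).astype(int)
                for r, c in zip(rows, cols):
                    mask[r - 2:r + 3, c - 2:c + 3] = True
            res[delay] = activation_signal(stack, mask, proto, band="deep")
        assert res[4.0].early_percent < res[0.0].early_percent - 5.0
        assert res[4.0].late_percent == pytest.approx(res[0.0].late_percent,
                                                      abs=15.0)

    def test_empty_band_is_named_in_error(self, grid, protocol):
        stack = pattern_average_from_tracks(TrackSet([], 500.0), grid,
                                            StimulusProtocol(n_patterns=1),
                                            duration_s=70.0)
        mask = np.zeros((grid.n_z_fine, grid.n_x_fine), bool)
        with pytest.raises(ValueError, match="band"):
            activation_signal(stack, mask, protocol, band="deep")


class TestPatternQC:
    def _signals(self, protocol, n_windows=35):
        t = np.arange(n_windows) * 2.0
        boxcar = ((t >= 30) & (t < 60)).astype(float)
        return t, boxcar

    def test_stimulus_locked_pattern_is_kept(self, protocol):
        t, boxcar = self._signals(protocol)
        roi = 100 + 20 * boxcar
        contra = np.full_like(roi, 100.0) + np.sin(t)  # uncorrelated wiggle
        glob = np.full_like(roi, 500.0)
        rep = pattern_qc(roi, contra, glob, protocol)
        assert rep.per_pattern.kept.all()
        assert rep.mean_stim_increase_percent == pytest.approx(20.0)
        assert rep.acquisition_kept

    def test_contralateral_correlation_out_of_band_rejects(self, protocol):
        t, boxcar = self._signals(protocol)
        roi = 100 + 20 * boxcar
        contra = 100 + 15 * boxcar  # corr = 1 > 0.5
        glob = np.full_like(roi, 500.0)
        rep = pattern_qc(roi, contra, glob, protocol)
        assert not rep.per_pattern.kept.iloc[0]
        assert "contralateral" in rep.per_pattern.reason.iloc[0]

    def test_weak_acquisition_increase_rejects_acquisition(self, protocol):
        t, boxcar = self._signals(protocol)
        roi = 100 + 8 * boxcar  # 8% < 10% rule
        contra = np.full_like(roi, 100.0) + np.sin(t)
        glob = np.full_like(roi, 500.0)
        rep = pattern_qc(roi, contra, glob, protocol)
        assert rep.per_pattern.kept.all()
        assert rep.mean_stim_increase_percent == pytest.approx(8.0)
        assert not rep.acquisition_kept

    def test_low_stimulus_correlation_rejects_pattern(self, protocol):
        rng = np.random.default_rng(0)
        t, boxcar = self._signals(protocol)
        roi = 100 + rng.normal(0, 5, len(t))  # noise, corr ~ 0
        contra = np.full_like(roi, 100.0) + np.sin(t)
        glob = np.full_like(roi, 500.0)
        rep = pattern_qc(roi, contra, glob, protocol)
        assert not rep.per_pattern.kept.iloc[0]
        assert "correlation" in rep.per_pattern.reason.iloc[0]

    def test_zero_variance_signal_rejected_with_reason(self, protocol):
        t, boxcar = self._signals(protocol)
        roi = np.full_like(boxcar, 100.0)
        rep = pattern_qc(roi, roi, roi, protocol)
        assert not rep.per_pattern.kept.iloc[0]
        assert "zero-variance" in rep.per_pattern.reason.iloc[0]

    def test_unstable_global_flux_rejects_pattern(self, protocol):
        t, boxcar = self._signals(protocol)
        roi = 100 + 20 * boxcar
        contra = np.full_like(roi, 100.0) + np.sin(t)
        glob = 500 + 400 * np.sin(0.2 * t)  # CV > 0.3
        rep = pattern_qc(roi, contra, glob, protocol)
        assert not rep.per_pattern.kept.iloc[0]
        assert "flux" in rep.per_pattern.reason.iloc[0]


class TestTrackWindows:
    def test_track_starting_at_31s_lands_in_30_34_bundle(self):
        f0 = int(31.0 * 500)
        tr = Track(0, f0 + np.arange(5), np.arange(5.0), np.arange(5.0))
        bundles = track_windows(TrackSet([tr], 500.0), 4.0, t0_s=30.0)
        assert list(bundles) == [0]  # [30, 34)

    def test_every_track_is_bundled_exactly_once(self):
        rng = np.random.default_rng(1)
        tracks = []
        for i in range(40):
            f0 = int(rng.integers(0, 20000))
            tracks.append(Track(i, f0 + np.arange(5), np.arange(5.0),
                                np.arange(5.0)))
        bundles = track_windows(TrackSet(tracks, 500.0), 4.0)
        assert sum(len(b) for b in bundles.values()) == 40

    def test_empty_trackset_gives_no_bundles(self):
        assert track_windows(TrackSet([], 500.0), 4.0) == {}

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            track_windows(TrackSet([], 500.0), 0.0)
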