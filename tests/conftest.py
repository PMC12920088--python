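import numpy as np
import pandas as pd
import pytest

from fulmkit.config import AcquisitionConfig, GridSpec, StimulusProtocol
from fulmkit.synth import (
    ClutterParams,
    PhenotypeParams,
    TreeLayout,
    build_vessel_tree,
    desk_grid,
    render_frames,
    simulate_tracks,
)
from fulmkit.synth.simulate import GroundTruth


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def grid(acq):
    return desk_grid(TreeLayout(), acq)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(n_x_native=16, n_z_native=16)


def make_point_ground_truth(positions_um, acq, amplitudes=None, frame_rate=None):
    """GroundTruth with one stationary bubble per frame (frame k holds
    positions_um[k]); handy for rendering isolated test bubbles."""
    positions_um = np.asarray(positions_um, dtype=float)
    n = len(positions_um)
    rate = frame_rate or acq.frame_rate_hz
    amps = np.ones(n) if amplitudes is None else np.asarray(amplitudes, float)
    tracks = pd.DataFrame({
        "track_id": np.arange(n),
        "frame": np.arange(n),
        "t_s": np.arange(n) / rate,
        "x_um": positions_um[:, 0],
        "z_um": positions_um[:, 1],
        "vx_mm_s": 0.0,
        "vz_mm_s": 0.0,
        "speed_mm_s": 0.0,
        "amplitude": amps,
        "segment_id": 0,
        "vessel_class": "venule",
    })
    return GroundTruth(tracks=tracks, flux=None, tree=[], seed=0,
                       frame_rate_hz=rate, duration_s=n / rate)


@pytest.fixture(scope="session")
def rest_scene(acq, protocol, grid):
    """One rendered + fully processed resting desk scene (control), shared
    across end-to-end tests."""
    from fulmkit.pipeline import resting_scene

    return resting_scene(PhenotypeParams(), seed=11, duration_s=8.0)


@pytest.fixture(scope="session")
def gt_tracks_scene(acq, grid):
    """Ground-truth tracks for a 3-pattern activation acquisition (no
    rendering), for map/fULM analyses with a known flux modulation."""
    proto = StimulusProtocol(n_patterns=3)
    phen = PhenotypeParams(activation_gain=0.5)
    tree = build_vessel_tree(TreeLayout(), phen, seed=5)
    gt = simulate_tracks(tree, proto, phen, acq, seed=6)
    return gt, proto, tree
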