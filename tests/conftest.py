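import numpy as np
import pytest

from echoarray.detection import CallTemplate, DetectionConfig, detect_calls
from echoarray.geometry import make_planar_grid
from echoarray.signal_chain import PcmRecording
from echoarray.simulate import SceneSpec, Trajectory, render_scene, synth_chirp

RATE = 450_000.0
SOURCE = np.array([0.55, 0.62, 0.75])
CALL_TIMES = np.array([0.03, 0.09, 0.15])


@pytest.fixture(scope="session")
def grid_layout():
    """The 8x8, 1.2 m x 1.2 m planar grid (64 mics, 8 devices)."""
    return make_planar_grid(8, 8, 1.2, 1.2, device_size=8, sample_rate=RATE)


@pytest.fixture(scope="session")
def noiseless_scene(grid_layout):
    """A static source above the grid emitting three chirps, no noise."""
    traj = Trajectory(times=np.array([0.0, 0.2]),
                      positions=np.array([SOURCE, SOURCE]))
    spec = SceneSpec(
        layout=grid_layout,
        trajectory=traj,
        call_schedule=CALL_TIMES,
        noise_rms=0.0,
        duration=0.2,
        seed=1,
    )
    recordings, gt = render_scene(spec)
    return spec, recordings, gt


@pytest.fixture(scope="session")
def merged_recording(noiseless_scene):
    """All devices stacked into one aligned channel matrix (no offsets)."""
    _, recordings, _ = noiseless_scene
    samples = np.vstack([r.samples for r in recordings])
    ids = [cid for r in recordings for cid in r.channel_ids]
    return PcmRecording(samples=samples, rate=RATE, channel_ids=ids)


@pytest.fixture(scope="session")
def chirp_template():
    return CallTemplate(synth_chirp(80e3, 30e3, 0.003, RATE), RATE)


@pytest.fixture(scope="session")
def scene_detections(merged_recording, chirp_template):
    return detect_calls(merged_recording, chirp_template, DetectionConfig())
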