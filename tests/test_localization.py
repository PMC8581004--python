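import numpy as np
import pytest

from echoarray.detection import Detection
from echoarray.geometry import ArrayLayout, DeviceSpec, Medium, MicPose, \
    make_small_scale_array
from echoarray.localization import (
    UnderdeterminedError,
    aoa_likelihood,
    build_path,
    fuse_aoa,
    localize_call,
    tdoa_likelihood,
)

C = 343.0


def _layout_from_positions(positions):
    dev = DeviceSpec(device_id="d0", sample_rate=450_000.0)
    mics = [
        MicPose(mic_id=f"m{k}", device_id="d0", position=p)
        for k, p in enumerate(positions)
    ]
    return ArrayLayout(devices=[dev], mics=mics,
                       medium=Medium(speed_of_sound=C))


def _detection_at(source, positions, sigma_t=0.0, rng=None, channel_ids=None):
    """Exact (optionally noise-perturbed) arrivals for a point source."""
    t = np.linalg.norm(np.asarray(positions) - source, axis=1) / C
    if sigma_t > 0:
        t = t + rng.normal(0.0, sigma_t, len(t))
    n = len(positions)
    return Detection(
        call_id=0,
        channel_ids=channel_ids or [f"m{k}" for k in range(n)],
        arrival_time=t,
        amplitude=np.ones(n),
        quality=np.full(n, 10.0),
        accepted=np.ones(n, dtype=bool),
    )


def brute_force_tdoa(det, positions, axes, sigma_t, c=C):
    """Independent oracle: explicit triple loop over the grid."""
    q = det.quality
    ref = int(np.argmax(q))
    delta = det.arrival_time - det.arrival_time[ref]
    ax, ay, az = axes
    out = np.empty((len(ax), len(ay), len(az)))
    for i, x in enumerate(ax):
        for j, y in enumerate(ay):
            for k, z in enumerate(az):
                p = np.array([x, y, z])
                ll = 0.0
                dref = np.linalg.norm(p - positions[ref])
                for m in range(len(positions)):
                    pred = (np.linalg.norm(p - positions[m]) - dref) / c
                    ll -= (delta[m] - pred) ** 2 / (2 * sigma_t**2)
                out[i, j, k] = ll / len(positions)
    out -= out.max()
    out = np.exp(out)
    return out / out.sum()


class TestTdoaLikelihood:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        positions = rng.uniform(0, 1, size=(5, 3))
        source = np.array([0.4, 0.6, 0.5])
        det = _detection_at(source, positions, sigma_t=1e-5, rng=rng)
        layout = _layout_from_positions(positions)
        axes = (np.linspace(0, 1, 6), np.linspace(0, 1, 5), np.linspace(0.1, 0.9, 4))
        grid = tdoa_likelihood(det, layout, axes, sigma_t=2e-6,
                               grid_quantization=False)
        expected = brute_force_tdoa(det, positions, axes, sigma_t=2e-6)
        assert np.max(np.abs(grid.values - expected) / expected.max()) <= 1e-10

    def test_noiseless_map_within_one_cell(self, grid_layout):
        source = np.array([0.55, 0.62, 0.75])
        det = _detection_at(source, grid_layout.mic_positions,
                            channel_ids=grid_layout.mic_ids)
        axes = (np.arange(0, 1.225, 0.05), np.arange(0, 1.225, 0.05),
                np.arange(0.05, 1.55, 0.05))
        est = localize_call(det, grid_layout, axes, sigma_t=2 / 450e3, c=C)
        assert np.all(np.abs(est.map_point - source) <= 0.05)

    def test_two_mics_hyperboloid_symmetry(self):
        positions = np.array([[-0.5, 0.0, 0.0], [0.5, 0.0, 0.0]])
        det = _detection_at(np.array([0.0, 0.7, 0.3]), positions)
        layout = _layout_from_positions(positions)
        ax = np.linspace(-1, 1, 11)
        axes = (ax, np.linspace(0.1, 1, 5), np.linspace(0.1, 1, 5))
        grid = tdoa_likelihood(det, layout, axes, sigma_t=1e-5,
                               allow_underdetermined=True)
        # source equidistant from both mics: likelihood mirror-symmetric in x
        assert np.allclose(grid.values, grid.values[::-1], rtol=1e-9)

    def test_large_sigma_flattens_to_uniform(self, grid_layout):
        det = _detection_at(np.array([0.5, 0.5, 0.5]), grid_layout.mic_positions,
                            channel_ids=grid_layout.mic_ids)
        axes = (np.linspace(0, 1.2, 7), np.linspace(0, 1.2, 7),
                np.linspace(0.1, 1.2, 5))
        grid = tdoa_likelihood(det, grid_layout, axes, sigma_t=10.0, c=C)
        assert grid.values.max() / grid.values.min() == pytest.approx(1.0, abs=1e-6)

    def test_underdetermined_raises_with_count(self):
        positions = np.eye(3)
        det = _detection_at(np.array([0.3, 0.3, 0.3]), positions)
        layout = _layout_from_positions(positions)
        axes = (np.linspace(0, 1, 3),) * 3
        with pytest.raises(UnderdeterminedError, match="3"):
            tdoa_likelihood(det, layout, axes)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        positions = rng.uniform(0, 1, size=(8, 3))
        source = np.array([0.5, 0.5, 0.4])
        shift = np.array([3.0, -2.0, 1.0])
        step = 0.05
        axes0 = tuple(np.arange(0, 1.0001, step) for _ in range(3))
        axes1 = tuple(a + s for a, s in zip(axes0, shift))
        det0 = _detection_at(source, positions)
        det1 = _detection_at(source + shift, positions + shift)
        est0 = localize_call(det0, _layout_from_positions(positions), axes0,
                             sigma_t=2 / 450e3)
        est1 = localize_call(det1, _layout_from_positions(positions + shift),
                             axes1, sigma_t=2 / 450e3)
        assert np.all(np.abs((est1.map_point - shift) - est0.map_point) <= step)

    def test_noise_coverage_and_monotone_error(self, grid_layout):
        # 0.5-fraction cloud contains the truth's grid cell in >= 90% of
        # noisy trials, and the median MAP error grows with timing noise
        axes = (np.arange(0, 1.225, 0.05), np.arange(0, 1.225, 0.05),
                np.arange(0.05, 1.55, 0.05))
        cell = 0.05
        sigma = 2 / 450e3
        rng = np.random.default_rng(42)
        hits = 0
        errs = {s: [] for s in (sigma, 30 * sigma)}
        for trial in range(100):
            source = rng.uniform([0.2, 0.2, 0.3], [1.0, 1.0, 1.0])
            for s in errs:
                det = _detection_at(source, grid_layout.mic_positions,
                                    sigma_t=s, rng=rng,
                                    channel_ids=grid_layout.mic_ids)
                est = localize_call(det, grid_layout, axes, sigma_t=s, c=C)
                errs[s].append(np.linalg.norm(est.map_point - source))
                if s == sigma:
                    inside = np.any(np.all(
                        np.abs(est.uncertainty_points - source) <= cell / 2 + 1e-12,
                        axis=1))
                    hits += inside
        assert hits >= 90
        assert np.median(errs[30 * sigma]) >= np.median(errs[sigma])


class TestAoa:
    def _arrival_times(self, array, source):
        return np.linalg.norm(array.mic_positions - source, axis=1) / C

    def test_known_direction_within_one_cell(self):
        arr = make_small_scale_array([0, 0, 0])
        az_true, el_true = 40.0, 25.0
        u = np.array([
            np.cos(np.radians(el_true)) * np.cos(np.radians(az_true)),
            np.cos(np.radians(el_true)) * np.sin(np.radians(az_true)),
            np.sin(np.radians(el_true)),
        ])
        t = self._arrival_times(arr, 30.0 * u)
        local = arr.mic_positions - arr.devices[0].origin
        dl = aoa_likelihood(t, local, sigma_t=2 / 450e3, c=C)
        az, el = dl.map_direction()
        assert abs(az - az_true) <= 2.0
        assert abs(el - el_true) <= 2.0

    def test_broadside_gives_zenith(self):
        arr = make_small_scale_array([0, 0, 0])
        t = self._arrival_times(arr, np.array([0.0, 0.0, 20.0]))
        local = arr.mic_positions
        dl = aoa_likelihood(t, local, sigma_t=2 / 450e3, c=C)
        _, el = dl.map_direction()
        assert el == pytest.approx(90.0, abs=2.0)

    def test_large_sigma_uniform_hemisphere(self):
        arr = make_small_scale_array([0, 0, 0])
        t = self._arrival_times(arr, np.array([5.0, 5.0, 5.0]))
        dl = aoa_likelihood(t, arr.mic_positions, sigma_t=10.0, c=C)
        assert dl.values.max() / dl.values.min() == pytest.approx(1.0, abs=1e-6)


class TestFusion:
    def _cone(self, center, source, step=1.0):
        arr = make_small_scale_array(center, device_id=f"d{center[0]}")
        dev = arr.devices[0]
        t = np.linalg.norm(arr.mic_positions - source, axis=1) / C
        local = (arr.mic_positions - dev.origin) @ dev.orientation
        return aoa_likelihood(t, local, sigma_t=2 / 450e3, c=C,
                              az_step_deg=step, el_step_deg=step,
                              origin=dev.origin, orientation=dev.orientation)

    def test_two_arrays_recover_distant_source(self):
        # rooftop scale: boards 17 m apart, source ~30 m away, 0.5 m cells
        source = np.array([8.0, 25.0, 12.0])
        cones = [self._cone([0.0, 0, 0], source), self._cone([17.0, 0, 0], source)]
        axes = (np.arange(-5, 25.5, 0.5), np.arange(0, 40.5, 0.5),
                np.arange(0, 25.5, 0.5))
        est = fuse_aoa(cones, axes)
        assert not est.range_ambiguous
        assert np.linalg.norm(est.map_point - source) <= 2 * 0.5

    def test_single_array_range_ambiguous_elongated(self):
        source = np.array([8.0, 25.0, 12.0])
        cone = self._cone([0.0, 0, 0], source)
        axes = (np.arange(-5, 25.5, 0.5), np.arange(0, 40.5, 0.5),
                np.arange(0, 25.5, 0.5))
        est = fuse_aoa([cone], axes)
        assert est.range_ambiguous
        ray = source / np.linalg.norm(source)
        pts = est.uncertainty_points
        along = pts @ ray
        perp = pts - np.outer(along, ray)
        assert along.std() > 5 * np.linalg.norm(perp, axis=1).std()

    def test_uniform_cones_fuse_to_uniform(self):
        cone = self._cone([0.0, 0, 0], np.array([5.0, 5.0, 5.0]))
        flat = type(cone)(
            azimuth_deg=cone.azimuth_deg,
            elevation_deg=cone.elevation_deg,
            values=np.ones_like(cone.values),
            origin=cone.origin,
            orientation=cone.orientation,
        )
        axes = (np.arange(1, 9.5, 1.0), np.arange(1, 9.5, 1.0), np.arange(1, 9.5, 1.0))
        est = fuse_aoa([flat, flat], axes)
        v = est.grid.values
        assert v.max() / v.min() == pytest.approx(1.0, abs=1e-9)


class TestPath:
    def _estimate(self, p):
        from echoarray.localization import PositionEstimate

        p = np.asarray(p, dtype=float)
        return PositionEstimate(map_point=p, uncertainty_points=p[None, :])

    def test_straight_trajectory_speeds(self):
        # source moving at 5 m/s, one call every 100 ms
        times = np.arange(0, 1.0, 0.1)
        pts = np.outer(times, [5.0, 0, 0])
        path = build_path([(t, self._estimate(p)) for t, p in zip(times, pts)])
        assert np.allclose(path.segment_speeds, 5.0)
        assert not path.implausible.any()

    def test_single_call_path(self):
        path = build_path([(0.0, self._estimate([1, 2, 3]))])
        assert len(path.estimates) == 1
        assert path.segment_speeds.size == 0

    def test_shuffled_input_sorted(self):
        times = np.array([0.3, 0.1, 0.2])
        pts = [[3, 0, 0], [1, 0, 0], [2, 0, 0]]
        path = build_path([(t, self._estimate(p)) for t, p in zip(times, pts)])
        assert np.array_equal(path.times, [0.1, 0.2, 0.3])
        assert np.allclose(path.points[:, 0], [1, 2, 3])

    def test_duplicate_times_rejected(self):
        ests = [(0.1, self._estimate([0, 0, 0])), (0.1, self._estimate([1, 0, 0]))]
        with pytest.raises(ValueError, match="duplicate"):
            build_path(ests)

    def test_implausible_segment_flagged(self):
        ests = [(0.0, self._estimate([0, 0, 0])), (0.1, self._estimate([50, 0, 0]))]
        path = build_path(ests)
        assert path.implausible[0]
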