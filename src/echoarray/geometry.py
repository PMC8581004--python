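"""Array geometry: microphone poses, device specs, layouts and config I/O.

Coordinate conventions used throughout the package: right-handed frame,
meters, z-up.  Azimuth is measured counter-clockwise from +x in the x-y
plane; elevation from the horizontal plane (so +z is elevation 90 deg).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "GeometryError",
    "MicPose",
    "DeviceSpec",
    "Medium",
    "ArrayLayout",
    "make_planar_grid",
    "make_small_scale_array",
    "default_small_scale_layout",
    "speed_of_sound_at",
    "read_layout",
    "write_layout",
]

SCHEMA_VERSION = 1

#: Maximum acoustic channels a single recording device supports.
MAX_CHANNELS_PER_DEVICE = 10


class GeometryError(ValueError):
    """Invalid array geometry (non-finite positions, bad rotations, ...)."""


def speed_of_sound_at(temperature_c: float) -> float:
    """Speed of sound in air [m/s] from a linear model in temperature.

    c = 331.3 + 0.606 * T, with T in deg C.  Valid roughly for
    -40 <= T <= 60; outside that range a warning is emitted but the
    value is still returned.
    """
    if not (-40.0 <= temperature_c <= 60.0):
        warnings.warn(
            f"temperature {temperature_c} degC outside the validated "
            "range [-40, 60]; extrapolating the linear model",
            stacklevel=2,
        )
    return 331.3 + 0.606 * temperature_c


@dataclass(frozen=True)
class Medium:
    """Propagation medium.  Either give an explicit speed of sound or a
    temperature from which it is derived."""

    temperature: float = 20.0
    speed_of_sound: float | None = None

    def __post_init__(self) -> None:
        c = self.c
        if not (c > 0 and np.isfinite(c)):
            raise GeometryError(f"speed of sound must be positive, got {c}")

    @property
    def c(self) -> float:
        if self.speed_of_sound is not None:
            return float(self.speed_of_sound)
        return speed_of_sound_at(self.temperature)


#: Package default: dry air at 20 degC, rounded to the customary 343 m/s.
DEFAULT_MEDIUM = Medium(temperature=20.0, speed_of_sound=343.0)


@dataclass(frozen=True)
class MicPose:
    mic_id: str
    device_id: str
    position: np.ndarray  # (3,) meters, global frame
    gain: float = 1.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise GeometryError(f"mic {self.mic_id}: non-finite position {pos}")
        if not self.gain > 0:
            raise GeometryError(f"mic {self.mic_id}: gain must be > 0")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class DeviceSpec:
    device_id: str
    sample_rate: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    n_acoustic_channels: int = MAX_CHANNELS_PER_DEVICE
    sync_channel_index: int = MAX_CHANNELS_PER_DEVICE

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise GeometryError(f"device {self.device_id}: sample_rate must be > 0")
        if not 1 <= self.n_acoustic_channels <= MAX_CHANNELS_PER_DEVICE:
            raise GeometryError(
                f"device {self.device_id}: n_acoustic_channels must be in "
                f"[1, {MAX_CHANNELS_PER_DEVICE}], got {self.n_acoustic_channels}"
            )
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        rot = _check_rotation(np.asarray(self.orientation, dtype=float))
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "orientation", rot)


def _check_rotation(rot: np.ndarray) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise GeometryError(f"rotation must be 3x3, got shape {rot.shape}")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9) or not np.isclose(
        np.linalg.det(rot), 1.0, atol=1e-9
    ):
        raise GeometryError("rotation matrix is not orthonormal/proper")
    return rot


@dataclass
class ArrayLayout:
    """Global array geometry: devices, mic poses and the medium."""

    devices: list[DeviceSpec]
    mics: list[MicPose]
    medium: Medium = field(default_factory=lambda: DEFAULT_MEDIUM)

    def __post_init__(self) -> None:
        dev_ids = {d.device_id for d in self.devices}
        mic_ids = [m.mic_id for m in self.mics]
        if len(set(mic_ids)) != len(mic_ids):
            raise GeometryError("mic_ids are not unique")
        for m in self.mics:
            if m.device_id not in dev_ids:
                raise GeometryError(
                    f"mic {m.mic_id} references unknown device {m.device_id}"
                )

    @property
    def mic_positions(self) -> np.ndarray:
        """(n_mics, 3) array of global positions, layout order."""
        return np.array([m.position for m in self.mics])

    @property
    def mic_ids(self) -> list[str]:
        return [m.mic_id for m in self.mics]

    def mics_of_device(self, device_id: str) -> list[MicPose]:
        return [m for m in self.mics if m.device_id == device_id]

    def device(self, device_id: str) -> DeviceSpec:
        for d in self.devices:
            if d.device_id == device_id:
                return d
        raise KeyError(device_id)

    def merged_with(self, other: "ArrayLayout") -> "ArrayLayout":
        """Combine two layouts into one (device/mic ids must not clash)."""
        return ArrayLayout(
            devices=self.devices + other.devices,
            mics=self.mics + other.mics,
            medium=self.medium,
        )


def make_planar_grid(
    nx: int,
    ny: int,
    extent_x: float,
    extent_y: float,
    device_size: int = 8,
    sample_rate: float = 450_000.0,
    medium: Medium | None = None,
) -> ArrayLayout:
    """Regular planar mic grid in the z=0 plane (e.g. 8x8 over 1.2 m x 1.2 m).

    Mics are ordered row-major (y-major: row j, column i) and partitioned
    into devices of at most ``device_size`` consecutive mics.  Adjacent-mic
    spacing is extent/(n-1) on each axis.
    """
    if nx < 2 or ny < 2:
        raise GeometryError("grid needs nx, ny >= 2")
    if extent_x <= 0 or extent_y <= 0:
        raise GeometryError("grid extents must be positive")
    if not 1 <= device_size <= MAX_CHANNELS_PER_DEVICE:
        raise GeometryError(
            f"device_size must be in [1, {MAX_CHANNELS_PER_DEVICE}]"
        )
    xs = np.linspace(0.0, extent_x, nx)
    ys = np.linspace(0.0, extent_y, ny)
    n_mics = nx * ny
    n_devices = int(np.ceil(n_mics / device_size))
    devices = [
        DeviceSpec(device_id=f"dev{d:02d}", sample_rate=sample_rate)
        for d in range(n_devices)
    ]
    mics = []
    for k in range(n_mics):
        j, i = divmod(k, nx)  # row-major: row j (y), column i (x)
        mics.append(
            MicPose(
                mic_id=f"m{k:03d}",
                device_id=f"dev{k // device_size:02d}",
                position=np.array([xs[i], ys[j], 0.0]),
            )
        )
    return ArrayLayout(devices=devices, mics=mics,
                       medium=medium or DEFAULT_MEDIUM)


def default_small_scale_layout(side: float = 0.10) -> np.ndarray:
    """Default 10-mic local PCB layout: 3x3 perimeter + center of a square.

    The true PCB pattern of the reference hardware is not published; this
    is a documented stand-in.  Returns (10, 2) local coordinates in meters,
    centered on the board origin.
    """
    h = side / 2.0
    pts = [(-h, -h), (0, -h), (h, -h), (-h, 0), (h, 0),
           (-h, h), (0, h), (h, h), (0.0, 0.0), (0.0, -side / 4)]
    return np.asarray(pts, dtype=float)


def make_small_scale_array(
    center: Sequence[float],
    orientation: np.ndarray | None = None,
    layout_spec: np.ndarray | None = None,
    device_id: str = "ssa0",
    sample_rate: float = 450_000.0,
    medium: Medium | None = None,
) -> ArrayLayout:
    """One 10-mic small-scale array (local direction estimator).

    ``layout_spec`` gives 10 local 2-vectors in the PCB plane; they are
    padded with z=0 and rigidly transformed by ``orientation`` about
    ``center`` into the global frame.  The board normal is local +z.
    """
    local = default_small_scale_layout() if layout_spec is None else np.asarray(
        layout_spec, dtype=float
    )
    if local.shape != (10, 2):
        raise GeometryError(f"layout_spec must be 10 local 2-vectors, got {local.shape}")
    rot = np.eye(3) if orientation is None else _check_rotation(orientation)
    center = np.asarray(center, dtype=float).reshape(3)
    local3 = np.column_stack([local, np.zeros(len(local))])
    global_pos = local3 @ rot.T + center
    device = DeviceSpec(
        device_id=device_id,
        sample_rate=sample_rate,
        origin=center,
        orientation=rot,
    )
    mics = [
        MicPose(mic_id=f"{device_id}_m{k}", device_id=device_id, position=p)
        for k, p in enumerate(global_pos)
    ]
    return ArrayLayout(devices=[device], mics=mics,
                       medium=medium or DEFAULT_MEDIUM)


# ---------------------------------------------------------------------------
# Config file I/O (YAML or JSON, schema version 1)

def _layout_to_dict(layout: ArrayLayout) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "medium": {
            "temperature": layout.medium.temperature,
            "speed_of_sound": layout.medium.speed_of_sound,
        },
        "devices": [
            {
                "device_id": d.device_id,
                "sample_rate": d.sample_rate,
                "origin": d.origin.tolist(),
                "orientation": d.orientation.tolist(),
                "n_acoustic_channels": d.n_acoustic_channels,
                "sync_channel_index": d.sync_channel_index,
            }
            for d in layout.devices
        ],
        "mics": [
            {
                "mic_id": m.mic_id,
                "device_id": m.device_id,
                "position": m.position.tolist(),
                "gain": m.gain,
            }
            for m in layout.mics
        ],
    }


def _layout_from_dict(data: dict) -> ArrayLayout:
    if data.get("schema") != SCHEMA_VERSION:
        raise GeometryError(
            f"unsupported layout schema {data.get('schema')!r}; expected {SCHEMA_VERSION}"
        )
    med = data.get("medium", {})
    medium = Medium(
        temperature=med.get("temperature", 20.0),
        speed_of_sound=med.get("speed_of_sound"),
    )
    devices = [
        DeviceSpec(
            device_id=d["device_id"],
            sample_rate=d["sample_rate"],
            origin=np.asarray(d.get("origin", [0, 0, 0])),
            orientation=np.asarray(d.get("orientation", np.eye(3).tolist())),
            n_acoustic_channels=d.get("n_acoustic_channels", MAX_CHANNELS_PER_DEVICE),
            sync_channel_index=d.get("sync_channel_index", MAX_CHANNELS_PER_DEVICE),
        )
        for d in data["devices"]
    ]
    mics = [
        MicPose(
            mic_id=m["mic_id"],
            device_id=m["device_id"],
            position=np.asarray(m["position"]),
            gain=m.get("gain", 1.0),
        )
        for m in data["mics"]
    ]
    return ArrayLayout(devices=devices, mics=mics, medium=medium)


def write_layout(layout: ArrayLayout, path: str | Path) -> None:
    """Write a layout config (YAML unless the suffix is .json)."""
    path = Path(path)
    data = _layout_to_dict(layout)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_layout(path: str | Path) -> ArrayLayout:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _layout_from_dict(data)
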