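"""Beam-intensity images on a planar mic grid, focus/centroid statistics,
and homography-based video overlay.

Each detected call's per-mic window-max amplitudes become one image on the
grid (pixel = calibrated amplitude squared, i.e. linear power).  From that
image two per-call statistics are derived:

* level of focus — how spatially distributed the call's energy is.  It is
  the ratio s_w/s_u of the intensity-weighted RMS spread of mic positions
  about the intensity-weighted centroid to the uniform-weight RMS spread
  about the grid center (the maximally distributed reference).  0 means all
  energy on one mic; 1 means perfectly uniform; > 1 is possible for
  strongly multimodal footprints and is reported as-is.  This numeric
  definition is this package's convention: it is dimensionless, scale- and
  translation-invariant, and matches the verbal notion "higher = less
  focused" with a usable 0.5 working threshold.
* beam centroid — the intensity-weighted mean position on the grid, and its
  distance to a target (e.g. a prey item).

A 3x3 homography estimated from the four grid corners as seen in a video
frame warps the (interpolated, colormapped) image into the camera view for
alpha-blended overlays.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from scipy.interpolate import RectBivariateSpline
from skimage import transform as sktf

from .detection import Detection
from .geometry import ArrayLayout, GeometryError

__all__ = [
    "BeamMap",
    "Homography",
    "grid_shape_of_layout",
    "beam_image",
    "interpolate_image",
    "level_of_focus",
    "focus_filter",
    "beam_centroid",
    "centroid_distance",
    "homography_from_corners",
    "overlay",
    "overlay_sequence",
    "write_beam_table_csv",
]

DEFAULT_FOCUS_THRESHOLD = 0.5


@dataclass
class BeamMap:
    """One call's intensity footprint on the planar grid."""

    grid_intensity: np.ndarray  # (ny, nx) linear power, row j = y index
    x_coords: np.ndarray  # (nx,) m
    y_coords: np.ndarray  # (ny,) m
    call_id: int = 0
    time_s: float = 0.0
    interpolated: np.ndarray | None = None
    interp_x: np.ndarray | None = None
    interp_y: np.ndarray | None = None
    imputed: np.ndarray | None = None  # bool mask of neighbor-filled pixels

    @property
    def focus(self) -> float:
        return level_of_focus(self)

    @property
    def centroid(self) -> np.ndarray:
        return beam_centroid(self)


@dataclass(frozen=True)
class Homography:
    """3x3 projective map: grid-plane meters -> image pixels."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(H)) < 1e-12:
            raise ValueError("homography is singular")
        object.__setattr__(self, "matrix", H)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return homo[:, :2] / homo[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.matrix.tolist()}))


def grid_shape_of_layout(layout: ArrayLayout, tol: float = 1e-6):
    """Recover (x_coords, y_coords, index map) of a regular planar grid.

    Raises GeometryError if the mics are not coplanar in z or not on the
    tensor grid of their unique x and y coordinates.
    """
    P = layout.mic_positions
    if np.ptp(P[:, 2]) > tol:
        raise GeometryError("layout is not planar (z varies)")
    xs = np.unique(np.round(P[:, 0] / tol) * tol)
    ys = np.unique(np.round(P[:, 1] / tol) * tol)
    if len(xs) * len(ys) != len(P):
        raise GeometryError("mic positions do not form a regular grid")
    index = {}
    for m in layout.mics:
        i = int(np.argmin(np.abs(xs - m.position[0])))
        j = int(np.argmin(np.abs(ys - m.position[1])))
        index[m.mic_id] = (j, i)  # row = y index, col = x index
    return xs, ys, index


def beam_image(
    det: Detection,
    layout: ArrayLayout,
    min_coverage: float = 0.9,
) -> BeamMap:
    """Raw per-call intensity image: pixel (j, i) = amplitude^2 of mic (i, j).

    Missing mics (channels absent or not accepted) are filled with the mean
    of their valid 4-neighbors and flagged in ``imputed``; more than
    1 - min_coverage of the grid missing is an error.  The sum of pixels
    equals the sum of squared amplitudes over valid mics plus the imputed
    values (no normalization is applied).
    """
    xs, ys, index = grid_shape_of_layout(layout)
    ny, nx = len(ys), len(xs)
    img = np.full((ny, nx), np.nan)
    for k, cid in enumerate(det.channel_ids):
        if cid in index and det.accepted[k]:
            j, i = index[cid]
            img[j, i] = det.amplitude[k] ** 2
    missing = np.isnan(img)
    if missing.mean() > 1.0 - min_coverage:
        raise ValueError(
            f"only {100 * (1 - missing.mean()):.0f}% of mics have amplitudes; "
            f"need >= {100 * min_coverage:.0f}%"
        )
    if missing.any():
        filled = img.copy()
        for j, i in zip(*np.where(missing)):
            neigh = [
                img[jj, ii]
                for jj, ii in ((j - 1, i), (j + 1, i), (j, i - 1), (j, i + 1))
                if 0 <= jj < ny and 0 <= ii < nx and not np.isnan(img[jj, ii])
            ]
            filled[j, i] = np.mean(neigh) if neigh else 0.0
        img = filled
    return BeamMap(
        grid_intensity=img,
        x_coords=xs,
        y_coords=ys,
        call_id=det.call_id,
        time_s=det.anchor_time,
        imputed=missing,
    )


def interpolate_image(bmap: BeamMap, factor: int = 8) -> BeamMap:
    """Bicubic upsampling of the grid image for smoother display.

    The fine grid steps at 1/factor of the mic spacing, so every original
    node lands exactly on a fine sample and keeps its value (the output is
    ((ny-1)*factor+1) x ((nx-1)*factor+1); factor 1 is the identity).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        out = BeamMap(**{**bmap.__dict__})
        out.interpolated = bmap.grid_intensity.copy()
        out.interp_x = bmap.x_coords.copy()
        out.interp_y = bmap.y_coords.copy()
        return out
    ny, nx = bmap.grid_intensity.shape
    ky = min(3, ny - 1)
    kx = min(3, nx - 1)
    spline = RectBivariateSpline(
        bmap.y_coords, bmap.x_coords, bmap.grid_intensity, kx=kx, ky=ky
    )
    fx = np.linspace(bmap.x_coords[0], bmap.x_coords[-1], (nx - 1) * factor + 1)
    fy = np.linspace(bmap.y_coords[0], bmap.y_coords[-1], (ny - 1) * factor + 1)
    out = BeamMap(**{**bmap.__dict__})
    out.interpolated = spline(fy, fx)
    out.interp_x = fx
    out.interp_y = fy
    return out


def _weighted_spread(pos: np.ndarray, w: np.ndarray) -> float:
    cw = (pos * w[:, None]).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((pos - cw) ** 2, axis=1)).sum() / w.sum()))


def level_of_focus(bmap: BeamMap) -> float:
    """Spread ratio s_w/s_u in [0, ~]: 0 all energy on one mic, 1 uniform."""
    w = bmap.grid_intensity.ravel()
    if w.sum() <= 0:
        raise ValueError("level of focus undefined for zero total intensity")
    Xg, Yg = np.meshgrid(bmap.x_coords, bmap.y_coords)
    pos = np.column_stack([Xg.ravel(), Yg.ravel()])
    s_w = _weighted_spread(pos, w)
    s_u = _weighted_spread(pos, np.ones(len(pos)))
    return s_w / s_u


def focus_filter(maps: list[BeamMap], threshold: float = DEFAULT_FOCUS_THRESHOLD) -> list[BeamMap]:
    """Keep only maps with level of focus <= threshold (default 0.5)."""
    return [m for m in maps if level_of_focus(m) <= threshold]


def beam_centroid(bmap: BeamMap) -> np.ndarray:
    """Intensity-weighted centroid (x, y) in grid-plane meters."""
    w = bmap.grid_intensity
    if w.sum() <= 0:
        raise ValueError("centroid undefined for zero total intensity")
    Xg, Yg = np.meshgrid(bmap.x_coords, bmap.y_coords)
    return np.array([(w * Xg).sum(), (w * Yg).sum()]) / w.sum()


def centroid_distance(bmap: BeamMap, target: np.ndarray) -> float:
    """Euclidean distance from the beam centroid to a target point (m)."""
    return float(np.linalg.norm(beam_centroid(bmap) - np.asarray(target, dtype=float)[:2]))


def homography_from_corners(world_corners: np.ndarray, image_corners: np.ndarray) -> Homography:
    """DLT homography mapping 4 grid-plane corners (m) to pixel corners.

    Corners must be in consistent cyclic order with no three collinear.
    """
    src = np.asarray(world_corners, dtype=float).reshape(4, 2)
    dst = np.asarray(image_corners, dtype=float).reshape(4, 2)
    for pts in (src, dst):
        # degenerate if any three corners are collinear
        for drop in range(4):
            sub = np.delete(pts, drop, axis=0)
            u, v = sub[1] - sub[0], sub[2] - sub[0]
            area = u[0] * v[1] - u[1] * v[0]
            if abs(area) < 1e-12:
                raise ValueError("degenerate corner set (three collinear points)")
    tf = sktf.estimate_transform("projective", src, dst)
    if not np.all(np.isfinite(tf.params)):
        raise ValueError("homography estimation failed")
    return Homography(tf.params)


def overlay(
    bmap: BeamMap,
    H: Homography,
    frame: np.ndarray,
    alpha: float = 0.5,
    colormap: str = "hot",
) -> np.ndarray:
    """Alpha-blend the (interpolated) heatmap into a video frame.

    out = (1 - alpha) * frame + alpha * colormap(intensity) inside the
    warped grid quadrilateral; the frame is unchanged outside.  ``frame``
    is (h, w) gray or (h, w, 3) RGB with values in [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    img = bmap.interpolated if bmap.interpolated is not None else bmap.grid_intensity
    gx = bmap.interp_x if bmap.interpolated is not None else bmap.x_coords
    gy = bmap.interp_y if bmap.interpolated is not None else bmap.y_coords

    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 2:
        frame = np.repeat(frame[:, :, None], 3, axis=2)
    out = frame.copy()
    if alpha == 0.0:
        return out
    h, w = out.shape[:2]

    # pixel -> world meters -> heatmap pixel indices
    Hinv = H.inverse()
    sx = (len(gx) - 1) / (gx[-1] - gx[0])
    sy = (len(gy) - 1) / (gy[-1] - gy[0])

    def inverse_map(coords: np.ndarray) -> np.ndarray:
        # skimage passes/expects (col, row) = (x_px, y_px) coordinate pairs
        world = Hinv.apply(coords)
        cols = (world[:, 0] - gx[0]) * sx
        rows = (world[:, 1] - gy[0]) * sy
        return np.column_stack([cols, rows])

    norm = img / img.max() if img.max() > 0 else img
    warped = sktf.warp(norm, inverse_map, output_shape=(h, w), order=1,
                       mode="constant", cval=np.nan)
    inside = ~np.isnan(warped)
    heat = colormaps[colormap](np.nan_to_num(warped))[:, :, :3]
    out[inside] = (1.0 - alpha) * frame[inside] + alpha * heat[inside]
    return out


def overlay_sequence(
    maps: list[BeamMap],
    frame_times: np.ndarray,
    frames: list[np.ndarray],
    H: Homography,
    alpha: float = 0.5,
    colormap: str = "hot",
) -> list[np.ndarray]:
    """Overlay each frame with the most recent call's map.

    Frames before the first call (or with no calls at all) pass through
    unchanged; the overlay switches at each new call's time.
    """
    maps = sorted(maps, key=lambda m: m.time_s)
    call_times = np.array([m.time_s for m in maps])
    out = []
    for t, frame in zip(frame_times, frames):
        k = int(np.searchsorted(call_times, t, side="right")) - 1
        if k < 0:
            out.append(np.asarray(frame, dtype=float).copy())
        else:
            out.append(overlay(maps[k], H, frame, alpha=alpha, colormap=colormap))
    return out


def write_beam_table_csv(
    maps: list[BeamMap],
    path: str | Path,
    target: np.ndarray | None = None,
    surface_label: str = "",
) -> None:
    """Per-call statistics table, the input downstream group comparisons
    (e.g. surface-type mixed models) consume."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["call_id", "time_s", "focus", "centroid_x", "centroid_y",
                    "centroid_distance_m", "surface_label"])
        for m in maps:
            cx, cy = beam_centroid(m)
            dist = centroid_distance(m, target) if target is not None else ""
            w.writerow([m.call_id, repr(float(m.time_s)),
                        repr(level_of_focus(m)), repr(float(cx)), repr(float(cy)),
                        repr(float(dist)) if dist != "" else "", surface_label])
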