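"""Probabilistic TDoA and AoA localization.

TDoA: for a detected call with per-channel arrival times, the measured delay
differences relative to a reference channel are compared against the
geometric predictions on a 3D grid; a Gaussian timing-error model (std
sigma_t, independent across channels) turns the misfit into a normalized
likelihood over the grid.  The reported position is the MAP cell, with an
uncertainty cloud of all cells whose likelihood exceeds a fraction
(default 0.5) of the maximum.

AoA: a small-aperture array sees far-field sources, so its delays constrain
only the arrival direction.  The same Gaussian model over a discretized
hemisphere of unit directions yields a direction likelihood ("probabilistic
cone"); multiplying the cones of several arrays evaluated toward each 3D
grid point fuses them into a position estimate.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .detection import Detection
from .geometry import ArrayLayout

__all__ = [
    "LikelihoodGrid",
    "PositionEstimate",
    "DirectionLikelihood",
    "Path3D",
    "UnderdeterminedError",
    "tdoa_likelihood",
    "localize_call",
    "aoa_likelihood",
    "fuse_aoa",
    "build_path",
    "write_positions_csv",
]

DEFAULT_SIGMA_T = 2.0 / 450_000.0  # 2 samples at the nominal 450 kHz
DEFAULT_CREDIBILITY = 0.5
PLAUSIBLE_SPEED = 20.0  # m/s; path segments above this are flagged


class UnderdeterminedError(ValueError):
    """Too few accepted channels for a 3D fix."""


@dataclass
class LikelihoodGrid:
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]  # monotone coords, m
    values: np.ndarray  # (nx, ny, nz), non-negative
    normalized: bool = False

    def __post_init__(self) -> None:
        shape = tuple(len(a) for a in self.axes)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != axes shape {shape}")

    def normalize(self) -> "LikelihoodGrid":
        s = self.values.sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero likelihood")
        return LikelihoodGrid(self.axes, self.values / s, normalized=True)

    def argmax_point(self) -> np.ndarray:
        # deterministic tie-break: np.argmax takes the first (lexicographic) cell
        i, j, k = np.unravel_index(np.argmax(self.values), self.values.shape)
        return np.array([self.axes[0][i], self.axes[1][j], self.axes[2][k]])

    def points_above(self, fraction: float) -> np.ndarray:
        idx = np.argwhere(self.values >= fraction * self.values.max())
        return np.column_stack([self.axes[d][idx[:, d]] for d in range(3)])


@dataclass
class PositionEstimate:
    map_point: np.ndarray
    uncertainty_points: np.ndarray  # (m, 3) grid cells above the fraction
    credibility_fraction: float = DEFAULT_CREDIBILITY
    range_ambiguous: bool = False
    grid: LikelihoodGrid | None = None

    def __post_init__(self) -> None:
        if len(self.uncertainty_points) and not np.any(
            np.all(np.isclose(self.uncertainty_points, self.map_point), axis=1)
        ):
            raise ValueError("map_point must be one of the uncertainty points")


@dataclass
class DirectionLikelihood:
    """Likelihood over the front hemisphere of arrival directions.

    Azimuth CCW from local +x (deg, grid over [0, 360)); elevation above
    the array plane (deg, grid over [0, 90]).  A planar array cannot tell
    mirror directions through its own plane apart, so only the +z (front)
    hemisphere is represented.  Normalization weights cells by solid angle.
    """

    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    values: np.ndarray  # (n_az, n_el)
    origin: np.ndarray  # array centroid, global frame
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def normalize(self) -> "DirectionLikelihood":
        w = np.cos(np.radians(self.elevation_deg))[np.newaxis, :]
        s = (self.values * w).sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero likelihood")
        return DirectionLikelihood(
            self.azimuth_deg, self.elevation_deg, self.values / s,
            self.origin, self.orientation,
        )

    def map_direction(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.azimuth_deg[i]), float(self.elevation_deg[j])

    def values_toward(self, points: np.ndarray) -> np.ndarray:
        """Nearest-cell likelihood of the directions from the array to points.

        Points behind the array plane (negative local elevation) get 0.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - self.origin) @ self.orientation  # rows in local frame
        r = np.linalg.norm(local, axis=1)
        ok = r > 0
        out = np.zeros(len(pts))
        el = np.degrees(np.arcsin(np.clip(local[ok, 2] / r[ok], -1.0, 1.0)))
        az = np.degrees(np.arctan2(local[ok, 1], local[ok, 0])) % 360.0
        # the az/el grids are uniform, so nearest cell is direct rounding
        az_step = self.azimuth_deg[1] - self.azimuth_deg[0]
        el_step = self.elevation_deg[1] - self.elevation_deg[0]
        i = np.round((az - self.azimuth_deg[0]) / az_step).astype(int) % len(self.azimuth_deg)
        j = np.clip(np.round((el - self.elevation_deg[0]) / el_step).astype(int),
                    0, len(self.elevation_deg) - 1)
        vals = self.values[i, j]
        vals[el < 0] = 0.0  # behind the array plane
        out[ok] = vals
        return out

    def value_toward(self, point: np.ndarray) -> float:
        """Nearest-cell likelihood of the direction from the array to a point."""
        return float(self.values_toward(np.asarray(point))[0])


@dataclass
class Path3D:
    """Time-ordered sequence of position estimates (a flight path)."""

    times: np.ndarray
    estimates: list[PositionEstimate]
    segment_speeds: np.ndarray  # m/s, len n-1
    implausible: np.ndarray  # bool, len n-1

    @property
    def points(self) -> np.ndarray:
        return np.array([e.map_point for e in self.estimates])


def _detection_subset(det: Detection, layout: ArrayLayout):
    """Accepted channels with known mic positions; returns (positions, times,
    qualities) in detection channel order."""
    pos_by_id = {m.mic_id: m.position for m in layout.mics}
    rows = [
        (pos_by_id[cid], det.arrival_time[k], det.quality[k])
        for k, cid in enumerate(det.channel_ids)
        if det.accepted[k] and cid in pos_by_id
    ]
    if not rows:
        return np.empty((0, 3)), np.empty(0), np.empty(0)
    P = np.array([r[0] for r in rows])
    t = np.array([r[1] for r in rows])
    q = np.array([r[2] for r in rows])
    return P, t, q


def tdoa_likelihood(
    det: Detection,
    layout: ArrayLayout,
    grid_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    sigma_t: float = DEFAULT_SIGMA_T,
    c: float | None = None,
    allow_underdetermined: bool = False,
    grid_quantization: bool = True,
) -> LikelihoodGrid:
    """Normalized TDoA likelihood of a call's origin over a 3D grid.

    The reference channel is the highest-quality accepted channel.  For a
    grid point p, the model predicts the delay difference of channel i
    relative to the reference as (|p - m_i| - |p - m_ref|)/c, and the
    log-likelihood is the per-channel mean Gaussian misfit

        loglik(p) = -mean_i (Delta_i - pred_i)^2 / (2 sigma_eff^2).

    Two conventions here matter for how the 0.5-fraction uncertainty cloud
    behaves and are deliberate:

    * ``sigma_eff`` inflates ``sigma_t`` with the timing error implied by
      evaluating only at cell centers, sigma_q = cell/(2c) (half a cell of
      unmodeled path length).  Without it, any grid coarser than c*sigma_t
      (a few mm at 450 kHz) yields meaninglessly overconfident posteriors.
      Disable with ``grid_quantization=False`` when the grid is fine.
    * the *mean* (not sum) over channels keeps the likelihood-fraction
      cloud's spatial extent independent of channel count; a summed misfit
      would shrink the displayed uncertainty as 1/sqrt(n_mics) and collapse
      it to a single cell for dense arrays.

    Fewer than 4 accepted channels cannot pin down a 3D position; that
    raises UnderdeterminedError unless ``allow_underdetermined`` is set
    (useful to inspect the ambiguity surface itself, e.g. the two-mic
    hyperboloid).
    """
    if sigma_t <= 0:
        raise ValueError("sigma_t must be > 0")
    c = layout.medium.c if c is None else c
    if grid_quantization:
        steps = [np.mean(np.diff(a)) for a in grid_axes if len(a) > 1]
        sigma_t = float(np.hypot(sigma_t, np.mean(steps) / (2.0 * c)))
    P, t, q = _detection_subset(det, layout)
    if len(P) < 4 and not allow_underdetermined:
        raise UnderdeterminedError(
            f"need >= 4 accepted channels for a 3D fix, have {len(P)}"
        )
    if len(P) < 2:
        raise UnderdeterminedError("need >= 2 accepted channels")
    ref = int(np.argmax(q))
    delta = t - t[ref]  # measured delay differences, s

    ax, ay, az = (np.asarray(a, dtype=float) for a in grid_axes)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)  # (nx, ny, nz, 3)
    dists = np.linalg.norm(pts[..., np.newaxis, :] - P, axis=-1)  # (...,n_mics)
    pred = (dists - dists[..., ref: ref + 1]) / c
    loglik = -np.mean((delta - pred) ** 2, axis=-1) / (2.0 * sigma_t**2)
    loglik -= loglik.max()
    return LikelihoodGrid((ax, ay, az), np.exp(loglik)).normalize()


def localize_call(
    det: Detection,
    layout: ArrayLayout,
    grid_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    sigma_t: float = DEFAULT_SIGMA_T,
    c: float | None = None,
    credibility_fraction: float = DEFAULT_CREDIBILITY,
) -> PositionEstimate:
    """MAP position with its credibility cloud (cells >= fraction of max)."""
    grid = tdoa_likelihood(det, layout, grid_axes, sigma_t=sigma_t, c=c)
    return PositionEstimate(
        map_point=grid.argmax_point(),
        uncertainty_points=grid.points_above(credibility_fraction),
        credibility_fraction=credibility_fraction,
        grid=grid,
    )


def aoa_likelihood(
    arrival_times: np.ndarray,
    local_positions: np.ndarray,
    sigma_t: float = DEFAULT_SIGMA_T,
    c: float = 343.0,
    az_step_deg: float = 2.0,
    el_step_deg: float = 2.0,
    origin: np.ndarray | None = None,
    orientation: np.ndarray | None = None,
) -> DirectionLikelihood:
    """Far-field direction likelihood for one small-scale array.

    ``local_positions`` are the (n, >=2) mic coordinates in the array's own
    frame (z = board normal); ``arrival_times`` the per-mic arrivals.  For a
    unit direction u the predicted relative delay at mic i (about the array
    centroid) is -(x_i . u)/c; measured and predicted delays are both
    centered before the Gaussian misfit, which removes the unknown emission
    time.  The result is normalized over the front hemisphere with
    solid-angle weighting.
    """
    t = np.asarray(arrival_times, dtype=float)
    X = np.asarray(local_positions, dtype=float)
    if X.shape[1] == 2:
        X = np.column_stack([X, np.zeros(len(X))])
    if len(t) != len(X):
        raise ValueError("one arrival time per microphone required")
    if len(t) < 3:
        raise UnderdeterminedError("need >= 3 mics for a direction estimate")
    Xc = X - X.mean(axis=0)
    tc = t - t.mean()

    az = np.arange(0.0, 360.0, az_step_deg)
    el = np.arange(0.0, 90.0 + 1e-9, el_step_deg)
    A, E = np.meshgrid(np.radians(az), np.radians(el), indexing="ij")
    U = np.stack(
        [np.cos(E) * np.cos(A), np.cos(E) * np.sin(A), np.sin(E)], axis=-1
    )  # (n_az, n_el, 3) unit directions, local frame
    pred = -np.tensordot(U, Xc.T, axes=1) / c  # (n_az, n_el, n_mics)
    pred -= pred.mean(axis=-1, keepdims=True)
    loglik = -np.sum((tc - pred) ** 2, axis=-1) / (2.0 * sigma_t**2)
    loglik -= loglik.max()
    like = DirectionLikelihood(
        azimuth_deg=az,
        elevation_deg=el,
        values=np.exp(loglik),
        origin=(np.zeros(3) if origin is None else np.asarray(origin, dtype=float)),
        orientation=(np.eye(3) if orientation is None else np.asarray(orientation)),
    )
    return like.normalize()


def fuse_aoa(
    direction_likelihoods: list[DirectionLikelihood],
    grid_axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    credibility_fraction: float = DEFAULT_CREDIBILITY,
) -> PositionEstimate:
    """Intersect the probabilistic cones of several arrays on a 3D grid.

    Each array's direction likelihood is evaluated (nearest cell) along the
    direction from that array's centroid to each grid point, the per-array
    values are multiplied and normalized.  A single array yields a valid
    posterior but only constrains direction, not range; that estimate is
    returned flagged ``range_ambiguous``.
    """
    if not direction_likelihoods:
        raise ValueError("need at least one direction likelihood")
    ax, ay, az = (np.asarray(a, dtype=float) for a in grid_axes)
    X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    log_post = np.zeros(len(pts))
    for dl in direction_likelihoods:
        log_post += np.log(np.maximum(dl.values_toward(pts), 1e-300))
    log_post -= log_post.max()
    values = np.exp(log_post).reshape(X.shape)
    grid = LikelihoodGrid((ax, ay, az), values).normalize()
    return PositionEstimate(
        map_point=grid.argmax_point(),
        uncertainty_points=grid.points_above(credibility_fraction),
        credibility_fraction=credibility_fraction,
        range_ambiguous=len(direction_likelihoods) < 2,
        grid=grid,
    )


def build_path(
    estimates: list[tuple[float, PositionEstimate]],
    plausible_speed: float = PLAUSIBLE_SPEED,
) -> Path3D:
    """Connect per-call position estimates into a time-ordered flight path.

    Input order does not matter (sorted internally); duplicate timestamps
    are an error.  Per-segment speeds are computed and segments exceeding
    ``plausible_speed`` are flagged.
    """
    if not estimates:
        raise ValueError("no estimates")
    items = sorted(estimates, key=lambda te: te[0])
    times = np.array([t for t, _ in items])
    if np.any(np.diff(times) == 0):
        raise ValueError("duplicate timestamps in path input")
    ests = [e for _, e in items]
    pts = np.array([e.map_point for e in ests])
    if len(pts) > 1:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) / np.diff(times)
    else:
        seg = np.empty(0)
    return Path3D(
        times=times,
        estimates=ests,
        segment_speeds=seg,
        implausible=seg > plausible_speed,
    )


def write_positions_csv(
    path: str | Path,
    times: np.ndarray,
    estimates: list[PositionEstimate],
    call_ids: list[int] | None = None,
) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["call_id", "t_s", "x", "y", "z", "n_uncertainty_points"])
        for k, (t, est) in enumerate(zip(times, estimates)):
            cid = call_ids[k] if call_ids is not None else k
            w.writerow([
                cid, repr(float(t)),
                repr(float(est.map_point[0])), repr(float(est.map_point[1])),
                repr(float(est.map_point[2])), len(est.uncertainty_points),
            ])
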