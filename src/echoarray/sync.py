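"""Cross-device synchronization via an embedded pseudo-random binary sequence.

A shared 1-bit PRBS is recorded alongside the data on every device (an audio
channel, an LED in a video, a marker in a motion-capture stream).  Because
the PRBS autocorrelation has a single sharp peak, cross-correlating the sync
tracks of two devices recovers their constant clock offset to about one
sample period of the slower device.

Parameter selection follows a simple rule set: with f_min the slowest device
rate and T_s = 1/f_min, the PRBS must hold each state at least P_min = 2*T_s
(so every transition spans >= 2 samples on the slowest device).  For a
minimal synchronizable fragment of L samples at f_min, the expected number
of transitions is

    K = 2 * L * T_s / (P_min * (P_max/P_min + 1)),

i.e. the fragment duration divided by the mean hold period
(P_min + P_max)/2.  P_max is chosen as the largest integer multiple of
P_min that keeps K above 10; more transitions sharpen the correlation peak,
longer holds let slow devices resolve them.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_chain import DeviceRecording, PcmRecording

logger = logging.getLogger(__name__)

__all__ = [
    "SyncParams",
    "PrbsSchedule",
    "OffsetEstimate",
    "SyncInfeasibleError",
    "derive_sync_params",
    "expected_transitions",
    "generate_schedule",
    "sample_schedule",
    "estimate_offset",
    "align_recordings",
    "write_schedule",
    "read_schedule",
]

MIN_QUALITY_FACTOR = 10.0  # minimum acceptable expected transition count
DEFAULT_QUALITY_THRESHOLD = 2.0  # peak-to-sidelobe below this => low confidence


class SyncInfeasibleError(ValueError):
    """No PRBS parameter set satisfies the transition-count constraint."""


@dataclass(frozen=True)
class SyncParams:
    f_min: float  # slowest device rate, Hz
    T_s: float  # largest sampling period, s
    P_min: float  # minimal hold period, s (= 2*T_s)
    P_max: float  # maximal hold period, s
    L: int  # minimal synchronizable fragment, samples at f_min
    K: float  # expected transition count within the fragment

    def __post_init__(self) -> None:
        if not self.P_max >= self.P_min > 0:
            raise ValueError("need P_max >= P_min > 0")


@dataclass
class PrbsSchedule:
    """State-transition schedule of the 1-bit sync signal."""

    seed: int
    transitions: list[tuple[float, int]]  # (time s, new state in {0,1})
    total_duration: float
    P_min: float
    P_max: float

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Schedule state at arbitrary times (vectorized, zero-order hold)."""
        t = np.asarray(t, dtype=float)
        times = np.array([tr[0] for tr in self.transitions])
        states = np.array([tr[1] for tr in self.transitions])
        idx = np.searchsorted(times, t, side="right") - 1
        idx = np.clip(idx, 0, len(states) - 1)
        return states[idx].astype(np.int8)


@dataclass(frozen=True)
class OffsetEstimate:
    offset: float  # seconds by which track B lags track A
    peak: float  # correlation value at the main peak
    quality: float  # main peak / largest sidelobe outside +-P_min
    low_confidence: bool = False


def expected_transitions(L: int, T_s: float, P_min: float, P_max: float) -> float:
    """Expected number of PRBS transitions in a fragment of L samples.

    K = 2*L*T_s / (P_min * (P_max/P_min + 1)) — the fragment duration
    L*T_s divided by the mean hold period (P_min + P_max)/2.
    """
    if not P_max >= P_min > 0:
        raise ValueError("need P_max >= P_min > 0")
    return 2.0 * L * T_s / (P_min * (P_max / P_min + 1.0))


def derive_sync_params(
    sample_rates: list[float],
    min_fragment: float,
    k_min: float = MIN_QUALITY_FACTOR,
    max_ratio: int = 10_000,
) -> SyncParams:
    """Select PRBS hold-period bounds for a set of heterogeneous devices.

    T_s = 1/min(rates); P_min = 2*T_s; L = round(min_fragment * f_min).
    P_max is the largest integer multiple r of P_min keeping the expected
    transition count K strictly above ``k_min`` (with P_min = 2*T_s the
    count reduces to K = L/(r+1), so the search is exact).
    """
    if not sample_rates:
        raise ValueError("need at least one sample rate")
    if min_fragment <= 0:
        raise ValueError("min_fragment must be > 0")
    f_min = float(min(sample_rates))
    T_s = 1.0 / f_min
    P_min = 2.0 * T_s
    L = int(round(min_fragment * f_min))
    # K(r) = L/(r+1) exactly; largest integer r with K(r) > k_min
    best_r = 0
    for r in range(1, max_ratio + 1):
        if L / (r + 1.0) > k_min:
            best_r = r
        else:
            break
    if best_r == 0:
        raise SyncInfeasibleError(
            f"no P_max >= P_min keeps K above {k_min}: fragment of L={L} "
            f"samples allows at most K={L / 2.0:.2f} at P_max=P_min; "
            "increase min_fragment or the slowest sample rate"
        )
    P_max = best_r * P_min
    K = expected_transitions(L, T_s, P_min, P_max)
    return SyncParams(f_min=f_min, T_s=T_s, P_min=P_min, P_max=P_max, L=L, K=K)


def generate_schedule(duration: float, params: SyncParams, seed: int) -> PrbsSchedule:
    """Draw a PRBS schedule: alternating states, hold times i.i.d. uniform
    on [P_min, P_max].  Reproducible for a fixed seed."""
    if duration <= params.P_min:
        raise ValueError("duration must exceed P_min")
    rng = np.random.default_rng(seed)
    transitions: list[tuple[float, int]] = []
    t = 0.0
    state = int(rng.integers(0, 2))
    while t < duration:
        transitions.append((t, state))
        t += rng.uniform(params.P_min, params.P_max)
        state ^= 1
    return PrbsSchedule(
        seed=seed,
        transitions=transitions,
        total_duration=duration,
        P_min=params.P_min,
        P_max=params.P_max,
    )


def sample_schedule(
    schedule: PrbsSchedule, rate: float, start_offset: float = 0.0,
    n_samples: int | None = None,
) -> np.ndarray:
    """Sample the schedule on a device clock: track[k] = state at
    start_offset + k/rate.  Models any modality (audio channel, LED in
    video frames, motion-capture marker visibility)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if n_samples is None:
        n_samples = int(np.floor((schedule.total_duration - start_offset) * rate))
    t = start_offset + np.arange(n_samples) / rate
    return schedule.state_at(t)


def _as_centered(track: np.ndarray) -> np.ndarray:
    # states {0,1} -> {-1,+1}, then mean-centered
    x = np.asarray(track, dtype=float) * 2.0 - 1.0
    return x - x.mean()


def estimate_offset(
    track_a: np.ndarray,
    rate_a: float,
    track_b: np.ndarray,
    rate_b: float,
    exclusion: float | None = None,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
) -> OffsetEstimate:
    """Clock offset between two sync tracks by cross-correlation.

    Both tracks are mean-centered, resampled to the faster of the two rates
    by zero-order hold (the PRBS is genuinely piecewise-constant), and fully
    cross-correlated.  The returned offset is the time by which B lags A:
    shifting B's timeline by -offset aligns it with A.

    Quality is the main peak divided by the largest correlation outside
    +-``exclusion`` of it.  The correlation main lobe of a PRBS is as wide
    as its hold times, so the exclusion defaults to the longest hold
    observed in the track (approximately P_max); pass it explicitly when
    the schedule parameters are known.
    """
    rate = max(rate_a, rate_b)

    def upsample(track: np.ndarray, r: float) -> np.ndarray:
        if r == rate:
            return np.asarray(track, dtype=float)
        # zero-order hold onto the fast clock
        n = int(np.floor(len(track) * rate / r))
        idx = np.minimum((np.arange(n) * r / rate).astype(int), len(track) - 1)
        return np.asarray(track, dtype=float)[idx]

    a = _as_centered(upsample(track_a, rate_a))
    b = _as_centered(upsample(track_b, rate_b))
    corr = sps.correlate(a, b, mode="full", method="fft")
    lags = sps.correlation_lags(len(a), len(b), mode="full")
    peak_i = int(np.argmax(corr))
    # correlate(a, b) peaks at lag d when b[n] ≈ a[n + d]; B's content
    # occurs later in A, i.e. B's clock started late: B lags A by d/rate.
    offset = lags[peak_i] / rate
    peak = float(corr[peak_i])

    if exclusion is None:
        exclusion = _estimate_p_max(a, rate)
    excl = max(1, int(round(exclusion * rate)))
    mask = np.ones_like(corr, dtype=bool)
    mask[max(0, peak_i - excl): peak_i + excl + 1] = False
    sidelobe = float(np.max(corr[mask])) if mask.any() else 0.0
    quality = peak / sidelobe if sidelobe > 0 else np.inf
    low = quality < quality_threshold
    if low:
        logger.warning(
            "low-confidence offset: quality %.2f < %.2f", quality, quality_threshold
        )
    return OffsetEstimate(offset=offset, peak=peak, quality=quality,
                          low_confidence=low)


def _estimate_p_max(track: np.ndarray, rate: float) -> float:
    """Longest observed hold time of a sampled PRBS track, in seconds."""
    edges = np.flatnonzero(np.diff(np.sign(track + 1e-12)))
    if len(edges) < 2:
        return 1.0 / rate
    return float(np.max(np.diff(edges))) / rate


def align_recordings(
    recordings: list[DeviceRecording],
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    force: bool = False,
) -> list[DeviceRecording]:
    """Shift a set of device recordings onto a common timeline.

    The reference device is the one with the highest sample rate (ties
    broken by device_id order).  Pairwise offsets are estimated from the
    embedded sync tracks; each recording's acoustic channels are shifted by
    an integer number of its own samples and all recordings are trimmed to
    the common overlap.  Any low-confidence offset refuses alignment unless
    ``force`` is given.
    """
    if len(recordings) <= 1:
        return list(recordings)
    for rec in recordings:
        if rec.sync_channel_index is None:
            raise ValueError(f"recording {rec.device_id} has no sync track")

    ref = sorted(recordings, key=lambda r: (-r.rate, r.device_id))[0]
    ref_sync = ref.samples[ref.sync_channel_index] > 0.5

    offsets: dict[str, float] = {}
    for rec in recordings:
        if rec is ref:
            offsets[rec.device_id] = 0.0
            continue
        sync = rec.samples[rec.sync_channel_index] > 0.5
        est = estimate_offset(ref_sync, ref.rate, sync, rec.rate,
                              quality_threshold=quality_threshold)
        if est.low_confidence and not force:
            raise ValueError(
                f"low-confidence sync between {ref.device_id} and "
                f"{rec.device_id} (quality {est.quality:.2f}); pass force=True "
                "to align anyway"
            )
        offsets[rec.device_id] = est.offset

    # Device d's sample k is at common time offset_d + k/rate_d.  Trim all
    # recordings to the overlapping window [t0, t1).
    t0 = max(offsets[r.device_id] for r in recordings)
    t1 = min(offsets[r.device_id] + r.duration for r in recordings)
    if t1 <= t0:
        raise ValueError("recordings do not overlap after offset compensation")

    aligned = []
    for rec in recordings:
        off = offsets[rec.device_id]
        i0 = int(np.ceil((t0 - off) * rec.rate - 1e-9))
        i1 = int(np.floor((t1 - off) * rec.rate + 1e-9))
        i1 = min(i1, rec.n_samples)
        aligned.append(
            DeviceRecording(
                samples=rec.samples[:, i0:i1],
                rate=rec.rate,
                channel_ids=list(rec.channel_ids),
                sync_channel_index=rec.sync_channel_index,
                start_time=off + i0 / rec.rate,
                device_id=rec.device_id,
            )
        )
    return aligned


# ---------------------------------------------------------------------------
# Serialization: schedule as CSV (time_s, state) + JSON header.

def write_schedule(schedule: PrbsSchedule, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "state"])
        for t, s in schedule.transitions:
            w.writerow([repr(t), s])
    header = {
        "seed": schedule.seed,
        "P_min": schedule.P_min,
        "P_max": schedule.P_max,
        "total_duration": schedule.total_duration,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))


def read_schedule(path: str | Path) -> PrbsSchedule:
    path = Path(path)
    transitions = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            transitions.append((float(row["time_s"]), int(row["state"])))
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PrbsSchedule(
        seed=header["seed"],
        transitions=transitions,
        total_duration=header["total_duration"],
        P_min=header["P_min"],
        P_max=header["P_max"],
    )
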