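"""Matched-filter call detection and per-channel arrival/amplitude extraction.

Arrival times are found by correlating each channel with a known call
template (a generalized cross-correlation; plain weighting by default, PHAT
optional).  Candidate calls are anchored on the globally strongest channel's
correlation peaks, then refined per channel within a short window, because
the same call arrives at slightly different times across the array.  A
peak-to-sidelobe quality ratio rejects channels where the correlation is no
longer a single sharp peak (reverberant or distorted arrivals).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .signal_chain import GainVector, PcmRecording, apply_gains

__all__ = [
    "CallTemplate",
    "Detection",
    "DetectionConfig",
    "matched_filter",
    "detect_calls",
    "peak_quality",
    "write_detections_csv",
]


@dataclass(frozen=True)
class CallTemplate:
    waveform: np.ndarray
    rate: float
    label: str = "call"

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        if not np.any(w != 0):
            raise ValueError("template has zero energy")
        object.__setattr__(self, "waveform", w)

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.rate

    def resampled_to(self, rate: float) -> "CallTemplate":
        if rate == self.rate:
            return self
        n = int(round(len(self.waveform) * rate / self.rate))
        return CallTemplate(
            waveform=sps.resample(self.waveform, n), rate=rate, label=self.label
        )


@dataclass
class DetectionConfig:
    """window: per-channel arrival-time tolerance around the anchor (s);
    min_gap: minimum spacing between distinct calls (s); the window must be
    short enough that two calls never share one window (window < min_gap)."""

    window: float = 0.010
    min_gap: float = 0.030
    quality_threshold: float = 2.0
    noise_floor_factor: float = 6.0  # candidate threshold, x median |corr|
    min_correlation: float = 0.2  # absolute floor on the normalized trace
    rel_peak_fraction: float = 0.3  # candidates must reach this x global max

    def __post_init__(self) -> None:
        if not self.window < self.min_gap:
            raise ValueError("window must be shorter than min_gap")


@dataclass
class Detection:
    """One detected call: per-channel arrivals on the common timeline."""

    call_id: int
    channel_ids: list[str]
    arrival_time: np.ndarray  # s, per channel
    amplitude: np.ndarray  # window-max of the calibrated envelope
    quality: np.ndarray  # peak-to-sidelobe ratio per channel
    accepted: np.ndarray  # bool per channel

    @property
    def anchor_time(self) -> float:
        return float(np.median(self.arrival_time[self.accepted])) if self.accepted.any() \
            else float(np.median(self.arrival_time))

    def n_accepted(self) -> int:
        return int(self.accepted.sum())


def matched_filter(
    signal: np.ndarray,
    template: CallTemplate,
    phat: bool = False,
) -> np.ndarray:
    """Normalized cross-correlation of a channel with the call template.

    trace[i] is the normalized correlation of the template aligned with its
    *start* at sample i (so the argmax indexes the call's arrival sample).
    The trace has the same length as the signal.  With ``phat`` the
    correlation is computed with PHAT spectral weighting (magnitude-
    whitened cross spectrum); the trace is then scale-free, not
    unit-normalized.
    """
    x = np.asarray(signal, dtype=float)
    h = template.waveform
    if len(h) > len(x):
        raise ValueError("template longer than signal")
    if phat:
        nfft = int(2 ** np.ceil(np.log2(len(x) + len(h))))
        X = np.fft.rfft(x, nfft)
        Hc = np.conj(np.fft.rfft(h, nfft))
        cross = X * Hc
        mag = np.abs(cross)
        cross = cross / np.maximum(mag, 1e-12 * mag.max() if mag.max() > 0 else 1.0)
        full = np.fft.irfft(cross, nfft)
        return full[: len(x)]
    corr = sps.correlate(x, h, mode="full", method="fft")[len(h) - 1:]
    # local-energy normalization: value 1 iff the window equals the template
    energy = sps.correlate(x * x, np.ones(len(h)), mode="full", method="fft")[len(h) - 1:]
    energy = np.maximum(energy, 0.0)
    denom = np.sqrt(energy * np.sum(h * h))
    floor = 1e-12 * denom.max() if denom.max() > 0 else 1.0
    return corr / np.maximum(denom, floor)


def peak_quality(trace: np.ndarray, peak_index: int, exclusion_samples: int) -> float:
    """Main-peak value / largest |trace| outside +-exclusion of the peak.

    A clean matched-filter response has a single sharp peak (high ratio);
    reverberant or distorted arrivals produce multiple lower peaks and a
    ratio near 1.  A flat trace returns 1.
    """
    trace = np.asarray(trace, dtype=float)
    if not 0 <= peak_index < len(trace):
        raise IndexError("peak_index outside trace")
    main = abs(trace[peak_index])
    mask = np.ones(len(trace), dtype=bool)
    lo = max(0, peak_index - exclusion_samples)
    mask[lo: peak_index + exclusion_samples + 1] = False
    if not mask.any():
        return 1.0
    sidelobe = np.max(np.abs(trace[mask]))
    if sidelobe == 0:
        return np.inf if main > 0 else 1.0
    return float(main / sidelobe)


def detect_calls(
    rec: PcmRecording,
    template: CallTemplate,
    cfg: DetectionConfig | None = None,
    gains: GainVector | None = None,
    phat: bool = False,
) -> list[Detection]:
    """Detect calls in an aligned multichannel recording.

    Candidate call times are peaks of the strongest channel's correlation,
    separated by at least ``min_gap`` and above a noise floor.  For each
    candidate, every channel's arrival time is the correlation argmax within
    +-window of the anchor, its amplitude the max of the calibrated signal's
    analytic (Hilbert) envelope in that window, and its quality the local
    peak-to-sidelobe ratio; channels below the quality threshold are flagged
    not-accepted.  Detections are ordered by time.
    """
    cfg = cfg or DetectionConfig()
    if gains is not None:
        rec = apply_gains(rec, gains)
    ch_idx = rec.acoustic_channel_indices()
    tmpl = template.resampled_to(rec.rate)
    rate = rec.rate

    traces = np.array([matched_filter(rec.samples[i], tmpl, phat=phat) for i in ch_idx])
    envelopes = np.abs(sps.hilbert(rec.samples[ch_idx], axis=1))

    # anchor channel: largest correlation peak anywhere
    flat = np.unravel_index(np.argmax(np.abs(traces)), traces.shape)
    anchor = traces[flat[0]]
    floor = max(
        cfg.noise_floor_factor * float(np.median(np.abs(anchor))),
        cfg.min_correlation,
        cfg.rel_peak_fraction * float(np.max(np.abs(anchor))),
    )
    dist = max(1, int(round(cfg.min_gap * rate)))
    peaks, _ = sps.find_peaks(np.abs(anchor), height=floor, distance=dist)
    if len(peaks) == 0:
        return []

    win = max(1, int(round(cfg.window * rate)))
    excl = max(1, len(tmpl.waveform) // 2)
    seg_half = max(win + excl + 1, int(round(cfg.min_gap * rate / 2)))
    detections = []
    for cid, p in enumerate(np.sort(peaks)):
        arrivals = np.empty(len(ch_idx))
        amps = np.empty(len(ch_idx))
        quals = np.empty(len(ch_idx))
        for k in range(len(ch_idx)):
            a = max(0, p - win)
            b = min(traces.shape[1], p + win + 1)
            local = int(np.argmax(np.abs(traces[k, a:b]))) + a
            arrivals[k] = rec.start_time + local / rate
            amps[k] = float(np.max(envelopes[k, a:b]))
            # quality within a min_gap-sized segment so neighboring calls do
            # not masquerade as sidelobes
            s0 = max(0, local - seg_half)
            s1 = min(traces.shape[1], local + seg_half + 1)
            quals[k] = peak_quality(traces[k, s0:s1], local - s0, excl)
        detections.append(
            Detection(
                call_id=cid,
                channel_ids=[rec.channel_ids[i] for i in ch_idx],
                arrival_time=arrivals,
                amplitude=amps,
                quality=quals,
                accepted=quals >= cfg.quality_threshold,
            )
        )
    return detections


def write_detections_csv(detections: list[Detection], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["call_id", "mic_id", "arrival_time_s", "amplitude",
                    "quality", "accepted"])
        for det in detections:
            for k, cid in enumerate(det.channel_ids):
                w.writerow([
                    det.call_id, cid, repr(float(det.arrival_time[k])),
                    repr(float(det.amplitude[k])), repr(float(det.quality[k])),
                    int(det.accepted[k]),
                ])
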