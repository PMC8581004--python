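"""Capture-capacity math, PDM-to-PCM conditioning, triggering, gains, WAV I/O.

The recording devices store a 1-bit pulse-density-modulated (PDM) stream per
microphone at a nominal 4.5 MHz.  Offline, the bitstream is low-pass
filtered (6th-order Butterworth, f_c = 100 kHz), quantized to the 16-bit
grid and decimated by an integer factor (4.5 MHz -> 450 kHz is factor 10).

The filter is applied as a single causal pass by default, matching the
one-way magnitude response 1/sqrt(1 + (f/f_c)^(2*order)) that the capture
chain realizes; pass ``zero_phase=True`` for forward-backward filtering
when group delay matters more than matching that response.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "PdmStream",
    "PcmRecording",
    "DeviceRecording",
    "CaptureSpec",
    "GainVector",
    "pad_channels",
    "max_capture_duration",
    "pdm_decode",
    "trigger_save",
    "calibrate_gains",
    "apply_gains",
    "read_wav",
    "write_wav",
]

PDM_RATE = 4.5e6  # nominal microphone bit rate, Hz
PCM_RATE = 450_000.0  # nominal decoded audio rate, Hz
DEFAULT_CUTOFF = 100_000.0  # Butterworth low-pass cutoff f_c, Hz
DEFAULT_ORDER = 6

_Q15 = 32767  # 16-bit full scale


@dataclass(frozen=True)
class PdmStream:
    """1-bit pulse-density stream; values in {0, 1}."""

    bits: np.ndarray
    rate: float = PDM_RATE

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.size and not np.isin(bits, (0, 1)).all():
            raise ValueError("PDM bits must be 0/1")
        object.__setattr__(self, "bits", bits.astype(np.uint8))


@dataclass
class PcmRecording:
    """Multichannel PCM audio: (channels, time) float matrix in [-1, 1]."""

    samples: np.ndarray
    rate: float
    channel_ids: list[str] = field(default_factory=list)
    sync_channel_index: int | None = None
    start_time: float = 0.0  # seconds on the common timeline, if aligned

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def acoustic_channel_indices(self) -> list[int]:
        return [i for i in range(self.n_channels) if i != self.sync_channel_index]


# A device recording is a PCM recording that knows which device produced it;
# the sync track is one row of the channel matrix, on the device's own clock.
@dataclass
class DeviceRecording(PcmRecording):
    device_id: str = ""


@dataclass(frozen=True)
class CaptureSpec:
    """Memory-limited capture capacity of one recording device.

    D = 8 * mem / (f_s * n_c): mem in bytes, f_s in bits/s per channel,
    n_c the channel count rounded up to the nearest multiple of 8
    (the device packs channels in bytes).
    """

    mem: int
    sample_rate: float = PDM_RATE
    requested_channels: int = 11

    @property
    def padded_channels(self) -> int:
        return pad_channels(self.requested_channels)

    @property
    def duration(self) -> float:
        return max_capture_duration(self.mem, self.sample_rate, self.requested_channels)


@dataclass(frozen=True)
class GainVector:
    """Per-channel multiplicative gains (linear scale)."""

    gains: np.ndarray
    flagged: np.ndarray | None = None  # True where the channel was silent

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if not np.all(g > 0):
            raise ValueError("gains must be positive")
        object.__setattr__(self, "gains", g)
        if self.flagged is None:
            object.__setattr__(self, "flagged", np.zeros(g.shape, dtype=bool))


def pad_channels(n: int) -> int:
    """Round a channel count up to the nearest multiple of 8."""
    n = int(n)
    if n < 1:
        raise ValueError(f"channel count must be >= 1, got {n}")
    return -(-n // 8) * 8


def max_capture_duration(mem: int, f_s: float, requested_channels: int) -> float:
    """Maximal capture duration D = 8*mem / (f_s * n_c) in seconds.

    ``mem`` is bytes of buffer memory, ``f_s`` the per-channel bit rate
    (bits/s), and ``requested_channels`` is padded up to a multiple of 8.
    Example: 180 MB at 4.5 MHz with 11 channels -> 20 s.
    """
    if mem < 0:
        raise ValueError("mem must be >= 0")
    if f_s <= 0:
        raise ValueError("f_s must be > 0")
    n_c = pad_channels(requested_channels)
    # exact rational arithmetic keeps the homogeneity identities exact
    return float(Fraction(8) * Fraction(mem) / (Fraction(f_s) * n_c))


def _butter_sos(cutoff: float, rate: float, order: int) -> np.ndarray:
    return sps.butter(order, cutoff, btype="low", fs=rate, output="sos")


def quantize16(x: np.ndarray) -> np.ndarray:
    """Quantize to the 16-bit grid: round half away from zero, saturate."""
    q = np.sign(x) * np.floor(np.abs(x) * _Q15 + 0.5)
    return np.clip(q, -_Q15 - 1, _Q15) / _Q15


def pdm_decode(
    stream: PdmStream,
    out_rate: float = PCM_RATE,
    cutoff: float = DEFAULT_CUTOFF,
    order: int = DEFAULT_ORDER,
    zero_phase: bool = False,
) -> PcmRecording:
    """Decode a 1-bit PDM stream to single-channel PCM.

    Bits are mapped to +-1, low-pass filtered with an ``order``-th order
    Butterworth at ``cutoff``, quantized to the 16-bit grid, and decimated
    by the integer factor stream.rate / out_rate.
    """
    k = stream.rate / out_rate
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"decimation factor {k} is not a positive integer "
            f"({stream.rate} Hz -> {out_rate} Hz)"
        )
    if cutoff >= out_rate / 2:
        raise ValueError("cutoff must be below the output Nyquist rate")
    x = stream.bits.astype(float) * 2.0 - 1.0
    sos = _butter_sos(cutoff, stream.rate, order)
    y = sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)
    y = quantize16(y)
    y = y[:: int(round(k))]
    return PcmRecording(samples=y[np.newaxis, :], rate=out_rate)


def trigger_save(ring: np.ndarray, rate: float, capacity_s: float,
                 write_index: int | None = None) -> PcmRecording:
    """Return the last ``capacity_s`` seconds before the trigger instant.

    ``ring`` is a (channels, n) circular buffer; ``write_index`` is the
    position the *next* sample would be written to (i.e. the trigger is at
    write_index - 1).  A buffer holding less than the requested duration
    returns what exists, with a warning (short-fill policy).
    """
    ring = np.atleast_2d(np.asarray(ring, dtype=float))
    n = ring.shape[1]
    if n == 0:
        raise ValueError("empty capture buffer")
    if write_index is None:
        write_index = n
    want = int(round(capacity_s * rate))
    if want > n:
        warnings.warn(
            f"buffer holds {n / rate:.3f} s < requested {capacity_s} s; "
            "returning the full buffer",
            stacklevel=2,
        )
        want = n
    idx = (np.arange(write_index - want, write_index)) % n
    return PcmRecording(samples=ring[:, idx], rate=rate)


def calibrate_gains(
    calib: PcmRecording,
    reference_channel: int = 0,
    silence_floor: float = 1e-9,
) -> GainVector:
    """Per-channel gains equalizing RMS response to a common calibration signal.

    gain_i = RMS(reference channel) / RMS(channel i).  Channels whose RMS
    falls below ``silence_floor`` are flagged and assigned gain 1.
    """
    rms = np.sqrt(np.mean(calib.samples**2, axis=1))
    ref = rms[reference_channel]
    if ref < silence_floor:
        raise ValueError("reference channel is silent")
    silent = rms < silence_floor
    gains = np.ones_like(rms)
    gains[~silent] = ref / rms[~silent]
    if silent.any():
        warnings.warn(
            f"{int(silent.sum())} silent channel(s) flagged; gain left at 1",
            stacklevel=2,
        )
    return GainVector(gains=gains, flagged=silent)


def apply_gains(rec: PcmRecording, gains: GainVector) -> PcmRecording:
    out = PcmRecording(
        samples=rec.samples * np.asarray(gains.gains)[:, None],
        rate=rec.rate,
        channel_ids=list(rec.channel_ids),
        sync_channel_index=rec.sync_channel_index,
        start_time=rec.start_time,
    )
    return out


# ---------------------------------------------------------------------------
# WAV I/O: 16-bit PCM, multichannel, with a JSON sidecar mapping WAV channel
# index -> mic_id and marking the sync track.

def write_wav(path: str | Path, rec: PcmRecording, sidecar: bool = True) -> None:
    path = Path(path)
    data = np.round(np.clip(rec.samples, -1.0, 1.0) * _Q15).astype(np.int16)
    wavfile.write(path, int(rec.rate), data.T)  # scipy wants (time, channels)
    if sidecar:
        meta = {
            "channel_map": {str(i): cid for i, cid in enumerate(rec.channel_ids)},
            "sync_channel_index": rec.sync_channel_index,
            "start_time": rec.start_time,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_wav(path: str | Path) -> PcmRecording:
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.dtype != np.int16:
        raise ValueError(f"expected 16-bit PCM WAV, got dtype {data.dtype}")
    if data.ndim == 1:
        data = data[:, None]
    samples = data.T.astype(float) / _Q15
    channel_ids: list[str] = []
    sync_idx = None
    start_time = 0.0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        cmap = meta.get("channel_map", {})
        channel_ids = [cmap[str(i)] for i in range(samples.shape[0])]
        sync_idx = meta.get("sync_channel_index")
        start_time = meta.get("start_time", 0.0)
    return PcmRecording(
        samples=samples,
        rate=float(rate),
        channel_ids=channel_ids,
        sync_channel_index=sync_idx,
        start_time=start_time,
    )
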