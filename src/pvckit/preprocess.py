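"""Signal conditioning: quality gating, band-pass filtering, R-peak
detection/refinement and beat windowing.

The processing chain mirrors standard ambulatory-ECG practice: reject
segments whose signal is flat, clipped or dominated by out-of-band power;
remove baseline drift and high-frequency noise with a zero-phase Butterworth
band-pass (0.1-45 Hz); locate R peaks on a squared wavelet reconstruction of
the QRS band with an adaptive threshold; snap each peak to the local
absolute-amplitude maximum (three +/-25 ms passes); and cut a 0.5 s window
around each peak (0.1 s before, 0.4 s after).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .io import ECGRecord

logger = logging.getLogger(__name__)

__all__ = [
    "BeatWindow", "QualityReport", "assess_quality", "bandpass_filter",
    "detect_r_peaks", "refine_r_peaks", "segment_beats",
    "window_pre_samples", "window_total_samples",
]

WINDOW_PRE_S = 0.1
WINDOW_TOTAL_S = 0.5


def window_pre_samples(fs: float) -> int:
    return int(np.floor(WINDOW_PRE_S * fs))


def window_total_samples(fs: float) -> int:
    # half-up rounding so e.g. fs=275 gives 138 samples regardless of the
    # platform's round-half-to-even convention
    return int(np.floor(WINDOW_TOTAL_S * fs + 0.5))


@dataclass
class BeatWindow:
    """One R-centred heartbeat waveform (``n_pre`` samples before R,
    ``n_post`` after; 0.5 s total)."""

    r_sample: int
    hw: np.ndarray
    n_pre: int
    n_post: int

    def __post_init__(self) -> None:
        self.hw = np.asarray(self.hw, dtype=float)
        if len(self.hw) != self.n_pre + self.n_post:
            raise ValueError("window length must equal n_pre + n_post")


@dataclass
class QualityReport:
    segment_ok: bool
    flat_fraction: float
    clipped_fraction: float
    band_power_ratio: float


def assess_quality(segment: ECGRecord, flat_max: float = 0.2,
                   clipped_max: float = 0.05, band_ratio_min: float = 0.5,
                   flat_eps: float = 0.01) -> QualityReport:
    """Rule-based segment quality gate.

    A segment passes when less than ``flat_max`` of its one-second blocks are
    flat (peak-to-peak below ``flat_eps`` mV), less than ``clipped_max`` of
    samples sit at the amplitude rails, and at least half of the in-band
    (0.5-45 Hz) power lies in the QRS band (5-40 Hz).  A pluggable stand-in
    for a learned signal-quality classifier: same accept/reject contract.
    """
    x, fs = segment.signal, segment.fs
    if len(x) < 10 * fs:
        raise ValueError("quality assessment requires at least 10 s of signal")

    nblk = int(len(x) // fs)
    blocks = x[: int(nblk * fs)].reshape(nblk, int(fs))
    flat_fraction = float(np.mean(np.ptp(blocks, axis=1) < flat_eps))

    amax = np.max(np.abs(x))
    if amax <= flat_eps:
        clipped_fraction = 0.0
    else:
        clipped_fraction = float(np.mean(np.abs(x) >= 0.999 * amax))

    freqs, psd = sps.welch(x, fs=fs, nperseg=min(len(x), int(4 * fs)))
    denom = float(np.trapezoid(psd[(freqs >= 0.5) & (freqs <= 45)],
                               freqs[(freqs >= 0.5) & (freqs <= 45)]))
    numer = float(np.trapezoid(psd[(freqs >= 5) & (freqs <= 40)],
                               freqs[(freqs >= 5) & (freqs <= 40)]))
    band_power_ratio = numer / denom if denom > 0 else 0.0

    ok = (flat_fraction < flat_max and clipped_fraction < clipped_max
          and band_power_ratio > band_ratio_min)
    return QualityReport(ok, flat_fraction, clipped_fraction, band_power_ratio)


def bandpass_filter(signal, fs: float, band=(0.1, 45.0), order: int = 4):
    """Zero-phase order-4 Butterworth band-pass (default 0.1-45 Hz)."""
    if fs <= 90:
        raise ValueError("fs must exceed 90 Hz so the 45 Hz edge is below Nyquist")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def _qrs_band_reconstruction(x: np.ndarray, fs: float, wavelet: str) -> np.ndarray:
    """Reconstruct the signal from wavelet detail levels covering ~5-22.5 Hz."""
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(x), w.dec_len)
    coeffs = pywt.wavedec(x, w, level=max_level)
    kept = [np.zeros_like(coeffs[0])]
    for lvl in range(1, max_level + 1):
        # coeffs[i] is detail level d = max_level - i + 1, band [fs/2^(d+1), fs/2^d]
        d = max_level - lvl + 1
        lo, hi = fs / 2 ** (d + 1), fs / 2 ** d
        if hi >= 5.0 and lo <= 22.5:
            kept.append(coeffs[lvl])
        else:
            kept.append(np.zeros_like(coeffs[lvl]))
    return pywt.waverec(kept, w)[: len(x)]


def detect_r_peaks(signal, fs: float, wavelet: str = "db4",
                   refractory_ms: float = 250.0, threshold_frac: float = 0.3,
                   env_window_s: float = 5.0, env_percentile: float = 98.0):
    """Adaptive R-peak detector.

    Steps: mirror-pad the edges by 1 s; reconstruct the QRS frequency band
    (about 5-22 Hz) from a discrete wavelet decomposition; square it; take
    local maxima above an adaptive threshold (a fraction of the recent
    98th-percentile envelope, blockwise over 5 s); enforce a 250 ms
    refractory interval keeping the larger peak.  Returns strictly
    increasing sample indices (empty for flat input).
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("R-peak detection requires at least 2 s of signal")
    pad = int(round(fs))
    x_pad = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])

    env = _qrs_band_reconstruction(x_pad, fs, wavelet) ** 2

    block = max(1, int(round(env_window_s * fs)))
    nblk = int(np.ceil(len(env) / block))
    thr = np.empty_like(env)
    for b in range(nblk):
        seg = env[b * block:(b + 1) * block]
        thr[b * block:(b + 1) * block] = np.percentile(seg, env_percentile)
    floor = 0.05 * np.max(env) if np.max(env) > 0 else np.inf
    height = np.maximum(threshold_frac * thr, max(floor, 1e-12))

    refractory = max(1, int(round(refractory_ms / 1000 * fs)))
    peaks, _ = sps.find_peaks(env, height=height, distance=refractory)
    peaks = peaks - pad
    peaks = peaks[(peaks >= 0) & (peaks < len(x))]

    # localise each envelope peak on the R wave: the squared QRS-band
    # envelope of wide or biphasic complexes can crest on a flank or the S
    # wave, so snap to the absolute-amplitude maximum nearby
    snap = int(round(0.1 * fs))
    absx = np.abs(x)
    located = np.empty_like(peaks)
    for k, p in enumerate(peaks):
        lo, hi = max(0, p - snap), min(len(x), p + snap + 1)
        located[k] = lo + int(np.argmax(absx[lo:hi]))
    located = np.unique(located)
    # re-enforce the refractory interval, keeping the larger peak
    out: list[int] = []
    for p in located:
        if out and p - out[-1] < refractory:
            if absx[p] > absx[out[-1]]:
                out[-1] = int(p)
        else:
            out.append(int(p))
    return np.asarray(out, dtype=np.int64)


def refine_r_peaks(signal, peaks, fs: float, n_passes: int = 3,
                   window_ms: float = 25.0):
    """Snap each peak to the +/-25 ms absolute-amplitude maximum, three times.

    Output is sorted with duplicates removed (first occurrence kept).
    """
    x = np.abs(np.asarray(signal, dtype=float))
    half = int(round(window_ms / 1000 * fs))
    refined = np.array(peaks, dtype=np.int64, copy=True)
    for _ in range(n_passes):
        for k, p in enumerate(refined):
            lo, hi = max(0, p - half), min(len(x), p + half + 1)
            refined[k] = lo + int(np.argmax(x[lo:hi]))
    refined = np.sort(refined)
    keep = np.concatenate([[True], np.diff(refined) > 0])
    return refined[keep]


def segment_beats(record: ECGRecord, peaks, signal=None) -> list[BeatWindow]:
    """Cut a 0.5 s window around each R peak (0.1 s before, 0.4 s after).

    ``n_pre = floor(0.1*fs)``, total ``= round(0.5*fs)`` (half-open slice).
    Windows that would cross the signal boundary are dropped and logged.
    ``signal`` overrides the record's own samples (e.g. to window a filtered
    copy at the same peak positions).
    """
    x = record.signal if signal is None else np.asarray(signal, dtype=float)
    n_pre = window_pre_samples(record.fs)
    total = window_total_samples(record.fs)
    n_post = total - n_pre
    beats = []
    dropped = 0
    for p in np.asarray(peaks, dtype=int):
        start, stop = p - n_pre, p + n_post
        if start < 0 or stop > len(x):
            dropped += 1
            continue
        beats.append(BeatWindow(int(p), x[start:stop].copy(), n_pre, n_post))
    if dropped:
        logger.info("segment_beats: dropped %d boundary beats", dropped)
    return beats
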