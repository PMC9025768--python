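"""Shared fixtures: small synthetic records and a trained auto-encoder.

Session-scoped so expensive artifacts (generator output, AE training) are
built once and reused across test modules.
"""

import numpy as np
import pytest

from pvckit.autoencoder import AEConfig, train_autoencoder
from pvckit.io import ECGRecord
from pvckit.preprocess import (bandpass_filter, detect_r_peaks,
                               refine_r_peaks, segment_beats)
from pvckit.synthetic import SynthConfig, generate_record

FS = 250.0


@pytest.fixture(scope="session")
def short_record():
    """120 s synthetic record with ~10% PVCs at 250 Hz."""
    cfg = SynthConfig(duration_s=120, fs=FS, seed=42)
    signal, truth = generate_record(cfg)
    return ECGRecord(signal, FS, record_id="synth42"), truth, cfg


@pytest.fixture(scope="session")
def short_beats(short_record):
    """Detected, windowed beats (raw + filtered) with per-beat truth labels."""
    record, truth, _ = short_record
    filtered = bandpass_filter(record.signal, FS)
    peaks = refine_r_peaks(filtered, detect_r_peaks(filtered, FS), FS)
    raw = segment_beats(record, peaks)
    fil = segment_beats(record, peaks, signal=filtered)
    scale = float(np.median(np.abs(filtered[[b.r_sample for b in raw]])))
    for b in raw:
        b.hw = b.hw / scale
    for b in fil:
        b.hw = b.hw / scale
    kept = np.array([b.r_sample for b in raw])
    nearest = np.argmin(np.abs(truth.r_samples[:, None] - kept[None, :]), axis=0)
    is_pvc = truth.pvc_mask[nearest]
    return raw, fil, is_pvc


@pytest.fixture(scope="session")
def trained_ae(short_beats):
    raw, fil, is_pvc = short_beats
    model = train_autoencoder(raw, fil, AEConfig(epochs=50, seed=7))
    return model, raw, fil, is_pvc
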