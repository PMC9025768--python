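"""Synthetic single-lead ECG with beat-level ground truth.

Generates sinus and premature-ventricular-contraction (PVC) beats as sums of
Gaussian bumps (McSharry-style morphology), places them on an RR grid with the
timing signature of a PVC — a shortened coupling interval followed by a
compensatory pause — and adds baseline wander plus broadband noise. Every
inserted beat is recorded in a ground-truth annotation list, so the whole
detection pipeline can be exercised without downloading any clinical database.

Morphological contrast between the two beat kinds mirrors what distinguishes a
PVC on a real ECG: no P wave, a QRS roughly twice as wide, a taller R wave and
an inverted T wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SynthConfig", "GroundTruth", "make_beat_morphology", "generate_record"]

#: Gaussian bump parameters per beat kind: (center_s relative to R, amplitude
#: relative to the R amplitude, width_s).  Normal: full P-QRS-T; PVC: no P,
#: QRS ~160 ms vs ~80 ms, R >=1.4x taller, inverted T.
_MORPHOLOGY = {
    "normal": (
        (-0.17, 0.12, 0.020),   # P
        (-0.025, -0.12, 0.008),  # Q
        (0.0, 1.0, 0.012),       # R
        (0.025, -0.20, 0.008),   # S
        (0.30, 0.30, 0.045),     # T
    ),
    "pvc": (
        (-0.09, -0.35, 0.025),   # Q
        (0.0, 1.5, 0.045),       # R (wide and tall)
        (0.09, -0.60, 0.030),    # S
        (0.36, -0.45, 0.060),    # inverted T
    ),
}

#: R-peak offset from the start of a beat waveform, in seconds.  The standard
#: beat window (0.1 s before R, 0.4 s after) then fits inside the 0.7 s
#: waveform with margin on both sides.
_R_OFFSET_S = 0.2
_BEAT_LEN_S = 0.7


def _round_half_up(x: float) -> int:
    """Half-up sample-count rounding (round(0.7*275) -> 193, not banker's 192)."""
    return int(np.floor(x + 0.5))


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording.

    Defaults describe a desk-scale stand-in for an ambulatory recording:
    360 Hz sampling (the rate of the classic arrhythmia databases), 70 bpm
    sinus rhythm with mild variability, 10% PVC burden, 0.05 mV broadband
    noise and 0.1 mV respiratory-band baseline wander.
    """

    duration_s: float = 600.0
    fs: float = 360.0
    mean_hr_bpm: float = 70.0
    hr_sd_bpm: float = 3.0
    pvc_fraction: float = 0.1
    pvc_prematurity: float = 0.65   # coupling RR = this multiple of local RR
    compensatory_factor: float = 1.0  # RR_pre + RR_post = factor * 2 * local RR
    noise_sd: float = 0.05          # mV
    baseline_wander_amp: float = 0.1  # mV
    baseline_wander_freq: float = 0.25  # Hz
    seed: int = 0
    allow_couplets: bool = False    # consecutive PVCs; off by default
    pvc_morphology: dict | None = None  # override bump table for PVC beats

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if not 0.0 <= self.pvc_fraction <= 0.5:
            raise ValueError("pvc_fraction must lie in [0, 0.5]")
        if not 0.0 < self.pvc_prematurity < 1.0:
            raise ValueError("pvc_prematurity must lie in (0, 1)")
        for name in ("noise_sd", "baseline_wander_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """True R-peak sample indices and per-beat labels ('PVC' / 'Non_PVC')."""

    r_samples: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r_samples = np.asarray(self.r_samples, dtype=np.int64)
        if len(self.labels) != len(self.r_samples):
            raise ValueError("labels and r_samples must have equal length")
        if np.any(np.diff(self.r_samples) <= 0):
            raise ValueError("r_samples must be strictly increasing")

    @property
    def pvc_mask(self) -> np.ndarray:
        return np.asarray([lab == "PVC" for lab in self.labels])


def make_beat_morphology(kind: str, fs: float, amplitude: float = 1.0,
                         bumps=None) -> np.ndarray:
    """Return one beat waveform of length ``round(0.7*fs)`` samples.

    ``kind`` is ``"normal"`` or ``"pvc"``; ``amplitude`` scales the R wave in
    mV. The R peak sits at 0.2 s so the 0.1 s / 0.4 s analysis window around
    it captures the full QRS and T wave.
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if bumps is None:
        try:
            bumps = _MORPHOLOGY[kind]
        except KeyError:
            raise ValueError(
                f"unknown beat kind {kind!r}; expected 'normal' or 'pvc'"
            ) from None
    n = _round_half_up(_BEAT_LEN_S * fs)
    t = np.arange(n) / fs - _R_OFFSET_S
    wave = np.zeros(n)
    for center, rel_amp, width in bumps:
        wave += rel_amp * amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)
    return wave


def r_offset_samples(fs: float) -> int:
    """Sample index of the designed R peak within a beat waveform."""
    return int(round(_R_OFFSET_S * fs))


def generate_record(config: SynthConfig):
    """Generate a synthetic ECG and its ground truth.

    Returns ``(signal, ground_truth)`` where ``signal`` is a float array in mV
    of length ``round(duration_s * fs)``.  Beat placement: sinus RR intervals
    are drawn from the configured heart-rate distribution; a beat flagged PVC
    has its coupling interval shortened to ``pvc_prematurity`` of the local RR
    and the following interval stretched so that the pre+post pair sums to
    ``compensatory_factor * 2`` local RRs (the classic full compensatory
    pause).  Two consecutive PVCs never occur unless ``allow_couplets``.
    Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_total = int(round(config.duration_s * fs))

    # --- beat schedule -----------------------------------------------------
    beat_times: list[float] = []
    labels: list[str] = []
    t = 0.5  # first R at 0.5 s
    carried_rr = None  # post-PVC interval imposed by the compensatory pause
    margin = _BEAT_LEN_S - _R_OFFSET_S  # tail of a waveform after its R
    while True:
        hr = np.clip(rng.normal(config.mean_hr_bpm, config.hr_sd_bpm), 30.0, 220.0)
        local_rr = 60.0 / hr
        prev_was_pvc = bool(labels) and labels[-1] == "PVC"
        is_pvc = (
            bool(beat_times)  # never the very first beat
            and (config.allow_couplets or not prev_was_pvc)
            and carried_rr is None
            and rng.random() < config.pvc_fraction
        )
        if carried_rr is not None:
            rr = carried_rr
            carried_rr = None
        elif is_pvc:
            rr = config.pvc_prematurity * local_rr
            carried_rr = config.compensatory_factor * 2.0 * local_rr - rr
        else:
            rr = local_rr
        t_next = t if not beat_times else beat_times[-1] + rr
        if t_next + margin > config.duration_s:
            break
        beat_times.append(t_next)
        labels.append("PVC" if is_pvc else "Non_PVC")
        t = t_next
    if len(beat_times) < 3:
        raise ValueError("configuration yields fewer than 3 beats")

    # --- waveform synthesis ------------------------------------------------
    signal = np.zeros(n_total)
    r_off = r_offset_samples(fs)
    protos = {
        "Non_PVC": make_beat_morphology("normal", fs),
        "PVC": make_beat_morphology("pvc", fs, bumps=config.pvc_morphology),
    }
    r_samples = []
    for bt, lab in zip(beat_times, labels):
        r = int(round(bt * fs))
        wave = protos[lab]
        start = r - r_off
        stop = start + len(wave)
        lo, hi = max(start, 0), min(stop, n_total)
        signal[lo:hi] += wave[lo - start:hi - start]
        r_samples.append(r)

    tgrid = np.arange(n_total) / fs
    if config.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += config.baseline_wander_amp * np.sin(
            2 * np.pi * config.baseline_wander_freq * tgrid + phase
        )
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n_total)

    return signal, GroundTruth(np.asarray(r_samples), labels)
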