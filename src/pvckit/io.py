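"""Reading and writing single-lead ECG records and beat annotations.

Two on-disk dialects are supported:

* A minimal WFDB subset: text ``.hea`` header, 16-bit little-endian ``.dat``
  signal (format 16), and MIT-format ``.atr`` beat annotations.  This covers
  what the MIT-BIH-style arrhythmia databases use for single-lead work.
* Plain CSV: a two-column ``sample_index,value`` signal file and a
  ``r_sample,symbol`` annotation file.

Annotation symbols follow the MIT-BIH alphabet and are mapped onto the
two-class scheme used throughout the package: ventricular ectopic beats are
``PVC``; other beat types (including fusion and supraventricular beats) are
``Non_PVC``; unclassifiable or non-beat symbols are ``Excluded``.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ECGRecord", "BeatAnnotation", "map_symbols",
    "read_record", "read_annotations",
    "write_wfdb", "write_csv", "write_labels", "read_labels",
]


@dataclass
class ECGRecord:
    """A single-lead ECG signal in mV with its sampling frequency."""

    signal: np.ndarray
    fs: float
    lead_name: str = "II"
    record_id: str = "rec"
    has_paced: bool = False  # record contains paced ('/') annotations

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.size == 0:
            raise ValueError("signal must be non-empty")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


@dataclass
class BeatAnnotation:
    r_sample: int
    symbol: str
    mapped: str = ""  # 'PVC' / 'Non_PVC' / 'Excluded'


# AAMI-style two-class mapping of MIT-BIH beat symbols.  Fusion (F) and the
# supraventricular family count as Non_PVC; unclassified and non-beat marks
# are excluded from scoring.
PVC_SYMBOLS = frozenset("V")
NON_PVC_SYMBOLS = frozenset("NLRejAaJSF")
EXCLUDED_SYMBOLS = frozenset("Q?|~+/\"!xf[]p")


def map_symbols(annotations: list[BeatAnnotation],
                pvc=PVC_SYMBOLS, non_pvc=NON_PVC_SYMBOLS) -> list[BeatAnnotation]:
    """Fill the ``mapped`` field of each annotation; total over any symbol.

    Unknown symbols map to ``Excluded`` with a logged warning rather than an
    exception, so an unusual annotation stream never aborts a run.
    """
    out = []
    for ann in annotations:
        if ann.symbol in pvc:
            mapped = "PVC"
        elif ann.symbol in non_pvc:
            mapped = "Non_PVC"
        else:
            if ann.symbol not in EXCLUDED_SYMBOLS:
                logger.warning("unknown annotation symbol %r -> Excluded", ann.symbol)
            mapped = "Excluded"
        out.append(BeatAnnotation(ann.r_sample, ann.symbol, mapped))
    return out


# ---------------------------------------------------------------------------
# Minimal WFDB subset (format 16, single signal)
# ---------------------------------------------------------------------------

# MIT annotation type codes for the symbols this package handles.
_SYMBOL_TO_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "~": 14, "|": 16,
    "+": 28, "e": 34, "x": 37, "f": 38,
}
_CODE_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_CODE.items()}
_SKIP = 59


def write_wfdb(record: ECGRecord, path, annotations=None, gain: float = 200.0) -> None:
    """Write ``path.hea`` / ``path.dat`` (+ ``path.atr`` if annotations)."""
    path = Path(path)
    name = path.name
    adu = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    (path.parent / f"{name}.dat").write_bytes(adu.tobytes())
    header = (
        f"{name} 1 {record.fs:g} {len(adu)}\n"
        f"{name}.dat 16 {gain:g} 16 0 {int(adu[0])} 0 0 {record.lead_name}\n"
    )
    (path.parent / f"{name}.hea").write_text(header)
    if annotations is not None:
        _write_atr(path.parent / f"{name}.atr", annotations)


def _write_atr(path: Path, annotations) -> None:
    buf = bytearray()
    prev = 0
    for ann in sorted(annotations, key=lambda a: a.r_sample):
        code = _SYMBOL_TO_CODE.get(ann.symbol, 13)
        delta = int(ann.r_sample) - prev
        if delta < 0:
            raise ValueError("annotation samples must be non-decreasing")
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = int(ann.r_sample)
    buf += struct.pack("<H", 0)  # end of annotations
    path.write_bytes(bytes(buf))


def _read_atr(path: Path) -> list[BeatAnnotation]:
    data = path.read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    while i + 2 <= len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            t += (hi << 16) | lo
            continue
        if code in (61, 62, 63):  # NUM/SUB/AUX fields: skip payload
            if code == 63:
                i += delta + (delta & 1)
            continue
        t += delta
        anns.append(BeatAnnotation(t, _CODE_TO_SYMBOL.get(code, "Q")))
    return anns


def _read_wfdb(header_path: Path, lead=None) -> ECGRecord:
    lines = [ln.strip() for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    name, nsig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    sig_lines = lines[1:1 + nsig]
    leads = [ln.split()[-1] for ln in sig_lines]
    idx = 0
    if lead is not None:
        if isinstance(lead, int):
            idx = lead
        elif lead in leads:
            idx = leads.index(lead)
        else:
            raise ValueError(
                f"lead {lead!r} not found; available leads: {leads}")
        if not 0 <= idx < nsig:
            raise ValueError(
                f"lead index {idx} out of range; available leads: {leads}")
    fields = sig_lines[idx].split()
    dat_name, fmt = fields[0], fields[1]
    if fmt.split("x")[0] != "16":
        raise ValueError(f"unsupported WFDB format {fmt!r}; only format 16")
    gain_field = fields[2] if len(fields) > 2 else "200"
    baseline = 0.0
    gain_part = gain_field.split("/")[0]
    if "(" in gain_part:
        gain_str, base_str = gain_part.rstrip(")").split("(")
        gain, baseline = float(gain_str), float(base_str)
    else:
        gain = float(gain_part)
    if gain == 0:
        gain = 200.0
    raw = np.frombuffer((header_path.parent / dat_name).read_bytes(), dtype="<i2")
    if nsig > 1:  # format-16 frames interleave signals
        raw = raw[idx::nsig]
    signal = (raw.astype(float) - baseline) / gain
    has_paced = False
    atr = header_path.parent / f"{name}.atr"
    if atr.exists():
        has_paced = any(a.symbol == "/" for a in _read_atr(atr))
    return ECGRecord(signal, fs, lead_name=leads[idx], record_id=name,
                     has_paced=has_paced)


# ---------------------------------------------------------------------------
# CSV dialect and top-level readers
# ---------------------------------------------------------------------------

def write_csv(record: ECGRecord, signal_path, annotations=None,
              ann_path=None) -> None:
    """Write ``sample_index,value`` signal CSV (+ ``r_sample,symbol`` CSV)."""
    df = pd.DataFrame({"sample_index": np.arange(len(record.signal)),
                       "value": record.signal})
    df.to_csv(signal_path, index=False)
    if annotations is not None:
        if ann_path is None:
            raise ValueError("ann_path required when writing annotations")
        pd.DataFrame({"r_sample": [a.r_sample for a in annotations],
                      "symbol": [a.symbol for a in annotations]}
                     ).to_csv(ann_path, index=False)


def read_record(path, lead=None, fs: float | None = None) -> ECGRecord:
    """Read a WFDB header or CSV signal file into an :class:`ECGRecord`.

    For CSV input the sampling frequency must be given via ``fs`` (or a
    ``<stem>.fs`` sidecar containing the number).
    """
    path = Path(path)
    if path.suffix == ".hea" or (path.suffix == "" and path.with_suffix(".hea").exists()):
        hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
        return _read_wfdb(hea, lead=lead)
    if path.suffix == ".csv":
        if fs is None:
            sidecar = path.with_suffix(".fs")
            if sidecar.exists():
                fs = float(sidecar.read_text().strip())
            else:
                raise ValueError("sampling frequency required for CSV input")
        df = pd.read_csv(path)
        if lead not in (None, 0, "0") and str(lead) not in df.columns:
            raise ValueError(f"lead {lead!r} not found; available leads: ['{df.columns[-1]}']")
        return ECGRecord(df.iloc[:, -1].to_numpy(float), fs,
                         record_id=path.stem)
    raise IOError(f"cannot read {path}: expected a .hea or .csv file")


def read_annotations(path, mapped: bool = True) -> list[BeatAnnotation]:
    """Read MIT ``.atr`` or CSV ``r_sample,symbol`` annotations."""
    path = Path(path)
    if path.suffix == ".atr":
        anns = _read_atr(path)
    else:
        df = pd.read_csv(path)
        anns = [BeatAnnotation(int(r), str(s))
                for r, s in zip(df.iloc[:, 0], df.iloc[:, 1])]
    return map_symbols(anns) if mapped else anns


def write_labels(path, r_samples, labels, provenance=None, best_covr=None) -> None:
    """Write the per-beat prediction file (``r_sample,label[,...]``)."""
    cols = {"r_sample": np.asarray(r_samples, dtype=int), "label": list(labels)}
    if provenance is not None:
        cols["provenance"] = list(provenance)
    if best_covr is not None:
        cols["best_covr"] = np.asarray(best_covr, dtype=float)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_labels(path):
    """Read a per-beat label file; returns (r_samples, labels)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the offending content
        raise ValueError(f"malformed label file {path}: {exc}") from exc
    if "r_sample" not in df.columns or "label" not in df.columns:
        raise ValueError(
            f"malformed label file {path}: expected columns r_sample,label "
            f"(line 1 reads {','.join(map(str, df.columns))!r})")
    return df["r_sample"].to_numpy(int), df["label"].astype(str).tolist()
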