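"""Beat-level scoring: confusion counts, Se/P+/ACC and the CPSC PVC penalty.

Predicted and reference beat lists are paired greedily by temporal proximity
within a tolerance (default 150 ms).  From the paired confusion counts:

    Se  = TP / (TP + FN) x 100
    P+  = TP / (TP + FP) x 100
    ACC = (TP + TN) / (TP + FP + TN + FN) x 100

The challenge-style PVC penalty deducts 1 point per false-positive PVC and 5
per false-negative PVC (missed diagnoses weigh more clinically); lower is
better.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "Metrics", "PVCScore", "match_beats",
           "compute_metrics", "cpsc_pvc_score", "report"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class Metrics:
    se: float
    pplus: float
    acc: float


@dataclass
class PVCScore:
    score: int
    fp_count: int
    fn_count: int


def _check_sorted(r_samples, name: str) -> np.ndarray:
    arr = np.asarray(r_samples, dtype=np.int64)
    if np.any(np.diff(arr) < 0):
        raise ValueError(f"{name} beat list must be sorted by sample index")
    return arr


def _pair(pred_r: np.ndarray, ref_r: np.ndarray, tol: float):
    """Greedy nearest-neighbour pairing within ``tol`` samples.

    Candidate pairs are taken in order of ascending |Δt|; each side pairs at
    most once.  Returns (pred_index -> ref_index) as a dict.
    """
    pairs = []
    j0 = 0
    for i, p in enumerate(pred_r):
        j0 = np.searchsorted(ref_r, p - tol)
        j = j0
        while j < len(ref_r) and ref_r[j] <= p + tol:
            pairs.append((abs(int(p) - int(ref_r[j])), i, j))
            j += 1
    pairs.sort()
    used_p, used_r, match = set(), set(), {}
    for _, i, j in pairs:
        if i not in used_p and j not in used_r:
            match[i] = j
            used_p.add(i)
            used_r.add(j)
    return match


def match_beats(pred_r, pred_labels, ref_r, ref_labels, fs: float,
                tol_ms: float = 150.0) -> ConfusionCounts:
    """Confusion counts for PVC-vs-Non_PVC beat classification.

    Reference beats labelled ``Excluded`` are ignored.  Unpaired reference
    PVCs count as FN; predicted PVCs with no reference partner count as FP;
    unpaired reference Non_PVC beats count as TN (they were not called PVC).
    """
    pred_r = _check_sorted(pred_r, "predicted")
    ref_r = _check_sorted(ref_r, "reference")
    keep = [k for k, lab in enumerate(ref_labels) if lab != "Excluded"]
    ref_r = ref_r[keep]
    ref_labels = [ref_labels[k] for k in keep]

    tol = tol_ms / 1000.0 * fs
    match = _pair(pred_r, ref_r, tol)
    inv = {j: i for i, j in match.items()}

    c = ConfusionCounts()
    for j, rlab in enumerate(ref_labels):
        ref_is_pvc = rlab == "PVC"
        if j in inv:
            pred_is_pvc = pred_labels[inv[j]] == "PVC"
        else:
            pred_is_pvc = False
        if ref_is_pvc and pred_is_pvc:
            c.tp += 1
        elif ref_is_pvc:
            c.fn += 1
        elif pred_is_pvc:
            c.fp += 1
        else:
            c.tn += 1
    for i, plab in enumerate(pred_labels):
        if plab == "PVC" and i not in match:
            c.fp += 1
    return c


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Se / P+ / ACC in percent; zero-denominator cases yield NaN flags."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    se = c.tp / (c.tp + c.fn) * 100.0 if (c.tp + c.fn) else float("nan")
    pplus = c.tp / (c.tp + c.fp) * 100.0 if (c.tp + c.fp) else float("nan")
    acc = (c.tp + c.tn) / c.total * 100.0
    return Metrics(se, pplus, acc)


def cpsc_pvc_score(pred_pvc_r, ref_pvc_r, fs: float,
                   tol_ms: float = 150.0) -> PVCScore:
    """Challenge penalty: 1 point per spurious PVC, 5 per missed PVC."""
    pred_r = _check_sorted(pred_pvc_r, "predicted")
    ref_r = _check_sorted(ref_pvc_r, "reference")
    match = _pair(pred_r, ref_r, tol_ms / 1000.0 * fs)
    fp = len(pred_r) - len(match)
    fn = len(ref_r) - len(match)
    return PVCScore(score=fp + 5 * fn, fp_count=fp, fn_count=fn)


def report(per_record: dict[str, ConfusionCounts], path=None) -> dict:
    """JSON-able report with per-record and pooled (summed-count) metrics."""
    out: dict = {"records": {}, "pooled": {}}
    pooled = ConfusionCounts()
    for rid, c in per_record.items():
        m = compute_metrics(c)
        out["records"][rid] = {
            "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "se": m.se, "pplus": m.pplus, "acc": m.acc,
        }
        pooled = pooled + c
    mp = compute_metrics(pooled)
    out["pooled"] = {"tp": pooled.tp, "tn": pooled.tn, "fp": pooled.fp,
                     "fn": pooled.fn, "se": mp.se, "pplus": mp.pplus,
                     "acc": mp.acc}
    ses = [v["se"] for v in out["records"].values() if not np.isnan(v["se"])]
    pps = [v["pplus"] for v in out["records"].values() if not np.isnan(v["pplus"])]
    out["record_mean"] = {
        "se": float(np.mean(ses)) if ses else float("nan"),
        "pplus": float(np.mean(pps)) if pps else float("nan"),
        "acc": float(np.mean([v["acc"] for v in out["records"].values()])),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)
    return out
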