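"""Rule-based beat classification against morphology templates.

Every detected beat is compared with its cluster's template through three
similarity measures:

* ``Covr`` — Pearson cross-correlation between the heartbeat waveform HW and
  the template waveform TW;
* ``ArDiff`` — relative absolute-area difference, in percent:
  |Σ|HW| − Σ|TW|| / Σ|TW| × 100;
* ``EnDiff`` — normalised energy of the residual: Σ(HW−TW)² / ΣTW².

Step 1 accepts the beat as the template's type when

    Covr >= 0.9  or  (Covr >= 0.8 and ArDiff < 10 and EnDiff < 1)

otherwise the beat is *Unknown* and step 2 re-scores it against every
template, falling back to an RR-interval rule (premature coupling followed by
a compensatory pause) when no template matches.

For long-term recordings the signal is split into 30-minute segments; the
first segment builds its own templates (auto-encoder → clustering → typing)
and later segments reuse them until an update rule — too many Unknowns, or a
drifting match against the dominant template — triggers a rebuild.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .autoencoder import encode, train_autoencoder
from .config import PipelineConfig
from .io import ECGRecord
from .templates import Template, build_typed_templates, select_k_and_cluster

logger = logging.getLogger(__name__)

__all__ = [
    "MatchScores", "RhythmContext", "SegmentResult",
    "covr", "ardiff", "endiff", "match_scores", "step1_match",
    "rhythmic_rule", "step2_resolve", "classify_segment",
    "needs_template_update", "process_long_term",
]


@dataclass
class MatchScores:
    covr: float
    ardiff: float
    endiff: float


@dataclass
class RhythmContext:
    """RR intervals around one beat, in seconds.

    ``rr_local`` is the median of the preceding 8 RR intervals (or of all
    available when fewer).
    """
    rr_pre: float
    rr_post: float
    rr_local: float


@dataclass
class SegmentResult:
    r_samples: np.ndarray
    labels: list[str]
    provenance: list[str]  # 'step1' / 'step2_template' / 'step2_rhythm' / 'unscored'
    best_covr: np.ndarray
    templates: list[Template]
    updated: bool = False
    k: int = 0
    step1_unknown_frac: float = 0.0
    dominant_mean_covr: float = 1.0
    scale: float = 1.0
    # long-term runs: one entry per 30-min segment
    segment_log: list = field(default_factory=list)


def covr(hw, tw) -> float:
    """Pearson cross-correlation of a beat and a template (0 if either is
    constant)."""
    hw = np.asarray(hw, dtype=float)
    tw = np.asarray(tw, dtype=float)
    if hw.shape != tw.shape:
        raise ValueError("HW and TW must have equal length")
    hd, td = hw - hw.mean(), tw - tw.mean()
    denom = np.sqrt((hd ** 2).sum() * (td ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((hd * td).sum() / denom, -1.0, 1.0))


def ardiff(hw, tw) -> float:
    """Absolute-area difference in percent."""
    hw = np.asarray(hw, dtype=float)
    tw = np.asarray(tw, dtype=float)
    if hw.shape != tw.shape:
        raise ValueError("HW and TW must have equal length")
    area_tw = np.abs(tw).sum()
    if area_tw == 0:
        raise ValueError("ArDiff undefined for an all-zero template")
    return float(abs(np.abs(hw).sum() - area_tw) / area_tw * 100.0)


def endiff(hw, tw) -> float:
    """Residual energy normalised by template energy."""
    hw = np.asarray(hw, dtype=float)
    tw = np.asarray(tw, dtype=float)
    if hw.shape != tw.shape:
        raise ValueError("HW and TW must have equal length")
    energy = (tw ** 2).sum()
    if energy == 0:
        raise ValueError("EnDiff undefined for an all-zero template")
    return float(((hw - tw) ** 2).sum() / energy)


def match_scores(hw, tw) -> MatchScores:
    return MatchScores(covr(hw, tw), ardiff(hw, tw), endiff(hw, tw))


def step1_match(scores: MatchScores, covr_hi: float = 0.9,
                covr_lo: float = 0.8, ardiff_max: float = 10.0,
                endiff_max: float = 1.0) -> bool:
    """The published acceptance rule; comparisons exactly as printed
    (>= on Covr, strict < on ArDiff/EnDiff)."""
    return bool(
        scores.covr >= covr_hi
        or (scores.covr >= covr_lo and scores.ardiff < ardiff_max
            and scores.endiff < endiff_max)
    )


def rhythmic_rule(ctx: RhythmContext, prematurity: float = 0.9,
                  pause: float = 1.8) -> bool:
    """True (pvc-like) iff the coupling interval is premature and followed by
    a compensatory pause."""
    return bool(ctx.rr_pre < prematurity * ctx.rr_local
                and ctx.rr_pre + ctx.rr_post >= pause * ctx.rr_local)


def step2_resolve(hw, templates: list[Template], ctx: RhythmContext,
                  config: PipelineConfig | None = None):
    """Resolve an Unknown beat against all templates, then rhythm.

    Returns ``(label, provenance, best_covr)``.  Among templates passing the
    acceptance rule the highest Covr wins (ties: lowest EnDiff); with no
    match, a pvc-like rhythm yields PVC, otherwise the configured fallback.
    """
    config = config or PipelineConfig()
    if not templates:
        raise ValueError("step 2 requires at least one template")
    scored = [(match_scores(hw, t.tw), t) for t in templates]
    best_covr = max(s.covr for s, _ in scored)
    matching = [(s, t) for s, t in scored
                if step1_match(s, config.covr_hi, config.covr_lo,
                               config.ardiff_max, config.endiff_max)]
    if matching:
        s, t = max(matching, key=lambda st: (st[0].covr, -st[0].endiff))
        return t.type, "step2_template", best_covr
    if rhythmic_rule(ctx, config.prematurity, config.pause):
        return "PVC", "step2_rhythm", best_covr
    return config.unknown_fallback, "step2_rhythm", best_covr


def _rhythm_contexts(r_samples: np.ndarray, fs: float) -> list[RhythmContext]:
    """Per-beat RR context from the full detected peak train."""
    r = np.asarray(r_samples, dtype=float) / fs
    n = len(r)
    rr = np.diff(r)
    ctxs = []
    for i in range(n):
        rr_pre = rr[i - 1] if i >= 1 else (rr[0] if len(rr) else 1.0)
        rr_post = rr[i] if i < len(rr) else (rr[-1] if len(rr) else 1.0)
        past = rr[max(0, i - 9):max(0, i - 1)]
        if len(past) == 0:
            past = rr[:8] if len(rr) else np.array([1.0])
        ctxs.append(RhythmContext(float(rr_pre), float(rr_post),
                                  float(np.median(past))))
    return ctxs


def _quality_mask(filtered: np.ndarray, fs: float, cfg: PipelineConfig):
    """Boolean per-sample mask of signal that fails the quality gate.

    Default granularity is the whole segment (an unacceptable segment is
    excluded outright); ``quality_granularity='subwindow'`` instead excises
    failing ``quality_window_s`` stretches.  Sub-window spectral gating is
    kept optional because stretches rich in ectopic beats legitimately carry
    more sub-QRS-band power and would otherwise be excised.
    """
    bad = np.zeros(len(filtered), dtype=bool)
    if cfg.quality_granularity == "segment":
        if len(filtered) >= 10 * fs:
            rep = preprocess.assess_quality(
                ECGRecord(filtered, fs), cfg.flat_max, cfg.clipped_max,
                cfg.band_ratio_min)
            if not rep.segment_ok:
                bad[:] = True
        return bad
    win = int(round(cfg.quality_window_s * fs))
    if len(filtered) < win:
        return bad
    for start in range(0, len(filtered) - win + 1, win):
        seg = ECGRecord(filtered[start:start + win], fs)
        rep = preprocess.assess_quality(seg, cfg.flat_max, cfg.clipped_max,
                                        cfg.band_ratio_min)
        if not rep.segment_ok:
            stop = start + win
            # final partial window rides along with the last full one
            if len(filtered) - stop < win:
                stop = len(filtered)
            bad[start:stop] = True
    return bad


def classify_segment(record: ECGRecord, templates: list[Template] | None = None,
                     config: PipelineConfig | None = None,
                     scale: float | None = None) -> SegmentResult:
    """Classify every beat of one segment.

    With ``templates=None`` the full personalised pipeline runs: band-pass,
    quality gating, R-peak detection, auto-encoder training, silhouette
    K-means, template construction/typing, then the two-step rule
    classification.  With reused ``templates`` the beats are matched directly
    (step 1 against the best-Covr template, then step 2).
    """
    config = config or PipelineConfig()
    fs = record.fs
    filtered = preprocess.bandpass_filter(record.signal, fs,
                                          config.filter_band,
                                          config.filter_order)
    bad = _quality_mask(filtered, fs, config)

    peaks = preprocess.detect_r_peaks(filtered, fs)
    peaks = preprocess.refine_r_peaks(filtered, peaks, fs)
    if len(peaks) == 0:
        logger.warning("no beats detected in segment %s", record.record_id)
        return SegmentResult(np.empty(0, int), [], [], np.empty(0), templates or [])

    beats_raw = preprocess.segment_beats(record, peaks)
    beats_fil = preprocess.segment_beats(record, peaks, signal=filtered)
    kept_peaks = np.asarray([b.r_sample for b in beats_raw], dtype=np.int64)
    scored = ~bad[kept_peaks]

    # amplitude normalisation: unit median |R| per segment
    if scale is None:
        ref = np.abs(filtered[kept_peaks[scored]]) if scored.any() \
            else np.abs(filtered[kept_peaks])
        scale = float(np.median(ref)) or 1.0
    for b in beats_raw:
        b.hw = b.hw / scale
    for b in beats_fil:
        b.hw = b.hw / scale

    idx_scored = np.nonzero(scored)[0]
    n = len(beats_raw)
    labels = ["Non_PVC"] * n
    provenance = ["unscored"] * n
    best_covr = np.zeros(n)
    ctxs = _rhythm_contexts(kept_peaks, fs)

    built_here = False
    assignment = np.full(n, -1)
    if templates is None:
        built_here = True
        train_idx = idx_scored if len(idx_scored) >= 8 else np.arange(n)
        ae_model = train_autoencoder([beats_raw[i] for i in train_idx],
                                     [beats_fil[i] for i in train_idx],
                                     config.ae)
        emb = encode(ae_model, beats_raw)
        clustering = select_k_and_cluster(emb[train_idx], config.k_min,
                                          config.k_max, config.ae.seed,
                                          config.cluster_restarts)
        templates = build_typed_templates(
            clustering, emb[train_idx],
            [beats_fil[i] for i in train_idx], fs,
            config.n_template, config.rules)
        k = clustering.k
        # map cluster labels back onto the full beat list
        for pos, i in enumerate(train_idx):
            assignment[i] = clustering.labels[pos]
        # any unscored/extra beat: nearest centroid
        for i in range(n):
            if assignment[i] < 0:
                d2 = np.sum((clustering.centroids - emb[i]) ** 2, axis=1)
                assignment[i] = int(np.argmin(d2))
    else:
        k = len(templates)
        for i in range(n):
            cv = [covr(beats_fil[i].hw, t.tw) for t in templates]
            assignment[i] = int(np.argmax(cv))

    dom_idx = int(np.argmax([getattr(t, "member_count_total", t.member_count)
                             for t in templates]))
    unknown_after_step1 = []
    dom_covrs = []
    for i in range(n):
        tpl = templates[assignment[i]]
        s = match_scores(beats_fil[i].hw, tpl.tw)
        best_covr[i] = s.covr
        if assignment[i] == dom_idx:
            dom_covrs.append(s.covr)
        if step1_match(s, config.covr_hi, config.covr_lo,
                       config.ardiff_max, config.endiff_max):
            lab, prov = tpl.type, "step1"
        else:
            unknown_after_step1.append(i)
            lab, prov, bc = step2_resolve(beats_fil[i].hw, templates,
                                          ctxs[i], config)
            best_covr[i] = bc
        if scored[i]:
            labels[i], provenance[i] = lab, prov

    return SegmentResult(
        r_samples=kept_peaks,
        labels=labels,
        provenance=provenance,
        best_covr=best_covr,
        templates=templates,
        updated=built_here,
        k=k,
        step1_unknown_frac=len(unknown_after_step1) / n,
        dominant_mean_covr=float(np.mean(dom_covrs)) if dom_covrs else 0.0,
        scale=scale,
    )


def needs_template_update(result: SegmentResult,
                          threshold_unknown: float = 0.10,
                          threshold_covr: float = 0.9) -> bool:
    """Update rule for reused templates: too many step-1 Unknowns, or the
    dominant cluster's mean Covr has drifted down."""
    return bool(result.step1_unknown_frac > threshold_unknown
                or result.dominant_mean_covr < threshold_covr)


def process_long_term(record: ECGRecord,
                      config: PipelineConfig | None = None) -> SegmentResult:
    """Segment-wise processing of a long recording with template reuse.

    The first segment runs the full pipeline; each later segment is first
    classified with the previous templates and rebuilt (and re-classified)
    only when :func:`needs_template_update` fires.  Results are concatenated
    in time order.
    """
    config = config or PipelineConfig()
    fs = record.fs
    seg_len = int(round(config.segment_minutes * 60 * fs))
    n = len(record.signal)
    bounds = list(range(0, n, seg_len))
    starts_stops = [(s, min(s + seg_len, n)) for s in bounds]
    # a short tail (< 20% of a segment) rides with the previous segment
    if len(starts_stops) > 1 and (starts_stops[-1][1] - starts_stops[-1][0]) < 0.2 * seg_len:
        starts_stops[-2] = (starts_stops[-2][0], n)
        starts_stops.pop()

    all_r, all_lab, all_prov, all_covr = [], [], [], []
    seg_log = []
    templates = None
    scale = None
    any_update = False
    for si, (start, stop) in enumerate(starts_stops):
        seg = ECGRecord(record.signal[start:stop], fs,
                        lead_name=record.lead_name,
                        record_id=f"{record.record_id}:{si}")
        updated_here = False
        if templates is None:
            res = classify_segment(seg, None, config)
            logger.info("segment %d: built %d templates (K=%d)",
                        si, len(res.templates), res.k)
        else:
            res = classify_segment(seg, templates, config, scale=scale)
            if needs_template_update(res, config.update_unknown_frac,
                                     config.update_min_covr):
                logger.info("segment %d: template update triggered "
                            "(unknown %.1f%%, dom covr %.3f)", si,
                            100 * res.step1_unknown_frac,
                            res.dominant_mean_covr)
                res = classify_segment(seg, None, config)
                any_update = True
                updated_here = True
        seg_log.append({"segment": si, "start": start, "stop": stop,
                        "built": si == 0, "updated": updated_here,
                        "unknown_frac": res.step1_unknown_frac,
                        "dominant_mean_covr": res.dominant_mean_covr})
        templates, scale = res.templates, res.scale
        all_r.append(res.r_samples + start)
        all_lab.extend(res.labels)
        all_prov.extend(res.provenance)
        all_covr.append(res.best_covr)

    return SegmentResult(
        r_samples=np.concatenate(all_r) if all_r else np.empty(0, int),
        labels=all_lab,
        provenance=all_prov,
        best_covr=np.concatenate(all_covr) if all_covr else np.empty(0),
        templates=templates or [],
        updated=any_update,
        segment_log=seg_log,
    )
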