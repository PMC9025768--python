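# pvckit

Unsupervised detection of premature ventricular contractions (PVCs) in
long-term single-lead ECG, fusing a deep-learning feature extractor with an
expert-system classifier.

PVCs are ectopic beats arising in the ventricle: they come early (a short
coupling interval followed by a compensatory pause), lack a P wave, and have
a wide, high-amplitude QRS complex. Automatic PVC screening of Holter-style
recordings has to work without per-patient labels and on hours of signal —
which is what this package targets. No training data is required: the
pipeline is personalised per recording segment.

## Method

For each 30-minute segment:

1. **Preprocess** — quality-gate the segment (flatline / clipping / spectral
   rules), band-pass 0.1–45 Hz (zero-phase order-4 Butterworth), detect
   R peaks on a squared wavelet QRS-band reconstruction with an adaptive
   threshold, refine each peak three times to the ±25 ms absolute maximum,
   and cut 0.5 s beat windows (0.1 s before R, 0.4 s after).
2. **Embed** — train an LSTM auto-encoder on the segment's beats (raw beat
   in, band-pass-filtered beat as reconstruction target); the encoder's
   final hidden state h ∈ R³² is the beat embedding.
3. **Cluster** — K-means over embeddings, K chosen by maximising the
   silhouette coefficient SC = (1/M) Σᵢ (b(i)−a(i))/max{a(i),b(i)}; each
   cluster's template TW is the mean filtered waveform of its 30 members
   closest to the centroid; templates are typed PVC/Non_PVC by QRS height,
   QRS width and correlation with the dominant (sinus) template.
4. **Classify** — every beat HW is scored against its template:
   Pearson correlation *Covr*, area difference
   *ArDiff* = |Σ|HW|−Σ|TW|| / Σ|TW| × 100%, and energy difference
   *EnDiff* = Σ(HW−TW)²/ΣTW². The beat inherits its template's type iff
   `Covr ≥ 0.9 or (Covr ≥ 0.8 and ArDiff < 10 and EnDiff < 1)`; otherwise it
   is re-scored against *all* templates, and failing that an RR-interval
   rule (premature coupling + compensatory pause) decides.
5. **Reuse** — later segments of a long recording reuse the previous
   templates until too many beats go unmatched or the dominant-template
   correlation drifts, at which point templates are rebuilt.

Evaluation follows the usual beat-level conventions: Se = TP/(TP+FN),
P+ = TP/(TP+FP), ACC = (TP+TN)/total (all ×100%), plus the
challenge-style PVC penalty (1 point per false positive, 5 per missed PVC;
lower is better).

A seeded synthetic ECG generator (Gaussian-bump P-QRS-T morphology, PVC
timing with compensatory pauses, baseline wander and broadband noise)
provides ground truth for every stage, so the whole pipeline is testable
offline. WFDB records (.hea/.dat/.atr) and plain CSV are supported for real
data.

## Worked example

```console
$ pvckit simulate -o rec --duration 300 --fs 250 --seed 7
wrote rec.hea/.dat/.atr (348 beats)
$ pvckit detect rec.hea -o labels.csv --seed 7 --epochs 20
348 beats, 26 PVC -> labels.csv
$ pvckit evaluate labels.csv rec.atr --fs 250
TP=26 TN=322 FP=0 FN=0
Se=100.00% P+=100.00% ACC=100.00% PVC-score=0
```

`simulate` writes a 5-minute synthetic record with 10% PVC burden as WFDB
files ('V' marks PVCs in `rec.atr`). `detect` runs the full pipeline and
writes one row per detected beat (`r_sample,label,provenance,best_covr`) —
here 26 beats were called PVC. `evaluate` pairs predictions with reference
beats within ±150 ms and reports the beat-level confusion counts, the three
percentage metrics and the penalty score; on this clean record every beat is
recovered and classified correctly, so the penalty is 0.

The same commands accept real WFDB recordings (e.g. 30-minute ambulatory
records); `pvckit sweep` grid-searches the auto-encoder's batch size and
feature number against reference annotations.

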