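# Methods

This note documents the models and procedures implemented in pvckit, the
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions that matter when reproducing
results.

## Signal model and preprocessing

Input is a single-lead ECG in mV at its native sampling rate (no resampling;
all windows are defined in seconds, so 250/275/360/400 Hz recordings are
handled identically).

**Quality gate.** A rule-based stand-in for a learned signal-quality
classifier, with the same accept/reject contract and a pluggable interface:
a segment passes when (i) fewer than 20% of its one-second blocks are flat
(peak-to-peak < 0.01 mV), (ii) fewer than 5% of samples sit at the amplitude
rails, and (iii) the power ratio (5–40 Hz)/(0.5–45 Hz) exceeds a floor.
As a stand-alone check the floor is 0.5; inside the pipeline it defaults to
0.25 because wide ectopic QRS complexes legitimately shift power below 5 Hz
— a segment with a 10–30% PVC burden scores 0.30–0.45 while flatline and
out-of-band artefact score ≈ 0, so 0.5 would reject exactly the segments the
method exists for. The gate is applied per segment by default; a
sub-window excision mode (`quality_granularity="subwindow"`) exists but is
off for the same reason. Beats inside rejected signal are emitted as
Non_PVC with provenance `unscored`.

**Band-pass.** Zero-phase (forward–backward) order-4 Butterworth, 0.1–45 Hz.
The 0.1 Hz edge settles slowly (seconds), which matters only for synthetic
step inputs, not for continuous ECG.

**R-peak detection.** The signal is mirror-padded by 1 s, decomposed with a
db4 discrete wavelet transform, and reconstructed from the detail levels
whose bands overlap ≈ 5–22.5 Hz (the QRS band). The reconstruction is
squared; local maxima must exceed an adaptive threshold of 0.3 × the running
98th-percentile envelope (5 s blocks, with an absolute floor at 5% of the
global envelope maximum so flat signal yields no peaks). A 250 ms refractory
interval keeps the larger of two competing peaks. Each envelope peak is then
localised to the absolute-amplitude maximum within ±100 ms: the squared
QRS-band envelope of a wide or biphasic complex can crest on a flank or the
S wave, and without this step the subsequent ±25 ms refinement gets trapped
on the S-wave local maximum of large PVCs. Finally each peak is refined
three times to the argmax of |signal| within ±25 ms (so a peak never moves
more than 3 × round(0.025·fs) samples).

**Beat windows.** 0.5 s per beat: `n_pre = floor(0.1·fs)` samples before R,
the rest after, with half-up rounding of `0.5·fs` (fs = 275 gives 138
samples, never banker's 137/192 artefacts). Windows crossing the signal
boundary are dropped and logged.

## LSTM auto-encoder

Single-layer LSTM encoder (standard gates: input, forget with bias
initialised to +1, candidate via tanh, output) consumes the beat as a
univariate sequence, one time step per sample. The final hidden state
h (dimension = `feature_number`, default 32) is the beat embedding. The
decoder is a single-layer LSTM that receives h as its **input at every
step** (zero initial state) followed by a linear read-out. Feeding the
embedding at each step rather than only as the initial state is the classic
Keras-style sequence auto-encoder layout; initial-state-only decoders were
tried first and converge an order of magnitude more slowly on the
degenerate single-waveform fit used as a training sanity check.

Training: the encoder sees the *raw* beat, the loss is mean squared error
against the *band-pass-filtered* beat (a denoising target); Adam at
learning rate 1e-3, batch size 128, 100 epochs by default. Beats are
amplitude-normalised per segment by the median |R| amplitude before
training, which stabilises the loss scale across recordings. The whole
network (BPTT and Adam) is plain numpy in float32, seeded and exactly
reproducible; gradients are verified against finite differences in the test
suite. On desk-scale segments (≈ 700 beats of 125–180 samples) 20 epochs
take ≈ 15 s on one CPU and already separate PVC from sinus embeddings
cleanly; the tests and the acceptance script therefore train 10–50 epochs
depending on fixture size, as their stated problem sizes.

A hyperparameter sweep utility covers batch ∈ {64,128,256} ×
features ∈ {16,32,64}; 128/32 are the shipped defaults.

## Clustering and templates

For K in [2, 8] (upper bound configurable; capped at the number of beats),
K-means (k-means++, 10 restarts, seeded) is run on the embeddings and the
silhouette coefficient is computed with the conventions: singleton-cluster
members contribute 0, and 0/0 := 0 for coincident points. The
silhouette-maximising K wins; ties go to the smaller K. Cluster members are
ranked by ascending squared Euclidean distance to their centroid (stable
sort, original order breaks ties) and the filtered waveforms of the first 30
are averaged pointwise into the cluster template (smaller clusters use all
members; the shortfall is logged). The mean (not median) keeps the template
linear in its members, consistent with the correlation-based matching.

**Template typing.** The most populous cluster is the dominant (assumed
sinus) template, always Non_PVC. Any other template is PVC iff its QRS width
exceeds 120 ms AND its correlation with the dominant template is below 0.8
AND it is either ≥ 1.2× taller or ≥ 1.4× wider than the dominant QRS.
Baseline for height/width is the median of the first `n_pre/2` samples;
the QRS region is ±100 ms around R; width is the span where
|TW − baseline| > 20% of the height. The 120 ms / 0.8 / 1.2 thresholds are
clinical-convention defaults (a PVC QRS is ≥ 120 ms by definition) and all
live in `RuleConfig`.

## Beat classification

Step 1 compares each beat with its own cluster's template and accepts the
template's type iff `Covr ≥ 0.9 or (Covr ≥ 0.8 and ArDiff < 10 and
EnDiff < 1)` — comparisons exactly as written (inclusive on Covr, strict on
ArDiff/EnDiff; Covr of a constant sequence is defined as 0). Unknown beats
are re-scored against every template; among templates passing the same rule
the highest Covr wins (ties: lowest EnDiff). If none passes, the rhythm rule
decides: PVC iff RR_pre < 0.9 × RR_local and RR_pre + RR_post ≥ 1.8 ×
RR_local, with RR_local the median of the preceding 8 RR intervals. The
rhythm rule is consulted only when no template matches; letting rhythm
override a confident template match was considered and rejected as it would
re-label interpolated PVCs' neighbours. A beat matching nothing with
inconclusive rhythm defaults to Non_PVC (favouring specificity; switchable
to PVC where missed diagnoses are costlier than false alarms).

**Long-term recordings** are split into 30-minute segments. Segment 1 runs
the full pipeline; later segments reuse the previous templates (beats are
assigned to their best-Covr template since no clustering exists for them)
and trigger a rebuild when the step-1 Unknown fraction exceeds 10% or the
dominant cluster's mean Covr falls below 0.9. Both thresholds are declared
reconstructions — the update criterion is a design choice, kept
conservative so stable morphology is never retrained. A trailing segment
shorter than 20% of the segment length rides with its predecessor.

## Evaluation

Predictions and reference beats are paired greedily by ascending |Δt| within
±150 ms (each side pairs at most once). The tolerance is a default, not a
published constant; greedy pairing (rather than optimal bipartite matching)
is deterministic and adequate at physiological heart rates, where beats are
≥ 250 ms apart. Unpaired reference PVCs are FN, unpaired predicted PVCs are
FP, unpaired reference Non_PVC beats are TN. Reports include both pooled
(summed-count) and per-record-mean metrics, since aggregation conventions
differ between studies. The penalty score is FP + 5·FN over PVC beats only.

## Synthetic generator

Beats are sums of Gaussian bumps. Sinus: P, Q, R (1 mV, ≈ 40 ms at the 20%
criterion), S, T. PVC: no P wave, R 1.5 mV with ≈ 160 ms QRS (20%
criterion), deep S, inverted T. Timing: RR intervals from a truncated
normal heart rate (default 70 ± 3 bpm); each beat is independently a PVC
with probability `pvc_fraction` (default 0.1), never two in a row by
default; a PVC's coupling interval is 0.65 × the local RR and the following
interval completes a full compensatory pause (pre + post = 2 × local RR).
Additives: 0.25 Hz sinusoidal baseline wander (0.1 mV) and white Gaussian
noise (0.05 mV). Everything is seeded and byte-reproducible.

What it does **not** emulate: muscle artefact and electrode motion
transients, heart-rate trends and respiratory sinus arrhythmia, atrial
arrhythmias, couplets/bigeminy (couplets exist behind a flag but are
untested), multifocal PVC variety within one record, and 12-lead geometry.
Consequently, passing tests demonstrate that the algorithm recovers the
morphological/rhythmic structure it assumes — near-perfect scores on this
generator do not forecast clinical-database performance, where reported
PVC sensitivities for template-matching methods are in the high-80s to
low-90s percent range.

## Numerical conventions and degenerate inputs

* Sample counts use half-up rounding; sample indices are 0-based; windows
  are half-open slices.
* Covr is clipped to [−1, 1]; constant sequences give 0. ArDiff/EnDiff
  raise on an all-zero template (no meaningful normalisation exists).
* Silhouette: singleton clusters and 0/0 contribute 0.
* Metrics with empty denominators (no reference PVCs, or no predicted PVCs)
  return NaN flags rather than raising.
* Flat input yields zero detected R peaks; a segment with no beats returns
  an empty, warned result rather than failing.
* All seeds fan out from one pipeline seed; reruns are bit-identical on a
  fixed platform.

## Known limitations

* The quality gate is a three-rule heuristic, not the learned
  signal-quality model it stands in for; its spectral index is blind to
  in-band artefact (e.g. electrode pops filtered into 5–40 Hz).
* R-peak localisation targets the absolute-amplitude extremum; low-amplitude
  PVCs (rare in lead II) or QS-pattern beats could localise on the wrong
  deflection.
* Template typing assumes the dominant cluster is sinus; in a record that is
  mostly ventricular rhythm the labels would invert.
* The per-sample LSTM sequence length grows with sampling rate; very high
  rates (> 500 Hz) make numpy training slow and would warrant decimation of
  the AE input (not of the matching waveforms).
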