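# Methods

This note documents the models, numerical choices and limitations behind
`mindeeg`.  It is written for a reader who wants to understand what the
synthetic experiments can and cannot show before applying the pipeline to
real recordings.

## The decoding problem

A cohort of novice meditators is recorded in four conditions: resting and
meditating, each at an early (stage 1) and a late (stage 2) point of an
8-week mindfulness course.  Six classification tasks are defined over the
four conditions: the four-class problem, three meditation-vs-rest ("state")
contrasts (within stage 1, within stage 2, and stages pooled), and two
stage ("trait") contrasts (meditation EEG and resting EEG).  Classifiers
are evaluated under four regimes that correspond to different deployment
scenarios: leave-one-subject-out (inter-subject), pooled random splits
(mix-subject), per-subject training (intra-subject), and subject-transfer
(pretrain on the other subjects, fine-tune on the target).

## Synthetic cohorts

The generator is a linear mixing model, not a biophysical head model.
Each band rhythm (delta 1–4, theta 5–8, alpha 8–12, beta 13–30, gamma
31–80 Hz) is band-limited Gaussian noise: unit-variance white noise passed
through a zero-phase (odd-length, linear-phase, centred) FIR bandpass whose
transition width is 15% of the band width, giving ≥ 90% of the power
inside the nominal band.  Four source locations carry independent
realisations of every band: a diffuse background (uniform pattern, 0.2
relative amplitude) and one Gaussian spatial bump (σ = 0.35 in unit-disc
coordinates) per region of interest — occipital, mid-frontal and
mid-parietal.  ROI channels are laid out in clusters around anatomically
placed anchors, so the bumps genuinely cover their ROI channels.

Default per-band RMS amplitudes are 8/4/10/3/1.5 µV
(delta/theta/alpha/beta/gamma) — the usual resting-EEG ordering with a
dominant alpha rhythm.  Conditions modulate source amplitudes through
positive gains per (band, ROI):

* meditation: alpha ×1.5 frontally and occipitally, beta ×1.3 frontally,
  delta ×0.7 mid-parietally (power therefore scales with gain², e.g. 2.25×
  for alpha);
* stage 2: all sources ×1.2 (a global trait shift) plus a fixed small
  rotation (0.08 rad) of the mixing patterns, making stage contrasts
  decodable from both meditation and resting EEG, with the rest contrast
  the harder of the two.

Measurement artefacts: white sensor noise (2 µV), 50 Hz line interference
(1 µV, per-channel amplitude spread), and slow drift (5 µV at 0.05 Hz).
Drift is modelled as common-mode with a ±10% per-channel gain spread.
This choice is deliberate: with independent per-channel drift phases, the
drift vector that survives the 0.1 Hz zero-phase highpass near segment
edges becomes a per-recording fingerprint in channel space, which a
supervised spatial filter will exploit at small cohort sizes.  Physically,
most slow drift is reference/amplifier common mode, which average
re-referencing removes exactly.

Inter-subject heterogeneity is a single `dispersion` knob: each subject's
mixing patterns are rotated by a random orthogonal transform `expm(θK)`
(K skew-symmetric, unit spectral norm, θ = dispersion) and each subject's
band amplitudes are jittered lognormally (σ = 0.25·dispersion).
`dispersion = 0` gives an exactly homogeneous population; the default 0.3
reflects that real cohorts of this kind are noticeably non-homogeneous.
Everything derives from a single integer seed through spawned NumPy seed
sequences, so cohorts are bit-reproducible.

What the generator does **not** emulate: volume conduction from a
realistic head model, ocular/muscle artifacts, non-stationarity within a
condition, 1/f background spectra, inter-session variability, and any
nonlinear or connectivity structure.  Consequently, passing tests show
that the pipeline recovers planted linear band-power effects under
realistic noise — not that it would reach comparable accuracies on human
data.

## Preprocessing

Fixed stage order: drop the 15 listed bad channels (128 → 113) → polyphase
FIR resampling to 250 Hz → whole-brain average re-reference → 50 and
100 Hz notches (2nd-order IIR, Q = 30) → 0.1–120 Hz bandpass (4th-order
Butterworth as second-order sections) → segmentation.  All filters are
applied forward–backward (zero phase).  An artifact-removal stage exists
as a logged no-op, since the synthetic data are artifact-free; on real
data a dedicated method should be substituted there.

Sample counts follow an inclusive-endpoint convention: a d-second segment
at rate r holds `round(d·r) + 1` samples, and consecutive 5-s trials share
exactly one boundary sample (window 1,251, hop 1,250).  This is the unique
convention under which a 10-minute condition yields both 120 trials and
1,251 samples per trial; it is isolated in `PreprocConfig`, so other
conventions are one parameter away.

## CSP, FBCSP, SVM

Per-trial covariances are computed after removing the per-channel trial
mean (otherwise sub-highpass residuals near segment edges leak into the
lowest band), trace-normalised (robustness to trial amplitude), averaged,
and stabilised with a shrinkage of 1e-8 × mean diagonal.  The whitened
class-1 covariance is eigendecomposed with eigenvalues sorted descending;
filters 1, 2, n−1, n are retained, giving 4 log-variance features
(`log(var + 1e-12)`); patterns are the matching columns of the
pseudo-inverse of the full filter matrix.  The filter bank is ten
contiguous 4-Hz Butterworth bands from 0–40 Hz (the 0–4 band is a lowpass),
applied zero-phase per trial.  One-vs-rest fits one (FB)CSP per class and
concatenates features in ascending label order.  The SVM stage z-scores
features with training statistics only and uses an RBF kernel with C = 1
and sklearn's `gamma="scale"`; a linear kernel is available by
configuration.

## Networks

Both ConvNets run on NumPy with hand-written backprop; convolutions are
expressed as BLAS matrix products over sliding windows.  The shallow net
is temporal conv (40 × 25) → spatial collapse (40 filters over all
channels) → batch norm → square → mean pool (75, stride 15) → log →
dropout 0.5 → dense softmax.  Batch normalisation before the squaring is
part of the reference shallow design and is what keeps the square/log head
trainable at µV input scales; it can be disabled.  The deep net is four
conv/max-pool blocks (25/50/100/200 filters, kernel 10, pool 3) with ELU
and batch norm, then dropout and a dense softmax.  Training: Adam
(lr 10⁻³), batch 32, up to 100 epochs, early stopping on validation
accuracy with patience 10, best-epoch weights (including batch-norm
running statistics) restored.  Fine-tuning for subject transfer reuses the
weights at lr/10 for up to 30 epochs.  All randomness (init, shuffling,
dropout) flows from one seed; on a fixed thread count two runs with the
same seed produce identical weights.  Penultimate features are the
flattened activations entering the dense layer, extracted in evaluation
mode.

Minimum input lengths are derived from the pooling chains (99 samples for
the shallow net, 441 for the deep net at default kernels); shorter inputs
are rejected with the required minimum in the message.

## Evaluation and statistics

Splits are stratified by class and deterministic given a seed:
mix/intra use 60/20/20 train/val/test for networks and 80/20 for SVM
methods; leave-one-subject-out uses one fold per subject with an 80/20
train/val split of the remaining subjects' trials (networks) or all of
them (SVM).  Intra-subject rows report the mean accuracy over subjects per
repetition.  Subject-transfer applies only to networks and, like
intra-subject evaluation, only to the state tasks.  Leakage guards raise
if any test index reaches train/val or if a held-out subject's trials
appear in pretraining; these guards are exercised by the test suite.

The Mann-Whitney U test is implemented directly (normal approximation with
tie correction; Z signed by the first sample's ranks; no continuity
correction) and cross-checked in tests against exact enumeration and
scipy.  Kruskal-Wallis delegates to `scipy.stats.kruskal` (tie-corrected
chi-square, k−1 df) with an explicit guard returning H = 0, p = 1 when all
values are identical.  The summary groups accuracies within a strategy:
shallow-vs-deep pooled across tasks (Mann-Whitney), and across tasks with
methods pooled (Kruskal-Wallis); other groupings are one `groupby` away.

## Feature analysis

Welch PSDs use 2-s Hann windows with 50% overlap (one-sided density;
integrating it recovers the variance to within a few percent).  ROI band
power is the trapezoidal integral over the band, averaged over the ROI's
channels.  The handcrafted features are δ/α and δ/β power ratios for each
of the three ROIs (6 columns, ROI-major order); the analysis-side beta
band is 12–30 Hz (the generator's rhythm definition uses 13–30 Hz — both
conventions appear in the field and are kept explicit per module).

The first canonical correlation between two feature blocks is computed by
whitening both covariance blocks (symmetric inverse square root) and
taking the largest singular value of the whitened cross-covariance.  Both
blocks receive a ridge of 1e-8 × their mean diagonal: scaling the ridge
with the data keeps r invariant under well-conditioned invertible linear
transforms, and at 1e-8 an exactly linear relation still yields r = 1 to
within 1e-6.  The chance level is the distribution of r against standard
normal white-noise matrices of matching shape (100 repetitions by
default); a correlation is significant when it exceeds the 95th percentile
of those draws, which by construction flags ≈ 5% of null draws.

## Problem sizes used in the shipped checks

The end-to-end checks run on reduced problem sizes chosen to exercise the
full pipeline faithfully:

* structural counts use one full-length 10-minute condition at 250 Hz
  through the complete chain, plus a 60-s 1 kHz recording for the
  1000 → 250 Hz resampling convention;
* parameter recovery uses a 16-channel compact montage (same anchor
  layout, proportional ROIs), 5 homogeneous subjects, 100-s segments.
  At the full 113 channels with ~100 trials per class, per-band CSP
  covariance overfit dominates any effect size — the original study had
  2,640 trials for the pooled state task — so the montage is scaled to the
  trial budget rather than pretending 113-channel results at desk scale;
* the FBCSP-vs-CSP comparison confines the planted effect to the alpha
  band **and** lowers the alpha baseline to 3 µV: if alpha dominates
  wideband variance, wideband CSP sees the effect just as well and the
  comparison is vacuous;
* the inter- vs mix-subject ordering uses 3 subjects at dispersion 1.0
  with 2-s trials and networks at 12 epochs.  At much higher dispersion
  pooled-subject CSP itself collapses (a single 4-filter set cannot serve
  several nearly orthogonal pattern sets), which destroys the comparison
  rather than strengthening it.

## Known limitations

* The ConvNets are CPU-scale; the default 113 × 1251 input is feasible but
  slow in pure NumPy, so network experiments are typically run on reduced
  montages/trial lengths.
* EDF export truncates to whole 1-s data records and quantises to 16 bits
  of the symmetric physical range; HDF5 is the lossless container.
* The intra-subject and transfer regimes assume each subject has enough
  trials per class for a stratified 60/20/20 split; degenerate cases raise
  rather than silently rebalance.
* CCA on penultimate features with far more columns than trials is rank
  deficient; the implementation warns and regularises, but per-subject
  analyses should use trial counts well above the handcrafted dimension.
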