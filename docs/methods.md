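# Methods

## Signal model

Imagined speech is assumed to leave a band-limited spectral signature
in scalp EEG: during a monosyllable chunk of 7–9 analysis frames the
high-gamma (80–180 Hz) spectrum carries two stable peaks (P1 < P2),
while the rest of the trial is background activity. The analysis model
is autoregressive: the observed sequence x(n) is white-noise excitation
through an all-pole filter,

    x̂(n) = −a₁x(n−1) − … − a_p x(n−p),    p = 8,

whose magnitude response L(k) = 1/|ℱ{1, a₁, …, a₈, 0, …}| carries the
linguistic information. Unlike speech LPC there is no voiced/unvoiced
source switch — the sole excitation is random noise. The synthetic
generator runs this model *forward* (planted pole pairs → waveform);
the pipeline runs it backward (waveform → Levinson-Durbin → spectrum),
so parameter recovery closes the loop end to end.

## Analysis grid

512 Hz sampling; 24-sample (≈47 ms) windows hopped every 12 samples
(exact 50% overlap); periodic Hann taper; zero-padding by 104 points to
a 128-point FFT. The bin spacing is therefore fs/128 = 4.0 Hz, and the
80–180 Hz pass band covers bins 20–45 inclusive (26 bins). All chunk
positions are expressed on this frame grid.

Two consequences of the short window are documented rather than hidden:

* **Stop-band rejection is leakage-limited.** The 24-sample Hann
  mainlobe spans roughly ±43 Hz, so per-frame brick-wall masking plus
  overlap-add attenuates a 50 Hz tone to ~3% RMS, not arbitrarily low.
* **Band-pass reconstruction is not a projection.** Re-windowing a
  band-limited signal leaks energy outside the mask, which a second
  pass removes; applying the operator twice changes the waveform by
  ~15% relative RMS. Downstream analysis is unaffected (it re-enters
  the spectral domain immediately), but the operator should not be
  treated as idempotent.

## Preprocessing choices

* DC removal subtracts the mean of consecutive 100 ms blocks
  (51 samples at 512 Hz, `round()`); the trailing partial block uses
  its own mean.
* The noise spectrum N̄(k) is the mean magnitude over the frames of the
  noise-only lead-in (default: frames 0–19, the 500 ms pre-imagery
  interval), estimated per trial and per channel.
* Spectral subtraction is magnitude-domain with half-wave
  rectification and unmodified phase; an optional floor factor
  (default 0) is exposed. No over-subtraction factor — the plainest
  variant, because nothing in the problem requires more.
* Band edges are inclusive; a bin belongs to the band if its centre
  k·fs/128 lies in [80, 180].

## LPA details

* Biased autocorrelation estimator (no lag normalisation): it keeps the
  Toeplitz system positive semidefinite, which the recursion needs.
* Order 8 by default; a 24-sample frame supports this marginally, and
  that marginality is a real property of the design — per-frame
  spectra scatter around the underlying peaks, and everything
  downstream is built to average that scatter out.
* No lag window by default; a Gaussian lag window is available but
  widening it trades peak sharpness for variance, and sharp peaks are
  what the line-spectrum conversion wants.
* Pipeline spectra carry the AR excitation gain √E (E = final
  prediction-error energy), so pooled amplitudes reflect power;
  the bare `lpa_spectrum` op returns the shape-only response.
* Line spectra: local maxima are + → − sign changes of the first
  difference (plateau ties to the lowest bin); shoulder inflections are
  − → + sign changes of the second difference where the slope keeps its
  sign, so peak flanks are not duplicated.

## Sample rendering for the vowel search

The search and classifiers consume one spectrum vector per (electrode,
frame) over the 26 pass-band bins. Two renderings exist:

* `lpa_spectrum` (default): the full all-pole spectrum. Chosen because
  the smooth spectrum preserves peak structure under the 4 Hz grid —
  with sparse spike renderings, per-frame peak scatter of ±1–2 bins
  splits eigenvector mass across adjacent bins, degrades the
  template-recovery cosine from ~0.95 to 0.4–0.8, and grows twin peaks
  in G(v).
* `line`: the sparse line-spectrum rendering (zeros off-line), kept as
  a config switch; it remains the representation used for pooling,
  chunk detection and the CNN input.

## Vowel search

PCA is **uncentered** (eigendecomposition of the second-moment matrix):
the subspace similarity projects raw spectra, and only without
centering does a sample lying in the subspace score S = 1. Eigenvalues
are normalised per sample; eigenvector signs are fixed by making the
largest-magnitude component positive. M = 8 components; search window =
last 6 of 9 chunk frames; 4 refinement rounds of select-best-frame
(global argmax over electrodes × frames per chunk, ties to earlier
frame then lower electrode) followed by PCA refit. Once selection has
concentrated the samples near a template the refit may find fewer than
M independent directions; the refit then keeps the achieved rank
rather than failing.

## Chunk detection

Hand labels remain the ground-truth route (TSV files). The unattended
proposer offers two gates over pooled line spectra:

* *similarity* — maximal runs of adjacent frames whose top-4 line bins
  agree (Jaccard with ±1-bin tolerance) above a threshold; suits clean
  or few-electrode data.
* *energy* (used by the pipeline) — runs of frames whose pooled line
  energy exceeds 1.3× the trial median, onset refined to the window
  position capturing maximal energy (±3 frames), runs longer than the
  maximum split into consecutive candidates. With 21 pooled electrodes
  the line positions of single frames scatter too much for the
  similarity gate, while sustained in-band power still marks a chunk
  cleanly: measured on the default corpus, 94/100 true chunks are found
  within ±1 frame with zero candidates on 30 noise-only trials.

The reported stability score is always the mean adjacent-frame line
similarity over the candidate.

## Reference vectors and the P1-P2 chart

G(v) is the eigenvalue-weighted root-sum-square of the eigenvectors;
the m = 1 weight is exactly 1. Because per-frame scatter smears G into
a broad envelope on which the true peaks ride as weak undulations, the
default peak picker ranks candidate bins by negative-second-difference
**curvature** rather than raw amplitude (the amplitude rule is kept as
an option and behaves identically on clean peaks). The "upper frequency
range" gate defaults to 120 Hz for hand analysis; the synthetic
pipeline admits the whole pass band because its planted peaks span it.
Per-vowel chart means are unweighted across subjects; a subject whose
G yields fewer than two qualifying peaks contributes no point for that
vowel.

## Classifiers

* **Subspace method**: a chunk is scored per vowel by the *mean*
  similarity over its candidate spectra (electrodes × last-6 frames);
  the single-sample rule (argmax of S, ties in vowel order /i e a o u/)
  is also exposed. The mean was chosen over the max because the max
  saturates — any sparse sample near a subspace scores ≈1 — and
  measured 30–40 points worse.
* **CNN**: conv(16, 3×3) → relu → maxpool(2×2) → conv(32, 3×3) → relu
  → maxpool(2×2) → dense(64) → softmax(5), Adam (lr 10⁻³), batch 32,
  50 epochs, cross-entropy, on the chunk's electrode-pooled
  line-spectrum image (6 frames × 26 bins). Implemented directly in
  NumPy (im2col convolution, explicit backprop) — fully deterministic
  per seed and comfortably fast at chunk scale.
* **Jackknife**: each subject held out once, all others pooled for
  training; summary = per-fold accuracies, mean, sample SD (n−1).

## Synthetic corpus: what it emulates, and what it does not

Defaults are the study conditions: 5 subjects; per-vowel chunk counts
(i, e, a, o, u) = (50, 50, 65, 60, 60) → 285 chunks per subject, 1425
total; 21 channels; 512 Hz; trials of 500 ms noise lead-in + 1000 ms
imagery; one true 9-frame chunk per trial at a hop-aligned onset;
Poisson(1) pseudo-syllable distractors at 0.5× gain; unit chunk RMS
against unit-σ white channel noise; per-channel gains uniform in
[0.5, 1.5].

Vowel templates place (P1, P2) at (96, 132), (104, 140), (112, 148),
(120, 156), (128, 164) Hz — exactly colinear, on bin centres, ≥16 Hz
from the band edges, pole bandwidth 8 Hz. These values balance four
constraints that pulled in different directions during design: peaks
must sit ≥10 dB above the template's own band-edge spectrum
(construction check; sharper poles or more edge margin help), the two
peaks must stay separable in G(v) (≥ ~32 Hz apart), five vowels must
fit the band, and adjacent vowels must remain confusable enough that
subject-independent classification is non-trivial.

Subject individuality = per-subject random channel gains plus a
zero-mean normal jitter (σ = 1.5 Hz) on each vowel's peaks. The jitter
is the designed difficulty of the transfer task: it is calibrated so
that leave-one-subject-out subspace accuracy lands in the 75–90% band
(measured means 82.6–86.4% over seeds), i.e. clearly above chance and
clearly below ceiling. Channel gains alone leave cross-subject accuracy
at ceiling (~97–100%).

Not modelled, deliberately: 1/f background spectra, volume conduction,
ocular/muscle artifacts, electrode drift, or any within-subject
nonstationarity. Passing tests on this corpus therefore demonstrate
that the pipeline recovers what its own signal model plants under
realistic noise and subject variation — not that comparable accuracies
would be reached on real recordings.

## Numerical and scale choices

* All randomness flows through `numpy.random.default_rng` seeds; same
  config ⇒ bit-identical corpus, search, and CNN training.
* The frequency grid is fs/n_fft = 4.0 Hz exactly; chart frequencies
  are reported on this grid.
* Acceptance-scale runs use the full 1425-chunk corpus (~40 s on one
  CPU); the test suite uses a 2-subject, 16-chunks-per-vowel corpus for
  cross-subject checks, where per-vowel peak recovery is still within
  one bin but individual-subject estimates are noisier.
* The Levinson-Durbin oracle comparison caps pole radii at 0.8: past
  that, the Toeplitz system's condition number (≳10⁸) consumes the
  double-precision agreement budget of *both* solvers.
* Silent frames are guarded by flooring r(0) at 10⁻¹²; degenerate
  (all-zero) chunks raise rather than return arbitrary selections.
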