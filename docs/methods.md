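# Methods

## Synthetic cohort model

Real two-session off-the-person ECG corpora are scarce and privacy-bound,
so the package ships a generator whose records carry exact ground truth.
Each heartbeat is the sum of five Gaussian bumps — P, Q, R, S, T — with a
per-wave amplitude (arbitrary mV-scale units), center offset relative to
the R apex (seconds), and width (seconds). Beats are placed at R times
whose inter-beat intervals are Gaussian around 60/HR seconds with a
standard deviation derived from a bpm-scale heart-rate-variability
parameter, truncated at ±3 sd so consecutive beats never overlap. Three
noise processes are overlaid:

* baseline wander — 2–3 sinusoids below 0.4 Hz with random phases, i.e.
  entirely inside the band-pass filter's stopband;
* powerline interference at 50 Hz (European mains);
* broadband Gaussian noise (EMG-like).

Default design: 63 subjects × 2 sessions × 120 s at 1000 Hz. Default wave
parameters are textbook PQRST values (R amplitude 1.0, Q/S at −32/+35 ms
with narrow widths so that the signal value at the R apex is within 1% of
the R amplitude in the noise-free case). Default noise levels — baseline
0.10, powerline 0.05, broadband sd 0.03 relative to the unit R wave — give
a clearly usable but visibly noisy trace, deliberately cleaner than the
worst dry-electrode finger recordings: the generator validates pipeline
mechanics, not field robustness.

**Subject and session structure.** A subject's morphology is the
population default with every parameter multiplied by (1 + sd·z), z
truncated standard normal, sd = `between_subject_sd` (default 0.15; offsets
and widths move at half that rate, so wave order is preserved). The second
session re-perturbs the subject's own morphology at scale `session_drift`.
Three named drift conditions are used in evaluation: **low = 0.02** (drift
small against the 0.15 between-subject spread — re-enrolment after days),
the **default = 0.05** (a months-long gap), and **high = 0.15** (drift on
the order of the between-subject spread — sessions barely recognizable).
Randomness is fanned out from the single cohort seed through per-record
streams keyed by (seed, subject index, session index), so any subset of a
cohort is reproducible bit-for-bit.

**What the generator does not emulate:** realistic HRV spectra
(intervals are i.i.d., no respiratory sinus arrhythmia), motion artifacts
and electrode detachment, ADC quantization, pathology, and the heavier
noise floor of real dry-electrode acquisitions. Passing recovery tests on
this cohort therefore demonstrates correctness of the pipeline under its
own assumptions, not expected accuracy on real recordings, which is known
to be substantially lower across sessions months apart.

## Preprocessing

* **Filter**: Butterworth band-pass of design order 4, 0.5–30 Hz, applied
  with `sosfiltfilt` (forward–backward). Zero-phase application squares
  the magnitude response and preserves fiducial latencies, which keeps the
  200/400-sample segmentation window centered on the R peak.
* **R-peak detection**: differentiate, square, integrate over 150 ms,
  adaptive threshold at 0.2 × the 99th percentile of the integrated
  energy, candidate spacing ≥ 200 ms (refractory). Each candidate is then
  refined in two stages: an argmax search over ±75 ms (the energy centroid
  can lag the apex by the QRS width), then a parabolic vertex fit over
  ±25 ms. The vertex fit matters: the 30 Hz band edge flattens the R apex,
  and a plain argmax on the flattened top jitters by up to ±10 samples
  under in-band noise — enough to misalign templates between sessions.
  The fitted vertex is a least-squares average over the window and is
  session-consistent to ±1 sample on the synthetic cohort; the returned
  index may therefore sit a sample or two off the literal sample-wise
  maximum.
* **Segmentation**: one 600-sample cycle per R peak with full margins
  (index ≥ 200, index + 400 ≤ length); peaks too close to a record
  boundary are dropped silently, as are constant (degenerate) cycles at
  normalization time (with a warning).
* **Segment elimination**: "most similar to each other" is operationalized
  as the minimal sum of Euclidean distances to all other cycles — a
  deterministic O(n²) ranking, with ties broken toward the earlier cycle,
  rather than the NP-hard minimal-total-distance subset. Elimination runs
  on the cycles in their current normalization state, so the normalized
  and raw arms may keep different cycles.

## Scalogram templates

The continuous wavelet transform uses a generalized Morse wavelet defined
in the frequency domain, Ψ(ω) ∝ ω^β e^(−ω^γ) for ω > 0 (analytic), with
γ = 3 and time-bandwidth product P² = 60, hence β = 20 and peak angular
frequency (β/γ)^(1/γ). The filter is unit-peak normalized and evaluated
per scale by frequency-domain multiplication; 12 voices per octave span
1–40 Hz (high frequency first), covering the band the filter passes.
Cycles are reflection-padded to three times their length before the FFT so
the long low-frequency wavelets do not wrap around the 600-sample window;
at the lowest analyzed frequencies the wavelet support still exceeds the
window, so those rows are edge-dominated — a property shared by any
time-frequency rendering of a 0.6 s segment.

Magnitudes are min–max normalized per scalogram (a constant magnitude maps
to the colormap midpoint), passed through a fixed 5-anchor piecewise-linear
blue→cyan→green→yellow→red colormap, and bilinearly resized (with
anti-aliasing when downsampling). The colormap only needs to be fixed and
documented, not identical to any particular plotting library's; per-image
scaling was chosen over a global color scale so each template uses the full
dynamic range.

## Concatenation and FastICA

Per-subject templates are flattened template-major, row-major within an
image, channel-last; `SubjectFeatureMatrix.unflatten` inverts the
convention exactly. For dimensionality reduction the subjects-by-features
matrix is handed to FastICA in the orientation where each *row is a mixed
signal* and the features are the observation samples: the algorithm
recovers 63 independent source waveforms (each of feature length), and a
subject's reduced representation is their 63 mixing coefficients. A test
row is reduced by removing its own mean and least-squares projecting onto
the sources. Because the sources are whitened, this projection is
orthogonal onto the span of the training rows, so Manhattan-distance
geometry within that span survives reduction up to rotation and a global
scale — the property the downstream matchers rely on. (The alternative
orientation — treating the 63 subjects as samples — makes 63 components
unattainable, since centering 63 rows leaves rank 62, and its per-direction
variance normalization amplifies noise directions; it was rejected on both
grounds.) FastICA runs the deflation variant with the logcosh contrast,
tol 1e-4, at most 500 iterations, fixed seed; fitting uses training
(session-1) rows only.

## Identification

Classifier identification treats each cycle as one 600-feature sample,
labels by subject, trains on session 1 and votes per subject over the
session-2 cycles; ties break by summed prediction confidence, then
lexicographic subject id. The vote bridges per-cycle training and the
subject-level accuracies reported (at 63 subjects, one subject = 1.59%).
Defaults where the choice was open: LDA with the SVD solver (at these
sample sizes the pooled covariance estimate is well-conditioned, and the
solver remains defined when it is not); kNN with k = 3, Euclidean; SVM
with RBF kernel, C = 1, variance-scaled gamma; decision tree with Gini
impurity, no depth cap, seeded. Distance identification is Manhattan 1-NN
over reduced rows; in Configuration 1/3 the three presentation templates
are the 60 selected session-2 cycles split into three consecutive blocks
of 20, each concatenated and ICA-transformed, and a subject needs at least
two of three nearest-neighbour hits. The convolutional-classifier route is
a pluggable interface (`identify_with_cnn(backend=...)`): no default
network is bundled, and calling it without a backend raises a clear
availability error.

## Authentication

Thresholds follow T_i = μ_i − σ_i over subject i's distance pool — their
presentation template(s) against *all* enrolment templates, the
self-distance included (both choices are config-switchable). σ_i is the
population standard deviation (divide by n): the threshold is a
descriptive statistic of a fixed pool, not an inferential estimate; the
sample-sd convention is exposed as an option. Boundary conventions follow
the rule's phrasing: genuine acceptance uses ≤ ("does not exceed"),
impostor flagging uses strict < ("below"), so exact ties resolve
pro-genuine and anti-impostor. The leave-one-out impostor evaluation
recomputes T_i from the n−1 remaining subjects for each held-out subject;
the self column is excluded by construction. The impostor score is
reported as the mean percentage of the n−1 possible impostors per subject.

## Problem sizes and numerical checks

The test suite exercises small cohorts (4–10 subjects, 30–60 s) for unit
and property tests, and full 63-subject, 120 s cohorts for the
cohort-scale checks: structural template dimensions on one cohort, and
recovery metrics averaged over five seeds at the low-drift condition
(identification ≥ 95% with LDA 60/60; authentication accuracy ≥ 85% with
impostor score ≤ 20% on not-normalized ICA-63 cycle templates; accuracy
non-increasing over the drift grid {0, low, high}). `scripts/acceptance.py`
reruns the same computations from a caller-supplied seed. Filter behaviour
is validated against the designed filter's own frequency response
(squared for the zero-phase pass), segment elimination against a
brute-force ranking, thresholds against a one-line mean/sd oracle to
1e-12, and Manhattan decisions against full-matrix recomputation.

## Known limitations

* Synthetic-cohort accuracies are far above what real cross-session
  dry-electrode data yields; they validate mechanics, not field
  performance.
* The detector is tuned for clean-to-moderate noise and a dominant
  positive R wave; inverted leads or severe artifacts are out of scope.
* Scalogram rows below ~2 Hz are edge-dominated for 600-sample cycles.
* The 1/3 presentation-template construction (three blocks of 20 from Set
  2) is one reasonable convention; others (disjoint recordings, random
  subsets) would change the numbers slightly.
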