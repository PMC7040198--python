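# Methods

This note records the models, conventions, parameter choices and known
limitations of the package, in the order data flows through the pipeline.

## Synthetic EEG generator

**Model.** Per frequency band, channel phases follow a stochastic Kuramoto
system with pairwise target lags, integrated by explicit Euler at the
sampling rate:

    theta_k[t+1] = theta_k[t] + dt*omega_k
                   + dt * sum_m K_km sin(theta_m - theta_k + lag_km)
                   + sqrt(dt) * sigma * xi_k[t]

The observed signal is `sum_bands amplitude * cos(theta)` plus white
measurement noise. The drive is evaluated with one complex mat-vec per step
(`Im((K e^{i lag} @ e^{i theta}) e^{-i theta})`), so a 16-channel, 50 s,
256 Hz band simulates in tens of milliseconds. Two burn-in seconds are
discarded so recordings start in the locked regime.

**Parameters (defaults, units, rationale).**

| parameter | default | why |
|---|---|---|
| natural frequency | band centre ± min(1 Hz, width/4), uniform per channel | keeps frequencies inside the band; a shared band rhythm with channel detuning |
| coupling strength K | 30 rad/s within clusters (20 for the central cluster) | comfortably above the locking threshold K > ~|Δω|/2, giving niPLV ≈ 0.95 for coupled pairs |
| target lags | per-node offsets spread over 1.5 rad within a cluster | globally consistent (lag_km = δ_k − δ_m), every locked pair holds a constant *non-zero* lag, which niPLV is designed to detect |
| phase noise σ | 1.5 rad/√s | decorrelates uncoupled pairs within ≪ 1 s while adding only ~0.15 rad lag dispersion to coupled pairs |
| amplitude / noise | 10 µV per band / 2 µV white | peak amplitudes ~40 µV, below the 80 µV artifact rule |
| default topology | frontal, posterior, central/temporal clusters, identical across bands | produces triangles (clustering) and non-trivial layer structure in every band |

**Randomness.** One root seed feeds `numpy.random.SeedSequence`; it spawns
one child per subject and, per subject, one child per band plus one for
measurement noise. Identical spec + seed is bit-identical.

**Planted group effect.** The default patient effect removes O1's
posterior-cluster beta couplings (multiplier 0). A multiplier is exposed,
but partial reductions that stay above the synchronization threshold leave
the pair locked and therefore produce *no* connectivity change — coupled
oscillators lose coherence abruptly, not gradually. Emulating a detectable
loss of functional connectivity therefore means crossing that threshold;
removal is the clean, reproducible case.

**What the generator does not emulate.** Volume conduction and field
spread, 1/f background spectra, non-stationary band power, eye-blink/EMG
artifacts (only optional amplitude spikes for testing the artifact rule),
and realistic cross-frequency phase coupling. Passing tests demonstrate
that the *pipeline* recovers planted phase-coupling structure; they do not
certify performance on clinical recordings.

## Preprocessing

- **Artifact rule:** an epoch is rejected if any channel exceeds 80 µV in
  absolute amplitude (inclusive threshold retains exactly-80 µV samples).
  Expert visual labelling is deliberately not emulated: only the amplitude
  rule is reproducible.
- **Epoch selection:** among clean epochs starting after a 2 min skip
  (configurable), `n` epochs are chosen at positions
  `floor(linspace(0, L-1, n) + 0.5)` — first, last, evenly spaced interior;
  deterministic by construction. "Spread through the recording" is
  under-determined; even spacing is this package's determinization.
- **FIR band-pass:** windowed-sinc (Hamming), length three cycles of the
  band's low edge (odd tap count), applied forward–backward (zero phase).
  The filtfilt pass squares the stopband attenuation; one octave outside
  any default band the response is ≥ 20 dB down (verified in tests). The
  input must exceed three filter lengths (9 s for the 1 Hz delta edge at
  any rate), so band filtering happens on whole epochs *before* windowing.
- **Windows:** left-aligned, non-overlapping, trailing partial window
  dropped (never zero-padded).
- **Referencing:** none by default (an average-reference helper exists but
  is off), matching acquisition-referenced input.

## Connectivity

Instantaneous phase is the angle of the analytic signal; 5% of samples are
trimmed from each end to suppress Hilbert edge effects (the trim fraction
is an implementation choice, not physiology). The pairwise mean phasors of
a whole montage are computed as one Gram matrix `E E^H / T` with
`E = exp(-i phases)`.

niPLV conventions: phase difference φ_k − φ_m (the estimator only uses the
phasor mean, so the convention is immaterial); denominator √(1 − (Re z)²)
treated as degenerate below 1e-12, returning 0 — the measure is built to
discard zero-lag coupling, so the zero-lag limit maps to "no (lagged)
coupling". Estimates are clipped to [0, 1] against round-off.

A practical caveat established by Monte-Carlo during development: the null
level of niPLV on independent *band-limited* channels is set by the
duration × bandwidth product, not the sample count. A 50 s alpha epoch
carries ~200 effective samples per pair, so single spurious edges up to
~0.2–0.3 occur among 120 channel pairs even with fully independent
sources. Tests bound the null accordingly (pair mean ≤ 0.1, max ≤ 0.3).

## Network construction

Candidate thresholds are the distinct positive off-diagonal weights; at
each, the graph keeps edges with weight ≥ τ and is scored by
J(τ) = E_glob − cost, where E_glob is the mean inverse shortest-path length
over ordered pairs of the *binary* graph (unreachable pairs contribute 0)
and cost is edge density. Ties in J resolve to the sparser graph; a 1e-12
comparison slack absorbs float round-off (J values are coarse rationals, so
the slack can never mask a real improvement). Surviving edges keep their
original weights for the weighted clustering numerators; degrees always
come from the binary graph. Each band and each time window is thresholded
independently (mirroring the per-band case; a common per-epoch threshold
would couple the temporal layers).

## Multiplex metrics

Ordered node pairs (j, m) are used in all triangle sums, matching the
k(k−1) ordered-pair denominators; this reading makes the boundary
constructions reach exactly 1 and 0. Degenerate denominators (no layer
with degree ≥ 2; overlapping degree 0) define the metric as 0. With zero
diagonals the triple sums reduce to diagonals of cube-rooted-weight matrix
products, which is how they are computed; brute-force enumeration is kept
in the test suite as an independent oracle (agreement to 1e-12 on random
multiplexes, N ≤ 8, M ≤ 4).

C_i,2 requires at least three layers and is exposed but not used by the
feature pipeline, which follows the two-layer-triangle coefficient C_i,1.

## Statistics

Features are averaged over epochs per subject before testing. Group tests
are two-sided Mann–Whitney U (patient vs control); p-values use scipy's
exact method for small untied samples, and the reported z is the
tie-corrected normal approximation, signed so positive means patients >
controls. A constant feature yields p = 1 with a warning. FDR control is
Benjamini–Hochberg at q = 0.05, applied within one analysis family (one
metric × one axis × one band set) — correcting across unrelated families
would change each family's effective level.

## Classification

Samples are epochs; by default all epochs of a subject share a
cross-validation fold (subject-grouped stratified k-fold), because
epoch-level folding leaks subject identity; an `epoch` unit mirrors that
leaky design where comparability is wanted. Inside every training fold, in
order: Mann–Whitney prefilter with BH-FDR (falling back to all features
when nothing is significant, so null data stays honestly at chance), LASSO
logistic selection with the penalty chosen by inner CV (falling back to the
prefiltered set if all coefficients vanish, with a warning), feature
standardisation, then the classifier (RBF-SVM with a small inner grid over
C ∈ {0.1, 1, 10, 100}, gamma = 'scale'; alternatives: linear SVM, k-NN with
k = min(5, training size), Gaussian naive Bayes, LDA). Accuracy,
sensitivity and specificity come from the pooled out-of-fold confusion
matrix (patient = positive); AUC from the pooled decision scores by
trapezoid. Mahalanobis scatter uses per-class means with Ledoit–Wolf
shrinkage covariance (plain sample covariance available for closed-form
checks).

## Problem sizes used by the test suite

The validation suite runs scaled-down study conditions chosen once:
boundary and oracle checks at N ≤ 10 nodes; trend and recovery checks on
single-band cohorts at 256 Hz with 20 s epochs (16 channels throughout);
planted-effect recovery over 50 replicate cohorts of 10 + 10 subjects with
30 null replicates; classification-direction comparison over 20 cohort
seeds of 10 + 10 subjects with four-band simulation. The full
study-scale defaults (20 + 20 subjects, four 50 s epochs, 1024 Hz) remain
the generator's defaults and run through the same code paths.

## Known limitations

- The generator's sharp locking threshold means "effect size" is not a
  smooth dial: group effects either cross the threshold or vanish.
- Cost-efficiency thresholding can retain isolated spurious edges on
  near-null matrices; node metrics on such graphs are small but not zero.
- The EDF writer emits plain 16-bit EDF with 1 s records and integer
  sampling rates only; quantisation is bounded by (physical range)/2^16.
- No source reconstruction, volume-conduction modelling, or inter-node
  cross-frequency coupling (node-aligned multiplexes only).
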