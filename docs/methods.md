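# Methods

This note documents the modelling choices behind `tvnet`: what is
computed, under which assumptions, which defaults matter, and what the
synthetic data do and do not establish.

## Signal model and estimation

Epoched, band-limited EEG segments are modelled as a time-varying vector
autoregression (MVAR): X(t) = Σ_{i=1..P} Λ(i,t) X(t−i) + E(t), with
E(t) multivariate independent white noise. All estimation runs at the
analysis rate of 128 Hz (Δt = 1/128 s) produced by the standard
preprocessing chain.

**Order selection.** P is selected once per subject by the Schwarz
Bayesian criterion, SBC(P) = ln det Σ̂_res + (ln N / N)·P·n², on a pooled
stationary least-squares fit across all retained segments, with
N = (segment length − p_max) · n_segments. All candidate orders are
scored on the same sample base (rows with t ≥ p_max) so their residual
covariances are comparable. A single P per subject keeps the
time-frequency transfer matrices dimensionally consistent across the
whole epoch. Default search range: 1–5; at 128 Hz five lags span 39 ms,
which covers the 3–30 Hz dynamics of interest.

**Kalman coefficient tracking.** The stacked MVAR coefficients form the
state of a Kalman filter with a random-walk transition; process noise is
isotropic with scale q(t) = uc · trace(S(t))/dim (the classic
adaptive-filter convention), initial coefficients are zero, the initial
state covariance is the identity, and the innovation covariance is
tracked as an EWMA with the same constant. Filtering is forward-only —
smoothing would mix post-stimulus information into pre-stimulus
estimates and blur the causality of the evoked response. Because all
output channels share one regressor (the stacked lags), a scalar
observation-noise proxy (mean innovation variance) makes the rows of the
coefficient matrix share a single (P·n × P·n) regressor covariance; the
implementation propagates that matrix instead of the full (P·n²)² state
covariance, which is exact under these assumptions and keeps the filter
O(P²n²) per step. `uc` defaults to 10⁻³ and is exposed in the config and
CLI.

**Multi-trial (ensemble) estimation — the pipeline default.** The
pipeline assimilates *all* retained segments at each time step through
an exact multi-measurement Kalman update (matrix inversion lemma over
the trial ensemble), yielding one shared coefficient trajectory per
subject. The alternative — filtering each segment independently and
averaging the resulting influence tensors — is retained as
`estimation="per_segment"`, but it cannot work at this study's
dimensions: with 32 channels and order ~5 each sink row has ~160
coefficients, while the pre-stimulus baseline grid begins ~80 samples
into the segment. A zero-initialized per-segment filter is then still
dominated by its convergence transient inside the baseline window (the
influence rises over the epoch regardless of the true couplings, which
flips the sign of baseline-corrected values), and a warm-started filter
with an uninformative prior discards its initialization within a few
samples. With ~100 trials per step, the ensemble filter is converged
within a few samples *and* tracks post-stimulus coefficient changes.
In per-segment mode the pipeline warm-starts each filter at the
subject's pooled OLS fit, which is the best available stationary prior.

## ADTF, band integration and baseline correction

At each retained time point, Λ(f,t) = I − Σ_k Λ(k,t) e^(−j2πfΔt·k) is
inverted to the transfer matrix H(f,t), and the directed influence is
normalized per sink row: γ²_ij = |H_ij|² / Σ_m |H_im|², so that each
sink's sources sum to one. The first index is always the sink, the
second the source; the information outflow of channel j is read down
column j. (One printed form of this ratio elsewhere carries a stray
leading minus sign; the positive ratio is the only reading compatible
with Θ² ∈ [0,1].)

The frequency grid is 3–30 Hz in 1 Hz steps (28 bins), the coarsest grid
that resolves the analysis band; band integration is the bin average, so
Θ²_ij(t) ∈ [0,1]. Numerically singular (f,t) points are flagged and
excluded from the average, and a run with more than 1% flagged points
fails loudly rather than averaging around a broken model.

**Time grids are defined by count, not window arithmetic.** The
baseline grid is 40 consecutive analysis samples starting at the sample
nearest −360 ms (−359.4 … −54.7 ms); the post-stimulus grid is 246
consecutive samples starting nearest +60 ms (62.5 … 1976.6 ms). Naive
sample counting over (−360, −40) and (60, 2000) ms would give 41 and 248
points; the 40/246 counts are enforced as the analysis contract and any
other count raises. The baseline matrix is the time-average over the 40
baseline points; subtracting it from each post-stimulus matrix gives
values in [−1, 1] where negative entries mark influence weaker than
baseline.

## Weakened networks and hubs

At each post-stimulus time point the off-diagonal entries of the
corrected matrix are sorted ascending and the ⌊0.10 · n(n−1)⌋ most
negative, strictly negative entries become directed edges (99 edges for
32 channels). Self-loops are never candidates; ties break by
(source, sink) index order so snapshots are platform-deterministic. The
"cutoff at 10% of the most negative value" reading was rejected: it
makes edge counts wildly unstable across time points. Hubs are ranked by
weakened out-degree, then by summed |corrected value|, then label.
Group-level networks threshold the grand-average of subject corrected
tensors (averaging before thresholding is stable under subject noise);
default report snapshots are 119, 212 and 415 ms.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass at
3–30 Hz — zero phase preserves the latency of evoked components, which
matters because snapshots are read at fixed post-stimulus times — then
8-fold decimation of the 1,024 Hz recording to 128 Hz (plain subsampling
when the tracked pass-band is already below the new Nyquist; an
anti-alias low-pass otherwise), then epoching over [−1000, 2000) ms
(384 samples, stimulus at sample 128). Segment rejection removes
segments whose peak |amplitude| exceeds 120 (µV-scaled units, the
conventional EEG artifact bound) or whose variance is a robust
(median/MAD) outlier beyond z = 5, and caps the retained count at 100 —
emulating analyses that keep roughly 80–100 of 120 stimuli. The
rejection criteria are declared stand-ins: only the retained count, not
the selection rule, is anchored in practice. No re-referencing is
applied.

## Synthetic sessions

The generator emulates a single-pulse TMS-EEG session: 32 channels
(10–20 montage, stimulation site F4), 1,024 Hz, 120 stimuli exactly 4 s
apart. Ground-truth dynamics are defined **at the 128 Hz analysis
rate**: AR(2) damped-oscillator diagonals (pole radius 0.8, resonant
frequencies spread 7–13 Hz across channels), three static couplings
(F4→C4, F4→F8 at 0.30; Pz→Oz at 0.25), and profile-specific weakened
couplings at lag 1 with baseline weight 0.5 dropping at the stimulus:

| profile | weakened sources | drop | onset |
| --- | --- | --- | --- |
| `control` | F3→Fz, F3→C3; T3→T5 | 0.5 → 0.10 | 0 ms; 150 ms |
| `gad_pre` | Fp1→F3, Fp1→F7; T5→P3 | 0.5 → 0.10 | 0 ms; 150 ms |
| `gad_post` | F3→Fz, F3→C3; T3→T5 | 0.5 → 0.12 | 0 ms; 150 ms |

Frontal-source drops onset at the stimulus and temporal-source drops at
150 ms, reproducing the frontal-early / temporal-late hub chronology of
weakened-outflow patterns; the treated profile is deliberately
control-like. The 1,024 Hz recording is the band-limited polyphase
upsampling of the 128 Hz process, globally scaled to ~10 µV median RMS.
Defining slow narrowband dynamics directly at 1,024 Hz would place poles
so close to the unit circle that resonance gain (~400× near 10 Hz)
saturates any normalized influence measure — couplings of 0.5 and 0.1
would be indistinguishable.

Innovations are Gaussian ("independent white noise" is the only
assumption the model makes; Gaussian is the simplest choice satisfying
it). Coefficient switches are instantaneous. A decaying-exponential
pulse artifact (400 µV, τ = 20 ms) can be injected at a random subset of
stimuli for rejection tests but is off by default — the analysis window
starts at +60 ms, after the pulse.

**What passing tests do and do not show.** The generator produces
exactly the process family the estimator assumes (linear, piecewise
stationary, Gaussian innovations, couplings at the analysis rate) plus
band-limiting and resampling. Recovery of planted effects therefore
validates the estimation and thresholding machinery, not robustness to
volume conduction, common reference, non-stationary artifacts,
non-Gaussian noise or model mismatch, none of which the generator
emulates. Real TMS-EEG evoked potentials, scalp topography and pulse
physics are out of scope.

## Numerical choices

- Transfer matrices are inverted in batch (LAPACK); points where the
  inverse is non-finite or exceeds 10¹² in magnitude are flagged
  singular rather than silently filled.
- The SBC design matrix uses the normal equations with a Gram-condition
  guard (> 10¹² raises, catching constant or duplicated channels).
- The Kalman regressor covariance is symmetrized every step.
- Segment rejection uses median/MAD variance scores so that a second
  application rejects nothing (idempotence).
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; identical seeds give bit-identical sessions,
  manifests and outputs.

## Problem sizes

The packaged checks run the full study geometry where it matters — 120
stimuli per session, 100 retained segments, 11-subject groups, the
complete 40 + 246 time-point grids — and scale down only auxiliary
comparisons (e.g. 3 subjects per group and 40 stimuli for the
three-group hub-similarity check, 2–5-channel systems for estimator
oracles), sizes chosen to exercise the same code paths at a fraction of
the cost.

## Known limitations

- The ensemble estimator assumes the coefficient trajectory is shared
  across trials (the stimulus-locked design); trial-to-trial variability
  in timing or strength of the evoked change is averaged over.
- Influence normalization is per sink row, so a genuine drop on one
  edge redistributes mass across that sink's remaining sources; small
  positive corrected values on null edges into the same sink are a
  structural side effect, visible in the group tests.
- Zero-phase filtering smears sharp coefficient changes ~tens of ms
  backward in time, so onset latencies read from the corrected tensors
  are lower bounds.
- No statistical inference on network differences is provided; group
  comparisons are descriptive, matching the qualitative use of these
  network patterns.
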