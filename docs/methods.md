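# Methods

This note documents the models, conventions and numerical choices behind
`mumse`, in the spirit of a methods appendix: what each stage computes, which
parameters matter, what the synthetic generator does and does not emulate,
and where the design was genuinely open.

## Signal model of the synthetic generator

Each channel of a generated recording is

    x(t) = Σ_bands A_b · cos(φ_b(t)) + σ_n · n_{1/f}(t)

* **Narrowband oscillations, not pure tones.** The instantaneous frequency
  of each band oscillation performs a smoothed Gaussian walk inside the band
  (clipped at 60 % of the half-bandwidth, 0.5 s smoothing). Pure tones would
  make the phase-locking value trivially 1 between any two channels sharing
  a generator and would render band-pass + Hilbert phase extraction
  degenerate; the drift keeps downstream phase estimation honest. A
  zero-mean oscillation of amplitude `A` µV contributes `A²/2` µV² of band
  power, which is the generator's calibration identity (verified to < 1 %
  relative error on noiseless signals).
* **1/f^β background.** White Gaussian noise spectrally shaped to
  `1/f^(β/2)` amplitude (β default 1, the standard EEG background model), DC
  removed, rescaled to unit RMS and multiplied by the configured noise
  amplitude (default 1 µV RMS).
* **Injected desynchronization.** The task/rest power ratio that produces a
  target score `D` is `P_task/P_rest = P_rest^(D/100)` (the exact inverse of
  the scoring formula), so the task amplitude is
  `A_task = A_rest · sqrt(P_rest^(D/100))` with `P_rest = A_rest²/2`. The
  identity requires `P_rest > 1 µV²`; the generator enforces it.
* **Phase coupling.** `gen_coupled_phases` adds i.i.d. von Mises jitter of
  concentration κ to a common phase series; the expected phase-locking value
  is the Bessel ratio `I₁(κ)/I₀(κ)` (κ=0 → 0, κ=∞ → 1, implemented as zero
  noise). Inside full recordings the jitter is instead a slow AR(1) Gaussian
  phase process (0.4 s correlation time) whose stationary SD is chosen so
  that `exp(−σ²/2)` equals the same Bessel ratio. The reason: i.i.d.
  per-sample jitter is spectrally white, and the band-pass filter applied
  before phase extraction averages it away almost completely, which would
  make the measured coupling insensitive to κ; a slow jitter process keeps
  the expected phase-locking value identical while surviving filtering.
  Coupling edges form a forest (BFS over the configured pairs); κ is the
  concentration across each edge.
* **Conditions are independent draws.** Rest and task recordings use fresh
  oscillation phases and noise; only the configured amplitudes and coupling
  strengths differ, mirroring separately recorded baseline and task runs.
* **Determinism.** All randomness flows from one integer seed through a
  `SeedSequence` spawn tree (per condition, per purpose); identical spec ⇒
  bit-identical samples.

## Preprocessing

* Sample indexing is 0-based with half-open segment intervals
  `[onset, onset+length)`.
* **Re-referencing.** The common average reference is implemented
  (idempotent, linear, channel mean exactly 0). Reference standardization
  against a head model is out of scope. In the synthetic cohort pipeline
  re-referencing defaults **off**: generated signals are reference-free by
  construction, and subtracting the channel mean from globally alpha-coupled
  channels removes the coherent alpha more strongly at rest than during the
  (decohered) task, injecting a spurious positive desynchronization at
  control electrodes. For recordings loaded from files — which do carry a
  physical reference — the `preprocess` CLI verb applies it.
* **Artifact screen.** An automated stand-in for manual artifact rejection:
  maximal contiguous segments where no channel reaches the amplitude limit
  (default 100 µV) and no channel is constant for the flatline limit
  (default 0.1 s). Per-channel rejection fractions are logged rather than
  excluding subjects.

## Band power and the desynchronization score

Welch averaging with 1 s Hamming windows and 25 % overlap, `scaling=
"density"`; band power is the sum of PSD bins with `low ≤ f ≤ high` (both
edges inclusive) times the bin width. Under this normalization an in-band
sinusoid of amplitude `A` integrates to `A²/2` exactly (calibration constant
1). The window length is configurable; 1 s gives 1 Hz resolution, enough to
resolve 8–13 Hz inside a 2 s epoch, whereas a 0.2 s window could not
separate the alpha band edges at all. Task power is averaged over per-epoch
estimates before a single log-ratio against the rest power (the alternative
— integrating one concatenated task record — is a config choice away but not
the default). `D = 0` iff task and rest power are equal; the score is
strictly increasing in task power.

## Multiscale entropy

* **Tolerance convention.** `r_abs = r × SD` of the original (scale-1)
  series — for band-limited profiles, the SD **after** filtering, otherwise
  the tolerance would be dominated by out-of-band variance — and the same
  absolute tolerance is reused at every scale (the Costa convention).
  A per-scale-SD variant sits behind the `r_per_scale` flag. The SD uses the
  population formula (`ddof=0`).
* **Match rule.** Chebyshev distance strictly below `r_abs`, self-matches
  excluded; template pairs are drawn from the first `N−m` start positions so
  every counted template has an `(m+1)`-point extension. The optimized
  counter (numba) is verified to agree *exactly* with an exhaustive
  brute-force enumerator on hundreds of random series, including tie-heavy
  integer series.
* **Undefined values.** Zero match counts (and zero-SD inputs at the curve
  level) yield NaN — a flagged undefined value, never a sentinel number —
  and the scale-averaged complexity score averages the defined scales only,
  with a logged count. A constant series at the raw counting level gives
  SE = 0 (every template matches); the degenerate-input flag comes from the
  zero-SD check in `mse_curve`.
* **Reliability floor.** A warning is emitted when the coarsest scale has
  fewer than ~100 points (`⌊N/SF_max⌋ < 100`), the conventional floor for
  stable SE estimates.
* **Filtering.** Zero-phase FIR band-pass: Hamming-window design (~53 dB
  stopband), transition width `max(0.5, min(low/2, bandwidth/2))` Hz, length
  capped at 2 s of taps (only the delta band hits the cap), applied
  forward-backward with even-reflection padding — even reflection keeps the
  padded extension value-continuous, whereas odd reflection adds a step
  whose low-frequency energy leaks into the delta/theta passbands.
* **Profile classification** against the rest reference uses per-scale
  differences with a dead band `tol`: increased complexity (above at all
  scales), toward regularity (below at all scales), toward randomness
  (above at fine scales, below past a single crossover), plus a fourth
  `mixed` outcome so the function is total.
* In the cohort pipeline, task MSE uses the first `N` samples of the task
  recording (clean by construction); with real data the intent is to
  concatenate artifact-free task segments up to `N`. Per-epoch profiles
  averaged afterward are a noted alternative, not implemented as a default.

## Phase-coherence networks

* Instantaneous phase = angle of the analytic signal of the band-passed
  series, in (−π, π]; one filter length is trimmed from each end because
  analytic-signal edge transients bias phase locking upward. Networks are
  built from phases estimated on the whole recording, so the analysis
  segment must lie inside the trimmed region.
* The synchronization index is the phase-locking value (circular-variance
  form). Among the family of phase-synchronization indices, this is the
  dominant reading; a Shannon-entropy index of the phase-difference
  histogram is available behind `method="entropy"`.
* The graph is fully connected: weights are used exactly as computed, with
  no thresholding or sparsification.
* **Clustering coefficient.** Implemented with the weighted degree
  `k_j = Σ_i w_ij` in the denominator, exactly as the source formulation
  prints it. With weights below 1 this ratio can exceed 1, and nodes with
  `k_j ≤ 1` are flagged undefined (`k_j(k_j−1) ≤ 0`); the conventional
  neighbor-count normalization (bounded by 1) is available via
  `degree="count"`. The average CC excludes undefined nodes with a log
  message.
* **Shortest paths and efficiency.** Edge lengths `f(w) = 1/w` by default
  (any positive map can be supplied); zero weights are non-edges. All-pairs
  shortest paths are delegated to `scipy.sparse.csgraph`; global efficiency
  averages `1/d_ij` over ordered pairs with `1/∞ = 0`, so isolated nodes are
  tolerated. Both metrics are cross-checked against exhaustive
  triangle-sum and path-enumeration oracles on random graphs.

## Group statistics

Two-sided tests throughout. Cohen's `d = |mean − μ₀| / SD` (one-sample) or
the same on paired differences. Degrees of freedom follow the standard
bookkeeping (`n−1` for one-sample/paired, `n−2` for the correlation,
`n − parameters` for OLS). The three desynchronization models are
single-predictor OLS fits (baseline complexity, task complexity, baseline mu
power) reporting coefficient (SE), R², residual RMSE and df. Repeated-
measures ANOVAs are deliberately not re-derived here; they are routine fits
available in any statistics package. Machine-readable outputs carry full
precision; printed summaries round to 3 decimals.

## Cohort pipeline and problem sizes

The default `CohortConfig` mirrors the target study design: 45 subjects,
32-channel 10–20 montage at 500 Hz, 28 s per condition (N = 14 000 entropy
samples), seven 2 s task epochs, `m=2, r=0.15, SF≤20`, alpha-band networks
on 2 s segments. Injected effects: subject-level desynchronization drawn
from N(−20 %, 8 %) at C3/C4, and an alpha coupling star around Cz whose
concentration drops from κ=4 (rest) to κ=1.5 (task). Between-subject
amplitude variation is lognormal (10 % on the log scale).

`CohortConfig.desk_scale()` is the documented reduced configuration used by
the test suite and the acceptance script: 8 s recordings, N = 4000, four
task epochs, analysis restricted to C3 and the alpha band. These sizes keep
a full 45-subject cohort run around a minute on one core while preserving
every qualitative property of the full-size configuration; N = 4000 still
leaves 200 points at the coarsest scale, above the reliability floor.

The null configuration (`null_cohort()`) removes the desynchronization and
equalizes coupling across conditions; measured scores then vary only through
estimation noise, which is what the null-pattern and type-I checks exercise.

## What the generator does and does not emulate

Emulated: 1/f background, narrowband rhythms with realistic drift,
condition-specific amplitude suppression calibrated to an exact
desynchronization target, tunable phase coupling with a known expected
phase-locking value, between-subject variability, optional amplitude spikes
for testing the artifact screen.

Not emulated: volume conduction and field spread (no forward model — weights
between uncoupled channels reflect chance phase alignment only), ocular/EMG
artifacts beyond amplitude spikes, non-stationarity across a session,
reference-electrode effects, and any genuine neural coupling between
desynchronization and entropy at the single-subject level. Consequently,
passing the end-to-end checks shows the *estimators* recover what was
injected under EEG-like statistics; it does not certify performance on real
recordings. Two visible side effects of the synthetic design are worth
knowing: (1) task-phase decoherence slightly lowers measured in-band power
(≈ −2…−3 %) at every coupled electrode, so control electrodes show a small
but statistically resolvable negative desynchronization in effect cohorts;
(2) the C3 clustering coefficient under the weighted-degree normalization
*rises* when coupling weakens (the weighted degree falls faster than the
triangle term), so the generator does not reproduce a task-related CC
decrease.

## Known limitations

* Sample entropy is O(N²) per scale; N = 14 000 at scale 1 takes ~0.3 s per
  series (numba), so full-size multi-band, multi-electrode cohorts are
  minutes, not seconds.
* The EDF path is read-only (via `mne`); the lossless interchange format is
  the TSV matrix dialect. EDF export would require an additional writer
  backend (`edfio`).
* The desynchronization score is undefined for rest powers ≤ 1 µV²; this is
  a property of the published formula made explicit, not a removable
  implementation limit. Unit changes (e.g. nV²) would change scores.
* The weighted-degree clustering coefficient is not bounded by 1 and its
  undefined region (`k_j ≤ 1`) grows as weights shrink; for
  literature-comparable values use `degree="count"`.
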