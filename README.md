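# mumse

EEG analysis of motor resonance: mu-rhythm desynchronization scoring,
multiscale entropy (MSE) of band-limited signals, phase-coherence network
metrics, and the group-level statistics that link baseline signal complexity
to desynchronization — packaged as a tested, reusable pipeline and exercised
end to end on synthetic EEG with known ground truth.

## Who this is for

Researchers studying sensorimotor EEG (action observation, motor imagery,
mirror-neuron-system paradigms) who want the full analysis chain — band
power, entropy, connectivity, statistics — as composable, unit-tested Python
functions rather than a GUI toolbox, plus a synthetic-EEG generator that
injects known effects so every stage can be validated before touching real
data.

## The quantities computed

**Mu desynchronization.** The mu rhythm is the 8–13 Hz oscillation over
sensorimotor cortex; its amplitude drop during action observation indexes
motor resonance. Per electrode, with `P` the integrated 8–13 Hz band power
(Welch average of Hamming-windowed, 25 %-overlapped periodograms),

```
D = (ln P_task − ln P_rest) / ln P_rest × 100
```

Negative `D` is desynchronization. The formula requires `P_rest > 1 µV²`
(the log denominator must be positive); smaller rest powers are a hard error.

**Multiscale entropy.** Sample entropy `SE(m, r) = −ln(A/B)` counts how often
length-`m` template matches (Chebyshev distance `< r`, self-matches excluded)
survive extension to `m+1`. MSE evaluates SE on coarse-grained series: at
scale factor `SF`, blocks of `SF` consecutive samples are averaged, giving
`⌊N/SF⌋` points. Defaults: `m = 2`, `r = 0.15 × SD`, scales 1–20,
`N = 14 000` samples. The mean of SE over scales is the complexity score;
task-vs-rest profiles are classified as increased complexity, shift toward
regularity, or shift toward randomness.

**Phase-coherence networks.** Each electrode is a node; the edge weight is
the phase-locking value between the two band-limited signals (modulus of the
circular mean of their Hilbert phase difference) over a 2 s segment — a
fully connected, undirected, weighted graph. Node-level clustering
coefficient (weighted-triangle form, weighted-degree normalization):

```
CC_j = Σ_{i,m} (w_ij w_im w_jm)^{1/3} / [k_j (k_j − 1)],   k_j = Σ_i w_ij
```

Global efficiency with edge lengths `f(w) = 1/w`:

```
GE = 1/(N(N−1)) Σ_{i≠j} 1/d_ij        (1/∞ = 0 for disconnected pairs)
```

**Group statistics.** One-sample and paired t-tests with Cohen's `d`,
Bonferroni-corrected thresholds (0.05/12 = 0.004 for the 12-electrode set),
single-predictor OLS models of desynchronization on baseline complexity, and
the Pearson correlation between entropy percent change and efficiency
percent change with `t = r√(n−2)/√(1−r²)`.

**Synthetic EEG.** Per channel: a sum of narrowband oscillations (drifting
instantaneous frequency inside each classical band) over 1/f^β background
noise. Task-vs-rest alpha suppression of controllable magnitude is injected
through the inverse of the desynchronization formula; pairwise phase coupling
of controllable strength κ yields an expected phase-locking value of
I₁(κ)/I₀(κ). Fixed seed ⇒ bit-identical recordings.

## Worked example

A 12-subject synthetic cohort with a mean −20 % mu suppression at C3/C4 and
weakened task-phase coupling, at desk-scale problem sizes (8 s recordings,
N = 4000 entropy samples):

```python
from mumse.pipeline import CohortConfig, run_pipeline

cfg = CohortConfig.desk_scale(seed=1, n_subjects=12)
res = run_pipeline(cfg)
for key in ("desync_C3", "desync_O1", "entropy_C3_alpha", "ge_alpha"):
    print(res.tests[key])
```

prints

```
desync C3: t(11) = -12.214, p = 0.000, d = 3.526
desync O1: t(11) = -11.241, p = 0.000, d = 3.245
C3 alpha avg entropy task vs rest: t(11) = 4.087, p = 0.002, d = 1.180
alpha global efficiency task vs rest: t(11) = -22.706, p = 0.000, d = 6.555
```

Reading the output: C3 carries the injected suppression (cohort mean
−28.4 %, combining the −20 % injected mean for this seed's draws with the
in-band power cost of the task-phase decoherence), and its alpha-band
entropy rises while alpha global efficiency falls — the motor-resonance
signature. O1 receives no injected suppression; its small mean change
(−3.5 %) is the decoherence side effect alone, which the t-test nonetheless
resolves because between-subject variance is tiny — a reminder that
significance and magnitude separate cleanly in synthetic cohorts.

The same pipeline is scriptable from the shell:

```sh
mumse all --desk-scale --seed 1 --out-dir out/      # full cohort + tables
mumse simulate --out-dir sim/                       # one subject's recordings
mumse mse sim/S01_rest.tsv --electrode C3 --band alpha --out mse.tsv
```

## Layout

| module | contents |
| --- | --- |
| `mumse.synthetic` | ground-truth EEG generator, desync/coupling calibration |
| `mumse.io` | `Recording`/`EpochSet`, TSV + EDF I/O, re-referencing, artifact screen, epoching |
| `mumse.spectral` | band definitions, Welch band power, desynchronization scores |
| `mumse.mse` | coarse-graining, sample entropy, MSE profiles, classification |
| `mumse.network` | Hilbert phase, phase-locking, weighted CC / GE |
| `mumse.stats` | t-tests, Cohen's d, Bonferroni, OLS models, correlation |
| `mumse.pipeline` | cohort config, per-subject analysis, group statistics, bundles |
| `mumse.cli` | `mumse` command (`simulate`, `preprocess`, `spectral`, `mse`, `network`, `stats`, `all`) |

See `docs/methods.md` for the modeling choices, parameter defaults and known
limitations.
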