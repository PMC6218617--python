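"""Synthetic multichannel EEG with known ground truth.

Generates paired rest/task recordings whose band powers, task-vs-rest mu
suppression and pairwise phase coupling are all set by construction, so every
downstream stage (band power, desynchronization score, multiscale entropy,
phase-locking networks, group statistics) can be validated against known
truth.

Signal model, per channel and condition:

    x(t) = sum_over_bands A_band * cos(phi_band(t)) + 1/f^beta noise

Each band oscillation is a *narrowband* process, not a pure tone: its
instantaneous frequency drifts slowly inside the band (smoothed Gaussian
walk), so band-pass + Hilbert phase extraction downstream is nondegenerate.
A zero-mean oscillation of amplitude A contributes band power A**2/2 µV².

Phase coupling between channel pairs is imposed per band: coupled channels
share a reference phase walk, and each coupling edge adds i.i.d. von Mises
phase jitter of concentration kappa, giving an expected phase-locking value
of I1(kappa)/I0(kappa) (ratio of modified Bessel functions) across that
edge.  kappa = 0 is independent phases (PLV -> 0); kappa = inf is rigid
locking (PLV = 1).

The background is 1/f^beta noise (spectral shaping of white Gaussian noise,
beta default 1), the standard model of broadband EEG background activity.

Everything is driven by a single integer seed through a SeedSequence spawn
tree: the same SynthSpec reproduces a bit-identical pair of recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import DEFAULT_MONTAGE_32, Recording
from .spectral import DEFAULT_BANDS, BandDefinition

CONDITIONS = ("rest", "task")

#: key types for readability: amplitudes are (channel, condition, band_name),
#: couplings are (channel_a, channel_b, band_name) with the pair unordered.
AmplitudeMap = Mapping[tuple[str, str, str], float]
CouplingMap = Mapping[tuple[str, str, str], float]


@dataclass(frozen=True)
class SynthSpec:
    """Full parameterization of the synthetic EEG generator.

    band_amplitudes maps (channel, condition, band) -> oscillation amplitude
    in µV; absent keys mean 0.  coupling maps (channel_a, channel_b, band)
    -> von Mises concentration kappa >= 0.  noise_exponent is the beta of the
    1/f^beta background, noise_amplitude its RMS in µV.
    """

    n_channels: int = 32
    fs: float = 500.0
    duration_rest: float = 28.0
    duration_task: float = 28.0
    band_amplitudes: AmplitudeMap = field(default_factory=dict)
    coupling: CouplingMap = field(default_factory=dict)
    noise_exponent: float = 1.0
    noise_amplitude: float = 1.0
    seed: int = 0
    labels: tuple[str, ...] = DEFAULT_MONTAGE_32
    bands: Mapping[str, BandDefinition] = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels)[: self.n_channels])
        if len(self.labels) != self.n_channels:
            raise ValueError(
                f"need {self.n_channels} labels, got {len(self.labels)}"
            )
        if self.fs <= 0 or self.duration_rest <= 0 or self.duration_task <= 0:
            raise ValueError("fs and durations must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        highest = max((b.high for b in self.bands.values()), default=0.0)
        if self.fs <= 2 * highest:
            raise ValueError(
                f"fs={self.fs} Hz violates Nyquist for the highest band edge "
                f"{highest} Hz (need fs > {2 * highest})"
            )
        for (ch, cond, band), amp in self.band_amplitudes.items():
            if amp < 0:
                raise ValueError(f"negative amplitude for {(ch, cond, band)}")
            if ch not in self.labels:
                raise ValueError(f"amplitude references unknown channel {ch!r}")
            if cond not in CONDITIONS:
                raise ValueError(f"amplitude references unknown condition {cond!r}")
            if band not in self.bands:
                raise ValueError(f"amplitude references unknown band {band!r}")
        for (a, b, band), kappa in self.coupling.items():
            if kappa < 0:
                raise ValueError(f"negative coupling kappa for {(a, b, band)}")
            if a not in self.labels or b not in self.labels:
                raise ValueError(f"coupling references unknown channel in {(a, b)}")
            if a == b:
                raise ValueError(f"coupling pair must be two distinct channels, got {(a, b)}")
            if band not in self.bands:
                raise ValueError(f"coupling references unknown band {band!r}")

    def amplitude(self, channel: str, condition: str, band: str) -> float:
        return float(self.band_amplitudes.get((channel, condition, band), 0.0))


def one_over_f_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^beta noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = freqs[nonzero] ** (-beta / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spectrum * scale, n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _narrowband_phase(
    band: BandDefinition, n: int, fs: float, rng: np.random.Generator,
    drift_frac: float = 0.6, drift_smooth_s: float = 0.5,
) -> np.ndarray:
    """Phase walk of a narrowband oscillation: instantaneous frequency drifts
    smoothly inside the band (clipped at drift_frac of the half-bandwidth)."""
    center = 0.5 * (band.low + band.high)
    half_bw = 0.5 * (band.high - band.low)
    width = max(1, int(round(drift_smooth_s * fs)))
    raw = rng.standard_normal(n + width)
    kernel = np.ones(width) / width
    smooth = np.convolve(raw, kernel, mode="valid")[:n]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    freq = center + drift_frac * half_bw * np.clip(smooth, -1.0, 1.0)
    phase0 = rng.uniform(-np.pi, np.pi)
    return phase0 + 2.0 * np.pi * np.cumsum(freq) / fs


def _vonmises_jitter(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if math.isinf(kappa):
        return np.zeros(n)
    return rng.vonmises(0.0, kappa, size=n)


def _slow_phase_jitter(kappa: float, n: int, fs: float, rng: np.random.Generator,
                       corr_time_s: float = 0.4) -> np.ndarray:
    """Slow Gaussian phase jitter with the mean resultant of vonMises(kappa).

    Per-sample independent jitter would be averaged away by the band-pass
    filters used downstream, so inside *recordings* the coupling jitter is an
    AR(1) Gaussian process with stationary SD sigma chosen so that
    E[exp(i eta)] = exp(-sigma^2/2) equals I1(kappa)/I0(kappa) — the same
    expected phase-locking value as i.i.d. von Mises jitter, but varying
    slowly enough (default 0.4 s correlation time) to survive filtering.
    kappa = 0 yields an unbounded phase walk (independent phases, PLV -> 0).
    """
    if math.isinf(kappa):
        return np.zeros(n)
    resultant = expected_plv(kappa)
    eps = rng.standard_normal(n)
    rho = math.exp(-1.0 / (corr_time_s * fs))
    if resultant <= 0:
        # kappa = 0: no locking; integrate noise into a free phase walk
        step_sd = 2.0 * math.pi / math.sqrt(corr_time_s * fs)
        return np.cumsum(step_sd * eps)
    sigma = math.sqrt(max(0.0, -2.0 * math.log(resultant)))
    ar = np.empty(n)
    ar[0] = eps[0]
    scale = math.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        ar[i] = rho * ar[i - 1] + scale * eps[i]
    return sigma * ar


def _coupling_components(
    spec: SynthSpec, band_name: str,
) -> tuple[dict[str, str | None], dict[str, float]]:
    """BFS forest over the coupling edges of one band.

    Returns (parent map, edge kappa to parent).  Channels outside any
    coupling edge are their own roots (parent None).
    """
    adjacency: dict[str, dict[str, float]] = {ch: {} for ch in spec.labels}
    for (a, b, bname), kappa in spec.coupling.items():
        if bname != band_name:
            continue
        adjacency[a][b] = kappa
        adjacency[b][a] = kappa
    parent: dict[str, str | None] = {}
    edge_kappa: dict[str, float] = {}
    for root in spec.labels:  # deterministic montage order
        if root in parent:
            continue
        parent[root] = None
        queue = [root]
        while queue:
            node = queue.pop(0)
            for nbr, kappa in sorted(adjacency[node].items()):
                if nbr in parent:
                    continue
                parent[nbr] = node
                edge_kappa[nbr] = kappa
                queue.append(nbr)
    return parent, edge_kappa


def _gen_condition(spec: SynthSpec, condition: str, n: int,
                   ss: np.random.SeedSequence) -> np.ndarray:
    children = ss.spawn(2)
    rng_osc = np.random.default_rng(children[0])
    rng_noise = np.random.default_rng(children[1])

    data = np.zeros((spec.n_channels, n))
    for band_name in sorted(spec.bands):
        band = spec.bands[band_name]
        parent, edge_kappa = _coupling_components(spec, band_name)
        phases: dict[str, np.ndarray] = {}

        def phase_of(ch: str) -> np.ndarray:
            if ch in phases:
                return phases[ch]
            par = parent[ch]
            if par is None:
                ph = _narrowband_phase(band, n, spec.fs, rng_osc)
            else:
                ph = phase_of(par) + _slow_phase_jitter(
                    edge_kappa[ch], n, spec.fs, rng_osc
                )
            phases[ch] = ph
            return ph

        # draw phases in montage order for reproducibility regardless of which
        # channels carry nonzero amplitude
        for ch in spec.labels:
            phase_of(ch)
        for i, ch in enumerate(spec.labels):
            amp = spec.amplitude(ch, condition, band_name)
            if amp > 0:
                data[i] += amp * np.cos(phases[ch])

    if spec.noise_amplitude > 0:
        for i in range(spec.n_channels):
            data[i] += spec.noise_amplitude * one_over_f_noise(
                n, spec.noise_exponent, rng_noise
            )
    return data


def gen_condition(spec: SynthSpec, condition: str) -> Recording:
    """Generate a single condition of the spec (bit-identical to the
    corresponding element of :func:`gen_recording`)."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    root = np.random.SeedSequence(spec.seed)
    ss_rest, ss_task = root.spawn(2)
    if condition == "rest":
        n = int(round(spec.duration_rest * spec.fs))
        return Recording(_gen_condition(spec, "rest", n, ss_rest), spec.fs, spec.labels)
    n = int(round(spec.duration_task * spec.fs))
    return Recording(_gen_condition(spec, "task", n, ss_task), spec.fs, spec.labels)


def gen_recording(spec: SynthSpec) -> tuple[Recording, Recording]:
    """Generate the (rest, task) pair of recordings defined by ``spec``.

    The two conditions are generated independently (fresh oscillation phases
    and noise), mirroring separately recorded baseline and task runs; only
    the per-condition amplitudes in the spec differ systematically.
    """
    return gen_condition(spec, "rest"), gen_condition(spec, "task")


def power_ratio_for_desync(target_desync: float, rest_power: float) -> float:
    """Task/rest band-power ratio that produces a given desynchronization.

    Inverts D = (ln P_task - ln P_rest)/ln P_rest * 100 to
    P_task/P_rest = P_rest^(D/100); feeding the scaled power back through the
    score returns D exactly.  Requires P_rest > 1 µV² (log denominator).
    """
    if not rest_power > 1.0:
        raise ValueError(
            f"rest power must exceed 1 µV² (got {rest_power}); the score's "
            "denominator ln(rest power) is zero or negative otherwise"
        )
    return float(rest_power ** (target_desync / 100.0))


def task_amplitude_for_desync(rest_amplitude: float, target_desync: float) -> float:
    """Task oscillation amplitude that injects a target desynchronization.

    Uses the noiseless band-power identity P = A**2/2; requires the implied
    rest power to exceed 1 µV² (i.e. rest amplitude > sqrt(2) µV).
    """
    rest_power = rest_amplitude**2 / 2.0
    ratio = power_ratio_for_desync(target_desync, rest_power)
    return rest_amplitude * math.sqrt(ratio)


def gen_coupled_phases(
    kappa: float, n: int, seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair of phase series with von Mises coupling of concentration kappa.

    ``phase_b = phase_a + vonMises(0, kappa)`` i.i.d. per sample, so the
    expected phase-locking value is I1(kappa)/I0(kappa).  kappa = inf is
    implemented as zero noise (PLV exactly 1).
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    phase_a = rng.uniform(-np.pi, np.pi, size=n)
    phase_b = phase_a + _vonmises_jitter(kappa, n, rng)
    return phase_a, phase_b


def expected_plv(kappa: float) -> float:
    """Theoretical PLV of von Mises phase jitter: I1(kappa)/I0(kappa)."""
    from scipy.special import iv

    if math.isinf(kappa):
        return 1.0
    return float(iv(1, kappa) / iv(0, kappa))


def with_seed(spec: SynthSpec, seed: int) -> SynthSpec:
    """Copy of a spec with a different seed (subject replication helper)."""
    return replace(spec, seed=seed)
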