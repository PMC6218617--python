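"""End-to-end cohort pipeline: generate/load -> preprocess -> spectral -> MSE
-> network -> group statistics.

The synthetic cohort emulates the study design this pipeline targets: per
subject, a resting (eyes-open baseline) recording and an action-observation
task recording from a 32-channel 10-20 montage at 500 Hz.  The task condition
suppresses the mu/alpha oscillation over the sensorimotor electrodes (C3, C4)
by a subject-specific amount — the injected desynchronization — and weakens
the alpha-band phase coupling of a hub network, lowering alpha global
efficiency.  Occipital alpha and all other bands are left unchanged, so the
expected group-level sign pattern is: negative C3/C4 desynchronization,
increased C3 alpha-band entropy, decreased alpha global efficiency, and null
results at control electrodes.

All randomness flows from one root seed through a SeedSequence spawn tree,
split per subject; identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .filters import fir_bandpass
from .io import (
    DEFAULT_MONTAGE_32,
    Recording,
    extract_epochs,
    rereference_average,
    screen_artifacts,
)
from .mse import MSEParams, band_limited_mse, percent_change
from .network import build_network, clustering_coefficient, global_efficiency, percent_change_ge
from .spectral import DEFAULT_BANDS, MU_BAND, trial_average_desync
from .stats import (
    CorrelationResult,
    RegressionResult,
    SubjectRecord,
    TestResult,
    bonferroni,
    corr_change,
    one_sample_t,
    paired_t,
    records_to_frame,
    regress_desync_on_baseline,
)
from .synthetic import SynthSpec, gen_condition, task_amplitude_for_desync

logger = logging.getLogger(__name__)

#: electrodes entering the desynchronization analysis (sensorimotor + controls)
ANALYSIS_ELECTRODES: tuple[str, ...] = (
    "C3", "C4", "Cz", "F3", "Fz", "F4", "P3", "Pz", "P4", "O1", "Oz", "O2",
)

OCCIPITAL: tuple[str, ...] = ("O1", "Oz", "O2")
CENTRAL: tuple[str, ...] = ("C3", "C4")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort plus analysis parameters.

    Amplitudes are rest-condition oscillation amplitudes in µV; the task
    condition copies them except for the mu suppression at the central
    electrodes and the coupling change.  ``desync_mean``/``desync_sd`` give
    the population distribution of the injected C3/C4 desynchronization in
    percent (0/0 is a null cohort).  Alpha-band phase coupling is a star
    around ``coupling_hub`` touching every other electrode with concentration
    ``kappa_rest`` at rest and ``kappa_task`` during the task.
    """

    n_subjects: int = 45
    seed: int = 0
    fs: float = 500.0
    duration_rest: float = 28.0
    duration_task: float = 28.0
    n_mse: int = 14000
    mse_params: MSEParams = field(default_factory=MSEParams)
    epoch_seconds: float = 2.0
    n_task_epochs: int = 7
    # rest-condition amplitudes (µV)
    alpha_amp_central: float = 14.0
    alpha_amp_cz: float = 10.0
    alpha_amp_occipital: float = 14.0
    alpha_amp_other: float = 6.0
    other_band_amps: Mapping[str, float] = field(
        default_factory=lambda: {"delta": 6.0, "theta": 5.0, "beta": 4.0, "gamma": 2.0}
    )
    # injected effects
    desync_mean: float = -20.0
    desync_sd: float = 8.0
    kappa_rest: float = 4.0
    kappa_task: float = 1.5
    coupling_hub: str = "Cz"
    # background
    noise_amplitude: float = 1.0
    noise_exponent: float = 1.0
    subject_amp_jitter: float = 0.10
    # analysis options; synthetic recordings are reference-free by
    # construction, so the average-reference stand-in defaults off here
    # (apply it when loading recordings referenced to a physical electrode)
    rereference: bool = False
    amplitude_limit: float = 100.0
    desync_electrodes: tuple[str, ...] = ANALYSIS_ELECTRODES
    mse_electrodes: tuple[str, ...] = ("C3",)
    mse_bands: tuple[str, ...] = ("alpha",)
    network_bands: tuple[str, ...] = ("alpha",)
    network_segment_seconds: float = 2.0
    labels: tuple[str, ...] = DEFAULT_MONTAGE_32

    def __post_init__(self) -> None:
        missing = [e for e in self.desync_electrodes if e not in self.labels]
        missing += [e for e in self.mse_electrodes if e not in self.labels]
        if self.coupling_hub not in self.labels:
            missing.append(self.coupling_hub)
        if missing:
            raise ValueError(f"electrodes not in montage: {sorted(set(missing))}")
        for band in (*self.mse_bands, *self.network_bands, *self.other_band_amps):
            if band not in DEFAULT_BANDS:
                raise ValueError(f"unknown band {band!r}")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        needed = self.n_mse / self.fs
        if self.duration_rest < needed or self.duration_task < needed:
            raise ValueError(
                f"durations must cover n_mse={self.n_mse} samples ({needed:.1f} s)"
            )

    def null_cohort(self) -> "CohortConfig":
        """Copy with every injected effect removed (no desynchronization, no
        condition difference in coupling)."""
        return dataclasses.replace(
            self, desync_mean=0.0, desync_sd=0.0, kappa_task=self.kappa_rest
        )

    @classmethod
    def desk_scale(cls, **overrides: Any) -> "CohortConfig":
        """Reduced problem size for fast desk runs: 8 s recordings, N = 4000
        entropy samples, 4 task epochs.  Same montage, bands and effects."""
        defaults: dict[str, Any] = dict(
            duration_rest=8.0, duration_task=8.0, n_mse=4000, n_task_epochs=4,
        )
        defaults.update(overrides)
        return cls(**defaults)


def subject_spec(config: CohortConfig, subject_index: int,
                 subject_seed: int, rng: np.random.Generator) -> tuple[SynthSpec, float]:
    """Build one subject's SynthSpec; returns (spec, injected desync in %).

    Per-subject variation: amplitudes are scaled by a lognormal factor
    (sd ``subject_amp_jitter`` on the log scale) and the injected
    desynchronization is drawn from N(desync_mean, desync_sd).
    """
    amp_factor = float(np.exp(rng.normal(0.0, config.subject_amp_jitter)))
    injected = float(rng.normal(config.desync_mean, config.desync_sd)) \
        if config.desync_sd > 0 else config.desync_mean

    amps: dict[tuple[str, str, str], float] = {}
    for ch in config.labels:
        if ch in CENTRAL:
            rest_alpha = config.alpha_amp_central * amp_factor
            task_alpha = task_amplitude_for_desync(rest_alpha, injected)
        elif ch == "Cz":
            rest_alpha = config.alpha_amp_cz * amp_factor
            task_alpha = rest_alpha
        elif ch in OCCIPITAL:
            rest_alpha = config.alpha_amp_occipital * amp_factor
            task_alpha = rest_alpha
        else:
            rest_alpha = config.alpha_amp_other * amp_factor
            task_alpha = rest_alpha
        amps[(ch, "rest", "alpha")] = rest_alpha
        amps[(ch, "task", "alpha")] = task_alpha
        for band, amp in config.other_band_amps.items():
            amps[(ch, "rest", band)] = amp * amp_factor
            amps[(ch, "task", band)] = amp * amp_factor

    coupling: dict[tuple[str, str, str], float] = {}
    # alpha-band hub star; rest and task specs differ only through kappa,
    # so coupling is resolved per condition by building two specs
    spec = SynthSpec(
        n_channels=len(config.labels),
        fs=config.fs,
        duration_rest=config.duration_rest,
        duration_task=config.duration_task,
        band_amplitudes=amps,
        coupling=coupling,
        noise_exponent=config.noise_exponent,
        noise_amplitude=config.noise_amplitude,
        seed=subject_seed,
        labels=config.labels,
    )
    return spec, injected


def _condition_coupling(config: CohortConfig, kappa: float) -> dict[tuple[str, str, str], float]:
    return {
        (config.coupling_hub, ch, "alpha"): kappa
        for ch in config.labels if ch != config.coupling_hub
    }


def generate_subject(config: CohortConfig, subject_index: int,
                     subject_seed: int, rng: np.random.Generator,
                     ) -> tuple[Recording, Recording, float]:
    """Generate one subject's (rest, task) pair with the injected effects."""
    spec, injected = subject_spec(config, subject_index, subject_seed, rng)
    # per-condition coupling strengths: generate each condition from a spec
    # carrying that condition's kappa (conditions are independent draws)
    rest_spec = dataclasses.replace(
        spec, coupling=_condition_coupling(config, config.kappa_rest)
    )
    task_spec = dataclasses.replace(
        spec, coupling=_condition_coupling(config, config.kappa_task)
    )
    rest = gen_condition(rest_spec, "rest")
    task = gen_condition(task_spec, "task")
    return rest, task, injected


def analyze_subject(config: CohortConfig, subject_id: str,
                    rest: Recording, task: Recording) -> SubjectRecord:
    """Run the full single-subject analysis on a (rest, task) recording pair."""
    if config.rereference:
        rest = rereference_average(rest)
        task = rereference_average(task)

    for name, rec in (("rest", rest), ("task", task)):
        segments = screen_artifacts(rec, config.amplitude_limit)
        clean = sum(n for _, n in segments)
        if clean < rec.n_samples:
            logger.warning("%s/%s: artifact screen kept %d/%d samples",
                           subject_id, name, clean, rec.n_samples)

    # --- spectral: trial-averaged mu desynchronization per electrode
    epoch_len = int(round(config.epoch_seconds * config.fs))
    onsets = [i * epoch_len for i in range(config.n_task_epochs)]
    epochs = extract_epochs(task, onsets, epoch_len, condition="task")
    desync: dict[str, float] = {}
    rest_mu_power: float | None = None
    for el in config.desync_electrodes:
        score = trial_average_desync(epochs, rest.channel(el)[: config.n_mse], el, MU_BAND)
        desync[el] = score.value
        if el == "C3":
            rest_mu_power = score.rest_power

    # --- multiscale entropy per electrode/band, matched series lengths
    rest_entropy: dict[tuple[str, str], float] = {}
    task_entropy: dict[tuple[str, str], float] = {}
    for el in config.mse_electrodes:
        for band_name in config.mse_bands:
            band = DEFAULT_BANDS[band_name]
            p_rest = band_limited_mse(rest, el, band, config.mse_params,
                                      n_samples=config.n_mse, condition="rest")
            p_task = band_limited_mse(task, el, band, config.mse_params,
                                      n_samples=config.n_mse, condition="task")
            rest_entropy[(el, band_name)] = p_rest.avg_entropy
            task_entropy[(el, band_name)] = p_task.avg_entropy

    # --- phase-coherence networks per band
    rest_ge: dict[str, float] = {}
    task_ge: dict[str, float] = {}
    rest_cc = task_cc = None
    seg_len = int(round(config.network_segment_seconds * config.fs))
    for band_name in config.network_bands:
        band = DEFAULT_BANDS[band_name]
        trim = len(fir_bandpass(config.fs, band.low, band.high))
        segment = (trim, seg_len)
        g_rest = build_network(rest, band, segment, condition="rest")
        g_task = build_network(task, band, segment, condition="task")
        rest_ge[band_name] = global_efficiency(g_rest)
        task_ge[band_name] = global_efficiency(g_task)
        if band_name == "alpha":
            rest_cc = clustering_coefficient(g_rest, "C3")
            task_cc = clustering_coefficient(g_task, "C3")

    return SubjectRecord(
        subject=subject_id, desync=desync,
        rest_entropy=rest_entropy, task_entropy=task_entropy,
        rest_ge=rest_ge, task_ge=task_ge,
        rest_cc_c3=rest_cc, task_cc_c3=task_cc,
        rest_mu_power=rest_mu_power,
    )


@dataclass(frozen=True)
class CohortResult:
    """Bundle of per-subject measures and group-level statistics."""

    records: tuple[SubjectRecord, ...]
    injected_desync: tuple[float, ...]
    tests: dict[str, TestResult]
    regressions: dict[str, RegressionResult]
    correlation: CorrelationResult | None
    bonferroni_threshold: float
    config: CohortConfig

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def group_analysis(records: Sequence[SubjectRecord],
                   config: CohortConfig) -> tuple[dict, dict, CorrelationResult | None]:
    """Group statistics mirroring the analysis plan: one-sample t on
    desynchronization per electrode, paired t on C3 alpha entropy and on
    alpha GE and C3 CC, the three single-predictor models, and the
    entropy-change/efficiency-change correlation."""
    frame = records_to_frame(records)
    tests: dict[str, TestResult] = {}
    for el in config.desync_electrodes:
        col = f"desync_{el}"
        if col in frame:
            tests[f"desync_{el}"] = one_sample_t(frame[col], 0.0, label=f"desync {el}")
    if "rest_entropy_C3_alpha" in frame and "task_entropy_C3_alpha" in frame:
        tests["entropy_C3_alpha"] = paired_t(
            frame["rest_entropy_C3_alpha"], frame["task_entropy_C3_alpha"],
            label="C3 alpha avg entropy task vs rest",
        )
    if "rest_ge_alpha" in frame and "task_ge_alpha" in frame:
        tests["ge_alpha"] = paired_t(
            frame["rest_ge_alpha"], frame["task_ge_alpha"],
            label="alpha global efficiency task vs rest",
        )
    if ("rest_cc_C3" in frame and "task_cc_C3" in frame
            and frame["rest_cc_C3"].notna().all() and frame["task_cc_C3"].notna().all()):
        tests["cc_C3_alpha"] = paired_t(
            frame["rest_cc_C3"], frame["task_cc_C3"],
            label="C3 alpha clustering coefficient task vs rest",
        )

    regressions: dict[str, RegressionResult] = {}
    for name in ("rest_entropy", "task_entropy", "rest_power"):
        try:
            regressions[name] = regress_desync_on_baseline(frame, predictor=name)
        except (KeyError, ValueError) as exc:
            logger.warning("regression %s skipped: %s", name, exc)

    correlation: CorrelationResult | None = None
    needed = ("rest_entropy_C3_alpha", "task_entropy_C3_alpha", "rest_ge_alpha", "task_ge_alpha")
    if all(c in frame for c in needed):
        ent_change = [
            percent_change(t, r) for r, t in
            zip(frame["rest_entropy_C3_alpha"], frame["task_entropy_C3_alpha"])
        ]
        ge_change = [
            percent_change_ge(t, r) for r, t in
            zip(frame["rest_ge_alpha"], frame["task_ge_alpha"])
        ]
        try:
            correlation = corr_change(ent_change, ge_change)
        except ValueError as exc:
            logger.warning("percent-change correlation skipped: %s", exc)
    return tests, regressions, correlation


def run_pipeline(config: CohortConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Generate and analyze a full synthetic cohort; optionally write the
    result bundle (tables, manifest) to ``out_dir``."""
    root = np.random.SeedSequence(config.seed)
    subject_seqs = root.spawn(config.n_subjects)
    records: list[SubjectRecord] = []
    injected: list[float] = []
    for i, seq in enumerate(subject_seqs):
        sid = f"S{i + 1:02d}"
        draw_rng = np.random.default_rng(seq.spawn(1)[0])
        subject_seed = int(seq.generate_state(1)[0] % (2**31))
        rest, task, d = generate_subject(config, i, subject_seed, draw_rng)
        records.append(analyze_subject(config, sid, rest, task))
        injected.append(d)
        logger.info("subject %s done (injected desync %.1f%%)", sid, d)

    tests, regressions, correlation = group_analysis(records, config)
    result = CohortResult(
        records=tuple(records), injected_desync=tuple(injected),
        tests=tests, regressions=regressions, correlation=correlation,
        bonferroni_threshold=bonferroni(0.05, len(config.desync_electrodes)).threshold,
        config=config,
    )
    if out_dir is not None:
        write_bundle(result, Path(out_dir))
    return result


def config_hash(config: CohortConfig) -> str:
    blob = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _config_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["mse_params"] = dataclasses.asdict(config.mse_params)
    d["other_band_amps"] = dict(config.other_band_amps)
    return d


def load_config(path: str | Path) -> CohortConfig:
    """Read a CohortConfig from YAML (keys = dataclass fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "mse_params" in raw:
        raw["mse_params"] = MSEParams(**raw["mse_params"])
    for key in ("labels", "desync_electrodes", "mse_electrodes", "mse_bands",
                "network_bands"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortConfig(**raw)


def write_bundle(result: CohortResult, out_dir: Path) -> None:
    """Write subject table, test/regression/correlation tables and a run
    manifest as TSV/JSON.  Deterministic: identical result writes identical
    bytes."""
    out_dir.mkdir(parents=True, exist_ok=True)
    result.frame.to_csv(out_dir / "subjects.tsv", sep="\t")

    rows = [
        {"comparison": t.label or key, "t": t.statistic, "df": t.df,
         "p": t.p, "cohens_d": t.effect_size}
        for key, t in result.tests.items()
    ]
    pd.DataFrame(rows).to_csv(out_dir / "tests.tsv", sep="\t", index=False)

    reg_rows = [
        {"model": name, "predictor": r.predictor,
         "intercept": r.intercept, "intercept_se": r.intercept_se,
         "slope": r.slope, "slope_se": r.slope_se, "slope_p": r.slope_p,
         "r_squared": r.r_squared, "rmse": r.rmse, "df": r.df}
        for name, r in result.regressions.items()
    ]
    pd.DataFrame(reg_rows).to_csv(out_dir / "regressions.tsv", sep="\t", index=False)

    manifest = {
        "package": "mumse",
        "version": __version__,
        "seed": result.config.seed,
        "n_subjects": result.config.n_subjects,
        "config_hash": config_hash(result.config),
        "bonferroni_threshold": result.bonferroni_threshold,
    }
    if result.correlation is not None:
        manifest["entropy_ge_correlation"] = {
            "r": result.correlation.r, "t": result.correlation.t,
            "df": result.correlation.df, "p": result.correlation.p,
        }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
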