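"""Multiscale entropy: coarse-graining, sample entropy, profiles, classification.

Sample entropy SE(m, r) of a series is -ln(A/B), where B counts pairs of
length-m templates agreeing within tolerance r under the Chebyshev (maximum)
distance, A counts the same pairs extended to length m+1, and self-matches
are excluded.  Multiscale entropy evaluates SE on coarse-grained versions of
the series: at scale factor SF, consecutive non-overlapping blocks of SF
samples are averaged, giving a series of floor(N/SF) points; scale 1 is the
original series.  The scale-averaged SE is the complexity score.

Conventions (standard in the MSE literature):

* the tolerance r is a fraction of the SD of the *original* (scale-1) series
  and the resulting absolute tolerance is reused at every scale, so entropy
  changes across scales reflect structure, not variance renormalization
  (a per-scale-SD variant is available behind ``r_per_scale``);
* a template match requires Chebyshev distance strictly below r;
* when either match count is zero the SE at that scale is undefined and
  propagates as NaN (flagged), never as a sentinel value.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .filters import bandpass_filtfilt
from .io import Recording
from .spectral import BandDefinition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MSEParams:
    """Multiscale-entropy parameters.

    m : template length (default 2)
    r : tolerance as a fraction of the series SD (default 0.15)
    sf_max : largest scale factor (default 20)
    """

    m: int = 2
    r: float = 0.15
    sf_max: int = 20

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"template length m must be >= 1, got {self.m}")
        if not 0 < self.r < 1:
            raise ValueError(f"tolerance fraction r must be in (0, 1), got {self.r}")
        if self.sf_max < 1:
            raise ValueError(f"sf_max must be >= 1, got {self.sf_max}")

    def check_length(self, n: int) -> None:
        """Warn when the coarsest scale falls below ~100 points, the usual
        reliability floor for SE estimates."""
        if n // self.sf_max < 100:
            warnings.warn(
                f"coarsest scale has only {n // self.sf_max} points "
                f"(N={n}, sf_max={self.sf_max}); sample entropy may be unreliable "
                "below ~100 points",
                stacklevel=3,
            )


@dataclass(frozen=True)
class MSEProfile:
    """Sample entropy per scale factor plus the scale-averaged complexity score.

    Undefined scales are NaN; ``avg_entropy`` averages the defined scales only.
    """

    entropy_by_scale: dict[int, float]
    params: MSEParams
    n_samples: int
    electrode: str | None = None
    band: str | None = None
    condition: str | None = None
    avg_entropy: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.array(list(self.entropy_by_scale.values()), dtype=float)
        defined = values[np.isfinite(values)]
        avg = float(defined.mean()) if defined.size else float("nan")
        object.__setattr__(self, "avg_entropy", avg)
        n_undef = len(values) - len(defined)
        if n_undef:
            logger.warning(
                "%d of %d scales undefined; complexity score averages the rest",
                n_undef, len(values),
            )

    @property
    def has_undefined(self) -> bool:
        return any(not math.isfinite(v) for v in self.entropy_by_scale.values())

    def values(self) -> np.ndarray:
        """SE values ordered by scale factor 1..sf_max."""
        return np.array([self.entropy_by_scale[sf] for sf in sorted(self.entropy_by_scale)])


class ProfileClass(enum.Enum):
    """Task-vs-rest MSE profile shapes.

    ``increased_complexity``: entropy higher at every scale.
    ``toward_regularity``: entropy lower at every scale.
    ``toward_randomness``: higher at fine scales, decaying below the
    reference at coarse scales (uncorrelated-randomness signature).
    ``mixed``: none of the above (totality extension).
    """

    increased_complexity = "increased_complexity"
    toward_regularity = "toward_regularity"
    toward_randomness = "toward_randomness"
    mixed = "mixed"


def coarse_grain(x: np.ndarray, sf: int) -> np.ndarray:
    """Average non-overlapping blocks of ``sf`` samples; trailing remainder
    discarded. Output length floor(N/sf); sf=1 returns the input unchanged."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("coarse_grain expects a 1-D series")
    if sf < 1:
        raise ValueError(f"scale factor must be >= 1, got {sf}")
    if sf > len(x):
        raise ValueError(f"scale factor {sf} exceeds series length {len(x)}")
    n_blocks = len(x) // sf
    if sf == 1:
        return x.copy()
    return x[: n_blocks * sf].reshape(n_blocks, sf).mean(axis=1)


@njit(cache=True)
def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:  # pragma: no cover
    """Count template-pair matches of lengths m (B) and m+1 (A).

    Pairs (i, j), i < j, both over the first N-m start positions so every
    template has an (m+1)-point extension; Chebyshev distance strictly < r.
    """
    n = len(x)
    n_templates = n - m
    a = 0
    b = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            match_m = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) >= r:
                    match_m = False
                    break
            if match_m:
                b += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r_abs: float = 0.15) -> float:
    """Sample entropy -ln(A/B) with absolute tolerance ``r_abs``.

    Returns NaN (undefined, flagged) when either match count is zero —
    including for constant series, which never raise.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D series")
    if len(x) <= m + 1:
        raise ValueError(f"series length {len(x)} must exceed m+1 = {m + 1}")
    if not r_abs > 0:
        raise ValueError(f"absolute tolerance must be positive, got {r_abs}")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    a, b = _match_counts(x, m, r_abs)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def mse_curve(
    x: np.ndarray,
    params: MSEParams = MSEParams(),
    r_per_scale: bool = False,
    electrode: str | None = None,
    band: str | None = None,
    condition: str | None = None,
) -> MSEProfile:
    """Multiscale entropy profile over scale factors 1..sf_max.

    The absolute tolerance is ``params.r`` x SD of the scale-1 series and is
    reused at all scales unless ``r_per_scale`` is set (then each scale uses
    its own coarse-grained SD).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("mse_curve expects a 1-D series")
    if params.sf_max > len(x):
        raise ValueError(f"sf_max={params.sf_max} exceeds series length {len(x)}")
    params.check_length(len(x))
    sd = float(np.std(x))
    entropy: dict[int, float] = {}
    for sf in range(1, params.sf_max + 1):
        cg = coarse_grain(x, sf)
        if r_per_scale:
            scale_sd = float(np.std(cg))
        else:
            scale_sd = sd
        if scale_sd == 0 or len(cg) <= params.m + 1:
            entropy[sf] = float("nan")
            continue
        entropy[sf] = sample_entropy(cg, params.m, params.r * scale_sd)
    return MSEProfile(entropy, params, len(x), electrode, band, condition)


def band_limited_mse(
    rec: Recording,
    electrode: str,
    band: BandDefinition | None,
    params: MSEParams = MSEParams(),
    n_samples: int | None = None,
    condition: str | None = None,
    r_per_scale: bool = False,
) -> MSEProfile:
    """MSE of one electrode after zero-phase band-pass filtering.

    ``band=None`` skips the filter (full-spectrum profile).  The tolerance SD
    is taken from the *filtered* series, otherwise r would be dominated by
    out-of-band variance.  ``n_samples`` truncates to the first N samples so
    profiles across conditions use matched lengths.
    """
    x = rec.channel(electrode)
    if n_samples is not None:
        if n_samples > len(x):
            raise ValueError(f"requested {n_samples} samples, recording has {len(x)}")
        x = x[:n_samples]
    if band is not None:
        band.validate_against(rec.fs)
        x, _ = bandpass_filtfilt(x, rec.fs, band.low, band.high)
    return mse_curve(
        x, params, r_per_scale=r_per_scale,
        electrode=electrode, band=band.name if band else "broadband",
        condition=condition,
    )


def classify_profile(task: MSEProfile, rest: MSEProfile, tol: float = 0.0) -> ProfileClass:
    """Classify the task profile against the rest reference.

    Uses per-scale differences task - rest at scales defined in both
    profiles; ``tol`` is the dead band around zero.
    """
    if task.params != rest.params:
        raise ValueError(
            f"profiles have mismatched parameters: {task.params} vs {rest.params}"
        )
    scales = sorted(
        sf for sf in task.entropy_by_scale
        if math.isfinite(task.entropy_by_scale[sf])
        and math.isfinite(rest.entropy_by_scale.get(sf, float("nan")))
    )
    if not scales:
        raise ValueError("no scale is defined in both profiles")
    diffs = np.array([task.entropy_by_scale[sf] - rest.entropy_by_scale[sf] for sf in scales])
    if (diffs > tol).all():
        return ProfileClass.increased_complexity
    if (diffs < -tol).all():
        return ProfileClass.toward_regularity
    # randomness signature: above at fine scales, below past a single crossover
    above = diffs > tol
    below = diffs < -tol
    for k in range(1, len(diffs)):
        if above[:k].all() and below[k:].all():
            return ProfileClass.toward_randomness
    return ProfileClass.mixed


def percent_change(task_avg: float, rest_avg: float) -> float:
    """(task - rest)/rest * 100 for scale-averaged entropies."""
    if rest_avg == 0:
        raise ValueError("rest average entropy is zero; percent change undefined")
    return (task_avg - rest_avg) / rest_avg * 100.0
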