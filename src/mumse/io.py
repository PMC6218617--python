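"""Recording container, file I/O, re-referencing, artifact screening and epoching.

A :class:`Recording` is a channels x samples matrix in microvolts with a
sampling rate and ordered 10-20 channel labels.  The lossless on-disk
interchange format is a tab-separated matrix (one row per channel, first
column the label) with a comment header carrying the sampling rate and
reference tag.  EDF reading is available when :mod:`mne` is installed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Electrode names of the international 10-20 system (superset used for the
#: 32-channel montages this package targets).  Unknown labels are accepted
#: with a warning so extended montages still load.
TEN_TWENTY_LABELS = frozenset(
    "Fp1 Fp2 F7 F3 Fz F4 F8 FC5 FC1 FC2 FC6 T7 C3 Cz C4 T8 TP9 CP5 CP1 CP2 "
    "CP6 TP10 P7 P3 Pz P4 P8 PO9 O1 Oz O2 PO10 AF3 AF4 FC3 FC4 CP3 CP4 PO3 "
    "PO4 F1 F2 C1 C2 P1 P2 POz FCz Iz A1 A2 M1 M2 T3 T4 T5 T6".split()
)

#: Default 32-channel montage used by the synthetic generator.
DEFAULT_MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)


@dataclass(frozen=True)
class Recording:
    """Multichannel EEG recording.

    Parameters
    ----------
    data
        Channels x samples array, microvolts.
    fs
        Sampling rate in Hz.
    labels
        Ordered channel names, one per row of ``data``.
    reference
        Reference tag, ``"as-recorded"`` or ``"average"``.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={data.ndim}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != data.shape[0]:
            raise ValueError(
                f"label count ({len(self.labels)}) != channel count ({data.shape[0]})"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording (labels: {self.labels})") from None

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's series (view, do not mutate)."""
        return self.data[self.channel_index(label)]


@dataclass(frozen=True)
class EpochSet:
    """Condition-labelled segments into a :class:`Recording`.

    Segments are half-open sample intervals ``[onset, onset + length)``,
    0-based, non-overlapping and in-bounds.
    """

    condition: str
    segments: tuple[tuple[int, int], ...]
    source: Recording = field(repr=False)

    def __post_init__(self) -> None:
        segs = tuple((int(o), int(n)) for o, n in self.segments)
        object.__setattr__(self, "segments", segs)
        if self.condition not in ("rest", "task"):
            raise ValueError(f"condition must be 'rest' or 'task', got {self.condition!r}")
        last_end = -1
        for onset, length in sorted(segs):
            if length <= 0:
                raise ValueError(f"segment length must be positive, got {length}")
            if onset < 0 or onset + length > self.source.n_samples:
                raise ValueError(
                    f"segment [{onset}, {onset + length}) out of bounds for "
                    f"{self.source.n_samples} samples"
                )
            if onset < last_end:
                raise ValueError("segments overlap")
            last_end = onset + length

    def __len__(self) -> int:
        return len(self.segments)

    def arrays(self, label: str) -> list[np.ndarray]:
        """Per-segment series for one channel."""
        ch = self.source.channel(label)
        return [ch[o : o + n] for o, n in self.segments]


# ---------------------------------------------------------------------------
# matrix (TSV) dialect
# ---------------------------------------------------------------------------

def save_matrix(rec: Recording, path: str | Path) -> None:
    """Write a recording as a TSV matrix: comment header, one row per channel.

    Floats are written with ``repr`` precision so a load round-trips
    bit-identically.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# reference={rec.reference}\n")
        for label, row in zip(rec.labels, rec.data):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _load_matrix(path: Path, fs: float | None) -> Recording:
    labels: list[str] = []
    rows: list[np.ndarray] = []
    reference = "as-recorded"
    header_fs: float | None = None
    offset = 0
    n_cols: int | None = None
    with path.open("r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                offset += len(line)
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith("fs="):
                    header_fs = float(body[3:])
                elif body.startswith("reference="):
                    reference = body[len("reference="):]
                offset += len(line)
                continue
            parts = stripped.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}: malformed row at line {lineno} (byte offset {offset}): "
                    f"expected label + samples, got {len(parts)} field(s)"
                )
            if n_cols is None:
                n_cols = len(parts)
            elif len(parts) != n_cols:
                raise ValueError(
                    f"{path}: truncated or ragged row at line {lineno} "
                    f"(byte offset {offset}): expected {n_cols - 1} samples, "
                    f"got {len(parts) - 1}"
                )
            labels.append(parts[0])
            try:
                rows.append(np.array(parts[1:], dtype=np.float64))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric sample at line {lineno} "
                    f"(byte offset {offset}): {exc}"
                ) from None
            offset += len(line)
    if not rows:
        raise ValueError(f"{path}: no channel rows found")
    effective_fs = fs if fs is not None else header_fs
    if effective_fs is None:
        raise ValueError(
            f"{path}: sampling rate missing — matrix dialect requires fs in the "
            "header ('# fs=...') or as an explicit argument"
        )
    _warn_unknown_labels(labels)
    return Recording(np.vstack(rows), effective_fs, tuple(labels), reference)


def _warn_unknown_labels(labels: Sequence[str]) -> None:
    unknown = [lb for lb in labels if lb not in TEN_TWENTY_LABELS]
    if unknown:
        warnings.warn(
            f"channel labels not in the 10-20 nomenclature (retained): {unknown}",
            stacklevel=3,
        )


def _load_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "EDF reading requires the optional dependency 'mne' "
            "(pip install mumse[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; we work in microvolts
    _warn_unknown_labels(raw.ch_names)
    return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))


def load_recording(path: str | Path, format: str = "matrix", fs: float | None = None) -> Recording:
    """Load a recording from disk.

    Parameters
    ----------
    path
        File path.
    format
        ``"matrix"`` (TSV dialect written by :func:`save_matrix`) or
        ``"edf"`` (requires ``mne``).
    fs
        Sampling rate override; required for matrix files without a header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix":
        return _load_matrix(path, fs)
    if format == "edf":
        return _load_edf(path)
    raise ValueError(f"unknown format {format!r}; expected 'matrix' or 'edf'")


def save_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording to EDF. Requires an EDF writer backend.

    Raises
    ------
    ImportError
        If no EDF export backend (``edfio``) is installed; the TSV matrix
        dialect (:func:`save_matrix`) is the lossless alternative.
    """
    try:
        import mne
        import edfio  # noqa: F401  (mne's EDF exporter backend)
    except ImportError as exc:
        raise ImportError(
            "EDF export requires 'mne' with the 'edfio' backend; "
            "use save_matrix() for the lossless TSV dialect instead"
        ) from exc
    info = mne.create_info(list(rec.labels), rec.fs, ch_types="eeg", verbose="error")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="error")
    mne.export.export_raw(str(path), raw, fmt="edf", overwrite=True, verbose="error")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def rereference_average(rec: Recording) -> Recording:
    """Subtract the per-sample channel mean (common average reference).

    Idempotent and linear; the channel mean of every output sample is 0.
    A head-model based reference standardization is out of scope; the
    common average is the standard sensor-space stand-in.
    """
    if rec.n_channels < 2:
        raise ValueError("average re-referencing needs at least 2 channels")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=centered, reference="average")


def screen_artifacts(
    rec: Recording,
    amplitude_limit: float = 100.0,
    flat_limit: int | None = None,
) -> list[tuple[int, int]]:
    """Find maximal clean segments: no channel exceeds ``amplitude_limit`` (µV)
    and no channel is constant for ``flat_limit`` or more samples.

    An automated stand-in for manual artifact rejection: amplitude excursions
    catch blink/EMG-like transients, flat runs catch saturated or disconnected
    electrodes.  Returns disjoint, sorted ``(onset, length)`` pairs; may be
    empty.

    ``flat_limit`` defaults to 0.1 s worth of samples.
    """
    if amplitude_limit <= 0:
        raise ValueError("amplitude_limit must be positive")
    if flat_limit is None:
        flat_limit = max(2, int(round(0.1 * rec.fs)))
    if flat_limit <= 0:
        raise ValueError("flat_limit must be positive")

    bad = (np.abs(rec.data) >= amplitude_limit).any(axis=0)

    # flat runs: a run of L equal consecutive values spans L samples and
    # yields L-1 zero first-differences
    if rec.n_samples >= flat_limit:
        for ch in range(rec.n_channels):
            flat = np.diff(rec.data[ch]) == 0
            # run boundaries of the boolean series
            edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
            starts = np.concatenate(([0], edges + 1))
            ends = np.concatenate((edges + 1, [flat.size]))
            for s, e in zip(starts, ends):
                if flat[s] and (e - s) >= flat_limit - 1:
                    bad[s : e + 1] = True

    segments: list[tuple[int, int]] = []
    start: int | None = None
    for i, is_bad in enumerate(bad):
        if not is_bad and start is None:
            start = i
        elif is_bad and start is not None:
            segments.append((start, i - start))
            start = None
    if start is not None:
        segments.append((start, rec.n_samples - start))

    rejected = bad.mean()
    if rejected > 0:
        logger.info("artifact screen rejected %.1f%% of samples", 100 * rejected)
    return segments


def extract_epochs(
    rec: Recording,
    onsets: Sequence[int],
    length: int,
    condition: str = "task",
) -> EpochSet:
    """Cut fixed-length epochs at the given onsets.

    Out-of-bounds onsets are dropped with a logged count; an empty result is
    an error.
    """
    if length <= 0:
        raise ValueError("epoch length must be positive")
    kept = [int(o) for o in onsets if 0 <= o and o + length <= rec.n_samples]
    dropped = len(onsets) - len(kept)
    if dropped:
        logger.warning("dropped %d out-of-bounds onset(s)", dropped)
    if not kept:
        raise ValueError("no epochs remain after bounds check")
    return EpochSet(condition, tuple((o, length) for o in kept), rec)
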