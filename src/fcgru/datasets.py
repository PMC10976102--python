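"""Recording containers, segmentation, label binarization and dataset loaders.

A :class:`Recording` holds one subject's multichannel EEG as a
``trials x channels x samples`` array together with per-trial ordinal
affect scores (arousal, valence, dominance, ...).  Recordings are cut
into fixed-length windows (:func:`segment_recording`), whose per-trial
scores are thresholded into binary low/high labels
(:func:`binarize_labels`).

Loaders are provided for the two public affect corpora this pipeline
targets: DEAP (32 subjects, 40 trials, 32 EEG channels, scores 1-9) and
DREAMER (23 subjects, 18 film clips, 14 channels, scores 1-5), plus an
internal HDF5 bundle format used by the synthetic generator and the CLI.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import io as sio
from scipy import signal as ssig

__all__ = [
    "Recording",
    "Sample",
    "segment_recording",
    "binarize_labels",
    "downsample",
    "read_deap",
    "read_dreamer",
    "read_bundle",
    "write_bundle",
    "FormatError",
    "DEAP_DIMENSIONS",
    "DREAMER_DIMENSIONS",
]

DEAP_DIMENSIONS = ("valence", "arousal", "dominance", "liking")
DREAMER_DIMENSIONS = ("arousal", "valence", "dominance")

#: pre-stimulus baseline seconds in the preprocessed DEAP archive
DEAP_BASELINE_SECONDS = 3.0


class FormatError(ValueError):
    """Raised when an on-disk dataset file does not match its documented layout."""


@dataclass
class Recording:
    """One subject's EEG block: ``signal[trial, channel, sample]`` plus scores.

    Parameters
    ----------
    subject_id:
        Stable identifier, e.g. ``"s01"``.
    signal:
        ``(n_trials, n_channels, n_samples)`` float array, microvolt scale.
    fs:
        Sampling rate in Hz.
    scores:
        ``(n_trials, n_dimensions)`` ordinal affect ratings.
    dimension_names:
        Ordered names matching the columns of ``scores``.
    """

    subject_id: str
    signal: np.ndarray
    fs: float
    scores: np.ndarray
    dimension_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.signal.ndim != 3:
            raise ValueError("signal must be trials x channels x samples")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.scores.ndim != 2 or self.scores.shape[0] != self.signal.shape[0]:
            raise ValueError(
                "scores must have one row per trial "
                f"({self.scores.shape[0]} rows vs {self.signal.shape[0]} trials)"
            )
        if self.scores.shape[1] != len(self.dimension_names):
            raise ValueError("scores columns must match dimension_names")
        self.dimension_names = tuple(self.dimension_names)

    @property
    def n_trials(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[2]

    def dimension_index(self, name: str) -> int:
        try:
            return self.dimension_names.index(name)
        except ValueError:
            raise KeyError(
                f"dimension {name!r} not in {self.dimension_names}"
            ) from None


@dataclass
class Sample:
    """One windowed segment: ``window[sample, channel]`` with binary labels.

    ``labels`` maps each affect dimension to 0 (low) / 1 (high); provenance
    (subject, trial, window index) is retained for fold bookkeeping.
    """

    window: np.ndarray
    subject_id: str
    trial_index: int
    window_index: int
    labels: dict[str, int] = field(default_factory=dict)


def _window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    """Start offsets of fully-contained windows: 0, step, 2*step, ..."""
    if n_samples < win:
        return np.empty(0, dtype=np.intp)
    return np.arange(0, n_samples - win + 1, step, dtype=np.intp)


def _to_sample_count(seconds: float, fs: float, what: str) -> int:
    n = seconds * fs
    n_int = round(n)
    if abs(n - n_int) > 1e-9 or n_int <= 0:
        raise ValueError(
            f"{what} of {seconds} s is not a positive whole number of samples at fs={fs}"
        )
    return n_int


def segment_recording(
    rec: Recording,
    window_seconds: float,
    step_seconds: float,
    threshold: float | None = None,
) -> list[Sample]:
    """Cut every trial into half-open windows ``[start, start + len)``.

    Windows start at sample 0 of each trial, advance by ``step_seconds``,
    never cross trial boundaries, and partial tail windows are dropped.
    A 60 s trial at 1 s windows / 1 s step therefore yields exactly 60
    windows; at 2 s / 0.125 s it yields 465.

    If ``threshold`` is given, each sample's per-dimension binary labels
    are attached via :func:`binarize_labels`.
    """
    win = _to_sample_count(window_seconds, rec.fs, "window")
    step = _to_sample_count(step_seconds, rec.fs, "step")
    starts = _window_starts(rec.n_samples, win, step)
    if starts.size == 0:
        warnings.warn(
            f"window ({window_seconds} s) longer than trial "
            f"({rec.n_samples / rec.fs} s); no samples produced",
            stacklevel=2,
        )
        return []
    labels_per_trial: list[dict[str, int]] | None = None
    if threshold is not None:
        binary = binarize_labels(rec.scores, threshold)
        labels_per_trial = [
            dict(zip(rec.dimension_names, row)) for row in binary.astype(int)
        ]
    samples: list[Sample] = []
    for trial in range(rec.n_trials):
        for w_idx, s0 in enumerate(starts):
            samples.append(
                Sample(
                    window=rec.signal[trial, :, s0 : s0 + win].T.copy(),
                    subject_id=rec.subject_id,
                    trial_index=trial,
                    window_index=w_idx,
                    labels=dict(labels_per_trial[trial]) if labels_per_trial else {},
                )
            )
    return samples


def binarize_labels(scores: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold ordinal scores into binary labels.

    A score strictly below ``threshold`` maps to 0 ("low"); anything else
    (including the threshold itself) maps to 1 ("high").  The conventional
    thresholds are 5 on the 1-9 DEAP scale and 3 on the 1-5 DREAMER scale.
    """
    scores = np.asarray(scores, dtype=np.float64)
    return (scores >= threshold).astype(np.int64)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filter and resample a recording to ``target_fs``.

    Uses polyphase resampling per trial; ``target_fs == fs`` is an exact
    pass-through.  Trial boundaries are preserved because trials are
    resampled independently.
    """
    if target_fs > rec.fs:
        raise ValueError(f"target_fs {target_fs} exceeds recording fs {rec.fs}")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = ssig.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=2)
    return Recording(
        subject_id=rec.subject_id,
        signal=out,
        fs=target_fs,
        scores=rec.scores,
        dimension_names=rec.dimension_names,
    )


def read_deap(path: str | Path, *, drop_baseline: bool = True) -> Recording:
    """Load one subject from the preprocessed DEAP per-subject archive.

    The archive is a pickled dict with ``data`` of shape (40, 40, 8064)
    — 40 trials, 40 channels of which the first 32 are EEG, 63 s at
    128 Hz — and ``labels`` of shape (40, 4) holding valence, arousal,
    dominance and liking ratings on a 1-9 scale.

    ``drop_baseline`` removes the 3 s pre-stimulus baseline so that each
    trial covers the 60 s stimulus presentation (the segmentation
    arithmetic of 40 trials x 60 one-second windows = 2400 samples per
    subject assumes this).  Set it to False to keep all 63 s.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh, encoding="latin1")
    except (pickle.UnpicklingError, EOFError, OSError) as exc:
        raise FormatError(f"cannot unpickle DEAP archive {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise FormatError(f"DEAP archive {path} is not a dict")
    for key in ("data", "labels"):
        if key not in payload:
            raise FormatError(f"DEAP archive {path} missing field {key!r}")
    data = np.asarray(payload["data"], dtype=np.float64)
    labels = np.asarray(payload["labels"], dtype=np.float64)
    if data.ndim != 3 or data.shape[0] != labels.shape[0]:
        raise FormatError(
            f"DEAP archive {path}: data {data.shape} / labels {labels.shape} mismatch"
        )
    if data.shape[1] < 32 or labels.shape[1] != 4:
        raise FormatError(
            f"DEAP archive {path}: expected >=32 channels and 4 label columns, "
            f"got data {data.shape}, labels {labels.shape}"
        )
    eeg = data[:, :32, :]
    if drop_baseline:
        eeg = eeg[:, :, int(DEAP_BASELINE_SECONDS * 128) :]
    return Recording(
        subject_id=path.stem,
        signal=eeg,
        fs=128.0,
        scores=labels,
        dimension_names=DEAP_DIMENSIONS,
    )


def read_dreamer(
    path: str | Path,
    subject_index: int = 0,
    *,
    clip_seconds: float | None = 60.0,
) -> Recording:
    """Load one subject from the DREAMER MATLAB-v5 container.

    The container holds a top-level ``DREAMER`` struct whose ``Data``
    cell array has one entry per subject; each entry carries
    ``EEG.stimuli`` (18 clips of variable length, 14 channels at 128 Hz)
    and per-clip ``ScoreArousal`` / ``ScoreValence`` / ``ScoreDominance``
    ratings on a 1-5 scale.

    Film clips have different durations, so the trailing ``clip_seconds``
    of each clip are kept (the affect rating refers to the clip just
    watched, and the emotional response is strongest near the end).  Set
    ``clip_seconds=None`` to truncate all clips to the shortest one.
    """
    path = Path(path)
    try:
        mat = sio.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except (OSError, ValueError, NotImplementedError) as exc:
        raise FormatError(f"cannot read DREAMER container {path}: {exc}") from exc
    if "DREAMER" not in mat:
        raise FormatError(f"DREAMER container {path} missing field 'DREAMER'")
    root = mat["DREAMER"]
    try:
        subjects = np.atleast_1d(root.Data)
        entry = subjects[subject_index]
        stimuli = np.atleast_1d(entry.EEG.stimuli)
        scores = np.column_stack(
            [
                np.atleast_1d(entry.ScoreArousal).astype(float),
                np.atleast_1d(entry.ScoreValence).astype(float),
                np.atleast_1d(entry.ScoreDominance).astype(float),
            ]
        )
    except AttributeError as exc:
        raise FormatError(
            f"DREAMER container {path} missing field {exc.name!r}"
        ) from exc
    clips = [np.atleast_2d(np.asarray(c, dtype=np.float64)) for c in stimuli]
    # clips are stored samples x channels
    n_keep = (
        min(c.shape[0] for c in clips)
        if clip_seconds is None
        else int(round(clip_seconds * 128))
    )
    for i, c in enumerate(clips):
        if c.shape[0] < n_keep:
            raise FormatError(
                f"DREAMER clip {i} has {c.shape[0]} samples, needs >= {n_keep}"
            )
    signal = np.stack([c[-n_keep:, :].T for c in clips])
    return Recording(
        subject_id=f"{path.stem}_s{subject_index:02d}",
        signal=signal,
        fs=128.0,
        scores=scores,
        dimension_names=DREAMER_DIMENSIONS,
    )


def write_bundle(path: str | Path, recordings: list[Recording]) -> None:
    """Write recordings to the internal HDF5 bundle.

    Layout: ``/subjects/<id>/signal``, ``/subjects/<id>/scores`` with
    ``fs`` and ``dimension_names`` attributes.  Object timestamps are
    disabled so identical inputs produce byte-identical files.
    """
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as fh:
        grp = fh.create_group("subjects", track_order=True)
        for rec in recordings:
            sub = grp.create_group(rec.subject_id, track_order=True)
            sub.create_dataset("signal", data=rec.signal, track_times=False)
            sub.create_dataset("scores", data=rec.scores, track_times=False)
            sub.attrs["fs"] = float(rec.fs)
            sub.attrs["dimension_names"] = list(rec.dimension_names)


def read_bundle(path: str | Path) -> list[Recording]:
    """Read recordings back from the internal HDF5 bundle."""
    path = Path(path)
    out: list[Recording] = []
    with h5py.File(path, "r") as fh:
        if "subjects" not in fh:
            raise FormatError(f"bundle {path} missing group 'subjects'")
        for sid, sub in fh["subjects"].items():
            for key in ("signal", "scores"):
                if key not in sub:
                    raise FormatError(f"bundle {path}: subject {sid} missing {key!r}")
            out.append(
                Recording(
                    subject_id=sid,
                    signal=sub["signal"][()],
                    fs=float(sub.attrs["fs"]),
                    scores=sub["scores"][()],
                    dimension_names=tuple(
                        str(d) for d in sub.attrs["dimension_names"]
                    ),
                )
            )
    return out
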