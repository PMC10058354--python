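"""Data model and file I/O for wrist-IMU streams and per-frame annotation tracks.

A recording is a fixed-rate, 6-channel inertial stream (3-axis linear
acceleration ``ax, ay, az`` and 3-axis angular velocity ``gx, gy, gz``,
nominally 200 Hz) from a single wrist.  Video-based behavioural codes are
carried per frame, per annotator, and mapped onto sensor samples by
:func:`align_annotations`.

Channel units are carried opaquely (device units): every downstream feature is
computed per channel and is either scale-covariant or scale-invariant, so no
calibration is applied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Fixed channel order, preserved through every I/O round-trip.
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")

#: The five valid per-frame behavioural codes (-1 is "Unknown").
VALID_CODES = (-1, 0, 1, 2, 3)


class ImuFormatError(ValueError):
    """CSV header does not match the expected column layout."""


class ImuParseError(ValueError):
    """A body cell could not be parsed as a number."""


class AlignmentError(ValueError):
    """Timestamps are not monotonically increasing."""


@dataclasses.dataclass
class ImuSeries:
    """One subject/limb worth of 6-channel inertial data at a uniform rate.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the recording belongs to.
    data : ndarray of shape (n_samples, 6)
        Samples in the fixed channel order :data:`CHANNELS`.
    sampling_rate_hz : float
        Uniform sampling rate; 200 Hz for the prototype device.
    limb : str
        ``"affected"`` (prosthetic side) or ``"nondominant"`` (controls).
    """

    subject_id: str
    data: np.ndarray
    sampling_rate_hz: float = 200.0
    limb: str = "nondominant"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNELS):
            raise ValueError(
                f"expected (n_samples, {len(CHANNELS)}) data, got {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValueError("an IMU series needs at least one sample")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.limb not in ("affected", "nondominant"):
            raise ValueError(f"unknown limb {self.limb!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]


@dataclasses.dataclass
class AnnotatorSet:
    """Per-frame behavioural codes from one to three independent annotators.

    ``tracks`` has shape (n_annotators, n_frames); every code is one of
    :data:`VALID_CODES`.
    """

    frame_rate_hz: float
    tracks: np.ndarray

    def __post_init__(self) -> None:
        self.tracks = np.asarray(self.tracks, dtype=int)
        if self.tracks.ndim != 2:
            raise ValueError("tracks must be a 2-D (n_annotators, n_frames) array")
        if not 1 <= self.tracks.shape[0] <= 3:
            raise ValueError("between 1 and 3 annotator tracks are supported")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if not np.isin(self.tracks, VALID_CODES).all():
            bad = np.unique(self.tracks[~np.isin(self.tracks, VALID_CODES)])
            raise ValueError(f"invalid behavioural codes {bad.tolist()}")

    @property
    def n_annotators(self) -> int:
        return self.tracks.shape[0]

    @property
    def n_frames(self) -> int:
        return self.tracks.shape[1]


@dataclasses.dataclass
class SubjectDataset:
    """An IMU series bound to its merged per-sample behavioural codes."""

    series: ImuSeries
    merged_codes: np.ndarray
    group: str = "control"

    def __post_init__(self) -> None:
        self.merged_codes = np.asarray(self.merged_codes, dtype=int)
        if self.merged_codes.shape != (self.series.n_samples,):
            raise ValueError("merged_codes must be aligned 1:1 with samples")
        if self.group not in ("control", "amputee"):
            raise ValueError(f"unknown group {self.group!r}")


def read_imu_csv(path: str | Path, sampling_rate_hz: float = 200.0,
                 subject_id: str | None = None,
                 limb: str = "nondominant") -> ImuSeries:
    """Read an IMU CSV (header ``t,ax,ay,az,gx,gy,gz``) into an :class:`ImuSeries`.

    The ``t`` column is validated as strictly monotonic but not stored: the
    stream is treated as uniformly sampled at ``sampling_rate_hz``.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    expected = ["t", *CHANNELS]
    if list(frame.columns) != expected:
        raise ImuFormatError(
            f"{path}: expected columns {expected}, found {list(frame.columns)}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ImuParseError(f"{path}: non-numeric value in data row {row}")
    t = numeric["t"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise AlignmentError(f"{path}: t column is not strictly increasing")
    data = numeric[list(CHANNELS)].to_numpy()
    return ImuSeries(subject_id or path.stem, data, sampling_rate_hz, limb)


def write_imu_csv(series: ImuSeries, path: str | Path) -> None:
    """Write an :class:`ImuSeries` back to CSV with synthesised uniform timestamps."""
    t = np.arange(series.n_samples) / series.sampling_rate_hz
    frame = pd.DataFrame({"t": t})
    for i, name in enumerate(CHANNELS):
        frame[name] = series.data[:, i]
    frame.to_csv(path, index=False, float_format="%.12g")


def read_annotation_csv(path: str | Path, frame_rate_hz: float) -> AnnotatorSet:
    """Read annotation CSV (``frame,code_a1[,code_a2,code_a3]``).

    Missing annotator columns are allowed; synthetic quick runs may use one.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    cols = [c for c in ("code_a1", "code_a2", "code_a3") if c in frame.columns]
    if "frame" not in frame.columns or not cols:
        raise ImuFormatError(
            f"{path}: expected 'frame' plus at least one code_aN column"
        )
    tracks = frame[cols].to_numpy().T
    return AnnotatorSet(frame_rate_hz, tracks)


def write_annotation_csv(ann: AnnotatorSet, path: str | Path) -> None:
    frame = pd.DataFrame({"frame": np.arange(ann.n_frames)})
    for k in range(ann.n_annotators):
        frame[f"code_a{k + 1}"] = ann.tracks[k]
    frame.to_csv(path, index=False)


def align_annotations(ann: AnnotatorSet, series: ImuSeries,
                      offset_s: float = 0.0) -> np.ndarray:
    """Map per-frame codes onto sensor samples; returns (n_annotators, n_samples).

    Video frame ``j`` covers the left-closed interval
    ``[j/frame_rate, (j+1)/frame_rate)`` of video time; sensor sample ``i``
    occurs at video time ``i/sampling_rate - offset_s`` (``offset_s`` places
    video time zero at sensor time ``offset_s``).  Samples falling before the
    first or after the last frame receive -1 (Unknown).
    """
    if ann.n_frames == 0:
        raise ValueError("annotation tracks are empty")
    if ann.frame_rate_hz > series.sampling_rate_hz:
        raise ValueError("frame rate must not exceed the sensor sampling rate")
    t_video = np.arange(series.n_samples) / series.sampling_rate_hz - offset_s
    idx = np.floor(t_video * ann.frame_rate_hz).astype(int)
    out = np.full((ann.n_annotators, series.n_samples), -1, dtype=int)
    ok = (idx >= 0) & (idx < ann.n_frames)
    out[:, ok] = ann.tracks[:, idx[ok]]
    return out


def load_config(path: str | Path) -> dict:
    """Load a YAML config mapping; unknown structure is left to the caller."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
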