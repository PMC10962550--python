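"""Raw-recording preprocessing: bad-channel detection, common-average
referencing, zero-phase filtering, downsampling, and 30-s windowing.

The intended order of operations for a continuous recording is

    detect_bad_channels -> rereference_common_average -> apply_filters
    -> downsample -> segment_windows

Filtering is applied to the continuous record (not per window) so that
filter edge transients do not contaminate every window. Common-average
referencing is pointwise across channels and commutes exactly with
per-channel LTI filtering, so referencing continuously is equivalent to
referencing each window after the fact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "WindowGrid",
    "ChannelMeta",
    "detect_bad_channels",
    "rereference_common_average",
    "apply_filters",
    "downsample",
    "segment_windows",
    "preprocess_recording",
    "WINDOW_LENGTH_S",
]

WINDOW_LENGTH_S = 30.0


@dataclass
class Recording:
    """Multichannel voltage recording.

    Attributes
    ----------
    channel_ids
        Unique channel labels, one per row of ``data``.
    fs
        Sampling rate in Hz.
    data
        Array of shape (n_channels, n_samples), microvolts.
    start_time
        Seconds from the recording origin (annotations share this origin).
    missing_mask
        Optional boolean array (n_samples,), True where data are missing.
    """

    channel_ids: list[str]
    fs: float
    data: np.ndarray
    start_time: float = 0.0
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match data rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if self.missing_mask is not None:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (self.data.shape[1],):
                raise ValueError("missing_mask must be per-sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class WindowGrid:
    """Consecutive, non-overlapping half-open windows [start, start+L)."""

    window_starts: np.ndarray  # seconds
    valid: np.ndarray  # bool per window
    window_length_s: float = WINDOW_LENGTH_S

    def __post_init__(self) -> None:
        self.window_starts = np.asarray(self.window_starts, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.window_starts.shape != self.valid.shape:
            raise ValueError("window_starts and valid must align")
        d = np.diff(self.window_starts)
        if d.size and not np.allclose(d, self.window_length_s):
            raise ValueError("window starts must step by exactly one window length")

    @property
    def n_windows(self) -> int:
        return self.window_starts.size


@dataclass(frozen=True)
class ChannelMeta:
    """Per-channel metadata row."""

    channel_id: str
    region_id: str | None
    resected: bool = False
    bad: bool = False
    normative_eligible: bool = True


def channel_meta_frame(meta: list[ChannelMeta]) -> pd.DataFrame:
    """Tabulate ChannelMeta rows (columns match the channels CSV schema)."""
    return pd.DataFrame(
        {
            "channel_id": [m.channel_id for m in meta],
            "region_id": [m.region_id for m in meta],
            "resected": [int(m.resected) for m in meta],
            "bad": [int(m.bad) for m in meta],
            "normative_eligible": [int(m.normative_eligible) for m in meta],
        }
    )


def detect_bad_channels(recording: Recording) -> set[str]:
    """Flag channels with outlier amplitude ranges.

    For each 30-s window the per-channel amplitude range (99th minus 1st
    percentile) is compared across channels: a channel is an outlier in
    that window if its range falls strictly outside
    ``median +/- 3 * IQR`` of the channel ranges. A channel flagged in
    any window, or flat (zero range) anywhere, is returned. With fewer
    than 4 channels detection is skipped with a warning.
    """
    if recording.n_channels < 4:
        warnings.warn("bad-channel detection skipped: fewer than 4 channels")
        return set()
    win = int(round(WINDOW_LENGTH_S * recording.fs))
    n = recording.n_samples
    starts = range(0, n, win) if n < win else range(0, n - win + 1, win)
    bad: set[str] = set()
    for s in starts:
        seg = recording.data[:, s : s + win]
        rng = np.percentile(seg, 99, axis=1) - np.percentile(seg, 1, axis=1)
        med = np.median(rng)
        iqr = np.percentile(rng, 75) - np.percentile(rng, 25)
        lo, hi = med - 3 * iqr, med + 3 * iqr
        outlier = (rng < lo) | (rng > hi) | (rng == 0)
        for ch, flag in zip(recording.channel_ids, outlier):
            if flag:
                bad.add(ch)
    return bad


def rereference_common_average(recording: Recording, excluded: set[str] | None = None) -> Recording:
    """Subtract the instantaneous mean of non-excluded channels from all channels.

    Excluded (e.g. bad) channels do not contribute to the reference but are
    re-referenced themselves and remain in the output.
    """
    excluded = excluded or set()
    keep = np.array([c not in excluded for c in recording.channel_ids])
    if keep.sum() < 2:
        raise ValueError("common average reference needs at least 2 usable channels")
    ref = recording.data[keep].mean(axis=0)
    return replace(recording, data=recording.data - ref[None, :])


def _sos_bandstop(line_hz: float, notch_width_hz: float, fs: float, order: int):
    lo = (line_hz - notch_width_hz / 2) / (fs / 2)
    hi = (line_hz + notch_width_hz / 2) / (fs / 2)
    return signal.butter(order, [lo, hi], btype="bandstop", output="sos")


def apply_filters(
    recording: Recording,
    line_hz: float = 50.0,
    notch_width_hz: float = 2.0,
    band: tuple[float, float] = (0.5, 80.0),
    order: int = 4,
) -> Recording:
    """Zero-phase notch then band-pass filter every channel.

    Both filters are Butterworth designs applied forward-backward
    (``sosfiltfilt``), giving zero group delay. The notch is a band-stop
    of total width ``notch_width_hz`` centred on ``line_hz``.
    """
    if recording.fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {recording.fs} Hz too low for a {band[1]} Hz band edge")
    sos_notch = _sos_bandstop(line_hz, notch_width_hz, recording.fs, order)
    sos_band = signal.butter(
        order, [band[0] / (recording.fs / 2), band[1] / (recording.fs / 2)], btype="bandpass", output="sos"
    )
    out = signal.sosfiltfilt(sos_notch, recording.data, axis=1)
    out = signal.sosfiltfilt(sos_band, out, axis=1)
    return replace(recording, data=out)


def downsample(recording: Recording, target_fs: float = 200.0) -> Recording:
    """Polyphase resample to ``target_fs`` (no upsampling allowed).

    Uses :func:`scipy.signal.resample_poly` (Kaiser-windowed FIR
    anti-aliasing). The rational resampling factor is derived from the
    exact ratio ``target_fs / fs``.
    """
    if recording.fs < target_fs:
        raise ValueError("downsample cannot increase the sampling rate")
    if recording.fs == target_fs:
        return recording
    frac = Fraction(target_fs / recording.fs).limit_denominator(10_000)
    out = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    mask = None
    if recording.missing_mask is not None:
        # a resampled sample is missing if any contributing source sample was
        idx = np.floor(np.arange(out.shape[1]) * recording.fs / target_fs).astype(int)
        idx = np.clip(idx, 0, recording.n_samples - 1)
        mask = recording.missing_mask[idx]
    return replace(recording, fs=float(target_fs), data=out, missing_mask=mask)


def segment_windows(recording: Recording, window_length_s: float = WINDOW_LENGTH_S) -> WindowGrid:
    """Cut the recording into consecutive half-open windows from t=0.

    A trailing partial window is discarded; any window that intersects
    missing samples is marked invalid.
    """
    win = int(round(window_length_s * recording.fs))
    n_win = recording.n_samples // win
    if n_win == 0:
        raise ValueError(f"recording shorter than one {window_length_s}-s window")
    starts = np.arange(n_win) * window_length_s
    valid = np.ones(n_win, dtype=bool)
    if recording.missing_mask is not None:
        m = recording.missing_mask[: n_win * win].reshape(n_win, win)
        valid &= ~m.any(axis=1)
    return WindowGrid(window_starts=starts, valid=valid, window_length_s=window_length_s)


def preprocess_recording(
    recording: Recording,
    line_hz: float = 50.0,
    target_fs: float = 200.0,
    known_bad: set[str] | None = None,
) -> tuple[Recording, WindowGrid, set[str]]:
    """Full preprocessing chain on a continuous recording.

    Returns the cleaned, referenced, filtered, downsampled recording, the
    30-s window grid, and the set of bad channel ids (detected plus any
    supplied in ``known_bad``).
    """
    bad = set(known_bad or set()) | detect_bad_channels(recording)
    rec = rereference_common_average(recording, excluded=bad)
    rec = apply_filters(rec, line_hz=line_hz)
    rec = downsample(rec, target_fs=target_fs)
    grid = segment_windows(rec)
    return rec, grid, bad
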