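"""Reading and writing the package's on-disk formats.

Recordings are stored as a float32 matrix (``<stem>.npy``, channels x
samples, microvolts) with a JSON sidecar (``<stem>.json``) holding the
sampling rate, start time, channel ids, and an optional run-length
encoded missing mask. EDF files are read through :mod:`mne` when it is
installed. Tabular artefacts (channel metadata, seizures, outcomes,
cohort tables, maps) are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_seizures_csv",
    "read_seizures_csv",
]


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean mask as [start, stop) sample pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    return [[int(a), int(b)] for a, b in zip(idx[::2], idx[1::2])]


def _runs_to_mask(runs: list[list[int]], n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for a, b in runs:
        mask[a:b] = True
    return mask


def write_recording(recording: Recording, stem: str | Path) -> None:
    """Write a recording as ``<stem>.npy`` + ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), recording.data.astype(np.float32))
    sidecar = {
        "fs_hz": recording.fs,
        "start_time_s": recording.start_time,
        "channel_ids": recording.channel_ids,
        "units": "uV",
    }
    if recording.missing_mask is not None:
        sidecar["missing_runs"] = _mask_to_runs(recording.missing_mask)
    stem.with_suffix(".json").write_text(json.dumps(sidecar))


def read_recording(path: str | Path) -> Recording:
    """Read a recording from the sidecar format or from EDF.

    ``path`` may be the ``.npy``, the ``.json``, the bare stem, or an
    ``.edf`` file (the latter requires mne).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    stem = path.with_suffix("")
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    data = np.load(stem.with_suffix(".npy")).astype(float)
    mask = None
    if "missing_runs" in sidecar:
        mask = _runs_to_mask(sidecar["missing_runs"], data.shape[1])
    return Recording(
        channel_ids=list(sidecar["channel_ids"]),
        fs=float(sidecar["fs_hz"]),
        data=data,
        start_time=float(sidecar.get("start_time_s", 0.0)),
        missing_mask=mask,
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        channel_ids=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=raw.get_data() * 1e6,  # volts -> microvolts
        start_time=0.0,
    )


def write_seizures_csv(tables: dict[str, "pd.DataFrame"], path: str | Path) -> None:
    """Concatenate per-patient seizure frames into one CSV."""
    pd.concat(tables.values(), ignore_index=True).to_csv(path, index=False)


def read_seizures_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
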