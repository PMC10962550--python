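"""Temporal structure of a recording: seizure-proximity labels, circadian
phase of the alpha/delta ratio, and data-requirement subsampling
experiments.

Window labels partition valid windows into ictal (the window contains a
seizure), peri-ictal (within one hour of an ictal window, measured
start-to-start), and interictal (everything else). Independently, the
circadian phase of the regionally averaged alpha/delta band-power ratio
assigns peak (wake-like) and trough (sleep-like) labels to windows whose
phase lies within pi/4 of the cycle maxima and minima respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.signal import hilbert

from .bandpower import RegionalBandPower
from .localization import DrsSeries, mann_whitney_auc
from .preprocess import WindowGrid

__all__ = [
    "SeizureTable",
    "label_seizure_proximity",
    "alpha_delta_ratio",
    "circadian_phase",
    "label_circadian",
    "window_label_frame",
    "subsample_drs",
    "run_subsampling_experiment",
]

PERIICTAL_HORIZON_S = 3600.0
CIRCADIAN_TOLERANCE_RAD = np.pi / 4


@dataclass
class SeizureTable:
    """Seizure events as half-open intervals [onset_s, offset_s).

    Events are given in seconds from the recording origin. Overlapping
    events are handled transparently by the labelling logic (a window is
    ictal if it intersects any event).
    """

    onsets_s: np.ndarray
    offsets_s: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_s = np.atleast_1d(np.asarray(self.onsets_s, dtype=float))
        self.offsets_s = np.atleast_1d(np.asarray(self.offsets_s, dtype=float))
        if self.onsets_s.shape != self.offsets_s.shape:
            raise ValueError("onsets and offsets must align")
        if np.any(self.offsets_s <= self.onsets_s):
            raise ValueError("seizure offsets must follow onsets")

    def __len__(self) -> int:
        return self.onsets_s.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SeizureTable":
        return cls(df["onset_s"].to_numpy(float), df["offset_s"].to_numpy(float))

    def to_frame(self, patient_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"onset_s": self.onsets_s, "offset_s": self.offsets_s})
        if patient_id is not None:
            df.insert(0, "patient_id", patient_id)
        return df


def label_seizure_proximity(
    grid: WindowGrid,
    seizures: SeizureTable,
    horizon_s: float = PERIICTAL_HORIZON_S,
) -> np.ndarray:
    """Label every window ictal / peri-ictal / interictal.

    A window [t, t+30) is *ictal* iff it intersects a seizure interval
    [onset, offset). A non-ictal window is *peri-ictal* iff its start
    lies within ``horizon_s`` of the start of some ictal window
    (start-to-start distance, boundary inclusive). All remaining windows
    are *interictal*. Seizures entirely outside the recording are
    ignored with a warning. Returns an object array of labels aligned
    with the grid (invalid windows are still labelled; callers restrict
    to valid windows as needed).
    """
    starts = grid.window_starts
    ends = starts + grid.window_length_s
    labels = np.full(grid.n_windows, "interictal", dtype=object)
    rec_end = ends[-1] if len(ends) else 0.0
    ictal = np.zeros(grid.n_windows, dtype=bool)
    for onset, offset in zip(seizures.onsets_s, seizures.offsets_s):
        if offset <= starts[0] or onset >= rec_end:
            import warnings

            warnings.warn(f"seizure [{onset}, {offset}) outside recording; ignored")
            continue
        ictal |= (starts < offset) & (ends > onset)
    labels[ictal] = "ictal"
    if ictal.any():
        ictal_starts = starts[ictal]
        dist = np.min(np.abs(starts[:, None] - ictal_starts[None, :]), axis=1)
        peri = (dist <= horizon_s) & ~ictal
        labels[peri] = "peri-ictal"
    return labels


def alpha_delta_ratio(bp: RegionalBandPower) -> np.ndarray:
    """Regionally averaged alpha/delta ratio per window (NaN when invalid)."""
    ia = bp.band_names.index("alpha")
    id_ = bp.band_names.index("delta")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = bp.values[:, :, ia] / bp.values[:, :, id_]
    out = np.full(ratio.shape[0], np.nan)
    valid = bp.valid & np.isfinite(ratio).any(axis=1)
    out[valid] = np.nanmean(ratio[valid], axis=1)
    return out


def _fft_bandpass(x: np.ndarray, dt_s: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Exactly zero-phase band-pass by masking the real FFT spectrum."""
    n = x.size
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(n, d=dt_s)
    spec[(freqs < lo_hz) | (freqs > hi_hz)] = 0.0
    return np.fft.irfft(spec, n=n)


def circadian_phase(
    ratio: np.ndarray,
    window_length_s: float = 30.0,
    period_h: float = 24.0,
    method: str = "analytic",
) -> np.ndarray:
    """Instantaneous circadian phase of an alpha/delta ratio series.

    The series (one value per 30-s window; NaN gaps allowed) is linearly
    interpolated across gaps, band-pass filtered to 0.5-1.5 cycles per
    ``period_h`` with an exactly zero-phase FFT mask, and the phase taken
    from the analytic (Hilbert) signal. Phase convention: 0 at ratio
    maxima (wake-like), pi at minima (sleep-like); values in [-pi, pi).

    ``method="cosinor"`` instead fits a single cosine at the nominal
    period by least squares and returns its phase ramp.
    """
    x = np.asarray(ratio, dtype=float)
    n = x.size
    if n * window_length_s < period_h * 3600.0:
        raise ValueError("recording shorter than one circadian period; cycle unidentifiable")
    t = np.arange(n) * window_length_s
    good = np.isfinite(x)
    if good.sum() < 2:
        raise ValueError("too few finite ratio values")
    xi = np.interp(t, t[good], x[good])
    f0 = 1.0 / (period_h * 3600.0)
    if method == "cosinor":
        def resid(p):
            return p[0] + p[1] * np.cos(2 * np.pi * f0 * t - p[2]) - xi

        amp0 = (xi.max() - xi.min()) / 2
        fit = least_squares(resid, x0=[xi.mean(), max(amp0, 1e-12), 0.0])
        if abs(fit.x[1]) < 1e-12 * max(1.0, abs(fit.x[0])):
            raise ValueError("zero-amplitude circadian cycle; phase undefined")
        phase = 2 * np.pi * f0 * t - fit.x[2]
        if fit.x[1] < 0:
            phase += np.pi
        return np.angle(np.exp(1j * phase))
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")
    filt = _fft_bandpass(xi, window_length_s, 0.5 * f0, 1.5 * f0)
    rms = np.sqrt(np.mean(filt**2))
    if rms < 1e-12 * max(1.0, np.abs(xi).max()):
        raise ValueError("zero-amplitude circadian cycle; phase undefined")
    return np.angle(hilbert(filt))


def label_circadian(
    phase: np.ndarray, tolerance: float = CIRCADIAN_TOLERANCE_RAD
) -> np.ndarray:
    """Peak / trough / neither labels from circadian phase.

    Peak iff the circular distance of the phase to 0 is <= tolerance;
    trough iff the circular distance to pi is <= tolerance (both
    boundary inclusive).
    """
    p = np.asarray(phase, dtype=float)
    d_peak = np.abs(np.angle(np.exp(1j * p)))
    d_trough = np.abs(np.angle(np.exp(1j * (p - np.pi))))
    labels = np.full(p.shape, "neither", dtype=object)
    labels[d_peak <= tolerance] = "peak"
    labels[d_trough <= tolerance] = "trough"
    return labels


def window_label_frame(
    grid: WindowGrid,
    seizure_labels: np.ndarray | None = None,
    circadian_labels: np.ndarray | None = None,
    circadian_phase_rad: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the per-window label table used by patient summaries."""
    df = pd.DataFrame({"window_start_s": grid.window_starts, "valid": grid.valid})
    if seizure_labels is not None:
        df["seizure_label"] = seizure_labels
    if circadian_labels is not None:
        df["circadian_label"] = circadian_labels
    if circadian_phase_rad is not None:
        df["circadian_phase"] = circadian_phase_rad
    return df


def _sample_nonconsecutive(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Uniform k-subset of range(n) with no two adjacent indices.

    Uses the classical bijection between nonconsecutive k-subsets of
    [0, n) and arbitrary k-subsets of [0, n-k+1): draw the latter and
    add 0, 1, ..., k-1 to its sorted elements.
    """
    if n - k + 1 < k:
        raise ValueError(f"no nonconsecutive sample of size {k} from {n} windows")
    base = np.sort(rng.choice(n - k + 1, size=k, replace=False))
    return base + np.arange(k)


def subsample_drs(
    series: DrsSeries,
    k: int,
    mode: str = "random_nonconsecutive",
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Median D_RS estimated from k sampled windows, per repetition.

    Modes: ``random_nonconsecutive`` draws k windows uniformly without
    replacement subject to no two being adjacent in the series (when
    k > (n+1)//2 no such subset exists and the adjacency constraint is
    waived, so k = n degenerates to the full-series median);
    ``consecutive`` draws a uniformly placed run of k consecutive
    windows. Returns an array of ``n_reps`` median estimates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(series)
    if k > n:
        raise ValueError(f"k={k} exceeds available windows ({n})")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    out = np.empty(n_reps)
    if mode == "random_nonconsecutive":
        constrained = k <= (n + 1) // 2
        for r in range(n_reps):
            if constrained:
                idx = _sample_nonconsecutive(rng, n, k)
            else:
                idx = rng.choice(n, size=k, replace=False)
            out[r] = np.median(series.values[idx])
    elif mode == "consecutive":
        if n - k < 0:
            raise ValueError(f"no run of {k} consecutive windows")
        for r in range(n_reps):
            s = rng.integers(0, n - k + 1)
            out[r] = np.median(series.values[s : s + k])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def run_subsampling_experiment(
    patient_series: dict[str, DrsSeries],
    outcomes: dict[str, int],
    k_grid: tuple[int, ...] = (1, 5, 10, 30, 60, 120),
    modes: tuple[str, ...] = ("random_nonconsecutive", "consecutive"),
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Outcome AUC when every patient's D_RS is estimated from k windows.

    For each repetition and each k, one median-D_RS estimate is drawn per
    patient (independent draws, shared k and mode) and the cohort outcome
    AUC (ILAE>1 vs ILAE=1) recomputed. Returns a tidy frame with columns
    (k, mode, rep, auc).
    """
    ids = sorted(patient_series)
    good = [i for i in ids if outcomes[i] == 1]
    poor = [i for i in ids if outcomes[i] > 1]
    if len(good) < 2 or len(poor) < 2:
        raise ValueError("need at least 2 patients per outcome group")
    rng = np.random.default_rng(seed)
    rows = []
    for mode in modes:
        for k in k_grid:
            est = {i: subsample_drs(patient_series[i], k, mode, n_reps, rng) for i in ids}
            for rep in range(n_reps):
                auc = mann_whitney_auc(
                    np.array([est[i][rep] for i in poor]),
                    np.array([est[i][rep] for i in good]),
                )
                rows.append((k, mode, rep, auc))
    return pd.DataFrame(rows, columns=["k", "mode", "rep", "auc"])
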