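"""Synthetic iEEG cohorts with known ground truth.

Two fidelity tiers are provided. The *feature-level* tier generates
regional relative band-power compositions directly: a fixed synthetic
atlas assigns each region a logistic-normal distribution on the 5-band
simplex (Gaussian in 4-dimensional additive log-ratio coordinates with
gamma as the reference part, closed to sum to 1), and patients are
window-wise draws from those distributions with AR(1) temporal noise,
circadian alpha/delta modulation, injected abnormality offsets, Poisson
seizure schedules, and missing windows. The *signal-level* tier
synthesizes raw multichannel voltage traces whose per-band variances are
chosen so that the spectral pipeline recovers a target composition,
exercising preprocessing end to end (line noise and outlier channels
included).

Ground truth (which regions carry injected abnormality, seizure times,
circadian phase) is returned alongside every patient so downstream
recovery can be tested without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition
from .bandpower import RegionalBandPower
from .preprocess import WINDOW_LENGTH_S, Recording
from .temporal import SeizureTable

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PatientFeatures",
    "Atlas",
    "generate_normative_cohort",
    "generate_patient_features",
    "generate_patient_signal",
    "generate_surgical_cohort",
]

# ALR coordinate order: (delta, theta, alpha, beta) against the gamma reference
_ALR_ALPHA, _ALR_DELTA = 2, 0

# synthesized band components keep this many Hz clear of the band edges so
# spectral-edge energy cannot fall into a neighbouring band's integral
SYNTH_EDGE_MARGIN_HZ = 0.75


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic cohorts.

    Defaults reproduce the study composition: a 249-subject normative
    cohort and a 39-patient surgical cohort split 16 good (ILAE 1) / 23
    poor (ILAE 2-5), on a 128-region atlas. Effect sizes are in SD units
    of the region's normative spread; the AR(1) coefficient sets the
    lag-1 autocorrelation of the window-wise noise.
    """

    seed: int = 0
    n_normative_subjects: int = 249
    n_patients_good: int = 16
    n_patients_poor: int = 23
    n_regions: int = 128
    n_regions_covered_range: tuple[int, int] = (30, 60)
    n_resected_range: tuple[int, int] = (5, 12)
    recording_hours: float = 24.0
    effect_size_resected: float = 1.5
    effect_size_spared: float = 1.5
    circadian_amplitude: float = 0.4
    circadian_period_h: float = 24.0
    seizure_rate_per_day: float = 3.0
    seizure_duration_s: float = 60.0
    noise_ar1_coefficient: float = 0.5
    missing_fraction: float = 0.05

    def validate(self) -> None:
        if self.n_normative_subjects < 1 or self.n_patients_good < 1 or self.n_patients_poor < 1:
            raise ValueError("cohort sizes must be >= 1")
        if self.n_regions < 2:
            raise ValueError("need at least 2 atlas regions")
        lo, hi = self.n_regions_covered_range
        if not (1 <= lo <= hi <= self.n_regions):
            raise ValueError("coverage range must satisfy 1 <= lo <= hi <= n_regions")
        rlo, rhi = self.n_resected_range
        if not (1 <= rlo <= rhi < lo):
            # resected set must be a nonempty strict subset of covered regions
            raise ValueError("resected range must satisfy 1 <= lo <= hi < min covered")
        if not 0 <= self.noise_ar1_coefficient < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.effect_size_resected < 0 or self.effect_size_spared < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing fraction must lie in [0, 1)")
        if self.recording_hours <= 0 or self.circadian_period_h <= 0:
            raise ValueError("durations must be positive")
        if self.seizure_rate_per_day < 0 or self.seizure_duration_s <= 0:
            raise ValueError("seizure schedule parameters invalid")


@dataclass
class GroundTruth:
    """Per-patient generative truth, for recovery tests."""

    patient_id: str
    ilae_class: int
    resected_regions: list[str]
    abnormal_regions: list[str]
    effect_size: float
    seizure_onsets_s: list[float]
    seizure_offsets_s: list[float]
    circadian_phase0_rad: float
    circadian_period_h: float
    noisy_channels: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class PatientFeatures:
    """Feature-level synthetic patient: band powers plus context."""

    patient_id: str
    bandpower: RegionalBandPower
    resected: dict[str, bool]  # per covered region
    seizures: SeizureTable
    truth: GroundTruth


class Atlas:
    """Fixed synthetic atlas of named regions with logistic-normal parameters.

    Each region i carries an ALR-space mean vector m_i (4-dim) and a
    scalar spread s_i; subjects and patient windows covering the region
    draw ALR coordinates m_i + s_i * noise and close them onto the
    simplex. The atlas is a deterministic function of (n_regions, seed),
    so a normative cohort and the patients scored against it share the
    same regional distributions.
    """

    def __init__(self, n_regions: int = 128, seed: int = 0):
        self.n_regions = n_regions
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA71A5]))
        self.region_ids = [f"region_{i:03d}" for i in range(n_regions)]
        # mild regional heterogeneity around a delta-dominant baseline typical
        # of filtered iEEG band-power compositions
        base = np.array([0.9, 0.3, 0.1, -0.1])
        self.alr_mean = base + rng.normal(0.0, 0.35, size=(n_regions, 4))
        self.alr_scale = rng.uniform(0.15, 0.35, size=n_regions)

    def close(self, alr: np.ndarray) -> np.ndarray:
        """Map ALR coordinates (..., 4) to 5-part compositions (..., 5)."""
        x = np.concatenate([alr, np.zeros(alr.shape[:-1] + (1,))], axis=-1)
        x = x - x.max(axis=-1, keepdims=True)
        p = np.exp(x)
        p /= p.sum(axis=-1, keepdims=True)
        p[..., -1] = 1.0 - p[..., :-1].sum(axis=-1)  # exact closure
        return p


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def generate_normative_cohort(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject region-level compositions for the normative cohort.

    Each subject covers a random subset of atlas regions and contributes
    one 5-band composition per covered region. Returns the long cohort
    table (subject_id, region_id, five band columns) and the per-region
    coverage counts.
    """
    spec.validate()
    atlas = Atlas(spec.n_regions, spec.seed)
    rng = _spawn(spec.seed, 1)
    lo, hi = spec.n_regions_covered_range
    rows_subject, rows_region, comps = [], [], []
    for s in range(spec.n_normative_subjects):
        n_cov = int(rng.integers(lo, hi + 1))
        covered = np.sort(rng.choice(spec.n_regions, size=n_cov, replace=False))
        alr = atlas.alr_mean[covered] + atlas.alr_scale[covered, None] * rng.standard_normal(
            (n_cov, 4)
        )
        comps.append(atlas.close(alr))
        rows_subject.extend([f"subject_{s:03d}"] * n_cov)
        rows_region.extend(atlas.region_ids[i] for i in covered)
    values = np.concatenate(comps, axis=0)
    cohort = pd.DataFrame({"subject_id": rows_subject, "region_id": rows_region})
    for j, b in enumerate(BAND_NAMES):
        cohort[b] = values[:, j]
    coverage = cohort.groupby("region_id")["subject_id"].nunique()
    return cohort, coverage


def _ar1_noise(rng: np.random.Generator, phi: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with unit marginal variance."""
    eps = rng.standard_normal(shape)
    innov = eps * np.sqrt(1.0 - phi**2)
    innov[0] = eps[0]  # stationary start
    return sps.lfilter([1.0], [1.0, -phi], innov, axis=0)


def _poisson_seizures(
    rng: np.random.Generator, rate_per_day: float, duration_s: float, total_s: float
) -> SeizureTable:
    """Homogeneous Poisson seizure schedule, overlaps dropped."""
    n = rng.poisson(rate_per_day * total_s / 86400.0)
    onsets = np.sort(rng.uniform(0.0, max(total_s - duration_s, 0.0), size=n))
    keep_on, keep_off = [], []
    last_end = -np.inf
    for on in onsets:
        if on >= last_end:
            keep_on.append(on)
            keep_off.append(on + duration_s)
            last_end = on + duration_s
    return SeizureTable(np.array(keep_on), np.array(keep_off))


def _select_regions(
    spec: SyntheticSpec, outcome: str, rng: np.random.Generator, overlap_fraction: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covered regions, resected subset, abnormal subset (atlas indices)."""
    lo, hi = spec.n_regions_covered_range
    n_cov = int(rng.integers(lo, hi + 1))
    covered = np.sort(rng.choice(spec.n_regions, size=n_cov, replace=False))
    rlo, rhi = spec.n_resected_range
    n_res = int(rng.integers(rlo, min(rhi, n_cov - 1) + 1))
    res_pos = rng.choice(n_cov, size=n_res, replace=False)
    resected = covered[np.sort(res_pos)]
    spared = np.setdiff1d(covered, resected)
    if outcome == "good":
        abnormal = resected
    else:
        n_from_res = int(round(overlap_fraction * n_res))
        n_from_spa = min(n_res - n_from_res, spared.size)
        pick_spa = rng.choice(spared, size=n_from_spa, replace=False)
        pick_res = (
            rng.choice(resected, size=n_from_res, replace=False)
            if n_from_res
            else np.array([], dtype=int)
        )
        abnormal = np.sort(np.concatenate([pick_spa, pick_res]))
    return covered, resected, abnormal


def generate_patient_features(
    spec: SyntheticSpec,
    outcome: str,
    seed: int,
    patient_id: str | None = None,
    overlap_fraction: float = 0.0,
) -> PatientFeatures:
    """One surgical patient at feature level.

    Window-wise regional compositions are logistic-normal draws around
    the region's normative mean with AR(1) noise; abnormality offsets of
    ``effect_size_resected`` SD (good outcome, on resected regions) or
    ``effect_size_spared`` SD (poor outcome, on an equally sized spared
    subset; ``overlap_fraction`` moves part of it into the resection)
    along a random fixed ALR direction; circadian modulation raises the
    alpha/delta log-ratio at the cycle peak and lowers it at the trough.
    Seizure schedules are Poisson; a fraction of windows is flagged
    missing.
    """
    if outcome not in ("good", "poor"):
        raise ValueError("outcome must be 'good' or 'poor'")
    spec.validate()
    atlas = Atlas(spec.n_regions, spec.seed)
    rng = _spawn(spec.seed, 2, int(seed))
    pid = patient_id or f"patient_{outcome}_{seed:03d}"

    covered, resected, abnormal = _select_regions(spec, outcome, rng, overlap_fraction)
    n_cov = covered.size
    effect = spec.effect_size_resected if outcome == "good" else spec.effect_size_spared

    n_win = int(spec.recording_hours * 3600.0 // WINDOW_LENGTH_S)
    starts = np.arange(n_win) * WINDOW_LENGTH_S

    m = atlas.alr_mean[covered]  # (n_cov, 4)
    s = atlas.alr_scale[covered]  # (n_cov,)
    noise = _ar1_noise(rng, spec.noise_ar1_coefficient, (n_win, n_cov, 4))
    alr = m[None, :, :] + s[None, :, None] * noise

    # abnormality offsets: fixed random unit direction per abnormal region
    offsets = np.zeros((n_cov, 4))
    abnormal_pos = np.nonzero(np.isin(covered, abnormal))[0]
    for i in abnormal_pos:
        u = rng.standard_normal(4)
        u /= np.linalg.norm(u)
        offsets[i] = effect * s[i] * u
    alr += offsets[None, :, :]

    # circadian modulation of the alpha/delta log-ratio
    phase0 = float(rng.uniform(0.0, 2.0 * np.pi))
    phase = 2.0 * np.pi * starts / (spec.circadian_period_h * 3600.0) - phase0
    c = spec.circadian_amplitude * np.cos(phase)
    alr[:, :, _ALR_ALPHA] += c[:, None] / 2.0
    alr[:, :, _ALR_DELTA] -= c[:, None] / 2.0

    values = atlas.close(alr)
    valid = rng.random(n_win) >= spec.missing_fraction
    values[~valid] = np.nan

    seizures = _poisson_seizures(
        rng, spec.seizure_rate_per_day, spec.seizure_duration_s, spec.recording_hours * 3600.0
    )
    ilae = 1 if outcome == "good" else int(rng.integers(2, 6))
    region_ids = [atlas.region_ids[i] for i in covered]
    truth = GroundTruth(
        patient_id=pid,
        ilae_class=ilae,
        resected_regions=[atlas.region_ids[i] for i in resected],
        abnormal_regions=[atlas.region_ids[i] for i in abnormal],
        effect_size=effect,
        seizure_onsets_s=seizures.onsets_s.tolist(),
        seizure_offsets_s=seizures.offsets_s.tolist(),
        circadian_phase0_rad=phase0,
        circadian_period_h=spec.circadian_period_h,
    )
    bp = RegionalBandPower(
        values=values, region_ids=region_ids, window_starts=starts, valid=valid
    )
    res_set = set(truth.resected_regions)
    return PatientFeatures(
        patient_id=pid,
        bandpower=bp,
        resected={r: r in res_set for r in region_ids},
        seizures=seizures,
        truth=truth,
    )


def generate_surgical_cohort(
    spec: SyntheticSpec, overlap_fraction: float = 0.0
) -> list[PatientFeatures]:
    """The full surgical cohort (good then poor patients), feature level."""
    patients = []
    for j in range(spec.n_patients_good):
        patients.append(
            generate_patient_features(
                spec, "good", seed=j, patient_id=f"patient_{j:03d}", overlap_fraction=overlap_fraction
            )
        )
    for j in range(spec.n_patients_poor):
        patients.append(
            generate_patient_features(
                spec,
                "poor",
                seed=spec.n_patients_good + j,
                patient_id=f"patient_{spec.n_patients_good + j:03d}",
                overlap_fraction=overlap_fraction,
            )
        )
    return patients


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float, target_std: float
) -> np.ndarray:
    """Gaussian noise confined to [lo, hi] Hz with a target SD.

    White noise is masked in the frequency domain (ideal band-pass) so
    the realised power lands entirely inside the band; a causal filter's
    skirts would otherwise leak across bands whose target powers differ
    by orders of magnitude.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y * (target_std / sd) if sd > 0 else y


def _composite_bandlimited(
    rng: np.random.Generator, n: int, fs: float, targets: list[tuple[float, float, float]]
) -> np.ndarray:
    """Sum of disjoint band-limited Gaussian components, one FFT pair.

    ``targets`` lists (lo_hz, hi_hz, target_std). Sub-band coefficient
    blocks of a single white-noise spectrum are rescaled so each block's
    exact time-domain variance (components are orthogonal by disjoint
    support) matches its target; everything outside the bands is zeroed.
    """
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = np.zeros(freqs.size, dtype=bool)
    for lo, hi, std in targets:
        sel = (freqs >= lo) & (freqs < hi)
        power = 2.0 * np.sum(np.abs(spec[sel]) ** 2) / n**2
        if power > 0:
            spec[sel] *= std / np.sqrt(power)
        keep |= sel
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n)


def generate_patient_signal(
    spec: SyntheticSpec,
    outcome: str,
    seed: int,
    fs: float = 512.0,
    n_signal_regions: int = 10,
    channels_per_region: int = 2,
    n_noisy_channels: int = 1,
    line_hz: float = 50.0,
    line_amplitude_uv: float = 20.0,
    log_power_scale: float = 25.0,
    bands: BandDefinition = DEFAULT_BANDS,
    patient_id: str | None = None,
) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """One surgical patient as a raw multichannel voltage recording.

    Each channel is a sum of band-limited Gaussian noise components
    whose variances realise the channel's region-target composition v:
    band powers are set to p_f = exp(L * v_f) microvolts-squared
    (L = ``log_power_scale``), so the spectral pipeline's
    log-then-normalise step recovers v up to estimation error. A line
    sinusoid at ``line_hz`` is injected into every channel, and
    ``n_noisy_channels`` channels are scaled x50 to exercise outlier
    channel detection.

    Returns the Recording, a channel-metadata table (channel_id,
    region_id, resected, bad, normative_eligible), and the ground truth.
    """
    if fs < 160:
        raise ValueError("sampling rate below 160 Hz cannot observe the 77.5 Hz gamma edge")
    if outcome not in ("good", "poor"):
        raise ValueError("outcome must be 'good' or 'poor'")
    if channels_per_region < 1:
        raise ValueError("need at least one channel per region")
    spec.validate()
    atlas = Atlas(spec.n_regions, spec.seed)
    rng = _spawn(spec.seed, 3, int(seed))
    pid = patient_id or f"patient_sig_{outcome}_{seed:03d}"

    n_cov = min(n_signal_regions, spec.n_regions - 1)
    covered = np.sort(rng.choice(spec.n_regions, size=n_cov, replace=False))
    n_res = max(1, min(int(rng.integers(*spec.n_resected_range)), n_cov - 1))
    resected = np.sort(rng.choice(covered, size=n_res, replace=False))
    spared = np.setdiff1d(covered, resected)
    effect = spec.effect_size_resected if outcome == "good" else spec.effect_size_spared
    if outcome == "good":
        abnormal = resected
    else:
        abnormal = np.sort(rng.choice(spared, size=min(n_res, spared.size), replace=False))

    # static region targets: normative mean ALR plus the abnormality offset
    targets = {}
    for i, reg in enumerate(covered):
        alr = atlas.alr_mean[reg].copy()
        if reg in abnormal:
            u = rng.standard_normal(4)
            u /= np.linalg.norm(u)
            alr += effect * atlas.alr_scale[reg] * u
        targets[reg] = atlas.close(alr[None, :])[0]

    n = int(round(spec.recording_hours * 3600.0 * fs))
    sub_intervals = [
        (name, lo, hi, (hi - lo) / bands.bandwidth(name))
        for name, ivs in bands.bands.items()
        for lo, hi in ivs
    ]
    band_index = {b: j for j, b in enumerate(BAND_NAMES)}

    channel_ids, regions_col, data = [], [], []
    for reg in covered:
        p = np.exp(log_power_scale * targets[reg])  # uV^2 per band
        for c in range(channels_per_region):
            m = SYNTH_EDGE_MARGIN_HZ
            targets_ch = [
                (lo + m, hi - m, np.sqrt(p[band_index[bname]] * share))
                for bname, lo, hi, share in sub_intervals
            ]
            trace = _composite_bandlimited(rng, n, fs, targets_ch)
            trace += line_amplitude_uv * np.sin(
                2 * np.pi * line_hz * np.arange(n) / fs + rng.uniform(0, 2 * np.pi)
            )
            channel_ids.append(f"{atlas.region_ids[reg]}_ch{c}")
            regions_col.append(atlas.region_ids[reg])
            data.append(trace)
    data = np.array(data)

    noisy = sorted(rng.choice(len(channel_ids), size=min(n_noisy_channels, len(channel_ids)), replace=False))
    for idx in noisy:
        data[idx] *= 50.0

    # window-level missingness expressed as a per-sample mask
    win = int(round(WINDOW_LENGTH_S * fs))
    n_win = n // win
    missing = np.zeros(n, dtype=bool)
    drop = rng.random(n_win) < spec.missing_fraction
    for t in np.nonzero(drop)[0]:
        missing[t * win : (t + 1) * win] = True

    seizures = _poisson_seizures(
        rng, spec.seizure_rate_per_day, spec.seizure_duration_s, spec.recording_hours * 3600.0
    )
    ilae = 1 if outcome == "good" else int(rng.integers(2, 6))
    res_names = {atlas.region_ids[r] for r in resected}
    abn_names = {atlas.region_ids[r] for r in abnormal}
    meta = pd.DataFrame(
        {
            "channel_id": channel_ids,
            "region_id": regions_col,
            "resected": [int(r in res_names) for r in regions_col],
            "bad": 0,
            "normative_eligible": [int(r not in abn_names) for r in regions_col],
        }
    )
    truth = GroundTruth(
        patient_id=pid,
        ilae_class=ilae,
        resected_regions=sorted(res_names),
        abnormal_regions=sorted(abn_names),
        effect_size=effect,
        seizure_onsets_s=seizures.onsets_s.tolist(),
        seizure_offsets_s=seizures.offsets_s.tolist(),
        circadian_phase0_rad=0.0,
        circadian_period_h=spec.circadian_period_h,
        noisy_channels=[channel_ids[i] for i in noisy],
    )
    rec = Recording(
        channel_ids=channel_ids, fs=float(fs), data=data, start_time=0.0, missing_mask=missing
    )
    return rec, meta, truth
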