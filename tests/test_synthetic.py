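"""Synthetic cohort generator: determinism, composition closure, ground-
truth recovery, seizure schedules, circadian structure, and the
signal-level tier."""

import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from abnmap import (
    SyntheticSpec,
    apply_filters,
    build_normative_map,
    compute_psd,
    detect_bad_channels,
    drs_timeseries,
    generate_normative_cohort,
    generate_patient_features,
    generate_patient_signal,
    integrate_band_power,
    relative_log_band_power,
    score_patient,
)
from abnmap.bands import BAND_NAMES
from abnmap.temporal import alpha_delta_ratio


@pytest.fixture(scope="module")
def spec():
    return SyntheticSpec(
        seed=7,
        n_normative_subjects=40,
        n_regions=24,
        n_regions_covered_range=(12, 18),
        n_resected_range=(3, 5),
        recording_hours=0.5,
        missing_fraction=0.0,
    )


@pytest.fixture(scope="module")
def nmap(spec):
    cohort, _ = generate_normative_cohort(spec)
    return build_normative_map(cohort, min_subjects=5)


def _median_drs(spec, outcome, seed, nmap):
    pat = generate_patient_features(spec, outcome, seed=seed)
    abnorm = score_patient(pat.bandpower, nmap)
    series = drs_timeseries(abnorm, {r: pat.resected[r] for r in abnorm.region_ids})
    return np.median(series.values), series


class TestNormativeCohort:
    def test_default_conditions_satisfy_coverage_rule(self):
        cohort, coverage = generate_normative_cohort(SyntheticSpec())
        assert cohort["subject_id"].nunique() == 249
        assert (coverage >= 5).all()

    def test_single_subject_cohort_retains_zero_regions_downstream(self):
        s = SyntheticSpec(
            n_normative_subjects=1, n_regions=24, n_regions_covered_range=(12, 18),
            n_resected_range=(3, 5),
        )
        cohort, coverage = generate_normative_cohort(s)
        assert (coverage == 1).all()
        with pytest.raises(ValueError):
            build_normative_map(cohort, min_subjects=5)

    def test_deterministic_under_fixed_seed(self, spec):
        a, _ = generate_normative_cohort(spec)
        b, _ = generate_normative_cohort(spec)
        assert a.equals(b)

    def test_composition_closure(self, spec):
        cohort, _ = generate_normative_cohort(spec)
        sums = cohort[list(BAND_NAMES)].sum(axis=1)
        assert np.abs(sums - 1.0).max() < 1e-9

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_normative_cohort(SyntheticSpec(n_regions_covered_range=(0, 0)))
        with pytest.raises(ValueError):
            SyntheticSpec(noise_ar1_coefficient=1.0).validate()
        with pytest.raises(ValueError):
            SyntheticSpec(effect_size_resected=-1.0).validate()
        with pytest.raises(ValueError):
            # resected range not a strict subset of minimum coverage
            SyntheticSpec(n_regions_covered_range=(5, 10), n_resected_range=(5, 6)).validate()


class TestPatientFeatures:
    def test_deterministic_and_closed(self, spec):
        a = generate_patient_features(spec, "good", seed=3)
        b = generate_patient_features(spec, "good", seed=3)
        assert np.array_equal(a.bandpower.values, b.bandpower.values, equal_nan=True)
        sums = a.bandpower.values.sum(axis=2)
        assert np.nanmax(np.abs(sums - 1.0)) < 1e-9

    def test_resected_set_is_strict_subset_and_truth_consistent(self, spec):
        pat = generate_patient_features(spec, "poor", seed=5)
        res = [r for r, f in pat.resected.items() if f]
        assert 0 < len(res) < len(pat.resected)
        assert set(res) == set(pat.truth.resected_regions)
        # poor outcome: abnormality injected on spared regions only (no overlap)
        assert not set(pat.truth.abnormal_regions) & set(res)

    def test_null_effect_gives_drs_near_half(self, spec, nmap):
        null = dataclasses.replace(spec, effect_size_resected=0.0, effect_size_spared=0.0)
        meds = [_median_drs(null, "good", s, nmap)[0] for s in range(8)]
        assert abs(np.mean(meds) - 0.5) < 0.1

    def test_good_outcome_effect2_median_below_half(self, spec, nmap):
        strong = dataclasses.replace(spec, effect_size_resected=2.0)
        meds = np.array([_median_drs(strong, "good", s, nmap)[0] for s in range(50)])
        assert np.mean(meds < 0.5) >= 0.9

    def test_effect_monotonicity_of_mean_drs(self, spec, nmap):
        """Mean windowwise D_RS of good-outcome patients decreases with effect size."""
        means = []
        for eff in (0.0, 0.5, 1.0, 2.0):
            sp = dataclasses.replace(spec, effect_size_resected=eff)
            vals = [np.mean(_median_drs(sp, "good", s, nmap)[1].values) for s in range(50)]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_seizure_rate_within_three_standard_errors(self):
        s = SyntheticSpec(
            n_regions=8, n_regions_covered_range=(4, 6), n_resected_range=(1, 2),
            recording_hours=240.0, seizure_rate_per_day=4.0, missing_fraction=0.0,
        )
        pat = generate_patient_features(s, "good", seed=0)
        expected = 4.0 * 10.0
        assert abs(len(pat.seizures) - expected) <= 3 * np.sqrt(expected)

    def test_seizures_disjoint_and_inside_recording(self, spec):
        pat = generate_patient_features(spec, "poor", seed=9)
        on, off = pat.seizures.onsets_s, pat.seizures.offsets_s
        assert np.all(off[:-1] <= on[1:]) if len(on) > 1 else True
        if len(on):
            assert on.min() >= 0 and off.max() <= spec.recording_hours * 3600.0

    def test_missing_fraction_flags_windows(self, spec):
        s = dataclasses.replace(spec, missing_fraction=0.3)
        pat = generate_patient_features(s, "good", seed=2)
        frac = 1.0 - pat.bandpower.valid.mean()
        assert 0.15 < frac < 0.45
        assert np.all(np.isnan(pat.bandpower.values[~pat.bandpower.valid]))


class TestCircadianStructure:
    def _ratio_spectrum(self, amplitude, hours=72.0):
        s = SyntheticSpec(
            seed=11, n_regions=12, n_regions_covered_range=(6, 9), n_resected_range=(1, 3),
            recording_hours=hours, circadian_amplitude=amplitude, missing_fraction=0.0,
        )
        pat = generate_patient_features(s, "good", seed=1)
        ratio = alpha_delta_ratio(pat.bandpower)
        f, p = sps.periodogram(ratio - ratio.mean(), fs=1 / 30.0)
        f_circ = 1.0 / 86400.0
        band = (f > 0.5 * f_circ) & (f < 1.5 * f_circ)
        noise_floor = np.median(p[f > 10 * f_circ])
        return p[band].max() / noise_floor

    def test_zero_amplitude_has_no_daily_peak(self):
        assert self._ratio_spectrum(0.0) < 50.0

    def test_default_amplitude_produces_daily_peak(self):
        assert self._ratio_spectrum(0.4) > 1e3


@pytest.fixture(scope="module")
def sig():
    spec = SyntheticSpec(
        seed=3, n_regions=16, n_regions_covered_range=(8, 10), n_resected_range=(2, 3),
        recording_hours=2 * 30.0 / 3600.0,  # two 30-s windows
        missing_fraction=0.0, seizure_rate_per_day=0.0,
    )
    return generate_patient_signal(
        spec, "good", seed=0, fs=200.0, n_signal_regions=5, channels_per_region=2,
        n_noisy_channels=1,
    )


class TestSignalLevel:
    def test_low_sampling_rate_rejected(self, spec):
        with pytest.raises(ValueError):
            generate_patient_signal(spec, "good", seed=0, fs=128.0)

    def test_alpha_dominant_target_recovered_through_pipeline(self):
        """A synthesised channel with alpha-dominant target composition yields
        alpha as the largest relative log band power after PSD + Simpson."""
        from abnmap.synthetic import SYNTH_EDGE_MARGIN_HZ, _bandlimited_noise
        from abnmap.bands import DEFAULT_BANDS

        rng = np.random.default_rng(0)
        target = np.array([0.15, 0.15, 0.40, 0.15, 0.15])  # relative log powers
        p = np.exp(25.0 * target)
        fs, n = 200.0, 6000
        m = SYNTH_EDGE_MARGIN_HZ
        trace = np.zeros(n)
        for j, (name, ivs) in enumerate(DEFAULT_BANDS.bands.items()):
            for lo, hi in ivs:
                share = (hi - lo) / DEFAULT_BANDS.bandwidth(name)
                trace += _bandlimited_noise(rng, n, fs, lo + m, hi - m, np.sqrt(p[j] * share))
        v = relative_log_band_power(integrate_band_power(compute_psd(trace)))
        assert np.argmax(v) == 2
        assert np.abs(v - target).max() < 0.05

    def test_notch_suppresses_injected_line_by_40_db(self, sig):
        rec, meta, truth = sig
        clean_idx = [i for i, c in enumerate(rec.channel_ids) if c not in truth.noisy_channels][0]
        filtered = apply_filters(rec, line_hz=50.0)
        f, p_before = sps.welch(rec.data[clean_idx], fs=rec.fs, nperseg=400)
        _, p_after = sps.welch(filtered.data[clean_idx], fs=rec.fs, nperseg=400)
        i50 = np.argmin(np.abs(f - 50.0))
        assert 10 * np.log10(p_before[i50] / p_after[i50]) >= 40.0

    def test_scaled_channel_flagged_bad(self, sig):
        rec, meta, truth = sig
        flagged = detect_bad_channels(rec)
        assert set(truth.noisy_channels) <= flagged

    def test_metadata_schema_and_resection_flags(self, sig):
        rec, meta, truth = sig
        assert list(meta.columns) == [
            "channel_id", "region_id", "resected", "bad", "normative_eligible",
        ]
        assert set(meta.loc[meta["resected"] == 1, "region_id"]) == set(truth.resected_regions)
        assert len(meta) == len(rec.channel_ids)
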