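# Methods

## Pipeline

The analysis chain is: (1) preprocess a continuous multichannel iEEG
recording; (2) reduce each 30-s window to a five-band *relative log band
power* composition per atlas region; (3) z-score each region's
composition against a normative map and collapse to a scalar abnormality
per region and window (maximum absolute z across bands); (4) summarise
each window by D_RS, the rank-based AUC separating resected from spared
regions by abnormality; (5) relate per-patient median D_RS to surgical
outcome, stratified by seizure proximity and circadian phase; and
(6) quantify how estimates degrade when D_RS is computed from only k
sampled windows.

### Preprocessing

Order: bad-channel detection → common-average reference (CAR) → 50/60 Hz
notch → 0.5–80 Hz band-pass → polyphase downsampling to 200 Hz → 30-s
half-open windows [t, t+30) cut from t = 0 on the downsampled record.
Filters are 4th-order Butterworth designs applied forward–backward
(`sosfiltfilt`), so the chain is zero-phase; the notch is a band-stop of
2 Hz total width centred on the line frequency (a configuration flag:
50 Hz by default, 60 Hz for recordings from 60 Hz mains regions).
Filtering is applied to the continuous record rather than per window so
window edges carry no filter transients. CAR is pointwise-linear across
channels and therefore commutes exactly with per-channel LTI filtering;
referencing continuously or per window yields the same windows, which
resolves an otherwise ambiguous ordering choice. A trailing partial
window is discarded, and any window intersecting missing samples is
invalid and carries no downstream values.

Bad channels: per 30-s window the amplitude range (99th − 1st percentile)
of each channel is compared across channels; a channel strictly outside
median ± 3·IQR in any window, or flat anywhere, is excluded from the
reference and from region aggregation. The rule is scale-free and
deterministic; the 3·IQR fence is conventional for robust outlier
screening. With fewer than 4 channels the screen is skipped (a warning),
since the fence is meaningless on tiny samples.

### Spectral features

Welch PSD per channel and 30-s window: fifteen 2-s non-overlapping
segments, Hann taper, density scaling, 0.5 Hz resolution. Band powers by
Simpson's rule over delta 1–4, theta 4–8, alpha 8–13, beta 13–30, and
gamma 30–47.5 ∪ 52.5–57.5 ∪ 62.5–77.5 Hz (the gamma gaps avoid mains
interference at 50/60 Hz); at the default grid every edge lands on a
bin, and off-grid edges are linearly interpolated before integrating.
The five log band powers are normalised to sum to 1:
v_f = log p_f / Σ_g log p_g, with the last component computed as one
minus the partial sum so closure is exact. The ratio cancels the
logarithm base (tested). When the log-sum is within 1e-6·max|log p| of
zero the normalisation is degenerate and an error is raised rather than
returning an arbitrarily amplified composition. An alternative reading
of the transform — L1-normalise the powers, then log — is available as
`relative_mode="normalize_then_log"`; the default follows the
log-then-normalise convention. Region values are the unweighted mean of
the region's non-bad channels; the mean of sum-to-1 vectors again sums
to 1.

### Normative map and abnormality

Per region and band, the map stores the mean and sample SD (n − 1
denominator, the standard unbiased-variance convention for cohort
statistics) of region-level compositions across subjects. Regions
covered by fewer than 5 subjects are dropped, as are regions with a
degenerate zero SD; patients' regions missing from the map are dropped
from analysis, not imputed. Abnormality is max_f |z_f| — sensitive to a
deviation in any single band, in either direction. Window-normalised
abnormality (regions summing to 1) is provided for display; D_RS is
rank-based and identical on raw and normalised values.

### D_RS and outcome evaluation

D_RS is the Mann–Whitney AUC with spared regions as the positive class,
computed from midranks, so ties receive half credit; values below .5
indicate abnormality concentrated in resected tissue. A region counts as
resected when strictly more than 25% of its contacts were removed.
Windows lacking either class are excluded; a patient with no computable
window is unevaluable. The *localizing percentage* is the share of
windows with D_RS ≤ .5 (boundary inclusive). Outcome discrimination
uses each patient's median D_RS (overall, or within a condition such as
interictal) as a score for not-seizure-free (ILAE > 1) vs seizure-free
(ILAE 1): AUC with midrank tie handling, a one-sided Wilcoxon rank-sum
test (exact distribution when both groups have ≤ 10 patients and no
ties, otherwise normal approximation with continuity correction), and
one-sided signed-rank tests of each group's medians against .5. When
every difference from .5 is exactly zero the signed-rank test carries no
information and p = 1 is reported.

### Temporal structure

A window is *ictal* iff its half-open interval intersects a seizure
interval [onset, offset); *peri-ictal* iff not ictal and its start lies
within 1 h of the start of some ictal window (start-to-start distance,
boundary inclusive — the convention under which a 60-s seizure at
t = 7200 s in a 4-h recording yields exactly 2 ictal, 240 peri-ictal and
238 interictal windows); all remaining windows are *interictal*. The
labels partition the grid by construction.

Circadian phase is extracted from the regionally averaged alpha/delta
ratio per window: gaps are linearly interpolated, the series band-passed
to 0.5–1.5 cycles/day with an FFT mask (exactly zero-phase; an IIR
design at ~10⁻⁵ of the 1/30 Hz sampling rate is numerically fragile),
and the instantaneous phase taken from the analytic (Hilbert) signal,
with 0 at ratio maxima (wake-like) and π at minima (sleep-like). A
single-cosine least-squares fit is available as `method="cosinor"`.
Windows within π/4 of phase 0 are labelled *peak*, within π/4 of π
*trough* (boundaries inclusive). At least one full period of data is
required; a zero-amplitude cycle raises an error rather than returning
meaningless phases.

### Subsampling experiment

`subsample_drs` estimates a patient's median D_RS from k windows, either
a uniformly placed run of k consecutive windows or k windows drawn
uniformly among adjacency-free subsets (sampled exactly via the
bijection between adjacency-free k-subsets of n slots and arbitrary
k-subsets of n − k + 1; when k > (n+1)/2 no adjacency-free subset exists
and the constraint is waived, so k = n returns the full-series median).
The cohort-level experiment redraws every patient's estimate per
repetition and recomputes the outcome AUC, giving an AUC distribution
per (k, mode). The default grid {1, 5, 10, 30, 60, 120} brackets the
regime where random sampling saturates.

## Synthetic cohorts

Feature-level generation works on the 5-part band-power simplex. A fixed
synthetic atlas (deterministic in the generator seed; 128 regions by
default, matching a scale-60 cortical/subcortical parcellation count)
assigns each region a logistic-normal distribution: Gaussian coordinates
in 4-dimensional additive log-ratio (ALR) space with gamma as reference
(mean m_i, scalar spread s_i ∈ [0.15, 0.35]), closed through softmax so
every generated vector is positive and sums to 1 exactly. Normative
subjects each cover a random subset of regions (30–60 of 128) and draw
one composition per covered region; patients draw one composition per
window with AR(1) noise (u_t = φu_{t−1} + √(1−φ²)ε_t, unit marginal
variance, lag-1 coefficient φ = 0.5 by default — within-patient temporal
autocorrelation is a free parameter of the generator, not an estimate).
Because patient windows are drawn from the same regional distributions
the cohort was, z-scores of unperturbed regions are approximately
standard normal and the null D_RS sits at .5.

Abnormality is injected as a fixed ALR offset of (effect size)·s_i along
a random unit direction: onto the resected regions for good-outcome
patients and onto an equally sized spared subset for poor-outcome
patients (an `overlap_fraction` parameter moves part of that subset into
the resection for mixture cases). The default effect is 1.5 SD — the
regime in which the cohort-level outcome AUC is reliably recovered while
window-level D_RS still fluctuates visibly. Circadian modulation adds
±c(t)/2 to the alpha and delta ALR coordinates with
c(t) = A·cos(2πt/T − φ₀), A = 0.4 log-ratio units and T = 24 h by
default, which raises the alpha/delta ratio at the cycle peak and lowers
it at the trough. Seizure onsets follow a homogeneous Poisson process
(3/day, 60-s events; overlapping draws are dropped so intervals are
disjoint), and 5% of windows are flagged missing. Default cohort
composition is 16 good / 23 poor patients and a 249-subject normative
cohort; the default recording length is 24 h (one full circadian
period), with multi-day recordings available by parameter.

Signal-level generation synthesises each channel as a sum of
band-limited Gaussian components realised by masking white noise in the
frequency domain and scaling each sub-band block so its exact
time-domain variance equals p_f = exp(L·v_f), where v is the channel's
region-target composition and L = 25 sets the overall power scale
(~10²–10⁴ µV², a plausible iEEG range). Components keep 0.75 Hz clear of
band edges so spectral-edge energy cannot leak into a neighbouring
band's integral. A 50 Hz line sinusoid (20 µV) is injected into every
channel, and a configurable number of channels is scaled ×50 to exercise
outlier detection. Brick-wall masking (rather than a causal filter) is
what makes the per-band variances analytically exact; a 4th-order
filter's skirts would leak across bands whose targets differ by orders
of magnitude.

What the generator does *not* emulate: 1/f spectral slope and its
regional gradients, ictal waveform morphology, spikes and high-frequency
oscillations, volume conduction and montage correlations between
channels, state-dependent (sleep) band-power changes beyond the single
sinusoidal alpha/delta cycle, subject-level offsets within patients
(windows fluctuate around the regional mean, so patients are stationary
by construction), and non-stationary seizure clustering. Passing
recovery tests on these cohorts therefore demonstrates correctness of
the statistical machinery under its own assumptions, not clinical
performance on real recordings — in particular, the stationarity of the
generator is what makes interictal and peri-ictal medians agree, so the
corresponding test checks internal consistency, not a biological
finding.

## Numerical choices

- Composition closure is enforced exactly (last component = 1 − partial
  sum); closure invariants are asserted at 1e-9.
- Welch taper: Hann with density scaling (segment length and non-overlap
  are fixed by convention; the taper is the package's choice).
- Logarithm base: natural; immaterial by the base-invariance property.
- Downsampling: `resample_poly` with its Kaiser-windowed anti-aliasing
  FIR; the rational factor is taken from the exact rate ratio.
- Missing data propagate as window invalidity, never as imputation.
- All randomness flows from `numpy.random.SeedSequence`; identical
  spec + seed is bit-reproducible, and the workbench manifest records a
  SHA-256 of the resolved configuration plus per-file checksums (the
  output directory is excluded from the hash so relocating a run does
  not change its identity).

## Problem sizes

Unit and property tests run on scaled-down conditions (20–40 subjects,
12–24 regions, 0.5–2 h recordings). The acceptance suite uses the full
cohort composition (16/23, 249 subjects, 128 regions) with 2-h
recordings for seed-loop tests and 48-h single patients for the
temporal-stability and circadian checks; the signal-level test runs 6
patients × 2 h × 20 channels at 200 Hz twice to verify bit-identical
artefacts. `scripts/acceptance.py` runs the default 24-h study plus a
zero-effect control in well under a minute.

## Known limitations

- The bad-channel fence is a per-window union; a channel that is an
  outlier in a single window is excluded everywhere. Real pipelines may
  prefer per-window exclusion masks.
- The log-then-normalise transform can produce compositions with
  negative components when some band power is below 1 in recording
  units; the degenerate-normalisation guard raises rather than rescales,
  and the alternative mode is provided for sensitivity analyses.
- Signal-level patients are scored against a feature-level normative
  map; spectral estimation noise and band-edge filter attenuation
  (e.g. the 0.5–80 Hz band-pass at the 77.5 Hz gamma edge) shift
  signal-derived compositions slightly relative to that map, uniformly
  across regions. Rank-based D_RS is insensitive to the common shift,
  but absolute abnormality values at the two tiers are not directly
  comparable.
- EDF files are read (via mne) but not written; recordings are exported
  in the matrix + JSON sidecar format.
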