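# Methods

## Signal model and preprocessing

Recordings are multichannel scalp EEG (default: the 8-channel 10–20 montage
Fz, C3, Cz, C4, Pz, PO7, Oz, PO8 at 250 Hz) held internally in µV; every
reader converts on ingest so that all powers downstream are µV². The
preprocessing chain is:

1. **Band-pass 0.5–70 Hz** — 4th-order Butterworth applied forward-backward
   (zero phase, magnitude response squared). Zero-phase application avoids
   latency distortion of band power at the cost of steeper effective rolloff;
   the response is flat to <1 dB over roughly [1, 56] Hz and reaches ~3 dB
   down near 0.9 of the upper corner — one reason high-gamma estimates are
   flagged low-confidence (below).
2. **Mains notch** — Q = 30 IIR notch at 50 Hz (60 Hz selectable), zero
   phase: ≥30 dB at the mains frequency, <3 dB at ±3 Hz.
3. **Epoching** — non-overlapping, contiguous 2.0-s epochs (500 samples at
   250 Hz), trailing remainder discarded. Exactly 2.0 s gives 0.5 Hz bins,
   aligning every canonical band edge with a bin centre.
4. **Artifact screening** — two deterministic rules replace manual visual
   inspection. *Amplitude*: any sample beyond 100 µV or channel peak-to-peak
   beyond 200 µV. *EMG*: the epoch's high-frequency power (30 Hz to
   min(110, 0.96·Nyquist)) is converted per channel to a robust z against
   the median and MAD of that channel's per-epoch *log* power over the whole
   recording; epochs with z > 5 on any channel are dropped. The log scale is
   essential: raw epoch band power is right-skewed, and a raw-scale z at a
   conventional threshold of 3 falsely flags several percent of clean epochs
   across the ~10³ epoch × channel comparisons per recording, whereas genuine
   muscle bursts raise log power by z ≈ 20. With these defaults a clean
   recording of ≥150 epochs is essentially never flagged, injected artifacts
   are detected with sensitivity ≥0.95, and a ~10% contamination load yields
   a rejection fraction inside the 8–12% range typical of portable
   eyes-closed recordings. Amplitude flags take precedence over EMG flags; a
   manual-override list of epoch indices is accepted for parity with human
   screening. All statistics are per recording block (subject × condition).

## Spectral estimation

Per retained epoch: demean, Hann window, one-sided FFT periodogram with
mean-squared-window compensation; densities averaged across epochs (a
non-overlapping Welch estimate whose segmentation *is* the epoching — no 50%
overlap). The calibration makes the integral of the density over
[0, Nyquist] equal the mean per-epoch variance (Parseval), so band powers
are variance-calibrated µV²; the tests pin this with closed forms (a 15 Hz
sine of amplitude A yields band power A²/2 within 2%; white noise of
variance 4 µV² integrates to 4 within 5%).

Band integration sums density × Δf over bins whose centre lies in the
half-open interval [f_low, f_high); a bin at exactly f_high belongs to the
band above, and DC/Nyquist bins belong to no band. The default band set
deliberately keeps the [7, 8) and [12, 13) Hz gaps; `bridged_bands()`
(CLI `--bridge-gaps`) closes them for sensitivity analyses. High gamma
(45–70 Hz) is flagged `low_confidence` because both the mains notch and the
band-pass corner sit inside it.

**Known estimator bias.** With 2-s Hann epochs, roughly half a
bin-equivalent of power smears past each band edge (window main-lobe
convolution). Absolute band power is therefore biased low by about 0.5/W,
where W is the number of bins in the band: ~8% for 3-Hz bands, ~12% for the
2-Hz alpha sub-bands. This is a property of the estimator, not of any
particular signal, and largely cancels in ratio indices (see below). Tests
of absolute-band recovery assert against this floor rather than exactness.

## The index

For each subject and condition, band powers are first aggregated across
channels (default: unweighted mean over all available channels — the least
assumptive reduction; a posterior subset Pz/PO7/Oz/PO8 is available because
eyes-closed alpha is posteriorly dominant), then combined as

    TI   = ln[(P_theta + P_alpha_low + P_alpha_high) / (P_beta_low + P_beta_high)]
    TI_D = ln[(P_delta + P_theta + P_alpha_low + P_alpha_high) / (P_beta_low + P_beta_high)]

The natural log is applied to the composite ratio, not to individual band
powers. Exact algebraic properties, all under test: invariance to global
amplitude scaling and to absolute-vs-relative power inputs (provided
normalisation happens after channel aggregation — the mean of per-channel
ratios is not the ratio of means); strict monotonicity in each component;
TI_D − TI = ln(1 + P_delta/(P_theta + P_alpha_low + P_alpha_high)).

The condition contrast is a paired t-test on within-subject TI differences
with effect size d = t/√n and normal-approximation 95% CI
d ± 1.96·√(1/n + d²/2n) — the convention that reproduces a reported
d = 0.35, CI [0.03, 0.67] exactly from t = 2.18 at n = 39. Identical
condition vectors return the null result (t = 0, d = 0, p = 1); constant
nonzero differences are rejected as degenerate rather than reported with a
divergent t.

## Statistics

Descriptives use sample (n−1) SD and the small-sample-adjusted
Fisher–Pearson G1/G2 skewness and excess kurtosis (the SPSS convention);
constant inputs are flagged, not thrown. Correlation families use two-tailed
Pearson r with pairwise deletion (per-pair n is reported; pairs with fewer
than 3 complete cases are marked unavailable) and Benjamini–Hochberg
step-up FDR at q = 0.05 applied within the declared family — one family per
correlation table. Report tables mark FDR-surviving pairs distinctly from
nominal-only ones, and adjusted p-values are reported alongside flags.
`bh_fdr` delegates to statsmodels' step-up implementation; the test suite
checks it against an independent brute-force evaluation of the step-up
definition, exhaustively over a probability grid for families up to size 8
and property-based beyond, and verifies null-calibration (the fraction of
all-null families with any rejection stays ≤0.07 over 2000 replicates).

## Synthetic studies

Each channel is the sum of one band-limited Gaussian noise process per
canonical band (4th-order Butterworth-filtered white noise, rescaled to an
exact target variance) plus a 1/f background at 10% of the summed band
variance. Filtered-noise components — rather than sinusoids — give PSD
estimates realistic sampling variance; pure-tone fixtures remain available
for closed-form tests.

Default band-variance means preserve the relative proportions of group-mean
band powers typical of portable eyes-closed recordings
(δ : θ : α_low : α_high : β_low : β_high : γ_low : γ_high ≈
9328 : 3850 : 5469 : 4730 : 2110 : 1415 : 943 : 479), rescaled by 1/250 to a
physiological ~11 µV total RMS. Device power units are arbitrary, and a
ratio index is invariant to the overall scale — but amplitude-threshold
artifact screening is not, so the generator works at a realistic amplitude.
Between-subject variation is log-normal (σ_log = 0.4 per band),
reproducing the right-skewed raw-power distributions and placing the true
standard index near 1.38 with a between-subject SD of ~0.35.

The two-condition design multiplies the theta, low-alpha and high-alpha
variances by (1+ε), ε = 0.25 by default, in the first condition only, with
subject effects shared across conditions. This makes the true paired TI
shift exactly ln(1+ε) — an analytic identity. The pipeline's mean estimate
recovers it within 0.02 at 40 subjects × 150 clean epochs; the residual
~0.015–0.02 compression is fully accounted for by two condition-independent
additive terms in the numerator bands (≈2 µV² of 1/f background plus
≈2.3 µV² of delta-edge window smear into theta) and is part of what passing
this check does and does not show: recovery of a multiplicative effect is
excellent, but absolute band powers inherit the estimator's smear bias.

Artifacts: spikes are 500 µV, 100-ms biphasic transients; EMG is 0.5 s of
40–110 Hz noise at 30 µV RMS across channels; per-block counts are Poisson
draws around the configured expected rates, epochs chosen without
replacement, with an exact injection log. The `paper_like_artifacts` preset
sets expected spike + EMG load to 10% of epochs. Covariates (anxiety and
five personality scales at realistic means/SDs) can be generated with
planted correlations to the subjects' true TI; the default is the all-null
table used for type-I calibration checks.

Everything is deterministic per seed (bit-identical EDF output), with
per-subject/condition/channel/band streams derived from one master seed.

**What the generator does not emulate:** topographic structure beyond an
optional posterior-alpha gain (no volume conduction or reference effects),
ocular dipole artifacts, non-stationarity within a block (drowsiness drift),
and any genuine coupling between covariates and spectra beyond the planted
linear correlation. Passing tests therefore demonstrate correctness of the
estimators and screening rules under a stationary band-structured model, not
robustness to every failure mode of real portable EEG.

## Problem sizes and determinism of the checks

The quantitative checks run at the following scales, chosen to make
sampling error small relative to each tolerance: condition-effect recovery
at 40 subjects × 2 conditions × 150 clean 2-s epochs; artifact operating
characteristics over ten 300-s blocks; FDR null calibration over 2000
simulated 39 × 10 families; planted-correlation power over 100 seeds and
type-I control over 200 seeds at n = 39. All use fixed seeds and complete in
about half a minute total.

## File formats

EDF reading goes through `mne`; mixed per-signal sampling rates are rejected
up front by direct header inspection (the reader names the offending header
field) because downstream resampling heuristics would silently change the
data. EDF writing is a minimal 16-bit encoder (one-second records, declared
physical range ±2000 µV, quantization ≤0.031 µV) sufficient for synthetic
output; its files round-trip through the mne-based reader in the tests.
Feature tables, covariates and reports are UTF-8 TSV with Unix newlines,
full-precision floats (bit-exact round trip) and `NA` for missing cells.
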