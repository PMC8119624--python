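# Methods

This note records the models, parameter choices and numerical decisions
behind `eegdiv`, and what the synthetic-data tests do and do not
establish about real recordings.

## Data model and preprocessing

Recordings are channels × samples matrices in microvolts with a sampling
rate, ordered unique channel labels, a condition
(meditation / mind_wandering), and the local mains frequency. The
canonical montage is the 16-site 10–20 subset
(Fp1…O2) at 250 Hz; other labels are accepted with a warning because
consumer-grade exports vary. Segmentation is half-open in samples,
`[start·rate, stop·rate)`, so adjacent segments never share a boundary
sample.

The filter chain is FIR throughout, applied with delay compensation
(symmetric kernels shifted by their group delay, reflect padding), which
gives a zero-phase response with the −6 dB points at the design edges:

* mains notch: Hamming band-stop over mains ± 2 Hz (≥ 30 dB at the
  mains line after a single pass; passband ripple ≤ 1 dB outside ± 2 Hz);
* band-pass 0.5–80 Hz: separate Hamming windowed-sinc high- and
  low-pass kernels with transition widths of 0.5 Hz and 10 Hz. These are
  conventional EEG values; both edges and widths are configurable.

Artifact handling replaces visual inspection with an automated,
parameterized criterion so runs are reproducible: a sample is rejected
when its absolute robust z-score (median/MAD per channel) exceeds 5 on
at least half the channels simultaneously, flags are dilated by 0.25 s,
and removed intervals are logged to a BED-like table. The
many-channels requirement deliberately keeps single-electrode
excursions: only non-local artifacts (movement, cable sway, ocular
bursts reaching many sites) are removed. If more than 90% of samples
flag, the recording is declared unusable rather than silently truncated.
All downstream analysis treats the post-rejection length as
authoritative. ICA-based ocular cleaning is intentionally out of scope;
the rejection stage is the only artifact defense, and the generator's
ocular transients exist to exercise it, not to model physiology.

## Spectra and the aperiodic trend

PSDs are Welch averages of Hamming-windowed periodograms, 2-s windows
with 50% overlap, computed independently inside each retained span so no
window straddles a rejected gap; spans contribute proportionally to
their window counts. At 250 Hz this yields a 0.5 Hz grid, which resolves
the 12.5 / 16.5 / 20.5 Hz band edges exactly. The DC bin is dropped.

The aperiodic ("1/f") trend is fit to the channel-averaged dB spectrum
over 1–40 Hz and subtracted from every channel, independently per
recording (hence per participant and condition). Two bases are
implemented:

* **power law** (default): dB linear in log10(f), i.e.
  `S(f) = c/f^β`. This is the standard aperiodic model; it removes a
  true power-law background exactly in expectation, and the package's
  spectral-fidelity checks (pure 1/f noise → all band residuals within
  ±0.5 dB) hold under it.
* **inverse-f**: `a·(1/f) + b` with 1/f itself as the dB-space
  regressor. This literal reading of a "polynomial of the form 1/f" is
  kept as an option, but it cannot flatten a genuine power law (it
  leaves ~3 dB of structured residual on 1/f noise), so it is not the
  default.

Whether such fits are best done in linear or log power, per channel or
channel-averaged, and over which range, is genuinely open; all three
choices are parameters (`fit_one_over_f`, `RunConfig.fit_basis`,
`fit_range_hz`), and the defaults are the ones under which the
self-consistency tests are exact.

Band power is the mean residual dB over channels and over grid bins in
`[low, high)` per band. The band list (delta 1–4, theta 4–8, alpha
8–12.5, beta1 12.5–16, beta2 16.5–20, beta3 20.5–28 Hz) intentionally
leaves 16–16.5 and 20–20.5 Hz unassigned; the gaps are preserved rather
than repaired, and the band set is configurable.

## Lempel–Ziv complexity

Per non-overlapping 10-s window: mean-removal, Hilbert envelope, 5%
edge trim per side (the analytic signal is unreliable at window edges),
per-channel binarization at the channel's mean envelope (strictly
greater → 1, so constant channels binarize to all zeros and the result
is invariant to per-channel gain), observation-major flattening (all
channels at t₁, then t₂, …; channel-major available for sensitivity
analysis), LZ76 word count, and normalization by the mean count over 10
seeded random permutations of the same string. The recording score is
the mean over windows. Windowing, shuffle count, trim fraction and
flattening order are all configurable; window seeds derive from the
recording seed by fixed offsets.

Numerical core: the LZ76 exhaustive-history count equals the number of
phrases when each phrase at position p extends one symbol past the
longest prefix of `s[p:]` that also occurs starting earlier (overlap
allowed) — the longest-previous-factor array. LPF is computed from a
prefix-doubling suffix array, Kasai's LCP, and the stack-based LPF
recurrence (O(n log n)); the final phrase counts even when it stays
reproducible to the end of the string. A brute-force parser written
directly from the definition serves as the oracle in the tests
(exact agreement on 1000+ random strings and the canonical forced
cases: a single symbol parses to 1 word, a constant run to 2).

Normalizing by shuffles rather than by the n/log₂n asymptote keeps the
score comparable across window lengths and symbol compositions; using
the mean of 10 seeded permutations (instead of a single shuffle) lowers
normalization variance at negligible cost and keeps runs reproducible.

## Synthetic study generator

Each participant draws an aperiodic exponent β ~ N(1.0, 0.15) clipped to
[0, 3] and an amplitude ~ N(10, 2) µV²/Hz at 1 Hz (clipped positive) —
realistic resting-EEG scales. Channels are sums of:

* 1/f^β colored noise synthesized in the frequency domain with an
  unbiased expected periodogram;
* narrowband-filtered Gaussian noise oscillations (default: 10 ± 1 Hz
  alpha at 1.5 µV RMS and 6 ± 1 Hz theta at 0.7 µV RMS, no condition
  effect by default). Filtered noise, not sinusoids: pure tones have a
  constant envelope, binarize degenerately, and collapse LZc;
* optionally a mains sinusoid and Poisson-scheduled half-sine ocular
  bursts (0.5–2 Hz equivalent width, 150 µV, frontal-weighted).

The diversity knob k ∈ [0, 1] per condition replaces a fraction k of
each channel's variance with one shared 10 ± 2 Hz source
(`√(1−k)·private + √k·σ_ch·shared`). Because shared activity repeats
across channels in the flattened sequence, LZc decreases monotonically
in k; the measured curve (8 participants × 60 s per knob) is shipped as
`data/knob_lzc_calibration.tsv`: mean LZc ≈ 0.98, 0.91, 0.72, 0.38 at
k = 0, 0.3, 0.6, 0.9. The default condition assignment (meditation 0.6,
mind-wandering 0.0) plants the direction the package is designed to
detect — lower complexity during meditation — at a size every stage
recovers per participant. The knob's spectral side effect (the shared
source adds narrowband power, so the mixed condition shows an apparent
alpha increase) is inherent to the mixing model; spectral-recovery tests
therefore plant band effects via condition multipliers with the knob
equalized, and complexity tests vice versa.

Seeding is hierarchical: every (participant, condition, component,
channel) stream is opened from the master seed plus fixed integer
offsets, so outputs are bit-reproducible and orthogonal — changing the
ocular rate does not perturb the background noise.

What the generator does *not* emulate: volume conduction and realistic
cross-channel covariance (channels are independent except for the shared
source), nonstationarity beyond the noise's own envelope, eye blinks
with realistic morphology, electrode drift or impedance artifacts, and
any quantitative match to the meditation literature's effect sizes. The
planted effects are illustrative and deliberately large; passing the
recovery tests shows the pipeline detects known structure of this kind,
not that real meditation data would show effects of this size.

## Statistics

With two within-subject levels the repeated-measures ANOVA is computed
from the subject × condition sum-of-squares decomposition; F(1, n−1)
equals the squared paired t, which is asserted to 1e−10 and
cross-checked against an independent general-linear-model implementation.
Partial η² = SS_state/(SS_state+SS_error) and Cohen's
f = √(η²/(1−η²)).

Achieved power uses the GPower within-factors convention: df₁ = (m−1)ε,
df₂ = (N−g)(m−1)ε, noncentrality λ = f²·N·m·ε/(1−ρ), power
P(F′ > F_crit). ρ defaults to 0.5 and ε to 1 (exact for two levels);
both are parameters. At f = 0 the routine returns α exactly.

Channel × band maps use paired two-tailed t-tests with
Benjamini–Hochberg adjustment across all cells of a practice group
jointly (the FDR family is a config choice; the default spans every
channel × band cell). Zero-variance cells yield p = 1 with a warning
rather than NaN. Bootstrap difference curves resample participants with
replacement (default B = 2000), use the (k+1)/(B+1) two-sided p
convention so p is never zero, and are BH-corrected across frequency
bins. Per-practice analyses are descriptive: they run only when a
practice has ≥ 3 participants and no cross-practice inferential test is
attempted.

## Problem sizes in the test suite

The suite favors exact small-scale oracles (brute-force LZ76 parsing,
definitional BH step-up, transfer-function checks of the FIR kernels)
plus synthetic recovery runs sized for a single CPU: parameter-recovery
studies use 20 participants × 60-s recordings; null calibration of the
ANOVA uses 2000 simulated 12-pair studies; spectral fidelity uses
240-s single-condition recordings. End-to-end pipeline tests use 3
participants × 30 s and assert byte-identical reruns. These sizes are
the package's chosen trade-off between statistical resolution and test
turnaround; every threshold asserted in the tests is stated in the test
itself.

## Known limitations

* The LZc score depends on window length and channel count; scores are
  comparable only within a fixed configuration. No attempt is made to
  normalize across montages.
* The aperiodic fit has no knee parameter and will mis-fit spectra with
  a low-frequency plateau; the fit range is the main defense.
* The artifact criterion is amplitude-based and will not catch
  stereotyped low-amplitude artifacts (e.g. saccadic spikes) that ICA
  would isolate.
* EDF support covers reading; writing is tabular-text only.
* The generator's ground truth is per-participant, not per-channel:
  aperiodic parameters are shared across channels within a participant.
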