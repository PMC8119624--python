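# eegdiv

Signal diversity (multichannel Lempel–Ziv complexity) and 1/f-normalized
band power for paired-condition EEG studies, with repeated-measures
statistics and a fully synthetic study generator.

`eegdiv` is aimed at researchers analyzing within-subject EEG designs —
the motivating case is contrasting meditation against an active
mind-wandering baseline in the same participants — who want the entire
chain, from raw multichannel recordings to the final ANOVA table, to be
scripted, seeded, and testable without access to any particular dataset.

## What it computes

**Lempel–Ziv complexity (LZc).** Per analysis window, each channel's
instantaneous amplitude (Hilbert envelope) is binarized against its own
mean, the channels × time binary matrix is flattened observation by
observation, and the number of words `c(s)` in the Lempel–Ziv 1976
exhaustive-history parsing is counted. The reported score is the
shuffle-normalized complexity

```
LZc = c(s) / mean_k c(shuffle_k(s)),    k = 1..10
```

which lies in (0, ~1]: 1 for signals indistinguishable from their own
shuffle (maximally diverse), near 0 for periodic or strongly shared
activity. The LZ76 parser is exact — suffix array, Kasai LCP and the
longest-previous-factor recurrence — and is validated in the test suite
against a brute-force transcription of the 1976 definition.

**1/f-normalized band power.** Welch PSDs (Hamming, 2-s windows, 50%
overlap → 0.5 Hz grid at 250 Hz) are detrended by a least-squares
aperiodic fit over 1–40 Hz (power law `S(f) = c/f^β` by default; a
literal `a·(1/f)+b` dB-space basis is available), and the residual dB is
averaged into six bands: delta 1–4, theta 4–8, alpha 8–12.5, beta1
12.5–16, beta2 16.5–20, beta3 20.5–28 Hz (half-open intervals).

**Statistics.** Two-level repeated-measures ANOVA (`F(1, n−1)`, partial
η², Cohen's `f = √(η²/(1−η²))`), noncentral-F achieved power under
GPower's within-factors conventions (noncentrality
`λ = f²·N·m·ε/(1−ρ)`), channel × band paired t maps with
Benjamini–Hochberg FDR, percentile-bootstrap difference curves per
frequency bin, and covariate correlations.

**Synthetic studies.** Paired-condition 16-channel recordings with
per-participant 1/f^β backgrounds, narrowband oscillatory peaks with
condition multipliers, optional mains noise and frontal ocular
transients, and a *diversity knob* that mixes a shared narrowband source
into all channels of one condition, lowering LZc by a known, empirically
calibrated amount (`src/eegdiv/data/knob_lzc_calibration.tsv`).

## Worked example

Simulate a 6-participant study (60 s per condition, meditation carrying
the default diversity-knob contrast of 0.6 vs 0.0) and analyze it:

```python
from eegdiv import RunConfig, run_study

cfg = RunConfig(
    synthetic={"n_participants": 6, "duration_meditation_s": 60.0,
               "duration_mind_wandering_s": 60.0},
    outdir="demo_out", master_seed=42, n_boot=500,
)
result = run_study(cfg)
print(result["report"])
```

prints (abridged):

```
LZc: F(1, 5) = 304.89, p = 0.000, partial eta2 = 0.98 (Cohen's f = 7.81)
...
LZc: meditation M = 0.69 (SD = 0.05), mind wandering M = 0.97 (SD = 0.01)
```

Meditation LZc is far below the mind-wandering baseline because 60% of
each channel's variance was replaced by one shared 10-Hz source: shared
activity repeats across channels, so the flattened binary sequence
compresses better and the normalized count drops. The mind-wandering
score sits near 1 (channels are independent, so the sequence is nearly
shuffle-like). The band table in the same report shows the collateral
spectral footprint of that mixing (a large apparent alpha increase),
which is why planted spectral effects and planted complexity effects are
exercised with separate generator configurations in the tests.

The same pipeline runs from the shell:

```
eegdiv simulate --outdir study/ --seed 42 --n-participants 6 \
    --duration-meditation 60 --duration-mind-wandering 60
eegdiv analyze --config run.yaml
eegdiv check --config run.yaml
```

where `run.yaml` holds a `manifest_path:` (to analyze existing EDF or
tabular recordings) or a `synthetic:` block, plus any stage parameters
(filter edges, rejection thresholds, PSD windows, LZc windowing and
shuffle count, bootstrap size — see `RunConfig`).

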