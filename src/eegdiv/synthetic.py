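"""Synthetic paired-condition EEG with known ground truth.

The generator emulates the structure of a two-condition within-subject
meditation study: each participant contributes one mind-wandering and one
meditation recording from the same 16-channel montage. Every channel is a
sum of

* a 1/f^beta aperiodic background with participant-specific exponent and
  amplitude (drawn once per participant),
* band-limited oscillations built as narrowband-filtered Gaussian noise
  (pure sinusoids are avoided because their binarized envelopes are
  trivially periodic and collapse Lempel-Ziv complexity),
* optionally a mains sinusoid and frontal low-frequency ocular transients.

Condition effects are planted in two ways: each oscillatory peak carries a
``condition_multiplier`` applied to its amplitude in the meditation
condition, and a per-condition ``diversity_knob`` in [0, 1] replaces that
fraction of each channel's variance with a single narrowband source shared
by all channels. A higher knob means more shared (less diverse) activity
and therefore lower multichannel Lempel-Ziv complexity; the mapping from
knob to complexity has no closed form and an empirically measured curve is
shipped in ``data/knob_lzc_calibration.tsv``.

Randomness is fully reproducible: every (participant, condition,
component) stream is seeded from the master seed by fixed integer offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_signals import (
    CONDITIONS,
    MONTAGE_10_20,
    ManifestEntry,
    Recording,
    StudyManifest,
    write_recording,
)

__all__ = [
    "BandPeak",
    "SyntheticStudyConfig",
    "colored_noise",
    "narrowband_noise",
    "generate_participant",
    "generate_study",
]

# component codes for per-stream seeding
_BACKGROUND, _BAND, _SHARED, _LINE, _OCULAR, _PARTICIPANT = 1, 2, 3, 4, 5, 6

#: relative ocular-artifact weighting by channel (frontal-dominant)
_OCULAR_WEIGHTS = {
    "Fp1": 1.0, "Fp2": 1.0, "F3": 0.3, "F4": 0.3, "F7": 0.3, "F8": 0.3,
}


@dataclass
class BandPeak:
    """One band-limited oscillatory component.

    ``amplitude`` is the RMS contribution in microvolts in the
    mind-wandering condition; the meditation condition uses
    ``amplitude * condition_multiplier``. ``channel_weights`` optionally
    restricts the peak to a subset of channels (label -> relative weight,
    missing labels get 0); by default all channels get weight 1.
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float
    condition_multiplier: float = 1.0
    channel_weights: dict | None = None

    def weight(self, label: str) -> float:
        if self.channel_weights is None:
            return 1.0
        return float(self.channel_weights.get(label, 0.0))


def _default_band_peaks() -> list[BandPeak]:
    # a posterior-dominant alpha rhythm and a weak global theta rhythm;
    # no condition effect by default (the study's band contrasts were null)
    return [
        BandPeak(10.0, 2.0, amplitude=1.5, condition_multiplier=1.0),
        BandPeak(6.0, 2.0, amplitude=0.7, condition_multiplier=1.0),
    ]


def _default_diversity_knob() -> dict:
    # the study's one positive finding: complexity is lower during
    # meditation; 0.6 vs 0.0 plants that effect at a size the complexity
    # stage recovers per participant (see data/knob_lzc_calibration.tsv)
    return {"meditation": 0.6, "mind_wandering": 0.0}


@dataclass
class SyntheticStudyConfig:
    """Study-level parameters of the synthetic generator.

    Defaults mirror the emulated acquisition: 16 channels of the 10-20
    montage at 250 Hz, an 80-s mind-wandering baseline and a 600-s
    meditation block per participant, 28 participants.
    """

    n_participants: int = 28
    rate_hz: float = 250.0
    duration_mind_wandering_s: float = 80.0
    duration_meditation_s: float = 600.0
    channel_labels: tuple[str, ...] = MONTAGE_10_20
    aperiodic_exponent_mean: float = 1.0
    aperiodic_exponent_sd: float = 0.15
    aperiodic_amplitude_mean: float = 10.0  # uV^2/Hz at 1 Hz
    aperiodic_amplitude_sd: float = 2.0
    band_peaks: list[BandPeak] = field(default_factory=_default_band_peaks)
    diversity_knob: dict = field(default_factory=_default_diversity_knob)
    shared_source_center_hz: float = 10.0
    shared_source_bandwidth_hz: float = 4.0
    line_noise_amplitude: float = 0.0  # uV peak; 0 = no mains component
    line_freq_hz: float = 50.0
    ocular_artifact_rate: float = 0.0  # events per second
    ocular_artifact_amplitude: float = 150.0  # uV peak at Fp1/Fp2
    master_seed: int = 0

    def __post_init__(self) -> None:
        for cond, k in self.diversity_knob.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in diversity_knob")
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"diversity_knob must be in [0, 1], got {k}")
        for sd in (self.aperiodic_exponent_sd, self.aperiodic_amplitude_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")

    def duration_s(self, condition: str) -> float:
        return (
            self.duration_meditation_s
            if condition == "meditation"
            else self.duration_mind_wandering_s
        )


def colored_noise(
    n_samples: int,
    rate_hz: float,
    exponent: float,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean Gaussian noise with one-sided PSD amplitude / f**exponent.

    Synthesized in the frequency domain: each positive-frequency Fourier
    coefficient is complex Gaussian with variance chosen so the expected
    periodogram is ``amplitude / f**exponent`` in uV^2/Hz.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    if not 0.0 <= exponent <= 3.0:
        raise ValueError("exponent must be in [0, 3]")
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    psd = np.zeros_like(freqs)
    psd[1:] = amplitude / freqs[1:] ** exponent
    # E|X_k|^2 = S(f_k) * rate * n / 2 makes the periodogram unbiased
    sigma = np.sqrt(psd * rate_hz * n_samples / 4.0)
    coefs = sigma * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    coefs[0] = 0.0
    x = np.fft.irfft(coefs, n=n_samples)
    return x - x.mean()


def narrowband_noise(
    n_samples: int,
    rate_hz: float,
    center_hz: float,
    bandwidth_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to center +/- bandwidth/2.

    Built by masking the spectrum of white noise, so the carrier has a
    random phase structure (not a sinusoid) with a slowly varying envelope.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    lo, hi = center_hz - bandwidth_hz / 2.0, center_hz + bandwidth_hz / 2.0
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz resolves no Fourier bins")
    coefs = np.zeros(len(freqs), dtype=complex)
    coefs[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(coefs, n=n_samples)
    x -= x.mean()
    rms = x.std()
    return x / rms if rms > 0 else x


def _rng(config: SyntheticStudyConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.master_seed & 0x7FFFFFFF, *stream])


def _participant_params(config: SyntheticStudyConfig, idx: int) -> dict:
    rng = _rng(config, idx, _PARTICIPANT)
    beta = float(
        np.clip(
            rng.normal(config.aperiodic_exponent_mean, config.aperiodic_exponent_sd),
            0.0, 3.0,
        )
    )
    amp = float(
        max(
            rng.normal(config.aperiodic_amplitude_mean, config.aperiodic_amplitude_sd),
            0.05 * config.aperiodic_amplitude_mean + 1e-6,
        )
    )
    return {"aperiodic_exponent": beta, "aperiodic_amplitude": amp}


def _ocular_transients(
    config: SyntheticStudyConfig,
    n_samples: int,
    labels: tuple[str, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Half-sine bursts (0.5-2 Hz equivalent) weighted toward Fp1/Fp2."""
    out = np.zeros((len(labels), n_samples))
    duration = n_samples / config.rate_hz
    n_events = rng.poisson(config.ocular_artifact_rate * duration)
    weights = np.array([_OCULAR_WEIGHTS.get(c, 0.05) for c in labels])
    for _ in range(n_events):
        f = rng.uniform(0.5, 2.0)  # half-sine of a 0.5-2 Hz cycle
        width = int(round(config.rate_hz / (2.0 * f)))
        start = rng.integers(0, max(1, n_samples - width))
        burst = np.sin(np.pi * np.arange(width) / width)
        out[:, start : start + width] += (
            config.ocular_artifact_amplitude * weights[:, None] * burst[None, :]
        )
    return out


def generate_participant(
    config: SyntheticStudyConfig, participant_index: int
) -> tuple[Recording, Recording]:
    """Generate the (meditation, mind_wandering) pair for one participant.

    Deterministic given (master_seed, participant_index, condition): the
    two conditions and all signal components use independent seeded
    streams, so changing e.g. the ocular rate does not perturb the
    background noise.
    """
    params = _participant_params(config, participant_index)
    labels = tuple(config.channel_labels)
    recs: dict[str, Recording] = {}
    for cond_code, condition in enumerate(CONDITIONS):
        n = int(round(config.duration_s(condition) * config.rate_hz))
        data = np.zeros((len(labels), n))
        for ch in range(len(labels)):
            rng = _rng(config, participant_index, cond_code, _BACKGROUND, ch)
            data[ch] = colored_noise(
                n, config.rate_hz,
                params["aperiodic_exponent"], params["aperiodic_amplitude"], rng,
            )
            for pk_i, pk in enumerate(config.band_peaks):
                w = pk.weight(labels[ch])
                if w == 0.0:
                    continue
                mult = pk.condition_multiplier if condition == "meditation" else 1.0
                rng_b = _rng(config, participant_index, cond_code, _BAND, pk_i, ch)
                carrier = narrowband_noise(
                    n, config.rate_hz, pk.center_hz, pk.bandwidth_hz, rng_b
                )
                data[ch] += pk.amplitude * mult * w * carrier

        knob = float(config.diversity_knob.get(condition, 0.0))
        if knob > 0.0:
            rng_s = _rng(config, participant_index, cond_code, _SHARED)
            shared = narrowband_noise(
                n, config.rate_hz,
                config.shared_source_center_hz,
                config.shared_source_bandwidth_hz, rng_s,
            )
            scale = data.std(axis=1, keepdims=True)
            data = np.sqrt(1.0 - knob) * data + np.sqrt(knob) * scale * shared[None, :]

        if config.line_noise_amplitude > 0.0:
            rng_l = _rng(config, participant_index, cond_code, _LINE)
            phase = rng_l.uniform(0, 2 * np.pi)
            t = np.arange(n) / config.rate_hz
            data += config.line_noise_amplitude * np.sin(
                2 * np.pi * config.line_freq_hz * t + phase
            )[None, :]

        if config.ocular_artifact_rate > 0.0:
            rng_o = _rng(config, participant_index, cond_code, _OCULAR)
            data += _ocular_transients(config, n, labels, rng_o)

        recs[condition] = Recording(
            participant_id=f"sim{participant_index:03d}",
            condition=condition,
            practice="unknown",
            channel_labels=labels,
            rate_hz=config.rate_hz,
            data=data,
            line_freq_hz=config.line_freq_hz,
        )
    return recs["meditation"], recs["mind_wandering"]


def generate_study(
    config: SyntheticStudyConfig, outdir: str | Path
) -> tuple[StudyManifest, pd.DataFrame]:
    """Write one pair of tabular recordings per participant plus manifest.

    Returns the manifest and a ground-truth sidecar table (one row per
    participant with the drawn aperiodic parameters and planted effects);
    both are also written to ``outdir`` (``manifest.yaml``,
    ``ground_truth.tsv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    truth_rows = []
    for idx in range(config.n_participants):
        med, mw = generate_participant(config, idx)
        pid = med.participant_id
        med_path = outdir / f"{pid}_meditation.tsv"
        mw_path = outdir / f"{pid}_mind_wandering.tsv"
        write_recording(med, med_path)
        write_recording(mw, mw_path)
        entries.append(
            ManifestEntry(
                participant_id=pid,
                practice="unknown",
                meditation_path=str(med_path),
                mind_wandering_path=str(mw_path),
                line_freq_hz=config.line_freq_hz,
            )
        )
        params = _participant_params(config, idx)
        truth_rows.append(
            {
                "participant": pid,
                **params,
                "diversity_knob_meditation": config.diversity_knob.get("meditation", 0.0),
                "diversity_knob_mind_wandering": config.diversity_knob.get(
                    "mind_wandering", 0.0
                ),
            }
        )
    manifest = StudyManifest(
        entries=entries,
        options={"rate_hz": config.rate_hz, "master_seed": config.master_seed},
    )
    manifest.to_yaml(outdir / "manifest.yaml")
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "participant", "aperiodic_exponent", "aperiodic_amplitude",
            "diversity_knob_meditation", "diversity_knob_mind_wandering",
        ],
    )
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return manifest, truth
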