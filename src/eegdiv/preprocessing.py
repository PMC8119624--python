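"""Filtering chain and automated artifact-segment rejection.

The chain mirrors conventional EEG practice for dry-electrode recordings:
a mains notch (50 or 60 Hz), a 0.5-80 Hz band-pass built from
windowed-sinc (Hamming) FIR kernels applied with delay compensation (the
symmetric kernels are linear-phase, so shifting by the group delay yields
a zero-phase response), and a robust multichannel amplitude criterion that
stands in for visual inspection: a sample is rejected only when it is
extreme on many channels at once, i.e. only *non-local* artifacts are
removed, and the flagged spans are padded and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .io_signals import Recording

__all__ = [
    "CleanRecording",
    "notch_filter",
    "bandpass_fir",
    "reject_artifact_segments",
    "as_clean",
    "write_rejection_log",
]


@dataclass
class CleanRecording:
    """A recording after artifact-segment removal.

    ``recording.data`` holds the retained samples concatenated in time
    order; ``retained_mask`` indexes the original (pre-rejection) samples;
    ``spans`` lists the retained contiguous runs in original sample
    indices, so spectral estimation can avoid windows that straddle a
    removed gap; ``rejection_log`` lists removed (start_s, stop_s, reason)
    intervals.
    """

    recording: Recording
    retained_mask: np.ndarray
    spans: list[tuple[int, int]]
    rejection_log: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        if int(self.retained_mask.sum()) != self.recording.n_samples:
            raise ValueError("retained_mask does not match retained data length")
        prev_stop = -1
        for start, stop in self.spans:
            if not (prev_stop < start < stop <= len(self.retained_mask)):
                raise ValueError("spans must be disjoint, ordered, in bounds")
            prev_stop = stop

    @property
    def rate_hz(self) -> float:
        return self.recording.rate_hz

    @property
    def data(self) -> np.ndarray:
        return self.recording.data


def _hamming_taps(transition_hz: float, rate_hz: float) -> int:
    """Odd tap count giving roughly the requested transition width."""
    n = int(np.ceil(3.3 * rate_hz / transition_hz))
    return n + 1 if n % 2 == 0 else n


def _apply_linear_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Filter with delay compensation and reflect padding (zero phase)."""
    pad = len(taps) // 2
    padded = np.pad(data, [(0, 0), (pad, pad)], mode="reflect")
    out = signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    return out[:, pad:-pad]


def notch_filter(rec: Recording, freq_hz: float) -> Recording:
    """FIR band-stop of +/- 2 Hz around the mains frequency, zero phase."""
    if freq_hz not in (50.0, 60.0, 50, 60):
        raise ValueError("notch frequency must be 50 or 60 Hz")
    if freq_hz >= rec.rate_hz / 2:
        raise ValueError("notch frequency at or above Nyquist")
    ntaps = _hamming_taps(1.0, rec.rate_hz)
    if rec.n_samples < 3 * ntaps:
        raise ValueError(
            f"recording too short for notch filter ({rec.n_samples} < {3 * ntaps} samples)"
        )
    taps = signal.firwin(
        ntaps, [freq_hz - 2.0, freq_hz + 2.0], fs=rec.rate_hz,
        window="hamming", pass_zero="bandstop",
    )
    return replace(rec, data=_apply_linear_phase(rec.data, taps))


def bandpass_fir(
    rec: Recording, hp_hz: float = 0.5, lp_hz: float = 80.0
) -> Recording:
    """High-pass then low-pass windowed-sinc FIR, both zero-phase.

    Transition widths are 0.5 Hz for the high-pass and 10 Hz for the
    low-pass (conventional EEG defaults); -6 dB points sit at the stated
    edges because the single-pass Hamming-sinc response crosses 0.5 at its
    cutoff.
    """
    nyq = rec.rate_hz / 2.0
    if not (0 < hp_hz < lp_hz < nyq):
        raise ValueError(
            f"need 0 < hp ({hp_hz}) < lp ({lp_hz}) < Nyquist ({nyq})"
        )
    hp_taps = signal.firwin(
        _hamming_taps(0.5, rec.rate_hz), hp_hz, fs=rec.rate_hz,
        window="hamming", pass_zero=False,
    )
    lp_taps = signal.firwin(
        _hamming_taps(10.0, rec.rate_hz), lp_hz, fs=rec.rate_hz,
        window="hamming", pass_zero=True,
    )
    longest = max(len(hp_taps), len(lp_taps))
    if rec.n_samples < 3 * longest:
        raise ValueError(
            f"recording too short for band-pass ({rec.n_samples} < {3 * longest} samples)"
        )
    data = _apply_linear_phase(rec.data, hp_taps)
    data = _apply_linear_phase(data, lp_taps)
    return replace(rec, data=data)


def reject_artifact_segments(
    rec: Recording,
    z_threshold: float = 5.0,
    min_channels_fraction: float = 0.5,
    pad_s: float = 0.25,
) -> CleanRecording:
    """Remove spans where many channels are simultaneously extreme.

    A sample is flagged when its absolute robust z-score (median/MAD per
    channel) exceeds ``z_threshold`` on at least ``min_channels_fraction``
    of channels; flags are dilated by ``pad_s`` seconds on each side and
    the flagged spans removed. Single-channel excursions are deliberately
    kept: only artifacts involving many electrodes qualify.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    if not 0 < min_channels_fraction <= 1:
        raise ValueError("min_channels_fraction must be in (0, 1]")
    data = rec.data
    med = np.median(data, axis=1, keepdims=True)
    mad = np.median(np.abs(data - med), axis=1, keepdims=True) * 1.4826
    mad = np.where(mad > 0, mad, np.inf)  # flat channel never flags
    z = np.abs(data - med) / mad
    n_extreme = (z > z_threshold).sum(axis=0)
    flagged = n_extreme >= np.ceil(min_channels_fraction * rec.n_channels)
    pad = int(round(pad_s * rec.rate_hz))
    if pad > 0 and flagged.any():
        flagged = ndimage.binary_dilation(flagged, np.ones(2 * pad + 1, bool))
    if flagged.mean() > 0.9:
        raise ValueError(
            f"{flagged.mean():.0%} of samples flagged as artifact; "
            "recording unusable"
        )
    retained = ~flagged
    spans = []
    log = []
    for sl in ndimage.find_objects(ndimage.label(retained)[0]):
        spans.append((sl[0].start, sl[0].stop))
    for sl in ndimage.find_objects(ndimage.label(flagged)[0]):
        log.append(
            (
                sl[0].start / rec.rate_hz,
                sl[0].stop / rec.rate_hz,
                f"robust z > {z_threshold} on >= "
                f"{min_channels_fraction:.0%} of channels",
            )
        )
    clean = replace(rec, data=data[:, retained].copy())
    return CleanRecording(
        recording=clean,
        retained_mask=retained,
        spans=spans,
        rejection_log=log,
    )


def as_clean(rec: Recording) -> CleanRecording:
    """Wrap a recording with an all-retained mask (no rejection applied)."""
    mask = np.ones(rec.n_samples, dtype=bool)
    return CleanRecording(
        recording=rec, retained_mask=mask,
        spans=[(0, rec.n_samples)], rejection_log=[],
    )


def write_rejection_log(clean: CleanRecording, path) -> None:
    """Export removed intervals as a BED-like text table."""
    with open(path, "w") as fh:
        fh.write("start_s\tstop_s\treason\n")
        for start, stop, reason in clean.rejection_log:
            fh.write(f"{start:.4f}\t{stop:.4f}\t{reason}\n")
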