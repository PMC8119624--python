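"""Power spectral density, 1/f detrending, and band power.

EEG spectra combine a power-law ("aperiodic", 1/f^beta) background with
narrowband oscillatory peaks. Because the background varies strongly
across individuals and recording conditions, band power is compared only
after subtracting a fitted aperiodic trend. The default trend model is
the two-parameter power law -- the dB spectrum linear in log10(f), i.e.
``S(f) = c / f**beta`` -- fit by least squares to the channel-averaged
dB spectrum over 1-40 Hz, independently per recording (i.e. per
participant and condition), and subtracted from every channel. A literal
``a * (1/f) + b`` regressor in dB space is available as an alternative
basis; it cannot flatten a true power-law background, which is why the
power law is the default.

The PSD is a Welch average of Hamming-windowed periodograms (2-s windows,
50% overlap by default, giving a 0.5 Hz grid at 250 Hz that resolves the
12.5/16.5/20.5 Hz band edges exactly). Windows never straddle a gap left
by artifact rejection. The band set defaults to delta (1-4), theta (4-8),
alpha (8-12.5), beta1 (12.5-16), beta2 (16.5-20) and beta3 (20.5-28) Hz,
half-open intervals; the 16-16.5 and 20-20.5 Hz gaps in that list are
preserved, not repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocessing import CleanRecording

__all__ = [
    "SpectrumSet",
    "DetrendedSpectrum",
    "BandDefinition",
    "DEFAULT_BANDS",
    "compute_psd",
    "fit_one_over_f",
    "band_power",
    "per_channel_band_power",
]


@dataclass
class BandDefinition:
    """A named half-open frequency interval [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low must be < high")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.low_hz) & (freqs < self.high_hz)


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.5),
    BandDefinition("beta1", 12.5, 16.0),
    BandDefinition("beta2", 16.5, 20.0),
    BandDefinition("beta3", 20.5, 28.0),
)


def _check_bands_disjoint(bands) -> None:
    ordered = sorted(bands, key=lambda b: b.low_hz)
    for a, b in zip(ordered, ordered[1:]):
        if b.low_hz < a.high_hz:
            raise ValueError(f"bands {a.name} and {b.name} overlap")


@dataclass
class SpectrumSet:
    """Per-channel PSD in dB (10*log10 of uV^2/Hz) on a shared grid."""

    freqs_hz: np.ndarray
    psd_db: np.ndarray  # channels x freqs
    channel_labels: tuple[str, ...]
    participant_id: str = "unknown"
    condition: str = "meditation"

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.psd_db = np.asarray(self.psd_db, dtype=float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.psd_db.shape != (len(self.channel_labels), len(self.freqs_hz)):
            raise ValueError("psd_db shape does not match labels x freqs")
        if not np.all(np.isfinite(self.psd_db)):
            raise ValueError("psd contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.psd_db.T, index=pd.Index(self.freqs_hz, name="freq_hz"),
            columns=list(self.channel_labels),
        )


@dataclass
class DetrendedSpectrum:
    """Residual spectrum after subtracting the fitted aperiodic trend.

    The trend in dB is ``a * basis(f) + b`` where ``basis`` is
    ``log10(f)`` for the default power-law model (so ``a`` is -10 times
    the aperiodic exponent) or ``1/f`` for the literal inverse-frequency
    basis.
    """

    freqs_hz: np.ndarray
    residual_db: np.ndarray  # channels x freqs
    channel_labels: tuple[str, ...]
    fit_params: tuple[float, float]  # (a, b) in dB units
    fit_range_hz: tuple[float, float]
    basis: str = "power_law"
    participant_id: str = "unknown"
    condition: str = "meditation"

    def channel_mean(self) -> np.ndarray:
        return self.residual_db.mean(axis=0)


def compute_psd(
    rec: CleanRecording, window_s: float = 2.0, overlap: float = 0.5
) -> SpectrumSet:
    """Welch PSD over retained spans only (no window straddles a gap).

    Periodograms from all spans are pooled with weights proportional to
    each span's window count. The DC bin is dropped (meaningless after
    high-pass filtering and undefined under the 1/f trend model).
    """
    rate = rec.rate_hz
    nperseg = int(round(window_s * rate))
    noverlap = int(round(nperseg * overlap))
    step = nperseg - noverlap
    offsets = np.concatenate([[0], np.cumsum([b - a for a, b in rec.spans])])
    pooled = None
    total_windows = 0
    for (start, stop), off in zip(rec.spans, offsets):
        length = stop - start
        if length < nperseg:
            continue
        chunk = rec.data[:, off : off + length]
        freqs, pxx = signal.welch(
            chunk, fs=rate, window="hamming", nperseg=nperseg,
            noverlap=noverlap, detrend="constant", axis=1,
        )
        n_windows = 1 + (length - nperseg) // step
        pooled = pxx * n_windows if pooled is None else pooled + pxx * n_windows
        total_windows += n_windows
    if total_windows < 2:
        raise ValueError(
            "retained data shorter than two Welch windows "
            f"({window_s} s each); cannot estimate a spectrum"
        )
    psd = pooled / total_windows
    keep = freqs > 0
    psd_db = 10.0 * np.log10(np.maximum(psd[:, keep], 1e-300))
    return SpectrumSet(
        freqs_hz=freqs[keep],
        psd_db=psd_db,
        channel_labels=rec.recording.channel_labels,
        participant_id=rec.recording.participant_id,
        condition=rec.recording.condition,
    )


_BASIS_FUNCTIONS = {
    "power_law": lambda f: np.log10(f),
    "inverse_f": lambda f: 1.0 / f,
}


def fit_one_over_f(
    spec: SpectrumSet,
    fit_range_hz: tuple[float, float] = (1.0, 40.0),
    basis: str = "power_law",
) -> DetrendedSpectrum:
    """Fit the aperiodic trend to the channel-averaged dB spectrum.

    Ordinary least squares of ``a * basis(f) + b`` over grid bins inside
    ``fit_range_hz``; the trend is evaluated and subtracted on the full
    grid for every channel. With the default ``power_law`` basis the
    trend is linear in log10(f), so a 1/f^beta background is removed
    exactly in expectation (``a = -10 * beta``). The ``inverse_f`` basis
    instead uses 1/f itself as the regressor in dB space.
    """
    if basis not in _BASIS_FUNCTIONS:
        raise ValueError(f"basis must be one of {sorted(_BASIS_FUNCTIONS)}")
    lo, hi = fit_range_hz
    if not (spec.freqs_hz[0] <= lo and spec.freqs_hz[-1] >= hi):
        raise ValueError(
            f"grid [{spec.freqs_hz[0]}, {spec.freqs_hz[-1]}] Hz does not "
            f"cover fit range [{lo}, {hi}] Hz"
        )
    in_range = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if in_range.sum() < 4:
        raise ValueError("fewer than 4 grid bins inside the fit range")
    basis_fn = _BASIS_FUNCTIONS[basis]
    mean_db = spec.psd_db.mean(axis=0)
    design = np.column_stack(
        [basis_fn(spec.freqs_hz[in_range]), np.ones(in_range.sum())]
    )
    (a, b), *_ = np.linalg.lstsq(design, mean_db[in_range], rcond=None)
    trend = a * basis_fn(spec.freqs_hz) + b
    return DetrendedSpectrum(
        freqs_hz=spec.freqs_hz,
        residual_db=spec.psd_db - trend[None, :],
        channel_labels=spec.channel_labels,
        fit_params=(float(a), float(b)),
        fit_range_hz=(float(lo), float(hi)),
        basis=basis,
        participant_id=spec.participant_id,
        condition=spec.condition,
    )


def per_channel_band_power(
    det: DetrendedSpectrum, bands=DEFAULT_BANDS
) -> pd.DataFrame:
    """Mean residual dB per (channel, band); channels x bands DataFrame."""
    _check_bands_disjoint(bands)
    values = {}
    for band in bands:
        m = band.mask(det.freqs_hz)
        if not m.any():
            raise ValueError(f"band {band.name} resolves no grid bins")
        values[band.name] = det.residual_db[:, m].mean(axis=1)
    return pd.DataFrame(values, index=list(det.channel_labels))


def band_power(det: DetrendedSpectrum, bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Channel-averaged mean residual dB per band (long-format rows)."""
    per_channel = per_channel_band_power(det, bands)
    rows = [
        {
            "participant": det.participant_id,
            "condition": det.condition,
            "measure": name,
            "value": float(col.mean()),
        }
        for name, col in per_channel.items()
    ]
    return pd.DataFrame(rows, columns=["participant", "condition", "measure", "value"])
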