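"""Reading, writing, validating and segmenting multichannel EEG recordings.

A :class:`Recording` is the package's in-memory container: a channels x
samples matrix in microvolts with acquisition metadata (sampling rate,
10-20 channel labels, experimental condition, meditation practice).
Recordings can be loaded from EDF files (via :mod:`mne`) or from a plain
tabular text dialect: one header row of channel labels, one column per
channel, one row per sample, microvolts, no time column (time is implied
by the sampling rate).

A :class:`StudyManifest` lists the paired recordings of a within-subject
study (one meditation and one mind-wandering file per participant) and is
serialized as YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MONTAGE_10_20",
    "CONDITIONS",
    "PRACTICES",
    "Recording",
    "ManifestEntry",
    "StudyManifest",
    "read_recording",
    "write_recording",
    "select_montage",
    "segment",
    "write_table",
    "read_table",
]

#: The 16-site subset of the International 10-20 System used by low-density
#: dry-electrode headsets (frontal, central, temporal, parietal, occipital).
MONTAGE_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "T5", "T6", "P3", "P4", "O1", "O2",
)

CONDITIONS: tuple[str, ...] = ("meditation", "mind_wandering")

PRACTICES: tuple[str, ...] = (
    "shamatha", "vipassana", "zazen", "dzogchen", "tonglen",
    "visualization", "unknown",
)

#: Columns of the long-format study table consumed by the statistics layer.
STUDY_TABLE_COLUMNS: tuple[str, ...] = (
    "participant", "practice", "condition", "measure", "value",
)


@dataclass
class Recording:
    """Multichannel uniformly sampled EEG with metadata.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    condition : str
        ``"meditation"`` or ``"mind_wandering"``.
    practice : str
        One of :data:`PRACTICES`.
    channel_labels : sequence of str
        Ordered, unique channel names (10-20 labels where applicable).
    rate_hz : float
        Sampling rate in Hz, strictly positive.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts; must be finite.
    line_freq_hz : float
        Mains frequency at the recording site (50 or 60 Hz).
    """

    participant_id: str
    condition: str
    practice: str
    channel_labels: tuple[str, ...]
    rate_hz: float
    data: np.ndarray
    line_freq_hz: float = 50.0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.practice not in PRACTICES:
            raise ValueError(
                f"practice must be one of {PRACTICES}, got {self.practice!r}"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.rate_hz > 0:
            raise ValueError(f"rate_hz must be > 0, got {self.rate_hz}")
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch, samp = np.argwhere(bad)[0]
            raise ValueError(
                "non-finite value in recording at channel "
                f"{self.channel_labels[ch]!r}, sample {samp}"
            )
        unknown = [c for c in self.channel_labels if c not in MONTAGE_10_20]
        if unknown:
            warnings.warn(
                f"channel labels not in the 10-20 montage list: {unknown}; "
                "keeping them verbatim",
                stacklevel=2,
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class ManifestEntry:
    """Paired recording paths for one participant."""

    participant_id: str
    practice: str
    meditation_path: str
    mind_wandering_path: str
    line_freq_hz: float = 50.0


@dataclass
class StudyManifest:
    """Per-study list of paired recordings plus study-level options."""

    entries: list[ManifestEntry] = field(default_factory=list)
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.participant_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant_id in manifest")

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "options": self.options,
            "participants": [
                {
                    "participant_id": e.participant_id,
                    "practice": e.practice,
                    "meditation_path": e.meditation_path,
                    "mind_wandering_path": e.mind_wandering_path,
                    "line_freq_hz": e.line_freq_hz,
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        doc = yaml.safe_load(Path(path).read_text())
        entries = [
            ManifestEntry(
                participant_id=str(p["participant_id"]),
                practice=p.get("practice", "unknown"),
                meditation_path=p["meditation_path"],
                mind_wandering_path=p["mind_wandering_path"],
                line_freq_hz=float(p.get("line_freq_hz", 50.0)),
            )
            for p in (doc.get("participants") or [])
        ]
        return cls(entries=entries, options=doc.get("options") or {})


def _infer_format(path: Path) -> str:
    if path.suffix.lower() == ".edf":
        return "edf"
    return "tabular_text"


def read_recording(
    path: str | Path,
    format: str | None = None,
    *,
    participant_id: str = "unknown",
    condition: str = "meditation",
    practice: str = "unknown",
    rate_hz: float | None = None,
    line_freq_hz: float = 50.0,
) -> Recording:
    """Read a recording from an EDF or tabular text file.

    The tabular dialect is one header row of channel labels and one column
    per channel in microvolts; the sampling rate must then be supplied via
    ``rate_hz``. For EDF the rate and labels come from the file header and
    the signal is converted to microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne loads volts; we keep microvolts
        labels = tuple(raw.ch_names)
        rate = float(raw.info["sfreq"])
    elif fmt == "tabular_text":
        if rate_hz is None:
            raise ValueError("tabular text carries no rate; pass rate_hz")
        frame = pd.read_csv(path, sep="\t", header=0)
        if frame.shape[1] == 0:
            raise ValueError(f"no channels parsed from {path}")
        bad = frame.isna()
        if bad.to_numpy().any():
            row = int(bad.any(axis=1).idxmax())
            col = bad.columns[bad.loc[row].to_numpy().argmax()]
            raise ValueError(
                f"missing/NaN value at data row {row}, channel {col!r} in {path}"
            )
        data = frame.to_numpy(dtype=np.float64).T
        labels = tuple(frame.columns)
        rate = float(rate_hz)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return Recording(
        participant_id=participant_id,
        condition=condition,
        practice=practice,
        channel_labels=labels,
        rate_hz=rate,
        data=data,
        line_freq_hz=line_freq_hz,
    )


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the tabular text dialect (lossless to ~1e-8 uV)."""
    frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    frame.to_csv(path, sep="\t", index=False, float_format="%.8f")


def select_montage(rec: Recording, wanted: Sequence[str]) -> Recording:
    """Reorder channels to ``wanted`` order, dropping all others."""
    missing = [c for c in wanted if c not in rec.channel_labels]
    if missing:
        raise ValueError(f"channels absent from recording: {missing}")
    idx = [rec.channel_labels.index(c) for c in wanted]
    return replace(
        rec, channel_labels=tuple(wanted), data=rec.data[idx].copy()
    )


def segment(rec: Recording, start_s: float, stop_s: float) -> Recording:
    """Sample-accurate half-open slice [start_s * rate, stop_s * rate)."""
    if not (0 <= start_s < stop_s <= rec.duration_s + 1e-12):
        raise ValueError(
            f"segment bounds [{start_s}, {stop_s}) outside "
            f"[0, {rec.duration_s:.6f}] or empty"
        )
    i0 = int(round(start_s * rec.rate_hz))
    i1 = int(round(stop_s * rec.rate_hz))
    return replace(rec, data=rec.data[:, i0:i1].copy())


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format study table as TSV with a stable column order."""
    missing = [c for c in STUDY_TABLE_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    rows[list(STUDY_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a study table written by :func:`write_table`."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"participant": str, "practice": str,
                               "condition": str, "measure": str},
    )
    return frame
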