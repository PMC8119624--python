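"""End-to-end study analysis: recordings -> report tables.

``run_study`` drives the full chain for a paired-condition study, from a
manifest of recordings (or a synthetic study generated on the fly) to the
result tables: the long-format study table of per-participant measures
(LZc plus six detrended band powers), the repeated-measures ANOVA per
measure with partial eta squared and Cohen's f, per-practice channel x
band contrast maps with FDR, and per-practice bootstrap difference
curves. Every tunable stage parameter lives in :class:`RunConfig` and is
echoed into ``run_metadata.json`` together with all derived seeds.
"""

from __future__ import annotations

import json
import shutil
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .complexity import lzc_for_recording
from .io_signals import (
    MONTAGE_10_20,
    Recording,
    StudyManifest,
    read_recording,
    select_montage,
    write_table,
)
from .preprocessing import (
    bandpass_fir,
    notch_filter,
    reject_artifact_segments,
    write_rejection_log,
)
from .spectral import (
    DEFAULT_BANDS,
    band_power,
    compute_psd,
    fit_one_over_f,
    per_channel_band_power,
)
from .stats import (
    bootstrap_band_difference,
    cell_tests,
    cohens_f_from_eta2,
    rm_anova_two_level,
)
from .synthetic import BandPeak, SyntheticStudyConfig, generate_study

__all__ = ["RunConfig", "StageError", "run_study", "make_report"]

MEASURES: tuple[str, ...] = (
    "LZc", "delta", "theta", "alpha", "beta1", "beta2", "beta3",
)


class StageError(RuntimeError):
    """A pipeline stage failed for a named participant."""

    def __init__(self, participant: str, stage: str, cause: Exception):
        super().__init__(
            f"participant {participant!r}, stage {stage!r}: {cause}"
        )
        self.participant = participant
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All tunable parameters of one study run."""

    manifest_path: str | None = None
    synthetic: dict | None = None
    outdir: str = "eegdiv_out"
    master_seed: int = 0
    keep_going: bool = False
    montage: tuple[str, ...] | None = MONTAGE_10_20
    # preprocessing
    apply_notch: bool = True
    z_threshold: float = 5.0
    min_channels_fraction: float = 0.5
    pad_s: float = 0.25
    hp_hz: float = 0.5
    lp_hz: float = 80.0
    # spectral
    psd_window_s: float = 2.0
    psd_overlap: float = 0.5
    fit_range_hz: tuple[float, float] = (1.0, 40.0)
    fit_basis: str = "power_law"
    # complexity
    lzc_window_s: float = 10.0
    n_shuffles: int = 10
    edge_trim_fraction: float = 0.05
    flatten_order: str = "time_major"
    # stats
    alpha: float = 0.05
    n_boot: int = 2000
    min_practice_n: int = 3

    def __post_init__(self) -> None:
        if self.manifest_path is None and self.synthetic is None:
            raise ValueError("config needs a manifest_path or a synthetic block")
        if self.manifest_path is not None and self.synthetic is not None:
            raise ValueError("manifest_path and synthetic are mutually exclusive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fit_range_hz" in doc:
            doc["fit_range_hz"] = tuple(doc["fit_range_hz"])
        if doc.get("montage") is not None:
            doc["montage"] = tuple(doc["montage"])
        return cls(**doc)

    def synthetic_config(self) -> SyntheticStudyConfig:
        block = dict(self.synthetic or {})
        peaks = block.pop("band_peaks", None)
        if peaks is not None:
            block["band_peaks"] = [BandPeak(**p) for p in peaks]
        block.setdefault("master_seed", self.master_seed)
        return SyntheticStudyConfig(**block)


def _participant_seed(master_seed: int, index: int, condition: str) -> int:
    offset = 0 if condition == "meditation" else 1
    return (master_seed * 1000003 + index * 131 + offset) & 0x7FFFFFFF


def _analyze_one(
    rec: Recording, cfg: RunConfig, seed: int, outdir: Path
):
    """Preprocess one recording and return its measures and spectra."""
    if cfg.montage is not None and set(cfg.montage) <= set(rec.channel_labels):
        rec = select_montage(rec, cfg.montage)
    if cfg.apply_notch:
        rec = notch_filter(rec, rec.line_freq_hz)
    rec = bandpass_fir(rec, cfg.hp_hz, cfg.lp_hz)
    clean = reject_artifact_segments(
        rec, cfg.z_threshold, cfg.min_channels_fraction, cfg.pad_s
    )
    write_rejection_log(
        clean,
        outdir / f"rejection_{rec.participant_id}_{rec.condition}.tsv",
    )
    spec = compute_psd(clean, cfg.psd_window_s, cfg.psd_overlap)
    det = fit_one_over_f(spec, cfg.fit_range_hz, basis=cfg.fit_basis)
    bands = band_power(det, DEFAULT_BANDS)
    per_channel = per_channel_band_power(det, DEFAULT_BANDS)
    lzc = lzc_for_recording(
        clean,
        window_s=cfg.lzc_window_s,
        n_shuffles=cfg.n_shuffles,
        seed=seed,
        edge_trim_fraction=cfg.edge_trim_fraction,
        order=cfg.flatten_order,
    )
    return bands, per_channel, det, lzc, clean


def run_study(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the result tables as a dict.

    Writes ``study_table.tsv``, ``anova_results.tsv``, per-practice
    ``cell_tests_*.tsv`` and ``bootstrap_*.tsv``, ``report.txt`` and
    ``run_metadata.json`` under ``cfg.outdir``. A stage failure aborts
    with the participant and stage named (unless ``keep_going``), and
    partial outputs are removed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    work = outdir / "_partial"
    if work.exists():
        shutil.rmtree(work)
    work.mkdir()
    try:
        result = _run_study_inner(cfg, outdir, work)
    except Exception:
        shutil.rmtree(work, ignore_errors=True)
        raise
    for item in work.iterdir():
        shutil.move(str(item), outdir / item.name)
    work.rmdir()
    return result


def _run_study_inner(cfg: RunConfig, outdir: Path, work: Path) -> dict:
    if cfg.synthetic is not None:
        syn = cfg.synthetic_config()
        manifest, _ = generate_study(syn, outdir / "synthetic_data")
    else:
        manifest = StudyManifest.from_yaml(cfg.manifest_path)

    rows = []
    per_channel_diffs: dict[str, list] = {}
    spectrum_diffs: dict[str, list] = {}
    practices: dict[str, str] = {}
    skipped: list[str] = []
    for index, entry in enumerate(manifest.entries):
        try:
            per_cond = {}
            for condition, path in (
                ("meditation", entry.meditation_path),
                ("mind_wandering", entry.mind_wandering_path),
            ):
                rec = read_recording(
                    path,
                    participant_id=entry.participant_id,
                    condition=condition,
                    practice=entry.practice,
                    rate_hz=manifest.options.get("rate_hz"),
                    line_freq_hz=entry.line_freq_hz,
                )
                seed = _participant_seed(cfg.master_seed, index, condition)
                per_cond[condition] = _analyze_one(rec, cfg, seed, work)
        except Exception as err:
            if cfg.keep_going:
                skipped.append(entry.participant_id)
                continue
            stage = getattr(err, "stage", "preprocess/measure")
            raise StageError(entry.participant_id, stage, err) from err

        practices[entry.participant_id] = entry.practice
        for condition, (bands, _, _, lzc, _) in per_cond.items():
            rows.append(
                {
                    "participant": entry.participant_id,
                    "practice": entry.practice,
                    "condition": condition,
                    "measure": "LZc",
                    "value": lzc.score,
                }
            )
            for _, row in bands.iterrows():
                rows.append(
                    {
                        "participant": entry.participant_id,
                        "practice": entry.practice,
                        "condition": condition,
                        "measure": row["measure"],
                        "value": row["value"],
                    }
                )
        med, mw = per_cond["meditation"], per_cond["mind_wandering"]
        diff = med[1] - mw[1]  # channels x bands
        per_channel_diffs.setdefault(entry.practice, []).append(
            (entry.participant_id, diff)
        )
        f_med, f_mw = med[2], mw[2]
        common = np.intersect1d(f_med.freqs_hz, f_mw.freqs_hz)
        d_spec = (
            f_med.channel_mean()[np.isin(f_med.freqs_hz, common)]
            - f_mw.channel_mean()[np.isin(f_mw.freqs_hz, common)]
        )
        spectrum_diffs.setdefault(entry.practice, []).append(
            (entry.participant_id, common, d_spec)
        )

    study_table = pd.DataFrame(
        rows, columns=["participant", "practice", "condition", "measure", "value"]
    )
    if study_table.empty:
        raise ValueError("no participants analyzed")
    write_table(study_table, work / "study_table.tsv")

    anova = _anova_table(study_table)
    anova.to_csv(work / "anova_results.tsv", sep="\t", index=False)

    cell_tables: dict[str, pd.DataFrame] = {}
    for practice, items in per_channel_diffs.items():
        if len(items) < cfg.min_practice_n:
            continue
        frames = [d.stack() for _, d in items]
        diffs = pd.DataFrame(
            [f.to_numpy() for f in frames], columns=frames[0].index
        )
        table = cell_tests(diffs, alpha=cfg.alpha)
        table.index.names = ["channel", "band"]
        cell_tables[practice] = table
        table.reset_index().to_csv(
            work / f"cell_tests_{practice}.tsv", sep="\t", index=False
        )

    bootstrap_tables: dict[str, pd.DataFrame] = {}
    for practice, items in spectrum_diffs.items():
        if len(items) < cfg.min_practice_n:
            continue
        freqs = items[0][1]
        diffs = pd.DataFrame(
            [d for _, _, d in items], columns=freqs
        )
        boot_seed = (
            cfg.master_seed * 7919 + zlib.crc32(practice.encode()) % 1000
        ) & 0x7FFFFFFF
        table = bootstrap_band_difference(
            diffs, n_boot=cfg.n_boot, alpha=cfg.alpha, seed=boot_seed
        )
        bootstrap_tables[practice] = table
        table.to_csv(work / f"bootstrap_{practice}.tsv", sep="\t", index=False)

    report = make_report(study_table, anova)
    (work / "report.txt").write_text(report)
    metadata = {
        "eegdiv_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "n_participants": int(study_table["participant"].nunique()),
        "skipped_participants": skipped,
        "practices": practices,
    }
    (work / "run_metadata.json").write_text(json.dumps(metadata, indent=2))
    return {
        "study_table": study_table,
        "anova": anova,
        "cell_tests": cell_tables,
        "bootstrap": bootstrap_tables,
        "report": report,
        "metadata": metadata,
    }


def _anova_table(study_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for measure in MEASURES:
        sub = study_table[study_table["measure"] == measure]
        if sub.empty:
            continue
        wide = sub.pivot(index="participant", columns="condition", values="value")
        if wide.isna().any().any():
            raise ValueError(f"incomplete pairs for measure {measure}")
        res = rm_anova_two_level(
            wide["meditation"].to_numpy(), wide["mind_wandering"].to_numpy()
        )
        rows.append(
            {
                "measure": measure,
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "partial_eta2": res.partial_eta2,
                "cohens_f": cohens_f_from_eta2(min(res.partial_eta2, 1 - 1e-12)),
                "meditation_mean": res.mean_a,
                "meditation_sd": res.sd_a,
                "mind_wandering_mean": res.mean_b,
                "mind_wandering_sd": res.sd_b,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def make_report(study_table: pd.DataFrame, anova: pd.DataFrame) -> str:
    """Human-readable summary: ANOVA lines plus a band table."""
    if study_table.empty or anova.empty:
        raise ValueError("cannot report on an empty study table")
    lines = ["Within-subject condition contrasts", "=" * 34, ""]
    for _, row in anova.iterrows():
        lines.append(
            f"{row['measure']}: F({int(row['df1'])}, {int(row['df2'])}) = "
            f"{row['F']:.2f}, p = {row['p']:.3f}, "
            f"partial eta2 = {row['partial_eta2']:.2f} "
            f"(Cohen's f = {row['cohens_f']:.2f})"
        )
    lines += ["", "Band power by state, mean (SD) of detrended dB", "-" * 46]
    lines.append(f"{'Band':<8}{'Mind wandering':>20}{'Meditation':>20}")
    for _, row in anova.iterrows():
        if row["measure"] == "LZc":
            continue
        mw = f"{row['mind_wandering_mean']:.2f} ({row['mind_wandering_sd']:.2f})"
        md = f"{row['meditation_mean']:.2f} ({row['meditation_sd']:.2f})"
        lines.append(f"{row['measure']:<8}{mw:>20}{md:>20}")
    lzc = anova[anova["measure"] == "LZc"]
    if not lzc.empty:
        row = lzc.iloc[0]
        lines += [
            "",
            f"LZc: meditation M = {row['meditation_mean']:.2f} "
            f"(SD = {row['meditation_sd']:.2f}), mind wandering "
            f"M = {row['mind_wandering_mean']:.2f} "
            f"(SD = {row['mind_wandering_sd']:.2f})",
        ]
    return "\n".join(lines) + "\n"
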