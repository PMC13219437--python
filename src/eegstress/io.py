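"""Delimiter-separated readers and writers for signals, tables and rankings.

Per-subject signal files are CSV with a leading time column followed by one
column per electrode; the participants table is CSV with subject_id and
psq_score (plus true_class for synthetic cohorts). A JSON manifest records
the generating parameters alongside every written cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import EEGRecording
from .simulate import SimParams, SyntheticCohort

logger = logging.getLogger(__name__)

PARTICIPANTS_FILE = "participants.csv"
MANIFEST_FILE = "manifest.json"


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Serialize a synthetic cohort: one signal CSV per subject, a
    participants table, and a manifest with the simulation parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_recording(rec, directory / f"{rec.subject_id}.csv")
    cohort.participants.to_csv(directory / PARTICIPANTS_FILE, index=False)
    params = dataclasses.asdict(cohort.params)
    params["channels"] = list(params["channels"])
    params["planted_features"] = list(params["planted_features"])
    params["psq_mean_by_class"] = list(params["psq_mean_by_class"])
    params["psq_range"] = list(params["psq_range"])
    params["noise_spectrum"] = dict(params["noise_spectrum"])
    (directory / MANIFEST_FILE).write_text(
        json.dumps({"sim_params": params}, indent=2) + "\n"
    )
    return directory


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(rec.channel_names):
        df[ch] = rec.samples[i]
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(
    path: str | Path, montage: tuple[str, ...], fs: float
) -> EEGRecording:
    """One subject's signal file; the subject id is the file stem."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [ch for ch in montage if ch not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing electrode column(s) {missing}")
    samples = df[list(montage)].to_numpy(dtype=float).T
    return EEGRecording(
        subject_id=path.stem, channel_names=tuple(montage), fs=fs,
        samples=samples,
    )


def read_signals(
    directory: str | Path,
    montage: tuple[str, ...],
    fs: float,
    min_duration_s: float | None = None,
) -> tuple[list[EEGRecording], list[dict]]:
    """All per-subject signal files in a directory.

    Subjects with missing electrode columns or non-finite samples are
    skipped with a logged reason; with ``min_duration_s`` set, shorter
    recordings are dropped too. Returns (recordings, skip records).
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.glob("*.csv") if p.name != PARTICIPANTS_FILE
    )
    if not files:
        raise FileNotFoundError(f"no signal files in {directory}")
    recordings: list[EEGRecording] = []
    skipped: list[dict] = []
    for path in files:
        try:
            rec = read_recording(path, montage, fs)
        except ValueError as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append({"subject": path.stem, "reason": str(exc)})
            continue
        if min_duration_s is not None and rec.duration_s < min_duration_s:
            reason = (
                f"duration {rec.duration_s:.1f} s below required "
                f"{min_duration_s:.1f} s"
            )
            logger.warning("skipping %s: %s", path.name, reason)
            skipped.append({"subject": path.stem, "reason": reason})
            continue
        recordings.append(rec)
    logger.info(
        "read %d recordings (%d skipped) from %s",
        len(recordings), len(skipped), directory,
    )
    return recordings, skipped


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "psq_score" not in df.columns:
        raise ValueError(
            f"{path}: participants table needs subject_id and psq_score columns"
        )
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_sim_params(directory: str | Path) -> SimParams:
    manifest = json.loads((Path(directory) / MANIFEST_FILE).read_text())
    p = manifest["sim_params"]
    return SimParams(
        n_subjects=p["n_subjects"],
        channels=tuple(p["channels"]),
        fs=p["fs"],
        duration_s=p["duration_s"],
        stress_prevalence=p["stress_prevalence"],
        psq_mean_by_class=tuple(p["psq_mean_by_class"]),
        psq_sd=p["psq_sd"],
        psq_range=tuple(p["psq_range"]),
        effect_size=p["effect_size"],
        planted_features=tuple(p["planted_features"]),
        noise_spectrum=p["noise_spectrum"],
        seed=p["seed"],
    )
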