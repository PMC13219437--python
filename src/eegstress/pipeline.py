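"""End-to-end orchestration: segment -> features -> label -> select -> CV.

``run_pipeline`` executes every configured (segmentation scheme, classifier)
pair on a cohort and returns the per-run metric reports, the comparison
table, and a run manifest carrying the full configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as eio
from .evaluation import (
    CLASSIFIER_NAMES,
    ClassifierSpec,
    MetricsReport,
    compare_report,
    cross_validate,
)
from .features import FeatureOptions, build_feature_table
from .labeling import assign_labels, attach_labels, compute_thresholds
from .segmentation import (
    DEFAULT_MONTAGE,
    EEGRecording,
    SegmentationScheme,
    segment_recording,
)
from .selection import DiscretizationSpec, rank_and_select

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    signals_dir: str | None = None
    participants_path: str | None = None
    output_dir: str = "eegstress_out"
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    fs: float = 250.0
    min_duration_s: float | None = None
    schemes: tuple[SegmentationScheme, ...] = (
        SegmentationScheme("non_overlapping", window_s=10.0),
        SegmentationScheme("overlapping", window_s=20.0, step_s=10.0),
    )
    feature_options: FeatureOptions = field(default_factory=FeatureOptions)
    aggregation: str = "per_subject_mean"
    labeling_moments: tuple[float, float] | None = None  # (mu, sigma) override
    k_features: int = 10
    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    n_folds: int = 10
    stratified: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifier(s): {sorted(unknown)}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        object.__setattr__(self, "montage", tuple(self.montage))
        object.__setattr__(self, "schemes", tuple(self.schemes))
        object.__setattr__(self, "classifiers", tuple(self.classifiers))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        schemes = tuple(
            SegmentationScheme(**s) for s in raw.pop("schemes", [])
        ) or cls.schemes
        fo = FeatureOptions(**raw.pop("feature_options", {}))
        disc = DiscretizationSpec(**raw.pop("discretization", {}))
        for key in ("montage", "classifiers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "labeling_moments" in raw and raw["labeling_moments"] is not None:
            raw["labeling_moments"] = tuple(raw["labeling_moments"])
        return cls(
            schemes=schemes, feature_options=fo, discretization=disc, **raw
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schemes"] = [dataclasses.asdict(s) for s in self.schemes]
        d["feature_options"] = dataclasses.asdict(self.feature_options)
        d["discretization"] = dataclasses.asdict(self.discretization)
        d["montage"] = list(self.montage)
        d["classifiers"] = list(self.classifiers)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RunManifest:
    config: dict
    config_hash: str
    stage_timings: Mapping[str, float]
    warnings: tuple[str, ...]
    retained_subjects: Mapping[str, int]

    def write(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "config_hash": self.config_hash,
            "stage_timings_s": dict(self.stage_timings),
            "warnings": list(self.warnings),
            "retained_subjects": dict(self.retained_subjects),
        }
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        tmp.replace(path)


@dataclass(frozen=True)
class PipelineResult:
    reports: Mapping[tuple[str, str], MetricsReport]
    rankings: Mapping[str, pd.DataFrame]
    comparison: pd.DataFrame
    manifest: RunManifest


def run_pipeline(
    config: PipelineConfig,
    recordings: list[EEGRecording] | None = None,
    participants: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every configured (scheme, classifier) pair.

    Inputs may be passed in memory or read from the configured paths.
    All randomness flows from ``config.seed``.
    """
    timings: dict[str, float] = {}
    warnings: list[str] = []
    t0 = time.perf_counter()
    if recordings is None:
        if config.signals_dir is None:
            raise ValueError("no recordings supplied and no signals_dir configured")
        recordings, skipped = eio.read_signals(
            config.signals_dir, config.montage, config.fs,
            min_duration_s=config.min_duration_s,
        )
        warnings.extend(f"skipped {s['subject']}: {s['reason']}" for s in skipped)
    if participants is None:
        if config.participants_path is None:
            raise ValueError("no participants table supplied or configured")
        participants = eio.read_participants(config.participants_path)
    timings["ingest"] = time.perf_counter() - t0

    subject_ids = {r.subject_id for r in recordings}
    scores = participants[participants["subject_id"].astype(str).isin(subject_ids)]
    if config.labeling_moments is not None:
        from .labeling import LabelingRule

        rule = LabelingRule(*config.labeling_moments)
    else:
        rule = compute_thresholds(scores["psq_score"].to_numpy())
    labels = assign_labels(scores, rule)

    reports: dict[tuple[str, str], MetricsReport] = {}
    rankings: dict[str, pd.DataFrame] = {}
    retained: dict[str, int] = {}
    for scheme in config.schemes:
        t1 = time.perf_counter()
        segments = []
        for rec in recordings:
            segments.extend(segment_recording(rec, scheme))
        if not segments:
            raise RuntimeError(
                f"stage segmentation ({scheme.mode}): no segments produced"
            )
        table = build_feature_table(
            segments, aggregation=config.aggregation,
            options=config.feature_options,
        )
        timings[f"features_{scheme.mode}"] = time.perf_counter() - t1
        labeled = attach_labels(table, labels)
        retained[scheme.mode] = len(labeled)
        ranked = rank_and_select(
            labeled, k=config.k_features, disc=config.discretization
        )
        rankings[scheme.mode] = ranked.to_frame()
        selected = labeled[list(ranked.selected) + ["label"]]
        for name in config.classifiers:
            t2 = time.perf_counter()
            rep = cross_validate(
                selected, ClassifierSpec(name), n_folds=config.n_folds,
                seed=config.seed, stratified=config.stratified,
            )
            reports[(name, scheme.mode)] = rep
            timings[f"cv_{name}_{scheme.mode}"] = time.perf_counter() - t2

    comparison = compare_report(reports)
    manifest = RunManifest(
        config=config.to_dict(),
        config_hash=config.config_hash,
        stage_timings=timings,
        warnings=tuple(warnings),
        retained_subjects=retained,
    )
    return PipelineResult(
        reports=reports, rankings=rankings, comparison=comparison,
        manifest=manifest,
    )


def write_result(result: PipelineResult, output_dir: str | Path) -> Path:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = result.manifest.config_hash
    result.comparison.to_csv(out / f"comparison_{h}.csv", index=False)
    for mode, ranking in result.rankings.items():
        ranking.to_csv(out / f"ranking_{mode}_{h}.csv", index=False)
    for (name, mode), rep in result.reports.items():
        rep.confusion.to_frame().to_csv(out / f"confusion_{name}_{mode}_{h}.csv")
    result.manifest.write(out / f"manifest_{h}.json")
    return out
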