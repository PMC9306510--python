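"""End-to-end pipeline: simulate -> detect -> measure -> classify -> compare.

A :class:`PipelineConfig` fully determines every output: all randomness
fans out from the single scenario seed (per-stage, per-cell child
streams), configs round-trip through YAML unchanged, and every output
file carries the SHA-256 hash of the canonical config, so re-running the
same configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import detect as det
from . import io as pio
from .events import EventTable, FilterCriteria, filter_events, measure_detections
from .simulate import CohortScenario, SimulationConfig, generate_cohort
from .stats import ComparisonConfig, run_comparison

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class DetectionSettings:
    template_rise_ms: float = 3.0
    template_decay_ms: float = 12.0
    threshold: float = 0.6
    refractory_ms: float = 2.0
    correlation_window_ms: float = 10.0


@dataclass(frozen=True)
class PipelineConfig:
    scenario: CohortScenario = field(default_factory=CohortScenario)
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    filters: FilterCriteria = field(default_factory=FilterCriteria)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    save_traces: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        scen = dict(d.get("scenario", {}))
        if "vehicle" in scen:
            scen["vehicle"] = SimulationConfig(**scen["vehicle"])
        return cls(
            scenario=CohortScenario(**scen),
            detection=DetectionSettings(**d.get("detection", {})),
            filters=FilterCriteria(**d.get("filters", {})),
            comparison=ComparisonConfig(**d.get("comparison", {})),
            save_traces=bool(d.get("save_traces", False)),
        )

    def to_yaml(self, path) -> None:
        pio.dump_yaml(path, self.to_dict())

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(pio.load_yaml(path))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, exc) from exc
            log.info("stage %-12s %.1f s", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("simulate")
def _simulate(config: PipelineConfig) -> dict:
    return generate_cohort(config.scenario)


@_stage("detect")
def _detect_and_measure(config: PipelineConfig, cohort: dict) -> dict[str, EventTable]:
    d = config.detection
    tables = {}
    for condition, cells in cohort.items():
        all_events = []
        for cell_id, cell in cells.items():
            trace = cell["trace"]
            template = det.build_template(d.template_rise_ms, d.template_decay_ms,
                                          trace.sampling_rate)
            result = det.detect_events(
                trace, template, d.threshold, d.refractory_ms,
                correlation_window_ms=d.correlation_window_ms)
            all_events.extend(measure_detections(
                trace, result, window_ms=template.length_ms, condition=condition))
        tables[condition] = filter_events(all_events, config.filters)
    return tables


@_stage("compare")
def _compare(config: PipelineConfig, tables: dict, durations: dict):
    return run_comparison(tables["vehicle"], tables["treated"],
                          config.comparison, recording_durations=durations)


def _json_default(o):
    if isinstance(o, (pd.DataFrame,)):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis and write the report bundle under ``outdir``.

    Writes per-arm event tables (CSV), ground truth (CSV), the comparison
    report (JSON), a manifest with the config hash and seeds, and —
    optionally — the raw traces (HDF5).  Returns the report dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    cohort = _simulate(config)
    durations = {}
    for condition, cells in cohort.items():
        pio.write_ground_truth_csv(outdir / f"ground_truth_{condition}.csv", cells)
        for cell_id, cell in cells.items():
            durations[cell_id] = cell["config"].duration
        if config.save_traces:
            pio.write_traces_hdf5(outdir / f"traces_{condition}.h5",
                                  {cid: c["trace"] for cid, c in cells.items()})

    tables = _detect_and_measure(config, cohort)
    for condition, table in tables.items():
        table.to_csv(outdir / f"events_{condition}.csv")

    report_obj = _compare(config, tables, durations)
    report = {"config_hash": chash, **report_obj.to_dict()}
    with open(outdir / "report.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True, default=_json_default)

    manifest = {
        "config_hash": chash,
        "config": config.to_dict(),
        "cells": {cond: sorted(cells) for cond, cells in cohort.items()},
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return report
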