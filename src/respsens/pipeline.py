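"""End-to-end pipeline: wells → CV75 → dose plan → rMFI → calls → accuracy."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .cytometry import rmfi_from_events, apply_viability_gate, compute_rmfi
from .errors import ConfigurationError, RespsensError
from .io import (
    read_events,
    read_mfi_summary,
    read_panel,
    read_wells,
    wells_from_frame,
    write_json,
)
from .prediction import DEFAULT_CRITERIA, panel_accuracy, threshold_call
from .types import (
    AVERAGE_CURVE,
    Criterion,
    MarkerMeasurement,
    RmfiResult,
    TIERS,
)
from .viability import build_dose_response, compute_cv75, select_exposure_doses

log = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Paths, criteria and gates for one end-to-end analysis run."""

    model_config = ConfigDict(frozen=True)

    wells_path: Optional[str] = None
    events_path: Optional[str] = None
    mfi_summary_path: Optional[str] = None
    panel_path: str
    out_dir: str
    criteria: Dict[str, Tuple[float, ...]] = Field(
        default_factory=lambda: {m: tuple(t) for m, t in DEFAULT_CRITERIA.items()}
    )
    accuracy_marker: str = "TSLPr"
    viability_gate: float = 75.0
    dead_stain_cutoff: Optional[float] = None  # gate raw intensities when set
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.viability_gate <= 100:
            raise ConfigurationError("viability_gate must lie in (0, 100]")
        for marker, thresholds in self.criteria.items():
            if any(t <= 100 for t in thresholds):
                raise ConfigurationError(f"thresholds must exceed 100% ({marker})")
        if self.events_path is None and self.mfi_summary_path is None:
            raise ConfigurationError("need events_path or mfi_summary_path")
        return self


def _stage(name: str):
    """Decorator attaching the stage name to propagated errors."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except RespsensError as e:
                raise type(e)(f"[stage {name}] {e}") from e
        return inner
    return wrap


@_stage("viability")
def _viability_stage(config: PipelineConfig, panel: List[dict]):
    curves_rows, cv75_report = [], {}
    if config.wells_path is None:
        return pd.DataFrame(), cv75_report
    wells = wells_from_frame(read_wells(config.wells_path))
    max_dose = {p["chemical"]: p.get("max_tested_dose") for p in panel}
    for chemical, readings in wells.items():
        curves = build_dose_response(readings)
        for curve_id, pts in curves.items():
            for p in pts:
                curves_rows.append({
                    "chemical": chemical, "curve_id": curve_id,
                    "dose_ug_cm2": p.dose, "viability_pct": p.viability,
                })
        result = compute_cv75(curves[AVERAGE_CURVE])
        mtd = max_dose.get(chemical) or max(p.dose for p in curves[AVERAGE_CURVE])
        plan = select_exposure_doses(result, max_tested_dose=mtd)
        cv75_report[chemical] = {
            "cv75_ug_cm2": result.cv75,
            "fallback": result.fallback,
            "bracket": (
                None if result.bracket is None
                else {k: getattr(result.bracket, k) for k in ("a", "b", "c", "d")}
            ),
            "plan": {
                "high_dose": plan.high_dose,
                "low_dose": plan.low_dose,
                "source": plan.source,
            },
        }
        log.info("chemical %s: CV75=%s plan=%s", chemical, result.cv75, plan)
    return pd.DataFrame(curves_rows), cv75_report


@_stage("cytometry")
def _rmfi_stage(config: PipelineConfig, panel: List[dict]) -> List[dict]:
    rows: List[dict] = []
    gate_kwargs = {}
    if config.dead_stain_cutoff is not None:
        gate_kwargs = {
            "dead_stain_col": "dead_stain", "dead_stain_cutoff": config.dead_stain_cutoff
        }
    if config.events_path is not None:
        events = read_events(config.events_path)
        by_condition = dict(tuple(events.groupby("condition_id")))
        for entry in panel:
            vehicle = by_condition[entry["vehicle_condition"]]
            for tier in TIERS:
                sample = by_condition[entry["conditions"][tier]]
                for marker in sorted(config.criteria):
                    result, frac = rmfi_from_events(
                        sample, vehicle, marker, gate=config.viability_gate, **gate_kwargs
                    )
                    rows.append(_rmfi_row(entry["chemical"], tier, result, frac))
    else:
        summary = read_mfi_summary(config.mfi_summary_path)
        for _, r in summary.iterrows():
            m = MarkerMeasurement(
                marker=r["marker"],
                mfi_sample=r["mfi_sample"],
                mfi_isotype_sample=r["mfi_isotype_sample"],
                mfi_vehicle=r["mfi_vehicle"],
                mfi_isotype_vehicle=r["mfi_isotype_vehicle"],
                viable_fraction=r["viable_fraction"],
                n_events=int(r.get("n_events", 0)),
            )
            result = apply_viability_gate(
                compute_rmfi(m), m.viable_fraction, gate=config.viability_gate
            )
            rows.append(_rmfi_row(r["chemical"], r["dose_tier"], result, m.viable_fraction))
    return rows


def _rmfi_row(chemical: str, tier: str, result: RmfiResult, viable_fraction: float) -> dict:
    return {
        "chemical": chemical, "dose_tier": tier, "marker": result.marker,
        "rmfi_pct": result.rmfi, "viable_fraction": viable_fraction,
        "evaluable": result.evaluable, "exclusion_reason": result.exclusion_reason or "",
    }


@_stage("prediction")
def _prediction_stage(config: PipelineConfig, panel: List[dict], rmfi_rows: List[dict]):
    truth = {p["chemical"]: bool(p.get("respiratory_sensitizer", False)) for p in panel}
    calls = []
    for row in rmfi_rows:
        result = RmfiResult(
            marker=row["marker"],
            rmfi=row["rmfi_pct"],
            evaluable=row["evaluable"],
            exclusion_reason=row["exclusion_reason"] or None,
        )
        for thr in config.criteria.get(row["marker"], ()):
            calls.append(threshold_call(
                result, Criterion(marker=row["marker"], threshold=thr),
                chemical=row["chemical"], dose_tier=row["dose_tier"],
            ))
    accuracy = {}
    for tier in TIERS:
        accuracy[tier] = {}
        for thr in config.criteria[config.accuracy_marker]:
            subset = [
                c for c in calls
                if c.dose_tier == tier and c.marker == config.accuracy_marker
                and c.threshold == thr
            ]
            report = panel_accuracy(subset, truth)
            accuracy[tier][f"{thr:g}"] = {
                "accuracy_pct": report.accuracy,
                "n_evaluable": report.n_evaluable,
                "n_correct": report.n_correct,
            }
    return calls, accuracy


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``out_dir``.

    Produces ``curves.csv``, ``cv75.json``, ``rmfi.csv``, ``calls.csv``,
    ``accuracy.json`` and a ``provenance.json`` recording the package
    version, seed and every gate and threshold applied. Byte-identical for
    identical configs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = read_panel(config.panel_path)

    curves, cv75_report = _viability_stage(config, panel)
    rmfi_rows = _rmfi_stage(config, panel)
    calls, accuracy = _prediction_stage(config, panel, rmfi_rows)

    if len(curves):
        curves.to_csv(out / "curves.csv", index=False)
    write_json(cv75_report, out / "cv75.json")
    pd.DataFrame(rmfi_rows).to_csv(out / "rmfi.csv", index=False)
    pd.DataFrame([{
        "chemical": c.chemical, "dose_tier": c.dose_tier, "marker": c.marker,
        "threshold_pct": c.threshold, "call": c.call,
    } for c in calls]).to_csv(out / "calls.csv", index=False)
    write_json(accuracy, out / "accuracy.json")
    write_json({
        "package": "respsens",
        "version": __version__,
        "seed": config.seed,
        "viability_gate_pct": config.viability_gate,
        "criteria": {m: list(t) for m, t in config.criteria.items()},
        "accuracy_marker": config.accuracy_marker,
        "inputs": {
            "wells": config.wells_path,
            "events": config.events_path,
            "mfi_summary": config.mfi_summary_path,
            "panel": config.panel_path,
        },
    }, out / "provenance.json")

    return {
        "curves": curves,
        "cv75": cv75_report,
        "rmfi": rmfi_rows,
        "calls": calls,
        "accuracy": accuracy,
        "out_dir": str(out),
    }
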