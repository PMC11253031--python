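"""End-to-end orchestration: simulate -> build cohort -> classify ->
link events -> validate -> report.

Each stage writes its artifact into the output directory; a ``MANIFEST``
records the stage sequence and, on failure, which stage broke.  All step
counts are logged as ``key=value`` pairs so runs are machine-checkable,
and the summary JSON is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from . import cohort_builder, event_linker, synthetic_registry
from .dislocation_algorithm import (
    compile_stages,
    flag_patients,
    match_contact,
    write_flags,
    write_matches,
)
from .registry_model import Source, bundle_to_dir
from .validation_metrics import (
    build_report,
    confusion,
    diagnostic_metrics,
    hospital_incidence_range,
    incidence_by_group,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


class RunConfig(BaseModel):
    """Resolved configuration of one full pipeline run."""

    seed: int
    n: int = Field(2000, ge=0)
    out_dir: Path
    params_path: Optional[Path] = None
    stage_spec_path: Optional[Path] = None
    horizon_days: int = 365
    gap_days: int = 1
    min_volume: int = 100
    delimiter: str = ","


def _load_yaml(path: Optional[Path]) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the JSON-ready summary dict.

    Artifacts land in ``config.out_dir``: the five simulated tables under
    ``sim/``, then ``cohort.csv``, ``flags_stage{1..4}.csv``,
    ``matches.csv``, ``events.csv``, ``report.json``/``report.txt``,
    ``summary.json`` and ``MANIFEST.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "failed_stage": None}
    summary: dict = {"config": json.loads(config.model_dump_json())}

    def record(stage: str, **counts):
        manifest["stages"].append(stage)
        pairs = " ".join(f"{k}={v}" for k, v in counts.items())
        logger.info("stage=%s %s", stage, pairs)
        summary.setdefault("counts", {}).update(
            {f"{stage}.{k}": v for k, v in counts.items()})

    current_stage = "simulate"
    try:
        overrides = _load_yaml(config.params_path)
        overrides.setdefault("cohort_n", config.n)
        overrides.setdefault("horizon_days", config.horizon_days)
        params = synthetic_registry.default_params(**overrides)
        bundle = synthetic_registry.generate_registry(params, config.seed)
        sim_dir = out / "sim"
        bundle_to_dir(bundle, sim_dir, delimiter=config.delimiter)
        (sim_dir / "provenance.json").write_text(
            json.dumps(bundle.provenance, indent=2, default=str) + "\n")
        record("simulate", thas=len(bundle.thas), contacts=len(bundle.contacts),
               gold_events=len(bundle.gold_events))

        current_stage = "build-cohort"
        arthro = [t for t in bundle.thas
                  if t.source is Source.ARTHROPLASTY_REGISTER]
        fracture = [t for t in bundle.thas
                    if t.source is Source.FRACTURE_REGISTER]
        cohort = cohort_builder.build_cohort(
            arthro, fracture, bundle.revisions, bundle.vitals,
            params.inclusion_window, horizon_days=config.horizon_days)
        cohort_builder.write_cohort(cohort, out / "cohort.csv")
        (out / "flowchart.json").write_text(json.dumps({
            "input": len(bundle.thas),
            "included": len(cohort),
            "excluded": cohort.exclusion_counts,
            "inclusion_window": [d.isoformat()
                                 for d in cohort.inclusion_window],
        }, indent=2) + "\n")
        record("build-cohort", included=len(cohort),
               **{f"excluded_{k}": v
                  for k, v in cohort.exclusion_counts.items()})

        current_stage = "classify"
        cfg = compile_stages(_load_yaml(config.stage_spec_path) or None)
        tha_by_patient = {t.patient_id: (t, w) for t, w in cohort.members}
        matches = []
        for c in bundle.contacts:
            entry = tha_by_patient.get(c.patient_id)
            if entry is None or not entry[1].contains(c.start_date):
                continue
            matches.append(match_contact(c, entry[0], cfg))
        write_matches(matches, out / "matches.csv")
        flags_by_stage = {}
        for stage in range(1, cfg.n_stages + 1):
            flags = flag_patients(cohort, bundle.contacts, cfg, stage)
            flags_by_stage[stage] = flags
            write_flags(flags, out / f"flags_stage{stage}.csv")
            record(f"classify-stage{stage}",
                   flagged=sum(f.flagged for f in flags))

        current_stage = "link-events"
        gold_channel = [c for c in bundle.contacts
                        if c.n_dislocations_in_admission >= 1
                        and c.patient_id in tha_by_patient]
        index_sides = {t.patient_id: t.side for t, _ in cohort.members}
        events = event_linker.collapse_events(
            gold_channel, gap_days=config.gap_days, index_sides=index_sides)
        event_linker.write_events(events, out / "events.csv")
        rec = event_linker.recurrence_summary(events)
        record("link-events", contacts=len(gold_channel), events=len(events),
               patients=rec.n_patients)

        current_stage = "validate"
        gold_patients = {e.patient_id for e in bundle.gold_events
                         if e.patient_id in tha_by_patient}
        two_by_twos = {}
        stage_metrics = []
        for stage, flags in flags_by_stage.items():
            tb = confusion(cohort, gold_patients, flags)
            two_by_twos[stage] = tb
            stage_metrics.append(diagnostic_metrics(tb, stage=stage))
        incidence = incidence_by_group(cohort, gold_patients)
        hosp_range = hospital_incidence_range(cohort, gold_patients,
                                              config.min_volume)
        report = build_report(
            stage_metrics, two_by_twos, incidence,
            recurrence=rec.recurrence, hospital_range=hosp_range,
            hospital_range_min_volume=config.min_volume,
            counts={"cohort": len(cohort),
                    "gold_patients": len(gold_patients),
                    "gold_events": len(events)})
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "report.txt").write_text(report.to_text())
        record("validate", gold_patients=len(gold_patients))

        summary["report"] = report.to_json_dict()
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        manifest["status"] = "ok"
        return summary
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current_stage
        raise
    finally:
        (out / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2) + "\n")
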