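"""End-to-end orchestration: wells in, potency and specificity calls out.

Stage order for each laboratory dataset: validate -> endpoint construction
-> vehicle-control QC -> BMR selection -> BMC fitting (test substances and
weekly-pooled PC) -> PC/duplicate/variability QC -> specificity scoring and
classification -> ontology collapse -> flat-file artifacts.  Every stage
writes its artifact as soon as it completes, so a failure in a later stage
(e.g. a missing mapping table) leaves the earlier outputs on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import bmc as bmc_mod
from . import endpoints as ep_mod
from . import ontology as onto_mod
from . import qc as qc_mod
from . import specificity as spec_mod
from .core_model import PlateDesign, RecordingDef, validate_dataset
from .io import read_manifest_csv, read_recordings_csv, read_wells_csv, recordings_from_frame

__all__ = ["RunConfig", "DatasetConfig", "PipelineError", "LabResults", "run_pipeline", "analyze_lab"]

logger = logging.getLogger(__name__)


class DatasetConfig(BaseModel):
    lab_id: str
    wells: str
    recordings: str


class RunConfig(BaseModel):
    """Run-level configuration (YAML-loadable)."""

    datasets: list[DatasetConfig]
    manifest: str
    mapping: Optional[str] = None
    outdir: str = "seazit-out"
    grid_start: float = Field(default=5.0, gt=0, lt=100)
    grid_stop: float = Field(default=95.0, gt=0, lt=100)
    grid_step: float = Field(default=5.0, gt=0)
    bmr_tol: float = Field(default=0.05, gt=0, lt=1)
    vc_threshold_pct: float = Field(default=20.0, gt=0)
    duplicate_threshold_log10: float = Field(default=0.5, gt=0)
    cutoff_quantile: float = Field(default=0.05, gt=0, lt=1)
    anchor_baseline: bool = True
    strict_qc: bool = False
    collapse_level: str = "general"
    seed: int = 0

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + 1e-9, self.grid_step)


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name and offending keys."""

    def __init__(self, stage: str, message: str, keys: Sequence[str] = ()):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.keys = list(keys)


@dataclass
class LabResults:
    """All per-laboratory analysis products."""

    lab_id: str
    violations: list
    curves: list
    vc_flags: pd.DataFrame
    bmr: dict[str, bmc_mod.BMRSelection]
    bmc_results: list[bmc_mod.BMCResult]
    pc_results: list[bmc_mod.BMCResult]
    qc_report: qc_mod.QCReport
    scores: list[spec_mod.SpecificityScore]
    cutoff: float
    plate_classes: pd.DataFrame
    substance_calls: list[spec_mod.SubstanceCall]
    group_calls: list[onto_mod.GroupCall] = field(default_factory=list)
    excluded_plates: list[str] = field(default_factory=list)


def _vc_baselines(
    wells: pd.DataFrame, recordings: Sequence[RecordingDef]
) -> dict[tuple[str, str], float]:
    """Plate x endpoint VC percent responses (for baseline anchoring)."""
    eps = ep_mod.enumerate_endpoints(recordings)
    out: dict[tuple[str, str], float] = {}
    vc = wells[wells["conc_uM"].astype(float) == 0.0]
    for plate_id, grp in vc.groupby("plate_id"):
        for ep in eps:
            out[(str(plate_id), ep.name)] = ep_mod.vc_response(grp, ep, recordings)
    return out


def analyze_lab(
    wells: pd.DataFrame,
    recordings: Sequence[RecordingDef],
    manifest: pd.DataFrame,
    lab_id: str,
    config: RunConfig,
) -> LabResults:
    """Run the full analysis for one laboratory dataset."""
    # ---- validate ----------------------------------------------------------
    violations = validate_dataset(wells, manifest, design=None)
    if violations:
        raise PipelineError(
            "validate",
            f"{len(violations)} invariant violations in {lab_id}",
            keys=[v.code for v in violations],
        )

    test_ids = set(
        manifest[manifest["role"] == "test"]["substance_id"]
    ) & set(wells["substance_id"])
    pc_ids = set(manifest[manifest["role"] == "positive_control"]["substance_id"])

    # ---- endpoints ---------------------------------------------------------
    curves = ep_mod.build_endpoint_curves(wells, recordings, test_ids)
    baselines = _vc_baselines(wells, recordings)

    # ---- VC QC -------------------------------------------------------------
    vc_rows = []
    for plate_id, grp in wells.groupby("plate_id"):
        vc_rows.append(
            qc_mod.check_vc(grp, recordings, threshold=config.vc_threshold_pct)
        )
    vc_flags = pd.concat(vc_rows, ignore_index=True)
    excluded: list[str] = []
    if config.strict_qc:
        excluded = sorted(vc_flags[~vc_flags["passed"]]["plate_id"].unique())
        curves = [c for c in curves if c.replicate_key not in excluded]

    if config.anchor_baseline:
        curves = [
            bmc_mod.anchor_to_baseline(
                c, baselines.get((c.replicate_key, c.endpoint.name), 0.0)
            )
            for c in curves
        ]

    # ---- BMR selection -----------------------------------------------------
    by_ep: dict[str, list] = {}
    for c in curves:
        by_ep.setdefault(c.endpoint.name, []).append(c)
    bmr: dict[str, bmc_mod.BMRSelection] = {}
    corrected: dict[str, list[bmc_mod.CorrectedCurve]] = {}
    for ep_name, eps_curves in sorted(by_ep.items()):
        corr = [bmc_mod.monotonize(c) for c in eps_curves]
        corrected[ep_name] = corr
        grid = config.grid
        profile = np.array(
            [bmc_mod.pooled_variance(bmc_mod.bmc_at(c, t) for c in corr) for t in grid]
        )
        bmr[ep_name] = bmc_mod.select_bmr(
            grid, profile, endpoint=ep_name, tol=config.bmr_tol
        )

    # ---- BMC fitting -------------------------------------------------------
    bmc_results = [
        bmc_mod.bmc_at(c, bmr[ep_name].bmr)
        for ep_name, corr in corrected.items()
        for c in corr
    ]

    pc_results: list[bmc_mod.BMCResult] = []
    pc_wells = wells[wells["substance_id"].isin(pc_ids)]
    if len(pc_wells):
        import warnings as _w

        for ep in ep_mod.enumerate_endpoints(recordings):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                pools = ep_mod.pool_pc_weekly(pc_wells, ep, recordings)
            for pool in pools:
                pc_results.append(
                    bmc_mod.bmc_at(bmc_mod.monotonize(pool), bmr[ep.name].bmr)
                )

    # ---- QC (PC, duplicates, variability) ----------------------------------
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        pc_table, pc_med, pc_fold = qc_mod.pc_reproducibility(pc_results)
        dup_tables: dict[str, pd.DataFrame] = {}
        groups = manifest[manifest["duplicate_group"].astype(str) != ""]
        for g, members in groups.groupby("duplicate_group"):
            ids = sorted(members["substance_id"])
            if len(ids) != 2:
                continue
            r1 = [r for r in bmc_results if r.substance_id == ids[0]]
            r2 = [r for r in bmc_results if r.substance_id == ids[1]]
            if r1 and r2:
                dup_tables[str(g)] = qc_mod.duplicate_concordance(
                    r1, r2, flag_threshold=config.duplicate_threshold_log10
                )
    variability = qc_mod.endpoint_variability(bmc_results)
    qc_report = qc_mod.QCReport(
        vc_flags=vc_flags,
        pc_sd=pc_table,
        pc_median_sd=pc_med,
        pc_median_fold=pc_fold,
        duplicate_tables=dup_tables,
        variability=variability,
    )

    # ---- specificity -------------------------------------------------------
    mort_name = ep_mod.MORTALITY_120.name
    by_rep: dict[tuple[str, str], dict[str, bmc_mod.BMCResult]] = {}
    for r in bmc_results:
        by_rep.setdefault((r.substance_id, r.replicate_key), {})[r.endpoint] = r
    scores: list[spec_mod.SpecificityScore] = []
    for (sub, rep), eps in sorted(by_rep.items()):
        mort = eps.get(mort_name)
        if mort is None:
            continue
        for ep_name, res in sorted(eps.items()):
            if ep_name == mort_name:
                continue
            scores.append(spec_mod.specificity_score(mort, res))
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        cutoff = spec_mod.derive_cutoff(scores, q=config.cutoff_quantile)

    plate_rows = []
    for s in scores:
        cls = spec_mod.classify_plate(s, cutoff)
        plate_rows.append(
            {
                "substance_id": s.substance_id,
                "endpoint": s.endpoint,
                "replicate_key": s.replicate_key,
                "cls": cls,
                "bmc_log10M": s.bmc_endpoint,
                "score": s.score,
            }
        )
    plate_classes = pd.DataFrame(plate_rows)
    substance_calls = []
    if len(plate_classes):
        for (sub, ep_name), grp in plate_classes.groupby(
            ["substance_id", "endpoint"], sort=True
        ):
            substance_calls.append(
                spec_mod.aggregate_substance(
                    sub,
                    ep_name,
                    list(zip(grp["cls"], grp["bmc_log10M"], grp["score"])),
                )
            )

    return LabResults(
        lab_id=lab_id,
        violations=violations,
        curves=curves,
        vc_flags=vc_flags,
        bmr=bmr,
        bmc_results=bmc_results,
        pc_results=pc_results,
        qc_report=qc_report,
        scores=scores,
        cutoff=cutoff,
        plate_classes=plate_classes,
        substance_calls=substance_calls,
        excluded_plates=excluded,
    )


# ---------------------------------------------------------------------------
# artifact writing


def _bmc_frame(results: Sequence[LabResults]) -> pd.DataFrame:
    rows = [
        {
            "lab_id": lr.lab_id,
            "endpoint": r.endpoint,
            "substance_id": r.substance_id,
            "replicate_key": r.replicate_key,
            "bmr": r.bmr_used,
            "active": r.active,
            "bmc_log10M": r.bmc_log10M,
            "censored_at_max": r.censored_at_max,
        }
        for lr in results
        for r in lr.bmc_results
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the pipeline over all configured datasets.

    Returns a map artifact-name -> path.  Raises :class:`PipelineError`
    with the failing stage name; artifacts from earlier stages are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    try:
        manifest = read_manifest_csv(config.manifest)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("load", f"cannot read manifest: {e}") from e

    lab_results: list[LabResults] = []
    for ds in config.datasets:
        try:
            wells = read_wells_csv(ds.wells)
            recs = recordings_from_frame(read_recordings_csv(ds.recordings))
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("load", f"dataset {ds.lab_id}: {e}") from e
        lab_results.append(analyze_lab(wells, recs, manifest, ds.lab_id, config))

    # BMR artifact
    bmr_obj = {
        lr.lab_id: {
            ep: {
                "bmr": sel.bmr,
                "converged": sel.converged,
                "plateau_variance": sel.plateau_value,
                "grid": list(sel.threshold_grid),
                "pooled_variance": list(sel.pooled_variance),
            }
            for ep, sel in lr.bmr.items()
        }
        for lr in lab_results
    }
    p = outdir / "bmr.json"
    p.write_text(json.dumps(bmr_obj, indent=1, sort_keys=True))
    artifacts["bmr"] = str(p)

    # BMC artifact
    p = outdir / "bmc.csv"
    _bmc_frame(lab_results).to_csv(p, index=False)
    artifacts["bmc"] = str(p)

    # specificity artifact
    rows = [
        {
            "lab_id": lr.lab_id,
            "substance_id": c.substance_id,
            "endpoint": c.endpoint,
            "class": c.cls,
            "bmc_summary": c.bmc_summary,
            "score_summary": c.score_summary,
            "n_plates": c.n_plates,
        }
        for lr in lab_results
        for c in lr.substance_calls
    ]
    p = outdir / "specificity.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    artifacts["specificity"] = str(p)

    # QC artifact
    qc_obj = {}
    for lr in lab_results:
        qc_obj[lr.lab_id] = {
            "specificity_cutoff": lr.cutoff,
            "vc_flags": lr.vc_flags.to_dict("records"),
            "vc_failing_plates": lr.qc_report.failing_plates(),
            "excluded_plates": lr.excluded_plates,
            "pc_sd": lr.qc_report.pc_sd.to_dict("records"),
            "pc_median_sd": lr.qc_report.pc_median_sd,
            "pc_median_fold": lr.qc_report.pc_median_fold,
            "duplicates": {
                g: t.to_dict("records")
                for g, t in lr.qc_report.duplicate_tables.items()
            },
            "bmc_sd_retained_median": (
                float(
                    lr.qc_report.variability[lr.qc_report.variability["retained"]][
                        "sd"
                    ].median()
                )
                if lr.qc_report.variability is not None
                and lr.qc_report.variability["retained"].any()
                else None
            ),
        }
    p = outdir / "qc_report.json"
    p.write_text(json.dumps(qc_obj, indent=1, sort_keys=True, default=str))
    artifacts["qc_report"] = str(p)

    # ontology collapse (last stage: earlier artifacts survive its failure)
    if config.mapping is None or not Path(config.mapping).exists():
        raise PipelineError(
            "ontology",
            f"mapping table not found: {config.mapping!r}",
            keys=[config.mapping or ""],
        )
    try:
        omap = onto_mod.OntologyMap.from_csv(config.mapping)
        rows = []
        for lr in lab_results:
            calls = onto_mod.collapse_substance_calls(
                lr.substance_calls, omap, lr.lab_id, level=config.collapse_level
            )
            for gc in calls:
                rows.append(
                    {
                        "lab_id": lr.lab_id,
                        "substance_id": gc.substance_id,
                        "level": gc.level,
                        "group": gc.group,
                        "class": gc.cls,
                        "bmc_log10M": gc.bmc,
                        "score": gc.score,
                        "provenance": ";".join(gc.provenance),
                    }
                )
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("ontology", str(e)) from e
    p = outdir / "groupcalls.csv"
    pd.DataFrame(
        rows,
        columns=[
            "lab_id",
            "substance_id",
            "level",
            "group",
            "class",
            "bmc_log10M",
            "score",
            "provenance",
        ],
    ).to_csv(p, index=False)
    artifacts["groupcalls"] = str(p)
    return artifacts
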