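"""Domain types for plate-based zebrafish embryo screening data.

A screen exposes single embryos (one per well of a 96-well plate) to a
dilution series of a test substance, alongside vehicle-control (VC) wells
and a single-embryo-per-concentration positive-control (PC) series.
Mortality is scored at 24 and 120 hours post-fertilization (hpf); altered
phenotypes are scored at 120 hpf on surviving embryos only.

Concentrations are stored in µM as dosed and converted to log10 molar
units only at analysis boundaries (potency estimates are reported in
log10 M).
"""

from __future__ import annotations

import datetime
import math
import sqlite3
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SubstanceRecord",
    "PlateDesign",
    "WellRecord",
    "RecordingDef",
    "Violation",
    "LAB_AC_DESIGN",
    "LAB_B_DESIGN",
    "WELL_BASE_COLUMNS",
    "validate_dataset",
    "log10_molar",
    "export_schema_ddl",
    "populate_database",
]

Role = Literal["test", "positive_control", "vehicle_control"]

#: fixed, protocol-mandated columns of a tidy wells table; one additional
#: boolean column per recording name follows these (empty = not assessed).
WELL_BASE_COLUMNS = [
    "plate_id",
    "run_date",
    "well",
    "substance_id",
    "conc_uM",
    "alive_24",
    "alive_120",
]


class SubstanceRecord(BaseModel):
    """One manifest entry: a blinded test substance, the PC, or the VC."""

    substance_id: str
    dtxsid: Optional[str] = None
    role: Role = "test"
    duplicate_group: Optional[str] = None
    level1_category: Optional[str] = None
    level2_category: Optional[str] = None


class PlateDesign(BaseModel):
    """Layout arithmetic of one 96-well screening plate.

    ``n_test_concentrations x n_embryos_per_concentration`` wells receive the
    test substance; the remainder are VC wells and the single-embryo PC
    dilution series.  The totals must sum to exactly 96.
    """

    n_test_concentrations: int = Field(gt=0)
    n_embryos_per_concentration: int = Field(gt=0)
    n_vc_wells: int = Field(default=12, ge=0)
    n_pc_wells: int = Field(default=7, ge=0)
    dosing_scenario: Literal["S", "SR"] = "S"
    chorion_status: Literal["C", "DC"] = "C"

    @property
    def total_wells(self) -> int:
        return (
            self.n_test_concentrations * self.n_embryos_per_concentration
            + self.n_vc_wells
            + self.n_pc_wells
        )

    @model_validator(mode="after")
    def _check_96(self) -> "PlateDesign":
        if self.total_wells != 96:
            raise ValueError(
                f"plate design does not fill a 96-well plate: "
                f"{self.n_test_concentrations}x{self.n_embryos_per_concentration}"
                f"+{self.n_vc_wells}+{self.n_pc_wells} = {self.total_wells}"
            )
        return self


#: 7 test concentrations x 11 embryos (plus 12 VC + 7 PC wells).
LAB_AC_DESIGN = PlateDesign(
    n_test_concentrations=7, n_embryos_per_concentration=11
)
#: 11 test concentrations x 7 embryos (finer dilution spacing).
LAB_B_DESIGN = PlateDesign(
    n_test_concentrations=11, n_embryos_per_concentration=7
)


class WellRecord(BaseModel):
    """One embryo in one well.

    ``phenotype_flags`` maps recording name -> presence, and is defined only
    for embryos alive at 120 hpf (phenotypes are scored on survivors).
    Mortality is absorbing: dead at 24 hpf implies dead at 120 hpf.
    """

    plate_id: str
    run_date: datetime.date
    well: str
    substance_id: str
    conc_uM: float = Field(ge=0.0)
    alive_24: bool
    alive_120: bool
    phenotype_flags: dict[str, bool] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_consistency(self) -> "WellRecord":
        if self.alive_120 and not self.alive_24:
            raise ValueError("alive at 120 hpf but dead at 24 hpf")
        if not self.alive_120 and self.phenotype_flags:
            raise ValueError("phenotype flags recorded on a dead embryo")
        return self


class RecordingDef(BaseModel):
    """A lab-specific altered-phenotype recording.

    ``is_binarized_quantitative`` marks thresholded continuous physical
    traits (e.g. trunk length vs. VC); those are excluded from the
    any-malformation endpoint.
    """

    lab_id: str
    recording_name: str
    is_binarized_quantitative: bool = False


@dataclass(frozen=True)
class Violation:
    """One named invariant breach found by :func:`validate_dataset`."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.message}"


def log10_molar(conc_uM):
    """Convert a µM concentration (scalar or array) to log10 molar units.

    100 µM -> -4.0; 1 µM -> -6.0.  Zero (a VC well) has no molar potency
    and raises ``ValueError``.
    """
    arr = np.asarray(conc_uM, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("log10_molar requires strictly positive µM concentrations")
    out = np.log10(arr * 1e-6)
    return float(out) if np.ndim(conc_uM) == 0 else out


def _recording_columns(wells: pd.DataFrame) -> list[str]:
    return [c for c in wells.columns if c not in WELL_BASE_COLUMNS]


def validate_dataset(
    wells: pd.DataFrame,
    manifest: Iterable[SubstanceRecord] | pd.DataFrame,
    design: PlateDesign | None = None,
) -> list[Violation]:
    """Check a tidy wells table against the screening invariants.

    Returns a list of :class:`Violation` (empty means valid); never raises
    for data problems and never mutates its inputs.  Checks: viability
    consistency (dead at 24 implies dead at 120), non-negative
    concentrations, no phenotype assessed on dead embryos, every substance
    present in the manifest, exactly one PC in the manifest, duplicate
    groups of exactly two, and (if a design is given) 96 wells per plate.
    """
    violations: list[Violation] = []

    if isinstance(manifest, pd.DataFrame):
        manifest_records = [
            SubstanceRecord(**{k: (None if pd.isna(v) else v) for k, v in row.items()})
            for row in manifest.to_dict("records")
        ]
    else:
        manifest_records = list(manifest)

    known = {m.substance_id for m in manifest_records}
    pc = [m for m in manifest_records if m.role == "positive_control"]
    if len(pc) != 1:
        violations.append(
            Violation(
                "manifest_pc_count",
                f"manifest must contain exactly one positive control, found {len(pc)}",
            )
        )
    groups: dict[str, list[str]] = {}
    for m in manifest_records:
        if m.duplicate_group:
            groups.setdefault(m.duplicate_group, []).append(m.substance_id)
    for g, members in groups.items():
        if len(members) != 2:
            violations.append(
                Violation(
                    "duplicate_group_size",
                    f"duplicate group {g!r} has {len(members)} members, expected 2",
                )
            )

    bad_viab = wells[wells["alive_120"] & ~wells["alive_24"]]
    for _, row in bad_viab.iterrows():
        violations.append(
            Violation(
                "viability_inconsistency",
                f"well {row['well']} on plate {row['plate_id']}: alive at 120 hpf "
                f"but dead at 24 hpf",
            )
        )

    neg = wells[wells["conc_uM"] < 0]
    for _, row in neg.iterrows():
        violations.append(
            Violation(
                "negative_concentration",
                f"well {row['well']} on plate {row['plate_id']}: conc_uM < 0",
            )
        )

    rec_cols = _recording_columns(wells)
    if rec_cols:
        dead = wells[~wells["alive_120"].astype(bool)]
        flagged = dead[dead[rec_cols].notna().any(axis=1)]
        for _, row in flagged.iterrows():
            violations.append(
                Violation(
                    "phenotype_on_dead_embryo",
                    f"well {row['well']} on plate {row['plate_id']}: phenotype "
                    f"assessed on an embryo dead at 120 hpf",
                )
            )

    missing = sorted(set(wells["substance_id"]) - known)
    for s in missing:
        violations.append(
            Violation("missing_substance", f"substance {s!r} not in manifest")
        )

    if design is not None:
        counts = wells.groupby("plate_id").size()
        for plate_id, n in counts.items():
            if n != 96:
                violations.append(
                    Violation(
                        "plate_well_count",
                        f"plate {plate_id} has {n} wells, expected 96",
                    )
                )

    return violations


# --------------------------------------------------------------------------
# Relational schema export

_SCHEMA_DDL = """\
-- Screening database schema (generic ANSI SQL).
-- Three table groups: substance information; screening data (well-centred);
-- analyses (BMC inputs/outputs and specificity calls).

-- substance information ----------------------------------------------------
CREATE TABLE test_substance (
    substance_id     TEXT PRIMARY KEY,
    role             TEXT NOT NULL,
    duplicate_group  TEXT,
    level1_category  TEXT,
    level2_category  TEXT
);

CREATE TABLE test_substance_identity (
    substance_id  TEXT PRIMARY KEY REFERENCES test_substance (substance_id),
    dtxsid        TEXT,
    lot           TEXT,
    supplier      TEXT,
    use_category  TEXT
);

-- screening data ------------------------------------------------------------
CREATE TABLE dataset (
    dataset_id       TEXT PRIMARY KEY,
    lab_id           TEXT NOT NULL,
    phase            TEXT NOT NULL,
    dosing_scenario  TEXT NOT NULL,
    chorion_status   TEXT NOT NULL
);

CREATE TABLE screen_plate (
    plate_id    TEXT PRIMARY KEY,
    dataset_id  TEXT NOT NULL REFERENCES dataset (dataset_id),
    run_date    TIMESTAMP NOT NULL
);

CREATE TABLE recording (
    recording_id               INTEGER PRIMARY KEY,
    dataset_id                 TEXT NOT NULL REFERENCES dataset (dataset_id),
    recording_name             TEXT NOT NULL,
    is_binarized_quantitative  INTEGER NOT NULL
);

CREATE TABLE dose (
    dose_id       INTEGER PRIMARY KEY,
    substance_id  TEXT NOT NULL REFERENCES test_substance (substance_id),
    conc_um       DOUBLE PRECISION NOT NULL
);

CREATE TABLE well (
    well_id        INTEGER PRIMARY KEY,
    plate_id       TEXT NOT NULL REFERENCES screen_plate (plate_id),
    dose_id        INTEGER NOT NULL REFERENCES dose (dose_id),
    well_position  TEXT NOT NULL,
    alive_24       INTEGER NOT NULL,
    alive_120      INTEGER NOT NULL
);

CREATE TABLE well_phenotype (
    well_id       INTEGER NOT NULL REFERENCES well (well_id),
    recording_id  INTEGER NOT NULL REFERENCES recording (recording_id),
    present       INTEGER NOT NULL,
    PRIMARY KEY (well_id, recording_id)
);

CREATE TABLE phenotype_ontology (
    recording_id    INTEGER NOT NULL REFERENCES recording (recording_id),
    ontology_id     TEXT,
    term_label      TEXT NOT NULL,
    granular_group  TEXT,
    general_group   TEXT,
    PRIMARY KEY (recording_id, term_label)
);

-- analyses -------------------------------------------------------------------
CREATE TABLE bmc_input_key (
    bmc_input_key_id  INTEGER PRIMARY KEY,
    dataset_id        TEXT NOT NULL REFERENCES dataset (dataset_id),
    endpoint          TEXT NOT NULL,
    substance_id      TEXT NOT NULL REFERENCES test_substance (substance_id),
    replicate_key     TEXT NOT NULL
);

CREATE TABLE bmc_input (
    bmc_input_id      INTEGER PRIMARY KEY,
    bmc_input_key_id  INTEGER NOT NULL REFERENCES bmc_input_key (bmc_input_key_id),
    conc_log10m       DOUBLE PRECISION NOT NULL,
    response_pct      DOUBLE PRECISION NOT NULL,
    n_embryos         INTEGER NOT NULL
);

CREATE TABLE bmc_output (
    bmc_output_id     INTEGER PRIMARY KEY,
    bmc_input_key_id  INTEGER NOT NULL REFERENCES bmc_input_key (bmc_input_key_id),
    bmr               DOUBLE PRECISION NOT NULL,
    active            INTEGER NOT NULL,
    bmc_log10m        DOUBLE PRECISION,
    censored_at_max   INTEGER NOT NULL
);

CREATE TABLE specificity (
    specificity_id    INTEGER PRIMARY KEY,
    dataset_id        TEXT NOT NULL REFERENCES dataset (dataset_id),
    substance_id      TEXT NOT NULL REFERENCES test_substance (substance_id),
    endpoint          TEXT NOT NULL,
    class             TEXT NOT NULL,
    score             DOUBLE PRECISION,
    bmc_log10m        DOUBLE PRECISION,
    n_plates          INTEGER NOT NULL
);
"""


def export_schema_ddl() -> str:
    """Return CREATE TABLE statements for the screening database schema.

    The schema mirrors the three-group layout used in production: substance
    information, screening data (with the ``well`` table central, holding
    foreign keys to plate and dose and linked to recordings via
    ``well_phenotype``), and analyses.
    """
    return _SCHEMA_DDL


def populate_database(
    conn: sqlite3.Connection,
    wells: pd.DataFrame,
    manifest: pd.DataFrame,
    recordings: pd.DataFrame,
    dataset_id: str = "dataset-1",
    lab_id: str = "lab",
    dosing_scenario: str = "S",
    chorion_status: str = "C",
) -> None:
    """Create the schema in ``conn`` and load a tidy dataset into it.

    Doses are normalised to unique (substance, concentration) pairs;
    each well gets one row in ``well`` and one ``well_phenotype`` row per
    assessed recording.
    """
    conn.executescript(export_schema_ddl())
    conn.execute(
        "INSERT INTO dataset VALUES (?,?,?,?,?)",
        (dataset_id, lab_id, "DRF", dosing_scenario, chorion_status),
    )
    for _, m in manifest.iterrows():
        conn.execute(
            "INSERT INTO test_substance VALUES (?,?,?,?,?)",
            (
                m["substance_id"],
                m.get("role", "test"),
                m.get("duplicate_group") or None,
                m.get("level1_category") or None,
                m.get("level2_category") or None,
            ),
        )
        conn.execute(
            "INSERT INTO test_substance_identity (substance_id, dtxsid) VALUES (?,?)",
            (m["substance_id"], m.get("dtxsid") or None),
        )
    rec_ids: dict[str, int] = {}
    for i, (_, r) in enumerate(recordings.iterrows(), start=1):
        rec_ids[r["recording_name"]] = i
        conn.execute(
            "INSERT INTO recording VALUES (?,?,?,?)",
            (
                i,
                dataset_id,
                r["recording_name"],
                int(bool(r.get("is_binarized_quantitative", False))),
            ),
        )
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        conn.execute(
            "INSERT INTO screen_plate VALUES (?,?,?)",
            (plate_id, dataset_id, str(grp["run_date"].iloc[0])),
        )
    dose_ids: dict[tuple[str, float], int] = {}
    for sub, conc in sorted(
        set(zip(wells["substance_id"], wells["conc_uM"].astype(float)))
    ):
        dose_ids[(sub, conc)] = len(dose_ids) + 1
        conn.execute(
            "INSERT INTO dose VALUES (?,?,?)", (dose_ids[(sub, conc)], sub, conc)
        )
    rec_cols = [c for c in wells.columns if c in rec_ids]
    for wid, (_, w) in enumerate(wells.iterrows(), start=1):
        conn.execute(
            "INSERT INTO well VALUES (?,?,?,?,?,?)",
            (
                wid,
                w["plate_id"],
                dose_ids[(w["substance_id"], float(w["conc_uM"]))],
                w["well"],
                int(bool(w["alive_24"])),
                int(bool(w["alive_120"])),
            ),
        )
        for c in rec_cols:
            v = w[c]
            if pd.notna(v):
                conn.execute(
                    "INSERT INTO well_phenotype VALUES (?,?,?)",
                    (wid, rec_ids[c], int(bool(v))),
                )
    conn.commit()
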