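"""Seeded synthetic screening-study generator.

Emulates the structure of a three-laboratory embryo screen so the whole
pipeline can run and be tested without external data: two plate layouts
(7 concentrations x 11 embryos, and 11 concentrations x 7 embryos with
finer dilution spacing), 12 VC wells and a 7-concentration single-embryo
PC series per plate, triplicate plates per substance on separate dates,
blinded duplicate pairs sharing ground-truth parameters, and lab-specific
baseline malformation rates (one lab with an elevated vehicle baseline).

Responses are Bernoulli draws from Hill-shaped concentration-probability
curves.  Phenotypes are scored only on embryos surviving to 120 hpf,
matching the recording protocol, so the combined phenotype+mortality
endpoints are monotone in expectation.  Each plate draws from a sub-seed
derived from the global seed and the plate id, making plates independently
reproducible.
"""

from __future__ import annotations

import datetime
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .core_model import (
    LAB_AC_DESIGN,
    LAB_B_DESIGN,
    PlateDesign,
    RecordingDef,
    WELL_BASE_COLUMNS,
)

__all__ = [
    "LabSimConfig",
    "SimConfig",
    "SimStudy",
    "hill_prob",
    "simulate_plate",
    "simulate_study",
    "default_config",
    "synthetic_ontology_map",
]


def hill_prob(conc_uM, ac50_uM: float, slope: float, p0: float, pmax: float):
    """Hill-shaped event probability at a concentration (scalar or array).

    ``p = p0 + (pmax - p0) * c**s / (ac50**s + c**s)``; ``p0`` at zero
    concentration, approaching ``pmax`` at saturation.
    """
    if ac50_uM <= 0 or slope <= 0:
        raise ValueError("ac50 and slope must be positive")
    if not (0.0 <= p0 <= pmax <= 1.0):
        raise ValueError("need 0 <= p0 <= pmax <= 1")
    c = np.asarray(conc_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    frac = np.where(c > 0, c**slope / (ac50_uM**slope + c**slope), 0.0)
    out = p0 + (pmax - p0) * frac
    return float(out) if np.ndim(conc_uM) == 0 else out


class LabSimConfig(BaseModel):
    """One laboratory's protocol and baseline profile."""

    lab_id: str
    design: PlateDesign
    n_binary_recordings: int = Field(ge=0)
    n_quantitative_recordings: int = Field(default=0, ge=0)
    conc_spacing_log10: float = Field(gt=0)
    vc_mort120: float = Field(default=0.04, ge=0, le=1)
    frac_dead_by_24: float = Field(default=0.4, ge=0, le=1)
    vc_malformed_any: float = Field(default=0.08, ge=0, lt=1)
    quant_baseline: float = Field(default=0.2, ge=0, lt=1)

    @property
    def recording_names(self) -> list[str]:
        binary = [
            f"{self.lab_id}_pheno_{j:02d}"
            for j in range(1, self.n_binary_recordings + 1)
        ]
        quant = [
            f"{self.lab_id}_trait_{j:02d}"
            for j in range(1, self.n_quantitative_recordings + 1)
        ]
        return binary + quant

    def recording_defs(self) -> list[RecordingDef]:
        return [
            RecordingDef(
                lab_id=self.lab_id,
                recording_name=n,
                is_binarized_quantitative=n.split("_")[1] == "trait",
            )
            for n in self.recording_names
        ]

    @property
    def per_recording_baseline(self) -> float:
        """Per-binary-recording baseline rate giving the configured
        any-malformation VC baseline under independence."""
        k = max(self.n_binary_recordings, 1)
        return 1.0 - (1.0 - self.vc_malformed_any) ** (1.0 / k)

    def conc_grid(self, max_conc_uM: float) -> np.ndarray:
        n = self.design.n_test_concentrations
        exps = np.arange(n - 1, -1, -1) * self.conc_spacing_log10
        return max_conc_uM / 10.0**exps


class SimConfig(BaseModel):
    """Full study configuration (defaults mirror the screening design)."""

    labs: list[LabSimConfig]
    n_singleton_substances: int = 35
    n_duplicate_pairs: int = 3
    max_conc_uM: float = 100.0
    pc_conc_uM: list[float] = Field(
        default_factory=lambda: [0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]
    )
    pc_ac50_uM: float = 2.0
    pc_slope: float = 4.0
    n_replicates: int = 3
    p_phenotype_affected: float = 0.35
    phenotype_shift_log10: tuple[float, float] = (0.1, 0.8)
    seed: int = 0

    @property
    def n_blinded_substances(self) -> int:
        return self.n_singleton_substances + 2 * self.n_duplicate_pairs

    @property
    def n_compounds(self) -> int:
        return self.n_singleton_substances + self.n_duplicate_pairs


def default_config(seed: int = 0) -> SimConfig:
    """The study-scale default: three labs, 41 blinded substances + PC.

    Lab-A (7x11, static-renewal/chorion, 21 binary recordings) and Lab-C
    (7x11, static/chorion, 12 binary + 9 binarized-quantitative recordings,
    elevated malformation baseline) use 0.5 log10 dilution spacing; Lab-B
    (11x7, static/dechorion, 9 binary recordings) uses 0.2.
    """
    return SimConfig(
        labs=[
            LabSimConfig(
                lab_id="Lab-A",
                design=LAB_AC_DESIGN.model_copy(
                    update={"dosing_scenario": "SR", "chorion_status": "C"}
                ),
                n_binary_recordings=21,
                conc_spacing_log10=0.5,
                vc_malformed_any=0.08,
            ),
            LabSimConfig(
                lab_id="Lab-B",
                design=LAB_B_DESIGN.model_copy(
                    update={"dosing_scenario": "S", "chorion_status": "DC"}
                ),
                n_binary_recordings=9,
                conc_spacing_log10=0.2,
                vc_malformed_any=0.08,
            ),
            LabSimConfig(
                lab_id="Lab-C",
                design=LAB_AC_DESIGN.model_copy(
                    update={"dosing_scenario": "S", "chorion_status": "C"}
                ),
                n_binary_recordings=12,
                n_quantitative_recordings=9,
                conc_spacing_log10=0.5,
                vc_malformed_any=0.15,
            ),
        ],
        seed=seed,
    )


@dataclass
class SimStudy:
    """Simulated study: per-lab wells tables, manifest, recordings, truth."""

    wells: dict[str, pd.DataFrame]
    manifest: pd.DataFrame
    recordings: pd.DataFrame
    truths: pd.DataFrame
    config: SimConfig

    def recording_defs(self, lab_id: str) -> list[RecordingDef]:
        sub = self.recordings[self.recordings["lab_id"] == lab_id]
        return [
            RecordingDef(
                lab_id=lab_id,
                recording_name=r["recording_name"],
                is_binarized_quantitative=bool(r["is_binarized_quantitative"]),
            )
            for _, r in sub.iterrows()
        ]

    def test_substance_ids(self) -> list[str]:
        return sorted(
            self.manifest[self.manifest["role"] == "test"]["substance_id"]
        )


#: synthetic term pool (label, granular group, general group); the first
#: entry carries no structural-defect group, like death/behaviour terms.
_TERM_POOL: list[tuple[str, str, str]] = [
    ("whole organism dead, abnormal", "", ""),
    ("hatching delayed, abnormal", "delayed hatching", "hatching defects"),
    ("ventral mandibular arch morphology, abnormal", "jaw defects", "head defects"),
    ("snout malformed, abnormal", "snout defects", "head defects"),
    ("eye decreased size, abnormal", "eye defects", "head defects"),
    ("axis curved, abnormal", "axis defects", "torso defects"),
    ("notochord morphology, abnormal", "notochord defects", "torso defects"),
    ("heart edematous, abnormal", "heart edema", "heart defects"),
    ("yolk edematous, abnormal", "yolk edema", "yolk defects"),
    ("yolk opaque, abnormal", "yolk opacity", "yolk defects"),
    ("pectoral fin morphology, abnormal", "pectoral fin defects", "fin defects"),
    ("caudal fin morphology, abnormal", "caudal fin defects", "fin defects"),
]


def synthetic_ontology_map(config: SimConfig) -> pd.DataFrame:
    """Synthetic recording -> ontology-term mapping for a simulated study.

    Each lab recording is assigned a term from a shared pool (cyclically,
    so terms overlap across labs); every second recording of the
    finest-spaced lab additionally maps to a second term, reproducing the
    one-to-many mappings seen when a lab records composite phenotypes.
    Purely synthetic — structured like, but not derived from, a curated
    ontology table.
    """
    rows = []
    for lab in config.labs:
        multi = lab.design.n_test_concentrations >= 11  # the composite-recording lab
        for j, rec in enumerate(lab.recording_names):
            term, gran, gen = _TERM_POOL[(j + 1) % len(_TERM_POOL)]
            rows.append(
                {
                    "lab": lab.lab_id,
                    "recording": rec,
                    "ontology_id": "",
                    "term_label": term,
                    "granular_group": gran,
                    "general_group": gen,
                }
            )
            if multi and j % 2 == 1:
                term2, gran2, gen2 = _TERM_POOL[(j + 2) % len(_TERM_POOL)]
                rows.append(
                    {
                        "lab": lab.lab_id,
                        "recording": rec,
                        "ontology_id": "",
                        "term_label": term2,
                        "granular_group": gran2,
                        "general_group": gen2,
                    }
                )
    return pd.DataFrame(rows)


_LEVEL1 = [
    "drug",
    "insecticide",
    "fungicide",
    "herbicide",
    "flame retardant",
    "industrial compound",
    "PAH",
    "preservative",
]


def _plate_rng(seed: int, plate_id: str) -> np.random.Generator:
    """Per-plate generator: global seed + CRC32 of the plate id."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(plate_id.encode())])
    )


def _well_labels(n: int) -> list[str]:
    rows = "ABCDEFGH"
    return [f"{rows[i // 12]}{i % 12 + 1}" for i in range(n)]


def _draw_truths(config: SimConfig) -> pd.DataFrame:
    """Ground-truth Hill parameters per compound, shared by duplicates."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows: list[dict] = []
    lo, hi = config.phenotype_shift_log10
    for ci in range(config.n_compounds):
        compound = f"C{ci + 1:02d}"
        mort_ac50 = 10.0 ** rng.uniform(0.0, 2.7)  # 1..500 µM
        mort_slope = rng.uniform(2.0, 6.0)
        mort_max = rng.uniform(0.9, 1.0)
        rows.append(
            {
                "compound_id": compound,
                "lab_id": "",
                "recording_name": "Mortality",
                "ac50_uM": mort_ac50,
                "slope": mort_slope,
                "max_response": mort_max,
            }
        )
        for lab in config.labs:
            for rec in lab.recording_names:
                if rng.random() < config.p_phenotype_affected:
                    shift = rng.uniform(lo, hi)
                    rows.append(
                        {
                            "compound_id": compound,
                            "lab_id": lab.lab_id,
                            "recording_name": rec,
                            "ac50_uM": mort_ac50 / 10.0**shift,
                            "slope": rng.uniform(1.5, 5.0),
                            "max_response": rng.uniform(0.6, 0.95),
                        }
                    )
    # the PC is a consistent, potent reference substance
    pc_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows.append(
        {
            "compound_id": "PC",
            "lab_id": "",
            "recording_name": "Mortality",
            "ac50_uM": config.pc_ac50_uM,
            "slope": config.pc_slope,
            "max_response": 1.0,
        }
    )
    for lab in config.labs:
        for rec in lab.recording_names:
            if pc_rng.random() < 0.5:
                rows.append(
                    {
                        "compound_id": "PC",
                        "lab_id": lab.lab_id,
                        "recording_name": rec,
                        "ac50_uM": config.pc_ac50_uM / 10.0 ** pc_rng.uniform(0.2, 0.6),
                        "slope": pc_rng.uniform(2.0, 5.0),
                        "max_response": pc_rng.uniform(0.7, 0.95),
                    }
                )
    return pd.DataFrame(rows)


def _build_manifest(config: SimConfig) -> pd.DataFrame:
    rows = []
    sidx = 0
    for ci in range(config.n_singleton_substances):
        sidx += 1
        rows.append(
            {
                "substance_id": f"S{sidx:02d}",
                "compound_id": f"C{ci + 1:02d}",
                "dtxsid": f"DTXSID{7000000 + sidx}",
                "role": "test",
                "duplicate_group": "",
                "level1_category": _LEVEL1[ci % len(_LEVEL1)],
                "level2_category": f"{_LEVEL1[ci % len(_LEVEL1)]}-"
                + ("organic" if ci % 2 else "element-organic"),
            }
        )
    for d in range(config.n_duplicate_pairs):
        compound = f"C{config.n_singleton_substances + d + 1:02d}"
        for member in range(2):
            sidx += 1
            rows.append(
                {
                    "substance_id": f"S{sidx:02d}",
                    "compound_id": compound,
                    "dtxsid": f"DTXSID{7000000 + sidx}",
                    "role": "test",
                    "duplicate_group": f"dup-{d + 1}",
                    "level1_category": _LEVEL1[d % len(_LEVEL1)],
                    "level2_category": f"{_LEVEL1[d % len(_LEVEL1)]}-organic",
                }
            )
    rows.append(
        {
            "substance_id": "PC",
            "compound_id": "PC",
            "dtxsid": "DTXSID7024035",
            "role": "positive_control",
            "duplicate_group": "",
            "level1_category": "reference",
            "level2_category": "reference-organic",
        }
    )
    rows.append(
        {
            "substance_id": "VC",
            "compound_id": "VC",
            "dtxsid": "",
            "role": "vehicle_control",
            "duplicate_group": "",
            "level1_category": "vehicle",
            "level2_category": "vehicle",
        }
    )
    return pd.DataFrame(rows)


def _truth_lookup(truths: pd.DataFrame) -> dict[tuple[str, str, str], tuple]:
    return {
        (r["compound_id"], r["lab_id"], r["recording_name"]): (
            r["ac50_uM"],
            r["slope"],
            r["max_response"],
        )
        for _, r in truths.iterrows()
    }


def simulate_plate(
    lab: LabSimConfig,
    compound_id: str,
    substance_id: str,
    truth_map: dict[tuple[str, str, str], tuple],
    config: SimConfig,
    plate_id: str,
    run_date: datetime.date,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate one 96-well plate as a tidy wells table.

    Test wells receive the substance's dilution series; 12 VC wells carry
    concentration 0; the PC series has one embryo per concentration.
    Death by 120 hpf is drawn from the mortality Hill curve (a fixed
    fraction of deaths occur by 24 hpf); phenotype flags are drawn only for
    survivors and left unassessed (NA) for dead embryos.
    """
    if rng is None:
        rng = _plate_rng(config.seed, plate_id)
    design = lab.design
    grid = lab.conc_grid(config.max_conc_uM)

    conc = np.concatenate(
        [
            np.repeat(grid, design.n_embryos_per_concentration),
            np.zeros(design.n_vc_wells),
            np.asarray(config.pc_conc_uM, dtype=float),
        ]
    )
    sub = (
        [substance_id] * (design.n_test_concentrations * design.n_embryos_per_concentration)
        + ["VC"] * design.n_vc_wells
        + ["PC"] * design.n_pc_wells
    )
    comp = np.array(
        [compound_id] * (design.n_test_concentrations * design.n_embryos_per_concentration)
        + ["VC"] * design.n_vc_wells
        + ["PC"] * design.n_pc_wells
    )
    n = len(conc)

    p_death = np.full(n, lab.vc_mort120)
    for c_id in (compound_id, "PC"):
        mask = comp == c_id
        ac50, slope, pmax = truth_map[(c_id, "", "Mortality")]
        p_death[mask] = hill_prob(conc[mask], ac50, slope, lab.vc_mort120, pmax)
    dead_120 = rng.random(n) < p_death
    dead_24 = dead_120 & (rng.random(n) < lab.frac_dead_by_24)

    data: dict[str, object] = {
        "plate_id": plate_id,
        "run_date": run_date.isoformat(),
        "well": _well_labels(n),
        "substance_id": sub,
        "conc_uM": conc,
        "alive_24": ~dead_24,
        "alive_120": ~dead_120,
    }
    per_rec_p0 = lab.per_recording_baseline
    for rec in lab.recording_names:
        is_quant = rec.split("_")[1] == "trait"
        p0 = lab.quant_baseline if is_quant else per_rec_p0
        p = np.full(n, p0)
        for c_id in (compound_id, "PC"):
            key = (c_id, lab.lab_id, rec)
            if key in truth_map:
                ac50, slope, pmax = truth_map[key]
                mask = comp == c_id
                p[mask] = hill_prob(conc[mask], ac50, slope, p0, max(pmax, p0))
        flags = rng.random(n) < p
        col = pd.array(flags, dtype="boolean")
        col[dead_120] = pd.NA  # phenotypes are scored on survivors only
        data[rec] = col
    return pd.DataFrame(data)


def simulate_study(
    config: Optional[SimConfig] = None, seed: Optional[int] = None
) -> SimStudy:
    """Simulate the full study: every lab screens every blinded substance in
    triplicate on separate dates, plus VC and PC wells on each plate.

    Duplicate pair members share ground-truth parameters under different
    blinded ids.  Output is byte-identical for a fixed seed.
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    manifest = _build_manifest(config)
    truths = _draw_truths(config)
    truth_map = _truth_lookup(truths)
    base_date = datetime.date(2021, 1, 4)

    recordings = pd.DataFrame(
        [
            {
                "lab_id": lab.lab_id,
                "recording_name": r.recording_name,
                "is_binarized_quantitative": r.is_binarized_quantitative,
            }
            for lab in config.labs
            for r in lab.recording_defs()
        ]
    )

    test_rows = manifest[manifest["role"] == "test"]
    wells: dict[str, pd.DataFrame] = {}
    for lab in config.labs:
        frames = []
        for i, (_, srow) in enumerate(test_rows.iterrows()):
            for rep in range(config.n_replicates):
                plate_id = f"{lab.lab_id}-{srow['substance_id']}-r{rep + 1}"
                run_date = base_date + datetime.timedelta(
                    days=7 * ((i // 14) + 3 * rep) + i % 5
                )
                frames.append(
                    simulate_plate(
                        lab,
                        srow["compound_id"],
                        srow["substance_id"],
                        truth_map,
                        config,
                        plate_id,
                        run_date,
                    )
                )
        wells[lab.lab_id] = pd.concat(frames, ignore_index=True)

    # duplicates: substance ids in the same group share a compound, so their
    # truth parameters coincide exactly by construction.
    manifest_out = manifest.drop(columns=[]).copy()
    truths = truths.merge(
        manifest[["substance_id", "compound_id"]], on="compound_id", how="left"
    )
    return SimStudy(
        wells=wells,
        manifest=manifest_out,
        recordings=recordings,
        truths=truths,
        config=config,
    )
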