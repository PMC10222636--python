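"""Well-level incidence to per-plate concentration-response endpoints.

Each 120-hpf endpoint combines mortality with one altered phenotype: an
embryo counts toward ``<recording>+Mort@120`` if it is dead at 120 hpf or
alive with that phenotype flagged.  ``MalformedAny+Mort@120`` counts an
embryo affected if it is dead or shows any binary phenotype (thresholded
quantitative traits are excluded).  Responses are percentages of the total
embryos dosed at each concentration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import RecordingDef, WELL_BASE_COLUMNS, log10_molar

__all__ = [
    "EndpointDef",
    "ConcentrationResponse",
    "MORTALITY_24",
    "MORTALITY_120",
    "MALFORMED_ANY",
    "combined_endpoint",
    "enumerate_endpoints",
    "percent_response",
    "malformed_any",
    "vc_response",
    "pool_pc_weekly",
    "build_endpoint_curves",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndpointDef:
    """A named screening endpoint at 24 or 120 hpf."""

    name: str
    timepoint: Literal[24, 120]
    kind: Literal["mortality", "combined_phenotype", "malformed_any"]
    recording_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "combined_phenotype" and not self.recording_name:
            raise ValueError("combined endpoints must reference one recording")


MORTALITY_24 = EndpointDef("Mortality@24", 24, "mortality")
MORTALITY_120 = EndpointDef("Mortality@120", 120, "mortality")
MALFORMED_ANY = EndpointDef("MalformedAny+Mort@120", 120, "malformed_any")


def combined_endpoint(recording_name: str) -> EndpointDef:
    """The combined phenotype+mortality endpoint for one recording."""
    return EndpointDef(
        f"{recording_name}+Mort@120", 120, "combined_phenotype", recording_name
    )


def enumerate_endpoints(
    recordings: Iterable[RecordingDef],
) -> list[EndpointDef]:
    """All 120-hpf endpoints for a lab: one combined endpoint per recorded
    altered phenotype, plus mortality and any-malformation.

    For ``n`` recordings this yields ``n + 2`` endpoints (e.g. 21
    recordings -> 23 endpoints).  ``Mortality@24`` is a QC endpoint and is
    produced separately.
    """
    recs = list(recordings)
    names = [r.recording_name for r in recs]
    if len(names) != len(set(names)):
        raise ValueError("recording names must be unique within a lab")
    return (
        [MORTALITY_120]
        + [combined_endpoint(n) for n in names]
        + [MALFORMED_ANY]
    )


@dataclass
class ConcentrationResponse:
    """One endpoint x substance x replicate concentration-response series.

    ``conc_log10M`` is strictly increasing; ``response_pct`` lies in
    [0, 100]; ``n_embryos`` are the per-concentration denominators.
    """

    endpoint: EndpointDef
    substance_id: str
    replicate_key: str
    conc_log10M: np.ndarray
    response_pct: np.ndarray
    n_embryos: np.ndarray
    low_n: bool = False

    def __post_init__(self) -> None:
        self.conc_log10M = np.asarray(self.conc_log10M, dtype=float)
        self.response_pct = np.asarray(self.response_pct, dtype=float)
        self.n_embryos = np.asarray(self.n_embryos, dtype=int)
        if not (
            len(self.conc_log10M) == len(self.response_pct) == len(self.n_embryos)
        ):
            raise ValueError("concentration, response and n vectors differ in length")
        if np.any(np.diff(self.conc_log10M) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((self.response_pct < 0) | (self.response_pct > 100)):
            raise ValueError("responses must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.conc_log10M)


def _affected_mask(
    wells: pd.DataFrame,
    endpoint: EndpointDef,
    recordings: Optional[Sequence[RecordingDef]] = None,
) -> pd.Series:
    """Boolean per-well 'counts in the numerator' mask for an endpoint."""
    dead_24 = ~wells["alive_24"].astype(bool)
    dead_120 = ~wells["alive_120"].astype(bool)
    if endpoint.kind == "mortality":
        return dead_24 if endpoint.timepoint == 24 else dead_120
    if endpoint.kind == "combined_phenotype":
        rec = endpoint.recording_name
        if rec not in wells.columns:
            raise KeyError(f"recording {rec!r} not present in wells table")
        flagged = wells[rec].fillna(False).astype(bool)
        return dead_120 | (~dead_120 & flagged)
    # malformed_any: dead, or any *binary* phenotype present (binarized
    # quantitative traits excluded — they produce non-monotone responses).
    if recordings is None:
        raise ValueError("malformed_any endpoint requires recording definitions")
    binary = [
        r.recording_name
        for r in recordings
        if not r.is_binarized_quantitative and r.recording_name in wells.columns
    ]
    if binary:
        any_flag = (
            wells[binary].fillna(False).astype(bool).any(axis=1)
        )
    else:
        any_flag = pd.Series(False, index=wells.index)
    return dead_120 | (~dead_120 & any_flag)


def percent_response(
    wells: pd.DataFrame,
    endpoint: EndpointDef,
    recordings: Optional[Sequence[RecordingDef]] = None,
    replicate_key: Optional[str] = None,
) -> ConcentrationResponse:
    """Percent-response series for one substance on one plate.

    The numerator at each concentration is the count of dead embryos plus —
    for combined endpoints — surviving embryos with the phenotype; the
    denominator is all embryos dosed at that concentration.  Concentrations
    with zero embryos are dropped with a warning.
    """
    subs = wells["substance_id"].unique()
    plates = wells["plate_id"].unique()
    if len(subs) != 1 or len(plates) != 1:
        raise ValueError("wells must come from a single substance on a single plate")
    if np.any(wells["conc_uM"].to_numpy(dtype=float) <= 0):
        raise ValueError("test wells must have positive concentrations (VC excluded)")

    affected = _affected_mask(wells, endpoint, recordings)
    grouped = pd.DataFrame(
        {"conc_uM": wells["conc_uM"].astype(float), "affected": affected}
    ).groupby("conc_uM", sort=True)
    conc = np.array(sorted(grouped.groups))
    n = grouped.size().to_numpy()
    k = grouped["affected"].sum().to_numpy()
    keep = n > 0
    if not np.all(keep):  # pragma: no cover - zero-count groups cannot arise
        logger.warning("dropping concentrations with zero embryos")
        conc, n, k = conc[keep], n[keep], k[keep]
    return ConcentrationResponse(
        endpoint=endpoint,
        substance_id=str(subs[0]),
        replicate_key=replicate_key or str(plates[0]),
        conc_log10M=log10_molar(conc),
        response_pct=100.0 * k / n,
        n_embryos=n,
    )


def malformed_any(
    wells: pd.DataFrame,
    recordings: Sequence[RecordingDef],
    replicate_key: Optional[str] = None,
) -> ConcentrationResponse:
    """Any-malformation-or-death response (binary recordings only)."""
    return percent_response(wells, MALFORMED_ANY, recordings, replicate_key)


def vc_response(
    vc_wells: pd.DataFrame,
    endpoint: EndpointDef,
    recordings: Optional[Sequence[RecordingDef]] = None,
) -> float:
    """Plate-level VC percent response for one endpoint (scalar; VC wells
    carry no concentration)."""
    if len(vc_wells) == 0:
        raise ValueError("no VC wells supplied")
    affected = _affected_mask(vc_wells, endpoint, recordings)
    return 100.0 * float(affected.sum()) / len(vc_wells)


def pool_pc_weekly(
    pc_wells: pd.DataFrame,
    endpoint: EndpointDef,
    recordings: Optional[Sequence[RecordingDef]] = None,
) -> list[ConcentrationResponse]:
    """Pool single-embryo PC series from plates run in the same ISO week.

    Each plate carries one embryo per PC concentration, so a pooled week of
    ``k`` plates has denominator ``k`` at each concentration.  Weeks with a
    single contributing plate are flagged ``low_n``.  Returns one series per
    ISO week (``replicate_key`` = ``"YYYY-Www"``), sorted; empty input gives
    an empty list.
    """
    if len(pc_wells) == 0:
        return []
    wells = pc_wells.copy()
    dates = pd.to_datetime(wells["run_date"])
    iso = dates.dt.isocalendar()
    wells["_week"] = [
        f"{y}-W{w:02d}" for y, w in zip(iso["year"], iso["week"])
    ]
    out: list[ConcentrationResponse] = []
    for week, grp in wells.groupby("_week", sort=True):
        n_plates = grp["plate_id"].nunique()
        affected = _affected_mask(grp, endpoint, recordings)
        g = pd.DataFrame(
            {"conc_uM": grp["conc_uM"].astype(float), "affected": affected}
        ).groupby("conc_uM", sort=True)
        conc = np.array(sorted(g.groups))
        n = g.size().to_numpy()
        k = g["affected"].sum().to_numpy()
        low_n = n_plates < 2
        if low_n:
            warnings.warn(
                f"PC pool {week} has a single contributing plate", stacklevel=2
            )
        out.append(
            ConcentrationResponse(
                endpoint=endpoint,
                substance_id=str(grp["substance_id"].iloc[0]),
                replicate_key=week,
                conc_log10M=log10_molar(conc),
                response_pct=100.0 * k / n,
                n_embryos=n,
                low_n=low_n,
            )
        )
    return out


def build_endpoint_curves(
    wells: pd.DataFrame,
    recordings: Sequence[RecordingDef],
    test_substance_ids: Iterable[str],
) -> list[ConcentrationResponse]:
    """All 120-hpf endpoint curves for every test substance x plate.

    The workhorse for the pipeline: enumerates the lab's endpoints and
    computes one :class:`ConcentrationResponse` per substance x plate x
    endpoint from the tidy wells table.
    """
    eps = enumerate_endpoints(recordings)
    test_ids = set(test_substance_ids)
    curves: list[ConcentrationResponse] = []
    mask = wells["substance_id"].isin(test_ids)
    for (sub, plate), grp in wells[mask].groupby(
        ["substance_id", "plate_id"], sort=True
    ):
        for ep in eps:
            curves.append(percent_response(grp, ep, recordings))
    return curves
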