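"""Plate and dataset quality checks.

Three QC gates: vehicle-control baseline responses (mortality at 24 and
120 hpf and any-malformation must stay at or below 20% per plate),
positive-control potency reproducibility across weekly pools (SD of BMC
values per endpoint), and blinded-duplicate concordance (median BMC of the
two members of a pair should agree within 0.5 log10 units, ~3.2-fold).
QC only flags; it never drops data (an optional strict mode lets callers
exclude failing plates themselves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .bmc import BMCResult
from .core_model import RecordingDef
from .endpoints import (
    MALFORMED_ANY,
    MORTALITY_120,
    MORTALITY_24,
    vc_response,
)

__all__ = [
    "VC_FAIL_THRESHOLD_PCT",
    "DUPLICATE_FLAG_LOG10",
    "fold_change",
    "check_vc",
    "pc_reproducibility",
    "duplicate_concordance",
    "endpoint_variability",
    "QCReport",
]

#: plate VC baseline must not exceed this percent response.
VC_FAIL_THRESHOLD_PCT = 20.0
#: duplicate median-BMC difference above this (log10 units) is discordant.
DUPLICATE_FLAG_LOG10 = 0.5


def fold_change(sd: float) -> float:
    """Fold-change equivalent of a log10-scale SD: ``10**sd`` (0 -> 1.0,
    0.5 -> ~3.16)."""
    return float(10.0**sd)


def check_vc(
    plate_wells: pd.DataFrame,
    recordings: Optional[Sequence[RecordingDef]] = None,
    threshold: float = VC_FAIL_THRESHOLD_PCT,
) -> pd.DataFrame:
    """VC baseline responses for one plate, flagged against the threshold.

    Computes the plate's VC response on the three baseline endpoints
    (mortality at 24 and 120 hpf and any-malformation+mortality) and fails
    a row iff the response strictly exceeds the threshold (exactly 20% still
    passes).  Raises when the plate carries no VC wells.
    """
    vc = plate_wells[plate_wells["conc_uM"].astype(float) == 0.0]
    if len(vc) == 0:
        raise ValueError("plate has no VC wells")
    rows = []
    for ep in (MORTALITY_24, MORTALITY_120, MALFORMED_ANY):
        if ep.kind == "malformed_any" and recordings is None:
            continue
        resp = vc_response(vc, ep, recordings)
        rows.append(
            {
                "plate_id": plate_wells["plate_id"].iloc[0],
                "endpoint": ep.name,
                "vc_response_pct": resp,
                "n_vc": len(vc),
                "passed": resp <= threshold,
            }
        )
    return pd.DataFrame(rows)


def pc_reproducibility(
    pc_results: Iterable[BMCResult],
) -> tuple[pd.DataFrame, Optional[float], Optional[float]]:
    """Positive-control potency spread across weekly pools.

    Groups the PC BMC values (one per weekly pool) by endpoint and takes
    the sample SD; returns the per-endpoint table (with fold equivalents),
    the median SD across endpoints, and its fold equivalent.  Endpoints
    with a single pool have undefined SD and are excluded with a warning.
    """
    by_ep: dict[str, list[float]] = {}
    for r in pc_results:
        by_ep.setdefault(r.endpoint, []).append(r.potency_value)
    rows = []
    for ep, vals in sorted(by_ep.items()):
        if len(vals) < 2:
            warnings.warn(
                f"PC endpoint {ep!r} has a single weekly pool; SD undefined",
                stacklevel=2,
            )
            continue
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {"endpoint": ep, "n_pools": len(vals), "sd": sd, "fold": fold_change(sd)}
        )
    table = pd.DataFrame(rows, columns=["endpoint", "n_pools", "sd", "fold"])
    if table.empty:
        return table, None, None
    med = float(table["sd"].median())
    return table, med, fold_change(med)


def duplicate_concordance(
    results_member1: Iterable[BMCResult],
    results_member2: Iterable[BMCResult],
    flag_threshold: float = DUPLICATE_FLAG_LOG10,
) -> pd.DataFrame:
    """Per-endpoint median-BMC agreement of a blinded duplicate pair.

    For each endpoint, the median potency over each member's triplicate
    runs is compared; ``|delta| > 0.5`` log10 units is flagged discordant.
    Identical medians are kept in the table but marked ``in_plot=False``
    (the concordance plot shows only differing pairs).  Endpoints missing
    from either member are skipped with a warning.
    """

    def medians(results: Iterable[BMCResult]) -> dict[str, float]:
        by_ep: dict[str, list[float]] = {}
        for r in results:
            by_ep.setdefault(r.endpoint, []).append(r.potency_value)
        return {ep: float(np.median(v)) for ep, v in by_ep.items()}

    m1, m2 = medians(results_member1), medians(results_member2)
    rows = []
    for ep in sorted(set(m1) | set(m2)):
        if ep not in m1 or ep not in m2:
            warnings.warn(
                f"endpoint {ep!r} tested in only one duplicate member; skipped",
                stacklevel=2,
            )
            continue
        diff = abs(m1[ep] - m2[ep])
        rows.append(
            {
                "endpoint": ep,
                "median_bmc_1": m1[ep],
                "median_bmc_2": m2[ep],
                "abs_diff": diff,
                "discordant": diff > flag_threshold,
                "in_plot": diff != 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "endpoint",
            "median_bmc_1",
            "median_bmc_2",
            "abs_diff",
            "discordant",
            "in_plot",
        ],
    )


def endpoint_variability(results: Iterable[BMCResult]) -> pd.DataFrame:
    """Triplicate BMC spread per substance x endpoint.

    The sample SD of each substance's replicate potencies (censored
    highest-tested values substituted for inactives) measures run-to-run
    BMC variation; rows with SD == 0 (including all-inactive triplicates)
    are marked ``retained=False`` and excluded from distribution summaries,
    keeping only substances active in at least one run.
    """
    by_key: dict[tuple[str, str], list[float]] = {}
    for r in results:
        by_key.setdefault((r.endpoint, r.substance_id), []).append(r.potency_value)
    rows = []
    for (ep, sub), vals in sorted(by_key.items()):
        if len(vals) < 2:
            continue
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {
                "endpoint": ep,
                "substance_id": sub,
                "n_replicates": len(vals),
                "sd": sd,
                "retained": sd > 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["endpoint", "substance_id", "n_replicates", "sd", "retained"]
    )


@dataclass
class QCReport:
    """Bundle of the three QC gates plus the variability summary."""

    vc_flags: pd.DataFrame
    pc_sd: pd.DataFrame
    pc_median_sd: Optional[float]
    pc_median_fold: Optional[float]
    duplicate_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    variability: Optional[pd.DataFrame] = None

    def failing_plates(self) -> list[str]:
        bad = self.vc_flags[~self.vc_flags["passed"]]
        return sorted(bad["plate_id"].unique())
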