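"""Phenotype specificity relative to mortality.

A phenotype endpoint is *specific* when it responds at concentrations
below those causing death.  The specificity score of an endpoint on a
plate is ``BMC(mortality) - BMC(phenotype)`` in log10 units, so positive
scores mean the phenotype is the more potent effect (a generalisation of
the classical teratogenic index).  In principle the score cannot be
negative — a dead embryo counts in every combined endpoint — but finite
dose spacing and interpolation noise produce a small negative tail, which
is used to estimate the noise scale: the cutoff separating specific from
non-specific is the mirrored 5th percentile of the negative scores in a
dataset.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .bmc import BMCResult

__all__ = [
    "SpecificityScore",
    "SubstanceCall",
    "CLASS_PRECEDENCE",
    "specificity_score",
    "derive_cutoff",
    "classify_plate",
    "aggregate_substance",
]

Cls = Literal["specific", "non-specific", "non-toxic", "inconclusive"]

#: collapse precedence, most informative first.
CLASS_PRECEDENCE: tuple[str, ...] = (
    "specific",
    "non-specific",
    "inconclusive",
    "non-toxic",
)


@dataclass
class SpecificityScore:
    """Plate-level specificity of one phenotype endpoint vs. mortality."""

    substance_id: str
    endpoint: str
    replicate_key: str
    score: Optional[float]
    endpoint_active: bool
    both_active: bool
    bmc_endpoint: Optional[float] = None

    def __post_init__(self) -> None:
        if self.endpoint_active and self.score is None:
            raise ValueError("active endpoints must carry a score")


@dataclass
class SubstanceCall:
    """Majority-vote substance-level specificity call for one endpoint."""

    substance_id: str
    endpoint: str
    cls: Cls
    bmc_summary: Optional[float]
    score_summary: Optional[float]
    n_plates: int


def specificity_score(
    bmc_mort: BMCResult, bmc_pheno: BMCResult
) -> SpecificityScore:
    """Score one plate: mortality BMC minus phenotype BMC (log10 units).

    When mortality is inactive its censored highest-tested concentration is
    substituted, so a phenotype active below an entirely non-lethal range
    still earns a large positive score.  An inactive phenotype endpoint has
    no score and is a non-toxic candidate.
    """
    if bmc_mort.substance_id != bmc_pheno.substance_id:
        raise ValueError("mortality and phenotype results are for different substances")
    if bmc_mort.replicate_key != bmc_pheno.replicate_key:
        raise ValueError("mortality and phenotype results are for different replicates")
    if not bmc_pheno.active:
        return SpecificityScore(
            substance_id=bmc_pheno.substance_id,
            endpoint=bmc_pheno.endpoint,
            replicate_key=bmc_pheno.replicate_key,
            score=None,
            endpoint_active=False,
            both_active=False,
        )
    score = bmc_mort.potency_value - bmc_pheno.bmc_log10M
    return SpecificityScore(
        substance_id=bmc_pheno.substance_id,
        endpoint=bmc_pheno.endpoint,
        replicate_key=bmc_pheno.replicate_key,
        score=float(score),
        endpoint_active=True,
        both_active=bmc_mort.active,
        bmc_endpoint=bmc_pheno.bmc_log10M,
    )


def derive_cutoff(
    scores: Iterable[SpecificityScore], q: float = 0.05
) -> float:
    """Dataset noise cutoff: the mirrored ``q``-quantile of negative scores.

    Negative scores are treated as draws from the (symmetric) noise
    distribution of the BMC calculation; the cutoff is ``-Q_q(scores < 0)``
    using linear-interpolation quantiles (``h = (n-1)q``), returned as a
    positive number.  With no negative scores the cutoff degrades to 0 with
    a warning.
    """
    negatives = [
        s.score for s in scores if s.score is not None and s.score < 0
    ]
    if not negatives:
        warnings.warn(
            "no negative specificity scores in dataset; cutoff set to 0",
            stacklevel=2,
        )
        return 0.0
    return float(-np.quantile(negatives, q, method="linear"))


def classify_plate(s: SpecificityScore, cutoff: float) -> str:
    """Three-way plate call: specific (score strictly above the cutoff),
    non-specific (score <= cutoff), or non-toxic (endpoint inactive)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if not s.endpoint_active:
        return "non-toxic"
    return "specific" if s.score > cutoff else "non-specific"


def aggregate_substance(
    substance_id: str,
    endpoint: str,
    plate_calls: Sequence[tuple[str, Optional[float], Optional[float]]],
) -> SubstanceCall:
    """Majority vote across plates for one substance x endpoint.

    ``plate_calls`` holds ``(class, bmc_log10M, score)`` triples, one per
    plate.  The majority class (> 50% of plates) is reported with the mean
    BMC and mean score of that class's plates; with no majority the call is
    *inconclusive* and the summaries are carried from the specific-class
    plates (if any).
    """
    if not plate_calls:
        raise ValueError("aggregate_substance requires at least one plate")
    n = len(plate_calls)
    counts = Counter(c for c, _, _ in plate_calls)
    majority = [c for c, k in counts.items() if k * 2 > n]

    def summarise(cls: str) -> tuple[Optional[float], Optional[float]]:
        bmcs = [b for c, b, _ in plate_calls if c == cls and b is not None]
        scs = [s for c, _, s in plate_calls if c == cls and s is not None]
        return (
            float(np.mean(bmcs)) if bmcs else None,
            float(np.mean(scs)) if scs else None,
        )

    if majority:
        cls = majority[0]
        bmc, score = summarise(cls)
        return SubstanceCall(substance_id, endpoint, cls, bmc, score, n)
    bmc, score = summarise("specific")
    return SubstanceCall(substance_id, endpoint, "inconclusive", bmc, score, n)
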