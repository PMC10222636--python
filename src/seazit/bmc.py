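"""Benchmark-concentration (BMC) modelling.

The potency of a substance on an endpoint is summarised as the BMC: the
log10-molar concentration at which the noise-corrected concentration-response
curve first reaches a benchmark response (BMR).  The BMR itself is chosen
per endpoint and dataset as the lowest response threshold at which the
pooled variance of the potency estimates across substances has stabilised —
thresholds below the data's noise floor produce erratic potencies, and the
variance-versus-threshold profile decays to a plateau once the threshold
clears the noise.

Curve processing is a weighted isotonic (monotone non-decreasing)
least-squares projection of the raw percent responses, which removes
non-monotone noise while preserving the response scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.isotonic import IsotonicRegression

from .endpoints import ConcentrationResponse

__all__ = [
    "CorrectedCurve",
    "BMCResult",
    "BMRSelection",
    "monotonize",
    "anchor_to_baseline",
    "bmc_at",
    "pooled_variance",
    "scan_thresholds",
    "select_bmr",
    "DEFAULT_GRID",
]

logger = logging.getLogger(__name__)

#: default BMR threshold grid: 5% .. 95% in steps of 5%.
DEFAULT_GRID = np.arange(5.0, 100.0, 5.0)


@dataclass
class CorrectedCurve:
    """A concentration-response series after monotone noise correction."""

    source: ConcentrationResponse
    response_corrected: np.ndarray
    max_response: float

    def __post_init__(self) -> None:
        self.response_corrected = np.asarray(self.response_corrected, dtype=float)
        if np.any(np.diff(self.response_corrected) < -1e-9):
            raise ValueError("corrected responses must be non-decreasing")


@dataclass
class BMCResult:
    """Potency of one substance x endpoint x replicate at a given BMR.

    When the corrected curve never reaches the BMR the response is inactive
    and no BMC exists; downstream variance and specificity computations then
    substitute the highest tested concentration (``censored_at_max``).
    ``censored_low`` marks curves already at or above the BMR at the lowest
    tested concentration, where the BMC is right at the bottom of the range.
    """

    endpoint: str
    substance_id: str
    replicate_key: str
    bmr_used: float
    active: bool
    bmc_log10M: Optional[float]
    max_conc_log10M: float
    censored_at_max: bool = False
    censored_low: bool = False

    @property
    def potency_value(self) -> float:
        """BMC when active, else the censored highest-tested concentration."""
        return self.bmc_log10M if self.active else self.max_conc_log10M


@dataclass
class BMRSelection:
    """Outcome of the variance-stabilisation scan for one endpoint."""

    endpoint: str
    threshold_grid: np.ndarray
    pooled_variance: np.ndarray
    bmr: float
    plateau_value: float
    converged: bool


def monotonize(cr: ConcentrationResponse) -> CorrectedCurve:
    """Weighted least-squares monotone (non-decreasing) fit of a response
    curve, weighted by the per-concentration embryo counts and clipped to
    [0, 100].  Requires at least two concentrations.
    """
    if len(cr) < 2:
        raise ValueError("monotonize requires at least 2 concentrations")
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(
        cr.conc_log10M, cr.response_pct, sample_weight=cr.n_embryos
    )
    fitted = np.clip(fitted, 0.0, 100.0)
    return CorrectedCurve(
        source=cr, response_corrected=fitted, max_response=float(fitted.max())
    )


def anchor_to_baseline(
    cr: ConcentrationResponse, vc_pct: float
) -> ConcentrationResponse:
    """Subtract the plate's VC response for the same endpoint, floored at 0.

    BMR thresholds are read as levels above the baseline noise, so responses
    are anchored to the plate's own vehicle baseline before curve
    processing.
    """
    return ConcentrationResponse(
        endpoint=cr.endpoint,
        substance_id=cr.substance_id,
        replicate_key=cr.replicate_key,
        conc_log10M=cr.conc_log10M,
        response_pct=np.maximum(cr.response_pct - vc_pct, 0.0),
        n_embryos=cr.n_embryos,
        low_n=cr.low_n,
    )


def bmc_at(curve: CorrectedCurve, bmr: float) -> BMCResult:
    """BMC of a corrected curve at a BMR, by linear interpolation in log10
    concentration between the bracketing tested concentrations.

    The response is active iff the corrected maximum reaches the BMR.  A
    curve already at/above the BMR at the lowest tested concentration
    returns that concentration with ``censored_low=True``; a flat corrected
    segment sitting exactly at the BMR resolves to its lowest
    concentration.
    """
    if not (0.0 < bmr < 100.0):
        raise ValueError("bmr must lie strictly between 0 and 100")
    cr = curve.source
    conc = cr.conc_log10M
    resp = curve.response_corrected
    max_conc = float(conc[-1])
    base = dict(
        endpoint=cr.endpoint.name,
        substance_id=cr.substance_id,
        replicate_key=cr.replicate_key,
        bmr_used=float(bmr),
        max_conc_log10M=max_conc,
    )
    if curve.max_response < bmr:
        return BMCResult(
            active=False, bmc_log10M=None, censored_at_max=True, **base
        )
    idx = int(np.argmax(resp >= bmr))  # first index reaching the BMR
    if idx == 0:
        return BMCResult(
            active=True, bmc_log10M=float(conc[0]), censored_low=True, **base
        )
    r0, r1 = resp[idx - 1], resp[idx]
    c0, c1 = conc[idx - 1], conc[idx]
    bmc = float(c0 + (bmr - r0) / (r1 - r0) * (c1 - c0))
    return BMCResult(active=True, bmc_log10M=bmc, **base)


def pooled_variance(results: Iterable[BMCResult]) -> float:
    """Pooled potency variance across substances.

    Groups replicate BMC values (censored max-concentration values
    substituted for inactives) by substance and pools the per-substance
    sample variances: ``sum((n_s-1)*var_s) / sum(n_s-1)`` over substances
    with at least two replicates.
    """
    by_sub: dict[str, list[float]] = {}
    for r in results:
        by_sub.setdefault(r.substance_id, []).append(r.potency_value)
    num = 0.0
    den = 0
    for vals in by_sub.values():
        if len(vals) >= 2:
            num += (len(vals) - 1) * float(np.var(vals, ddof=1))
            den += len(vals) - 1
    if den == 0:
        raise ValueError("pooled_variance needs >=1 substance with >=2 replicates")
    return num / den


def scan_thresholds(
    dataset: Sequence[ConcentrationResponse],
    grid: np.ndarray = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance profile of one endpoint's dataset over a BMR grid.

    Every substance x replicate curve is monotonized once, then the BMC is
    evaluated at each candidate threshold and the across-substance pooled
    variance recorded.  Returns ``(grid, variance_per_threshold)``.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or np.any((grid <= 0) | (grid >= 100)):
        raise ValueError("grid must be ascending within (0, 100)")
    curves = [monotonize(cr) for cr in dataset]
    profile = np.array(
        [pooled_variance(bmc_at(c, t) for c in curves) for t in grid]
    )
    return grid, profile


def _decay(t, a, k, c):
    return a * np.exp(-k * t) + c


def select_bmr(
    grid: np.ndarray,
    variance: np.ndarray,
    endpoint: str = "",
    tol: float = 0.05,
) -> BMRSelection:
    """Pick the BMR as the lowest threshold with stabilised pooled variance.

    An exponential decay ``v(t) = a*exp(-k*t) + c`` is fitted to the
    decaying phase of the variance profile (up to its minimum — at very
    high thresholds censoring of inactive replicates drives the pooled
    variance back up, which is an artifact of the substitution rule, not
    instability of the potency estimate); the BMR is the smallest grid
    threshold where the fitted curve is within ``tol`` of its full decay
    amplitude above the asymptote (``v(t) <= c + tol*a``).  A flat profile
    is already stable (BMR = lowest threshold); a profile that never
    decays, or a failed fit, degrades to ``converged=False`` with the
    highest threshold.
    """
    grid = np.asarray(grid, dtype=float)
    v = np.asarray(variance, dtype=float)
    if len(grid) == 0 or len(grid) != len(v):
        raise ValueError("empty or mismatched variance profile")

    def fallback() -> BMRSelection:
        warnings.warn(
            f"variance profile for {endpoint or 'endpoint'} did not stabilise; "
            f"falling back to the highest grid threshold",
            stacklevel=3,
        )
        return BMRSelection(
            endpoint, grid, v, float(grid[-1]), float(v[-1]), converged=False
        )

    spread = float(v.max() - v.min())
    scale = max(float(np.abs(v).max()), 1.0e-12)
    if spread <= 1.0e-9 * scale:  # flat: already stabilised everywhere
        return BMRSelection(
            endpoint, grid, v, float(grid[0]), float(v.mean()), converged=True
        )
    i_min = int(np.argmin(v))
    g_dec, v_dec = grid[: i_min + 1], v[: i_min + 1]
    if len(g_dec) < 3 or v_dec[-1] >= v_dec[0]:  # no decaying phase
        return fallback()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            (a, k, c), _ = curve_fit(
                _decay,
                g_dec,
                v_dec,
                p0=[spread, 2.0 / (g_dec[-1] - g_dec[0] + 1.0), float(v_dec.min())],
                bounds=([0.0, 1.0e-9, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except Exception:
        return fallback()
    if a <= 0 or k <= 0:
        return fallback()
    # a*exp(-k t) <= tol*a  <=>  t >= ln(1/tol)/k
    t_star = np.log(1.0 / tol) / k
    reached = g_dec[g_dec >= t_star]
    if len(reached) == 0:
        return fallback()
    return BMRSelection(
        endpoint, grid, v, float(reached[0]), float(c), converged=True
    )
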