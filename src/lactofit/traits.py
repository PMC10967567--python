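"""Per-lactation curve traits derived from a fitted Wood curve.

Nine characteristics are computed per lactation from the Wood parameters
(A, B, C) and the recording calendar:

==================  ======  =====================================================
trait               unit    definition
==================  ======  =====================================================
initial production  g/day   the fitted A
rise rate           --      the fitted B
decline rate        1/day   the fitted C
lactation length    days    last test-day DIM + 7
total production    kg      integral of the fitted curve from kidding to LL
mean production     kg/day  TP / LL
peak date           days    B / C
persistency         %       100 - (1 - B) * ln C
peak production     g/day   A * (B/C)**B * exp(-B)  (the curve maximum)
==================  ======  =====================================================

The persistency statistic is the classical scale-sensitive form and is
implemented verbatim; it can exceed 100% when C < 1 in day^-1 units (an
alternative per-cent scaling of C is available via ``c_scale``). Total
production uses the closed form A*C^-(B+1)*gamma_lower(B+1, C*t_end); the
adaptive-quadrature route is exposed for cross-checking.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special

from .dataio import LactationRecord
from .exceptions import DomainError, InsufficientData, NoPeak
from .model import CurveFitResult

__all__ = [
    "peak_date",
    "peak_production",
    "persistency",
    "total_production",
    "total_production_quad",
    "lactation_length",
    "compute_traits",
    "traits_table",
    "summarize_traits",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = ["A", "B", "C", "LL", "TP", "MP", "PD", "PC", "PP"]

#: Table-3-style display labels
TRAIT_LABELS = {
    "A": "Initial production (g/day)",
    "B": "Rate of increase to peak",
    "C": "Rate of decline after peak",
    "LL": "Lactation length (days)",
    "TP": "Total production (kg)",
    "MP": "Mean production (kg/day)",
    "PD": "Peak date (days)",
    "PC": "Persistence coefficient (%)",
    "PP": "Peak production (g/day)",
}


def peak_date(B: float, C: float) -> float:
    """DIM of the Wood-curve maximum, B/C (days)."""
    if C <= 0:
        raise NoPeak(f"C = {C} <= 0: monotone non-declining curve has no peak")
    if B < 0:
        raise DomainError(f"B = {B} < 0")
    return B / C


def peak_production(A: float, B: float, C: float) -> float:
    """Yield at the Wood-curve maximum: A*(B/C)^B*e^-B (g/day); 0^0 = 1."""
    if C <= 0:
        raise NoPeak(f"C = {C} <= 0: no interior maximum")
    if A <= 0 or B < 0:
        raise DomainError(f"need A > 0, B >= 0; got A={A}, B={B}")
    ratio = 1.0 if B == 0 else (B / C) ** B
    return A * ratio * np.exp(-B)


def persistency(B: float, C: float) -> float:
    """Persistency coefficient 100 - (1 - B) * ln C, in percent.

    Scale-sensitive in C: with C in 1/day it typically exceeds 100 since
    ln C < 0; the statistic is reported as defined.
    """
    if C <= 0:
        raise DomainError(f"C = {C} <= 0: ln C undefined")
    return 100.0 - (1.0 - B) * np.log(C)


def total_production(A: float, B: float, C: float, t_end: float) -> float:
    """Integral of the Wood curve over [0, t_end], in kg.

    Uses the lower-incomplete-gamma closed form
    ``A * C**-(B+1) * gamma_lower(B+1, C*t_end)``; degenerate C = 0 falls
    back to the power-law primitive A*t^(B+1)/(B+1).
    """
    if t_end <= 0:
        raise DomainError(f"t_end = {t_end} <= 0")
    if A <= 0 or B < 0 or C < 0:
        raise DomainError(f"need A > 0, B >= 0, C >= 0; got {(A, B, C)}")
    if C == 0:
        grams = A * t_end ** (B + 1.0) / (B + 1.0)
    else:
        grams = A * C ** -(B + 1.0) * special.gammainc(B + 1.0, C * t_end) \
            * special.gamma(B + 1.0)
    return grams / 1000.0


def total_production_quad(A: float, B: float, C: float, t_end: float) -> float:
    """Adaptive-quadrature route for the same integral (cross-check), kg."""
    if t_end <= 0:
        raise DomainError(f"t_end = {t_end} <= 0")
    val, _ = integrate.quad(lambda t: A * t**B * np.exp(-C * t), 0.0, t_end,
                            limit=200)
    return val / 1000.0


def lactation_length(lact: LactationRecord | Sequence[float]) -> float:
    """Lactation length: last recording DIM + 7 days."""
    dim = lact.dim if isinstance(lact, LactationRecord) else np.asarray(lact, float)
    if np.size(dim) == 0:
        raise InsufficientData("no test-day records")
    return float(np.max(dim)) + 7.0


def compute_traits(fit: CurveFitResult, t_end: float | None = None,
                   c_scale: float = 1.0) -> pd.Series:
    """All nine traits for one converged Wood fit.

    ``t_end`` defaults to the lactation length (last DIM + 7); ``c_scale``
    rescales C inside the persistency formula only (1.0 = verbatim).
    """
    if fit.spec.name != "wood":
        raise DomainError(f"trait calculus is defined for the wood family, got {fit.spec.name}")
    A, B, C = (float(fit.params[k]) for k in ("A", "B", "C"))
    ll = lactation_length(fit.model.dim)
    if t_end is None:
        t_end = ll
    tp = total_production(A, B, C, t_end)
    return pd.Series({
        "A": A, "B": B, "C": C,
        "LL": ll,
        "TP": tp,
        "MP": tp / ll,
        "PD": peak_date(B, C),
        "PC": persistency(B, max(C * c_scale, np.finfo(float).tiny)),
        "PP": peak_production(A, B, C),
    })


def traits_table(fits: Iterable[tuple[LactationRecord, CurveFitResult]] | Iterable[CurveFitResult],
                 c_scale: float = 1.0) -> pd.DataFrame:
    """Per-lactation trait rows for a collection of converged Wood fits.

    Accepts either bare :class:`CurveFitResult` objects or
    ``(LactationRecord, CurveFitResult)`` pairs; pairs carry the covariates
    through to the output for the downstream effects analysis.
    """
    rows = []
    for item in fits:
        if isinstance(item, tuple):
            lact, fit = item
            meta = {"lactation_id": lact.lactation_id, **lact.covariates}
        else:
            lact, fit = None, item
            meta = {"lactation_id": getattr(fit.model, "lactation_id", "")}
        if not fit.converged or fit.spec.name != "wood":
            continue
        rows.append({**meta, **compute_traits(fit, c_scale=c_scale)})
    return pd.DataFrame(rows)


def summarize_traits(traits: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Descriptive summary of the trait table: mean, min, max, SD (n-1
    denominator) and a Lilliefors-corrected Kolmogorov-Smirnov normality
    verdict per trait."""
    from .effects import ks_normality

    rows = []
    for key in TRAIT_COLUMNS:
        if key not in traits.columns:
            continue
        x = traits[key].dropna().to_numpy(float)
        if x.size == 0:
            continue
        try:
            verdict = "Accepted" if ks_normality(x, alpha=alpha).normal else "Rejected"
        except Exception:
            verdict = "n/a"
        rows.append({
            "trait": TRAIT_LABELS[key],
            "key": key,
            "n": x.size,
            "mean": x.mean(),
            "min": x.min(),
            "max": x.max(),
            "sd": x.std(ddof=1) if x.size > 1 else 0.0,
            "normality": verdict,
        })
    return pd.DataFrame(rows)
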