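"""Cohort-level fitting: per-lactation estimation and multi-model comparison.

Thin functional layer over :class:`~lactofit.model.LactationCurveModel` for
datasets of many lactations: ``fit_dataset`` produces the one-row-per-
lactation fit table and ``compare_models`` the model-battery report (median
iteration count, pooled and mean per-lactation R², total RSS, ranking).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataio import LactationRecord
from .exceptions import DegenerateLactation, InsufficientData, LactofitError
from .families import DEFAULT_COMPARISON_MODELS, ModelSpec, get_model
from .model import CurveFitResult, LactationCurveModel, SolverSettings

__all__ = [
    "fit_lactation",
    "initial_values",
    "fit_dataset",
    "compare_models",
    "ModelComparison",
]


def fit_lactation(lact: LactationRecord, spec: ModelSpec | str = "wood",
                  settings: SolverSettings | None = None) -> CurveFitResult:
    """Nonlinear least-squares fit of one family to one lactation."""
    return LactationCurveModel.from_record(lact, family=spec).fit(settings=settings)


def initial_values(lact: LactationRecord, spec: ModelSpec | str = "wood") -> np.ndarray:
    """Admissible heuristic starting values (log-linear OLS for Wood cores)."""
    return LactationCurveModel.from_record(lact, family=spec).start_params()


def fit_dataset(lactations: Iterable[LactationRecord],
                spec: ModelSpec | str = "wood",
                settings: SolverSettings | None = None) -> pd.DataFrame:
    """Fit one family to every lactation.

    Returns a DataFrame with one row per lactation: parameter columns, rss,
    r2, n_iter, converged, n_obs and an ``error`` column naming the failure
    for unfittable lactations (too few test days, all-zero yields).
    """
    spec = get_model(spec) if isinstance(spec, str) else spec
    rows = []
    for lact in lactations:
        base = {"lactation_id": lact.lactation_id, "goat_id": lact.goat_id,
                "model": spec.name}
        try:
            res = fit_lactation(lact, spec, settings)
        except (InsufficientData, DegenerateLactation) as err:
            rows.append({**base, "error": type(err).__name__})
            continue
        rows.append({
            **base, **res.params.to_dict(),
            "rss": res.rss, "r2": res.rsquared, "n_iter": res.n_iter,
            "converged": res.converged, "n_obs": res.nobs, "error": "",
        })
    cols = ["lactation_id", "goat_id", "model", *spec.param_names,
            "rss", "r2", "n_iter", "converged", "n_obs", "error"]
    return pd.DataFrame(rows, columns=cols)


class ModelComparison:
    """Battery comparison of curve families over one dataset.

    ``table`` has one row per family: converged count, median iterations,
    pooled R² (1 − ΣRSS / pooled total SS over the concatenated records),
    mean per-lactation R² and total RSS. The ranking maximises pooled R²
    with RSS as tie-breaker; families with no converged fit are excluded.
    """

    def __init__(self, table: pd.DataFrame, per_lactation: dict[str, pd.DataFrame]):
        self.table = table
        self.per_lactation = per_lactation

    @property
    def ranking(self) -> list[str]:
        ok = self.table[self.table["n_converged"] > 0]
        ordered = ok.sort_values(["r2_pooled", "rss"], ascending=[False, True])
        return list(ordered["model"])

    @property
    def best_model(self) -> str:
        rank = self.ranking
        if not rank:
            raise LactofitError("no model produced a converged fit")
        return rank[0]

    def summary(self) -> str:
        lines = [f"{'Model comparison':^72}", "=" * 72,
                 f"{'model':<16}{'N.it':>6}{'R2':>10}{'R2(mean)':>10}{'RSS':>16}{'conv':>7}"]
        for row in self.table.itertuples():
            lines.append(
                f"{row.model:<16}{row.n_iter_median:>6.0f}{row.r2_pooled:>10.4f}"
                f"{row.r2_mean:>10.4f}{row.rss:>16.6g}{row.n_converged:>7d}"
            )
        lines.append("=" * 72)
        lines.append("ranking: " + " > ".join(self.ranking))
        return "\n".join(lines)


def compare_models(lactations: Sequence[LactationRecord],
                   specs: Sequence[ModelSpec | str] | None = None,
                   settings: SolverSettings | None = None) -> ModelComparison:
    """Fit a battery of families to every lactation and rank them.

    By default all registered families except ``cobby_le_du`` enter the
    comparison (its B/C ridge makes it non-identifiable on sparse test-day
    data).
    """
    lactations = list(lactations)
    if not lactations:
        raise InsufficientData("empty dataset: nothing to compare")
    names = [get_model(s).name if isinstance(s, str) else s.name
             for s in (specs or DEFAULT_COMPARISON_MODELS)]

    rows = []
    per_lact: dict[str, pd.DataFrame] = {}
    for name in names:
        fits = fit_dataset(lactations, name, settings)
        per_lact[name] = fits
        ok = fits[(fits["error"] == "") & fits["converged"]]
        # pooled R2 over the concatenated residuals of converged fits
        ids = set(ok["lactation_id"])
        used = [l for l in lactations if l.lactation_id in ids]
        if used:
            y_all = np.concatenate([l.yield_g for l in used])
            sst = float(np.sum((y_all - y_all.mean()) ** 2))
            rss = float(ok["rss"].sum())
            r2_pooled = 1.0 - rss / sst if sst > 0 else np.nan
        else:
            rss, r2_pooled = np.nan, np.nan
        rows.append({
            "model": name,
            "n_converged": int(ok.shape[0]),
            "n_failed": int(fits.shape[0] - ok.shape[0]),
            "n_iter_median": float(ok["n_iter"].median()) if len(ok) else np.nan,
            "r2_pooled": r2_pooled,
            "r2_mean": float(ok["r2"].mean()) if len(ok) else np.nan,
            "rss": rss,
        })
    table = pd.DataFrame(rows)
    return ModelComparison(table, per_lact)
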