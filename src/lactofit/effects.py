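"""Non-genetic factor effects on lactation-curve traits.

Implements the fixed-effects screen used for pastoral test-day traits:

* a Lilliefors-corrected Kolmogorov-Smirnov normality check,
* the five-factor additive fixed-effects ANOVA
  ``trait ~ herd + year + month + litter + dam_age`` (Type III sums of
  squares on sum-coded contrasts for unbalanced designs; Type I available),
* Duncan's multiple range test with protection levels
  ``alpha_p = 1 - (1 - alpha)**(p - 1)`` and studentized-range critical
  values, producing the familiar superscript-letter groupings,
* the trait-by-trait Pearson correlation matrix with significance flags.

The linear-model machinery is statsmodels OLS; the Duncan stepwise logic is
implemented here (no installed package provides it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import DegenerateLactation, InsufficientData, LactofitError

__all__ = [
    "FACTORS",
    "NormalityResult",
    "ks_normality",
    "AnovaResult",
    "anova_fixed_effects",
    "DuncanGrouping",
    "duncan_mrt",
    "correlation_matrix",
]

#: the five non-genetic factors of the adopted model, in model order
FACTORS = ["herd", "kidding_year", "kidding_month", "litter_size", "dam_age"]


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

@dataclass
class NormalityResult:
    statistic: float
    pvalue: float
    normal: bool
    n: int


def ks_normality(sample: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Kolmogorov-Smirnov normality check with Lilliefors correction.

    The reference normal has mean and SD estimated from the sample, so the
    Lilliefors small-sample null distribution is used for the p-value.
    ``normal`` is True when p >= alpha.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise InsufficientData(f"normality check needs n >= 5, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateLactation("zero-variance sample: normality undefined")
    stat, pval = lilliefors(x, dist="norm", pvalmethod="table")
    return NormalityResult(float(stat), float(pval), bool(pval >= alpha), int(x.size))


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _significance_flag(p: float) -> str:
    if not np.isfinite(p):
        return "n/a"
    if p < 0.01:
        return "HS"
    if p < 0.05:
        return "S"
    return "NS"


@dataclass
class AnovaResult:
    """Per-trait fixed-effects ANOVA table and model fit."""

    trait: str
    table: pd.DataFrame  # factor, df, sum_sq, mean_sq, F, p, flag
    rsquared: float
    nobs: int
    resid_df: int
    resid_ms: float
    inestimable: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [f"ANOVA for {self.trait}  (R2 = {self.rsquared:.4f}, n = {self.nobs})",
                 self.table.to_string(index=False)]
        if self.inestimable:
            lines.append("inestimable (aliased) factors: " + ", ".join(self.inestimable))
        return "\n".join(lines)


def _aliased_factors(data: pd.DataFrame, factors: Sequence[str]) -> list[str]:
    """Factors whose dummy columns are linearly dependent on earlier ones.

    Greedy in model order: a factor is aliased (inestimable) when adding its
    contrasts to the design built from the factors kept so far raises the
    design rank by less than its level count minus one.
    """
    from patsy import dmatrix

    kept: list[str] = []
    aliased: list[str] = []
    rank = 1  # intercept
    for f in factors:
        rhs = " + ".join(f"C({g})" for g in [*kept, f])
        new_rank = np.linalg.matrix_rank(np.asarray(dmatrix(rhs, data)))
        if new_rank - rank < data[f].nunique() - 1:
            aliased.append(f)
        else:
            kept.append(f)
            rank = new_rank
    return aliased


def anova_fixed_effects(traits: pd.DataFrame, trait: str,
                        factors: Sequence[str] | None = None,
                        typ: int = 3) -> AnovaResult:
    """Additive fixed-effects ANOVA for one trait.

    Parameters
    ----------
    traits : per-lactation table holding the trait column and factor columns.
    trait : response column name.
    factors : factor columns (default the five non-genetic factors present
        in the table with >= 2 observed levels).
    typ : 3 (default; Type III on sum-coded contrasts, appropriate for the
        unbalanced pastoral design) or 1 (sequential).

    Confounded factors are reported in ``inestimable`` with NaN test rows
    rather than silently dropped.
    """
    if factors is None:
        factors = [f for f in FACTORS if f in traits.columns]
    data = traits[[trait, *factors]].dropna().copy()
    observed = [f for f in factors if data[f].nunique() >= 2]
    dropped_const = [f for f in factors if f not in observed]
    if not observed:
        raise InsufficientData("no factor with >= 2 observed levels")
    data = data.rename(columns={trait: "_y"})

    aliased = _aliased_factors(data, observed)
    estim = [f for f in observed if f not in aliased]
    if not estim:
        raise LactofitError(f"all factors aliased: {aliased}")

    contrast = "Sum" if typ == 3 else "Treatment"
    rhs = " + ".join(f"C({f}, {contrast})" for f in estim)
    fit = smf.ols(f"_y ~ {rhs}", data=data).fit()
    if fit.df_resid < 1:
        raise InsufficientData("no residual degrees of freedom")
    aov = sm.stats.anova_lm(fit, typ=typ)

    rows = []
    for f in estim:
        key = f"C({f}, {contrast})"
        r = aov.loc[key]
        rows.append({
            "factor": f, "df": int(r["df"]), "sum_sq": float(r["sum_sq"]),
            "mean_sq": float(r["sum_sq"] / r["df"]),
            "F": float(r["F"]), "p": float(r["PR(>F)"]),
            "flag": _significance_flag(float(r["PR(>F)"])),
        })
    for f in aliased:
        rows.append({"factor": f, "df": np.nan, "sum_sq": np.nan,
                     "mean_sq": np.nan, "F": np.nan, "p": np.nan,
                     "flag": "inestimable"})
    resid = aov.loc["Residual"]
    rows.append({
        "factor": "Residual", "df": int(resid["df"]),
        "sum_sq": float(resid["sum_sq"]),
        "mean_sq": float(resid["sum_sq"] / resid["df"]),
        "F": np.nan, "p": np.nan, "flag": "",
    })
    table = pd.DataFrame(rows, columns=["factor", "df", "sum_sq", "mean_sq",
                                        "F", "p", "flag"])
    return AnovaResult(
        trait=trait, table=table, rsquared=float(fit.rsquared),
        nobs=int(fit.nobs), resid_df=int(resid["df"]),
        resid_ms=float(resid["sum_sq"] / resid["df"]),
        inestimable=tuple(aliased + dropped_const) if (aliased or dropped_const)
        else (),
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def duncan_critical_range(p: int, df: int, ms_error: float, n_harm: float,
                          alpha: float = 0.05) -> float:
    """Duncan least significant range for a span of ``p`` ordered means.

    Uses the protection level ``alpha_p = 1 - (1 - alpha)**(p - 1)`` and the
    studentized-range quantile q(1 - alpha_p; p, df); the standard error is
    sqrt(MS_e / n_h) with ``n_harm`` the harmonic mean group size.
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    q = stats.studentized_range.ppf(1.0 - alpha_p, p, df)
    return float(q * np.sqrt(ms_error / n_harm))


@dataclass
class DuncanGrouping:
    """Letter grouping of factor-level means (means sorted descending)."""

    factor: str
    trait: str
    table: pd.DataFrame  # level, n, mean, letters
    alpha: float
    significant: dict[tuple, bool]  # (level_i, level_j) -> separated?

    def letters(self) -> dict:
        return dict(zip(self.table["level"], self.table["letters"]))

    def summary(self) -> str:
        head = f"Duncan grouping: {self.trait} by {self.factor} (alpha={self.alpha})"
        return head + "\n" + self.table.to_string(index=False)


def duncan_mrt(values: Sequence[float], groups: Sequence,
               ms_error: float, df_error: int, alpha: float = 0.05,
               factor: str = "factor", trait: str = "trait") -> DuncanGrouping:
    """Duncan's multiple range test over the levels of one factor.

    The stepwise protection rule is enforced: a pair spanning ``p`` ordered
    means is declared separated only if its difference exceeds the Duncan
    range R_p *and* it is not contained in a wider span already declared
    homogeneous. Letters are assigned over means sorted descending, so 'a'
    marks the top group, as in the classical livestock tables.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = np.isfinite(values)
    values, groups = values[mask], groups[mask]
    levels, counts = np.unique(groups, return_counts=True)
    keep = counts > 0
    levels = levels[keep]
    if levels.size < 2:
        raise InsufficientData("Duncan test needs >= 2 non-empty levels")
    if df_error < 1:
        raise InsufficientData("residual df must be >= 1")

    means = np.array([values[groups == g].mean() for g in levels])
    ns = np.array([(groups == g).sum() for g in levels])
    order = np.argsort(-means)
    levels, means, ns = levels[order], means[order], ns[order]
    k = levels.size

    # stepwise: spans from widest to narrowest; containment protection
    homogeneous = np.zeros((k, k), dtype=bool)  # span (i..j) declared NS
    separated: dict[tuple, bool] = {}
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            inside_ns = any(
                homogeneous[a, b]
                for a in range(0, i + 1) for b in range(j, k)
                if (b - a + 1) > span
            )
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            rp = duncan_critical_range(span, df_error, ms_error, n_h, alpha)
            diff = means[i] - means[j]
            sig = (not inside_ns) and (diff > rp)
            separated[(levels[i], levels[j])] = sig
            separated[(levels[j], levels[i])] = sig
            if not sig:
                homogeneous[i, j] = True

    # letter assignment: maximal homogeneous runs over the sorted means
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not separated[(levels[i], levels[j + 1])]:
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                          for o in intervals)]
    maximal = sorted(set(maximal))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_sets = ["" for _ in range(k)]
    for li, (a, b) in enumerate(maximal):
        for idx in range(a, b + 1):
            letter_sets[idx] += alphabet[li % len(alphabet)]

    table = pd.DataFrame({
        "level": levels, "n": ns, "mean": means, "letters": letter_sets,
    })
    return DuncanGrouping(factor=factor, trait=trait, table=table,
                          alpha=alpha, significant=separated)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlation_matrix(traits: pd.DataFrame,
                       columns: Sequence[str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between traits with significance flags.

    Returns ``(r, p, flags)`` DataFrames. Zero-variance traits yield NaN
    entries (reported missing, not dropped). Needs >= 3 complete rows.
    """
    if columns is None:
        from .traits import TRAIT_COLUMNS
        columns = [c for c in TRAIT_COLUMNS if c in traits.columns]
    data = traits[list(columns)].dropna()
    if data.shape[0] < 3:
        raise InsufficientData(f"need >= 3 complete rows, got {data.shape[0]}")
    k = len(columns)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        xi = data.iloc[:, i].to_numpy(float)
        for j in range(i, k):
            xj = data.iloc[:, j].to_numpy(float)
            if i == j:
                r[i, j] = 1.0 if np.ptp(xi) > 0 else np.nan
                p[i, j] = 0.0 if np.ptp(xi) > 0 else np.nan
                continue
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=columns, columns=columns)
    pdf = pd.DataFrame(p, index=columns, columns=columns)
    flags = pdf.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    flags[pdf.isna()] = "n/a"
    return rdf, pdf, flags
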