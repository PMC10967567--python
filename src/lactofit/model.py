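"""Per-lactation curve model and fit results.

:class:`LactationCurveModel` is built from one lactation's test-day data and
a curve family; :meth:`LactationCurveModel.fit` runs bounded trust-region
nonlinear least squares (analytic Jacobians) and returns a
:class:`CurveFitResult` carrying the estimates, their asymptotic standard
errors, fit diagnostics and a ``summary()`` table.

Example
-------
>>> from lactofit import LactationCurveModel
>>> import numpy as np
>>> t = np.arange(14, 141, 14.0)
>>> y = 730 * t**0.26 * np.exp(-0.09 * t)
>>> res = LactationCurveModel(t, y, family="wood").fit()
>>> round(res.params["A"])
730
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dataio import LactationRecord
from .exceptions import DegenerateLactation, InsufficientData
from .families import ModelSpec, get_model

__all__ = ["LactationCurveModel", "CurveFitResult", "SolverSettings"]


class SolverSettings:
    """Trust-region solver knobs.

    ftol/xtol follow the usual relative-change semantics; ``max_iter`` caps
    solver iterations per start; ``n_restarts`` seeded random restarts are
    attempted before a fit is declared non-converged.
    """

    def __init__(self, ftol: float = 1e-8, xtol: float = 1e-10,
                 max_iter: int = 200, n_restarts: int = 3, seed: int = 0):
        self.ftol = ftol
        self.xtol = xtol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.seed = seed


class LactationCurveModel:
    """A lactation-curve family attached to one lactation's test days.

    Parameters
    ----------
    dim : days in milk of the test days (must be > 0 for families with
        reciprocal terms; >= 0 otherwise).
    yield_g : measured yields in g/day (>= 0).
    family : registered family name or :class:`~lactofit.families.ModelSpec`.
    """

    def __init__(self, dim: Sequence[float], yield_g: Sequence[float],
                 family: str | ModelSpec = "wood"):
        self.spec = get_model(family) if isinstance(family, str) else family
        self.dim = np.asarray(dim, dtype=float)
        self.yield_g = np.asarray(yield_g, dtype=float)
        if self.dim.shape != self.yield_g.shape or self.dim.ndim != 1:
            raise ValueError("dim and yield_g must be 1-D arrays of equal length")
        order = np.argsort(self.dim)
        self.dim = self.dim[order]
        self.yield_g = self.yield_g[order]
        if self.nobs < self.spec.n_params + 1:
            raise InsufficientData(
                f"{self.spec.name} needs >= {self.spec.n_params + 1} test days, "
                f"got {self.nobs}"
            )
        if np.all(self.yield_g == 0):
            raise DegenerateLactation("all test-day yields are zero")

    @classmethod
    def from_record(cls, lact: LactationRecord,
                    family: str | ModelSpec = "wood") -> "LactationCurveModel":
        m = cls(lact.dim, lact.yield_g, family=family)
        m.lactation_id = lact.lactation_id
        return m

    @property
    def nobs(self) -> int:
        return int(self.dim.size)

    # ------------------------------------------------------------------
    def start_params(self) -> np.ndarray:
        """Heuristic admissible starting values.

        For the gamma-core families the log-linearised regression
        ``ln y = ln A + B ln t - C t`` over the strictly positive yields is
        solved by OLS (exact on noiseless Wood data); the linear families use
        their exact OLS solution; the rest use documented moment heuristics.
        Zero-yield records are kept for the NLS objective but excluded here
        (ln 0 undefined).
        """
        spec = self.spec
        t, y = self.dim, self.yield_g
        pos = (y > 0) & (t > 0)
        if pos.sum() < spec.n_params + 1:
            raise DegenerateLactation(
                f"only {int(pos.sum())} strictly positive records; "
                f"cannot initialise a {spec.n_params}-parameter start"
            )
        tp, yp = t[pos], y[pos]
        name = spec.name

        if name in ("wood", "goodall", "grossman", "cappio_borlino"):
            X = np.column_stack([np.ones_like(tp), np.log(tp), -tp])
            coef, *_ = np.linalg.lstsq(X, np.log(yp), rcond=None)
            A = float(np.exp(coef[0]))
            B = float(coef[1])
            C = float(coef[2])
            if name == "wood":
                p = [A, B, C]
            elif name == "goodall":
                p = [A, B, C, 0.0]
            elif name == "grossman":
                p = [A, B, C, 0.0, 0.0]
            else:  # cappio_borlino: exponent decays, start undamped
                p = [A, max(B, 1e-3), max(C, 1e-3)]
        elif name == "yadav":
            X = np.column_stack([np.ones_like(tp), 1.0 / tp, tp])
            coef, *_ = np.linalg.lstsq(X, yp, rcond=None)
            p = list(coef)
        elif name == "wilmink":
            # linear in (A, B, C) given the decay rate D; coarse grid on D
            best, best_rss = None, np.inf
            for D in (0.02, 0.05, 0.1, 0.2):
                X = np.column_stack([np.ones_like(tp), np.exp(-D * tp), tp])
                coef, *_ = np.linalg.lstsq(X, yp, rcond=None)
                rss = float(np.sum((yp - X @ coef) ** 2))
                if rss < best_rss:
                    best, best_rss = [*coef, D], rss
            p = best
        elif name == "morant":
            tau = (tp - 150.0) / 100.0
            X = np.column_stack([np.ones_like(tp), tau, tau**2, 1.0 / tp])
            coef, *_ = np.linalg.lstsq(X, np.log(yp), rcond=None)
            p = [float(np.exp(coef[0])), *coef[1:]]
        elif name == "dhanoa":
            i_pk = int(np.argmax(yp))
            p = [float(yp.max()), 0.01, float(tp[i_pk]), 0.05]
        elif name == "cobby_le_du":
            p = [float(yp.max()) * 1.2, 0.1, 0.01]
        else:  # pragma: no cover - registry and branches are kept in sync
            raise NotImplementedError(name)
        return spec.clip_to_bounds(p)

    # ------------------------------------------------------------------
    def fit(self, start_params: Sequence[float] | None = None,
            settings: SolverSettings | None = None) -> "CurveFitResult":
        """Bounded nonlinear least squares; returns a :class:`CurveFitResult`.

        On non-convergence after the seeded random restarts, the best
        solution seen is returned with ``converged=False``.
        """
        settings = settings or SolverSettings()
        spec = self.spec
        t, y = self.dim, self.yield_g
        lo = np.array([b[0] for b in spec.bounds])
        hi = np.array([b[1] for b in spec.bounds])

        def resid(p):
            return spec._eval(p, t) - y

        def jac(p):
            return spec._jac(p, t)

        x0 = np.asarray(start_params, float) if start_params is not None else self.start_params()
        x0 = spec.clip_to_bounds(x0)

        rng = np.random.default_rng(settings.seed)
        best = None
        total_nit = 0
        for attempt in range(1 + settings.n_restarts):
            if attempt > 0:  # seeded random restart inside the box
                x0_try = spec.clip_to_bounds(
                    x0 * np.exp(rng.normal(0, 0.3, spec.n_params))
                    + rng.normal(0, 0.05, spec.n_params)
                )
            else:
                x0_try = x0
            sol = least_squares(
                resid, x0_try, jac=jac, bounds=(lo, hi), method="trf",
                ftol=settings.ftol, xtol=settings.xtol, gtol=1e-12,
                max_nfev=settings.max_iter,
            )
            nit = int(sol.njev if sol.njev is not None else sol.nfev)
            total_nit += max(nit, 1)
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.status > 0:  # converged by ftol/xtol/gtol
                best = sol if sol.cost <= best.cost else best
                break
        converged = best.status > 0

        rss = float(2.0 * best.cost)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / sst if sst > 0 else (1.0 if rss == 0 else np.nan)

        # asymptotic covariance from the Jacobian at the optimum
        dof = self.nobs - spec.n_params
        J = spec._jac(best.x, t)
        try:
            JtJ_inv = np.linalg.pinv(J.T @ J)
            cov = JtJ_inv * (rss / dof if dof > 0 else np.nan)
            bse = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:  # pragma: no cover
            cov = np.full((spec.n_params,) * 2, np.nan)
            bse = np.full(spec.n_params, np.nan)

        return CurveFitResult(
            model=self, params=best.x.copy(), bse=bse, cov_params=cov,
            rss=rss, rsquared=r2, n_iter=max(total_nit, 1),
            converged=bool(converged), message=str(best.message),
        )


class CurveFitResult:
    """Estimates and diagnostics for one fitted lactation curve."""

    def __init__(self, model: LactationCurveModel, params: np.ndarray,
                 bse: np.ndarray, cov_params: np.ndarray, rss: float,
                 rsquared: float, n_iter: int, converged: bool,
                 message: str = ""):
        self.model = model
        self.spec = model.spec
        self.params = pd.Series(params, index=model.spec.param_names, name="estimate")
        self.bse = pd.Series(bse, index=model.spec.param_names, name="std err")
        self.cov_params = cov_params
        self.rss = rss
        self.rsquared = rsquared
        self.n_iter = n_iter
        self.converged = converged
        self.message = message
        self.nobs = model.nobs

    @property
    def resid(self) -> np.ndarray:
        return self.model.yield_g - self.fittedvalues

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.atleast_1d(self.spec(self.params.to_numpy(), self.model.dim))

    def predict(self, t) -> np.ndarray | float:
        """Expected yield (g/day) at DIM ``t`` under the fitted curve."""
        return self.spec(self.params.to_numpy(), t)

    def traits(self, t_end: float | None = None):
        """The Wood-curve trait bundle for this fit (Wood family only)."""
        from .traits import compute_traits
        if t_end is None:
            t_end = float(self.model.dim.max()) + 7.0
        return compute_traits(self, t_end=t_end)

    def plot(self, ax=None, n_grid: int = 200):
        """Observed test days and the fitted curve on a DIM axis."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = self.model.dim
        grid = np.linspace(max(t.min() * 0.25, 1e-3), t.max() * 1.05, n_grid)
        ax.scatter(t, self.model.yield_g, s=18, color="k", label="test days")
        ax.plot(grid, self.predict(grid), color="C0", label=f"{self.spec.name} fit")
        ax.set_xlabel("days in milk")
        ax.set_ylabel("yield (g/day)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"{'Lactation curve fit':^58}",
            "=" * 58,
            f"Family:      {self.spec.name:<20} No. test days: {self.nobs}",
            f"Converged:   {str(self.converged):<20} Iterations:    {self.n_iter}",
            f"RSS:         {self.rss:<20.6g} R-squared:     {self.rsquared:.4f}",
            "-" * 58,
            f"{'param':>8} {'estimate':>14} {'std err':>12} {'unit':>12}",
        ]
        units = {"A": "g/day", "B": "-", "C": "1/day"}
        for name in self.spec.param_names:
            lines.append(
                f"{name:>8} {self.params[name]:>14.6g} "
                f"{self.bse[name]:>12.4g} {units.get(name, '-'):>12}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (f"<CurveFitResult {self.spec.name}({pars}) "
                f"r2={self.rsquared:.4f} converged={self.converged}>")
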