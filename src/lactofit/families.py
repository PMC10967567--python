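"""Parametric lactation-curve families.

Nine classical test-day models are registered by name. Each family maps a
parameter vector and days in milk (DIM, ``t``, continuous, 0-based on the
kidding day) to an expected daily yield in g/day. The workhorse is Wood's
gamma-type curve

    Y(t) = A * t**B * exp(-C * t)

where ``A`` (g/day) scales initial yield, ``B`` (dimensionless) governs the
rise to peak and ``C`` (1/day) the post-peak decline. The other families are
the standard alternatives used in small-ruminant test-day comparisons
(Yadav, Dhanoa, Wilmink, Cappio-Borlino, Cobby-Le Du, Morant-Gnanasakthy,
Goodall, Grossman).

Conventions
-----------
* ``0**0 == 1`` so that ``B == 0`` gives a finite constant-times-exponential
  curve.
* Families with a reciprocal term (``yadav``, ``morant``) are evaluated for
  ``t > 0`` only; the others accept ``t >= 0``.
* Every family supplies an analytic parameter Jacobian for the trust-region
  least-squares solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "ModelSpec",
    "MODELS",
    "DEFAULT_COMPARISON_MODELS",
    "get_model",
    "evaluate",
    "gradient",
]


def _pow(t: np.ndarray, b: float) -> np.ndarray:
    """t**b with the 0**0 = 1 convention (and 0**b = 0 for b > 0)."""
    t = np.asarray(t, dtype=float)
    if b == 0.0:
        return np.ones_like(t)
    with np.errstate(divide="ignore"):
        return np.power(t, b)


@dataclass(frozen=True)
class ModelSpec:
    """An evaluable, differentiable lactation-curve family.

    Attributes
    ----------
    name : registry identifier.
    param_names : ordered parameter labels (A, B, C[, D[, E]]).
    bounds : per-parameter (lower, upper) admissible intervals.
    requires_positive_t : family contains a 1/t (or log t at the origin)
        term and is only defined for t > 0.
    """

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    _eval: Callable[[np.ndarray, np.ndarray], np.ndarray]
    _jac: Callable[[np.ndarray, np.ndarray], np.ndarray]
    requires_positive_t: bool = False
    description: str = ""

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.param_names):
            raise ConfigurationError(
                f"{self.name}: {len(self.bounds)} bounds for "
                f"{len(self.param_names)} parameters"
            )
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ConfigurationError(f"{self.name}: empty bound interval ({lo}, {hi})")

    # -- parameter handling -------------------------------------------------
    def validate_params(self, params: Sequence[float]) -> np.ndarray:
        p = np.asarray(params, dtype=float)
        if p.shape != (self.n_params,):
            raise DomainError(
                f"{self.name} expects {self.n_params} parameters "
                f"({', '.join(self.param_names)}); got shape {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise DomainError(f"{self.name}: non-finite parameter in {p}")
        return p

    def clip_to_bounds(self, params: Sequence[float], margin: float = 1e-8) -> np.ndarray:
        """Project a parameter vector into the admissible box (used for starts)."""
        p = np.asarray(params, dtype=float)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        span = hi - lo
        return np.clip(p, lo + margin * np.minimum(span, 1.0), hi - margin * np.minimum(span, 1.0))

    def params_as_dict(self, params: Sequence[float]) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, params)))

    # -- evaluation ---------------------------------------------------------
    def _check_t(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError(f"{self.name}: days in milk must be >= 0, got min {t.min()}")
        if self.requires_positive_t and np.any(t == 0):
            raise DomainError(f"{self.name} is undefined at t = 0 (reciprocal term)")
        return t

    def __call__(self, params: Sequence[float], t) -> np.ndarray | float:
        """Expected yield (g/day) at DIM ``t``."""
        p = self.validate_params(params)
        t_arr = self._check_t(t)
        y = self._eval(p, np.atleast_1d(t_arr))
        return float(y[0]) if np.isscalar(t) or np.ndim(t) == 0 else y

    def jacobian(self, params: Sequence[float], t) -> np.ndarray:
        """Partial derivatives dY/dtheta, shape (len(t), n_params)."""
        p = self.validate_params(params)
        t_arr = np.atleast_1d(self._check_t(t))
        return self._jac(p, t_arr)


# ---------------------------------------------------------------------------
# family definitions
# ---------------------------------------------------------------------------

def _wood_eval(p, t):
    A, B, C = p
    return A * _pow(t, B) * np.exp(-C * t)


def _wood_jac(p, t):
    A, B, C = p
    core = _pow(t, B) * np.exp(-C * t)
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), 0.0)
    # d/dB of t^B at t=0 is 0 for B>0 (the curve is pinned at 0 there)
    return np.column_stack([core, A * core * logt, -A * core * t])


def _yadav_eval(p, t):
    A, B, C = p
    return A + B / t + C * t


def _yadav_jac(p, t):
    return np.column_stack([np.ones_like(t), 1.0 / t, t])


def _dhanoa_eval(p, t):
    A, B, C, D = p
    u = t - C
    return A * np.exp(-B * u) * np.exp(-2.0 * np.exp(-D * u))


def _dhanoa_jac(p, t):
    A, B, C, D = p
    u = t - C
    g = np.exp(-D * u)
    y = A * np.exp(-B * u) * np.exp(-2.0 * g)
    return np.column_stack([
        y / A,
        -u * y,
        y * (B - 2.0 * D * g),
        2.0 * u * g * y,
    ])


def _wilmink_eval(p, t):
    A, B, C, D = p
    return A + B * np.exp(-D * t) + C * t


def _wilmink_jac(p, t):
    A, B, C, D = p
    e = np.exp(-D * t)
    return np.column_stack([np.ones_like(t), e, t, -B * t * e])


def _cappio_eval_safe(p, t):
    # power reading of the Cappio-Borlino form: Y = A * t**(B * exp(-C t))
    A, B, C = p
    out = np.empty_like(t)
    pos = t > 0
    expo = B * np.exp(-C * t[pos])
    out[pos] = A * np.exp(expo * np.log(t[pos]))
    # at t=0: t^(B e^0) = 0^B -> 0 for B>0, 1 for B=0
    out[~pos] = A if B == 0 else 0.0
    return out


def _cappio_jac(p, t):
    A, B, C = p
    y = _cappio_eval_safe(p, t)
    logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), 0.0)
    e = np.exp(-C * t)
    return np.column_stack([
        y / A,
        y * e * logt,
        -y * B * t * e * logt,
    ])


def _cobby_eval(p, t):
    A, B, C = p
    return A * (1.0 - np.exp(-B * t)) * np.exp(-C * t)


def _cobby_jac(p, t):
    A, B, C = p
    eB = np.exp(-B * t)
    eC = np.exp(-C * t)
    return np.column_stack([
        (1.0 - eB) * eC,
        A * t * eB * eC,
        -A * (1.0 - eB) * t * eC,
    ])


def _morant_eval(p, t):
    A, B, C, D = p
    tau = (t - 150.0) / 100.0
    return A * np.exp(B * tau + C * tau**2 + D / t)


def _morant_jac(p, t):
    A, B, C, D = p
    tau = (t - 150.0) / 100.0
    y = A * np.exp(B * tau + C * tau**2 + D / t)
    return np.column_stack([y / A, y * tau, y * tau**2, y / t])


def _goodall_eval(p, t):
    A, B, C, D = p
    return A * _pow(t, B) * np.exp(-C * t) + D


def _goodall_jac(p, t):
    A, B, C, D = p
    core = _pow(t, B) * np.exp(-C * t)
    logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), 0.0)
    return np.column_stack([core, A * core * logt, -A * core * t, np.ones_like(t)])


def _grossman_eval(p, t):
    A, B, C, D, E = p
    return A * _pow(t, B) * np.exp(-C * t) * (1.0 + D * np.sin(t) + E * np.cos(t))


def _grossman_jac(p, t):
    A, B, C, D, E = p
    core = _pow(t, B) * np.exp(-C * t)
    trig = 1.0 + D * np.sin(t) + E * np.cos(t)
    logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), 0.0)
    return np.column_stack([
        core * trig,
        A * core * trig * logt,
        -A * core * trig * t,
        A * core * np.sin(t),
        A * core * np.cos(t),
    ])


_A_BOUND = (1e-6, 1e5)  # g/day

MODELS: dict[str, ModelSpec] = {}


def _register(spec: ModelSpec) -> ModelSpec:
    MODELS[spec.name] = spec
    return spec


WOOD = _register(ModelSpec(
    name="wood",
    param_names=("A", "B", "C"),
    bounds=(_A_BOUND, (0.0, 5.0), (0.0, 1.0)),
    _eval=_wood_eval,
    _jac=_wood_jac,
    description="Gamma-type curve A*t^B*exp(-C t)",
))

_register(ModelSpec(
    name="yadav",
    param_names=("A", "B", "C"),
    bounds=(_A_BOUND, (-1e4, 1e4), (-1e2, 1e2)),
    _eval=_yadav_eval,
    _jac=_yadav_jac,
    requires_positive_t=True,
    description="Hyperbolic A + B/t + C*t",
))

_register(ModelSpec(
    name="dhanoa",
    param_names=("A", "B", "C", "D"),
    bounds=(_A_BOUND, (0.0, 1.0), (0.0, 200.0), (0.0, 1.0)),
    _eval=_dhanoa_eval,
    _jac=_dhanoa_jac,
    description="Gompertz-type A*exp(-B(t-C))*exp(-2 exp(-D(t-C)))",
))

_register(ModelSpec(
    name="wilmink",
    param_names=("A", "B", "C", "D"),
    bounds=((0.0, 1e5), (-1e5, 1e5), (-1e3, 1e3), (1e-4, 1.0)),
    _eval=_wilmink_eval,
    _jac=_wilmink_jac,
    description="A + B*exp(-D t) + C*t with estimated decay rate D",
))

_register(ModelSpec(
    name="cappio_borlino",
    param_names=("A", "B", "C"),
    bounds=(_A_BOUND, (0.0, 5.0), (0.0, 1.0)),
    _eval=_cappio_eval_safe,
    _jac=_cappio_jac,
    description="A*t^(B*exp(-C t)) (time-decaying power)",
))

_register(ModelSpec(
    name="cobby_le_du",
    param_names=("A", "B", "C"),
    bounds=(_A_BOUND, (1e-6, 1.0), (0.0, 1.0)),
    _eval=_cobby_eval,
    _jac=_cobby_jac,
    description="A*(1-exp(-B t))*exp(-C t)",
))

_register(ModelSpec(
    name="morant",
    param_names=("A", "B", "C", "D"),
    bounds=(_A_BOUND, (-5.0, 5.0), (-5.0, 5.0), (-50.0, 50.0)),
    _eval=_morant_eval,
    _jac=_morant_jac,
    requires_positive_t=True,
    description="Morant-Gnanasakthy A*exp(B*tau + C*tau^2 + D/t), tau=(t-150)/100",
))

_register(ModelSpec(
    name="goodall",
    param_names=("A", "B", "C", "D"),
    bounds=(_A_BOUND, (0.0, 5.0), (0.0, 1.0), (-1e4, 1e4)),
    _eval=_goodall_eval,
    _jac=_goodall_jac,
    description="Wood plus additive offset: A*t^B*exp(-C t) + D",
))

_register(ModelSpec(
    name="grossman",
    param_names=("A", "B", "C", "D", "E"),
    bounds=(_A_BOUND, (0.0, 5.0), (0.0, 1.0), (-1.0, 1.0), (-1.0, 1.0)),
    _eval=_grossman_eval,
    _jac=_grossman_jac,
    description="Wood modulated by a daily harmonic: *(1 + D sin t + E cos t)",
))

#: families entering multi-model comparisons by default. cobby_le_du is kept
#: in the registry but excluded here: its three parameters are near-aliased
#: on sparse test-day data (B and C trade off along a ridge) and the
#: comparison literature for this population reports no fit for it.
DEFAULT_COMPARISON_MODELS: tuple[str, ...] = tuple(
    n for n in MODELS if n != "cobby_le_du"
)


def get_model(name: str) -> ModelSpec:
    """Look up a registered family by name."""
    try:
        return MODELS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {', '.join(sorted(MODELS))}"
        ) from None


def evaluate(spec: ModelSpec | str, params: Sequence[float], t):
    """Evaluate a family (by spec or name) at DIM ``t``. Returns g/day."""
    if isinstance(spec, str):
        spec = get_model(spec)
    return spec(params, t)


def gradient(spec: ModelSpec | str, params: Sequence[float], t) -> np.ndarray:
    """Per-parameter partial derivatives of the yield at DIM ``t``."""
    if isinstance(spec, str):
        spec = get_model(spec)
    return spec.jacobian(params, t)
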