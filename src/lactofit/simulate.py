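"""Synthetic pastoral test-day datasets.

Emulates the structure of once-daily goat milk recording in an extensive
pastoral system: per-goat Wood curves with between-goat variation, additive
non-genetic factor effects (herd, kidding year, kidding month, litter size,
dam age), a fortnightly recording calendar, truncated-normal lactation
lengths and Gaussian measurement noise truncated at zero.

Defaults encode the study conditions this package targets: population mean
curve (A, B, C) = (730 g/day, 0.26, 0.09 /day) with SDs (250, 0.04, 0.01),
14-day recording from DIM 14, lactation length ~ N(146, 30.71) clipped to
[62, 189] days, measurement noise SD 50 g/day, a roughly 66/34 single/twin
split and herd/year/month frequencies mirroring the unbalanced field
design. Factor effects are additive on A (and on C for kidding month),
ordered like the field tables and frequency-centred so they do not shift
the population means.

A and C are drawn log-normal (they must stay positive), B truncated normal
on its admissible interval; all draws are parameterised by their arithmetic
mean and SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import dataio
from .exceptions import ConfigurationError
from .families import get_model

__all__ = [
    "FactorEffects",
    "SimulationConfig",
    "SyntheticDataset",
    "sample_population",
    "generate_test_days",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

_WOOD = get_model("wood")

#: default covariate level frequencies (unbalanced, field-like)
DEFAULT_FREQUENCIES: dict[str, dict] = {
    "herd": {1: 96, 2: 108, 3: 974, 4: 148, 5: 66},
    "kidding_year": {1998: 434, 1999: 625, 2000: 333},
    "kidding_month": {"Jan": 32, "Feb": 24, "Nov": 5, "Dec": 157},
    "litter_size": {"single": 66, "twin": 34},
    "dam_age": {1: 4, 2: 28, 3: 60, 4: 22, 5: 31, 6: 27, 7: 30, 8: 12},
}


def _table5_like_a_effects() -> dict[str, dict]:
    """Additive shifts on A (g/day) ordered like the field means tables."""
    return {
        "herd": {1: 60.0, 2: -40.0, 3: -80.0, 4: -90.0, 5: 150.0},
        "kidding_year": {1998: 30.0, 1999: -90.0, 2000: 60.0},
        "kidding_month": {"Jan": 20.0, "Feb": -80.0, "Nov": 120.0, "Dec": -10.0},
        "litter_size": {"single": -10.0, "twin": 10.0},
        "dam_age": {1: 10.0, 2: -60.0, 3: 90.0, 4: 40.0, 5: 20.0,
                    6: 0.0, 7: -30.0, 8: -60.0},
    }


def _table5_like_c_effects() -> dict[str, dict]:
    """Additive shifts on C (1/day) for the kidding-month seasonality."""
    return {
        "kidding_month": {"Jan": -0.01, "Feb": -0.015, "Nov": 0.01, "Dec": 0.0},
    }


@dataclass
class FactorEffects:
    """Additive factor effects on the per-goat curve parameters.

    ``on_a`` and ``on_c`` map factor -> level -> shift. Effects are centred
    at sampling time against the configured level frequencies, so the
    population means of A and C are invariant to the effect tables.
    """

    on_a: dict[str, dict] = field(default_factory=dict)
    on_c: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def none(cls) -> "FactorEffects":
        return cls()

    @classmethod
    def field_like(cls) -> "FactorEffects":
        """Effects at field-table-like magnitudes and orderings."""
        return cls(on_a=_table5_like_a_effects(), on_c=_table5_like_c_effects())


@dataclass
class SimulationConfig:
    """Everything the generator needs; a fixed seed gives byte-identical output."""

    n_lactations: int = 400
    a_mean: float = 730.0      # g/day
    a_sd: float = 250.0
    b_mean: float = 0.26
    b_sd: float = 0.04
    c_mean: float = 0.09       # 1/day
    c_sd: float = 0.01
    recording_interval: float = 14.0   # days
    first_test_day: float = 14.0       # days
    ll_mean: float = 146.0     # days
    ll_sd: float = 30.71
    ll_min: float = 62.0
    ll_max: float = 189.0
    noise_sd: float = 50.0     # g/day
    multiplier: float = 1.0    # once-daily -> daily convention (2.0 doubles)
    effects: FactorEffects = field(default_factory=FactorEffects.field_like)
    frequencies: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_FREQUENCIES.items()})
    seed: int = 0

    def validate(self) -> None:
        if self.n_lactations < 0:
            raise ConfigurationError("n_lactations must be >= 0")
        if self.recording_interval < 1:
            raise ConfigurationError("recording interval must be >= 1 day")
        if not self.ll_min < self.ll_max:
            raise ConfigurationError("LL bounds must satisfy min < max")
        for name, mean, sd in (("A", self.a_mean, self.a_sd),
                               ("C", self.c_mean, self.c_sd)):
            if mean <= 0:
                raise ConfigurationError(f"{name} mean must be > 0")
            if sd < 0 or (sd > 0 and sd / mean > 2.0):
                raise ConfigurationError(
                    f"{name}: CV {sd / mean:.2f} too large for a positive "
                    "log-normal parameter")
        lo, hi = 0.0, 5.0
        if not lo <= self.b_mean <= hi or self.b_sd < 0:
            raise ConfigurationError("B mean outside admissible [0, 5] or SD < 0")
        for f, freq in self.frequencies.items():
            if not freq or any(w < 0 for w in freq.values()) or sum(freq.values()) <= 0:
                raise ConfigurationError(f"invalid frequencies for {f}")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "effects" in d and not isinstance(d["effects"], FactorEffects):
            eff = d["effects"] or {}
            d["effects"] = FactorEffects(on_a=eff.get("on_a", {}),
                                         on_c=eff.get("on_c", {}))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    """Generated tables plus full provenance (the generating config and the
    latent per-lactation true parameters)."""

    records: pd.DataFrame
    lactations: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with given arithmetic mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _sample_levels(rng: np.random.Generator, freq: dict, n: int) -> np.ndarray:
    levels = list(freq.keys())
    w = np.array([freq[l] for l in levels], dtype=float)
    w /= w.sum()
    idx = rng.choice(len(levels), size=n, p=w)
    return np.asarray(levels)[idx]


def _centred_effect(effect: dict, freq: dict) -> dict:
    """Shift an effect table so its frequency-weighted mean is zero."""
    levels = list(freq.keys())
    w = np.array([freq[l] for l in levels], dtype=float)
    w /= w.sum()
    e = np.array([effect.get(l, 0.0) for l in levels], dtype=float)
    e -= float(w @ e)
    return dict(zip(levels, e))


def sample_population(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-lactation true curve parameters and covariates.

    Returns one row per lactation: lactation_id, goat_id, the five factor
    levels, the latent true (A, B, C) after centred factor effects, and the
    drawn lactation length.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_lactations

    cov = {f: _sample_levels(rng, config.frequencies[f], n)
           for f in dataio.FACTOR_LEVELS}

    def _draw_lognormal(mean: float, sd: float) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        mu, sg = _lognormal_params(mean, sd)
        return np.exp(rng.normal(mu, sg, n))

    A = _draw_lognormal(config.a_mean, config.a_sd)
    C = _draw_lognormal(config.c_mean, config.c_sd)
    b_lo, b_hi = 0.0, 5.0
    if config.b_sd == 0:
        B = np.full(n, config.b_mean)
    else:
        a_, b_ = (b_lo - config.b_mean) / config.b_sd, (b_hi - config.b_mean) / config.b_sd
        from scipy.stats import truncnorm
        B = truncnorm.rvs(a_, b_, loc=config.b_mean, scale=config.b_sd,
                          size=n, random_state=rng)

    for factor, eff in config.effects.on_a.items():
        cen = _centred_effect(eff, config.frequencies[factor])
        A = A + np.array([cen[l] for l in cov[factor]])
    for factor, eff in config.effects.on_c.items():
        cen = _centred_effect(eff, config.frequencies[factor])
        C = C + np.array([cen[l] for l in cov[factor]])

    lo = np.array([b[0] for b in _WOOD.bounds])
    hi = np.array([b[1] for b in _WOOD.bounds])
    A = np.clip(A, 1.0, hi[0])
    B = np.clip(B, lo[1], hi[1])
    C = np.clip(C, 1e-4, hi[2])

    if config.ll_sd == 0:
        ll = np.full(n, config.ll_mean)
    else:
        from scipy.stats import truncnorm
        a_, b_ = ((config.ll_min - config.ll_mean) / config.ll_sd,
                  (config.ll_max - config.ll_mean) / config.ll_sd)
        ll = truncnorm.rvs(a_, b_, loc=config.ll_mean, scale=config.ll_sd,
                           size=n, random_state=rng)

    width = max(4, len(str(max(n, 1))))
    ids = [f"L{str(i + 1).zfill(width)}" for i in range(n)]
    goats = [f"G{str(i + 1).zfill(width)}" for i in range(n)]
    return pd.DataFrame({
        "lactation_id": ids, "goat_id": goats,
        **{f: cov[f] for f in dataio.FACTOR_LEVELS},
        "true_A": A, "true_B": B, "true_C": C, "true_LL": ll,
    })


def generate_test_days(population: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> SyntheticDataset:
    """Emit the fortnightly test-day records for a sampled population.

    Per lactation, records fall at ``first_test_day, +interval, ... <= LL``;
    each yield is ``multiplier * (Wood(A, B, C; t) + noise)`` truncated at 0.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    rec_rows = []
    for row in population.itertuples():
        t = np.arange(config.first_test_day, row.true_LL + 1e-9,
                      config.recording_interval)
        if t.size == 0:
            continue
        mu = _WOOD._eval(np.array([row.true_A, row.true_B, row.true_C]), t)
        noise = rng.normal(0.0, config.noise_sd, t.size) if config.noise_sd > 0 \
            else np.zeros(t.size)
        y = np.maximum(config.multiplier * (mu + noise), 0.0)
        for ti, yi in zip(t, y):
            rec_rows.append({"goat_id": row.goat_id,
                             "lactation_id": row.lactation_id,
                             "dim": float(ti), "yield_g": float(yi)})
    records = pd.DataFrame(rec_rows, columns=dataio.RECORD_COLUMNS)
    lactations = population[dataio.LACTATION_COLUMNS].copy()
    return SyntheticDataset(records=records, lactations=lactations,
                            truth=population.copy(), config=config)


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Sample a population and its test-day records in one call."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(), "seed": seed})
    rng = np.random.default_rng(config.seed)
    pop = sample_population(config, rng)
    return generate_test_days(pop, config, rng)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write records.csv, lactations.csv, truth.csv and the provenance
    config (sim_config.yaml) under ``outdir``."""
    outdir = Path(outdir)
    paths = dataio.write_frames(ds.records, ds.lactations, outdir)
    paths["truth"] = outdir / "truth.csv"
    ds.truth.to_csv(paths["truth"], index=False)
    paths["config"] = outdir / "sim_config.yaml"
    ds.config.to_yaml(paths["config"])
    return paths


def read_dataset(outdir: str | Path) -> SyntheticDataset:
    """Read back a written dataset (inverse of :func:`write_dataset`)."""
    outdir = Path(outdir)
    return SyntheticDataset(
        records=pd.read_csv(outdir / "records.csv"),
        lactations=pd.read_csv(outdir / "lactations.csv"),
        truth=pd.read_csv(outdir / "truth.csv"),
        config=SimulationConfig.from_yaml(outdir / "sim_config.yaml"),
    )
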