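"""End-to-end pipeline: simulate/read -> compare -> fit -> traits -> effects.

The pipeline is a pure function of (input files, config, seed): re-running
with the same config reproduces the same output tree apart from timestamps
in the log. Each stage writes its CSV outputs under the configured output
directory and appends to a stage-stamped text log.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__, dataio
from .effects import FACTORS, anova_fixed_effects, correlation_matrix, duncan_mrt
from .exceptions import LactofitError
from .fitting import compare_models, fit_lactation
from .model import SolverSettings
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .traits import TRAIT_COLUMNS, summarize_traits, traits_table

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "compare", "fit", "traits", "effects")


@dataclass
class PipelineConfig:
    """Declarative pipeline run description (YAML-mappable)."""

    outdir: str = "lactofit_out"
    stages: Sequence[str] = ALL_STAGES
    records: str | None = None      # input CSVs; ignored when simulating
    lactations: str | None = None
    simulate: SimulationConfig | None = field(default_factory=SimulationConfig)
    model: str = "wood"
    compare_models: Sequence[str] | None = None
    seed: int = 0
    duncan_alpha: float = 0.05
    anova_type: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        return cls(**d)


def _stage_logger(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"lactofit.pipeline.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s [%(levelname)s] %(message)s"))
    logger.addHandler(fh)
    logger.propagate = False
    return logger


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Any stage failure is re-raised with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _stage_logger(outdir)
    log.info("lactofit %s; seed=%d; stages=%s", __version__, config.seed,
             ",".join(config.stages))

    stage = "setup"
    try:
        settings = SolverSettings(seed=config.seed)

        if "simulate" in config.stages:
            stage = "simulate"
            t0 = time.perf_counter()
            sim_cfg = config.simulate or SimulationConfig()
            ds = simulate_dataset(sim_cfg, seed=config.seed)
            write_dataset(ds, outdir)
            lactations = dataio.frames_to_records(ds.records, ds.lactations)
            log.info("simulate: %d lactations, %d records (%.2fs)",
                     len(lactations), len(ds.records), time.perf_counter() - t0)
        else:
            stage = "read"
            if config.records is None:
                raise LactofitError("no input: set records/lactations or the simulate stage")
            lactations, rejects = dataio.read_records(config.records, config.lactations)
            rejects.to_csv(outdir / "rejections.csv", index=False)
            log.info("read: %d lactations, %d rejected rows",
                     len(lactations), len(rejects))

        if "compare" in config.stages:
            stage = "compare"
            t0 = time.perf_counter()
            comp = compare_models(lactations, config.compare_models, settings)
            comp.table.to_csv(outdir / "table2.csv", index=False)
            log.info("compare: best=%s (%.2fs)", comp.best_model,
                     time.perf_counter() - t0)

        fits = None
        if "fit" in config.stages or "traits" in config.stages or "effects" in config.stages:
            stage = "fit"
            t0 = time.perf_counter()
            from .exceptions import DegenerateLactation, InsufficientData
            spec = config.model
            fits, rows = [], []
            for lact in lactations:
                base = {"lactation_id": lact.lactation_id,
                        "goat_id": lact.goat_id, "model": spec}
                try:
                    res = fit_lactation(lact, spec, settings)
                except (InsufficientData, DegenerateLactation) as e:
                    rows.append({**base, "error": type(e).__name__})
                    continue
                rows.append({**base, **res.params.to_dict(), "rss": res.rss,
                             "r2": res.rsquared, "n_iter": res.n_iter,
                             "converged": res.converged, "n_obs": res.nobs,
                             "error": ""})
                if res.converged:
                    fits.append((lact, res))
            fit_rows = pd.DataFrame(rows)
            fit_rows.to_csv(outdir / "fits.csv", index=False)
            log.info("fit: %d/%d converged (%.2fs)", len(fits),
                     len(lactations), time.perf_counter() - t0)

        traits = None
        if "traits" in config.stages or "effects" in config.stages:
            stage = "traits"
            t0 = time.perf_counter()
            traits = traits_table(fits)
            traits.to_csv(outdir / "traits.csv", index=False)
            summarize_traits(traits).to_csv(outdir / "traits_summary.csv", index=False)
            log.info("traits: %d rows (%.2fs)", len(traits),
                     time.perf_counter() - t0)

        if "effects" in config.stages:
            stage = "effects"
            t0 = time.perf_counter()
            anova_rows, duncan_rows = [], []
            corr_written = False
            usable = [f for f in FACTORS
                      if f in traits.columns and traits[f].nunique() >= 2]
            for trait in [c for c in TRAIT_COLUMNS if c in traits.columns]:
                if usable:
                    res = anova_fixed_effects(traits, trait, usable,
                                              typ=config.anova_type)
                    tbl = res.table.copy()
                    tbl.insert(0, "trait", trait)
                    tbl["model_r2"] = res.rsquared
                    anova_rows.append(tbl)
                    for f in usable:
                        if f in res.inestimable:
                            continue
                        grp = duncan_mrt(
                            traits[trait], traits[f], res.resid_ms,
                            res.resid_df, alpha=config.duncan_alpha,
                            factor=f, trait=trait)
                        d = grp.table.copy()
                        d.insert(0, "trait", trait)
                        d.insert(0, "factor", f)
                        duncan_rows.append(d)
            if anova_rows:
                pd.concat(anova_rows).to_csv(outdir / "anova.csv", index=False)
                pd.concat(duncan_rows).to_csv(outdir / "duncan.csv", index=False)
            r, p, flags = correlation_matrix(traits)
            r.round(6).to_csv(outdir / "correlations.csv")
            flags.to_csv(outdir / "correlation_flags.csv")
            corr_written = True
            log.info("effects: anova=%s, correlations=%s (%.2fs)",
                     bool(anova_rows), corr_written, time.perf_counter() - t0)
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        raise LactofitError(f"stage {stage!r} failed: {err}") from err
    finally:
        for h in log.handlers:
            h.close()

    return outdir
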