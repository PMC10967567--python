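"""Test-day record containers, CSV schemas and validation.

Two flat CSV tables carry a dataset:

``records.csv``    — goat_id, lactation_id, dim, yield_g (one row per test day)
``lactations.csv`` — lactation_id, goat_id, herd, kidding_year, kidding_month,
                     litter_size, dam_age (one row per goat-lactation)

DIM (days in milk) is the integer day offset from kidding, 0-based on the
kidding day itself; yields are once-daily measures in g/day. Malformed rows
are never silently dropped: :func:`read_records` collects them into a
rejection report with reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import LactofitError

__all__ = [
    "RECORD_COLUMNS",
    "LACTATION_COLUMNS",
    "FACTOR_LEVELS",
    "LactationRecord",
    "read_records",
    "records_to_frames",
    "frames_to_records",
    "write_frames",
]

RECORD_COLUMNS = ["goat_id", "lactation_id", "dim", "yield_g"]
LACTATION_COLUMNS = [
    "lactation_id", "goat_id", "herd", "kidding_year", "kidding_month",
    "litter_size", "dam_age",
]

#: admissible covariate levels for this pastoral population; other
#: populations can widen these via the ``factor_levels`` argument of
#: :func:`read_records`.
FACTOR_LEVELS: dict[str, list] = {
    "herd": [1, 2, 3, 4, 5],
    "kidding_year": [1998, 1999, 2000],
    "kidding_month": ["Jan", "Feb", "Nov", "Dec"],
    "litter_size": ["single", "twin"],
    "dam_age": [1, 2, 3, 4, 5, 6, 7, 8],
}

_MONTH_ALIASES = {
    "jan": "Jan", "january": "Jan", "1": "Jan",
    "feb": "Feb", "february": "Feb", "2": "Feb",
    "nov": "Nov", "november": "Nov", "11": "Nov",
    "dec": "Dec", "december": "Dec", "12": "Dec",
}


class SchemaError(LactofitError):
    """A mandatory column is missing from an input table."""


class ValidationError(LactofitError):
    """Structurally invalid data (e.g. duplicate test days within a lactation)."""


@dataclass
class LactationRecord:
    """One goat-lactation: covariates plus its DIM-ordered test days."""

    lactation_id: str
    goat_id: str
    herd: int
    kidding_year: int
    kidding_month: str
    litter_size: str
    dam_age: int
    dim: np.ndarray = field(default_factory=lambda: np.empty(0))
    yield_g: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.dim = np.asarray(self.dim, dtype=float)
        self.yield_g = np.asarray(self.yield_g, dtype=float)
        if self.dim.shape != self.yield_g.shape:
            raise ValidationError(
                f"lactation {self.lactation_id}: {self.dim.size} DIM values "
                f"vs {self.yield_g.size} yields"
            )
        order = np.argsort(self.dim)
        self.dim = self.dim[order]
        self.yield_g = self.yield_g[order]

    @property
    def n_records(self) -> int:
        return int(self.dim.size)

    @property
    def covariates(self) -> dict:
        return {
            "herd": self.herd,
            "kidding_year": self.kidding_year,
            "kidding_month": self.kidding_month,
            "litter_size": self.litter_size,
            "dam_age": self.dam_age,
        }


def normalize_month(value) -> str:
    """Normalize month labels to English three-letter form."""
    key = str(value).strip().lower()
    return _MONTH_ALIASES.get(key, str(value).strip()[:3].capitalize())


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def read_records(
    records_path: str | Path,
    lactations_path: str | Path | None = None,
    factor_levels: dict | None = None,
) -> tuple[list[LactationRecord], pd.DataFrame]:
    """Read, validate and join test-day records into lactations.

    Parameters
    ----------
    records_path : CSV with columns ``goat_id, lactation_id, dim, yield_g``.
    lactations_path : optional covariate CSV; when absent, covariates are
        filled with placeholder level 0 / "NA" values (fitting does not need
        them, the effects stage does).
    factor_levels : admissible covariate levels; defaults to
        :data:`FACTOR_LEVELS`.

    Returns
    -------
    (lactations, rejections) : the validated lactations, DIM-sorted, and a
    rejection report DataFrame with columns ``table, row, reason``.
    """
    levels = factor_levels or FACTOR_LEVELS
    rec = pd.read_csv(records_path)
    _check_columns(rec, RECORD_COLUMNS, "records")

    rejections: list[dict] = []

    def reject(table: str, idx, reason: str) -> None:
        rejections.append({"table": table, "row": int(idx), "reason": reason})

    rec = rec.copy()
    rec["dim"] = pd.to_numeric(rec["dim"], errors="coerce")
    rec["yield_g"] = pd.to_numeric(rec["yield_g"], errors="coerce")
    bad = rec["dim"].isna() | rec["yield_g"].isna()
    for i in rec.index[bad]:
        reject("records", i, "non-numeric dim or yield")
    rec = rec[~bad]
    neg_t = rec["dim"] <= 0
    for i in rec.index[neg_t]:
        reject("records", i, "dim must be > 0")
    rec = rec[~neg_t]
    neg_y = rec["yield_g"] < 0
    for i in rec.index[neg_y]:
        reject("records", i, "negative yield")
    rec = rec[~neg_y]

    dup = rec.duplicated(subset=["lactation_id", "dim"], keep=False)
    if dup.any():
        offenders = rec.loc[dup, ["lactation_id", "dim"]].drop_duplicates()
        raise ValidationError(
            "duplicate (lactation_id, dim) pairs: "
            + "; ".join(f"{r.lactation_id}@{r.dim:g}" for r in offenders.itertuples())
        )

    if lactations_path is not None:
        lac = pd.read_csv(lactations_path)
        _check_columns(lac, LACTATION_COLUMNS, "lactations")
        lac = lac.copy()
        lac["kidding_month"] = lac["kidding_month"].map(normalize_month)
        for col in ("herd", "kidding_year", "dam_age"):
            lac[col] = pd.to_numeric(lac[col], errors="coerce")
        bad_level = pd.Series(False, index=lac.index)
        for col in ("herd", "kidding_year", "kidding_month", "litter_size", "dam_age"):
            ok = lac[col].isin(levels[col])
            for i in lac.index[~ok]:
                reject("lactations", i, f"inadmissible {col}: {lac.at[i, col]!r}")
            bad_level |= ~ok
        lac = lac[~bad_level]
        lac = lac.set_index("lactation_id")
    else:
        lac = None

    lactations: list[LactationRecord] = []
    for lact_id, grp in rec.groupby("lactation_id", sort=True):
        goat_id = str(grp["goat_id"].iloc[0])
        if lac is not None:
            if lact_id not in lac.index:
                for i in grp.index:
                    reject("records", i, f"no covariate row for lactation {lact_id}")
                continue
            row = lac.loc[lact_id]
            cov = dict(
                herd=int(row["herd"]), kidding_year=int(row["kidding_year"]),
                kidding_month=str(row["kidding_month"]),
                litter_size=str(row["litter_size"]), dam_age=int(row["dam_age"]),
            )
        else:
            cov = dict(herd=0, kidding_year=0, kidding_month="NA",
                       litter_size="NA", dam_age=0)
        lactations.append(LactationRecord(
            lactation_id=str(lact_id), goat_id=goat_id,
            dim=grp["dim"].to_numpy(), yield_g=grp["yield_g"].to_numpy(), **cov,
        ))

    report = pd.DataFrame(rejections, columns=["table", "row", "reason"])
    return lactations, report


def records_to_frames(lactations: Iterable[LactationRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten lactations into the two canonical tables."""
    rec_rows, lac_rows = [], []
    for l in lactations:
        lac_rows.append({
            "lactation_id": l.lactation_id, "goat_id": l.goat_id, **l.covariates,
        })
        for t, y in zip(l.dim, l.yield_g):
            rec_rows.append({
                "goat_id": l.goat_id, "lactation_id": l.lactation_id,
                "dim": t, "yield_g": y,
            })
    return (
        pd.DataFrame(rec_rows, columns=RECORD_COLUMNS),
        pd.DataFrame(lac_rows, columns=LACTATION_COLUMNS),
    )


def frames_to_records(records: pd.DataFrame, lactations: pd.DataFrame) -> list[LactationRecord]:
    """Inverse of :func:`records_to_frames` (in-memory, no validation report)."""
    lac = lactations.set_index("lactation_id")
    out = []
    for lact_id, grp in records.groupby("lactation_id", sort=True):
        row = lac.loc[lact_id]
        out.append(LactationRecord(
            lactation_id=str(lact_id), goat_id=str(row["goat_id"]),
            herd=int(row["herd"]), kidding_year=int(row["kidding_year"]),
            kidding_month=str(row["kidding_month"]),
            litter_size=str(row["litter_size"]), dam_age=int(row["dam_age"]),
            dim=grp["dim"].to_numpy(), yield_g=grp["yield_g"].to_numpy(),
        ))
    return out


def write_frames(records: pd.DataFrame, lactations: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write the canonical tables under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "lactations": outdir / "lactations.csv",
    }
    records.to_csv(paths["records"], index=False)
    lactations.to_csv(paths["lactations"], index=False)
    return paths
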