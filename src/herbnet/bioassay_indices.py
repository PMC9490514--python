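"""Fasting-sample insulin-resistance indices and qPCR relative expression.

Index definitions (glucose mg/dl, insulin uU/ml, triglycerides mg/dl):

* HOMA-IR = glucose x insulin / 405  — insulin resistance
* TyG     = ln(triglycerides x glucose / 2)  — hepatic insulin
  resistance / fatty-liver marker (natural log, per the standard
  definition)
* QUICKI  = 1 / (log10 insulin + log10 glucose)  — insulin sensitivity
  (base-10 logs, per the standard definition)
* HOMA-B  = 20 x insulin / (glucose - 63)  — beta-cell secretory
  capacity, defined only for glucose > 63 mg/dl

Relative gene expression uses the 2^-ddCt method: per sample
dCt = Ct(target) - Ct(reference); ddCt = dCt - mean dCt of the
calibrator group; fold change = 2^-ddCt.

Group statistics follow the per-animal-then-average convention: indices
are computed for each animal and then summarized as mean +/- SEM
(sd/sqrt(n), sd with n-1 denominator).  Averaging first and then
applying the index formula gives slightly different numbers; the
per-animal convention is frozen here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnimalRecord",
    "IndexRow",
    "UndefinedIndexError",
    "homa_ir",
    "homa_b",
    "tyg",
    "quicki",
    "compute_indices",
    "compute_index_table",
    "fold_change_ddct",
    "fold_change_table",
    "group_summary",
    "anova_oneway",
]


class UndefinedIndexError(ValueError):
    """An index is undefined for the supplied analyte values."""


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's fasting biochemistry (Ct values optional)."""

    animal_id: str
    group: str
    fasting_glucose: float  # mg/dl
    fasting_insulin: float  # uU/ml
    triglycerides: float | None = None  # mg/dl
    ct_target: float | None = None
    ct_reference: float | None = None

    def __post_init__(self) -> None:
        for name in ("fasting_glucose", "fasting_insulin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.triglycerides is not None and self.triglycerides <= 0:
            raise ValueError("triglycerides must be > 0")


@dataclass(frozen=True)
class IndexRow:
    animal_id: str
    group: str
    homa_ir: float
    quicki: float | None
    tyg: float | None
    homa_b: float | None
    flags: tuple[str, ...] = ()


def homa_ir(glucose: float, insulin: float) -> float:
    return glucose * insulin / 405.0


def tyg(triglycerides: float, glucose: float) -> float:
    return math.log(triglycerides * glucose / 2.0)


def quicki(glucose: float, insulin: float) -> float:
    denom = math.log10(insulin) + math.log10(glucose)
    if denom == 0:
        raise UndefinedIndexError("QUICKI undefined: log10(insulin) + log10(glucose) = 0")
    return 1.0 / denom


def homa_b(glucose: float, insulin: float) -> float:
    if glucose <= 63:
        raise UndefinedIndexError(
            f"HOMA-B undefined for glucose <= 63 mg/dl (got {glucose})"
        )
    return 20.0 * insulin / (glucose - 63.0)


def compute_indices(r: AnimalRecord) -> IndexRow:
    """All four indices for one animal; undefined ones are flagged, not faked."""
    flags: list[str] = []
    try:
        q = quicki(r.fasting_glucose, r.fasting_insulin)
    except UndefinedIndexError as exc:
        q = None
        flags.append(str(exc))
    if r.triglycerides is None:
        t = None
        flags.append("TyG not computed: triglycerides missing")
    else:
        t = tyg(r.triglycerides, r.fasting_glucose)
    try:
        b = homa_b(r.fasting_glucose, r.fasting_insulin)
    except UndefinedIndexError as exc:
        b = None
        flags.append(str(exc))
    return IndexRow(
        animal_id=r.animal_id,
        group=r.group,
        homa_ir=homa_ir(r.fasting_glucose, r.fasting_insulin),
        quicki=q,
        tyg=t,
        homa_b=b,
        flags=tuple(flags),
    )


def compute_index_table(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Per-animal index table (one row per animal, input order)."""
    rows = [compute_indices(r) for r in records]
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in rows],
            "group": [r.group for r in rows],
            "homa_ir": [r.homa_ir for r in rows],
            "quicki": [r.quicki for r in rows],
            "tyg": [r.tyg for r in rows],
            "homa_b": [r.homa_b for r in rows],
        }
    )


def fold_change_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    mean_ct_target_calibrator: float,
    mean_ct_ref_calibrator: float,
) -> float:
    """2^-ddCt fold change of one sample against the calibrator group."""
    for v in (ct_target_sample, ct_ref_sample, mean_ct_target_calibrator, mean_ct_ref_calibrator):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    dct_sample = ct_target_sample - ct_ref_sample
    dct_cal = mean_ct_target_calibrator - mean_ct_ref_calibrator
    return 2.0 ** (-(dct_sample - dct_cal))


def fold_change_table(
    df: pd.DataFrame,
    calibrator_group: str,
    group_col: str = "group",
    ct_target_col: str = "ct_target",
    ct_ref_col: str = "ct_reference",
) -> pd.DataFrame:
    """Per-sample fold changes normalized to the calibrator group's mean dCt."""
    cal = df[df[group_col] == calibrator_group]
    if cal.empty:
        raise ValueError(f"no rows for calibrator group {calibrator_group!r}")
    mean_t = float(cal[ct_target_col].mean())
    mean_r = float(cal[ct_ref_col].mean())
    out = df.copy()
    out["fold_change"] = [
        fold_change_ddct(t, r, mean_t, mean_r)
        for t, r in zip(df[ct_target_col], df[ct_ref_col])
    ]
    return out


def group_summary(
    df: pd.DataFrame,
    group_col: str = "group",
    value_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean +/- SEM per group per measure (SEM = sd / sqrt(n), sd ddof=1).

    A group of size 1 gets SEM NaN and a ``sem_undefined`` flag.
    """
    if value_cols is None:
        value_cols = [c for c in df.columns if c != group_col and pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for group, sub in df.groupby(group_col, sort=True):
        for col in value_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            n = len(vals)
            mean = float(np.mean(vals)) if n else math.nan
            sem = float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
            rows.append(
                {
                    "group": group,
                    "measure": col,
                    "n": n,
                    "mean": mean,
                    "sem": sem,
                    "sem_undefined": n < 2,
                }
            )
    return pd.DataFrame(rows)


def anova_oneway(df: pd.DataFrame, value_col: str, group_col: str = "group") -> dict:
    """One-way ANOVA across groups (delegated to standard routines)."""
    groups = [sub[value_col].dropna().to_numpy(dtype=float) for _, sub in df.groupby(group_col)]
    f, p = stats.f_oneway(*groups)
    return {"F": float(f), "p_value": float(p)}
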