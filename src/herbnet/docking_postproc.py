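"""Classification of molecular-docking binding energies into affinity bands.

Docking scores (kcal/mol, lower = stronger predicted binding) are
assigned to four bands that partition the real line:

* ``strong``  : score < -7
* ``good``    : -7 <= score < -5
* ``certain`` : -5 <= score <= -4.25
* ``weak``    : score > -4.25

The published band edges overlap at their boundaries; here the boundary
values -7 and -5 fall into the weaker neighbouring band and -4.25 into
``certain``, frozen so that every finite score gets exactly one class.
Scores above -4.25 carry no published label; ``weak`` is this package's
name for that remainder.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AFFINITY_CLASSES",
    "classify_affinity",
    "read_docking_matrix",
    "classify_matrix",
    "summarize_matrix",
]

AFFINITY_CLASSES = ("strong", "good", "certain", "weak")

STRONG_MAX = -7.0   # exclusive upper edge of "strong"
GOOD_MAX = -5.0     # exclusive upper edge of "good"
CERTAIN_MAX = -4.25  # inclusive upper edge of "certain"


def classify_affinity(score: float) -> str:
    """Affinity band for one binding energy (kcal/mol)."""
    if not math.isfinite(score):
        raise ValueError(f"docking score must be finite, got {score}")
    if score < STRONG_MAX:
        return "strong"
    if score < GOOD_MAX:
        return "good"
    if score <= CERTAIN_MAX:
        return "certain"
    return "weak"


def read_docking_matrix(path: str | Path) -> pd.DataFrame:
    """TSV grid: rows compounds, columns proteins, blank cells missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def classify_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Same-shape grid of band labels; missing cells stay missing (NA)."""
    def _cell(v):
        return pd.NA if pd.isna(v) else classify_affinity(float(v))

    return matrix.map(_cell)


def summarize_matrix(matrix: pd.DataFrame) -> dict:
    """Per-class counts overall, per protein and per compound, plus a
    long-format classified table sorted by (protein, compound).

    Missing cells are counted separately; an all-missing matrix is an
    error.
    """
    values = matrix.to_numpy(dtype=float)
    if np.all(np.isnan(values)):
        raise ValueError("docking matrix has no filled cells")

    rows = []
    for compound in matrix.index:
        for protein in matrix.columns:
            v = matrix.loc[compound, protein]
            if pd.isna(v):
                continue
            rows.append((protein, compound, float(v), classify_affinity(float(v))))
    rows.sort(key=lambda r: (r[0], r[1]))
    long = pd.DataFrame(rows, columns=["protein", "compound", "score", "affinity_class"])

    def _counts(frame: pd.DataFrame) -> dict[str, int]:
        c = frame["affinity_class"].value_counts()
        return {cls: int(c.get(cls, 0)) for cls in AFFINITY_CLASSES}

    return {
        "class_counts": _counts(long),
        "per_protein": {p: _counts(sub) for p, sub in long.groupby("protein")},
        "per_compound": {c: _counts(sub) for c, sub in long.groupby("compound")},
        "n_missing": int(np.isnan(values).sum()),
        "long_table": long,
    }
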