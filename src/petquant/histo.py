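"""Semi-quantitative histopathology scoring.

Counts of mitotic, apoptotic and Ki-67-positive cells are reported per
10 high-power fields (HPF, 40x).  Immunostaining is scored with the
intensity score (IS, 0-3: none / weak / moderate / strong), the extent
score (ES, 0-4 bins of the percentage of immunopositive cells) and their
product, the immunoreactivity score (IRS, 0-12).

The published ES categories are integer anchors (<5 %, 5-30 %, 31-50 %,
51-75 %, >75 %) that leave real-valued gaps between bins; the cut points
here sit at half-integers (5, 30.5, 50.5, 75.5) so every real percentage
maps to exactly one bin and each printed anchor lands in its printed
bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

#: Upper edges of extent-score bins 0..3 (bin 4 runs to 100).
_ES_EDGES = (5.0, 30.5, 50.5, 75.5)

COUNT_COLUMNS = ("mitotic", "apoptotic", "ki67_pos")


@dataclass(frozen=True)
class HistoScore:
    intensity_score: int
    extent_score: int
    irs: int
    pct_positive: Optional[float] = None


@dataclass(frozen=True)
class HPFSummary:
    """Cell counts per 10 high-power fields."""

    counts_per_10hpf: dict[str, float]
    n_fields_used: int
    averaged: bool
    extrapolated: bool
    warnings: tuple[str, ...] = ()


def extent_bin(pct_positive: float) -> int:
    """Bin a percentage of immunopositive cells into the extent score 0-4."""
    if not 0.0 <= pct_positive <= 100.0:
        raise ValueError("percentage must lie in [0, 100]")
    for es, edge in enumerate(_ES_EDGES):
        if pct_positive < edge:
            return es
    return 4


def irs(intensity_score: int, extent_score: int) -> int:
    """Immunoreactivity score: IS x ES."""
    if intensity_score not in range(4):
        raise ValueError("intensity score must be an integer in 0..3")
    if extent_score not in range(5):
        raise ValueError("extent score must be an integer in 0..4")
    return intensity_score * extent_score


def score_staining(intensity_score: int, pct_positive: float) -> HistoScore:
    """Full IS/ES/IRS scoring from intensity grade and percent positivity."""
    es = extent_bin(pct_positive)
    return HistoScore(
        intensity_score=int(intensity_score),
        extent_score=es,
        irs=irs(int(intensity_score), es),
        pct_positive=float(pct_positive),
    )


def per_hpf_summary(
    cell_table: Union[pd.DataFrame, str, Path],
    average: bool = False,
) -> HPFSummary:
    """Summarize per-field cell counts to counts per 10 HPF.

    The table needs one row per field with non-negative integer columns
    ``mitotic``, ``apoptotic`` and ``ki67_pos``.  With 10 or more fields
    the first 10 are summed, or, with ``average=True``, all fields are
    averaged and scaled to 10.  Fewer than 10 fields are scaled up to 10
    and flagged as extrapolated with a warning.
    """
    if not isinstance(cell_table, pd.DataFrame):
        cell_table = pd.read_csv(cell_table)
    missing = [c for c in COUNT_COLUMNS if c not in cell_table.columns]
    if missing:
        raise ValueError(f"cell table is missing columns: {missing}")
    counts = cell_table[list(COUNT_COLUMNS)]
    if counts.isna().any().any():
        raise ValueError("cell counts must not contain missing values")
    arr = counts.to_numpy()
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("cell counts must be non-negative integers")

    n = len(counts)
    notes: list[str] = []
    extrapolated = False
    if n >= 10 and not average:
        per10 = counts.iloc[:10].sum()
        used = 10
    elif n >= 10:
        per10 = counts.mean() * 10.0
        used = n
    else:
        msg = f"only {n} fields available; counts extrapolated to 10 HPF"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
        extrapolated = True
        per10 = counts.sum() * (10.0 / n)
        used = n
    return HPFSummary(
        counts_per_10hpf={c: float(per10[c]) for c in COUNT_COLUMNS},
        n_fields_used=used,
        averaged=bool(average and n >= 10),
        extrapolated=extrapolated,
        warnings=tuple(notes),
    )
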