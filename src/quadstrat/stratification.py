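"""Percentile banding, quadrant assignment, and clinical category rules.

Patients are banded on the composite inflammation score at its 40th and 60th
percentiles — the central 20% is deliberately left unclassified to give the
low/high contrast biological separation — and crossed with the NEFL
normal/high dichotomy into four quadrants.  Clinical categories (seizure
status, drug-resistance status, seizure-frequency bins) are pure functions
of the covariate table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import NEFL_CUTOFF_NPX, NeflClassification

QUADRANTS = ("Normal-Low", "High-High", "Normal-High", "High-Low")
UNCLASSIFIED = "unclassified"

#: Calendar phrases operationalized in days.
TWO_MONTHS_DAYS = 61
ONE_YEAR_DAYS = 365


class StratificationError(ValueError):
    pass


@dataclass(frozen=True)
class StratificationParams:
    lower_percentile: float = 40.0
    upper_percentile: float = 60.0
    nefl_cutoff_npx: float = NEFL_CUTOFF_NPX

    def __post_init__(self) -> None:
        if not 0 < self.lower_percentile < self.upper_percentile < 100:
            raise StratificationError(
                "need 0 < lower_percentile < upper_percentile < 100"
            )


def inflammation_class(
    pi: pd.Series, params: StratificationParams = StratificationParams()
) -> pd.Series:
    """Band scores into low / high / unclassified at the P40/P60 cuts.

    Percentiles use linear interpolation (rank = 1 + p*(n-1)).  Scores
    strictly below P40 are "low", strictly above P60 "high"; anything else,
    including exact ties with either cut, stays unclassified.
    """
    if len(pi) == 0:
        raise StratificationError("empty score vector")
    if len(pi) < 5:
        raise StratificationError("need at least 5 patients to band")
    lo = np.percentile(pi.to_numpy(), params.lower_percentile)
    hi = np.percentile(pi.to_numpy(), params.upper_percentile)
    out = pd.Series(UNCLASSIFIED, index=pi.index, name="inflammation_class")
    out[pi < lo] = "low"
    out[pi > hi] = "high"
    return out


def assign_quadrants(nefl: NeflClassification, infl: pd.Series) -> pd.Series:
    """Cross NEFL class with inflammation band into quadrant labels.

    Labels are "<NEFL class>-<inflammation band>" with NEFL first
    (e.g. "High-Low" = high NEFL, low inflammation).  An unclassified
    inflammation band dominates: the patient is excluded.
    """
    nefl_cls = nefl.nefl_class
    if set(nefl_cls.index) != set(infl.index):
        raise StratificationError("patient sets differ between NEFL and band")
    infl = infl.reindex(nefl_cls.index)
    out = pd.Series(UNCLASSIFIED, index=nefl_cls.index, name="quadrant")
    classified = infl != UNCLASSIFIED
    out[classified] = (
        nefl_cls[classified].str.capitalize()
        + "-"
        + infl[classified].str.capitalize()
    )
    return out


def derive_seizure_status(days_since_last_seizure: float | None) -> str:
    """Map days since the last seizure to the three-level seizure status.

    <= 61 days (two months) is "recent"; 62-365 days "intermediate";
    more than a year — or no seizure on record (None/NaN) — "seizure_free".
    """
    d = days_since_last_seizure
    if d is None or (isinstance(d, float) and math.isnan(d)):
        return "seizure_free"
    if d < 0:
        raise StratificationError(f"negative days since last seizure: {d}")
    if d <= TWO_MONTHS_DAYS:
        return "recent"
    if d <= ONE_YEAR_DAYS:
        return "intermediate"
    return "seizure_free"


def derive_epilepsy_status(n_asm: int, seizure_within_1yr: bool) -> str:
    """DRE / WCE / undetermined from medication count and 1-year seizure recency.

    Drug-resistant epilepsy (DRE): on >= 2 anti-seizure medications with a
    seizure in the last year.  Well-controlled epilepsy (WCE): exactly one
    medication and seizure-free for over a year.  Everyone else — including
    patients on no medication — is undetermined.
    """
    if n_asm < 0:
        raise StratificationError(f"negative ASM count: {n_asm}")
    if n_asm >= 2 and seizure_within_1yr:
        return "DRE"
    if n_asm == 1 and not seizure_within_1yr:
        return "WCE"
    return "undetermined"


def bin_seizure_frequency(count: int) -> str:
    """Bin a 2-month seizure count into the 0 / 1 / 2-100 groups."""
    if count < 0:
        raise StratificationError(f"negative seizure count: {count}")
    if count > 100:
        raise StratificationError(f"seizure count {count} outside the 0-100 range")
    if count == 0:
        return "0"
    if count == 1:
        return "1"
    return "2-100"


def derive_clinical_categories(clinical: pd.DataFrame) -> pd.DataFrame:
    """Attach seizure_status, epilepsy_status and freq_bin columns."""
    out = clinical.copy()
    out["seizure_status"] = [
        derive_seizure_status(d) for d in out["days_since_last_seizure"]
    ]
    out["epilepsy_status"] = [
        derive_epilepsy_status(int(a), s != "seizure_free")
        for a, s in zip(out["n_asm"], out["seizure_status"])
    ]
    out["freq_bin"] = [bin_seizure_frequency(int(c)) for c in out["seizure_count_2mo"]]
    return out


def contingency_table(
    quadrant: pd.Series,
    category: pd.Series,
    drop_unclassified: bool = True,
    row_order: tuple[str, ...] = ("High-Low", "High-High", "Normal-High", "Normal-Low"),
) -> pd.DataFrame:
    """Quadrant x category count table (unclassified patients dropped)."""
    df = pd.DataFrame({"quadrant": quadrant, "category": category})
    if drop_unclassified:
        df = df[df["quadrant"] != UNCLASSIFIED]
    table = pd.crosstab(df["quadrant"], df["category"])
    rows = [r for r in row_order if r in table.index]
    rows += [r for r in table.index if r not in rows]
    return table.loc[rows]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def quadrant_percentage(
    table: pd.DataFrame, row: str, cols: list[str] | tuple[str, ...]
) -> tuple[int, int, int]:
    """Share of a quadrant's patients falling in the selected categories.

    Returns (integer percent rounded half-away-from-zero, numerator,
    row total) so callers can report both the rounded figure and the ratio.
    """
    if row not in table.index:
        raise StratificationError(f"unknown quadrant row {row!r}")
    if not cols:
        raise StratificationError("no columns selected")
    total = int(table.loc[row].sum())
    if total == 0:
        raise StratificationError(f"zero total for quadrant {row!r}")
    num = int(table.loc[row, list(cols)].sum())
    return _round_half_away(100.0 * num / total), num, total
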