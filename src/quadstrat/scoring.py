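"""Z-score standardization, composite pro-inflammatory score, NEFL cutoff.

The composite pro-inflammatory score (PI score) is the sum of per-protein
Z-scores for a fixed 12-protein panel of cytokines/chemokines reported as
upregulated in blood of epilepsy patients.  Plasma neurofilament light chain
(NEFL), a marker of neuro-axonal injury, is dichotomized at a fixed NPX
cutoff calibrated externally against an absolute (pg/mL) assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .npx_io import NPXMatrix

#: The 12 pro-inflammatory proteins entering the composite score.
PI_PROTEINS: tuple[str, ...] = (
    "CASP1",
    "CCL11",
    "CCL2",
    "CCL3",
    "CXCL8",
    "IFNG",
    "IL17A",
    "IL18",
    "IL1B",
    "IL2",
    "IL6",
    "TNF",
)

#: NEFL NPX threshold above which plasma NEFL is considered abnormal for
#: adults aged 18-50; corresponds to 10 pg/mL on an absolute immunoassay.
NEFL_CUTOFF_NPX: float = 0.5
NEFL_CUTOFF_PG_ML: float = 10.0


class ScoringError(ValueError):
    pass


@dataclass
class NeflClassification:
    """Per-sample NEFL level and its normal/high dichotomy."""

    nefl_npx: pd.Series
    nefl_class: pd.Series  # "normal" | "high"
    cutoff_npx: float = NEFL_CUTOFF_NPX
    cutoff_pg_ml: float = field(default=NEFL_CUTOFF_PG_ML)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.nefl_npx.index)


def zscore(
    matrix: NPXMatrix | pd.DataFrame, proteins: Sequence[str] | None = None
) -> pd.DataFrame:
    """Column-wise standardization: (x - mean) / sd with the n-1 denominator.

    Standardization is over the full cohort passed in; downstream percentile
    banding assumes every patient contributed to the column statistics.

    Raises :class:`ScoringError` for unknown symbols or zero-variance columns.
    """
    data = matrix.data if isinstance(matrix, NPXMatrix) else matrix
    if proteins is not None:
        unknown = [p for p in proteins if p not in data.columns]
        if unknown:
            raise ScoringError(f"unknown protein symbols: {unknown}")
        data = data.loc[:, list(proteins)]
    sd = data.std(axis=0, ddof=1)
    degenerate = sd.index[(sd == 0) | sd.isna()].tolist()
    if degenerate:
        raise ScoringError(f"zero-variance columns: {degenerate}")
    return (data - data.mean(axis=0)) / sd


def pi_score(z: pd.DataFrame, block: Sequence[str] = PI_PROTEINS) -> pd.Series:
    """Sum the Z-scores of the pro-inflammatory block, per sample."""
    missing = [p for p in block if p not in z.columns]
    if missing:
        raise ScoringError(f"missing pro-inflammatory block symbols: {missing}")
    score = z.loc[:, list(block)].sum(axis=1)
    score.name = "pi_score"
    return score


def classify_nefl(
    nefl_npx: pd.Series, cutoff: float = NEFL_CUTOFF_NPX
) -> NeflClassification:
    """Dichotomize NEFL: strictly above the cutoff is "high", else "normal"."""
    values = pd.Series(nefl_npx, dtype=float)
    if not np.isfinite(values.to_numpy()).all():
        raise ScoringError("non-finite NEFL values")
    cls = pd.Series(
        np.where(values > cutoff, "high", "normal"), index=values.index,
        name="nefl_class",
    )
    return NeflClassification(nefl_npx=values, nefl_class=cls, cutoff_npx=cutoff)
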