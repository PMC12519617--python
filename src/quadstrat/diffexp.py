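"""Per-protein differential expression between two quadrant groups.

NPX is log2-scale, so a difference of group mean NPX is directly a log2
fold change.  The per-protein test defaults to Welch's unequal-variance t
test, with a Wilcoxon rank-sum alternative; p-values are BH-adjusted across
all proteins.  A protein is "significant" when the FDR-adjusted p < 0.05,
raw p < 0.05, and |log2 FC| >= 1; the relaxed flag lowers the fold-change
gate to |log2 FC| > 0.5.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_stats import bh_adjust
from .npx_io import NPXMatrix
from .scoring import PI_PROTEINS

logger = logging.getLogger(__name__)

ALPHA = 0.05
FDR_Q = 0.05
LFC_CUTOFF = 1.0
LFC_CUTOFF_RELAXED = 0.5


class DiffExpError(ValueError):
    pass


def diff_expression(
    matrix: NPXMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    test: str = "welch",
    alpha: float = ALPHA,
    fdr_q: float = FDR_Q,
    lfc: float = LFC_CUTOFF,
    lfc_relaxed: float = LFC_CUTOFF_RELAXED,
) -> pd.DataFrame:
    """Differential expression of every protein, group_a vs group_b.

    Returns a frame with columns protein_symbol, log2_fc, p, fdr,
    significant, significant_relaxed; log2_fc > 0 means higher in group_a.
    """
    data = matrix.data if isinstance(matrix, NPXMatrix) else matrix
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise DiffExpError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DiffExpError("each group needs >= 2 samples")
    missing = (set(group_a) | set(group_b)) - set(data.index)
    if missing:
        raise DiffExpError(f"samples not in matrix: {sorted(missing)}")
    if test not in ("welch", "ranksum"):
        raise DiffExpError(f"unknown test {test!r}")

    a = data.loc[group_a].to_numpy()
    b = data.loc[group_b].to_numpy()
    log2_fc = a.mean(axis=0) - b.mean(axis=0)
    if test == "welch":
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    else:
        _, p = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    fdr = bh_adjust(p)
    out = pd.DataFrame(
        {
            "protein_symbol": data.columns,
            "log2_fc": log2_fc,
            "p": p,
            "fdr": fdr,
        }
    )
    out["significant"] = (
        (out["fdr"] < fdr_q) & (out["p"] < alpha) & (out["log2_fc"].abs() >= lfc)
    )
    out["significant_relaxed"] = (
        (out["fdr"] < fdr_q) & (out["p"] < alpha) & (out["log2_fc"].abs() > lfc_relaxed)
    )
    return out


def top_n(results: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The n most differentially expressed proteins.

    Ordered by ascending p; ties broken by descending |log2 FC|, then by
    symbol for determinism.
    """
    if n < 1:
        raise DiffExpError("n must be >= 1")
    ranked = results.assign(_abs_lfc=results["log2_fc"].abs()).sort_values(
        ["p", "_abs_lfc", "protein_symbol"],
        ascending=[True, False, True],
        kind="stable",
    )
    return ranked.drop(columns="_abs_lfc").head(n).reset_index(drop=True)


def volcano_coordinates(
    results: pd.DataFrame,
    pi_proteins: Sequence[str] = PI_PROTEINS,
    nefl_symbol: str = "NEFL",
) -> pd.DataFrame:
    """(log2 FC, -log10 p) coordinates with plot categories.

    Categories: "pi_score_protein" for the 12 score constituents and NEFL
    (flagged regardless of significance), then "significant", then "other".
    Zero p-values are mapped to the smallest positive float and logged.
    """
    p = results["p"].to_numpy(dtype=float).copy()
    if (p == 0).any():
        logger.warning(
            "volcano_coordinates: %d zero p-values clamped", int((p == 0).sum())
        )
        p[p == 0] = np.finfo(float).tiny
    special = set(pi_proteins) | {nefl_symbol}
    category = np.where(
        results["protein_symbol"].isin(special),
        "pi_score_protein",
        np.where(results["significant"], "significant", "other"),
    )
    return pd.DataFrame(
        {
            "protein_symbol": results["protein_symbol"],
            "log2_fc": results["log2_fc"],
            "neg_log10_p": -np.log10(p),
            "category": category,
        }
    )
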