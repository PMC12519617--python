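"""Hypothesis tests and correlation machinery for the quadrant analysis.

Continuous covariates are compared across quadrants with the Kruskal-Wallis
H test followed by Dunn's pairwise test with Bonferroni correction;
categorical covariates with the Pearson chi-square test of independence
followed by pairwise 2 x c chi-square sub-tables with Benjamini-Hochberg
correction.  No continuity correction is applied anywhere and no
minimum-expected-count rule is enforced (a warning is logged when an
expected count falls below 5).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Highlight rule for correlation plots.
HIGHLIGHT_R = 0.1
HIGHLIGHT_P = 0.05


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class KWResult:
    H: float
    p: float
    group_sizes: tuple[int, ...]


@dataclass
class PosthocResult:
    pairs: list[tuple[str, str]]
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    method: str
    statistics: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "group_a": [a for a, _ in self.pairs],
                "group_b": [b for _, b in self.pairs],
                "raw_p": self.raw_p,
                "adjusted_p": self.adjusted_p,
            }
        )
        if self.statistics is not None:
            df.insert(2, "statistic", self.statistics)
        return df


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float

    @property
    def highlight(self) -> bool:
        return abs(self.r) > HIGHLIGHT_R and self.p < HIGHLIGHT_P


def spearman(x, y, method: str = "asymptotic") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Mid-ranks for ties; p from the t approximation on n-2 degrees of
    freedom.  ``method="exact"`` switches to an exact pairing-permutation
    p-value, intended for very small samples (n <= 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StatsError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for a constant vector")
    if method == "exact":
        if len(x) > 10:
            raise StatsError("exact Spearman p only supported for n <= 10")
        return _spearman_exact(x, y)
    res = stats.spearmanr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue))


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Exact two-sided permutation p by exhausting all pairings.

    The rank correlation depends on the permutation only through the dot
    product of the rank vectors, so the n! arrangements are scored in
    vectorized chunks.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    denom = np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    observed = float((rx - rx.mean()) @ (ry - ry.mean()) / denom)

    centered_x = rx - rx.mean()
    count = total = 0
    chunk: list[tuple[float, ...]] = []

    def _flush() -> tuple[int, int]:
        block = np.array(chunk)
        stat = (block - ry.mean()) @ centered_x / denom
        return int(np.sum(np.abs(stat) >= abs(observed) - 1e-12)), len(block)

    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 40320:
            c, t = _flush()
            count, total, chunk = count + c, total + t, []
    if chunk:
        c, t = _flush()
        count, total = count + c, total + t
    return CorrelationResult(r=observed, p=count / total)


def correlation_matrix(
    data: pd.DataFrame, targets: list[str] | None = None
) -> pd.DataFrame:
    """All pairwise Spearman correlations among the given columns.

    Returns a tidy frame with columns (a, b, r, p, highlight) covering every
    unordered pair (and each column against itself with r = 1).
    """
    cols = list(targets) if targets is not None else list(data.columns)
    unknown = [c for c in cols if c not in data.columns]
    if unknown:
        raise StatsError(f"unknown columns: {unknown}")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            if a == b:
                rows.append((a, b, 1.0, 0.0, True))
            else:
                res = spearman(data[a], data[b])
                rows.append((a, b, res.r, res.p, res.highlight))
    return pd.DataFrame(rows, columns=["a", "b", "r", "p", "highlight"])


def kruskal_wallis(groups: list) -> KWResult:
    """Kruskal-Wallis H with tie correction; p from chi-square on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatsError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if len(pooled) < 3:
        raise StatsError("pooled n must be >= 3")
    sizes = tuple(len(g) for g in groups)
    if np.ptp(pooled) == 0:
        return KWResult(H=0.0, p=1.0, group_sizes=sizes)
    H, p = stats.kruskal(*groups)
    return KWResult(H=float(H), p=float(p), group_sizes=sizes)


def dunn_posthoc(groups: list, labels: list[str] | None = None) -> PosthocResult:
    """Dunn's pairwise rank test with Bonferroni-adjusted two-sided p-values.

    z for a pair (i, j) is the difference of mean pooled ranks over
    sqrt(V * (1/n_i + 1/n_j)) with the tie-corrected pooled rank variance
    V = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatsError("need >= 2 nonempty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    variance = N * (N + 1) / 12.0 - tie_term

    pairs, zs, raw = [], [], []
    for i, j in itertools.combinations(range(len(groups)), 2):
        pairs.append((labels[i], labels[j]))
        if variance <= 0:  # every pooled value tied
            zs.append(0.0)
            raw.append(1.0)
            continue
        se = np.sqrt(variance * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        zs.append(float(z))
        raw.append(float(2.0 * stats.norm.sf(abs(z))))
    raw = np.array(raw)
    return PosthocResult(
        pairs=pairs,
        raw_p=raw,
        adjusted_p=bonferroni_adjust(raw),
        method="bonferroni",
        statistics=np.array(zs),
    )


def chi_square(table: pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = np.asarray(table, dtype=float)
    if counts.min() < 0 or counts.sum() <= 0:
        raise StatsError("contingency table must be non-negative with total >= 1")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise StatsError("zero marginal row or column")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()
    if (expected < 5).any():
        logger.warning(
            "chi_square: %d of %d expected counts below 5",
            int((expected < 5).sum()),
            expected.size,
        )
    statistic, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ChiSquareResult(statistic=float(statistic), df=int(df), p=float(p))


def pairwise_chi_square(
    table: pd.DataFrame, pair_order: list[tuple[str, str]] | None = None
) -> PosthocResult:
    """Chi-square on every unordered row pair, BH-adjusted across pairs.

    Columns with a zero margin within a 2 x c sub-table are dropped for that
    pair (and logged) so the sub-test stays well defined.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table))
    if table.shape[0] < 3:
        raise StatsError("pairwise post hoc needs >= 3 rows")
    if pair_order is None:
        pair_order = list(itertools.combinations(table.index, 2))
    pairs, raw, statistics = [], [], []
    for a, b in pair_order:
        sub = table.loc[[a, b]]
        nonzero = sub.columns[sub.sum(axis=0) > 0]
        if len(nonzero) < len(sub.columns):
            dropped = [c for c in sub.columns if c not in set(nonzero)]
            logger.info(
                "pairwise_chi_square: dropping zero-margin columns %s for (%s, %s)",
                dropped, a, b,
            )
            sub = sub.loc[:, nonzero]
        res = chi_square(sub)
        pairs.append((a, b))
        raw.append(res.p)
        statistics.append(res.statistic)
    raw = np.array(raw)
    return PosthocResult(
        pairs=pairs,
        raw_p=raw,
        adjusted_p=bh_adjust(raw),
        method="benjamini_hochberg",
        statistics=np.array(statistics),
    )


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise StatsError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order."""
    p = _check_p(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p) -> np.ndarray:
    """Bonferroni adjustment: p * m, capped at 1, input order preserved."""
    p = _check_p(p)
    if p.size == 0:
        return p
    return np.minimum(p * p.size, 1.0)
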