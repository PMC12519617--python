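"""Correspondence analysis of labeled contingency tables.

CA decomposes the standardized residuals of a contingency table by SVD.
With row and column points both scaled to principal coordinates (the
symmetric map), the geometry summarizes departures from independence and
the total inertia — the sum of squared singular values — equals the
Pearson chi-square statistic divided by the grand total.

Euclidean distances between a row (quadrant) point and a column (clinical
category) point in the first-two-dimension symmetric map are used as
descriptive proximities; note that row-to-column distances in a symmetric
map are not chi-square distances and carry no inferential calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class CAError(ValueError):
    pass


@dataclass
class CAResult:
    row_masses: pd.Series
    col_masses: pd.Series
    singular_values: np.ndarray  # all nontrivial dimensions, descending
    row_coords: pd.DataFrame  # rows x k, principal coordinates
    col_coords: pd.DataFrame  # cols x k, principal coordinates
    total_inertia: float  # over ALL nontrivial dimensions
    grand_total: float

    @property
    def k(self) -> int:
        return self.row_coords.shape[1]


def ca_fit(table: pd.DataFrame | np.ndarray, k: int = 2) -> CAResult:
    """Fit correspondence analysis, keeping the first ``k`` dimensions.

    Steps: correspondence matrix P = counts / N; standardized residuals
    S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j); thin SVD S = U diag(s) V';
    principal coordinates F = diag(r)^(-1/2) U diag(s) for rows and
    G = diag(c)^(-1/2) V diag(s) for columns.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table))
    counts = table.to_numpy(dtype=float)
    if counts.min() < 0 or counts.sum() <= 0:
        raise CAError("table must be non-negative with a positive total")
    N = counts.sum()
    r = counts.sum(axis=1) / N
    c = counts.sum(axis=0) / N
    if (r == 0).any() or (c == 0).any():
        raise CAError("zero row or column margin")
    max_k = min(counts.shape) - 1
    if not 1 <= k <= max_k:
        raise CAError(f"k must be in [1, {max_k}] for a {counts.shape} table")

    P = counts / N
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    # drop the structural zero dimension(s); keep the max_k nontrivial ones
    s = s[:max_k]
    U = U[:, :max_k]
    V = Vt.T[:, :max_k]

    F = (U / np.sqrt(r)[:, None]) * s
    G = (V / np.sqrt(c)[:, None]) * s
    return CAResult(
        row_masses=pd.Series(r, index=table.index, name="row_mass"),
        col_masses=pd.Series(c, index=table.columns, name="col_mass"),
        singular_values=s,
        row_coords=pd.DataFrame(
            F[:, :k], index=table.index, columns=[f"dim{i+1}" for i in range(k)]
        ),
        col_coords=pd.DataFrame(
            G[:, :k], index=table.columns, columns=[f"dim{i+1}" for i in range(k)]
        ),
        total_inertia=float(np.sum(s**2)),
        grand_total=float(N),
    )


def ca_distances(result: CAResult) -> pd.DataFrame:
    """Row-to-column Euclidean distances in the retained symmetric map."""
    F = result.row_coords.to_numpy()
    G = result.col_coords.to_numpy()
    d = np.sqrt(((F[:, None, :] - G[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(
        d, index=result.row_coords.index, columns=result.col_coords.index
    )
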