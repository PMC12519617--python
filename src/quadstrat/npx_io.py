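"""Reading, merging and QC-filtering of Olink-style NPX data.

Olink panels ship as long-format tables: one row per (sample, assay, panel)
carrying an NPX value (relative abundance, log2 scale) and a QC flag.  This
module parses those tables into :class:`AssayRecord` lists, pivots them into
a samples x proteins :class:`NPXMatrix`, resolves assays duplicated across
panels, and drops assays that failed batch-release QC.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default column names of an Olink-style long export.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "sample": "SampleID",
    "assay": "Assay",
    "assay_id": "OlinkID",
    "panel": "Panel",
    "npx": "NPX",
    "qc": "QC_Warning",
}

QC_PASS_VALUE = "PASS"

CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "gender",
    "epilepsy_type",
    "days_since_last_seizure",
    "seizure_count_2mo",
    "n_asm",
]


class NPXFormatError(ValueError):
    """Malformed NPX input (missing column, bad value, unknown panel)."""


class PanelAlignmentError(ValueError):
    """Panels do not share the same sample set and cannot be merged."""


@dataclass(frozen=True)
class AssayRecord:
    """One long-format NPX measurement."""

    sample_id: str
    protein_symbol: str
    assay_id: str
    panel: str
    npx: float
    qc_pass: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.npx):
            raise NPXFormatError(
                f"non-finite NPX for sample {self.sample_id!r}, "
                f"assay {self.protein_symbol!r}"
            )


@dataclass
class NPXMatrix:
    """Samples x proteins NPX matrix with per-assay metadata.

    ``data`` holds log2-scale NPX values with sample IDs as the index and
    protein symbols as columns.  ``assay_meta`` is indexed by protein symbol
    and carries ``panel``, ``assay_id`` and ``qc_pass``.
    """

    data: pd.DataFrame
    assay_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.assay_meta.empty:
            self.assay_meta = pd.DataFrame(
                {
                    "panel": "unknown",
                    "assay_id": list(self.data.columns),
                    "qc_pass": True,
                },
                index=self.data.columns,
            )
        if list(self.assay_meta.index) != list(self.data.columns):
            raise ValueError("assay_meta index must match data columns")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicated protein symbols: {dupes}")
        if self.data.isna().any().any():
            raise NPXFormatError("missing NPX cells are not supported")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def protein_symbols(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.data.shape[1]


def read_npx_long(
    path: str | Path,
    panel_names: Sequence[str],
    columns: Mapping[str, str] | None = None,
) -> list[AssayRecord]:
    """Parse a long-format Olink CSV into assay records.

    Parameters
    ----------
    path
        CSV file with a header row; comma-delimited, UTF-8.
    panel_names
        Allowed panel names; a row naming any other panel is an error.
    columns
        Overrides for the default column names (keys: ``sample``, ``assay``,
        ``assay_id``, ``panel``, ``npx``, ``qc``).  The ``assay_id`` column is
        optional in the file; when absent, ``symbol@panel`` is used.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    path = Path(path)
    df = pd.read_csv(path, dtype=str)

    required = ["sample", "assay", "panel", "npx", "qc"]
    for key in required:
        if cols[key] not in df.columns:
            raise NPXFormatError(
                f"missing required column {cols[key]!r} in {path.name}"
            )
    has_assay_id = cols["assay_id"] in df.columns

    allowed = set(panel_names)
    records: list[AssayRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        panel = row[cols["panel"]]
        if panel not in allowed:
            raise NPXFormatError(
                f"unknown panel {panel!r} at line {i}; "
                f"allowed panels: {sorted(allowed)}"
            )
        try:
            npx = float(row[cols["npx"]])
        except (TypeError, ValueError) as exc:
            raise NPXFormatError(
                f"non-numeric NPX {row[cols['npx']]!r} at line {i}"
            ) from exc
        symbol = row[cols["assay"]]
        assay_id = row[cols["assay_id"]] if has_assay_id else f"{symbol}@{panel}"
        key = (panel, row[cols["sample"]], assay_id)
        if key in seen:
            raise NPXFormatError(
                f"duplicate (sample, assay) pair within panel {panel!r} at line {i}"
            )
        seen.add(key)
        records.append(
            AssayRecord(
                sample_id=row[cols["sample"]],
                protein_symbol=symbol,
                assay_id=assay_id,
                panel=panel,
                npx=npx,
                qc_pass=row[cols["qc"]] == QC_PASS_VALUE,
            )
        )
    return records


def merge_panels(records: Sequence[AssayRecord]) -> NPXMatrix:
    """Pivot long records into a wide matrix, resolving cross-panel duplicates.

    A protein measured on more than one panel keeps the panel whose geometric
    mean expression on the linear scale is highest.  Since NPX is log2, the
    geometric mean of 2**NPX is ordered exactly like the arithmetic mean of
    NPX, so the comparison is done on mean NPX (numerically safer).  Exact
    ties keep the lexicographically first panel name and log a warning.
    """
    if not records:
        raise NPXFormatError("no assay records to merge")

    long = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "protein_symbol": [r.protein_symbol for r in records],
            "assay_id": [r.assay_id for r in records],
            "panel": [r.panel for r in records],
            "npx": [r.npx for r in records],
            "qc_pass": [r.qc_pass for r in records],
        }
    )

    sample_sets = long.groupby("panel")["sample_id"].agg(frozenset)
    reference = sample_sets.iloc[0]
    for panel, samples in sample_sets.items():
        if samples != reference:
            raise PanelAlignmentError(
                f"panel {panel!r} sample set differs from panel "
                f"{sample_sets.index[0]!r}"
            )

    # (symbol, panel) candidate columns; pick the winner per symbol.
    per_assay = (
        long.groupby(["protein_symbol", "panel"])
        .agg(
            mean_npx=("npx", "mean"),
            assay_id=("assay_id", "first"),
            qc_pass=("qc_pass", "all"),
        )
        .reset_index()
        .sort_values(["protein_symbol", "panel"], kind="stable")
    )
    winners = {}
    for symbol, grp in per_assay.groupby("protein_symbol", sort=False):
        best = grp.loc[grp["mean_npx"].idxmax()]  # idxmax keeps first on ties
        if len(grp) > 1:
            top = grp["mean_npx"].max()
            tied = grp[grp["mean_npx"] == top]
            if len(tied) > 1:
                logger.warning(
                    "exact mean-NPX tie for %s across panels %s; keeping %s",
                    symbol,
                    sorted(tied["panel"]),
                    best["panel"],
                )
        winners[symbol] = best

    keep = {(s, w["panel"]) for s, w in winners.items()}
    kept_long = long[
        [(s, p) in keep for s, p in zip(long["protein_symbol"], long["panel"])]
    ]
    wide = kept_long.pivot(index="sample_id", columns="protein_symbol", values="npx")
    # preserve first-appearance protein order from the input records
    order = list(dict.fromkeys(long["protein_symbol"]))
    wide = wide.loc[sorted(wide.index), order]
    meta = pd.DataFrame(
        {
            "panel": [winners[s]["panel"] for s in order],
            "assay_id": [winners[s]["assay_id"] for s in order],
            "qc_pass": [bool(winners[s]["qc_pass"]) for s in order],
        },
        index=pd.Index(order, name="protein_symbol"),
    )
    return NPXMatrix(data=wide, assay_meta=meta)


def qc_filter(matrix: NPXMatrix) -> NPXMatrix:
    """Drop proteins whose assays failed batch-release QC.

    Column order among survivors is preserved; the sample set is unchanged.
    """
    mask = matrix.assay_meta["qc_pass"].astype(bool)
    removed = (~mask).sum()
    if mask.sum() == 0:
        raise NPXFormatError("all proteins fail QC; empty matrix is invalid")
    logger.info("qc_filter: removed %d of %d proteins", removed, len(mask))
    keep = matrix.assay_meta.index[mask]
    return NPXMatrix(
        data=matrix.data.loc[:, keep].copy(),
        assay_meta=matrix.assay_meta.loc[keep].copy(),
    )


def write_wide(matrix: NPXMatrix, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write the wide samples x proteins TSV plus a JSON metadata sidecar."""
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", index_label="sample_id")
    if sidecar is None:
        sidecar = path.with_suffix(".meta.json")
    meta = {
        "proteins": {
            symbol: {
                "panel": row["panel"],
                "assay_id": row["assay_id"],
                "qc_pass": bool(row["qc_pass"]),
            }
            for symbol, row in matrix.assay_meta.iterrows()
        }
    }
    Path(sidecar).write_text(json.dumps(meta, indent=2))


def read_wide(path: str | Path) -> NPXMatrix:
    """Read a wide TSV written by :func:`write_wide` (metadata optional)."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    return NPXMatrix(data=df.astype(float))


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical covariate CSV.

    Expected columns: patient_id, age, gender, epilepsy_type,
    days_since_last_seizure (empty = no seizure on record),
    seizure_count_2mo, n_asm.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise NPXFormatError(f"clinical table missing columns: {missing}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["days_since_last_seizure"] = pd.to_numeric(
        df["days_since_last_seizure"], errors="coerce"
    )
    for col in ("age", "seizure_count_2mo", "n_asm"):
        df[col] = pd.to_numeric(df[col])
    return df
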