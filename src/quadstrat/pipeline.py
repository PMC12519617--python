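"""End-to-end pipeline: ingest -> score -> stratify -> associate -> CA -> DE.

The pipeline mirrors the stages of the stratification analysis: NPX
preprocessing, composite inflammation scoring and NEFL dichotomy, quadrant
assignment with the central-band exclusion, the battery of association
tests, correspondence-analysis distances, and differential expression
between the High-High and Normal-Low quadrants.  Everything is driven from
a :class:`PipelineConfig` and produces a machine-readable report plus TSV
stage outputs; given the same config and seed the report is reproducible
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc_stats, correspondence, diffexp, npx_io, scoring, synthetic
from .stratification import (
    StratificationParams,
    UNCLASSIFIED,
    assign_quadrants,
    contingency_table,
    derive_clinical_categories,
    inflammation_class,
)

logger = logging.getLogger(__name__)

CATEGORICAL_VARIABLES = (
    "seizure_status",
    "epilepsy_type",
    "gender",
    "epilepsy_status",
    "n_asm",
    "freq_bin",
)
CONTINUOUS_VARIABLES = ("age", "seizure_count_2mo")
CA_VARIABLES = ("seizure_status", "epilepsy_status")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    npx_path: str | None = None
    clinical_path: str | None = None
    simulate: dict | None = None
    panels: tuple[str, ...] = synthetic.DEFAULT_PANELS
    stratification: StratificationParams = field(default_factory=StratificationParams)
    de_test: str = "welch"
    alpha: float = 0.05
    fdr_q: float = 0.05
    lfc: float = 1.0
    lfc_relaxed: float = 0.5
    out_dir: str = "quadstrat_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_inputs = self.npx_path is not None and self.clinical_path is not None
        if not has_inputs and self.simulate is None:
            raise PipelineError(
                "config needs either input paths or a simulate block"
            )
        if min(self.alpha, self.fdr_q, self.lfc, self.lfc_relaxed) <= 0:
            raise PipelineError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        strat = raw.pop("stratification", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if strat:
            cfg.stratification = StratificationParams(**strat)
        return cfg

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload["stratification"] = dataclasses.asdict(self.stratification)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _round_floats(obj: Any, ndigits: int = 10) -> Any:
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def _ingest(config: PipelineConfig) -> tuple[npx_io.NPXMatrix, pd.DataFrame]:
    if config.simulate is not None:
        params = synthetic.SyntheticParams(seed=config.seed, **config.simulate)
        clinical = synthetic.generate_clinical(params)
        matrix = synthetic.generate_npx(clinical, params)
        matrix = npx_io.qc_filter(matrix)
        return matrix, clinical
    records = npx_io.read_npx_long(config.npx_path, panel_names=config.panels)
    matrix = npx_io.qc_filter(npx_io.merge_panels(records))
    clinical = npx_io.read_clinical(config.clinical_path)
    missing = set(clinical["patient_id"]) ^ set(matrix.sample_ids)
    if missing:
        raise PipelineError(
            f"clinical and NPX patient sets differ: {sorted(missing)[:5]} ..."
        )
    return matrix, clinical


def _score_and_stratify(
    matrix: npx_io.NPXMatrix, clinical: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Per-patient table with scores, quadrant and derived categories."""
    z = scoring.zscore(matrix, scoring.PI_PROTEINS)
    pi = scoring.pi_score(z)
    nefl = scoring.classify_nefl(
        matrix.data["NEFL"], cutoff=config.stratification.nefl_cutoff_npx
    )
    infl = inflammation_class(pi, config.stratification)
    quadrant = assign_quadrants(nefl, infl)
    per_patient = pd.DataFrame(
        {
            "nefl_npx": nefl.nefl_npx,
            "nefl_class": nefl.nefl_class,
            "pi_score": pi,
            "inflammation_class": infl,
            "quadrant": quadrant,
        }
    )
    for p in scoring.PI_PROTEINS:
        per_patient[f"z_{p}"] = z[p]
    per_patient.index.name = "patient_id"
    clin = derive_clinical_categories(clinical).set_index("patient_id")
    return clin.join(per_patient, how="inner")


def _associations(table: pd.DataFrame, alpha: float) -> dict:
    out: dict[str, Any] = {}
    classified = table[table["quadrant"] != UNCLASSIFIED]
    quadrants = [q for q in
                 ("Normal-Low", "High-High", "Normal-High", "High-Low")
                 if q in set(classified["quadrant"])]
    for var in CATEGORICAL_VARIABLES:
        ct = contingency_table(table["quadrant"], table[var].astype(str))
        ct = ct.loc[:, ct.sum(axis=0) > 0]
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            out[var] = {"skipped": "degenerate contingency table"}
            continue
        res = assoc_stats.chi_square(ct)
        entry = {
            "table": {r: ct.loc[r].to_dict() for r in ct.index},
            "chi2": res.statistic,
            "df": res.df,
            "p": res.p,
        }
        if res.p < alpha and ct.shape[0] >= 3:
            entry["posthoc"] = assoc_stats.pairwise_chi_square(ct).as_frame().to_dict(
                orient="records"
            )
        out[var] = entry
    for var in CONTINUOUS_VARIABLES:
        groups = [
            classified.loc[classified["quadrant"] == q, var].dropna().to_numpy()
            for q in quadrants
        ]
        if len(groups) < 2 or any(len(g) == 0 for g in groups):
            out[var] = {"skipped": "fewer than two nonempty quadrant groups"}
            continue
        kw = assoc_stats.kruskal_wallis(groups)
        entry = {"H": kw.H, "p": kw.p, "group_sizes": list(kw.group_sizes)}
        if kw.p < alpha:
            entry["posthoc"] = assoc_stats.dunn_posthoc(
                groups, labels=quadrants
            ).as_frame().to_dict(orient="records")
        out[var] = entry
    return out


def _ca_section(table: pd.DataFrame) -> dict:
    out = {}
    for var in CA_VARIABLES:
        ct = contingency_table(table["quadrant"], table[var].astype(str))
        ct = ct.loc[ct.sum(axis=1) > 0, ct.sum(axis=0) > 0]
        if min(ct.shape) < 3:  # need >= 2 nontrivial dimensions
            out[var] = {"skipped": "table too small for a 2D map"}
            continue
        fit = correspondence.ca_fit(ct, k=2)
        dist = correspondence.ca_distances(fit)
        out[var] = {
            "singular_values": fit.singular_values.tolist(),
            "total_inertia": fit.total_inertia,
            "distances": {r: dist.loc[r].to_dict() for r in dist.index},
        }
    return out


def _diffexp_section(
    matrix: npx_io.NPXMatrix, table: pd.DataFrame, config: PipelineConfig,
    out_dir: Path | None,
) -> dict:
    group_a = table.index[table["quadrant"] == "High-High"].tolist()
    group_b = table.index[table["quadrant"] == "Normal-Low"].tolist()
    if len(group_a) < 2 or len(group_b) < 2:
        return {"skipped": "quadrant groups too small"}
    results = diffexp.diff_expression(
        matrix.data.loc[table.index], group_a, group_b,
        test=config.de_test, alpha=config.alpha, fdr_q=config.fdr_q,
        lfc=config.lfc, lfc_relaxed=config.lfc_relaxed,
    )
    top = diffexp.top_n(results, 20)
    if out_dir is not None:
        results.to_csv(out_dir / "diffexp.tsv", sep="\t", index=False)
        diffexp.volcano_coordinates(results).to_csv(
            out_dir / "volcano.tsv", sep="\t", index=False
        )
    return {
        "group_a": "High-High",
        "group_b": "Normal-Low",
        "n_a": len(group_a),
        "n_b": len(group_b),
        "n_significant": int(results["significant"].sum()),
        "n_significant_relaxed": int(results["significant_relaxed"].sum()),
        "top20": top["protein_symbol"].tolist(),
    }


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute all stages and return (and optionally write) the report."""
    out_dir = Path(config.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        matrix, clinical = _ingest(config)
        logger.info("ingest: %d samples x %d proteins", *matrix.data.shape)
        stage = "score/stratify"
        table = _score_and_stratify(matrix, clinical, config)
        stage = "associate"
        assoc = _associations(table, config.alpha)
        stage = "ca"
        ca = _ca_section(table)
        stage = "diffexp"
        de = _diffexp_section(matrix, table, config, out_dir if write else None)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    counts = table["quadrant"].value_counts().to_dict()
    report = _round_floats(
        {
            "provenance": {
                "config_hash": config.digest(),
                "seed": config.seed,
                "version": __version__,
            },
            "n_patients": int(len(table)),
            "n_proteins": int(matrix.n_proteins),
            "quadrant_counts": {str(k): int(v) for k, v in counts.items()},
            "associations": assoc,
            "correspondence": ca,
            "diffexp": de,
        }
    )
    if write:
        table.to_csv(out_dir / "per_patient.tsv", sep="\t")
        npx_io.write_wide(matrix, out_dir / "npx_wide.tsv")
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def subgroup_run(
    config: PipelineConfig, filter_epilepsy_type: str, write: bool = False
) -> dict:
    """Re-tabulate the pipeline within one epilepsy type.

    Quadrant membership (the percentile banding) is computed once on the
    full cohort and reused; only the association/CA/DE tabulations are
    restricted to the subgroup.
    """
    if filter_epilepsy_type not in ("focal", "generalized", "unknown"):
        raise PipelineError(f"unknown epilepsy type {filter_epilepsy_type!r}")
    matrix, clinical = _ingest(config)
    table = _score_and_stratify(matrix, clinical, config)
    sub = table[table["epilepsy_type"] == filter_epilepsy_type]
    if sub.empty:
        raise PipelineError(f"no patients with epilepsy type {filter_epilepsy_type!r}")
    report = _round_floats(
        {
            "provenance": {
                "config_hash": config.digest(),
                "seed": config.seed,
                "version": __version__,
                "subgroup": filter_epilepsy_type,
            },
            "n_patients": int(len(sub)),
            "quadrant_counts": {
                str(k): int(v) for k, v in sub["quadrant"].value_counts().items()
            },
            "quadrants": sub["quadrant"].to_dict(),
            "associations": _associations(sub, config.alpha),
            "correspondence": _ca_section(sub),
        }
    )
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"report_{filter_epilepsy_type}.json").write_text(
            json.dumps(report, indent=2)
        )
    return report


def fixture_report() -> dict:
    """Validation run on the embedded contingency tables.

    Recomputes, from the packaged quadrant x category tables, every
    chi-square statistic, the BH-corrected pairwise post hoc p-values for
    epilepsy status, and the CA row-to-column distance matrices for the
    seizure-status and epilepsy-status tables.
    """
    tables = synthetic.fixture_tables()
    out: dict[str, Any] = {}
    for name, table in tables.items():
        res = assoc_stats.chi_square(table)
        entry: dict[str, Any] = {
            "chi2": res.statistic, "df": res.df, "p": res.p,
        }
        if name == "epilepsy_status":
            entry["posthoc"] = assoc_stats.pairwise_chi_square(table).as_frame().to_dict(
                orient="records"
            )
        if name in CA_VARIABLES:
            fit = correspondence.ca_fit(table, k=2)
            dist = correspondence.ca_distances(fit)
            entry["ca"] = {
                "total_inertia": fit.total_inertia,
                "distances": {r: dist.loc[r].to_dict() for r in dist.index},
            }
        out[name] = entry
    return _round_floats(out)
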