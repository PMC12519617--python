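"""Synthetic epilepsy-cohort generator and embedded contingency fixtures.

The raw study data (plasma Olink proteomics of adult epilepsy patients)
cannot be shared, so this module generates cohorts carrying the statistical
structure the downstream analysis assumes:

* a 12-protein pro-inflammatory block driven by a single Gaussian latent
  inflammation factor (pairwise correlation ``rho_block``; CASP1 and IL2
  load more weakly than the rest),
* NEFL coupled to the composite score only weakly (target Spearman
  ``rho_nefl``, default 0.1),
* a latent "high NEFL / high inflammation" stratum whose members receive an
  NPX shift on the blood-brain-barrier proteins MMP1/VEGFA/HGF and elevated
  odds of drug resistance and recent seizures,
* clinical covariates whose marginals mirror the study cohort (n = 176,
  ages 18-50, ~58.5% female, seizure-status mix 50/40/10, ASM-count mix
  9/55.7/23.3/11.9).

The outcome tilt for the high-high stratum is compensated in the remaining
patients so that the configured cohort-level marginals are preserved.

The module also ships, as packaged CSVs, the five quadrant x category
contingency tables of the source cohort (seizure status, epilepsy type,
gender, epilepsy status, ASM count) used to validate every test statistic
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .npx_io import NPXMatrix
from .scoring import PI_PROTEINS

#: Proteins with a planted NPX shift in the high-high stratum
#: (blood-brain-barrier dysfunction markers).
BBB_PROTEINS: tuple[str, ...] = ("MMP1", "VEGFA", "HGF")

NEFL_SYMBOL = "NEFL"

DEFAULT_PANELS: tuple[str, ...] = (
    "Inflammation_I",
    "Inflammation_II",
    "Neurology_I",
    "Neurology_II",
)

#: Block members loading more weakly on the latent factor.
WEAK_BLOCK_MEMBERS: tuple[str, ...] = ("CASP1", "IL2")
WEAK_BLOCK_FACTOR = 0.6

#: NEFL NPX distribution: location/scale chosen so that roughly a quarter of
#: patients fall above the 0.5 NPX cutoff, as in the study cohort.
NEFL_LOC = 0.0
NEFL_SCALE = 0.75
NEFL_NPX_CUTOFF = 0.5

#: Marginal category probabilities emulating the study cohort.
P_FEMALE = 0.585
P_EPILEPSY_TYPE = {"focal": 0.477, "generalized": 0.278, "unknown": 0.245}
P_SEIZURE_STATUS = {"seizure_free": 0.50, "recent": 0.40, "intermediate": 0.10}
P_N_ASM = {0: 0.09, 1: 0.557, 2: 0.233, 3: 0.119}  # 3 means "3 or more"

FIXTURE_NAMES = (
    "seizure_status",
    "epilepsy_type",
    "gender",
    "epilepsy_status",
    "n_asm",
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticParams:
    n_patients: int = 176
    n_proteins: int = 1447
    pi_block_symbols: tuple[str, ...] = PI_PROTEINS
    rho_block: float = 0.4
    rho_nefl: float = 0.1
    bbb_shift: float = 1.0
    outcome_odds: float = 4.0
    seed: int = 0
    n_qc_fail: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_block < 1:
            raise SyntheticError("rho_block must be in [0, 1)")
        if not abs(self.rho_nefl) < 1:
            raise SyntheticError("|rho_nefl| must be < 1")
        if self.n_patients < 8:
            raise SyntheticError("n_patients must be >= 8")
        if len(self.pi_block_symbols) != 12:
            raise SyntheticError("pi_block_symbols must list 12 proteins")
        n_named = len(self.pi_block_symbols) + 1 + len(BBB_PROTEINS)
        if self.n_proteins < n_named:
            raise SyntheticError(
                f"n_proteins must be >= {n_named} to hold the named proteins"
            )
        if self.outcome_odds <= 0:
            raise SyntheticError("outcome_odds must be positive")
        if not 0 <= self.n_qc_fail < self.n_proteins:
            raise SyntheticError("n_qc_fail must be in [0, n_proteins)")


# ---------------------------------------------------------------------------
# latent structure shared by the clinical and NPX generators


def _block_loadings(params: SyntheticParams) -> np.ndarray:
    base = np.sqrt(params.rho_block)
    return np.array(
        [
            base * WEAK_BLOCK_FACTOR if s in WEAK_BLOCK_MEMBERS else base
            for s in params.pi_block_symbols
        ]
    )


def _nefl_loading(params: SyntheticParams) -> float:
    """Solve the NEFL factor loading for the target Spearman correlation.

    The composite score is (approximately) the standardized sum
    S = sum_p (a_p u + sqrt(1 - a_p^2) eps_p), so corr(u, S) =
    sum(a) / sqrt(var S).  For a bivariate normal pair, Spearman rho_s and
    Pearson rho relate by rho = 2 sin(pi rho_s / 6); the NEFL loading lam
    then satisfies lam * corr(u, S) = rho.
    """
    a = _block_loadings(params)
    sum_a = a.sum()
    if sum_a == 0:  # independent block: the score carries no factor signal
        return 0.0
    var_s = sum_a**2 + np.sum(1 - a**2)
    corr_u_s = sum_a / np.sqrt(var_s)
    pearson_target = 2.0 * np.sin(np.pi * params.rho_nefl / 6.0)
    lam = pearson_target / corr_u_s
    return float(np.clip(lam, -0.99, 0.99))


def _latents(params: SyntheticParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent inflammation factor u, NEFL NPX, and high-high indicator.

    Drawn from a dedicated seed stream so the clinical and NPX generators
    agree on patient-level latent state without sharing a generator.
    """
    ss_latent, _, _ = np.random.SeedSequence(params.seed).spawn(3)
    rng = np.random.default_rng(ss_latent)
    u = rng.standard_normal(params.n_patients)
    e = rng.standard_normal(params.n_patients)
    lam = _nefl_loading(params)
    nefl_z = lam * u + np.sqrt(1.0 - lam**2) * e
    nefl_npx = NEFL_LOC + NEFL_SCALE * nefl_z
    high_high = (u > stats.norm.ppf(0.6)) & (nefl_npx > NEFL_NPX_CUTOFF)
    return u, nefl_npx, high_high


def _highhigh_probability(params: SyntheticParams) -> float:
    """P(u above its 60th percentile and NEFL above the cutoff), analytic."""
    lam = _nefl_loading(params)
    a = stats.norm.ppf(0.6)
    b = (NEFL_NPX_CUTOFF - NEFL_LOC) / NEFL_SCALE
    bvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, lam], [lam, 1]])
    return float(1 - stats.norm.cdf(a) - stats.norm.cdf(b) + bvn.cdf([a, b]))


def _tilted_probs(
    base: dict, tilted_levels: set, odds: float, p_high: float
) -> tuple[dict, dict]:
    """Per-stratum category probabilities preserving the cohort marginal.

    High-high patients get the odds of ``tilted_levels`` multiplied by
    ``odds``; the remaining patients get compensated probabilities so that
    the mixture reproduces ``base`` exactly (clipped at zero and
    renormalized if the tilt is too extreme for the requested marginal).
    """
    levels = list(base)
    w = np.array([base[l] * (odds if l in tilted_levels else 1.0) for l in levels])
    p_hh = w / w.sum()
    p_rest = np.array([(base[l] - p_high * p) for l, p in zip(levels, p_hh)])
    p_rest = np.clip(p_rest / max(1.0 - p_high, 1e-12), 0.0, None)
    p_rest = p_rest / p_rest.sum()
    return dict(zip(levels, p_hh)), dict(zip(levels, p_rest))


# ---------------------------------------------------------------------------
# generators


def generate_clinical(params: SyntheticParams) -> pd.DataFrame:
    """Simulate the per-patient covariate table.

    Ages uniform on 18-50 years; gender, epilepsy type, seizure status and
    ASM count follow the configured marginals; patients in the latent
    high-high stratum carry ``outcome_odds``-fold odds of recent seizures
    and of being on >= 2 medications (the combination that downstream rules
    classify as drug-resistant epilepsy).
    """
    _, _, high_high = _latents(params)
    p_high = _highhigh_probability(params)
    _, ss_clin, _ = np.random.SeedSequence(params.seed).spawn(3)
    rng = np.random.default_rng(ss_clin)
    n = params.n_patients

    status_hh, status_rest = _tilted_probs(
        P_SEIZURE_STATUS, {"recent"}, params.outcome_odds, p_high
    )
    asm_hh, asm_rest = _tilted_probs(
        P_N_ASM, {2, 3}, params.outcome_odds, p_high
    )

    age = rng.integers(18, 51, size=n)
    gender = np.where(rng.random(n) < P_FEMALE, "female", "male")
    etype = rng.choice(
        list(P_EPILEPSY_TYPE), size=n, p=list(P_EPILEPSY_TYPE.values())
    )

    status = np.empty(n, dtype=object)
    n_asm = np.empty(n, dtype=int)
    for i in range(n):
        sp = status_hh if high_high[i] else status_rest
        status[i] = rng.choice(list(sp), p=list(sp.values()))
        ap = asm_hh if high_high[i] else asm_rest
        cat = int(rng.choice(list(ap), p=list(ap.values())))
        n_asm[i] = cat if cat < 3 else int(rng.choice([3, 4, 5], p=[0.6, 0.3, 0.1]))

    days = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for i, s in enumerate(status):
        if s == "recent":
            days[i] = rng.integers(0, 62)
            counts[i] = min(int(rng.exponential(6.0)) + 1, 98)
        elif s == "intermediate":
            days[i] = rng.integers(62, 366)
        else:  # seizure-free: > 1 year ago, or never (missing)
            if rng.random() < 0.8:
                days[i] = rng.integers(366, 2001)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "age": age,
            "gender": gender,
            "epilepsy_type": etype,
            "days_since_last_seizure": days,
            "seizure_count_2mo": counts,
            "n_asm": n_asm,
        }
    )


def _protein_roster(params: SyntheticParams) -> list[str]:
    named = list(params.pi_block_symbols) + [NEFL_SYMBOL] + list(BBB_PROTEINS)
    n_other = params.n_proteins - len(named)
    return named + [f"PROT{i + 1:04d}" for i in range(n_other)]


def generate_npx(clinical: pd.DataFrame, params: SyntheticParams) -> NPXMatrix:
    """Simulate the samples x proteins NPX matrix for a clinical table.

    The 12 block proteins share the latent inflammation factor; NEFL is
    coupled to it with the loading solved in :func:`_nefl_loading`; the
    BBB proteins are pure noise plus the planted ``bbb_shift`` for latent
    high-high patients; 50 of the remaining proteins load weakly (0.2) on
    the factor and the rest are independent noise.
    """
    if clinical.empty:
        raise SyntheticError("clinical table is empty")
    if len(clinical) != params.n_patients:
        raise SyntheticError(
            f"clinical table has {len(clinical)} rows, params expect "
            f"{params.n_patients}"
        )
    u, nefl_npx, high_high = _latents(params)
    _, _, ss_npx = np.random.SeedSequence(params.seed).spawn(3)
    rng = np.random.default_rng(ss_npx)
    n = params.n_patients
    roster = _protein_roster(params)
    missing = set(params.pi_block_symbols) - set(roster)
    if missing:
        raise SyntheticError(f"block symbols missing from protein set: {missing}")

    values = np.empty((n, len(roster)))
    loadings_block = _block_loadings(params)
    n_block = len(params.pi_block_symbols)

    # pro-inflammatory block: unit-variance factor structure, then an
    # arbitrary NPX location/scale (rank statistics are unaffected)
    eps = rng.standard_normal((n, n_block))
    block = loadings_block * u[:, None] + np.sqrt(1 - loadings_block**2) * eps
    loc = rng.uniform(1.0, 5.0, size=n_block)
    scale = rng.uniform(0.8, 1.2, size=n_block)
    values[:, :n_block] = loc + scale * block

    values[:, n_block] = nefl_npx

    # BBB markers: independent noise plus the planted stratum shift
    for j, _symbol in enumerate(BBB_PROTEINS):
        col = n_block + 1 + j
        base = rng.uniform(1.0, 5.0)
        values[:, col] = base + 0.5 * rng.standard_normal(n)
        values[high_high, col] += params.bbb_shift

    # background proteome: a weakly factor-loaded subset, then pure noise
    n_named = n_block + 1 + len(BBB_PROTEINS)
    n_other = len(roster) - n_named
    n_weak = min(50, n_other)
    other = rng.standard_normal((n, n_other))
    if n_weak:
        other[:, :n_weak] = 0.2 * u[:, None] + np.sqrt(1 - 0.04) * other[:, :n_weak]
    loc = rng.uniform(0.0, 6.0, size=n_other)
    scale = rng.uniform(0.4, 1.2, size=n_other)
    values[:, n_named:] = loc + scale * other

    data = pd.DataFrame(
        values, index=pd.Index(clinical["patient_id"], name="sample_id"),
        columns=roster,
    )
    panel = {}
    background = []
    for s in roster:
        if s in params.pi_block_symbols:
            panel[s] = "Inflammation_I"
        elif s in (NEFL_SYMBOL,) + BBB_PROTEINS:
            panel[s] = "Neurology_I"
        else:
            background.append(s)
    # deterministic round-robin for the background proteome
    for i, s in enumerate(background):
        panel[s] = DEFAULT_PANELS[i % len(DEFAULT_PANELS)]
    qc_pass = np.ones(len(roster), dtype=bool)
    if params.n_qc_fail:
        qc_pass[-params.n_qc_fail :] = False
    meta = pd.DataFrame(
        {
            "panel": [panel[s] for s in roster],
            "assay_id": [f"OID{i + 1:05d}" for i in range(len(roster))],
            "qc_pass": qc_pass,
        },
        index=pd.Index(roster, name="protein_symbol"),
    )
    return NPXMatrix(data=data, assay_meta=meta)


def latent_high_high(params: SyntheticParams) -> np.ndarray:
    """Boolean indicator of the planted high-high stratum, per patient."""
    return _latents(params)[2]


# ---------------------------------------------------------------------------
# long-format export (the dialect npx_io reads)


def write_long_csv(
    matrix: NPXMatrix,
    path: str | Path,
    duplicate_symbols: tuple[str, ...] = ("TNF", "IL6", "CXCL8"),
    duplicate_panel: str = "Neurology_I",
    duplicate_offset: float = -0.5,
) -> None:
    """Write a long-format Olink-style CSV.

    ``duplicate_symbols`` get a second, lower-expression copy on
    ``duplicate_panel`` — emulating assays measured on two panels — so the
    panel-merging step has real work to do on simulated exports.
    """
    rows = []
    for symbol in matrix.protein_symbols:
        meta = matrix.assay_meta.loc[symbol]
        qc = "PASS" if meta["qc_pass"] else "WARN"
        for sample, value in matrix.data[symbol].items():
            rows.append(
                (sample, symbol, meta["assay_id"], meta["panel"], value, qc)
            )
        if symbol in duplicate_symbols and meta["panel"] != duplicate_panel:
            for sample, value in matrix.data[symbol].items():
                rows.append(
                    (
                        sample,
                        symbol,
                        f"{meta['assay_id']}-DUP",
                        duplicate_panel,
                        value + duplicate_offset,
                        qc,
                    )
                )
    pd.DataFrame(
        rows, columns=["SampleID", "Assay", "OlinkID", "Panel", "NPX", "QC_Warning"]
    ).to_csv(path, index=False)


def write_simulation(out_dir: str | Path, params: SyntheticParams) -> dict:
    """Simulate a cohort and write npx_long.csv + clinical.csv to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clinical = generate_clinical(params)
    matrix = generate_npx(clinical, params)
    npx_path = out_dir / "npx_long.csv"
    clin_path = out_dir / "clinical.csv"
    write_long_csv(matrix, npx_path)
    clinical.to_csv(clin_path, index=False)
    return {"npx": str(npx_path), "clinical": str(clin_path)}


# ---------------------------------------------------------------------------
# packaged contingency-table fixtures


def fixture_tables() -> dict[str, pd.DataFrame]:
    """The five quadrant x category contingency tables of the source cohort.

    Row labels are the four quadrants (High-Low, High-High, Normal-High,
    Normal-Low; NEFL class first, inflammation band second); every table
    totals the 139 quadrant-classified patients.
    """
    tables = {}
    for name in FIXTURE_NAMES:
        with resources.files("quadstrat.data").joinpath(
            f"table3_{name}.csv"
        ).open() as fh:
            tables[name] = pd.read_csv(fh, index_col="quadrant")
    return tables
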