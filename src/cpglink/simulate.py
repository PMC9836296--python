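"""Synthetic cohorts with known mediation/moderation structure.

The generator mirrors the linear models the analysis fits, so every
downstream stage has a ground-truth test surface:

    exposure  X  ~ shifted gamma, truncated to the CTQ range [25, 125]
    methylation  M_j = mu_j + a_j (X - X_mean) + covariate terms
                       + region latent + N(0, sd_j),   clipped to [0, 100]
    outcome   Y = intercept + c' (X - X_mean) + sum_j b_j (M_j - mu_j)
                  + sum_j omega_j (X - X_mean)(M_j - mu_j)
                  + covariate terms + N(0, outcome_sd), clipped to [0, 63]

Interaction terms are generated on centered scales so the direct effect c'
keeps its main-effect meaning under the centered fitting convention.
Duplicate units are exact copies; region blocks share a latent factor and
adjacent coordinates; missingness is applied completely at random per unit,
after the outcome is computed from the complete latent methylation.

The default truth emulates the study the pipeline was designed around:
n = 156 men, 191 CpG units across 9 stress-related candidate genes, CTQ
mean 37.43 / SD 11.04, BDI-II mean 10.48 / SD 8.79, two mediating units
with opposite-signed exposure paths, and fourteen moderating units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AnalysisConfig, Cohort, CpGUnit, MethylationMatrix

__all__ = ["CovariateEffect", "SimulationTruth", "default_truth", "generate_cohort", "inject_outliers"]


@dataclass(frozen=True)
class CovariateEffect:
    """Planted slopes of one covariate on methylation units and on the outcome."""

    on_methylation: dict[str, float] = field(default_factory=dict)  # unit_id -> % per covariate unit
    on_outcome: float = 0.0  # BDI points per covariate unit


@dataclass
class SimulationTruth:
    """Planted structural coefficients and noise scales for one cohort draw.

    Per-unit dictionaries default to 0 (or to scalar fallbacks) for units
    they do not mention.  Units named in ``duplicate_map`` are generated as
    exact copies of their source; units grouped in ``region_map`` share a
    Gaussian latent factor of the given SD.
    """

    n_participants: int
    units: list[CpGUnit]
    a: dict[str, float] = field(default_factory=dict)            # % methylation per CTQ point
    b: dict[str, float] = field(default_factory=dict)            # BDI points per % methylation
    omega: dict[str, float] = field(default_factory=dict)        # BDI per CTQ point per %
    c_prime: float = 0.0                                          # direct effect, BDI per CTQ point
    outcome_intercept: float = 10.48
    unit_mean: dict[str, float] = field(default_factory=dict)
    unit_sd: dict[str, float] = field(default_factory=dict)
    default_unit_mean: float = 50.0
    default_unit_sd: float = 2.0
    outcome_sd: float = 8.0
    cov_effects: dict[str, CovariateEffect] = field(default_factory=dict)
    exposure_mean: float = 37.43
    exposure_sd: float = 11.04
    missing_frac: float | dict[str, float] = 0.0
    duplicate_map: dict[str, str] = field(default_factory=dict)   # copy unit -> source unit
    region_map: dict[str, tuple[list[str], float]] = field(default_factory=dict)
    round_outcome: bool = False

    def __post_init__(self) -> None:
        ids = {u.unit_id for u in self.units}
        if len(ids) != len(self.units):
            raise ValueError("duplicate unit_id in truth.units")
        for d in (self.a, self.b, self.omega, self.unit_mean, self.unit_sd):
            unknown = set(d) - ids
            if unknown:
                raise ValueError(f"truth references unknown units: {sorted(unknown)}")
        for dup, src in self.duplicate_map.items():
            if dup not in ids or src not in ids:
                raise ValueError(f"duplicate_map references unknown units: {dup!r} -> {src!r}")
            if dup == src:
                raise ValueError("duplicate_map maps a unit to itself")
        for name, (members, latent_sd) in self.region_map.items():
            if set(members) - ids:
                raise ValueError(f"region {name!r} references unknown units")
            if latent_sd < 0:
                raise ValueError("region latent SD must be >= 0")
        if self.exposure_sd < 0 or self.outcome_sd < 0:
            raise ValueError("SDs must be >= 0")
        fracs = (
            self.missing_frac.values()
            if isinstance(self.missing_frac, dict)
            else [self.missing_frac]
        )
        if any(not (0 <= f < 1) for f in fracs):
            raise ValueError("missing_frac must lie in [0, 1)")

    # -- per-unit lookups with defaults -----------------------------------
    def mean_of(self, unit_id: str) -> float:
        return self.unit_mean.get(unit_id, self.default_unit_mean)

    def sd_of(self, unit_id: str) -> float:
        return self.unit_sd.get(unit_id, self.default_unit_sd)

    def missing_of(self, unit_id: str) -> float:
        if isinstance(self.missing_frac, dict):
            return self.missing_frac.get(unit_id, 0.0)
        return self.missing_frac


# ---------------------------------------------------------------------------
# Default truth: the study conditions
# ---------------------------------------------------------------------------

# Candidate-gene panel: (chrom, first CpG coordinate, number of units).
# Unit counts follow the per-gene totals of the assay panel (191 units).
_GENE_PANEL = {
    "COMT": ("chr22", 19950000, 12),
    "FKBP5": ("chr6", 35558000, 25),
    "IL6": ("chr7", 22764000, 10),
    "IL10": ("chr1", 206939900, 12),
    "MAOA": ("chrX", 43515000, 20),
    "NR3C1": ("chr5", 142782000, 34),
    "OXTR": ("chr3", 8810000, 20),
    "SLC6A3": ("chr5", 1446000, 27),
    "SLC6A4": ("chr17", 28562000, 31),
}

#: Two mediating units with opposite-signed exposure paths: a * b sums to
#: ~0.038 BDI per CTQ point, so with c' = 0.21 the total effect is ~0.25
#: and the proportion mediated ~16%.
_MEDIATOR_TRUTH = {
    "NR3C1_1_CpG_10": (0.04, 0.47),
    "SLC6A3_1_CpG_16": (-0.05, -0.39),
}

#: Fourteen moderating units, mixed orientations (8 positive, 6 negative).
_MODERATOR_TRUTH = {
    "FKBP5_1_CpG_3": 0.022,
    "FKBP5_1_CpG_4": 0.024,
    "IL10_1_CpG_5": -0.043,
    "IL10_1_CpG_6": -0.032,
    "MAOA_1_CpG_1": 0.025,
    "NR3C1_1_CpG_5": -0.030,
    "NR3C1_1_CpG_23": -0.026,
    "NR3C1_1_CpG_8": 0.030,
    "SLC6A3_1_CpG_7": -0.026,
    "SLC6A3_1_CpG_20": -0.025,
    "SLC6A3_1_CpG_27": -0.029,
    "SLC6A4_1_CpG_13": 0.025,
    "SLC6A4_1_CpG_23": 0.021,
    "SLC6A4_1_CpG_31": 0.026,
}


def default_truth(n_participants: int = 156, seed: int = 20230112) -> SimulationTruth:
    """The default study conditions: 191-unit panel with planted effects.

    Per-unit baselines (means 5-85%, SDs 1-4%) are drawn once from ``seed``,
    which parameterizes the *truth*, not a cohort draw; the same seed always
    yields the same truth.  Age and drug consumption carry planted effects on
    several units and on the outcome (so confounder selection has structure
    to find); smoking, alcohol and BMI are generated null.
    """
    rng = np.random.default_rng(seed)
    units: list[CpGUnit] = []
    for gene, (chrom, start, n_units) in _GENE_PANEL.items():
        for k in range(1, n_units + 1):
            pos = start + 30 * (k - 1)
            units.append(CpGUnit(f"{gene}_1_CpG_{k}", gene, chrom, (pos,)))
    unit_ids = [u.unit_id for u in units]

    unit_mean = {u: float(m) for u, m in zip(unit_ids, rng.uniform(5, 85, len(unit_ids)))}
    unit_sd = {u: float(s) for u, s in zip(unit_ids, rng.uniform(1.0, 4.0, len(unit_ids)))}
    for uid in list(_MEDIATOR_TRUTH) + list(_MODERATOR_TRUTH):
        unit_sd[uid] = 2.0  # planted units at the panel-typical noise scale

    a = {u: av for u, (av, _) in _MEDIATOR_TRUTH.items()}
    b = {u: bv for u, (_, bv) in _MEDIATOR_TRUTH.items()}

    age_meth = {u: 0.08 for u in list(unit_ids)[::12]}  # age drifts ~16 scattered units
    drug_meth = {u: 1.5 for u in list(unit_ids)[5::25]}
    cov_effects = {
        "age": CovariateEffect(on_methylation=age_meth, on_outcome=-0.15),
        "drug_use": CovariateEffect(on_methylation=drug_meth, on_outcome=2.0),
    }
    return SimulationTruth(
        n_participants=n_participants,
        units=units,
        a=a,
        b=b,
        omega=dict(_MODERATOR_TRUTH),
        c_prime=0.21,
        unit_mean=unit_mean,
        unit_sd=unit_sd,
        outcome_sd=8.0,
        cov_effects=cov_effects,
        missing_frac=0.02,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _draw_truncated_shifted_gamma(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Right-skewed scores with floor ``lo``: lo + Gamma, rejection-truncated to [lo, hi]."""
    mu = mean - lo
    if mu <= 0 or sd == 0:
        return np.full(n, mean, dtype=float).clip(lo, hi)
    shape = (mu / sd) ** 2
    scale = sd**2 / mu
    out = lo + rng.gamma(shape, scale, size=n)
    bad = out > hi
    while bad.any():
        out[bad] = lo + rng.gamma(shape, scale, size=int(bad.sum()))
        bad = out > hi
    return out


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(24.06, 3.70, n), 18, 35)
    return pd.DataFrame(
        {
            "age": age,
            "drug_use": rng.binomial(1, 0.30, n).astype(float),
            "smoking": rng.binomial(1, 0.25, n).astype(float),
            "alcohol": rng.poisson(2.0, n).astype(float),
            "bmi": np.clip(rng.normal(24.5, 3.5, n), 16, 45),
        }
    )


def generate_cohort(
    truth: SimulationTruth, seed: int, config: AnalysisConfig | None = None
) -> Cohort:
    """Draw one cohort from ``truth``; identical ``truth`` + ``seed`` give a
    bit-identical cohort.

    Clipping at the score/percent bounds is accounted per variable in
    ``cohort.meta["clipped_frac"]``; a truth that clips more than half of a
    variable's values triggers a "degenerate truth" warning, surfaced in the
    run summary.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_participants
    ids = [f"P{i:04d}" for i in range(1, n + 1)]

    x = _draw_truncated_shifted_gamma(
        rng, n, truth.exposure_mean, truth.exposure_sd, 25.0, 125.0
    )
    xc = x - truth.exposure_mean
    cov = _draw_covariates(rng, n)
    cov_centered = cov - cov.mean(axis=0)

    region_latent: dict[str, np.ndarray] = {}
    unit_latent_term: dict[str, np.ndarray] = {}
    for name, (members, latent_sd) in truth.region_map.items():
        z = rng.normal(0.0, latent_sd, n)
        region_latent[name] = z
        for uid in members:
            unit_latent_term[uid] = unit_latent_term.get(uid, 0.0) + z

    clipped: dict[str, float] = {}
    meth = np.empty((n, len(truth.units)))
    col_of = {u.unit_id: j for j, u in enumerate(truth.units)}
    for j, unit in enumerate(truth.units):
        uid = unit.unit_id
        if uid in truth.duplicate_map:
            continue  # filled after sources exist
        m = (
            truth.mean_of(uid)
            + truth.a.get(uid, 0.0) * xc
            + unit_latent_term.get(uid, 0.0)
            + rng.normal(0.0, truth.sd_of(uid), n)
        )
        for cov_name, eff in truth.cov_effects.items():
            slope = eff.on_methylation.get(uid, 0.0)
            if slope:
                m = m + slope * cov_centered[cov_name].to_numpy()
        frac = float(np.mean((m < 0) | (m > 100)))
        clipped[uid] = frac
        meth[:, j] = np.clip(m, 0.0, 100.0)
    for dup, src in truth.duplicate_map.items():
        meth[:, col_of[dup]] = meth[:, col_of[src]]
        clipped[dup] = clipped[src]

    y = np.full(n, truth.outcome_intercept) + truth.c_prime * xc
    for uid, bj in truth.b.items():
        y = y + bj * (meth[:, col_of[uid]] - truth.mean_of(uid))
    for uid, wj in truth.omega.items():
        y = y + wj * xc * (meth[:, col_of[uid]] - truth.mean_of(uid))
    for cov_name, eff in truth.cov_effects.items():
        if eff.on_outcome:
            y = y + eff.on_outcome * cov_centered[cov_name].to_numpy()
    y = y + rng.normal(0.0, truth.outcome_sd, n)
    clipped["depression"] = float(np.mean((y < 0) | (y > 63)))
    y = np.clip(y, 0.0, 63.0)
    if truth.round_outcome:
        y = np.round(y)

    degenerate = sorted(k for k, f in clipped.items() if f > 0.5)
    if degenerate:
        warnings.warn(
            f"degenerate truth: >50% of values clipped for {degenerate}", stacklevel=2
        )

    # MCAR missingness, after the outcome used the complete latent methylation
    for j, unit in enumerate(truth.units):
        frac = truth.missing_of(unit.unit_id)
        if frac > 0:
            mask = rng.random(n) < frac
            meth[mask, j] = np.nan

    phenotypes = pd.DataFrame({"participant_id": ids, "maltreatment": x, "depression": y})
    phenotypes = pd.concat([phenotypes, cov], axis=1)
    matrix = MethylationMatrix(
        pd.DataFrame(meth, index=pd.Index(ids, name="participant_id"),
                     columns=[u.unit_id for u in truth.units]),
        truth.units,
    )
    cfg = config if config is not None else AnalysisConfig(rng_seed=int(seed))
    meta = {
        "generator_seed": int(seed),
        "clipped_frac": clipped,
        "degenerate_truth": degenerate,
    }
    return Cohort(phenotypes, matrix, cfg, meta)


def inject_outliers(
    cohort: Cohort, field_name: str, values: list[float], ids: list[str]
) -> Cohort:
    """Return a copy of ``cohort`` with raw phenotype values substituted.

    Used to plant known extremes that downstream winsorization must catch;
    the original cohort is untouched.
    """
    if len(values) != len(ids):
        raise ValueError("values and ids must have equal length")
    if field_name not in cohort.phenotypes.columns:
        raise KeyError(f"unknown phenotype field {field_name!r}")
    unknown = [i for i in ids if i not in cohort.phenotypes.index]
    if unknown:
        raise KeyError(f"unknown participant ids: {unknown}")
    ph = cohort.phenotypes.copy()
    for pid, v in zip(ids, values):
        ph.loc[pid, field_name] = v
    return Cohort(ph, cohort.methylation, cohort.config, dict(cohort.meta))
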