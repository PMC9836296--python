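"""Exposure x methylation interaction models, simple slopes, and the
tertile-signed cumulative methylation risk score.

The moderation model mean-centers the exposure and the moderator on the
analysis sample, forms the product term after centering, and fits OLS
(optionally with covariates):

    Y = i + b_x Xc + b_m Mc + b_xm Xc*Mc + (covariates) + e

With centered inputs the conditional exposure->outcome slope at moderator
level m (on the centered scale) is b_x + b_xm * m, with standard error from
the coefficient covariance; simple slopes default to the moderator mean
+- 1 SD.  Units whose interaction reaches significance feed a cumulative
risk score: each unit's methylation is cut at empirical tertiles and scored
-1/0/+1, oriented by the interaction sign, then summed across units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, InsufficientDataError, MethylationMatrix

__all__ = [
    "ModerationResult",
    "RiskScore",
    "fit_moderation",
    "simple_slopes",
    "build_risk_score",
    "moderate_cumulative",
]


@dataclass(frozen=True)
class ModerationResult:
    """Interaction coefficient, model stats, and machinery for simple slopes."""

    b_interaction: float   # outcome units per exposure unit per moderator unit
    se: float
    p: float
    b_exposure: float      # conditional slope at the moderator mean (centered 0)
    r2: float
    F: float
    df: tuple[int, int]
    n: int
    moderator_sd: float
    moderator_range: tuple[float, float]   # centered scale
    slopes: pd.DataFrame                   # default levels: mean +- 1 SD
    _cov: np.ndarray = field(repr=False, default=None)  # 2x2 cov of (b_x, b_xm)

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)


def fit_moderation(
    exposure,
    moderator,
    outcome,
    covariates: pd.DataFrame | None = None,
    slope_sd_offset: float = 1.0,
    alpha: float = 0.05,
) -> ModerationResult:
    """Centered interaction model with default simple slopes at mean +- 1 SD."""
    df = pd.DataFrame(
        {
            "exposure": np.asarray(exposure, dtype=float),
            "moderator": np.asarray(moderator, dtype=float),
            "outcome": np.asarray(outcome, dtype=float),
        }
    )
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        cov.columns = [str(c) for c in cov.columns]
        df = pd.concat([df, cov], axis=1)
    df = df.dropna().reset_index(drop=True)
    n = len(df)
    if n < 10:
        raise InsufficientDataError(f"moderation needs >= 10 complete cases, got {n}")
    xc = df["exposure"] - df["exposure"].mean()
    mc = df["moderator"] - df["moderator"].mean()
    design = pd.DataFrame({"exposure_c": xc, "moderator_c": mc, "interaction": xc * mc})
    cov_cols = [c for c in df.columns if c not in ("exposure", "moderator", "outcome")]
    for c in cov_cols:
        design[c] = df[c] - df[c].mean()
    design = sm.add_constant(design, has_constant="add")
    fit = sm.OLS(df["outcome"], design).fit()

    names = list(design.columns)
    cov_full = fit.cov_params().to_numpy()
    ix, ixm = names.index("exposure_c"), names.index("interaction")
    cov2 = cov_full[np.ix_([ix, ixm], [ix, ixm])]
    m_sd = float(mc.std(ddof=1))
    result = ModerationResult(
        b_interaction=float(fit.params["interaction"]),
        se=float(fit.bse["interaction"]),
        p=float(fit.pvalues["interaction"]),
        b_exposure=float(fit.params["exposure_c"]),
        r2=float(fit.rsquared),
        F=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        n=n,
        moderator_sd=m_sd,
        moderator_range=(float(mc.min()), float(mc.max())),
        slopes=pd.DataFrame(),
        _cov=cov2,
    )
    levels = pd.Series(
        {"low (-1 SD)": -slope_sd_offset * m_sd, "high (+1 SD)": slope_sd_offset * m_sd}
    )
    slopes = simple_slopes(result, levels)
    object.__setattr__(result, "slopes", slopes)
    return result


def simple_slopes(result: ModerationResult, levels) -> pd.DataFrame:
    """Conditional exposure->outcome slopes at centered moderator ``levels``.

    slope(m) = b_exposure + b_interaction * m, with SE from the coefficient
    covariance: Var = Var(b_x) + m^2 Var(b_xm) + 2 m Cov(b_x, b_xm); p-values
    are two-sided t-tests on the residual degrees of freedom.  Levels outside
    the observed (centered) moderator range are still computed, with a warning.
    """
    if isinstance(levels, pd.Series):
        names, values = list(levels.index), levels.to_numpy(dtype=float)
    else:
        values = np.asarray(list(levels), dtype=float)
        names = [f"m={v:g}" for v in values]
    lo, hi = result.moderator_range
    outside = [n for n, v in zip(names, values) if not lo <= v <= hi]
    if outside:
        warnings.warn(f"moderator level(s) outside observed range: {outside}")
    cov = result._cov
    rows = []
    for name, m in zip(names, values):
        slope = result.b_exposure + result.b_interaction * m
        var = cov[0, 0] + m**2 * cov[1, 1] + 2 * m * cov[0, 1]
        se = float(np.sqrt(max(var, 0.0)))
        if se > 0:
            t = slope / se
            p = 2 * stats.t.sf(abs(t), result.df[1])
        else:
            p = 0.0 if slope != 0 else 1.0
        rows.append(
            {"level": name, "moderator_value": float(m), "slope": float(slope),
             "se": se, "p": float(p)}
        )
    return pd.DataFrame(rows, columns=["level", "moderator_value", "slope", "se", "p"])


# ---------------------------------------------------------------------------
# Tertile risk score
# ---------------------------------------------------------------------------


@dataclass
class RiskScore:
    """Summed -1/0/+1 tertile scores across moderating units.

    Per unit, empirical tertile cutpoints (1/3 and 2/3 quantiles with linear
    interpolation) are computed on non-missing values; a participant scores
    -1/0/+1 by tertile with ties at a cutpoint assigned to the lower tertile.
    Positive interaction sign: top tertile = +1; negative sign flips the
    orientation.  A missing unit value contributes 0 and is counted.
    """

    scores: pd.Series                      # per-participant integer score
    cutpoints: dict[str, tuple[float, float]]
    signs: dict[str, int]
    units: list[str]
    n_missing: pd.Series                   # units missing per participant
    excluded: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.units)


def _tertile_codes(values: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    nonmiss = values.dropna().to_numpy()
    q1, q2 = np.quantile(nonmiss, [1 / 3, 2 / 3], method="linear")
    codes = pd.Series(0, index=values.index, dtype=int)
    codes[values <= q1] = -1
    codes[values > q2] = 1
    codes[values.isna()] = 0
    return codes, (float(q1), float(q2))


def build_risk_score(matrix: MethylationMatrix, moderating_units: pd.DataFrame) -> RiskScore:
    """Construct the cumulative tertile risk score.

    ``moderating_units`` needs columns ``unit_id`` and ``sign`` (the sign of
    each unit's interaction coefficient).  Units with fewer than 3 distinct
    non-missing values are excluded with a warning.
    """
    scores = pd.Series(0, index=matrix.values.index, dtype=int)
    n_missing = pd.Series(0, index=matrix.values.index, dtype=int)
    cutpoints: dict[str, tuple[float, float]] = {}
    signs: dict[str, int] = {}
    used: list[str] = []
    excluded: list[str] = []
    for row in moderating_units.itertuples(index=False):
        uid = row.unit_id
        if uid not in matrix.values.columns:
            raise KeyError(f"moderating unit {uid!r} not in matrix")
        col = matrix.values[uid]
        if col.dropna().nunique() < 3:
            warnings.warn(f"unit {uid!r} has < 3 distinct values; excluded from risk score")
            excluded.append(uid)
            continue
        sign = int(np.sign(row.sign)) or 1
        codes, cuts = _tertile_codes(col)
        scores = scores + sign * codes
        n_missing = n_missing + col.isna().astype(int)
        cutpoints[uid] = cuts
        signs[uid] = sign
        used.append(uid)
    return RiskScore(
        scores=scores, cutpoints=cutpoints, signs=signs, units=used,
        n_missing=n_missing, excluded=excluded,
    )


def moderate_cumulative(
    cohort: Cohort,
    risk_score: RiskScore,
    covariates: list[str] | None = None,
) -> ModerationResult:
    """Interaction model with the risk score as moderator; slopes at the mean
    score of each of three equal score groups (low/mid/high)."""
    cov_df = cohort.phenotypes[covariates].astype(float) if covariates else None
    score = risk_score.scores.reindex(cohort.participants).astype(float)
    result = fit_moderation(
        cohort.exposure().to_numpy(),
        score.to_numpy(),
        cohort.outcome().to_numpy(),
        covariates=cov_df,
    )
    centered = score - score.mean()
    q1, q2 = np.quantile(centered, [1 / 3, 2 / 3], method="linear")
    group = pd.Series("mid", index=centered.index)
    group[centered <= q1] = "low"
    group[centered > q2] = "high"
    levels = pd.Series(
        {f"{g} score group": float(centered[group == g].mean()) for g in ("low", "mid", "high")}
    )
    slopes = simple_slopes(result, levels)
    object.__setattr__(result, "slopes", slopes)
    return result
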