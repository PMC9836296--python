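"""Per-CpG linear screening, confounder selection and FDR correction.

Each CpG unit (and each derived region, as a separate family) is screened
with the methylation level as the dependent variable and the exposure
(childhood-maltreatment total) or the outcome (depressive-symptom total) as
the independent variable, unadjusted and covariate-adjusted.  Models use
ordinary least squares on complete cases; Benjamini-Hochberg adjustment is
applied within each screen family over the unit-level unadjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .cohort import (
    CollinearDesignError,
    Cohort,
    InsufficientDataError,
    MethylationMatrix,
    ValueDomainError,
)

__all__ = [
    "RegressionResult",
    "fit_linear",
    "screen_units",
    "select_confounders",
    "fdr_adjust",
    "r2_from_standardized_slope",
]


@dataclass(frozen=True)
class RegressionResult:
    """One fitted linear-model term: B, SE, p plus whole-model statistics."""

    term: str
    B: float
    SE: float
    p: float
    r2: float
    F: float
    df: tuple[int, int]  # (model, residual)
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _design_frame(predictors) -> pd.DataFrame:
    if isinstance(predictors, pd.DataFrame):
        return predictors.astype(float)
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in predictors.items()})


def fit_linear(y, predictors, focal: str) -> RegressionResult:
    """OLS with intercept on complete cases; reports the ``focal`` term.

    ``predictors`` is a DataFrame or a mapping of name -> vector.  Raises
    :class:`CollinearDesignError` naming the offending terms on rank
    deficiency and :class:`InsufficientDataError` when complete cases
    n < p + 2.
    """
    X = _design_frame(predictors)
    if focal not in X.columns:
        raise KeyError(f"focal term {focal!r} not among predictors {list(X.columns)}")
    yv = pd.Series(np.asarray(y, dtype=float), index=X.index, name="__y__")
    ok = yv.notna() & X.notna().all(axis=1)
    yv, X = yv[ok], X[ok]
    n, p = X.shape
    if n < p + 2:
        raise InsufficientDataError(f"need >= {p + 2} complete cases, got {n}")
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        raise CollinearDesignError(f"collinear design: constant predictor(s) {constant}")
    if np.ptp(yv.to_numpy()) == 0:
        raise CollinearDesignError("collinear design: zero-variance response")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        # identify columns linearly dependent on the preceding ones
        arr = design.to_numpy()
        offending = [
            design.columns[j]
            for j in range(1, arr.shape[1])
            if np.linalg.matrix_rank(arr[:, : j + 1]) == np.linalg.matrix_rank(arr[:, :j])
        ]
        raise CollinearDesignError(f"collinear design: dependent term(s) {offending}")
    fit = sm.OLS(yv, design).fit()
    return RegressionResult(
        term=focal,
        B=float(fit.params[focal]),
        SE=float(fit.bse[focal]),
        p=float(fit.pvalues[focal]),
        r2=float(fit.rsquared),
        F=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        n=int(n),
    )


def r2_from_standardized_slope(B: float, sd_x: float, sd_y: float) -> float:
    """R-squared implied by an unstandardized simple-regression slope.

    In simple regression R^2 = (B * SD_x / SD_y)^2, the squared standardized
    slope; useful for checking printed coefficients against printed R^2.
    """
    return (B * sd_x / sd_y) ** 2


# ---------------------------------------------------------------------------
# Unit screens
# ---------------------------------------------------------------------------

_SCREEN_COLUMNS = [
    "unit_id",
    "level",
    "B",
    "SE",
    "p",
    "r2",
    "F",
    "n",
    "B_adj",
    "SE_adj",
    "p_adj_model",
    "r2_adj",
    "F_adj",
    "n_adj",
    "fdr_p",
    "significant_unadjusted",
    "significant_adjusted",
    "error",
]


def screen_units(
    cohort: Cohort,
    response_side: str,
    covariates: list[str] | None = None,
    regions: MethylationMatrix | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Screen every unit (and optionally every region) against one phenotype.

    ``response_side`` is ``"exposure"`` (methylation ~ maltreatment) or
    ``"outcome"`` (methylation ~ depression); methylation is always the
    dependent variable.  Returns one row per unit with unadjusted and
    adjusted focal statistics, a BH-FDR column over the unit-level
    unadjusted p-values, and significance flags at ``alpha`` (default:
    cohort config ``screen_alpha``).  Regions form a separate FDR family.
    Per-unit fit failures are recorded in the ``error`` column, not raised.
    """
    if response_side not in ("exposure", "outcome"):
        raise ValueError("response_side must be 'exposure' or 'outcome'")
    alpha = cohort.config.screen_alpha if alpha is None else alpha
    predictor = (
        cohort.exposure() if response_side == "exposure" else cohort.outcome()
    )
    pred_name = "maltreatment" if response_side == "exposure" else "depression"
    covariates = covariates or []
    cov_df = cohort.phenotypes[covariates].astype(float) if covariates else None

    def _screen_level(matrix: MethylationMatrix, level: str) -> pd.DataFrame:
        rows = []
        for uid in matrix.unit_ids:
            m = matrix.values[uid]
            row: dict = {"unit_id": uid, "level": level, "error": ""}
            base = pd.DataFrame({pred_name: predictor})
            try:
                res = fit_linear(m, base, focal=pred_name)
                row.update(
                    B=res.B, SE=res.SE, p=res.p, r2=res.r2, F=res.F, n=res.n
                )
            except (CollinearDesignError, InsufficientDataError) as exc:
                row["error"] = str(exc)
            if cov_df is not None and not row["error"]:
                try:
                    res_a = fit_linear(m, pd.concat([base, cov_df], axis=1), focal=pred_name)
                    row.update(
                        B_adj=res_a.B,
                        SE_adj=res_a.SE,
                        p_adj_model=res_a.p,
                        r2_adj=res_a.r2,
                        F_adj=res_a.F,
                        n_adj=res_a.n,
                    )
                except (CollinearDesignError, InsufficientDataError) as exc:
                    row["error"] = str(exc)
            rows.append(row)
        table = pd.DataFrame(rows).reindex(columns=_SCREEN_COLUMNS)
        ok = table["p"].notna()
        if ok.any():
            table.loc[ok, "fdr_p"] = fdr_adjust(table.loc[ok, "p"].to_list())
        table["significant_unadjusted"] = table["p"] < alpha
        table["significant_adjusted"] = (
            table["p_adj_model"] < alpha
            if cov_df is not None
            else table["significant_unadjusted"]
        )
        return table

    out = _screen_level(cohort.methylation, "unit")
    if regions is not None and regions.unit_ids:
        out = pd.concat(
            [out, _screen_level(regions, "region")], ignore_index=True
        )
    return out


# ---------------------------------------------------------------------------
# Confounder selection
# ---------------------------------------------------------------------------


def select_confounders(
    cohort: Cohort,
    candidates: list[str],
    alpha: float | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Retain candidates with a simple-regression p < alpha against the
    exposure, the outcome, or at least one methylation unit.

    Returns (retained names, log of qualifying associations).  A candidate
    with no variation (e.g. a one-level binary) is excluded with a warning.
    """
    alpha = cohort.config.confounder_alpha if alpha is None else alpha
    retained: list[str] = []
    log_rows: list[dict] = []
    for cand in candidates:
        if cand not in cohort.phenotypes.columns:
            raise KeyError(f"candidate confounder {cand!r} not in phenotype table")
        c = cohort.phenotypes[cand].astype(float)
        if c.dropna().nunique() < 2:
            warnings.warn(f"candidate {cand!r} has a single level; excluded")
            continue
        hits: list[tuple[str, float]] = []
        for target_name, target in (
            ("maltreatment", cohort.exposure()),
            ("depression", cohort.outcome()),
        ):
            try:
                res = fit_linear(target, {cand: c}, focal=cand)
            except (CollinearDesignError, InsufficientDataError):
                continue
            if res.p < alpha:
                hits.append((target_name, res.p))
        for uid in cohort.methylation.unit_ids:
            try:
                res = fit_linear(cohort.methylation.values[uid], {cand: c}, focal=cand)
            except (CollinearDesignError, InsufficientDataError):
                continue
            if res.p < alpha:
                hits.append((uid, res.p))
        if hits:
            retained.append(cand)
            for target_name, p in hits:
                log_rows.append({"candidate": cand, "associated_with": target_name, "p": p})
    log = pd.DataFrame(log_rows, columns=["candidate", "associated_with", "p"])
    return retained, log


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueDomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
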