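"""Screening-gated causal mediation with Monte-Carlo interval estimation.

The estimator follows the classic two-model decomposition for linear
models without exposure-mediator interaction:

    (1)  M = i1 + a X + (covariates)            -> a-path
    (2)  Y = i2 + c' X + b M + (covariates)     -> b-path, direct effect

ACME (average causal mediation effect, the indirect effect) is a*b, the
direct effect (ADE) is c', and the total effect is a*b + c'.  Uncertainty
is quantified quasi-Bayesianly: ``n_sims`` coefficient vectors are drawn
from the multivariate-normal sampling distribution of each fitted model,
and per draw indirect/direct/total effects are recomputed; 95% intervals
are percentile intervals over the draws.  A case-resampling bootstrap mode
is provided for sensitivity.

Mediation is only run for units whose associations with both the exposure
and the outcome passed the screen, and for the cumulative methylation
index summed over those units (sign-aligned by default, so units whose
exposure associations have opposite signs reinforce rather than cancel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort, InsufficientDataError, MethylationMatrix, ValueDomainError
from .screen import RegressionResult, fit_linear

__all__ = [
    "MediationResult",
    "select_mediation_candidates",
    "fit_mediation",
    "build_mediator_index",
    "mediate_cumulative",
    "proportion_mediated",
]

_TOTAL_EPS = 1e-8  # draws with |total| below this are excluded from the ratio CI


def proportion_mediated(acme: float, total: float) -> float:
    """Indirect effect as a fraction of the total effect (ACME / total)."""
    if abs(total) < _TOTAL_EPS:
        raise ZeroDivisionError("total effect is numerically zero")
    return acme / total


@dataclass(frozen=True)
class MediationResult:
    """Point estimates, percentile CIs and component fits for one mediator."""

    acme: float                      # indirect effect, outcome units per exposure unit
    ade: float                       # direct effect c'
    total: float
    prop_mediated: float
    ci_acme: tuple[float, float]
    ci_ade: tuple[float, float]
    ci_total: tuple[float, float]
    ci_prop: tuple[float, float]
    p_acme: float
    n_sims: int
    a_path: RegressionResult
    b_path: RegressionResult
    n: int
    method: str = "quasi-bayesian"
    n_ratio_excluded: int = 0        # draws dropped from the ratio CI (|total| ~ 0)

    @property
    def significant(self) -> bool:
        """Significant iff the 95% CI of the indirect effect excludes zero."""
        lo, hi = self.ci_acme
        return lo > 0 or hi < 0


def select_mediation_candidates(
    exposure_screen: pd.DataFrame,
    outcome_screen: pd.DataFrame,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Units significant in both screens, annotated with exposure-association sign.

    Both tables must cover the same unit universe (unit-level rows).  The
    ``use_adjusted`` flag selects which significance flags gate the
    intersection.  An empty intersection is a valid result.
    """
    flag = "significant_adjusted" if use_adjusted else "significant_unadjusted"
    b_col = "B_adj" if use_adjusted else "B"
    exp_units = exposure_screen[exposure_screen["level"] == "unit"].set_index("unit_id")
    out_units = outcome_screen[outcome_screen["level"] == "unit"].set_index("unit_id")
    if set(exp_units.index) != set(out_units.index):
        raise ValueError("screens cover different unit universes")
    both = exp_units.index[
        exp_units[flag].fillna(False) & out_units[flag].reindex(exp_units.index).fillna(False)
    ]
    if b_col in exp_units.columns:
        b_vals = exp_units.loc[both, b_col].fillna(exp_units.loc[both, "B"])
    else:
        b_vals = exp_units.loc[both, "B"]
    return pd.DataFrame(
        {
            "unit_id": list(both),
            "exposure_B": b_vals.to_numpy(dtype=float),
            "sign": np.sign(b_vals.to_numpy(dtype=float)).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# Core estimator
# ---------------------------------------------------------------------------


def _complete_frame(
    exposure, mediator, outcome, covariates: pd.DataFrame | None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "exposure": np.asarray(exposure, dtype=float),
            "mediator": np.asarray(mediator, dtype=float),
            "outcome": np.asarray(outcome, dtype=float),
        }
    )
    if covariates is not None:
        cov = covariates.reset_index(drop=True).astype(float)
        cov.columns = [str(c) for c in cov.columns]
        df = pd.concat([df, cov], axis=1)
    return df.dropna().reset_index(drop=True)


def fit_mediation(
    exposure,
    mediator,
    outcome,
    covariates: pd.DataFrame | None = None,
    n_sims: int = 1000,
    seed: int = 0,
    method: str = "quasi-bayesian",
) -> MediationResult:
    """Estimate ACME/ADE/total with Monte-Carlo percentile intervals.

    ``method="quasi-bayesian"`` (default) draws coefficient vectors from
    each model's estimated sampling distribution; ``method="bootstrap"``
    refits both models on case resamples.  Point estimates always come from
    the original fits, so ``acme == a_path.B * b_path.B`` exactly.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if method not in ("quasi-bayesian", "bootstrap"):
        raise ValueError(f"unknown mediation method {method!r}")
    df = _complete_frame(exposure, mediator, outcome, covariates)
    n = len(df)
    if n < 10:
        raise InsufficientDataError(f"mediation needs >= 10 complete cases, got {n}")
    if float(df["mediator"].std()) == 0:
        raise ValueDomainError("mediator has zero variance")
    cov_cols = [c for c in df.columns if c not in ("exposure", "mediator", "outcome")]

    x_m = sm.add_constant(df[["exposure", *cov_cols]], has_constant="add")
    x_y = sm.add_constant(df[["exposure", "mediator", *cov_cols]], has_constant="add")
    fit_m = sm.OLS(df["mediator"], x_m).fit()
    fit_y = sm.OLS(df["outcome"], x_y).fit()
    a_hat = float(fit_m.params["exposure"])
    b_hat = float(fit_y.params["mediator"])
    c_hat = float(fit_y.params["exposure"])

    rng = np.random.default_rng(seed)
    if method == "quasi-bayesian":
        draws_m = rng.multivariate_normal(
            fit_m.params.to_numpy(), fit_m.cov_params().to_numpy(),
            size=n_sims, method="svd", check_valid="ignore",
        )
        draws_y = rng.multivariate_normal(
            fit_y.params.to_numpy(), fit_y.cov_params().to_numpy(),
            size=n_sims, method="svd", check_valid="ignore",
        )
        a_s = draws_m[:, list(x_m.columns).index("exposure")]
        b_s = draws_y[:, list(x_y.columns).index("mediator")]
        c_s = draws_y[:, list(x_y.columns).index("exposure")]
    else:
        a_s = np.empty(n_sims)
        b_s = np.empty(n_sims)
        c_s = np.empty(n_sims)
        idx = np.arange(n)
        for s in range(n_sims):
            take = rng.choice(idx, size=n, replace=True)
            sub = df.iloc[take]
            fm = sm.OLS(
                sub["mediator"], sm.add_constant(sub[["exposure", *cov_cols]], has_constant="add")
            ).fit()
            fy = sm.OLS(
                sub["outcome"],
                sm.add_constant(sub[["exposure", "mediator", *cov_cols]], has_constant="add"),
            ).fit()
            a_s[s] = fm.params["exposure"]
            b_s[s] = fy.params["mediator"]
            c_s[s] = fy.params["exposure"]
    if not (np.all(np.isfinite(a_s)) and np.all(np.isfinite(b_s)) and np.all(np.isfinite(c_s))):
        raise ValueDomainError(f"non-finite Monte-Carlo draws (seed={seed})")

    acme_s = a_s * b_s
    ade_s = c_s
    total_s = acme_s + ade_s
    ok_ratio = np.abs(total_s) >= _TOTAL_EPS
    prop_s = acme_s[ok_ratio] / total_s[ok_ratio]

    def ci(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return (float("nan"), float("nan"))
        lo, hi = np.percentile(v, [2.5, 97.5])
        return (float(lo), float(hi))

    p_acme = 2 * min(float(np.mean(acme_s <= 0)), float(np.mean(acme_s >= 0)))
    total_hat = a_hat * b_hat + c_hat
    return MediationResult(
        acme=a_hat * b_hat,
        ade=c_hat,
        total=total_hat,
        prop_mediated=(a_hat * b_hat) / total_hat if abs(total_hat) >= _TOTAL_EPS else float("nan"),
        ci_acme=ci(acme_s),
        ci_ade=ci(ade_s),
        ci_total=ci(total_s),
        ci_prop=ci(prop_s),
        p_acme=min(1.0, p_acme),
        n_sims=n_sims,
        a_path=RegressionResult(
            term="exposure", B=a_hat, SE=float(fit_m.bse["exposure"]),
            p=float(fit_m.pvalues["exposure"]), r2=float(fit_m.rsquared),
            F=float(fit_m.fvalue), df=(int(fit_m.df_model), int(fit_m.df_resid)), n=n,
        ),
        b_path=RegressionResult(
            term="mediator", B=b_hat, SE=float(fit_y.bse["mediator"]),
            p=float(fit_y.pvalues["mediator"]), r2=float(fit_y.rsquared),
            F=float(fit_y.fvalue), df=(int(fit_y.df_model), int(fit_y.df_resid)), n=n,
        ),
        n=n,
        method=method,
        n_ratio_excluded=int(np.sum(~ok_ratio)),
    )


# ---------------------------------------------------------------------------
# Cumulative methylation index
# ---------------------------------------------------------------------------


def build_mediator_index(
    matrix: MethylationMatrix,
    candidates: pd.DataFrame,
    mode: str = "sign-aligned",
) -> pd.Series:
    """Cumulative methylation index over the mediation candidates.

    ``candidates`` needs columns ``unit_id`` and ``sign``.  In the default
    ``"sign-aligned"`` mode the index is sum(s_j * M_j) with s_j the sign
    of unit j's exposure association, so opposite-signed mediators add
    coherently; ``"literal"`` sums raw values (s_j = +1).  A participant
    missing any member unit gets a missing index value.
    """
    if mode not in ("sign-aligned", "literal"):
        raise ValueError(f"unknown index mode {mode!r}")
    if len(candidates) == 0:
        raise ValueError("no candidate units to build an index from")
    idx = pd.Series(0.0, index=matrix.values.index, name=f"methylation_index[{mode}]")
    for row in candidates.itertuples(index=False):
        uid = row.unit_id
        if uid not in matrix.values.columns:
            raise KeyError(f"candidate unit {uid!r} not in matrix")
        col = matrix.values[uid]
        if col.isna().all():
            raise ValueDomainError(f"candidate unit {uid!r} is fully missing")
        s = int(row.sign) if mode == "sign-aligned" else 1
        if s == 0:
            s = 1
        idx = idx + s * col
    return idx


def mediate_cumulative(
    cohort: Cohort,
    candidates: pd.DataFrame,
    covariates: list[str] | None = None,
    n_sims: int | None = None,
    seed: int | None = None,
    mode: str = "sign-aligned",
) -> MediationResult:
    """Mediation with the cumulative index as the single mediator."""
    index = build_mediator_index(cohort.methylation, candidates, mode=mode)
    cov_df = cohort.phenotypes[covariates].astype(float) if covariates else None
    return fit_mediation(
        cohort.exposure().to_numpy(),
        index.to_numpy(),
        cohort.outcome().to_numpy(),
        covariates=cov_df,
        n_sims=n_sims if n_sims is not None else cohort.config.n_mediation_sims,
        seed=seed if seed is not None else cohort.config.rng_seed,
    )
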