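"""End-to-end orchestration: winsorize -> QC -> collapse -> regions ->
confounder selection -> screens -> FDR -> gated mediation -> moderation ->
risk score -> cumulative moderation.

All randomness derives from ``config.rng_seed`` through named child seeds
(a single global seed spawns per-stage seeds deterministically, so adding a
stage never perturbs earlier stages' randomness).  Every stage logs its row
counts and decisions into a structured run summary; reports are written as
deterministic TSVs so identical inputs and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import AnalysisConfig, Cohort, CohortError, write_report
from .mediation import (
    MediationResult,
    build_mediator_index,
    fit_mediation,
    mediate_cumulative,
    select_mediation_candidates,
)
from .moderation import (
    ModerationResult,
    RiskScore,
    build_risk_score,
    fit_moderation,
    moderate_cumulative,
)
from .preprocess import PreprocessResult, preprocess_cohort
from .screen import screen_units, select_confounders

__all__ = ["PipelineResult", "run_pipeline", "stage_seed", "CONFOUNDER_CANDIDATES"]

#: Candidate confounders screened with the p < 0.10 unique-association rule.
CONFOUNDER_CANDIDATES = ["age", "smoking", "drug_use", "alcohol", "bmi"]

#: Fixed stage order for seed spawning; appending stages never changes
#: the seeds of existing ones.
_STAGES = ("simulate", "mediation_units", "mediation_cumulative", "reserved_a", "reserved_b")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    if stage not in _STAGES:
        raise KeyError(f"unknown pipeline stage {stage!r}")
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGES))
    return int(children[_STAGES.index(stage)].generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, plus the audit trail."""

    preprocess: PreprocessResult
    confounders: list[str]
    confounder_log: pd.DataFrame
    screen_exposure: pd.DataFrame
    screen_outcome: pd.DataFrame
    mediation_candidates: pd.DataFrame
    mediation_units: dict[str, MediationResult]
    mediation_cumulative: MediationResult | None
    moderation_table: pd.DataFrame
    moderating_units: pd.DataFrame
    risk_score: RiskScore | None
    moderation_cumulative: ModerationResult | None
    summary: dict = field(default_factory=dict)


def _mediation_row(uid: str, res: MediationResult) -> dict:
    return {
        "mediator": uid,
        "acme": res.acme,
        "acme_ci_lo": res.ci_acme[0],
        "acme_ci_hi": res.ci_acme[1],
        "ade": res.ade,
        "total": res.total,
        "prop_mediated": res.prop_mediated,
        "prop_ci_lo": res.ci_prop[0],
        "prop_ci_hi": res.ci_prop[1],
        "p_acme": res.p_acme,
        "a_B": res.a_path.B,
        "a_p": res.a_path.p,
        "b_B": res.b_path.B,
        "b_p": res.b_path.p,
        "n": res.n,
        "n_sims": res.n_sims,
        "significant": res.significant,
    }


def _moderation_screen(
    cohort: Cohort, confounders: list[str], alpha: float
) -> pd.DataFrame:
    """Per-unit interaction models, unadjusted and adjusted."""
    rows = []
    x = cohort.exposure().to_numpy()
    y = cohort.outcome().to_numpy()
    cov_df = cohort.phenotypes[confounders].astype(float) if confounders else None
    p_unadj: list[float] = []
    for uid in cohort.methylation.unit_ids:
        m = cohort.methylation.values[uid].to_numpy()
        row: dict = {"unit_id": uid, "error": ""}
        try:
            res = fit_moderation(x, m, y)
            row.update(B=res.b_interaction, SE=res.se, p=res.p, r2=res.r2, n=res.n)
            if cov_df is not None:
                res_a = fit_moderation(x, m, y, covariates=cov_df)
                row.update(
                    B_adj=res_a.b_interaction, SE_adj=res_a.se,
                    p_adj_model=res_a.p, r2_adj=res_a.r2, n_adj=res_a.n,
                )
        except CohortError as exc:
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    from .screen import fdr_adjust

    ok = table["p"].notna() if "p" in table.columns else pd.Series(False, index=table.index)
    table["fdr_p"] = np.nan
    if ok.any():
        table.loc[ok, "fdr_p"] = fdr_adjust(table.loc[ok, "p"].to_list())
    table["significant_unadjusted"] = table.get("p", pd.Series(dtype=float)) < alpha
    if "p_adj_model" in table.columns:
        table["significant_adjusted"] = table["p_adj_model"] < alpha
    else:
        table["significant_adjusted"] = table["significant_unadjusted"]
    return table


def run_pipeline(
    cohort: Cohort,
    out_dir: str | Path | None = None,
    config: AnalysisConfig | None = None,
    use_adjusted_gating: bool = True,
    index_mode: str = "sign-aligned",
) -> PipelineResult:
    """Execute the full analysis on a validated cohort.

    Mirrors the analysis order of the study design: preprocessing, the two
    unit screens (methylation on exposure; methylation on outcome) with FDR,
    confounder selection, screening-gated per-unit mediation plus the
    cumulative methylation index, per-unit moderation, the tertile risk
    score over (adjusted-model) moderating units, and cumulative moderation
    with three score groups.  If ``out_dir`` is given, reports and the run
    summary are written there.
    """
    cfg = config or cohort.config
    if config is not None:
        cohort = Cohort(cohort.phenotypes, cohort.methylation, config, dict(cohort.meta))
    pre = preprocess_cohort(cohort, cfg)
    analysis = pre.cohort

    confounders, conf_log = select_confounders(
        analysis, CONFOUNDER_CANDIDATES, cfg.confounder_alpha
    )

    regions = pre.grouping.regions if pre.grouping.membership else None
    screen_exp = screen_units(analysis, "exposure", confounders, regions=regions)
    screen_out = screen_units(analysis, "outcome", confounders, regions=regions)

    candidates = select_mediation_candidates(
        screen_exp, screen_out, use_adjusted=use_adjusted_gating
    )
    med_seed = stage_seed(cfg.rng_seed, "mediation_units")
    mediation_units: dict[str, MediationResult] = {}
    for k, row in enumerate(candidates.itertuples(index=False)):
        mediation_units[row.unit_id] = fit_mediation(
            analysis.exposure().to_numpy(),
            analysis.methylation.values[row.unit_id].to_numpy(),
            analysis.outcome().to_numpy(),
            covariates=analysis.phenotypes[confounders].astype(float) if confounders else None,
            n_sims=cfg.n_mediation_sims,
            seed=(med_seed + k) % (2**31),
        )
    mediation_cum = None
    if len(candidates) > 0:
        mediation_cum = mediate_cumulative(
            analysis,
            candidates,
            covariates=confounders,
            n_sims=cfg.n_mediation_sims,
            seed=stage_seed(cfg.rng_seed, "mediation_cumulative"),
            mode=index_mode,
        )

    moderation_table = _moderation_screen(analysis, confounders, cfg.screen_alpha)
    mod_flag = "significant_adjusted" if confounders else "significant_unadjusted"
    b_col = "B_adj" if (confounders and "B_adj" in moderation_table.columns) else "B"
    mod_units = moderation_table.loc[
        moderation_table[mod_flag].fillna(False), ["unit_id", b_col]
    ].rename(columns={b_col: "B"})
    mod_units["sign"] = np.sign(mod_units["B"]).astype(int)

    risk_score = None
    moderation_cum = None
    if len(mod_units) > 0:
        risk_score = build_risk_score(analysis.methylation, mod_units)
        if risk_score.k > 0 and risk_score.scores.nunique() >= 3:
            moderation_cum = moderate_cumulative(analysis, risk_score, confounders)

    summary = {
        "config": cfg.to_dict(),
        "seed": cfg.rng_seed,
        "n_participants": analysis.n,
        "winsorized": pre.n_winsorized,
        "accounting": pre.accounting,
        "confounders_retained": confounders,
        "index_mode": index_mode,
        "adjusted_gating": use_adjusted_gating,
        "fdr_family": "per-screen",
        "n_exposure_significant": int(
            screen_exp.loc[screen_exp["level"] == "unit", "significant_unadjusted"].sum()
        ),
        "n_outcome_significant": int(
            screen_out.loc[screen_out["level"] == "unit", "significant_unadjusted"].sum()
        ),
        "n_fdr_significant": int(
            (
                screen_exp.loc[screen_exp["level"] == "unit", "fdr_p"] < cfg.fdr_q
            ).sum()
            + (screen_out.loc[screen_out["level"] == "unit", "fdr_p"] < cfg.fdr_q).sum()
            + (moderation_table["fdr_p"] < cfg.fdr_q).sum()
        ),
        "n_mediation_candidates": int(len(candidates)),
        "n_moderating_units": int(len(mod_units)),
        "degenerate_truth": cohort.meta.get("degenerate_truth", []),
        "mediation_ratio_draws_excluded": (
            mediation_cum.n_ratio_excluded if mediation_cum else None
        ),
    }
    result = PipelineResult(
        preprocess=pre,
        confounders=confounders,
        confounder_log=conf_log,
        screen_exposure=screen_exp,
        screen_outcome=screen_out,
        mediation_candidates=candidates,
        mediation_units=mediation_units,
        mediation_cumulative=mediation_cum,
        moderation_table=moderation_table,
        moderating_units=mod_units,
        risk_score=risk_score,
        moderation_cumulative=moderation_cum,
        summary=summary,
    )
    if out_dir is not None:
        write_pipeline_reports(result, out_dir)
    return result


def write_pipeline_reports(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per analysis family plus run_summary.json."""
    med_rows = [_mediation_row(uid, r) for uid, r in result.mediation_units.items()]
    if result.mediation_cumulative is not None:
        med_rows.append(_mediation_row("cumulative_index", result.mediation_cumulative))
    med_cols = [
        "mediator", "acme", "acme_ci_lo", "acme_ci_hi", "ade", "total",
        "prop_mediated", "prop_ci_lo", "prop_ci_hi", "p_acme", "a_B", "a_p",
        "b_B", "b_p", "n", "n_sims", "significant",
    ]
    tables: dict[str, pd.DataFrame] = {
        "qc_removals": result.preprocess.qc_report,
        "duplicate_merges": result.preprocess.merge_report,
        "regions": result.preprocess.grouping.report,
        "confounder_log": result.confounder_log,
        "screen_exposure": result.screen_exposure,
        "screen_outcome": result.screen_outcome,
        "mediation": pd.DataFrame(med_rows, columns=med_cols),
        "moderation": result.moderation_table,
    }
    if result.moderation_cumulative is not None:
        tables["cumulative_moderation_slopes"] = result.moderation_cumulative.slopes
        result.summary["cumulative_moderation"] = {
            "b_interaction": result.moderation_cumulative.b_interaction,
            "p": result.moderation_cumulative.p,
            "r2": result.moderation_cumulative.r2,
        }
    if result.risk_score is not None:
        tables["risk_score"] = (
            result.risk_score.scores.rename("score")
            .reset_index()
            .rename(columns={"index": "participant_id"})
        )
    return write_report(tables, out_dir, run_summary=result.summary)
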