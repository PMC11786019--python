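"""Stage functions binding the modules into the end-to-end analysis.

Each stage consumes and produces tidy tables so the pipeline can run either
in memory or through the CLI's delimited files: simulate -> fit -> exposure
-> associate -> report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, exposure, io, mapfit
from .cohort import SNP_PANEL
from .exceptions import InsufficientDataError
from .pk import protocol_schedule


def fit_concentrations(
    conc: pd.DataFrame,
    prior: mapfit.PriorSpec | None = None,
    error_model: mapfit.ErrorModel | None = None,
) -> tuple:
    """MAP-fit every patient-course in a validated concentration table.

    Returns ``(course_fits, patient_summaries)`` DataFrames.  Courses with
    fewer than two usable levels are skipped with a note in the fits table.
    """
    if conc.empty:
        raise InsufficientDataError("concentration table is empty")
    fit_rows = []
    summary_rows = []
    for patient_id, pdf in conc.groupby("patient_id", sort=True):
        results = []
        levels_24 = []
        for course, cdf in pdf.groupby("course", sort=True):
            dose = float(cdf["dose_g_m2"].iloc[0])
            schedule = protocol_schedule(dose * 1000.0)
            samples = io.samples_from_frame(cdf)
            row = {"patient_id": patient_id, "course": int(course), "dose_g_m2": dose}
            try:
                res = mapfit.fit_course(
                    samples, schedule, prior=prior, error_model=error_model,
                    dose_g_m2=dose,
                )
            except InsufficientDataError as err:
                row.update({"status": f"skipped: {err}", "converged": False})
                fit_rows.append(row)
                continue
            results.append(res)
            eoi = cdf.loc[(cdf["time_h"] - schedule.end_of_infusion_h).abs() < 0.5,
                          "conc_um"]
            if len(eoi):
                levels_24.append(float(eoi.iloc[0]))
            row.update(
                {
                    "status": "ok",
                    "converged": bool(res.converged),
                    "branch": res.branch,
                    "n_samples": res.n_samples,
                    "V": res.params.V,
                    "ke": res.params.ke,
                    "kcp": res.params.kcp,
                    "kpc": res.params.kpc,
                    "clearance": res.clearance,
                    "objective": res.objective,
                }
            )
            fit_rows.append(row)
        if results:
            summ = mapfit.summarize_patient(results, levels_24 or None)
            summary_rows.append(
                {
                    "patient_id": patient_id,
                    "mean_level_24h_um": summ.mean_level_24h_um,
                    "mean_clearance": summ.mean_clearance,
                    "cv_level_pct": summ.cv_level_pct,
                    "cv_clearance_pct": summ.cv_clearance_pct,
                    "n_courses": summ.n_courses,
                }
            )
    return pd.DataFrame(fit_rows), pd.DataFrame(summary_rows)


def exposure_tables(conc: pd.DataFrame, summary: pd.DataFrame) -> tuple:
    """Per-course threshold flags and per-patient exposure classes."""
    flag_rows = []
    for (patient_id, course), cdf in conc.groupby(["patient_id", "course"], sort=True):
        def _level(t):
            sel = cdf.loc[(cdf["time_h"] - t).abs() < 0.5, "conc_um"]
            return float(sel.iloc[0]) if len(sel) else None

        l24, l42, l48 = _level(24.0), _level(42.0), _level(48.0)
        if l24 is None:
            continue
        flags = exposure.flag_course(l24, l42, l48)
        flag_rows.append(
            {
                "patient_id": patient_id,
                "course": int(course),
                "over_150_at_24h": flags.over_150_at_24h,
                "over_1_at_42h": flags.over_1_at_42h,
                "over_05_at_48h": flags.over_05_at_48h,
                "delayed_excretion": flags.delayed_excretion,
            }
        )
    flags_df = pd.DataFrame(flag_rows)
    leuco = (
        flags_df.assign(over_05_at_48h=flags_df["over_05_at_48h"].fillna(False))
        .groupby("patient_id")["over_05_at_48h"].any()
        .rename("intensified_leucovorin")
        .reset_index()
    )
    classes = exposure.classify_exposure(summary).merge(leuco, on="patient_id", how="left")
    return flags_df, classes


def run_associations(
    patients: pd.DataFrame,
    exposure_classes: pd.DataFrame,
    config: io.RunConfig | None = None,
) -> pd.DataFrame:
    """The association stage on the merged per-patient table.

    Runs, per SNP: Fisher exact tests of the coded genotype on severe HEM
    and GI; a Cox model of relapse; linear models of log10 mean 24 h level
    and clearance; plus exposure-class tests.  Returns one tidy row per test
    with raw and Bonferroni-adjusted p-values (family = all toxicity tests).
    """
    config = config or io.RunConfig()
    df = patients.merge(exposure_classes, on="patient_id", how="inner")
    rows = []

    tox_model = config.genetic_models.get("toxicity", "dominant")
    for snp in SNP_PANEL:
        if snp not in df.columns:
            continue
        coded = assoc.genetic_coding(df[snp], tox_model).astype(bool)
        for outcome in ("severe_hem", "severe_gi"):
            try:
                res = assoc.fisher_exact(
                    assoc.ContingencyTable2x2.from_groups(
                        coded, df[outcome].astype(bool),
                        (f"{snp} {tox_model}", "reference"), outcome,
                    )
                )
                rows.append(_tidy(res, analysis=f"{outcome}~{snp}"))
            except assoc.ZeroMarginError:
                rows.append(
                    {
                        "analysis": f"{outcome}~{snp}", "term": snp,
                        "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "pvalue": np.nan, "test": "fisher_exact_cmle",
                        "n": len(df), "direction": "undefined (zero margin)",
                    }
                )

    pk_model = config.genetic_models.get("pk", "recessive")
    lm_df = df.copy()
    lm_df["age_years"] = lm_df["age_years"].astype(float)
    for snp in SNP_PANEL:
        if snp in lm_df.columns:
            lm_df[f"{snp}_{pk_model}"] = assoc.genetic_coding(lm_df[snp], pk_model)
    pk_covs = _prune_degenerate(
        lm_df,
        ["age_years"] + [f"{snp}_{pk_model}" for snp in SNP_PANEL if snp in df.columns],
    )
    for endpoint, logscale in (("mean_level_24h_um", True), ("mean_clearance", False)):
        if endpoint not in lm_df.columns:
            continue
        for res in assoc.pk_linear_model(lm_df, endpoint, pk_covs, multivariate=True,
                                         log10_endpoint=logscale):
            rows.append(_tidy(res, analysis=f"{endpoint}~multivariate"))

    rel_model = config.genetic_models.get("relapse", "dominant")
    cox_df = df.copy()
    cox_covs = []
    for snp in SNP_PANEL:
        if snp in cox_df.columns:
            col = f"{snp}_{rel_model}"
            cox_df[col] = assoc.genetic_coding(cox_df[snp], rel_model)
            cox_covs.append(col)
    cox_df["age_ge_cutoff"] = (cox_df["age_years"] >= config.age_cutoff).astype(float)
    cox_df["cl_q1"] = (cox_df["cl_quartile"] == 1).astype(float)
    cox_df["level_q4"] = (cox_df["level_quartile"] == 4).astype(float)
    cox_covs = _prune_degenerate(cox_df, cox_covs + ["age_ge_cutoff", "cl_q1", "level_q4"])
    if cox_df["relapse"].sum() > 0 and cox_covs:
        for res in assoc.relapse_cox(cox_df, covariates=cox_covs):
            rows.append(_tidy(res, analysis="relapse~multivariate"))

    out = pd.DataFrame(rows)
    tox_mask = out["analysis"].str.startswith(("severe_hem", "severe_gi")) & out["pvalue"].notna()
    if tox_mask.any():
        adj = assoc.adjust_multiplicity(
            out.loc[tox_mask, "pvalue"],
            method=config.multiplicity_method,
            m=config.multiplicity_m,
            alpha=config.alpha,
        )
        out.loc[tox_mask, "p_adj"] = adj["p_adj"].to_numpy()
    return out


def _prune_degenerate(df: pd.DataFrame, cols: list) -> list:
    """Greedily keep covariates that add rank to the design.

    In small cohorts a coding can be monomorphic or coincide with another
    column; the joint models then need a reduced design rather than an error.
    """
    kept = []
    n = len(df)
    current = np.ones((n, 1))
    for col in cols:
        candidate = np.column_stack([current, df[col].astype(float).to_numpy()])
        if np.linalg.matrix_rank(candidate) > current.shape[1]:
            kept.append(col)
            current = candidate
    return kept


def _tidy(res: assoc.AssociationResult, analysis: str) -> dict:
    return {
        "analysis": analysis,
        "term": res.term or analysis.split("~")[-1],
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pvalue": res.pvalue,
        "test": res.test,
        "n": res.n,
        "direction": res.direction,
    }


def report_text(results: pd.DataFrame, config: io.RunConfig) -> str:
    """Plain-text run report: every fitted analysis with its headline row."""
    lines = [
        "HD-MTX pharmacogenetic analysis report",
        f"config digest: {config.digest()}  seed: {config.seed}",
        f"multiplicity: {config.multiplicity_method} "
        f"(m={config.multiplicity_m if config.multiplicity_m else 'n tests'})",
        "",
    ]
    for analysis, adf in results.groupby("analysis", sort=True):
        lines.append(f"== {analysis} (test: {adf['test'].iloc[0]}, n={adf['n'].iloc[0]})")
        for _, r in adf.iterrows():
            est = "NA" if pd.isna(r["estimate"]) else f"{r['estimate']:.3g}"
            ci = (
                "" if pd.isna(r["ci_low"])
                else f" (95% CI {r['ci_low']:.3g}-{r['ci_high']:.3g})"
            )
            p = "NA" if pd.isna(r["pvalue"]) else f"{r['pvalue']:.3g}"
            padj = ""
            if "p_adj" in r and not pd.isna(r.get("p_adj", np.nan)):
                padj = f", adj p={r['p_adj']:.3g}"
            lines.append(f"  {r['term']}: {est}{ci}, p={p}{padj}  [{r['direction']}]")
        lines.append("")
    return "\n".join(lines)
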