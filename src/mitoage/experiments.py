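"""Simulation experiments: calibration and parameter-recovery studies.

Each experiment generates synthetic studies with known ground truth and
pushes them through the same analysis stages as the pipeline, measuring
whether the inference machinery recovers the generating coefficients at
the advertised confidence levels.  These are the package's validation
workloads: coverage of the pooled IVW estimate, type-I error of the
association stage under a null generator, false-discovery control of the
per-CpG analysis, mediation proportion recovery, and bias of the MR
estimators under valid and invalid instruments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import association, copy_number, heteroplasmy, mediation, mr
from .clocks import compute_clock_value, compute_eaa
from .simulate import (
    SimConfig,
    generate_cohort,
    generate_methylation_clocks,
    generate_mr_dataset,
    generate_mtdna,
    generate_traits,
)

ASSOC_COVARIATES = ["age", "age_sq", "female", "smoking",
                    "wbc_neut", "wbc_lymph", "wbc_mono", "wbc_eos", "batch", "lab"]


def _active(df: pd.DataFrame, candidates: list[str]) -> list[str]:
    return [c for c in candidates if c in df.columns and df[c].nunique() > 1]


def _standardized_metrics(cohort: pd.DataFrame, mtdna, ledger) -> pd.DataFrame:
    """Score burden, compute CN, apply QC, residualize/standardize."""
    ids = cohort["sample_id"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        burden = heteroplasmy.score_study(
            mtdna.calls, ids, mlc=mtdna.mlc, panel=mtdna.panel,
            site_coverage=mtdna.site_coverage,
        )
    cn = copy_number.compute_mtdna_cn(
        mtdna.coverage_summary["mt_coverage"].to_numpy(),
        mtdna.coverage_summary["nuclear_coverage"].to_numpy(),
    )
    cn_table = pd.DataFrame(
        {"sample_id": mtdna.coverage_summary["sample_id"], "mtDNA_CN": cn}
    )
    retained, _ = copy_number.apply_sample_qc(burden.scores, cn_table)
    merged = (cohort.merge(burden.scores, on="sample_id").merge(cn_table, on="sample_id"))
    merged = merged[merged["sample_id"].isin(retained)].reset_index(drop=True)
    merged["age_sq"] = merged["age"] ** 2
    return copy_number.residualize_standardize(
        merged, ["MHcount", "MSS", "MH_com_count", "mtDNA_CN"],
        _active(merged, ["wbc_neut", "wbc_lymph", "wbc_mono", "wbc_eos", "batch", "smoking"]),
    )


def _eaa_column(metrics: pd.DataFrame, betas: pd.DataFrame, clock) -> pd.Series:
    sub = betas.loc[betas.index.isin(metrics["sample_id"])]
    values = compute_clock_value(sub, clock)
    keyed = metrics.set_index("sample_id")
    eaa = compute_eaa(values, keyed.loc[sub.index, "age"], keyed.loc[sub.index, "cohort"])
    return eaa.table.set_index("sample_id")["eaa"]


def _simulate_analysis_frame(config: SimConfig, seed: int, clock_scale: str):
    """One study through scoring, QC, clocks; returns (data, clock name)."""
    cohort, ledger = generate_cohort(config, seed)
    mtdna = generate_mtdna(cohort, config, seed, ledger=ledger)
    betas, clocks = generate_methylation_clocks(cohort, ledger, config, seed)
    metrics = _standardized_metrics(cohort, mtdna, ledger)
    clock = next(c for c in clocks if c.scale == clock_scale
                 and c.weights is not None)
    eaa = _eaa_column(metrics, betas, clock).rename("eaa")
    data = metrics.set_index("sample_id").join(eaa).reset_index()
    return data, ledger


def pooled_metric_association(
    config: SimConfig, seed: int, metric: str = "MSS_std", clock_scale: str = "years"
) -> association.MetaResult:
    """Simulate one study and IVW-pool the per-cohort EAA~metric fits."""
    data, _ = _simulate_analysis_frame(config, seed, clock_scale)
    results = []
    for cohort_name, sub in data.groupby("cohort"):
        covs = _active(sub, ASSOC_COVARIATES)
        results.append(association.fit_association(sub, metric, "eaa", covs,
                                                   cohort=cohort_name))
    return association.meta_analyze(results)


def association_coverage(
    n_reps: int = 200,
    n_per_cohort: int = 1500,
    seed: int = 0,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """Coverage of the pooled 95% CI for the MSS→EAA effect γ_MSS.

    Four cohorts of ``n_per_cohort`` samples per replicate; returns one
    row per replicate with the pooled estimate, CI and coverage flag.
    """
    overrides = {"n_per_cohort": (n_per_cohort,) * 4}
    overrides.update(config_overrides or {})
    config = SimConfig.from_dict(overrides)
    truth = config.gamma_mss
    rows = []
    for r in range(n_reps):
        meta = pooled_metric_association(config, seed=seed * n_reps + r + 1)
        lo = meta.beta - 1.959963984540054 * meta.se
        hi = meta.beta + 1.959963984540054 * meta.se
        rows.append({"rep": r, "beta": meta.beta, "se": meta.se,
                     "lo": lo, "hi": hi, "covers": lo <= truth <= hi})
    return pd.DataFrame(rows)


def null_type1_pvalues(
    n_studies: int = 250,
    n_per_cohort: int = 150,
    seed: int = 0,
) -> np.ndarray:
    """Per-cohort association p-values under an all-null generator.

    The generator's effect coefficients (γ_MSS, γ_CN, θ_CN) are zero, so
    every EAA~MSS_std test is null; four cohorts per study give
    ``4 × n_studies`` p-values.
    """
    config = SimConfig.from_dict({
        "n_per_cohort": (n_per_cohort,) * 4,
        "gamma_mss": 0.0, "gamma_cn": 0.0, "theta_cn": 0.0,
        "n_cpgs_year": 40, "n_cpgs_pace": 10,
    })
    pvals = []
    for r in range(n_studies):
        data, _ = _simulate_analysis_frame(config, seed=seed * n_studies + r + 1,
                                           clock_scale="years")
        for cohort_name, sub in data.groupby("cohort"):
            covs = _active(sub, ASSOC_COVARIATES)
            res = association.fit_association(sub, "MSS_std", "eaa", covs,
                                              cohort=cohort_name)
            pvals.append(res.p)
    return np.asarray(pvals)


def null_ewas_fdp(
    n_reps: int = 100,
    n_samples: int = 150,
    n_cpgs: int = 200,
    seed: int = 0,
    fdr_level: float = 0.05,
) -> np.ndarray:
    """False-discovery proportion of the per-CpG analysis on null data.

    Single-cohort null studies; the metric is independent of every CpG
    given the covariates, so any BH discovery is false.  Returns one FDP
    per replicate.
    """
    year = int(n_cpgs * 0.75)
    config = SimConfig.from_dict({
        "n_cohorts": 1, "n_per_cohort": (n_samples,),
        "age_mean": (60.8,), "age_sd": (13.6,),
        "gamma_mss": 0.0, "gamma_cn": 0.0, "theta_cn": 0.0,
        "n_cpgs_year": year, "n_cpgs_pace": n_cpgs - year,
    })
    fdp = np.empty(n_reps)
    for r in range(n_reps):
        s = seed * n_reps + r + 1
        cohort, ledger = generate_cohort(config, s)
        mtdna = generate_mtdna(cohort, config, s, ledger=ledger)
        betas, _ = generate_methylation_clocks(cohort, ledger, config, s)
        metrics = _standardized_metrics(cohort, mtdna, ledger)
        keyed = metrics.set_index("sample_id")
        covs = _active(keyed, ASSOC_COVARIATES)
        ewas = association.cpg_level_ewas(
            betas.loc[betas.index.isin(keyed.index)], keyed, "MSS_std", covs,
            fdr_level=fdr_level,
        )
        n_disc = int(ewas["significant"].sum())
        fdp[r] = 0.0 if n_disc == 0 else 1.0  # all discoveries are false here
    return fdp


def mediation_pm_recovery(
    n_reps: int = 100,
    n: int = 2000,
    seed: int = 0,
    outcome: str = "obesity",
) -> pd.DataFrame:
    """Recovery of the true percent-mediated in the CN→pace→trait chain.

    Single cohort of ``n`` samples per replicate; the mediator is the
    pace-clock EAA and the predictor the standardized CN residual, as in
    the pipeline.  Returns per-replicate PM estimates plus the truth.
    """
    config = SimConfig.from_dict({
        "n_cohorts": 1, "n_per_cohort": (n,),
        "age_mean": (60.8,), "age_sd": (13.6,),
        "n_cpgs_year": 40, "n_cpgs_pace": 60,
    })
    a = config.theta_cn
    b = config.obesity_b_pace if outcome == "obesity" else config.t2dm_b_pace
    c = config.obesity_c_cn if outcome == "obesity" else config.t2dm_c_cn
    true_pm = 100.0 * a * b / (a * b + c)
    rows = []
    for r in range(n_reps):
        s = seed * n_reps + r + 1
        cohort, ledger = generate_cohort(config, s)
        mtdna = generate_mtdna(cohort, config, s, ledger=ledger)
        betas, clocks = generate_methylation_clocks(cohort, ledger, config, s)
        traits = generate_traits(cohort, ledger, config, s)
        metrics = _standardized_metrics(cohort, mtdna, ledger)
        pace_clock = next(c_ for c_ in clocks if c_.scale == "pace")
        eaa = _eaa_column(metrics, betas, pace_clock).rename("pace_eaa")
        data = (metrics.set_index("sample_id").join(eaa)
                .join(traits.set_index("sample_id")[[outcome]]).reset_index())
        covs = _active(data, ASSOC_COVARIATES)
        res = mediation.fit_mediation(
            data, predictor="mtDNA_CN_std", mediator="pace_eaa", outcome=outcome,
            covariates=covs, outcome_type="binary",
        )
        rows.append({"rep": r, "a": res.a, "b": res.b, "c_prime": res.c_prime,
                     "nie": res.nie, "te": res.te,
                     "pm": res.pm if res.pm is not None else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["true_pm"] = true_pm
    return out


def mr_bias(
    n_sims: int = 200,
    seed: int = 0,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """Bias of IVW / Egger / weighted-median over simulated MR datasets."""
    config = SimConfig.from_dict(config_overrides or {})
    rows = []
    for r in range(n_sims):
        exposure, outcome, truth = generate_mr_dataset(config, seed=seed * n_sims + r + 1)
        harmonized, _ = mr.harmonize(exposure, outcome)
        row = {"rep": r, "theta_true": truth["theta"]}
        row["ivw"] = mr.mr_ivw(harmonized).theta
        egger = mr.mr_egger(harmonized)
        row["egger"] = egger.theta
        row["egger_intercept"] = egger.intercept
        row["wmedian"] = mr.mr_weighted_median(harmonized, bootstrap_reps=100,
                                               seed=seed * n_sims + r + 1).theta
        rows.append(row)
    return pd.DataFrame(rows)


def egger_intercept_type1(
    n_sims: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the Egger intercept test with valid instruments."""
    config = SimConfig()
    rejections = 0
    for r in range(n_sims):
        exposure, outcome, _ = generate_mr_dataset(config, seed=seed * n_sims + r + 1)
        harmonized, _ = mr.harmonize(exposure, outcome)
        est = mr.mr_egger(harmonized)
        if est.intercept_p < alpha:
            rejections += 1
    return rejections / n_sims
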