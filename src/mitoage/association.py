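"""Covariate-adjusted EAA–mtDNA associations and fixed-effect IVW pooling.

The primary model regresses an epigenetic age acceleration (EAA) outcome
on one standardized mtDNA metric plus covariates (age, age², sex, smoking,
white-blood-cell composition, batch, lab index where applicable), per
cohort and optionally per stratum (age < 60 / ≥ 60, female / male).
Cohort estimates are pooled with a fixed-effect inverse-variance-weighted
(IVW) meta-analysis: w_i = 1/SE_i², β_pool = Σ w_i β_i / Σ w_i,
SE_pool = 1/√(Σ w_i).

A secondary per-CpG analysis regresses each CpG's methylation beta on the
metric and covariates, with Benjamini–Hochberg control of the false
discovery rate.

The default significance flag for the primary analysis is p < 0.01,
i.e. 0.05 Bonferroni-divided by the five EAA outcomes of the study design;
the family size is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .copy_number import SingularDesignError, _design_matrix

DEFAULT_ALPHA_FAMILY = 0.05
DEFAULT_N_EAA_OUTCOMES = 5
DEFAULT_SIGNIFICANCE_THRESHOLD = DEFAULT_ALPHA_FAMILY / DEFAULT_N_EAA_OUTCOMES  # 0.01
DEFAULT_AGE_CUT = 60.0

STRATA = ("all", "age<60", "age>=60", "female", "male")


@dataclass
class AssocResult:
    metric: str
    outcome: str
    cohort: str
    stratum: str
    beta: float
    se: float
    p: float
    n: int

    def to_row(self) -> dict:
        return self.__dict__.copy()


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    k: int
    weights: np.ndarray
    q: float  # Cochran's Q
    i2: float  # I² heterogeneity (%)

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        d["weights"] = ";".join(f"{w:.6g}" for w in self.weights)
        return d


def fit_association(
    data: pd.DataFrame,
    metric: str,
    outcome: str,
    covariates: list[str],
    cohort: str = "pooled",
    stratum: str = "all",
) -> AssocResult:
    """OLS of ``outcome`` on ``metric`` + covariates; t-based two-sided p.

    Categorical covariates are expanded to indicator contrasts.  Raises
    :class:`SingularDesignError` on rank-deficient designs and
    ``ValueError`` when complete cases are insufficient.
    """
    cols = [outcome, metric] + list(covariates)
    sub = data[cols].dropna()
    X = _design_matrix(sub[[metric] + list(covariates)])
    if len(sub) < X.shape[1] + 2:
        raise ValueError(
            f"{len(sub)} complete cases insufficient for {X.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        from .copy_number import _check_rank

        _check_rank(X)  # raises with column names
    model = sm.OLS(sub[outcome].to_numpy(dtype=float), X.to_numpy())
    res = model.fit()
    j = list(X.columns).index(metric)
    return AssocResult(
        metric=metric, outcome=outcome, cohort=cohort, stratum=stratum,
        beta=float(res.params[j]), se=float(res.bse[j]),
        p=float(res.pvalues[j]), n=int(len(sub)),
    )


def stratified_associations(
    data: pd.DataFrame,
    metric: str,
    outcome: str,
    covariates: list[str],
    cohort: str = "pooled",
    age_column: str = "age",
    sex_column: str = "female",
    age_cut: float = DEFAULT_AGE_CUT,
) -> list[AssocResult]:
    """Fit the association overall and within age/sex strata.

    Age strata split at ``age_cut`` with age = cut assigned to the older
    stratum (< cut vs ≥ cut).  Sex strata drop the sex covariate; age
    strata keep age and age².  Empty or under-sized strata are skipped,
    not fatal.
    """
    results: list[AssocResult] = []

    def _try(sub: pd.DataFrame, label: str, covs: list[str]) -> None:
        try:
            results.append(
                fit_association(sub, metric, outcome, covs, cohort=cohort, stratum=label)
            )
        except (ValueError, SingularDesignError):
            pass  # recorded as skipped by absence

    _try(data, "all", covariates)
    _try(data[data[age_column] < age_cut], "age<60", covariates)
    _try(data[data[age_column] >= age_cut], "age>=60", covariates)
    no_sex = [c for c in covariates if c != sex_column]
    _try(data[data[sex_column] == 1], "female", no_sex)
    _try(data[data[sex_column] == 0], "male", no_sex)
    return results


def ivw_meta(betas, ses) -> MetaResult:
    """Fixed-effect inverse-variance-weighted pooling of study estimates."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no studies to pool")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (b - beta) ** 2))
    df = b.size - 1
    i2 = float(max(0.0, (q - df) / q) * 100) if q > 0 and df > 0 else 0.0
    return MetaResult(beta=beta, se=se, z=float(z), p=p, k=int(b.size), weights=w, q=q, i2=i2)


def meta_analyze(results: list[AssocResult]) -> MetaResult:
    """IVW-pool a list of per-cohort :class:`AssocResult` rows."""
    return ivw_meta([r.beta for r in results], [r.se for r in results])


def cpg_level_ewas(
    betas: pd.DataFrame,
    data: pd.DataFrame,
    metric: str,
    covariates: list[str],
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG OLS of methylation beta on the metric plus covariates.

    All CpGs share one design matrix, so the fits are solved jointly.
    Returns one row per CpG with beta, se, p, BH-adjusted q, and a
    significance flag at ``q < fdr_level``.
    """
    common = betas.index.intersection(data.index)
    X = _design_matrix(data.loc[common, [metric] + list(covariates)])
    Y = betas.loc[common].to_numpy(dtype=float)
    Xm = X.to_numpy()
    n, p = Xm.shape
    if n < p + 2:
        raise ValueError(f"{n} samples insufficient for {p} parameters")
    pinv = np.linalg.pinv(Xm)
    coef = pinv @ Y                       # p × n_cpgs
    resid = Y - Xm @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    # variance of the metric coefficient: (XᵀX)⁻¹[j,j] · σ²
    j = list(X.columns).index(metric)
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(xtx_inv[j, j] * sigma2)
    b = coef[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "cpg": betas.columns,
            "beta": b,
            "se": se,
            "p": pvals,
            "q": qvals,
            "significant": qvals < fdr_level,
        }
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    _, q, _, _ = multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")
    return q
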