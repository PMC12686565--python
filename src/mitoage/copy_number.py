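"""mtDNA copy number, sample-level QC, and metric residualization.

mtDNA copy number (CN) per cell is estimated as twice the ratio of mean
mitochondrial to mean nuclear sequencing coverage — the factor two accounts
for the haploid mitochondrial genome against the diploid nuclear one.

Samples with implausible heteroplasmy loads (MHcount > 5) or very low CN
(< 40), both suggestive of contamination or sequencing error, are excluded
before inference.  Each mtDNA metric is then residualized within cohort on
technical/behavioural covariates (white-blood-cell composition, batch,
smoking) and standardized to mean 0 / SD 1, so association coefficients
are per-SD effects comparable across cohorts.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

DEFAULT_MAX_MHCOUNT = 5
DEFAULT_MIN_CN = 40.0

MT_METRICS = ("MHcount", "MSS", "MH_com_count", "mtDNA_CN")


class CoverageError(ValueError):
    """Raised when nuclear coverage is zero or negative."""


class SingularDesignError(ValueError):
    """Raised when the residualization design matrix is rank deficient."""


def compute_mtdna_cn(mt_coverage, nuclear_coverage):
    """CN = 2 × (mean mitochondrial coverage / mean nuclear coverage).

    Accepts scalars or aligned array-likes; zero nuclear coverage raises
    :class:`CoverageError`.
    """
    mt = np.asarray(mt_coverage, dtype=float)
    nuc = np.asarray(nuclear_coverage, dtype=float)
    if np.any(nuc <= 0):
        raise CoverageError("nuclear coverage must be positive to form the CN ratio")
    cn = 2.0 * mt / nuc
    if isinstance(mt_coverage, numbers.Number) and isinstance(nuclear_coverage, numbers.Number):
        return float(cn)
    return cn


def apply_sample_qc(
    scores: pd.DataFrame,
    copy_number: pd.DataFrame,
    max_mhcount: int = DEFAULT_MAX_MHCOUNT,
    min_cn: float = DEFAULT_MIN_CN,
) -> tuple[pd.Index, pd.DataFrame]:
    """Exclude samples with MHcount > ``max_mhcount`` or CN < ``min_cn``.

    Both inequalities are strict, so the boundary sample (MHcount = 5,
    CN = 40.0) is retained.  ``scores`` needs columns sample_id/MHcount and
    ``copy_number`` sample_id/mtDNA_CN; a sample present in only one table
    raises ``KeyError``.

    Returns (retained sample index, audit frame with a reasons column).
    """
    s = scores.set_index("sample_id")
    c = copy_number.set_index("sample_id")
    only_scores = s.index.difference(c.index)
    only_cn = c.index.difference(s.index)
    if len(only_scores) or len(only_cn):
        raise KeyError(
            "sample id mismatch between burden and CN tables: "
            f"burden-only={sorted(only_scores)[:5]}, cn-only={sorted(only_cn)[:5]}"
        )
    merged = s.join(c, how="inner")
    high_burden = merged["MHcount"] > max_mhcount
    low_cn = merged["mtDNA_CN"] < min_cn

    reasons = []
    for hb, lc in zip(high_burden, low_cn):
        r = []
        if hb:
            r.append("MHcount")
        if lc:
            r.append("CN")
        reasons.append(";".join(r))
    audit = pd.DataFrame(
        {
            "sample_id": merged.index,
            "MHcount": merged["MHcount"].to_numpy(),
            "mtDNA_CN": merged["mtDNA_CN"].to_numpy(),
            "excluded": (high_burden | low_cn).to_numpy(),
            "reason": reasons,
        }
    )
    retained = merged.index[~(high_burden | low_cn)]
    return retained, audit


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns + indicator contrasts for categoricals.

    Constant columns are dropped (they are absorbed by the intercept), so
    all-constant covariates reduce the fit to intercept-only.
    """
    parts = [pd.Series(1.0, index=covariates.index, name="const")]
    for col in covariates.columns:
        s = covariates[col]
        if s.nunique(dropna=False) <= 1:
            continue
        if s.dtype.kind in "biufc":
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns implicated in the collinearity
        bad = []
        cols = X.columns.tolist()
        for j, col in enumerate(cols):
            others = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(others) == rank:
                bad.append(col)
        raise SingularDesignError(f"collinear design columns: {bad or cols}")


def residualize_standardize(
    data: pd.DataFrame,
    metric_columns: list[str],
    covariate_columns: list[str],
    cohort_column: str = "cohort",
) -> pd.DataFrame:
    """Within-cohort residualization and standardization of mtDNA metrics.

    For each cohort, each metric is regressed by ordinary least squares on
    the covariates (categoricals expanded to indicator contrasts); the
    residual is divided by its within-cohort sample SD (denominator n−1).
    Output columns: ``<metric>_resid`` and ``<metric>_std``.

    Raises
    ------
    SingularDesignError
        if a cohort's design matrix is rank deficient, naming the columns.
    ValueError
        if a cohort has fewer than (number of design columns + 1) samples.
    """
    out = data.copy()
    for metric in metric_columns:
        out[f"{metric}_resid"] = np.nan
        out[f"{metric}_std"] = np.nan

    for cohort, idx in data.groupby(cohort_column).groups.items():
        sub = data.loc[idx]
        X = _design_matrix(sub[covariate_columns])
        if len(sub) < X.shape[1] + 1:
            raise ValueError(
                f"cohort {cohort!r}: {len(sub)} samples insufficient for "
                f"{X.shape[1]} design columns"
            )
        _check_rank(X)
        Xm = X.to_numpy()
        # hat projection shared across metrics
        XtX_inv_Xt = np.linalg.pinv(Xm)
        for metric in metric_columns:
            y = sub[metric].to_numpy(dtype=float)
            resid = y - Xm @ (XtX_inv_Xt @ y)
            sd = resid.std(ddof=1)
            if sd <= 0:
                raise ValueError(f"cohort {cohort!r}: metric {metric!r} has zero residual variance")
            out.loc[idx, f"{metric}_resid"] = resid
            out.loc[idx, f"{metric}_std"] = resid / sd
    return out
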