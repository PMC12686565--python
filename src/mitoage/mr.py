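"""Two-sample univariable Mendelian randomization from summary statistics.

Given pre-clumped GWAS summary statistics for an exposure (e.g. mtDNA
copy number) and an outcome (e.g. an epigenetic age acceleration GWAS),
the per-SNP causal estimate is the Wald ratio β_out/β_exp.  Estimators:

IVW
    inverse-variance-weighted average of Wald ratios with weights
    w_j = β_exp,j² / SE_out,j² — equivalent to weighted regression of
    β_out on β_exp through the origin.  The default SE uses
    multiplicative random-error scaling (inflated by the residual
    dispersion when it exceeds 1); a fixed-error variant is available.
MR-Egger
    weighted regression *with* an intercept after orienting all
    exposure effects positive; the intercept estimates average
    directional pleiotropy, the slope the causal effect.
Weighted median
    the weighted median of Wald ratios, consistent when at least half
    the weight lies on valid instruments; SE by seeded parametric
    bootstrap.

Leave-one-out re-runs IVW dropping each SNP in turn to flag influential
instruments.  Harmonization aligns outcome effects to the exposure effect
allele and drops strand-ambiguous palindromic SNPs with allele frequency
near 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SUMMARY_COLUMNS = ["snp", "ea", "oa", "eaf", "beta", "se", "p"]
DEFAULT_PALINDROME_WINDOW = (0.42, 0.58)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class MREstimate:
    method: str  # "ivw" | "egger" | "weighted_median"
    theta: float
    se: float
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    wald_ratios: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        d.pop("wald_ratios")
        return d


def _validate_side(df: pd.DataFrame, side: str) -> pd.DataFrame:
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{side} summary statistics missing columns: {missing}")
    if df["snp"].duplicated().any():
        dups = df.loc[df["snp"].duplicated(), "snp"].tolist()[:5]
        warnings.warn(
            f"{side} side has duplicate SNP ids (inputs should be pre-clumped): {dups}",
            stacklevel=3,
        )
        df = df.drop_duplicates("snp")
    return df


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome effects to the exposure effect allele.

    Outcome rows whose (ea, oa) pair is swapped relative to the exposure
    are sign-flipped; allele-incompatible rows and palindromic SNPs with
    exposure EAF inside ``palindrome_window`` are dropped.  Returns the
    harmonized table (exposure/outcome betas and SEs per SNP) and an
    audit of dropped SNPs with reasons.
    """
    exposure = _validate_side(exposure, "exposure")
    outcome = _validate_side(outcome, "outcome")
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    if merged.empty:
        raise ValueError("no overlapping SNPs between exposure and outcome")

    rows, dropped = [], []
    lo, hi = palindrome_window
    for r in merged.itertuples(index=False):
        beta_out, eaf_out = r.beta_out, r.eaf_out
        if _is_palindromic(r.ea_exp, r.oa_exp) and lo < r.eaf_exp < hi:
            dropped.append({"snp": r.snp, "reason": "palindromic_ambiguous"})
            continue
        if (r.ea_out, r.oa_out) == (r.ea_exp, r.oa_exp):
            pass
        elif (r.ea_out, r.oa_out) == (r.oa_exp, r.ea_exp):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
        elif (
            _COMPLEMENT.get(r.ea_out), _COMPLEMENT.get(r.oa_out)
        ) == (r.ea_exp, r.oa_exp):
            pass  # strand flip, same orientation
        elif (
            _COMPLEMENT.get(r.ea_out), _COMPLEMENT.get(r.oa_out)
        ) == (r.oa_exp, r.ea_exp):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
        else:
            dropped.append({"snp": r.snp, "reason": "allele_mismatch"})
            continue
        rows.append(
            {
                "snp": r.snp, "ea": r.ea_exp, "oa": r.oa_exp, "eaf": r.eaf_exp,
                "beta_exp": r.beta_exp, "se_exp": r.se_exp, "p_exp": r.p_exp,
                "beta_out": beta_out, "se_out": r.se_out, "eaf_out": eaf_out,
            }
        )
    harmonized = pd.DataFrame(rows)
    audit = pd.DataFrame(dropped, columns=["snp", "reason"])
    return harmonized, audit


def _usable(stats_df: pd.DataFrame) -> pd.DataFrame:
    zero = stats_df["beta_exp"] == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} SNP(s) with zero exposure effect",
            stacklevel=3,
        )
    out = stats_df.loc[~zero]
    if out.empty:
        raise ValueError("no usable SNPs (all exposure effects zero)")
    return out


def mr_ivw(harmonized: pd.DataFrame, error_model: str = "multiplicative") -> MREstimate:
    """Inverse-variance-weighted causal estimate.

    ``error_model='multiplicative'`` inflates the SE by the residual
    dispersion when it exceeds 1 (never deflates); ``'fixed'`` uses the
    analytic fixed-error SE.
    """
    h = _usable(harmonized)
    ratios = (h["beta_out"] / h["beta_exp"]).to_numpy()
    w = (h["beta_exp"] ** 2 / h["se_out"] ** 2).to_numpy()
    theta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    k = len(h)
    if error_model == "multiplicative" and k > 1:
        dispersion = float(np.sum(w * (ratios - theta) ** 2) / (k - 1))
        se = se_fixed * np.sqrt(max(1.0, dispersion))
    elif error_model in ("fixed", "multiplicative"):
        se = se_fixed
    else:
        raise ValueError("error_model must be 'multiplicative' or 'fixed'")
    z = theta / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    return MREstimate(method="ivw", theta=theta, se=float(se), p=p,
                      n_snps=k, wald_ratios=ratios)


def mr_egger(harmonized: pd.DataFrame) -> MREstimate:
    """MR-Egger weighted regression with pleiotropy intercept.

    Requires ≥ 3 SNPs.  Exposure effects are oriented positive by
    flipping (β_exp, β_out) pairs.  With exactly 3 SNPs the residual df
    is 1 and the SEs are unstable; a warning is emitted.
    """
    h = _usable(harmonized)
    k = len(h)
    if k < 3:
        raise ValueError(f"MR-Egger needs at least 3 SNPs, got {k}")
    if k == 3:
        warnings.warn("MR-Egger with exactly 3 SNPs: 1 residual df, SEs unstable",
                      stacklevel=2)
    sign = np.sign(h["beta_exp"].to_numpy())
    bx = h["beta_exp"].to_numpy() * sign
    by = h["beta_out"].to_numpy() * sign
    w = 1.0 / h["se_out"].to_numpy() ** 2
    X = np.column_stack([np.ones(k), bx])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    coefs = np.linalg.solve(xtwx, X.T @ W @ by)
    resid = by - X @ coefs
    dispersion = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, dispersion)
    intercept, theta = float(coefs[0]), float(coefs[1])
    se_int, se_theta = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_theta = float(2 * stats.t.sf(abs(theta / se_theta), k - 2))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), k - 2))
    ratios = (h["beta_out"] / h["beta_exp"]).to_numpy()
    return MREstimate(method="egger", theta=theta, se=se_theta, p=p_theta,
                      n_snps=k, intercept=intercept, intercept_se=se_int,
                      intercept_p=p_int, wald_ratios=ratios)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation at cumulative weight 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def mr_weighted_median(
    harmonized: pd.DataFrame,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    h = _usable(harmonized)
    k = len(h)
    if k < 3:
        raise ValueError(f"weighted median needs at least 3 SNPs, got {k}")
    ratios = (h["beta_out"] / h["beta_exp"]).to_numpy()
    w = (h["beta_exp"] ** 2 / h["se_out"] ** 2).to_numpy()
    theta = weighted_median_point(ratios, w)
    ratio_se = (h["se_out"] / h["beta_exp"].abs()).to_numpy()
    rng = np.random.default_rng(seed)
    boot = np.empty(bootstrap_reps)
    for i in range(bootstrap_reps):
        boot[i] = weighted_median_point(
            rng.normal(ratios, ratio_se), w
        )
    se = float(boot.std(ddof=1))
    z = theta / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    return MREstimate(method="weighted_median", theta=theta, se=se, p=p,
                      n_snps=k, wald_ratios=ratios)


def leave_one_out(
    harmonized: pd.DataFrame,
    error_model: str = "multiplicative",
    flag_multiple: float = 1.0,
) -> pd.DataFrame:
    """IVW estimates dropping each SNP in turn.

    A SNP is flagged influential when its removal shifts θ by more than
    ``flag_multiple`` × the full-sample SE.
    """
    h = _usable(harmonized).reset_index(drop=True)
    if len(h) < 2:
        raise ValueError("leave-one-out needs at least 2 SNPs")
    full = mr_ivw(h, error_model=error_model)
    rows = []
    for i in range(len(h)):
        est = mr_ivw(h.drop(index=i), error_model=error_model)
        rows.append(
            {
                "snp": h.loc[i, "snp"],
                "theta": est.theta,
                "se": est.se,
                "p": est.p,
                "shift": est.theta - full.theta,
                "influential": abs(est.theta - full.theta) > flag_multiple * full.se,
            }
        )
    return pd.DataFrame(rows)


def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median"),
    loo: bool = True,
    seed: int | None = None,
) -> dict:
    """Harmonize and run the requested estimators; returns a result dict."""
    harmonized, audit = harmonize(exposure, outcome)
    out: dict = {"harmonized": harmonized, "harmonization_audit": audit, "estimates": []}
    dispatch = {
        "ivw": lambda: mr_ivw(harmonized),
        "egger": lambda: mr_egger(harmonized),
        "weighted_median": lambda: mr_weighted_median(harmonized, seed=seed),
    }
    for m in methods:
        if m not in dispatch:
            raise ValueError(f"unknown MR method {m!r}")
        out["estimates"].append(dispatch[m]())
    if loo:
        out["leave_one_out"] = leave_one_out(harmonized)
    return out
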