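"""Product-of-coefficients mediation between mtDNA CN and metabolic traits.

Two regression models decompose the effect of a predictor on an outcome
through a mediator (here, an epigenetic pace-of-aging metric):

    Model 1:  mediator = a·predictor + covariates
    Model 2:  outcome  = b·mediator + c′·predictor + covariates

The natural indirect effect is NIE = a·b, the total effect TE = a·b + c′,
and the percentage mediated PM = NIE/TE × 100.  Model 1 is always OLS;
Model 2 is OLS for continuous outcomes or logistic for binary outcomes,
in which case the decomposition lives on the log-odds scale under the
rare-outcome convention.  SE(NIE) uses the Sobel delta method
√(a²·SE_b² + b²·SE_a²); a seeded nonparametric bootstrap CI is optional.

Both causal directions are fit by swapping the predictor/outcome roles
(mitochondrial metric ↔ metabolic trait), since cross-sectional data
cannot privilege one orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .copy_number import _design_matrix

PM_TE_TOLERANCE = 1e-8


class SeparationError(RuntimeError):
    """Raised when the logistic outcome model exhibits separation."""


@dataclass
class MediationResult:
    direction: str  # "forward" | "reverse"
    a: float
    se_a: float
    b: float
    se_b: float
    c_prime: float
    se_c_prime: float
    nie: float
    te: float
    pm: float | None  # percent; None when TE ≈ 0 or signs disagree
    se_nie: float
    p_nie: float
    n: int
    boot_ci: tuple[float, float] | None = None

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        ci = d.pop("boot_ci")
        d["boot_lo"], d["boot_hi"] = (ci if ci is not None else (np.nan, np.nan))
        return d


def _fit_ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, X).fit()


def _fit_logit(y: np.ndarray, X: np.ndarray):
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"binary outcome must be coded 0/1; saw values {uniq[:5]}")
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation surfaces as our own error below
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and kin
        raise SeparationError(f"logistic outcome model failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic outcome model did not converge (possible separation)")
    if np.any(np.abs(res.params) > 50):
        raise SeparationError("implausibly large logistic coefficients suggest separation")
    return res


def _mediation_point(
    sub: pd.DataFrame, predictor: str, mediator: str, outcome: str,
    covariates: list[str], outcome_type: str,
):
    Xm = _design_matrix(sub[[predictor] + list(covariates)])
    m1 = _fit_ols(sub[mediator].to_numpy(dtype=float), Xm.to_numpy())
    ja = list(Xm.columns).index(predictor)

    Xo = _design_matrix(sub[[mediator, predictor] + list(covariates)])
    y = sub[outcome].to_numpy(dtype=float)
    if outcome_type == "binary":
        m2 = _fit_logit(y, Xo.to_numpy())
    else:
        m2 = _fit_ols(y, Xo.to_numpy())
    jb = list(Xo.columns).index(mediator)
    jc = list(Xo.columns).index(predictor)
    return (
        float(m1.params[ja]), float(m1.bse[ja]),
        float(m2.params[jb]), float(m2.bse[jb]),
        float(m2.params[jc]), float(m2.bse[jc]),
    )


def fit_mediation(
    data: pd.DataFrame,
    predictor: str,
    mediator: str,
    outcome: str,
    covariates: list[str] = (),
    outcome_type: str = "continuous",
    direction: str = "forward",
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> MediationResult:
    """Fit the two-model decomposition and return NIE/TE/PM with Sobel SE.

    PM is ``None`` (reported NA downstream) when |TE| < 1e-8 or when NIE
    and TE disagree in sign, which would place PM outside [0, 100]%.
    """
    if outcome_type not in ("continuous", "binary"):
        raise ValueError("outcome_type must be 'continuous' or 'binary'")
    for col in (predictor, mediator, outcome):
        if col not in data.columns:
            raise KeyError(f"column {col!r} missing from mediation input")
    sub = data[[predictor, mediator, outcome] + list(covariates)].dropna()
    n_params = _design_matrix(sub[[mediator, predictor] + list(covariates)]).shape[1]
    if len(sub) < n_params + 2:
        raise ValueError(
            f"{len(sub)} complete cases insufficient for {n_params} parameters"
        )

    a, se_a, b, se_b, c_prime, se_c = _mediation_point(
        sub, predictor, mediator, outcome, list(covariates), outcome_type
    )
    nie = a * b
    te = nie + c_prime
    if abs(te) < PM_TE_TOLERANCE:
        pm = None
    elif abs(nie) < PM_TE_TOLERANCE:
        pm = 0.0
    elif nie * te < 0:
        pm = None  # opposite signs would put PM outside [0, 100]%
    else:
        pm = 100.0 * nie / te
    se_nie = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    z = nie / se_nie if se_nie > 0 else np.inf
    p_nie = float(2 * stats.norm.sf(abs(z)))

    boot_ci = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        n = len(sub)
        draws = np.empty(bootstrap_reps)
        for r in range(bootstrap_reps):
            take = rng.integers(0, n, size=n)
            bsub = sub.iloc[take]
            try:
                ab = _mediation_point(bsub, predictor, mediator, outcome,
                                      list(covariates), outcome_type)
                draws[r] = ab[0] * ab[2]
            except (SeparationError, np.linalg.LinAlgError):
                draws[r] = np.nan
        ok = draws[~np.isnan(draws)]
        boot_ci = (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))

    return MediationResult(
        direction=direction, a=a, se_a=se_a, b=b, se_b=se_b,
        c_prime=c_prime, se_c_prime=se_c, nie=nie, te=te, pm=pm,
        se_nie=se_nie, p_nie=p_nie, n=len(sub), boot_ci=boot_ci,
    )


def bidirectional_mediation(
    data: pd.DataFrame,
    x: str,
    y: str,
    mediator: str,
    covariates: list[str] = (),
    x_type: str = "continuous",
    y_type: str = "continuous",
    bootstrap_reps: int = 0,
    seed: int | None = None,
) -> tuple[MediationResult, MediationResult]:
    """Forward (x → mediator → y) and reverse (y → mediator → x) fits."""
    forward = fit_mediation(
        data, predictor=x, mediator=mediator, outcome=y, covariates=covariates,
        outcome_type=y_type, direction="forward",
        bootstrap_reps=bootstrap_reps, seed=seed,
    )
    reverse = fit_mediation(
        data, predictor=y, mediator=mediator, outcome=x, covariates=covariates,
        outcome_type=x_type, direction="reverse",
        bootstrap_reps=bootstrap_reps, seed=seed,
    )
    return forward, reverse
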