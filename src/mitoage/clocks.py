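"""Linear and PC-linear epigenetic clock application and age acceleration.

A clock maps a methylation beta profile to either an age in years or a
yearly pace of aging (pace ≈ 1 means aging at the average rate).  Two
functional forms are supported:

direct
    value = intercept + Σ_k w_k · β_k over the clock's CpG support;
PC
    value = intercept + Σ_c u_c · (Σ_k L_kc · (β_k − μ_k)), i.e. the betas
    are centered, projected onto components, and the components weighted —
    the form used by principal-component clocks trained to suppress
    probe-level technical noise.

Epigenetic age acceleration (EAA) is the residual of the clock value
regressed on chronological age within explicit strata (typically cohort ×
ancestry group), so EAA is zero-mean and age-uncorrelated by construction
within each stratum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ClockError(ValueError):
    """Raised for malformed clock definitions or unusable beta matrices."""


@dataclass
class ClockDefinition:
    """A linear (direct or PC-form) DNA-methylation clock.

    Exactly one of ``weights`` (direct form) or the PC triple
    (``loadings``, ``component_weights``, ``centering``) must be set.
    """

    name: str
    scale: str  # "years" | "pace"
    intercept: float = 0.0
    weights: dict[str, float] | None = None
    loadings: pd.DataFrame | None = None           # CpG × component
    component_weights: np.ndarray | None = None    # per component
    centering: dict[str, float] | None = None      # CpG → μ
    max_missing: float = 0.05

    def __post_init__(self):
        if self.scale not in ("years", "pace"):
            raise ClockError(f"clock {self.name!r}: scale must be 'years' or 'pace'")
        direct = self.weights is not None
        pc = self.loadings is not None
        if direct == pc:
            raise ClockError(
                f"clock {self.name!r}: exactly one of direct weights or PC form required"
            )
        if direct and not self.weights:
            raise ClockError(f"clock {self.name!r}: empty weight support")
        if pc:
            if self.component_weights is None or self.centering is None:
                raise ClockError(f"clock {self.name!r}: PC form needs component weights and centering")
            if len(self.component_weights) != self.loadings.shape[1]:
                raise ClockError(f"clock {self.name!r}: component dimension mismatch")

    @property
    def support(self) -> list[str]:
        if self.weights is not None:
            return list(self.weights)
        return list(self.loadings.index)

    # --- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        d = {"name": self.name, "scale": self.scale, "intercept": self.intercept,
             "max_missing": self.max_missing}
        if self.weights is not None:
            d["weights"] = self.weights
        else:
            d["loadings"] = {cpg: self.loadings.loc[cpg].tolist() for cpg in self.loadings.index}
            d["component_weights"] = np.asarray(self.component_weights).tolist()
            d["centering"] = self.centering
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ClockDefinition":
        kwargs = dict(name=d["name"], scale=d["scale"],
                      intercept=float(d.get("intercept", 0.0)),
                      max_missing=float(d.get("max_missing", 0.05)))
        if "weights" in d:
            kwargs["weights"] = {k: float(v) for k, v in d["weights"].items()}
        else:
            loadings = pd.DataFrame.from_dict(d["loadings"], orient="index")
            kwargs["loadings"] = loadings
            kwargs["component_weights"] = np.asarray(d["component_weights"], dtype=float)
            kwargs["centering"] = {k: float(v) for k, v in d["centering"].items()}
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ClockDefinition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _prepare_betas(betas: pd.DataFrame, clock: ClockDefinition) -> pd.DataFrame:
    """Subset betas to the clock support, mean-imputing sparse missingness."""
    support = clock.support
    missing = [c for c in support if c not in betas.columns]
    frac = len(missing) / len(support)
    if frac > clock.max_missing:
        raise ClockError(
            f"clock {clock.name!r}: {len(missing)}/{len(support)} CpGs missing "
            f"({frac:.1%} > allowed {clock.max_missing:.1%})"
        )
    sub = betas.reindex(columns=support)
    if missing or sub.isna().any().any():
        if missing:
            warnings.warn(
                f"clock {clock.name!r}: mean-imputing {len(missing)} absent CpG(s)",
                stacklevel=3,
            )
        col_means = sub.mean(axis=0).fillna(betas.to_numpy().mean())
        sub = sub.fillna(col_means)
    return sub


def compute_clock_value(betas: pd.DataFrame, clock: ClockDefinition) -> pd.Series:
    """Apply a clock to a beta matrix (rows samples, columns CpGs)."""
    sub = _prepare_betas(betas, clock)
    if clock.weights is not None:
        w = np.array([clock.weights[c] for c in sub.columns])
        values = clock.intercept + sub.to_numpy() @ w
    else:
        mu = np.array([clock.centering.get(c, 0.0) for c in sub.columns])
        centered = sub.to_numpy() - mu
        scores = centered @ clock.loadings.loc[sub.columns].to_numpy()
        values = clock.intercept + scores @ np.asarray(clock.component_weights, dtype=float)
    return pd.Series(values, index=betas.index, name=clock.name)


@dataclass
class EAAResult:
    """Per-sample clock values and their age-residualized accelerations."""

    table: pd.DataFrame  # sample_id, clock, stratum, clock_value, eaa
    fits: dict = field(default_factory=dict)  # stratum → (intercept, slope)


def compute_eaa(
    clock_values: pd.Series,
    ages: pd.Series,
    strata: pd.Series,
    min_stratum_size: int = 3,
) -> EAAResult:
    """Residualize clock values on chronological age within strata.

    All three inputs must share an index of sample ids.  Raises
    ``ValueError`` naming any stratum with fewer than ``min_stratum_size``
    samples.
    """
    df = pd.DataFrame({"clock_value": clock_values, "age": ages, "stratum": strata})
    if df[["clock_value", "age"]].isna().any().any():
        raise ValueError("clock values and ages must be complete")
    eaa = pd.Series(np.nan, index=df.index)
    fits: dict = {}
    for stratum, sub in df.groupby("stratum"):
        if len(sub) < min_stratum_size:
            raise ValueError(
                f"stratum {stratum!r} has {len(sub)} samples (< {min_stratum_size})"
            )
        slope, intercept = np.polyfit(sub["age"], sub["clock_value"], 1)
        eaa.loc[sub.index] = sub["clock_value"] - (intercept + slope * sub["age"])
        fits[stratum] = (float(intercept), float(slope))
    out = df.assign(eaa=eaa)
    out.index.name = "sample_id"
    return EAAResult(table=out.reset_index(), fits=fits)
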