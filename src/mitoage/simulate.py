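"""Multi-cohort synthetic data with the statistical structure of an
mtDNA-aging / epigenetic-clock study, plus a ground-truth ledger.

The generator emulates, with known generating coefficients:

* four cohorts with distinct age distributions, sex/smoking composition,
  white-blood-cell proportions (Dirichlet), batches, and a two-lab split
  in the first cohort;
* rare heteroplasmic variant counts that are Poisson with a log-rate
  hinge at age 55 (flat before, rising after), VAFs skewed to low
  fractions, an MLC deleteriousness score per variant (a fraction
  missing, as for D-loop INDELs), plus decoy calls at blacklisted sites,
  at sub-threshold VAFs, and at low-coverage sample-sites so the
  filtering stages have something to remove;
* a common-heteroplasmy panel carried independently of age, partly
  placed inside the blacklist region;
* an mtDNA copy-number trajectory peaking near age 45–50 and declining
  linearly afterwards, expressed through mitochondrial/nuclear coverage
  summaries;
* a methylation beta matrix whose CpGs track a latent biological age
  BA = age + γ_MSS·MSS_std + γ_CN·CN_std + noise and a pace of aging
  pace = 1 + θ_CN·CN_std + noise, together with emitted year-scale
  (direct and PC-form) and pace-scale clock definitions that recover BA
  and pace up to noise;
* metabolic traits generated with a mediation structure
  CN → pace → trait on the log-odds scale, dichotomized at clinical
  thresholds (BMI ≥ 30, glucose ≥ 126 mg/dL or treatment, ...);
* two-sample GWAS summary statistics with a known causal effect and
  optional directional pleiotropy / invalid instruments.

Every quantity needed to verify downstream inference is recorded in the
:class:`TruthLedger`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clocks import ClockDefinition
from .heteroplasmy import (
    DEFAULT_BLACKLIST_RANGES,
    DEFAULT_VAF_WINDOW,
    MT_GENOME_LENGTH,
    build_site_mask,
)

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

WBC_COLUMNS = ("wbc_neut", "wbc_lymph", "wbc_mono", "wbc_eos", "wbc_baso")


class ConfigError(ValueError):
    """Raised when a :class:`SimConfig` field is out of bounds."""


@dataclass
class SimConfig:
    """All generator knobs.  Defaults describe the emulated study:
    four cohorts whose age distributions, sex balance and sequencing
    depth mirror a multi-cohort whole-genome + methylation design.
    """

    # --- cohorts ---------------------------------------------------------
    n_cohorts: int = 4
    n_per_cohort: tuple[int, ...] = (1745, 2289, 1424, 858)
    age_mean: tuple[float, ...] = (60.8, 45.6, 55.3, 60.2)
    age_sd: tuple[float, ...] = (13.6, 6.3, 12.4, 9.7)
    female_prop: float = 0.58
    smoking_current: float = 0.15
    smoking_former: float = 0.30
    wbc_concentration: tuple[float, ...] = (55.0, 30.0, 8.0, 5.0, 2.0)
    n_batches: int = 3
    n_labs_cohort1: int = 2  # FHS-style lab index in the first cohort

    # --- heteroplasmy ----------------------------------------------------
    het_eta0: float = -1.05   # baseline log-rate of rare variants
    het_eta1: float = 0.035   # extra log-rate per year past age 55
    vaf_alpha: float = 0.6
    vaf_beta: float = 2.5
    blacklist_call_rate: float = 0.05     # decoy calls per sample at masked sites
    subthreshold_call_rate: float = 0.05  # decoy calls per sample outside VAF window
    lowcov_call_fraction: float = 0.02    # true calls flagged low-coverage
    mlc_alpha: float = 2.0
    mlc_beta: float = 5.0
    mlc_missing: float = 0.2
    panel_positions: int = 16
    panel_alleles: int = 39
    panel_carriage: float = 0.025
    panel_blacklist_positions: int = 3

    # --- copy number -----------------------------------------------------
    cn_peak_age: float = 47.5
    cn_peak_mean: float = 110.0
    cn_rise_slope: float = 0.3     # per year below the peak age
    cn_decline_slope: float = 0.6  # per year above the peak age
    cn_noise_sd: float = 15.0
    cn_floor: float = 5.0
    nuclear_cov_mean: float = 39.0
    nuclear_cov_sd: float = 3.0

    # --- methylation / clocks -------------------------------------------
    n_cpgs_year: int = 120
    n_cpgs_pace: int = 60
    cpg_noise_sd: float = 0.01
    ba_noise_sd: float = 3.0
    gamma_mss: float = 0.2     # years of BA per SD of MSS
    gamma_cn: float = -0.15    # years of BA per SD of CN
    theta_cn: float = -0.005   # pace units per SD of CN
    pace_noise_sd: float = 0.05

    # --- traits (log-odds scale) ----------------------------------------
    obesity_intercept: float = -1.0
    obesity_b_pace: float = 4.0    # per pace unit
    obesity_c_cn: float = -0.16    # direct effect per SD of CN
    t2dm_intercept: float = -1.7
    t2dm_b_pace: float = 4.0
    t2dm_c_cn: float = -0.165
    treated_fraction: float = 0.4

    # --- Mendelian randomization ----------------------------------------
    mr_n_snps: int = 41
    mr_theta: float = 0.3
    mr_pleiotropy: float = 0.0          # constant δ added to every outcome β
    mr_invalid_fraction: float = 0.0
    mr_invalid_pleiotropy: float = 0.1  # extra δ on invalid instruments
    mr_beta_exp_low: float = 0.02
    mr_beta_exp_high: float = 0.10
    mr_se_exp: float = 0.005
    mr_se_out: float = 0.01
    mr_noise_sd: float | None = None    # outcome noise; defaults to mr_se_out

    seed: int = 0

    def __post_init__(self):
        def _tuple(name, value):
            v = tuple(value) if np.iterable(value) else (value,) * self.n_cohorts
            if len(v) == 1:
                v = v * self.n_cohorts
            if len(v) != self.n_cohorts:
                raise ConfigError(f"{name}: expected {self.n_cohorts} values, got {len(v)}")
            return v

        if self.n_cohorts < 1:
            raise ConfigError("n_cohorts: must be >= 1")
        self.n_per_cohort = _tuple("n_per_cohort", self.n_per_cohort)
        self.age_mean = _tuple("age_mean", self.age_mean)
        self.age_sd = _tuple("age_sd", self.age_sd)
        for name in ("female_prop", "smoking_current", "smoking_former",
                     "mlc_missing", "panel_carriage", "lowcov_call_fraction",
                     "mr_invalid_fraction", "treated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: proportion {v} outside [0, 1]")
        if self.smoking_current + self.smoking_former > 1.0:
            raise ConfigError("smoking_current + smoking_former exceeds 1")
        for name in ("n_per_cohort",):
            if any(n < 1 for n in self.n_per_cohort):
                raise ConfigError("n_per_cohort: all counts must be >= 1")
        self.wbc_concentration = tuple(self.wbc_concentration)
        if any(c <= 0 for c in self.wbc_concentration):
            raise ConfigError("wbc_concentration: all concentrations must be positive")
        for name in ("n_batches", "panel_positions", "panel_alleles",
                     "n_cpgs_year", "n_cpgs_pace"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name}: must be >= 1")
        if self.mr_n_snps < 2:
            raise ConfigError("mr_n_snps: need at least 2 SNPs")
        if self.panel_blacklist_positions > self.panel_positions:
            raise ConfigError("panel_blacklist_positions exceeds panel_positions")
        if self.n_cpgs_year < 2 or self.n_cpgs_pace < 2:
            raise ConfigError("clock CpG counts must be >= 2 to support a clock")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TruthLedger:
    """Ground truth of a simulated study: per-sample latent quantities and
    the generating coefficients downstream inference should recover."""

    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    coefficients: dict = field(default_factory=dict)

    def update_samples(self, frame: pd.DataFrame) -> None:
        if self.samples.empty:
            self.samples = frame.copy()
        else:
            new_cols = [c for c in frame.columns if c not in self.samples.columns]
            self.samples = self.samples.join(frame[new_cols], how="left")

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "samples": self.samples.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        samples = pd.DataFrame(payload["samples"]).set_index("sample_id")
        return cls(samples=samples, coefficients=payload["coefficients"])


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


def cohort_names(config: SimConfig) -> list[str]:
    return [f"cohort{i + 1}" for i in range(config.n_cohorts)]


# ---------------------------------------------------------------------------
# stage 1: covariates
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig, seed: int | None = None) -> tuple[pd.DataFrame, TruthLedger]:
    """Per-sample covariate table: cohort, age, sex, smoking, WBC
    proportions (summing to 1), batch, lab index."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)
    frames = []
    for c, name in enumerate(cohort_names(config)):
        n = config.n_per_cohort[c]
        ids = [f"{name}_s{i:05d}" for i in range(n)]
        age = np.clip(rng.normal(config.age_mean[c], config.age_sd[c], n), 18.0, 100.0)
        female = (rng.random(n) < config.female_prop).astype(int)
        u = rng.random(n)
        smoking = np.where(
            u < config.smoking_current, "current",
            np.where(u < config.smoking_current + config.smoking_former, "former", "never"),
        )
        wbc = rng.dirichlet(np.asarray(config.wbc_concentration, dtype=float), size=n)
        batch = np.array([f"b{j + 1}" for j in rng.integers(0, config.n_batches, n)])
        if c == 0 and config.n_labs_cohort1 > 1:
            lab = np.array([f"L{j + 1}" for j in rng.integers(0, config.n_labs_cohort1, n)])
        else:
            lab = np.array(["L1"] * n)
        frame = pd.DataFrame(
            {"sample_id": ids, "cohort": name, "age": age, "female": female,
             "smoking": smoking, "batch": batch, "lab": lab}
        )
        for j, col in enumerate(WBC_COLUMNS):
            frame[col] = wbc[:, j]
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True).set_index("sample_id")
    ledger = TruthLedger()
    ledger.update_samples(table[["cohort", "age"]])
    return table.reset_index(), ledger


# ---------------------------------------------------------------------------
# stage 2: mtDNA variants and coverage
# ---------------------------------------------------------------------------

@dataclass
class MtdnaData:
    calls: pd.DataFrame           # sample_id, position, ref, alt, vaf, depth
    coverage_summary: pd.DataFrame  # sample_id, mt_coverage, nuclear_coverage
    site_coverage: pd.DataFrame   # sample_id, position, coverage (sparse)
    mlc: pd.DataFrame             # position, ref, alt, mlc
    panel: pd.DataFrame           # position, ref, alt


def _truncated_beta(rng, a, b, lo, hi, size):
    flo, fhi = sps.beta.cdf([lo, hi], a, b)
    return sps.beta.ppf(flo + rng.random(size) * (fhi - flo), a, b)


def generate_mtdna(
    cohort: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    ledger: TruthLedger | None = None,
) -> MtdnaData:
    """Variant calls, coverage summaries, MLC table and common panel.

    Rare-variant counts are Poisson with log-rate
    η0 + η1·max(0, age − 55); positions are uniform over retained sites.
    Decoy calls at blacklisted positions, at out-of-window VAFs, and at
    low-coverage sample-sites are added so the filters are exercised; the
    truth ledger records only calls that survive all filters.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 2)
    mask = build_site_mask()
    blacklisted = np.fromiter(mask.excluded, dtype=int)
    retained = np.setdiff1d(np.arange(1, MT_GENOME_LENGTH + 1), blacklisted)
    lo, hi = DEFAULT_VAF_WINDOW

    n = len(cohort)
    ids = cohort["sample_id"].to_numpy()
    age = cohort["age"].to_numpy()

    # copy number trajectory → coverage
    dist = age - config.cn_peak_age
    cn_mean = (config.cn_peak_mean
               - config.cn_rise_slope * np.maximum(0.0, -dist)
               - config.cn_decline_slope * np.maximum(0.0, dist))
    true_cn = np.maximum(config.cn_floor, cn_mean + rng.normal(0, config.cn_noise_sd, n))
    nuclear = np.clip(rng.normal(config.nuclear_cov_mean, config.nuclear_cov_sd, n), 10.0, None)
    mt_cov = true_cn * nuclear / 2.0
    coverage_summary = pd.DataFrame(
        {"sample_id": ids, "mt_coverage": mt_cov, "nuclear_coverage": nuclear}
    )

    # common panel: some positions inside the blacklist to exercise masking
    panel_bl = rng.choice(blacklisted, size=config.panel_blacklist_positions, replace=False)
    panel_ok = rng.choice(retained, size=config.panel_positions - config.panel_blacklist_positions,
                          replace=False)
    panel_pos = np.concatenate([panel_ok, panel_bl])
    pos_of_allele = rng.choice(panel_pos, size=config.panel_alleles, replace=True)
    panel_rows, seen = [], set()
    for p in pos_of_allele:
        ref = _BASES[rng.integers(4)]
        alts = [b for b in _BASES if b != ref]
        for _ in range(8):
            alt = alts[rng.integers(3)]
            if (int(p), alt) not in seen:
                seen.add((int(p), alt))
                panel_rows.append({"position": int(p), "ref": ref, "alt": alt})
                break
    panel = pd.DataFrame(panel_rows).drop_duplicates(["position", "alt"]).reset_index(drop=True)

    call_frames = []
    # panel carriage, age-independent
    carry = rng.random((n, len(panel))) < config.panel_carriage
    si, vi = np.nonzero(carry)
    if len(si):
        call_frames.append(pd.DataFrame({
            "sample_id": ids[si],
            "position": panel.loc[vi, "position"].to_numpy(),
            "ref": panel.loc[vi, "ref"].to_numpy(),
            "alt": panel.loc[vi, "alt"].to_numpy(),
            "vaf": _truncated_beta(rng, 2.0, 2.0, lo, hi, len(si)),
            "kind": "panel",
        }))

    # rare variants: Poisson hinge model.  Panel positions are excluded
    # from the draw so no rare variant aliases a common-panel variant.
    rare_pool = np.setdiff1d(retained, panel_pos)
    lam = np.exp(config.het_eta0 + config.het_eta1 * np.maximum(0.0, age - 55.0))
    counts = rng.poisson(lam)
    owner = np.repeat(np.arange(n), counts)
    m = len(owner)
    if m:
        positions = rng.choice(rare_pool, size=m, replace=True)
        refs = _BASES[rng.integers(0, 4, m)]
        shift = rng.integers(1, 4, m)
        alts = _BASES[(np.searchsorted(_BASES, refs) + shift) % 4]
        same = alts == refs
        alts[same] = _BASES[(np.searchsorted(_BASES, refs[same]) + 1) % 4]
        lowcov = rng.random(m) < config.lowcov_call_fraction
        call_frames.append(pd.DataFrame({
            "sample_id": ids[owner],
            "position": positions,
            "ref": refs,
            "alt": alts,
            "vaf": _truncated_beta(rng, config.vaf_alpha, config.vaf_beta, lo, hi, m),
            "kind": np.where(lowcov, "rare_lowcov", "rare"),
        }))

    # decoys: blacklisted-site calls and out-of-window VAFs
    for rate, kind in ((config.blacklist_call_rate, "decoy_masked"),
                       (config.subthreshold_call_rate, "decoy_vaf")):
        cnt = rng.poisson(rate, n)
        owner_d = np.repeat(np.arange(n), cnt)
        md = len(owner_d)
        if not md:
            continue
        if kind == "decoy_masked":
            pos_d = rng.choice(blacklisted, size=md, replace=True)
            vaf_d = _truncated_beta(rng, config.vaf_alpha, config.vaf_beta, lo, hi, md)
        else:
            pos_d = rng.choice(retained, size=md, replace=True)
            below = rng.random(md) < 0.5
            vaf_d = np.where(below,
                             rng.uniform(0.005, lo - 0.005, md),
                             rng.uniform(hi + 0.005, 0.999, md))
        refs_d = _BASES[rng.integers(0, 4, md)]
        alts_d = _BASES[(np.searchsorted(_BASES, refs_d) + rng.integers(1, 4, md)) % 4]
        same = alts_d == refs_d
        alts_d[same] = _BASES[(np.searchsorted(_BASES, refs_d[same]) + 1) % 4]
        call_frames.append(pd.DataFrame({
            "sample_id": ids[owner_d], "position": pos_d, "ref": refs_d,
            "alt": alts_d, "vaf": vaf_d, "kind": kind,
        }))

    calls = (pd.concat(call_frames, ignore_index=True) if call_frames
             else pd.DataFrame(columns=["sample_id", "position", "ref", "alt", "vaf", "kind"]))
    calls = calls.drop_duplicates(["sample_id", "position", "alt"]).reset_index(drop=True)

    # per-call depth around the sample's mitochondrial coverage
    cov_of = dict(zip(ids, mt_cov))
    depths = rng.poisson([max(cov_of[s], 1.0) for s in calls["sample_id"]]) if len(calls) else []
    calls["depth"] = np.asarray(depths, dtype=int) if len(calls) else pd.Series(dtype=int)

    # sparse per-site coverage table: low-coverage entries for flagged calls
    low = calls["kind"] == "rare_lowcov"
    site_cov = pd.DataFrame({
        "sample_id": calls.loc[low, "sample_id"].to_numpy(),
        "position": calls.loc[low, "position"].to_numpy(),
        "coverage": rng.uniform(50, 249, int(low.sum())),
    })

    # MLC table over observed non-panel variants (a fraction missing)
    rare_variants = (calls.loc[calls["kind"].isin(["rare", "rare_lowcov"]),
                               ["position", "ref", "alt"]]
                     .drop_duplicates(["position", "alt"]).reset_index(drop=True))
    has_mlc = rng.random(len(rare_variants)) >= config.mlc_missing
    mlc = rare_variants.loc[has_mlc].copy()
    mlc["mlc"] = rng.beta(config.mlc_alpha, config.mlc_beta, len(mlc))

    # ground truth burden scores (calls surviving every filter)
    valid = calls.loc[calls["kind"] == "rare"].copy()
    mlc_map = mlc.set_index(["position", "alt"])["mlc"]
    keys = pd.MultiIndex.from_arrays([valid["position"], valid["alt"]])
    valid["mlc"] = mlc_map.reindex(keys).fillna(0.0).to_numpy()
    panel_kept = calls.loc[(calls["kind"] == "panel")
                           & ~calls["position"].isin(blacklisted)]
    truth = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    truth["true_MHcount"] = valid.groupby("sample_id").size().reindex(truth.index, fill_value=0)
    truth["true_MSS"] = valid.groupby("sample_id")["mlc"].sum().reindex(truth.index, fill_value=0.0)
    truth["true_MH_com_count"] = (panel_kept.groupby("sample_id").size()
                                  .reindex(truth.index, fill_value=0))
    truth["true_mtDNA_CN"] = true_cn

    if ledger is not None:
        ledger.update_samples(truth)
        ledger.coefficients.update({
            "het_eta0": config.het_eta0, "het_eta1": config.het_eta1,
            "cn_peak_age": config.cn_peak_age, "cn_peak_mean": config.cn_peak_mean,
        })

    calls = calls.drop(columns=["kind"]).sort_values(
        ["sample_id", "position", "alt"]).reset_index(drop=True)
    return MtdnaData(calls=calls, coverage_summary=coverage_summary,
                     site_coverage=site_cov, mlc=mlc, panel=panel)


# ---------------------------------------------------------------------------
# stage 3: methylation and clocks
# ---------------------------------------------------------------------------

def _cohort_standardize(values: pd.Series, cohorts: pd.Series) -> pd.Series:
    def z(x):
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0
    return values.groupby(cohorts).transform(z)


def generate_methylation_clocks(
    cohort: pd.DataFrame,
    ledger: TruthLedger,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[ClockDefinition]]:
    """Beta matrix plus clock definitions that recover the latent truth.

    The year-scale clock is emitted in both direct and PC form (the two
    are algebraically identical); the pace-scale clock is direct.  CpG
    betas are linear in the latent quantity plus Gaussian noise, clipped
    to [0, 1]; slopes and intercepts are chosen so clipping is rare.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 3)
    df = cohort.set_index("sample_id")
    truth = ledger.samples.loc[df.index]

    mss_std = _cohort_standardize(truth["true_MSS"], truth["cohort"])
    cn_std = _cohort_standardize(truth["true_mtDNA_CN"], truth["cohort"])
    n = len(df)
    ba = (df["age"].to_numpy()
          + config.gamma_mss * mss_std.to_numpy()
          + config.gamma_cn * cn_std.to_numpy()
          + rng.normal(0, config.ba_noise_sd, n))
    pace = 1.0 + config.theta_cn * cn_std.to_numpy() + rng.normal(0, config.pace_noise_sd, n)

    ba_center = 55.0
    ky = config.n_cpgs_year
    cy = rng.uniform(0.3, 0.7, ky)
    sy = rng.uniform(0.001, 0.003, ky) * rng.choice([-1.0, 1.0], ky)
    year_block = np.clip(
        cy + np.outer(ba - ba_center, sy) + rng.normal(0, config.cpg_noise_sd, (n, ky)),
        0.0, 1.0,
    )
    kp = config.n_cpgs_pace
    cp = rng.uniform(0.35, 0.65, kp)
    sp = rng.uniform(0.1, 0.3, kp) * rng.choice([-1.0, 1.0], kp)
    pace_block = np.clip(
        cp + np.outer(pace - 1.0, sp) + rng.normal(0, config.cpg_noise_sd, (n, kp)),
        0.0, 1.0,
    )

    year_cpgs = [f"cgY{j:05d}" for j in range(ky)]
    pace_cpgs = [f"cgP{j:05d}" for j in range(kp)]
    betas = pd.DataFrame(
        np.hstack([year_block, pace_block]),
        index=df.index, columns=year_cpgs + pace_cpgs,
    )

    wy = sy / np.sum(sy**2)
    year_clock = ClockDefinition(
        name="sim_year_clock", scale="years",
        intercept=float(ba_center - np.dot(wy, cy)),
        weights=dict(zip(year_cpgs, wy.astype(float))),
    )
    # PC form of the same clock: first loading column carries the signal
    loadings = pd.DataFrame(
        np.column_stack([sy, rng.normal(0, 1e-3, ky)]),
        index=year_cpgs, columns=[0, 1],
    )
    pc_year_clock = ClockDefinition(
        name="sim_pc_year_clock", scale="years", intercept=ba_center,
        loadings=loadings,
        component_weights=np.array([1.0 / np.sum(sy**2), 0.0]),
        centering=dict(zip(year_cpgs, cy.astype(float))),
    )
    wp = sp / np.sum(sp**2)
    pace_clock = ClockDefinition(
        name="sim_pace_clock", scale="pace",
        intercept=float(1.0 - np.dot(wp, cp)),
        weights=dict(zip(pace_cpgs, wp.astype(float))),
    )

    ledger.update_samples(pd.DataFrame(
        {"true_BA": ba, "true_pace": pace,
         "true_MSS_std": mss_std.to_numpy(), "true_CN_std": cn_std.to_numpy()},
        index=df.index,
    ))
    ledger.coefficients.update({
        "gamma_mss": config.gamma_mss, "gamma_cn": config.gamma_cn,
        "theta_cn": config.theta_cn,
    })
    return betas, [year_clock, pc_year_clock, pace_clock]


# ---------------------------------------------------------------------------
# stage 4: metabolic traits
# ---------------------------------------------------------------------------

def threshold_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the clinical threshold definitions to continuous measures.

    obesity: BMI ≥ 30 kg/m² (inclusive); T2DM: fasting glucose ≥ 126
    mg/dL or diabetes treatment; stage-2 hypertension: SBP ≥ 140 or
    DBP ≥ 90 mmHg or antihypertensive use; hyperlipidemia: total
    cholesterol ≥ 200 or triglycerides ≥ 150 mg/dL or lipid-lowering use.
    """
    out = df.copy()
    out["obesity"] = (df["bmi"] >= 30.0).astype(int)
    out["t2dm"] = ((df["glucose"] >= 126.0) | (df["diabetes_treatment"] == 1)).astype(int)
    out["hypertension"] = ((df["sbp"] >= 140.0) | (df["dbp"] >= 90.0)
                           | (df["bp_treatment"] == 1)).astype(int)
    out["hyperlipidemia"] = ((df["cholesterol"] >= 200.0) | (df["triglycerides"] >= 150.0)
                             | (df["lipid_treatment"] == 1)).astype(int)
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_traits(
    cohort: pd.DataFrame,
    ledger: TruthLedger,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Metabolic phenotypes with a CN → pace → trait mediation structure.

    Obesity and T2DM case status is drawn from a logistic model in the
    latent pace (mediator path b) and standardized CN (direct path c′);
    continuous BMI/glucose are then drawn consistently with case status
    so the clinical threshold rules reproduce the flags exactly.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 4)
    df = cohort.set_index("sample_id")
    truth = ledger.samples.loc[df.index]
    if "true_pace" not in truth.columns:
        raise ValueError("clock truth must be generated before traits")
    pace = truth["true_pace"].to_numpy()
    cn_std = truth["true_CN_std"].to_numpy()
    age = df["age"].to_numpy()
    n = len(df)

    p_ob = _sigmoid(config.obesity_intercept
                    + config.obesity_b_pace * (pace - 1.0)
                    + config.obesity_c_cn * cn_std)
    obese = rng.random(n) < p_ob
    bmi = np.where(obese,
                   30.0 + rng.gamma(2.0, 2.0, n),
                   18.5 + 11.4 * rng.beta(2.0, 2.0, n))

    p_dm = _sigmoid(config.t2dm_intercept
                    + config.t2dm_b_pace * (pace - 1.0)
                    + config.t2dm_c_cn * cn_std)
    dm = rng.random(n) < p_dm
    treated = dm & (rng.random(n) < config.treated_fraction)
    glucose = np.where(
        dm & ~treated, 126.0 + rng.exponential(20.0, n),
        np.where(treated,
                 np.clip(rng.normal(115.0, 15.0, n), 70.0, 400.0),
                 np.clip(rng.normal(95.0, 10.0, n), 60.0, 125.0)),
    )

    sbp = rng.normal(118.0 + 0.35 * (age - 50.0), 12.0)
    dbp = rng.normal(75.0 + 0.10 * (age - 50.0), 8.0)
    bp_rx = rng.random(n) < np.where(age >= 60, 0.20, 0.08)
    chol = rng.normal(190.0 + 0.3 * (age - 50.0), 30.0)
    trig = np.clip(rng.normal(130.0, 40.0, n), 30.0, None)
    lipid_rx = rng.random(n) < 0.15
    cvd = rng.random(n) < _sigmoid(-4.0 + 0.05 * (age - 50.0))

    traits = pd.DataFrame(
        {"bmi": bmi, "glucose": glucose, "diabetes_treatment": treated.astype(int),
         "sbp": sbp, "dbp": dbp, "bp_treatment": bp_rx.astype(int),
         "cholesterol": chol, "triglycerides": trig,
         "lipid_treatment": lipid_rx.astype(int), "cvd": cvd.astype(int)},
        index=df.index,
    )
    traits = threshold_traits(traits)
    ledger.coefficients.update({
        "obesity_a": config.theta_cn, "obesity_b": config.obesity_b_pace,
        "obesity_c_prime": config.obesity_c_cn,
        "obesity_true_pm": 100.0 * (config.theta_cn * config.obesity_b_pace)
        / (config.theta_cn * config.obesity_b_pace + config.obesity_c_cn),
        "t2dm_a": config.theta_cn, "t2dm_b": config.t2dm_b_pace,
        "t2dm_c_prime": config.t2dm_c_cn,
        "t2dm_true_pm": 100.0 * (config.theta_cn * config.t2dm_b_pace)
        / (config.theta_cn * config.t2dm_b_pace + config.t2dm_c_cn),
    })
    return traits.reset_index()


# ---------------------------------------------------------------------------
# stage 5: two-sample MR summary statistics
# ---------------------------------------------------------------------------

def generate_mr_dataset(
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Exposure/outcome GWAS summary statistics with known causal effect.

    Outcome β = θ·exposure β + δ + (invalid extra δ) + noise.  Exposure
    effect alleles are oriented so all exposure betas are positive, the
    convention under which a constant δ is the MR-Egger intercept.
    """
    if config.mr_n_snps < 2:
        raise ConfigError("mr_n_snps: need at least 2 SNPs")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 5)
    k = config.mr_n_snps
    snps = [f"rs{i + 1:06d}" for i in range(k)]
    ea = _BASES[rng.integers(0, 4, k)]
    # avoid palindromic pairs so no instruments are lost in harmonization
    oa = np.array([
        rng.choice([b for b in _BASES if b != e and b != _COMPLEMENT[e]])
        for e in ea
    ])
    eaf = rng.uniform(0.1, 0.9, k)
    beta_exp = rng.uniform(config.mr_beta_exp_low, config.mr_beta_exp_high, k)
    n_invalid = int(round(config.mr_invalid_fraction * k))
    invalid = np.zeros(k, dtype=bool)
    invalid[:n_invalid] = True
    noise_sd = config.mr_se_out if config.mr_noise_sd is None else config.mr_noise_sd
    beta_out = (config.mr_theta * beta_exp
                + config.mr_pleiotropy
                + np.where(invalid, config.mr_invalid_pleiotropy, 0.0)
                + (rng.normal(0, noise_sd, k) if noise_sd > 0 else 0.0))

    def _side(beta, se):
        z = beta / se
        return pd.DataFrame({
            "snp": snps, "ea": ea, "oa": oa, "eaf": eaf,
            "beta": beta, "se": se, "p": 2 * sps.norm.sf(np.abs(z)),
        })

    exposure = _side(beta_exp, np.full(k, config.mr_se_exp))
    outcome = _side(beta_out, np.full(k, config.mr_se_out))
    truth = {"theta": config.mr_theta, "pleiotropy": config.mr_pleiotropy,
             "invalid_snps": list(np.asarray(snps)[invalid])}
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# one-call study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    config: SimConfig
    cohort: pd.DataFrame
    mtdna: MtdnaData
    betas: pd.DataFrame
    clocks: list[ClockDefinition]
    traits: pd.DataFrame
    mr_exposure: pd.DataFrame
    mr_outcome: pd.DataFrame
    mr_truth: dict
    ledger: TruthLedger


def simulate_study(config: SimConfig, seed: int | None = None) -> StudyData:
    """Run every generator stage with per-stage seeds derived from one seed."""
    seed = config.seed if seed is None else seed
    cohort, ledger = generate_cohort(config, seed)
    mtdna = generate_mtdna(cohort, config, seed, ledger=ledger)
    betas, clocks = generate_methylation_clocks(cohort, ledger, config, seed)
    traits = generate_traits(cohort, ledger, config, seed)
    mr_exp, mr_out, mr_truth = generate_mr_dataset(config, seed)
    return StudyData(config=config, cohort=cohort, mtdna=mtdna, betas=betas,
                     clocks=clocks, traits=traits, mr_exposure=mr_exp,
                     mr_outcome=mr_out, mr_truth=mr_truth, ledger=ledger)
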