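"""End-to-end orchestration: simulate/ingest → score → QC → clocks →
associate → meta → mediate → MR, from a single config.

Each stage writes tidy TSVs into the output directory; a JSON manifest
records the config hash, seeds and package versions so a run can be
reproduced or resumed per stage.  Numeric output uses a fixed float
format, making re-runs with identical config and seed byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association, copy_number, heteroplasmy, io, mediation, mr, simulate
from . import clocks as clocks_mod

logger = logging.getLogger("mitoage")

STAGES = ("simulate", "score", "qc", "clocks", "associate", "ewas", "mediate", "mr")

RESULT_FILES = {
    "burden": "burden.tsv",
    "filter_audit": "filter_audit.tsv",
    "metrics": "metrics.tsv",
    "qc_audit": "qc_audit.tsv",
    "eaa": "eaa.tsv",
    "associations": "associations.tsv",
    "meta": "meta.tsv",
    "forest": "forest.tsv",
    "mediation": "mediation.tsv",
    "mr_results": "mr_results.tsv",
    "mr_loo": "mr_loo.tsv",
}

MT_METRICS_STD = ["MHcount_std", "MSS_std", "MH_com_count_std", "mtDNA_CN_std"]
RESID_COVARIATES = ["wbc_neut", "wbc_lymph", "wbc_mono", "wbc_eos", "batch", "smoking"]
ASSOC_COVARIATES = ["age", "age_sq", "female", "smoking",
                    "wbc_neut", "wbc_lymph", "wbc_mono", "wbc_eos", "batch", "lab"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""


@dataclass
class RunConfig:
    outdir: str = "results"
    seed: int = 0
    simulation: dict | None = field(default_factory=dict)  # SimConfig overrides; None → ingest
    inputs: dict | None = None      # paths, when not simulating
    discovery_cohort: str = "cohort1"
    significance_threshold: float = association.DEFAULT_SIGNIFICANCE_THRESHOLD
    n_eaa_outcomes: int = association.DEFAULT_N_EAA_OUTCOMES
    fdr_level: float = 0.05
    age_cut: float = 60.0
    run_ewas: bool = True
    ewas_metric: str = "MSS_std"
    skip_stages: tuple[str, ...] = ()

    def __post_init__(self):
        for name in ("significance_threshold", "fdr_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        bad = set(self.skip_stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages in skip_stages: {sorted(bad)}")
        if self.simulation is None and not self.inputs:
            raise ValueError("either a simulation block or input paths are required")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if "skip_stages" in d:
            d["skip_stages"] = tuple(d["skip_stages"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def _active_covariates(df: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Drop covariates that are constant within the fitted subset."""
    return [c for c in candidates if c in df.columns and df[c].nunique() > 1]


def _simulate_inputs(cfg: RunConfig, outdir: Path) -> dict:
    sim_cfg = simulate.SimConfig.from_dict({**(cfg.simulation or {}), "seed": cfg.seed})
    study = simulate.simulate_study(sim_cfg)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    io.write_tsv(study.cohort, inputs / "covariates.tsv")
    io.write_vcf(study.mtdna.calls, inputs / "calls.vcf",
                 sample_ids=study.cohort["sample_id"].tolist())
    io.write_tsv(study.mtdna.coverage_summary, inputs / "coverage.tsv")
    io.write_tsv(study.mtdna.site_coverage, inputs / "site_coverage.tsv")
    io.write_tsv(study.mtdna.mlc, inputs / "mlc.tsv")
    io.write_tsv(study.mtdna.panel, inputs / "panel.tsv")
    io.write_beta_matrix(study.betas, inputs / "betas.tsv")
    io.write_clocks(study.clocks, inputs / "clocks")
    io.write_tsv(study.traits, inputs / "traits.tsv")
    io.write_tsv(study.mr_exposure, inputs / "mr_exposure.tsv")
    io.write_tsv(study.mr_outcome, inputs / "mr_outcome.tsv")
    study.ledger.to_json(inputs / "truth.json")
    return {
        "covariates": inputs / "covariates.tsv",
        "vcf": inputs / "calls.vcf",
        "coverage": inputs / "coverage.tsv",
        "site_coverage": inputs / "site_coverage.tsv",
        "mlc": inputs / "mlc.tsv",
        "panel": inputs / "panel.tsv",
        "betas": inputs / "betas.tsv",
        "clocks": inputs / "clocks",
        "traits": inputs / "traits.tsv",
        "mr_exposure": inputs / "mr_exposure.tsv",
        "mr_outcome": inputs / "mr_outcome.tsv",
    }


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all configured stages; returns the results directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            def run(*args, **kwargs):
                if name in cfg.skip_stages:
                    logger.info("stage %s skipped by config", name)
                    return None
                t0 = time.perf_counter()
                logger.info("stage %s started", name)
                try:
                    result = fn(*args, **kwargs)
                except Exception as exc:
                    logger.error("stage %s failed: %s", name, exc)
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                timings[name] = time.perf_counter() - t0
                logger.info("stage %s finished in %.2fs", name, timings[name])
                return result
            return run
        return deco

    # ------------------------------------------------------------------ inputs
    if cfg.simulation is not None:
        paths = stage("simulate")(_simulate_inputs)(cfg, outdir)
    else:
        paths = {k: Path(v) for k, v in cfg.inputs.items()}
        missing = [str(p) for p in paths.values() if not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing input path(s): {missing}")

    covariates = io.read_tsv(paths["covariates"])
    covariates["age_sq"] = covariates["age"] ** 2
    sample_ids = covariates["sample_id"].tolist()

    # ------------------------------------------------------------------ score
    @stage("score")
    def _score():
        calls = io.read_vcf(paths["vcf"])
        site_cov = io.read_tsv(paths["site_coverage"]) if "site_coverage" in paths else None
        mlc = io.read_tsv(paths["mlc"]) if "mlc" in paths else None
        panel = io.read_tsv(paths["panel"]) if "panel" in paths else None
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # missing-MLC warnings are summarised in the audit log
            result = heteroplasmy.score_study(
                calls, sample_ids, mlc=mlc, panel=panel, site_coverage=site_cov
            )
        io.write_tsv(result.scores, outdir / RESULT_FILES["burden"])
        io.write_tsv(result.audit, outdir / RESULT_FILES["filter_audit"])
        logger.info("filter audit: %s", result.audit["reason"].value_counts().to_dict()
                    if len(result.audit) else {})
        return result.scores

    scores = _score()

    # ------------------------------------------------------------------ qc
    @stage("qc")
    def _qc():
        coverage = io.read_tsv(paths["coverage"])
        cn = copy_number.compute_mtdna_cn(
            coverage["mt_coverage"].to_numpy(), coverage["nuclear_coverage"].to_numpy()
        )
        cn_table = pd.DataFrame({"sample_id": coverage["sample_id"], "mtDNA_CN": cn})
        retained, audit = copy_number.apply_sample_qc(scores, cn_table)
        io.write_tsv(audit, outdir / RESULT_FILES["qc_audit"])
        merged = (covariates.merge(scores, on="sample_id")
                  .merge(cn_table, on="sample_id"))
        merged = merged[merged["sample_id"].isin(retained)].reset_index(drop=True)
        metrics = copy_number.residualize_standardize(
            merged, ["MHcount", "MSS", "MH_com_count", "mtDNA_CN"],
            _active_covariates(merged, RESID_COVARIATES),
        )
        io.write_tsv(metrics, outdir / RESULT_FILES["metrics"])
        return metrics

    metrics = _qc()

    # ------------------------------------------------------------------ clocks
    @stage("clocks")
    def _clocks():
        betas = io.read_beta_matrix(paths["betas"])
        clock_defs = io.read_clocks(paths["clocks"])
        keep = metrics.set_index("sample_id")
        betas = betas.loc[betas.index.isin(keep.index)]
        rows = []
        for clock in clock_defs:
            values = clocks_mod.compute_clock_value(betas, clock)
            eaa = clocks_mod.compute_eaa(values, keep.loc[betas.index, "age"],
                                         keep.loc[betas.index, "cohort"])
            t = eaa.table.assign(clock=clock.name, scale=clock.scale)
            rows.append(t)
        table = pd.concat(rows, ignore_index=True)
        io.write_tsv(table, outdir / RESULT_FILES["eaa"])
        return table, clock_defs, betas

    eaa_table, clock_defs, betas = _clocks()

    # ------------------------------------------------------------------ associate
    @stage("associate")
    def _associate():
        assoc_rows, meta_rows, forest_rows = [], [], []
        for clock in clock_defs:
            eaa_wide = (eaa_table[eaa_table["clock"] == clock.name]
                        .set_index("sample_id")["eaa"].rename(f"EAA_{clock.name}"))
            data = metrics.set_index("sample_id").join(eaa_wide).reset_index()
            outcome = f"EAA_{clock.name}"
            for metric in MT_METRICS_STD:
                per_stratum: dict[str, list] = {}
                for cohort_name, sub in data.groupby("cohort"):
                    covs = _active_covariates(sub, ASSOC_COVARIATES)
                    results = association.stratified_associations(
                        sub, metric, outcome, covs, cohort=cohort_name,
                        age_cut=cfg.age_cut,
                    )
                    for r in results:
                        assoc_rows.append(r.to_row())
                        per_stratum.setdefault(r.stratum, []).append(r)
                for stratum, results in per_stratum.items():
                    m = association.meta_analyze(results)
                    meta_rows.append({"metric": metric, "outcome": outcome,
                                      "stratum": stratum, **m.to_row(),
                                      "significant": m.p < cfg.significance_threshold})
                    for r in results:
                        forest_rows.append({"metric": metric, "outcome": outcome,
                                            "stratum": stratum, "study": r.cohort,
                                            "beta": r.beta, "se": r.se,
                                            "weight": 1.0 / r.se**2})
        io.write_tsv(pd.DataFrame(assoc_rows), outdir / RESULT_FILES["associations"])
        io.write_tsv(pd.DataFrame(meta_rows), outdir / RESULT_FILES["meta"])
        io.write_tsv(pd.DataFrame(forest_rows), outdir / RESULT_FILES["forest"])

    _associate()

    # ------------------------------------------------------------------ ewas
    @stage("ewas")
    def _ewas():
        if not cfg.run_ewas:
            return
        disc = metrics[metrics["cohort"] == cfg.discovery_cohort].set_index("sample_id")
        if disc.empty:
            logger.info("discovery cohort %r absent; EWAS skipped", cfg.discovery_cohort)
            return
        sub_betas = betas.loc[betas.index.isin(disc.index)]
        covs = _active_covariates(disc, ASSOC_COVARIATES)
        ewas = association.cpg_level_ewas(sub_betas, disc, cfg.ewas_metric, covs,
                                          fdr_level=cfg.fdr_level)
        io.write_tsv(ewas, outdir / "ewas.tsv")

    _ewas()

    # ------------------------------------------------------------------ mediate
    @stage("mediate")
    def _mediate():
        pace_clocks = [c for c in clock_defs if c.scale == "pace"]
        if not pace_clocks:
            logger.info("no pace-scale clock available; mediation skipped")
            return
        mediator_col = f"EAA_{pace_clocks[0].name}"
        eaa_wide = (eaa_table[eaa_table["clock"] == pace_clocks[0].name]
                    .set_index("sample_id")["eaa"].rename(mediator_col))
        traits = io.read_tsv(paths["traits"]).set_index("sample_id")
        data = (metrics.set_index("sample_id").join(eaa_wide).join(traits)
                .reset_index())
        older = data[data["age"] >= cfg.age_cut]
        rows = []
        for outcome in ("obesity", "t2dm"):
            for cohort_name, sub in older.groupby("cohort"):
                covs = _active_covariates(sub, ASSOC_COVARIATES)
                try:
                    fwd, rev = mediation.bidirectional_mediation(
                        sub, x="mtDNA_CN_std", y=outcome, mediator=mediator_col,
                        covariates=covs, x_type="continuous", y_type="binary",
                    )
                except (ValueError, mediation.SeparationError) as exc:
                    logger.info("mediation %s/%s skipped: %s", cohort_name, outcome, exc)
                    continue
                for res in (fwd, rev):
                    rows.append({"cohort": cohort_name, "outcome": outcome,
                                 "mediator": mediator_col, **res.to_row()})
        io.write_tsv(pd.DataFrame(rows), outdir / RESULT_FILES["mediation"])

    _mediate()

    # ------------------------------------------------------------------ MR
    @stage("mr")
    def _mr():
        exposure = io.read_tsv(paths["mr_exposure"])
        mr_outcome = io.read_tsv(paths["mr_outcome"])
        result = mr.run_mr(exposure, mr_outcome, seed=cfg.seed)
        io.write_tsv(pd.DataFrame([e.to_row() for e in result["estimates"]]),
                     outdir / RESULT_FILES["mr_results"])
        io.write_tsv(result["leave_one_out"], outdir / RESULT_FILES["mr_loo"])

    _mr()

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stages_run": [s for s in STAGES if s not in cfg.skip_stages],
    }
    io.write_json(json.loads(json.dumps(manifest, default=str)), outdir / "manifest.json")
    logger.removeHandler(handler)
    handler.close()
    return outdir


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def summarize_report(results_dir, significance_threshold: float | None = None) -> str:
    """Markdown summary of a completed run.

    Raises ``FileNotFoundError`` listing missing result files, or a parse
    error naming a corrupted table.
    """
    results_dir = Path(results_dir)
    required = ["meta.tsv", "associations.tsv", "mediation.tsv", "mr_results.tsv",
                "manifest.json"]
    missing = [f for f in required if not (results_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"results directory incomplete; missing: {missing}")

    def _read(name):
        try:
            return io.read_tsv(results_dir / name)
        except Exception as exc:
            raise ValueError(f"could not parse {name}: {exc}") from exc

    manifest = io.read_json(results_dir / "manifest.json")
    if significance_threshold is None:
        significance_threshold = manifest["config"].get(
            "significance_threshold", association.DEFAULT_SIGNIFICANCE_THRESHOLD)
    meta = _read("meta.tsv")
    mediation_t = _read("mediation.tsv")
    mr_t = _read("mr_results.tsv")

    lines = ["# Run summary", "",
             f"- config hash: `{manifest['config_hash'][:12]}`",
             f"- seed: {manifest['seed']}",
             f"- significance threshold: p < {significance_threshold}", ""]

    lines.append("## Pooled associations (fixed-effect IVW)")
    if meta.empty:
        lines.append(f"\nno associations at threshold {significance_threshold}\n")
    else:
        sig = meta[meta["p"] < significance_threshold]
        lines.append("")
        lines.append(meta.to_string(index=False,
                                    columns=[c for c in ("metric", "outcome", "stratum",
                                                         "beta", "se", "p", "k") if c in meta],
                                    float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        if sig.empty:
            lines.append(f"no associations at threshold {significance_threshold}")
        else:
            lines.append(f"{len(sig)} pooled association(s) significant at "
                         f"p < {significance_threshold}")
    lines.append("")
    lines.append("## Mediation (percent mediated)")
    if not mediation_t.empty:
        cols = [c for c in ("cohort", "outcome", "direction", "nie", "te", "pm", "p_nie", "n")
                if c in mediation_t]
        lines += ["", mediation_t.to_string(index=False, columns=cols,
                                            float_format=lambda v: f"{v:.4g}"), ""]
    lines.append("## Mendelian randomization")
    lines += ["", mr_t.to_string(index=False, float_format=lambda v: f"{v:.4g}"), ""]
    text = "\n".join(lines)
    (results_dir / "report.md").write_text(text)
    return text
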