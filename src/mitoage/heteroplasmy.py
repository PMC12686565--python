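"""Heteroplasmy burden scoring from per-sample mtDNA variant calls.

A heteroplasmic variant is an mtDNA position where an alternate allele is
observed at an intermediate variant allele fraction (VAF), by default within
the inclusive window [0.05, 0.95].  Three per-sample burden scores are
computed after site masking and coverage filtering:

``MHcount``
    number of *rare* heteroplasmic variants (cohort-wide carrier frequency
    below 1%) at retained sites;
``MSS``
    the mitochondrial local constraint (MLC) weighted counterpart of
    MHcount — the sum of MLC scores (each in [0, 1]) over the same calls,
    so higher MSS means a more predicted-deleterious variant load;
``MH_com_count``
    number of carried variants from a fixed panel of common heteroplasmies.

Sites inside homopolymer runs or NUMT-prone regions are excluded via a
blacklist over the 16,569 bp rCRS coordinate system, and sites with read
coverage below a threshold (default 250) are dropped per sample when a
per-site coverage table is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MT_GENOME_LENGTH = 16_569

#: Blacklisted coordinate ranges (1-based, inclusive): the control-region
#: homopolymer tracts, known artifact positions and the hypervariable
#: D-loop tail.  550 positions in total, leaving 16,019 retained.
DEFAULT_BLACKLIST_RANGES: tuple[tuple[int, int], ...] = (
    (1, 61),
    (301, 301),
    (302, 302),
    (310, 310),
    (316, 316),
    (499, 499),
    (567, 567),
    (3107, 3107),
    (16088, 16569),
)

DEFAULT_MIN_SITE_COVERAGE = 250
DEFAULT_VAF_WINDOW = (0.05, 0.95)
DEFAULT_RARITY_THRESHOLD = 0.01

#: Columns expected in a call table.
CALL_COLUMNS = ["sample_id", "position", "ref", "alt", "vaf", "depth"]


class MaskError(ValueError):
    """Raised for blacklist positions outside the mtDNA coordinate space."""


@dataclass(frozen=True)
class SiteMask:
    """Excluded mtDNA positions plus the per-site coverage threshold."""

    excluded: frozenset[int]
    min_coverage: int = DEFAULT_MIN_SITE_COVERAGE

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def n_retained(self) -> int:
        return MT_GENOME_LENGTH - len(self.excluded)

    def is_retained(self, position: int) -> bool:
        return position not in self.excluded


def build_site_mask(
    blacklist_ranges: tuple[tuple[int, int], ...] | list[tuple[int, int]] = DEFAULT_BLACKLIST_RANGES,
    min_coverage: int = DEFAULT_MIN_SITE_COVERAGE,
) -> SiteMask:
    """Build a :class:`SiteMask` from inclusive 1-based position ranges.

    Raises :class:`MaskError` if any range leaves [1, 16569].
    """
    excluded: set[int] = set()
    for lo, hi in blacklist_ranges:
        if lo < 1 or hi > MT_GENOME_LENGTH or lo > hi:
            raise MaskError(
                f"blacklist range ({lo}, {hi}) outside mtDNA coordinates "
                f"[1, {MT_GENOME_LENGTH}]"
            )
        excluded.update(range(lo, hi + 1))
    return SiteMask(excluded=frozenset(excluded), min_coverage=min_coverage)


def classify_heteroplasmic(
    vaf: float | np.ndarray,
    window: tuple[float, float] = DEFAULT_VAF_WINDOW,
) -> bool | np.ndarray:
    """True iff the VAF lies in the inclusive heteroplasmy window.

    Both endpoints count as heteroplasmic, so a 5% or 95% allele fraction
    is in-window under the defaults.
    """
    lo, hi = window
    result = (np.asarray(vaf) >= lo) & (np.asarray(vaf) <= hi)
    if np.isscalar(vaf):
        return bool(result)
    return result


def classify_rarity(
    calls: pd.DataFrame,
    n_participants: int,
    threshold: float = DEFAULT_RARITY_THRESHOLD,
    window: tuple[float, float] = DEFAULT_VAF_WINDOW,
) -> pd.DataFrame:
    """Classify every observed (position, alt) variant as rare or common.

    The carrier frequency of a variant is the number of distinct samples
    with a heteroplasmic (in-window) call for that (position, alt), divided
    by the total number of study participants — not just carriers.  A
    variant is rare iff its frequency is strictly below ``threshold``.

    Returns a frame indexed by (position, alt) with ``carriers``,
    ``frequency`` and boolean ``rare`` columns.
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive to compute carrier frequencies")
    het = calls.loc[classify_heteroplasmic(calls["vaf"].to_numpy(), window)]
    carriers = (
        het.drop_duplicates(["sample_id", "position", "alt"])
        .groupby(["position", "alt"])
        .size()
        .rename("carriers")
        .to_frame()
    )
    carriers["frequency"] = carriers["carriers"] / n_participants
    carriers["rare"] = carriers["frequency"] < threshold
    return carriers


def _coverage_lookup(site_coverage: pd.DataFrame | None) -> dict[tuple[str, int], float]:
    if site_coverage is None or len(site_coverage) == 0:
        return {}
    return {
        (row.sample_id, int(row.position)): float(row.coverage)
        for row in site_coverage.itertuples(index=False)
    }


def compute_burden_scores(
    calls: pd.DataFrame,
    mask: SiteMask,
    rarity: pd.DataFrame,
    mlc: pd.DataFrame | None = None,
    panel: pd.DataFrame | None = None,
    site_coverage: pd.DataFrame | None = None,
    sample_ids: list[str] | pd.Index | None = None,
    window: tuple[float, float] = DEFAULT_VAF_WINDOW,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-sample (MHcount, MSS, MH_com_count) and a filter audit.

    Parameters
    ----------
    calls
        Call table with :data:`CALL_COLUMNS`; duplicated identical records
        are collapsed before scoring.
    mask
        Site blacklist and minimum per-site coverage.
    rarity
        Output of :func:`classify_rarity` over the pooled study calls.
    mlc
        Optional MLC table with columns position, alt, mlc (scores in
        [0, 1]).  Calls without an MLC entry (e.g. D-loop INDELs)
        contribute 0 to MSS; the number of such calls is warned about.
    panel
        Optional common-variant panel with columns position, ref, alt.
    site_coverage
        Optional long table (sample_id, position, coverage); sample-sites
        absent from the table are treated as passing the coverage filter.
    sample_ids
        The sample roster.  Samples with no calls get (0, 0, 0); calls for
        samples outside the roster raise a ``KeyError`` listing them.

    Returns
    -------
    (scores, audit)
        ``scores``: one row per roster sample with MHcount, MSS,
        MH_com_count.  ``audit``: removed calls with a ``reason`` column
        (``masked_site`` | ``low_coverage`` | ``vaf_out_of_window``).
    """
    calls = calls.drop_duplicates(CALL_COLUMNS).reset_index(drop=True)
    if sample_ids is None:
        sample_ids = calls["sample_id"].unique()
    roster = pd.Index(sample_ids, name="sample_id")
    unknown = set(calls["sample_id"]) - set(roster)
    if unknown:
        raise KeyError(f"calls reference samples absent from the roster: {sorted(unknown)}")

    pos = calls["position"].to_numpy()
    masked = np.isin(pos, np.fromiter(mask.excluded, dtype=int)) if mask.excluded else np.zeros(len(calls), bool)

    cov = _coverage_lookup(site_coverage)
    if cov:
        low_cov = np.array(
            [cov.get((s, int(p)), np.inf) < mask.min_coverage
             for s, p in zip(calls["sample_id"], pos)]
        )
    else:
        low_cov = np.zeros(len(calls), bool)

    in_window = classify_heteroplasmic(calls["vaf"].to_numpy(), window)

    reason = np.full(len(calls), "", dtype=object)
    reason[~in_window] = "vaf_out_of_window"
    reason[low_cov] = "low_coverage"
    reason[masked] = "masked_site"  # highest precedence in the audit
    removed = reason != ""
    audit = calls.loc[removed].copy()
    audit["reason"] = reason[removed]

    kept = calls.loc[~removed].copy()

    # rare / common status per (position, alt)
    rare_map = rarity["rare"] if "rare" in rarity else pd.Series(dtype=bool)
    keys = pd.MultiIndex.from_arrays([kept["position"], kept["alt"]])
    kept["rare"] = rare_map.reindex(keys).fillna(True).to_numpy(dtype=bool)

    if mlc is not None and len(mlc):
        mlc_map = mlc.set_index(["position", "alt"])["mlc"]
        kept["mlc"] = mlc_map.reindex(keys).to_numpy()
    else:
        kept["mlc"] = np.nan
    n_missing_mlc = int(kept.loc[kept["rare"], "mlc"].isna().sum())
    if n_missing_mlc:
        warnings.warn(
            f"{n_missing_mlc} rare heteroplasmic call(s) lack an MLC score; "
            "they contribute 0 to MSS",
            stacklevel=2,
        )

    if panel is not None and len(panel):
        panel_keys = set(zip(panel["position"].astype(int), panel["ref"], panel["alt"]))
        kept["in_panel"] = [
            (int(p), r, a) in panel_keys
            for p, r, a in zip(kept["position"], kept["ref"], kept["alt"])
        ]
    else:
        kept["in_panel"] = False

    rare_calls = kept.loc[kept["rare"]]
    scores = pd.DataFrame(
        {
            "MHcount": rare_calls.groupby("sample_id").size().reindex(roster, fill_value=0),
            "MSS": rare_calls.groupby("sample_id")["mlc"].sum(min_count=0).reindex(roster, fill_value=0.0).fillna(0.0),
            "MH_com_count": kept.loc[kept["in_panel"]].groupby("sample_id").size().reindex(roster, fill_value=0),
        }
    )
    scores.index.name = "sample_id"
    return scores.reset_index(), audit.reset_index(drop=True)


@dataclass
class BurdenResult:
    """Scores plus the audit trail of filtered calls."""

    scores: pd.DataFrame
    audit: pd.DataFrame
    rarity: pd.DataFrame = field(default_factory=pd.DataFrame)


def score_study(
    calls: pd.DataFrame,
    sample_ids: list[str] | pd.Index,
    mask: SiteMask | None = None,
    mlc: pd.DataFrame | None = None,
    panel: pd.DataFrame | None = None,
    site_coverage: pd.DataFrame | None = None,
    window: tuple[float, float] = DEFAULT_VAF_WINDOW,
    rarity_threshold: float = DEFAULT_RARITY_THRESHOLD,
) -> BurdenResult:
    """Convenience wrapper: rarity classification then burden scoring."""
    if mask is None:
        mask = build_site_mask()
    rarity = classify_rarity(calls, n_participants=len(sample_ids),
                             threshold=rarity_threshold, window=window)
    scores, audit = compute_burden_scores(
        calls, mask, rarity, mlc=mlc, panel=panel,
        site_coverage=site_coverage, sample_ids=sample_ids, window=window,
    )
    return BurdenResult(scores=scores, audit=audit, rarity=rarity)
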