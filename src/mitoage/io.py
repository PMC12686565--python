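"""Readers and writers for the study's file formats.

Variant calls travel as a multi-sample VCF on the mitochondrial contig
(default ``chrM``, 1-based positions) with per-sample ``GT:DP:VAF``
FORMAT fields; everything else is plain TSV (covariates, phenotypes,
coverage, MLC scores, common panel, GWAS summary statistics, burden
scores) or JSON (clock definitions, truth ledger, run manifests).
Reading VCFs goes through cyvcf2; writing emits the text format
directly, one record per (position, ref, alt).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clocks import ClockDefinition

DEFAULT_CONTIG = "chrM"
MT_LENGTH = 16_569

_FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# TSV helpers (fixed float formatting keeps reruns byte-identical)
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(calls: pd.DataFrame, path, sample_ids=None, contig: str = DEFAULT_CONTIG) -> None:
    """Write a multi-sample VCF with GT:DP:VAF per sample.

    ``calls`` needs columns sample_id, position, ref, alt, vaf, depth.
    Samples without a call at a record get ``./.:.:.``.
    """
    if sample_ids is None:
        sample_ids = sorted(calls["sample_id"].unique())
    sample_ids = list(sample_ids)
    col_of = {s: i for i, s in enumerate(sample_ids)}

    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={MT_LENGTH}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    lines = []
    grouped = calls.sort_values(["position", "alt", "sample_id"]).groupby(
        ["position", "ref", "alt"], sort=True
    )
    for (pos, ref, alt), grp in grouped:
        cells = ["./.:.:."] * len(sample_ids)
        for r in grp.itertuples(index=False):
            cells[col_of[r.sample_id]] = f"0/1:{int(r.depth)}:{r.vaf:.6f}"
        lines.append(
            f"{contig}\t{int(pos)}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP:VAF\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(header + lines) + "\n")


def read_vcf(path, vaf_key: str = "VAF") -> pd.DataFrame:
    """Read mtDNA variant calls from a VCF into the long call table.

    Per-sample VAF is taken from the FORMAT field named ``vaf_key``; if
    absent, it falls back to the AD/DP ratio.  Multi-allelic records are
    decomposed into one call per alternate allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows = []
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT):
            vafs = None
            try:
                vafs = rec.format(vaf_key)
            except KeyError:
                vafs = None
            dps = None
            try:
                dps = rec.format("DP")
            except KeyError:
                dps = None
            if vafs is None:
                ad = rec.format("AD")
                if ad is None or dps is None:
                    raise ValueError(
                        f"record {rec.CHROM}:{rec.POS} lacks both {vaf_key!r} and AD/DP"
                    )
                with np.errstate(divide="ignore", invalid="ignore"):
                    vafs = ad[:, ai + 1] / dps[:, 0]
            vcol = np.asarray(vafs, dtype=float).reshape(len(samples), -1)[:, 0]
            dcol = (np.asarray(dps, dtype=float).reshape(len(samples), -1)[:, 0]
                    if dps is not None else np.full(len(samples), np.nan))
            called = np.isfinite(vcol) & (vcol >= 0)
            for si in np.nonzero(called)[0]:
                rows.append(
                    {"sample_id": samples[si], "position": rec.POS, "ref": rec.REF,
                     "alt": alt, "vaf": float(vcol[si]),
                     "depth": int(dcol[si]) if np.isfinite(dcol[si]) else 0}
                )
    return pd.DataFrame(rows, columns=["sample_id", "position", "ref", "alt", "vaf", "depth"])


# ---------------------------------------------------------------------------
# beta matrix and clocks
# ---------------------------------------------------------------------------

def write_beta_matrix(betas: pd.DataFrame, path) -> None:
    betas.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FORMAT)


def read_beta_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_clocks(clocks: list[ClockDefinition], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for clock in clocks:
        p = directory / f"{clock.name}.json"
        clock.to_json(p)
        paths.append(p)
    return paths


def read_clocks(directory) -> list[ClockDefinition]:
    return [ClockDefinition.from_json(p) for p in sorted(Path(directory).glob("*.json"))]


# ---------------------------------------------------------------------------
# misc JSON
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
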