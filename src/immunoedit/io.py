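"""Readers and writers for the package's TSV/VCF/JSON interchange formats.

TSV is the canonical interchange: variant tables as written by the cohort
simulator, MAGeCK-style count tables (sgRNA, gene, sample columns) with a
sample sheet, and per-cohort expression matrices.  VCF ingestion is a
convenience adapter reading allele depths from the AD format field.  All
writers are deterministic: stable column order, floats at 6 significant
digits.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .screen import ScreenCounts
from .variants import GROUPS, VARIANT_COLUMNS, CohortSample

FLOAT_FMT = "%.6g"


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_variant_table(cohort: list[CohortSample], path) -> None:
    """Write a cohort as a single TSV with the canonical column order."""
    frames = [
        s.variants.assign(sample_id=s.sample_id, group=s.group)[list(VARIANT_COLUMNS)]
        for s in cohort
    ]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_variant_table(path) -> list[CohortSample]:
    """Read a cohort TSV, validating each row.

    AF is recomputed from the depths; a provided ``af`` column is checked
    against the recomputation (tolerance 1e-6, mismatch warns).  Malformed
    rows raise with their line number (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variant_id": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            alt, tot = int(row.alt_depth), int(row.total_depth)
        except (TypeError, ValueError):
            raise ValueError(f"{path}:{line}: non-integer depth") from None
        if not 0 <= alt <= tot:
            raise ValueError(
                f"{path}:{line}: require 0 <= alt_depth <= total_depth, got {alt}/{tot}"
            )
        if row.group not in GROUPS:
            raise ValueError(f"{path}:{line}: unknown group {row.group!r}")
    if "af" in df.columns:
        tot = df["total_depth"].to_numpy(dtype=float)
        expect = np.where(tot > 0, df["alt_depth"] / np.maximum(tot, 1), 0.0)
        bad = np.abs(df["af"].to_numpy(dtype=float) - expect) > 1e-6
        if bad.any():
            warnings.warn(
                f"{path}: {int(bad.sum())} rows with AF inconsistent with depths",
                stacklevel=2,
            )
    cohort = []
    for sid in df["sample_id"].unique():
        sub = df[df["sample_id"] == sid]
        group = sub["group"].iloc[0]
        if (sub["group"] != group).any():
            raise ValueError(f"{path}: sample {sid!r} listed under multiple groups")
        cohort.append(
            CohortSample(
                sample_id=str(sid),
                group=str(group),
                variants=sub[
                    ["gene", "variant_id", "annotation", "alt_depth", "total_depth"]
                ].reset_index(drop=True),
            )
        )
    return cohort


def write_count_matrix(sc: ScreenCounts, counts_path, samples_path) -> None:
    """Write a MAGeCK-style count table plus a sample sheet."""
    out = sc.counts.copy()
    out.insert(0, "gene", sc.gene_map)
    out.index.name = "sgRNA"
    out.to_csv(counts_path, sep="\t")
    sheet = pd.DataFrame(
        {
            "sample_id": list(sc.counts.columns),
            "condition": [sc.conditions[c] for c in sc.counts.columns],
        }
    )
    sheet["replicate"] = sheet.groupby("condition").cumcount() + 1
    sheet.to_csv(samples_path, sep="\t", index=False)


def read_count_matrix(counts_path, samples_path) -> ScreenCounts:
    """Read a MAGeCK-style count table with its sample sheet."""
    df = pd.read_csv(counts_path, sep="\t")
    guide_col, gene_col = df.columns[0], df.columns[1]
    if df[guide_col].duplicated().any():
        dup = df.loc[df[guide_col].duplicated(), guide_col].iloc[0]
        raise ValueError(f"{counts_path}: duplicated guide ID {dup!r}")
    sheet = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    sample_cols = [c for c in df.columns[2:]]
    unknown = set(sample_cols) - set(sheet["sample_id"])
    if unknown:
        raise ValueError(f"{counts_path}: samples not in sheet: {sorted(unknown)}")
    counts = df.set_index(guide_col)[sample_cols]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr), atol=0):
            raise ValueError(f"{counts_path}: non-integer counts")
        counts = counts.astype(np.int64)
    counts.index.name = "sgRNA"
    return ScreenCounts(
        counts=counts,
        gene_map=df.set_index(guide_col)[gene_col].rename("gene"),
        conditions=sheet.set_index("sample_id")["condition"],
    )


def write_vcf(sample: CohortSample, path) -> None:
    """Write one sample as a minimal VCF, allele depths in the AD field.

    Variant IDs of the form ``chrom:pos:ref:alt`` supply the coordinate
    columns verbatim; other IDs get placeholder coordinates and are carried
    in the ID column either way.
    """
    records = []
    contigs: list[str] = []
    for i, row in enumerate(sample.variants.itertuples(index=False)):
        parts = str(row.variant_id).split(":")
        if len(parts) == 4 and parts[1].isdigit():
            chrom, pos, ref, alt = parts
        else:
            chrom, pos, ref, alt = "chrUn", str(i + 1), "N", "<ALT>"
        if chrom not in contigs:
            contigs.append(chrom)
        ref_depth = int(row.total_depth) - int(row.alt_depth)
        records.append(
            "\t".join(
                [
                    chrom,
                    pos,
                    str(row.variant_id),
                    ref,
                    alt,
                    ".",
                    "PASS",
                    f"GENE={row.gene};ANN={row.annotation}",
                    "AD:DP",
                    f"{ref_depth},{int(row.alt_depth)}:{int(row.total_depth)}",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=immunoedit\n")
        fh.write(f"##immunoedit_group={sample.group}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation class">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample.sample_id}\n"
        )
        fh.write("\n".join(records) + ("\n" if records else ""))


def read_vcf(path, group: str | None = None) -> CohortSample:
    """Read a single-sample VCF written by :func:`write_vcf` (or compatible).

    Depths come from the AD format field; genotype fields are otherwise
    ignored.  The immune-pressure group is taken from the
    ``##immunoedit_group`` header line unless given explicitly.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if group is None:
        for line in vcf.raw_header.splitlines():
            if line.startswith("##immunoedit_group="):
                group = line.split("=", 1)[1]
                break
    if group is None:
        raise ValueError(f"{path}: no group header; pass group= explicitly")
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected exactly one sample, got {len(vcf.samples)}")
    sample_id = vcf.samples[0]
    rows = []
    for v in vcf:
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {v.ID} lacks AD field")
        ref_depth, alt_depth = int(ad[0][0]), int(ad[0][1])
        rows.append(
            {
                "gene": v.INFO.get("GENE", "."),
                "variant_id": v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}",
                "annotation": v.INFO.get("ANN", "other"),
                "alt_depth": alt_depth,
                "total_depth": ref_depth + alt_depth,
            }
        )
    return CohortSample(
        sample_id=sample_id,
        group=group,
        variants=pd.DataFrame(
            rows, columns=["gene", "variant_id", "annotation", "alt_depth", "total_depth"]
        ),
    )


def read_expression_manifest(manifest_path) -> dict[str, pd.DataFrame]:
    """Read a manifest TSV (cohort_id, path) of gene x sample matrices."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    out = {}
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        out[str(row.cohort_id)] = pd.read_csv(p, sep="\t", index_col=0)
    return out


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_manifest(path, parameters: dict, seed: int | None, inputs: dict[str, str]) -> None:
    """Record run parameters, seed, input checksums and package version."""
    from . import __version__

    write_json(
        {
            "version": __version__,
            "seed": seed,
            "parameters": parameters,
            "input_sha256": {k: sha256_of(v) for k, v in inputs.items()},
        },
        path,
    )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Deterministic TSV writer used by all pipeline stages."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
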