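"""Allele-frequency profiling of immune-selected tumor cohorts.

A cohort of tumors grown under graded T cell pressure (cultured baseline,
immunodeficient hosts, immunocompetent hosts, and checkpoint-blockade-treated
hosts) is screened for *hotspot* mutations: variants whose alternate-allele
frequency (AF = alt depth / total depth) is positive (AF >= 0.1 by default)
in at least two immunocompetent tumors while remaining negative in the
cultured baseline and every immunodeficient tumor.  Hotspots are then split
by their behaviour under PD-1/PD-L1 blockade:

* ``PD1_dependent`` — negative in every immunotherapy tumor (the mutant
  clone is presumed eliminated once the checkpoint is blocked);
* ``PD1_independent`` — still positive in at least one immunotherapy tumor
  (escape does not require the PD-1 axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_IN_VITRO = "in_vitro"
GROUP_IMMUNODEFICIENT = "immunodeficient"
GROUP_IMMUNOCOMPETENT = "immunocompetent"
GROUP_APD1 = "immunotherapy_aPD1"
GROUP_APDL1 = "immunotherapy_aPDL1"

GROUPS = (
    GROUP_IN_VITRO,
    GROUP_IMMUNODEFICIENT,
    GROUP_IMMUNOCOMPETENT,
    GROUP_APD1,
    GROUP_APDL1,
)
IMMUNOTHERAPY_GROUPS = (GROUP_APD1, GROUP_APDL1)
#: Groups in which a hotspot must be negative everywhere.
EXCLUSION_GROUPS = (GROUP_IN_VITRO, GROUP_IMMUNODEFICIENT)

ANNOTATION_CLASSES = ("missense", "splicing", "frameshift", "deletion", "other")

CATEGORY_PD1_DEPENDENT = "PD1_dependent"
CATEGORY_PD1_INDEPENDENT = "PD1_independent"

#: Canonical column order of a per-sample variant table.
VARIANT_COLUMNS = (
    "sample_id",
    "group",
    "gene",
    "variant_id",
    "annotation",
    "alt_depth",
    "total_depth",
)


class CohortError(ValueError):
    """A cohort is missing a group the filter requires."""


@dataclass
class VariantCall:
    """One observed mutation in one sample."""

    sample_id: str
    group: str
    gene: str
    variant_id: str
    annotation: str
    alt_depth: int
    total_depth: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not (0 <= self.alt_depth <= self.total_depth):
            raise ValueError(
                f"variant {self.variant_id!r} in {self.sample_id!r}: "
                f"require 0 <= alt_depth <= total_depth, got "
                f"{self.alt_depth}/{self.total_depth}"
            )

    @property
    def af(self) -> float:
        return compute_af(self.alt_depth, self.total_depth)


@dataclass
class CohortSample:
    """A tumor (or cultured baseline) with its variant calls.

    ``variants`` holds one row per call with columns
    ``gene, variant_id, annotation, alt_depth, total_depth``.
    """

    sample_id: str
    group: str
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        missing = {"gene", "variant_id", "annotation", "alt_depth", "total_depth"} - set(
            self.variants.columns
        )
        if missing:
            raise ValueError(f"sample {self.sample_id!r}: missing columns {sorted(missing)}")


@dataclass
class HotspotCall:
    """A mutation surviving the cross-cohort filter."""

    variant_id: str
    gene: str
    annotation: str
    category: str
    supporting_immunocompetent: list[str]
    positive_immunotherapy: list[str]
    af: pd.Series = field(repr=False)  # per-sample AF row

    def __post_init__(self) -> None:
        if len(self.supporting_immunocompetent) < 2:
            raise ValueError("hotspot requires >= 2 supporting immunocompetent tumors")
        if self.category == CATEGORY_PD1_DEPENDENT and self.positive_immunotherapy:
            raise ValueError("PD1_dependent hotspot cannot be positive under immunotherapy")
        if self.category == CATEGORY_PD1_INDEPENDENT and not self.positive_immunotherapy:
            raise ValueError("PD1_independent hotspot needs >= 1 positive immunotherapy tumor")


def compute_af(alt_depth: int, total_depth: int) -> float:
    """Allele frequency: depth of the alteration over total depth at the locus.

    A locus with zero total depth carries no evidence of alteration and is
    assigned AF 0 (with a warning).
    """
    if alt_depth < 0 or total_depth < 0:
        raise ValueError("depths must be non-negative")
    if alt_depth > total_depth:
        raise ValueError(f"alt_depth {alt_depth} exceeds total_depth {total_depth}")
    if total_depth == 0:
        warnings.warn("total_depth is 0; AF defined as 0", stacklevel=2)
        return 0.0
    return alt_depth / total_depth


def call_status(af: float, threshold: float = 0.1, boundary: str = "ge") -> str:
    """Dichotomize an AF into ``positive``/``negative``.

    ``boundary="ge"`` marks AF >= threshold positive (the rule-table
    convention); ``"gt"`` uses a strict inequality.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"AF must lie in [0, 1], got {af}")
    if boundary == "ge":
        positive = af >= threshold
    elif boundary == "gt":
        positive = af > threshold
    else:
        raise ValueError(f"boundary must be 'ge' or 'gt', got {boundary!r}")
    return "positive" if positive else "negative"


def cohort_af_matrix(cohort: list[CohortSample]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a cohort into a variants x samples AF matrix.

    Returns ``(af, meta)`` where ``af`` is indexed by variant_id with one
    column per sample (variants absent from a sample get AF 0), and ``meta``
    maps variant_id -> (gene, annotation).  Duplicate (sample, variant) rows
    raise a validation error.
    """
    frames = []
    for s in cohort:
        df = s.variants
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant {dup!r} in sample {s.sample_id!r}")
        bad = df["alt_depth"] > df["total_depth"]
        if bad.any():
            v = df.loc[bad, "variant_id"].iloc[0]
            raise ValueError(f"alt_depth > total_depth for {v!r} in {s.sample_id!r}")
        frames.append(df.assign(sample_id=s.sample_id))
    allcalls = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(VARIANT_COLUMNS)
    )
    if len(allcalls):
        total = allcalls["total_depth"].to_numpy(dtype=float)
        alt = allcalls["alt_depth"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            af_vals = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
        allcalls = allcalls.assign(af=af_vals)
        af = allcalls.pivot_table(
            index="variant_id", columns="sample_id", values="af", fill_value=0.0
        )
    else:
        af = pd.DataFrame()
    # ensure every sample has a column even with an empty table
    for s in cohort:
        if s.sample_id not in af.columns:
            af[s.sample_id] = 0.0
    meta = (
        allcalls.drop_duplicates("variant_id").set_index("variant_id")[["gene", "annotation"]]
        if len(allcalls)
        else pd.DataFrame(columns=["gene", "annotation"])
    )
    return af, meta


def classify_hotspots(
    cohort: list[CohortSample],
    min_support: int = 2,
    threshold: float = 0.1,
    boundary: str = "ge",
) -> list[HotspotCall]:
    """Apply the cross-cohort filter and categorize surviving mutations.

    A variant is reported iff it is negative in every cultured baseline and
    every immunodeficient tumor, and positive in at least ``min_support``
    distinct immunocompetent tumors.  Reported variants are
    ``PD1_dependent`` when negative in all immunotherapy tumors (both
    antibody arms) and ``PD1_independent`` otherwise.  Variants absent from
    a sample's table are treated as negative there.
    """
    groups = pd.Series({s.sample_id: s.group for s in cohort})
    if len(groups) != len(cohort):
        raise ValueError("duplicate sample_id in cohort")
    n_ic = (groups == GROUP_IMMUNOCOMPETENT).sum()
    if (groups == GROUP_IN_VITRO).sum() < 1:
        raise CohortError("cohort has no in_vitro baseline sample")
    if (groups == GROUP_IMMUNODEFICIENT).sum() < 1:
        raise CohortError("cohort has no immunodeficient sample")
    if n_ic < min_support:
        raise CohortError(
            f"cohort has {n_ic} immunocompetent samples; need >= {min_support}"
        )

    af, meta = cohort_af_matrix(cohort)
    if af.empty:
        return []
    af = af[groups.index]  # stable sample order as given
    pos = af >= threshold if boundary == "ge" else af > threshold
    if boundary not in ("ge", "gt"):
        raise ValueError(f"boundary must be 'ge' or 'gt', got {boundary!r}")

    excl_cols = groups.index[groups.isin(EXCLUSION_GROUPS)]
    ic_cols = groups.index[groups == GROUP_IMMUNOCOMPETENT]
    it_cols = groups.index[groups.isin(IMMUNOTHERAPY_GROUPS)]

    keep = (~pos[excl_cols].any(axis=1)) & (pos[ic_cols].sum(axis=1) >= min_support)
    hotspots: list[HotspotCall] = []
    for vid in af.index[keep]:
        support = [c for c in ic_cols if pos.at[vid, c]]
        it_pos = [c for c in it_cols if pos.at[vid, c]]
        category = CATEGORY_PD1_INDEPENDENT if it_pos else CATEGORY_PD1_DEPENDENT
        hotspots.append(
            HotspotCall(
                variant_id=vid,
                gene=str(meta.at[vid, "gene"]),
                annotation=str(meta.at[vid, "annotation"]),
                category=category,
                supporting_immunocompetent=support,
                positive_immunotherapy=it_pos,
                af=af.loc[vid],
            )
        )
    return hotspots


def summarize_hotspots(hotspots: list[HotspotCall]) -> dict:
    """Tally hotspots by annotation class and checkpoint-dependence category."""
    by_annotation = {a: 0 for a in ANNOTATION_CLASSES}
    by_category = {CATEGORY_PD1_DEPENDENT: 0, CATEGORY_PD1_INDEPENDENT: 0}
    genes = set()
    for h in hotspots:
        by_annotation[h.annotation] = by_annotation.get(h.annotation, 0) + 1
        by_category[h.category] += 1
        genes.add(h.gene)
    return {
        "total": len(hotspots),
        "n_genes": len(genes),
        "by_annotation": by_annotation,
        "by_category": by_category,
    }


def hotspots_to_frame(hotspots: list[HotspotCall]) -> pd.DataFrame:
    """Flatten hotspot calls into a table (one row per variant, per-sample AFs)."""
    rows = []
    for h in hotspots:
        row = {
            "variant_id": h.variant_id,
            "gene": h.gene,
            "annotation": h.annotation,
            "category": h.category,
            "n_support": len(h.supporting_immunocompetent),
        }
        row.update({f"af:{s}": v for s, v in h.af.items()})
        rows.append(row)
    return pd.DataFrame(rows)
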