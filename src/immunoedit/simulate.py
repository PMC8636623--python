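"""Synthetic clonal-evolution cohorts and pooled-screen count matrices.

The cohort generator emulates the selection structure the profiling filter
assumes: a cultured baseline, tumors grown in immunodeficient hosts (minimal
T cell pressure), immunocompetent hosts, and two checkpoint-blockade arms.
Each planted driver carries a per-group clone fraction; sequencing is
emulated by drawing a site's total depth from a negative binomial (RNA-seq
site coverage is overdispersed) and the alt depth binomially from the clone
fraction.  PD-1-dependent drivers rise only under intact T cell immunity and
are planted low in *all* immunotherapy samples (eliminated once the
checkpoint is blocked); PD-1-independent drivers stay high under blockade.

The screen generator emulates a pooled knockout library: per-guide baseline
abundances are log-normal, a gene-level selection effect acts through a
per-guide efficacy (a property of the guide, reused across conditions), and
observed counts are negative-binomial at a stated sequencing depth.

Ground truth (clone fractions, categories, gene effects, efficacies) is
emitted alongside the data, never embedded in it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import (
    ANNOTATION_CLASSES,
    CATEGORY_PD1_DEPENDENT,
    CATEGORY_PD1_INDEPENDENT,
    GROUP_APD1,
    GROUP_APDL1,
    GROUP_IMMUNOCOMPETENT,
    GROUP_IMMUNODEFICIENT,
    GROUP_IN_VITRO,
    GROUPS,
    CohortSample,
)

DEFAULT_CONTROL_GENES = ("Pdcd1", "Cd274", "Jak1", "Jak2", "B2m")

#: Annotation class mix of the profiled mutation set (24 missense,
#: 18 splicing, 15 frameshift, 2 deletion out of 59).
_ANNOTATION_WEIGHTS = np.array([24, 18, 15, 2, 0], dtype=float) / 59.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class DriverSpec:
    """A planted mutation: gene, category, and per-group clone fractions."""

    gene: str
    category: str  # PD1_dependent | PD1_independent | none
    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, f in self.fractions.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r} in driver {self.gene!r}")
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"clone fraction {f} outside [0,1] for {self.gene!r}")


def default_driver_spec(
    n_dependent: int = 23,
    n_independent: int = 30,
    high: float = 0.4,
    low: float = 0.01,
) -> list[DriverSpec]:
    """Driver panel mirroring the profiled 23/30 dependent/independent split."""
    drivers = []
    for i in range(n_dependent):
        drivers.append(
            DriverSpec(
                gene=f"DrvD{i + 1:02d}",
                category=CATEGORY_PD1_DEPENDENT,
                fractions={
                    GROUP_IN_VITRO: low,
                    GROUP_IMMUNODEFICIENT: low,
                    GROUP_IMMUNOCOMPETENT: high,
                    GROUP_APD1: low,
                    GROUP_APDL1: low,
                },
            )
        )
    for i in range(n_independent):
        drivers.append(
            DriverSpec(
                gene=f"DrvI{i + 1:02d}",
                category=CATEGORY_PD1_INDEPENDENT,
                fractions={
                    GROUP_IN_VITRO: low,
                    GROUP_IMMUNODEFICIENT: low,
                    GROUP_IMMUNOCOMPETENT: high,
                    GROUP_APD1: high,
                    GROUP_APDL1: high,
                },
            )
        )
    return drivers


@dataclass
class CohortSimConfig:
    """Study design for the clonal-evolution cohort simulator.

    Cohort sizes default to the profiled design (1 cultured baseline,
    10 immunodeficient, 13 immunocompetent, 8 immunotherapy tumors split as
    evenly as possible between the two antibody arms).
    """

    n_in_vitro: int = 1
    n_immunodeficient: int = 10
    n_immunocompetent: int = 13
    n_immunotherapy: int = 8
    n_passenger_sites: int = 200
    driver_spec: list[DriverSpec] = field(default_factory=default_driver_spec)
    depth_mean: float = 100.0
    depth_dispersion: float = 0.1
    af_noise: float = 0.02  # sd of multiplicative lognormal noise on fractions
    passenger_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_in_vitro", "n_immunodeficient", "n_immunocompetent", "n_immunotherapy"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_passenger_sites < 0:
            raise ConfigurationError("n_passenger_sites must be >= 0")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.depth_dispersion < 0 or self.af_noise < 0:
            raise ConfigurationError("dispersion and noise must be >= 0")
        if not 0.0 <= self.passenger_fraction <= 1.0:
            raise ConfigurationError("passenger_fraction must lie in [0,1]")


@dataclass
class ScreenSimConfig:
    """Design of a pooled knockout screen simulation.

    ``n_genes`` counts candidate genes; ``control_genes`` are appended, so
    the default library is 53 + 5 = 58 genes x 10 guides.  ``gene_effect``
    maps gene -> {condition: fold-change} on clonal fitness in that
    condition (1.0 = neutral).
    """

    n_genes: int = 53
    guides_per_gene: int = 10
    control_genes: Sequence[str] = DEFAULT_CONTROL_GENES
    conditions: Sequence[str] = ("control", "selected")
    baseline_abundance_sigma: float = 0.5
    gene_effect: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    guide_efficacy_distribution: tuple = ("beta", 3.0, 1.0)
    sample_depth: float = 200_000.0
    nb_dispersion: float = 0.2
    replicates_per_condition: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.guides_per_gene <= 0:
            raise ConfigurationError("gene/guide counts must be positive")
        if self.sample_depth <= 0:
            raise ConfigurationError("sample_depth must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.replicates_per_condition < 1:
            raise ConfigurationError("replicates_per_condition must be >= 1")
        for g, eff in self.gene_effect.items():
            for c, f in eff.items():
                if c not in self.conditions:
                    raise ConfigurationError(f"gene_effect condition {c!r} not in conditions")
                if f <= 0:
                    raise ConfigurationError(f"fold-change for {g!r} must be > 0")

    @property
    def genes(self) -> list[str]:
        return [f"Gene{i + 1:03d}" for i in range(self.n_genes)] + list(self.control_genes)


@dataclass
class SimTruth:
    """Ground truth emitted next to simulated data.

    ``variants``: per-mutation category and per-group clone fractions.
    ``genes``: per-gene selection effect per condition.
    ``guides``: per-guide efficacy and baseline abundance.
    """

    variants: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    guides: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        import json

        payload = {}
        for name in ("variants", "genes", "guides"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _nb_counts(rng: np.random.Generator, mean, dispersion: float):
    """Overdispersed counts with the given mean; dispersion 0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    # NB parameterization: var = mean + dispersion * mean^2
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _sample_ids(config: CohortSimConfig) -> list[tuple[str, str]]:
    n_apd1 = math.ceil(config.n_immunotherapy / 2)
    n_apdl1 = config.n_immunotherapy - n_apd1
    ids = []
    ids += [(f"invitro_{i + 1}", GROUP_IN_VITRO) for i in range(config.n_in_vitro)]
    ids += [(f"nude_{i + 1}", GROUP_IMMUNODEFICIENT) for i in range(config.n_immunodeficient)]
    ids += [(f"wt_{i + 1}", GROUP_IMMUNOCOMPETENT) for i in range(config.n_immunocompetent)]
    ids += [(f"aPD1_{i + 1}", GROUP_APD1) for i in range(n_apd1)]
    ids += [(f"aPDL1_{i + 1}", GROUP_APDL1) for i in range(n_apdl1)]
    return ids


def simulate_clonal_cohort(
    config: CohortSimConfig,
) -> tuple[list[CohortSample], SimTruth]:
    """Simulate per-tumor variant tables under group-specific selection.

    Every simulated site appears in every sample's table (joint-call style);
    sites the sample does not carry simply have alt depth 0.
    """
    if config.n_in_vitro < 1 or config.n_immunodeficient < 1:
        raise ConfigurationError("need >= 1 in_vitro and >= 1 immunodeficient sample")
    if config.n_immunocompetent < 2:
        raise ConfigurationError("need >= 2 immunocompetent samples")
    rng = np.random.default_rng(config.seed)
    samples = _sample_ids(config)

    sites: list[DriverSpec] = list(config.driver_spec)
    for i in range(config.n_passenger_sites):
        sites.append(
            DriverSpec(
                gene=f"Psg{i + 1:04d}",
                category="none",
                fractions={g: config.passenger_fraction for g in GROUPS},
            )
        )
    seen = [s.gene for s in config.driver_spec]
    if len(set(seen)) != len(seen):
        raise ConfigurationError("duplicate driver gene in driver_spec")

    n_sites = len(sites)
    chroms = [f"chr{(i % 19) + 1}" for i in range(n_sites)]
    positions = 10_000 + 997 * np.arange(n_sites)
    variant_ids = [f"{c}:{p}:A:G" for c, p in zip(chroms, positions)]
    annotations = rng.choice(ANNOTATION_CLASSES, size=n_sites, p=_ANNOTATION_WEIGHTS)

    fractions = np.array(
        [[site.fractions.get(group, 0.0) for _, group in samples] for site in sites]
    )
    noise = rng.lognormal(mean=0.0, sigma=config.af_noise, size=fractions.shape)
    f_eff = np.minimum(fractions * noise, 1.0)  # zero fractions stay exactly zero
    total = _nb_counts(
        rng, np.full(fractions.shape, config.depth_mean), config.depth_dispersion
    )
    alt = rng.binomial(total, f_eff)

    cohort = []
    for j, (sample_id, group) in enumerate(samples):
        df = pd.DataFrame(
            {
                "gene": [s.gene for s in sites],
                "variant_id": variant_ids,
                "annotation": annotations,
                "alt_depth": alt[:, j].astype(int),
                "total_depth": total[:, j].astype(int),
            }
        )
        cohort.append(CohortSample(sample_id=sample_id, group=group, variants=df))

    truth_rows = []
    for i, site in enumerate(sites):
        row = {"variant_id": variant_ids[i], "gene": site.gene, "category": site.category}
        row.update({f"fraction_{g}": site.fractions.get(g, 0.0) for g in GROUPS})
        truth_rows.append(row)
    truth = SimTruth(variants=pd.DataFrame(truth_rows))
    return cohort, truth


def _draw_efficacy(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "beta":
        e = rng.beta(dist[1], dist[2], size=size)
    elif kind == "fixed":
        e = np.full(size, float(dist[1]))
    elif kind == "uniform":
        e = rng.uniform(dist[1], dist[2], size=size)
    else:
        raise ConfigurationError(f"unknown efficacy distribution {kind!r}")
    if np.any((e < 0) | (e > 1)):
        raise ConfigurationError("guide efficacies must lie in [0,1]")
    return e


def simulate_screen_counts(config: ScreenSimConfig):
    """Simulate a guide x sample count matrix with gene-level selection.

    Returns ``(ScreenCounts, SimTruth)``.  Expected counts in a sample are
    proportional to baseline abundance times ``effect ** efficacy`` for the
    guide's gene in that sample's condition; observed counts are negative
    binomial at ``sample_depth`` total expected reads.
    """
    from .screen import ScreenCounts  # local import to avoid a cycle

    genes = config.genes
    unknown = set(config.gene_effect) - set(genes)
    if unknown:
        raise ConfigurationError(f"gene_effect references unknown genes: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)

    guide_ids, gene_of = [], []
    for g in genes:
        for j in range(config.guides_per_gene):
            guide_ids.append(f"{g}_sg{j + 1}")
            gene_of.append(g)
    n_guides = len(guide_ids)
    base = rng.lognormal(mean=0.0, sigma=config.baseline_abundance_sigma, size=n_guides)
    efficacy = _draw_efficacy(rng, config.guide_efficacy_distribution, n_guides)
    effect = np.ones((n_guides, len(config.conditions)))
    for ci, cond in enumerate(config.conditions):
        for i, g in enumerate(gene_of):
            effect[i, ci] = config.gene_effect.get(g, {}).get(cond, 1.0)

    cols, conds = {}, {}
    for ci, cond in enumerate(config.conditions):
        w = base * effect[:, ci] ** efficacy
        mean = w / w.sum() * config.sample_depth
        for rep in range(config.replicates_per_condition):
            sid = f"{cond}_r{rep + 1}"
            cols[sid] = _nb_counts(rng, mean, config.nb_dispersion).astype(int)
            conds[sid] = cond

    counts = pd.DataFrame(cols, index=pd.Index(guide_ids, name="sgRNA"))
    sc = ScreenCounts(
        counts=counts,
        gene_map=pd.Series(gene_of, index=counts.index, name="gene"),
        conditions=pd.Series(conds, name="condition"),
    )
    gene_rows = [
        {"gene": g, **{f"effect_{c}": config.gene_effect.get(g, {}).get(c, 1.0) for c in config.conditions}}
        for g in genes
    ]
    truth = SimTruth(
        genes=pd.DataFrame(gene_rows),
        guides=pd.DataFrame(
            {"sgRNA": guide_ids, "gene": gene_of, "efficacy": efficacy, "baseline": base}
        ),
    )
    return sc, truth


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-approximation tumor volume, (L x W^2) / 2, in mm^3."""
    if length_mm < 0 or width_mm < 0:
        raise ValueError("tumor dimensions must be non-negative")
    if width_mm > length_mm:
        warnings.warn(
            f"width ({width_mm}) exceeds length ({length_mm}); "
            "length should be the longest dimension",
            stacklevel=2,
        )
    return length_mm * width_mm**2 / 2.0
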