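import numpy as np
import pandas as pd
import pytest

from immunoedit import CohortSample, ScreenCounts
from immunoedit.variants import GROUPS


def make_sample(sample_id, group, calls):
    """calls: list of (gene, variant_id, annotation, alt, total)."""
    return CohortSample(
        sample_id=sample_id,
        group=group,
        variants=pd.DataFrame(
            calls, columns=["gene", "variant_id", "annotation", "alt_depth", "total_depth"]
        ),
    )


def random_cohort(rng, n_variants=20, depth=100):
    """A small random cohort covering all five groups."""
    layout = [
        ("iv1", "in_vitro"),
        ("nd1", "immunodeficient"),
        ("nd2", "immunodeficient"),
        ("wt1", "immunocompetent"),
        ("wt2", "immunocompetent"),
        ("wt3", "immunocompetent"),
        ("wt4", "immunocompetent"),
        ("pd1_1", "immunotherapy_aPD1"),
        ("pdl1_1", "immunotherapy_aPDL1"),
        ("pd1_2", "immunotherapy_aPD1"),
    ]
    vids = [f"chr1:{1000 + i}:A:G" for i in range(n_variants)]
    genes = [f"G{i}" for i in range(n_variants)]
    anns = rng.choice(["missense", "splicing", "frameshift", "deletion"], size=n_variants)
    cohort = []
    for sid, group in layout:
        total = rng.integers(depth // 2, depth * 2, size=n_variants)
        # mixture: many near-zero AFs, some clearly positive
        af = np.where(rng.random(n_variants) < 0.35, rng.uniform(0.1, 0.6, n_variants),
                      rng.uniform(0.0, 0.09, n_variants))
        alt = rng.binomial(total, af)
        cohort.append(
            make_sample(sid, group, list(zip(genes, vids, anns, alt, total)))
        )
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_counts():
    """4 guides / 2 genes, 2+2 samples, hand-checkable totals."""
    counts = pd.DataFrame(
        {
            "a_r1": [100, 200, 300, 400],
            "a_r2": [50, 100, 150, 200],
            "b_r1": [400, 300, 200, 100],
            "b_r2": [200, 150, 100, 50],
        },
        index=pd.Index(["g1_sg1", "g1_sg2", "g2_sg1", "g2_sg2"], name="sgRNA"),
    )
    return ScreenCounts(
        counts=counts,
        gene_map=pd.Series(["g1", "g1", "g2", "g2"], index=counts.index, name="gene"),
        conditions=pd.Series(
            {"a_r1": "a", "a_r2": "a", "b_r1": "b", "b_r2": "b"}, name="condition"
        ),
    )


def brute_force_hotspots(cohort, min_support=2, threshold=0.1, boundary="ge"):
    """Independent rule evaluator: plain dict loops over the filter table."""
    af = {}
    meta = {}
    for s in cohort:
        for row in s.variants.itertuples(index=False):
            f = row.alt_depth / row.total_depth if row.total_depth > 0 else 0.0
            af[(row.variant_id, s.sample_id)] = f
            meta[row.variant_id] = (row.gene, row.annotation)
    out = {}
    for vid in sorted({v for v, _ in af}):
        def positive(sid):
            f = af.get((vid, sid), 0.0)
            return f >= threshold if boundary == "ge" else f > threshold

        if any(positive(s.sample_id) for s in cohort
               if s.group in ("in_vitro", "immunodeficient")):
            continue
        support = [s.sample_id for s in cohort
                   if s.group == "immunocompetent" and positive(s.sample_id)]
        if len(support) < min_support:
            continue
        it_pos = [s.sample_id for s in cohort
                  if s.group in ("immunotherapy_aPD1", "immunotherapy_aPDL1")
                  and positive(s.sample_id)]
        out[vid] = "PD1_independent" if it_pos else "PD1_dependent"
    return out
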