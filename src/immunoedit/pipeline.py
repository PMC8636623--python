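"""Pipeline driver: simulate -> profile -> screen, with manifests.

Each stage logs its parameters and row counts to stderr and writes
deterministic TSV/JSON outputs into the run directory; identical
configuration and seed reproduce the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from . import io as eio
from .screen import (
    PRESETS,
    call_hits,
    estimate_dispersion,
    exact_test,
    normalize_counts,
    rra_gene_score,
)
from .simulate import (
    CohortSimConfig,
    ScreenSimConfig,
    simulate_clonal_cohort,
    simulate_screen_counts,
)
from .variants import classify_hotspots, hotspots_to_frame, summarize_hotspots

logger = logging.getLogger("immunoedit.pipeline")


def _asdict(cfg):
    d = dataclasses.asdict(cfg)
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def run_pipeline(
    out_dir,
    seed: int = 0,
    cohort_config: CohortSimConfig | None = None,
    screen_config: ScreenSimConfig | None = None,
    af_threshold: float = 0.1,
    min_support: int = 2,
    boundary: str = "ge",
    contrast: tuple[str, str] = ("control", "selected"),
    preset: str = "invivo",
    alpha: float = 0.25,
    n_perm: int = 1000,
    stages: tuple[str, ...] = ("simulate", "profile", "screen"),
) -> Path:
    """Run the requested stages in order; returns the run directory.

    ``simulate`` writes a cohort variant table, screen count matrix, sample
    sheet and ground truth; ``profile`` applies the hotspot filter to the
    cohort table; ``screen`` runs normalization, dispersion estimation, the
    per-guide exact test, RRA gene aggregation and hit calling on the
    counts.  Any stage failure aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort_config is None:
        cohort_config = CohortSimConfig(seed=seed)
    if screen_config is None:
        screen_config = ScreenSimConfig(
            seed=seed + 1,
            gene_effect={"Gene001": {contrast[1]: 3.0}},
        )

    paths = {
        "cohort": out / "cohort.tsv",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.json",
        "hotspots": out / "hotspots.tsv",
        "summary": out / "hotspot_summary.json",
        "guides": out / "guide_results.tsv",
        "genes": out / "gene_results.tsv",
        "manifest": out / "manifest.json",
    }

    try:
        if "simulate" in stages:
            logger.info("[simulate] cohort seed=%d", cohort_config.seed)
            cohort, truth_c = simulate_clonal_cohort(cohort_config)
            eio.write_variant_table(cohort, paths["cohort"])
            logger.info("[simulate] screen seed=%d", screen_config.seed)
            sc, truth_s = simulate_screen_counts(screen_config)
            eio.write_count_matrix(sc, paths["counts"], paths["samples"])
            truth_s.variants = truth_c.variants
            truth_s.to_json(paths["truth"])
            logger.info(
                "[simulate] wrote %d samples, %d guides", len(cohort), len(sc.counts)
            )
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    try:
        if "profile" in stages:
            cohort = eio.read_variant_table(paths["cohort"])
            hotspots = classify_hotspots(
                cohort, min_support=min_support, threshold=af_threshold, boundary=boundary
            )
            eio.write_table(hotspots_to_frame(hotspots), paths["hotspots"])
            eio.write_json(summarize_hotspots(hotspots), paths["summary"])
            logger.info("[profile] %d hotspot calls", len(hotspots))
    except Exception as e:
        raise RuntimeError(f"stage 'profile' failed: {e}") from e

    try:
        if "screen" in stages:
            sc = eio.read_count_matrix(paths["counts"], paths["samples"])
            norm = normalize_counts(sc)
            disp = estimate_dispersion(norm)
            guide_res = exact_test(norm, contrast[0], contrast[1], disp.phi_common)
            gene_res = rra_gene_score(
                guide_res, alpha=alpha, n_perm=n_perm, seed=seed + 2
            )
            gene_res = call_hits(
                gene_res,
                log2fc_col="median_log2fc",
                p_col="perm_p",
                **PRESETS[preset],
            )
            eio.write_table(
                call_hits(guide_res.reset_index(), **PRESETS[preset]), paths["guides"]
            )
            eio.write_table(gene_res, paths["genes"])
            logger.info(
                "[screen] phi=%.4g, %d guides, %d gene hits",
                disp.phi_common,
                len(guide_res),
                int(gene_res["hit"].sum()),
            )
    except Exception as e:
        raise RuntimeError(f"stage 'screen' failed: {e}") from e

    eio.write_manifest(
        paths["manifest"],
        parameters={
            "stages": list(stages),
            "cohort_config": _asdict(cohort_config),
            "screen_config": {
                k: v
                for k, v in _asdict(screen_config).items()
                if k != "gene_effect"
            }
            | {"gene_effect": {g: dict(e) for g, e in screen_config.gene_effect.items()}},
            "af_threshold": af_threshold,
            "min_support": min_support,
            "boundary": boundary,
            "contrast": list(contrast),
            "preset": preset,
            "alpha": alpha,
            "n_perm": n_perm,
        },
        seed=seed,
        inputs={
            k: str(p)
            for k, p in paths.items()
            if k in ("cohort", "counts", "samples") and p.exists()
        },
    )
    return out
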