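"""Cytotoxic-infiltration scoring and pan-cohort expression correlations.

The cytotoxic CD8 T cell infiltration score of a tumor sample is the mean
expression of CD8A, CD8B, GZMB and PRF1; cohorts are stratified at the 75th
percentile of that score.  Pan-cohort association between a gene of interest
and a target (another gene, the infiltration score, or a supplied
per-sample abundance vector) is summarized per cancer type by Spearman
correlation, flagging significant negative correlations (rho < 0,
P < 0.05).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

logger = logging.getLogger(__name__)

CYTOTOXIC_GENES = ("CD8A", "CD8B", "GZMB", "PRF1")
SCORE_TARGET = "cytotoxic_score"


def cytotoxic_score(expr: pd.DataFrame, genes=CYTOTOXIC_GENES) -> pd.Series:
    """Per-sample mean expression of the cytotoxic marker genes.

    ``expr`` is genes x samples.  A missing marker raises a KeyError naming
    it.
    """
    for g in genes:
        if g not in expr.index:
            raise KeyError(f"gene {g!r} missing from expression matrix")
    return expr.loc[list(genes)].mean(axis=0)


def stratify_by_score(scores: pd.Series, percentile: float = 0.75) -> pd.Series:
    """Label samples ``high`` iff strictly above the cohort percentile-quantile.

    The quantile is computed with linear interpolation; ties at the quantile
    fall in the ``low`` stratum (strict inequality).
    """
    if len(scores) < 4:
        raise ValueError("need >= 4 samples to stratify")
    q = float(np.quantile(np.asarray(scores, dtype=float), percentile))
    return pd.Series(
        np.where(np.asarray(scores, dtype=float) > q, "high", "low"),
        index=scores.index,
        name="stratum",
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n)."""
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    rys = ry[perms]
    rx_c = rx - rx.mean()
    rys_c = rys - rys.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (rys_c**2).sum(axis=1))
    rhos = rys_c @ rx_c / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_assoc(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the t approximation, or exhaustive permutation of one
    vector when ``n < exact_below``.  Constant input is not computable and
    returns ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman correlation undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    rho, p = spearmanr(x, y)
    rho, p = float(rho), float(p)
    if len(x) < exact_below:
        p = _exact_spearman_p(x, y, rho)
    return rho, p


def mutation_prevalence(n_mutated: int, n_total: int) -> float:
    """Mutation prevalence as a percentage, rounded half-up to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_mutated <= n_total:
        raise ValueError("require 0 <= n_mutated <= n_total")
    pct = Decimal(100 * n_mutated) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pan_cohort_volcano(
    matrices: dict[str, pd.DataFrame],
    gene_x: str,
    target: str | dict[str, pd.Series] = SCORE_TARGET,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """One Spearman correlation per cohort between ``gene_x`` and a target.

    ``target`` may be a gene symbol, the sentinel ``"cytotoxic_score"``, or
    a mapping cohort -> per-sample abundance (e.g. a deconvolution output).
    Cohorts missing a required gene are skipped with a logged warning.
    ``significant_negative`` flags rho < 0 with p < ``p_cut``.
    """
    rows = []
    for cohort_id, expr in matrices.items():
        if gene_x not in expr.index:
            logger.warning("cohort %s: gene %s missing; skipped", cohort_id, gene_x)
            continue
        x = expr.loc[gene_x]
        if isinstance(target, dict):
            yv = target.get(cohort_id)
            if yv is None:
                logger.warning("cohort %s: no target vector; skipped", cohort_id)
                continue
            y = yv.reindex(x.index)
            target_name = "abundance"
        elif target == SCORE_TARGET:
            try:
                y = cytotoxic_score(expr)
            except KeyError as e:
                logger.warning("cohort %s: %s; skipped", cohort_id, e)
                continue
            target_name = SCORE_TARGET
        else:
            if target not in expr.index:
                logger.warning("cohort %s: gene %s missing; skipped", cohort_id, target)
                continue
            y = expr.loc[target]
            target_name = target
        rho, p = spearman_assoc(x, y)
        rows.append(
            {
                "cohort_id": cohort_id,
                "gene_x": gene_x,
                "target": target_name,
                "n": len(x),
                "rho": rho,
                "p_value": p,
                "significant_negative": bool(rho < 0 and p < p_cut),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cohort_id",
            "gene_x",
            "target",
            "n",
            "rho",
            "p_value",
            "significant_negative",
        ],
    )
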