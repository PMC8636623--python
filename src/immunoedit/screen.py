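"""Pooled CRISPR screen statistics.

The analysis chain mirrors the count-based screen workflow:

1. **Normalization** — reads per guide are scaled by the sample's total
   mapped reads to the *largest* library size seen in the comparison, plus a
   pseudo-count of one::

       normalized = reads / total_reads * max_total_over_samples + 1

2. **Dispersion** — a common negative-binomial dispersion ``phi``
   (``var = mu + phi * mu^2``) is estimated by conditional maximum
   likelihood on within-condition replicates, optionally shrunk to tagwise
   values by a weighted empirical-Bayes combination.

3. **Per-guide exact test** — per-condition normalized counts are summed to
   pseudo-counts and compared by a conditional negative-binomial exact test
   (an adapted Fisher's exact test): given the two-group total, the null
   distribution of one group's sum is beta-binomial with shapes
   ``(n_a/phi, n_b/phi)``; the two-sided p-value sums the probabilities of
   all outcomes no more likely than the observed one.  ``phi = 0`` reduces
   to the conditional binomial test.

4. **Gene aggregation (alpha-RRA)** — guides are ranked by one-sided
   evidence; a gene's score ``rho`` is the minimum beta order-statistic
   tail probability over its guides with rank percentile below ``alpha``,
   and its significance comes from permuting the guide-to-gene assignment.

5. **Hit calling** — fold-change plus p-value cut-offs, with presets for
   the in-vivo (|FC| > 1.5, P < 0.05, both directions) and co-culture
   (FC > 1.4, P < 0.05, enrichment) screen designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

DIRECTION_ENRICHED = "enriched"
DIRECTION_DEPLETED = "depleted"

#: Hit-calling presets from the two screen designs.
PRESETS = {
    "invivo": {"fc_cut": 1.5, "p_cut": 0.05, "direction": "both"},
    "coculture": {"fc_cut": 1.4, "p_cut": 0.05, "direction": DIRECTION_ENRICHED},
}


@dataclass
class ScreenCounts:
    """Raw guide x sample integer counts with guide->gene and sample->condition maps."""

    counts: pd.DataFrame
    gene_map: pd.Series
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate guide ID {dup!r}")
        if not self.gene_map.index.equals(self.counts.index):
            raise ValueError("gene_map index must match the count matrix guides")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_of(self, condition: str) -> list[str]:
        cols = [c for c in self.counts.columns if self.conditions[c] == condition]
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return cols


@dataclass
class NormalizedCounts:
    """Library-size-normalized counts (floored at 1 by the pseudo-count)."""

    values: pd.DataFrame
    gene_map: pd.Series
    conditions: pd.Series

    def samples_of(self, condition: str) -> list[str]:
        cols = [c for c in self.values.columns if self.conditions[c] == condition]
        if not cols:
            raise ValueError(f"no samples with condition {condition!r}")
        return cols


@dataclass
class DispersionEstimate:
    """Common (and optionally tagwise) NB dispersion, var = mu + phi mu^2."""

    phi_common: float
    phi_tagwise: pd.Series | None = None
    shrinkage_weight: float = 10.0


def normalize_counts(raw: ScreenCounts) -> NormalizedCounts:
    """Scale each sample to the largest library size and add a pseudo-count.

    ``norm[g, s] = raw[g, s] / total[s] * max_total + 1``.
    """
    totals = raw.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total mapped reads")
    values = raw.counts / totals * totals.max() + 1.0
    return NormalizedCounts(values=values, gene_map=raw.gene_map, conditions=raw.conditions)


def _cond_log_lik(delta: float, blocks: list[np.ndarray]) -> float:
    """Conditional log-likelihood of delta = phi/(1+phi) given replicate sums."""
    r = (1.0 - delta) / delta
    total = 0.0
    for y in blocks:
        n_g, m = y.shape
        z = y.sum(axis=1)
        total += (
            gammaln(y + r).sum()
            - n_g * m * gammaln(r)
            + n_g * gammaln(m * r)
            - gammaln(z + m * r).sum()
        )
    return total


def estimate_dispersion(
    norm: NormalizedCounts,
    fallback: float = 0.1,
    tagwise: bool = False,
    shrinkage_weight: float = 10.0,
) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    Only conditions with >= 2 replicates inform the estimate (the
    conditional likelihood given each guide's within-condition sum removes
    the per-guide means).  A design with no replicated condition returns the
    configured ``fallback`` with a warning.  With ``tagwise=True``, per-guide
    dispersions are shrunk toward the common value by weighting each guide's
    own conditional likelihood with ``shrinkage_weight`` pseudo-guides of
    the pooled likelihood.
    """
    y = np.rint(norm.values.to_numpy()).astype(np.int64)
    blocks = []
    for cond in norm.conditions.unique():
        cols = [i for i, c in enumerate(norm.values.columns) if norm.conditions[c] == cond]
        if len(cols) >= 2:
            blocks.append(y[:, cols])
    if not blocks:
        warnings.warn(
            f"no condition has replicates; returning fallback dispersion {fallback}",
            stacklevel=2,
        )
        return DispersionEstimate(phi_common=fallback, shrinkage_weight=shrinkage_weight)

    res = minimize_scalar(
        lambda d: -_cond_log_lik(d, blocks),
        bounds=(1e-4, 0.95),
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(res.x)
    phi = delta / (1.0 - delta)
    if phi < 1e-3:  # boundary solution: no evidence of extra-Poisson variance
        phi = 0.0

    phi_tag = None
    if tagwise:
        n_guides = y.shape[0]
        pooled = [b.copy() for b in blocks]
        vals = np.empty(n_guides)
        for g in range(n_guides):
            own = [b[g : g + 1, :] for b in blocks]

            def neg(d, own=own):
                return -(
                    _cond_log_lik(d, own)
                    + shrinkage_weight * _cond_log_lik(d, pooled) / n_guides
                )

            r = minimize_scalar(neg, bounds=(1e-4, 0.95), method="bounded",
                                options={"xatol": 1e-4})
            ph = float(r.x) / (1.0 - float(r.x))
            vals[g] = 0.0 if ph < 1e-3 else ph
        phi_tag = pd.Series(vals, index=norm.values.index, name="phi")
    return DispersionEstimate(
        phi_common=phi, phi_tagwise=phi_tag, shrinkage_weight=shrinkage_weight
    )


def conditional_nb_pvalue(a: int, b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional NB exact test of a vs b given their sum.

    ``a`` and ``b`` are the two groups' pseudo-counts (sums over ``n_a`` and
    ``n_b`` equal-size libraries).  Under the null of a common mean, the
    conditional law of ``a`` given ``n = a + b`` is beta-binomial with
    shapes ``(n_a/phi, n_b/phi)``; at ``phi = 0`` it is
    ``Binomial(n, n_a/(n_a+n_b))``.  The two-sided p-value sums the
    probabilities of all outcomes no more likely than the observed one
    (minimum-likelihood method).
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if a < 0 or b < 0:
        raise ValueError("counts must be >= 0")
    n = a + b
    if n == 0:
        return 1.0
    k = np.arange(n + 1)
    if phi == 0.0:
        pa = n_a / (n_a + n_b)
        logpmf = (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + k * np.log(pa)
            + (n - k) * np.log1p(-pa)
        )
    else:
        al, be = n_a / phi, n_b / phi
        logpmf = (
            gammaln(n + 1)
            - gammaln(k + 1)
            - gammaln(n - k + 1)
            + gammaln(k + al)
            + gammaln(n - k + be)
            - gammaln(n + al + be)
            - (gammaln(al) + gammaln(be) - gammaln(al + be))
        )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p_obs = pmf[a]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-10)].sum())
    return min(p, 1.0)


def exact_test(
    norm: NormalizedCounts, condition_a: str, condition_b: str, phi: float
) -> pd.DataFrame:
    """Per-guide log2 fold-change (b over a) and conditional NB exact p-value.

    Per-condition normalized counts are summed into integer pseudo-counts
    before conditioning; normalization has already equalized effective
    library sizes, and unequal replicate numbers enter through the
    beta-binomial shapes.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    cols_a = norm.samples_of(condition_a)
    cols_b = norm.samples_of(condition_b)
    va = norm.values[cols_a].to_numpy()
    vb = norm.values[cols_b].to_numpy()
    mean_a, mean_b = va.mean(axis=1), vb.mean(axis=1)
    log2fc = np.log2(mean_b / mean_a)
    s_a = np.rint(va.sum(axis=1)).astype(np.int64)
    s_b = np.rint(vb.sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [
            conditional_nb_pvalue(int(a), int(b), len(cols_a), len(cols_b), phi)
            for a, b in zip(s_a, s_b)
        ]
    )
    return pd.DataFrame(
        {
            "guide": norm.values.index,
            "gene": norm.gene_map.to_numpy(),
            "log2fc": log2fc,
            "p_value": pvals,
            "direction": np.where(log2fc < 0, DIRECTION_DEPLETED, DIRECTION_ENRICHED),
        }
    ).set_index("guide")


def _rra_rho_sorted(u_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """alpha-restricted RRA score for pre-sorted percentile rows.

    ``u_sorted`` has one row per (gene, permutation) and k ascending
    percentiles per row.  For each row, rho = min over positions j with
    u_(j) <= alpha of BetaCDF(u_(j); j, k - j + 1); rho = 1 when no
    percentile passes alpha.
    """
    k = u_sorted.shape[1]
    j = np.arange(1, k + 1, dtype=float)
    vals = beta_dist.cdf(u_sorted, j, k - j + 1.0)
    vals = np.where(u_sorted <= alpha, vals, 1.0)
    return vals.min(axis=1)


def rra_gene_score(
    sgrna_results: pd.DataFrame,
    gene_map: pd.Series | None = None,
    alpha: float = 0.25,
    n_perm: int = 10_000,
    seed: int | None = None,
    direction: str = DIRECTION_ENRICHED,
) -> pd.DataFrame:
    """Aggregate per-guide evidence into gene scores by modified RRA.

    Guides are ranked by one-sided evidence in ``direction`` (the two-sided
    p is halved on the matching side); the gene score ``rho`` is the
    minimum beta order-statistic tail probability over guides with rank
    percentile <= ``alpha``.  The permutation p-value randomly reassigns
    guides to genes (preserving per-gene guide counts): ``perm_p =
    (1 + #{rho_perm <= rho_obs}) / (n_perm + 1)``.  ``n_perm = 0`` skips
    permutation (``perm_p`` is NaN).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if direction not in (DIRECTION_ENRICHED, DIRECTION_DEPLETED):
        raise ValueError(f"direction must be enriched or depleted, got {direction!r}")
    if n_perm > 0 and seed is None:
        raise ValueError("seed is required when n_perm > 0")
    df = sgrna_results
    genes = gene_map.reindex(df.index) if gene_map is not None else df["gene"]
    p = df["p_value"].to_numpy(dtype=float)
    lfc = df["log2fc"].to_numpy(dtype=float)
    sign = lfc if direction == DIRECTION_ENRICHED else -lfc
    one_sided = np.where(sign > 0, p / 2.0, np.where(sign < 0, 1.0 - p / 2.0, 0.5))
    m = len(df)
    u = rankdata(one_sided, method="average") / m

    order = np.argsort(genes.to_numpy(), kind="stable")
    u_ord = u[order]
    genes_ord = genes.to_numpy()[order]
    lfc_ord = lfc[order]
    blocks: dict[str, slice] = {}
    start = 0
    for i in range(1, m + 1):
        if i == m or genes_ord[i] != genes_ord[start]:
            blocks[genes_ord[start]] = slice(start, i)
            start = i

    rng = np.random.default_rng(seed) if n_perm > 0 else None
    perm_u = None
    if n_perm > 0:
        perm_u = np.tile(u_ord, (n_perm, 1))
        perm_u = rng.permuted(perm_u, axis=1)

    rows = []
    for gene, sl in blocks.items():
        ug = np.sort(u_ord[sl])
        rho = float(_rra_rho_sorted(ug[None, :], alpha)[0])
        if n_perm > 0:
            rho_null = _rra_rho_sorted(np.sort(perm_u[:, sl], axis=1), alpha)
            perm_p = (1.0 + np.count_nonzero(rho_null <= rho)) / (n_perm + 1.0)
        else:
            perm_p = np.nan
        rows.append(
            {
                "gene": gene,
                "rho": rho,
                "perm_p": perm_p,
                "median_log2fc": float(np.median(lfc_ord[sl])),
                "n_guides": sl.stop - sl.start,
                "n_guides_passing_alpha": int(np.count_nonzero(u_ord[sl] <= alpha)),
            }
        )
    out = pd.DataFrame(rows).sort_values(["rho", "gene"]).reset_index(drop=True)
    return out


def call_hits(
    results: pd.DataFrame,
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
    direction: str = "both",
    adjust: str = "none",
    log2fc_col: str = "log2fc",
    p_col: str = "p_value",
) -> pd.DataFrame:
    """Flag entries passing fold-change and p-value cut-offs.

    ``fc_cut`` is on the fold-change scale (> 1); ``direction`` is
    ``both``/``enriched``/``depleted``; ``adjust="BH"`` applies
    Benjamini-Hochberg before thresholding.  Works on per-guide or per-gene
    tables (point ``log2fc_col``/``p_col`` at the relevant columns).
    """
    if fc_cut <= 1:
        raise ValueError("fc_cut must exceed 1")
    if direction not in ("both", DIRECTION_ENRICHED, DIRECTION_DEPLETED):
        raise ValueError(f"unknown direction {direction!r}")
    out = results.copy()
    p = out[p_col].to_numpy(dtype=float)
    if adjust == "BH":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
        out["p_adj"] = p
    elif adjust != "none":
        raise ValueError(f"adjust must be 'none' or 'BH', got {adjust!r}")
    lfc = out[log2fc_col].to_numpy(dtype=float)
    log2cut = np.log2(fc_cut)
    if direction == "both":
        pass_fc = np.abs(lfc) > log2cut
    elif direction == DIRECTION_ENRICHED:
        pass_fc = lfc > log2cut
    else:
        pass_fc = lfc < -log2cut
    out["hit"] = pass_fc & (p < p_cut)
    return out


def competition_log2fc(
    norm: NormalizedCounts, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Per-guide log2 ratio of mean normalized abundance, b over a."""
    cols_a = norm.samples_of(condition_a)
    cols_b = norm.samples_of(condition_b)
    mean_a = norm.values[cols_a].mean(axis=1)
    mean_b = norm.values[cols_b].mean(axis=1)
    return pd.DataFrame(
        {
            "gene": norm.gene_map,
            "log2fc": np.log2(mean_b / mean_a),
        },
        index=norm.values.index,
    )
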