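# Methods

## Scientific setting

A genetically heterogeneous cancer cell line implanted into hosts with
graded T cell immunity is a natural selection experiment: clones carrying
immune-evasion mutations expand preferentially where T cell pressure is
high. Comparing the mutational composition of tumors across a cultured
baseline, immunodeficient hosts, immunocompetent hosts, and hosts under
PD-1/PD-L1 checkpoint blockade separates candidate evasion drivers from
passengers, and the behaviour of each candidate under blockade indicates
whether the escape route runs through the PD-1 axis. Candidates are then
validated functionally by a pooled CRISPR knockout screen: guides against a
gene whose loss confers resistance to T cell killing become enriched in
tumors grown under immune pressure.

This package implements the statistical chain of that design — hotspot
mutation profiling, screen enrichment statistics, and
infiltration-correlation summaries — plus seeded generators that produce
synthetic cohorts and screens with known ground truth, so every stage can
be exercised and power-checked without sequencing data.

## Hotspot mutation profiling

For each called variant in each sample the allele frequency is
AF = alt depth / total depth at the locus (AF := 0 at zero depth — no
evidence of alteration; a warning is emitted). A sample is *positive* for a
variant when AF ≥ 0.1 (the comparator is configurable: the rule table uses
≥, while a strict > variant is also in circulation; we default to ≥). A
variant is reported as a hotspot iff it is

* negative in every cultured baseline sample and every immunodeficient
  tumor, and
* positive in at least `min_support = 2` distinct immunocompetent tumors.

Reported hotspots are `PD1_dependent` when negative in *all* immunotherapy
tumors (both antibody arms — the mutant clone is presumed eliminated once
T cells are unleashed) and `PD1_independent` when positive in at least one.
Variants absent from a sample's table count as negative there (joint
calling emits cohort-wide sites; a consumer of per-sample tables needs a
stated convention). Variant identity is the exact `variant_id` string; no
positional merging is attempted.

Note that the reported set is *not* monotone in the AF threshold in full
generality: raising the threshold can flip an immunodeficient sample from
positive to negative and thereby admit a previously excluded variant. It is
monotone when the exclusion groups are clean, which is the regime the
filter is designed for.

## Screen count statistics

**Normalization.** `normalized = reads / total_mapped_reads ×
max_total_over_all_samples + 1`. Scaling to the *largest* library keeps
values on a counts-like scale and the +1 pseudo-count floors every entry at
1, so fold-changes are always defined. The maximum is taken over all
samples loaded in the comparison set, baselines included.

**Dispersion.** Counts are modelled as negative binomial,
var = μ + φμ². The common φ is estimated by conditional maximum
likelihood: within each condition with ≥ 2 replicates, the likelihood of
the replicate vector given its sum does not involve the per-guide mean, so
the profile over δ = φ/(1+φ) can be maximized directly (bounded scalar
search, δ ∈ [10⁻⁴, 0.95]). Estimates below 10⁻³ are reported as exactly 0
(boundary solution: no extra-Poisson variance). Optional tagwise values
maximize each guide's own conditional likelihood plus `shrinkage_weight`
(default 10) pseudo-guides of the pooled likelihood — a weighted
empirical-Bayes shrinkage toward the common value. A design with no
replicated condition returns a configurable fallback (default 0.1) with a
warning.

**Per-guide exact test.** Normalized counts are summed per condition into
pseudo-counts (a, b). Under the null of a common mean and a shared φ, and
with library sizes equalized by normalization, the conditional law of `a`
given n = a + b is beta-binomial with shapes (n_a/φ, n_b/φ), where n_a and
n_b are the replicate numbers; at φ = 0 this is Binomial(n, n_a/(n_a+n_b)).
The two-sided p-value is the sum of the probabilities of all outcomes no
more likely than the one observed (minimum-likelihood method, the adapted
Fisher's-exact construction). The log₂ fold-change is
log₂(mean_b / mean_a) of normalized values. The implementation enumerates
the conditional pmf with log-gamma arithmetic and normalizes it; tests
check it against independent scipy enumeration to |Δp| < 10⁻⁹.

**Gene aggregation (α-RRA).** Guides are ordered by one-sided evidence in
the chosen direction (two-sided p halved on the matching side of the
fold-change, reflected on the other), giving rank percentiles
u_i = rank_i/m. For a gene with k guides, the percentiles are sorted and
those with u ≤ α (default α = 0.25; the method is named in the source
workflow without a stated α, and 0.25 is the conventional default) are
scored by the beta order-statistic tail probability Beta(u_(j); j, k−j+1);
ρ is the minimum over kept j, and ρ = 1 when no guide passes α. Because
only ranks enter, ρ is invariant under monotone transforms of the guide
p-values. Significance comes from permuting the guide→gene assignment
(preserving per-gene guide counts): perm_p = (1 + #{ρ_perm ≤ ρ_obs}) /
(n_perm + 1), so perm_p ∈ [1/(n_perm+1), 1]. The permutation stream is
seeded and bit-reproducible.

**Hit calling.** An entry is a hit when its fold-change exceeds the cut in
the stated direction and its (optionally BH-adjusted) p-value is below the
cut. Presets: in-vivo screen |FC| > 1.5, P < 0.05, both directions;
co-culture screen FC > 1.4, P < 0.05, enrichment only. Gene-level calls
use the median guide log₂FC with the permutation p. The competition-assay
helper reports per-guide log₂ ratios of mean normalized abundance.

## Infiltration correlation

The cytotoxic CD8 T cell infiltration score of a sample is the arithmetic
mean of CD8A, CD8B, GZMB and PRF1 expression. Cohorts are stratified at
the 75th percentile (linear-interpolation quantile, strictly-above =
high; with all-tied scores everything is low). Spearman correlation uses
mid-ranks for ties, the t approximation for p, and exhaustive permutation
(two-sided on |ρ|) below n = 10. The pan-cohort volcano computes one
correlation per cancer-type matrix between a gene of interest and a target
(another gene, the infiltration score, or a supplied per-sample abundance
vector, e.g. a deconvolution output) and flags significant negative
correlations (ρ < 0, two-sided p < 0.05). Under independence the
two-sided rejection rate is 5% and the negative-flag rate is therefore
2.5% by symmetry. Mutation prevalence is 100·m/t rounded half-up to one
decimal, matching printed percentages. Expression is used as provided
(FPKM-like); rank statistics are transform-invariant, so no log transform
is applied.

## Synthetic data generators

**Clonal cohort.** Each planted site has a per-group clone fraction; the
default driver panel mirrors the profiled design: 23 PD-1-dependent
drivers (fraction 0.4 in immunocompetent tumors, 0.01 elsewhere —
including all immunotherapy samples, eliminated under blockade), 30
PD-1-independent drivers (0.4 in immunocompetent *and* both immunotherapy
arms), and 200 passengers at 0.01 everywhere. Cohort sizes default to 1
cultured baseline, 10 immunodeficient, 13 immunocompetent and 8
immunotherapy tumors (split 4/4 across the αPD-1/αPD-L1 arms; the extra
sample goes to αPD-1 when odd). Per site and sample, total depth is
negative binomial (mean 100, dispersion 0.1 — overdispersed transcript
coverage at deep-RNA-seq scale) and alt depth is binomial in an effective
fraction f·exp(ε), ε ~ N(0, af_noise²) with af_noise = 0.02.
Multiplicative noise keeps zero fractions exactly zero (an absent clone
never produces alt reads) and leaves the marginal mean AF within a
fraction of a percent of the configured fraction. Clone fraction is used
directly as the binomial success probability; tumor purity and subclone
phylogeny are not modelled separately.

**Pooled screen.** The default library is 53 candidate genes plus 5
control genes (Pdcd1, Cd274, Jak1, Jak2, B2m) × 10 guides. Per-guide
baseline abundances are log-normal (σ = 0.5, typical cloning spread);
guide efficacy is drawn once per guide from Beta(3, 1) (most guides cut
well, a tail does not) and reused across conditions — efficacy is a
property of the guide. Expected counts in a sample are proportional to
baseline × effect^efficacy for the guide's gene in that sample's
condition, scaled to `sample_depth` (default 2×10⁵ reads, ≈ 350 reads per
guide); observed counts are negative binomial with dispersion 0.2
(biological replicate tumors). Defaults: 8 replicates per condition.

**What the generators do not emulate.** No read-level errors, alignment or
variant-calling artifacts; no clonal interference or phylogeny; no
guide-level off-target effects; no correlation between guides beyond the
shared gene effect; screen samples are independent given the condition
(real replicate tumors share engraftment bottlenecks). Passing recovery
tests therefore demonstrates that the statistics behave as designed under
the stated generative model, not that the upstream wet-lab and alignment
steps are error-free.

## Numerical choices

* Exact-test pmf: log-gamma enumeration, max-subtracted exponentiation,
  renormalized; outcomes within a 1+10⁻¹⁰ relative factor of the observed
  probability count as "as likely" (tie tolerance on the discrete pmf).
* Dispersion search: bounded on δ ∈ [10⁻⁴, 0.95], xatol 10⁻⁶; sub-10⁻³
  estimates snap to 0.
* Pseudo-counts are rounded to integers before conditioning.
* Writers emit floats at 6 significant digits with stable column order;
  identical configuration and seed reproduce all pipeline outputs
  byte-for-byte.
* Quantiles use linear interpolation; stratification is strictly above.
* Permutation p-values use the add-one estimator, never exactly zero.

## Problem sizes in the shipped checks

Simulation-backed checks run at sizes chosen to make Monte-Carlo bands
tight while keeping the suite quick on a laptop: 200 seeds for
cohort-driver recovery, 100 seeds for planted-screen-gene recovery (500
permutations each), a single 1000-guide 4v4 null screen for type I error
(3 MC SE band), 50 seeds × 1000 guides for dispersion recovery, 1000
cohorts of n = 50 for the volcano null. `scripts/acceptance.py` re-runs
the same analyses at comparable sizes from a single command-line seed.

## Known limitations

* The exact test collapses replicates into per-condition sums; per-sample
  variation enters only through φ. Quantile re-adjustment of unequal
  library sizes is handled by the normalization itself.
* α-RRA permutes guide→gene labels globally; with very few genes the
  permutation null is coarse, and perm_p saturates at 1/(n_perm+1).
* The hotspot filter is deliberately rule-based (no uncertainty on AF);
  depth enters only through the binomial noise the simulator emulates.
* Gene-level "hits" combine the RRA permutation p with the median guide
  fold-change; no fusion with an MLE-style beta score is attempted — the
  ranking reported here is ρ plus median log₂FC.
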