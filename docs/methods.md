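# Methods

This note documents the statistical procedure the package implements, the
choices that were genuinely open, and what the synthetic benchmark does and
does not establish.

## The enrichment model

The object being tested is the column-merged regulator list *L*. Given the
sorted deregulated gene list *D* (Step 1) and each gene's regulator list
sorted by correlation strength (Step 2), *L* interleaves the per-gene
rankings column by column; exhausted genes are skipped, so *L* has exactly
one entry per (gene, regulator) interaction with expression data
(N = Σᵢ |R_gᵢ|). A regulator that influences many deregulated genes, and
does so more strongly than competing regulators of the same genes, collects
early positions in *L*. Each of its occurrences counts separately — a
regulator targeting 25 listed genes contributes 25 positions.

Two one-sided tests of "enriched toward the top" are offered:

* **WRS** (default): the rank sum W of the regulator's positions against
  the remaining N−k positions. Positions are distinct, so the null is the
  tie-free rank-sum distribution: for N·k ≤ `exact_threshold` (default 10⁶)
  the p-value is exact (scipy's exact Mann–Whitney null distribution);
  beyond it, the continuity-corrected normal approximation
  z = (W − k(N+1)/2 + ½)/√(k(N−k)(N+1)/12), p = Φ(z). A scan against
  exhaustive enumeration shows the approximation stays within 0.05 of the
  exact tail whenever both groups have at least two members; with a single
  member no normal curve can track the few-atom discrete null, which is why
  the exact mode exists and covers all small problems.
* **KS**: the unweighted running sum (+1/k at occurrences, −1/(N−k)
  elsewhere), ES = supremum of the prefix values (≥ 0; the walk ends at 0).
  The p-value Pr(ES* ≥ ES) under uniform placement is computed exactly by a
  lattice-path dynamic program over the hit count — the walk is scaled by
  k(N−k) so all prefix values are integers, and the DP (float64, vectorised
  over hits) accumulates the probability of staying strictly below the
  observed supremum. Beyond the threshold the one-sided tail
  exp(−2·ES²·k(N−k)/N) is used; that large-deviation form is accurate for
  small p (observed |Δ| ≤ 0.012 at N = 200 for p ≤ 0.05) but drifts
  mid-range, which is acceptable because decisions are made in the tail.

k = N (a regulator filling the whole list) carries no contrast and is
defined as p = 1. Raw p-values across all tested regulators are adjusted by
the Benjamini–Yekutieli step-up (statsmodels), which controls the FDR under
the arbitrary dependence created by regulators competing for positions in
one shared list.

WRS is the default test (it gave the sharper rankings in our comparisons of
the two on synthetic data, and it has an exact null at all practical sizes);
both remain available.

## Correlations and direction calls

Correlations are computed across all samples, case and control alike — the
group split enters only through Step 1. Pearson is the default (regulatory
couplings are conventionally modelled linearly); Spearman (average ranks on
ties) is available for monotone non-linear relations. The default per-gene
sort is by absolute correlation, so strong repressors rank as high as strong
activators; signed sorting is available but always descending, so analysts
hunting repressors should prefer absolute mode. Ties break on regulator id.

A zero-variance expression vector — possible in bootstrap resamples that
draw one column many times — yields correlation 0 rather than an error: the
resample must not abort, and "no information" deserves the worst rank in
absolute mode.

Each regulator's mean signed correlation over its listed targets is
reported; above +τ it is called an activator, below −τ a repressor,
otherwise ambiguous (τ defaults to 0, so "ambiguous" is reserved for an
exactly balanced mean).

## Differential expression

Step 1 offers ratio/difference scores (fold change, log fold change,
signal-to-noise), Student and Welch *t*, a rank-sum z, label correlations,
and the default shrinkage *t*: the per-gene pooled variance v_g (two-group
centred residuals, n−2 df) is shrunk toward the median variance with
intensity λ* = min(1, Σ V̂ar(v_g) / Σ (v_g − v_med)²), where
V̂ar(v_g) = n/(n−1)³ Σ(wᵢ − w̄)² and wᵢ are squared residuals; p-values come
from the standard normal. When all empirical variances coincide the
denominator guard sets λ* = 1, which is then identical to the pooled *t*.
Downstream only the ordering matters, so infinite statistics from
zero-variance genes are demoted to (largest finite |score| + 1), and plain
fold change (neutral value 1, undefined for a zero control mean — such genes
are dropped with a warning) selects "up" as ratio > 1.

## Bootstrap

B matrices are drawn by resampling the m sample columns i.i.d. with
replacement — unstratified, since group labels play no role in Steps 2–4.
The gene list stays fixed from the original matrix; only Steps 2–4 repeat,
so N and each regulator's k are constant across replicates and only the
positions move. Per regulator the replicate **adjusted** p-values (Step 4
includes the adjustment, and the option `median_on="raw"` is provided for
the alternative reading) are summarised by:

* the **median** — the regulator's new ranking score (even B: midpoint
  average),
* the standard deviation (ddof = 1) and the mean absolute deviation about
  the replicate mean,
* a **BCa interval**: bias term z₀ = Φ⁻¹(fraction of replicates below the
  original-run estimate), acceleration a from the jackknife skewness over
  leave-one-column-out re-runs, endpoints at the
  Φ(z₀ + (z₀+z_{α/2})/(1−a(z₀+z_{α/2}))) replicate quantiles. All-identical
  replicates give a degenerate (v, v) interval; an infinite z₀ (all
  replicates on one side) clamps to the percentile interval with a warning.
  The interval covers the adjusted p-value, the scale on which results are
  reported; percentile intervals and no intervals are options (the
  jackknife doubles the run cost at m ≈ B).

A regulator untested in a replicate contributes p = 1 there, keeping the
replicate vectors aligned. Randomness flows from one master seed through
spawned per-replicate substreams, so enlarging B leaves earlier replicates
unchanged.

The **pair-swap trace** counts discordant regulator pairs between the
cumulative rankings after i and i+1 replicates (consecutive cumulative
rankings are the only reading under which convergence to a handful of swaps
is expected). The trace ranks cumulative medians of the **raw** p-values:
the step-up adjustment maps nearly all null regulators to exactly p = 1,
whose id-broken ties never move, and the diagnostic would be blind to the
order fluctuation it is meant to expose. The reported ranking itself still
uses the median adjusted p.

## Aggregation

Result lists for several gene-list sizes are combined over the union of
regulators: rank sum (a regulator missing from a list is imputed at its
worst rank, list length + 1) and maximum p (missing → 1) — worst-case
imputation is deliberately conservative. The max-p vector receives a final
BY adjustment, which is the primary sort key (ties: rank sum, then id);
rank sum is reported alongside as the alternative consensus. The aggregate
also reports pairwise and all-way overlaps of the per-list significant sets.

## Synthetic benchmark

The generator emulates a perturbation experiment (artificial overexpression
of one regulator): the planted regulator's row gains a case shift of β
expression units; each of its targets follows it linearly
(γ·regulator + noise), so targets are both differentially expressed (shift
γβ) and correlated with their regulator (≈ γ·sd_r/√(γ²sd_r² + σ²); with the
defaults β = γ = 2, σ = 1 that is ≈ 0.94). Decoy regulators are pure noise
and draw their target sets from the same gene universe as the planted one
(planted sets are mutually disjoint for clean attribution), so neither the
group split nor the interaction structure alone identifies the planted
regulator — with β = γ = 0 its p-value is uniform, which the tests check.

Defaults: 2000 genes, 100 regulators × 25 targets, 10 vs 10 samples, one
planted regulator. Under these conditions the planted regulator is
recovered at rank 1 in ≥ 90% of 50 seeded replicates (observed: 100%) with
20 bootstrap replicates per run — sizes chosen so the whole benchmark is a
few minutes of single-core work.

What this does **not** show: real expression data have correlated null
genes, batch structure, heavy-tailed noise and count-based measurement
error; real RTI collections are incomplete and biased toward well-studied
factors; and real regulators share targets in structured, not uniform,
ways. Passing the benchmark demonstrates the machinery is correct and the
pipeline recovers a strong planted signal, not that the method's error
rates transfer to any particular biological dataset.

## Numerical conventions

* Identifiers match as exact case-sensitive strings; no symbol aliasing.
* All orderings break ties deterministically (score, then id), so repeated
  runs with one seed are byte-identical.
* Exact p-value floors at 10⁻³⁰⁰ keep values inside (0, 1] for the step-up
  adjustment when float cancellation would round them to 0.
* Fewer than 10 samples triggers a warning (correlation estimates are
  unstable), fewer than 2 per group is an error.
* Regulators in the RTI collection without an expression row are dropped
  from the per-gene lists and counted as untestable interactions; genes
  with no testable regulator are omitted from *L* with a log entry.
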