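# reggae

Prioritization of transcriptional regulators from two-group gene-expression
data by **REG**ulator–**G**ene **A**ssociation **E**nrichment.

Transcription factors, coregulators and epigenetic modifiers steer the
transcriptional program, and changes in their activity underlie many disease
phenotypes. Given (i) a normalized expression matrix whose samples fall into
two groups (e.g. disease vs control) and (ii) a collection of
regulator–target interactions (RTIs, typically ChIP-seq–derived), this
package ranks regulators by how strongly they are associated with the genes
that separate the two groups.

## Method

1. **Differential expression.** Every gene is scored between the groups
   (shrinkage *t* by default; fold changes, signal-to-noise, Student/Welch
   *t*, rank-sum and label-correlation scores are available) and a sorted
   up- or down-regulated gene list *D* = {g₁, …, gₙ} is selected (top-*k* or
   a p-value cutoff).
2. **Association.** For each gene gᵢ ∈ *D*, its regulator list R_gᵢ from the
   RTI collection is sorted by the (absolute or signed) Pearson or Spearman
   correlation between regulator and target expression across *all* samples.
3. **Merge.** The per-gene rankings are merged column by column into one
   list *L* = {r₁₁, r₂₁, …, rₙ₁, r₁₂, …}: every gene's best regulator first
   (in gene order), then every gene's second-best, and so on.
4. **Enrichment.** A regulator occupying *k* of the *N* entries of *L* is
   tested for enrichment toward the top — one-sided Wilcoxon rank-sum on its
   positions (default; exact null distribution for N·k up to 10⁶), or the
   unweighted Kolmogorov–Smirnov running sum (+1/k at hits, −1/(N−k)
   elsewhere; ES = sup of the prefix sums, exact p by lattice-path counting).
   P-values are Benjamini–Yekutieli adjusted.

Robustness comes from a column bootstrap: B resampled matrices repeat steps
2–4, each regulator is re-scored by its **median adjusted p**, with standard
deviation, mean absolute deviation and BCa confidence intervals reported,
plus a pair-swap trace that shows when the ranking has stabilized.
Analyses over several gene-list sizes are aggregated by rank sums and
maximum p (BY-adjusted).

A mean signed target correlation per regulator suggests whether it acts as
an activator or a repressor.

## Worked example

The package ships a generator that plants a perturbed regulator (case-group
shift β, linear target coupling γ) among decoys:

```python
from reggae import ReggaeModel, SimulationConfig, simulate

expr, rti, truth = simulate(SimulationConfig(seed=7))   # plants R0001
model = ReggaeModel(expr, rti)                          # WRS, Pearson, absolute
res = model.fit(top_k=(250, 500), bootstrap=50, seed=7, ci_method="percentile")
print(res.summary(n=5))
```

```
Regulator-gene association enrichment
======================================
test: wrs   correlation: pearson (absolute)   DE method: shrinkage_t (up)
samples: 20   bootstrap replicates: 50

[top250] 95 regulators tested (N=308, untested=0)
 rank regulator  n_occurrences  p_median  mean_signed_correlation direction
    1     R0001             25  1.26e-34                    0.946 activator
    2     R0073              3         1                  -0.0574 repressor
...
[aggregated over 2 lists]
 rank regulator  rank_sum    p_max  p_max_adjusted  n_lists_present
    1     R0001         2 1.26e-34        6.45e-32                2
    2     R0085         9        1               1                2
```

The planted regulator occupies all 25 of its target slots near the top of
*L* (n_occurrences = 25 out of N = 308), its median adjusted p across the 50
bootstrap replicates is ≈10⁻³⁴ while every decoy sits at p ≈ 1, and its mean
signed target correlation (0.946) calls it an activator. The consensus over
both list sizes keeps it at rank 1 with the minimum possible rank sum.

The same analysis from the shell:

```bash
reggae simulate --config sim.yaml --out-prefix sim/toy
reggae run --expression sim/toy.expression.tsv --groups sim/toy.groups.tsv \
           --rti sim/toy.rti.gmt --case-group case \
           --top-k 250,500 --bootstrap 50 --seed 7 --out results/
reggae aggregate results/results_top250.tsv results/results_top500.tsv --out agg.tsv
```

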