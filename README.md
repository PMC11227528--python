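# cellprop

Differential cell-type **proportion analysis** (PA) for single-cell
resolution data — for anyone who has clustered an scRNA-seq / scATAC-seq
experiment and wants to know *which cell types change in relative abundance
between conditions*, with honest statistics for both replicated and
unreplicated designs.

## The statistical model

Given a table with one row per cell (sample, cluster/cell type, condition),
cells are tabulated into a samples × clusters count matrix and row-normalized
to proportions $p_{jk}$ (sample $j$, cluster $k$).  Because cluster
proportions are binomial fractions, their variance depends on their mean, so
a variance-stabilizing transform is applied first:

- **arcsin square root** (default): $y = \arcsin\sqrt{p}$
- **logit**: $y = \log\!\big(p/(1-p)\big)$, with a 0.5 pseudo-count on the
  counts so the transform is defined at empty clusters.

For every cluster $k$ an ordinary least-squares model $y_k = X\beta_k + \varepsilon$
is fit against a shared group-means design $X$ (one indicator column per
condition, optional covariate columns), exactly as gene-wise linear models
are fit in differential expression.  With only a handful of samples the
residual variances $s_k^2$ are noisy, so they are moderated by empirical
Bayes: assuming a scaled inverse-chi-square prior with $d_0$ degrees of
freedom and location $s_0^2$ — estimated from all clusters jointly by
moments on $\log s_k^2$ — the posterior variance is

$$\tilde{s}_k^2 = \frac{d_0 s_0^2 + d_k s_k^2}{d_0 + d_k},$$

and condition effects are tested with the **moderated t** (two conditions)
or **moderated F** (more than two; ANOVA) on $d_0 + d_k$ degrees of freedom,
followed by Benjamini–Hochberg adjustment (significance at adjusted
p < 0.05).

**Unreplicated data.**  When a condition has a single sample, the bootstrap
engine partitions each condition's cells into `n_reps` disjoint
*pseudo-replicates* ("bootstrapping without replacement": every cell is used
exactly once per iteration, so pooled cluster proportions are preserved
exactly).  The full test is repeated 100 times on fresh random partitions;
effects are pooled by Rubin's rule and the per-cluster median of the
adjusted p-values is reported.

A hierarchical benchmark simulator (negative-binomial replicate totals →
beta per-replicate proportions → binomial cluster counts) and a scoring
harness (accuracy, FPR/sensitivity, auROC) are included, so the method's
operating characteristics can be reproduced from nothing.

## Worked example

Simulate a two-condition dataset (7 cell types, 3 truly changed, four
replicates of roughly 5,000 cells each per condition) and test it:

```python
import cellprop as cp

ds = cp.simulate_dataset(cp.make_changed_scenario(4, seed=3))
res = cp.run_analysis(ds.counts)
print(res.table[["prop_cond1", "prop_cond2", "statistic",
                 "p_adjusted", "significant"]].round(4))
```

```
          prop_cond1  prop_cond2  statistic  p_adjusted  significant
cluster
Changed1      0.3074      0.1639    -4.9453      0.0001         True
Changed2      0.0989      0.2129     4.6884      0.0001         True
Changed3      0.0105      0.0128     0.3863      0.9458        False
Stable1       0.0722      0.0683    -0.2478      0.9458        False
Stable2       0.0962      0.1166     0.9228      0.8432        False
Stable3       0.1536      0.1559     0.0683      0.9458        False
Stable4       0.2614      0.2696     0.2138      0.9458        False
```

The two large changed clusters are recovered; `Changed3` holds under 2% of
all cells — below the scale at which proportion shifts are reliably
detectable — and is flagged `low_count` in the full table.  Merging the
replicates (one sample per condition) switches `run_analysis` onto the
bootstrap path automatically (here 8 pseudo-replicates are auto-chosen for
~20,000 cells per condition, 100 iterations):

```python
merged = cp.merge_replicates(ds)
res2 = cp.run_analysis(merged.counts, seed=3)
# res2.metadata["mode"] == "bootstrapped"; Changed1/Changed2 again significant
# with median adjusted p of 0.0023 / 0.0027
```

The same analyses are available from the shell:

```bash
cellprop simulate --scenario changed --n-reps 4 --seed 3 --out cells.tsv --cell-level
cellprop run --input cells.tsv --sample-col sample --cluster-col cluster \
             --cond-col condition --seed 3 --out results.tsv --plot props.png
cellprop benchmark --scenario null --n-sims 100 --seed 0 --out bench.tsv
```

`cellprop run` also reads `.h5ad` files (only the per-cell observation table
is used).

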