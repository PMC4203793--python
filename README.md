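# microdab

Differential-abundance analysis for small-cohort 16S rRNA microbiome
studies, built around a **two-part presence/abundance statistic** for
zero-inflated taxon tables. The package covers the full path from
demultiplexed reads to ranked taxa:

1. **Read QC** — sliding-window quality trimming (window 5, mean
   quality ≥ 20 at both ends), ambiguity (> 1 ambiguous base) and
   length (< 200 nt) filters;
2. **OTU tables** — reads sharing an identical taxonomy-assignment
   string are grouped and counted per sample;
3. **Two-part testing** — per taxon, with a ≥ 50 % prevalence filter
   and Benjamini–Hochberg FDR, plus a Kruskal–Wallis screen across all
   groups;
4. **Effect views** — Manhattan data (−log₁₀ p) and
   Δmedian-abundance / Δproportion-positive quadrant data;
5. **Ordination** — centered log-ratio transform (pseudocount
   1/sample total) and PCA with loading vectors;
6. **Random forest** — 10,000-tree classification of group labels from
   relative abundances, taxa ranked by mean decrease in impurity;
7. **Simulator** — Dirichlet-multinomial community generator with
   explicit zero-inflation and injected group effects, used as ground
   truth for every stage.

It is aimed at studies of the typical mouse-cohort scale: 5–14 animals
per group, roughly a thousand reads per animal, tens of taxa — settings
where abundances are heavily zero-inflated and compositional.

## The two-part statistic

For a taxon with relative abundances `x` (group 1, size n₁) and `y`
(group 2, size n₂):

* **Presence part.** With k₁, k₂ samples positive, p̂ᵢ = kᵢ/nᵢ and
  pooled p̄ = (k₁+k₂)/(n₁+n₂),

      Z_p = (p̂₁ − p̂₂) / √( p̄(1−p̄)(1/n₁ + 1/n₂) ),

  Z_p ≡ 0 when p̄ ∈ {0, 1}.
* **Abundance part.** Z_w is the standardized Wilcoxon rank-sum
  statistic over the *non-zero* values only (normal approximation,
  tie-corrected, no continuity correction).
* **Combination.** When both parts are defined,
  `X² = Z_p² + Z_w² ~ χ²(2)`. When every sample is positive in both
  groups, the rank-sum alone is used on all values (χ²(1)); when one
  group has no positive samples, the presence part alone (χ²(1)).

Taxa are tested only if present in ≥ 50 % of samples of at least one
group, and BH-FDR is applied within each comparison.

## Worked example

```python
import microdab as m

# a synthetic study: 14 control vs 14 treatment animals, 45 taxa,
# ~1,000 reads each, with a fold-30 bloom injected on a 0.5% baseline
table, truth = m.simulate_counts(m.bloom_study_config(seed=7))

results = m.run_comparison(table, "treatment", "control")
for r in results[:3]:
    print(f"{r.taxon.split('/')[-1]:24s} stat={r.statistic:7.3f} "
          f"df={r.df} p={r.p_raw:.2e} p_adj={r.p_adj:.2e}")
```

prints

```
Erysipelotrichaceae      stat= 14.743 df=2 p=6.29e-04 p_adj=1.26e-02
Taxon_14                 stat=  5.971 df=2 p=5.05e-02 p_adj=5.05e-01
Taxon_03                 stat=  3.507 df=2 p=1.73e-01 p_adj=7.66e-01
```

The injected bloom (an *Erysipelotrichaceae*-like lineage that rises
from 0.55 % of the community in controls to 9.4 % under treatment in
this draw) is recovered as the top-ranked taxon, significant after FDR;
the next taxa are noise. The same study ordinated and classified:

```python
pca = m.pca_fit(m.clr_transform(table), 2)
rf = m.rf_importance(table, n_trees=2000, seed=7)
print(rf.taxa[0].split("/")[-1], rf.oob_error)   # Erysipelotrichaceae 0.357
```

A command-line interface mirrors the stages
(`microdab simulate|qc|test|ordinate|rf|all`); `microdab all
--config run.yaml` executes the whole pipeline and writes TSV tables,
figures and a JSON manifest.

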