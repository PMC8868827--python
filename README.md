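# hrcoreg

Analysis toolkit for coordinated expression of *BRCA1/2* and homologous
recombination (HR) genes in ovarian tumors, built around digital counting
assays that tolerate degraded FFPE RNA:

* **NanoString-style normalization** — background adjustment from internal
  negative controls, within-sample positive-control scaling, across-sample
  housekeeping correction, gene exclusion and replicate averaging.
* **Rank-based differential expression** — per-gene two-tailed Welch t-test
  on pooled ranks between tumor and fallopian-tube samples, Bonferroni
  corrected, with pathway classification that merges the Homologous
  Recombination and Fanconi Anemia pathways into one HR group.
* **Heatmap clustering** — per-gene standardization, `1 − Spearman ρ`
  distance, complete-linkage dendrograms for genes and samples.
* **Co-regulation statistic** — for an anchor gene (BRCA1 or BRCA2) and a
  target gene set, the Spearman correlations are pooled through Fisher's
  Z-transformation, `tanh(mean(atanh ρ))`, and compared with random
  same-size subsets of a candidate pool; the empirical p-value is add-one
  smoothed, `P = (n+1)/(m+1)`.
* **NMD rule classifier** — locates the premature termination codon (PTC)
  created by nonsense or frameshift variants (scanning the shifted reading
  frame of the mutant transcript) and predicts nonsense-mediated decay when
  the PTC is >50 nt upstream of the last exon–exon junction, the transcript
  has more than two exons, and the PTC is >200 nt downstream of the start
  codon.
* **ddPCR quantitation** — Poisson occupancy fitting of droplet counts,
  `λ = −ln(negatives/total)`, `c = λ/V_d` copies/µL, with delta-method 95%
  CIs, duplex reference-gene ratios, the 0.05 copies-per-droplet input
  equalization scheme, no-RT contamination checks and cross-platform
  concordance.

A synthetic-data module generates complete panel studies (11 normal + 38
tumor samples, 180 endogenous + 12 housekeeping probes plus controls, a
latent-factor co-regulated HR module), droplet wells and transcript/variant
fixtures, so the entire pipeline runs and is tested without any download.

## Worked example

```python
from hrcoreg import synthetic, normalize, diffexpr, coreg

study = synthetic.simulate_nanostring_study(seed=7)
res = normalize.normalize_pipeline(study.counts, study.samples)

de = diffexpr.differential_expression(res.matrix, res.samples)
print("tested:", len(de), "significant:", int(de.significant.sum()))

cfg = study.truth["config"]
tumors = res.samples.index[res.samples.group == "tumor"]
stat = coreg.coregulation_test(
    res.matrix.values[list(tumors)], "BRCA1",
    targets=[g for g in cfg.hr_module_genes if g != "BRCA1"],
    pool=[g for g in cfg.upregulated_genes if g != "BRCA1"],
    k=12, m=10_000, seed=1,
)
print(stat.pooled, stat.null_mean, stat.p_empirical)
```

prints

```
tested: 180 significant: 40
0.4801883244975865 0.1215891991171152 9.999000099990002e-05
```

meaning: of the 180 genes tested (168 endogenous after the 12-gene TagSet
exclusion, plus 12 housekeeping), 40 pass Bonferroni at α = 0.05 in this
simulated study; the anchored co-regulation statistic of BRCA1 with the
13-gene HR target set is 0.48 versus a random-subset expectation of 0.12,
and none of the 10,000 null draws reaches the observed value, so
P = 1/10,001 ≈ 1.0 × 10⁻⁴ — the anchor is specifically co-expressed with
the HR module, as designed into the generator's shared latent factor.

Every module is also reachable from the command line:

```bash
hrcoreg simulate nanostring --seed 2 --out study/
hrcoreg normalize --counts study/counts.tsv --annotation study/annotation.tsv \
    --samples study/samples.tsv --out normalized.tsv
hrcoreg de --counts study/counts.tsv --annotation study/annotation.tsv \
    --samples study/samples.tsv --out de.csv
hrcoreg ddpcr quant --wells wells.csv --out quant.csv
```

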