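# rvburden

Multi-mask rare-variant burden meta-analysis for case-control traits.

Large sequencing studies of common diseases test each gene by pooling its
rare coding variants into *masks* — combinations of an annotation class
(protein-truncating variants, predicted-damaging missense by one or more
tools, or their unions) and a frequency ceiling on the maximum population
minor allele frequency — and regressing case status on the pooled burden
genotype.  `rvburden` implements that framework end to end for
statisticians and genetic epidemiologists who want a tested, reusable
version of the whole chain:

* **Mask construction** — 20 annotation schemes x 3 nested frequency
  tiers, up to 60 masks per gene, with cumulative minor allele count
  (cMAC) accounting.
* **Per-study burden tests** — Firth-penalized logistic regression
  (exact and fast approximate modes), covariate adjustment, chrX
  sex-stratified testing, count-based result filters.
* **Meta-analysis** — inverse-variance-weighted fixed effects with
  Cochran's Q, plus a genotype-count saddlepoint adjustment that corrects
  the anti-conservative normal tail under case-control imbalance:
  under the null each of a mask's cmac_s carrier alleles falls in a case
  with probability phi_s, so the meta score is a weighted sum of centred
  binomials whose exact tail replaces the normal reference.
* **Gene-level tests** — layered Cauchy (ACAT) combination
  (missense / PTV / PTV+missense layers, then across layers),
  lambda90 calibration diagnostics, and sensitivity re-combinations
  (rare-only, PTV-only, missense-only).
* **GWAS integration** — Fisher exact enrichment grids (conditional-MLE
  odds ratios with exact CIs), Bonferroni subset discovery within
  GWAS-nominated genes, and the log-log power law of |beta| against MAF.
* **Burden heritability** — regression of squared standardised burden
  effects on burden scores gamma_g = sum 2p(1-p), with fixed-gene
  partitioning, genome-wide correction, block-jackknife SEs and
  liability-scale conversion.
* **Synthetic cohorts** — a liability-threshold multi-study simulator
  that reproduces the statistical structure the analysis assumes, so the
  whole pipeline is testable without any data access.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from rvburden import (SimulationConfig, StudySpec, EffectModel,
                      PipelineConfig, run_pipeline, lambda90)

config = SimulationConfig(
    n_genes=60, n_causal_genes=8, variants_per_gene=10.0,
    effect_model=EffectModel(ptv=0.9, damaging_missense=0.6),
    freq_range=(3e-4, 5e-3), prevalence=0.1,
    studies=(StudySpec(n_cases=500, n_referents=4500),
             StudySpec(n_cases=1500, n_referents=1500, case_ascertainment=True)),
    seed=42)

result = run_pipeline(PipelineConfig(simulation=config))
genes = result["gene_results"]
print(f"{len(genes)} gene tests at alpha = {genes.attrs['alpha']:.3g}")
print(genes.loc[genes.significant,
                ["gene", "p_final", "best_mask", "best_or", "best_cmac"]])
```

Output:

```
34 gene tests at alpha = 0.00147
         gene       p_final        best_mask   best_or  best_cmac
3   GENE00008  9.255044e-08  PTV+miss1of4.RL  3.961404        106
5   GENE00010  3.820806e-06      miss1of4.RL  4.119496         83
17  GENE00029  5.488998e-18  PTV+miss1of4.RL  4.628708        218
31  GENE00055  7.369775e-06      miss1of4.RL  2.684307        127
```

Each row is one gene: `p_final` is the layered Cauchy combination of all
of the gene's surviving masks, `best_mask` names the annotation x tier
mask with the smallest (saddlepoint-adjusted) meta-analysis p-value, and
`best_or` its meta-analytic carrier odds ratio.  All four hits are among
the eight simulated causal genes (per-allele liability effect 0.9 for
PTVs, 0.6 for damaging missense), surfacing with carrier ORs of 2.7-4.6
and gene p-values far below the Bonferroni threshold of 0.05/34; the
remaining causal genes fall short of exome-wide significance at this
deliberately small sample size.  The run returns the per-study,
meta-level and sensitivity tables alongside, and writes them as TSV plus
a run manifest when `out_dir` is set.

The same stages are exposed on the command line via the `rvburden`
entry point (`simulate`, `mask`, `test`, `meta`, `cauchy`, `converge`,
`bhr`, and `run`), all driven by a YAML configuration.

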