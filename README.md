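# evmeth

Paired-sample differential DNA methylation analysis on Illumina-style
beta-values, for experiments in which each treated sample has exactly one
matched control and no replication — the situation that arises when, for
example, pooled CD34+ hematopoietic stem/progenitor cells are exposed to
tumor-derived extracellular vesicles and profiled on a methylation array
alongside their untreated control, in a handful of independent experiments.

With one pair per group and donor (subject) variation far exceeding the
treatment effect, FDR-controlled per-probe linear modelling on M-values
finds nothing. `evmeth` implements a rank-based alternative:

1. **npCV** — for every probe, the non-parametric coefficient of variation of
   the treated/control beta pair, MAD/median by default. For a pair
   {β_t, β_c} this reduces to |β_t − β_c| / (β_t + β_c) (the IQR/median
   variant is exactly twice that and rank-equivalent).
2. **Upper-quartile filter** — per group, only probes in the top 25% of the
   npCV distribution are retained (Q3 cut-off, boundary ties kept).
3. **Effect-size filter** — retained probes with |Δβ| = |β_t − β_c| > 0.2
   are called differentially methylated CpGs (dmCpGs), hypo- or
   hyper-methylated by the sign of Δβ (treated − control).

Calls are then projected onto genes via the manifest's UCSC RefGene
annotations — promoter (TSS200, TSS1500, 5′UTR) versus body (1st exon, gene
body, 3′UTR, exon boundaries) — intersected across groups through an exact
Venn partition ("common" genes are members of ≥ 2 groups in the same
region/direction stratum), crossed with a differential-expression table into
methylation/expression concordance classes, and tested for gene-set
over-representation with the hypergeometric upper tail and
Benjamini–Hochberg adjustment.

A synthetic-data module generates EPIC-like paired studies (logit-normal
betas, probe-wise subject shifts, planted effects of exact beta-scale size)
with full ground truth, so every stage is benchmarked against known answers.

## Worked example

```python
from evmeth import PairedMethylationModel, make_manifest, simulate_expression, simulate_study

manifest = make_manifest(n_probes=1000, n_genes=300, seed=7)
beta, design, truth = simulate_study(manifest, seed=8)
results = PairedMethylationModel(beta, design, manifest).fit()
print(results.summary())
```

```text
Paired differential methylation (npCV / Q3 / |dB|) summary

group     probes     q3_cv  retained   dmCpG   hypo  hyper
a           1000    0.0583       250     100     50     50
b           1000    0.0614       250     100     50     50
c           1000    0.0600       250     100     50     50

group a: 95 dmGs (53 hypo, 53 hyper records)
group b: 83 dmGs (51 hypo, 50 hyper records)
group c: 89 dmGs (47 hypo, 58 hyper records)

common dmGs (>= 2 groups): 41 distinct 21 hyper, 23 hypo
```

Each of the three simulated groups carries 50 planted hypo- and 50 planted
hyper-methylated probes of effect size 0.3; the Q3 filter keeps 250 of 1000
probes per group and the Δβ > 0.2 filter recovers exactly the 100 planted
probes in each (sensitivity 1.0, no false calls at these settings). The
dmG lines count distinct genes touched per group; 41 genes recur in ≥ 2
groups within the same stratum, driven by the generator's shared planted
core.

Crossing with a matched expression table classifies each common gene by
concordance:

```python
degs = simulate_expression(truth, flip_fraction=0.1, seed=9)
integrated = results.integrate(degs)
print(integrated.table.head(3).to_string(index=False))
```

```text
     gene region_class meth_direction expr_direction    adj_p concordance_class
GENE00003         body           hypo             up 0.045769      body-hypo/up
GENE00003     promoter          hyper             up 0.045769             other
GENE00003     promoter           hypo             up 0.045769  promoter-hypo/up
```

`body-hypo/up` marks the pattern of interest — gene-body hypo-methylation
with over-expression — while `other` collects combinations without a named
interpretation.

The same pipeline is scriptable end to end:

```sh
evmeth-dm simulate --seed 5 --out sim/
evmeth-dm run --config run.yaml --out results/
```

where `run.yaml` names the beta matrix, manifest, design JSON and optional
deG/GMT inputs; `results/run_summary.json` echoes every count, threshold
and input digest.

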