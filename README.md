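# zonepipe

Hepatocyte gene expression is zonated along the porto-central axis of the
liver lobule: ammonia detoxification via glutamine synthetase, xenobiotic
metabolism and other CYP-driven programs sit pericentrally (near the central
vein), while urea cycle, gluconeogenesis and related programs sit
periportally. Chronic fibrosis disturbs this organisation: pericentral
programs collapse while periportal programs extend across the lobule — a
shift we call **periportalization**. `zonepipe` is a tested, reusable
pipeline for quantifying that shift from transcriptomic data, aimed at
computational biologists studying liver damage models (e.g. chronic CCl4
intoxication with olive-oil solvent controls).

The pipeline has four analysis stages, each usable on its own:

1. **Zonation gene sets** (`zonepipe.zonation`). From a single-cell UMI
   matrix whose cells carry probabilistic membership over L ordered lobule
   layers (layer 1 most pericentral, layer L most periportal): drop genes
   expressed in < 15 cells, normalise by median-of-ratios size factors,
   assign each cell to its maximum-probability layer, and screen each gene
   for a monotone trend across layers with the **Jonckheere–Terpstra test**

   U = Σ_{a<b} [ #{x_a < x_b} + ½·#{x_a = x_b} ],

   using the exact permutation null (convolution of Mann–Whitney nulls) for
   small tie-free samples and the tie-corrected normal approximation
   otherwise. Genes with BH-FDR ≤ 0.001 are called periportal (increasing)
   or pericentral (decreasing). Cross-study **consensus sets** keep genes
   called in the same direction by ≥ 2 studies, after gene-symbol alias
   harmonisation.

2. **Differential expression** (`zonepipe.diffexp`). Per-month ccl4-vs-oil
   contrasts on TMM-normalised log2-CPM with **empirical-Bayes moderated
   t-statistics**: per-gene variances are shrunk toward a
   scaled-inverse-χ² prior fitted by moment matching on log variances,
   t̃_g = logFC_g / (u·s̃_g), s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d),
   with d₀ + d degrees of freedom. The missing month-6 oil group is imputed
   as the mean of the month-2 and month-12 oil means (contributing no
   residual df). DE calls use |logFC| ≥ 1.5 and FDR ≤ 0.05.

3. **Enrichment** (`zonepipe.enrichment`). Genes are ranked by moderated t;
   the two consensus sets are scored by **weighted-KS GSEA** (ES, NES,
   gene-set permutation p, leading edge). Supporting tools: one-sided
   Fisher over-representation against a 20,000-gene background,
   footprint-based pathway activity (weighted sums of responsive-gene
   statistics, z-scored against a permutation null) and rank-based regulon
   activity NES for transcription factors.

4. **Synthetic data** (`zonepipe.synthetic`). Negative-binomial generators
   (var = μ + φμ², log-normal depth factors) that plant the exact structure
   above: 1415 cells over 9 layers with Dirichlet layer memberships and
   geometric monotone profiles, and a 6-replicate CCl4/oil time course
   (months 0/2/6/12) with pericentral downregulation growing over time and
   transient periportal upregulation — plus ground-truth labels, so every
   stage is testable without downloads.

A periportalized signature then shows as pericentral NES < 0 (enrichment
among downregulated genes) and periportal NES > 0.

## Worked example

```python
from zonepipe import (SimConfig, simulate_layered_cells, simulate_bulk_timecourse,
                      filter_low_expression, normalize_cells, assign_layers,
                      call_zonation, run_diffexp, rank_signature, GeneSet,
                      periportalization_report, select_de)

cfg = SimConfig(n_genes=1500, seed=1)   # defaults: 1415 cells, 9 layers, 5%+5% zonated
cells, truth = simulate_layered_cells(cfg)
kept = filter_low_expression(cells, min_cells=15)
expr = normalize_cells(kept)
layers = assign_layers(kept.layer_probs)
calls = call_zonation(expr, kept.gene_ids, layers, fdr_threshold=0.001)
print(calls["direction"].value_counts().to_dict())

bulk, _ = simulate_bulk_timecourse(cfg)
tables, prior = run_diffexp(bulk)
for m in (2, 6, 12):
    up, down = select_de(tables[m])
    print(f"month {m:>2}: {len(up)} up / {len(down)} down")

pc = GeneSet("pericentral", frozenset(calls.index[calls.direction == "pericentral"]), "pericentral")
pp = GeneSet("periportal", frozenset(calls.index[calls.direction == "periportal"]), "periportal")
sigs = {m: rank_signature(tables[m]) for m in (2, 6, 12)}
report = periportalization_report(sigs, pc, pp, n_perm=10_000, seed=1)
print(report[["month", "set", "es", "nes", "p"]])
```

Output:

```
{'none': 1353, 'pericentral': 74, 'periportal': 73}
month  2: 71 up / 42 down
month  6: 38 up / 72 down
month 12: 0 up / 75 down
 month         set      es    nes         p
     2 pericentral -0.9829 -3.344 0.0002755
     2  periportal  0.9986  3.115 0.0001568
     6 pericentral -0.9972 -2.993 0.0001588
     6  periportal  0.9986  3.238 0.0002655
    12 pericentral -0.9993 -2.488 0.0001064
    12  periportal  0.3131   1.27    0.0939
```

Reading the report: the trend screen recovers the planted zonated genes
(74 + 73 of 150 planted; the rest fall below the expression filter or the
FDR bar). In the fibrosis time course the pericentral set is strongly
enriched among downregulated genes at every month (NES < 0, p < 3e-4) and
grows in magnitude as the planted downregulation deepens; the periportal
set is enriched among upregulated genes at months 2 and 6 only — by month
12 its planted upregulation has subsided, and the enrichment is no longer
significant (p = 0.094). That asymmetric, time-resolved pattern is the
periportalization readout.

The same stages run from the shell:

```sh
zonepipe run --config config.yaml --seed 1          # simulate → … → report
zonepipe simulate sc --out simdir --seed 1
zonepipe zonation call --counts simdir/sc_counts.tsv --layers simdir/layer_probs.tsv \
    --min-cells 15 --fdr 0.001 --out calls.tsv
zonepipe de --counts bulk.tsv --design design.tsv --lfc 1.5 --fdr 0.05 --out dedir
zonepipe enrich report --signature 2 dedir/contrast_m2.tsv ... --sets consensus.gmt \
    --nperm 100000 --seed 1 --out report.tsv
```

The YAML config accepts every `RunConfig` field (`out_dir`, `seed`, `sim`
with any `SimConfig` field, the thresholds `min_cells`, `zonation_fdr`,
`lfc_min`/`fdr_max`, `overlap_lfc_min`/`overlap_fdr_max`, `background_n`,
`n_perm`, `min_studies`). Exit codes: 0 ok, 2 config error, 3 data error,
4 stage failure.

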