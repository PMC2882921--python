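# mgfscreen

Compartment classification of myeloma growth-factor (MGF) gene expression in
the multiple-myeloma bone marrow, from Affymetrix-style microarray data.

Multiple myeloma cells depend on growth factors supplied partly by themselves
and largely by their bone-marrow microenvironment — stromal cells,
osteoclasts, T cells, monocytes and neutrophils.  Given a probe-set × sample
signal matrix, the matching Present/Marginal/Absent detection-call matrix and
per-sample population labels, `mgfscreen` determines, for each growth-factor
gene, *which cell compartment expresses it*: the tumor cells, the putative
stromal/osteoclast niche, the wider marrow environment, several compartments
at once, or none.  It also follows MGF and MGF-receptor expression across
normal plasma-cell differentiation (memory B cell → plasmablast → bone-marrow
plasma cell → tumor cell) and summarises receptor expression per patient.

The package is written for transcriptomics analysts who have MAS5/GCOS-style
condensed data (signals + detection calls); CEL-file processing is out of
scope.

## Method

For every pair of populations the contrast engine computes, per gene *g*:

* a Student (pooled-variance) t-test on log2 signal,
  t_g = (x̄_A − x̄_B) / s_p √(1/n_A + 1/n_B),
* Benjamini–Hochberg adjustment of the p-values across the genes of the
  contrast, with significance at p_adj ≤ 0.05,
* the fold change FC_g = mean_A / mean_B on linear-scale signal, retained
  when FC ≥ 2,
* an exclusion flag: a gene "overexpressed" in a population where it has
  100% absent calls is not biologically relevant.

Samples are first scaled to a mean intensity of 100 and floored at 1; when a
gene has several probe sets, the one with the highest present-call percentage
(highest variance at ties) represents it.  Whole-bone-marrow samples, which
mix tumor and environment cells, never enter a supervised contrast.

A deterministic rule cascade then assigns each gene exactly one label:
`NOT_EXPRESSED` (&lt; 5% presence everywhere, none in the niche populations),
`MYELOMA` (tumor cells beat all five other populations), `NICHE_BMSC` /
`NICHE_OC` (stromal cells / osteoclasts beat tumor cells and the marrow
subpopulations), `ENVIRONMENT` (a marrow subpopulation beats tumor and niche),
`MYELOMA_RESCUED` (present only in some tumor samples, absent everywhere
else), and `SHARED` as the residual.

Because the original patient-level data live in controlled repositories, the
package ships a synthetic-data generator that reproduces the study design
(sample sizes, signal scale, detection-call behaviour) with planted ground
truth, so the whole pipeline is testable offline; the published gene catalogs
and the receptor summary table are included as transcriptions.

## Worked example

```python
import mgfscreen as m

# a study-shaped dataset with planted compartment truth
ds, truth = m.generate_dataset(m.SyntheticConfig(seed=1))

results = m.CompartmentModel(ds, catalog=truth.catalog).fit()
print(results.summary())

report = m.recovery_report(truth, results.assignments)
print("core recall", round(report.macro_recall(m.CORE_RECOVERY_CATEGORIES), 3))
```

prints (abridged):

```
Growth-factor compartment classification
==============================================
Genes classified: 51
Samples per population: MB=6, PPC=7, BMPC=7, MMC=131, CD3=5, CD14=5, PMN=5, BMSC=5, OC=7
Thresholds: adj. p <= 0.05, fold change >= 2.0
----------------------------------------------
MYELOMA             3
MYELOMA_RESCUED     1
NICHE_BMSC         11
NICHE_OC            3
ENVIRONMENT         8
SHARED             18
NOT_EXPRESSED       7
----------------------------------------------
FGF7         MYELOMA          MMC
NRG3         MYELOMA          MMC
WNT10A       MYELOMA          MMC
BDNF         NICHE_BMSC       BMSC
...
core recall 0.956
```

The three planted tumor-compartment genes, all eleven stromal-niche genes,
the three osteoclast genes and all eight environment genes are recovered; a
few genes planted as silent or rescue-class drift into `SHARED` because
detection-call noise (2% spurious present calls in silent populations)
breaks their strict zero-presence rules — the per-category recall in the
report quantifies exactly this.

The same pipeline runs from the shell:

```bash
mgfscreen simulate --out-dir sim --seed 1
mgfscreen classify --signal sim/signal.tsv --calls sim/calls.tsv \
    --samples sim/samples.tsv --catalog sim/catalog.csv --out-dir out
mgfscreen differentiation --signal sim/signal.tsv --calls sim/calls.tsv \
    --samples sim/samples.tsv --catalog sim/catalog.csv --out-dir out
```

`classify` writes `category_table.tsv` (gene, category, winning population,
rule, worst adjusted p and fold change among the supporting contrasts),
`venn_counts.json` and `contrasts.tsv`.  The contrast table columns are, in
order: `gene_symbol, group_a, group_b, n_a, n_b, mean_a, mean_b, median_a,
median_b, fold_change, t_statistic, p_raw, p_adj, present_frac_a,
present_frac_b, all_absent_in_winner, significant_over_b`.

For real data, the packaged catalog of 51 interrogable growth factors and 36
interrogable receptors is the default:

```python
import mgfscreen as m
catalog = m.mgf_catalog()
m.count_interrogable(catalog, "FGF", "LIGAND")    # (13, 22)
m.count_interrogable(catalog, role="RECEPTOR")    # (36, 48)
```

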