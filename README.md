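# ssmprone

Which genes are disproportionately broken by splicing mutations?

Canonical splice-site mutations (SSM) — disease alleles falling in the
donor window (−3 exonic to +6 intronic) or the acceptor window (−20
intronic to +3 exonic) and annotated as splicing mutations — make up about
13.4% of reported hereditary disease alleles, but the rate varies sharply
from gene to gene, and exonic alleles that silently disrupt splicing (ESM)
add an unreported layer on top. `ssmprone` is a toolkit for geneticists who
want to quantify that variation:

* **MaPSy-style quantification** — splicing efficiency
  `log2((spl_i/Σspl)/(inp_i/Σinp))` per reporter species, wild-type/mutant
  allelic ratios `log2((mi_e/mi_i)/(mj_e/mj_i))` per spliceosomal fraction,
  panel-level ESM calls (≥1.5-fold allelic change in both the in vivo and in
  vitro assay plus a count test at Benjamini–Hochberg FDR 0.05), and
  spliceosomal-complex blockage profiles (E → A → B/C → mRNA/lariat).
* **Weighted-random-sampling envelopes** — the core statistic. For each gene,
  SSM\* ~ Binomial(n_muts, w) is simulated 1,000 times with
  `w = totalspl/totalmuts` (global mode) or
  `w_gene = (totalspl/totalmuts)·(totalCDS/totalSS)·(geneSS/geneCDS)`
  (normalized mode, removing the "more introns = bigger target" effect);
  genes outside the simulated 99.9% envelope are **Upper** (SSM-prone) or
  **Lower**. The same machinery flags exons enriched for ESMs.
* **Sequence scores** — ΔESR (wild-type minus mutant summed
  exonic-splicing-regulatory hexamer score over the windows covering a
  variant), splice-site position-weight-matrix models, and the variant
  Δ score (reference minus alternate; Δ > 5 abolishes a site, Δ < −2
  strengthens it).
* **Gene classification** — random-forest and logistic-regression models
  over a 19-feature gene table (intron count, exon length and structure,
  haploinsufficiency, motif densities, splice-site strengths, SNP densities,
  conservation, …), with permutation variable importance and genome-wide
  prediction of SSM-prone genes at a probability threshold of 0.6.
* **Selection statistics** — rare splice-site variant density per splice
  site, MAF-stratified Δ-score depletion (rare < 0.01%, common > 1%), exact
  set-overlap tests, permutation enrichment, and rank tests.
* **Synthetic data** — every input (catalog, gene models, count tables,
  feature tables, population variants) can be generated with known ground
  truth, so the full pipeline runs self-contained and every stage is
  scored against the planted signal.

## Worked example

```python
from ssmprone import SpliceEnrichmentModel, exon_esm_envelope, tally_genes
from ssmprone.datasets import mlh1_exon_tallies
from ssmprone.synth import gen_catalog

# a synthetic disease-mutation catalog: 500 genes, 5% of them SSM-prone
# (four-fold elevated splice-site mutation rate)
sim = gen_catalog(n_genes=500, enriched_fraction=0.05, multiplier=4.0, seed=7)
tallies, weights = tally_genes(sim.records, sim.models)
res = SpliceEnrichmentModel(tallies, weights).fit(n_reps=1000, ci_level=0.999, seed=7)
print(res.summary())
```

```
Splice-site mutation enrichment envelope
============================================
mode:          global
genes:         500
global weight: 0.1482 (1484/10015)
replicates:    1000   envelope: 99.9%
Upper:         12
Expected:      488
Lower:         0
```

The catalog-wide sampling weight is the pooled SSM fraction (0.148 here —
slightly above the 0.134 null rate because the enriched genes contaminate
the pool). Twelve genes exceed their simulated 99.9% envelope; in this run
all twelve are genes the generator actually planted as SSM-prone
(`sim.truth` carries the per-gene multipliers). `res.plot()` draws the
SSM-versus-total-mutations scatter coloured by category.

The same envelope applied to the published per-exon counts of the MLH1
reporter panel (36 exonic disease mutations over five exons, 10% background
disruption rate):

```python
print(exon_esm_envelope(mlh1_exon_tallies(), weight=0.10, n_reps=50_000, seed=0))
```

```
  entity_id  n  observed  lower  upper    p_emp category
 MLH1_exon4  8         0      0      4 0.860143 Expected
 MLH1_exon5  8         0      0      4 0.853063 Expected
 MLH1_exon7  7         0      0      4 0.957261 Expected
 MLH1_exon8  6         6      0      4 0.000040    Upper
MLH1_exon15  7         5      0      4 0.000440    Upper
```

Exactly the two exons in which the assay found splicing disruption (6/6 and
5/7 disruptive mutations) are flagged as ESM-enriched; the three clean exons
stay inside the envelope.

A thin CLI mirrors the main stages:

```bash
ssm-prone simulate --n-genes 500 --seed 7 --out-prefix sim
ssm-prone envelope --catalog sim.catalog.tsv --genes sim.genes.bed --seed 7 --out env.tsv
ssm-prone mapsy-quant --counts counts.tsv --out calls.tsv
```

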