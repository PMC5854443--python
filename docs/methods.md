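# Methods

## The model

The package treats a disease-mutation catalog as a collection of per-gene
draws: gene *g* carries `n_muts(g)` reported single-nucleotide disease
mutations, of which `n_ssm(g)` are canonical splice-site mutations (SSM). A
mutation is an SSM only when **both** conditions hold: it lies inside a
canonical splice-site window — donor −3 (exonic) to +6 (intronic), acceptor
−20 (intronic) to +3 (exonic), offsets counted in transcript orientation
with no position zero — and the catalog labels it as a splicing mutation. A
window position mislabelled as missense, or an exonic splicing-labelled
allele, is not an SSM.

Under the null, every mutation in every gene has the same probability of
being an SSM:

    w = totalspl / totalmuts                                    (global)

the catalog-wide SSM fraction (13.4% in large hereditary-disease catalogs).
The alternative of interest is a gene-specific excess. The test statistic is
the observed `n_ssm(g)` against `n_reps` Monte-Carlo draws of
Binomial(`n_muts(g)`, w); a gene strictly above the simulated 99.9% envelope
is *Upper* (SSM-prone), strictly below is *Lower*, otherwise *Expected*.

Genes with many introns present a larger splice-site target, so a second,
*normalized* null rescales the weight by splice-site density:

    w_gene = (totalspl/totalmuts) · (totalCDS/totalSS) · (geneSS/geneCDS)

where `geneSS = 2 × introns` and `geneCDS` is the coding length. The middle
factor makes the catalog-average gene keep weight w; weights above 1
(intron-dense, short-CDS genes — the formula permits them) are clipped to 1
with a warning. When every gene has the catalog-average splice-site density
the two modes coincide exactly (same seed, same draws; verified by test).

The identical machinery applies per exon to assayed exonic splicing
mutations (ESM), with n = mutations tested in the exon and weight
`totalESM/totalmutstested` (default 0.10, the background rate at which
assayed exonic disease alleles disrupt splicing).

## Numerical choices

* **Envelope bounds** are symmetric tail order statistics: with
  `q = (1 − ci_level)/2`, the `ceil(q · n_reps)`-th draw from either end of
  the sorted replicates. The symmetric upper rank (rather than
  `ceil((1−q)·n_reps)`) is used because the latter is biased one rank low at
  the top tail; with the symmetric convention the Monte-Carlo bounds agree
  with exact binomial quantiles to within one count across a grid of
  realistic per-gene mutation counts (n ≤ 100) at 10,000 replicates. For
  per-gene counts far above that range the binomial CDF near the 0.05% tails
  becomes finer than the Monte-Carlo resolution and occasional two-count
  excursions are expected; they do not change categories except exactly at
  the boundary.
* **Categories use strict inequalities** ("falling outside the simulated
  values"): a boundary tie stays Expected.
* **Empirical p** is the two-sided add-one estimate
  `min(1, 2·min(p_up, p_dn))` with `p_up = (1 + #{SSM* ≥ obs})/(1 + n_reps)`.
  The envelope criterion, not the p-value, defines the category; both are
  reported because the published convention pairs a 99.9% interval with a
  p < 0.01 statement, which are not the same threshold. Both are exposed in
  the configuration (`ci_level`, default 0.999).
* **Per-entity RNG substreams** are keyed by a CRC32 hash of the entity id
  together with the master seed, so results are invariant to catalog order
  and adding entities does not perturb existing draws.
* **Genes with zero mutations** are Expected by fiat; intronless genes are
  excluded from tallies (they have no splice sites).
* **Micro-exons/introns**: a position inside both a donor and an acceptor
  window takes the nearer boundary; an exact distance tie goes to the donor
  window.
* **Pseudocount 0.5** is added to every raw read count before any log ratio,
  so zero counts never produce infinities.

## Reporter-assay quantification

Splicing efficiency of species *i* in a pooled assay is
`log2((spl_i/Σspl)/(inp_i/Σinp))`; it is invariant to global rescaling of
either pool. Allelic ratios per spliceosomal fraction are
`log2((mi_e/mi_i)/(mj_e/mj_i))`, with the major allele fixed per pair from
the released-mRNA fraction (the allele that splices more efficiently). An
ESM call requires, in *both* the in vivo and the in vitro assay, an absolute
allelic log2 ratio of at least log2(1.5) **and** a count-based
two-proportion test significant at Benjamini–Hochberg FDR 0.05 across the
panel. The published analyses state only "significantly altered splicing";
the 1.5-fold + count-test rule reconstructs the methodology of the
underlying assay literature and both knobs are configurable
(`fold_threshold`, `esm_fdr`). Complex blockage converts the per-fraction
allelic ratio to percent mutant retention (wild type = 100%); a stage is
blocked when the mutant accumulates there (retention ≥ 120%) while some
later fraction is depleted (≤ 80%), and the primary block is the flagged
stage with maximal retention. The 120/80 thresholds are package defaults;
the published figures do not state a numeric rule.

## Sequence scores

ΔESR is the wild-type-minus-mutant sum of hexamer scores over the at most
six windows (step 1 nt, truncated at exon ends) overlapping a substitution;
windows away from the variant cancel, so this equals the full-sequence score
difference (property-tested against a full-rescan oracle). Splice-site
strength uses per-position log2-odds PWMs,
`log2(((count + pc)/(N + 4·pc))/background)` with pseudocount 0.5 and
uniform background by default — a transparent stand-in for maximum-entropy
splice-site models behind the same interface; the Δ analyses depend only on
score *differences*. The variant Δ is score(ref site) − score(alt site):
positive weakens the site (Δ > 5 is treated as site-abolishing), negative
strengthens it (Δ < −2 is the strengthening class).

RNA secondary structure enters only through a pluggable `fold_backend`
callable (sequence → free-energy-like scalar). The default is a dinucleotide
stacking heuristic (−0.5 per G/C, −0.1 per A/T, averaged per step) that
captures the first-order GC trend; an `rnafold_backend` shelling out to the
RNAfold binary is provided for hosts that have it, and tests inject fixed
scores. Splice-site ΔG folds the 70 nt on each side of the boundary as one
140-nt window, averaged per gene; the published description ("70 nucleotides
up- and down-stream") does not specify the exact windowing.

## Classification

The classifiers separate Upper from Expected genes on 19 features. Protocol:
one stratified 2/3 train / 1/3 holdout split per seed (replicated over seeds
for mean ± SD), random downsampling of the majority class to the minority
count in the training portion, random forest with 500 trees and √p features
per split (the conventional defaults) or an unpenalised additive-logit
regression on standardised features. Variable importance is the mean
decrease in holdout accuracy under single-feature permutation; held-out data
play the role of the out-of-bag sample in the classical forest formulation.
The sign attached to each feature is the sign of the difference in
class-conditional means (the ensemble itself is direction-free). Genome-wide
prediction calls a gene SSM-prone when its probability exceeds 0.6
(threshold only; no upper cap).

Because training is balanced by downsampling, predicted probabilities are
calibrated to a ~50% prevalence; at realistic low prevalence the 0.6
threshold trades precision for recall accordingly.

## What the synthetic generators emulate — and what they do not

* `gen_catalog`: per-gene mutation counts follow 1 + NegBin(mean 20,
  shape 2) — a long-tailed stand-in; the true per-gene count law of curated
  catalogs is unpublished. Null genes draw SSM counts at the global 13.4%
  weight; SSM-prone genes multiply that weight (clipped at 1). SSM are
  placed uniformly within windows and labelled splicing; the remaining
  mutations split missense:nonsense 3:1 at uniform exonic positions.
* `gen_mapsy_counts`: gamma-Poisson input counts (shape 10) around the
  target depth (5,000 by default); ESM pairs (10% by default) impose a
  planted log2 effect, drawn N(−2, 0.5), on the mutant's spliced share.
* `gen_feature_table`: Gaussian features with class-shifted means in the
  observed directions (Upper genes: 2.5-fold more introns — planted as the
  single largest effect — higher haploinsufficiency, shorter and more
  structured exons, less conserved population variants); intron counts are
  1 + NegBin so the class-mean fold is exact. `effect_profile=0` gives
  exchangeable features.
* `gen_population_variants`: splice-window variants with N(0, 3) Δ scores
  and log10-uniform MAFs on [1e-6, 0.3]; site-abolishing alleles (Δ > 5)
  landing in the common stratum are rejected with probability 1 − 1/s, so
  the measured rare:common depletion factor of the loss bin recovers s
  (up to a small second-order term from the rejected mass).

None of the generators simulate nucleotide sequence evolution, linkage,
exon-specific mutational spectra, ascertainment bias of disease catalogs, or
correlated feature noise. Passing tests therefore demonstrate the
correctness and calibration of the *statistics* under their stated sampling
models, not the real-data effect sizes: headline real-data results (the 86
SSM-prone catalog genes, the 499 predicted genes, AUC 0.839) depend on
proprietary or external resources and are out of reach of a self-contained
run. The per-variant MLH1 reporter panel is likewise not redistributable;
the two tests that check its group ΔESR means and ESM count run only when a
local copy is supplied, and fail otherwise rather than substituting
fabricated data.

## Problem sizes used in the shipped checks

Null-catalog calibration uses 2,000 genes × 1,000 replicates averaged over
10 seeds; power checks use 1,000 genes with 5% SSM-prone at multiplier 4
(a minority, as in real catalogs — a large enriched fraction would
contaminate the pooled weight and shrink power); envelope-versus-exact
comparisons use a (n ≤ 100) × (w ≤ 0.5) grid at 10,000 replicates; selection
recovery uses 3 × 20,000 variants; classifier checks use 480-gene tables
with 500-tree forests (unit tests use 150 trees where forest size is not the
property under test).

## Known limitations

* One canonical transcript per gene; no isoform resolution, no liftover.
* The PWM stand-in ignores positional dependencies that maximum-entropy
  models capture; absolute site scores are not comparable to MaxEnt scores,
  only Δ-based analyses are.
* The ESM significance rule is a reconstruction; with very deep count tables
  the count test detects fold changes smaller than biological interest — the
  1.5-fold gate is the effective filter.
* The default fold backend is a heuristic, not thermodynamics; use the
  RNAfold backend (or any callable) for real free energies.
* The envelope applies no multiple-testing correction across genes, by
  design: the published procedure reports per-gene envelope exceedance.
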