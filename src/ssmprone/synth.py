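"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the enrichment analysis
assumes, so the whole pipeline runs end-to-end without any external mutation
catalog, assay or population resource:

* a disease-mutation catalog in which, for null genes, the per-gene count of
  canonical splice-site mutations (SSM) is binomial at the global 13.4% rate,
  while a minority of "SSM-prone" genes carry an elevated rate;
* pooled splicing-reporter count tables with a 10% background rate of exonic
  splicing mutations (ESM) and planted log2 allelic effects;
* gene-level feature tables in which SSM-prone genes differ in intron count
  (2.5-fold), haploinsufficiency, exon length/structure and population-variant
  conservation;
* MAF-annotated splice-region population variants in which site-weakening
  alleles are purged from the common stratum.

Every generator is bit-reproducible under a fixed seed; per-entity RNG
substreams are keyed by a stable hash of the entity id so adding entities
does not perturb existing draws. Each generator returns a truth table
sufficient to score the downstream stage that consumes its output.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import GeneModel, MutationRecord, ACCEPTOR_WINDOW, DONOR_WINDOW

log = logging.getLogger("ssmprone")

_BASES = np.array(list("ACGT"))


def entity_rng(seed: int, entity_id: str) -> np.random.Generator:
    """Deterministic per-entity RNG substream (stable under reordering)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(entity_id.encode())])
    )


def _shifted_negbin(rng: np.random.Generator, size: int,
                    mean: float = 20.0, k: float = 2.0) -> np.ndarray:
    """Default per-gene mutation-count law: 1 + NB(mean, shape k).

    A long-tailed stand-in for the per-gene disease-mutation counts of a
    curated catalog, whose true distribution is not published.
    """
    p = k / (k + mean)
    return 1 + rng.negative_binomial(k, p, size=size)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def gen_gene_models(n_genes: int, seed: int = 0, mean_exons: float = 9.0,
                    min_exon_len: int = 30, min_intron_len: int = 80) -> dict[str, GeneModel]:
    """Random multi-exon gene models on one synthetic chromosome.

    Exon counts are 2 + Poisson, exon/intron lengths log-normal with floors
    wide enough that canonical splice-site windows never collide.
    """
    models: dict[str, GeneModel] = {}
    cursor = 1000
    for i in range(n_genes):
        gid = f"G{i:05d}"
        rng = entity_rng(seed, gid)
        n_exons = 2 + int(rng.poisson(max(mean_exons - 2, 0.0)))
        exon_lens = min_exon_len + np.rint(rng.lognormal(np.log(90), 0.5, n_exons)).astype(int)
        intron_lens = min_intron_len + np.rint(
            rng.lognormal(np.log(700), 0.7, n_exons - 1)).astype(int)
        exons = []
        pos = cursor
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        models[gid] = GeneModel(gene_id=gid, chrom="chrS", strand=strand, exons=tuple(exons))
        cursor = pos + 5000
    return models


# ---------------------------------------------------------------------------
# Mutation catalog
# ---------------------------------------------------------------------------

@dataclass
class CatalogSim:
    """A synthetic mutation catalog together with its generating truth."""

    records: list[MutationRecord]
    models: dict[str, GeneModel]
    truth: pd.DataFrame  # gene_id, multiplier, p_ssm, n_muts, n_ssm


def gen_catalog(n_genes: int = 2000,
                mut_count_law: Callable[[np.random.Generator, int], np.ndarray] | None = None,
                enriched_fraction: float = 0.0,
                multiplier: float = 4.0,
                seed: int = 0,
                config: PipelineConfig | None = None,
                models: Mapping[str, GeneModel] | None = None) -> CatalogSim:
    """Simulate a disease-mutation catalog over synthetic gene models.

    For null genes the SSM count given ``n_mut`` mutations is
    Binomial(n_mut, global_ssm_weight); for the ``enriched_fraction`` of
    SSM-prone genes the success probability is multiplied by ``multiplier``
    (clipped to 1 with a warning). Non-SSM mutations split missense:nonsense
    roughly 3:1 and are placed at uniform exonic positions; SSM are placed at
    uniform positions inside canonical donor/acceptor windows and labelled
    as splicing mutations.
    """
    if not (0.0 <= enriched_fraction <= 1.0):
        raise ValueError("enriched_fraction must be in [0, 1]")
    cfg = config or PipelineConfig(seed=seed)
    w0 = cfg.global_ssm_weight
    if models is None:
        models = gen_gene_models(n_genes, seed=seed)
    gene_ids = sorted(models)
    law = mut_count_law or _shifted_negbin

    head_rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xC_A_7]))
    n_enriched = int(round(enriched_fraction * len(gene_ids)))
    enriched = set(head_rng.choice(gene_ids, size=n_enriched, replace=False)) if n_enriched else set()

    records: list[MutationRecord] = []
    truth_rows = []
    clipped = 0
    for gid in gene_ids:
        g = models[gid]
        rng = entity_rng(seed, gid + ":cat")
        n_mut = int(law(rng, 1)[0])
        mult = multiplier if gid in enriched else 1.0
        p = w0 * mult
        if p > 1.0:
            p, clipped = 1.0, clipped + 1
        n_ssm = int(rng.binomial(n_mut, p))
        records.extend(_place_ssm(g, n_ssm, rng))
        records.extend(_place_coding(g, n_mut - n_ssm, rng))
        truth_rows.append((gid, mult, p, n_mut, n_ssm))
    if clipped:
        log.warning("SSM probability clipped to 1 for %d genes (multiplier too large)", clipped)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "multiplier", "p_ssm", "n_muts", "n_ssm"])
    return CatalogSim(records=records, models=dict(models), truth=truth)


def _rand_substitution(rng: np.random.Generator) -> tuple[str, str]:
    i = rng.integers(4)
    j = (i + 1 + rng.integers(3)) % 4
    return str(_BASES[i]), str(_BASES[j])


def _place_ssm(g: GeneModel, n: int, rng: np.random.Generator) -> list[MutationRecord]:
    out = []
    sites = g.splice_sites()
    for _ in range(n):
        kind, intron = sites[rng.integers(len(sites))]
        lo, hi = DONOR_WINDOW if kind == "5ss" else ACCEPTOR_WINDOW
        offsets = [o for o in range(lo, hi + 1) if o != 0]
        off = offsets[rng.integers(len(offsets))]
        pos = g.site_position(kind, intron, off)
        ref, alt = _rand_substitution(rng)
        out.append(MutationRecord(g.gene_id, g.chrom, pos, ref, alt, "splicing"))
    return out


def _place_coding(g: GeneModel, n: int, rng: np.random.Generator) -> list[MutationRecord]:
    out = []
    exon_lens = np.array([e - s for s, e in g.exons])
    cum = np.cumsum(exon_lens)
    total = int(cum[-1])
    for _ in range(n):
        k = int(rng.integers(total))
        ei = int(np.searchsorted(cum, k, side="right"))
        pos = g.exons[ei][0] + (k - (int(cum[ei - 1]) if ei else 0))
        ref, alt = _rand_substitution(rng)
        dm = "missense" if rng.random() < 0.75 else "nonsense"
        out.append(MutationRecord(g.gene_id, g.chrom, pos, ref, alt, dm))
    return out


# ---------------------------------------------------------------------------
# MaPSy-like count tables
# ---------------------------------------------------------------------------

@dataclass
class MapsySim:
    """Synthetic pooled splicing-reporter counts plus per-pair truth."""

    counts: pd.DataFrame  # pair_id, allele, assay, inp, spl
    truth: pd.DataFrame   # pair_id, is_esm, effect (log2 allelic imbalance)


def gen_mapsy_counts(n_pairs: int = 5000, depth: float = 5000.0,
                     esm_fraction: float = 0.10,
                     effect_law: Callable[[np.random.Generator], float] | None = None,
                     dispersion: float = 10.0, seed: int = 0,
                     assays: Sequence[str] = ("in_vivo", "in_vitro")) -> MapsySim:
    """Simulate wild-type/mutant input and spliced read counts.

    Input counts are gamma-Poisson (shape ``dispersion``) around ``depth``.
    Spliced counts follow each species' splicing rate; for non-ESM pairs the
    mutant splices like the wild type, while ESM pairs impose a planted log2
    effect on the mutant's spliced share. The default effect law is
    N(-2, 0.5) on the log2 scale (clearly disruptive alleles).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0.0 <= esm_fraction <= 1.0):
        raise ValueError("esm_fraction must be in [0, 1]")
    draw_effect = effect_law or (lambda rng: rng.normal(-2.0, 0.5))

    rows, truth_rows = [], []
    for i in range(n_pairs):
        pid = f"P{i:05d}"
        rng = entity_rng(seed, pid)
        is_esm = rng.random() < esm_fraction
        effect = float(draw_effect(rng)) if is_esm else 0.0
        s_wt = float(np.clip(rng.lognormal(np.log(0.5), 0.3), 0.05, 0.95))
        s_mt = min(s_wt * 2.0 ** effect, 1.0)
        for assay in assays:
            for allele, s in (("wt", s_wt), ("mt", s_mt)):
                lam_inp = rng.gamma(dispersion, depth / dispersion)
                inp = int(rng.poisson(lam_inp))
                spl = int(rng.poisson(lam_inp * s))
                rows.append((pid, allele, assay, inp, spl))
        truth_rows.append((pid, is_esm, effect))
    counts = pd.DataFrame(rows, columns=["pair_id", "allele", "assay", "inp", "spl"])
    truth = pd.DataFrame(truth_rows, columns=["pair_id", "is_esm", "effect"])
    return MapsySim(counts=counts, truth=truth)


# ---------------------------------------------------------------------------
# Gene-level feature tables
# ---------------------------------------------------------------------------

# name -> (mean, sd, shift of the Upper class in SDs at effect_profile=1)
FEATURE_SPEC: dict[str, tuple[float, float, float]] = {
    "intron_count": (8.0, 6.0, 2.0),          # Upper genes ~2.5x more introns
    "mean_exon_length": (150.0, 40.0, -0.8),  # shorter exons
    "exon_dg": (-30.0, 10.0, -0.6),           # more structured exons (lower dG)
    "ss_dg": (-20.0, 8.0, -0.6),
    "hi_score": (0.35, 0.18, 0.8),            # more haploinsufficient
    "exac_variant_conservation": (0.55, 0.15, -0.7),  # less conserved variants
    "exon_conservation": (0.70, 0.10, 0.3),
    "gene_conservation": (0.50, 0.10, 0.2),
    "ese_density": (0.06, 0.015, 0.3),
    "ess_density": (0.04, 0.010, -0.2),
    "esr_density": (0.10, 0.020, 0.2),
    "mean_5ss_strength": (8.0, 1.5, -0.3),
    "mean_3ss_strength": (8.0, 1.5, -0.3),
    "exon_snp_density": (0.010, 0.003, -0.3),
    "gene_snp_density": (0.008, 0.002, -0.2),
    "cds_length": (1800.0, 700.0, 0.3),
    "gene_length": (30000.0, 15000.0, 0.5),
    "mean_intron_length": (2000.0, 900.0, 0.2),
    "gc_content": (0.45, 0.05, 0.0),
}

FEATURE_NAMES: tuple[str, ...] = tuple(FEATURE_SPEC)

# intron_count is generated on a multiplicative scale so that the Upper class
# has a configurable mean fold change (2.5x at effect_profile=1).
_INTRON_FOLD = 2.5


def feature_directions() -> pd.Series:
    """Planted direction of each feature's association with the Upper class."""
    return pd.Series({k: float(np.sign(v[2])) for k, v in FEATURE_SPEC.items()})


def gen_feature_table(labels: Sequence[str] | pd.Series,
                      effect_profile: float = 1.0, noise: float = 1.0,
                      seed: int = 0) -> pd.DataFrame:
    """Generate the 19-feature gene table for a vector of envelope labels.

    ``labels`` take values in {'Upper', 'Expected', 'Lower'}; Upper genes are
    drawn with shifted means in the planted directions, Lower genes with the
    opposite (half-sized) shifts. ``effect_profile=0`` gives exchangeable
    features; the default profile plants a 2.5-fold intron-count ratio and
    makes intron count the single most separating feature.
    """
    labels = pd.Series(labels).astype(str)
    bad = set(labels.unique()) - {"Upper", "Expected", "Lower"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    n = len(labels)
    ids = [f"G{i:05d}" for i in range(n)]
    cols = {}
    master = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xFEA7]))
    up = (labels == "Upper").to_numpy()
    lo = (labels == "Lower").to_numpy()
    for name, (mean, sd, shift) in FEATURE_SPEC.items():
        rng = np.random.default_rng(master.integers(2**31))
        if name == "intron_count":
            # 1 + NB keeps the class means exact, so the Upper:Expected mean
            # ratio is the configured fold (2.5 at effect_profile=1).
            fold = 1.0 + effect_profile * (_INTRON_FOLD - 1.0)
            mu = np.where(up, mean * fold, np.where(lo, mean / max(fold, 1e-9), mean))
            k = 4.0
            vals = 1.0 + rng.negative_binomial(k, k / (k + (mu - 1.0))).astype(float)
        else:
            mu = mean + shift * sd * effect_profile * (up.astype(float) - 0.5 * lo.astype(float))
            vals = mu + rng.normal(0, sd * noise, n)
            if name in ("hi_score", "exon_conservation", "gene_conservation",
                        "exac_variant_conservation", "gc_content"):
                vals = np.clip(vals, 0.0, 1.0)
            if name.endswith("density") or name.endswith("length") or name == "cds_length":
                vals = np.maximum(vals, 0.0)
        cols[name] = vals
    df = pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))
    df.insert(0, "label", labels.to_numpy())
    return df


# ---------------------------------------------------------------------------
# Population variants
# ---------------------------------------------------------------------------

@dataclass
class PopulationSim:
    """Synthetic splice-region population variants plus generator truth."""

    variants: pd.DataFrame  # gene_id, chrom, pos_1based, position, ref, alt, maf, delta, region
    selection_strength: float
    delta_cut: float


def gen_population_variants(gene_models: Mapping[str, GeneModel],
                            n_variants: int = 10000,
                            selection_strength: float = 4.0,
                            seed: int = 0,
                            delta_cut: float = 5.0,
                            delta_sd: float = 3.0,
                            prone_genes: Iterable[str] | None = None,
                            prone_thinning: float = 0.5) -> PopulationSim:
    """MAF-annotated variants inside canonical splice-site windows.

    MAFs follow a heavy-tailed law (log10-uniform over [1e-6, 0.3]);
    splice-site-weakening alleles (PWM delta above ``delta_cut``) that land
    in the common stratum (MAF > 1%) are rejected with probability
    ``1 - 1/selection_strength``, so the expected depletion factor of
    strong-loss alleles among common variants is ~``selection_strength``.
    When ``prone_genes`` is given, variants in those genes are additionally
    thinned by ``prone_thinning`` (stronger purifying selection on the
    splice sites of SSM-prone genes).
    """
    if selection_strength < 1.0:
        raise ValueError("selection_strength must be >= 1 (1 = neutral)")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x9E1]))
    gene_ids = sorted(g for g, m in gene_models.items() if m.n_introns > 0)
    if not gene_ids:
        raise ValueError("no intron-containing gene models supplied")
    prone = set(prone_genes or ())
    keep_common = 0.0 if np.isinf(selection_strength) else 1.0 / selection_strength

    rows = []
    while len(rows) < n_variants:
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        g = gene_models[gid]
        if gid in prone and rng.random() < prone_thinning:
            continue
        kind, intron = g.splice_sites()[int(rng.integers(g.n_splice_sites))]
        lo, hi = DONOR_WINDOW if kind == "5ss" else ACCEPTOR_WINDOW
        offsets = [o for o in range(lo, hi + 1) if o != 0]
        pos = g.site_position(kind, intron, offsets[int(rng.integers(len(offsets)))])
        delta = float(rng.normal(0.0, delta_sd))
        maf = float(10.0 ** rng.uniform(-6.0, np.log10(0.3)))
        if delta > delta_cut and maf > 0.01 and rng.random() > keep_common:
            continue  # purged before reaching appreciable frequency
        ref, alt = _rand_substitution(rng)
        region = "ss5_window" if kind == "5ss" else "ss3_window"
        rows.append((gid, g.chrom, pos + 1, pos, ref, alt, maf, delta, region))
    variants = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "pos_1based", "position", "ref", "alt", "maf", "delta", "region",
    ])
    return PopulationSim(variants=variants, selection_strength=selection_strength,
                         delta_cut=delta_cut)
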