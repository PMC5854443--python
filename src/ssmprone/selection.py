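"""Population-variant selection analyses and gene-set enrichment tests.

Works on MAF-annotated splice-region variants and on gene sets:

* per-gene density of rare splice-site-region variants per splice site, and
  its comparison between predicted SSM-prone genes and the rest (rank-sum);
* stratification of PWM delta scores by MAF (rare < 0.01%, common > 1%) and
  the depletion factor of site-abolishing alleles (delta > 5) among common
  variants;
* Fisher's exact / hypergeometric overlap of two gene sets in a universe;
* a permutation test for over-representation of a gene category (e.g.
  cancer genes) among flagged genes;
* Mann-Whitney / Kruskal-Wallis rank tests with tie correction, exact when
  both groups are tiny.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, classify_region, REGION_3SS, REGION_5SS

LOSS_DELTA = 5.0   # delta above this abolishes the site
GAIN_DELTA = -2.0  # delta below this strengthens the site


# ---------------------------------------------------------------------------
# Splice-site variant density
# ---------------------------------------------------------------------------

def ss_variant_density(variants: pd.DataFrame, models: Mapping[str, GeneModel],
                       maf_cutoff: float = 1e-4) -> pd.Series:
    """Per-gene low-frequency splice-region variants per splice site.

    Counts variants with MAF below ``maf_cutoff`` falling in the canonical
    donor/acceptor windows of each intron-containing gene and divides by the
    gene's number of splice sites. Genes with no qualifying variants get 0;
    intronless genes are excluded. Duplicate variant rows (same gene,
    position, ref, alt) are collapsed before counting.
    """
    v = variants.drop_duplicates(subset=["gene_id", "position", "ref", "alt"])
    v = v[v["maf"] < maf_cutoff]
    if "region" in v.columns:
        in_window = v["region"].isin([REGION_5SS, REGION_3SS])
    else:
        in_window = pd.Series(
            [
                r.gene_id in models
                and classify_region(int(r.position), models[r.gene_id])
                in (REGION_5SS, REGION_3SS)
                for r in v.itertuples(index=False)
            ],
            index=v.index,
            dtype=bool,
        )
    counts = v[in_window].groupby("gene_id").size()
    dens = {}
    for gid, g in models.items():
        if g.n_introns == 0:
            continue
        dens[gid] = counts.get(gid, 0) / g.n_splice_sites
    return pd.Series(dens, name="ss_variants_per_site").sort_index()


def compare_density_groups(density: pd.Series, prone_genes: Iterable[str]) -> tuple[float, float]:
    """Rank-sum comparison of splice-site variant density, prone vs rest."""
    prone = set(prone_genes)
    a = density[density.index.isin(prone)]
    b = density[~density.index.isin(prone)]
    return group_rank_tests({"prone": a.to_numpy(), "other": b.to_numpy()},
                            test="mann_whitney")


# ---------------------------------------------------------------------------
# Delta-score stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaStrataResult:
    """MAF-stratified splice-site delta-score comparison."""

    n_rare: int
    n_common: int
    share_loss_rare: float      # P(delta > LOSS_DELTA | rare)
    share_loss_common: float
    share_gain_rare: float      # P(delta < GAIN_DELTA | rare)
    share_gain_common: float
    depletion_factor_loss: float  # rare share / common share of loss alleles
    enrichment_factor_gain: float

    def summary(self) -> str:
        dep = ("undefined" if np.isnan(self.depletion_factor_loss)
               else f"{self.depletion_factor_loss:.2f}x")
        return (
            f"rare n={self.n_rare}, common n={self.n_common}\n"
            f"site-abolishing (delta>{LOSS_DELTA:g}) share: "
            f"rare {self.share_loss_rare:.4f}, common {self.share_loss_common:.4f} "
            f"-> depletion {dep}\n"
            f"site-strengthening (delta<{GAIN_DELTA:g}) share: "
            f"rare {self.share_gain_rare:.4f}, common {self.share_gain_common:.4f}"
        )


def delta_strata_compare(variants: pd.DataFrame, maf_rare: float = 1e-4,
                         maf_common: float = 1e-2, loss_delta: float = LOSS_DELTA,
                         gain_delta: float = GAIN_DELTA) -> DeltaStrataResult:
    """Compare the delta-score distribution between rare and common variants.

    Intermediate-frequency variants are excluded. The depletion factor of
    site-abolishing alleles among common variants is the ratio of their
    share among rare variants to their share among common ones; an empty
    stratum (or an empty loss bin among common variants) leaves the factor
    undefined (NaN).
    """
    if "delta" not in variants.columns:
        raise ValueError("variants need a 'delta' column")
    rare = variants[variants["maf"] < maf_rare]
    common = variants[variants["maf"] > maf_common]

    def share(df: pd.DataFrame, mask) -> float:
        return float(mask.mean()) if len(df) else float("nan")

    slr = share(rare, rare["delta"] > loss_delta)
    slc = share(common, common["delta"] > loss_delta)
    sgr = share(rare, rare["delta"] < gain_delta)
    sgc = share(common, common["delta"] < gain_delta)
    depletion = slr / slc if slc and not np.isnan(slc) else float("nan")
    gain_enr = sgc / sgr if sgr and not np.isnan(sgr) else float("nan")
    return DeltaStrataResult(
        n_rare=len(rare), n_common=len(common),
        share_loss_rare=slr, share_loss_common=slc,
        share_gain_rare=sgr, share_gain_common=sgc,
        depletion_factor_loss=depletion, enrichment_factor_gain=gain_enr)


# ---------------------------------------------------------------------------
# Gene-set overlap tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    fold_enrichment: float
    observed_overlap: int
    expected_overlap: float


def overlap_fisher(set_a: Iterable[str], set_b: Iterable[str],
                   universe: Iterable[str]) -> ContingencyResult:
    """Two-sided Fisher's exact test for the overlap of two gene sets.

    Both sets must be subsets of the universe. Fold enrichment is the
    observed overlap over the independence expectation |A||B|/|U|.
    """
    u = set(universe)
    if not u:
        raise ValueError("empty universe")
    a, b = set(set_a), set(set_b)
    if not a <= u or not b <= u:
        raise ValueError("gene sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(u) - len(a | b)
    table = np.array([[n11, n12], [n21, n22]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    expected = len(a) * len(b) / len(u)
    fold = n11 / expected if expected > 0 else float("nan")
    return ContingencyResult(
        table=((n11, n12), (n21, n22)), odds_ratio=float(odds), p_value=float(p),
        fold_enrichment=fold, observed_overlap=n11, expected_overlap=expected)


@dataclass(frozen=True)
class PermutationResult:
    observed_overlap: int
    expected_overlap: float
    fold_enrichment: float
    p_value: float
    n_perm: int


def category_permutation(category_genes: Iterable[str], marked_genes: Iterable[str],
                         universe: Iterable[str], n_perm: int = 10000,
                         seed: int = 0) -> PermutationResult:
    """Permutation test for over-representation of a category among marked genes.

    Draws |category| genes uniformly without replacement from the universe
    ``n_perm`` times and reports the add-one upper-tail probability of an
    overlap with ``marked_genes`` at least as large as observed.
    """
    u = sorted(set(universe))
    cat = set(category_genes)
    marked = set(marked_genes)
    if len(cat) > len(u):
        raise ValueError("category larger than universe")
    if not cat <= set(u) or not marked <= set(u):
        raise ValueError("gene sets must be subsets of the universe")
    observed = len(cat & marked)
    rng = np.random.default_rng(seed)
    is_marked = np.array([g in marked for g in u])
    k = len(cat)
    sims = np.array([is_marked[rng.choice(len(u), size=k, replace=False)].sum()
                     for _ in range(n_perm)])
    p = (1 + int((sims >= observed).sum())) / (1 + n_perm)
    expected = k * len(marked) / len(u)
    fold = observed / expected if expected > 0 else float("nan")
    return PermutationResult(observed_overlap=observed, expected_overlap=expected,
                             fold_enrichment=fold, p_value=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def group_rank_tests(groups: Mapping[str, Sequence[float]],
                     test: str = "mann_whitney") -> tuple[float, float]:
    """Rank statistics across groups with tie correction.

    ``mann_whitney`` requires exactly two groups (exact enumeration when both
    have at most 8 values, normal approximation with tie correction
    otherwise); ``kruskal_wallis`` takes two or more. Returns (statistic, p).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    if test == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("mann_whitney needs exactly two groups")
        a, b = arrays.values()
        combined = np.concatenate([a, b])
        no_ties = np.unique(combined).size == combined.size
        method = "exact" if (max(a.size, b.size) <= 8 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        if len(arrays) < 2:
            raise ValueError("kruskal_wallis needs at least two groups")
        res = stats.kruskal(*arrays.values())
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
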