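"""Weighted-random-sampling enrichment envelopes for SSM and ESM counts.

The core statistic of the package. For every gene the observed number of
canonical splice-site mutations (SSM) among its disease mutations is compared
to a Monte-Carlo null in which each of the gene's ``n_muts`` mutations is a
splice-site mutation with probability

* global mode:      w = totalspl / totalmuts   (the catalog-wide SSM rate),
* normalized mode:  w_gene = (totalspl/totalmuts) * (totalCDS/totalSS)
                             * (geneSS/geneCDS),

i.e. the normalized mode rescales the global rate by how splice-site-dense
the gene is relative to the catalog, removing the trivial "more introns =
bigger target" effect. SSM counts are simulated ``n_reps`` times per gene;
the empirical envelope at ``ci_level`` (default 99.9%) yields the category:

* Upper    — observed count strictly above the simulated upper bound,
* Lower    — strictly below the lower bound,
* Expected — inside the envelope.

The same machinery applies per exon to assayed exonic splicing mutations
(ESM), with the weight totalESM / totalmutstested.

The class surface follows the fit/Results convention: build a
:class:`SpliceEnrichmentModel` from tallies or a catalog, call ``fit()`` and
inspect the returned :class:`SpliceEnrichmentResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, MutationRecord, is_ssm
from .synth import entity_rng

log = logging.getLogger("ssmprone")

CATEGORY_UPPER = "Upper"
CATEGORY_EXPECTED = "Expected"
CATEGORY_LOWER = "Lower"


@dataclass(frozen=True)
class GlobalWeights:
    """Catalog-wide totals behind the sampling weights."""

    totalspl: int
    totalmuts: int
    totalSS: int
    totalCDS: int

    def __post_init__(self) -> None:
        if self.totalspl > self.totalmuts:
            raise ValueError("totalspl cannot exceed totalmuts")
        if min(self.totalspl, self.totalmuts, self.totalSS, self.totalCDS) < 0:
            raise ValueError("totals must be non-negative")

    @property
    def weight(self) -> float:
        """Global sampling weight: the catalog-wide SSM fraction."""
        return self.totalspl / self.totalmuts if self.totalmuts else 0.0

    @property
    def normalization(self) -> float:
        """totalCDS / totalSS, the catalog-average CDS length per splice site."""
        return self.totalCDS / self.totalSS if self.totalSS else 0.0


def tally_genes(records: Iterable[MutationRecord],
                models: Mapping[str, GeneModel]) -> tuple[pd.DataFrame, GlobalWeights]:
    """Roll a mutation catalog up to per-gene SSM/total counts.

    Records in unknown genes are logged and skipped; intronless genes are
    excluded (they have no splice sites to mutate). Returns the per-gene
    tally table (gene_id, n_muts, n_ssm, geneSS, geneCDS) and the catalog
    totals.
    """
    skipped = 0
    n_muts: dict[str, int] = {}
    n_ssm: dict[str, int] = {}
    for r in records:
        g = models.get(r.gene_id)
        if g is None or g.n_introns == 0:
            skipped += 1
            continue
        n_muts[r.gene_id] = n_muts.get(r.gene_id, 0) + 1
        if is_ssm(r, g):
            n_ssm[r.gene_id] = n_ssm.get(r.gene_id, 0) + 1
    if skipped:
        log.warning("skipped %d records in unknown or intronless genes", skipped)
    rows = [
        (gid, n, n_ssm.get(gid, 0), models[gid].n_splice_sites, models[gid].cds_length)
        for gid, n in sorted(n_muts.items())
    ]
    tallies = pd.DataFrame(rows, columns=["gene_id", "n_muts", "n_ssm", "geneSS", "geneCDS"])
    weights = GlobalWeights(
        totalspl=int(tallies["n_ssm"].sum()) if len(tallies) else 0,
        totalmuts=int(tallies["n_muts"].sum()) if len(tallies) else 0,
        totalSS=int(tallies["geneSS"].sum()) if len(tallies) else 0,
        totalCDS=int(tallies["geneCDS"].sum()) if len(tallies) else 0,
    )
    return tallies, weights


def gene_weights(tallies: pd.DataFrame, weights: GlobalWeights, mode: str) -> pd.Series:
    """Per-gene sampling weight under the chosen null.

    Normalized weights larger than 1 (possible for intron-dense genes with
    short CDS) are clipped to 1 with a warning.
    """
    if mode == "global":
        return pd.Series(weights.weight, index=tallies.index)
    if mode == "normalized":
        w = weights.weight * weights.normalization * (
            tallies["geneSS"] / tallies["geneCDS"])
        n_clip = int((w > 1.0).sum())
        if n_clip:
            log.warning("clipped %d per-gene weights > 1 to 1", n_clip)
        return w.clip(upper=1.0)
    raise ValueError(f"unknown mode {mode!r} (use 'global' or 'normalized')")


def _envelope_one(n: int, w: float, observed: int, n_reps: int, ci_level: float,
                  rng: np.random.Generator) -> tuple[int, int, float, str]:
    """Simulate one entity's envelope; returns (lower, upper, p_emp, category)."""
    if n == 0:
        return 0, 0, 1.0, CATEGORY_EXPECTED
    sims = np.sort(rng.binomial(n, w, size=n_reps))
    q_lo = (1.0 - ci_level) / 2.0
    # symmetric tail order statistics: the ceil(q_lo * n_reps)-th draw from
    # either end of the sorted replicates
    rank = max(math.ceil(q_lo * n_reps), 1)
    lower = int(sims[rank - 1])
    upper = int(sims[n_reps - rank])
    p_up = (1 + int((sims >= observed).sum())) / (1 + n_reps)
    p_dn = (1 + int((sims <= observed).sum())) / (1 + n_reps)
    p = min(1.0, 2.0 * min(p_up, p_dn))
    if observed > upper:
        cat = CATEGORY_UPPER
    elif observed < lower:
        cat = CATEGORY_LOWER
    else:
        cat = CATEGORY_EXPECTED
    return lower, upper, p, cat


def mc_envelope(tallies: pd.DataFrame, weights: GlobalWeights, mode: str = "global",
                n_reps: int = 1000, ci_level: float = 0.999, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo sampling envelope over all genes of a tally table.

    Per gene, SSM* ~ Binomial(n_muts, w) is drawn ``n_reps`` times with a
    per-gene RNG substream keyed by the gene id (results do not depend on
    catalog order). Bounds are the empirical order statistics at
    ceil(q * n_reps); a gene is Upper/Lower only when its observed count
    falls strictly outside the simulated values. The reported ``p_emp`` is
    the two-sided add-one empirical p-value.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    w = gene_weights(tallies, weights, mode)
    rows = []
    for i, row in zip(tallies.index, tallies.itertuples(index=False)):
        rng = entity_rng(seed, f"env:{row.gene_id}")
        lower, upper, p, cat = _envelope_one(
            int(row.n_muts), float(w.loc[i]), int(row.n_ssm), n_reps, ci_level, rng)
        rows.append((row.gene_id, int(row.n_muts), int(row.n_ssm), lower, upper, p, cat))
    return pd.DataFrame(
        rows, columns=["entity_id", "n", "observed", "lower", "upper", "p_emp", "category"])


def exon_esm_envelope(exon_tallies: pd.DataFrame, weight: float | None = None,
                      n_reps: int = 1000, ci_level: float = 0.999,
                      seed: int = 0) -> pd.DataFrame:
    """ESM envelope per exon: n = mutations tested, observed = ESM called.

    ``exon_tallies`` has columns exon_id, n_tested, n_esm; the sampling
    weight defaults to totalESM / totalmutstested over the panel. Exons with
    no tested mutations are excluded. Upper exons are enriched for ESMs.
    """
    t = exon_tallies[exon_tallies["n_tested"] > 0]
    if (t["n_esm"] > t["n_tested"]).any():
        raise ValueError("n_esm cannot exceed n_tested")
    if weight is None:
        weight = float(t["n_esm"].sum() / t["n_tested"].sum())
    if not (0.0 <= weight <= 1.0):
        raise ValueError("weight must be in [0, 1]")
    rows = []
    for row in t.itertuples(index=False):
        rng = entity_rng(seed, f"exon:{row.exon_id}")
        lower, upper, p, cat = _envelope_one(
            int(row.n_tested), weight, int(row.n_esm), n_reps, ci_level, rng)
        rows.append((row.exon_id, int(row.n_tested), int(row.n_esm), lower, upper, p, cat))
    return pd.DataFrame(
        rows, columns=["entity_id", "n", "observed", "lower", "upper", "p_emp", "category"])


def binomial_oracle(n: int, w: float, ci_level: float = 0.999) -> tuple[int, int]:
    """Exact binomial envelope bounds at the same tail fractions.

    The Monte-Carlo order statistics converge to these quantiles as the
    replicate count grows; used for validation, not in the pipeline.
    """
    if n == 0:
        return 0, 0
    q_lo = (1.0 - ci_level) / 2.0
    lower = int(stats.binom.ppf(q_lo, n, w))
    upper = int(stats.binom.ppf(1.0 - q_lo, n, w))
    return lower, upper


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class SpliceEnrichmentModel:
    """Weighted-sampling null model of per-gene splice-site mutation counts.

    Parameters
    ----------
    tallies
        Per-gene counts with columns gene_id, n_muts, n_ssm, geneSS, geneCDS.
    weights
        Catalog totals; recomputed from the tallies when omitted.
    mode
        'global' (one catalog-wide weight) or 'normalized' (per-gene weight
        rescaled by splice-site density).
    """

    def __init__(self, tallies: pd.DataFrame, weights: GlobalWeights | None = None,
                 mode: str = "global") -> None:
        required = {"gene_id", "n_muts", "n_ssm", "geneSS", "geneCDS"}
        missing = required - set(tallies.columns)
        if missing:
            raise ValueError(f"tally table missing columns: {sorted(missing)}")
        if (tallies["n_ssm"] > tallies["n_muts"]).any():
            raise ValueError("n_ssm cannot exceed n_muts")
        if mode not in ("global", "normalized"):
            raise ValueError(f"unknown mode {mode!r}")
        self.tallies = tallies.reset_index(drop=True)
        self.weights = weights if weights is not None else GlobalWeights(
            totalspl=int(tallies["n_ssm"].sum()),
            totalmuts=int(tallies["n_muts"].sum()),
            totalSS=int(tallies["geneSS"].sum()),
            totalCDS=int(tallies["geneCDS"].sum()),
        )
        self.mode = mode

    @classmethod
    def from_catalog(cls, records: Iterable[MutationRecord],
                     models: Mapping[str, GeneModel], mode: str = "global",
                     ) -> "SpliceEnrichmentModel":
        tallies, weights = tally_genes(records, models)
        return cls(tallies, weights, mode=mode)

    def fit(self, n_reps: int = 1000, ci_level: float = 0.999,
            seed: int = 0) -> "SpliceEnrichmentResults":
        """Run the Monte-Carlo envelope and return the results object."""
        envelope = mc_envelope(self.tallies, self.weights, mode=self.mode,
                               n_reps=n_reps, ci_level=ci_level, seed=seed)
        return SpliceEnrichmentResults(self, envelope, n_reps=n_reps,
                                       ci_level=ci_level, seed=seed)


class SpliceEnrichmentResults:
    """Fitted envelope: per-gene bounds, empirical p-values and categories."""

    def __init__(self, model: SpliceEnrichmentModel, envelope: pd.DataFrame,
                 n_reps: int, ci_level: float, seed: int) -> None:
        self.model = model
        self.envelope = envelope
        self.n_reps = n_reps
        self.ci_level = ci_level
        self.seed = seed

    @property
    def categories(self) -> pd.Series:
        return self.envelope.set_index("entity_id")["category"]

    def genes_in(self, category: str) -> list[str]:
        return self.envelope.loc[self.envelope["category"] == category, "entity_id"].tolist()

    @property
    def upper_genes(self) -> list[str]:
        """Genes with more splice-site mutations than the envelope allows."""
        return self.genes_in(CATEGORY_UPPER)

    @property
    def flagged_fraction(self) -> float:
        """Fraction of genes outside the envelope (Upper or Lower)."""
        return float((self.envelope["category"] != CATEGORY_EXPECTED).mean())

    def summary(self) -> str:
        env = self.envelope
        counts = env["category"].value_counts()
        lines = [
            "Splice-site mutation enrichment envelope",
            "=" * 44,
            f"mode:          {self.model.mode}",
            f"genes:         {len(env)}",
            f"global weight: {self.model.weights.weight:.4f} "
            f"({self.model.weights.totalspl}/{self.model.weights.totalmuts})",
            f"replicates:    {self.n_reps}   envelope: {self.ci_level:.1%}",
            f"Upper:         {counts.get(CATEGORY_UPPER, 0)}",
            f"Expected:      {counts.get(CATEGORY_EXPECTED, 0)}",
            f"Lower:         {counts.get(CATEGORY_LOWER, 0)}",
        ]
        top = env[env["category"] == CATEGORY_UPPER].sort_values("p_emp").head(10)
        if len(top):
            lines.append("top Upper genes (entity, n, observed, upper bound, p_emp):")
            for r in top.itertuples(index=False):
                lines.append(f"  {r.entity_id:<12} {r.n:>5} {r.observed:>5} {r.upper:>5} {r.p_emp:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of SSM vs total mutations coloured by envelope category."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots(figsize=(6, 5))
        colors = {CATEGORY_UPPER: "#c0392b", CATEGORY_EXPECTED: "#2c6fbb",
                  CATEGORY_LOWER: "#1e8449"}
        for cat, sub in self.envelope.groupby("category"):
            ax.scatter(sub["n"], sub["observed"], s=8, alpha=0.6,
                       color=colors.get(cat, "gray"), label=cat)
        ax.set_xlabel("total mutations in gene")
        ax.set_ylabel("splice-site mutations")
        ax.legend(frameon=False)
        return ax

    def to_tsv(self, path) -> None:
        self.envelope.to_csv(path, sep="\t", index=False)
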