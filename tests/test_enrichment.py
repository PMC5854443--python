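"""The weighted-sampling envelope: tallies, bounds, categories, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssmprone import (
    GeneModel, GlobalWeights, MutationRecord, SpliceEnrichmentModel,
    binomial_oracle, exon_esm_envelope, mc_envelope, tally_genes,
)
from ssmprone.enrichment import gene_weights
from ssmprone.synth import gen_catalog


def make_tallies(rows):
    return pd.DataFrame(rows, columns=["gene_id", "n_muts", "n_ssm", "geneSS", "geneCDS"])


@pytest.fixture
def toy_weights():
    return GlobalWeights(totalspl=134, totalmuts=1000, totalSS=200, totalCDS=40_000)


class TestTallyGenes:
    def test_rule_conjunction_on_constructed_records(self, two_exon_plus):
        """3 window records but only 2 splicing-labelled -> n_ssm = 2."""
        models = {"gp": two_exon_plus}
        recs = (
            [MutationRecord("gp", "chr1", 200 + i, "G", "A", "splicing") for i in range(2)]
            + [MutationRecord("gp", "chr1", 203, "G", "A", "missense")]  # window, mislabelled
            + [MutationRecord("gp", "chr1", 150, "G", "A", "splicing")]  # exonic, labelled
            + [MutationRecord("gp", "chr1", 120 + i, "C", "T", "missense") for i in range(6)]
        )
        t, w = tally_genes(recs, models)
        assert t.loc[0, "n_muts"] == 10
        assert t.loc[0, "n_ssm"] == 2
        assert w.totalspl == 2 and w.totalmuts == 10

    def test_no_splicing_records_gives_zero_weight(self, two_exon_plus):
        recs = [MutationRecord("gp", "chr1", 150 + i, "G", "A", "missense") for i in range(5)]
        _t, w = tally_genes(recs, {"gp": two_exon_plus})
        assert w.totalspl == 0
        assert w.weight == 0.0

    def test_unknown_and_intronless_genes_skipped(self, two_exon_plus):
        single = GeneModel("solo", "chr1", "+", ((0, 500),))
        recs = [MutationRecord("gp", "chr1", 150, "G", "A", "missense"),
                MutationRecord("solo", "chr1", 100, "G", "A", "missense"),
                MutationRecord("ghost", "chr1", 100, "G", "A", "missense")]
        t, _ = tally_genes(recs, {"gp": two_exon_plus, "solo": single})
        assert t["gene_id"].tolist() == ["gp"]

    def test_default_catalog_recovers_global_ssm_fraction(self):
        sim = gen_catalog(n_genes=2000, seed=0)
        _t, w = tally_genes(sim.records, sim.models)
        se = np.sqrt(0.134 * 0.866 / w.totalmuts)
        assert abs(w.weight - 0.134) < 3 * se


class TestEnvelope:
    def test_observed_at_null_center_is_expected(self, toy_weights):
        t = make_tallies([(f"g{i}", 100, round(100 * 0.134), 20, 2000)
                          for i in range(20)])
        env = mc_envelope(t, toy_weights, n_reps=1000, seed=0)
        assert (env["category"] == "Expected").all()

    def test_extreme_observation_is_upper(self, toy_weights):
        """9/10 SSM at weight 0.134: exact binomial tail P(X>=9) < 1e-6."""
        t = make_tallies([("g", 10, 9, 4, 1000)])
        env = mc_envelope(t, toy_weights, n_reps=1000, seed=0)
        assert env.loc[0, "category"] == "Upper"
        assert env.loc[0, "p_emp"] <= 2 / 1001 * 2

    def test_zero_mutation_gene_is_expected_by_fiat(self, toy_weights):
        t = make_tallies([("g", 0, 0, 4, 1000)])
        env = mc_envelope(t, toy_weights, n_reps=1000, seed=0)
        assert env.loc[0, "category"] == "Expected"
        assert (env.loc[0, "lower"], env.loc[0, "upper"]) == (0, 0)

    def test_monotone_in_observed_count(self, toy_weights):
        """Raising observed SSM never moves the category toward Lower."""
        order = {"Lower": 0, "Expected": 1, "Upper": 2}
        cats = []
        for obs in range(0, 31):
            t = make_tallies([("g", 30, obs, 4, 1000)])
            env = mc_envelope(t, toy_weights, n_reps=500, seed=1)
            cats.append(order[env.loc[0, "category"]])
        assert all(b >= a for a, b in zip(cats, cats[1:]))

    def test_independent_of_catalog_order(self, toy_weights):
        t = make_tallies([(f"g{i}", 50, 5 + i % 3, 10, 1500) for i in range(10)])
        env1 = mc_envelope(t, toy_weights, seed=5)
        env2 = mc_envelope(t.iloc[::-1].reset_index(drop=True), toy_weights, seed=5)
        merged = env1.merge(env2, on="entity_id", suffixes=("_a", "_b"))
        assert (merged["lower_a"] == merged["lower_b"]).all()
        assert (merged["upper_a"] == merged["upper_b"]).all()

    def test_normalized_equals_global_when_ss_density_uniform(self):
        """Identical geneSS/geneCDS in all genes: the two modes coincide."""
        t = make_tallies([(f"g{i}", 40 + i, 5, 10, 1000) for i in range(8)])
        w = GlobalWeights(totalspl=40, totalmuts=350, totalSS=80, totalCDS=8000)
        env_g = mc_envelope(t, w, mode="global", seed=3)
        env_n = mc_envelope(t, w, mode="normalized", seed=3)
        pd.testing.assert_frame_equal(env_g, env_n)

    def test_normalized_weights_follow_ss_density(self, toy_weights):
        t = make_tallies([("dense", 10, 1, 40, 1000), ("sparse", 10, 1, 4, 4000)])
        w = gene_weights(t, toy_weights, "normalized")
        assert w.iloc[0] > w.iloc[1]
        assert (w <= 1.0).all()

    def test_normalized_weight_clipped_at_one(self, toy_weights):
        t = make_tallies([("extreme", 10, 1, 400, 100)])
        w = gene_weights(t, toy_weights, "normalized")
        assert w.iloc[0] == 1.0


class TestExonEnvelope:
    def test_fully_disrupted_exon_is_upper(self):
        t = pd.DataFrame({"exon_id": ["e8"], "n_tested": [6], "n_esm": [6]})
        env = exon_esm_envelope(t, weight=0.10, n_reps=2000, seed=0)
        assert env.loc[0, "category"] == "Upper"

    def test_clean_exon_is_not_upper(self):
        t = pd.DataFrame({"exon_id": ["e4"], "n_tested": [8], "n_esm": [0]})
        env = exon_esm_envelope(t, weight=0.10, n_reps=2000, seed=0)
        assert env.loc[0, "category"] != "Upper"

    def test_one_in_ten_is_expected(self):
        """P(X>=1 | n=10, w=0.1) = 0.651: well inside the envelope."""
        t = pd.DataFrame({"exon_id": ["e"], "n_tested": [10], "n_esm": [1]})
        env = exon_esm_envelope(t, weight=0.10, n_reps=2000, seed=0)
        assert env.loc[0, "category"] == "Expected"

    def test_untested_exons_excluded(self):
        t = pd.DataFrame({"exon_id": ["a", "b"], "n_tested": [10, 0], "n_esm": [1, 0]})
        env = exon_esm_envelope(t, weight=0.10, seed=0)
        assert env["entity_id"].tolist() == ["a"]

    def test_default_weight_is_pooled_esm_fraction(self):
        t = pd.DataFrame({"exon_id": ["a", "b"], "n_tested": [30, 70], "n_esm": [3, 7]})
        env = exon_esm_envelope(t, n_reps=500, seed=0)
        oracle = binomial_oracle(30, 0.10, 0.999)
        assert abs(env.loc[0, "upper"] - oracle[1]) <= 1


class TestBinomialOracle:
    def test_degenerate_cases(self):
        assert binomial_oracle(0, 0.134) == (0, 0)
        assert binomial_oracle(100, 0.0) == (0, 0)

    def test_exact_bounds_from_cdf_inversion(self):
        """n=100, w=0.134: full-CDF enumeration of the 0.05%/99.95% quantiles."""
        cdf = np.cumsum(stats.binom.pmf(np.arange(101), 100, 0.134))
        lower = int(np.searchsorted(cdf, 0.0005))
        upper = int(np.searchsorted(cdf, 0.9995))
        assert binomial_oracle(100, 0.134, 0.999) == (lower, upper)

    def test_mc_bounds_converge_to_oracle(self):
        """At 1e4 replicates, MC bounds sit within 1 count of the exact ones."""
        w0 = GlobalWeights(totalspl=134, totalmuts=1000, totalSS=10, totalCDS=1000)
        mismatches = total = 0
        for n in (5, 20, 50, 100):
            for wgt in (0.05, 0.134, 0.3):
                w = GlobalWeights(totalspl=int(wgt * 1000), totalmuts=1000,
                                  totalSS=10, totalCDS=1000)
                t = make_tallies([(f"g_{n}_{wgt}", n, 0, 10, 1000)])
                env = mc_envelope(t, w, n_reps=10_000, seed=0)
                lo, hi = binomial_oracle(n, wgt, 0.999)
                total += 2
                mismatches += (abs(env.loc[0, "lower"] - lo) > 1)
                mismatches += (abs(env.loc[0, "upper"] - hi) > 1)
        assert mismatches / total <= 0.01
        assert w0.weight == pytest.approx(0.134)


class TestModelResults:
    def test_fit_returns_results_with_summary_and_upper_genes(self):
        sim = gen_catalog(n_genes=150, enriched_fraction=0.1, multiplier=4.0, seed=4)
        model = SpliceEnrichmentModel.from_catalog(sim.records, sim.models)
        res = model.fit(n_reps=1000, seed=4)
        enriched = set(sim.truth.loc[sim.truth["multiplier"] > 1, "gene_id"])
        assert set(res.upper_genes) & enriched
        text = res.summary()
        assert "Upper" in text and "global" in text
        assert 0.0 <= res.flagged_fraction <= 1.0

    def test_invalid_tallies_rejected(self):
        bad = make_tallies([("g", 5, 9, 4, 100)])
        with pytest.raises(ValueError, match="n_ssm"):
            SpliceEnrichmentModel(bad)

    def test_plot_returns_axes(self):
        import matplotlib
        matplotlib.use("Agg")
        sim = gen_catalog(n_genes=30, seed=1)
        res = SpliceEnrichmentModel.from_catalog(sim.records, sim.models).fit(seed=1)
        ax = res.plot()
        assert ax.get_xlabel()
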