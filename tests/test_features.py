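"""ESR hexamer scoring, splice-site PWMs and feature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ssmprone import (
    GeneModel, HexamerTable, SpliceSitePWM, assemble_features, build_pwm,
    delta_esr, score_variant_delta,
)
from ssmprone.features import (
    FEATURE_COLUMNS, esr_density, site_sequence, stacking_fold_backend,
    window_esr_score,
)

dna = st.text(alphabet="ACGT", min_size=8, max_size=40)


def brute_force_delta(wt: str, mt: str, table: HexamerTable) -> float:
    """Independent oracle: rescan both full sequences and subtract totals."""
    return window_esr_score(wt, table) - window_esr_score(mt, table)


@pytest.fixture
def toy_table():
    return HexamerTable({"AAAAAA": 2.0, "AAAACA": -1.0, "GGGGGG": 3.0},
                        classes={"AAAAAA": "ESE", "GGGGGG": "ESS"})


class TestDeltaEsr:
    def test_equal_sequences_rejected(self, toy_table):
        with pytest.raises(ValueError):
            delta_esr("AAAAAAAA", "AAAAAAAA", toy_table, 4)

    def test_poly_a_center_substitution(self, toy_table):
        """wt = A^8: windows through the variant enumerated by hand."""
        wt, mt = "AAAAAAAA", "AAAACAAA"
        # 3 windows of A^8 overlap position 4 (offsets 0..2); in mt none
        # match AAAAAA but window starting at 0 is AAAACA (-1) -> delta
        # = 3*2 - (-1) = 7?  No: mt windows are AAAACA, AAACAA, AACAAA
        # scoring -1, 0, 0 -> delta = 6 - (-1) = 7
        assert delta_esr(wt, mt, toy_table, 4) == pytest.approx(7.0)
        assert brute_force_delta(wt, mt, toy_table) == pytest.approx(7.0)

    @given(dna, st.data())
    def test_matches_full_rescan_oracle(self, seq, data):
        """Windowed difference equals the full-sequence score difference."""
        table = HexamerTable({"ACGTAC": 1.5, "AAAAAA": 2.0, "CCCCCC": -2.0,
                              "ACGTAA": 0.5, "TTTTTT": -1.0})
        pos = data.draw(st.integers(min_value=0, max_value=len(seq) - 1))
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != seq[pos]]))
        mt = seq[:pos] + alt + seq[pos + 1:]
        assert delta_esr(seq, mt, table, pos) == pytest.approx(
            brute_force_delta(seq, mt, table))

    def test_indels_unsupported(self, toy_table):
        with pytest.raises(ValueError):
            delta_esr("AAAAAAAA", "AAAAAAA", toy_table, 4)

    def test_density_counts_hits_per_length(self, toy_table):
        # A^20: every one of the 15 windows matches AAAAAA
        assert esr_density("A" * 20, toy_table) == pytest.approx(15 / 20)
        assert esr_density("A" * 20, toy_table, "ESS") == 0.0
        assert esr_density("", toy_table) == 0.0


class TestBuildPwm:
    def test_degenerate_training_set(self):
        pwm = build_pwm(["GTAAGTAAA"] * 60, "5ss")
        assert pwm.consensus == "GTAAGTAAA"
        assert pwm.score("GTAAGTAAA") == pytest.approx(pwm.max_score)
        assert pwm.score("CTAAGTAAA") < pwm.score("GTAAGTAAA")

    def test_uniform_training_set_scores_zero(self):
        sites = [a + b for a in "ACGT" for b in "ACGT"] * 4  # uniform 2-mers
        pwm = build_pwm(sites, "toy", pseudocount=0.0, min_sites=10)
        assert pwm.score("AC") == pytest.approx(0.0)
        assert pwm.max_score == pytest.approx(0.0)

    def test_two_position_hand_arithmetic(self):
        """Counts {G:9,A:1} x {T:9,C:1}, pc=1, uniform background:
        p(G) = 10/14 so score(GT) = 2*log2(10/14*4)."""
        sites = ["GT"] * 9 + ["AC"]
        pwm = build_pwm(sites, "toy", pseudocount=1.0, min_sites=5)
        expected = 2 * np.log2((10 / 14) * 4)
        assert pwm.score("GT") == pytest.approx(expected)

    def test_wrong_length_site_names_index(self):
        with pytest.raises(ValueError, match="site 3"):
            build_pwm(["GT", "GT", "GT", "GTA"], "toy", min_sites=2)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            build_pwm(["GTAAGTAAA"] * 10, "5ss")

    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=4),
                    min_size=60, max_size=80))
    def test_no_sequence_outscores_consensus(self, sites):
        pwm = build_pwm(sites, "toy", min_sites=50)
        rng = np.random.default_rng(0)
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), 4))
            assert pwm.score(s) <= pwm.max_score + 1e-9


class TestVariantDelta:
    @pytest.fixture
    def toy_genome_and_gene(self):
        gene = GeneModel("g", "chrT", "+", ((10, 40), (60, 100)))
        seq = ["A"] * 120
        # donor window at boundary 40: exonic 37-39, intronic 40-45 -> GTAAGT
        for i, b in enumerate("CAGGTAAGT"):
            seq[37 + i] = b
        # acceptor at 60: intronic 40..59 (-20..-1), exonic 60-62
        for i, b in enumerate("TTTTTTTTTTTTTTTTTCAGGAA"):
            seq[40 + i] = b  # overwrites intron start; donor seq kept at 37-45
        seq[40:46] = list("GTAAGT")  # restore donor intronic bases
        return {"chrT": "".join(seq)}, gene

    def test_site_sequence_orientation_minus_strand(self):
        gene = GeneModel("gm", "chrT", "-", ((10, 40), (60, 100)))
        # transcript-first exon is [60,100); donor boundary at 59 going left
        seq = ["A"] * 120
        # exonic -3..-1 = 62,61,60 ; intronic +1..+6 = 59..54 (revcomp'd)
        for pos, b in zip((62, 61, 60), "GTC"):  # reads CTG on + strand... set directly
            seq[pos] = b
        genome = {"chrT": "".join(seq)}
        site = site_sequence(gene, "5ss", 0, genome)
        assert len(site) == 9
        # first three bases are the complements of positions 62,61,60
        assert site[:3] == "CAG"  # complement of G,T,C

    def test_consensus_change_delta_equals_logodds_gap(self):
        sites = ["GT"] * 90 + ["AT"] * 10
        pwm = build_pwm(sites, "toy", pseudocount=0.5, min_sites=50)
        gap = pwm.matrix[0, 2] - pwm.matrix[0, 0]  # G vs A at position 0
        assert pwm.delta("GT", "AT") == pytest.approx(gap)

    def test_delta_antisymmetric(self):
        pwm = build_pwm(["GTAAGTAAA"] * 50 + ["GCAAGTAAA"] * 10, "5ss")
        assert pwm.delta("GTAAGTAAA", "GCAAGTAAA") == pytest.approx(
            -pwm.delta("GCAAGTAAA", "GTAAGTAAA"))

    def test_variant_outside_windows_rejected(self, toy_genome_and_gene):
        genome, gene = toy_genome_and_gene
        pwm5 = build_pwm(["GTAAGTAAA"] * 60, "5ss")
        pwm3 = build_pwm(["T" * 20 + "AGG"] * 60, "3ss")

        class V:
            position, ref, alt = 20, "A", "C"  # mid-exon

        with pytest.raises(ValueError, match="not a splice-site"):
            score_variant_delta(V, pwm5, pwm3, gene, genome)

    def test_donor_variant_scored(self, toy_genome_and_gene):
        genome, gene = toy_genome_and_gene
        pwm5 = build_pwm(["CAGGTAAGT"] * 90 + ["CAGGCAAGT"] * 10, "5ss")
        pwm3 = build_pwm(["T" * 20 + "AGG"] * 60, "3ss")

        class V:
            position, ref, alt = 41, "T", "C"  # donor +2: GT -> GC

        delta = score_variant_delta(V, pwm5, pwm3, gene, genome)
        assert delta > 0  # weakens the site


class TestAssembleFeatures:
    @pytest.fixture
    def toy_setup(self):
        genes = {
            "gA": GeneModel("gA", "chrT", "+", ((10, 110), (210, 310))),
            "gB": GeneModel("gB", "chrT", "+", ((400, 500), (600, 640), (700, 800))),
            "solo": GeneModel("solo", "chrT", "+", ((900, 950),)),
        }
        rng = np.random.default_rng(1)
        genome = {"chrT": "".join(rng.choice(list("ACGT"), 1200))}
        return genes, genome

    def test_column_complete_and_deterministic(self, toy_setup):
        genes, genome = toy_setup
        tracks = {"hi": {"gA": 0.8}}  # gB missing -> imputed
        df1 = assemble_features(genes, genome, tracks=tracks,
                                fold_backend=lambda s: -1.0)
        df2 = assemble_features(genes, genome, tracks=tracks,
                                fold_backend=lambda s: -1.0)
        pd.testing.assert_frame_equal(df1, df2)
        assert list(df1.columns) == FEATURE_COLUMNS
        assert len(FEATURE_COLUMNS) == 19
        assert not df1.isna().any().any()
        assert df1.attrs["imputed_hi"] == ["gB"]
        assert "solo" not in df1.index  # intronless genes excluded

    def test_injected_fold_scores_propagate(self, toy_setup):
        genes, genome = toy_setup
        df = assemble_features(genes, genome, fold_backend=lambda s: -7.5)
        assert (df["exon_dg"] == -7.5).all()
        assert (df["ss_dg"] == -7.5).all()

    def test_motif_density_from_toy_hexamers(self, toy_setup):
        genes, genome = toy_setup
        table = HexamerTable({h: 1.0 for h in ["AAAAAA"]}, classes={"AAAAAA": "ESE"})
        df = assemble_features(genes, genome, hexamers=table,
                               fold_backend=lambda s: 0.0)
        assert (df["ese_density"] >= 0).all()
        # a genome of all A: every window in every exon is a hit
        genome_a = {"chrT": "A" * 1200}
        df_a = assemble_features(genes, genome_a, hexamers=table,
                                 fold_backend=lambda s: 0.0)
        exonic_len = 200  # gA: two 100-nt exons
        hits = (100 - 5) * 2
        assert df_a.loc["gA", "ese_density"] == pytest.approx(hits / exonic_len)

    def test_structure_features(self, toy_setup):
        genes, genome = toy_setup
        df = assemble_features(genes, genome, fold_backend=stacking_fold_backend)
        assert df.loc["gA", "intron_count"] == 1
        assert df.loc["gB", "intron_count"] == 2
        assert df.loc["gA", "mean_exon_length"] == 100.0
        assert df.loc["gB", "mean_intron_length"] == pytest.approx((100 + 60) / 2)
        assert (df["exon_dg"] < 0).all()
        assert (df["gc_content"].between(0, 1)).all()
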