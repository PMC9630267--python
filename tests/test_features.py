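"""Feature engineering: expression normalization, tau, CpG density,
conservation scoring, positional features and table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from xprio import schema
from xprio.features import (ConservationTrack, FeatureError,
                            aggregate_brain, assemble_feature_table,
                            compute_cpg_density, compute_tau,
                            conservation_score, positional_features,
                            rpkm_to_tpm)


class TestRpkmToTpm:
    def test_single_gene_normalizes_to_million(self):
        df = pd.DataFrame({"s1": [7.0]}, index=["g1"])
        assert rpkm_to_tpm(df).iloc[0, 0] == pytest.approx(1e6)

    def test_proportions(self):
        df = pd.DataFrame({"s1": [1.0, 3.0]}, index=["g1", "g2"])
        out = rpkm_to_tpm(df)
        assert out["s1"].tolist() == pytest.approx([250000, 750000])

    def test_zero_passes_through(self):
        df = pd.DataFrame({"s1": [0.0, 5.0]}, index=["g1", "g2"])
        assert rpkm_to_tpm(df)["s1"].tolist() == pytest.approx([0, 1e6])

    def test_sample_sums(self, rng):
        df = pd.DataFrame(rng.gamma(2, 5, size=(50, 4)))
        assert rpkm_to_tpm(df).sum(axis=0).to_numpy() == pytest.approx(
            [1e6] * 4, rel=1e-9)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"bad": [0.0, 0.0]})
        with pytest.raises(FeatureError, match="bad"):
            rpkm_to_tpm(df)


class TestAggregateBrain:
    def test_median_of_two(self):
        cereb, brain = aggregate_brain(
            {"c1": 2.0, "c2": 4.0, "b1": 1.0, "b2": 2.0, "b3": 9.0},
            {"c1", "c2"}, {"b1", "b2", "b3"})
        assert cereb == 3.0
        assert brain == 2.0

    def test_constant_tissues(self):
        out = aggregate_brain({"c1": 5.0, "b1": 5.0}, {"c1"}, {"b1"})
        assert out == (5.0, 5.0)

    def test_missing_tissue_rejected(self):
        with pytest.raises(FeatureError):
            aggregate_brain({"c1": 1.0}, {"c1"}, {"b1"})

    def test_overlapping_sets_rejected(self):
        with pytest.raises(FeatureError):
            aggregate_brain({"t": 1.0}, {"t"}, {"t"})


class TestTau:
    def test_uniform_expression_is_zero(self):
        assert compute_tau({f"t{i}": 8.0 for i in range(5)}) == pytest.approx(0.0)

    def test_single_tissue_is_one(self):
        vals = {"t0": 100.0, "t1": 0.0, "t2": 0.0}
        assert compute_tau(vals) == pytest.approx(1.0)

    def test_hand_worked_profile(self):
        # log2(TPM+1) profile [4, 2, 1, 1] is proportional to [1, .5, .25, .25]
        vals = {f"t{i}": 2.0 ** x - 1 for i, x in enumerate([4, 2, 1, 1])}
        assert compute_tau(vals) == pytest.approx(2 / 3)

    def test_unexpressed_gene_is_missing(self):
        assert compute_tau({"a": 0.0, "b": 0.0}) is None

    def test_fewer_than_two_tissues_rejected(self):
        with pytest.raises(FeatureError):
            compute_tau({"a": 1.0})

    @given(st.lists(st.floats(0.1, 12.0), min_size=3, max_size=8),
           st.floats(0.2, 4.0))
    def test_permutation_and_log_scale_invariance(self, logs, k):
        tissues = [f"t{i}" for i in range(len(logs))]
        base = {t: 2.0 ** x - 1 for t, x in zip(tissues, logs)}
        tau = compute_tau(base)
        assert 0.0 <= tau <= 1.0
        reordered = dict(reversed(list(base.items())))
        assert compute_tau(reordered) == pytest.approx(tau)
        scaled = {t: 2.0 ** (k * x) - 1 for t, x in zip(tissues, logs)}
        assert compute_tau(scaled) == pytest.approx(tau)


class TestCpgDensity:
    @pytest.mark.parametrize("seq,expected", [
        ("AACGTT", 6.0),          # 1 CpG / (1 C * 1 G) * 6
        ("CGCGCG", 2.0),          # 3 CpG / (3 * 3) * 6
    ])
    def test_worked_examples(self, seq, expected):
        assert compute_cpg_density(seq) == pytest.approx(expected)

    def test_degenerate_denominator_is_missing(self):
        assert compute_cpg_density("AATTAA") is None

    def test_short_sequence_rejected(self):
        with pytest.raises(FeatureError):
            compute_cpg_density("A")

    @given(st.text(alphabet="ACGT", min_size=2, max_size=200))
    def test_matches_dinucleotide_enumeration(self, seq):
        pairs = [seq[i:i + 2] for i in range(len(seq) - 1)]
        n_cg = sum(p == "CG" for p in pairs)
        c, g = seq.count("C"), seq.count("G")
        expected = None if c == 0 or g == 0 else n_cg / (c * g) * len(seq)
        got = compute_cpg_density(seq)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


def _track(rows):
    return ConservationTrack.from_frame(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))


class TestConservationScore:
    def test_constant_track(self):
        t = _track([("X", 0, 100, 1.0)])
        assert conservation_score(t, "X", [(10, 50)]) == 1.0

    def test_mean_of_per_base_scores(self):
        t = _track([("X", 0, 2, 0.0), ("X", 2, 4, 1.0)])
        assert conservation_score(t, "X", [(0, 4)]) == pytest.approx(0.5)

    def test_union_invariance(self):
        t = _track([("X", 0, 2, 0.2), ("X", 2, 4, 0.8)])
        split = conservation_score(t, "X", [(0, 2), (2, 4)])
        merged = conservation_score(t, "X", [(0, 4)])
        assert split == pytest.approx(merged)

    def test_disjoint_intervals_weighted_mean(self):
        t = _track([("X", 0, 10, 0.0), ("X", 100, 104, 1.0)])
        got = conservation_score(t, "X", [(0, 10), (100, 104)])
        assert got == pytest.approx((10 * 0.0 + 4 * 1.0) / 14)

    def test_uncovered_bases_excluded(self):
        t = _track([("X", 0, 2, 1.0)])       # bases 2..9 uncovered
        assert conservation_score(t, "X", [(0, 10)]) == pytest.approx(1.0)

    def test_zero_coverage_raises(self):
        t = _track([("X", 0, 2, 1.0)])
        with pytest.raises(FeatureError):
            conservation_score(t, "X", [(50, 60)])


class TestPositionalFeatures:
    def test_p_arm(self):
        assert positional_features(10, (100, 200), (0, 1000)) == (90, 10)

    def test_q_arm(self):
        assert positional_features(500, (100, 200), (0, 1000)) == (300, 500)

    def test_centromere_boundary(self):
        d_cen, _ = positional_features(200, (100, 200), (0, 1000))
        assert d_cen == 0

    def test_tss_inside_centromere_rejected(self):
        with pytest.raises(FeatureError):
            positional_features(150, (100, 200), (0, 1000))


class TestAssembly:
    def test_exactly_83_columns_no_missingness(self, small_features):
        assert small_features.values.shape[1] == 83
        assert list(small_features.values.columns) == schema.feature_names()
        assert int(small_features.mask.to_numpy().sum()) == 0

    def test_bounded_features_in_range(self, small_features):
        v = small_features.values
        for col in ("exon_score", "promoter_score", "tau", "tau_1", "tau_2"):
            assert v[col].between(0, 1).all()
        assert (v[["dist_centromere", "dist_telomere"]] >= 0).all().all()

    def test_lowest_loeuf_transcript_kept(self, small_universe):
        inputs = small_universe.feature_inputs()
        cons = inputs.constraint.copy()
        gene = cons["gene"].iloc[0]
        rows = cons[cons["gene"] == gene]
        # plant a second transcript with a lower LOEUF and a sentinel mis_z
        extra = rows.iloc[[0]].copy()
        extra["transcript_id"] = "T_planted"
        extra["loeuf"] = rows["loeuf"].min() / 2
        extra["mis_z"] = 42.0
        inputs.constraint = pd.concat([cons, extra], ignore_index=True)
        table = assemble_feature_table(inputs)
        assert table.values.loc[gene, "mis_z"] == pytest.approx(42.0)
        assert table.values.loc[gene, "loeuf"] == pytest.approx(
            float(extra["loeuf"].iloc[0]))

    def test_unexpressed_gene_masks_expression_only(self, small_universe):
        inputs = small_universe.feature_inputs()
        gene = inputs.genes["symbol"].iloc[0]
        inputs.expression = inputs.expression.drop(index=gene)
        table = assemble_feature_table(inputs)
        expr_cols = (schema.load_schema()["expression_adult"]
                     + schema.load_schema()["expression_developmental"])
        assert table.mask.loc[gene, expr_cols].all()
        non_expr = [c for c in table.values.columns if c not in expr_cols]
        assert not table.mask.loc[gene, non_expr].any()

    def test_duplicate_symbols_rejected(self, small_universe):
        inputs = small_universe.feature_inputs()
        inputs.genes = pd.concat([inputs.genes, inputs.genes.iloc[[0]]],
                                 ignore_index=True)
        with pytest.raises(FeatureError, match="duplicate"):
            assemble_feature_table(inputs)

    def test_roundtrip_tsv(self, small_features, tmp_path):
        p = tmp_path / "features.tsv"
        small_features.to_tsv(p)
        from xprio.features import FeatureTable
        back = FeatureTable.from_tsv(p)
        pd.testing.assert_frame_equal(back.values, small_features.values,
                                      check_exact=False, rtol=1e-12)
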