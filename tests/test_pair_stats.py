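import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_expression
from operonwave.pair_stats import (
    classify_supercoiling_pairs,
    delta_lfc_curve,
    enumerate_pairs,
    fold_change_se,
    gene_lp,
    operon_autocorrelation,
    pooled_curve_identity,
    promoter_lp,
    response_vs_lp,
    response_vs_position,
    stratified_delta_curve,
)
from operonwave.synthetic_data import SyntheticConfig, generate_annotation, generate_expression


class TestEnumeratePairs:
    def test_three_gene_operon_combinatorics(self, tiny_annotation):
        expr = make_expression({"a1": 1.0, "a2": 0.5, "a3": 2.0, "b1": 0.0, "b2": 0.0, "c1": 0.0})
        pairs = enumerate_pairs(tiny_annotation, expr)
        op1 = pairs[pairs["operon_id"] == "op1"]
        assert sorted(op1["L_G"]) == [1, 1, 2]
        assert op1.set_index(["gene_i", "gene_j"]).loc[("a1", "a3"), "abs_delta_lfc"] == 1.0

    def test_missing_lfc_drops_pairs_and_counts_them(self, tiny_annotation):
        expr = make_expression({"a1": 1.0, "a3": 2.0, "b1": 0.0, "b2": 0.0})
        pairs = enumerate_pairs(tiny_annotation, expr)
        assert len(pairs[pairs["operon_id"] == "op1"]) == 1
        assert pairs.attrs["n_dropped"] == 2

    def test_total_pair_count_matches_combinatorial_identity(self, default_dataset):
        _, ann, expr = default_dataset
        pairs = enumerate_pairs(ann, expr)
        expected = sum(n * (n - 1) // 2 for n in (len(g) for g in ann.operons.values()))
        assert len(pairs) == expected

    def test_internal_tss_between_uses_intergenic_convention(self, tiny_annotation):
        # op1 has an internal TSS at first_gene_index 3: it lies between (2,3)
        # and (1,3) but not between (1,2)
        expr = make_expression({"a1": 0.0, "a2": 0.0, "a3": 0.0})
        pairs = enumerate_pairs(tiny_annotation, expr).set_index(["gene_i", "gene_j"])
        assert pairs.loc[("a1", "a2"), "n_internal_tss_between"] == 0
        assert pairs.loc[("a2", "a3"), "n_internal_tss_between"] == 1
        assert pairs.loc[("a1", "a3"), "n_internal_tss_between"] == 1


class TestDeltaCurve:
    def test_hand_computed_bin_means(self):
        pairs = pd.DataFrame(
            dict(operon_id="o", gene_i=["a", "b", "c"], gene_j=["x", "y", "z"],
                 L_G=[1, 1, 2], abs_delta_lfc=[0.2, 0.4, 0.6],
                 n_internal_tss_between=0, has_internal_tss_between=False,
                 supercoiling_sensitive=False, condition_id="s")
        )
        curve = delta_lfc_curve(pairs, n_boot=0)
        assert dict(zip(curve.x, curve.mean)) == {1: pytest.approx(0.3), 2: pytest.approx(0.6)}
        assert dict(zip(curve.x, curve.n)) == {1: 2, 2: 1}

    def test_identical_lfcs_give_zero_curve(self, tiny_annotation):
        expr = make_expression({g: 1.5 for g in ("a1", "a2", "a3", "b1", "b2")})
        curve = delta_lfc_curve(enumerate_pairs(tiny_annotation, expr), n_boot=0)
        assert np.allclose(curve.mean, 0)

    def test_permutation_invariance(self, default_dataset):
        _, ann, expr = default_dataset
        pairs = enumerate_pairs(ann, expr)
        shuffled = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = delta_lfc_curve(pairs, n_boot=0)
        b = delta_lfc_curve(shuffled, n_boot=0)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            delta_lfc_curve(pd.DataFrame(columns=["L_G", "abs_delta_lfc"]))


class TestStratification:
    def test_label_flip_swaps_strata_exactly(self, default_dataset):
        _, ann, expr = default_dataset
        pairs = enumerate_pairs(ann, expr)
        from operonwave.null_models import flip_internal_tss_labels

        flipped = flip_internal_tss_labels(pairs, fraction=1.0, seed=0)
        a = stratified_delta_curve(pairs, "internal_tss", n_boot=0)
        b = stratified_delta_curve(flipped, "internal_tss", n_boot=0)
        pd.testing.assert_frame_equal(a.with_stratum.data, b.without_stratum.data)
        pd.testing.assert_frame_equal(a.without_stratum.data, b.with_stratum.data)

    def test_constant_stratifier_rejected(self, default_dataset):
        _, ann, expr = default_dataset
        pairs = enumerate_pairs(ann, expr)
        with pytest.raises(ValueError, match="stratum"):
            stratified_delta_curve(pairs, pd.Series(True, index=pairs.index), n_boot=0)

    def test_pooled_curve_is_weighted_average_of_strata(self, default_dataset):
        _, ann, expr = default_dataset
        pairs = enumerate_pairs(ann, expr)
        strata = stratified_delta_curve(pairs, "internal_tss", max_lg=5, n_boot=0)
        pooled = delta_lfc_curve(pairs[pairs["L_G"] <= 5], n_boot=0)
        merged = pooled_curve_identity(strata)
        joined = pooled.data.merge(merged.data, on="x", suffixes=("_p", "_w"))
        assert np.allclose(joined["mean_p"], joined["mean_w"], atol=1e-12)
        assert (joined["n_p"] == joined["n_w"]).all()

    def test_no_tss_stratum_slope_positive_under_falloff(self):
        cfg = SyntheticConfig(seed=17, n_operons=250, noise_sd=0.05)
        ann = generate_annotation(cfg)
        expr = generate_expression(ann, cfg)
        pairs = enumerate_pairs(ann, expr)
        strata = stratified_delta_curve(pairs, "internal_tss", n_boot=0)
        assert strata.fit_without.slope > 0
        assert strata.fit_without.slope_p_value < 0.05


class TestSupercoilingClassification:
    def test_gene_rule_and_between_rule(self, tiny_annotation):
        ref = pd.DataFrame(
            dict(gene_id=["a1", "a2", "a3"], condition_id="novo",
                 lfc=[0.1, 0.5, 0.5], p_value=[0.01, 0.01, 0.2])
        )
        expr = make_expression({"a1": 0.0, "a2": 0.0, "a3": 0.0})
        pairs = enumerate_pairs(tiny_annotation, expr)
        flagged, sens = classify_supercoiling_pairs(tiny_annotation, ref, pairs)
        assert sens == {"a2"}  # |LFC|>0.4 and p<0.05; a3 fails on p, a1 on LFC
        by = flagged.set_index(["gene_i", "gene_j"])["supercoiling_sensitive"]
        assert bool(by[("a1", "a3")])  # a2 lies between them
        assert bool(by[("a1", "a2")]) and bool(by[("a2", "a3")])

    def test_missing_pvalues_treated_as_nonsensitive(self, tiny_annotation):
        ref = make_expression({"a1": 2.0, "a2": 2.0, "a3": 2.0})  # p_value all NaN
        expr = make_expression({"a1": 0.0, "a2": 0.0, "a3": 0.0})
        pairs = enumerate_pairs(tiny_annotation, expr)
        _, sens = classify_supercoiling_pairs(tiny_annotation, ref, pairs)
        assert sens == set()


class TestPositionalResponse:
    def test_equal_lfcs_give_zero_divergence(self, tiny_annotation):
        expr = make_expression({g: 0.7 for g in ("a1", "a2", "a3", "b1", "b2")})
        curve = response_vs_position(expr, tiny_annotation, mode="delta_to_others")
        assert np.allclose(curve.mean, 0)

    def test_two_gene_operon_hand_case(self, tiny_annotation):
        expr = make_expression({"b1": 1.0, "b2": 3.0})
        curve = response_vs_position(expr, tiny_annotation, mode="delta_to_others")
        assert dict(zip(curve.x, curve.mean)) == {1: pytest.approx(2.0), 2: pytest.approx(2.0)}

    def test_abs_mode_reports_magnitudes(self, tiny_annotation):
        expr = make_expression({"b1": -1.5, "b2": 0.5})
        curve = response_vs_position(expr, tiny_annotation, mode="abs_lfc")
        assert dict(zip(curve.x, curve.mean)) == {1: pytest.approx(1.5), 2: pytest.approx(0.5)}

    def test_falloff_only_divergence_grows_with_position(self):
        cfg = SyntheticConfig(seed=23, n_operons=300, internal_tss_spacing=0,
                              noise_sd=0.02, operon_size_pmf={8: 1.0})
        ann = generate_annotation(cfg)
        expr = generate_expression(ann, cfg)
        curve = response_vs_position(expr, ann, mode="delta_to_others")
        assert curve.mean[-1] > curve.mean[1]  # edge positions diverge most under a pure drift


class TestPromoterDistances:
    def test_lp_conventions(self, tiny_annotation):
        lp = promoter_lp(tiny_annotation, convention="zero").set_index("promoter_id")
        assert lp.loc["P1", "L_P"] == 2  # primary to internal TSS at gene 3
        assert lp.loc["P2", "L_P"] == 0  # no downstream TSS
        lp_rem = promoter_lp(tiny_annotation, convention="remaining").set_index("promoter_id")
        assert lp_rem.loc["P2", "L_P"] == 1 and bool(lp_rem.loc["P2", "open_ended"])

    def test_gene_lp_uses_nearest_flanking_tss(self, tiny_annotation):
        lp = gene_lp(tiny_annotation, convention="zero")
        assert lp["a1"] == 2 and lp["a2"] == 2  # between P1 (gene 1) and P2 (gene 3)
        assert lp["a3"] == 0  # no TSS downstream of gene 3

    def test_single_lp_bin_when_structure_is_uniform(self):
        cfg = SyntheticConfig(seed=2, n_operons=30, operon_size_pmf={8: 1.0}, internal_tss_spacing=4)
        ann = generate_annotation(cfg)
        expr = generate_expression(ann, cfg)
        curve, _ = response_vs_lp(expr, ann)
        assert set(curve.x) == {0, 4}  # regular grid: L_P 4, plus last promoters at 0

    def test_compensated_promoters_show_positive_lp_slope(self):
        cfg = SyntheticConfig(seed=6, n_operons=150, operon_size_pmf={8: 1.0},
                              internal_tss_placement="random", internal_tss_spacing=3,
                              lp_response_slope=0.3, stress_survival_multiplier=1.0)
        ann = generate_annotation(cfg)
        expr = generate_expression(ann, cfg)
        _, fit = response_vs_lp(expr, ann, convention="remaining")
        assert fit.slope > 0 and fit.slope_p_value < 1e-6


class TestFoldChangeSE:
    def test_hand_value(self):
        assert fold_change_se(1, 0.1, 1, 0.1) == pytest.approx(np.sqrt(0.02))

    def test_zero_sems_give_zero(self):
        assert fold_change_se(2.0, 0.0, 3.0, 0.0) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change_se(0.0, 0.1, 1.0, 0.1)

    @given(
        c=st.floats(0.1, 10), a=st.floats(0.5, 4), b=st.floats(0.5, 4),
        sa=st.floats(0, 1), sb=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scaling_both_measurements_leaves_relative_se_invariant(self, c, a, b, sa, sb):
        # rescaling the measurement unit (means and their SEMs together by c)
        # must not change SE relative to the fold change
        se1 = fold_change_se(a, sa, b, sb) / (b / a)
        se2 = fold_change_se(c * a, c * sa, c * b, c * sb) / ((c * b) / (c * a))
        assert se1 == pytest.approx(se2, rel=1e-9)


class TestAutocorrelation:
    def _annotation_series(self, series_list):
        from operonwave.operon_io import GeneRecord, GenomeAnnotation, PromoterRecord

        genes, proms, lfcs = [], [], {}
        pos = 100
        for i, series in enumerate(series_list):
            oid = f"o{i}"
            for p, v in enumerate(series, start=1):
                gid = f"o{i}g{p}"
                genes.append(GeneRecord(gid, oid, p, pos, pos + 50, "+"))
                lfcs[gid] = float(v)
                pos += 100
            proms.append(PromoterRecord(f"P{i}", oid, genes[-len(series)].start_nt - 5, 1))
        ann = GenomeAnnotation(genes=genes, promoters=proms, terminators=[], genome_length_nt=pos + 100)
        return ann, make_expression(lfcs)

    def test_lag_zero_is_exactly_one(self):
        ann, expr = self._annotation_series([[1.0, 2.0, 0.5, 1.5]])
        ac = operon_autocorrelation(expr, ann)
        assert ac.set_index("lag").loc[0, "mean"] == pytest.approx(1.0)

    def test_iid_noise_matches_centering_bias_expectation(self):
        # per-operon mean-centering biases each lag toward -1/(N-1) for iid
        # series of length N (exact expectation, derived from E[x_i x_j])
        rng = np.random.default_rng(3)
        N = 6
        ann, expr = self._annotation_series([rng.normal(size=N) for _ in range(400)])
        ac = operon_autocorrelation(expr, ann, max_lag=3).set_index("lag")
        for k in (1, 2, 3):
            assert ac.loc[k, "mean"] == pytest.approx(-1 / (N - 1), abs=4 * ac.loc[k, "sem"] + 0.02)

    def test_ar_fluctuations_give_decaying_positive_autocorrelation(self):
        rng = np.random.default_rng(4)
        series = []
        for _ in range(300):
            x = np.empty(8)
            x[0] = rng.normal()
            for p in range(1, 8):
                x[p] = 0.7 * x[p - 1] + rng.normal(0, 0.5)
            series.append(x)
        ann, expr = self._annotation_series(series)
        ac = operon_autocorrelation(expr, ann, max_lag=3).set_index("lag")["mean"]
        assert ac[1] > ac[2] > ac[3]
        assert ac[1] > 0.2

    def test_operons_with_unknown_lfc_and_flat_series_are_excluded(self):
        ann, expr = self._annotation_series([[1.0, 2.0, 1.5], [2.0, 2.0, 2.0]])
        expr = expr[expr["gene_id"] != "o0g2"]  # break the first operon
        ac = operon_autocorrelation(expr, ann)
        # first operon has a missing LFC, second has zero variance: nothing remains
        assert ac.empty
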