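import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from kinomescreen import (
    aggregate_arm,
    apply_count_filter,
    classify_by_ntc_envelope,
    gene_summary,
    guide_fold_changes,
    normalize_cpm,
    ntc_envelope,
    representation_coverage,
    temporal_selection_test,
)
from kinomescreen._stats import P_UNDERFLOW_FLOOR, welch_ttest
from kinomescreen.screen import DEPLETED, ENRICHED, LOW_COUNT_EXCLUDED, NEUTRAL, UNANALYZABLE


from _oracles import welch_oracle


class TestCountFilter:
    def test_boundary_39_excluded_40_retained(self):
        raw = pd.DataFrame({"s": [39, 40, 41]}, index=["a", "b", "c"])
        passed = apply_count_filter(raw)
        assert list(passed["s"]) == [False, True, True]

    def test_filter_does_not_alter_counts(self):
        raw = pd.DataFrame({"s": [0, 39, 100]})
        before = raw.copy()
        apply_count_filter(raw)
        pd.testing.assert_frame_equal(raw, before)

    def test_all_zero_sample_warns_everything_excluded(self):
        raw = pd.DataFrame({"dead": [0, 0], "ok": [50, 60]})
        with pytest.warns(UserWarning, match="dead"):
            passed = apply_count_filter(raw)
        assert not passed["dead"].any()


class TestNormalizeCpm:
    def test_formula_on_quarter_of_a_million_total(self):
        raw = pd.DataFrame({"s": [250_000, 750_000]})
        norm = normalize_cpm(raw)
        assert norm.loc[0, "s"] == pytest.approx(250_001.0)

    def test_zero_count_maps_to_pseudocount_floor(self):
        raw = pd.DataFrame({"s": [0, 10]})
        assert normalize_cpm(raw).loc[0, "s"] == pytest.approx(1.0)

    def test_per_sample_conservation(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.integers(0, 1000, size=(50, 3)), columns=list("abc"))
        norm = normalize_cpm(raw)
        np.testing.assert_allclose((norm - 1).sum(axis=0), 1e6, rtol=1e-9)

    @given(scale=hst.integers(min_value=2, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_depth_invariance(self, scale):
        raw = pd.DataFrame({"s": [5, 17, 120, 0]})
        a = normalize_cpm(raw)
        b = normalize_cpm(raw * scale)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_total_sample_named_in_error(self):
        raw = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            normalize_cpm(raw)


class TestAggregateArm:
    def _inputs(self, values, passes, sheet):
        norm = pd.DataFrame({s: [v] for s, v in zip(sheet.sample_ids, values)}, index=["g"])
        mask = pd.DataFrame({s: [p] for s, p in zip(sheet.sample_ids, passes)}, index=["g"])
        return norm, mask

    def test_two_mouse_arm_mean(self, tiny_sheet):
        norm, mask = self._inputs([101.0, 103.0, 50.0, 70.0], [True] * 4, tiny_sheet)
        means, usable = aggregate_arm(norm, mask, tiny_sheet)
        assert means.loc["g", "WT"] == pytest.approx(102.0)
        assert means.loc["g", "CD8KO"] == pytest.approx(60.0)
        assert usable.loc["g"].all()

    def test_guide_failing_one_of_four_uses_remaining_three(self):
        sheet_df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(4)],
                "genotype": ["WT"] * 4,
                "stage": ["late"] * 4,
                "mouse_id": [f"m{i}" for i in range(4)],
                "barcode": ["AAAA", "CCCC", "GGGG", "TTTT"],
            }
        )
        from kinomescreen import SampleSheet

        sheet = SampleSheet(sheet_df)
        norm = pd.DataFrame([[10.0, 20.0, 30.0, 999.0]], index=["g"], columns=sheet.sample_ids)
        mask = pd.DataFrame([[True, True, True, False]], index=["g"], columns=sheet.sample_ids)
        means, usable = aggregate_arm(norm, mask, sheet)
        assert means.loc["g", "WT"] == pytest.approx(20.0)
        assert usable.loc["g", "WT"]
        # failing 3 of 4 -> below the max(2, ceil(4/2)) = 2 pass threshold
        mask.iloc[0, 1:] = False
        _, usable2 = aggregate_arm(norm, mask, sheet)
        assert not usable2.loc["g", "WT"]


def _guide_table(fcs_ntc, fcs_target, mean=100.0):
    """Build a classified-ready guide table from fold changes (means >= min_norm)."""
    rows = []
    for i, fc in enumerate(fcs_ntc):
        rows.append((f"NTC_g{i}", "NTC", True, mean * fc, mean, fc))
    for i, fc in enumerate(fcs_target):
        rows.append((f"T{i}_g1", f"T{i}", False, mean * fc, mean, fc))
    t = pd.DataFrame(
        rows, columns=["guide_id", "gene", "is_ntc", "mean_WT", "mean_CD8KO", "fc"]
    ).set_index("guide_id")
    t["log2fc"] = np.log2(t["fc"])
    t["class"] = NEUTRAL
    return t


class TestFoldChangesAndEnvelope:
    def test_fold_change_and_log2(self, tiny_library):
        means = pd.DataFrame(
            {"WT": [200.0, 100.0, 4.2, 6, 100, 100], "CD8KO": [100.0, 100.0, 3.1, 6, 100, 100]},
            index=tiny_library.guide_ids,
        )
        usable = pd.DataFrame(True, index=means.index, columns=means.columns)
        t = guide_fold_changes(means, usable, tiny_library)
        assert t.loc["KIN1_g1", "fc"] == pytest.approx(2.0)
        assert t.loc["KIN1_g1", "log2fc"] == pytest.approx(1.0)
        assert t.loc["KIN1_g2", "fc"] == pytest.approx(1.0)
        assert t.loc["KIN2_g1", "class"] == UNANALYZABLE  # both arm means < 5
        assert t.loc["KIN2_g2", "class"] == NEUTRAL  # both exactly at/above threshold

    def test_low_count_exclusion_wins_over_fc(self, tiny_library):
        means = pd.DataFrame({"WT": [200.0] * 6, "CD8KO": [100.0] * 6}, index=tiny_library.guide_ids)
        usable = pd.DataFrame(True, index=means.index, columns=means.columns)
        usable.loc["KIN1_g1", "WT"] = False
        t = guide_fold_changes(means, usable, tiny_library)
        assert t.loc["KIN1_g1", "class"] == LOW_COUNT_EXCLUDED
        assert np.isnan(t.loc["KIN1_g1", "fc"])

    def test_envelope_classification_with_strict_inequalities(self):
        t = _guide_table([0.8, 1.0, 1.25], [1.3, 0.7, 1.25, 1.0])
        env = ntc_envelope(t)
        assert env.max_ntc_fc == pytest.approx(1.25)
        assert env.min_ntc_fc == pytest.approx(0.8)
        out = classify_by_ntc_envelope(t, env)
        assert out.loc["T0_g1", "class"] == ENRICHED  # 1.3 > 1.25
        assert out.loc["T1_g1", "class"] == DEPLETED  # 0.7 < 0.8
        assert out.loc["T2_g1", "class"] == NEUTRAL  # ties at the bound stay neutral
        assert out.loc["T3_g1", "class"] == NEUTRAL

    def test_ntc_guides_never_labelled(self):
        t = _guide_table([0.5, 2.0], [3.0])
        out = classify_by_ntc_envelope(t, ntc_envelope(t))
        assert (out.loc[out["is_ntc"], "class"] == NEUTRAL).all()

    def test_too_few_usable_ntcs_rejected(self):
        t = _guide_table([1.0], [1.2])
        with pytest.raises(ValueError, match="NTC"):
            ntc_envelope(t)

    def test_fc_strictly_monotone_in_wt_mean(self, tiny_library):
        base = pd.DataFrame({"WT": [100.0] * 6, "CD8KO": [100.0] * 6}, index=tiny_library.guide_ids)
        usable = pd.DataFrame(True, index=base.index, columns=base.columns)
        fcs = []
        for wt in [100.0, 150.0, 200.0]:
            m = base.copy()
            m.loc["KIN1_g1", "WT"] = wt
            fcs.append(guide_fold_changes(m, usable, tiny_library).loc["KIN1_g1", "fc"])
        assert fcs[0] < fcs[1] < fcs[2]


class TestGeneSummary:
    def test_gene_inside_envelope_has_zero_calls(self):
        t = _guide_table([0.5, 2.0], [1.1, 0.9, 1.0, 1.0])
        t["gene"] = ["NTC", "NTC", "A", "A", "B", "B"]
        out = gene_summary(classify_by_ntc_envelope(t, ntc_envelope(t)))
        assert out.loc["A", "n_depleted"] == 0 and out.loc["A", "n_enriched"] == 0

    def test_depletion_rank_orders_mean_log2fc(self):
        t = _guide_table([0.9, 1.1], [0.2, 0.25, 4.0, 5.0, 1.0, 1.0])
        t["gene"] = ["NTC", "NTC", "down", "down", "up", "up", "flat", "flat"]
        out = gene_summary(classify_by_ntc_envelope(t, ntc_envelope(t)))
        assert out.loc["down", "depletion_rank"] == 1
        assert out.loc["flat", "depletion_rank"] == 2
        assert out.loc["up", "depletion_rank"] == 3
        assert sorted(out["depletion_rank"]) == [1, 2, 3]

    def test_gene_with_no_usable_guides_flagged_unranked(self):
        t = _guide_table([0.9, 1.1], [1.0, 1.0])
        t["gene"] = ["NTC", "NTC", "A", "B"]
        t2 = classify_by_ntc_envelope(t, ntc_envelope(t))
        # classification resets open rows, so apply the exclusion afterwards
        t2.loc["T1_g1", "class"] = LOW_COUNT_EXCLUDED
        out = gene_summary(t2)
        assert bool(out.loc["B", "no_usable_guides"])
        assert np.isnan(out.loc["B", "depletion_rank"])


class TestWelch:
    def test_matches_textbook_oracle_on_random_samples(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 10))
            res = welch_ttest(a, b)
            t, p, df = welch_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.pvalue == pytest.approx(p, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)

    def test_identical_samples_give_t0_p1(self):
        res = welch_ttest([3.0, 3.0, 3.0], [3.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.degenerate

    def test_zero_variance_unequal_means_floors_p(self):
        res = welch_ttest([1.0, 1.0], [2.0, 2.0])
        assert res.pvalue == P_UNDERFLOW_FLOOR and res.degenerate


class TestTemporal:
    def _screen(self):
        from kinomescreen import ScreenSimConfig, simulate_screen

        cfg = ScreenSimConfig(
            seed=42, n_genes=30, n_ntc=10, selection={"G0001": (-1.0, 0.0)}, depth_per_sample=1e6
        )
        return simulate_screen(cfg)

    def test_welch_values_match_oracle(self, tiny_library, tiny_sheet):
        # early/late toy built directly on normalized counts
        import kinomescreen as ks

        lib, sheet, counts, _ = self._screen()
        norm = normalize_cpm(counts)
        res = temporal_selection_test(norm, sheet, lib, "G0002", "WT")
        early = norm.loc[[f"G0002_g{k}" for k in range(1, 5)], sheet.samples_in("WT", "early")]
        late = norm.loc[[f"G0002_g{k}" for k in range(1, 5)], sheet.samples_in("WT", "late")]
        t, p, df = welch_oracle(early.to_numpy().ravel(), late.to_numpy().ravel())
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_two_sided == pytest.approx(p, abs=1e-10)

    def test_planted_gene_declines_in_wt_only(self):
        lib, sheet, counts, _ = self._screen()
        norm = normalize_cpm(counts)
        wt = temporal_selection_test(norm, sheet, lib, "G0001", "WT")
        ko = temporal_selection_test(norm, sheet, lib, "G0001", "CD8KO")
        assert wt.p_two_sided < 0.05 and wt.direction == -1
        assert ko.p_two_sided > 0.05

    def test_unknown_gene_rejected(self):
        lib, sheet, counts, _ = self._screen()
        with pytest.raises(ValueError, match="not in library"):
            temporal_selection_test(normalize_cpm(counts), sheet, lib, "NOPE", "WT")


class TestCoverage:
    @pytest.mark.parametrize(
        "cells, mice, guides, expected",
        [(200_000, 12, 3000, 800), (200_000, 11, 3000, 733), (200_000, 0, 3000, 0)],
    )
    def test_floor_coverage(self, cells, mice, guides, expected):
        assert representation_coverage(cells, mice, guides) == expected

    def test_zero_guides_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            representation_coverage(1000, 2, 0)
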