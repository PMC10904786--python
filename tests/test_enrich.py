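import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import exact_rank_sum_p
from lnpscreen.enrich import (
    bh_adjust,
    build_normalized_table,
    classify_tropism,
    enrichment_analysis,
    heatmap_matrix,
    normalize_to_pool,
    normalize_within_sample,
    wilcoxon_rank_sum,
)
from lnpscreen.quantify import CountTable
from lnpscreen.simulate import (
    ORGANS,
    BiodistributionModel,
    simulate_screen,
)


def count_table_from_truth(truth):
    return CountTable(
        counts=truth.counts,
        samples=truth.samples,
        qc=pd.DataFrame({"sample_id": truth.samples["sample_id"]}),
    )


class TestNormalizeWithinSample:
    def test_plain_fractions_with_zero_pseudocount(self):
        counts = pd.DataFrame({"s": [10, 30, 60]}, index=["a", "b", "c"])
        frac = normalize_within_sample(counts, pseudocount=0.0)
        np.testing.assert_allclose(frac["s"], [0.1, 0.3, 0.6])

    def test_pseudocount_hand_arithmetic(self):
        counts = pd.DataFrame({"s": [0, 0, 100]}, index=["a", "b", "c"])
        frac = normalize_within_sample(counts, pseudocount=0.5)
        np.testing.assert_allclose(frac["s"], np.array([0.5, 0.5, 100.5]) / 101.5)

    def test_single_barcode_fraction_one(self):
        counts = pd.DataFrame({"s": [7]}, index=["a"])
        assert normalize_within_sample(counts)["s"].iloc[0] == 1.0

    def test_fractions_sum_to_one_per_sample(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 6)))
        frac = normalize_within_sample(counts)
        np.testing.assert_allclose(frac.sum(axis=0), 1.0, atol=1e-9)

    def test_all_zero_sample_excluded_with_warning(self):
        counts = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.warns(UserWarning, match="empty"):
            frac = normalize_within_sample(counts)
        assert list(frac.columns) == ["ok"]


class TestNormalizeToPool:
    def test_elementwise_ratio(self):
        tissue = pd.Series([0.1, 0.3, 0.6], index=["a", "b", "c"])
        pool = pd.Series([0.2, 0.2, 0.6], index=["a", "b", "c"])
        np.testing.assert_allclose(normalize_to_pool(tissue, pool), [0.5, 1.5, 1.0])

    def test_identity_when_tissue_equals_pool(self):
        frac = pd.Series([0.25, 0.75], index=["a", "b"])
        acc = normalize_to_pool(frac, frac)
        np.testing.assert_allclose(acc, 1.0)
        np.testing.assert_allclose(np.log2(acc), 0.0)

    def test_zero_pool_fraction_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            normalize_to_pool(pd.Series([1.0]), pd.Series([0.0]))

    def test_planted_lung_accumulation_closed_form(self, whitelist96):
        # 8-fold lung barcode at pool fraction 1/96:
        # normalized accumulation ~ (8/103)/(1/96) = 7.456
        medians = []
        for seed in range(5):
            model = BiodistributionModel.neutral(
                whitelist96, mouse_sd=0.0, molecules_per_organ=200_000, seed=seed
            ).with_planted_tropism(["bc010"], "lung", 8.0)
            truth = simulate_screen(model, whitelist96, n_mice=5, organs=["lung"],
                                    naked_reference=False)
            table = build_normalized_table(count_table_from_truth(truth), pseudocount=0.5)
            medians.append(table.organ_matrix("lung").loc["bc010"].median())
        assert np.mean(medians) == pytest.approx((8 / 103) / (1 / 96), rel=0.03)


class TestWilcoxon:
    def test_three_vs_three_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_five_vs_five_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(2 / 252)

    def test_identical_multisets_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0, abs=0.05)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        p = wilcoxon_rank_sum(x, y)
        assert 0 < p < 0.01

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_matches_full_enumeration_tie_free(self, data):
        n = data.draw(st.integers(1, 5))
        m = data.draw(st.integers(1, min(5, 10 - n)))
        values = data.draw(
            st.lists(
                st.integers(-50, 50), min_size=n + m, max_size=n + m, unique=True
            )
        )
        x, y = values[:n], values[n:]
        assert wilcoxon_rank_sum(x, y) == pytest.approx(exact_rank_sum_p(x, y))


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_monotone_floor(self):
        np.testing.assert_allclose(bh_adjust([0.5, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_monotone_and_permutation_invariant(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), q[perm])


def _screen_table(whitelist, planted=(), fold=8.0, seed=0, molecules=20_000,
                  mouse_sd=0.3, n_mice=5, organs=ORGANS):
    model = BiodistributionModel.neutral(
        whitelist, mouse_sd=mouse_sd, molecules_per_organ=molecules, seed=seed
    )
    if planted:
        model = model.with_planted_tropism(list(planted), "lung", fold)
    truth = simulate_screen(model, whitelist, n_mice=n_mice, organs=organs)
    return build_normalized_table(count_table_from_truth(truth))


class TestEnrichmentAnalysis:
    def test_one_mouse_errors(self, whitelist96):
        table = _screen_table(whitelist96, n_mice=1)
        with pytest.raises(ValueError, match="mice"):
            enrichment_analysis(table)

    def test_planted_barcodes_called_enriched(self, whitelist96):
        planted = ["bc005", "bc050"]
        table = _screen_table(whitelist96, planted=planted, seed=2)
        records = enrichment_analysis(table)
        lung = records[records["organ"] == "lung"].set_index("barcode_id")
        for b in planted:
            assert lung.loc[b, "log2fc"] > 1
            assert lung.loc[b, "q_value"] < 0.05
            assert lung.loc[b, "call"] == "enriched"

    def test_null_type_one_error_controlled(self, whitelist96):
        hits = total = 0
        for seed in range(3):
            records = enrichment_analysis(_screen_table(whitelist96, seed=seed))
            hits += (records["q_value"] < 0.05).sum()
            total += len(records)
        assert hits / total <= 0.05

    def test_naked_barcode_excluded_from_records(self, whitelist96):
        table = _screen_table(whitelist96)
        # whitelist96 has no naked entry; simulate one via naked_ids
        table.naked_ids = ("bc001",)
        records = enrichment_analysis(table)
        assert "bc001" not in set(records["barcode_id"])

    def test_vs_pool_replicates_requires_three_pools(self, whitelist96):
        table = _screen_table(whitelist96)
        with pytest.raises(ValueError, match="one_vs_rest"):
            enrichment_analysis(table, comparison="vs_pool_replicates")

    def test_vs_pool_replicates_runs_with_three_pools(self, whitelist96):
        model = BiodistributionModel.neutral(
            whitelist96, mouse_sd=0.1, molecules_per_organ=5000, seed=4
        ).with_planted_tropism(["bc009"], "lung", 8.0)
        truth = simulate_screen(model, whitelist96, n_mice=5, organs=["lung", "liver"],
                                pool_replicates=3)
        table = build_normalized_table(count_table_from_truth(truth))
        records = enrichment_analysis(table, comparison="vs_pool_replicates")
        lung = records[records["organ"] == "lung"].set_index("barcode_id")
        assert lung.loc["bc009", "p_value"] < 0.05

    def test_record_schema_and_ranges(self, whitelist96):
        records = enrichment_analysis(_screen_table(whitelist96, seed=6))
        assert set(records.columns) == {
            "barcode_id", "organ", "log2fc", "p_value", "q_value", "call"
        }
        assert records["p_value"].between(0, 1).all()
        assert records["q_value"].between(0, 1).all()
        assert (records["q_value"] >= records["p_value"] - 1e-12).all()
        assert len(records) == 96 * 5


class TestClassifyTropism:
    @staticmethod
    def _records(rows):
        return pd.DataFrame(
            rows, columns=["barcode_id", "organ", "log2fc", "p_value", "q_value", "call"]
        )

    def test_lung_only_enrichment_is_candidate(self):
        rows = [("b1", o, (2.0 if o == "lung" else 0.0), 0.001, 0.001, "x") for o in ORGANS]
        assert classify_tropism(self._records(rows)) == ["b1"]

    def test_lung_and_liver_enrichment_excluded(self):
        rows = [
            ("b1", o, (2.0 if o in ("lung", "liver") else 0.0), 0.001, 0.001, "x")
            for o in ORGANS
        ]
        assert classify_tropism(self._records(rows)) == []

    def test_no_candidates_is_empty_not_error(self):
        rows = [("b1", o, 0.0, 0.9, 0.9, "neutral") for o in ORGANS]
        assert classify_tropism(self._records(rows)) == []

    def test_missing_organ_errors(self):
        rows = [("b1", "lung", 2.0, 0.001, 0.001, "x")]
        with pytest.raises(KeyError, match="liver"):
            classify_tropism(self._records(rows))

    @given(
        fc=st.floats(0.5, 3.0),
        q=st.floats(0.001, 0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_target_organ_enrichment_monotone_in_thresholds(self, fc, q):
        """The per-organ enriched set shrinks under stricter thresholds; the
        combined candidate rule is monotone only once off-target calls are
        held fixed (see the counterexample below)."""
        rng = np.random.default_rng(17)
        rows = [
            (f"b{i}", o, rng.normal(0, 2), 0.0, rng.random() * 0.2, "x")
            for i in range(10)
            for o in ORGANS
        ]
        rec = self._records(rows)

        def lung_enriched(fc_t, q_t):
            sub = rec[rec["organ"] == "lung"]
            return set(
                sub.loc[(sub["log2fc"] >= fc_t) & (sub["q_value"] <= q_t), "barcode_id"]
            )

        base = lung_enriched(fc, q)
        assert lung_enriched(fc + 0.5, q) <= base
        assert lung_enriched(fc, q / 2) <= base
        # candidates are monotone whenever no off-target call flips
        off = rec[rec["organ"].isin(["liver", "spleen"])]
        flips = ((off["q_value"] > q / 2) & (off["q_value"] <= q)).any()
        if not flips:
            assert set(classify_tropism(rec, fc_threshold=fc, q_threshold=q / 2)) <= set(
                classify_tropism(rec, fc_threshold=fc, q_threshold=q)
            )

    def test_candidate_rule_not_monotone_in_q_counterexample(self):
        # stricter q de-enriches the liver record, *adding* a lung candidate
        rows = [("b1", o, 0.0, 0.9, 0.9, "x") for o in ORGANS if o not in ("lung", "liver")]
        rows += [("b1", "lung", 3.0, 0.001, 0.001, "x"), ("b1", "liver", 3.0, 0.02, 0.02, "x")]
        rec = self._records(rows)
        assert classify_tropism(rec, q_threshold=0.05) == []
        assert classify_tropism(rec, q_threshold=0.01) == ["b1"]


class TestHeatmap:
    def test_neutral_matrix_near_one(self, whitelist96):
        table = _screen_table(whitelist96, mouse_sd=0.0, molecules=100_000, seed=8)
        mat = heatmap_matrix(table)
        assert list(mat.columns) == list(ORGANS)
        assert np.abs(mat.to_numpy() - 1.0).mean() < 0.1

    def test_row_scaling_maps_max_to_one(self, whitelist96):
        mat = heatmap_matrix(_screen_table(whitelist96, seed=9), row_scale=True)
        np.testing.assert_allclose(mat.max(axis=1), 1.0)

    def test_planted_row_max_in_lung(self, whitelist96):
        table = _screen_table(whitelist96, planted=["bc033"], seed=10)
        mat = heatmap_matrix(table)
        assert mat.loc["bc033"].idxmax() == "lung"
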