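"""Synthetic-cohort generator: ground-truth algebra, sampling laws, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symptomnet import (
    GroundTruthModel,
    default_model,
    generate_cohort,
    ground_truth_from_partials,
    make_ground_truth,
    sample_items,
)
from symptomnet.cohort import ISI_LABELS, calibrate_threshold_shift


class TestMakeGroundTruth:
    def test_zero_density_gives_empty_graph(self):
        m = make_ground_truth(5, density=0.0, weight_range=(0.1, 0.4), seed=3)
        assert np.all(m.partials_true == 0)

    def test_same_seed_reproduces_model(self):
        a = make_ground_truth(7, 0.5, (0.1, 0.4), seed=42)
        b = make_ground_truth(7, 0.5, (0.1, 0.4), seed=42)
        np.testing.assert_array_equal(a.precision, b.precision)

    def test_realized_partials_match_request_via_inversion_formula(self):
        """Oracle: recompute partials as -K_ij/sqrt(K_ii K_jj) from the precision."""
        m = make_ground_truth(7, 0.5, (0.1, 0.4), seed=7)
        K = m.precision
        d = np.sqrt(np.diag(K))
        oracle = -K / np.outer(d, d)
        np.fill_diagonal(oracle, 0.0)
        np.testing.assert_allclose(m.partials_true, oracle, atol=1e-12)
        iu = np.triu_indices(7, k=1)
        nz = oracle[iu][oracle[iu] != 0]
        assert nz.size == round(0.5 * 21)
        assert np.all((np.abs(nz) >= 0.1 - 0.01) & (np.abs(nz) <= 0.4 + 0.01))

    def test_precision_positive_definite(self):
        m = make_ground_truth(10, 0.3, (-0.3, 0.3), seed=1)
        assert np.linalg.eigvalsh(m.precision).min() > 0

    def test_infeasible_combination_rejected(self):
        with pytest.raises(ValueError, match="infeasible|positive definite"):
            make_ground_truth(10, 1.0, (0.5, 0.6), seed=0)

    @pytest.mark.parametrize("bad", [(-1.2, 0.3), (0.3, 1.0)])
    def test_weight_range_bounds_validated(self, bad):
        with pytest.raises(ValueError):
            make_ground_truth(5, 0.5, bad, seed=0)


class TestGroundTruthModel:
    def test_non_pd_precision_rejected(self):
        K = np.array([[1.0, 0.99], [0.99, 0.5]])  # eigmin < 0
        with pytest.raises(ValueError, match="positive definite"):
            GroundTruthModel(["a", "b"], K, {"a": [0.0], "b": [0.0]})

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ground_truth_from_partials(
                np.zeros((2, 2)), ["a", "b"],
                {"a": [0.5, 0.5], "b": [0.0]},
            )

    def test_json_round_trip(self):
        m = default_model(include_qol=True)
        back = GroundTruthModel.from_json(m.to_json())
        np.testing.assert_allclose(back.precision, m.precision)
        assert back.node_labels == m.node_labels
        assert back.item_thresholds["QOL"] is None


class TestSampleItems:
    def test_identity_precision_gives_independent_items(self):
        m = ground_truth_from_partials(np.zeros((7, 7)), list(ISI_LABELS))
        items = sample_items(m, 5000, seed=0)
        corr = items.corr(method="spearman").to_numpy()
        off = corr[np.triu_indices(7, k=1)]
        assert np.all(np.abs(off) < 0.05)

    def test_single_median_cut_gives_half_frequency(self):
        m = ground_truth_from_partials(
            np.zeros((2, 2)), ["a", "b"], {"a": np.array([0.0]), "b": np.array([0.0])}
        )
        items = sample_items(m, 20000, seed=1)
        assert abs(items["a"].mean() - 0.5) < 0.02  # categories are 0/1

    def test_connected_items_correlate_more_than_disconnected(self, chain_model):
        items = sample_items(chain_model, 5000, seed=2)
        corr = items.corr(method="spearman").to_numpy()
        true = chain_model.partials_true
        iu = np.triu_indices(7, k=1)
        edge = true[iu] != 0
        assert corr[iu][edge].mean() > corr[iu][~edge].mean()

    def test_marginal_law_matches_orthant_probabilities(self, reference_model):
        """Empirical category frequencies vs the normal-orthant probabilities."""
        n = 50_000
        items = sample_items(reference_model, n, seed=3)
        for lab in ISI_LABELS:
            thr = reference_model.item_thresholds[lab]
            cdf = np.concatenate([[0.0], stats.norm.cdf(thr), [1.0]])
            expected = np.diff(cdf)
            observed = np.bincount(items[lab], minlength=5) / n
            tv = 0.5 * np.abs(observed - expected).sum()
            assert tv < 0.01

    def test_determinism(self, reference_model):
        a = sample_items(reference_model, 100, seed=9)
        b = sample_items(reference_model, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestGenerateCohort:
    def test_prevalence_close_to_target_at_large_n(self):
        df = generate_cohort(10_000, target_prevalence=0.189, seed=5)
        prev = (df["isi_total"] >= 8).mean()
        assert abs(prev - 0.189) < 0.02

    def test_isi_total_is_item_sum(self, small_cohort):
        items = small_cohort[[f"isi{i}" for i in range(1, 8)]]
        assert (items.sum(axis=1) == small_cohort["isi_total"]).all()

    def test_ranges_and_no_missing(self, small_cohort):
        df = small_cohort
        assert not df.isna().any().any()
        for i in range(1, 8):
            assert df[f"isi{i}"].between(0, 4).all()
        assert df["phq9_total"].between(0, 27).all()
        assert df["gad7_total"].between(0, 21).all()
        assert df["fatigue"].between(0, 10).all()
        assert df["qol"].between(2, 10).all()

    def test_zero_qol_coefficient_breaks_linkage(self):
        m = default_model()
        m.outcome_spec["qol"]["coef"] = 0.0
        df = generate_cohort(10_000, model=m, seed=6)
        r = np.corrcoef(df["isi_total"], df["qol"])[0, 1]
        assert abs(r) < 0.05

    def test_same_seed_byte_identical(self, tmp_path):
        a = generate_cohort(300, seed=13)
        b = generate_cohort(300, seed=13)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_unattainable_prevalence_reports_range(self):
        thresholds = {lab: np.array([-3.0, -2.5, -2.0, -1.5]) for lab in ISI_LABELS}
        m = ground_truth_from_partials(np.zeros((7, 7)), list(ISI_LABELS), thresholds)
        # with cuts that deep, nearly everyone scores >= 8 at any feasible shift
        with pytest.raises(ValueError, match="achievable range"):
            calibrate_threshold_shift(m, 1e-6, seed=0)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(100, target_prevalence=1.5, seed=0)
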