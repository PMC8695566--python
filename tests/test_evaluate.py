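"""Evaluation-battery tests: metrics, splits, nulls, dendrogram, external."""

import numpy as np
import pandas as pd
import pytest

from icimeth.diffstats import beta_to_m
from icimeth.evaluate import (
    apply_external, biomarker_separation, combined_model_eval,
    dendrogram_adjacency_test, expected_random_f1, feature_matrix, metrics,
    permutation_null, per_type_eval, repeated_split_eval,
)
from icimeth.simulate import SimConfig, generate_cohort, generate_external_cohort


def brute_force_metrics(y_true, y_pred):
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return f1, mcc


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 0, 1, 1])
        m = metrics(y, y, scores=y.astype(float))
        assert (m["f1"], m["mcc"], m["auc"]) == (1.0, 1.0, 1.0)

    def test_hand_contingency(self):
        # TP=3, FP=1, FN=2, TN=4
        y_true = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        m = metrics(y_true, y_pred)
        assert m["f1"] == pytest.approx(2 * 3 / (2 * 3 + 1 + 2))  # 2/3
        assert m["mcc"] == pytest.approx((3 * 4 - 1 * 2) / np.sqrt(4 * 5 * 5 * 6))

    def test_all_positive_on_balanced_truth_zero_mcc(self):
        y_true = np.array([0, 1] * 10)
        m = metrics(y_true, np.ones(20, dtype=int))
        assert m["mcc"] == 0.0

    def test_single_class_truth_no_auc(self):
        m = metrics(np.ones(5), np.ones(5), scores=np.arange(5.0))
        assert m["auc"] is None

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_bruteforce_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            n = rng.integers(4, 30)
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            m = metrics(y_true, y_pred)
            f1, mcc = brute_force_metrics(y_true, y_pred)
            assert m["f1"] == pytest.approx(f1, abs=1e-12)
            assert m["mcc"] == pytest.approx(mcc, abs=1e-12)


@pytest.fixture(scope="module")
def tiny_eval_setup():
    cfg = SimConfig(n_types=3, cases_per_type=70, n_probes=400, n_informative=60,
                    n_signature=40, n_genes=200, seed=77)
    bundle = generate_cohort(cfg)
    from icimeth.labeling import assign_labels, compute_tgfb_score, compute_tmb
    from icimeth.pathways import default_pathway
    tmb = compute_tmb(bundle.mutations, bundle.case_ids)
    labels = assign_labels(tmb, compute_tgfb_score(bundle.counts, default_pathway())).labels
    X = feature_matrix(bundle, bundle.informative_probes)
    return bundle, X, labels


class TestRepeatedSplitEval:
    def test_deterministic_under_seed(self, tiny_eval_setup):
        _, X, y = tiny_eval_setup
        r1 = repeated_split_eval(X, y, n_splits=3, seed=5, lam=13.0)
        r2 = repeated_split_eval(X, y, n_splits=3, seed=5, lam=13.0)
        pd.testing.assert_frame_equal(r1.per_split, r2.per_split)

    def test_single_split_on_strong_signal(self, tiny_eval_setup):
        _, X, y = tiny_eval_setup
        rep = repeated_split_eval(X, y, n_splits=1, seed=1, lam=13.0)
        row = rep.per_split.iloc[0]
        assert row["auc"] > 0.9

    def test_extra_predictions_evaluated(self, tiny_eval_setup):
        _, X, y = tiny_eval_setup
        fixed = pd.Series(y, index=X.index)  # oracle predictor
        rep = repeated_split_eval(X, y, n_splits=2, seed=2, lam=13.0,
                                  extra_predictions={"oracle": fixed})
        oracle = rep.per_split[rep.per_split["model"] == "oracle"]
        assert (oracle["f1"] == 1.0).all() and (oracle["mcc"] == 1.0).all()

    def test_paired_tests_self_comparison(self, tiny_eval_setup):
        _, X, y = tiny_eval_setup
        rep = repeated_split_eval(X, y, n_splits=4, seed=3, lam=13.0,
                                  extra_predictions={"oracle": pd.Series(y, index=X.index)})
        res = rep.paired_tests("SVM", "SVM", "f1")
        assert res["wilcoxon_p"] == 1.0 and res["mean_diff"] == 0.0

    def test_aggregate_ci_ordering(self, tiny_eval_setup):
        _, X, y = tiny_eval_setup
        rep = repeated_split_eval(X, y, n_splits=4, seed=4, lam=13.0)
        agg = rep.aggregate()
        assert (agg["ci_low"] <= agg["mean"]).all()
        assert (agg["mean"] <= agg["ci_high"]).all()


class TestNulls:
    def test_permutation_null_centered_at_zero(self, tiny_eval_setup):
        _, X, y = tiny_eval_setup
        table = permutation_null(X, y, n_perm=15, seed=0, lam=13.0)
        assert abs(table["model_mcc"].mean()) < 0.1
        assert abs(table["total_random_mcc"].mean()) < 0.1

    def test_total_random_f1_matches_closed_form(self, tiny_eval_setup):
        _, X, y = tiny_eval_setup
        table = permutation_null(X, y, n_perm=15, seed=1, lam=13.0)
        expected = expected_random_f1(float(np.mean(y)))
        assert table["total_random_f1"].mean() == pytest.approx(expected, abs=0.05)


class TestBiomarkersAndPerType:
    def test_planted_biomarkers_separate(self, tiny_eval_setup):
        bundle, X, y = tiny_eval_setup
        rep = repeated_split_eval(X, y, n_splits=10, seed=6, lam=13.0)
        table = biomarker_separation(bundle, rep).set_index("biomarker")
        for marker in ("PDCD1", "CTLA4", "CD8_fraction", "MSI_proportion"):
            assert table.loc[marker, "p"] < 0.01
            assert table.loc[marker, "mean_positive"] > table.loc[marker, "mean_negative"]

    def test_per_type_perfect_predictions_give_rho_one(self, tiny_eval_setup):
        bundle, X, y = tiny_eval_setup
        rep = repeated_split_eval(X, y, n_splits=3, seed=7, lam=13.0,
                                  extra_predictions={"oracle": pd.Series(y, index=X.index)})
        _, rho = per_type_eval(rep, bundle.clinical, y, model="oracle",
                               min_pos=2, min_pos_frac=0.01)
        vals = rho["spearman_rho"].dropna()
        assert len(vals) and np.allclose(vals, 1.0)


class TestDendrogram:
    def test_two_pure_blocks_tiny_p(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 30 + [1] * 30)
        m = pd.DataFrame(
            labels[None, :] * 5.0 + rng.normal(0, 0.2, size=(20, 60)),
            columns=[f"c{i}" for i in range(60)],
        )
        out = dendrogram_adjacency_test(m, pd.Series(labels, index=m.columns))
        assert out["p"] < 1e-8
        # off-diagonal transitions at most 1 per boundary crossing
        assert out["table"][0, 1] + out["table"][1, 0] <= 2

    def test_random_labels_not_significant(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(20, 80)),
                         columns=[f"c{i}" for i in range(80)])
        labels = pd.Series(rng.integers(0, 2, 80), index=m.columns)
        out = dendrogram_adjacency_test(m, labels)
        assert out["p"] > 0.001

    def test_uniform_labels_undefined(self):
        m = pd.DataFrame(np.random.default_rng(2).normal(size=(5, 10)),
                         columns=[f"c{i}" for i in range(10)])
        out = dendrogram_adjacency_test(m, pd.Series(1, index=m.columns))
        assert np.isnan(out["p"])


class TestExternal:
    def test_probe_intersection_and_transfer(self, tiny_eval_setup):
        bundle, X, y = tiny_eval_setup
        cfg = SimConfig(n_types=3, cases_per_type=70, n_probes=400, n_informative=60,
                        n_signature=40, n_genes=200, seed=77)
        external = generate_external_cohort(cfg, probe_overlap_fraction=0.8)
        out = apply_external(bundle.informative_probes, bundle, y, external,
                             lam=13.0, seed=0)
        assert 0 < out["n_shared_probes"] <= len(bundle.informative_probes)
        assert out["metrics"]["auc"] > 0.75

    def test_shuffled_external_labels_zero_mcc(self, tiny_eval_setup):
        bundle, X, y = tiny_eval_setup
        cfg = SimConfig(n_types=3, cases_per_type=70, n_probes=400, n_informative=60,
                        n_signature=40, n_genes=200, seed=77)
        external = generate_external_cohort(cfg, probe_overlap_fraction=0.8)
        rng = np.random.default_rng(3)
        external.clinical["response"] = rng.permutation(
            external.clinical["response"].to_numpy())
        out = apply_external(bundle.informative_probes, bundle, y, external,
                             lam=13.0, seed=0)
        assert abs(out["metrics"]["mcc"]) < 0.25

    def test_empty_intersection_error(self, tiny_eval_setup):
        bundle, _, y = tiny_eval_setup
        cfg = SimConfig(n_types=3, cases_per_type=70, n_probes=400, n_informative=60,
                        n_signature=40, n_genes=200, seed=78)
        external = generate_external_cohort(cfg, probe_overlap_fraction=0.9)
        external.beta.index = pd.Index([f"zz{i}" for i in range(len(external.beta))])
        with pytest.raises(ValueError):
            apply_external(bundle.informative_probes, bundle, y, external)


class TestCombined:
    def test_duplicated_block_leaves_performance_unchanged(self, tiny_eval_setup):
        # duplicating every (standardized) feature doubles squared distances
        # AND the kernel scale, so the SVM is exactly unchanged
        _, X, y = tiny_eval_setup
        X2 = pd.concat(
            [X, X.add_suffix("_copy")], axis=1
        )
        r1 = repeated_split_eval(X, y, n_splits=3, seed=8, lam=13.0, standardize=True)
        r2 = repeated_split_eval(X2, y, n_splits=3, seed=8, lam=13.0, standardize=True)
        pd.testing.assert_frame_equal(r1.per_split, r2.per_split, atol=1e-10)

    def test_feature_collision_rejected(self, tiny_eval_setup):
        bundle, _, y = tiny_eval_setup
        original = bundle.counts.index
        clashing = list(bundle.informative_probes[:5])
        bundle.counts.index = pd.Index(
            clashing + list(original[5:]), name="gene")
        try:
            with pytest.raises(ValueError):
                combined_model_eval(bundle, bundle.informative_probes,
                                    clashing, y, n_splits=1, lam=13.0)
        finally:
            bundle.counts.index = original
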