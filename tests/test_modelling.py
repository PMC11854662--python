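import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from petww.imaging_io import FeatureTable
from petww.modelling import (
    cv_report,
    forward_select,
    loocv,
    median_class_labels,
    svm_fit,
    zscore,
)


def make_table(X, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(np.asarray(X, dtype=float), columns=names)
    df.insert(0, "scanner", "A")
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(df))])
    return FeatureTable(df)


class TestZscore:
    def test_hand_computed_column(self):
        t = zscore(make_table(np.array([[1.0], [2.0], [3.0]])))
        np.testing.assert_allclose(t.features()["f0"].to_numpy(), [-1, 0, 1], atol=1e-12)

    def test_idempotence(self, rng):
        t = zscore(make_table(rng.standard_normal((20, 3))))
        t2 = zscore(t)
        np.testing.assert_allclose(
            t2.features().to_numpy(), t.features().to_numpy(), atol=1e-12
        )

    def test_constant_column_rejected(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="f1"):
            zscore(make_table(X))

    def test_moments(self, rng):
        t = zscore(make_table(rng.uniform(0, 50, (30, 4))))
        f = t.features()
        np.testing.assert_allclose(f.mean().to_numpy(), 0, atol=1e-10)
        np.testing.assert_allclose(f.std(ddof=1).to_numpy(), 1, atol=1e-10)


class TestMedianClass:
    def test_balanced_split_distinct_values(self):
        labels = median_class_labels(np.arange(1.0, 39.0))
        assert abs(labels.sum() - (~labels).sum()) <= 1

    def test_tie_at_median_goes_early(self):
        labels = median_class_labels([1.0, 2.0, 2.0, 5.0])
        assert list(labels) == [True, True, True, False]


class TestForwardSelect:
    def test_perfect_predictor_found_first(self, rng):
        X = rng.standard_normal((30, 6))
        y = 3.0 * X[:, 4] + 1.0
        sel, scores = forward_select(make_table(X), y, "LR", max_k=2)
        assert sel[0] == "f4"
        assert scores[0] == pytest.approx(1.0, abs=1e-10)

    def test_two_signal_features_recovered(self, rng):
        X = rng.standard_normal((200, 10))
        y = 2.0 * X[:, 1] + 1.0 * X[:, 7] + rng.normal(0, 0.1, 200)
        sel, _ = forward_select(make_table(X), y, "LR", max_k=2)
        assert set(sel) == {"f1", "f7"}

    def test_greedy_matches_exhaustive_pairs_mostly(self):
        """On low-correlation designs the greedy pair usually equals the
        exhaustive-search best pair (>= 80% of simulations)."""
        hits = 0
        n_sim = 30
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((60, 8))
            beta = np.zeros(8)
            beta[rng.choice(8, 2, replace=False)] = rng.uniform(0.8, 1.5, 2)
            y = X @ beta + rng.normal(0, 0.5, 60)
            t = make_table(X)
            sel, _ = forward_select(t, y, "LR", max_k=2)
            best_pair, best_r2 = None, -np.inf
            for pair in itertools.combinations(range(8), 2):
                A = np.column_stack([np.ones(60), X[:, pair]])
                beta_h, *_ = np.linalg.lstsq(A, y, rcond=None)
                r2 = 1 - np.sum((y - A @ beta_h) ** 2) / np.sum((y - y.mean()) ** 2)
                if r2 > best_r2:
                    best_pair, best_r2 = {f"f{i}" for i in pair}, r2
            hits += set(sel) == best_pair
        assert hits >= 0.8 * n_sim

    def test_nestedness(self, rng):
        X = rng.standard_normal((40, 9))
        y = X[:, 0] + 0.5 * X[:, 3] + rng.normal(0, 1, 40)
        sel3, _ = forward_select(make_table(X), y, "LR", max_k=3)
        sel4, _ = forward_select(make_table(X), y, "LR", max_k=4)
        assert sel4[:3] == sel3

    def test_too_few_subjects_rejected(self, rng):
        X = rng.standard_normal((4, 6))
        with pytest.raises(ValueError, match="subjects"):
            forward_select(make_table(X), np.arange(4.0), "LR", max_k=4)


class TestLoocvLR:
    def test_intercept_only_closed_form(self):
        """With no features the held-out prediction for subject i is the
        mean of the other K-1 outcomes."""
        y = np.array([3.0, 7.0, 11.0, 20.0, 4.0])
        n = len(y)
        expected = np.array([(y.sum() - y[i]) / (n - 1) for i in range(n)])
        res = loocv(make_table(np.arange(5.0)[:, None]), y, [], "LR")
        np.testing.assert_allclose(res["predictions"]["y_pred"], expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_press_hat_matrix_oracle(self, seed):
        """LR held-out residuals equal e_i / (1 - h_ii) from the full-data
        hat matrix (z-scoring per fold is affine, so predictions agree)."""
        rng = np.random.default_rng(seed)
        n, p = 25, 3
        X = rng.standard_normal((n, p))
        y = X @ rng.uniform(-2, 2, p) + rng.normal(0, 1.0, n)
        res = loocv(make_table(X), y, [f"f{i}" for i in range(p)], "LR")
        A = np.column_stack([np.ones(n), X])
        H = A @ np.linalg.solve(A.T @ A, A.T)
        e = y - H @ y
        press = e / (1 - np.diag(H))
        np.testing.assert_allclose(
            y - res["predictions"]["y_pred"].to_numpy(), press, atol=1e-8
        )

    def test_heldout_r2_can_be_negative(self, rng):
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)  # pure noise
        res = loocv(make_table(X), y, ["f0", "f1"], "LR")
        assert res["test"]["r2"] < 0.5  # and typically < 0; contract allows it


class TestSvm:
    def test_xor_separated_by_rbf(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([0, 0, 1, 1])
        clf = svm_fit(X, y, C=100.0, gamma=5.0)
        assert np.array_equal(clf.predict(X), y)

    def test_label_swap_flips_predictions(self, rng):
        X = rng.standard_normal((30, 2))
        y = (X[:, 0] > 0).astype(int)
        a = svm_fit(X, y).predict(X)
        b = svm_fit(X, 1 - y).predict(X)
        assert np.array_equal(a, 1 - b)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            svm_fit(rng.standard_normal((10, 2)), np.zeros(10))

    def test_separable_loocv_near_perfect(self, rng):
        X = np.vstack([rng.normal(-4, 0.3, (20, 2)), rng.normal(4, 0.3, (20, 2))])
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        res = loocv(make_table(X), y, ["f0", "f1"], "SVM")
        assert res["test"]["accuracy"] >= 0.95
        assert res["test"]["auc"] >= 0.95

    def test_two_gaussian_auc_close_to_closed_form(self):
        """1D classes N(0,1) vs N(2,1): AUC -> Phi(2/sqrt(2)) ~ 0.921."""
        target = norm.cdf(np.sqrt(2.0))
        aucs = []
        for s in range(6):
            rng = np.random.default_rng(s)
            X = np.r_[rng.normal(0, 1, 50), rng.normal(2, 1, 50)][:, None]
            y = np.r_[np.ones(50), np.zeros(50)].astype(int)  # early = low TTT side
            res = loocv(make_table(X), y, ["f0"], "SVM")
            aucs.append(res["test"]["auc"])
        assert abs(np.mean(aucs) - target) < 0.05


class TestCvReport:
    def test_nested_selection_and_determinism(self, rng):
        X = rng.standard_normal((30, 8))
        y = 2 * X[:, 2] + rng.normal(0, 1, 30)
        t = make_table(X)
        rep1 = cv_report(t, y, "LR", max_k=4)
        rep2 = cv_report(t, y, "LR", max_k=4)
        assert rep1.selected == rep2.selected
        for k in range(1, 5):
            assert rep1.per_k[k]["features"] == rep1.selected[:k]
            assert rep1.per_k[k]["test"] == rep2.per_k[k]["test"]

    def test_metrics_frame_shape(self, rng):
        X = rng.standard_normal((25, 6))
        y = (X[:, 0] > 0).astype(int)
        rep = cv_report(make_table(X), y, "SVM", max_k=2)
        frame = rep.metrics_frame()
        assert set(frame["split"]) == {"train", "test"}
        assert set(frame["k"]) == {1, 2}
        assert {"accuracy", "precision", "sensitivity", "auc"} <= set(frame["metric"])

    def test_honest_nested_mode_runs(self, rng):
        X = rng.standard_normal((20, 6))
        y = X[:, 1] + rng.normal(0, 0.5, 20)
        rep = cv_report(make_table(X), y, "LR", max_k=2, nested=True)
        assert "rmse" in rep.per_k[2]["test"]
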