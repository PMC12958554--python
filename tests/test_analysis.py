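"""Representation analytics: features, clustering, MMD screen, cosine, metrics."""

import numpy as np
import pandas as pd
import pytest

from nucmim.analysis import (
    balance_group,
    change_vectors,
    classification_report,
    cluster_reps,
    cosine_matrix,
    eval_clustering,
    flag_significant,
    genewise_pcc,
    high_low_groups,
    mmd_rbf,
    morph_features,
    rbf_gamma_from_control,
    regression_report,
    run_perturbation_screen,
)
from nucmim.synthetic import SyntheticScreen, generate_perturbation_screen


class TestMorphFeatures:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 15:25] = True  # 20 x 10
        img = mask.astype(float)
        area, aspect, _ = morph_features(img, mask=mask)
        assert area == 200
        assert aspect == pytest.approx(2.0, rel=0.02)

    def test_disk_aspect_ratio_near_one(self):
        yy, xx = np.mgrid[0:41, 0:41]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        _, aspect, _ = morph_features(mask.astype(float), mask=mask)
        assert aspect == pytest.approx(1.0, rel=0.05)

    def test_mean_intensity_on_native_scale(self):
        img = np.full((10, 10), 1234.0)
        mask = np.ones((10, 10), dtype=bool)
        _, _, mean_int = morph_features(img, mask=mask)
        assert mean_int == 1234.0

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            morph_features(np.ones((5, 5)), mask=np.zeros((5, 5), dtype=bool))


class TestHighLowGroups:
    def test_published_five_percent_sizes(self, rng):
        x = rng.normal(size=1000)
        high, low = high_low_groups(x, 5.0)
        assert len(high) == 50 and len(low) == 50
        assert x[high].min() >= x[low].max()

    def test_all_equal_values_stable_order(self):
        high, low = high_low_groups(np.ones(100), 10.0)
        np.testing.assert_array_equal(low, np.arange(10))
        np.testing.assert_array_equal(high, np.arange(90, 100))

    def test_linked_feature_separates_groups(self, rng):
        area = rng.uniform(100, 600, 400)
        expr = 2.0 * area + rng.normal(0, 10, 400)
        high, low = high_low_groups(expr, 5.0)
        assert area[high].mean() > area[low].mean()


class TestClustering:
    @pytest.mark.parametrize("method", ["agglomerative", "kmeans", "gmm", "spectral",
                                        "knn_spectral", "leiden"])
    def test_separable_blobs_recovered(self, rng, method):
        a = rng.normal(0, 0.3, size=(60, 4))
        b = rng.normal(5, 0.3, size=(60, 4))
        X = np.vstack([a, b])
        truth = np.repeat([0, 1], 60)
        labels = cluster_reps(X, method, k=2, resolution=0.05, seed=0)
        assert eval_clustering(labels, truth)["f1"] == 1.0

    def test_single_blob_split_is_chance_level(self, rng):
        X = rng.normal(0, 1, size=(200, 4))
        truth = np.repeat([0, 1], 100)  # arbitrary half-split truth
        labels = cluster_reps(X, "kmeans", k=2, seed=0)
        assert eval_clustering(labels, truth)["accuracy"] < 0.7

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(50, 3))
        np.testing.assert_array_equal(
            cluster_reps(X, "gmm", 2, seed=3), cluster_reps(X, "gmm", 2, seed=3)
        )

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_reps(rng.normal(size=(10, 2)), "dbscan")


class TestEvalClustering:
    def test_swapped_ids_still_perfect(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([1, 1, 0, 0])
        metrics = eval_clustering(pred, truth)
        assert all(v == 1.0 for v in metrics.values())

    def test_known_confusion_closed_form(self):
        # TP=40, FP=10, FN=10, TN=40 after alignment
        truth = np.array([1] * 50 + [0] * 50)
        pred = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        metrics = eval_clustering(pred, truth)
        assert metrics == {
            "precision": pytest.approx(0.8),
            "accuracy": pytest.approx(0.8),
            "recall": pytest.approx(0.8),
            "f1": pytest.approx(0.8),
        }

    def test_random_labels_near_half_accuracy(self, rng):
        truth = np.repeat([0, 1], 500)
        pred = rng.integers(0, 2, 1000)
        assert eval_clustering(pred, truth)["accuracy"] == pytest.approx(0.5, abs=0.06)


class TestMMD:
    def test_gamma_from_single_pair(self):
        control = np.array([[0.0, 0.0], [1.0, 1.0]])  # distance sqrt(2)
        assert rbf_gamma_from_control(control) == pytest.approx(0.5)

    def test_gamma_scale_equivariance(self, rng):
        X = rng.normal(size=(30, 4))
        g1 = rbf_gamma_from_control(X)
        g2 = rbf_gamma_from_control(3.0 * X)
        assert g2 == pytest.approx(g1 / 9.0, rel=1e-6)

    def test_identical_multisets_give_exact_zero(self, rng):
        A = rng.normal(size=(20, 3))
        assert mmd_rbf(A, A.copy(), gamma=0.5) == 0.0

    def test_small_case_matches_double_loop_oracle(self, rng):
        A = rng.normal(size=(3, 1))
        B = rng.normal(size=(4, 1))
        gamma = 0.7

        def k(x, y):
            return np.exp(-gamma * np.sum((x - y) ** 2))

        kaa = np.mean([[k(a, b) for b in A] for a in A])
        kbb = np.mean([[k(a, b) for b in B] for a in B])
        kab = np.mean([[k(a, b) for b in B] for a in A])
        assert mmd_rbf(A, B, gamma) == pytest.approx(kaa + kbb - 2 * kab, abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        A = rng.normal(size=(15, 4))
        B = rng.normal(1.0, 1.0, size=(12, 4))
        g = rbf_gamma_from_control(A)
        assert mmd_rbf(A, B, g) == pytest.approx(mmd_rbf(B, A, g), abs=1e-12)
        assert mmd_rbf(A, B, g) >= 0

    def test_shifted_gaussian_beats_permutation_null(self, rng):
        n = 200
        A = rng.normal(0, 1, size=(n, 2))
        B = rng.normal(3, 1, size=(n, 2))  # 3 SD mean gap
        g = rbf_gamma_from_control(A)
        observed = mmd_rbf(A, B, g)
        pooled = np.vstack([A, B])
        null = []
        for _ in range(50):
            perm = rng.permutation(2 * n)
            null.append(mmd_rbf(pooled[perm[:n]], pooled[perm[n:]], g))
        assert observed > np.percentile(null, 95)

    def test_monotone_in_effect_size(self, rng):
        n = 200
        A = np.random.default_rng(0).normal(size=(n, 4))
        g = rbf_gamma_from_control(A)
        mmds = []
        for delta in (0, 1, 2, 3):
            B = np.random.default_rng(1).normal(size=(n, 4))
            B[:, 0] += delta
            mmds.append(mmd_rbf(A, B, g))
        assert all(a <= b for a, b in zip(mmds, mmds[1:]))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mmd_rbf(rng.normal(size=(5, 2)), rng.normal(size=(5, 3)), 1.0)


class TestBalance:
    def test_identity_at_target_size(self, rng):
        X = rng.normal(size=(10, 3))
        np.testing.assert_array_equal(balance_group(X, 10, seed=0), X)

    def test_upsample_closure(self, rng):
        X = rng.normal(size=(10, 2))
        up = balance_group(X, 100, seed=1)
        assert up.shape == (100, 2)
        rows = {tuple(r) for r in np.round(X, 9)}
        assert all(tuple(r) in rows for r in np.round(up, 9))

    def test_downsample_without_replacement(self, rng):
        X = np.arange(50, dtype=float).reshape(50, 1)
        down = balance_group(X, 20, seed=2)
        assert len(np.unique(down)) == 20

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(7, 2))
        np.testing.assert_array_equal(balance_group(X, 30, 9), balance_group(X, 30, 9))


class TestIQRRule:
    def test_single_outlier_flagged(self):
        rule, flags = flag_significant([1, 1, 1, 1, 1, 10])
        assert flags.tolist() == [False] * 5 + [True]
        q1, q3 = np.percentile([1, 1, 1, 1, 1, 10], [25, 75])
        assert rule.threshold == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_all_equal_flags_nothing(self):
        _, flags = flag_significant([2.0] * 8)
        assert not flags.any()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            flag_significant([1, 2, 3])

    def test_planted_screen_recovery_single_seed(self):
        screen = SyntheticScreen.random(50, 5, 3.0, 32, seed=7)
        control, groups = generate_perturbation_screen(screen, 200, 32, seed=7,
                                                       n_control=2000)
        result = run_perturbation_screen(groups, control, seed=7)
        flagged = set(result.table.loc[result.table["significant"], "group_id"])
        recall = len(flagged & screen.planted_significant) / 5
        assert recall >= 0.8
        assert len(flagged - screen.planted_significant) <= 3


class TestCosine:
    def test_scale_invariance(self):
        C = cosine_matrix({"a": np.array([1.0, 0.0]), "b": np.array([2.0, 0.0])})
        assert C.loc["a", "b"] == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        C = cosine_matrix({"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])})
        assert C.loc["a", "b"] == pytest.approx(0.0)

    def test_hand_case(self):
        C = cosine_matrix({"a": np.array([1.0, 0.0]), "b": np.array([1.0, 1.0])})
        assert C.loc["a", "b"] == pytest.approx(0.7071, abs=1e-4)

    def test_zero_vector_reported_missing_not_zero(self):
        C = cosine_matrix({"a": np.zeros(3), "b": np.ones(3)})
        assert np.isnan(C.loc["a", "b"]) and np.isnan(C.loc["a", "a"])
        assert C.loc["b", "b"] == 1.0

    def test_matrix_properties(self, rng):
        vecs = {f"g{i}": rng.normal(size=6) for i in range(5)}
        C = cosine_matrix(vecs).to_numpy()
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.all(C >= -1 - 1e-12) and np.all(C <= 1 + 1e-12)

    def test_change_vectors_subtract_control_mean(self, rng):
        control = rng.normal(size=(50, 4))
        group = control + np.array([2.0, 0, 0, 0])
        v = change_vectors({"g": group}, control)["g"]
        np.testing.assert_allclose(v, [2, 0, 0, 0], atol=1e-10)


def _closed_form_classification(scores, truth):
    """Independent metric oracle built from first-principles formulas."""
    n, C = scores.shape
    pred = scores.argmax(axis=1)
    acc = (pred == truth).mean()
    precs, recs, f1s, aucs = [], [], [], []
    for c in range(C):
        tp = np.sum((pred == c) & (truth == c))
        fp = np.sum((pred == c) & (truth != c))
        fn = np.sum((pred != c) & (truth == c))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precs.append(p)
        recs.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
        pos = scores[truth == c, c]
        neg = scores[truth != c, c]
        if len(pos) and len(neg):
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            aucs.append(wins / (len(pos) * len(neg)))
    # multiclass MCC (covariance form) and Cohen's kappa
    conf = np.zeros((C, C))
    for t, p in zip(truth, pred):
        conf[t, p] += 1
    t_sum = conf.sum(axis=1)
    p_sum = conf.sum(axis=0)
    cov_tp = conf.trace() * n - t_sum @ p_sum
    denom = np.sqrt(n**2 - (p_sum @ p_sum)) * np.sqrt(n**2 - (t_sum @ t_sum))
    mcc = cov_tp / denom if denom else 0.0
    pe = (t_sum @ p_sum) / n**2
    po = conf.trace() / n
    kappa = (po - pe) / (1 - pe) if pe != 1 else 0.0
    return {
        "accuracy": acc,
        "f1_macro": np.mean(f1s),
        "precision_macro": np.mean(precs),
        "recall_macro": np.mean(recs),
        "auroc_macro": np.mean(aucs),
        "mcc": mcc,
        "cohen_kappa": kappa,
    }


class TestClassificationReport:
    def test_perfect_predictions(self):
        truth = np.array([0, 1, 2, 0, 1, 2])
        scores = np.eye(3)[truth]
        m = classification_report(scores, truth)
        for v in m.values():
            assert v == pytest.approx(1.0)

    def test_random_scores_near_chance(self, rng):
        truth = np.repeat([0, 1], 400)
        scores = rng.random((800, 2))
        scores /= scores.sum(axis=1, keepdims=True)
        m = classification_report(scores, truth)
        assert m["auroc_macro"] == pytest.approx(0.5, abs=0.07)
        assert m["cohen_kappa"] == pytest.approx(0.0, abs=0.1)
        assert m["mcc"] == pytest.approx(0.0, abs=0.1)

    def test_matches_closed_form_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n, C = int(rng.integers(12, 40)), int(rng.integers(2, 5))
            truth = rng.integers(0, C, n)
            while len(np.unique(truth)) < C:
                truth = rng.integers(0, C, n)
            scores = rng.random((n, C))
            scores /= scores.sum(axis=1, keepdims=True)
            got = classification_report(scores, truth)
            want = _closed_form_classification(scores, truth)
            for key, v in want.items():
                assert got[key] == pytest.approx(v, abs=1e-9), key


def _closed_form_regression(p, t, tau=0.5):
    n = len(t)
    mp, mt = p.mean(), t.mean()
    cov = ((p - mp) * (t - mt)).mean()
    pcc = cov / (p.std() * t.std())
    rp = np.argsort(np.argsort(p)).astype(float)
    rt = np.argsort(np.argsort(t)).astype(float)
    scc = np.corrcoef(rp, rt)[0, 1]
    ss_res = np.sum((t - p) ** 2)
    ss_tot = np.sum((t - mt) ** 2)
    r2 = 1 - ss_res / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    ccc = 2 * cov / (p.var() + t.var() + (mp - mt) ** 2)
    ev = 1 - np.var(t - p) / np.var(t)
    mse = np.mean((t - p) ** 2)
    mae = np.mean(np.abs(t - p))
    ql = np.mean(np.where(t >= p, tau * (t - p), (1 - tau) * (p - t)))
    return {"pcc": pcc, "scc": scc, "r2": r2, "adjusted_r2": adj, "ccc": ccc,
            "explained_variance": ev, "rmse": np.sqrt(mse), "mse": mse,
            "mae": mae, "quantile_loss": ql}


class TestRegressionReport:
    def test_identity_prediction(self, rng):
        t = rng.normal(size=20)
        m = regression_report(t, t)
        assert m["pcc"] == pytest.approx(1.0)
        assert m["scc"] == pytest.approx(1.0)
        assert m["r2"] == pytest.approx(1.0)
        assert m["ccc"] == pytest.approx(1.0)
        assert m["rmse"] == 0.0 and m["mse"] == 0.0 and m["mae"] == 0.0
        assert m["quantile_loss"] == 0.0

    def test_constant_shift_keeps_pcc_but_penalizes_ccc(self, rng):
        t = rng.normal(size=30)
        m = regression_report(t + 2.0, t)
        assert m["pcc"] == pytest.approx(1.0)
        assert m["ccc"] < 1.0

    def test_matches_textbook_formulas_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 25))
            t = rng.normal(size=n)
            p = t * rng.uniform(0.3, 1.5) + rng.normal(0, 0.5, n)
            got = regression_report(p, t)
            want = _closed_form_regression(p, t)
            for key, v in want.items():
                assert got[key] == pytest.approx(v, abs=1e-9), key

    def test_genewise_pcc_per_column(self, rng):
        t = rng.normal(size=(40, 3))
        p = t.copy()
        p[:, 1] = -t[:, 1]  # perfectly anti-correlated column
        p[:, 2] = rng.normal(size=40)
        r = genewise_pcc(p, t)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)
        assert abs(r[2]) < 0.5

    def test_zero_variance_truth_column_reported_missing(self, rng):
        t = np.ones((10, 2))
        t[:, 1] = rng.normal(size=10)
        r = genewise_pcc(rng.normal(size=(10, 2)), t)
        assert np.isnan(r[0]) and not np.isnan(r[1])
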