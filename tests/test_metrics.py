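"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from gmdecon import metrics as M


def rand_simplex(rng, n, ct):
    y = rng.random((n, ct))
    return y / y.sum(axis=1, keepdims=True)


class TestPerSpotMetrics:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        y = rand_simplex(rng, 8, 5)
        out = M.per_spot_metrics(y, y)
        assert np.allclose(out["pcc"], 1.0)
        assert np.allclose(out["ssim"], 1.0)
        assert np.allclose(out["rmse"], 0.0)
        assert np.allclose(out["jsd"], 0.0, atol=1e-12)

    def test_disjoint_one_hot_forced_values(self):
        pred = np.array([[1.0, 0.0]])
        truth = np.array([[0.0, 1.0]])
        out = M.per_spot_metrics(pred, truth)
        assert abs(out["jsd"][0] - 1.0) < 1e-12
        # rmse = sqrt(mean over the two types of squared diffs) = sqrt((1+1)/2)
        assert abs(out["rmse"][0] - 1.0) < 1e-12
        assert abs(out["pcc"][0] + 1.0) < 1e-12

    def test_constant_vector_pcc_is_zero(self):
        out = M.per_spot_metrics(np.array([[0.25, 0.25, 0.25, 0.25]]),
                                 np.array([[0.7, 0.1, 0.1, 0.1]]))
        assert out["pcc"][0] == 0.0

    def test_matches_scalar_oracles_on_random_input(self):
        rng = np.random.default_rng(1)
        pred, truth = rand_simplex(rng, 10, 5), rand_simplex(rng, 10, 5)
        out = M.per_spot_metrics(pred, truth)
        # min-max scaling for the SSIM oracle
        ps = (pred - pred.min()) / (pred.max() - pred.min())
        ts = (truth - truth.min()) / (truth.max() - truth.min())
        for i in range(10):
            x, y = pred[i], truth[i]
            pcc = np.sum((x - x.mean()) * (y - y.mean())) / (
                np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2)))
            assert abs(out["pcc"][i] - pcc) < 1e-9
            assert abs(out["rmse"][i] - np.sqrt(np.mean((x - y) ** 2))) < 1e-9
            # scipy's jensenshannon returns the distance (sqrt of the divergence)
            assert abs(out["jsd"][i] - jensenshannon(x, y, base=2) ** 2) < 1e-9
            a, b = ps[i], ts[i]
            c1, c2 = 0.01 ** 2, 0.03 ** 2
            ssim = ((2 * a.mean() * b.mean() + c1)
                    * (2 * np.mean((a - a.mean()) * (b - b.mean())) + c2)) / (
                (a.mean() ** 2 + b.mean() ** 2 + c1) * (a.var() + b.var() + c2))
            assert abs(out["ssim"][i] - ssim) < 1e-9

    def test_jsd_is_symmetric(self):
        rng = np.random.default_rng(2)
        p, q = rand_simplex(rng, 1, 6)[0], rand_simplex(rng, 1, 6)[0]
        assert abs(M.jensen_shannon_divergence(p, q)
                   - M.jensen_shannon_divergence(q, p)) < 1e-12


class TestAccuracyScore:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["PCC", "SSIM", "RMSE", "JSD"],
                            index=[f"m{i}" for i in range(len(rows))])

    def test_all_best_method_scores_one(self):
        t = self._table([[0.9, 0.9, 0.1, 0.1], [0.5, 0.5, 0.3, 0.3], [0.2, 0.2, 0.6, 0.6]])
        s = M.accuracy_score(t)
        assert s["m0"] == 1.0

    def test_all_worst_among_three_scores_one_third(self):
        t = self._table([[0.9, 0.9, 0.1, 0.1], [0.5, 0.5, 0.3, 0.3], [0.2, 0.2, 0.6, 0.6]])
        s = M.accuracy_score(t)
        # hand rank arithmetic: rank 3 in all four metrics -> (3 - 3 + 1)/3 = 1/3
        assert abs(s["m2"] - 1.0 / 3.0) < 1e-12

    def test_identical_rows_share_score(self):
        t = self._table([[0.5, 0.5, 0.3, 0.3], [0.5, 0.5, 0.3, 0.3], [0.9, 0.9, 0.1, 0.1]])
        s = M.accuracy_score(t)
        assert s["m0"] == s["m1"]

    def test_invariant_to_monotone_transform_of_columns(self):
        rng = np.random.default_rng(3)
        t = self._table(rng.random((5, 4)))
        t2 = t.copy()
        t2["PCC"] = np.exp(t2["PCC"] * 3)     # order-preserving
        t2["RMSE"] = t2["RMSE"] ** 3
        assert np.allclose(M.accuracy_score(t), M.accuracy_score(t2))

    def test_missing_cell_rejected(self):
        t = self._table([[0.9, 0.9, 0.1, 0.1], [0.5, np.nan, 0.3, 0.3]])
        with pytest.raises(ValueError):
            M.accuracy_score(t)


class TestEntropyAndFractions:
    def test_spot_entropy_forced_values_and_oracle(self):
        assert M.spot_entropy(np.array([[1.0, 0.0, 0.0]]))[0] == 0.0
        ct = 5
        assert abs(M.spot_entropy(np.full((1, ct), 1 / ct))[0] - np.log(ct)) < 1e-12
        rng = np.random.default_rng(4)
        y = rand_simplex(rng, 10, 5)
        ent = M.spot_entropy(y)
        for i in range(10):
            assert abs(ent[i] + sum(v * np.log(v) for v in y[i] if v > 0)) < 1e-9

    def test_sample_level_perfect_and_oracle(self):
        rng = np.random.default_rng(5)
        y = rand_simplex(rng, 12, 4)
        res = M.sample_level_eval(y, y)
        assert abs(res.r2 - 1.0) < 1e-12 and res.rmse == 0.0
        assert abs(res.pred_fractions.sum() - 1.0) < 1e-12
        pred, truth = rand_simplex(rng, 12, 4), rand_simplex(rng, 12, 4)
        res = M.sample_level_eval(pred, truth)
        # normal-equations oracle for r^2 of true on predicted fractions
        x, yv = pred.mean(0), truth.mean(0)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ yv)
        resid = yv - X @ beta
        r2 = 1 - resid @ resid / np.sum((yv - yv.mean()) ** 2)
        assert abs(res.r2 - r2) < 1e-9
        assert abs(res.rmse - np.sqrt(np.mean((x - yv) ** 2))) < 1e-12

    def test_single_type_r2_rejected(self):
        with pytest.raises(ValueError):
            M.sample_level_eval(np.ones((5, 1)), np.ones((5, 1)))


class TestClustering:
    def test_exact_label_recovery(self):
        rng = np.random.default_rng(6)
        centers = np.eye(3)
        labels = np.repeat([0, 1, 2], 30)
        pred = centers[labels] + rng.normal(0, 0.01, (90, 3))
        res = M.cluster_domains(pred, K=3, true_labels=labels, seed=0)
        assert res.ari == 1.0 and res.purity == 1.0

    def test_random_labels_near_zero_ari(self):
        rng = np.random.default_rng(7)
        truth = rng.integers(0, 4, 800)
        pred = rand_simplex(rng, 800, 5)  # structureless predictions
        res = M.cluster_domains(pred, K=4, true_labels=truth, seed=0)
        assert abs(res.ari) < 0.05

    def test_purity_hand_contingency(self):
        # contingency [[5, 0], [1, 4]] -> (5 + 4) / 10
        pred = np.array([0] * 5 + [1] * 5)
        truth = np.array([0] * 5 + [0] + [1] * 4)
        assert M.purity_score(pred, truth) == 0.9

    def test_k_bounds_rejected(self):
        with pytest.raises(ValueError):
            M.cluster_domains(np.ones((3, 2)), K=4)


class TestPlatformMixing:
    def test_separated_blobs_score_high(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.5, (40, 3))
        b = rng.normal(10, 0.5, (40, 3))
        assert M.platform_mixing_score(a, b) > 0.5

    def test_interleaved_sets_score_low(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((60, 3))
        assert M.platform_mixing_score(pts[::2], pts[1::2]) <= 0.05

    def test_single_point_group_rejected(self):
        with pytest.raises(ValueError):
            M.platform_mixing_score(np.zeros((1, 3)), np.ones((5, 3)))


def test_drop_excluded_types_renormalizes():
    pred = np.array([[0.5, 0.3, 0.2], [0.0, 0.5, 0.5]])
    truth = np.array([[0.4, 0.6, 0.0], [1.0, 0.0, 0.0]])
    p, t, names = M.drop_excluded_types(pred, truth, ["a", "b", "c"], ["a"])
    assert names == ["b", "c"]
    assert np.allclose(t.sum(axis=1), 1.0)
    assert p.shape == (1, 2)  # second spot's truth mass was all excluded
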