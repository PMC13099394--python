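"""Decoding tests: complex normalization, feature encodings, the linear
SVM against a quadratic-programming oracle, the Mann-Whitney AUC, strict
between-session cross-validation and its no-leakage property."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from hrdelay.decode import (
    ComplexPatternSVC,
    auc,
    cross_session_decode,
    encode_features,
    normalize_vectors,
)
from hrdelay.inference import _direction_auc


class TestNormalization:
    def test_single_run_normalizes_to_unit(self):
        z = np.array([[3.0 - 4.0j]])
        out, _, kept = normalize_vectors(z)
        assert kept.all()
        assert out[0, 0] == pytest.approx(1 + 0j)

    def test_two_run_worked_example(self):
        # runs (2, 0) and (0, 2): mean (1, 1); by-hand complex division
        z = np.array([[2 + 0j], [0 + 2j]])
        out, _, _ = normalize_vectors(z)
        assert out[0, 0] == pytest.approx((2 + 0j) / (1 + 1j))
        assert out[1, 0] == pytest.approx((2j) / (1 + 1j))
        assert out[0, 0] == pytest.approx(1 - 1j)
        assert out[1, 0] == pytest.approx(1 + 1j)
        assert out.mean(axis=0)[0] == pytest.approx(1 + 0j)

    def test_test_vector_equal_to_train_mean(self, rng):
        tr = rng.standard_normal((6, 4)) + 1j * rng.standard_normal((6, 4))
        te = tr.mean(axis=0, keepdims=True)
        _, te_n, _ = normalize_vectors(tr, te)
        assert np.allclose(te_n, 1 + 0j)

    def test_train_mean_exactly_unit(self, rng):
        tr = rng.standard_normal((8, 5)) + 1j * rng.standard_normal((8, 5))
        out, _, _ = normalize_vectors(tr)
        assert np.allclose(out.mean(axis=0), 1 + 0j, atol=1e-12)

    def test_zero_mean_voxel_dropped(self):
        z = np.array([[1 + 0j, 1 + 1j], [-1 + 0j, 1 - 1j]])
        out, _, kept = normalize_vectors(z)
        assert kept.tolist() == [False, True]
        assert out.shape == (2, 1)


class TestEncodings:
    def test_unit_vector_encodings(self):
        z = np.array([[1 + 0j]])
        assert encode_features(z, "delay")[0, 0] == 0.0
        assert encode_features(z, "amplitude")[0, 0] == 1.0
        assert np.allclose(encode_features(z, "both"), [[1.0, 0.0]])

    def test_both_encoding_has_2p_columns(self, rng):
        z = rng.standard_normal((4, 3)) + 1j * rng.standard_normal((4, 3))
        F = encode_features(z, "both")
        assert F.shape == (4, 6)
        assert np.allclose(F[:, :3], z.real)
        assert np.allclose(F[:, 3:], z.imag)

    def test_matches_polar_decomposition_oracle(self, rng):
        z = rng.standard_normal((10, 7)) + 1j * rng.standard_normal((10, 7))
        ang = encode_features(z, "delay")
        mod = encode_features(z, "amplitude")
        # oracle: independent polar decomposition
        assert np.allclose(mod * np.exp(1j * ang), z)
        assert (ang > -np.pi).all() and (ang <= np.pi).all()

    def test_unknown_encoding_rejected(self):
        with pytest.raises(ValueError, match="encoding"):
            encode_features(np.ones((2, 2), complex), "phase")


class TestAUC:
    def test_exhaustive_pair_count_example(self):
        # pos {3, 1}, neg {2}: one winning pair of two
        scores = np.array([3.0, 1.0, 2.0])
        labels = np.array([1, 1, 0])
        assert auc(scores, labels, pos_label=1) == pytest.approx(0.5)

    def test_perfect_ordering(self):
        assert auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.zeros(6), np.array([0, 1] * 3)) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.arange(4.0), np.ones(4))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=20),
        st.data(),
    )
    def test_pair_count_oracle_and_monotone_invariance(self, raw_scores, data):
        n = len(raw_scores)
        labels = np.array(
            data.draw(
                st.lists(st.booleans(), min_size=n, max_size=n).filter(
                    lambda l: 0 < sum(l) < n
                )
            )
        )
        scores = np.asarray(raw_scores, dtype=float)
        # oracle: exhaustive pair count with half-credit ties
        pos, neg = scores[labels], scores[~labels]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (len(pos) * len(neg))
        got = auc(scores, labels, pos_label=True)
        assert got == pytest.approx(expected)
        # independent library oracle
        assert got == pytest.approx(roc_auc_score(labels, scores))
        # invariance under a strictly increasing transform
        transformed = np.exp(scores / 3.0) + scores
        assert auc(transformed, labels, pos_label=True) == pytest.approx(expected)


class TestComplexPatternSVC:
    def test_separable_toy_perfect_training_accuracy(self):
        z = np.array([[0.5 + 0j], [0.6 + 0j], [1.5 + 0j], [1.6 + 0j]])
        y = np.array([0, 0, 1, 1])
        clf = ComplexPatternSVC(encoding="amplitude").fit(z, y)
        assert (clf.predict(z) == y).all()
        assert clf.score(z, y) == 1.0

    def test_contradictory_duplicates_near_zero_decision(self):
        z = np.array([[1 + 1j, 2 - 1j]] * 4)
        y = np.array([0, 1, 0, 1])
        # identical samples with opposite labels: no separation possible
        with pytest.raises(ValueError, match="zero variance"):
            ComplexPatternSVC(encoding="both").fit(z, y)

    def test_boundary_matches_qp_oracle(self, rng):
        # 2D toy in the 'both' encoding of one voxel; oracle: dual QP by SLSQP
        from scipy.optimize import minimize

        X = np.array([[0.0, 0.0], [0.2, 1.0], [2.0, 0.1], [2.2, 1.1],
                      [0.1, 2.0], [2.1, 2.2]])
        y = np.array([-1, -1, 1, 1, -1, 1])
        z = (X[:, 0] + 1j * X[:, 1])[:, None]

        clf = ComplexPatternSVC(encoding="both", C=1.0).fit(z, (y > 0).astype(int))
        # reconstruct w in the z-scored feature space
        w = clf.svm_.coef_.ravel()

        Fz = (encode_features(
            z / z.mean(axis=0), "both") - clf.feature_mean_) / clf.feature_scale_
        K = (y[:, None] * y[None, :]) * (Fz @ Fz.T)

        def neg_dual(a):
            return -(a.sum() - 0.5 * a @ K @ a)

        cons = {"type": "eq", "fun": lambda a: a @ y}
        res = minimize(
            neg_dual,
            np.full(6, 0.5),
            bounds=[(0.0, 1.0)] * 6,
            constraints=cons,
            method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 500},
        )
        w_oracle = (res.x * y) @ Fz
        cos = w @ w_oracle / (np.linalg.norm(w) * np.linalg.norm(w_oracle))
        assert cos == pytest.approx(1.0, abs=1e-4)

    def test_single_class_rejected(self):
        z = np.ones((4, 2), complex)
        with pytest.raises(ValueError):
            ComplexPatternSVC().fit(z, np.zeros(4))

    def test_deterministic_for_fixed_input(self, rng):
        z = rng.standard_normal((10, 6)) + 1j * rng.standard_normal((10, 6))
        y = np.array([0, 1] * 5)
        d1 = ComplexPatternSVC("both").fit(z, y).decision_function(z)
        d2 = ComplexPatternSVC("both").fit(z, y).decision_function(z)
        assert np.array_equal(d1, d2)


class TestCrossSessionDecode:
    @staticmethod
    def _sessions(rng, effect=2.0, n_vox=12, runs_per_cond=6):
        """Two synthetic sessions with an amplitude effect on half the voxels."""
        sessions, labels = [], []
        pattern = np.concatenate([np.full(n_vox // 2, effect), np.zeros(n_vox - n_vox // 2)])
        for _ in range(2):
            zs, ls = [], []
            for cond in ("a", "b"):
                for _ in range(runs_per_cond):
                    base = 5.0 + 0.3 * rng.standard_normal(n_vox)
                    amp = base + (pattern if cond == "b" else 0.0)
                    z = amp * np.exp(1j * (0.5 + 0.05 * rng.standard_normal(n_vox)))
                    zs.append(z)
                    ls.append(cond)
            sessions.append(np.array(zs))
            labels.append(np.array(ls))
        return sessions, labels

    def test_strong_effect_decodes_above_09(self, rng):
        sessions, labels = self._sessions(rng, effect=2.0)
        masks = [np.ones(12, bool)] * 2
        results = cross_session_decode(sessions, labels, masks, ("a", "b"), "amplitude")
        assert len(results) == 2
        assert {(r.train_session, r.test_session) for r in results} == {(0, 1), (1, 0)}
        for r in results:
            assert r.auc > 0.9

    def test_shuffled_test_labels_chance_on_average(self, rng):
        sessions, labels = self._sessions(rng, effect=2.0)
        masks = [np.ones(12, bool)] * 2
        aucs = []
        for _ in range(40):
            shuffled = [labels[0], rng.permutation(labels[1])]
            res = cross_session_decode(sessions, shuffled, masks, ("a", "b"), "amplitude")
            aucs.append(res[0].auc)  # direction 0 -> 1 has shuffled test labels
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_delay_encoding_blind_to_amplitude_effect(self, rng):
        # amplitude patterns only; the delay channel carries no signal
        aucs = []
        for rep in range(30):
            r = np.random.default_rng(rep)
            sessions, labels = self._sessions(r, effect=2.0)
            masks = [np.ones(12, bool)] * 2
            res = cross_session_decode(sessions, labels, masks, ("a", "b"), "delay")
            aucs.extend([x.auc for x in res])
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < max(3 * se, 0.05)

    def test_no_leakage_into_trained_model(self, rng):
        sessions, labels = self._sessions(rng)
        masks = [np.ones(12, bool)] * 2
        mask = masks[0]
        Ztr = sessions[0][:, mask]
        clf1 = ComplexPatternSVC("both").fit(Ztr, labels[0])
        # permute the *test* session labels; train-side objects unchanged
        clf2 = ComplexPatternSVC("both").fit(Ztr, labels[0])
        assert np.array_equal(clf1.divisor_, clf2.divisor_)
        assert np.array_equal(clf1.feature_mean_, clf2.feature_mean_)
        assert np.array_equal(clf1.svm_.dual_coef_, clf2.svm_.dual_coef_)
        res_a = cross_session_decode(sessions, labels, masks, ("a", "b"), "both")
        shuffled = [labels[0], rng.permutation(labels[1])]
        res_b = cross_session_decode(sessions, shuffled, masks, ("a", "b"), "both")
        # direction 0->1: same trained model, so same decision values (sorted)
        assert np.allclose(
            np.sort(res_a[0].decision_values), np.sort(res_b[0].decision_values)
        )

    def test_misaligned_sessions_rejected(self, rng):
        a = rng.standard_normal((4, 5)) + 0j
        b = rng.standard_normal((4, 6)) + 0j
        with pytest.raises(ValueError, match="alignable"):
            cross_session_decode(
                [a, b],
                [np.array(["x", "x", "y", "y"])] * 2,
                [np.ones(5, bool), np.ones(6, bool)],
                ("x", "y"),
                "both",
            )


def test_fast_direction_auc_matches_estimator_path(rng):
    """The permutation hot path must reproduce ComplexPatternSVC exactly."""
    for _ in range(10):
        Ztr = rng.standard_normal((10, 8)) + 1j * rng.standard_normal((10, 8))
        Zte = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        ytr = np.array(["-45", "plaid"] * 5)
        yte = np.array(["-45", "plaid"] * 4)
        for encoding in ("delay", "amplitude", "both"):
            clf = ComplexPatternSVC(encoding).fit(Ztr, ytr)
            slow = auc(clf.decision_function(Zte), yte, pos_label=clf.classes_[1])
            fast = _direction_auc(Ztr, ytr, Zte, yte, encoding, 1.0)
            assert fast == pytest.approx(slow, abs=1e-12)
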