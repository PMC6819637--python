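import numpy as np
import pytest
import scipy.optimize

from morfmpm.io_formats import ValidationError, read_model, write_model
from morfmpm.mpm import (
    ClassStats,
    calibrate_thresholds,
    class_stats,
    fit,
    score,
    solve_mpm,
)


def socp_oracle(mu1, R1, mu2, R2):
    """Independent convex solve of min ||R1^1/2 W|| + ||R2^1/2 W|| subject
    to W^T (mu1 - mu2) = 1, via SLSQP from several feasible starts."""
    a = mu1 - mu2
    d = a.size

    def objective(w):
        return np.sqrt(w @ R1 @ w) + np.sqrt(w @ R2 @ w)

    best = None
    rng = np.random.default_rng(0)
    starts = [a / (a @ a)]
    for _ in range(4):
        w = rng.standard_normal(d)
        w = w - a * ((a @ w - 1.0) / (a @ a))  # project onto the constraint
        starts.append(w)
    for w0 in starts:
        res = scipy.optimize.minimize(
            objective, w0, method="SLSQP",
            constraints=[{"type": "eq", "fun": lambda w: a @ w - 1.0}],
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    assert best is not None
    return best.x, float(best.fun)


def random_instance(rng, d):
    def cov():
        A = rng.standard_normal((d, d))
        return A @ A.T + 0.1 * np.eye(d)

    mu1 = rng.standard_normal(d)
    mu2 = mu1 + rng.standard_normal(d)
    return ClassStats(mu=mu1, R=cov()), ClassStats(mu=mu2, R=cov())


class TestClassStats:
    def test_hand_computed_moments(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array([1, 1, 0, 0])
        s1, s2 = class_stats(X, y)
        assert s1.mu[0] == pytest.approx(1.0)
        assert s2.mu[0] == pytest.approx(5.0)
        assert s1.R[0, 0] == pytest.approx(2.0, rel=1e-5)  # unbiased + ridge
        assert s2.R[0, 0] == pytest.approx(2.0, rel=1e-5)

    def test_degenerate_class_still_invertible(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        y = np.array([1, 1, 0, 0])
        s1, _ = class_stats(X, y)
        assert np.all(np.linalg.eigvalsh(s1.R) > 0)

    def test_matches_two_pass_covariance_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 3))
        y = (rng.random(50) < 0.5).astype(int)
        y[:4] = [0, 0, 1, 1]
        s1, _ = class_stats(X, y, ridge=0.0)
        Xi = X[y == 1]
        mu = Xi.sum(axis=0) / len(Xi)
        R = np.zeros((3, 3))
        for row in Xi:
            R += np.outer(row - mu, row - mu)
        R /= len(Xi) - 1
        np.testing.assert_allclose(s1.R, R, rtol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            class_stats(np.ones((4, 2)), np.ones(4))


class TestSolveMPM:
    def test_equal_identity_covariance_closed_form(self):
        m = solve_mpm(
            ClassStats(mu=[1.0, 0.0], R=np.eye(2)),
            ClassStats(mu=[-1.0, 0.0], R=np.eye(2)),
        )
        np.testing.assert_allclose(m.W, [0.5, 0.0], atol=1e-9)
        assert m.kappa == pytest.approx(1.0, abs=1e-9)
        assert m.b == pytest.approx(0.0, abs=1e-9)

    def test_equal_covariance_closed_form_randomized(self):
        # with R1 = R2 = R, the optimum is W = R^-1 a / (a^T R^-1 a)
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = int(rng.integers(2, 6))
            A = rng.standard_normal((d, d))
            R = A @ A.T + 0.1 * np.eye(d)
            mu1 = rng.standard_normal(d)
            mu2 = mu1 + rng.standard_normal(d)
            a = mu1 - mu2
            expected = np.linalg.solve(R, a)
            expected /= a @ expected
            m = solve_mpm(ClassStats(mu=mu1, R=R), ClassStats(mu=mu2, R=R))
            np.testing.assert_allclose(m.W, expected, rtol=1e-6, atol=1e-9)

    def test_covariance_scaling_moves_kappa_not_w(self):
        rng = np.random.default_rng(3)
        s1, s2 = random_instance(rng, 3)
        base = solve_mpm(s1, s2)
        t = 2.5
        scaled = solve_mpm(
            ClassStats(mu=s1.mu, R=t**2 * s1.R),
            ClassStats(mu=s2.mu, R=t**2 * s2.R),
        )
        np.testing.assert_allclose(scaled.W, base.W, rtol=1e-6)
        assert scaled.kappa == pytest.approx(base.kappa / t, rel=1e-6)

    def test_objective_matches_socp_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            d = int(rng.integers(2, 6))
            s1, s2 = random_instance(rng, d)
            m = solve_mpm(s1, s2)
            _, oracle_obj = socp_oracle(s1.mu, s1.R, s2.mu, s2.R)
            assert m.objective == pytest.approx(oracle_obj, rel=1e-6)

    def test_constraint_and_offset_consistency(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s1, s2 = random_instance(rng, 4)
            m = solve_mpm(s1, s2)
            assert abs(m.W @ (s1.mu - s2.mu) - 1.0) <= 1e-8
            g1 = np.sqrt(m.W @ s1.R @ m.W)
            g2 = np.sqrt(m.W @ s2.R @ m.W)
            assert m.kappa == pytest.approx(1.0 / (g1 + g2), abs=1e-8)
            b1 = m.W @ s1.mu - m.kappa * g1
            b2 = m.W @ s2.mu + m.kappa * g2
            assert abs(b1 - b2) <= 1e-8
            assert m.b == pytest.approx(b2, abs=1e-8)
            assert 0 < m.worst_case_misclassification < 1

    def test_identical_means_infeasible(self):
        with pytest.raises(ValidationError):
            solve_mpm(
                ClassStats(mu=[1.0, 1.0], R=np.eye(2)),
                ClassStats(mu=[1.0, 1.0], R=2 * np.eye(2)),
            )


class TestScore:
    def test_class_means_score_on_their_side(self):
        rng = np.random.default_rng(6)
        s1, s2 = random_instance(rng, 3)
        m = solve_mpm(s1, s2)
        g1 = np.sqrt(m.W @ s1.R @ m.W)
        g2 = np.sqrt(m.W @ s2.R @ m.W)
        assert score(m, s1.mu)[0] == pytest.approx(m.kappa * g1, abs=1e-8)
        assert score(m, s2.mu)[0] == pytest.approx(-m.kappa * g2, abs=1e-8)

    def test_midpoint_is_neutral_under_equal_covariance(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((3, 3))
        R = A @ A.T + 0.1 * np.eye(3)
        mu1 = rng.standard_normal(3)
        mu2 = mu1 + rng.standard_normal(3)
        m = solve_mpm(ClassStats(mu=mu1, R=R), ClassStats(mu=mu2, R=R))
        assert score(m, (mu1 + mu2) / 2)[0] == pytest.approx(0.0, abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        m = solve_mpm(
            ClassStats(mu=[1.0, 0.0], R=np.eye(2)),
            ClassStats(mu=[-1.0, 0.0], R=np.eye(2)),
        )
        with pytest.raises(ValidationError):
            score(m, np.ones((3, 1)))


def planted_gaussians(rng, n=400, d=4, sep=3.0):
    mu = rng.standard_normal(d)
    X1 = rng.standard_normal((n, d)) + mu + sep
    X0 = rng.standard_normal((n, d)) + mu
    X = np.vstack([X1, X0])
    y = np.r_[np.ones(n), np.zeros(n)].astype(int)
    return X, y


class TestFit:
    def test_training_rates_beat_worst_case_bound(self):
        # the worst-case guarantee holds in particular for the empirical
        # training distribution, whose moments the model was built from
        rng = np.random.default_rng(8)
        X, y = planted_gaussians(rng)
        m = fit(X, y)
        s = score(m, X)
        tpr = np.mean(s[y == 1] > 0)
        tnr = np.mean(s[y == 0] <= 0)
        floor = 1.0 - m.worst_case_misclassification
        assert tpr >= floor - 1e-9
        assert tnr >= floor - 1e-9

    def test_label_flip_negates_scores(self):
        rng = np.random.default_rng(9)
        X, y = planted_gaussians(rng, n=100)
        a = fit(X, y)
        b = fit(X, 1 - y)
        np.testing.assert_allclose(score(b, X), -score(a, X), atol=1e-6)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(10)
        X, y = planted_gaussians(rng, n=100)
        X_aug = np.hstack([X[:, :1] * 0 + 7.0, X])
        m = fit(X_aug, y)
        assert 0 not in m.kept_columns.tolist()
        np.testing.assert_allclose(score(m, X_aug), score(fit(X, y), X), atol=1e-6)

    def test_affine_rescaling_of_columns_is_absorbed(self):
        rng = np.random.default_rng(11)
        X, y = planted_gaussians(rng, n=150)
        scale = rng.uniform(0.5, 20.0, size=X.shape[1])
        shift = rng.standard_normal(X.shape[1]) * 5
        m_raw = fit(X, y)
        m_aff = fit(X * scale + shift, y)
        np.testing.assert_allclose(
            score(m_aff, X * scale + shift), score(m_raw, X), rtol=1e-6, atol=1e-8
        )

    def test_model_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(12)
        X, y = planted_gaussians(rng, n=100)
        m = fit(X, y, feature_names=("a", "b", "c", "d"), window_sizes=(3, 9))
        p = tmp_path / "model.json"
        write_model(p, m)
        back = read_model(p)
        np.testing.assert_allclose(score(back, X), score(m, X))
        assert back.feature_names == ("a", "b", "c", "d")
        assert back.window_sizes == (3, 9)


def sweep_oracle(scores, labels, target):
    """Exhaustive check over every cut point: the smallest threshold whose
    FPR does not exceed the target."""
    neg = scores[labels == 0]
    candidates = sorted(set(scores.tolist()) | {scores.min() - 1.0})
    for t in candidates:
        if np.mean(neg > t) <= target:
            return t
    raise AssertionError("unreachable")


class TestCalibrateThresholds:
    def test_enumerated_example(self):
        scores = np.array([-1.0, -0.5, 0.2, 0.4, 0.9])
        labels = np.array([0, 0, 0, 1, 1])
        table = calibrate_thresholds(scores, labels, [0.34])
        t, tpr, fpr = table[0.34]
        assert t == pytest.approx(-0.5)  # admits exactly one of three negatives
        assert fpr == pytest.approx(1 / 3)
        assert tpr == pytest.approx(1.0)

    def test_zero_target_clears_all_negatives(self):
        scores = np.array([-1.0, 0.5, 2.0, 3.0])
        labels = np.array([0, 0, 1, 1])
        t, _, fpr = calibrate_thresholds(scores, labels, [0.0])[0.0]
        assert fpr == 0.0
        assert t >= 0.5

    def test_unit_target_admits_everything(self):
        scores = np.array([-1.0, 0.5, 2.0])
        labels = np.array([0, 1, 1])
        t, tpr, fpr = calibrate_thresholds(scores, labels, [1.0])[1.0]
        assert t < scores.min()
        assert (tpr, fpr) == (1.0, 1.0)

    def test_matches_sweep_oracle_and_respects_target(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.standard_normal(n), 2)
            labels = (rng.random(n) < 0.5).astype(int)
            labels[0] = 0
            targets = [0.0, 0.1, 0.25, 0.5, 1.0]
            table = calibrate_thresholds(scores, labels, targets)
            neg = scores[labels == 0]
            for target in targets:
                t, _, fpr = table[target]
                assert fpr <= target + 1e-12
                assert t == pytest.approx(sweep_oracle(scores, labels, target))

    def test_no_negatives_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_thresholds(np.ones(3), np.ones(3), [0.1])
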