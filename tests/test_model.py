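"""RBF-SVM training, decision function, calibration, serialization."""

import math

import numpy as np
import pytest

from maturescan import ModelConfig, TrainedModel, TrainingSet, fit
from maturescan.features import N_FEATURES
from maturescan.model import ModelError, _exact_hit_rate


def _separable_set(n_groups: int = 24, n_per: int = 8, seed: int = 0) -> TrainingSet:
    """One positive per group, offset by a large margin in the MFE1 slot."""
    rng = np.random.default_rng(seed)
    X, y, groups = [], [], []
    for g in range(n_groups):
        block = rng.integers(0, 10, size=(n_per, N_FEATURES)).astype(float)
        block[:, 84] = rng.uniform(-20, -10, size=n_per)  # MFE1 background
        block[0, 84] = -60.0  # the true duplex is far more stable
        X.append(block)
        y += [1] + [-1] * (n_per - 1)
        groups += [f"g{g}"] * n_per
    return TrainingSet(np.vstack(X), np.array(y), np.array(groups))


SMALL = ModelConfig(
    c_grid=np.array([1.0, 32.0]),
    gamma_grid=np.array([2.0**-5, 2.0**-2]),
    cv_folds=3,
    seed=0,
)


@pytest.fixture(scope="module")
def separable_model():
    return fit(_separable_set(), SMALL)


class TestFit:
    def test_separable_set_reaches_perfect_training_exact_hit(
        self, separable_model
    ):
        train = _separable_set()
        dec = separable_model.decision_function(train.X)
        assert _exact_hit_rate(dec, train.y, train.groups) == 1.0

    def test_single_class_rejected(self):
        t = _separable_set()
        with pytest.raises(ModelError, match="both classes"):
            fit(TrainingSet(t.X, np.full(len(t.y), -1), t.groups), SMALL)

    def test_empty_grid_rejected(self):
        cfg = ModelConfig(c_grid=np.array([]), gamma_grid=np.array([1.0]))
        with pytest.raises(ModelError, match="empty"):
            fit(_separable_set(), cfg)

    def test_nan_features_rejected(self):
        t = _separable_set()
        X = t.X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ModelError, match="NaN"):
            TrainingSet(X, t.y, t.groups)

    def test_row_permutation_leaves_decisions_unchanged(self):
        """The fitted decision function is invariant to training row order
        (up to the SMO optimizer's convergence tolerance)."""
        t = _separable_set()
        m1 = fit(t, SMALL)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(t.y))
        m2 = fit(TrainingSet(t.X[perm], t.y[perm], t.groups[perm]), SMALL)
        assert (m1.c, m1.gamma) == (m2.c, m2.gamma)
        probe = t.X[:20]
        np.testing.assert_allclose(
            m1.decision_function(probe), m2.decision_function(probe), atol=5e-3
        )

    def test_same_seed_gives_byte_identical_model_file(self, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        fit(_separable_set(), SMALL).save(p1)
        fit(_separable_set(), SMALL).save(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestDecisionFunction:
    def test_matches_brute_force_kernel_expansion(self, separable_model):
        """g(x) = sum_i z_i a_i exp(-gamma ||x - x_i||^2) + w0, by hand."""
        m = separable_model
        rows = _separable_set().X[:20]
        got = m.decision_function(rows)
        for x, g_vec in zip(rows, got):
            xs = (x - m.scale_min) / m.scale_range
            g = m.intercept
            for coef, sv in zip(m.dual_coef, m.support_vectors):
                d2 = sum((a - b) ** 2 for a, b in zip(xs, sv))
                g += coef * math.exp(-m.gamma * d2)
            assert g == pytest.approx(g_vec, rel=1e-8, abs=1e-10)

    def test_matches_reference_svm_implementation(self):
        """Stored-array evaluation agrees with the fitting library's SVC."""
        from sklearn.svm import SVC

        t = _separable_set()
        m = fit(t, SMALL)
        Xs = m.scale(t.X)
        svc = SVC(
            C=m.c, gamma=m.gamma, class_weight="balanced", random_state=0
        ).fit(Xs, t.y)
        np.testing.assert_allclose(
            m.decision_function(t.X), svc.decision_function(Xs), atol=1e-9
        )


class TestPredictProba:
    def test_probabilities_sum_to_one(self, separable_model):
        p = separable_model.predict_proba(_separable_set().X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all() and (p <= 1).all()

    def test_training_positives_score_high(self, separable_model):
        t = _separable_set()
        p_pos = separable_model.predict_proba(t.X)[:, 0]
        assert (p_pos[t.y == 1] > 0.5).all()

    def test_monotone_in_decision_value(self, separable_model):
        t = _separable_set()
        dec = separable_model.decision_function(t.X)
        p = separable_model.predict_proba(t.X)[:, 0]
        order = np.argsort(dec)
        assert (np.diff(p[order]) >= 0).all()

    def test_zero_vector_yields_finite_probabilities(self, separable_model):
        p = separable_model.predict_proba(np.zeros((1, N_FEATURES)))
        assert np.isfinite(p).all()

    def test_column_count_mismatch_rejected(self, separable_model):
        with pytest.raises(ModelError):
            separable_model.predict_proba(np.zeros((1, 10)))


class TestSerialization:
    def test_round_trip_preserves_decision_values(
        self, separable_model, tmp_path
    ):
        path = tmp_path / "model.json"
        separable_model.save(path)
        loaded = TrainedModel.load(path)
        X = _separable_set().X
        assert np.array_equal(
            separable_model.decision_function(X), loaded.decision_function(X)
        )

    def test_layout_version_mismatch_refused(self, separable_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        separable_model.save(path)
        payload = json.loads(path.read_text())
        payload["feature_layout"] = "other-layout"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelError, match="layout"):
            TrainedModel.load(path)
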