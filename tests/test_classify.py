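"""Feature extraction and the cost-sensitive cascade."""

import numpy as np
import pytest

from thyroprep import (CascadeModel, ContractError, CostMatrix,
                       ValidationError, build_cost_matrix, extract_features,
                       predict, register_embedding, train_cascade,
                       save_model, load_model)
from thyroprep.augmentation import Sample
from thyroprep.classify import EMBEDDING_DIM, N_MEMBERS


def make_sample(patch, label="benign"):
    return Sample(patch=patch, label=label, parent_id="p0", crop_index=0,
                  offset=(0, 0))


class StubForest:
    """Fixed-probability member used to test the decision rule in isolation."""

    classes_ = np.array([0, 1])

    def __init__(self, p_malignant):
        self.p = p_malignant

    def predict_proba(self, X):
        p = np.broadcast_to(np.asarray(self.p, dtype=float), (len(X),))
        return np.column_stack([1 - p, p])


def stub_cascade(p_malignant, cost=CostMatrix(1.0, 1.0), n_features=4):
    return CascadeModel(members=[StubForest(p_malignant)] * N_MEMBERS,
                        cost=cost, member_seeds=[0] * N_MEMBERS,
                        extractor_id="default", n_features=n_features)


def test_constant_patch_degenerate_texture():
    patch = np.full((256, 256), 200, dtype=np.uint8)
    fv = extract_features(make_sample(patch))
    hist = fv.values[:16]
    assert hist[200 // 16] == 1.0 and hist.sum() == pytest.approx(1.0)
    # GLCM energy of a constant patch is 1 at every offset
    energy = fv.values[16 + 8:16 + 12]
    assert np.allclose(energy, 1.0)


def test_features_deterministic_and_finite():
    rng = np.random.default_rng(1)
    patch = rng.integers(0, 256, size=(256, 256)).astype(np.uint8)
    a = extract_features(make_sample(patch))
    b = extract_features(make_sample(patch))
    assert np.array_equal(a.values, b.values)
    assert np.all(np.isfinite(a.values))


def test_wrong_patch_size_rejected():
    with pytest.raises(ValidationError):
        extract_features(make_sample(np.zeros((128, 128), dtype=np.uint8)))


def test_embedding_contract_enforced():
    register_embedding("short", lambda patch: np.zeros(1000))
    with pytest.raises(ContractError, match="1024"):
        extract_features(make_sample(np.zeros((256, 256), dtype=np.uint8)),
                         extractor="short")
    register_embedding("ok", lambda patch: np.arange(EMBEDDING_DIM, dtype=float))
    fv = extract_features(make_sample(np.zeros((256, 256), dtype=np.uint8)),
                          extractor="ok")
    assert fv.values.size == EMBEDDING_DIM


@pytest.mark.parametrize("counts,expected", [
    ((50, 50), 1.0),
    ((129, 35), 129 / 35),
    ((1, 1), 1.0),
])
def test_cost_matrix_from_class_distribution(counts, expected):
    cm = build_cost_matrix(counts)
    assert cm.benign_as_malignant == 1.0
    assert cm.malignant_as_benign == pytest.approx(expected)
    assert cm.matrix[0, 0] == cm.matrix[1, 1] == 0.0


def test_cost_matrix_rejects_empty_class():
    with pytest.raises(ValidationError):
        build_cost_matrix((0, 10))


def separable_data(n=200, seed=0, d=4):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(-3.0, 1.0, size=(n // 2, d))
    X1 = rng.normal(+3.0, 1.0, size=(n - n // 2, d))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return X, y


def test_separable_clusters_train_to_perfect_accuracy():
    X, y = separable_data()
    model = train_cascade(X, y, CostMatrix(1.0, 1.0), seed=1)
    _, labels = predict(model, X)
    assert np.array_equal(labels, y)


def test_training_is_a_pure_function_of_data_seed_cost():
    X, y = separable_data(seed=2)
    Xtest = np.random.default_rng(3).normal(0, 3, size=(50, 4))
    m1 = train_cascade(X, y, CostMatrix(1.0, 2.0), seed=42)
    m2 = train_cascade(X, y, CostMatrix(1.0, 2.0), seed=42)
    s1, l1 = predict(m1, Xtest)
    s2, l2 = predict(m2, Xtest)
    assert np.array_equal(s1, s2) and np.array_equal(l1, l2)


def test_single_class_training_rejected():
    X = np.zeros((10, 3))
    with pytest.raises(ValidationError):
        train_cascade(X, np.zeros(10, dtype=int), CostMatrix(1.0, 1.0), seed=0)


def test_unanimous_members_give_score_one_and_malignant():
    model = stub_cascade(1.0)
    scores, labels = predict(model, np.zeros((3, 4)))
    assert np.all(scores == 1.0) and np.all(labels == 1)


def test_tie_at_half_goes_malignant_under_equal_costs():
    model = stub_cascade(0.5)
    _, labels = predict(model, np.zeros((1, 4)))
    assert labels[0] == 1


def test_equal_costs_reduce_to_argmax():
    rng = np.random.default_rng(4)
    probs = rng.uniform(0, 1, size=40)
    for p in probs:
        _, lb = predict(stub_cascade(float(p)), np.zeros((1, 4)))
        assert lb[0] == int(p >= 0.5)


def test_sensitivity_monotone_in_missed_malignancy_cost():
    rng = np.random.default_rng(5)
    scores = rng.uniform(0, 1, size=200)
    truth = rng.integers(0, 2, size=200)
    prev_sens, prev_spec = -1.0, 2.0
    for c in (0.5, 1.0, 2.0, 5.0, 10.0):
        model = stub_cascade(scores, cost=CostMatrix(1.0, c))
        _, labels = predict(model, np.zeros((scores.size, 4)))
        sens = np.mean(labels[truth == 1])
        spec = np.mean(1 - labels[truth == 0])
        assert sens >= prev_sens and spec <= prev_spec
        prev_sens, prev_spec = sens, spec


def test_prediction_dimension_checked():
    model = stub_cascade(0.5, n_features=7)
    with pytest.raises(ContractError):
        predict(model, np.zeros((2, 4)))


def test_cascade_has_ten_members_of_hundred_trees():
    X, y = separable_data(n=40, seed=6)
    model = train_cascade(X, y, CostMatrix(1.0, 1.0), seed=0)
    assert len(model.members) == 10
    assert all(len(rf.estimators_) == 100 for rf in model.members)


def test_model_roundtrip(tmp_path):
    X, y = separable_data(n=60, seed=7)
    model = train_cascade(X, y, CostMatrix(1.0, 1.5), seed=9)
    path = tmp_path / "cascade.joblib"
    save_model(model, path)
    loaded = load_model(path)
    Xq = np.random.default_rng(8).normal(0, 3, size=(20, 4))
    assert np.array_equal(predict(model, Xq)[0], predict(loaded, Xq)[0])
    assert loaded.cost.malignant_as_benign == 1.5


def test_cascade_near_bayes_on_overlapping_gaussians():
    """Two unit-variance Gaussians at +/- mu: Bayes accuracy is Phi(mu)."""
    from scipy.stats import norm
    rng = np.random.default_rng(10)
    mu, n, d = 1.0, 2000, 3
    # class separation only along the first axis
    X = rng.normal(0, 1, size=(n, d))
    y = rng.integers(0, 2, size=n)
    X[:, 0] += np.where(y == 1, mu, -mu)
    Xt = rng.normal(0, 1, size=(n, d))
    yt = rng.integers(0, 2, size=n)
    Xt[:, 0] += np.where(yt == 1, mu, -mu)
    model = train_cascade(X, y, CostMatrix(1.0, 1.0), seed=11)
    _, labels = predict(model, Xt)
    acc = np.mean(labels == yt)
    bayes = norm.cdf(mu)
    assert acc >= bayes - 0.05


def test_permuted_labels_give_chance_level_accuracy():
    rng = np.random.default_rng(12)
    n = 200
    X = rng.normal(size=(n, 5))
    y = np.array([0] * 120 + [1] * 80)
    y = rng.permutation(y)
    k = 5
    folds = np.arange(n) % k
    accs = []
    for f in range(k):
        tr, te = folds != f, folds == f
        model = train_cascade(X[tr], y[tr], CostMatrix(1.0, 1.0), seed=f)
        _, lb = predict(model, X[te])
        accs.append(np.mean(lb == y[te]))
    majority = max(np.mean(y == 0), np.mean(y == 1))
    se = np.std(accs, ddof=1) / np.sqrt(k)
    assert abs(np.mean(accs) - majority) <= max(3 * se, 0.12)
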