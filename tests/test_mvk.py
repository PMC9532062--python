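import numpy as np
import pytest
from hypothesis import given, strategies as st

import mvkmeans as mk
from mvkmeans.mvk import ViewWeights, _objective


def _single_view(X):
    return mk.MultiViewDataset(views=[np.asarray(X, float)])


# ---------------------------------------------------------------------------
# Weights type
# ---------------------------------------------------------------------------

def test_view_weights_invariants():
    ViewWeights(w=[0.25, 0.75], p=2.0, eta=0.0)
    with pytest.raises(ValueError, match="sum to 1"):
        ViewWeights(w=[0.5, 0.6])
    with pytest.raises(ValueError, match="p must exceed 1"):
        ViewWeights(w=[1.0], p=1.0)
    with pytest.raises(ValueError, match="eta"):
        ViewWeights(w=[1.0], eta=-0.1)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def test_objective_single_view_reduction(rng):
    X = rng.standard_normal((12, 2))
    centers = X[:3]
    assignment = mk.assign_nearest(X, centers)
    ds = _single_view(X)
    model = mk.MvKMeansModel(
        centers=[centers], weights=ViewWeights(w=[1.0], p=3.0, eta=0.0),
        assignment=assignment, objective_trajectory=[0.0], n_iter=1,
        converged=True, n_clusters=3,
    )
    assert mk.mvk_objective(ds, model) == pytest.approx(
        mk.kmeans_objective(X, centers, assignment)
    )


def test_objective_hand_case_two_views():
    # one point per view at squared distance 1 and 3 from a single center
    ds = mk.MultiViewDataset(views=[np.array([[1.0]]), np.array([[np.sqrt(3.0)]])])
    model = mk.MvKMeansModel(
        centers=[np.array([[0.0]]), np.array([[0.0]])],
        weights=ViewWeights(w=[0.5, 0.5], p=2.0, eta=0.0),
        assignment=np.array([0]), objective_trajectory=[0.0],
        n_iter=1, converged=True, n_clusters=1,
    )
    assert mk.mvk_objective(ds, model) == pytest.approx(1.0)  # 0.25*1 + 0.25*3


def test_objective_zero_when_points_on_centers():
    ds = mk.MultiViewDataset(views=[np.array([[2.0], [4.0]])])
    model = mk.MvKMeansModel(
        centers=[np.array([[2.0], [4.0]])], weights=ViewWeights(w=[1.0]),
        assignment=np.array([0, 1]), objective_trajectory=[0.0],
        n_iter=1, converged=True, n_clusters=2,
    )
    assert mk.mvk_objective(ds, model) == 0.0


def test_objective_eta_term():
    D = np.array([2.0, 6.0])
    w = np.array([0.5, 0.5])
    val = _objective(
        [np.array([[np.sqrt(2.0)]]), np.array([[np.sqrt(6.0)]])],
        [np.array([[0.0]]), np.array([[0.0]])],
        np.array([0]), w, 2.0, 4.0,
    )
    assert val == pytest.approx((w**2 * D).sum() + 4.0 * (w**2).sum())


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def test_assign_single_view_reduces_to_nearest(rng):
    X = rng.standard_normal((25, 3))
    centers = X[:4]
    ds = _single_view(X)
    out = mk.mvk_assign(ds, [centers], ViewWeights(w=[1.0]))
    np.testing.assert_array_equal(out, mk.assign_nearest(X, centers))


def test_assign_zero_weight_view_ignored():
    # view 2 says cluster 1, but its weight is 0
    ds = mk.MultiViewDataset(views=[np.array([[0.0]]), np.array([[10.0]])])
    centers = [np.array([[0.0], [9.0]]), np.array([[0.0], [10.0]])]
    out = mk.mvk_assign(ds, centers, ViewWeights(w=[1.0, 0.0], p=2.0))
    assert out.tolist() == [0]


def test_assign_follows_dominant_view():
    # the two views disagree on the nearest center; w=(0.9,0.1) follows view 1
    ds = mk.MultiViewDataset(views=[np.array([[0.0]]), np.array([[10.0]])])
    centers = [np.array([[1.0], [8.0]]), np.array([[2.0], [10.0]])]
    heavy1 = mk.mvk_assign(ds, centers, ViewWeights(w=[0.9, 0.1], p=2.0))
    heavy2 = mk.mvk_assign(ds, centers, ViewWeights(w=[0.1, 0.9], p=2.0))
    assert heavy1.tolist() == [0] and heavy2.tolist() == [1]


def test_update_centers_per_view_independent():
    ds = mk.MultiViewDataset(
        views=[np.array([[2.0], [4.0], [10.0]]), np.array([[0.0], [6.0], [7.0]])]
    )
    centers = mk.mvk_update_centers(ds, np.array([0, 0, 1]), n_clusters=2)
    np.testing.assert_allclose(centers[0], [[3.0], [10.0]])
    np.testing.assert_allclose(centers[1], [[3.0], [7.0]])


# ---------------------------------------------------------------------------
# Weight update
# ---------------------------------------------------------------------------

def test_weight_update_hand_case():
    w = mk.mvk_update_weights([1.0, 3.0], p=2.0, eta=0.0)
    np.testing.assert_allclose(w.w, [0.75, 0.25])


def test_weight_update_symmetry_and_limits():
    np.testing.assert_allclose(mk.mvk_update_weights([7.0] * 4, p=2.0).w, 0.25)
    near_uniform = mk.mvk_update_weights([1.0, 3.0], p=2.0, eta=1e9).w
    np.testing.assert_allclose(near_uniform, 0.5, atol=1e-6)


def test_weight_update_zero_dispersion_convention():
    w = mk.mvk_update_weights([0.0, 2.0, 0.0], p=2.0, eta=0.0)
    np.testing.assert_allclose(w.w, [0.5, 0.0, 0.5])


def test_weight_update_rejects_bad_exponent():
    with pytest.raises(ValueError, match="p must exceed 1"):
        mk.mvk_update_weights([1.0, 2.0], p=1.0)


@given(
    st.floats(min_value=1.1, max_value=6.0),
    st.floats(min_value=0.0, max_value=10.0),
    st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=2, max_size=6),
)
def test_weight_update_simplex_and_monotone(p, eta, disps):
    D = np.asarray(disps)
    w = mk.mvk_update_weights(D, p=p, eta=eta).w
    assert w.sum() == pytest.approx(1.0)
    assert ((w >= 0) & (w <= 1)).all()
    # increasing one view's dispersion strictly decreases its weight
    D2 = D.copy()
    D2[0] *= 2.0
    w2 = mk.mvk_update_weights(D2, p=p, eta=eta).w
    assert w2[0] < w[0]


# ---------------------------------------------------------------------------
# Fit
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 7])
def test_single_view_fit_matches_kmeans_trajectories(rng, seed):
    X = np.random.default_rng(seed).standard_normal((60, 4)) * 3
    km = mk.kmeans_fit(X, k=4, seed=seed, n_restarts=3)
    mv = mk.mvk_fit(_single_view(X), n_clusters=4, eta=0.0, seed=seed, n_restarts=3)
    np.testing.assert_allclose(mv.objective_trajectory, km.objective_trajectory)
    for a, b in zip(mv.assignment_trajectory, km.assignment_trajectory):
        np.testing.assert_array_equal(a, b)
    np.testing.assert_allclose(mv.weights.w, [1.0])


def test_fixed_uniform_equals_scaled_concat_kmeans(two_view_blobs):
    """Uniform-weight multi-view == K-means on concatenated views, with the
    objective scaled by (1/V)^p."""
    V, p = 2, 2.0
    km = mk.kmeans_fit(two_view_blobs.concatenated(), k=3, seed=3, n_restarts=3, tol=0.0)
    mv = mk.mvk_fit(two_view_blobs, n_clusters=3, p=p, seed=3, n_restarts=3,
                    weight_mode="fixed_uniform", tol=0.0)
    np.testing.assert_array_equal(mv.assignment, km.assignment)
    np.testing.assert_allclose(
        mv.objective_trajectory, np.asarray(km.objective_trajectory) * (1 / V) ** p
    )


@given(st.integers(min_value=0, max_value=2**31 - 1), st.sampled_from([0.0, 5.0]))
def test_objective_non_increasing_every_iteration(seed, eta):
    gen = np.random.default_rng(seed)
    ds = mk.MultiViewDataset(
        views=[gen.standard_normal((30, 2)), 4 * gen.standard_normal((30, 3))]
    )
    model = mk.mvk_fit(ds, n_clusters=3, eta=eta, seed=seed, n_restarts=1)
    assert (np.diff(model.objective_trajectory) <= 1e-9).all()
    for w in model.weight_trajectory:
        assert w.sum() == pytest.approx(1.0)
        assert ((w >= 0) & (w <= 1)).all()


def test_view_permutation_symmetry(two_view_blobs):
    ds = two_view_blobs
    swapped = mk.MultiViewDataset(views=[ds.views[1], ds.views[0]], labels=ds.labels)
    a = mk.mvk_fit(ds, n_clusters=3, seed=5, n_restarts=3)
    b = mk.mvk_fit(swapped, n_clusters=3, seed=5, n_restarts=3)
    np.testing.assert_array_equal(a.assignment, b.assignment)
    np.testing.assert_allclose(a.weights.w, b.weights.w[::-1])


def test_fit_validates_inputs(two_view_blobs):
    with pytest.raises(ValueError, match="n_clusters"):
        mk.mvk_fit(two_view_blobs, n_clusters=61)
    with pytest.raises(ValueError, match="p must exceed 1"):
        mk.mvk_fit(two_view_blobs, n_clusters=3, p=1.0)
    with pytest.raises(ValueError, match="weight_mode"):
        mk.mvk_fit(two_view_blobs, n_clusters=3, weight_mode="nope")


def test_predict_fixed_point_and_dimension_check(two_view_blobs):
    model = mk.mvk_fit(two_view_blobs, n_clusters=3, seed=2, n_restarts=3)
    np.testing.assert_array_equal(mk.mvk_predict(model, two_view_blobs), model.assignment)
    # a new point equal to a training point lands in the same cluster
    one = two_view_blobs.subset(np.array([17]))
    assert mk.mvk_predict(model, one)[0] == model.assignment[17]
    bad = mk.MultiViewDataset(views=[two_view_blobs.views[0]])
    with pytest.raises(ValueError, match="views"):
        mk.mvk_predict(model, bad)


def test_model_json_roundtrip(two_view_blobs, tmp_path):
    model = mk.mvk_fit(two_view_blobs, n_clusters=3, seed=0, n_restarts=2)
    path = tmp_path / "m.json"
    model.save(path)
    import json

    again = mk.MvKMeansModel.from_json_dict(json.loads(path.read_text()))
    np.testing.assert_array_equal(again.assignment, model.assignment)
    np.testing.assert_allclose(again.weights.w, model.weights.w)
    pred = mk.mvk_predict(again, two_view_blobs)
    np.testing.assert_array_equal(pred, model.assignment)


def test_noisy_view_gets_less_weight(high_sep_dataset):
    noisy = mk.corrupt_view(high_sep_dataset, 1, 0.9, seed=0)
    model = mk.mvk_fit(noisy, n_clusters=5, seed=0, n_restarts=3)
    assert model.weights.w[1] < model.weights.w[0]
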