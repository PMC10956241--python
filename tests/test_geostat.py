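"""Semivariogram estimation, model fitting, and ordinary kriging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

import stareal as st
from stareal.geostat import FAMILIES


def brute_force_semivariogram(locations, values, edges):
    """Independent pairwise-loop oracle for the binned semivariogram."""
    n = len(values)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(locations[i] - locations[j]))
            for b in range(len(edges) - 1):
                if edges[b] < d <= edges[b + 1]:
                    sums[b] += (values[i] - values[j]) ** 2
                    counts[b] += 1
    return sums, counts


# ---------------------------------------------------------------------------
# Empirical semivariogram
# ---------------------------------------------------------------------------


def test_constant_field_has_zero_semivariance():
    pts = np.array([[0, 0], [1, 0], [0, 1], [2, 2]], dtype=float)
    emp = st.empirical_semivariogram(pts, np.full(4, 3.3), n_bins=3, max_dist=3.0)
    np.testing.assert_allclose(emp.gamma_hat, 0.0)


def test_single_pair_closed_form():
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    emp = st.empirical_semivariogram(pts, np.array([0.0, 2.0]), n_bins=1, max_dist=1.0)
    assert emp.gamma_hat[0] == pytest.approx(2.0)  # 2^2 / (2*1)
    assert emp.pair_count[0] == 1


def test_unit_square_corners_match_pair_enumeration():
    """gamma(1) = 0.25 from the 4 side pairs, gamma(sqrt 2) = 0.5 from the
    2 diagonal pairs; verified against a brute force over all 6 pairs."""
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    vals = np.array([0.0, 1.0, 1.0, 0.0])
    emp = st.empirical_semivariogram(pts, vals, n_bins=3, max_dist=1.5)
    assert emp.gamma_hat[0] == pytest.approx(0.25)
    assert emp.pair_count[0] == 4
    assert emp.gamma_hat[1] == pytest.approx(0.5)
    assert emp.pair_count[1] == 2
    edges = np.array([0.5, 1.0, 1.5])
    sums, counts = brute_force_semivariogram(pts, vals, edges)
    np.testing.assert_allclose(emp.gamma_hat, sums / (2 * counts))


def test_degenerate_inputs_rejected():
    pts = np.zeros((3, 2))
    with pytest.raises(ValueError, match="coincident"):
        st.empirical_semivariogram(pts, np.arange(3.0))
    with pytest.raises(ValueError, match="n_bins"):
        st.empirical_semivariogram(np.array([[0, 0], [1, 1]]), np.array([0.0, 1.0]), n_bins=0)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(
    hyp.floats(min_value=-5, max_value=5, allow_nan=False),
    hyp.floats(min_value=0.1, max_value=4, allow_nan=False),
    hyp.integers(min_value=0, max_value=2**31 - 1),
)
def test_semivariogram_affine_property(shift, scale, seed):
    """gamma_hat is invariant to adding a constant and scales with the
    square of a multiplicative factor."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 10, size=(12, 2))
    vals = rng.normal(size=12)
    base = st.empirical_semivariogram(pts, vals, n_bins=5)
    shifted = st.empirical_semivariogram(pts, vals + shift, n_bins=5)
    scaled = st.empirical_semivariogram(pts, vals * scale, n_bins=5)
    np.testing.assert_allclose(shifted.gamma_hat, base.gamma_hat, atol=1e-9)
    np.testing.assert_allclose(scaled.gamma_hat, scale**2 * base.gamma_hat, rtol=1e-9)


# ---------------------------------------------------------------------------
# Variogram models
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("family", FAMILIES)
def test_model_plateau_and_origin(family):
    nugget, sill, rng_ = 0.01, 0.05, 2.0
    far = 1e3 if family in ("exponential", "gaussian") else rng_
    assert st.variogram_model(family, nugget, sill, rng_, far) == pytest.approx(sill, rel=1e-6)
    assert st.variogram_model(family, nugget, sill, rng_, 0.0) == 0.0  # process convention
    just = st.variogram_model(family, nugget, sill, rng_, 1e-9)
    assert just == pytest.approx(nugget, abs=1e-6)  # nugget discontinuity


def test_spherical_hits_sill_exactly_at_range():
    assert st.variogram_model("spherical", 0.002, 0.03, 1.7, 1.7) == pytest.approx(0.03)


def test_exponential_at_range_uses_study_scale_parameters():
    """Exponential curve evaluated at h=range with nugget 0.002274 and sill
    0.02453 equals nugget + (sill-nugget)(1 - e^-1) by the closed form."""
    nugget, sill, r = 0.002274, 0.02453, 3.0
    expected = nugget + (sill - nugget) * (1.0 - np.exp(-1.0))
    assert st.variogram_model("exponential", nugget, sill, r, r) == pytest.approx(expected)


def test_negative_distance_rejected():
    with pytest.raises(ValueError):
        st.variogram_model("exponential", 0, 1, 1, -0.5)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("family", FAMILIES)
def test_zero_noise_fit_recovers_truth(family):
    truth = st.VariogramFit(family, 0.004, 0.03, 2.5)
    h = np.linspace(0.3, 6.0, 12)
    emp = st.EmpiricalVariogram(h, truth(h), np.full(12, 30))
    fit = st.fit_variogram(emp, family)
    assert fit.nugget == pytest.approx(truth.nugget, abs=1e-6)
    assert fit.sill == pytest.approx(truth.sill, abs=1e-6)
    assert fit.range_ == pytest.approx(truth.range_, rel=1e-4)


def test_fit_requires_three_bins():
    emp = st.EmpiricalVariogram(np.array([1.0, 2.0]), np.array([0.1, 0.2]), np.array([5, 5]))
    with pytest.raises(ValueError):
        st.fit_variogram(emp, "exponential")


def test_all_families_carry_table_schema(study_map):
    """Fitting the four families returns four records each carrying nugget,
    sill, MSE and RMSSE."""
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 10, size=(40, 2))
    truth = st.VariogramFit("exponential", 0.002, 0.02, 3.0)
    vals = st.simulate_gaussian_field(truth, pts, seed=9)
    emp = st.empirical_semivariogram(pts, vals)
    fits = st.fit_all_families(emp, pts, vals)
    assert [f.family for f in fits] == list(FAMILIES)
    for f in fits:
        assert f.nugget >= 0 and f.sill >= f.nugget and f.range_ > 0
        assert np.isfinite(f.mse) and np.isfinite(f.rmsse)
    chosen = st.select_variogram(fits)
    assert chosen.mse == min(f.mse for f in fits)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------


def test_exact_interpolation_with_zero_nugget():
    rng = np.random.default_rng(10)
    pts = rng.uniform(0, 5, size=(8, 2))
    vals = rng.normal(size=8)
    fit = st.VariogramFit("exponential", 0.0, 0.04, 2.0)
    res = st.ordinary_kriging(fit, pts, vals, pts)
    np.testing.assert_allclose(res.prediction, vals, atol=1e-8)
    np.testing.assert_allclose(res.variance, 0.0, atol=1e-8)


def test_symmetric_pair_gives_half_weights():
    pts = np.array([[0.0, 0.0], [2.0, 0.0]])
    vals = np.array([1.0, 3.0])
    for family in FAMILIES:
        fit = st.VariogramFit(family, 0.001, 0.02, 1.5)
        res = st.ordinary_kriging(fit, pts, vals, np.array([[1.0, 0.0]]), return_weights=True)
        np.testing.assert_allclose(res.weights[0], [0.5, 0.5], atol=1e-10)
        assert res.prediction[0] == pytest.approx(2.0)


def test_weights_sum_to_one_and_match_dense_solver():
    """Kriging weights from the implementation equal an independently built
    dense bordered-system solve at every target."""
    rng = np.random.default_rng(11)
    pts = rng.uniform(0, 10, size=(10, 2))
    vals = rng.normal(size=10)
    targets = rng.uniform(0, 10, size=(6, 2))
    fit = st.VariogramFit("spherical", 0.003, 0.05, 4.0)
    res = st.ordinary_kriging(fit, pts, vals, targets, return_weights=True)
    np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-10)
    for t in range(len(targets)):
        n = len(pts)
        lhs = np.zeros((n + 1, n + 1))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d = np.linalg.norm(pts[i] - pts[j])
                    lhs[i, j] = fit(d)
        lhs[:n, n] = 1.0
        lhs[n, :n] = 1.0
        rhs = np.zeros(n + 1)
        for i in range(n):
            d = np.linalg.norm(pts[i] - targets[t])
            rhs[i] = fit(d) if d > 0 else fit.nugget
        rhs[n] = 1.0
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(res.weights[t], sol[:10], atol=1e-8)
        assert res.prediction[t] == pytest.approx(float(sol[:10] @ vals), abs=1e-8)


def test_duplicate_locations_error_names_pairs():
    pts = np.array([[0, 0], [1, 1], [0, 0]], dtype=float)
    fit = st.VariogramFit("exponential", 0.0, 0.02, 1.0)
    with pytest.raises(ValueError, match=r"duplicate.*\(0, 2\)"):
        st.ordinary_kriging(fit, pts, np.zeros(3), np.array([[0.5, 0.5]]))


# ---------------------------------------------------------------------------
# LOO cross-validation
# ---------------------------------------------------------------------------


def test_loo_matches_per_site_kriging_loop():
    rng = np.random.default_rng(12)
    pts = rng.uniform(0, 8, size=(12, 2))
    vals = rng.normal(size=12)
    fit = st.VariogramFit("exponential", 0.002, 0.03, 2.0)
    mse, rmsse = st.loo_cross_validate(fit, pts, vals)
    errs, stds = [], []
    for i in range(12):
        keep = np.arange(12) != i
        res = st.ordinary_kriging(fit, pts[keep], vals[keep], pts[i])
        e = res.prediction[0] - vals[i]
        errs.append(e**2)
        stds.append(e**2 / res.variance[0])
    assert mse == pytest.approx(np.mean(errs), rel=1e-10)
    assert rmsse == pytest.approx(np.sqrt(np.mean(stds)), rel=1e-10)


def test_deterministic_field_with_matching_model_has_tiny_mse():
    pts = np.stack(np.meshgrid(np.arange(5.0), np.arange(5.0)), -1).reshape(-1, 2)
    vals = 0.05 * pts[:, 0] + 0.03 * pts[:, 1]  # smooth deterministic trend
    fit = st.VariogramFit("gaussian", 0.0, 0.05, 6.0)
    mse, _ = st.loo_cross_validate(fit, pts, vals)
    assert mse < 1e-4


def test_pure_nugget_model_standardized_errors_near_unit_variance():
    """iid data kriged with a pure-nugget model: LOO standardized residuals
    are approximately unit variance, so RMSSE is near 1."""
    rng = np.random.default_rng(13)
    pts = rng.uniform(0, 20, size=(150, 2))
    sigma = 0.2
    vals = rng.normal(0, sigma, size=150)
    fit = st.VariogramFit("exponential", sigma**2, sigma**2 + 1e-9, 1e-3)
    _, rmsse = st.loo_cross_validate(fit, pts, vals)
    assert rmsse == pytest.approx(1.0, abs=0.15)
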