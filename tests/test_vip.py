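"""VIP scoring: closed forms, the normalization identity, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilfusion import fit_pls, compute_vip, select_variables, fit_sf_vip_sopls
from soilfusion import fit_sopls, select_lv_grid


def test_single_component_closed_form(rng):
    """w = (1,0,0,0) on 4 channels gives VIP = (2, 0, 0, 0)."""
    t = rng.standard_normal(30)
    X = np.column_stack([t, np.zeros((30, 3))])
    model = fit_pls(X, 2.0 * t, 1)
    vip = compute_vip(model)
    np.testing.assert_allclose(vip.scores, [2.0, 0.0, 0.0, 0.0], atol=1e-10)


def test_symmetric_channels_all_score_one(rng):
    """Exchangeable identical channels carry identical unit importance."""
    t = rng.standard_normal(40)
    X = np.tile(t[:, None], (1, 5))
    model = fit_pls(X, t, 1)
    vip = compute_vip(model)
    np.testing.assert_allclose(vip.scores, 1.0, atol=1e-10)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(1, 5))
def test_mean_squared_vip_is_one(seed, n_lv):
    """The normalization identity: mean(VIP^2) = 1 for any fitted model."""
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((40, 4))
    X = Z @ rng.standard_normal((4, 25)) + 0.05 * rng.standard_normal((40, 25))
    y = Z @ rng.standard_normal(4) + 0.05 * rng.standard_normal(40)
    model = fit_pls(X, y, n_lv)
    vip = compute_vip(model)
    assert np.mean(vip.scores**2) == pytest.approx(1.0, abs=1e-8)
    assert (vip.scores >= 0).all()


def test_vip_invariant_to_positive_y_scaling(rng):
    Z = rng.standard_normal((40, 3))
    X = Z @ rng.standard_normal((3, 20))
    y = Z @ rng.standard_normal(3)
    a = compute_vip(fit_pls(X, y, 3)).scores
    b = compute_vip(fit_pls(X, 1000.0 * y, 3)).scores
    np.testing.assert_allclose(a, b, rtol=1e-8)


def test_one_lv_vip_ranks_like_abs_weights(rng):
    """Single-component VIP is a monotone transform of |w|."""
    Z = rng.standard_normal((50, 2))
    X = Z @ rng.standard_normal((2, 15)) + 0.1 * rng.standard_normal((50, 15))
    y = Z @ rng.standard_normal(2)
    model = fit_pls(X, y, 1)
    vip = compute_vip(model)
    np.testing.assert_array_equal(
        np.argsort(vip.scores), np.argsort(np.abs(model.W[:, 0]))
    )


def test_strict_threshold_boundary():
    from soilfusion.vip import VIPResult

    exactly_one = VIPResult(scores=np.ones(4), threshold=1.0, strict=True)
    assert exactly_one.n_selected == 0  # strict > drops boundary scores
    gte = VIPResult(scores=np.ones(4), threshold=1.0, strict=False)
    assert gte.n_selected == 4


def test_select_variables_counts(rng):
    from soilfusion.vip import VIPResult

    v1 = VIPResult(scores=np.array([2.0, 0.0, 0.0, 0.0]))
    v2 = VIPResult(scores=np.array([1.5, 1.2, 0.1]))
    m1, m2 = select_variables(v1, v2, threshold=1.0)
    assert m1.sum() == 1 and m2.sum() == 2


def test_empty_selection_rejected(rng):
    from soilfusion.vip import VIPResult

    v1 = VIPResult(scores=np.array([2.0, 0.0]))
    v2 = VIPResult(scores=np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="lower the threshold"):
        select_variables(v1, v2, threshold=1.0)


def test_recovers_planted_informative_channels():
    """>= 8 of 10 informative channels among 500 selected in >= 90% of reps."""
    hits = 0
    reps = 20
    for seed in range(reps):
        rng = np.random.default_rng(400 + seed)
        n, p, k = 150, 500, 3
        Z = rng.standard_normal((n, k))
        S = np.zeros((k, p))
        info = np.arange(10)
        S[:, info] = rng.standard_normal((k, 10)) + np.sign(
            rng.standard_normal((k, 10))
        )
        X = Z @ S + 0.3 * rng.standard_normal((n, p))
        y = Z @ rng.standard_normal(k) + 0.1 * rng.standard_normal(n)
        vip = compute_vip(fit_pls(X, y, k))
        selected = np.flatnonzero(vip.mask)
        hits += np.isin(info, selected).sum() >= 8
    assert hits >= 18


def test_threshold_zero_reduces_to_full_sopls(rng):
    Z1 = rng.standard_normal((60, 2))
    Z2 = rng.standard_normal((60, 2))
    X1 = Z1 @ rng.standard_normal((2, 20)) + 0.05 * rng.standard_normal((60, 20))
    X2 = Z2 @ rng.standard_normal((2, 25)) + 0.05 * rng.standard_normal((60, 25))
    y = Z1[:, 0] + Z2[:, 0] + 0.05 * rng.standard_normal(60)
    vm = fit_sf_vip_sopls(X1, X2, y, folds=5, seed=1, threshold=-1.0, max_a1=3, max_a2=3)
    assert vm.n_variables == 45  # every channel retained
    grid = select_lv_grid(X1, X2, y, max_a1=3, max_a2=3, folds=5, seed=1)
    full = fit_sopls(X1, X2, y, grid.a1, grid.a2)
    np.testing.assert_allclose(
        vm.predict(X1, X2), full.predict(X1, X2), atol=1e-10
    )


def test_vip_sopls_deterministic(rng):
    Z1 = rng.standard_normal((50, 2))
    Z2 = rng.standard_normal((50, 2))
    X1 = Z1 @ rng.standard_normal((2, 30)) + 0.1 * rng.standard_normal((50, 30))
    X2 = Z2 @ rng.standard_normal((2, 30)) + 0.1 * rng.standard_normal((50, 30))
    y = Z1[:, 0] + Z2[:, 1]
    a = fit_sf_vip_sopls(X1, X2, y, folds=5, seed=2, max_a1=3, max_a2=3)
    b = fit_sf_vip_sopls(X1, X2, y, folds=5, seed=2, max_a1=3, max_a2=3)
    np.testing.assert_array_equal(a.mask1, b.mask1)
    np.testing.assert_array_equal(a.mask2, b.mask2)
    np.testing.assert_allclose(a.predict(X1, X2), b.predict(X1, X2), atol=0)


def test_vip_requires_fitted_components(rng):
    X = rng.standard_normal((20, 5))
    y = rng.standard_normal(20)
    model = fit_pls(X, y, 2).truncate(0)
    with pytest.raises(ValueError, match="latent variable"):
        compute_vip(model)
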