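"""Sequential orthogonalized two-block PLS: equivalences and invariances."""

import numpy as np
import pytest

from soilfusion import fit_pls, fit_sopls, predict_sopls, select_lv_grid
from soilfusion import SynthConfig, generate


def _two_block_data(rng, n=60, p1=25, p2=30, k1=2, k2=2, noise=0.05, c=0.5):
    """Block 1 sees k1 factors, block 2 sees k2 others; y mixes them."""
    Z1 = rng.standard_normal((n, k1))
    Z2 = rng.standard_normal((n, k2))
    X1 = Z1 @ rng.standard_normal((k1, p1)) + noise * rng.standard_normal((n, p1))
    X2 = Z2 @ rng.standard_normal((k2, p2)) + noise * rng.standard_normal((n, p2))
    s1 = Z1 @ rng.standard_normal(k1)
    s2 = Z2 @ rng.standard_normal(k2)
    y = np.sqrt(1 - c) * s1 / s1.std() + np.sqrt(c) * s2 / s2.std()
    y = y + noise * rng.standard_normal(n)
    return X1, X2, y


def test_a2_zero_reduces_to_block1_pls(rng):
    X1, X2, y = _two_block_data(rng)
    so = fit_sopls(X1, X2, y, a1=3, a2=0)
    pls = fit_pls(X1, y, 3)
    np.testing.assert_array_equal(so.predict(X1, X2), pls.predict(X1))


def test_a1_zero_fits_block2_alone(rng):
    X1, X2, y = _two_block_data(rng)
    so = fit_sopls(X1, X2, y, a1=0, a2=3)
    pls = fit_pls(X2, y, 3)
    np.testing.assert_allclose(so.predict(X1, X2), pls.predict(X2), atol=1e-10)


def test_orthogonality_of_x2orth_to_t1(rng):
    X1, X2, y = _two_block_data(rng)
    so = fit_sopls(X1, X2, y, a1=3, a2=2)
    t1 = so.block1.T
    X2c = X2 - so.x2_mean
    X2orth = X2c - t1 @ so.ortho_coef
    cross = t1.T @ X2orth
    scale = np.abs(t1).max() * np.abs(X2orth).max() + 1e-30
    assert np.abs(cross).max() < 1e-8 * scale


def test_duplicate_block_contributes_nothing(rng):
    """X2 = X1 at full stage-1 rank leaves no stage-2 signal."""
    n, k = 50, 3
    Z = rng.standard_normal((n, k))
    X1 = Z @ rng.standard_normal((k, 20))
    y = Z @ rng.standard_normal(k)
    with pytest.warns(UserWarning, match="exhausted"):  # X2orth is ~zero
        so = fit_sopls(X1, X1.copy(), y, a1=k, a2=1)
    y1, y2 = so.stage_predictions(X1, X1)
    assert np.abs(y2).max() < 1e-6 * max(np.abs(y1 + y2).max(), 1e-30)


@pytest.mark.parametrize("which", ["block1", "block2"])
def test_block_scaling_invariance(rng, which):
    X1, X2, y = _two_block_data(rng)
    base = fit_sopls(X1, X2, y, a1=2, a2=2)
    if which == "block1":
        scaled = fit_sopls(1000.0 * X1, X2, y, a1=2, a2=2)
        pred = scaled.predict(1000.0 * X1, X2)
    else:
        scaled = fit_sopls(X1, 1000.0 * X2, y, a1=2, a2=2)
        pred = scaled.predict(X1, 1000.0 * X2)
    np.testing.assert_allclose(pred, base.predict(X1, X2), rtol=1e-8)


def test_additivity_of_stage_predictions(rng):
    X1, X2, y = _two_block_data(rng)
    so = fit_sopls(X1, X2, y, a1=2, a2=2)
    y1, y2 = so.stage_predictions(X1, X2)
    np.testing.assert_array_equal(y1 + y2, so.predict(X1, X2))


def test_training_prediction_matches_fit(rng):
    X1, X2, y = _two_block_data(rng, noise=0.0)
    so = fit_sopls(X1, X2, y, a1=2, a2=2)
    np.testing.assert_allclose(so.predict(X1, X2).ravel(), y, atol=1e-8)


def test_single_sample_prediction_matches_batch_row(rng):
    X1, X2, y = _two_block_data(rng)
    so = fit_sopls(X1, X2, y, a1=2, a2=1)
    batch = predict_sopls(so, X1, X2)
    single = predict_sopls(so, X1[3:4], X2[3:4])
    np.testing.assert_allclose(single, batch[3:4], atol=1e-12)


def test_x2_in_span_of_orthogonalizer_gives_zero_stage2_scores(rng):
    X1, X2, y = _two_block_data(rng)
    so = fit_sopls(X1, X2, y, a1=3, a2=2)
    # craft new X2 rows lying exactly on the stored T1 -> X2 map
    t_new = so.block1.scores(X1[:5])
    X2_new = so.x2_mean + t_new @ so.ortho_coef
    _, X2orth = so._stage_inputs(X1[:5], X2_new)
    assert np.abs(X2orth).max() < 1e-8 * (np.abs(X2).max() + 1)


def test_sample_mismatch_rejected(rng):
    X1, X2, y = _two_block_data(rng)
    with pytest.raises(ValueError, match="sample mismatch"):
        fit_sopls(X1[:-1], X2, y, 2, 2)


def test_empty_model_rejected(rng):
    X1, X2, y = _two_block_data(rng)
    with pytest.raises(ValueError, match="empty model"):
        fit_sopls(X1, X2, y, 0, 0)


def test_grid_prefers_a2_zero_when_y_depends_only_on_block1():
    """An uninformative second block should be assigned zero components.

    n is large enough that chance correlations between block-2 factors
    and the response noise fall inside the parsimony tolerance.
    """
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        X1, X2, y = _two_block_data(rng, n=150, c=0.0, noise=0.05)
        res = select_lv_grid(X1, X2, y, max_a1=4, max_a2=4, folds=5, seed=seed)
        hits += res.a2 == 0
    assert hits >= 8


def test_grid_uses_block2_when_blocks_complement():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(300 + seed)
        X1, X2, y = _two_block_data(rng, c=0.5, noise=0.05)
        res = select_lv_grid(X1, X2, y, max_a1=4, max_a2=4, folds=5, seed=seed)
        hits += res.a2 >= 1
    assert hits >= 8


def test_grid_deterministic(rng):
    X1, X2, y = _two_block_data(rng)
    a = select_lv_grid(X1, X2, y, max_a1=3, max_a2=3, folds=5, seed=1)
    b = select_lv_grid(X1, X2, y, max_a1=3, max_a2=3, folds=5, seed=1)
    assert (a.a1, a.a2) == (b.a1, b.a2)
    np.testing.assert_array_equal(a.rmsecv, b.rmsecv)


def test_grid_matches_per_fold_refit_oracle(rng):
    """The nested-path grid equals explicit fit_sopls refits in each fold."""
    from soilfusion.pls import make_folds

    X1, X2, y = _two_block_data(rng, n=40)
    folds, seed = 4, 5
    res = select_lv_grid(X1, X2, y, max_a1=2, max_a2=2, folds=folds, seed=seed)
    labels = make_folds(len(y), folds, seed)
    for a1, a2 in [(1, 1), (2, 0), (0, 2), (2, 2)]:
        sse = 0.0
        for f in range(folds):
            te = labels == f
            m = fit_sopls(X1[~te], X2[~te], y[~te], a1, a2)
            sse += float(np.sum((y[te] - m.predict(X1[te], X2[te]).ravel()) ** 2))
        np.testing.assert_allclose(res.rmsecv[a1, a2], np.sqrt(sse / len(y)), atol=1e-10)


def test_fusion_beats_block1_alone_on_complementary_data():
    """With complementary blocks, sequential fusion should not lose to
    block 1 alone at matched CV-selected complexity."""
    from soilfusion import select_lv, kennard_stone

    wins = 0
    reps = 10
    for seed in range(reps):
        cfg = SynthConfig(
            n_samples=90, n_mir_channels=80, n_xrf_channels=100, n_latents=6,
            complementarity=0.5, seed=700 + seed,
        )
        ds = generate(cfg)
        split = kennard_stone(ds.mir, 0.8)
        tr, te = list(split.train_ids), list(split.test_ids)
        X1tr, X1te = ds.mir.subset(tr).values, ds.mir.subset(te).values
        X2tr, X2te = ds.xrf.subset(tr).values, ds.xrf.subset(te).values
        y_tr = ds.attributes.subset(tr).column("pH")
        y_te = ds.attributes.subset(te).column("pH")
        cv1 = select_lv(X1tr, y_tr, max_lv=8, folds=5, seed=seed)
        rmse_pls = np.sqrt(
            np.mean((y_te - fit_pls(X1tr, y_tr, cv1.n_lv).predict(X1te).ravel()) ** 2)
        )
        grid = select_lv_grid(X1tr, X2tr, y_tr, max_a1=6, max_a2=6, folds=5, seed=seed)
        so = fit_sopls(X1tr, X2tr, y_tr, grid.a1, grid.a2)
        rmse_so = np.sqrt(np.mean((y_te - so.predict(X1te, X2te).ravel()) ** 2))
        wins += rmse_so <= rmse_pls
    assert wins >= 9
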