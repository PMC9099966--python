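"""Spectral pre-treatment operators and the per-sensor recipe chains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilfusion import SpectraBlock, mir_preset, xrf_preset, apply_recipe, fit_recipe
from soilfusion.preprocess import (
    moving_average,
    max_normalize,
    snv,
    msc,
    msc_reference,
    savitzky_golay,
    baseline_correct,
    compton_normalize,
    mask_channels,
    PreprocessSpec,
)


def _block(values, axis=None, label="B"):
    values = np.atleast_2d(np.asarray(values, float))
    axis = np.arange(values.shape[1], dtype=float) if axis is None else np.asarray(axis, float)
    return SpectraBlock(
        samples=[f"s{i}" for i in range(values.shape[0])], axis=axis, values=values, label=label
    )


# --- moving average ------------------------------------------------------

def test_moving_average_constant_unchanged():
    b = _block([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
    np.testing.assert_array_equal(moving_average(b, 5).values, b.values)


def test_moving_average_window_one_is_identity():
    b = _block([1.0, 5.0, 2.0, 8.0])
    np.testing.assert_array_equal(moving_average(b, 1).values, b.values)


def test_moving_average_shrinking_edges():
    b = _block([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    out = moving_average(b, 5).values[0]
    assert out[2] == pytest.approx(3.0)          # full window
    assert out[0] == pytest.approx(2.0)          # mean(1, 2, 3)
    assert out[6] == pytest.approx(6.0)          # mean(5, 6, 7)


@pytest.mark.parametrize("window", [2, 4, 9])
def test_moving_average_invalid_window(window):
    b = _block([1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.raises(ValueError):
        moving_average(b, window)


# --- normalizations ------------------------------------------------------

def test_max_normalize_example():
    out = max_normalize(_block([2.0, 4.0, 8.0]))
    np.testing.assert_allclose(out.values[0], [0.25, 0.5, 1.0])


def test_max_normalize_rejects_nonpositive_max():
    with pytest.raises(ValueError, match="s1"):
        max_normalize(_block([[1.0, 2.0], [0.0, 0.0]]))


def test_snv_example_and_moments():
    out = snv(_block([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(out.values[0], [-1.0, 0.0, 1.0])


def test_snv_affine_invariance(rng):
    x = rng.random((3, 40))
    base = snv(_block(x)).values
    shifted = snv(_block(3.0 + 2.5 * x)).values
    np.testing.assert_allclose(base, shifted, atol=1e-12)


def test_snv_rejects_constant_spectrum():
    with pytest.raises(ValueError, match="constant"):
        snv(_block([5.0, 5.0, 5.0]))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_idempotence_of_row_normalizations(seed):
    """max-normalize and SNV are fixed points on their own output."""
    x = np.random.default_rng(seed).random((4, 30)) + 0.1
    b = _block(x)
    one = max_normalize(b)
    np.testing.assert_allclose(max_normalize(one).values, one.values, atol=1e-12)
    one = snv(b)
    np.testing.assert_allclose(snv(one).values, one.values, atol=1e-12)


# --- MSC -----------------------------------------------------------------

def test_msc_reference_spectrum_unchanged(rng):
    ref = rng.random(50)
    b = _block(ref)
    np.testing.assert_allclose(msc(b, reference=ref).values[0], ref, atol=1e-10)


def test_msc_recovers_reference_from_affine_distortion(rng):
    ref = rng.random(50)
    distorted = _block(np.vstack([3.0 + 2.0 * ref, -1.0 + 0.5 * ref]))
    out = msc(distorted, reference=ref)
    np.testing.assert_allclose(out.values[0], ref, atol=1e-9)
    np.testing.assert_allclose(out.values[1], ref, atol=1e-9)


def test_msc_rejects_constant_reference():
    with pytest.raises(ValueError, match="constant reference"):
        msc(_block([1.0, 2.0, 3.0]), reference=np.full(3, 7.0))


def test_msc_training_reference_frozen_for_test_data(small_dataset):
    """Recipe state learned on train is reused verbatim on test spectra."""
    mir = small_dataset.mir
    train = mir.subset(mir.samples[:40])
    test = mir.subset(mir.samples[40:])
    spec = PreprocessSpec(steps=(("msc", {}),), sensor="MIR")
    recipe = fit_recipe(train, spec)
    out = recipe.transform(test)
    expected = msc(test, reference=msc_reference(train))
    np.testing.assert_allclose(out.values, expected.values, atol=1e-12)
    own = apply_recipe(test, spec)  # test's own reference differs
    assert not np.allclose(out.values, own.values)


# --- Savitzky-Golay ------------------------------------------------------

def test_savgol_reproduces_quadratic_interior(rng):
    i = np.arange(60, dtype=float)
    quad = 2.0 + 0.3 * i - 0.01 * i**2
    out = savitzky_golay(_block(quad), window=11, polyorder=2).values[0]
    np.testing.assert_allclose(out[5:-5], quad[5:-5], atol=1e-9)


def test_savgol_smooths_noise(rng):
    i = np.arange(200, dtype=float)
    noisy = np.sin(i / 10) + 0.3 * rng.standard_normal(200)
    out = savitzky_golay(_block(noisy)).values[0]
    assert out.var() <= noisy.var()


def test_savgol_window_larger_than_block_rejected():
    with pytest.raises(ValueError, match="window"):
        savitzky_golay(_block([1.0, 2.0, 3.0, 4.0, 5.0]), window=11)


# --- baseline + Compton --------------------------------------------------

def test_baseline_removes_pure_ramp():
    axis = np.linspace(0, 30, 400)
    ramp = 5.0 + 0.8 * axis
    out = baseline_correct(_block(ramp, axis=axis), smoothness=1e4).values[0]
    assert np.abs(out).max() < 0.05 * ramp.max()


def test_baseline_preserves_peak_on_ramp():
    axis = np.linspace(0, 30, 600)
    peak = 10.0 * np.exp(-0.5 * ((axis - 12.0) / 0.25) ** 2)
    spectrum = peak + 2.0 + 0.5 * axis
    out = baseline_correct(_block(spectrum, axis=axis), smoothness=1e5).values[0]
    recovered = out[np.argmin(np.abs(axis - 12.0))]
    assert recovered == pytest.approx(10.0, rel=0.05)


def test_baseline_zero_spectrum_stays_zero():
    out = baseline_correct(_block(np.zeros(50)))
    np.testing.assert_array_equal(out.values, np.zeros((1, 50)))


def test_compton_normalize_unit_window_integral(small_dataset):
    xrf = small_dataset.xrf
    out = compton_normalize(xrf, window=(18.0, 22.0))
    inside = (xrf.axis >= 18.0) & (xrf.axis <= 22.0)
    integrals = np.trapezoid(out.values[:, inside], xrf.axis[inside], axis=1)
    np.testing.assert_allclose(integrals, 1.0, atol=1e-12)
    # idempotence and scale invariance
    again = compton_normalize(out, window=(18.0, 22.0))
    np.testing.assert_allclose(again.values, out.values, atol=1e-12)
    scaled = compton_normalize(xrf.with_values(10.0 * xrf.values), window=(18.0, 22.0))
    np.testing.assert_allclose(scaled.values, out.values, atol=1e-12)


def test_compton_window_outside_axis_rejected(small_dataset):
    with pytest.raises(ValueError, match="outside axis"):
        compton_normalize(small_dataset.xrf, window=(40.0, 50.0))


def test_mask_channels_drops_detector_spike(small_dataset):
    out = mask_channels(small_dataset.xrf, interval=(2.3, 2.7))
    assert not np.any((out.axis >= 2.3) & (out.axis <= 2.7))
    assert out.n_channels < small_dataset.xrf.n_channels


# --- recipes -------------------------------------------------------------

def test_recipes_preserve_sample_count_and_order(small_dataset):
    for preset in (mir_preset("pH"), mir_preset("Ca")):
        out = apply_recipe(small_dataset.mir, preset)
        assert out.samples == small_dataset.mir.samples
    out = apply_recipe(small_dataset.xrf, xrf_preset("K"))
    assert out.samples == small_dataset.xrf.samples


def test_mir_ph_preset_normalizes_to_unity(small_dataset):
    out = apply_recipe(small_dataset.mir, mir_preset("pH"))
    np.testing.assert_allclose(out.values.max(axis=1), 1.0, atol=1e-12)


def test_preset_structure_matches_recipe_table():
    assert [s for s, _ in mir_preset("pH").steps] == ["moving_average", "max_normalize"]
    assert [s for s, _ in mir_preset("K").steps] == ["moving_average"]
    assert [s for s, _ in mir_preset("P").steps] == ["moving_average", "snv"]
    assert [s for s, _ in xrf_preset("Ca").steps] == [
        "baseline_correct", "compton_normalize", "moving_average", "msc",
    ]


def test_empty_recipe_is_identity(small_dataset):
    spec = PreprocessSpec(steps=(), sensor="MIR")
    out = apply_recipe(small_dataset.mir, spec)
    np.testing.assert_array_equal(out.values, small_dataset.mir.values)


def test_unknown_operator_rejected():
    with pytest.raises(ValueError, match="unknown preprocessing operator"):
        PreprocessSpec(steps=(("wavelet", {}),), sensor="MIR")


def test_recipe_yaml_round_trip(tmp_path):
    spec = xrf_preset("P")
    spec.save(tmp_path / "r.yaml")
    back = PreprocessSpec.load(tmp_path / "r.yaml")
    assert back.steps == spec.steps
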