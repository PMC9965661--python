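import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_corrected
from marbod.errors import ValidationError
from marbod.kinetics import (
    ModelForm,
    fit,
    half_degradation_time,
    model_value,
)

POSITIVE = st.floats(0.1, 50.0)

ID016 = {"bod_l": 22.2, "a": 10.0, "b": 1.40}


# -- model curves -----------------------------------------------------------


@pytest.mark.parametrize(
    "form, params",
    [
        (ModelForm.FIXED_SLOPE, {"bod_l": 30.0, "a": 7.0}),
        (ModelForm.VARIABLE_SLOPE, {"bod_l": 30.0, "a": 7.0, "b": 2.3}),
        (ModelForm.ASYMMETRIC, {"bod_l": 30.0, "a": 7.0, "b": 2.3, "s": 0.4}),
        (ModelForm.ASYMMETRIC, {"bod_l": 30.0, "a": 7.0, "b": 2.3, "s": 5.0}),
    ],
)
def test_half_asymptote_at_x_equals_a(form, params):
    """Every form passes through BOD_L/2 at the half-degradation time."""
    assert model_value(form, params, params["a"]) == pytest.approx(params["bod_l"] / 2)


def test_fixed_slope_is_variable_slope_with_b_1():
    x = np.linspace(0.0, 30.0, 61)
    fixed = model_value(ModelForm.FIXED_SLOPE, {"bod_l": 18.0, "a": 9.0}, x)
    var = model_value(ModelForm.VARIABLE_SLOPE, {"bod_l": 18.0, "a": 9.0, "b": 1.0}, x)
    assert np.allclose(fixed, var)


def test_asymmetric_reduces_to_variable_slope_at_s_1():
    x = np.linspace(0.0, 30.0, 61)
    var = model_value(ModelForm.VARIABLE_SLOPE, {"bod_l": 18.0, "a": 9.0, "b": 1.7}, x)
    asym = model_value(
        ModelForm.ASYMMETRIC, {"bod_l": 18.0, "a": 9.0, "b": 1.7, "s": 1.0}, x
    )
    assert np.allclose(var, asym)


def test_asymptote_approached_at_long_times():
    assert model_value(ModelForm.VARIABLE_SLOPE, ID016, 1e4) == pytest.approx(
        22.2, rel=1e-3
    )


def test_zero_time_maps_to_zero_and_negatives_rejected():
    assert model_value(ModelForm.VARIABLE_SLOPE, ID016, 0.0) == 0.0
    with pytest.raises(ValidationError):
        model_value(ModelForm.VARIABLE_SLOPE, ID016, -1.0)
    with pytest.raises(ValidationError):
        model_value(ModelForm.VARIABLE_SLOPE, {**ID016, "b": -1.0}, 5.0)
    with pytest.raises(ValidationError, match="missing"):
        model_value(ModelForm.VARIABLE_SLOPE, {"bod_l": 1.0, "a": 1.0}, 5.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(bod_l=POSITIVE, a=POSITIVE, b=st.floats(0.1, 10.0), s=st.floats(0.1, 10.0))
def test_curves_strictly_increase_in_time(bod_l, a, b, s):
    x = np.linspace(0.1, 40.0, 200)
    for form, params in [
        (ModelForm.VARIABLE_SLOPE, {"bod_l": bod_l, "a": a, "b": b}),
        (ModelForm.ASYMMETRIC, {"bod_l": bod_l, "a": a, "b": b, "s": s}),
    ]:
        y = model_value(form, params, x)
        assert np.all(np.diff(y) > 0)


# -- fitting ----------------------------------------------------------------


def test_noiseless_variable_slope_round_trip():
    series = make_corrected(params=ID016)
    f = fit(series, ModelForm.VARIABLE_SLOPE)
    assert f.params["b"] == pytest.approx(1.40, rel=1e-4)
    assert f.params["bod_l"] == pytest.approx(22.2, rel=1e-4)
    assert f.params["a"] == pytest.approx(10.0, rel=1e-4)
    assert f.rss == pytest.approx(0.0, abs=1e-10)
    for name in ("bod_l", "a", "b"):
        lo, hi = f.ci[name]
        assert lo <= f.params[name] <= hi


def test_noiseless_fixed_slope_round_trip():
    series = make_corrected(ModelForm.FIXED_SLOPE, {"bod_l": 40.0, "a": 6.0})
    f = fit(series, ModelForm.FIXED_SLOPE)
    assert f.params["bod_l"] == pytest.approx(40.0, rel=1e-6)
    assert f.params["a"] == pytest.approx(6.0, rel=1e-6)
    assert f.rss == pytest.approx(0.0, abs=1e-12)


def test_noiseless_asymmetric_round_trip():
    truth = {"bod_l": 60.0, "a": 12.0, "b": 2.0, "s": 0.5}
    f = fit(make_corrected(ModelForm.ASYMMETRIC, truth), ModelForm.ASYMMETRIC)
    for k, v in truth.items():
        assert f.params[k] == pytest.approx(v, rel=1e-3)


def test_constant_zero_series_is_refused():
    series = make_corrected(params={"bod_l": 1.0, "a": 1.0, "b": 1.0})
    series.bod_replicates = np.zeros_like(series.bod_replicates)
    series.bod_corrected = np.zeros_like(series.bod_corrected)
    f = fit(series, ModelForm.VARIABLE_SLOPE)
    assert f.refused
    assert not f.ci_calculable["bod_l"]
    assert f.bod_l == pytest.approx(0.0)


def test_refused_fit_reports_mean_of_last_three_readings():
    series = make_corrected(params={"bod_l": 1.0, "a": 1.0, "b": 1.0})
    noise = np.array([-0.5] * (len(series.times) - 3) + [1.0, 2.0, 3.0])
    # pull the whole curve below zero except a spurious tail
    series.bod_corrected = noise - 10.0
    series.bod_replicates = np.tile(noise - 10.0, (2, 1))
    f = fit(series)
    assert f.refused
    assert f.bod_l == pytest.approx(np.mean([-9.0, -8.0, -7.0]))


def test_half_degradation_time_is_a():
    f = fit(make_corrected(params=ID016))
    a = half_degradation_time(f)
    assert model_value(f.model, f.params, a) == pytest.approx(f.bod_l / 2, rel=1e-6)


def test_time_rescaling_doubles_a_and_preserves_b():
    base = make_corrected(params=ID016)
    f1 = fit(base)
    scaled = make_corrected(params=ID016, times=base.times)
    scaled.times = base.times * 2.0
    f2 = fit(scaled)
    assert f2.params["a"] == pytest.approx(2 * f1.params["a"], rel=1e-4)
    assert f2.params["b"] == pytest.approx(f1.params["b"], rel=1e-4)
    assert f2.params["bod_l"] == pytest.approx(f1.params["bod_l"], rel=1e-4)


def test_optimizer_beats_grid_search_oracle():
    """On a small dataset the optimizer's rss is no worse than a brute-force
    lattice over (BOD_L, a, b)."""
    rng = np.random.default_rng(7)
    series = make_corrected(
        params=ID016, times=[3.0, 7.0, 14.0, 21.0, 28.0], noise_sd=0.8,
        n_replicates=1, rng=rng,
    )
    f = fit(series, ModelForm.VARIABLE_SLOPE)
    x, y = series.times, series.bod_corrected
    best = np.inf
    for bod_l, a, b in itertools.product(
        np.linspace(15.0, 30.0, 40), np.linspace(5.0, 15.0, 40), np.linspace(0.5, 3.0, 40)
    ):
        rss = np.sum((bod_l / (1.0 + (a / x) ** b) - y) ** 2)
        best = min(best, rss)
    assert f.rss <= best + 1e-6


def test_recovery_under_noise_is_unbiased_enough():
    """Median relative error of BOD_L stays within 5% for noise at 5% of the
    asymptote (200 stochastic replicates)."""
    rng = np.random.default_rng(42)
    errs = []
    for _ in range(200):
        series = make_corrected(params=ID016, noise_sd=0.05 * 22.2, rng=rng)
        f = fit(series)
        errs.append(abs(f.params["bod_l"] - 22.2) / 22.2)
    assert np.median(errs) <= 0.05


def test_pooled_replicates_enter_the_fit():
    series = make_corrected(params=ID016, n_replicates=2)
    f = fit(series)
    assert f.n_obs == 2 * len(series.times)
    assert f.df == f.n_obs - 3
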