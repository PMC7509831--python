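"""Sigmoidal fibrillation-kinetics fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npamyloid.errors import DataError, NoTransitionError
from npamyloid.synth import gen_tht
from npamyloid.tht import (SigmoidFit, ThTCurve, compare_fits, fit_sigmoid,
                           max_intensity_decrease, read_tht, sigmoid_model,
                           write_tht)

GRID = np.arange(0.0, 48.1, 0.5)


def make_curve(f0, a, k, th, noise=0.0, seed=0, label="c"):
    f = sigmoid_model(GRID, f0, a, k, th)
    if noise:
        f = f + np.random.default_rng(seed).normal(0, noise, GRID.shape)
    return ThTCurve(GRID.copy(), f, label=label)


def test_model_midpoint_and_asymptotes():
    assert sigmoid_model(20.0, 5.0, 100.0, 0.5, 20.0) == pytest.approx(55.0)
    assert sigmoid_model(1e6, 5.0, 100.0, 0.5, 20.0) == pytest.approx(105.0)
    assert sigmoid_model(-1e6, 5.0, 100.0, 0.5, 20.0) == pytest.approx(5.0)


def test_model_closed_form_value():
    # F0=0, A=100, k=0.5, t_half=20 at t=24: 100 / (1 + e^-2)
    expect = 100.0 / (1.0 + np.exp(-2.0))
    assert sigmoid_model(24.0, 0.0, 100.0, 0.5, 20.0) == pytest.approx(
        expect)
    assert expect == pytest.approx(88.08, abs=0.005)


@pytest.mark.parametrize("theta", [
    (5.0, 95.0, 0.4, 18.0),
    (0.0, 100.0, 0.5, 20.0),
    (12.0, 40.0, 0.15, 30.0),
    (2.0, 300.0, 1.2, 8.0),
])
def test_noise_free_round_trip(theta):
    fit = fit_sigmoid(make_curve(*theta))
    assert fit.converged
    rec = (fit.f0, fit.amplitude, fit.rate, fit.t_half)
    for got, want in zip(rec, theta):
        assert got == pytest.approx(want, rel=1e-6, abs=1e-6)
    assert fit.lag_time == pytest.approx(theta[3] - 2.0 / theta[2], rel=1e-6)


def test_lag_identity_holds_for_every_fit():
    for seed in range(20):
        fit = fit_sigmoid(make_curve(5, 95, 0.4, 18, noise=2.0, seed=seed))
        assert fit.lag_time + 2.0 / fit.rate == pytest.approx(fit.t_half,
                                                              abs=1e-12)


def test_noisy_rate_recovery_median_within_ten_percent():
    ks = []
    for seed in range(200):
        fit = fit_sigmoid(make_curve(5, 95, 0.4, 18, noise=2.0, seed=seed))
        if fit.converged:
            ks.append(fit.rate)
    assert len(ks) > 190
    assert abs(np.median(ks) - 0.4) / 0.4 < 0.10


def test_flat_curve_raises_no_transition():
    with pytest.raises(NoTransitionError, match="no transition"):
        fit_sigmoid(ThTCurve(GRID, np.full_like(GRID, 7.0)))


def test_too_few_points_rejected():
    with pytest.raises(DataError):
        ThTCurve(np.arange(4.0), np.arange(4.0))


def fake_fit(a, k=0.5, lag=10.0, label="x"):
    return SigmoidFit(f0=0.0, amplitude=a, rate=k, t_half=lag + 2 / k,
                      lag_time=lag, rss=0.0, converged=True, label=label)


def test_max_intensity_decrease_formula():
    assert max_intensity_decrease(fake_fit(100), fake_fit(100)) == 0.0
    assert max_intensity_decrease(fake_fit(100), fake_fit(40)) == \
        pytest.approx(60.0)
    assert max_intensity_decrease(fake_fit(100), fake_fit(0)) == \
        pytest.approx(100.0)
    with pytest.raises(DataError):
        max_intensity_decrease(fake_fit(0.0), fake_fit(10))


def test_compare_fits_flags_inhibition_direction():
    fits = [fake_fit(100, k=0.5, lag=10, label="control"),
            fake_fit(40, k=0.25, lag=16, label="treated")]
    table = compare_fits(fits, "control")
    treated = table[table.label == "treated"].iloc[0]
    assert treated.lag_increased and treated.rate_decreased \
        and treated.amplitude_decreased
    assert treated.pct_decrease == pytest.approx(60.0)
    ctrl = table[table.label == "control"].iloc[0]
    assert not (ctrl.lag_increased or ctrl.rate_decreased
                or ctrl.amplitude_decreased)
    assert ctrl.pct_decrease == 0.0


def test_graded_amplitudes_give_ordered_decreases():
    fits = [fake_fit(100, label="control"), fake_fit(80, label="a"),
            fake_fit(50, label="b"), fake_fit(20, label="c")]
    table = compare_fits(fits, "control").set_index("label")
    decs = table.loc[["a", "b", "c"], "pct_decrease"].to_numpy()
    assert (np.diff(decs) > 0).all()


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.floats(-30.0, 30.0))
def test_fit_invariant_under_time_shift(shift):
    base = make_curve(5, 95, 0.4, 18)
    shifted = ThTCurve(GRID + shift + 31.0, base.fluorescence)
    a = fit_sigmoid(base)
    b = fit_sigmoid(shifted)
    assert b.t_half - a.t_half == pytest.approx(shift + 31.0, rel=1e-5,
                                                abs=1e-5)
    assert b.rate == pytest.approx(a.rate, rel=1e-5)
    assert b.amplitude == pytest.approx(a.amplitude, rel=1e-5)
    assert b.f0 == pytest.approx(a.f0, rel=1e-4, abs=1e-6)


def test_io_round_trip(tmp_path):
    curves = gen_tht(seed=4, n_replicates=2)
    path = tmp_path / "tht.tsv"
    write_tht(curves, path)
    back = read_tht(path)
    assert len(back) == len(curves)
    key = {(c.label, c.replicate): c for c in curves}
    for c in back:
        orig = key[(c.label, c.replicate)]
        assert np.allclose(c.fluorescence, orig.fluorescence)
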