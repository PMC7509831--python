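"""First-order elimination fitting and biodistribution summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npamyloid.errors import DataError
from npamyloid.pk import (PKSeries, fit_first_order, group_mean_series,
                          half_life, peak_summary, read_pk, write_pk)
from npamyloid.synth import gen_pk


def test_half_life_worked_values():
    assert round(half_life(0.0211), 1) == 14.3
    assert round(half_life(0.0203), 1) == 14.8
    assert half_life(np.log10(2.0)) == pytest.approx(1.0)
    with pytest.raises(DataError):
        half_life(0.0)


def test_half_life_times_slope_identity():
    for b in (0.001, 0.0211, 0.5, 3.0):
        assert half_life(b) * b == pytest.approx(np.log10(2.0), abs=1e-15)


def test_noise_free_round_trip_exact():
    t = np.array([0.0, 6.0, 12.0, 24.0, 48.0])
    series = PKSeries(t, 10 ** (1.4 - 0.02 * t))
    fit = fit_first_order(series)
    assert fit.intercept == pytest.approx(1.4, abs=1e-12)
    assert fit.slope == pytest.approx(0.02, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
    assert fit.eliminating


def test_two_point_half_life():
    fit = fit_first_order(PKSeries(np.array([0.0, 10.0, 20.0]),
                                   np.array([100.0, 50.0, 25.0])))
    assert fit.half_life_h == pytest.approx(10.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_constant_concentration_flagged():
    fit = fit_first_order(PKSeries(np.array([0.0, 6.0, 12.0]),
                                   np.array([5.0, 5.0, 5.0])))
    assert not fit.eliminating
    assert np.isnan(fit.half_life_h)


def test_nonpositive_concentration_rejected():
    with pytest.raises(DataError):
        PKSeries(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.0, 2.0]))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.floats(0.01, 1e4))
def test_scale_equivariance(c):
    t = np.array([6.0, 12.0, 24.0, 48.0])
    base = PKSeries(t, 10 ** (1.396 - 0.0211 * t))
    scaled = PKSeries(t, base.concentration * c)
    fa, fb = fit_first_order(base), fit_first_order(scaled)
    assert fb.intercept - fa.intercept == pytest.approx(np.log10(c),
                                                        abs=1e-9)
    assert fb.slope == pytest.approx(fa.slope, abs=1e-12)
    assert fb.half_life_h == pytest.approx(fa.half_life_h, rel=1e-9)


def test_noisy_slope_recovery():
    """Lognormal noise, 4 subjects/time: median slope within 10% of truth."""
    slopes = []
    for seed in range(300):
        series = gen_pk(seed=seed, noise_sd=0.1)
        fit = fit_first_order(group_mean_series(series))
        slopes.append(fit.slope)
    assert abs(np.median(slopes) - 0.0211) / 0.0211 < 0.10


def grid_series(values, group=""):
    t = np.array([6.0, 12.0, 24.0, 48.0])
    return PKSeries(t, np.asarray(values, dtype=float), group=group)


def test_peak_identity_fold_change():
    control = grid_series([4.0, 3.0, 2.0, 1.0])
    summary = peak_summary([control], control)
    assert summary.fold_change_vs_control == pytest.approx(1.0)
    assert summary.time_of_peak_h == 6.0


def test_peak_ten_fold_at_twelve_hours():
    control = grid_series([1.0, 1.0, 1.0, 1.0])
    group = [grid_series([2.0, 10.0, 3.0, 1.0]),
             grid_series([2.0, 10.0, 3.0, 1.0])]
    s = peak_summary(group, control)
    assert s.time_of_peak_h == 12.0
    assert s.fold_change_vs_control == pytest.approx(10.0)


def test_peak_tie_breaks_to_earliest():
    control = grid_series([1.0, 1.0, 1.0, 1.0])
    s = peak_summary([grid_series([5.0, 5.0, 2.0, 1.0])], control)
    assert s.time_of_peak_h == 6.0


def test_mismatched_grids_rejected():
    a = grid_series([1, 2, 3, 4])
    b = PKSeries(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))
    with pytest.raises(DataError):
        peak_summary([a], b)


def test_io_round_trip(tmp_path):
    series = gen_pk(seed=2, group="L3.3") + gen_pk(seed=3, group="D3.3")
    path = tmp_path / "pk.tsv"
    write_pk(series, path)
    back = read_pk(path)
    assert len(back) == len(series)
    key = {(s.group, s.subject): s for s in series}
    for s in back:
        assert np.allclose(s.concentration,
                           key[(s.group, s.subject)].concentration)
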