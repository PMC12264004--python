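"""Rendering, profiles, rolling-ball correction, ACF spacing, hex pattern."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from rumposcope.periodicity import (HexPatternParams, IntensityProfile,
                                    RenderedImage, autocorrelate,
                                    extract_profile, first_peak_spacing,
                                    hex_pattern_nodes, render_thompson,
                                    rolling_ball_1d,
                                    rotated_projection_analysis,
                                    simulate_hex_pattern)


def _loc_table(points, precision):
    return pd.DataFrame({
        "frame": np.arange(len(points)),
        "x_nm": [p[0] for p in points],
        "y_nm": [p[1] for p in points],
        "photons": 350.0,
        "precision_nm": precision})


# --------------------------------------------------------------------------
# Thompson rendering


def test_single_localization_has_unit_mass():
    img = render_thompson(_loc_table([(500.0, 500.0)], 20.0),
                          render_pixel=5.0)
    assert img.intensity.sum() == pytest.approx(1.0, abs=1e-6)


def test_rendering_is_linear():
    one = render_thompson(_loc_table([(500.0, 500.0)], 20.0),
                          render_pixel=5.0)
    two = render_thompson(_loc_table([(500.0, 500.0)] * 2, 20.0),
                          render_pixel=5.0)
    assert np.allclose(two.intensity, 2.0 * one.intensity, atol=1e-12)


def test_rendered_width_matches_precision():
    prec = 24.0
    img = render_thompson(_loc_table([(500.0, 500.0)], prec),
                          render_pixel=2.0)
    h, w = img.intensity.shape
    profile = img.intensity.sum(axis=0)
    xs = (np.arange(w) + 0.5) * img.render_pixel + img.origin[0]

    def gauss(x, a, mu, sig):
        return a * np.exp(-0.5 * ((x - mu) / sig)**2)

    popt, _ = curve_fit(gauss, xs, profile, p0=[profile.max(), 500.0, 20.0])
    assert abs(popt[2]) == pytest.approx(prec, rel=0.02)


# --------------------------------------------------------------------------
# profiles


def test_uniform_image_gives_constant_profile():
    img = RenderedImage(intensity=np.full((100, 100), 3.0), render_pixel=5.0)
    path = np.array([[50.0, 250.0], [450.0, 250.0]])
    prof = extract_profile(img, path, width=40.0, step=5.0)
    assert np.allclose(prof.intensity, 3.0, atol=1e-9)


def test_cosine_grating_period_is_preserved():
    period = 80.0
    px = 2.0
    x = (np.arange(400) + 0.5) * px
    img = RenderedImage(intensity=np.tile(1 + np.cos(2 * np.pi * x / period),
                                          (50, 1)), render_pixel=px)
    path = np.array([[20.0, 50.0], [780.0, 50.0]])
    prof = extract_profile(img, path, width=20.0, step=2.0)
    lags, acf = autocorrelate(prof)
    est = first_peak_spacing(lags, acf)
    assert est.spacing == pytest.approx(period, abs=2.0)


def test_profile_peaks_at_emitter_crossings():
    """Geometry oracle: profile maxima along a path through rendered
    spots coincide with the arc positions computed from the emitter
    coordinates directly."""
    pts = [(300.0, 400.0), (520.0, 400.0), (760.0, 400.0)]
    img = render_thompson(_loc_table(pts, 12.0), render_pixel=2.0)
    path = np.array([[250.0, 400.0], [810.0, 400.0]])
    prof = extract_profile(img, path, width=10.0, step=2.0)
    expected_arcs = [p[0] - 250.0 for p in pts]
    for arc in expected_arcs:
        window = (prof.arc_nm > arc - 30) & (prof.arc_nm < arc + 30)
        peak_arc = prof.arc_nm[window][np.argmax(prof.intensity[window])]
        assert abs(peak_arc - arc) < 6.0


def test_profile_out_of_bounds_raises():
    img = RenderedImage(intensity=np.zeros((50, 50)), render_pixel=5.0)
    with pytest.raises(ValueError):
        extract_profile(img, np.array([[0.0, 0.0], [1000.0, 0.0]]),
                        width=20.0, step=5.0)


# --------------------------------------------------------------------------
# rolling ball


def _profile(y, step=2.0):
    return IntensityProfile(arc_nm=np.arange(len(y)) * step,
                            intensity=np.asarray(y, dtype=float))


def test_rolling_ball_flat_profile_vanishes():
    out = rolling_ball_1d(_profile(np.full(200, 5.0)), ball_radius=50.0)
    assert np.allclose(out.intensity, 0.0, atol=1e-9)


def test_rolling_ball_preserves_narrow_peak():
    y = np.full(300, 10.0)
    x = np.arange(300) * 2.0
    y += 8.0 * np.exp(-0.5 * ((x - 300) / 8.0)**2)
    out = rolling_ball_1d(_profile(y), ball_radius=120.0)
    assert out.intensity.max() == pytest.approx(8.0, rel=0.05)
    # baseline removed away from the peak
    assert np.abs(out.intensity[:100]).max() < 0.4


def test_rolling_ball_removes_slow_ramp():
    x = np.arange(500) * 2.0
    ramp = 0.01 * x
    osc = 0.5 * (1 + np.cos(2 * np.pi * x / 30.0))
    out = rolling_ball_1d(_profile(ramp + osc), ball_radius=120.0)
    trend = np.polyfit(x[50:-50], out.intensity[50:-50], 1)[0]
    assert abs(trend) < 0.05 * 0.01
    # oscillation retained
    assert out.intensity[50:-50].std() > 0.2


def test_rolling_ball_validates_radius():
    with pytest.raises(ValueError):
        rolling_ball_1d(_profile(np.ones(50), step=5.0), ball_radius=4.0)


# --------------------------------------------------------------------------
# autocorrelation and peak picking


def test_white_noise_acf_is_bounded():
    rng = np.random.default_rng(0)
    prof = _profile(rng.normal(0, 1, 4000), step=1.0)
    lags, acf = autocorrelate(prof)
    assert acf[0] == 1.0
    assert np.quantile(np.abs(acf[1:]), 0.99) < 3.0 / np.sqrt(4000)


def test_cosine_acf_maxima_at_multiples_of_period():
    period, step = 60.0, 2.0
    x = np.arange(1500) * step
    prof = _profile(np.cos(2 * np.pi * x / period), step=step)
    lags, acf = autocorrelate(prof)
    for k in (1, 2, 3):
        i = int(round(k * period / step))
        assert acf[i] > acf[i - 5] and acf[i] > acf[i + 5]
    est = first_peak_spacing(lags, acf)
    assert est.spacing == pytest.approx(period, abs=1.0)


def test_short_profile_rejected():
    with pytest.raises(ValueError):
        autocorrelate(np.ones(3), step=1.0)


def test_pure_noise_yields_no_period():
    rng = np.random.default_rng(1)
    lags, acf = autocorrelate(_profile(rng.normal(0, 1, 2000), step=1.0))
    est = first_peak_spacing(lags, acf)
    assert not est.found


# --------------------------------------------------------------------------
# hexagonal pattern forward simulation


def test_hex_nodes_same_row_spacing_is_pitch():
    pts = hex_pattern_nodes(HexPatternParams(grid=(10, 10)), seed=0)
    ys = np.unique(np.round(pts[:, 1], 6))
    row0 = pts[np.isclose(pts[:, 1], ys[0])]
    gaps = np.diff(np.sort(row0[:, 0]))
    assert np.allclose(gaps, 30.0)
    # adjacent row is offset by half a pitch and root3/2 pitch vertically
    assert ys[1] - ys[0] == pytest.approx(30.0 * np.sqrt(3) / 2)


def test_hex_pattern_delta_limit():
    p = HexPatternParams(fwhm=1e-6, localization_accuracy=0.0,
                         grid=(20, 20))
    img = simulate_hex_pattern(p, seed=0, render_pixel=2.0)
    assert np.count_nonzero(img.intensity) == 400
    assert img.intensity.sum() == pytest.approx(400.0)


def test_gaussian_convolution_widths_add_in_quadrature():
    p = HexPatternParams(fwhm=30.0, localization_accuracy=9.0)
    expected = np.hypot(30.0 / (2 * np.sqrt(2 * np.log(2))), 9.0)
    assert p.sigma_total == pytest.approx(expected, rel=1e-12)


def test_axis_aligned_rotation_recovers_pitch_exactly():
    p = HexPatternParams(rotation_range=(0.0, 5.0))
    est = rotated_projection_analysis(p, seed=0)
    assert est.spacing == pytest.approx(30.0, abs=0.5)


def test_rotation_average_scales_with_pitch():
    base = rotated_projection_analysis(HexPatternParams(), seed=0)
    doubled = rotated_projection_analysis(
        HexPatternParams(pitch=60.0, fwhm=60.0), seed=0)
    assert doubled.spacing == pytest.approx(2 * base.spacing, rel=0.10)


@pytest.mark.parametrize("pitch", [24.0, 30.0, 39.0])
def test_rotation_average_bias_below_ten_percent(pitch):
    p = HexPatternParams(pitch=pitch, fwhm=pitch)
    est = rotated_projection_analysis(p, seed=0)
    assert abs(est.spacing - pitch) / pitch < 0.10


def test_hex_params_validation():
    with pytest.raises(ValueError):
        HexPatternParams(pitch=-1.0)
    with pytest.raises(ValueError):
        HexPatternParams(rotation_step=7.0)  # does not divide 360
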