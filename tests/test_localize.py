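"""Spot detection, Poisson-MLE fitting, and the Thompson precision model."""

import numpy as np
import pytest
from scipy import stats

from rumposcope.camera import CameraModel, psf_pixel_stamp
from rumposcope.localize import (calibrate_background_rate, detect_spots,
                                 filter_localizations, fit_rois, fit_spot,
                                 thompson_precision)

CAM = CameraModel()
A = CAM.pixel_size
S = 13


def _roi(N, x, y, rng=None, background=None, sigma=None):
    bg = CAM.background_rate if background is None else background
    sig = CAM.psf_sigma if sigma is None else sigma
    expected = N * psf_pixel_stamp(x, y, sig, A, 0, 0, S) + bg
    if rng is None:
        return expected
    return rng.poisson(expected).astype(float)


# --------------------------------------------------------------------------
# detection


def test_empty_frame_yields_no_candidates():
    assert len(detect_spots(np.zeros((64, 64)), CAM)) == 0


def test_single_bright_emitter_detected_within_one_pixel():
    rng = np.random.default_rng(0)
    frame = np.full((64, 64), CAM.background_rate)
    i, j = 30, 33
    frame[i - 6:i + 7, j - 6:j + 7] += 2000 * psf_pixel_stamp(
        (j + 0.5) * A, (i + 0.5) * A, CAM.psf_sigma, A,
        i - 6, j - 6, 13)
    frame = rng.poisson(frame)
    cands = detect_spots(frame, CAM)
    assert len(cands) == 1
    assert abs(cands[0][0] - i) <= 1 and abs(cands[0][1] - j) <= 1


def test_resolvable_pair_detected_as_two():
    rng = np.random.default_rng(1)
    frame = np.full((96, 96), CAM.background_rate)
    sep_px = int(np.ceil(4 * CAM.psf_sigma / A)) + 1
    for (i, j) in [(40, 30), (40, 30 + sep_px)]:
        frame[i - 6:i + 7, j - 6:j + 7] += 2000 * psf_pixel_stamp(
            (j + 0.5) * A, (i + 0.5) * A, CAM.psf_sigma, A,
            i - 6, j - 6, 13)
    cands = detect_spots(rng.poisson(frame), CAM)
    assert len(cands) == 2


# --------------------------------------------------------------------------
# fitting


def test_noiseless_fit_recovers_exactly():
    x, y = A * (S / 2) + 37.0, A * (S / 2) - 21.0
    roi = _roi(1000.0, x, y, background=5.0)
    fit = fit_spot(roi, CAM)
    assert fit["x"] == pytest.approx(x, abs=0.5)
    assert fit["y"] == pytest.approx(y, abs=0.5)
    assert fit["photons"] == pytest.approx(1000.0, rel=0.01)


def test_fit_rejects_undersized_roi():
    with pytest.raises(ValueError):
        fit_spot(np.ones((3, 3)), CAM)


def test_precision_consistency_across_photon_counts():
    """Empirical localization scatter stays within [0.75, 1.3] of the
    Thompson prediction for N in {100, 350, 1000} under the calibrated
    background (the exact information bound itself sits ~1.28x above the
    Thompson approximation in this background-dominated regime)."""
    rng = np.random.default_rng(0)
    for N in (100.0, 350.0, 1000.0):
        R = 2000
        xs = A * (S / 2) + rng.uniform(-A / 2, A / 2, R)
        ys = A * (S / 2) + rng.uniform(-A / 2, A / 2, R)
        rois = np.stack([_roi(N, xs[r], ys[r], rng) for r in range(R)])
        fits = fit_rois(rois, CAM, fit_sigma=False,
                        background=CAM.background_rate)
        d = np.concatenate([fits["x"].to_numpy() - xs,
                            fits["y"].to_numpy() - ys])
        scatter = stats.median_abs_deviation(d, scale="normal")
        ratio = scatter / thompson_precision(N, CAM.psf_sigma, A,
                                             np.sqrt(CAM.background_rate))
        assert 0.75 <= ratio <= 1.3, (N, ratio)


def test_fit_is_unbiased():
    rng = np.random.default_rng(2)
    N, R = 1000.0, 600
    x = y = A * (S / 2) + 30.0
    rois = np.stack([_roi(N, x, y, rng) for _ in range(R)])
    fits = fit_rois(rois, CAM, fit_sigma=False,
                    background=CAM.background_rate)
    sigma_loc = thompson_precision(N, CAM.psf_sigma, A,
                                   np.sqrt(CAM.background_rate))
    assert abs(fits["x"].mean() - x) < sigma_loc / 5
    assert abs(fits["y"].mean() - y) < sigma_loc / 5


def test_photon_linearity_background_free():
    rng = np.random.default_rng(3)
    true_n, fitted = [], []
    for N in (200.0, 500.0, 1000.0, 2000.0):
        for _ in range(40):
            roi = _roi(N, A * S / 2, A * S / 2, rng, background=0.5)
            true_n.append(N)
            fitted.append(float(fit_spot(roi, CAM)["photons"]))
    slope = np.polyfit(true_n, fitted, 1)[0]
    assert 0.95 <= slope <= 1.05


def test_mean_fitted_photons_under_fixture_statistics():
    """Fits at the true burst positions of fixture-statistics emission
    (geometric, mean 350) recover the 350-photon average."""
    rng = np.random.default_rng(4)
    R = 600
    N = rng.geometric(1 / 350.0, R).astype(float)
    rois = np.stack([_roi(N[r], A * S / 2 + rng.uniform(-80, 80),
                          A * S / 2 + rng.uniform(-80, 80), rng)
                     for r in range(R)])
    fits = fit_rois(rois, CAM, fit_sigma=False,
                    background=CAM.background_rate)
    sem = N.std() / np.sqrt(R)
    assert fits["photons"].mean() == pytest.approx(350.0, abs=4 * sem + 10)


# --------------------------------------------------------------------------
# Thompson precision


def test_thompson_shot_noise_limit():
    # b = 0 and vanishing pixel size: sigma -> s / sqrt(N)
    assert thompson_precision(400.0, 100.0, 1e-6, 0.0) == pytest.approx(
        100.0 / 20.0, rel=1e-6)


def test_thompson_calibrated_background_gives_32nm():
    rate = calibrate_background_rate()
    assert thompson_precision(350.0, 102.0, 160.0,
                              np.sqrt(rate)) == pytest.approx(32.0, abs=1e-6)
    assert rate == pytest.approx(CAM.background_rate, rel=1e-4)


def test_thompson_scaling_identity():
    # doubling N at b = 0 halves the variance exactly
    v1 = thompson_precision(300.0, 102.0, 160.0, 0.0)**2
    v2 = thompson_precision(600.0, 102.0, 160.0, 0.0)**2
    assert v1 == pytest.approx(2 * v2, rel=1e-12)
    with pytest.raises(ValueError):
        thompson_precision(0.0, 102.0, 160.0, 1.0)


# --------------------------------------------------------------------------
# filtering


def test_filter_identity_and_empty():
    import pandas as pd
    rng = np.random.default_rng(5)
    table = pd.DataFrame({
        "frame": np.arange(10), "x_nm": rng.random(10),
        "y_nm": rng.random(10), "photons": rng.uniform(50, 500, 10),
        "background": np.ones(10), "sigma_nm": np.full(10, 102.0),
        "precision_nm": rng.uniform(10, 60, 10), "quality": np.ones(10)})
    assert filter_localizations(table).equals(table)
    assert len(filter_localizations(table, min_photons=1e9)) == 0
    # brute-force oracle
    kept = filter_localizations(table, min_photons=100.0)
    expect = [i for i in range(10) if table["photons"][i] >= 100.0]
    assert list(kept.index) == list(range(len(expect)))
    assert np.array_equal(kept["photons"].to_numpy(),
                          table["photons"].to_numpy()[expect])
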