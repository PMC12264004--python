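"""EMCCD frame rendering, photon conservation, and drift synthesis."""

import numpy as np
import pytest

from rumposcope.camera import CameraModel
from rumposcope.simulate import (DriftModel, EmitterField,
                                 PhotophysicsParams, RumposomeGeometry,
                                 StateTrajectory, apply_drift,
                                 build_rumposome_lattice, bulk_switch_fraction,
                                 expected_frame, make_drift, render_frames,
                                 simulate_states)


def _single_emitter(x=10240.0, y=10240.0):
    return EmitterField(positions=np.array([[x, y]]),
                        molecule_id=np.array([0]),
                        label=np.array(["lattice"]))


def _constant_trajectory(n_frames, photons):
    states = np.ones((1, n_frames), dtype=np.uint8)
    return StateTrajectory(states=states,
                           frame_idx=np.arange(n_frames),
                           mol_idx=np.zeros(n_frames, dtype=np.int64),
                           photons=np.full(n_frames, photons,
                                           dtype=np.int64),
                           activation_counts=np.zeros(n_frames,
                                                      dtype=np.int64))


def test_photon_conservation_in_expectation():
    """Noise-free expected image integrates to emitted photons plus
    background times pixel count."""
    cam = CameraModel(background_rate=3.0)
    pos = np.array([[10240.0, 10240.0], [9000.0, 11000.0]])
    photons = np.array([500.0, 1200.0])
    img = expected_frame(pos, photons, cam)
    expected = photons.sum() + cam.background_rate * img.size
    assert img.sum() == pytest.approx(expected, rel=1e-6)


def test_empty_frame_is_all_zero():
    cam = CameraModel(background_rate=0.0, read_noise=0.0)
    field = _single_emitter()
    states = np.zeros((1, 5), dtype=np.uint8)
    traj = StateTrajectory(states=states, frame_idx=np.array([], dtype=int),
                           mol_idx=np.array([], dtype=int),
                           photons=np.array([], dtype=int),
                           activation_counts=np.zeros(5, dtype=int))
    stack = render_frames(field, traj, cam, seed=0)
    assert stack.frames.sum() == 0


def test_rendered_counts_match_photon_input():
    """Monte-Carlo: mean detected photons per frame equals the drawn
    photon count for a background-free single emitter."""
    cam = CameraModel(background_rate=0.0)
    field = _single_emitter()
    n, photons = 400, 700
    stack = render_frames(field, _constant_trajectory(n, photons), cam,
                          seed=1)
    totals = stack.frames.reshape(n, -1).sum(axis=1)
    assert totals.mean() == pytest.approx(photons, abs=3 * np.sqrt(photons / n) + 1)


def test_mean_photons_per_on_frame_matches_fixture():
    """The fixture photophysics emits on average ~350 detected photons
    per ON frame."""
    field = build_rumposome_lattice(RumposomeGeometry(), 1000, seed=0)
    traj = simulate_states(field, PhotophysicsParams(n_frames=4000), seed=2)
    assert len(traj.photons) > 500
    sem = traj.photons.std() / np.sqrt(len(traj.photons))
    assert traj.photons.mean() == pytest.approx(350.0, abs=4 * sem)


def test_render_seed_determinism():
    cam = CameraModel()
    field = _single_emitter()
    traj = _constant_trajectory(20, 350)
    a = render_frames(field, traj, cam, seed=5)
    b = render_frames(field, traj, cam, seed=5)
    assert np.array_equal(a.frames, b.frames)


def test_emitter_outside_sensor_is_clipped_silently():
    cam = CameraModel(background_rate=0.0)
    field = _single_emitter(x=-5000.0, y=-5000.0)
    stack = render_frames(field, _constant_trajectory(3, 350), cam, seed=0)
    assert stack.frames.sum() == 0


# --------------------------------------------------------------------------
# drift synthesis


def test_zero_drift_is_identity():
    d = make_drift(100, DriftModel(), seed=0)
    assert np.all(d == 0.0)


def test_linear_drift_endpoint():
    d = make_drift(10_000, DriftModel(velocity=(0.05, 0.0)), seed=0)
    assert d[-1, 0] == pytest.approx(0.05 * 9999, rel=1e-12)
    assert d[-1, 1] == 0.0


def test_random_walk_msd_grows_linearly():
    sigma = 0.5
    rows = [make_drift(4000, DriftModel(rw_sigma=sigma), seed=s)[:, 0]
            for s in range(200)]
    d = np.array(rows)
    for lag in (100, 400, 1600):
        msd = np.mean((d[:, lag:] - d[:, :-lag])**2)
        assert msd == pytest.approx(sigma**2 * lag, rel=0.15)


def test_apply_drift_shifts_by_frame():
    import pandas as pd
    table = pd.DataFrame({"frame": [0, 1, 2], "x_nm": [0.0, 0.0, 0.0],
                          "y_nm": [0.0, 0.0, 0.0]})
    drift = np.array([[0.0, 0.0], [10.0, -5.0], [20.0, -10.0]])
    out = apply_drift(table, drift)
    assert np.allclose(out["x_nm"], [0, 10, 20])
    assert np.allclose(out["y_nm"], [0, -5, -10])


# --------------------------------------------------------------------------
# bulk two-state model


def test_bulk_switch_fraction_identities():
    assert bulk_switch_fraction(0.0, 100.0) == 0.0
    k = 0.01
    assert bulk_switch_fraction(k, np.log(2) / k) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        bulk_switch_fraction(-1.0, 1.0)
    with pytest.raises(ValueError):
        bulk_switch_fraction(1.0, -1.0)


def test_bulk_switch_reaches_deep_bleach_regime():
    """A rate constant of ~5.3e-4 / s drives >85% conversion within the
    hour-long bleach protocol, matching the single-cell bleach depth."""
    k = 5.3e-4
    assert bulk_switch_fraction(k, 3600.0) > 0.85
    t = np.linspace(0, 3600, 50)
    f = bulk_switch_fraction(k, t)
    assert np.all(np.diff(f) > 0)
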