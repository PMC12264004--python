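"""Shared fixtures: cameras, synthetic tables, and the full-scale movie.

The expensive end-to-end acquisition (10,000 frames, 3417 emitters) is
simulated once per session and shared by every test that needs the
realistic pipeline output.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from rumposcope.camera import CameraModel
from rumposcope.localize import thompson_precision
from rumposcope.pipeline import localize_and_correct, simulate_zoospore_movie


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


def make_scatter_table(seed: int, n_mol: int = 3417, bursts: float = 1.46,
                       n_frames: int = 10_000) -> pd.DataFrame:
    """Generic SMLM cell: molecules scattered in a 4-um disc, blinking in
    bursts with fixture-like photon statistics.  Used for drift tests,
    where a periodic specimen would make any estimator degenerate."""
    rng = np.random.default_rng(seed)
    r = 2000.0 * np.sqrt(rng.random(n_mol))
    th = rng.uniform(0, 2 * np.pi, n_mol)
    pos = np.column_stack([10240 + r * np.cos(th), 10240 + r * np.sin(th)])
    bg_noise = np.sqrt(CameraModel().background_rate)
    rows = []
    for m in range(n_mol):
        for _ in range(rng.poisson(bursts)):
            f0 = int(rng.integers(0, n_frames - 200))
            L = max(1, int(rng.geometric(1.0 / 6.0)))
            N = rng.geometric(1.0 / 350.0, L)
            detected = N > 380 + rng.normal(0, 76, L)
            for k in np.flatnonzero(detected):
                s = thompson_precision(float(N[k]), 102.0, 160.0, bg_noise)
                p = pos[m] + rng.normal(0, s, 2)
                rows.append((f0 + k, p[0], p[1], float(N[k]), s))
    df = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "photons",
                                     "precision_nm"])
    return df.sort_values("frame", kind="stable").reset_index(drop=True)


@pytest.fixture(scope="session")
def fixture_movie():
    """Full-scale simulated acquisition, localized and drift-corrected."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sim = simulate_zoospore_movie(n_molecules=3417, seed=1)
        table, traj = localize_and_correct(sim)
    return {"sim": sim, "table": table, "traj": traj}
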