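"""End-to-end convenience drivers tying the modules together.

These functions reproduce the full in-silico experiment: simulate a
photoswitching movie of a zoospore, localize and drift-correct it, count
molecules from blink events, and measure the lattice spacing along the
rumposome band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drift as drift_mod
from . import events as events_mod
from . import periodicity as per_mod
from .camera import CameraModel
from .localize import filter_localizations, localize_stack
from .simulate import (DriftModel, EmitterField, PhotophysicsParams,
                       RumposomeGeometry, StateTrajectory,
                       band_row_paths, build_rumposome_lattice, make_drift,
                       render_frames, simulate_states)

#: blink-linkage radius: three times the fixture's mean precision (32 nm)
DEFAULT_LINK_RADIUS_NM = 96.0


@dataclass
class ZoosporeSimulation:
    """Everything produced by one simulated acquisition."""

    emitters: EmitterField
    trajectory: StateTrajectory
    stack: object
    drift_true: np.ndarray
    geometry: RumposomeGeometry
    camera: CameraModel
    params: PhotophysicsParams


def simulate_zoospore_movie(n_molecules: int = 3417,
                            seed: int = 0,
                            geometry: RumposomeGeometry | None = None,
                            params: PhotophysicsParams | None = None,
                            camera: CameraModel | None = None,
                            drift_model: DriftModel | None = None,
                            jitter_sd: float = 0.0) -> ZoosporeSimulation:
    """Simulate one zoospore acquisition under the fixture defaults.

    Child seeds for geometry, photophysics, rendering and drift are
    derived from ``seed`` so the whole acquisition is reproducible from
    one integer.
    """
    ss = np.random.SeedSequence(seed)
    s_geom, s_states, s_render, s_drift = ss.spawn(4)
    geometry = geometry or RumposomeGeometry()
    params = params or PhotophysicsParams()
    camera = camera or CameraModel()
    drift_model = drift_model or DriftModel(velocity=(0.015, -0.01),
                                            rw_sigma=0.2)
    emitters = build_rumposome_lattice(
        geometry, n_molecules, seed=np.random.default_rng(s_geom),
        jitter_sd=jitter_sd, camera=camera)
    trajectory = simulate_states(emitters, params,
                                 seed=np.random.default_rng(s_states))
    drift_true = make_drift(params.n_frames, drift_model,
                            seed=np.random.default_rng(s_drift))
    stack = render_frames(emitters, trajectory, camera,
                          seed=np.random.default_rng(s_render),
                          drift=drift_true, frame_time=params.frame_time)
    return ZoosporeSimulation(emitters=emitters, trajectory=trajectory,
                              stack=stack, drift_true=drift_true,
                              geometry=geometry, camera=camera,
                              params=params)


def localize_and_correct(sim: ZoosporeSimulation,
                         n_blocks: int = 10,
                         render_pixel: float = 25.0
                         ) -> tuple[pd.DataFrame, drift_mod.DriftTrajectory]:
    """Localize every frame and remove lateral drift."""
    table = localize_stack(sim.stack)
    traj = drift_mod.estimate_drift(table, n_blocks=n_blocks,
                                    render_pixel=render_pixel,
                                    n_frames=sim.params.n_frames)
    return drift_mod.correct(table, traj), traj


def count_zoospore(table: pd.DataFrame,
                   radius: float = DEFAULT_LINK_RADIUS_NM,
                   max_dark_frames: int = 2) -> tuple[int,
                                                      events_mod.BlinkEventSet]:
    """Molecule count of one cell from merged blink events."""
    ev = events_mod.merge_into_events(table, radius=radius,
                                      max_dark_frames=max_dark_frames)
    return events_mod.count_molecules(ev), ev


def rumposome_spacing(table: pd.DataFrame,
                      geometry: RumposomeGeometry,
                      camera: CameraModel | None = None,
                      max_event_precision: float = 9.0,
                      n_time_blocks: int = 10,
                      n_frames: int = 10_000,
                      render_pixel: float = 2.0,
                      render_sigma: float = 3.0,
                      profile_width: float = 18.0,
                      profile_step: float = 2.0,
                      ball_radius: float = 120.0,
                      acf_smooth: float = 2.0,
                      link_radius: float = 60.0,
                      max_dark_frames: int = 2,
                      min_prominence: float = 0.0
                      ) -> per_mod.SpacingEstimate:
    """Lattice spacing along the band from a drift-corrected table.

    Localizations are first merged into blink events; grouping the
    frames of one burst multiplies the usable photons and pushes the
    centroid precision below the lattice pitch.  Only events localized
    to better than ``max_event_precision`` (nm) are rendered, with a
    narrow fixed kernel so the rendering itself does not blur away the
    30 nm repeat.  Profiles are extracted along each lattice row of the
    band, rolling-ball corrected and autocorrelated; the correlations
    are accumulated over rows and over temporal blocks (the ACF is
    invariant both to each row's half-pitch stagger and to any residual
    per-block drift offset) and normalized at the end, which weights
    each profile by its own pair count.
    """
    ev = events_mod.merge_into_events(table, radius=link_radius,
                                      max_dark_frames=max_dark_frames)
    events = ev.events
    good = events[np.isfinite(events["precision_nm"]) &
                  (events["precision_nm"] <= max_event_precision)]
    if len(good) < 10:
        raise ValueError("too few well-localized events for spacing analysis")
    paths = band_row_paths(geometry, camera=camera)
    block = np.clip(good["first_frame"].to_numpy() //
                    max(1, n_frames // n_time_blocks), 0, n_time_blocks - 1)
    num = None
    for b in range(n_time_blocks):
        sub = good[block == b]
        if len(sub) < 5:
            continue
        image = per_mod.render_thompson(sub, render_pixel=render_pixel,
                                        sigma=render_sigma)
        for path in paths:
            try:
                prof = per_mod.extract_profile(image, path,
                                               width=profile_width,
                                               step=profile_step)
            except ValueError:
                continue
            corrected = per_mod.rolling_ball_1d(prof, ball_radius=ball_radius)
            x = corrected.intensity - corrected.intensity.mean()
            if x.std() < 1e-12:
                continue
            n = len(x)
            nfft = 1 << int(np.ceil(np.log2(2 * n)))
            spec = np.fft.rfft(x, nfft)
            ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n // 2]
            if num is None:
                num = ac
            elif len(ac) < len(num):
                num = num[:len(ac)] + ac
            else:
                num = num + ac[:len(num)]
    if num is None or num[0] <= 0:
        raise ValueError("no usable profiles along the band rows")
    acf = num / num[0]
    if acf_smooth > 0:
        from scipy.ndimage import gaussian_filter1d
        acf = gaussian_filter1d(acf, acf_smooth / profile_step)
    lags = np.arange(len(acf)) * profile_step
    est = per_mod.first_peak_spacing(lags, acf,
                                     min_prominence=min_prominence)
    # harmonic disambiguation: when the fundamental tooth is too weak to
    # register as a local maximum, the first detected peak sits at twice
    # the repeat; accept the subharmonic if the ACF is locally elevated
    # there relative to its neighbourhood.
    if est.found and est.spacing > 40.0:
        half = est.spacing / 2.0
        v_half = np.interp(half, lags, acf)
        flank = 0.5 * (np.interp(0.5 * half, lags, acf) +
                       np.interp(1.5 * half, lags, acf))
        if v_half > flank:
            i = int(round(half / profile_step))
            lo = max(1, i - 3)
            j = int(np.argmax(acf[lo:i + 4])) + lo
            if 0 < j < len(acf) - 1:
                cm, c0, cp = acf[j - 1], acf[j], acf[j + 1]
                denom = cm - 2 * c0 + cp
                delta = 0.5 * (cm - cp) / denom if denom < 0 else 0.0
                est = per_mod.SpacingEstimate(
                    spacing=float((j + delta) * profile_step),
                    lags_nm=lags, acf=acf, peak_index=j,
                    peak_value=float(acf[j]))
    return est
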