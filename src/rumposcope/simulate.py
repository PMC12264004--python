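"""Forward simulation of photoswitching SMLM movies of the rumposome.

The rumposome of chytrid zoospores is a honeycomb-like tubular membrane
organelle that carries the natively fluorescent, bistable photoreceptor
NeoR.  This module generates ground-truth emitter geometry (a hexagonal
lattice restricted to a crescent band inside a ~4 um cell body), simulates
per-frame photoswitching state trajectories (ON / DARK / BLEACHED) under a
feedback-controlled reactivation schedule that keeps the localization rate
constant, and renders pixelated EMCCD photon-count movies.

It also provides the bulk two-state photoswitch model used to emulate
ensemble bleach/recovery curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .camera import CameraModel, psf_pixel_stamp

ROW_SPACING_FACTOR = np.sqrt(3.0) / 2.0

STATE_DARK = 0
STATE_ON = 1
STATE_BLEACHED = 2


class CapacityError(ValueError):
    """The band cannot host the requested number of molecules at this pitch."""


@dataclass(frozen=True)
class RumposomeGeometry:
    """Geometry of the simulated rumposome band inside the cell body.

    All lengths in the units noted; angles in degrees.  The band is an
    annular arc of mean radius ``band_arc_radius`` spanning
    ``band_arc_span`` degrees, with radial width ``band_width``.  Setting
    ``band_arc_radius = inf`` gives a straight band of length
    ``band_length_nm`` (used for exact-pitch checks).
    """

    cell_diameter: float = 4.0          # um
    globule_diameter: float = 1.0       # um
    band_arc_radius: float = 1.4        # um
    band_arc_span: float = 206.0        # degrees
    band_width: float = 530.0           # nm
    lattice_pitch: float = 30.0         # nm
    lattice_orientation: float = 90.0   # degrees, direction of band center
    band_length_nm: float | None = None

    def __post_init__(self) -> None:
        if min(self.cell_diameter, self.globule_diameter,
               self.band_width, self.lattice_pitch) <= 0:
            raise ValueError("all lengths must be positive")
        if np.isfinite(self.band_arc_radius):
            outer = self.band_arc_radius * 1000.0 + self.band_width / 2.0
            if outer > self.cell_diameter * 1000.0 / 2.0:
                raise ValueError("band does not fit inside the cell circle")

    @property
    def row_spacing(self) -> float:
        """Distance between adjacent lattice rows in nm."""
        return self.lattice_pitch * ROW_SPACING_FACTOR


@dataclass
class EmitterField:
    """Ground-truth emitter coordinates in the sample frame (nm)."""

    positions: np.ndarray          # (n, 2) [x, y] nm
    molecule_id: np.ndarray        # (n,) int
    label: np.ndarray              # (n,) str, 'lattice' or 'background'
    row: np.ndarray | None = None  # (n,) lattice row index, if on lattice

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if len(np.unique(self.molecule_id)) != len(self.molecule_id):
            raise ValueError("molecule_ids must be unique")

    def __len__(self) -> int:
        return len(self.molecule_id)


def _band_rows(geometry: RumposomeGeometry) -> np.ndarray:
    """Radial offsets of the lattice rows from the band center line."""
    n_rows = int(np.floor(geometry.band_width / geometry.row_spacing)) + 1
    return (np.arange(n_rows) - (n_rows - 1) / 2.0) * geometry.row_spacing


def band_center(geometry: RumposomeGeometry,
                camera: CameraModel | None = None) -> np.ndarray:
    """Center of the cell in sensor coordinates (nm)."""
    if camera is None:
        camera = CameraModel()
    h, w = camera.extent_nm
    return np.array([w / 2.0, h / 2.0])


def _lattice_nodes(geometry: RumposomeGeometry,
                   center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All hexagonal lattice nodes of the band.

    Rows are concentric arcs with exact arc-length spacing equal to the
    lattice pitch at each row's own radius; alternate rows are staggered
    by half a pitch, so nearest neighbours sit one pitch apart (exactly
    for a straight band, to curvature accuracy otherwise).

    Returns (positions (n, 2), row_index (n,)).
    """
    pitch = geometry.lattice_pitch
    rows = _band_rows(geometry)
    pts, row_idx = [], []
    if np.isinf(geometry.band_arc_radius):
        length = geometry.band_length_nm
        if length is None:
            raise ValueError("straight band requires band_length_nm")
        n_cols = int(np.floor(length / pitch)) + 1
        x0 = center[0] - (n_cols - 1) * pitch / 2.0
        for j, d in enumerate(rows):
            xs = x0 + np.arange(n_cols) * pitch + (j % 2) * pitch / 2.0
            xs = xs[xs <= center[0] + length / 2.0 + 1e-9]
            pts.append(np.column_stack([xs, np.full(len(xs), center[1] + d)]))
            row_idx.append(np.full(len(xs), j))
    else:
        R = geometry.band_arc_radius * 1000.0
        span = np.deg2rad(geometry.band_arc_span)
        phi_c = np.deg2rad(geometry.lattice_orientation)
        for j, d in enumerate(rows):
            r = R + d
            dphi = pitch / r
            n_half = int(np.floor((span / 2.0) / dphi))
            k = np.arange(-n_half, n_half + 1, dtype=float) + (j % 2) * 0.5
            phi = phi_c + k * dphi
            phi = phi[np.abs(phi - phi_c) <= span / 2.0 + 1e-12]
            pts.append(np.column_stack([center[0] + r * np.cos(phi),
                                        center[1] + r * np.sin(phi)]))
            row_idx.append(np.full(len(phi), j))
    return np.concatenate(pts), np.concatenate(row_idx).astype(int)


def build_rumposome_lattice(geometry: RumposomeGeometry, n_molecules: int,
                            seed: int | np.random.Generator | None = 0,
                            jitter_sd: float = 0.0,
                            center: np.ndarray | None = None,
                            camera: CameraModel | None = None) -> EmitterField:
    """Place ``n_molecules`` emitters on the hexagonal band lattice.

    If the band holds more nodes than requested, a deterministic (seeded)
    random subset is kept; if it holds fewer, a :class:`CapacityError` is
    raised.  ``jitter_sd`` adds isotropic Gaussian positional jitter (nm)
    emulating the random placement of photoreceptors on the membrane
    tubes.
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    rng = np.random.default_rng(seed)
    if center is None:
        center = band_center(geometry, camera)
    nodes, row_idx = _lattice_nodes(geometry, np.asarray(center, float))
    if len(nodes) < n_molecules:
        raise CapacityError(
            f"band holds {len(nodes)} nodes at pitch "
            f"{geometry.lattice_pitch} nm but {n_molecules} were requested")
    if n_molecules == 1:
        # degenerate case: single emitter at the band midpoint
        mid = np.argmin(np.linalg.norm(nodes - np.mean(nodes, axis=0), axis=1))
        keep = np.array([mid])
    else:
        keep = np.sort(rng.choice(len(nodes), size=n_molecules, replace=False))
    pos = nodes[keep]
    if jitter_sd > 0:
        pos = pos + rng.normal(0.0, jitter_sd, size=pos.shape)
    return EmitterField(positions=pos,
                        molecule_id=np.arange(n_molecules),
                        label=np.full(n_molecules, "lattice"),
                        row=row_idx[keep])


def band_row_paths(geometry: RumposomeGeometry,
                   center: np.ndarray | None = None,
                   camera: CameraModel | None = None,
                   step_nm: float = 10.0) -> list[np.ndarray]:
    """Polylines tracing each lattice row (used as profile paths).

    Returns one (k, 2) polyline per row, ordered like the ``row`` labels
    of :func:`build_rumposome_lattice`.
    """
    if center is None:
        center = band_center(geometry, camera)
    center = np.asarray(center, float)
    paths = []
    rows = _band_rows(geometry)
    if np.isinf(geometry.band_arc_radius):
        length = geometry.band_length_nm
        for d in rows:
            xs = np.arange(center[0] - length / 2.0,
                           center[0] + length / 2.0 + step_nm, step_nm)
            paths.append(np.column_stack([xs, np.full(len(xs), center[1] + d)]))
        return paths
    R = geometry.band_arc_radius * 1000.0
    span = np.deg2rad(geometry.band_arc_span)
    phi_c = np.deg2rad(geometry.lattice_orientation)
    for d in rows:
        r = R + d
        n = int(np.ceil(r * span / step_nm))
        phi = phi_c + np.linspace(-span / 2.0, span / 2.0, n)
        paths.append(np.column_stack([center[0] + r * np.cos(phi),
                                      center[1] + r * np.sin(phi)]))
    return paths


# --------------------------------------------------------------------------
# photophysics


@dataclass(frozen=True)
class PhotophysicsParams:
    """Per-frame photoswitching rates of the bistable fluorophore.

    The chain is a discrete-frame Markov process: an ON molecule bleaches
    with probability ``p_bleach`` per frame, otherwise returns to the
    reversible DARK state with probability ``p_off``; DARK molecules are
    reactivated at a controller-set rate.  ``frame_time`` only scales
    rates to physical time.
    """

    p_off: float = 0.04
    p_bleach: float = 0.13
    photons_mean: float = 350.0
    frame_time: float = 0.035
    n_frames: int = 10_000
    photon_dist: str = "geometric"

    def __post_init__(self) -> None:
        for p in (self.p_off, self.p_bleach):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.photons_mean <= 0:
            raise ValueError("photons_mean must be positive")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")

    @property
    def expected_bursts_per_molecule(self) -> float:
        """Mean number of ON spells before photobleaching."""
        q = self.p_off + self.p_bleach - self.p_off * self.p_bleach
        if self.p_bleach == 0:
            return np.inf
        # probability that a spell ends in bleaching rather than DARK
        beta = self.p_bleach / q
        return 1.0 / beta


class ReactivationController:
    """Proportional feedback on the 405 nm reactivation rate.

    Emulates the gradual increase of activation laser power that keeps
    the number of activations per frame constant as the dark pool is
    depleted.  The controller tracks activations over a trailing window
    and nudges the expected ON-switch rate ``r`` toward the target.
    """

    def __init__(self, target_rate: float, window: int = 200,
                 gain: float = 0.002, r0: float | None = None):
        if target_rate < 0:
            raise ValueError("target_rate must be non-negative")
        self.target_rate = target_rate
        self.window = window
        self.gain = gain
        self.r = target_rate if r0 is None else r0
        self._recent: list[int] = []
        self.saturated = False

    def rate(self) -> float:
        """Expected number of ON-switches requested for the next frame."""
        return self.r

    def update(self, n_activated: int) -> None:
        self._recent.append(n_activated)
        if len(self._recent) > self.window:
            self._recent.pop(0)
        err = self.target_rate - np.mean(self._recent)
        self.r = max(0.0, self.r + self.gain * err)


@dataclass
class StateTrajectory:
    """Per-molecule, per-frame photoswitching record.

    ``states`` is an (n_molecules, n_frames) uint8 matrix with values
    0 = DARK, 1 = ON, 2 = BLEACHED; photons are stored sparsely for the
    ON entries.
    """

    states: np.ndarray
    frame_idx: np.ndarray     # (k,) frame of each ON entry
    mol_idx: np.ndarray       # (k,) molecule of each ON entry
    photons: np.ndarray       # (k,) photons emitted in that frame
    activation_counts: np.ndarray  # (n_frames,) ON-switches per frame
    controller_saturated: bool = False

    @property
    def n_molecules(self) -> int:
        return self.states.shape[0]

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def on_spells(self, molecule: int) -> list[tuple[int, int]]:
        """[(first_frame, last_frame)] of each ON spell of one molecule."""
        on = np.flatnonzero(self.states[molecule] == STATE_ON)
        if len(on) == 0:
            return []
        breaks = np.flatnonzero(np.diff(on) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(on) - 1]])
        return [(int(on[s]), int(on[e])) for s, e in zip(starts, ends)]


def simulate_states(emitters: EmitterField, params: PhotophysicsParams,
                    controller: ReactivationController | None = None,
                    seed: int | np.random.Generator | None = 0,
                    fill_fraction: float = 0.98) -> StateTrajectory:
    """Run the discrete-frame photoswitching Markov chain.

    All molecules start DARK (the post-bleach regime: the far-red state
    was bleached away and molecules are recovered in low doses by 405 nm
    light).  If no controller is given, the activation target is chosen
    so that the expected burst supply of the field is spent within
    ``fill_fraction`` of the movie, which leaves every molecule a chance
    to blink at least once.
    """
    rng = np.random.default_rng(seed)
    n_mol = len(emitters)
    n_frames = params.n_frames
    if controller is None:
        supply = n_mol * params.expected_bursts_per_molecule
        target = supply / (fill_fraction * n_frames)
        controller = ReactivationController(target)

    states = np.zeros((n_mol, n_frames), dtype=np.uint8)
    current = np.zeros(n_mol, dtype=np.uint8)
    frame_idx, mol_idx, photons = [], [], []
    activation_counts = np.zeros(n_frames, dtype=np.int64)

    for t in range(n_frames):
        on = current == STATE_ON
        if on.any():
            u = rng.random(n_mol)
            bleach = on & (u < params.p_bleach)
            turn_off = on & ~bleach & (u < params.p_bleach + params.p_off *
                                       (1.0 - params.p_bleach))
            current[bleach] = STATE_BLEACHED
            current[turn_off] = STATE_DARK
        dark = np.flatnonzero(current == STATE_DARK)
        r = controller.rate()
        n_act = 0
        if len(dark) > 0 and r > 0:
            p_act = r / len(dark)
            if p_act >= 1.0:
                if not controller.saturated:
                    warnings.warn("reactivation controller saturated: target "
                                  "rate exceeds remaining dark molecules",
                                  RuntimeWarning, stacklevel=2)
                controller.saturated = True
                p_act = 1.0
            activate = dark[rng.random(len(dark)) < p_act]
            current[activate] = STATE_ON
            n_act = len(activate)
        elif r > 0:
            controller.saturated = True
        controller.update(n_act)
        activation_counts[t] = n_act

        on_now = np.flatnonzero(current == STATE_ON)
        if len(on_now) > 0:
            if params.photon_dist == "geometric":
                ph = rng.geometric(1.0 / params.photons_mean, size=len(on_now))
            elif params.photon_dist == "poisson":
                ph = rng.poisson(params.photons_mean, size=len(on_now))
            elif params.photon_dist == "constant":
                ph = np.full(len(on_now), int(round(params.photons_mean)))
            else:
                raise ValueError(f"unknown photon_dist {params.photon_dist!r}")
            frame_idx.extend([t] * len(on_now))
            mol_idx.extend(on_now.tolist())
            photons.extend(ph.tolist())
        states[:, t] = current

    return StateTrajectory(states=states,
                           frame_idx=np.asarray(frame_idx, dtype=np.int64),
                           mol_idx=np.asarray(mol_idx, dtype=np.int64),
                           photons=np.asarray(photons, dtype=np.int64),
                           activation_counts=activation_counts,
                           controller_saturated=controller.saturated)


# --------------------------------------------------------------------------
# drift


@dataclass(frozen=True)
class DriftModel:
    """Lateral stage drift: linear velocity plus a Gaussian random walk."""

    velocity: tuple[float, float] = (0.0, 0.0)  # nm/frame
    rw_sigma: float = 0.0                       # nm/frame step SD


def make_drift(n_frames: int, model: DriftModel,
               seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Cumulative (dx, dy) drift per frame, (n_frames, 2) nm; starts at 0."""
    rng = np.random.default_rng(seed)
    steps = np.tile(np.asarray(model.velocity, float), (n_frames, 1))
    if model.rw_sigma > 0:
        steps = steps + rng.normal(0.0, model.rw_sigma, size=(n_frames, 2))
    drift = np.cumsum(steps, axis=0)
    drift -= drift[0]
    return drift


def apply_drift(table, drift: np.ndarray):
    """Shift localization coordinates by the per-frame drift.

    ``table`` is a localization DataFrame (columns ``frame, x_nm, y_nm``);
    a shifted copy is returned.  The true trajectory used is whatever was
    passed in, so recovery tests can compare against it directly.
    """
    out = table.copy()
    f = out["frame"].to_numpy().astype(int)
    out["x_nm"] = out["x_nm"].to_numpy() + drift[f, 0]
    out["y_nm"] = out["y_nm"].to_numpy() + drift[f, 1]
    return out


# --------------------------------------------------------------------------
# rendering


@dataclass
class FrameStack:
    """Integer-valued photon-count movie plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, h, w) uint16
    camera: CameraModel
    frame_time: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def expected_frame(positions: np.ndarray, photons: np.ndarray,
                   camera: CameraModel,
                   background: float | None = None) -> np.ndarray:
    """Noise-free expected photon image for a set of active emitters."""
    h, w = camera.sensor_shape
    if background is None:
        background = camera.background_rate
    img = np.full((h, w), float(background))
    half = int(np.ceil(4.0 * camera.psf_sigma / camera.pixel_size))
    for (x, y), n in zip(positions, photons):
        j0 = int(np.floor(x / camera.pixel_size)) - half
        i0 = int(np.floor(y / camera.pixel_size)) - half
        size = 2 * half + 1
        stamp = n * psf_pixel_stamp(x, y, camera.psf_sigma,
                                    camera.pixel_size, i0, j0, size)
        ia, ib = max(i0, 0), min(i0 + size, h)
        ja, jb = max(j0, 0), min(j0 + size, w)
        if ia >= ib or ja >= jb:
            continue  # emitter outside the sensor: silently clipped
        img[ia:ib, ja:jb] += stamp[ia - i0:ib - i0, ja - j0:jb - j0]
    return img


def render_frames(emitters: EmitterField, trajectory: StateTrajectory,
                  camera: CameraModel,
                  seed: int | np.random.Generator | None = 0,
                  drift: np.ndarray | None = None,
                  frame_time: float = 0.035,
                  chunk: int = 500) -> FrameStack:
    """Render the movie: Poisson photon noise on PSF + background images.

    Emitters outside the sensor are silently clipped.  With ``em_gain``
    > 1 the photon counts are amplified through a Gamma multiplication
    register; Gaussian read noise is added if configured.  Output is a
    uint16 stack.
    """
    rng = np.random.default_rng(seed)
    h, w = camera.sensor_shape
    n_frames = trajectory.n_frames
    order = np.argsort(trajectory.frame_idx, kind="stable")
    f_sorted = trajectory.frame_idx[order]
    m_sorted = trajectory.mol_idx[order]
    p_sorted = trajectory.photons[order]
    starts = np.searchsorted(f_sorted, np.arange(n_frames + 1))

    half = int(np.ceil(4.0 * camera.psf_sigma / camera.pixel_size))
    size = 2 * half + 1
    out = np.empty((n_frames, h, w), dtype=np.uint16)

    for c0 in range(0, n_frames, chunk):
        c1 = min(c0 + chunk, n_frames)
        block = rng.poisson(camera.background_rate,
                            size=(c1 - c0, h, w)).astype(np.int64)
        for t in range(c0, c1):
            for k in range(starts[t], starts[t + 1]):
                x, y = emitters.positions[m_sorted[k]]
                if drift is not None:
                    x = x + drift[t, 0]
                    y = y + drift[t, 1]
                j0 = int(np.floor(x / camera.pixel_size)) - half
                i0 = int(np.floor(y / camera.pixel_size)) - half
                stamp = p_sorted[k] * psf_pixel_stamp(
                    x, y, camera.psf_sigma, camera.pixel_size, i0, j0, size)
                ia, ib = max(i0, 0), min(i0 + size, h)
                ja, jb = max(j0, 0), min(j0 + size, w)
                if ia >= ib or ja >= jb:
                    continue
                block[t - c0, ia:ib, ja:jb] += rng.poisson(
                    stamp[ia - i0:ib - i0, ja - j0:jb - j0])
        if camera.em_gain > 1.0:
            amp = rng.standard_gamma(block.astype(float)) * camera.em_gain
            block = np.rint(amp).astype(np.int64)
        if camera.read_noise > 0:
            block = np.rint(block + rng.normal(
                0.0, camera.read_noise, size=block.shape)).astype(np.int64)
        out[c0:c1] = np.clip(block, 0, np.iinfo(np.uint16).max)
    return FrameStack(frames=out, camera=camera, frame_time=frame_time)


# --------------------------------------------------------------------------
# bulk ensemble model


def bulk_switch_fraction(k: float, t) -> np.ndarray | float:
    """Fraction of a molecular ensemble converted after time ``t``.

    First-order two-state kinetics, ``1 - exp(-k t)``; describes both the
    ensemble photobleach of the far-red state and its 405 nm-driven
    recovery (>85% conversion / >80% recovery regimes of the bulk
    experiments).
    """
    k = float(k)
    t_arr = np.asarray(t, dtype=float)
    if k < 0 or np.any(t_arr < 0):
        raise ValueError("rate constant and time must be non-negative")
    out = 1.0 - np.exp(-k * t_arr)
    return out if out.ndim else float(out)
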