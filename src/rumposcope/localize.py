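"""Frame-by-frame single-molecule spot detection and fitting.

Detection is a band-pass (difference of Gaussians at the PSF scale)
followed by local-maximum selection; candidate regions of interest are
then fit with a pixel-integrated 2D Gaussian by maximum likelihood under
Poisson noise (Fisher-scoring iterations, batched over all candidates of
a movie).  Per-localization precision follows the Thompson formula from
the fitted photon count, PSF width, pixel size and background.

Localization tables are plain :class:`pandas.DataFrame` objects with the
fixed column schema

    frame, x_nm, y_nm, photons, background, sigma_nm, precision_nm, quality

where ``background`` is the fitted background rate in photons/pixel and
``quality`` is the Poisson deviance per degree of freedom of the fit.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage

from .camera import CameraModel, pixel_edges
from .simulate import FrameStack

LOCALIZATION_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "background",
                        "sigma_nm", "precision_nm", "quality"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def thompson_precision(N, s, a, b):
    """Lateral localization precision (nm) of a fitted Gaussian spot.

    ``sigma_loc**2 = (s**2 + a**2/12) / N + 8*pi*s**4*b**2 / (a**2*N**2)``

    Parameters
    ----------
    N : photons in the spot (must be positive).
    s : fitted PSF standard deviation, nm.
    a : pixel size, nm.
    b : background noise per pixel in photons (the standard deviation of
        the background; for Poisson background this is the square root
        of the background rate).
    """
    N = np.asarray(N, dtype=float)
    if np.any(N <= 0):
        raise ValueError("photon count must be positive")
    s = np.asarray(s, dtype=float)
    var = (s**2 + a**2 / 12.0) / N + 8.0 * np.pi * s**4 * b**2 / (a**2 * N**2)
    out = np.sqrt(var)
    return out if out.ndim else float(out)


def calibrate_background_rate(target_precision: float = 32.0,
                              photons: float = 350.0,
                              s: float = 102.0, a: float = 160.0) -> float:
    """Background rate (photons/pixel/frame) whose Poisson noise makes the
    Thompson precision of a ``photons``-photon localization equal to the
    target.  Inverts the Thompson formula for ``b**2`` with ``b = sqrt(rate)``.
    """
    resid = target_precision**2 - (s**2 + a**2 / 12.0) / photons
    if resid <= 0:
        raise ValueError("target precision below the shot-noise limit")
    return resid * a**2 * photons**2 / (8.0 * np.pi * s**4)


# --------------------------------------------------------------------------
# detection


@lru_cache(maxsize=8)
def _dog_calibration(sigma_px: float, size: int = 33) -> tuple[float, float]:
    """(peak response to a unit-photon PSF, sum of squared impulse response)
    of the DoG filter at this PSF scale."""
    half = size // 2
    e = np.arange(size + 1, dtype=float) - half - 0.5
    from scipy.special import erf
    f = np.diff(0.5 * erf(e / (_SQRT2 * sigma_px)))
    psf = np.outer(f, f)
    filt = (ndimage.gaussian_filter(psf, sigma_px) -
            ndimage.gaussian_filter(psf, 2.0 * sigma_px))
    delta = np.zeros((size, size))
    delta[half, half] = 1.0
    imp = (ndimage.gaussian_filter(delta, sigma_px) -
           ndimage.gaussian_filter(delta, 2.0 * sigma_px))
    return float(filt.max()), float(np.sum(imp**2))


def detect_spots(frame: np.ndarray, camera: CameraModel,
                 threshold: float | None = None,
                 min_separation: int | None = None,
                 n_sigma: float = 5.0) -> np.ndarray:
    """Candidate spot pixels of one frame.

    Band-pass filters the frame with a difference of Gaussians at the PSF
    scale, converts the response to an equivalent photon amplitude, and
    keeps local maxima above ``threshold`` photons after non-maximum
    suppression within ``min_separation`` pixels.  If no threshold is
    given it is set to ``n_sigma`` times the photon-equivalent background
    noise estimated from the frame median.

    Returns an (n, 2) integer array of (row, col) candidates (possibly
    empty).
    """
    frame = np.asarray(frame, dtype=float)
    sigma_px = camera.psf_sigma / camera.pixel_size
    if min_separation is None:
        min_separation = max(2, int(np.ceil(2.0 * sigma_px)))
    eta, s2 = _dog_calibration(round(float(sigma_px), 3))
    dog = (ndimage.gaussian_filter(frame, sigma_px) -
           ndimage.gaussian_filter(frame, 2.0 * sigma_px))
    amp = dog / eta
    if threshold is None:
        lam = max(float(np.median(frame)), 0.0)
        threshold = n_sigma * np.sqrt(lam * s2) / eta
    foot = 2 * min_separation + 1
    peaks = (dog == ndimage.maximum_filter(dog, size=foot)) & (amp > threshold)
    rc = np.argwhere(peaks)
    if len(rc) > 1:
        # greedy suppression of remaining close pairs, brightest first
        order = np.argsort(-amp[rc[:, 0], rc[:, 1]])
        kept: list[np.ndarray] = []
        for idx in order:
            p = rc[idx]
            if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) > min_separation
                   for q in kept):
                kept.append(p)
        rc = np.array(kept)
        rc = rc[np.lexsort((rc[:, 1], rc[:, 0]))]
    return rc.astype(int)


# --------------------------------------------------------------------------
# fitting


def _erf_frac(edges: np.ndarray, mu: np.ndarray,
              sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel fractions f and their derivatives wrt mu and sigma.

    edges: (S+1,), mu, sigma: (R, 1).  Returns arrays of shape (R, S).
    """
    from scipy.special import erf
    u = (edges[None, :] - mu) / (sigma * _SQRT2)
    c = 0.5 * erf(u)
    # d/dmu Phi((e-mu)/sigma) = -pdf((e-mu)/sigma)/sigma with z = (e-mu)/sigma
    z = u * _SQRT2
    pdf = _INV_SQRT2PI * np.exp(-0.5 * z**2)
    f = np.diff(c, axis=1)
    dmu = -np.diff(pdf, axis=1) / sigma
    dsig = -np.diff(pdf * z, axis=1) / sigma
    return f, dmu, dsig


def fit_rois(rois: np.ndarray, camera: CameraModel,
             x0: np.ndarray | None = None, y0: np.ndarray | None = None,
             fit_sigma: bool = True, background: np.ndarray | float |
             None = None, max_iter: int = 50,
             tol: float = 1e-4) -> pd.DataFrame:
    """Batched Poisson maximum-likelihood Gaussian fits.

    ``rois`` is (R, S, S) photon counts.  Coordinates are local to each
    ROI (nm from its top-left corner).  If ``background`` is given (per
    ROI or scalar, e.g. estimated from the whole frame) it is held fixed
    instead of fitted, which brings the position estimator close to the
    information bound in background-dominated data.  Returns a DataFrame
    with columns x, y, photons, background, sigma, quality, converged.
    """
    rois = np.asarray(rois, dtype=float)
    if rois.ndim == 2:
        rois = rois[None]
    R, S, _ = rois.shape
    a = camera.pixel_size
    edges = pixel_edges(S, a)
    s_nom = camera.psf_sigma
    s_lo, s_hi = 0.5 * s_nom, 2.0 * s_nom

    fit_bg = background is None
    if fit_bg:
        b = np.empty(R)
        for r in range(R):
            edge = np.concatenate([rois[r, 0], rois[r, -1],
                                   rois[r, 1:-1, 0], rois[r, 1:-1, -1]])
            b[r] = max(np.median(edge), 0.01)
    else:
        b = np.broadcast_to(np.asarray(background, dtype=float),
                            (R,)).copy()
        b = np.maximum(b, 1e-3)
    tot = rois.sum(axis=(1, 2))
    N = np.maximum(tot - b * S * S, 10.0)
    if x0 is None or y0 is None:
        sub = np.maximum(rois - b[:, None, None], 0.0)
        grid = (np.arange(S) + 0.5) * a
        w = sub.sum(axis=(1, 2)) + 1e-12
        y0 = (sub.sum(axis=2) @ grid) / w
        x0 = (sub.sum(axis=1) @ grid) / w
    x = np.asarray(x0, dtype=float).copy()
    y = np.asarray(y0, dtype=float).copy()
    sig = np.full(R, float(s_nom))

    n_par = 3 + int(fit_bg) + int(fit_sigma)
    converged = np.zeros(R, dtype=bool)
    lam = np.full(R, 1e-3)  # Levenberg damping
    ll_prev = np.full(R, np.inf)

    for _ in range(max_iter):
        fx, dfx_dx, dfx_ds = _erf_frac(edges, x[:, None], sig[:, None])
        fy, dfy_dy, dfy_ds = _erf_frac(edges, y[:, None], sig[:, None])
        shape = fy[:, :, None] * fx[:, None, :]
        m = b[:, None, None] + N[:, None, None] * shape
        m = np.maximum(m, 1e-9)

        d = np.empty((R, n_par, S, S))
        d[:, 0] = N[:, None, None] * fy[:, :, None] * dfx_dx[:, None, :]
        d[:, 1] = N[:, None, None] * dfy_dy[:, :, None] * fx[:, None, :]
        d[:, 2] = shape
        p = 3
        if fit_bg:
            d[:, p] = 1.0
            p += 1
        if fit_sigma:
            d[:, p] = N[:, None, None] * (
                dfy_ds[:, :, None] * fx[:, None, :] +
                fy[:, :, None] * dfx_ds[:, None, :])

        resid = 1.0 - rois / m
        g = np.einsum("rij,rpij->rp", resid, d)
        H = np.einsum("rpij,rqij,rij->rpq", d, d, 1.0 / m)
        H = H + lam[:, None, None] * np.eye(n_par)[None]
        try:
            step = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            H = H + 1e-2 * np.eye(n_par)[None]
            step = np.linalg.solve(H, g[..., None])[..., 0]

        ll = np.sum(m - rois * np.log(m), axis=(1, 2))
        improved = ll < ll_prev + 1e-9
        lam = np.where(improved, lam * 0.7, lam * 3.0)
        ll_prev = np.minimum(ll, ll_prev)

        x = np.clip(x - step[:, 0], 0.0, S * a)
        y = np.clip(y - step[:, 1], 0.0, S * a)
        N = np.maximum(N - step[:, 2], 1.0)
        p = 3
        if fit_bg:
            b = np.maximum(b - step[:, p], 1e-3)
            p += 1
        if fit_sigma:
            sig = np.clip(sig - step[:, p], s_lo, s_hi)
        converged = np.max(np.abs(step[:, :2]), axis=1) < tol * a

    fx, _, _ = _erf_frac(edges, x[:, None], sig[:, None])
    fy, _, _ = _erf_frac(edges, y[:, None], sig[:, None])
    m = np.maximum(b[:, None, None] +
                   N[:, None, None] * fy[:, :, None] * fx[:, None, :], 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(rois > 0, rois * np.log(rois / m), 0.0)
    deviance = 2.0 * np.sum(dev_terms - (rois - m), axis=(1, 2))
    dof = S * S - n_par
    return pd.DataFrame({"x": x, "y": y, "photons": N, "background": b,
                         "sigma": sig, "quality": deviance / dof,
                         "converged": converged})


def fit_spot(roi: np.ndarray, camera: CameraModel,
             initial: tuple[float, float] | None = None,
             fit_sigma: bool = True) -> pd.Series:
    """Fit a single ROI; see :func:`fit_rois`.  Coordinates are local nm."""
    roi = np.asarray(roi, dtype=float)
    if roi.shape[0] < 2 * 3 * camera.psf_sigma / camera.pixel_size:
        raise ValueError("ROI smaller than 2 x 3 PSF sigma")
    x0 = y0 = None
    if initial is not None:
        x0 = np.array([initial[0]])
        y0 = np.array([initial[1]])
    return fit_rois(roi[None], camera, x0=x0, y0=y0,
                    fit_sigma=fit_sigma).iloc[0]


# --------------------------------------------------------------------------
# movie-level driver


def localize_stack(stack: FrameStack, threshold: float | None = None,
                   roi_size: int = 13, fit_sigma: bool = True,
                   fit_background: bool = False, n_sigma: float = 5.0,
                   max_quality: float = 3.0) -> pd.DataFrame:
    """Detect and fit all frames of a movie; returns a localization table.

    Candidates closer than half an ROI to the sensor border are dropped;
    when two candidates share one ROI only the brighter is fit in this
    pass.  By default the (spatially uniform) background is estimated
    per frame as the frame median and held fixed during fitting;
    ``fit_background=True`` fits it per ROI instead.  Non-converged fits
    and fits with deviance/dof above ``max_quality`` are excluded.
    """
    camera = stack.camera
    half = roi_size // 2
    h, w = camera.sensor_shape
    gain = camera.em_gain
    rois, frames_out, corners, bgs = [], [], [], []
    for t in range(stack.n_frames):
        frame = stack.frames[t].astype(float)
        if gain > 1.0:
            frame = frame / gain  # documented EM-gain pre-correction
        cands = detect_spots(frame, camera, threshold=threshold,
                             n_sigma=n_sigma)
        if len(cands) == 0:
            continue
        bg_frame = float(np.median(frame))
        taken: list[np.ndarray] = []
        for (i, j) in cands:
            if i < half or j < half or i >= h - half or j >= w - half:
                continue
            if any(max(abs(i - q[0]), abs(j - q[1])) <= half for q in taken):
                continue  # ROI collision: brighter candidate was kept first
            taken.append(np.array([i, j]))
            rois.append(frame[i - half:i + half + 1, j - half:j + half + 1])
            frames_out.append(t)
            corners.append((i - half, j - half))
            bgs.append(bg_frame)
    if not rois:
        return pd.DataFrame(columns=LOCALIZATION_COLUMNS)

    fits = fit_rois(np.asarray(rois), camera, fit_sigma=fit_sigma,
                    background=None if fit_background
                    else np.asarray(bgs))
    corners = np.asarray(corners, dtype=float)
    a = camera.pixel_size
    table = pd.DataFrame({
        "frame": np.asarray(frames_out, dtype=int),
        "x_nm": fits["x"].to_numpy() + corners[:, 1] * a,
        "y_nm": fits["y"].to_numpy() + corners[:, 0] * a,
        "photons": fits["photons"].to_numpy(),
        "background": fits["background"].to_numpy(),
        "sigma_nm": fits["sigma"].to_numpy(),
        "quality": fits["quality"].to_numpy(),
    })
    table["precision_nm"] = thompson_precision(
        table["photons"].to_numpy(), table["sigma_nm"].to_numpy(), a,
        np.sqrt(table["background"].to_numpy()))
    ok = fits["converged"].to_numpy() & (table["quality"] < max_quality)
    table = table[ok].reset_index(drop=True)
    table = table[LOCALIZATION_COLUMNS]
    return table.sort_values("frame", kind="stable").reset_index(drop=True)


def filter_localizations(table: pd.DataFrame,
                         min_photons: float | None = None,
                         max_precision: float | None = None,
                         max_quality: float | None = None,
                         verbose: bool = False) -> pd.DataFrame:
    """Subset a localization table by photon count, precision and quality.

    Order is preserved; the number of removed rows is reported when
    ``verbose``.
    """
    mask = np.ones(len(table), dtype=bool)
    if min_photons is not None:
        mask &= table["photons"].to_numpy() >= min_photons
    if max_precision is not None:
        mask &= table["precision_nm"].to_numpy() <= max_precision
    if max_quality is not None:
        mask &= table["quality"].to_numpy() <= max_quality
    removed = int((~mask).sum())
    if verbose:
        print(f"filter_localizations: removed {removed} of {len(table)} rows")
    return table[mask].reset_index(drop=True)
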