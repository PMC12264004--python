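"""Lateral drift estimation and correction for localization tables.

The estimator follows the standard temporal-block scheme: localizations
are split into contiguous blocks, each block is rendered as a 2D
histogram, and block displacements are found by image cross-correlation
with sub-pixel parabolic peak interpolation, chained consecutively (or
against the first block) and polished by correlating each block against
the sum of all others.  Correlations are overlap-corrected per-lag
Pearson coefficients, which removes the spurious zero-lag bias that
plain mean-subtracted correlation acquires from finite image supports.

Because a fluorophore blinks in short bursts, localizations are first
grouped into burst events and one centroid per burst enters the block
images; otherwise bursts straddling a block boundary place identical
coordinates in adjacent blocks and pin their correlation at zero lag.

An optional (default-on) refinement links well-localized events that
recur at the same position across the movie — repeated activations of
the same molecule — and solves a weighted least-squares problem for the
drift at node frames, which sharpens both the interior trajectory and
its endpoints well beyond the render-pixel scale.  Per-frame drift is a
monotone cubic interpolation of the node offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, sparse, spatial
from scipy.interpolate import PchipInterpolator
from scipy.sparse.csgraph import connected_components


@dataclass
class DriftTrajectory:
    """Estimated per-frame lateral drift.

    ``drift`` is (n_frames, 2) nm; ``anchors`` holds the node frames and
    ``anchor_offsets`` the estimated displacements there (the first
    block is anchored at zero).
    """

    drift: np.ndarray
    anchors: np.ndarray
    anchor_offsets: np.ndarray
    interpolation: str = "pchip"

    @property
    def n_frames(self) -> int:
        return self.drift.shape[0]


# --------------------------------------------------------------------------
# correlation primitives


def _pearson_xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-lag Pearson correlation of ``b`` relative to ``a`` (full mode)."""
    flip = lambda u: u[::-1, ::-1]  # noqa: E731
    corr = lambda u, v: signal.fftconvolve(u, flip(v), mode="full")  # noqa: E731
    one_a, one_b = np.ones_like(a), np.ones_like(b)
    n = corr(one_b, one_a)
    sa = corr(one_b, a)
    sb = corr(b, one_a)
    num = corr(b, a) - sa * sb / n
    var_a = np.maximum(corr(one_b, a * a) - sa**2 / n, 1e-12)
    var_b = np.maximum(corr(b * b, one_a) - sb**2 / n, 1e-12)
    return num / np.sqrt(var_a * var_b)


def _peak_offset(c: np.ndarray, shape: tuple[int, int], px: float,
                 search: int) -> np.ndarray:
    """(dx, dy) nm of the correlation maximum within +-search pixels,
    refined by 3-point parabolas per axis."""
    ci, cj = shape[0] - 1, shape[1] - 1
    s = int(search)
    sub = c[ci - s:ci + s + 1, cj - s:cj + s + 1]
    i, j = np.unravel_index(np.argmax(sub), sub.shape)

    def parabola(cm, c0, cp):
        d = cm - 2 * c0 + cp
        return 0.5 * (cm - cp) / d if d < 0 else 0.0

    ii, jj = i + ci - s, j + cj - s
    di = i - s + (parabola(c[ii - 1, jj], c[ii, jj], c[ii + 1, jj])
                  if 0 < ii < c.shape[0] - 1 else 0.0)
    dj = j - s + (parabola(c[ii, jj - 1], c[ii, jj], c[ii, jj + 1])
                  if 0 < jj < c.shape[1] - 1 else 0.0)
    return np.array([dj * px, di * px])


def _hat_weights(t: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation weights with linear extrapolation."""
    W = np.zeros((len(t), len(nodes)))
    for k in range(len(nodes)):
        e = np.zeros(len(nodes))
        e[k] = 1.0
        W[:, k] = np.interp(t, nodes, e)
    lo = t < nodes[0]
    hi = t > nodes[-1]
    if lo.any():
        s = (t[lo] - nodes[0]) / (nodes[1] - nodes[0])
        W[lo, :] = 0.0
        W[lo, 0] = 1 - s
        W[lo, 1] = s
    if hi.any():
        s = (t[hi] - nodes[-1]) / (nodes[-1] - nodes[-2])
        W[hi, :] = 0.0
        W[hi, -1] = 1 + s
        W[hi, -2] = -s
    return W


# --------------------------------------------------------------------------
# event grouping (burst centroids)


def _burst_centroids(table: pd.DataFrame, max_gap: int = 2,
                     radius: float = 150.0) -> pd.DataFrame:
    """One centroid per fluorescence burst.

    Greedy temporal linkage identical in spirit to the blink-event
    merger, kept local to avoid a circular import; the generous radius
    only needs to distinguish simultaneous molecules, not re-identify
    them across the movie.
    """
    frames = table["frame"].to_numpy().astype(int)
    xs = table["x_nm"].to_numpy(dtype=float)
    ys = table["y_nm"].to_numpy(dtype=float)
    if "precision_nm" in table.columns:
        w = 1.0 / np.maximum(table["precision_nm"].to_numpy(float), 1e-3)**2
    else:
        w = np.ones(len(table))
    order = np.argsort(frames, kind="stable")
    open_events: list[list[float]] = []  # [sw, swx, swy, last_frame, n]
    done: list[list[float]] = []
    for r in order:
        f = frames[r]
        still_open = []
        for ev in open_events:
            if f - ev[3] <= max_gap + 1:
                still_open.append(ev)
            else:
                done.append(ev)
        open_events = still_open
        best, best_d = None, np.inf
        for ev in open_events:
            d = np.hypot(xs[r] - ev[1] / ev[0], ys[r] - ev[2] / ev[0])
            if d <= radius and d < best_d:
                best, best_d = ev, d
        if best is None:
            best = [0.0, 0.0, 0.0, f, 0.0]
            open_events.append(best)
        best[0] += w[r]
        best[1] += w[r] * xs[r]
        best[2] += w[r] * ys[r]
        best[3] = f
        best[4] += 1
    done.extend(open_events)
    arr = np.array([[ev[1] / ev[0], ev[2] / ev[0], ev[3],
                     1.0 / np.sqrt(ev[0])] for ev in done])
    return pd.DataFrame(arr, columns=["x", "y", "frame", "sigma"])


# --------------------------------------------------------------------------
# estimator


def estimate_drift(table: pd.DataFrame, n_blocks: int = 10,
                   render_pixel: float = 25.0, mode: str = "consecutive",
                   min_per_block: int = 50, n_frames: int | None = None,
                   smooth_px: float = 1.5, refine: bool = True,
                   refine_sigma_max: float = 8.0,
                   refine_smoothness: float = 0.3,
                   select_model: bool = False) -> DriftTrajectory:
    """Estimate lateral drift from a localization table.

    ``mode`` selects whether each block is correlated against the
    previous one (offsets chained by summation; robust when the observed
    structure evolves) or against the first block; both are followed by
    correlation of each block against the sum of the others with a
    shrinking search window.  ``refine=True`` adds the recurring-event
    linkage stage (skipped automatically when the table carries no
    precision column or too few recurrences are found).
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 temporal blocks")
    frames = table["frame"].to_numpy()
    if n_frames is None:
        n_frames = int(frames.max()) + 1

    ev = _burst_centroids(table)
    ef = ev["frame"].to_numpy()
    ex = ev["x"].to_numpy()
    ey = ev["y"].to_numpy()
    esig = ev["sigma"].to_numpy()

    edges = np.linspace(0, n_frames, n_blocks + 1)
    idx = np.clip(np.searchsorted(edges, ef, side="right") - 1,
                  0, n_blocks - 1)
    counts = np.bincount(idx, minlength=n_blocks)
    if counts.min() < min_per_block:
        b = int(np.argmin(counts))
        raise ValueError(f"block {b} has only {counts[b]} localizations "
                         f"(minimum {min_per_block})")
    anchors = 0.5 * (edges[:-1] + edges[1:])
    px = render_pixel

    def build(x, y):
        pad = 12 * px
        bx = np.arange(x.min() - pad, x.max() + pad + px, px)
        by = np.arange(y.min() - pad, y.max() + pad + px, px)
        return [ndimage.gaussian_filter(
            np.histogram2d(y[idx == b], x[idx == b], bins=(by, bx))[0],
            smooth_px) for b in range(n_blocks)]

    imgs = build(ex, ey)
    offs = np.zeros((n_blocks, 2))
    if mode == "consecutive":
        for b in range(1, n_blocks):
            c = _pearson_xcorr(imgs[b - 1], imgs[b])
            offs[b] = offs[b - 1] + _peak_offset(c, imgs[b].shape, px, 8)
    elif mode == "to_first":
        for b in range(1, n_blocks):
            c = _pearson_xcorr(imgs[0], imgs[b])
            offs[b] = _peak_offset(c, imgs[b].shape, px, 8)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for search in (10, 8, 6, 4):
        x = ex - offs[idx, 0]
        y = ey - offs[idx, 1]
        imgs = build(x, y)
        tot = np.sum(imgs, axis=0)
        for b in range(n_blocks):
            c = _pearson_xcorr(tot - imgs[b], imgs[b])
            offs[b] = offs[b] + _peak_offset(c, imgs[b].shape, px, search)

    nodes = np.linspace(0, n_frames, n_blocks + 1)
    node_offs = _hat_weights(nodes, anchors) @ offs
    if refine and "precision_nm" in table.columns:
        node_offs = _linked_event_refinement(
            ef, ex, ey, esig, nodes, node_offs,
            sigma_max=refine_sigma_max, lam=refine_smoothness)

    if select_model:
        # optional parsimony check: keep the anchored estimate only if it
        # aligns recurring events better than a constant-velocity model
        # (useful when the specimen under-determines block offsets).
        W_ev = _hat_weights(ef, nodes)
        linear_offs = np.column_stack([
            np.polyval(np.polyfit(nodes, node_offs[:, k], 1), nodes)
            for k in range(2)])
        score_full = _recurrence_coherence(ef, ex, ey, esig,
                                           W_ev @ node_offs)
        score_lin = _recurrence_coherence(ef, ex, ey, esig,
                                          W_ev @ linear_offs)
        if score_full <= 1.25 * score_lin:
            node_offs = linear_offs

    frames_all = np.arange(n_frames)
    drift = np.column_stack([
        PchipInterpolator(nodes, node_offs[:, k])(frames_all)
        for k in range(2)])
    drift -= drift[int(round(anchors[0]))]  # first block anchored at (0, 0)
    return DriftTrajectory(drift=drift, anchors=nodes,
                           anchor_offsets=node_offs)


def _recurrence_coherence(ef, ex, ey, esig, corr, sigma_max: float = 8.0,
                          radius: float = 15.0, min_gap: float = 500.0
                          ) -> float:
    """Number of well-localized event pairs that coincide within
    ``radius`` nm across distant times after applying a correction —
    a drift-quality score driven by repeated activations of the same
    molecules."""
    gi = np.flatnonzero(esig <= sigma_max)
    if len(gi) < 20:
        return 0.0
    xc = ex[gi] - corr[gi, 0]
    yc = ey[gi] - corr[gi, 1]
    tree = spatial.cKDTree(np.column_stack([xc, yc]))
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs) == 0:
        return 0.0
    gap = np.abs(ef[gi[pairs[:, 0]]] - ef[gi[pairs[:, 1]]])
    return float(np.sum(gap > min_gap))


def _linked_event_refinement(ef, ex, ey, esig, nodes, node_offs,
                             sigma_max: float = 8.0, lam: float = 0.3,
                             schedule=((20.0, 2.8, 1.25), (20.0, 2.8, 1.25),
                                       (20.0, 2.8, 1.25), (12.0, 2.2, 1.0),
                                       (12.0, 2.2, 1.0), (12.0, 2.2, 1.0),
                                       (12.0, 2.2, 1.0))):
    """Least-squares drift refinement from recurring blink events.

    Events that fall within the link radius of each other after the
    current correction are treated as repeated activations of the same
    molecule (connected components); clusters whose internal spread is
    inconsistent with the member precisions are discarded.  Node offsets
    are solved from the within-cluster demeaned positions with a mild
    second-difference smoothness penalty.
    """
    n_nodes = len(nodes)
    W = _hat_weights(ef, nodes)
    D = np.diff(np.eye(n_nodes), 2, axis=0)
    offs = node_offs.copy()
    for (link_r, z_drop, sig_scale) in schedule:
        smax = sigma_max * sig_scale
        gi = np.flatnonzero(esig <= smax)
        if len(gi) < 50:
            break
        corr = W @ offs
        xc = ex - corr[:, 0]
        yc = ey - corr[:, 1]
        tree = spatial.cKDTree(np.column_stack([xc, yc])[gi])
        pairs = tree.query_pairs(r=link_r, output_type="ndarray")
        adj = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(len(gi), len(gi)))
        _, labels = connected_components(adj, directed=False)
        rows_A, rows_t, rows_w = [], [], []
        order = np.argsort(labels)
        sorted_ids = gi[order]
        sorted_lab = labels[order]
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_lab) > 0])
        starts = np.r_[starts, len(sorted_lab)]
        for s0, s1 in zip(starts[:-1], starts[1:]):
            ids = sorted_ids[s0:s1]
            if len(ids) < 2:
                continue
            w = 1.0 / esig[ids]**2
            wx = np.average(xc[ids], weights=w)
            wy = np.average(yc[ids], weights=w)
            z = np.hypot(xc[ids] - wx, yc[ids] - wy) / esig[ids]
            if z.max() > z_drop:
                continue
            Wm = np.average(W[ids], axis=0, weights=w)
            for e in ids:
                rows_A.append(W[e] - Wm)
                rows_t.append([xc[e] - wx, yc[e] - wy])
                rows_w.append(1.0 / esig[e]**2)
        if len(rows_A) < 30:
            break
        A = np.asarray(rows_A)
        T = np.asarray(rows_t)
        wv = np.asarray(rows_w)
        H = (A * wv[:, None]).T @ A + lam * D.T @ D + 1e-5 * np.eye(n_nodes)
        offs = offs + np.column_stack([
            np.linalg.solve(H, (A * wv[:, None]).T @ T[:, 0]),
            np.linalg.solve(H, (A * wv[:, None]).T @ T[:, 1])])
    return offs


def correct(table: pd.DataFrame,
            trajectory: DriftTrajectory | np.ndarray) -> pd.DataFrame:
    """Subtract the per-frame drift from a localization table."""
    drift = (trajectory.drift if isinstance(trajectory, DriftTrajectory)
             else np.asarray(trajectory, dtype=float))
    f = table["frame"].to_numpy().astype(int)
    if f.min() < 0 or f.max() >= drift.shape[0]:
        raise ValueError("trajectory does not cover the table's frame range")
    out = table.copy()
    out["x_nm"] = out["x_nm"].to_numpy() - drift[f, 0]
    out["y_nm"] = out["y_nm"].to_numpy() - drift[f, 1]
    out.attrs["drift_corrected"] = True
    return out
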