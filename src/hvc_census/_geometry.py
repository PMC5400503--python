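"""Low-level geometric primitives shared across modules.

All coordinates are in micrometres, in continuous physical space.
"""

from __future__ import annotations

import numpy as np


def segment_lengths(p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Euclidean lengths of segments p0[i] -> p1[i]."""
    return np.linalg.norm(np.asarray(p1, float) - np.asarray(p0, float), axis=-1)


def clip_segments_to_box(
    p0: np.ndarray,
    p1: np.ndarray,
    box_min: np.ndarray,
    box_max: np.ndarray,
) -> np.ndarray:
    """Length of each segment's intersection with an axis-aligned box.

    Vectorized slab (Liang–Barsky) clipping.  Segments fully outside
    contribute 0; segments fully inside contribute their full length.
    """
    p0 = np.atleast_2d(np.asarray(p0, float))
    p1 = np.atleast_2d(np.asarray(p1, float))
    box_min = np.asarray(box_min, float)
    box_max = np.asarray(box_max, float)
    d = p1 - p0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (box_min - p0) / d
        t_hi = (box_max - p0) / d
    # where d == 0: inside slab -> (-inf, inf); outside -> empty
    inside0 = (p0 >= box_min) & (p0 <= box_max)
    zero = d == 0.0
    t_lo = np.where(zero, np.where(inside0, -np.inf, np.inf), t_lo)
    t_hi = np.where(zero, np.where(inside0, np.inf, -np.inf), t_hi)
    t_enter = np.minimum(t_lo, t_hi)
    t_exit = np.maximum(t_lo, t_hi)
    t0 = np.maximum(t_enter.max(axis=-1), 0.0)
    t1 = np.minimum(t_exit.min(axis=-1), 1.0)
    frac = np.clip(t1 - t0, 0.0, 1.0)
    return frac * np.linalg.norm(d, axis=-1)


def segment_box_interval(
    p0: np.ndarray, p1: np.ndarray, box_min: np.ndarray, box_max: np.ndarray
) -> tuple[float, float] | None:
    """Parameter interval [t0, t1] of a single segment inside a box, or None."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0.0:
            if p0[ax] < box_min[ax] or p0[ax] > box_max[ax]:
                return None
            continue
        lo = (box_min[ax] - p0[ax]) / d[ax]
        hi = (box_max[ax] - p0[ax]) / d[ax]
        if lo > hi:
            lo, hi = hi, lo
        t0 = max(t0, lo)
        t1 = min(t1, hi)
    if t1 <= t0:
        return None
    return (t0, t1)


def point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distances from each point to the segment a->b (all shapes (n,3)/(3,))."""
    points = np.atleast_2d(np.asarray(points, float))
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def min_point_to_polyline_distance(
    points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """For each point, the minimum distance to any segment (seg_a[j], seg_b[j])."""
    points = np.atleast_2d(np.asarray(points, float))
    best = np.full(len(points), np.inf)
    for a, b in zip(seg_a, seg_b):
        d = point_segment_distance(points, a, b)
        np.minimum(best, d, out=best)
    return best


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an ordered polyline at ~uniform spacing, keeping both endpoints.

    The number of intervals is round(total/spacing) (minimum 1) so the
    realized spacing is as close to the request as the total length allows.
    """
    points = np.asarray(points, float)
    if len(points) < 2:
        return points.copy()
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        return points[[0, -1]].copy()
    n_int = max(1, int(round(total / spacing)))
    targets = np.linspace(0.0, total, n_int + 1)
    out = np.empty((len(targets), 3))
    for k in range(3):
        out[:, k] = np.interp(targets, cum, points[:, k])
    return out


def apportion_to_bins(
    r0: np.ndarray, r1: np.ndarray, lengths: np.ndarray, bin_edges: np.ndarray
) -> np.ndarray:
    """Apportion segment lengths across radial bins by linear interpolation.

    Each segment runs from radius r0[i] to r1[i]; its length is split among
    the bins its radius interval overlaps, proportionally to the overlap.
    Removes the bin-width bias of midpoint assignment for long segments.
    """
    r_lo = np.minimum(r0, r1)
    r_hi = np.maximum(r0, r1)
    span = r_hi - r_lo
    out = np.zeros(len(bin_edges) - 1)
    degenerate = span <= 0
    if degenerate.any():
        idx = np.clip(
            np.searchsorted(bin_edges, r_lo[degenerate], side="right") - 1,
            0,
            len(out) - 1,
        )
        np.add.at(out, idx, lengths[degenerate])
    ok = ~degenerate
    if ok.any():
        lo, hi, ln = r_lo[ok], r_hi[ok], lengths[ok]
        for b in range(len(out)):
            olap = np.clip(
                np.minimum(hi, bin_edges[b + 1]) - np.maximum(lo, bin_edges[b]),
                0.0,
                None,
            )
            out[b] += np.sum(ln * olap / (hi - lo))
        # anything beyond the last edge piles into the last bin
        beyond = np.clip(hi - bin_edges[-1], 0.0, None) - np.clip(
            lo - bin_edges[-1], 0.0, None
        )
        out[-1] += np.sum(ln * beyond / (hi - lo))
        below = np.clip(bin_edges[0] - lo, 0.0, None) - np.clip(
            bin_edges[0] - hi, 0.0, None
        )
        out[0] += np.sum(ln * below / (hi - lo))
    return out
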