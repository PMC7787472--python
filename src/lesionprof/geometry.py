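"""Polyline geometry helpers: arc-length resampling, tangents, distances."""

from __future__ import annotations

import numpy as np

__all__ = [
    "arc_lengths",
    "resample_polyline",
    "polyline_tangents",
    "point_to_polyline_distance",
]


def arc_lengths(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (mm) at each vertex, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _interp_at(points: np.ndarray, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.stack([np.interp(t, s, points[:, k]) for k in range(3)], axis=1)


def resample_polyline(
    points: np.ndarray,
    step: float | None = None,
    n: int | None = None,
) -> np.ndarray:
    """Resample a polyline at fixed arc-length spacing.

    Exactly one of ``step`` (mm spacing, first sample at the start vertex)
    or ``n`` (sample count spanning the full length) must be given.
    """
    if (step is None) == (n is None):
        raise ValueError("specify exactly one of step and n")
    points = np.asarray(points, dtype=float)
    s = arc_lengths(points)
    total = s[-1]
    if n is not None:
        if n < 2:
            raise ValueError("n must be >= 2")
        t = np.linspace(0.0, total, n)
    else:
        if step <= 0:
            raise ValueError("step must be positive")
        t = np.arange(0.0, total + 1e-9, step)
    return _interp_at(points, s, t)


def polyline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at each vertex (central differences, one-sided at ends)."""
    points = np.asarray(points, dtype=float)
    grad = np.gradient(points, axis=0)
    norms = np.linalg.norm(grad, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return grad / norms


def point_to_polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from each query point to a polyline.

    Distances are to the segments, not just the vertices, so the result is
    exact for straight sections regardless of vertex spacing.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(poly, dtype=float)
    a, b = poly[:-1], poly[1:]
    d = b - a  # (S, 3)
    dd = (d * d).sum(axis=1)
    dd[dd == 0] = 1.0
    ap = points[:, None, :] - a[None, :, :]  # (P, S, 3)
    t = np.clip(np.einsum("psk,sk->ps", ap, d) / dd, 0.0, 1.0)
    proj = a[None] + t[..., None] * d[None]
    return np.linalg.norm(points[:, None, :] - proj, axis=2).min(axis=1)
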