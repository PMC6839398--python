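"""Planar outline primitives shared by all pipeline stages.

An :class:`Outline` is a closed, simple polygon traversed counterclockwise,
with coordinates in micrometres and an implicit closing edge (the first
vertex is not repeated at the end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "Outline",
    "signed_area",
    "polygon_perimeter",
    "resample_closed",
    "smooth_closed",
    "max_caliper",
]


def signed_area(vertices: np.ndarray) -> float:
    """Shoelace area; positive for counterclockwise traversal."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(vertices: np.ndarray) -> float:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


@dataclass
class Outline:
    """Closed simple polygon border of one nucleus, counterclockwise, in µm."""

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs an (n, 2) array with n >= 3")
        # drop an explicit closing vertex if present
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("degenerate outline")
        if polygon_perimeter(v) <= 0:
            raise ValueError("degenerate outline: zero perimeter")
        if signed_area(v) < 0:
            v = v[::-1].copy()
        self.vertices = v

    def __len__(self) -> int:
        return self.vertices.shape[0]

    @property
    def area(self) -> float:
        return abs(signed_area(self.vertices))

    @property
    def perimeter(self) -> float:
        return polygon_perimeter(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def is_simple(self) -> bool:
        return Polygon(self.vertices).is_simple

    def rolled(self, k: int) -> "Outline":
        """Outline with vertex ``k`` moved to index 0 (traversal unchanged)."""
        return Outline(np.roll(self.vertices, -k, axis=0))

    def transformed(self, scale: float = 1.0, angle: float = 0.0,
                    shift=(0.0, 0.0)) -> "Outline":
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        return Outline(scale * self.vertices @ rot.T + np.asarray(shift, float))


def _cumulative_arclength(vertices: np.ndarray) -> np.ndarray:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    return np.concatenate([[0.0], np.cumsum(steps)])


def resample_closed(vertices: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polygon to ``n_points`` vertices equally spaced by
    arc length, starting at the current first vertex."""
    s = _cumulative_arclength(vertices)
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-length outline cannot be resampled")
    closed = np.vstack([vertices, vertices[:1]])
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def smooth_closed(vertices: np.ndarray, window_fraction: float) -> np.ndarray:
    """Circular moving-average smoothing over a window expressed as a fraction
    of the perimeter. Suppresses pixelation without moving the shape."""
    if window_fraction <= 0:
        return vertices.copy()
    n = vertices.shape[0]
    w = max(1, int(round(window_fraction * n)))
    if w % 2 == 0:
        w += 1
    if w <= 1:
        return vertices.copy()
    kernel = np.ones(w) / w
    out = np.empty_like(vertices)
    for j in range(2):
        padded = np.concatenate([vertices[-(w // 2):, j], vertices[:, j],
                                 vertices[: w // 2, j]])
        out[:, j] = np.convolve(padded, kernel, mode="valid")
    return out


def max_caliper(vertices: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum caliper (Feret) diameter and its unit direction.

    Brute force over convex-hull vertex pairs; hulls of nucleus outlines are
    small so this is cheap.
    """
    from scipy.spatial import ConvexHull

    hull = vertices[ConvexHull(vertices).vertices]
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = float(np.sqrt(d2[i, j]))
    direction = (hull[i] - hull[j]) / length
    return length, direction
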