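"""Consensus ("average") nuclear outlines from landmark-aligned shapes.

Outlines are brought into correspondence by rolling the hook apex to vertex
0, centering on the centroid, and a rotation-only Procrustes pass iterated
against the running mean. Reflections are never applied: a mirror-image cell
stays mirrored. The consensus is the vertexwise mean with a per-vertex
radial interquartile envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Outline

__all__ = ["ConsensusShape", "align_outlines", "consensus_shape",
           "consensus_to_svg_path"]


@dataclass
class ConsensusShape:
    mean_outline: Outline
    envelope: np.ndarray = field(repr=False)   # per-vertex radial IQR
    n_cells: int = 0


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> float:
    """Angle rotating centered ``src`` onto centered ``dst`` in least squares,
    without reflection."""
    num = float(np.sum(src[:, 0] * dst[:, 1] - src[:, 1] * dst[:, 0]))
    den = float(np.sum(src[:, 0] * dst[:, 0] + src[:, 1] * dst[:, 1]))
    return float(np.arctan2(num, den))


def align_outlines(outlines: list[Outline], apexes: list[int],
                   scale_mode: str = "size-preserving",
                   tol: float = 1e-6, max_iter: int = 200) -> np.ndarray:
    """Landmark-then-Procrustes alignment; returns an (N, P, 2) array.

    Each outline is index-rotated so its apex becomes vertex 0, translated
    to centroid origin, optionally scaled to unit centroid size, then
    rigidly rotated to the running mean until the mean shape moves by less
    than ``tol`` of the mean radius.
    """
    if scale_mode not in ("size-preserving", "unit-scaled"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    counts = {len(o) for o in outlines}
    if len(counts) != 1:
        raise ValueError("all outlines must share one point count; "
                         f"got counts {sorted(counts)}")
    if len(outlines) != len(apexes):
        raise ValueError("one apex index required per outline")
    stack = []
    for o, apex in zip(outlines, apexes):
        v = o.rolled(int(apex)).vertices
        v = v - v.mean(axis=0)
        if scale_mode == "unit-scaled":
            v = v / np.sqrt(np.mean(np.sum(v ** 2, axis=1)))
        stack.append(v)
    arr = np.array(stack)
    mean = arr.mean(axis=0)   # permutation-invariant starting frame
    for _ in range(max_iter):
        for i in range(arr.shape[0]):
            ang = _optimal_rotation(arr[i], mean)
            c, s = np.cos(ang), np.sin(ang)
            arr[i] = arr[i] @ np.array([[c, -s], [s, c]]).T
        new_mean = arr.mean(axis=0)
        radius = float(np.mean(np.linalg.norm(new_mean, axis=1)))
        move = float(np.mean(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if radius > 0 and move < tol * radius:
            break
    return arr


def consensus_shape(aligned: np.ndarray) -> ConsensusShape:
    """Vertexwise mean outline with a radial interquartile-range envelope."""
    aligned = np.asarray(aligned, dtype=float)
    if aligned.ndim != 3 or aligned.shape[0] == 0:
        raise ValueError("aligned set must be a non-empty (N, P, 2) array")
    mean = aligned.mean(axis=0)
    radii = np.linalg.norm(aligned - mean[None, :, :], axis=2)
    signed = np.einsum("npk,pk->np", aligned - mean[None, :, :],
                       _unit_radial(mean))
    q75, q25 = np.percentile(signed, [75, 25], axis=0)
    return ConsensusShape(mean_outline=Outline(mean),
                          envelope=q75 - q25, n_cells=aligned.shape[0])


def _unit_radial(mean: np.ndarray) -> np.ndarray:
    center = mean.mean(axis=0)
    rad = mean - center
    norms = np.maximum(np.linalg.norm(rad, axis=1, keepdims=True), 1e-12)
    return rad / norms


def consensus_to_svg_path(shape: ConsensusShape, decimals: int = 3) -> str:
    """Consensus mean outline as an SVG path string (closed polyline)."""
    v = np.round(shape.mean_outline.vertices, decimals)
    parts = [f"M {v[0,0]},{-v[0,1]}"]
    parts += [f"L {x},{-y}" for x, y in v[1:]]
    parts.append("Z")
    return " ".join(parts)
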