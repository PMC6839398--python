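"""Capture/recapture matching of pre- and post-FISH images.

Morphology is imaged before FISH; the FISH protocol then reveals the sex
chromosome but swells the chromatin and distorts detail. Re-identification
of the same nuclei combines the recorded stage coordinates (coarse gate)
with a multi-scale structural-similarity score (fine ranking), followed by
a greedy one-to-one assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .synthetic import GrayImage

__all__ = ["CapturedImage", "MatchResult", "pair_by_coordinates",
           "ssim_score", "score_candidates", "assign_matches"]


@dataclass
class CapturedImage:
    image: GrayImage
    stage_xy: tuple[float, float]
    slide_id: str
    capture_phase: str            # "pre" or "post"
    image_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.stage_xy)):
            raise ValueError("stage coordinates must be finite")
        if self.capture_phase not in ("pre", "post"):
            raise ValueError("capture_phase must be 'pre' or 'post'")


@dataclass
class MatchResult:
    pre_id: str
    post_id: str
    coordinate_distance: float
    similarity: float
    accepted: bool


def pair_by_coordinates(pre: list[CapturedImage], post: list[CapturedImage],
                        radius: float) -> pd.DataFrame:
    """All cross-phase image pairs within ``radius`` µm of stage distance,
    sorted by distance. Both lists must come from a single slide."""
    slides = {c.slide_id for c in pre} | {c.slide_id for c in post}
    if len(slides) > 1:
        raise ValueError(f"images span multiple slides: {sorted(slides)}")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if not pre or not post:
        return pd.DataFrame(columns=["pre_id", "post_id", "distance"])
    post_xy = np.array([c.stage_xy for c in post])
    tree = cKDTree(post_xy)
    rows = []
    for c in pre:
        for j in tree.query_ball_point(c.stage_xy, r=radius):
            d = float(np.hypot(c.stage_xy[0] - post_xy[j, 0],
                               c.stage_xy[1] - post_xy[j, 1]))
            rows.append({"pre_id": c.image_id, "post_id": post[j].image_id,
                         "distance": d})
    return (pd.DataFrame(rows, columns=["pre_id", "post_id", "distance"])
            .sort_values(["distance", "pre_id", "post_id"],
                         ignore_index=True))


def ssim_score(a: GrayImage, b: GrayImage, levels: int = 3) -> float:
    """Multi-scale structural similarity: Gaussian-windowed SSIM averaged
    over ``levels`` dyadic downscalings. Identical images score 1.0."""
    pa = np.asarray(a.pixels, dtype=float)
    pb = np.asarray(b.pixels, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError(f"image dimensions differ: {pa.shape} vs {pb.shape}")
    data_range = max(pa.max() - pa.min(), pb.max() - pb.min(), 1.0)
    scores = []
    for level in range(levels):
        if min(pa.shape) < 16:
            break
        scores.append(structural_similarity(
            pa, pb, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=data_range))
        if level < levels - 1:
            new_shape = (pa.shape[0] // 2, pa.shape[1] // 2)
            pa = resize(pa, new_shape, anti_aliasing=True)
            pb = resize(pb, new_shape, anti_aliasing=True)
    if not scores:
        raise ValueError("images too small for SSIM")
    return float(np.mean(scores))


def _center_embed(img: np.ndarray, shape: tuple[int, int],
                  fill: float) -> np.ndarray:
    """Place ``img`` centered on a canvas of ``shape`` (crop if larger)."""
    out = np.full(shape, fill, dtype=float)
    r0 = (shape[0] - img.shape[0]) // 2
    c0 = (shape[1] - img.shape[1]) // 2
    if r0 >= 0 and c0 >= 0:
        out[r0:r0 + img.shape[0], c0:c0 + img.shape[1]] = img
    else:
        rr, cc = max(-r0, 0), max(-c0, 0)
        crop = img[rr:rr + shape[0], cc:cc + shape[1]]
        out[:crop.shape[0], :crop.shape[1]] = crop
    return out


def score_candidates(candidates: pd.DataFrame,
                     pre: dict[str, CapturedImage],
                     post: dict[str, CapturedImage],
                     levels: int = 3,
                     register: bool = True) -> pd.DataFrame:
    """Attach a similarity column to a candidate-pair table.

    Before scoring, the post-FISH image is resampled to the pre image's
    pixel size (the recapture has its own effective magnification after
    chromatin swelling), centered on the pre canvas and, with ``register``,
    aligned by translation via phase cross-correlation — stage repositioning
    is only accurate to about a micrometre.
    """
    from scipy.ndimage import shift as nd_shift
    from skimage.registration import phase_cross_correlation
    from skimage.transform import rescale

    sims = []
    for _, row in candidates.iterrows():
        ia = pre[row["pre_id"]].image
        ib = post[row["post_id"]].image
        pa = np.asarray(ia.pixels, dtype=float)
        pb = np.asarray(ib.pixels, dtype=float)
        factor = ib.pixel_size / ia.pixel_size
        if abs(factor - 1.0) > 1e-9:
            pb = rescale(pb, factor, anti_aliasing=factor < 1)
        if pb.shape != pa.shape:
            pb = _center_embed(pb, pa.shape, float(np.median(pb)))
        if register:
            offset, _, _ = phase_cross_correlation(
                pa, pb, upsample_factor=4, normalization=None)
            pb = nd_shift(pb, offset, mode="nearest")
        sims.append(ssim_score(GrayImage(pa, ia.pixel_size),
                               GrayImage(pb, ia.pixel_size), levels=levels))
    out = candidates.copy()
    out["similarity"] = sims
    return out


def assign_matches(candidates: pd.DataFrame,
                   min_similarity: float = 0.5) -> list[MatchResult]:
    """Greedy descending-similarity one-to-one assignment.

    Pairs below ``min_similarity`` are rejected. Ties in similarity break
    deterministically by smaller coordinate distance, then by lowest
    pre_id / post_id.
    """
    if "similarity" not in candidates.columns:
        raise ValueError("candidates must be scored first")
    order = candidates.sort_values(
        ["similarity", "distance", "pre_id", "post_id"],
        ascending=[False, True, True, True])
    used_pre: set = set()
    used_post: set = set()
    matches = []
    for _, row in order.iterrows():
        if row["pre_id"] in used_pre or row["post_id"] in used_post:
            continue
        accepted = bool(row["similarity"] >= min_similarity)
        if accepted:
            used_pre.add(row["pre_id"])
            used_post.add(row["post_id"])
            matches.append(MatchResult(
                pre_id=row["pre_id"], post_id=row["post_id"],
                coordinate_distance=float(row["distance"]),
                similarity=float(row["similarity"]), accepted=True))
    return matches
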