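"""Synthetic study-data generators.

Everything the pipeline consumes can be produced here with full seed
control: parametric falciform (hook-shaped) sperm-head outlines with
genotype and sex-chromosome effects planted in the shape parameters,
rasterized noisy grayscale images emulating DAPI micrographs, swim-up
fractionation X/Y count tables, and midpiece-length samples.

The shape model is a superellipse body fused with a tapering circular-arc
hook. The knobs map one-to-one onto the morphological effects reported for
Yq-deficient sperm: acrosomal curvature (hook bend), hook length, head
area, and hook base width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .geometry import Outline, resample_closed

__all__ = [
    "ShapeParams",
    "PopulationSpec",
    "SwimUpModelSpec",
    "NucleusRecord",
    "GrayImage",
    "ImageSpec",
    "generate_shape",
    "generate_population",
    "rasterize",
    "simulate_fish_distortion",
    "generate_swimup_counts",
    "generate_midpiece_lengths",
    "WT_PARAMS",
    "GENOTYPE_EFFECTS",
    "SEX_EFFECTS",
    "NOISE_SD",
]

PARAM_NAMES = ("body_length", "body_width", "hook_length",
               "acrosome_curvature", "base_width", "area_scale")


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one synthetic sperm-head outline (lengths in µm)."""

    body_length: float = 8.0
    body_width: float = 4.0
    hook_length: float = 3.2
    acrosome_curvature: float = 1.0   # dimensionless bend of the dorsal hook
    base_width: float = 1.4
    area_scale: float = 1.0

    def validate(self) -> None:
        for name in ("body_length", "body_width", "hook_length", "base_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.acrosome_curvature < 0:
            raise ValueError("acrosome_curvature must be >= 0")
        if self.area_scale <= 0:
            raise ValueError("area_scale must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_NAMES}


WT_PARAMS = ShapeParams()

# Additive shifts applied to every cell of a genotype. Mutants have more
# curved acrosomes, shorter hooks and smaller heads than wild type; the
# short-hairpin Sly knockdown exceeds the Yq-deletion phenotype.
GENOTYPE_EFFECTS: dict[str, dict[str, float]] = {
    "WT": {},
    "YQDEL": {"acrosome_curvature": 0.45, "hook_length": -0.35,
              "area_scale": -0.06, "body_length": -0.30, "base_width": -0.10},
    "SHSLY": {"acrosome_curvature": 0.70, "hook_length": -0.55,
              "area_scale": -0.10, "body_length": -0.45, "base_width": -0.15},
}

# Additional shifts applied to Y-bearing cells only, in mutant genotypes:
# Y-bearing sperm deviate further from wild-type values than X-bearing.
# Magnitudes are roughly half a within-population SD per parameter so that
# the X and Y shape distributions overlap substantially, as in real data.
SEX_EFFECTS: dict[str, float] = {
    "acrosome_curvature": 0.10,
    "hook_length": -0.08,
    "area_scale": -0.015,
}

# Within-population SD of each parameter (biological cell-to-cell spread).
NOISE_SD: dict[str, float] = {
    "body_length": 0.25, "body_width": 0.15, "hook_length": 0.20,
    "acrosome_curvature": 0.22, "base_width": 0.10, "area_scale": 0.035,
}


@dataclass
class PopulationSpec:
    """A population of synthetic nuclei with planted genotype/sex effects."""

    genotype: str = "WT"
    n_cells: int = 200
    sex_effect: dict[str, float] = field(default_factory=lambda: dict(SEX_EFFECTS))
    genotype_effect: dict[str, float] | None = None
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(NOISE_SD))
    base_params: ShapeParams = WT_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        self.genotype = self.genotype.upper()
        if self.genotype not in GENOTYPE_EFFECTS:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if self.genotype_effect is None:
            self.genotype_effect = dict(GENOTYPE_EFFECTS[self.genotype])


@dataclass
class NucleusRecord:
    """One cell: identity, ground-truth parameters and derived measurements."""

    cell_id: str
    genotype: str
    sex: str                      # "X" or "Y" bearing
    params: ShapeParams
    outline: Outline | None = None
    hook_tip: np.ndarray | None = None
    profile: np.ndarray | None = None   # filled by morphometry
    stats: dict[str, float] | None = None
    cluster: int | None = None


@dataclass
class GrayImage:
    """Single-channel intensity image with physical pixel size (µm/px)."""

    pixels: np.ndarray
    pixel_size: float = 0.05

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.size == 0:
            raise ValueError("image must be a non-empty 2D array")
        self.pixels = p


@dataclass
class ImageSpec:
    """Rasterization settings for synthetic micrographs."""

    pixel_size: float = 0.05       # µm per pixel
    blur_sd: float = 1.0           # px, optical blur
    noise_sd: float = 300.0        # intensity units (16-bit scale)
    background: float = 2000.0
    foreground: float = 30000.0
    shape: tuple[int, int] | None = None   # (rows, cols); auto-fit if None
    margin: float = 1.0            # µm of padding when auto-fitting


# ---------------------------------------------------------------------------
# outline generation

def _superellipse(a: float, b: float, exponent: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    ct, st = np.cos(t), np.sin(t)
    x = a * np.sign(ct) * np.abs(ct) ** (2.0 / exponent)
    y = b * np.sign(st) * np.abs(st) ** (2.0 / exponent)
    return np.column_stack([x, y])


def _hook_band(params: ShapeParams) -> tuple[np.ndarray, np.ndarray]:
    """Tapering band around a circular-arc centerline; returns (polygon, tip).

    The hook roots on the anterior (positive-x) end of the body, initially
    pointing forward-dorsal and curving back over the dorsal edge. Higher
    ``acrosome_curvature`` bends the arc harder.
    """
    a = params.body_length / 2.0
    b = params.body_width / 2.0
    # total turning of the centerline, radians
    phi = float(np.clip(0.55 + 0.55 * params.acrosome_curvature, 0.15, 2.7))
    radius = params.hook_length / phi
    n = 60
    s = np.linspace(0.0, params.hook_length, n)
    theta0 = np.deg2rad(55.0)                  # take-off direction from +x axis
    theta = theta0 + s / radius                # left turn (dorsal, over the body)
    root = np.array([0.88 * a, 0.30 * b])      # attachment inside the body edge
    cx = np.concatenate([[0.0], np.cumsum(np.cos((theta[:-1] + theta[1:]) / 2)
                                          * np.diff(s))])
    cy = np.concatenate([[0.0], np.cumsum(np.sin((theta[:-1] + theta[1:]) / 2)
                                          * np.diff(s))])
    center = root + np.column_stack([cx, cy])
    # taper accelerates with curvature so a more curved acrosome also ends
    # in a sharper apex (the two effects co-occur in the malformed hooks)
    q = 0.8 + 0.5 * params.acrosome_curvature
    frac = s / params.hook_length
    half_w = (params.base_width / 2.0 - 0.03) * (1 - frac) ** q + 0.03
    normal = np.column_stack([-np.sin(theta), np.cos(theta)])
    left = center + normal * half_w[:, None]
    right = center - normal * half_w[:, None]
    band = np.vstack([left, right[::-1]])
    return band, center[-1]


def generate_shape(params: ShapeParams, seed: int = 0,
                   n_points: int = 400,
                   return_landmarks: bool = False):
    """Generate one closed, simple, counterclockwise sperm-head outline.

    The body is a superellipse, the hook a tapering circular-arc band; the
    two are fused by polygon union and the result is resampled to
    ``n_points`` equally spaced vertices. A small smooth radial perturbation
    (low-order Fourier series, 0.5% amplitude) individualizes cells without
    disturbing the landmark structure. With ``return_landmarks`` the planted
    hook-tip coordinate is returned alongside the outline.
    """
    params.validate()
    if n_points < 200:
        raise ValueError("n_points must be >= 200")
    body = _superellipse(params.body_length / 2.0, params.body_width / 2.0,
                         exponent=2.5, n=360)
    band, tip = _hook_band(params)
    merged = Polygon(body).buffer(0).union(Polygon(band).buffer(0))
    if merged.geom_type != "Polygon":
        merged = max(merged.geoms, key=lambda g: g.area)
    merged = orient(merged, sign=1.0)
    verts = np.asarray(merged.exterior.coords)[:-1]
    verts = resample_closed(verts, n_points)

    # smooth per-cell perturbation
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    wobble = np.zeros(n_points)
    for h in range(2, 6):
        wobble += rng.normal(0, 1) * np.cos(h * t) + rng.normal(0, 1) * np.sin(h * t)
    centroid = verts.mean(axis=0)
    radial = verts - centroid
    r = np.hypot(radial[:, 0], radial[:, 1])
    scale_r = 1.0 + 0.005 * wobble / max(1.0, np.max(np.abs(wobble)))
    verts = centroid + radial * scale_r[:, None]

    s = float(np.sqrt(params.area_scale))
    verts = verts * s
    tip = tip * s
    outline = Outline(verts)
    if return_landmarks:
        return outline, tip
    return outline


def _draw_params(spec: PopulationSpec, sex: str,
                 rng: np.random.Generator) -> ShapeParams:
    values = dict(WT_PARAMS.as_dict())
    for k, v in spec.base_params.as_dict().items():
        values[k] = v
    for k, v in (spec.genotype_effect or {}).items():
        values[k] += v
    if spec.genotype != "WT" and sex == "Y":
        for k, v in spec.sex_effect.items():
            values[k] += v
    for k, sd in spec.noise_sd.items():
        values[k] += rng.normal(0.0, sd)
    # keep parameters physical
    for k in ("body_length", "body_width", "hook_length", "base_width",
              "area_scale"):
        values[k] = max(values[k], 0.05)
    values["acrosome_curvature"] = max(values["acrosome_curvature"], 0.0)
    return ShapeParams(**values)


def generate_population(spec: PopulationSpec,
                        build_outlines: bool = True) -> list[NucleusRecord]:
    """Draw ``spec.n_cells`` nuclei with a 50:50 latent X:Y label ratio.

    In wild type, X- and Y-bearing cells are exchangeable; in the mutant
    genotypes the Y-bearing subpopulation is shifted by ``spec.sex_effect``
    on top of the genotype effect.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_cells):
        sex = "X" if rng.random() < 0.5 else "Y"
        params = _draw_params(spec, sex, rng)
        rec = NucleusRecord(
            cell_id=f"{spec.genotype}_{spec.seed}_{i:05d}",
            genotype=spec.genotype, sex=sex, params=params)
        if build_outlines:
            shape_seed = int(rng.integers(0, 2**31 - 1))
            rec.outline, rec.hook_tip = generate_shape(
                params, seed=shape_seed, return_landmarks=True)
        records.append(rec)
    return records


def population_table(records: list[NucleusRecord]) -> pd.DataFrame:
    """Sidecar table: one row per nucleus with identity and true parameters."""
    rows = []
    for r in records:
        row = {"id": r.cell_id, "genotype": r.genotype, "sex_label": r.sex}
        row.update(r.params.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rasterization

def rasterize(outline: Outline, spec: ImageSpec = ImageSpec(),
              seed: int = 0) -> GrayImage:
    """Render an outline as a noisy 16-bit-range grayscale image.

    Polygon fill at ``spec.foreground`` over ``spec.background``, Gaussian
    optical blur, then additive Gaussian noise. Deterministic per seed.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.draw import polygon as draw_polygon

    verts = outline.vertices
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    if spec.shape is None:
        extent = hi - lo + 2 * spec.margin
        shape = (int(np.ceil(extent[1] / spec.pixel_size)),
                 int(np.ceil(extent[0] / spec.pixel_size)))
        origin = lo - spec.margin
    else:
        shape = spec.shape
        canvas_um = np.array([shape[1], shape[0]]) * spec.pixel_size
        size = hi - lo
        if size[0] > canvas_um[0] or size[1] > canvas_um[1]:
            raise ValueError("outline exceeds the image canvas")
        origin = (lo + hi) / 2 - canvas_um / 2
    # image rows increase downward; outline y increases upward
    cols = (verts[:, 0] - origin[0]) / spec.pixel_size
    rows = (shape[0] - 1) - (verts[:, 1] - origin[1]) / spec.pixel_size
    img = np.full(shape, spec.background, dtype=float)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    if rr.size == 0:
        raise ValueError("outline rasterizes to an empty region")
    img[rr, cc] = spec.foreground
    if spec.blur_sd > 0:
        img = gaussian_filter(img, spec.blur_sd)
    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return GrayImage(img, pixel_size=spec.pixel_size)


def simulate_fish_distortion(image: GrayImage, dilation: float = 1.10,
                             blur_sd: float = 2.0, noise_sd: float = 300.0,
                             seed: int = 0) -> GrayImage:
    """Emulate the chromatin swelling of the FISH protocol on an image:
    isotropic dilation about the center plus Gaussian blur and fresh noise.
    Used to build capture/recapture fixtures."""
    from scipy.ndimage import gaussian_filter, zoom

    px = image.pixels.astype(float)
    scaled = zoom(px, dilation, order=1)
    r0 = (scaled.shape[0] - px.shape[0]) // 2
    c0 = (scaled.shape[1] - px.shape[1]) // 2
    r0, c0 = max(r0, 0), max(c0, 0)
    cropped = scaled[r0:r0 + px.shape[0], c0:c0 + px.shape[1]]
    out = np.full_like(px, float(np.median(px)))
    out[:cropped.shape[0], :cropped.shape[1]] = cropped
    out = gaussian_filter(out, blur_sd)
    rng = np.random.default_rng(seed)
    out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return GrayImage(np.clip(out, 0, 65535).astype(np.uint16),
                     pixel_size=image.pixel_size / dilation)


# ---------------------------------------------------------------------------
# swim-up counts and midpiece lengths

@dataclass
class SwimUpModelSpec:
    """Generative model for swim-up fractionation X/Y counts.

    The latent X proportion is logit-linear in the (centered) fraction
    index; per-slide proportions get beta-distributed overdispersion with
    precision ``precision_phi``, and counts are binomial. Killed-sperm
    control rows always use slope 0 (no motility, no enrichment).
    """

    n_males: int = 10
    n_fractions: int = 6
    cells_per_fraction: int = 400
    logit_intercept: float = 0.0
    logit_slope: dict[str, float] = field(
        default_factory=lambda: {"WT": -0.05, "YQDEL": 0.15})
    precision_phi: float = 150.0
    genotypes: tuple[str, ...] = ("WT", "YQDEL")
    states: tuple[str, ...] = ("live", "killed")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males <= 0 or self.n_fractions <= 0:
            raise ValueError("n_males and n_fractions must be > 0")
        if self.cells_per_fraction <= 0:
            raise ValueError("cells_per_fraction must be > 0")
        if self.precision_phi <= 0:
            raise ValueError("precision_phi must be > 0")


def generate_swimup_counts(spec: SwimUpModelSpec) -> pd.DataFrame:
    """One row per male x state x fraction with x_count / y_count columns."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for genotype in spec.genotypes:
        slope = spec.logit_slope.get(genotype, 0.0)
        for m in range(spec.n_males):
            male_id = f"{genotype}_m{m:02d}"
            for state in spec.states:
                eff_slope = 0.0 if state == "killed" else slope
                for frac in range(1, spec.n_fractions + 1):
                    eta = spec.logit_intercept + eff_slope * (
                        frac - (spec.n_fractions + 1) / 2.0)
                    mu = 1.0 / (1.0 + np.exp(-eta))
                    p = rng.beta(mu * spec.precision_phi,
                                 (1 - mu) * spec.precision_phi)
                    x = int(rng.binomial(spec.cells_per_fraction, p))
                    rows.append({"male_id": male_id, "genotype": genotype,
                                 "state": state, "fraction": frac,
                                 "x_count": x,
                                 "y_count": spec.cells_per_fraction - x})
    return pd.DataFrame(rows)


def generate_midpiece_lengths(n_top: int, n_bottom: int, shift: float,
                              seed: int = 0, mean: float = 21.0,
                              sd: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Midpiece-length samples (µm) for a top and a bottom swim-up fraction;
    the top fraction mean exceeds the bottom by ``shift`` in expectation."""
    if n_top <= 0 or n_bottom <= 0:
        raise ValueError("sample sizes must be > 0")
    rng = np.random.default_rng(seed)
    top = rng.normal(mean + shift, sd, size=n_top)
    bottom = rng.normal(mean, sd, size=n_bottom)
    return top, bottom
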