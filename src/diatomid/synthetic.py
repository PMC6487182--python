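"""Synthetic pennate-valve image generator with ground-truth masks.

Each sample is a single elongated valve on a darker (or brighter) background
with periodic striae ornamentation, uneven illumination and additive Gaussian
noise — the structure of single-valve brightfield micrographs.  Outlines are
closed-form (superellipse / Cassini oval / bulbed profiles) so masks are
exact analytic rasters and areas have analytic oracles.

Life-cycle size reduction is modelled geometrically: every asexual division
stage shrinks the apical length by a fixed ratio (default 0.93) while the
transapical width stays nearly constant, and a morph parameter rounds the
outline slightly toward the senescent form.  No quantitative per-stage
statistics exist for real taxa; this is a deliberate caricature that puts
life-cycle-like within-class variability into every class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ShapeFamily",
    "SpeciesParams",
    "LifeCycleStage",
    "SyntheticSample",
    "make_catalog",
    "render_valve",
    "make_dataset",
    "DEFAULT_CANVAS",
    "DEFAULT_NOISE_SIGMA",
    "DEFAULT_ILLUM_GRADIENT",
    "LENGTH_RATIO_PER_STAGE",
    "WIDTH_RATIO_PER_STAGE",
]

DEFAULT_CANVAS: tuple[int, int] = (384, 512)  # (rows, cols), 8-bit
DEFAULT_NOISE_SIGMA = 0.01        # fraction of dynamic range
DEFAULT_ILLUM_GRADIENT = 0.10     # fraction of peak-to-peak illumination ramp
LENGTH_RATIO_PER_STAGE = 0.93     # geometric apical shrink per life-cycle stage
WIDTH_RATIO_PER_STAGE = 0.985

_BG_LEVEL = 70.0
_FG_LEVEL = 180.0


class ShapeFamily(str, Enum):
    ELLIPSE = "ellipse"
    CAPITATE = "capitate"
    LANCEOLATE = "lanceolate"
    CASSINI = "cassini"


class Polarity(str, Enum):
    BRIGHT_VALVE = "bright_valve"
    DARK_VALVE = "dark_valve"


@dataclass(frozen=True)
class SpeciesParams:
    """Morphology parameters of one synthetic taxon."""

    class_id: int
    shape_family: ShapeFamily
    base_length: float  # full apical length, px
    base_width: float   # full transapical width, px
    end_bulb_ratio: float = 0.0
    striae_period: float = 8.0       # px
    striae_orientation: float = 0.0  # radians; direction of intensity variation
    striae_contrast: float = 0.25    # fraction of dynamic range
    raphe: bool = False
    polarity: Polarity = Polarity.BRIGHT_VALVE

    def __post_init__(self) -> None:
        if not self.base_length >= self.base_width > 0:
            raise ValueError("need base_length >= base_width > 0")
        if self.striae_period <= 1:
            raise ValueError("striae_period must exceed 1 px")
        if not 0.0 <= self.striae_contrast <= 1.0:
            raise ValueError("striae_contrast must lie in [0, 1]")
        if self.end_bulb_ratio < 0:
            raise ValueError("end_bulb_ratio must be >= 0")


@dataclass(frozen=True)
class LifeCycleStage:
    """One step of the asexual size-reduction series."""

    stage_index: int = 0
    length_scale: float = 1.0
    width_scale: float = 1.0
    shape_morph: float = 0.0

    def __post_init__(self) -> None:
        if self.stage_index < 0:
            raise ValueError("stage_index must be >= 0")
        if not 0.0 < self.length_scale <= 1.0 or not 0.0 < self.width_scale <= 1.0:
            raise ValueError("scales must lie in (0, 1]")
        if not 0.0 <= self.shape_morph <= 1.0:
            raise ValueError("shape_morph must lie in [0, 1]")

    @classmethod
    def from_index(cls, stage_index: int, n_stages: int = 1) -> "LifeCycleStage":
        morph = stage_index / max(n_stages - 1, 1)
        return cls(
            stage_index=stage_index,
            length_scale=LENGTH_RATIO_PER_STAGE ** stage_index,
            width_scale=WIDTH_RATIO_PER_STAGE ** stage_index,
            shape_morph=min(morph, 1.0),
        )


@dataclass(frozen=True)
class SyntheticSample:
    image: np.ndarray  # uint8 grayscale
    mask: np.ndarray   # bool, exact analytic raster
    label: int
    stage: LifeCycleStage
    seed: int


def _inside(
    family: ShapeFamily,
    x: np.ndarray,
    y: np.ndarray,
    half_len: float,
    half_wid: float,
    end_bulb_ratio: float,
    morph: float,
) -> np.ndarray:
    """Boolean inside-test of the outline at points (x, y), axis along x.

    ``morph`` in [0, 1] rounds the shape toward the senescent form by easing
    the family's exponent toward the plain ellipse value 2.
    """
    u = x / half_len
    v = y / half_wid
    if family is ShapeFamily.ELLIPSE:
        return u ** 2 + v ** 2 <= 1.0
    if family is ShapeFamily.LANCEOLATE:
        # superellipse exponent < 2 gives pointed apices
        p = 1.5 + 0.5 * morph
        return np.abs(u) ** p + np.abs(v) ** p <= 1.0
    if family is ShapeFamily.CAPITATE:
        # elliptical body plus Gaussian end bulbs on the half-width profile
        au = np.abs(u)
        base = np.sqrt(np.clip(1.0 - u ** 2, 0.0, None))
        bulb = end_bulb_ratio * np.exp(-(((au - 0.82) / 0.10) ** 2))
        profile = np.clip(base + (1.0 - 0.5 * morph) * bulb, 0.0, 1.35)
        return (au <= 1.0) & (np.abs(v) <= profile)
    if family is ShapeFamily.CASSINI:
        # Cassini oval scaled so the x/y extents match the half axes; the
        # ratio e = b/c controls the central constriction (e > 1: connected)
        r = half_wid / half_len
        e2 = (1.0 + r ** 2) / (1.0 - r ** 2) if r < 1.0 else 4.0
        e2 = e2 + 3.0 * morph  # morphing inflates toward an ellipse-like oval
        c = half_len / np.sqrt(1.0 + e2)
        b4 = (e2 * c ** 2) ** 2
        xs, ys = x, y * (np.sqrt(e2 - 1.0) * c / half_wid)
        q = (xs ** 2 + ys ** 2) ** 2 - 2.0 * c ** 2 * (xs ** 2 - ys ** 2) + c ** 4
        return q <= b4
    raise ValueError(f"unknown shape family {family}")


def make_catalog(n_classes: int, seed: int) -> list[SpeciesParams]:
    """Deterministic catalog of pairwise-distinct synthetic taxa.

    Classes cycle through the four outline families and stride through
    disjoint size slots, striae periods and orientations, so any two classes
    differ in at least two morphology parameters.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    families = list(ShapeFamily)
    catalog: list[SpeciesParams] = []
    for i in range(n_classes):
        family = families[i % len(families)]
        base_length = 150.0 + 22.0 * i + rng.uniform(-3.0, 3.0)
        aspect = 3.2 + 0.35 * (i % 5) + rng.uniform(-0.05, 0.05)
        base_width = base_length / aspect
        catalog.append(
            SpeciesParams(
                class_id=i,
                shape_family=family,
                base_length=float(base_length),
                base_width=float(base_width),
                end_bulb_ratio=0.35 if family is ShapeFamily.CAPITATE else 0.0,
                striae_period=float(5.0 + (i % 6) * 1.5),
                striae_orientation=float((i % 4) * 0.12),
                striae_contrast=float(0.18 + 0.03 * (i % 4)),
                raphe=bool(i % 2),
                polarity=Polarity.BRIGHT_VALVE,
            )
        )
    return catalog


def render_valve(
    params: SpeciesParams,
    stage: LifeCycleStage = LifeCycleStage(),
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    illum_gradient: float = DEFAULT_ILLUM_GRADIENT,
    seed: int = 0,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> SyntheticSample:
    """Render one valve image plus its exact ground-truth mask.

    The valve sits at the canvas centre, apical axis horizontal.  Striae are
    a cosine grating clipped to the valve interior; illumination is a linear
    horizontal ramp; noise is additive Gaussian with standard deviation
    ``noise_sigma`` times the 8-bit dynamic range.
    """
    rows, cols = canvas
    half_len = 0.5 * params.base_length * stage.length_scale
    half_wid = 0.5 * params.base_width * stage.width_scale
    margin = 12.0
    if 2 * half_len > cols - 2 * margin or 2 * half_wid > rows - 2 * margin:
        raise ValueError("shape exceeds canvas (need a margin of 12 px)")
    fg_bg_gap = abs(_FG_LEVEL - _BG_LEVEL)
    if fg_bg_gap < 3.0 * noise_sigma * 255.0:
        raise ValueError("noise_sigma too large for the fixed valve/background contrast")

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    x = xx - (cols - 1) / 2.0
    y = yy - (rows - 1) / 2.0
    mask = _inside(
        params.shape_family, x, y, half_len, half_wid,
        params.end_bulb_ratio, stage.shape_morph,
    )

    if params.polarity is Polarity.BRIGHT_VALVE:
        fg, bg = _FG_LEVEL, _BG_LEVEL
    else:
        fg, bg = _BG_LEVEL, _FG_LEVEL
    img = np.full((rows, cols), bg, dtype=np.float64)
    img[mask] = fg

    # striae: cosine grating along the stated direction of variation
    u = x * np.cos(params.striae_orientation) + y * np.sin(params.striae_orientation)
    grating = 0.5 * 255.0 * params.striae_contrast * np.cos(2.0 * np.pi * u / params.striae_period)
    img[mask] += grating[mask]

    if params.raphe:
        raphe_band = mask & (np.abs(y) < 1.5) & (np.abs(x) < 0.9 * half_len)
        img[raphe_band] -= 0.20 * fg_bg_gap

    if illum_gradient:
        img *= 1.0 + illum_gradient * (xx / (cols - 1) - 0.5)

    if noise_sigma:
        img += rng.normal(0.0, noise_sigma * 255.0, size=img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticSample(image=image, mask=mask, label=params.class_id,
                           stage=stage, seed=seed)


def make_dataset(
    catalog: list[SpeciesParams],
    n_per_class: int,
    n_stages: int = 5,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int = 0,
    illum_gradient: float = DEFAULT_ILLUM_GRADIENT,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> list[SyntheticSample]:
    """Labeled dataset spanning the life-cycle stages of every catalog class.

    Per class, samples are assigned round-robin to stages 0..n_stages-1 with
    a small per-sample size jitter; total count is len(catalog) * n_per_class
    and the whole dataset is a pure function of its arguments.
    """
    if n_per_class < 1 or n_stages < 1:
        raise ValueError("n_per_class and n_stages must be >= 1")
    samples: list[SyntheticSample] = []
    for params in catalog:
        child = np.random.SeedSequence(entropy=seed, spawn_key=(params.class_id,))
        jitter_rng = np.random.default_rng(child)
        for j in range(n_per_class):
            stage_index = j % n_stages
            base = LifeCycleStage.from_index(stage_index, n_stages)
            jl = float(np.clip(base.length_scale * jitter_rng.uniform(0.98, 1.02), 1e-3, 1.0))
            jw = float(np.clip(base.width_scale * jitter_rng.uniform(0.99, 1.01), 1e-3, 1.0))
            stage = LifeCycleStage(
                stage_index=stage_index,
                length_scale=jl,
                width_scale=jw,
                shape_morph=base.shape_morph,
            )
            sample_seed = int(jitter_rng.integers(0, 2 ** 31 - 1))
            samples.append(
                render_valve(
                    params, stage,
                    noise_sigma=noise_sigma,
                    illum_gradient=illum_gradient,
                    seed=sample_seed,
                    canvas=canvas,
                )
            )
    return samples
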