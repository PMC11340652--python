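"""Synthetic organ silhouettes and cohorts with analytic ground truth.

Shapes come from a star-shaped polar curve family around the origin with
the apex at the top (θ = π/2):

    ρ(θ) = ρ_se(θ) · (1 − taper·sinθ) + bump(θ) + noise(θ)

where ρ_se is a per-half superellipse radius (exponent 2 on the base
half, 2/apex_sharpness on the apex half, so sharpness > 1 gives a
pointier apex), taper > 0 moves the widest section toward the base
(ovoid/egg shapes), ``bump`` is a Gaussian angular bump at the apex
(fruit nipple, endocarp mucro) and ``noise`` is band-limited boundary
roughness (Fourier orders 6–12).  Because ρ > 0 everywhere the curve is
always a simple polygon, and area/height/width/bump-area ground truth
follows from dense quadrature on the curve itself.

Cohorts draw per-sample parameters from lognormal perturbations around
per-cultivar means, apply a multiplicative year effect in the second
season, and couple endocarp size to fruit size of the same sample — the
features real olive cohorts show (size-coupled organs, between-season
size shifts, within-cultivar spread).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from . import geometry
from .features import FeatureTable, OrganSample, build_feature_table
from .imaging import Silhouette

DENSE_THETA = 2048
DEFAULT_MM_PER_PX = 0.05

#: noise-amplitude ceiling (fraction of width); beyond this the curve
#: family is no longer guaranteed star-shaped in practice
MAX_NOISE_AMP = 0.05


class ShapeGenerationError(ValueError):
    """The requested parameters produced a degenerate boundary curve."""


@dataclass
class ShapeParams:
    """Parameters of one synthetic organ silhouette."""

    organ: str
    height_mm: float
    width_A_mm: float
    width_B_mm: float = 0.0
    taper: float = 0.0
    apex_sharpness: float = 1.0
    nipple_amplitude: float = 0.0
    #: angular sigma of the apex bump (radians); narrow by default — olive
    #: nipples and mucros are short, pointed protuberances
    nipple_width: float = 0.12
    mucro_amplitude: float = 0.0
    petiole_length_mm: float = 0.0
    petiole_width_mm: float = 0.0
    noise_amp: float = 0.0
    seed: int = 0

    def validate(self) -> "ShapeParams":
        if self.height_mm <= 0 or self.width_A_mm <= 0:
            raise ValueError("lengths must be positive")
        if self.organ in ("fruit", "endocarp") and self.width_B_mm <= 0:
            raise ValueError("fruit/endocarp need width_B_mm > 0")
        if not -0.5 <= self.taper <= 0.5:
            raise ValueError("taper must lie in [-0.5, 0.5]")
        if self.apex_sharpness < 1.0:
            raise ValueError("apex_sharpness must be >= 1")
        if not 0.0 <= self.noise_amp < MAX_NOISE_AMP:
            raise ValueError(f"noise_amp must lie in [0, {MAX_NOISE_AMP})")
        return self


@dataclass
class CultivarSpec:
    """Per-cultivar parameter means plus within-cultivar variation."""

    name: str
    fruit: ShapeParams
    leaf: ShapeParams
    endocarp: ShapeParams
    #: relative standard deviation of the lognormal size perturbations
    rel_sd: float = 0.05
    #: multiplicative size shift applied in the second sampling year
    year_effect: float = 1.0

    def validate(self) -> "CultivarSpec":
        if self.rel_sd < 0:
            raise ValueError("rel_sd must be >= 0")
        if self.year_effect <= 0:
            raise ValueError("year_effect must be positive")
        for p in (self.fruit, self.leaf, self.endocarp):
            p.validate()
        return self


def _wrapped_angle(theta: np.ndarray, center: float) -> np.ndarray:
    d = theta - center
    return (d + np.pi) % (2 * np.pi) - np.pi


def outline_radius(
    p: ShapeParams, width_mm: float, rng: np.random.Generator, theta: np.ndarray
) -> np.ndarray:
    """Polar radius ρ(θ) of the boundary curve for one viewing position."""
    a = p.height_mm / 2.0  # vertical semi-axis
    b = width_mm / 2.0  # horizontal semi-axis
    n_exp = np.where(np.sin(theta) > 0, 2.0 / p.apex_sharpness, 2.0)
    rho = (np.abs(np.cos(theta) / b) ** n_exp + np.abs(np.sin(theta) / a) ** n_exp) ** (
        -1.0 / n_exp
    )
    rho = rho * (1.0 - p.taper * np.sin(theta))
    amp = p.nipple_amplitude if p.organ == "fruit" else p.mucro_amplitude
    if amp > 0:
        d = _wrapped_angle(theta, np.pi / 2)
        rho = rho + amp * p.height_mm * np.exp(-0.5 * (d / p.nipple_width) ** 2)
    if p.noise_amp > 0:
        orders = np.arange(6, 13)
        coef = rng.standard_normal((2, len(orders)))
        raw = coef[0] @ np.cos(np.outer(orders, theta)) + coef[1] @ np.sin(
            np.outer(orders, theta)
        )
        rho = rho + p.noise_amp * width_mm * raw / np.max(np.abs(raw))
    if np.any(rho <= 0):
        raise ShapeGenerationError("boundary radius became non-positive (excess noise)")
    return rho


def _curve_truth(points: np.ndarray, theta: np.ndarray, rho: np.ndarray) -> dict:
    """Ground truth from the continuous curve: quadrature area, caliper
    dimensions and widest-section height measured on the dense polygon."""
    area = 0.5 * float(np.trapezoid(rho**2, theta))
    y = points[:, 1]
    height = float(y.max() - y.min())
    poly = Polygon(points)
    x_lo, x_hi = points[:, 0].min() - 1.0, points[:, 0].max() + 1.0
    hs = np.linspace(0.002, 0.998, 513)
    widths = np.array(
        [
            poly.intersection(
                LineString([(x_lo, y.min() + h * height), (x_hi, y.min() + h * height)])
            ).length
            for h in hs
        ]
    )
    width = float(widths.max())
    return {
        "area_mm2": area,
        "height_mm": height,
        "width_mm": width,
        "shape_index": height / width,
        "widest_height_norm": float(hs[int(np.argmax(widths))]),
    }


def _bump_area(p: ShapeParams, width_mm: float, theta: np.ndarray) -> float:
    amp = p.nipple_amplitude if p.organ == "fruit" else p.mucro_amplitude
    if amp <= 0:
        return 0.0
    q = replace(p, nipple_amplitude=0.0, mucro_amplitude=0.0, noise_amp=0.0)
    rng = np.random.default_rng(0)
    rho0 = outline_radius(q, width_mm, rng, theta)
    d = _wrapped_angle(theta, np.pi / 2)
    bump = amp * p.height_mm * np.exp(-0.5 * (d / p.nipple_width) ** 2)
    return 0.5 * float(np.trapezoid((rho0 + bump) ** 2 - rho0**2, theta))


def _scanline_fill(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd scanline rasterization of a closed polygon.

    A pixel is foreground iff its center (integer row/col) lies inside
    the polygon — unbiased, and consistent with the 0.5 iso-level that
    boundary tracing uses later.
    """
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = rows, cols
    r1, c1 = np.roll(rows, -1), np.roll(cols, -1)
    scan = np.arange(shape[0], dtype=float)[:, None]
    crosses = (r0[None, :] <= scan) != (r1[None, :] <= scan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (scan - r0[None, :]) / (r1 - r0)[None, :]
        xs = c0[None, :] + t * (c1 - c0)[None, :]
    for r in range(shape[0]):
        x = np.sort(xs[r, crosses[r]])
        for a, b in zip(x[0::2], x[1::2]):
            mask[r, int(np.ceil(a)) : int(np.ceil(b))] = True
    return mask


def _rasterize(
    polys: list[np.ndarray], mm_per_px: float, margin_px: int = 3
) -> tuple[np.ndarray, float, float]:
    """Rasterize mm-frame polygons onto a shared boolean canvas."""
    allpts = np.vstack(polys)
    x_min, y_min = allpts.min(axis=0) - margin_px * mm_per_px
    x_max, y_max = allpts.max(axis=0) + margin_px * mm_per_px
    w = int(np.ceil((x_max - x_min) / mm_per_px)) + 1
    h = int(np.ceil((y_max - y_min) / mm_per_px)) + 1
    mask = np.zeros((h, w), dtype=bool)
    for pts in polys:
        rows = (y_max - pts[:, 1]) / mm_per_px
        cols = (pts[:, 0] - x_min) / mm_per_px
        mask |= _scanline_fill(rows, cols, mask.shape)
    return mask, x_min, y_max


def curve_points(
    p: ShapeParams, width_mm: float, rng: np.random.Generator, n_theta: int = DENSE_THETA
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    rho = outline_radius(p, width_mm, rng, theta)
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta)])
    return theta, rho, pts


def generate_shape(
    p: ShapeParams,
    mm_per_px: float = DEFAULT_MM_PER_PX,
    position: str = "A",
    rng: np.random.Generator | None = None,
) -> tuple[Silhouette, dict]:
    """Render one fruit/endocarp silhouette and return its ground truth."""
    p.validate()
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    width = p.width_A_mm if position in ("A", "none") else p.width_B_mm
    theta, rho, pts = curve_points(p, width, rng)
    truth = _curve_truth(pts, theta, rho)
    truth["bump_area_mm2"] = _bump_area(p, width, theta)
    truth["position"] = position
    mask, _, _ = _rasterize([pts], mm_per_px)
    sil = Silhouette(
        mask=mask,
        mm_per_px=mm_per_px,
        organ=p.organ,
        position=position if p.organ in ("fruit", "endocarp") else "none",
    )
    return sil, truth


def generate_leaf(
    p: ShapeParams,
    mm_per_px: float = DEFAULT_MM_PER_PX,
    rng: np.random.Generator | None = None,
) -> tuple[Silhouette, dict]:
    """Render a leaf: blade from the curve family plus a petiole rectangle."""
    p.validate()
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    theta, rho, blade = curve_points(p, p.width_A_mm, rng)
    truth = _curve_truth(blade, theta, rho)
    truth["petiole_length_mm"] = p.petiole_length_mm
    truth["petiole_width_mm"] = p.petiole_width_mm
    polys = [blade]
    if p.petiole_length_mm > 0:
        y_base = blade[:, 1].min()
        overlap = 2.0 * mm_per_px
        hw = p.petiole_width_mm / 2.0
        rect = np.array(
            [
                [-hw, y_base + overlap],
                [hw, y_base + overlap],
                [hw, y_base - p.petiole_length_mm],
                [-hw, y_base - p.petiole_length_mm],
            ]
        )
        polys.append(rect)
    mask, _, _ = _rasterize(polys, mm_per_px)
    return Silhouette(mask=mask, mm_per_px=mm_per_px, organ="leaf"), truth


@dataclass
class Cohort:
    """Feature tables for the three organs plus the ground-truth log."""

    fruit: FeatureTable
    leaf: FeatureTable
    endocarp: FeatureTable
    truth: pd.DataFrame


def _perturb(
    p: ShapeParams, rel_sd: float, size_factor: float, rng: np.random.Generator, seed: int
) -> ShapeParams:
    """Draw one sample's parameters around the cultivar means.

    Lengths get lognormal noise times the shared size factor; taper gets
    additive noise; sharpness stays >= 1.
    """

    def ln(mean: float) -> float:
        return mean * np.exp(rel_sd * rng.standard_normal()) if mean > 0 else 0.0

    return replace(
        p,
        height_mm=ln(p.height_mm) * size_factor,
        width_A_mm=ln(p.width_A_mm) * size_factor,
        width_B_mm=ln(p.width_B_mm) * size_factor,
        petiole_length_mm=ln(p.petiole_length_mm),
        petiole_width_mm=ln(p.petiole_width_mm),
        taper=float(np.clip(p.taper + 0.3 * rel_sd * rng.standard_normal(), -0.5, 0.5)),
        apex_sharpness=max(1.0, ln(p.apex_sharpness)),
        nipple_amplitude=ln(p.nipple_amplitude),
        mucro_amplitude=ln(p.mucro_amplitude),
        seed=seed,
    )


def _fast_contour(p: ShapeParams, width: float, rng: np.random.Generator, mm_per_px: float):
    _, _, pts = curve_points(p, width, rng, n_theta=1024)
    return geometry.normalize_points(pts, mm_per_px, apex_hint=np.array([0.0, 1.0]))


def generate_cohort(
    specs: Iterable[CultivarSpec],
    n_per_organ: int = 30,
    years: tuple[int, ...] = (1, 2),
    seed: int = 0,
    mode: str = "fast",
    mm_per_px: float = DEFAULT_MM_PER_PX,
    extended_endocarp: bool = False,
) -> Cohort:
    """Generate a labeled multi-organ cohort with known ground truth.

    ``n_per_organ`` samples per cultivar and year for each organ.  In
    ``fast`` mode descriptors are computed directly on the analytic
    boundary polygons; ``image`` mode renders binary masks and runs the
    full segmentation-free imaging path (slower, used for cross-mode
    consistency checks).  Fruit and endocarp of the same sample share a
    latent size factor, emulating the coupling of fruit and stone size.
    """
    specs = [s.validate() for s in specs]
    if len(specs) < 2:
        raise ValueError("need at least two cultivar specs")
    if mode not in ("fast", "image"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    fruit_samples: list[OrganSample] = []
    leaf_samples: list[OrganSample] = []
    endocarp_samples: list[OrganSample] = []
    truth_rows: list[dict] = []

    for spec in specs:
        for year in years:
            year_factor = spec.year_effect if year == max(years) and len(years) > 1 else 1.0
            for i in range(n_per_organ):
                sid = f"{spec.name}_y{year}_{i:03d}"
                sub_seed = int(rng.integers(0, 2**31 - 1))
                # shared latent size factor couples fruit and endocarp
                size = float(np.exp(spec.rel_sd * rng.standard_normal())) * year_factor
                fruit_p = _perturb(spec.fruit, spec.rel_sd, size, rng, sub_seed)
                endo_size = size * float(np.exp(0.02 * rng.standard_normal()))
                endo_p = _perturb(spec.endocarp, spec.rel_sd, endo_size, rng, sub_seed)
                leaf_p = _perturb(spec.leaf, spec.rel_sd, year_factor, rng, sub_seed)

                for organ, p, bucket in (
                    ("fruit", fruit_p, fruit_samples),
                    ("endocarp", endo_p, endocarp_samples),
                ):
                    sample = OrganSample(sid, spec.name, year, organ)
                    for pos in ("A", "B"):
                        width = p.width_A_mm if pos == "A" else p.width_B_mm
                        if mode == "fast":
                            sample.contours[pos] = _fast_contour(p, width, rng, mm_per_px)
                        else:
                            sil, _ = generate_shape(p, mm_per_px, position=pos, rng=rng)
                            sample.silhouettes[pos] = sil
                    bucket.append(sample)

                leaf_sample = OrganSample(sid, spec.name, year, "leaf")
                if mode == "fast":
                    leaf_sample.contours["leaf"] = _fast_contour(
                        leaf_p, leaf_p.width_A_mm, rng, mm_per_px
                    )
                    leaf_sample.petiole = (
                        leaf_p.petiole_length_mm,
                        leaf_p.petiole_width_mm,
                        leaf_p.petiole_width_mm,
                    )
                else:
                    sil, _ = generate_leaf(leaf_p, mm_per_px, rng=rng)
                    leaf_sample.silhouettes["leaf"] = sil
                leaf_samples.append(leaf_sample)

                truth_rows.append(
                    {
                        "sample_id": sid,
                        "cultivar": spec.name,
                        "year": year,
                        "fruit_height_mm": fruit_p.height_mm,
                        "fruit_width_A_mm": fruit_p.width_A_mm,
                        "endocarp_height_mm": endo_p.height_mm,
                        "leaf_length_mm": leaf_p.height_mm,
                        "leaf_width_mm": leaf_p.width_A_mm,
                        "petiole_length_mm": leaf_p.petiole_length_mm,
                        "size_factor": size,
                    }
                )

    return Cohort(
        fruit=build_feature_table(fruit_samples),
        leaf=build_feature_table(leaf_samples),
        endocarp=build_feature_table(endocarp_samples, extended_endocarp=extended_endocarp),
        truth=pd.DataFrame(truth_rows),
    )


def _base_params(organ: str, **kw) -> ShapeParams:
    defaults = {
        "fruit": dict(height_mm=20.0, width_A_mm=15.0, width_B_mm=14.5, taper=0.08,
                      apex_sharpness=1.3),
        "endocarp": dict(height_mm=13.0, width_A_mm=7.0, width_B_mm=6.6, taper=0.10,
                         apex_sharpness=1.4),
        "leaf": dict(height_mm=55.0, width_A_mm=12.0, width_B_mm=0.0, taper=0.12,
                     apex_sharpness=1.6, petiole_length_mm=7.0, petiole_width_mm=1.2),
    }
    d = dict(defaults[organ])
    d.update(kw)
    return ShapeParams(organ=organ, **d)


def preset_cohorts() -> dict[str, list[CultivarSpec]]:
    """Named frozen cultivar-spec sets for tests and demonstrations.

    - ``separable3``: three cultivars with widely separated means and
      tiny within-cultivar spread — trivially classifiable.
    - ``overlap14``: fourteen cultivars spanning realistic olive trait
      ranges with overlapping means and realistic spread.
    - ``kalamon_leaf``: one cultivar distinguishable only by its wide
      leaf blade (its fruit/endocarp means coincide with a sibling's).
    - ``complementary``: organ-complementary signal — fruit separates
      {c1,c2} from c3, endocarp separates c1 from c2, leaves carry none.
    """
    presets: dict[str, list[CultivarSpec]] = {}

    presets["separable3"] = [
        CultivarSpec(
            "alpha",
            fruit=_base_params("fruit", height_mm=20, width_A_mm=16, width_B_mm=15.5),
            leaf=_base_params("leaf", height_mm=55, width_A_mm=12),
            endocarp=_base_params("endocarp", height_mm=13, width_A_mm=7, width_B_mm=6.6),
            rel_sd=0.02,
        ),
        CultivarSpec(
            "beta",
            fruit=_base_params(
                "fruit", height_mm=27, width_A_mm=13, width_B_mm=12.6,
                apex_sharpness=1.8, nipple_amplitude=0.05,
            ),
            leaf=_base_params("leaf", height_mm=68, width_A_mm=9.5),
            endocarp=_base_params(
                "endocarp", height_mm=16.5, width_A_mm=6.2, width_B_mm=5.9,
                mucro_amplitude=0.04,
            ),
            rel_sd=0.02,
        ),
        CultivarSpec(
            "gamma",
            fruit=_base_params(
                "fruit", height_mm=15.5, width_A_mm=14.5, width_B_mm=14.2, taper=0.02,
                apex_sharpness=1.05,
            ),
            leaf=_base_params("leaf", height_mm=42, width_A_mm=16, taper=0.05),
            endocarp=_base_params(
                "endocarp", height_mm=10.5, width_A_mm=8.2, width_B_mm=7.9, taper=0.04,
            ),
            rel_sd=0.02,
        ),
    ]

    # fourteen cultivars spanning realistic trait ranges; deterministic
    # construction from a fixed internal seed keeps the preset frozen
    gen = np.random.default_rng(20160801)
    specs = []
    for k in range(14):
        elong = 1.1 + 0.9 * k / 13 + 0.08 * gen.standard_normal()
        f_h = float(gen.uniform(15, 26))
        f_w = f_h / elong
        e_h = 0.62 * f_h * float(gen.uniform(0.92, 1.08))
        e_w = e_h / float(gen.uniform(1.6, 2.2))
        # leaf blades overlap heavily across cultivars: in real cohorts the
        # leaf is the least discriminative organ
        l_h = float(gen.uniform(50, 58))
        l_w = l_h / float(gen.uniform(4.0, 4.8))
        specs.append(
            CultivarSpec(
                f"cv{k:02d}",
                fruit=_base_params(
                    "fruit", height_mm=f_h, width_A_mm=f_w, width_B_mm=0.96 * f_w,
                    taper=float(gen.uniform(0.0, 0.15)),
                    apex_sharpness=float(gen.uniform(1.05, 1.8)),
                    nipple_amplitude=float(gen.choice([0.0, 0.04], p=[0.6, 0.4])),
                ),
                leaf=_base_params(
                    "leaf", height_mm=l_h, width_A_mm=l_w,
                    taper=float(gen.uniform(0.08, 0.16)),
                    petiole_length_mm=float(gen.uniform(6, 8)),
                    petiole_width_mm=float(gen.uniform(1.0, 1.3)),
                ),
                endocarp=_base_params(
                    "endocarp", height_mm=e_h, width_A_mm=e_w, width_B_mm=0.95 * e_w,
                    taper=float(gen.uniform(0.02, 0.15)),
                    apex_sharpness=float(gen.uniform(1.1, 1.7)),
                    mucro_amplitude=float(gen.choice([0.0, 0.035], p=[0.5, 0.5])),
                ),
                rel_sd=0.07,
                year_effect=float(gen.uniform(0.94, 1.08)),
            )
        )
    presets["overlap14"] = specs

    shared_fruit = dict(height_mm=20, width_A_mm=15, width_B_mm=14.5)
    shared_endo = dict(height_mm=13, width_A_mm=7, width_B_mm=6.7)
    presets["kalamon_leaf"] = [
        CultivarSpec(
            "kalamon_like",
            fruit=_base_params("fruit", **shared_fruit),
            leaf=_base_params("leaf", height_mm=60, width_A_mm=24, taper=0.06),
            endocarp=_base_params("endocarp", **shared_endo),
            rel_sd=0.04,
        ),
        CultivarSpec(
            "sibling",
            fruit=_base_params("fruit", **shared_fruit),
            leaf=_base_params("leaf", height_mm=52, width_A_mm=11),
            endocarp=_base_params("endocarp", **shared_endo),
            rel_sd=0.04,
        ),
        CultivarSpec(
            "other",
            fruit=_base_params("fruit", height_mm=25, width_A_mm=13, width_B_mm=12.5),
            leaf=_base_params("leaf", height_mm=52, width_A_mm=11),
            endocarp=_base_params("endocarp", height_mm=16, width_A_mm=6.3, width_B_mm=6.0),
            rel_sd=0.04,
        ),
    ]

    shared_leaf = dict(height_mm=55, width_A_mm=12)
    presets["complementary"] = [
        CultivarSpec(
            "c1",
            fruit=_base_params("fruit", height_mm=20, width_A_mm=15, width_B_mm=14.5),
            leaf=_base_params("leaf", **shared_leaf),
            endocarp=_base_params("endocarp", height_mm=13, width_A_mm=7, width_B_mm=6.7),
            rel_sd=0.04,
        ),
        CultivarSpec(
            "c2",
            fruit=_base_params("fruit", height_mm=20, width_A_mm=15, width_B_mm=14.5),
            leaf=_base_params("leaf", **shared_leaf),
            endocarp=_base_params("endocarp", height_mm=17, width_A_mm=6.2, width_B_mm=5.9),
            rel_sd=0.04,
        ),
        CultivarSpec(
            "c3",
            fruit=_base_params("fruit", height_mm=26, width_A_mm=12.5, width_B_mm=12.0),
            leaf=_base_params("leaf", **shared_leaf),
            endocarp=_base_params("endocarp", height_mm=13, width_A_mm=7, width_B_mm=6.7),
            rel_sd=0.04,
        ),
    ]
    return presets


def get_preset(name: str) -> list[CultivarSpec]:
    presets = preset_cohorts()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
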