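"""Organ-specific morphological descriptor catalogs.

Per sample the catalogs hold 24 values for fruits (12 per viewing
position A/B), 16 for leaves and 22 for endocarps (11 per position,
optionally +3 cross-position extras).  Descriptors the source field uses
by name — shape index, circularity, fitted-ellipse axes, apex curvature,
nipple index/size, mucro signal, petiole thickness, vertical and
transversal symmetry — are computed from the geometry primitives; the
remaining slots are standard contour descriptors (perimeter, convexity,
ellipse major axis), flagged ``reconstructed`` in the docs.

Binary descriptors are stored as 0/1 floats so the whole table is one
numeric matrix.  Curvature-based descriptors are nondimensionalized
(κ × organ length) so they are scale-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .imaging import Silhouette
from .geometry import (
    Contour,
    caliper_dimensions,
    contour_from_silhouette,
    curvature_profile,
    fit_ellipse,
    landmark_window,
    polygon_area,
    polygon_perimeter,
)

logger = logging.getLogger(__name__)

META_COLS = ["sample_id", "cultivar", "year", "organ"]

#: outward deviation from the ellipse arc must exceed this fraction of the
#: organ height for a nipple to be scored present
NIPPLE_DEVIATION_FLOOR = 0.02
#: apex-curve area above this fraction of the endocarp area scores a mucro
MUCRO_AREA_FLOOR = 0.01
#: width-profile threshold (fraction of max width) defining the petiole run
PETIOLE_WIDTH_FRAC = 0.20
#: minimum petiole run length as a fraction of total leaf length
PETIOLE_MIN_LENGTH_FRAC = 0.05

_PER_POSITION_FRUIT = [
    "area",
    "perimeter",
    "height",
    "width",
    "shape_index",
    "circularity",
    "ellipse_semi_major",
    "ellipse_semi_minor",
    "apex_pointedness",
    "nipple_index",
    "nipple_size",
    "transversal_asymmetry",
]

_PER_POSITION_ENDOCARP = [
    "area",
    "perimeter",
    "height",
    "width",
    "shape_index",
    "circularity",
    "ellipse_semi_minor",
    "apex_curve_area",
    "base_length",
    "transversal_position",
    "min_dist_transversal_to_contour",
]

FRUIT_FEATURE_NAMES = [f"{n}_{p}" for p in ("A", "B") for n in _PER_POSITION_FRUIT]
ENDOCARP_FEATURE_NAMES = [f"{n}_{p}" for p in ("A", "B") for n in _PER_POSITION_ENDOCARP]
ENDOCARP_EXTENDED_NAMES = ENDOCARP_FEATURE_NAMES + [
    "mucro_index",
    "mean_circularity",
    "width_ratio_AB",
]
LEAF_FEATURE_NAMES = [
    "blade_area",
    "blade_perimeter",
    "blade_length",
    "blade_width",
    "shape_index",
    "circularity",
    "ellipse_semi_major",
    "ellipse_semi_minor",
    "apex_pointedness",
    "base_pointedness",
    "vertical_symmetry",
    "transversal_asymmetry",
    "convexity",
    "petiole_length",
    "petiole_thickness_upper",
    "petiole_thickness_lower",
]


def feature_names_for(organ: str, extended: bool = False) -> list[str]:
    if organ == "fruit":
        return list(FRUIT_FEATURE_NAMES)
    if organ == "leaf":
        return list(LEAF_FEATURE_NAMES)
    if organ == "endocarp":
        return list(ENDOCARP_EXTENDED_NAMES if extended else ENDOCARP_FEATURE_NAMES)
    raise ValueError(f"unknown organ {organ!r}")


@dataclass
class FeatureVector:
    organ: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


class _ContourSummary:
    """Primitive measurements of one contour, computed once and shared."""

    def __init__(self, c: Contour):
        from shapely import affinity

        self.contour = c
        self.area = polygon_area(c)
        self.perimeter = polygon_perimeter(c)
        self.height, self.width, self.h_grid, self.width_profile = caliper_dimensions(c)
        self.ellipse = fit_ellipse(c)
        self.kappa = curvature_profile(c).kappa
        poly = c.polygon()
        mirrored = affinity.scale(poly, xfact=-1.0, yfact=1.0, origin=(0.0, 0.0))
        self.transversal_asymmetry = max(
            1.0 - poly.intersection(mirrored).area / poly.area, 0.0
        )
        self.vertical_symmetry = float(self.h_grid[int(np.argmax(self.width_profile))])

    @property
    def shape_index(self) -> float:
        return self.height / self.width

    @property
    def circularity(self) -> float:
        return 4.0 * np.pi * self.area / self.perimeter**2

    def window_mean_abs_kappa(self, index: int) -> float:
        return float(np.mean(np.abs(self.kappa[landmark_window(self.contour.n_points, index)])))

    def max_width_chord_midpoint(self) -> np.ndarray:
        """Midpoint of the maximum-width horizontal chord."""
        i = int(np.argmax(self.width_profile))
        y = self.contour.points[:, 1]
        yy = float(y.min()) + self.h_grid[i] * self.height
        from shapely.geometry import LineString

        x_lo = self.contour.points[:, 0].min() - 1.0
        x_hi = self.contour.points[:, 0].max() + 1.0
        cut = self.contour.polygon().intersection(LineString([(x_lo, yy), (x_hi, yy)]))
        if cut.geom_type == "MultiLineString":
            cut = max(cut.geoms, key=lambda g: g.length)
        mid = cut.interpolate(0.5, normalized=True)
        return np.array([mid.x, mid.y])


def _arc_length_step(c: Contour) -> float:
    return polygon_perimeter(c) / c.n_points


def _apex_deviation(summary: _ContourSummary) -> tuple[np.ndarray, np.ndarray]:
    """Window indices around the apex and the signed radial deviation of
    the contour from the body-ellipse arc over them.

    The baseline ellipse is fitted to the contour *outside* the apex
    window so that an apex protrusion (nipple, mucro) cannot drag its
    own baseline outward.
    """
    from .geometry import Contour, fit_ellipse

    c = summary.contour
    win = landmark_window(c.n_points, c.apex_index)
    body_idx = np.setdiff1d(np.arange(c.n_points), win)
    body = Contour(points=c.points[body_idx], mm_per_px=c.mm_per_px)
    try:
        ellipse = fit_ellipse(body)
    except ValueError:
        ellipse = summary.ellipse
    dev = ellipse.radial_deviation(c.points[win])
    return win, dev


def detect_nipple(c: Contour, summary: _ContourSummary | None = None) -> tuple[int, float]:
    """Detect a protruding fruit-apex nipple and measure its size.

    The baseline is the arc of the ellipse fitted to the whole contour.
    A nipple is scored present when, inside the apex landmark window,
    the maximum outward deviation from that arc exceeds 2% of the fruit
    height and the deviation region carries a local curvature maximum at
    least twice the window median.  The size is the area (mm²) between
    contour and arc over the deviation region.
    """
    summary = summary or _ContourSummary(c)
    win, dev = _apex_deviation(summary)
    floor = NIPPLE_DEVIATION_FLOOR * summary.height
    peak = int(np.argmax(dev))
    if dev[peak] <= floor:
        return 0, 0.0
    # contiguous outward-deviation run containing the peak
    lo = peak
    while lo > 0 and dev[lo - 1] > 0:
        lo -= 1
    hi = peak
    while hi < len(dev) - 1 and dev[hi + 1] > 0:
        hi += 1
    region = win[lo : hi + 1]
    kappa_win = np.abs(summary.kappa[win])
    if np.max(np.abs(summary.kappa[region])) < 2.0 * np.median(kappa_win):
        return 0, 0.0
    size = float(np.sum(np.clip(dev[lo : hi + 1], 0.0, None)) * _arc_length_step(c))
    return 1, size


def _apex_curve_area(summary: _ContourSummary) -> float:
    """Area between contour and ellipse arc over the apex window (mucro)."""
    win, dev = _apex_deviation(summary)
    return float(np.sum(np.clip(dev, 0.0, None)) * _arc_length_step(summary.contour))


def _base_length(summary: _ContourSummary) -> float:
    """Chord length of the flat base region (|κ| < 0.5 × contour median)."""
    c = summary.contour
    win = landmark_window(c.n_points, c.base_index)
    flat = np.abs(summary.kappa[win]) < 0.5 * np.median(np.abs(summary.kappa))
    if not flat.any():
        return 0.0
    # maximal contiguous flat run inside the base window
    best_lo = best_hi = None
    lo = None
    for i, f in enumerate(np.append(flat, False)):
        if f and lo is None:
            lo = i
        elif not f and lo is not None:
            if best_lo is None or i - lo > best_hi - best_lo:
                best_lo, best_hi = lo, i
            lo = None
    run = win[best_lo:best_hi]
    p0, p1 = c.points[run[0]], c.points[run[-1]]
    return float(np.hypot(*(p1 - p0)))


def _fruit_position(summary: _ContourSummary) -> dict[str, float]:
    nip_idx, nip_size = detect_nipple(summary.contour, summary)
    return {
        "area": summary.area,
        "perimeter": summary.perimeter,
        "height": summary.height,
        "width": summary.width,
        "shape_index": summary.shape_index,
        "circularity": summary.circularity,
        "ellipse_semi_major": summary.ellipse.semi_major,
        "ellipse_semi_minor": summary.ellipse.semi_minor,
        "apex_pointedness": summary.window_mean_abs_kappa(summary.contour.apex_index)
        * summary.height,
        "nipple_index": float(nip_idx),
        "nipple_size": nip_size,
        "transversal_asymmetry": summary.transversal_asymmetry,
    }


def _endocarp_position(summary: _ContourSummary) -> dict[str, float]:
    mid = summary.max_width_chord_midpoint()
    dists = np.hypot(*(summary.contour.points - mid).T)
    return {
        "area": summary.area,
        "perimeter": summary.perimeter,
        "height": summary.height,
        "width": summary.width,
        "shape_index": summary.shape_index,
        "circularity": summary.circularity,
        "ellipse_semi_minor": summary.ellipse.semi_minor,
        "apex_curve_area": _apex_curve_area(summary),
        "base_length": _base_length(summary),
        "transversal_position": summary.vertical_symmetry,
        "min_dist_transversal_to_contour": float(dists.min()),
    }


def fruit_features(contour_A: Contour, contour_B: Contour) -> FeatureVector:
    """24 fruit descriptors: 12 per viewing position (A then B)."""
    values: list[float] = []
    for c in (contour_A, contour_B):
        d = _fruit_position(_ContourSummary(c))
        values.extend(d[n] for n in _PER_POSITION_FRUIT)
    return FeatureVector("fruit", list(FRUIT_FEATURE_NAMES), np.array(values))


def endocarp_features(
    contour_A: Contour, contour_B: Contour, extended: bool = False
) -> FeatureVector:
    """22 endocarp descriptors (11 per position), +3 cross-position extras.

    The extras (``extended=True``): a mucro presence flag from the mean
    apex-curve area, the mean circularity of both positions, and the
    width ratio A/B.
    """
    summaries = [_ContourSummary(c) for c in (contour_A, contour_B)]
    dicts = [_endocarp_position(s) for s in summaries]
    values = []
    for d in dicts:
        values.extend(d[n] for n in _PER_POSITION_ENDOCARP)
    names = list(ENDOCARP_FEATURE_NAMES)
    if extended:
        mean_area = float(np.mean([s.area for s in summaries]))
        mean_apex_curve = float(np.mean([d["apex_curve_area"] for d in dicts]))
        values.extend(
            [
                1.0 if mean_apex_curve > MUCRO_AREA_FLOOR * mean_area else 0.0,
                float(np.mean([s.circularity for s in summaries])),
                summaries[0].width / summaries[1].width,
            ]
        )
        names = list(ENDOCARP_EXTENDED_NAMES)
    return FeatureVector("endocarp", names, np.array(values))


@dataclass
class PetioleSplit:
    """Result of separating a leaf silhouette into blade and petiole."""

    blade: Silhouette
    petiole: Silhouette | None
    petiole_length_mm: float = 0.0
    thickness_upper_mm: float = 0.0
    thickness_lower_mm: float = 0.0
    #: direction (mm frame, y-up) from the petiole toward the blade,
    #: i.e. base → apex; None when no petiole was found
    apex_hint: np.ndarray | None = None


def split_petiole(s: Silhouette) -> PetioleSplit:
    """Separate the petiole from the leaf blade along the leaf's long axis.

    The leaf pixels are projected on their principal axis; the petiole is
    the maximal run of width-profile bins below 20% of the maximum
    width, adjacent to one end and longer than 5% of the total length.
    Upper thickness is the mean width over the petiole quarter adjoining
    the blade, lower thickness over the distal quarter.
    """
    mm = s.mm_per_px
    rows, cols = np.nonzero(s.mask)
    h = s.mask.shape[0]
    pts = np.column_stack([cols * mm, (h - rows) * mm])
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    perp = np.array([-axis[1], axis[0]])
    t = centered @ axis
    w = centered @ perp
    n_bins = max(16, int(np.ceil((t.max() - t.min()) / mm)))
    edges = np.linspace(t.min(), t.max() + 1e-9, n_bins + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    width = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            width[b] = w[sel].max() - w[sel].min() + mm
    low = width < PETIOLE_WIDTH_FRAC * width.max()
    min_run = int(np.ceil(PETIOLE_MIN_LENGTH_FRAC * n_bins))

    def run_from(start: int, step: int) -> int:
        n = 0
        i = start
        while 0 <= i < n_bins and low[i]:
            n += 1
            i += step
        return n

    run_lo, run_hi = run_from(0, 1), run_from(n_bins - 1, -1)
    if max(run_lo, run_hi) <= min_run:
        return PetioleSplit(blade=s, petiole=None)
    # median over each quarter: robust to the blade flare at the junction
    if run_lo >= run_hi:
        pet_bins = np.arange(0, run_lo)
        quarter = max(1, run_lo // 4)
        upper = np.median(width[pet_bins[-quarter:]])
        lower = np.median(width[pet_bins[:quarter]])
    else:
        pet_bins = np.arange(n_bins - run_hi, n_bins)
        quarter = max(1, run_hi // 4)
        upper = np.median(width[pet_bins[:quarter]])
        lower = np.median(width[pet_bins[-quarter:]])
    pet_sel = np.isin(idx, pet_bins)
    pet_mask = np.zeros_like(s.mask)
    pet_mask[rows[pet_sel], cols[pet_sel]] = True
    blade_mask = s.mask & ~pet_mask
    hint = pts[~pet_sel].mean(axis=0) - pts[pet_sel].mean(axis=0)
    from dataclasses import replace

    return PetioleSplit(
        blade=replace(s, mask=blade_mask),
        petiole=replace(s, mask=pet_mask),
        petiole_length_mm=float(len(pet_bins) * (edges[1] - edges[0])),
        thickness_upper_mm=float(upper),
        thickness_lower_mm=float(lower),
        apex_hint=hint / np.hypot(*hint),
    )


def leaf_features(
    blade: Contour, split: "PetioleSplit | tuple[float, float, float] | None" = None
) -> FeatureVector:
    """16 leaf descriptors: 13 blade descriptors plus 3 petiole measures.

    ``split`` may be a :class:`PetioleSplit` or a precomputed
    (length, upper thickness, lower thickness) triple.  With no petiole
    (entire leaves, or blades supplied alone) the three petiole
    descriptors are 0 and a warning is logged.
    """
    s = _ContourSummary(blade)
    hull_area = blade.polygon().convex_hull.area
    if isinstance(split, tuple):
        pet = split
    elif split is None or split.petiole is None:
        logger.warning("leaf without petiole: petiole descriptors set to 0")
        pet = (0.0, 0.0, 0.0)
    else:
        pet = (split.petiole_length_mm, split.thickness_upper_mm, split.thickness_lower_mm)
    values = [
        s.area,
        s.perimeter,
        s.height,
        s.width,
        s.shape_index,
        s.circularity,
        s.ellipse.semi_major,
        s.ellipse.semi_minor,
        s.window_mean_abs_kappa(blade.apex_index) * s.height,
        s.window_mean_abs_kappa(blade.base_index) * s.height,
        s.vertical_symmetry,
        s.transversal_asymmetry,
        s.area / hull_area,
        *pet,
    ]
    return FeatureVector("leaf", list(LEAF_FEATURE_NAMES), np.array(values))


def leaf_features_from_silhouette(s: Silhouette, n_points: int = 512) -> FeatureVector:
    """Full leaf pipeline: petiole split, blade contour, 16 descriptors."""
    split = split_petiole(s)
    blade = contour_from_silhouette(
        split.blade, n_points=n_points, apex_hint=split.apex_hint
    )
    return leaf_features(blade, split)


@dataclass
class OrganSample:
    """One physical sample: its silhouettes keyed by position ('A'/'B')
    for fruits and endocarps, or 'leaf' for leaves."""

    sample_id: str
    cultivar: str
    year: int
    organ: str
    silhouettes: dict[str, Silhouette] = field(default_factory=dict)
    #: precomputed contours (fast synthetic mode) keyed like silhouettes
    contours: dict[str, Contour] = field(default_factory=dict)
    #: precomputed petiole measurements for fast-mode leaves
    petiole: tuple[float, float, float] | None = None


@dataclass
class FeatureTable:
    """Samples × descriptors for one organ, with metadata columns."""

    df: pd.DataFrame
    organ: str

    def __post_init__(self) -> None:
        missing = [c for c in META_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table missing metadata columns {missing}")
        if self.df["sample_id"].duplicated().any():
            dup = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if self.df[self.feature_names].isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in META_COLS]

    @property
    def cultivars(self) -> list[str]:
        return sorted(self.df["cultivar"].unique().tolist())

    def matrix(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        return self.df["cultivar"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        organs = df["organ"].unique()
        if len(organs) != 1:
            raise ValueError(f"feature table must hold one organ, found {organs}")
        return cls(df=df, organ=str(organs[0]))


def _sample_features(sample: OrganSample, n_points: int, extended: bool) -> FeatureVector:
    def get_contour(key: str) -> Contour:
        if key in sample.contours:
            return sample.contours[key]
        return contour_from_silhouette(sample.silhouettes[key], n_points=n_points)

    if sample.organ == "fruit":
        return fruit_features(get_contour("A"), get_contour("B"))
    if sample.organ == "endocarp":
        return endocarp_features(get_contour("A"), get_contour("B"), extended=extended)
    if sample.organ == "leaf":
        if "leaf" in sample.contours:
            return leaf_features(sample.contours["leaf"], sample.petiole)
        return leaf_features_from_silhouette(sample.silhouettes["leaf"], n_points=n_points)
    raise ValueError(f"unknown organ {sample.organ!r}")


def build_feature_table(
    samples: list[OrganSample],
    n_points: int = 512,
    extended_endocarp: bool = False,
) -> FeatureTable:
    """Compute descriptors for every sample and assemble one organ table.

    Failed samples are logged and skipped, never imputed.  Rows are
    ordered deterministically by (cultivar, sample_id).
    """
    if not samples:
        raise ValueError("no samples supplied")
    organ = samples[0].organ
    seen: set[str] = set()
    rows = []
    for sample in samples:
        if sample.organ != organ:
            raise ValueError("all samples in one table must share the organ")
        if sample.sample_id in seen:
            raise ValueError(f"duplicate sample_id {sample.sample_id!r}")
        seen.add(sample.sample_id)
        try:
            fv = _sample_features(sample, n_points, extended_endocarp)
        except Exception as exc:  # noqa: BLE001 - skip-and-log contract
            logger.warning("skipping sample %s: %s", sample.sample_id, exc)
            continue
        rows.append(
            {
                "sample_id": sample.sample_id,
                "cultivar": sample.cultivar,
                "year": sample.year,
                "organ": organ,
                **fv.as_dict(),
            }
        )
    if not rows:
        raise ValueError("every sample failed feature extraction")
    df = pd.DataFrame(rows).sort_values(["cultivar", "sample_id"], ignore_index=True)
    cols = META_COLS + feature_names_for(organ, extended_endocarp)
    return FeatureTable(df=df[cols], organ=organ)
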