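"""Orientation-normalized contours and primitive shape measurements.

Every descriptor in the feature catalogs is built from the primitives
here: a closed boundary polygon in millimetres, resampled to equal arc
length, rotated so the organ's long (principal) axis is vertical with
the apex up and the centroid at the origin.  On top of that sit the
caliper dimensions, least-squares ellipse fit, signed curvature profile,
apex/base landmarks and the two symmetry measures.

Pixel space has row 0 at the top; contours live in a y-up mm frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from shapely import affinity
from shapely.geometry import Polygon
from skimage.measure import EllipseModel, find_contours

from .imaging import MIN_FOREGROUND_PX, SegmentationError, Silhouette

DEFAULT_N_POINTS = 512
DEFAULT_CURVATURE_WINDOW = 15
#: half-width of the apex/base landmark windows, as a fraction of the perimeter
LANDMARK_WINDOW_FRAC = 0.10


@dataclass
class Contour:
    """Closed boundary polygon in mm, counter-clockwise, apex-up.

    ``points`` is an (n, 2) array of (x, y); closure is implicit (the
    first point is not repeated).  After normalization the centroid is
    at the origin, the principal axis is vertical and ``apex_index`` is
    the boundary point of maximal y.
    """

    points: np.ndarray
    mm_per_px: float
    apex_index: int = 0
    base_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def polygon(self) -> Polygon:
        poly = Polygon(self.points)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly

    def to_csv(self, path, **metadata) -> None:
        header = "x_mm,y_mm"
        if metadata:
            header = (
                "# " + ",".join(f"{k}={v}" for k, v in sorted(metadata.items())) + "\n" + header
            )
        np.savetxt(path, self.points, delimiter=",", header=header, comments="")


@dataclass
class EllipseFit:
    """Direct least-squares ellipse fit to the boundary points."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float
    rms_residual: float

    def radius_at(self, points: np.ndarray) -> np.ndarray:
        """Ellipse radius along the ray from the center through each point."""
        d = np.asarray(points, dtype=float) - np.asarray(self.center)
        # rotate into the ellipse frame
        c, s = np.cos(-self.angle), np.sin(-self.angle)
        u = d[:, 0] * c - d[:, 1] * s
        v = d[:, 0] * s + d[:, 1] * c
        phi = np.arctan2(v, u)
        a, b = self.semi_major, self.semi_minor
        return a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)

    def radial_deviation(self, points: np.ndarray) -> np.ndarray:
        """Signed distance outside (+) / inside (−) the ellipse, radially."""
        d = np.asarray(points, dtype=float) - np.asarray(self.center)
        return np.hypot(d[:, 0], d[:, 1]) - self.radius_at(points)


@dataclass
class CurvatureProfile:
    """Signed curvature (1/mm) per boundary point; convex regions positive."""

    kappa: np.ndarray
    smoothing_window: int


def signed_area(points: np.ndarray) -> float:
    """Shoelace area; positive for counter-clockwise polygons."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(c: Contour) -> float:
    """Enclosed area in mm² (positive; contour is counter-clockwise)."""
    return abs(signed_area(c.points))


def polygon_perimeter(c: Contour) -> float:
    """Sum of segment lengths in mm, including the closing segment."""
    diffs = np.diff(np.vstack([c.points, c.points[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a simple closed polygon."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-15:
        return points.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def resample_closed(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polyline to ``n_points`` at equal arc length."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polyline with zero length")
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def _principal_axis_angle(points: np.ndarray) -> float:
    """Angle of the first principal axis of the boundary points."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    return float(np.arctan2(v[1], v[0]))


def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T


def curvature_of_points(points: np.ndarray, window: int) -> np.ndarray:
    """Signed curvature of an equal-arc-length closed polyline.

    Derivatives come from periodic Savitzky-Golay smoothing over
    ``window`` points; positive where the (counter-clockwise) curve is
    locally convex.
    """
    n = len(points)
    if window >= n / 2:
        raise ValueError(f"smoothing window {window} too large for {n} points")
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be an odd integer >= 5")
    perim = np.hypot(*np.diff(np.vstack([points, points[:1]]), axis=0).T).sum()
    ds = perim / n
    x, y = points[:, 0], points[:, 1]
    dx = savgol_filter(x, window, 3, deriv=1, delta=ds, mode="wrap")
    dy = savgol_filter(y, window, 3, deriv=1, delta=ds, mode="wrap")
    ddx = savgol_filter(x, window, 3, deriv=2, delta=ds, mode="wrap")
    ddy = savgol_filter(y, window, 3, deriv=2, delta=ds, mode="wrap")
    denom = (dx**2 + dy**2) ** 1.5
    denom = np.where(denom < 1e-12, 1e-12, denom)
    return (dx * ddy - dy * ddx) / denom


def landmark_window(n_points: int, index: int, frac: float = LANDMARK_WINDOW_FRAC) -> np.ndarray:
    """Indices within ±``frac`` of the perimeter around ``index`` (wrapped)."""
    half = max(1, int(round(frac * n_points)))
    return (np.arange(index - half, index + half + 1)) % n_points


def normalize_points(
    points: np.ndarray,
    mm_per_px: float,
    n_points: int = DEFAULT_N_POINTS,
    apex_hint: np.ndarray | None = None,
    smooth_window: int | None = None,
) -> Contour:
    """Build an orientation-normalized Contour from raw boundary points (mm).

    Steps: enforce counter-clockwise order, resample to equal arc
    length, rotate the principal axis vertical, pick the apex end, and
    center the polygon centroid on the origin.

    Apex disambiguation: by default the end whose landmark window has
    the larger mean |curvature| is the apex (fruits and endocarps narrow
    toward the apex).  ``apex_hint`` — a direction vector in the input
    frame — overrides this; the contour is rotated so the hint points up
    (used for leaves, where the petiole attachment marks the base).
    """
    pts = np.asarray(points, dtype=float)
    if signed_area(pts) < 0:
        pts = pts[::-1]
    pts = resample_closed(pts, n_points)
    if smooth_window is not None:
        # suppress pixel-scale staircase on traced raster boundaries
        pts = np.column_stack(
            [savgol_filter(pts[:, i], smooth_window, 2, mode="wrap") for i in (0, 1)]
        )
    angle = _principal_axis_angle(pts)
    rot = np.pi / 2 - angle
    pts = _rotate(pts, rot)
    if apex_hint is not None:
        hint = _rotate(np.asarray(apex_hint, dtype=float)[None, :], rot)[0]
        flip = hint[1] < 0
    else:
        kappa = curvature_of_points(pts, DEFAULT_CURVATURE_WINDOW)
        top = int(np.argmax(pts[:, 1]))
        bottom = int(np.argmin(pts[:, 1]))
        k_top = np.mean(np.abs(kappa[landmark_window(n_points, top)]))
        k_bottom = np.mean(np.abs(kappa[landmark_window(n_points, bottom)]))
        flip = k_bottom > k_top
    if flip:
        pts = -pts  # 180° rotation keeps counter-clockwise order
    pts = pts - polygon_centroid(pts)
    apex = int(np.argmax(pts[:, 1]))
    pts = np.roll(pts, -apex, axis=0)
    c = Contour(points=pts, mm_per_px=mm_per_px, apex_index=0)
    c.base_index = int(np.argmin(pts[:, 1]))
    return c


def contour_from_silhouette(
    s: Silhouette,
    n_points: int = DEFAULT_N_POINTS,
    apex_hint: np.ndarray | None = None,
) -> Contour:
    """Trace the sub-pixel boundary of a silhouette and normalize it.

    The mask boundary is traced at the 0.5 iso-level, converted to the
    y-up mm frame, then passed through :func:`normalize_points`.
    ``apex_hint`` is a direction in the mm frame (x right, y up).
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    if int(s.mask.sum()) < MIN_FOREGROUND_PX:
        raise SegmentationError("degenerate mask: fewer than 100 foreground px")
    contours = find_contours(s.mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no boundary found in mask")
    boundary = max(contours, key=len)
    rows, cols = boundary[:, 0], boundary[:, 1]
    h = s.mask.shape[0]
    pts = np.column_stack([cols * s.mm_per_px, (h - rows) * s.mm_per_px])
    # smoothing window sized to ~8 px of boundary: wide enough to kill the
    # rasterization staircase, narrow enough to keep mm-scale features
    perimeter_px = np.hypot(*np.diff(pts, axis=0).T).sum() / s.mm_per_px
    window = max(9, int(round(8.0 * n_points / perimeter_px)) | 1)
    return normalize_points(
        pts, s.mm_per_px, n_points=n_points, apex_hint=apex_hint, smooth_window=window
    )


def caliper_dimensions(
    c: Contour, n_heights: int = 257
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Height, maximum width, and the width profile of a normalized contour.

    Returns ``(height, width, heights_norm, widths)`` where ``widths[i]``
    is the total horizontal chord length across the interior at
    normalized height ``heights_norm[i]`` (0 = base, 1 = apex), and
    ``width = max(widths)``.
    """
    import shapely

    y = c.points[:, 1]
    y_min, y_max = float(y.min()), float(y.max())
    height = y_max - y_min
    poly = c.polygon()
    x_min, x_max = c.points[:, 0].min() - 1.0, c.points[:, 0].max() + 1.0
    hs = np.linspace(0.002, 0.998, n_heights)
    yy = y_min + hs * height
    coords = np.empty((n_heights, 2, 2))
    coords[:, 0, 0] = x_min
    coords[:, 1, 0] = x_max
    coords[:, 0, 1] = yy
    coords[:, 1, 1] = yy
    lines = shapely.linestrings(coords)
    widths = shapely.length(shapely.intersection(lines, poly))
    return height, float(widths.max()), hs, widths


def fit_ellipse(c: Contour) -> EllipseFit:
    """Stable direct least-squares ellipse fit (Halir–Flusser) to the contour."""
    if c.n_points < 64:
        raise ValueError("need at least 64 points for a reliable ellipse fit")
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(c.points)
        if not model:
            raise ValueError("degenerate ellipse fit (collinear points?)")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # skimage < 0.26
        model = EllipseModel()
        if not model.estimate(c.points):
            raise ValueError("degenerate ellipse fit (collinear points?)")
        xc, yc, a, b, theta = model.params
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    fit = EllipseFit(
        center=(float(xc), float(yc)),
        semi_major=float(a),
        semi_minor=float(b),
        angle=float(np.arctan2(np.sin(theta), np.cos(theta))),
        rms_residual=0.0,
    )
    fit.rms_residual = float(np.sqrt(np.mean(fit.radial_deviation(c.points) ** 2)))
    return fit


def curvature_profile(c: Contour, window: int = DEFAULT_CURVATURE_WINDOW) -> CurvatureProfile:
    """Signed curvature at every boundary point (1/mm)."""
    return CurvatureProfile(
        kappa=curvature_of_points(c.points, window), smoothing_window=window
    )


def locate_landmarks(c: Contour) -> tuple[int, int]:
    """Apex (max y) and base (min y) boundary-point indices."""
    return int(np.argmax(c.points[:, 1])), int(np.argmin(c.points[:, 1]))


def symmetry_measures(c: Contour) -> tuple[float, float]:
    """Transversal asymmetry and vertical symmetry of a normalized contour.

    ``transversal_asymmetry`` = 1 − overlap of the shape with its mirror
    image about the vertical axis, as a fraction of its area (0 for a
    bilaterally symmetric shape).  ``vertical_symmetry`` = normalized
    height (from the base) of the maximum transversal diameter (0.5 for
    an ellipse; > 0.5 means the widest section sits toward the apex).
    """
    poly = c.polygon()
    mirrored = affinity.scale(poly, xfact=-1.0, yfact=1.0, origin=(0.0, 0.0))
    overlap = poly.intersection(mirrored).area
    asym = 1.0 - overlap / poly.area
    _, _, hs, widths = caliper_dimensions(c)
    v_sym = float(hs[int(np.argmax(widths))])
    return float(max(asym, 0.0)), v_sym
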