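"""Image segmentation and binary silhouette I/O.

A *silhouette* is the binary foreground mask of a single plant organ
(fruit, leaf or endocarp) photographed or scanned on a uniform
background, together with the physical pixel scale and the sample
metadata every downstream module needs (cultivar, year, viewing
position).  Segmentation assumes exactly one dominant object whose
intensity contrasts with the background; polarity (dark-on-light vs
light-on-dark) is chosen automatically.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label

logger = logging.getLogger(__name__)

ORGANS = ("fruit", "leaf", "endocarp")
POSITIONS = ("A", "B", "none")

#: minimum number of foreground pixels for a usable silhouette
MIN_FOREGROUND_PX = 100


class SegmentationError(ValueError):
    """No usable foreground object could be extracted."""


class MaskFormatError(ValueError):
    """A mask file violates the binary single-channel PNG contract."""


def scale_from_dpi(dpi: float) -> float:
    """Convert a scan resolution in dots per inch to mm per pixel.

    One inch is 25.4 mm, so a 600 dpi scan has 25.4/600 ≈ 0.0423 mm/px.
    """
    if dpi <= 0:
        raise ValueError(f"dpi must be positive, got {dpi}")
    return 25.4 / dpi


@dataclass
class RawImage:
    """A grayscale or RGB photograph of a single organ."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D grid or an RGB stack")
        if self.height_px < 16 or self.width_px < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=float))):
            raise ValueError("image intensities must be finite")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @classmethod
    def from_file(cls, path: str | Path) -> "RawImage":
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB" if img.mode not in ("L", "I;16", "F") else "L"))
        return cls(pixels=arr, source_path=str(path))

    def to_gray(self) -> np.ndarray:
        """Return intensities scaled to [0, 1]."""
        px = self.pixels
        if px.ndim == 3:
            return rgb2gray(px)
        px = px.astype(float)
        span = px.max() - px.min()
        return (px - px.min()) / span if span > 0 else np.zeros_like(px)


@dataclass
class Silhouette:
    """Binary foreground mask of one organ plus physical scale and metadata.

    Invariants: a single 4-connected foreground component of at least
    ``MIN_FOREGROUND_PX`` pixels that does not touch the image border.
    """

    mask: np.ndarray
    mm_per_px: float
    organ: str = "fruit"
    position: str = "none"
    sample_id: str = ""
    cultivar: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    def validate(self) -> "Silhouette":
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.organ not in ORGANS:
            raise ValueError(f"organ must be one of {ORGANS}")
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")
        n_fg = int(self.mask.sum())
        if n_fg < MIN_FOREGROUND_PX:
            raise SegmentationError(f"foreground has {n_fg} px < {MIN_FOREGROUND_PX}")
        lab, n = label(self.mask, connectivity=1, return_num=True)
        if n != 1:
            raise SegmentationError(f"expected one 4-connected component, found {n}")
        border = np.concatenate(
            [self.mask[0, :], self.mask[-1, :], self.mask[:, 0], self.mask[:, -1]]
        )
        if border.any():
            raise SegmentationError("foreground touches the image border")
        return self

    @property
    def area_mm2(self) -> float:
        """Pixel-count area estimate in mm²."""
        return float(self.mask.sum()) * self.mm_per_px**2

    def padded(self, margin: int = 2) -> "Silhouette":
        """Return a copy with a clear margin added around the canvas."""
        m = np.pad(self.mask, margin, mode="constant", constant_values=False)
        return replace(self, mask=m)


@dataclass
class SegmentationConfig:
    mm_per_px: float | None = None
    dpi: float | None = None
    organ: str = "fruit"
    position: str = "none"
    sample_id: str = ""
    cultivar: str | None = None
    year: int | None = None
    #: second-largest / largest component ratio above which a warning is raised
    multi_object_ratio: float = 0.25

    def resolve_scale(self) -> float:
        if self.mm_per_px is not None:
            if self.mm_per_px <= 0:
                raise ValueError("mm_per_px must be positive")
            return self.mm_per_px
        if self.dpi is not None:
            return scale_from_dpi(self.dpi)
        raise ValueError("segmentation config must supply mm_per_px or dpi")


def _touched_borders(mask: np.ndarray) -> int:
    return sum(
        side.any()
        for side in (mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1])
    )


def _clean_components(fg: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Fill holes, keep the largest 4-connected component.

    Returns the component mask plus the largest and second-largest sizes.
    """
    fg = ndimage.binary_fill_holes(fg)
    lab, n = label(fg, connectivity=1, return_num=True)
    if n == 0:
        return np.zeros_like(fg, dtype=bool), 0, 0
    sizes = np.bincount(lab.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    largest = int(sizes[order[0]])
    second = int(sizes[order[1]]) if n > 1 else 0
    return lab == order[0] + 1, largest, second


def segment_image(image: RawImage, config: SegmentationConfig) -> Silhouette:
    """Segment the single dominant object of ``image`` into a silhouette.

    Global Otsu thresholding, hole filling and small-component removal;
    the foreground polarity is chosen so that the object does not touch
    three or more image borders (the organ sits inside the frame, the
    background does not).
    """
    gray = image.to_gray()
    if np.ptp(gray) < 1e-12:
        raise SegmentationError("uniform image: no foreground object")
    thresh = threshold_otsu(gray)

    candidates = []
    for fg in (gray < thresh, gray > thresh):
        comp, largest, second = _clean_components(fg)
        candidates.append((comp, largest, second))

    # prefer the polarity whose object stays inside the frame
    viable = [c for c in candidates if c[1] >= MIN_FOREGROUND_PX and _touched_borders(c[0]) < 3]
    if not viable:
        raise SegmentationError("no foreground component of at least 100 px found")
    comp, largest, second = max(viable, key=lambda c: c[1])
    if second > config.multi_object_ratio * largest:
        warnings.warn(
            f"second-largest component is {second}/{largest} of the largest; "
            "image may contain more than one object",
            stacklevel=2,
        )
    sil = Silhouette(
        mask=comp,
        mm_per_px=config.resolve_scale(),
        organ=config.organ,
        position=config.position,
        sample_id=config.sample_id or Path(image.source_path).stem,
        cultivar=config.cultivar,
        year=config.year,
    )
    if _touched_borders(comp) > 0:
        sil = replace(sil, mask=np.pad(comp, 2, constant_values=False))
    return sil.validate()


def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_mask(silhouette: Silhouette, path: str | Path) -> None:
    """Write a binary PNG mask (0/255) plus a JSON metadata sidecar."""
    arr = (silhouette.mask.astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path, format="PNG")
    meta = {
        "sample_id": silhouette.sample_id,
        "cultivar": silhouette.cultivar,
        "year": silhouette.year,
        "organ": silhouette.organ,
        "position": silhouette.position,
        "mm_per_px": silhouette.mm_per_px,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_mask(path: str | Path, mm_per_px: float | None = None) -> Silhouette:
    """Read a binary PNG mask and its JSON sidecar back into a Silhouette.

    A missing sidecar yields unknown cultivar/year (with a logged warning);
    ``mm_per_px`` must then be supplied by the caller.
    """
    with Image.open(path) as img:
        if img.mode != "L":
            img = img.convert("L")
        arr = np.asarray(img)
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 255}:
        raise MaskFormatError(
            f"mask {path} is not binary: pixel values {values[:10].tolist()}"
        )
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        logger.warning("no metadata sidecar for %s; cultivar/year unknown", path)
        meta = {}
    scale = meta.get("mm_per_px", mm_per_px)
    if scale is None:
        raise ValueError(f"no mm_per_px in sidecar or argument for {path}")
    return Silhouette(
        mask=arr == 255,
        mm_per_px=float(scale),
        organ=meta.get("organ", "fruit"),
        position=meta.get("position", "none"),
        sample_id=meta.get("sample_id", Path(path).stem),
        cultivar=meta.get("cultivar"),
        year=meta.get("year"),
    )
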