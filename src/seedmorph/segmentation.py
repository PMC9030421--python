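"""Silhouette segmentation of flatbed-scanner seed images.

A scan shows several seeds lying on a uniform (white or black) background.
Segmentation picks a global Otsu threshold, labels 8-connected foreground
components, fills interior holes (4-connected background duality) and
returns one binary :class:`SeedMask` per seed, ordered top-to-bottom then
left-to-right by centroid.  Touching seeds are *not* separated; they come
back as one merged mask with a logged warning.

All coordinates are 0-based ``(row, col)`` with pixel centres at integer
positions; lengths are in pixels (convert to mm with ``25.4 / dpi``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateShapeError, InputError, ValidationError

logger = logging.getLogger(__name__)

#: 8-connectivity structuring element for foreground labelling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class RasterImage:
    """A grayscale scan with its acquisition metadata.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities, row-major.
    dpi : float
        Scan resolution in dots per inch; must be positive.
    background_mode : {'white', 'black'}
        Whether seeds are dark objects on a light background or the
        reverse.
    """

    pixels: np.ndarray
    dpi: float
    background_mode: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValidationError(
                f"image must be a 2-D grid of at least 2x2 pixels, got shape {px.shape}"
            )
        if not np.isfinite(self.dpi) or self.dpi <= 0:
            raise ValidationError(f"dpi must be positive, got {self.dpi}")
        if self.background_mode not in ("white", "black"):
            raise ValidationError(
                f"background_mode must be 'white' or 'black', got {self.background_mode!r}"
            )
        object.__setattr__(self, "pixels", px)


@dataclass
class SeedMask:
    """Binary silhouette of a single specimen.

    ``mask`` is a cropped boolean array (True = seed); ``offset`` locates
    its origin inside the source scan.  A valid mask holds exactly one
    8-connected foreground component with no interior holes.
    """

    mask: np.ndarray
    offset: tuple[int, int] = (0, 0)
    specimen_id: str = ""
    source_id: str = ""
    class_label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValidationError(
                f"mask for specimen {self.specimen_id!r} must be a non-empty 2-D binary grid"
            )

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def validate(self, min_area_px: int = 1) -> None:
        """Check the single-component / hole-free / size invariants."""
        n_comp = ndimage.label(self.mask, structure=_STRUCT8)[1]
        if n_comp != 1:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: expected one 8-connected component, found {n_comp}"
            )
        filled = ndimage.binary_fill_holes(self.mask)
        if not np.array_equal(filled, self.mask):
            raise ValidationError(f"specimen {self.specimen_id!r}: mask has interior holes")
        if self.area_px < min_area_px:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: area {self.area_px} px below minimum {min_area_px}"
            )


@dataclass(frozen=True)
class BoundaryPolygon:
    """Closed outer boundary traced through foreground pixel centres.

    Vertices are ``(row, col)`` coordinates in the mask's local frame,
    ordered counter-clockwise with respect to conventional axes (x = col
    rightwards, y upwards, i.e. decreasing row).  The polygon is implicitly
    closed: the first vertex is not repeated at the end.
    """

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise DegenerateShapeError(
                f"boundary polygon needs at least 3 vertices, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise orientation."""
        y = -self.vertices[:, 0]  # y axis points up
        x = self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def load_scan(path, dpi: float, background_mode: str) -> RasterImage:
    """Read a PNG/TIFF scan, converting colour to grayscale by luminance."""
    if not np.isfinite(dpi) or dpi <= 0:
        raise ValidationError(f"dpi must be positive, got {dpi}")
    try:
        with Image.open(path) as im:
            im.load()
            gray = im.convert("L")
            pixels = np.asarray(gray, dtype=np.uint8)
    except (FileNotFoundError, UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise InputError(f"cannot read image file {path}: {exc}") from exc
    return RasterImage(pixels=pixels, dpi=float(dpi), background_mode=background_mode)


def compute_threshold(image: RasterImage) -> float:
    """Global bimodal-histogram (Otsu) threshold for a scan."""
    return float(threshold_otsu(np.asarray(image.pixels, dtype=float)))


def segment_seeds(
    image: RasterImage,
    min_area_px: int = 50,
    exclude_border: bool = False,
    source_id: str = "scan",
) -> list[SeedMask]:
    """Split a scan into per-specimen binary masks.

    Thresholds with the Otsu criterion (polarity flipped for white
    backgrounds so foreground = seed), fills holes, labels 8-connected
    components, drops those below ``min_area_px`` and, optionally, those
    touching the image border.  Masks are returned sorted by centroid
    (top-to-bottom, then left-to-right) with ids assigned in that order.
    """
    arr = np.asarray(image.pixels, dtype=float)
    thresh = compute_threshold(image)
    fg = arr < thresh if image.background_mode == "white" else arr > thresh
    fg = ndimage.binary_fill_holes(fg)

    labels, n = ndimage.label(fg, structure=_STRUCT8)
    if n == 0:
        logger.warning("segment_seeds: no foreground component found in %s", source_id)
        return []

    objects = ndimage.find_objects(labels)
    nrow, ncol = fg.shape
    kept: list[tuple[float, float, np.ndarray, tuple[int, int]]] = []
    n_small = n_border = 0
    for lab, sl in enumerate(objects, start=1):
        comp = labels[sl] == lab
        area = int(comp.sum())
        if area < min_area_px:
            n_small += 1
            continue
        if exclude_border:
            r0, c0 = sl[0].start, sl[1].start
            r1, c1 = sl[0].stop, sl[1].stop
            if r0 == 0 or c0 == 0 or r1 == nrow or c1 == ncol:
                n_border += 1
                continue
        rows, cols = np.nonzero(comp)
        centroid = (rows.mean() + sl[0].start, cols.mean() + sl[1].start)
        kept.append((centroid[0], centroid[1], comp, (sl[0].start, sl[1].start)))

    if n_small:
        logger.info("segment_seeds: dropped %d components below %d px", n_small, min_area_px)
    if n_border:
        logger.info("segment_seeds: dropped %d border-touching components", n_border)
    if not kept:
        logger.warning(
            "segment_seeds: no component of %s survived filtering (min_area_px=%d)",
            source_id,
            min_area_px,
        )
        return []

    kept.sort(key=lambda t: (t[0], t[1]))
    masks = [
        SeedMask(
            mask=comp,
            offset=offset,
            specimen_id=f"{source_id}-{i:03d}",
            source_id=source_id,
        )
        for i, (_, _, comp, offset) in enumerate(kept)
    ]
    return masks


# Moore neighbourhood in clockwise order starting North, image coordinates
# (row grows downward).
_MOORE = np.array(
    [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)],
    dtype=int,
)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (or to the array edge).

    This is the pixel set the Moore trace walks: the boundary curve of an
    8-connected object is 8-connected and consists of exactly these pixels
    once interior holes are filled.
    """
    m = np.asarray(mask, dtype=bool)
    interior = (
        m
        & np.pad(m, 1)[:-2, 1:-1]
        & np.pad(m, 1)[2:, 1:-1]
        & np.pad(m, 1)[1:-1, :-2]
        & np.pad(m, 1)[1:-1, 2:]
    )
    return np.argwhere(m & ~interior)


def trace_boundary(mask: SeedMask) -> BoundaryPolygon:
    """Moore-neighbour outer-boundary trace of a seed mask.

    Walks the outer contour through foreground pixel centres, starting at
    the top-most then left-most boundary pixel, and returns the vertex
    sequence oriented counter-clockwise.  Uses Jacob's stopping criterion
    (terminate on re-entering the start pixel from the same direction).
    """
    m = np.asarray(mask.mask, dtype=bool)
    if len(boundary_pixels(m)) < 3:
        raise DegenerateShapeError(
            f"specimen {mask.specimen_id!r}: fewer than 3 boundary pixels"
        )
    padded = np.pad(m, 1)
    moore = [(int(dr), int(dc)) for dr, dc in _MOORE]
    ring_index = {d: k for k, d in enumerate(moore)}

    rows, cols = np.nonzero(padded)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))
    # The west neighbour of the top-most/left-most pixel is background.
    start_back = (start[0], start[1] - 1)

    contour: list[tuple[int, int]] = [start]
    cur, back = start, start_back
    first_next: tuple[int, int] | None = None
    seen_states: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    max_iter = 4 * int(padded.sum()) + 8
    for _ in range(max_iter):
        if (cur, back) in seen_states:  # backstop against pathological cycles
            break
        seen_states.add((cur, back))
        # clockwise scan of the Moore ring, starting just after backtrack
        k0 = ring_index[(back[0] - cur[0], back[1] - cur[1])]
        nxt = None
        last_bg = back
        for step in range(1, 9):
            dr, dc = moore[(k0 + step) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                nxt = cand
                break
            last_bg = cand
        if nxt is None:  # isolated pixel; excluded by the >=3 check above
            break
        # stop when, standing on the start pixel, the walk is about to
        # repeat its very first move (the contour has closed)
        if cur == start and first_next is not None and nxt == first_next:
            break
        if first_next is None:
            first_next = nxt
        contour.append(nxt)
        cur, back = nxt, last_bg

    if len(contour) > 1 and contour[-1] == start:
        contour.pop()

    verts = np.asarray(contour, dtype=float) - 1.0  # undo padding offset
    poly = BoundaryPolygon(vertices=verts)
    if poly.signed_area < 0:
        verts = np.vstack([verts[:1], verts[1:][::-1]])
        poly = BoundaryPolygon(vertices=verts)
    return poly
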