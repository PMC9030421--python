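"""The 26 morphometric descriptors measured on each seed silhouette.

Ten *primary* measures are taken from the mask and its traced boundary
polygon (perimeter, area, pixel count, inscribed/enclosing radii about the
centroid, Feret diameter, breadth, convex-hull perimeter and area, minimal
bounding circle radius); sixteen *derived* descriptors are algebraic
combinations of them (circularity, roundness, solidity, rectangularity,
...).  The perimeter is the arc length of the polygon joining boundary
pixel centres, summing unit and sqrt(2) steps with no corner-smoothing
correction; on smooth outlines this dialect overestimates the continuous
perimeter by a factor of about 1.055, which propagates into Circ, Shape
and Convexity (see the methods note).

``PerEquivD`` follows the printed formula ``Area/pi`` by default, although
the conventional perimeter-equivalent diameter is ``Perimeter/pi``; the
alternative is available via ``perequivd_convention='perimeter_over_pi'``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from ._geometry import (
    minimum_enclosing_circle,
    polygon_area,
    polygon_perimeter,
    rotating_calipers_diameter,
)
from .errors import DegenerateShapeError, ValidationError
from .segmentation import BoundaryPolygon, SeedMask, trace_boundary

logger = logging.getLogger(__name__)

PRIMARY_FEATURES = [
    "Perim", "Area", "Pixels", "MinR", "MaxR",
    "Feret", "Breadth", "CHull", "CArea", "MBCRadius",
]

DERIVED_FEATURES = [
    "AspRatio", "Circ", "Roundness", "ArEquivD", "PerEquivD", "EquivEllAr",
    "Compactness", "Solidity", "Concavity", "Convexity", "Shape", "RFactor",
    "ModRatio", "Sphericity", "ArBBox", "Rectang",
]

#: Canonical column order of the full descriptor set.
FEATURE_NAMES = PRIMARY_FEATURES + DERIVED_FEATURES

#: Descriptors with length dimension (scale with 25.4/dpi when units=mm).
LENGTH_FEATURES = frozenset(
    ["Perim", "MinR", "MaxR", "Feret", "Breadth", "CHull", "MBCRadius", "ArEquivD"]
)
#: Descriptors with area dimension (scale with (25.4/dpi)**2).
AREA_FEATURES = frozenset(["Area", "CArea", "EquivEllAr", "Concavity", "ArBBox"])
#: Dimensionless ratios, unchanged by the px/mm choice.
RATIO_FEATURES = frozenset(
    ["AspRatio", "Circ", "Roundness", "Compactness", "Solidity", "Convexity",
     "Shape", "RFactor", "ModRatio", "Sphericity", "Rectang"]
)

CSV_COLUMNS = ["specimen_id", "class_label"] + FEATURE_NAMES

UNKNOWN_LABEL = "UNKNOWN"


def primary_measures(mask: SeedMask, polygon: BoundaryPolygon) -> dict[str, float]:
    """The ten direct measures of a silhouette.

    ``Perim``/``Area`` come from the boundary polygon, ``Pixels`` from the
    mask, ``MinR``/``MaxR`` are centroid-to-boundary distance extremes,
    the hull yields ``CHull``/``CArea``, rotating calipers the ``Feret``,
    ``Breadth`` is the caliper extent perpendicular to the Feret axis and
    ``MBCRadius`` the minimal enclosing circle radius of hull vertices.
    """
    verts = polygon.vertices
    perim = polygon_perimeter(verts)
    area = polygon_area(verts)
    if area <= 0.0:
        raise DegenerateShapeError(
            f"specimen {mask.specimen_id!r}: zero-area boundary polygon"
        )
    pixels = float(mask.mask.sum())
    centroid = np.argwhere(mask.mask).mean(axis=0)
    dists = np.linalg.norm(verts - centroid, axis=1)
    minr, maxr = float(dists.min()), float(dists.max())

    try:
        hull = ConvexHull(verts)
    except QhullError as exc:
        raise DegenerateShapeError(
            f"specimen {mask.specimen_id!r}: degenerate convex hull ({exc})"
        ) from exc
    hull_pts = verts[hull.vertices]  # counter-clockwise
    chull = polygon_perimeter(hull_pts)
    carea = float(hull.volume)  # 2-D: volume is the area

    feret, i, j = rotating_calipers_diameter(hull_pts)
    if feret <= 0.0:
        raise DegenerateShapeError(f"specimen {mask.specimen_id!r}: zero Feret diameter")
    axis = (hull_pts[j] - hull_pts[i]) / feret
    perp = np.array([-axis[1], axis[0]])
    proj = hull_pts @ perp
    breadth = float(proj.max() - proj.min())

    _, mbc_radius = minimum_enclosing_circle(hull_pts)

    return {
        "Perim": perim,
        "Area": area,
        "Pixels": pixels,
        "MinR": minr,
        "MaxR": maxr,
        "Feret": feret,
        "Breadth": breadth,
        "CHull": chull,
        "CArea": carea,
        "MBCRadius": float(mbc_radius),
    }


def derived_measures(
    primary: dict[str, float], perequivd_convention: str = "as_printed"
) -> dict[str, float]:
    """Add the sixteen derived descriptors to the primary ones.

    ``perequivd_convention`` selects ``Area/pi`` (``'as_printed'``, the
    published formula) or the conventional ``Perimeter/pi``
    (``'perimeter_over_pi'``) for ``PerEquivD``.
    """
    missing = [k for k in PRIMARY_FEATURES if k not in primary]
    if missing:
        raise ValidationError(f"primary measures missing: {missing}")
    if perequivd_convention not in ("as_printed", "perimeter_over_pi"):
        raise ValidationError(
            f"unknown perequivd_convention {perequivd_convention!r}"
        )
    p = {k: float(primary[k]) for k in PRIMARY_FEATURES}
    if not all(math.isfinite(v) for v in p.values()):
        raise DegenerateShapeError("non-finite primary measure")
    for key in ("Perim", "Feret", "Breadth", "CArea", "MaxR", "Area"):
        if p[key] <= 0.0:
            raise DegenerateShapeError(f"degenerate primaries: {key} = {p[key]}")

    arbbox = p["Feret"] * p["Breadth"]
    out = dict(p)
    out.update(
        {
            "AspRatio": p["Feret"] / p["Breadth"],
            "Circ": 4.0 * math.pi * p["Area"] / p["Perim"] ** 2,
            "Roundness": 4.0 * p["Area"] / (math.pi * p["Feret"] ** 2),
            "ArEquivD": math.sqrt(4.0 / math.pi * p["Area"]),
            "PerEquivD": (
                p["Area"] / math.pi
                if perequivd_convention == "as_printed"
                else p["Perim"] / math.pi
            ),
            "EquivEllAr": math.pi * p["Feret"] * p["Breadth"] / 4.0,
            "Compactness": math.sqrt(4.0 / math.pi * p["Area"]) / p["Feret"],
            "Solidity": p["Area"] / p["CArea"],
            "Concavity": max(p["CArea"] - p["Area"], 0.0),
            "Convexity": p["CHull"] / p["Perim"],
            "Shape": p["Perim"] ** 2 / p["Area"],
            "RFactor": p["CHull"] / (p["Feret"] * math.pi),
            "ModRatio": 2.0 * p["MinR"] / p["Feret"],
            "Sphericity": p["MinR"] / p["MaxR"],
            "ArBBox": arbbox,
            "Rectang": p["Area"] / arbbox,
        }
    )
    return out


def measure_specimen(
    mask: SeedMask, perequivd_convention: str = "as_printed"
) -> dict[str, float]:
    """Trace the boundary and compute all 26 descriptors for one mask."""
    polygon = trace_boundary(mask)
    return derived_measures(primary_measures(mask, polygon), perequivd_convention)


@dataclass
class FeatureTable:
    """Specimen-by-descriptor matrix with class labels.

    ``data`` holds one row per specimen: ``specimen_id``, ``class_label``
    (a class name or ``UNKNOWN``) and the 26 descriptor columns in
    canonical order.  ``units`` records whether lengths are in pixels or
    millimetres.
    """

    data: pd.DataFrame
    units: str = "px"
    rejects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.units not in ("px", "mm"):
            raise ValidationError(f"units must be 'px' or 'mm', got {self.units!r}")
        if list(self.data.columns) != CSV_COLUMNS:
            raise ValidationError(
                "feature table columns must be exactly the canonical 28 "
                f"(specimen_id, class_label + 26 descriptors); got {list(self.data.columns)}"
            )
        if self.data[FEATURE_NAMES].isna().any().any():
            raise ValidationError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data[FEATURE_NAMES]

    @property
    def labels(self) -> pd.Series:
        return self.data["class_label"]

    def labelled(self) -> "FeatureTable":
        """Rows with a known class label (the reference collections)."""
        sub = self.data[self.data["class_label"] != UNKNOWN_LABEL].reset_index(drop=True)
        return FeatureTable(data=sub, units=self.units)

    def unknowns(self) -> "FeatureTable":
        """Rows labelled UNKNOWN (e.g. the archaeological cohort)."""
        sub = self.data[self.data["class_label"] == UNKNOWN_LABEL].reset_index(drop=True)
        return FeatureTable(data=sub, units=self.units)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path, units: str = "px") -> "FeatureTable":
        df = pd.read_csv(path)
        return cls(data=df[CSV_COLUMNS], units=units)


def extract_features(
    masks: list[SeedMask],
    units: str = "px",
    dpi: float | None = None,
    perequivd_convention: str = "as_printed",
) -> FeatureTable:
    """Measure every mask and assemble the labelled feature table.

    Degenerate specimens (too small or flat to trace and measure) are
    skipped with a warning and listed in ``FeatureTable.rejects``; it is an
    error only when *all* specimens are rejected.  With ``units='mm'``,
    lengths scale by ``25.4/dpi`` and areas by its square; dimensionless
    ratios are unaffected.
    """
    if not masks:
        raise ValidationError("extract_features requires at least one mask")
    if units == "mm":
        if dpi is None or dpi <= 0:
            raise ValidationError("units='mm' requires a positive dpi")
        scale = 25.4 / dpi
    else:
        scale = 1.0

    rows = []
    rejects = []
    for mask in masks:
        try:
            feats = measure_specimen(mask, perequivd_convention)
        except DegenerateShapeError as exc:
            logger.warning("rejecting specimen %s: %s", mask.specimen_id, exc)
            rejects.append(mask.specimen_id)
            continue
        if units == "mm":
            for name in feats:
                if name in LENGTH_FEATURES:
                    feats[name] *= scale
                elif name in AREA_FEATURES:
                    feats[name] *= scale**2
                elif name == "PerEquivD":
                    # dimension follows the convention actually used
                    feats[name] *= scale**2 if perequivd_convention == "as_printed" else scale
        rows.append({"specimen_id": mask.specimen_id, "class_label": mask.class_label, **feats})

    if not rows:
        raise DegenerateShapeError("all specimens were rejected as degenerate")
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return FeatureTable(data=df, units=units, rejects=rejects)
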