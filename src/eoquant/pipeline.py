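"""Endocrine-object detection, filtering, classification and morphometry.

An endocrine object (EO) is a contiguous hormone-positive structure in a
2D section — a single endocrine cell up to a whole islet.  The pipeline:

1. connected components (8-connectivity) of the union of the insulin
   and glucagon positivity masks; components smaller than 170 μm² (the
   approximate area of one endocrine cell) are discarded;
2. artifact filter: an object is retained only if its insulin- or
   glucagon-labeled area exceeds 40 μm²;
3. content classification from the per-hormone positivity flags
   (labeled area > 40 μm²): Ins+Gluc- / Ins+Gluc+ / Ins-Gluc+;
4. size bin = floor(log2(area / 170 μm²)), i.e. log2 of the approximate
   cell count; bins 0-3 are small, 4-6 medium, 7-9 large, and bins
   above 9 are clamped to 9;
5. shape descriptors: circularity 4πA/P², solidity A/convex-hull area,
   max/min Feret (caliper) diameters, equivalent circular diameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.measure import find_contours, label as cc_label, regionprops

from .stains import StainMaskSet

__all__ = [
    "EndocrineObject",
    "SectionProfile",
    "MIN_OBJECT_AREA_UM2",
    "POSITIVITY_AREA_UM2",
    "MAX_BIN",
    "SIZE_CLASSES",
    "assign_bin",
    "size_class",
    "classify_content",
    "morphology",
    "detect_eos",
    "filter_by_positivity",
    "build_section_profile",
    "objects_to_frame",
]

#: minimum object area, the approximate size of one endocrine cell
MIN_OBJECT_AREA_UM2 = 170.0
#: per-hormone positivity threshold on labeled area
POSITIVITY_AREA_UM2 = 40.0
MAX_BIN = 9
SIZE_CLASSES = {"small": range(0, 4), "medium": range(4, 7), "large": range(7, 10)}
CONTENT_CLASSES = ("InsOnly", "InsGluc", "GlucOnly")


def assign_bin(area_um2: float, clamp: bool = True) -> int:
    """Size bin = floor(log2(area / 170 μm²)).

    Bin 0 starts at 170 μm² (one cell); each bin doubles the area.
    Bins above 9 are clamped to 9 with a warning (``clamp=False``
    returns the raw bin).  Areas below 170 μm² are an error: they
    should have been removed by the detection size filter.
    """
    if area_um2 < MIN_OBJECT_AREA_UM2:
        raise ValueError(
            f"area {area_um2} μm² is below the {MIN_OBJECT_AREA_UM2} μm² "
            "minimum object size")
    b = math.floor(math.log2(area_um2 / MIN_OBJECT_AREA_UM2))
    if clamp and b > MAX_BIN:
        warnings.warn(f"bin {b} clamped to {MAX_BIN} (area {area_um2:.0f} μm²)")
        b = MAX_BIN
    return b


def size_class(eo_bin: int) -> str:
    """small (bins 0-3), medium (4-6) or large (7-9)."""
    for name, bins in SIZE_CLASSES.items():
        if eo_bin in bins:
            return name
    raise ValueError(f"bin {eo_bin} outside 0-{MAX_BIN}")


def classify_content(ins_area_um2: float, gluc_area_um2: float,
                     threshold_um2: float = POSITIVITY_AREA_UM2) -> str:
    """Content class from per-hormone positivity (area > 40 μm²)."""
    ins_pos = ins_area_um2 > threshold_um2
    gluc_pos = gluc_area_um2 > threshold_um2
    if ins_pos and gluc_pos:
        return "InsGluc"
    if ins_pos:
        return "InsOnly"
    if gluc_pos:
        return "GlucOnly"
    raise ValueError(
        "object with neither hormone positive reached classification; "
        "the 40 μm² filter should have excluded it")


@dataclass
class EndocrineObject:
    """One retained EO with areas (μm²), size bin, class and shape."""

    object_id: str
    area_um2: float
    ins_area_um2: float
    gluc_area_um2: float
    eo_bin: int
    size_class: str
    content_class: str
    centroid: tuple[float, float]  # (x, y) μm
    bbox: tuple[float, float, float, float]  # (x0, y0, x1, y1) μm
    polygon: np.ndarray | None = None  # boundary ring, μm
    circularity: float = math.nan
    solidity: float = math.nan
    feret_max_um: float = math.nan
    feret_min_um: float = math.nan
    equivalent_diameter_um: float = math.nan
    touches_border: bool = False
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# morphology


def _as_ring(polygon) -> np.ndarray:
    if isinstance(polygon, Polygon):
        ring = np.asarray(polygon.exterior.coords)
    else:
        ring = np.asarray(polygon, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2 or len(ring) < 3:
        raise ValueError("polygon must be an (N, 2) ring with N >= 3")
    return ring


def _hull_feret(hull_xy: np.ndarray) -> tuple[float, float]:
    """Max/min caliper width of a convex hull (rotating calipers).

    Max Feret is the hull diameter (max pairwise vertex distance); min
    Feret is the smallest width over directions normal to hull edges —
    for a convex polygon the minimum width is always attained at an
    edge normal.
    """
    pts = hull_xy
    d = pts[:, None, :] - pts[None, :, :]
    feret_max = float(np.sqrt((d**2).sum(-1)).max())
    edges = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
    widths = np.ptp(pts @ normals.T, axis=0)
    feret_min = float(widths.min())
    return feret_max, feret_min


def morphology(polygon) -> dict[str, float]:
    """Shape descriptors of a simple closed polygon.

    Returns circularity ``4πA/P²``, solidity ``A / hull area``,
    ``feret_max``, ``feret_min`` and ``equivalent_diameter``
    ``2·sqrt(A/π)``, all in the polygon's length units.
    """
    ring = _as_ring(polygon)
    poly = Polygon(ring)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    if poly.area == 0:
        raise ValueError("polygon has zero area")
    area = poly.area
    perim = poly.length
    hull = poly.convex_hull
    feret_max, feret_min = _hull_feret(np.asarray(hull.exterior.coords)[:-1])
    return {
        "circularity": 4.0 * math.pi * area / perim**2,
        "solidity": area / hull.area,
        "feret_max": feret_max,
        "feret_min": feret_min,
        "equivalent_diameter": 2.0 * math.sqrt(area / math.pi),
    }


def _object_polygon(mask: np.ndarray, origin_rc: tuple[int, int],
                    mpp: float) -> np.ndarray | None:
    """Outer boundary (μm) of a component mask via marching squares."""
    padded = np.pad(mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # outer ring is the longest
    rows = contour[:, 0] - 1 + origin_rc[0]
    cols = contour[:, 1] - 1 + origin_rc[1]
    return np.column_stack([(cols + 0.5) * mpp, (rows + 0.5) * mpp])


# ---------------------------------------------------------------------------
# detection


def detect_eos(masks: StainMaskSet,
               min_area_um2: float = MIN_OBJECT_AREA_UM2,
               compute_morphology: bool = True) -> list[EndocrineObject]:
    """Candidate EOs from the hormone-positivity masks.

    Connected components (8-connectivity) of the union of the ``ins``
    and ``gluc`` masks; components below ``min_area_um2`` are dropped.
    Candidates are *not* yet filtered for the 40 μm² positivity rule —
    apply :func:`filter_by_positivity` next.  Objects touching the
    image border are retained but flagged.
    """
    ins = masks.masks.get("ins")
    gluc = masks.masks.get("gluc")
    if ins is None and gluc is None:
        return []
    union = np.zeros(masks.shape, dtype=bool)
    if ins is not None:
        union |= ins
    if gluc is not None:
        union |= gluc
    labels = cc_label(union, connectivity=2)
    px = masks.px_area_um2
    mpp = masks.microns_per_px
    h, w = masks.shape
    out: list[EndocrineObject] = []
    for prop in regionprops(labels):
        area = prop.area * px
        if area < min_area_um2:
            continue
        r0, c0, r1, c1 = prop.bbox
        sub = labels[r0:r1, c0:c1] == prop.label
        ins_area = float((sub & ins[r0:r1, c0:c1]).sum()) * px if ins is not None else 0.0
        gluc_area = float((sub & gluc[r0:r1, c0:c1]).sum()) * px if gluc is not None else 0.0
        cy, cx = prop.centroid
        obj = EndocrineObject(
            object_id=f"eo_{prop.label:04d}",
            area_um2=float(area),
            ins_area_um2=ins_area,
            gluc_area_um2=gluc_area,
            eo_bin=assign_bin(area),
            size_class="",
            content_class="",
            centroid=((cx + 0.5) * mpp, (cy + 0.5) * mpp),
            bbox=(c0 * mpp, r0 * mpp, c1 * mpp, r1 * mpp),
            touches_border=(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
        )
        obj.size_class = size_class(obj.eo_bin)
        if compute_morphology:
            ring = _object_polygon(sub, (r0, c0), mpp)
            if ring is not None:
                obj.polygon = ring
                try:
                    shape = morphology(ring)
                except ValueError:
                    shape = None
                if shape is not None:
                    obj.circularity = shape["circularity"]
                    obj.solidity = shape["solidity"]
                    obj.feret_max_um = shape["feret_max"]
                    obj.feret_min_um = shape["feret_min"]
                    obj.equivalent_diameter_um = shape["equivalent_diameter"]
        out.append(obj)
    return out


def filter_by_positivity(candidates: list[EndocrineObject],
                         threshold_um2: float = POSITIVITY_AREA_UM2
                         ) -> list[EndocrineObject]:
    """Artifact filter: retain iff ins or gluc labeled area > 40 μm².

    Retained objects get their content class assigned from the
    per-hormone positivity flags.
    """
    kept = []
    for obj in candidates:
        if obj.ins_area_um2 > threshold_um2 or obj.gluc_area_um2 > threshold_um2:
            obj.content_class = classify_content(
                obj.ins_area_um2, obj.gluc_area_um2, threshold_um2)
            kept.append(obj)
    return kept


# ---------------------------------------------------------------------------
# section profile


@dataclass
class SectionProfile:
    """Per-section EO collection plus derived per-bin metrics."""

    section_id: str
    donor_id: str
    region: str
    tissue_area_mm2: float
    objects: list[EndocrineObject]
    metrics: pd.Series  # flat metric vector (see build_section_profile)

    @property
    def endocrine_area_um2(self) -> float:
        return float(sum(o.area_um2 for o in self.objects))


def _metric_index() -> list[str]:
    names = ["eo_density_per_mm2", "pct_endocrine_area"]
    for cls in CONTENT_CLASSES:
        names.append(f"count_share_{cls}")
        names.append(f"area_share_{cls}")
    for b in range(MAX_BIN + 1):
        names.append(f"density_bin{b}_per_mm2")
        for cls in CONTENT_CLASSES:
            names.append(f"density_bin{b}_{cls}_per_mm2")
        names.append(f"pct_count_bin{b}")
        names.append(f"pct_area_bin{b}")
        names.append(f"pct_tissue_ins_bin{b}")
        names.append(f"pct_tissue_gluc_bin{b}")
    for sc in SIZE_CLASSES:
        names.append(f"density_{sc}_per_mm2")
        for cls in CONTENT_CLASSES:
            names.append(f"density_{sc}_{cls}_per_mm2")
    return names


METRIC_INDEX = _metric_index()


def build_section_profile(objects: list[EndocrineObject],
                          tissue_area_mm2: float,
                          section_id: str = "",
                          donor_id: str = "",
                          region: str = "PO") -> SectionProfile:
    """Derive the per-section metric vector from retained objects.

    Metrics: total EO density (count/mm² of tissue), % endocrine area of
    tissue, per-class count/area shares (% of section totals), per-bin
    densities overall and by content class, per-bin % of total count and
    of total endocrine area, per-bin hormone-positive area as % of
    tissue, and small/medium/large density sums.
    """
    if tissue_area_mm2 <= 0:
        raise ValueError("tissue_area_mm2 must be positive")
    m = pd.Series(0.0, index=METRIC_INDEX)
    n = len(objects)
    tissue_um2 = tissue_area_mm2 * 1e6
    total_area = sum(o.area_um2 for o in objects)
    m["eo_density_per_mm2"] = n / tissue_area_mm2
    m["pct_endocrine_area"] = 100.0 * total_area / tissue_um2
    for o in objects:
        cls, b, sc = o.content_class, o.eo_bin, o.size_class
        m[f"count_share_{cls}"] += 100.0 / n
        m[f"area_share_{cls}"] += 100.0 * o.area_um2 / total_area
        m[f"density_bin{b}_per_mm2"] += 1.0 / tissue_area_mm2
        m[f"density_bin{b}_{cls}_per_mm2"] += 1.0 / tissue_area_mm2
        m[f"pct_count_bin{b}"] += 100.0 / n
        m[f"pct_area_bin{b}"] += 100.0 * o.area_um2 / total_area
        m[f"pct_tissue_ins_bin{b}"] += 100.0 * o.ins_area_um2 / tissue_um2
        m[f"pct_tissue_gluc_bin{b}"] += 100.0 * o.gluc_area_um2 / tissue_um2
        m[f"density_{sc}_per_mm2"] += 1.0 / tissue_area_mm2
        m[f"density_{sc}_{cls}_per_mm2"] += 1.0 / tissue_area_mm2
    return SectionProfile(section_id=section_id, donor_id=donor_id,
                          region=region, tissue_area_mm2=tissue_area_mm2,
                          objects=objects, metrics=m)


def objects_from_table(df: pd.DataFrame,
                       min_area_um2: float = MIN_OBJECT_AREA_UM2,
                       positivity_um2: float = POSITIVITY_AREA_UM2
                       ) -> list[EndocrineObject]:
    """Typed, filtered, classified EOs from a per-object area table.

    This is the imaging-bypass entry point: rows below the minimum
    object size or failing the per-hormone positivity filter are
    dropped, the rest get bin, size class and content class assigned.
    Expected columns: ``object_id, area_um2, ins_area_um2,
    gluc_area_um2`` plus optional centroid/bbox (pixel) columns.
    """
    objects = []
    for r in df.itertuples(index=False):
        area = float(r.area_um2)
        ins = float(r.ins_area_um2)
        gluc = float(r.gluc_area_um2)
        if area < min_area_um2:
            continue
        if not (ins > positivity_um2 or gluc > positivity_um2):
            continue
        b = assign_bin(area)
        cx = float(getattr(r, "centroid_x_px", 0.0))
        cy = float(getattr(r, "centroid_y_px", 0.0))
        objects.append(EndocrineObject(
            object_id=str(r.object_id), area_um2=area,
            ins_area_um2=ins, gluc_area_um2=gluc,
            eo_bin=b, size_class=size_class(b),
            content_class=classify_content(ins, gluc),
            centroid=(cx, cy),
            bbox=(float(getattr(r, "bbox_x0", 0.0)),
                  float(getattr(r, "bbox_y0", 0.0)),
                  float(getattr(r, "bbox_x1", 0.0)),
                  float(getattr(r, "bbox_y1", 0.0)))))
    return objects


def objects_to_frame(objects: list[EndocrineObject]) -> pd.DataFrame:
    """Flat table (one row per EO) for CSV export."""
    rows = []
    for o in objects:
        rows.append({
            "object_id": o.object_id,
            "area_um2": o.area_um2,
            "ins_area_um2": o.ins_area_um2,
            "gluc_area_um2": o.gluc_area_um2,
            "eo_bin": o.eo_bin,
            "size_class": o.size_class,
            "content_class": o.content_class,
            "centroid_x_um": o.centroid[0],
            "centroid_y_um": o.centroid[1],
            "bbox_x0_um": o.bbox[0], "bbox_y0_um": o.bbox[1],
            "bbox_x1_um": o.bbox[2], "bbox_y1_um": o.bbox[3],
            "circularity": o.circularity,
            "solidity": o.solidity,
            "feret_max_um": o.feret_max_um,
            "feret_min_um": o.feret_min_um,
            "equivalent_diameter_um": o.equivalent_diameter_um,
            "touches_border": o.touches_border,
            **o.extra,
        })
    return pd.DataFrame(rows)
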