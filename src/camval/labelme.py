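"""LabelMe-style polygon annotations: parsing, writing, rasterization.

Only ``polygon`` shapes are accepted (other shape types are rejected by
name).  Rasterization sets a pixel iff its center ``(col + 0.5, row + 0.5)``
lies inside any polygon under the even-odd (crossing-number) rule; the
union over polygons is taken.  An ``all_touched`` alternative that also
sets pixels whose cell intersects a polygon edge is available behind a
flag.  Vertices outside the image bounds are clipped with a warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError

_VALID_RULES = ("center_even_odd", "all_touched")


@dataclass(frozen=True)
class Polygon:
    label: str
    vertices: tuple[tuple[float, float], ...]  # (x, y) pixel coordinates

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ParseError("points", "polygon needs at least 3 vertices")


@dataclass
class PolygonAnnotation:
    image_path: str
    image_size: tuple[int, int]  # (height, width)
    polygons: list[Polygon]
    annotator_id: str = ""


def read_labelme(source: str | Path | dict, annotator_id: str = "") -> PolygonAnnotation:
    """Parse a LabelMe-style JSON document (path or already-loaded dict)."""
    if isinstance(source, (str, Path)):
        try:
            doc = json.loads(Path(source).read_text())
        except json.JSONDecodeError as e:
            raise ParseError("document", f"malformed JSON: {e}") from e
    else:
        doc = source
    if "imageHeight" not in doc or "imageWidth" not in doc:
        raise ParseError("imageHeight/imageWidth", "missing image size")
    h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
    polys = []
    for i, shape in enumerate(doc.get("shapes", [])):
        stype = shape.get("shape_type", "polygon")
        if stype != "polygon":
            raise ParseError("shape_type", f"shape {i} has type {stype!r}; "
                             "only 'polygon' is supported")
        pts = shape.get("points", [])
        if len(pts) < 3:
            raise ParseError("points", f"shape {i} has {len(pts)} vertices (< 3)")
        polys.append(Polygon(label=str(shape.get("label", "")),
                             vertices=tuple((float(x), float(y)) for x, y in pts)))
    return PolygonAnnotation(image_path=str(doc.get("imagePath", "")),
                             image_size=(h, w), polygons=polys,
                             annotator_id=annotator_id)


def write_labelme(ann: PolygonAnnotation, path: str | Path | None = None) -> dict:
    doc = {
        "version": "5.1.1",
        "imagePath": ann.image_path,
        "imageHeight": ann.image_size[0],
        "imageWidth": ann.image_size[1],
        "imageData": None,
        "shapes": [
            {"label": p.label, "shape_type": "polygon", "group_id": None,
             "points": [[x, y] for x, y in p.vertices], "flags": {}}
            for p in ann.polygons
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def _even_odd_inside(px: np.ndarray, py: np.ndarray,
                     verts: np.ndarray) -> np.ndarray:
    """Crossing-number point-in-polygon test for arrays of points."""
    inside = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(invalid="ignore"):
            x_at = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
        inside ^= crosses & (px < x_at)
    return inside


def rasterize(ann: PolygonAnnotation, image_size: tuple[int, int] | None = None,
              rule: str = "center_even_odd") -> np.ndarray:
    """Union of all polygons as a binary mask."""
    if rule not in _VALID_RULES:
        raise ParseError("rule", f"unknown rasterization rule {rule!r}")
    h, w = image_size or ann.image_size
    if image_size is not None and tuple(image_size) != tuple(ann.image_size):
        raise ParseError("image_size",
                         f"requested {image_size} but annotation says {ann.image_size}")
    mask = np.zeros((h, w), dtype=bool)
    if not ann.polygons:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    cx = xx + 0.5
    cy = yy + 0.5
    for poly in ann.polygons:
        verts = np.array(poly.vertices, dtype=float)
        if (verts[:, 0].min() < 0 or verts[:, 1].min() < 0
                or verts[:, 0].max() > w or verts[:, 1].max() > h):
            warnings.warn(f"polygon {poly.label!r} has out-of-bounds vertices; "
                          "clipping to image", stacklevel=2)
            verts[:, 0] = np.clip(verts[:, 0], 0, w)
            verts[:, 1] = np.clip(verts[:, 1], 0, h)
        inside = _even_odd_inside(cx, cy, verts)
        if rule == "all_touched":
            # also set cells whose bounding box an edge passes through
            n = len(verts)
            for i in range(n):
                x1, y1 = verts[i]
                x2, y2 = verts[(i + 1) % n]
                steps = int(max(abs(x2 - x1), abs(y2 - y1)) * 2) + 1
                ts = np.linspace(0.0, 1.0, steps)
                ex = np.clip((x1 + ts * (x2 - x1)).astype(int), 0, w - 1)
                ey = np.clip((y1 + ts * (y2 - y1)).astype(int), 0, h - 1)
                inside[ey, ex] = True
        mask |= inside
    return mask


def mask_to_annotation(mask: np.ndarray, image_path: str = "",
                       annotator_id: str = "", label: str = "feature") -> PolygonAnnotation:
    """Trace mask component contours into polygons (approximate inverse)."""
    from skimage import measure

    h, w = mask.shape
    polys = []
    for contour in measure.find_contours(mask.astype(float), 0.5):
        # contours are (row, col); convert to (x, y)
        verts = [(float(c), float(r)) for r, c in contour[:-1]]
        if len(verts) >= 3:
            polys.append(Polygon(label=label, vertices=tuple(verts)))
    return PolygonAnnotation(image_path=image_path, image_size=(h, w),
                             polygons=polys, annotator_id=annotator_id)
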