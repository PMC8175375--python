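"""ROI definition, JSON serialization, and rasterization to pixel masks.

Three shapes are supported — circle, rectangle, and freehand polygon —
mirroring the shapes an operator draws on an intraoperative CEUS frame.

Coordinate convention (declared once, enforced everywhere): 0-based,
row-major pixel indices; a pixel's reference point is its *center*, so
pixel (r, c) occupies the unit square centered on the point (r, c).
Boundary pixels are included: a pixel center at distance exactly equal
to the circle radius, or exactly on a polygon edge, belongs to the mask.
ROIs partially outside the frame are clipped silently; an ROI whose mask
is empty after clipping is an error.

JSON schema (top-level list, one record per ROI)::

    [{"label": "artery",       "shape": "circle",    "center": [r, c], "radius": x},
     {"label": "tumor",        "shape": "rectangle", "bounds": [top, left, height, width]},
     {"label": "white_matter", "shape": "polygon",   "vertices": [[r, c], ...]}]
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

KNOWN_LABELS = ("artery", "tumor", "white_matter", "grey_matter")

_EDGE_EPS = 1e-9


@dataclass
class Roi:
    """A labeled geometric region rasterizable to a pixel mask.

    Exactly one geometry is populated according to ``shape_kind``:

    - ``circle``: ``center`` (row, col) and ``radius`` (pixels, > 0)
    - ``rectangle``: ``bounds`` (top_row, left_col, height, width) with
      height, width >= 1; the half-open index block
      [top, top+height) x [left, left+width)
    - ``polygon``: ``vertices``, an ordered list of >= 3 (row, col) pairs

    ``label`` is a tissue tag: one of artery / tumor / white_matter /
    grey_matter, or free text ``other:<text>``.
    """

    label: str
    shape_kind: str
    center: tuple[float, float] | None = None
    radius: float | None = None
    bounds: tuple[float, float, float, float] | None = None
    vertices: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.shape_kind == "circle":
            if self.center is None or self.radius is None:
                raise ValueError("circle ROI requires center and radius")
            if not self.radius > 0:
                raise ValueError(f"circle radius must be > 0, got {self.radius}")
        elif self.shape_kind == "rectangle":
            if self.bounds is None:
                raise ValueError("rectangle ROI requires bounds")
            _, _, h, w = self.bounds
            if h < 1 or w < 1:
                raise ValueError(f"rectangle height/width must be >= 1, got {h}x{w}")
        elif self.shape_kind == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                n = 0 if self.vertices is None else len(self.vertices)
                raise ValueError(f"polygon requires >= 3 vertices, got {n}")
        else:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")


@dataclass
class RoiMask:
    """A 2-D boolean mask plus its pixel count (always >= 1)."""

    mask: np.ndarray
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("RoiMask must cover at least one pixel")


def _point_on_segment(pr: float, pc: float, a, b) -> bool:
    ar, ac = a
    br, bc = b
    cross = (br - ar) * (pc - ac) - (bc - ac) * (pr - ar)
    if abs(cross) > _EDGE_EPS * max(1.0, abs(br - ar) + abs(bc - ac)):
        return False
    dot = (pr - ar) * (br - ar) + (pc - ac) * (bc - ac)
    sq_len = (br - ar) ** 2 + (bc - ac) ** 2
    return -_EDGE_EPS <= dot <= sq_len + _EDGE_EPS


def point_in_polygon(pr: float, pc: float, vertices: Sequence[tuple[float, float]]) -> bool:
    """Even-odd membership test with boundary points included.

    Casts a ray in the +col direction and counts edge crossings; a point
    lying exactly on an edge or vertex is inside by convention.
    """
    n = len(vertices)
    for i in range(n):
        if _point_on_segment(pr, pc, vertices[i], vertices[(i + 1) % n]):
            return True
    inside = False
    for i in range(n):
        ar, ac = vertices[i]
        br, bc = vertices[(i + 1) % n]
        # half-open rule on the row interval avoids double-counting vertices
        if (ar > pr) != (br > pr):
            c_cross = ac + (pr - ar) / (br - ar) * (bc - ac)
            if pc < c_cross:
                inside = not inside
    return inside


def rasterize(roi: Roi, frame_shape: tuple[int, int]) -> RoiMask:
    """Rasterize an ROI into a boolean mask over pixel centers.

    Circle: pixels whose centers lie at Euclidean distance <= radius
    from the center.  Rectangle: the half-open index block.  Polygon:
    even-odd rule over pixel centers, boundary included.  The mask is
    clipped to the frame; an ROI entirely outside the frame raises.
    """
    rows, cols = frame_shape
    if rows < 1 or cols < 1:
        raise ValueError(f"frame_shape must be positive, got {frame_shape}")
    mask = np.zeros((rows, cols), dtype=bool)

    if roi.shape_kind == "circle":
        cr, cc = roi.center
        rr, cc_grid = np.mgrid[0:rows, 0:cols]
        dist2 = (rr - cr) ** 2 + (cc_grid - cc) ** 2
        mask = dist2 <= roi.radius**2 + _EDGE_EPS
    elif roi.shape_kind == "rectangle":
        top, left, h, w = roi.bounds
        r0 = max(int(np.ceil(top)), 0)
        c0 = max(int(np.ceil(left)), 0)
        r1 = min(int(np.ceil(top + h)), rows)
        c1 = min(int(np.ceil(left + w)), cols)
        if r1 > r0 and c1 > c0:
            mask[r0:r1, c0:c1] = True
    else:  # polygon
        verts = [(float(r), float(c)) for r, c in roi.vertices]
        vr = [v[0] for v in verts]
        vc = [v[1] for v in verts]
        r0 = max(int(np.floor(min(vr))), 0)
        r1 = min(int(np.ceil(max(vr))) + 1, rows)
        c0 = max(int(np.floor(min(vc))), 0)
        c1 = min(int(np.ceil(max(vc))) + 1, cols)
        for r in range(r0, r1):
            for c in range(c0, c1):
                if point_in_polygon(float(r), float(c), verts):
                    mask[r, c] = True

    count = int(mask.sum())
    if count == 0:
        raise ValueError(
            f"ROI {roi.label!r} ({roi.shape_kind}) rasterizes to zero pixels "
            f"within frame {frame_shape}"
        )
    return RoiMask(mask=mask, pixel_count=count)


def _roi_to_record(roi: Roi) -> dict:
    rec: dict = {"label": roi.label, "shape": roi.shape_kind}
    if roi.shape_kind == "circle":
        rec["center"] = [float(roi.center[0]), float(roi.center[1])]
        rec["radius"] = float(roi.radius)
    elif roi.shape_kind == "rectangle":
        rec["bounds"] = [float(v) for v in roi.bounds]
    else:
        rec["vertices"] = [[float(r), float(c)] for r, c in roi.vertices]
    return rec


def _record_to_roi(rec: dict, index: int) -> Roi:
    try:
        label = rec["label"]
        shape = rec["shape"]
        if shape == "circle":
            return Roi(label=label, shape_kind="circle",
                       center=tuple(rec["center"]), radius=rec["radius"])
        if shape == "rectangle":
            return Roi(label=label, shape_kind="rectangle", bounds=tuple(rec["bounds"]))
        if shape == "polygon":
            return Roi(label=label, shape_kind="polygon",
                       vertices=[tuple(v) for v in rec["vertices"]])
        raise ValueError(f"unknown shape {shape!r}")
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid ROI record at index {index}: {exc}") from exc


def parse_rois(path: str | Path) -> list[Roi]:
    """Read an ROI list from JSON.

    Duplicate labels are allowed (an operator may draw several ROIs in
    one tissue) but trigger a warning.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed ROI JSON {path}: {exc}") from exc
    if not isinstance(doc, list):
        raise ValueError(f"ROI JSON {path} must contain a top-level list")
    rois = [_record_to_roi(rec, i) for i, rec in enumerate(doc)]
    labels = [r.label for r in rois]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        warnings.warn(f"duplicate ROI labels in {path}: {sorted(dupes)}", stacklevel=2)
    return rois


def serialize_rois(rois: Sequence[Roi], path: str | Path) -> None:
    """Write an ROI list as JSON; round-trips losslessly through parse_rois."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([_roi_to_record(r) for r in rois], fh, indent=1)
        fh.write("\n")
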