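"""Region-of-interest polygons in pixel coordinates.

ROIs mirror the freeform annotations drawn on scanned slides: an ordered
vertex list in (x, y) pixel coordinates. Pixel membership uses the
pixel-center convention — pixel (row i, col j) belongs to the ROI iff the
point (j, i) lies inside the polygon (even-odd rule), with 0-based
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path


@dataclass(frozen=True)
class ROIPolygon:
    """A simple (non-self-intersecting) polygon ROI.

    Parameters
    ----------
    vertices : (n, 2) array-like
        Ordered ``[x, y]`` vertices in pixel coordinates; ``n >= 3``.
    """

    vertices: np.ndarray = field()

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ROI polygon needs an (n>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)
        if self.signed_area_px == 0:
            raise ValueError("ROI polygon has zero area")

    @property
    def signed_area_px(self) -> float:
        """Shoelace area in pixel² (positive for CCW vertex order)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def polygon_area_mm2(self, pixel_size_um: float) -> float:
        """Geometric (shoelace) polygon area in mm²."""
        return abs(self.signed_area_px) * pixel_size_um**2 / 1e6

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean membership mask of the given (H, W) image shape.

        A pixel is in the ROI iff its center lies inside the polygon.
        """
        h, w = shape[:2]
        # restrict the point-in-polygon test to the bounding box
        xmin = max(int(np.floor(self.vertices[:, 0].min())), 0)
        xmax = min(int(np.ceil(self.vertices[:, 0].max())) + 1, w)
        ymin = max(int(np.floor(self.vertices[:, 1].min())), 0)
        ymax = min(int(np.ceil(self.vertices[:, 1].max())) + 1, h)
        out = np.zeros((h, w), dtype=bool)
        if xmin >= xmax or ymin >= ymax:
            return out
        xs, ys = np.meshgrid(np.arange(xmin, xmax), np.arange(ymin, ymax))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        inside = Path(self.vertices).contains_points(pts)
        out[ymin:ymax, xmin:xmax] = inside.reshape(ymax - ymin, xmax - xmin)
        return out

    def pixel_area_mm2(self, shape: tuple[int, int], pixel_size_um: float) -> float:
        """ROI area in mm² counted as member pixels × pixel area.

        This is the area used for densities: it tiles exactly (two disjoint
        halves of an ROI sum to the whole), unlike the shoelace area.
        """
        return int(self.mask(shape).sum()) * pixel_size_um**2 / 1e6

    @staticmethod
    def rectangle(x0: float, y0: float, x1: float, y1: float) -> "ROIPolygon":
        """Axis-aligned rectangle covering pixel centers in [x0,x1)×[y0,y1)."""
        return ROIPolygon(np.array(
            [[x0 - 0.5, y0 - 0.5], [x1 - 0.5, y0 - 0.5],
             [x1 - 0.5, y1 - 0.5], [x0 - 0.5, y1 - 0.5]]))


def load_rois(path) -> list[ROIPolygon]:
    """Read ROIs from JSON: a list of polygons, each an [[x, y], ...] array."""
    with open(path) as fh:
        data = json.load(fh)
    return [ROIPolygon(np.asarray(p, dtype=float)) for p in data]


def save_rois(rois: list[ROIPolygon], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.vertices.tolist() for r in rois], fh)
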