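"""ROI statistics on parametric maps and slice-summation liver volumetry.

Mirrors the study's manual analysis: three independent polygonal ROIs in
vessel-free parenchyma are averaged (mean of ROI means, with their SD as the
spread), the background noise ROI sits in the upper-left image corner, and
the liver volume is the sum of per-slice segmented areas times the slice
thickness, normalized to the pre-operative (day 0) volume.

A voxel belongs to a polygon iff its centre lies inside (even-odd rule);
boundary centres are included.  Because manual contouring is out of scope,
:func:`auto_place_rois` places three non-overlapping circular ROIs in the
largest vessel-free parenchyma region, deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from matplotlib.path import Path
from scipy import ndimage

from .mapfit import ParameterMap
from .phantom import LABEL_PARENCHYMA, Phantom

__all__ = [
    "ROISet",
    "VolumeSeries",
    "rasterize_polygon",
    "roi_statistic",
    "liver_volume",
    "relative_volume",
    "auto_place_rois",
    "default_background_polygon",
]


@dataclass
class ROISet:
    """Named parenchymal polygons plus one background polygon on a slice.

    Polygons are vertex lists in (row, col) voxel coordinates.
    """

    parenchyma: Dict[str, np.ndarray]
    background: np.ndarray
    slice_index: int = 0
    source_map_id: str = ""

    def to_dict(self) -> dict:
        return {
            "slice_index": self.slice_index,
            "source_map_id": self.source_map_id,
            "parenchyma": {k: np.asarray(v, dtype=float).tolist() for k, v in self.parenchyma.items()},
            "background": np.asarray(self.background, dtype=float).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROISet":
        return cls(
            parenchyma={k: np.asarray(v, dtype=float) for k, v in d["parenchyma"].items()},
            background=np.asarray(d["background"], dtype=float),
            slice_index=int(d.get("slice_index", 0)),
            source_map_id=d.get("source_map_id", ""),
        )


@dataclass
class VolumeSeries:
    """Per-day absolute (mm^3) and relative (% of day 0) liver volumes."""

    animal_id: str
    volumes_mm3: Dict[int, float]
    relative_pct: Dict[int, float] = field(default_factory=dict)


def rasterize_polygon(vertices: Sequence, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask of voxels whose centres fall inside the polygon.

    ``vertices`` are (row, col) pairs; the even-odd/center rule is applied
    with boundary centres counted as inside.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    xy = verts[:, ::-1]  # Path expects (x, y) = (col, row)
    # normalize to counter-clockwise so the boundary-inclusion radius always
    # expands outward regardless of the vertex ordering supplied
    x, y = xy[:, 0], xy[:, 1]
    signed_area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed_area < 0:
        xy = xy[::-1]
    path = Path(xy)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([cols.ravel(), rows.ravel()])
    inside = path.contains_points(pts, radius=1e-9)
    return inside.reshape(shape)


def default_background_polygon(shape: Tuple[int, int], size: int = 8) -> np.ndarray:
    """Rectangle in the upper-left image corner for noise estimation."""
    size = min(size, shape[0] - 1, shape[1] - 1)
    return np.array(
        [[0.5, 0.5], [0.5, size - 0.5], [size - 0.5, size - 0.5], [size - 0.5, 0.5]], dtype=float
    ) - 0.5


def roi_statistic(pmap: ParameterMap, rois: ROISet) -> Tuple[float, float]:
    """Mean of the per-ROI means over the parenchymal ROIs, and their SD.

    Each polygon is rasterized; within an ROI only unmasked map voxels enter
    its mean.  An ROI that rasterizes to nothing is an error; one with more
    than half of its voxels masked triggers a warning.
    """
    grid = pmap.values
    if grid.ndim != 2:
        raise ValueError("roi_statistic expects a 2-D map slice")
    means: List[float] = []
    for name, poly in rois.parenchyma.items():
        sel = rasterize_polygon(poly, grid.shape)
        n_total = int(sel.sum())
        if n_total == 0:
            raise ValueError(f"ROI {name!r} rasterizes to zero voxels")
        sel_valid = sel & pmap.mask
        n_valid = int(sel_valid.sum())
        if n_valid == 0:
            raise ValueError(f"ROI {name!r} contains no valid (unmasked) voxels")
        if n_valid < 0.5 * n_total:
            warnings.warn(f"ROI {name!r}: more than half of its voxels are masked")
        means.append(float(grid[sel_valid].mean()))
    mean = float(np.mean(means))
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return mean, sd


def liver_volume(mask_slices: np.ndarray, voxel_area_mm2: float, slice_thickness_mm: float) -> float:
    """Slice-summation volumetry: sum of per-slice areas times thickness.

    ``mask_slices`` is a binary grid (one or more slices); the result is
    voxel count x voxel area x slice thickness in mm^3.
    """
    if slice_thickness_mm <= 0:
        raise ValueError("slice thickness must be positive")
    mask = np.asarray(mask_slices).astype(bool)
    count = int(mask.sum())
    if count == 0:
        warnings.warn("empty liver mask: volume is 0")
        return 0.0
    return count * voxel_area_mm2 * slice_thickness_mm


def relative_volume(volumes_mm3: Dict[int, float], animal_id: str = "") -> VolumeSeries:
    """Normalize per-day volumes to the pre-operative (day 0) volume in percent."""
    if 0 not in volumes_mm3:
        raise ValueError("day-0 (pre-operative) volume is required for normalization")
    v0 = volumes_mm3[0]
    if v0 <= 0:
        raise ValueError("day-0 volume must be positive")
    rel = {day: 100.0 * v / v0 for day, v in volumes_mm3.items()}
    return VolumeSeries(animal_id=animal_id, volumes_mm3=dict(volumes_mm3), relative_pct=rel)


def _circle_polygon(center: Tuple[float, float], radius: float, n: int = 16) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(ang), center[1] + radius * np.cos(ang)])


def auto_place_rois(
    phantom: Phantom,
    n_rois: int = 3,
    radius_vox: float = 3.5,
    background_size: int = 8,
) -> ROISet:
    """Place ``n_rois`` non-overlapping circular ROIs in vessel-free parenchyma.

    Candidate centres are ranked by their Euclidean distance from anything
    that is not parenchyma (background or vessel), then picked greedily with
    a non-overlap constraint — a deterministic stand-in for the study's
    manual ROIs drawn "under avoidance of large vessel structures".
    """
    paren = phantom.labels == LABEL_PARENCHYMA
    dist = ndimage.distance_transform_edt(paren)
    order = np.argsort(dist, axis=None)[::-1]
    centers: List[Tuple[int, int]] = []
    for flat in order:
        d = dist.flat[flat]
        if d < radius_vox + 0.5:
            break
        r, c = np.unravel_index(flat, paren.shape)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= (2.0 * radius_vox) ** 2 for r2, c2 in centers):
            centers.append((int(r), int(c)))
        if len(centers) == n_rois:
            break
    if len(centers) < n_rois:
        raise ValueError(
            f"could not place {n_rois} vessel-free ROIs of radius {radius_vox} voxels"
        )
    rois = {f"roi{i + 1}": _circle_polygon(ctr, radius_vox) for i, ctr in enumerate(centers)}
    return ROISet(
        parenchyma=rois,
        background=default_background_polygon(phantom.labels.shape, background_size),
    )
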