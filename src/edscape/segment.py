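"""Nucleus segmentation, fixed-distance soma expansion, read assignment.

Cells are approximated by their soma: each DAPI nucleus is used as a seed
and the cell border is drawn a fixed Euclidean distance (20 px by default)
from the nucleus border, with watershed-style frontiers between neighbours
so that cells never overlap.  Reads are assigned to the cell whose label
covers their coordinate and to the named region polygon containing them
(boundary-inclusive); reads on background / outside every region keep
sentinel values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed

import shapely
from shapely.geometry import Polygon, shape

from .scene import NO_REGION

#: cell_id for reads on background pixels
UNASSIGNED = 0

DEFAULT_EXPANSION_PX = 20.0


class SegmentationError(ValueError):
    pass


@dataclass
class CellLabelMap:
    """Nucleus and cell label images plus per-cell properties.

    ``cells`` columns: cell_id, x, y (nucleus centroid), nucleus_area.
    Label 0 is background; nucleus pixels of a cell are a subset of its
    cell pixels and cells are pairwise disjoint by construction.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    cells: pd.DataFrame


def segment_nuclei(
    dapi: np.ndarray,
    min_area: float = 20.0,
    max_area: float = 10_000.0,
    min_solidity: float | None = None,
    peak_min_distance: int = 5,
) -> CellLabelMap:
    """Otsu threshold, watershed split of touching nuclei, shape filtering.

    Touching nuclei are separated by a watershed on the negated distance
    transform seeded at its local maxima.  Components outside
    ``[min_area, max_area]`` (px^2), or below ``min_solidity`` when given,
    are discarded — a reproducible proxy for shape-descriptor filtering.
    """
    if min_area >= max_area:
        raise SegmentationError("min_area must be < max_area")
    img = np.asarray(dapi, dtype=float)
    if img.ndim != 2:
        raise SegmentationError("DAPI image must be 2D")
    empty = CellLabelMap(
        nucleus_labels=np.zeros(img.shape, dtype=np.int32),
        cell_labels=np.zeros(img.shape, dtype=np.int32),
        cells=pd.DataFrame(columns=["cell_id", "x", "y", "nucleus_area"]),
    )
    if img.max() == img.min():
        return empty
    binary = img > threshold_otsu(img)
    if not binary.any():
        return empty
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance, min_distance=peak_min_distance, labels=binary, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers=markers, mask=binary)

    keep = np.zeros(img.shape, dtype=np.int32)
    rows = []
    next_id = 1
    for prop in regionprops(labels):
        if not (min_area <= prop.area <= max_area):
            continue
        if min_solidity is not None and prop.solidity < min_solidity:
            continue
        keep[labels == prop.label] = next_id
        cy, cx = prop.centroid
        rows.append(
            {"cell_id": next_id, "x": cx, "y": cy, "nucleus_area": int(prop.area)}
        )
        next_id += 1
    cells = pd.DataFrame(rows, columns=["cell_id", "x", "y", "nucleus_area"])
    return CellLabelMap(nucleus_labels=keep, cell_labels=keep.copy(), cells=cells)


def expand_cells(
    nuclei: CellLabelMap, distance: float = DEFAULT_EXPANSION_PX
) -> CellLabelMap:
    """Expand each nucleus by <= ``distance`` px (Euclidean).

    Contested pixels within reach of several nuclei go to the nearest one
    (exact Euclidean distance transform), drawing watershed-like frontiers;
    cells remain pairwise disjoint and every cell pixel lies within
    ``distance`` of its own nucleus.
    """
    if distance < 0:
        raise SegmentationError("expansion distance must be >= 0")
    cell_labels = expand_labels(nuclei.nucleus_labels, distance=distance)
    return CellLabelMap(
        nucleus_labels=nuclei.nucleus_labels,
        cell_labels=cell_labels,
        cells=nuclei.cells.copy(),
    )


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def load_regions(path) -> dict[str, Polygon]:
    """Load named ROI polygons from a GeoJSON FeatureCollection.

    Requires simple polygons with unique ``name`` properties; overlapping
    polygons are rejected (the anatomical ROIs are disjoint areas).
    """
    data = json.loads(Path(path).read_text())
    regions: dict[str, Polygon] = {}
    for feat in data.get("features", []):
        name = feat.get("properties", {}).get("name")
        if not name:
            raise SegmentationError("region feature without a 'name' property")
        if name in regions:
            raise SegmentationError(f"duplicate region name {name!r}")
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise SegmentationError(f"region {name!r} is not a Polygon")
        regions[name] = geom
    validate_regions(regions)
    return regions


def validate_regions(regions: dict[str, Polygon]) -> None:
    names = list(regions)
    for name in names:
        poly = regions[name]
        if not poly.is_valid or not poly.is_simple:
            raise SegmentationError(f"region {name!r} is not a simple polygon")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = regions[a].intersection(regions[b])
            if inter.area > 1e-9:
                raise SegmentationError(f"regions {a!r} and {b!r} overlap")


def save_regions(regions: dict[str, Polygon], path) -> None:
    feats = []
    for name, poly in regions.items():
        feats.append(
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": json.loads(shapely.to_geojson(poly)),
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=1)
    )


def assign_regions(
    x: np.ndarray, y: np.ndarray, regions: dict[str, Polygon]
) -> np.ndarray:
    """Region name per point (boundary-inclusive), NONE outside all polygons."""
    out = np.full(len(x), NO_REGION, dtype=object)
    if not regions:
        return out
    pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    for name, poly in regions.items():
        inside = shapely.covers(poly, pts)
        out[inside & (out == NO_REGION)] = name
    return out


def assign_reads(
    reads: pd.DataFrame,
    cells: CellLabelMap,
    regions: dict[str, Polygon] | None = None,
) -> pd.DataFrame:
    """Assign each read to a cell (label at its pixel) and a region polygon.

    Reads on background pixels get ``cell_id`` = :data:`UNASSIGNED` (0);
    reads outside every polygon get region :data:`NO_REGION`.  Raises when
    any read coordinate falls outside the label image, listing the
    offending spot_ids.
    """
    out = reads.copy()
    h, w = cells.cell_labels.shape
    xi = np.rint(out["x"].to_numpy(dtype=float)).astype(int)
    yi = np.rint(out["y"].to_numpy(dtype=float)).astype(int)
    bad = (xi < 0) | (yi < 0) | (xi >= w) | (yi >= h)
    if bad.any():
        ids = out.loc[bad, "spot_id"].tolist()
        raise SegmentationError(f"read coordinates outside image for spots {ids}")
    out["cell_id"] = cells.cell_labels[yi, xi].astype(int)
    out["region"] = assign_regions(
        out["x"].to_numpy(dtype=float), out["y"].to_numpy(dtype=float), regions or {}
    )
    return out
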