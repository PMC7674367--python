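"""The ten morphometric descriptors, neighbour counts and cell typing.

Descriptors span three domains.  Size: area (µm²), perimeter (µm), major
and minor axis length (µm).  Regularity, all dimensionless in [0, 1]:
solidity (area / convex-hull area), extent (area / bounding-box area),
inverse aspect ratio (minor / major) and convex circularity
(4π · convex area / convex perimeter², computed on the hull so that ragged
boundaries cannot push it past 1).  Density: the number of neighbour cells
within 50 µm and within 100 µm of the cell centre.

Cell typing is layer-aware: the Purkinje monolayer holds Purkinje somata;
the granular layer splits into granules (major axis up to 15 µm) and
larger Golgi type II neurons (over 15 µm); the molecular layer splits into
stellate-like (smaller, mean major axis near 11 µm) and basket-like
(larger, near 19.5 µm) interneurons, with a data-driven two-means split.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure
from skimage.morphology import convex_hull_image

from . import records
from .detect import DetectedCell


def _ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation to the ellipse perimeter (semi-axes a, b)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def compute_descriptors_ellipse(major_um: float, minor_um: float) -> dict:
    """Closed-form size and regularity descriptors of an ellipse.

    ``major_um``/``minor_um`` are full axis lengths.  An ellipse is its own
    convex hull, fills π/4 of an axis-aligned bounding box, and has
    solidity 1 by construction.
    """
    if major_um <= 0 or minor_um <= 0:
        raise ValueError("degenerate boundary: axes must be positive")
    if minor_um > major_um:
        major_um, minor_um = minor_um, major_um
    a, b = major_um / 2.0, minor_um / 2.0
    area = math.pi * a * b
    perim = _ramanujan_perimeter(a, b)
    return {
        "area_um2": area,
        "perimeter_um": perim,
        "major_um": major_um,
        "minor_um": minor_um,
        "solidity": 1.0,
        "extent": math.pi / 4.0,
        "inv_ar": minor_um / major_um,
        "convex_circ": min(1.0, 4 * math.pi * area / perim**2),
    }


def convex_circularity(mask: np.ndarray) -> float:
    """4π · convex area / convex perimeter², from the polygon hull.

    The hull polygon through the pixel centres gives a *consistent*
    area/perimeter pair, so the isoperimetric inequality bounds the value
    by 1 for any shape — rasterized hull estimates do not, which is why
    this quantity replaces plain circularity on ragged masks.
    """
    from scipy.spatial import ConvexHull

    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) < 3:
        return 1.0
    try:
        hull = ConvexHull(pts)
    except Exception:  # collinear points
        return 1.0
    if hull.area <= 0:
        return 1.0
    return min(1.0, 4 * math.pi * hull.volume / hull.area**2)


def compute_descriptors_mask(mask: np.ndarray, scale_um_per_px: float = 1.0) -> dict:
    """Size and regularity descriptors of a binary pixel mask.

    Axis lengths come from the normalised second central moments;
    perimeters use the Crofton estimator (naive edge counting would
    overestimate by up to 4/π and break the circularity bound ≤ 1).
    """
    mask = np.asarray(mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < 5:
        raise ValueError("degenerate boundary: fewer than 5 pixels")
    scale = scale_um_per_px
    rp = measure.regionprops(mask.astype(np.uint8))[0]
    if rp.axis_minor_length <= 0:
        raise ValueError("degenerate boundary: zero minor axis")
    # pixel-centre hull: the corner-offset variant systematically inflates
    # hull area and would push solidity of convex shapes below 1
    hull = convex_hull_image(mask, offset_coordinates=False)
    hull_area = float(hull.sum()) * scale**2
    area = n_px * scale**2
    r0, c0, r1, c1 = rp.bbox
    bbox_area = (r1 - r0) * (c1 - c0) * scale**2
    return {
        "area_um2": area,
        "perimeter_um": float(measure.perimeter_crofton(mask, directions=4)) * scale,
        "major_um": rp.axis_major_length * scale,
        "minor_um": rp.axis_minor_length * scale,
        "solidity": min(1.0, area / hull_area),
        "extent": min(1.0, area / bbox_area),
        "inv_ar": rp.axis_minor_length / rp.axis_major_length,
        "convex_circ": convex_circularity(mask),
    }


def compute_descriptors(boundary, scale_um_per_px: float = 1.0) -> dict:
    """Dispatch on the boundary representation: mask array or (major, minor)."""
    if isinstance(boundary, np.ndarray):
        return compute_descriptors_mask(boundary, scale_um_per_px)
    major, minor = boundary
    return compute_descriptors_ellipse(major, minor)


def neighbor_counts(xy_um: np.ndarray, radii_um: tuple[float, ...] = (50.0, 100.0),
                    section: np.ndarray | None = None) -> np.ndarray:
    """Neighbours within each radius of every cell, excluding the cell itself.

    ``section`` optionally assigns each cell to a tissue section; neighbours
    are then counted within the same section only.  Returns an array of
    shape ``(n_cells, len(radii))``.
    """
    xy_um = np.asarray(xy_um, dtype=float)
    if xy_um.ndim != 2 or len(xy_um) == 0:
        raise ValueError("need at least one centroid")
    out = np.zeros((len(xy_um), len(radii_um)), dtype=int)
    groups = ([np.arange(len(xy_um))] if section is None else
              [np.flatnonzero(np.asarray(section) == s)
               for s in np.unique(section)])
    for idx in groups:
        tree = cKDTree(xy_um[idx])
        for j, r in enumerate(radii_um):
            counts = tree.query_ball_point(xy_um[idx], r, return_length=True)
            out[idx, j] = counts - 1  # drop self
    return out


def assign_cell_type(layer: str, major_axis_um: float,
                     molecular_split_um: float = 15.0) -> str:
    """Layer-aware typing from the major axis length.

    Granular layer: granules up to 15 µm, Golgi-like above.  Molecular
    layer: stellate-like up to the molecular split, basket-like above.
    """
    if layer == "purkinje":
        return "purkinje"
    if layer == "granular":
        return "granule" if major_axis_um <= 15.0 else "golgi"
    if layer == "molecular":
        return "stellate" if major_axis_um <= molecular_split_um else "basket"
    raise ValueError(f"unknown layer '{layer}'")


def fit_molecular_split(major_axes_um, default_um: float = 15.0) -> float:
    """Two-means split of molecular-layer major axes (stellate vs basket).

    The exact 1-D two-means partition is found by scanning all split points
    of the sorted sample; the returned cutoff is the midpoint of the two
    cluster means.  Degenerate samples (fewer than 10 cells, or no spread)
    fall back to the fixed default with a warning.
    """
    values = np.sort(np.asarray(major_axes_um, dtype=float))
    if len(values) < 10:
        warnings.warn("fewer than 10 molecular cells; using the default split")
        return default_um
    if values[0] == values[-1]:
        warnings.warn("no spread in major axes; using the default split")
        return default_um
    n = len(values)
    csum = np.cumsum(values)
    total = csum[-1]
    best_sse, best_i = np.inf, 1
    for i in range(1, n):
        m1 = csum[i - 1] / i
        m2 = (total - csum[i - 1]) / (n - i)
        sse = (np.sum((values[:i] - m1) ** 2) + np.sum((values[i:] - m2) ** 2))
        if sse < best_sse:
            best_sse, best_i = sse, i
    m1 = csum[best_i - 1] / best_i
    m2 = (total - csum[best_i - 1]) / (n - best_i)
    return float((m1 + m2) / 2.0)


def measure_cells(detections: list[DetectedCell], scale_um_per_px: float = 1.0,
                  animal_id: str = "A00", population: str = "M",
                  molecular_split_um: float | None = None,
                  section: np.ndarray | None = None) -> pd.DataFrame:
    """Build the cell-record table for one slide's detections.

    Computes size/regularity descriptors from each cell's boundary (mask or
    fitted ellipse), neighbour counts over the detected centroids, and the
    layer-aware cell type.  When ``molecular_split_um`` is None the
    molecular split is fitted from the data (two-means), falling back to
    15 µm for small samples.
    """
    rows = []
    kept: list[DetectedCell] = []
    for cell in detections:
        try:
            if cell.mask is not None:
                desc = compute_descriptors_mask(cell.mask, scale_um_per_px)
            else:
                desc = compute_descriptors_ellipse(cell.major_um, cell.minor_um)
        except ValueError:
            continue
        rows.append(desc)
        kept.append(cell)
    if not rows:
        return pd.DataFrame(columns=records.RECORD_COLUMNS)

    xy = np.array([[c.x_um, c.y_um] for c in kept])
    counts = neighbor_counts(xy, (50.0, 100.0), section=section)
    df = pd.DataFrame(rows)
    df["ngb50"] = counts[:, 0]
    df["ngb100"] = counts[:, 1]
    df["cell_id"] = [c.id for c in kept]
    df["animal_id"] = animal_id
    df["population"] = population
    df["layer"] = [c.layer for c in kept]

    if molecular_split_um is None:
        mol = df.loc[df["layer"] == "molecular", "major_um"]
        molecular_split_um = fit_molecular_split(mol) if len(mol) else 15.0
    df["cell_type"] = [
        assign_cell_type(l, m, molecular_split_um) if l is not None else "granule"
        for l, m in zip(df["layer"], df["major_um"])
    ]
    return df[records.RECORD_COLUMNS]
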