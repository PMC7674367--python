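"""Automatic cell identification on Nissl-like grayscale histology.

The detection pipeline separates stained somata from background with a
local space-varying (moving-average) threshold, partitions the slide into
dense and sparse regions, triages connected components into single small
cells, Purkinje cells, clusters of touching cells and rejects, and splits
each cluster by fitting a bi-dimensional Gaussian mixture — one mode per
local intensity maximum — to the polarity-corrected sub-image by
non-linear least squares.  The fitted covariances give both the centre and
the extent of every cell in the clump.

Coordinates are 0-based, ``(x, y) = (column, row)``, pixel centres at
integer indices, physical position = index × scale (µm per pixel).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import measure
from skimage.feature import peak_local_max
from skimage.morphology import convex_hull_image


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SlideImage:
    """A single-channel slide: intensity raster in [0, 1] plus physical scale.

    ``cells_dark`` records the stain polarity: Nissl-stained somata are
    darker than background.
    """

    image: np.ndarray
    scale_um_per_px: float = 1.0
    cells_dark: bool = True

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("slide image must be a 2-D array")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("slide image contains non-finite values")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be positive")

    @property
    def signal(self) -> np.ndarray:
        """Polarity-corrected intensity: cells bright, background dark."""
        return 1.0 - self.image if self.cells_dark else self.image


@dataclass
class ForegroundObject:
    """One 8-connected component of the thresholded foreground."""

    label: int
    mask: np.ndarray              # boolean crop, tight bounding box
    bbox_origin: tuple[int, int]  # (row, col) of the crop origin
    centroid_xy_um: tuple[float, float]
    area_um2: float
    eccentricity: float
    solidity: float
    convex_circularity: float
    mean_intensity: float


@dataclass
class TriageRules:
    """Thresholds classifying foreground objects by area/shape.

    Defaults derive from the printed archetype geometries (granules around
    83 µm², Purkinje somata around 2500 µm²); every threshold is a config
    knob because the original cutoffs are not published.
    """

    single_area_min_um2: float = 20.0
    single_area_max_um2: float = 400.0
    single_solidity: float = 0.88
    purkinje_area_min_um2: float = 800.0
    purkinje_circularity: float = 0.7
    purkinje_solidity_floor: float = 0.75
    purkinje_solidity_intercept: float = 0.95
    purkinje_solidity_slope_per_um2: float = 1e-5  # solidity floor decreases with area
    reject_area_um2: float = 20.0

    def purkinje_solidity_at(self, area_um2: float) -> float:
        return max(
            self.purkinje_solidity_floor,
            self.purkinje_solidity_intercept
            - self.purkinje_solidity_slope_per_um2 * area_um2,
        )


@dataclass
class ClusterFit:
    """A fitted bi-dimensional Gaussian mixture for one clump sub-image.

    Each of the ``n_modes`` Gaussians has amplitude ``alpha_i``, centre
    ``c_i`` (µm, sub-image frame) and a symmetric positive-definite 2×2
    covariance ``Sigma_i``; ``G(x, y; c, Sigma) = exp(-0.5 d²)`` with
    Mahalanobis distance d, so G equals 1 at the centre for any Sigma.
    """

    n_modes: int
    amplitudes: np.ndarray          # (N,)
    centers_um: np.ndarray          # (N, 2) in (x, y) sub-image coordinates
    covariances: np.ndarray         # (N, 2, 2), µm²
    residual: float                 # sum of squared fit residuals
    converged: bool
    origin_offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("a cluster fit needs at least one mode")
        for S in self.covariances:
            if np.linalg.eigvalsh(S)[0] <= 0:
                raise ValueError("covariance is not positive-definite")


@dataclass
class DetectedCell:
    """One detected cell: centroid plus a boundary representation.

    The boundary is either a pixel mask (objects accepted whole) or a
    fitted ellipse (cells recovered from a split cluster).
    """

    id: int
    x_um: float
    y_um: float
    provenance: str                 # single | purkinje | split-from-cluster
    layer: str | None = None
    mask: np.ndarray | None = None
    bbox_origin: tuple[int, int] | None = None
    major_um: float | None = None
    minor_um: float | None = None
    theta_rad: float | None = None


@dataclass
class DetectionScore:
    TP: int
    FP: int
    FN: int
    remaining_clusters: int

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def f1(self) -> float:
        denom = 2 * self.TP + self.FP + self.FN
        return 2 * self.TP / denom if denom else 0.0


@dataclass
class DetectConfig:
    """Parameters of the whole detection stage."""

    window_um: float = 25.0
    offset: float = 0.08
    triage: TriageRules = field(default_factory=TriageRules)
    mass_level: float = 2.0             # Sigma -> ellipse contour (≈86% mass)
    min_peak_distance_um: float = 4.0
    peak_rel_threshold: float = 0.10
    crop_pad_um: float = 10.0           # ≈ two granule radii
    dense_fraction: float = 0.35


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def adaptive_threshold(slide: SlideImage, window_um: float = 25.0,
                       offset: float = 0.08) -> np.ndarray:
    """Local space-varying threshold separating stained objects from background.

    A pixel is foreground iff its polarity-corrected intensity exceeds the
    mean of a square window centred on it by ``offset``.  The moving
    average uses reflected borders so that edge cells are treated like
    interior ones.
    """
    scale = slide.scale_um_per_px
    if window_um < 3 * scale:
        raise ValueError("window_um must span at least 3 pixels")
    if not -1.0 <= offset <= 1.0:
        raise ValueError("offset must lie in [-1, 1]")
    size = int(round(window_um / scale))
    size += 1 - size % 2  # odd window
    if size > min(slide.image.shape):
        raise ValueError("threshold window is larger than the image")
    signal = slide.signal
    local_mean = ndimage.uniform_filter(signal, size=size, mode="reflect")
    return signal > local_mean + offset


def density_partition(mask: np.ndarray, cell_diameter_um: float,
                      scale_um_per_px: float = 1.0,
                      dense_fraction: float = 0.35) -> np.ndarray:
    """Label each pixel dense/sparse from the local foreground fraction.

    The window side is four cell diameters; a pixel is *dense* when the
    foreground fraction inside the window exceeds ``dense_fraction``.
    Returns a boolean array, True where dense.
    """
    if cell_diameter_um <= 0:
        raise ValueError("cell_diameter_um must be positive")
    size = max(1, int(round(4 * cell_diameter_um / scale_um_per_px)))
    size = min(size, max(mask.shape))
    frac = ndimage.uniform_filter(mask.astype(float), size=size, mode="reflect")
    return frac > dense_fraction


def _convex_circularity(mask: np.ndarray) -> float:
    # polygon hull through pixel centres: consistent area/perimeter pair,
    # bounded by 1 via the isoperimetric inequality
    from scipy.spatial import ConvexHull

    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) < 3:
        return 1.0
    try:
        hull = ConvexHull(pts)
    except Exception:
        return 1.0
    if hull.area <= 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * hull.volume / hull.area**2)


def extract_objects(mask: np.ndarray, slide: SlideImage,
                    min_area_px: int = 5) -> list[ForegroundObject]:
    """8-connected components of the foreground with their shape features."""
    labels = measure.label(mask, connectivity=2)
    scale = slide.scale_um_per_px
    objects: list[ForegroundObject] = []
    for rp in measure.regionprops(labels, intensity_image=slide.image):
        if rp.area < min_area_px:
            continue
        r0, c0, _, _ = rp.bbox
        cy, cx = rp.centroid
        objects.append(ForegroundObject(
            label=rp.label,
            mask=rp.image.copy(),
            bbox_origin=(r0, c0),
            centroid_xy_um=(cx * scale, cy * scale),
            area_um2=rp.area * scale**2,
            eccentricity=rp.eccentricity,
            solidity=rp.solidity,
            convex_circularity=_convex_circularity(rp.image),
            mean_intensity=float(rp.intensity_mean),
        ))
    return objects


def triage_objects(objects: list[ForegroundObject],
                   rules: TriageRules | None = None) -> list[str]:
    """Classify each object as single_small, purkinje, cluster or reject.

    Small compact objects are accepted as single cells; large round solid
    objects as Purkinje somata (with a solidity requirement that relaxes
    linearly with area); remaining objects of plausible cell area are
    clusters to be split; tiny specks are rejected.
    """
    rules = rules or TriageRules()
    classes = []
    for obj in objects:
        a = obj.area_um2
        if a < rules.reject_area_um2:
            classes.append("reject")
        elif (rules.single_area_min_um2 <= a <= rules.single_area_max_um2
              and obj.solidity >= rules.single_solidity):
            classes.append("single_small")
        elif (a >= rules.purkinje_area_min_um2
              and obj.convex_circularity >= rules.purkinje_circularity
              and obj.solidity >= rules.purkinje_solidity_at(a)):
            classes.append("purkinje")
        else:
            classes.append("cluster")
    return classes


# ---------------------------------------------------------------------------
# Gaussian-mixture declumping
# ---------------------------------------------------------------------------

def gaussian_2d(x: np.ndarray, y: np.ndarray, center: np.ndarray,
                cov: np.ndarray) -> np.ndarray:
    """Unnormalised anisotropic Gaussian: exp(-0.5 d²), 1 at the centre."""
    inv = np.linalg.inv(cov)
    dx = x - center[0]
    dy = y - center[1]
    d2 = inv[0, 0] * dx**2 + 2 * inv[0, 1] * dx * dy + inv[1, 1] * dy**2
    return np.exp(-0.5 * d2)


def gmm_model(x: np.ndarray, y: np.ndarray, amplitudes: np.ndarray,
              centers: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    out = np.zeros(np.broadcast(x, y).shape)
    for a, c, S in zip(amplitudes, centers, covariances):
        out += a * gaussian_2d(x, y, c, S)
    return out


def _unpack_params(params: np.ndarray, n: int):
    p = params.reshape(n, 6)
    amps = p[:, 0]
    centers = p[:, 1:3]
    covs = np.empty((n, 2, 2))
    for i in range(n):
        L = np.array([[p[i, 3], 0.0], [p[i, 4], p[i, 5]]])
        covs[i] = L @ L.T
    return amps, centers, covs


def fit_gmm_cluster(sub_image: np.ndarray, scale_um_per_px: float = 1.0,
                    min_peak_distance_um: float = 4.0,
                    peak_rel_threshold: float = 0.10,
                    sigma_init_um: float = 2.5,
                    max_iter: int = 500) -> ClusterFit:
    """Fit a 2-D Gaussian mixture to a polarity-corrected clump crop.

    The number of modes equals the number of local maxima of the smoothed
    crop (maxima below ``peak_rel_threshold`` of the dynamic range, or
    closer than ``min_peak_distance_um``, are suppressed as noise).  The
    amplitudes, centres and covariances then minimise the sum of squared
    differences between the mixture and the crop.  Covariances are
    parameterised by their lower-triangular square root, which keeps them
    positive-definite throughout the optimisation.

    Parameters are returned in physical units (µm) in the sub-image frame.
    """
    data = np.asarray(sub_image, dtype=float)
    if data.ndim != 2 or data.size == 0:
        raise ValueError("sub_image must be a non-empty 2-D array")
    scale = scale_um_per_px
    rng_dyn = data.max() - data.min()
    smoothed = ndimage.gaussian_filter(data, sigma=1.0)
    min_dist_px = max(1, int(round(min_peak_distance_um / scale)))
    peaks = peak_local_max(
        smoothed,
        min_distance=min_dist_px,
        threshold_abs=data.min() + peak_rel_threshold * rng_dyn,
        exclude_border=False,
    )
    if len(peaks) == 0:
        raise ValueError("no modes: the crop has no local maxima")
    n = len(peaks)

    rows, cols = data.shape
    y_grid, x_grid = np.mgrid[0:rows, 0:cols]
    x_um = x_grid * scale
    y_um = y_grid * scale
    flat_x, flat_y, flat_d = x_um.ravel(), y_um.ravel(), data.ravel()

    # eigenvalue box [1, 400] µm² translates to sqrt bounds on L entries
    lo_l, hi_l = 1.0, 20.0
    sigma0 = min(max(sigma_init_um, lo_l), hi_l)
    x0 = np.empty(6 * n)
    lb = np.empty(6 * n)
    ub = np.empty(6 * n)
    x_max, y_max = (cols - 1) * scale, (rows - 1) * scale
    for i, (pr, pc) in enumerate(peaks):
        amp = float(np.clip(data[pr, pc], 1e-3, 2.0))
        x0[6 * i: 6 * i + 6] = [amp, pc * scale, pr * scale, sigma0, 0.0, sigma0]
        lb[6 * i: 6 * i + 6] = [1e-6, 0.0, 0.0, lo_l, -hi_l, lo_l]
        ub[6 * i: 6 * i + 6] = [2.0, max(x_max, 1e-6), max(y_max, 1e-6), hi_l, hi_l, hi_l]

    def residuals(params):
        amps, centers, covs = _unpack_params(params, n)
        return gmm_model(flat_x, flat_y, amps, centers, covs) - flat_d

    result = optimize.least_squares(
        residuals, x0, bounds=(lb, ub),
        ftol=1e-10, xtol=1e-10, gtol=1e-10,
        max_nfev=max_iter * (6 * n + 1),
    )
    converged = result.status > 0
    if not converged:
        warnings.warn("GMM fit did not converge; returning best-so-far parameters")
    amps, centers, covs = _unpack_params(result.x, n)
    return ClusterFit(
        n_modes=n,
        amplitudes=amps,
        centers_um=centers,
        covariances=covs,
        residual=float(2 * result.cost),
        converged=converged,
    )


def split_cluster(fit: ClusterFit, mass_level: float = 2.0,
                  first_id: int = 0) -> list[DetectedCell]:
    """Convert each fitted mode into one cell with an elliptical boundary.

    The semi-axes are ``mass_level × sqrt(eigenvalues of Sigma)`` (the
    default 2.0 traces the ≈86%-mass contour) and the orientation comes
    from the principal eigenvector.  Centres are translated back to slide
    coordinates via the fit's origin offset.
    """
    ox, oy = fit.origin_offset_um
    cells = []
    for i in range(fit.n_modes):
        evals, evecs = np.linalg.eigh(fit.covariances[i])
        # eigh sorts ascending: index 1 is the major direction
        major = 2 * mass_level * math.sqrt(evals[1])
        minor = 2 * mass_level * math.sqrt(evals[0])
        theta = math.atan2(evecs[1, 1], evecs[0, 1])
        cells.append(DetectedCell(
            id=first_id + i,
            x_um=fit.centers_um[i, 0] + ox,
            y_um=fit.centers_um[i, 1] + oy,
            provenance="split-from-cluster",
            major_um=major,
            minor_um=minor,
            theta_rad=theta,
        ))
    return cells


# ---------------------------------------------------------------------------
# Whole-slide detection
# ---------------------------------------------------------------------------

def _crop_signal(slide: SlideImage, obj: ForegroundObject, pad_px: int):
    """Polarity-corrected, background-subtracted crop around one object."""
    r0, c0 = obj.bbox_origin
    rows, cols = obj.mask.shape
    r1 = max(0, r0 - pad_px)
    c1 = max(0, c0 - pad_px)
    r2 = min(slide.image.shape[0], r0 + rows + pad_px)
    c2 = min(slide.image.shape[1], c0 + cols + pad_px)
    crop = slide.signal[r1:r2, c1:c2]
    border = np.concatenate([crop[0, :], crop[-1, :], crop[:, 0], crop[:, -1]])
    baseline = float(np.median(border))
    return np.clip(crop - baseline, 0.0, None), (r1, c1)


def detect_slide(slide: SlideImage, config: DetectConfig | None = None,
                 layer_mask: np.ndarray | None = None) -> list[DetectedCell]:
    """Full detection: threshold → components → triage → declump clusters.

    ``layer_mask`` is an optional label image (1 = molecular, 2 = purkinje,
    3 = granular) used to tag each detection with its cortical layer.
    The pipeline is fully deterministic.
    """
    config = config or DetectConfig()
    scale = slide.scale_um_per_px
    mask = adaptive_threshold(slide, config.window_um, config.offset)
    objects = extract_objects(mask, slide)
    classes = triage_objects(objects, config.triage)

    pad_px = max(1, int(round(config.crop_pad_um / scale)))
    cells: list[DetectedCell] = []
    next_id = 0
    for obj, cls in zip(objects, classes):
        if cls == "reject":
            continue
        if cls in ("single_small", "purkinje"):
            cells.append(DetectedCell(
                id=next_id,
                x_um=obj.centroid_xy_um[0],
                y_um=obj.centroid_xy_um[1],
                provenance="single" if cls == "single_small" else "purkinje",
                mask=obj.mask,
                bbox_origin=obj.bbox_origin,
            ))
            next_id += 1
            continue
        crop, (r1, c1) = _crop_signal(slide, obj, pad_px)
        try:
            fit = fit_gmm_cluster(
                crop, scale,
                min_peak_distance_um=config.min_peak_distance_um,
                peak_rel_threshold=config.peak_rel_threshold,
            )
        except ValueError:
            # flat crop: keep the component as a single cell rather than drop it
            cells.append(DetectedCell(
                id=next_id,
                x_um=obj.centroid_xy_um[0],
                y_um=obj.centroid_xy_um[1],
                provenance="single",
                mask=obj.mask,
                bbox_origin=obj.bbox_origin,
            ))
            next_id += 1
            continue
        fit.origin_offset_um = (c1 * scale, r1 * scale)
        split = split_cluster(fit, config.mass_level, first_id=next_id)
        cells.extend(split)
        next_id += len(split)

    if layer_mask is not None:
        names = {1: "molecular", 2: "purkinje", 3: "granular"}
        for cell in cells:
            r = int(round(cell.y_um / scale))
            c = int(round(cell.x_um / scale))
            r = min(max(r, 0), layer_mask.shape[0] - 1)
            c = min(max(c, 0), layer_mask.shape[1] - 1)
            cell.layer = names.get(int(layer_mask[r, c]))
    return cells


def evaluate_detection(detected, truth, match_radius_um: float = 5.0) -> DetectionScore:
    """Score detections against ground truth by greedy one-to-one matching.

    Candidate (detection, truth) pairs within ``match_radius_um`` are taken
    nearest-first (ties broken by smaller detection id); each side may be
    used once.  Matched detections are TP, leftover detections FP, leftover
    truths FN.  A detection whose neighbourhood still holds unmatched truth
    centres after matching counts one *remaining cluster* — an unsplit or
    under-split clump.
    """
    if match_radius_um <= 0:
        raise ValueError("match_radius_um must be positive")
    det_xy = np.array([[d.x_um, d.y_um] for d in detected], dtype=float)
    tru_xy = np.array([[t.center_xy_um[0], t.center_xy_um[1]] for t in truth],
                      dtype=float)
    n_det, n_tru = len(det_xy), len(tru_xy)
    if n_det == 0 or n_tru == 0:
        return DetectionScore(TP=0, FP=n_det, FN=n_tru, remaining_clusters=0)

    from scipy.spatial import cKDTree
    tree = cKDTree(tru_xy)
    pairs = []
    for di, xy in enumerate(det_xy):
        for ti in tree.query_ball_point(xy, match_radius_um):
            d = float(np.hypot(*(xy - tru_xy[ti])))
            pairs.append((d, di, ti))
    pairs.sort()
    det_used = np.zeros(n_det, dtype=bool)
    tru_used = np.zeros(n_tru, dtype=bool)
    for _, di, ti in pairs:
        if not det_used[di] and not tru_used[ti]:
            det_used[di] = True
            tru_used[ti] = True
    tp = int(det_used.sum())
    fp = n_det - tp
    fn = n_tru - int(tru_used.sum())

    remaining = 0
    for di, xy in enumerate(det_xy):
        near = tree.query_ball_point(xy, match_radius_um)
        unmatched_near = sum(1 for ti in near if not tru_used[ti])
        attached = unmatched_near + (1 if det_used[di] else 0)
        if attached >= 2:
            remaining += 1

    score = DetectionScore(TP=tp, FP=fp, FN=fn, remaining_clusters=remaining)
    assert score.TP + score.FN == n_tru
    assert score.TP + score.FP == n_det
    return score
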