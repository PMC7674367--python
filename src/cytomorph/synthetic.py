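"""Seeded synthetic Nissl-like slides and cell tables with ground truth.

Two generators make the whole pipeline testable without any real data:

* :func:`generate_slide` renders a grayscale slide in which each cell is a
  dark anisotropic 2-D Gaussian intensity dip truncated at its elliptical
  boundary, laid out in the three cerebellar cortical bands (molecular,
  Purkinje, granular), optionally with a fraction of cells in touching
  pairs.  Every rendered cell is returned as a ground-truth record.

* :func:`generate_cell_table` draws per-cell morphometric descriptors from
  an additive model ``Y = mu + tau_j + animal effect + s_j * noise`` with a
  shared per-animal random effect, mirroring the grouping structure of a
  multi-animal histology study (populations M / F / FM, several animals
  per population, many cells per animal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .detect import SlideImage
from .records import DESCRIPTORS, POPULATIONS, RECORD_COLUMNS, REGULARITY_DESCRIPTORS


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place the requested cells."""


# ---------------------------------------------------------------------------
# Slide generator
# ---------------------------------------------------------------------------

@dataclass
class CellArchetype:
    """Geometry and contrast of one cell class.

    Axis lengths are full lengths in µm (mean, SD); ``intensity_depth`` is
    how much darker than background the cell centre is, as an intensity
    fraction.  Draws with minor > major are swapped.
    """

    name: str
    major_axis_um: tuple[float, float]
    minor_axis_um: tuple[float, float]
    intensity_depth: float = 0.45

    def sample_axes(self, rng: np.random.Generator) -> tuple[float, float]:
        major = rng.normal(*self.major_axis_um)
        minor = rng.normal(*self.minor_axis_um)
        major = max(major, 1.0)
        minor = max(minor, 1.0)
        if minor > major:
            major, minor = minor, major
        return major, minor


#: Archetypes parameterised from the printed per-type descriptor means:
#: stellate mean major axis 11 µm, basket 19.5 µm, granules 11 µm (round),
#: Golgi type II 28 µm, Purkinje somata ≈ 2500 µm² (70 × 50 µm axes).
DEFAULT_ARCHETYPES = {
    "stellate": CellArchetype("stellate", (11.0, 1.2), (8.0, 1.0)),
    "basket": CellArchetype("basket", (19.5, 1.8), (15.0, 1.5)),
    "purkinje": CellArchetype("purkinje", (70.0, 5.0), (50.0, 4.0), 0.5),
    "granule": CellArchetype("granule", (11.0, 1.0), (9.0, 0.9)),
    "golgi": CellArchetype("golgi", (28.0, 2.5), (13.5, 1.5)),
}


@dataclass
class LayerSpec:
    """One horizontal band of the slide and its cell content.

    ``counts`` maps archetype name → number of cells; ``clustering`` is the
    fraction of the band's cells placed in touching pairs; non-clustered
    cells keep at least ``min_center_spacing_um`` between centres.
    """

    name: str
    counts: dict[str, int] = field(default_factory=dict)
    clustering: float = 0.0
    min_center_spacing_um: float = 18.0
    height_fraction: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("cell counts must be non-negative")
        if not 0.0 <= self.clustering <= 1.0:
            raise ValueError("clustering fraction must lie in [0, 1]")


@dataclass
class SlideConfig:
    width_um: float = 400.0
    height_um: float = 400.0
    scale_um_per_px: float = 1.0
    layers: list[LayerSpec] = field(default_factory=list)
    background_level: float = 0.71  # mean background intensity fraction
    noise_sd: float = 0.02
    seed: int = 0
    archetypes: dict[str, CellArchetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES))

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("slide extent must be positive")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")
        if not 0.0 < self.background_level < 1.0:
            raise ValueError("background_level must lie in (0, 1)")
        fracs = [l.height_fraction for l in self.layers]
        if self.layers:
            if all(f is None for f in fracs):
                for l in self.layers:
                    l.height_fraction = 1.0 / len(self.layers)
            elif any(f is None for f in fracs):
                raise ValueError("specify height_fraction for all layers or none")
            if abs(sum(l.height_fraction for l in self.layers) - 1.0) > 1e-9:
                raise ValueError("layer bands must tile the image height")

    def layer_bands_um(self) -> list[tuple[float, float]]:
        """(y_top, y_bottom) of each band, in listed order."""
        bands = []
        y = 0.0
        for layer in self.layers:
            h = layer.height_fraction * self.height_um
            bands.append((y, y + h))
            y += h
        return bands


@dataclass
class GroundTruthCell:
    id: int
    center_xy_um: tuple[float, float]
    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float
    layer: str
    archetype: str


def _cov_from_axes(major_um: float, minor_um: float, theta: float) -> np.ndarray:
    # the ellipse boundary is the 2-sigma contour of the rendered Gaussian
    sa, sb = major_um / 4.0, minor_um / 4.0
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s], [s, c]])
    return R @ np.diag([sa**2, sb**2]) @ R.T


def _render_cell(image: np.ndarray, cell: GroundTruthCell, depth: float,
                 scale: float) -> None:
    cov = _cov_from_axes(cell.major_axis_um, cell.minor_axis_um,
                         cell.orientation_rad)
    inv = np.linalg.inv(cov)
    cx, cy = cell.center_xy_um
    r_um = cell.major_axis_um / 2.0
    r0 = max(0, int((cy - r_um) / scale) - 1)
    r1 = min(image.shape[0], int((cy + r_um) / scale) + 2)
    c0 = max(0, int((cx - r_um) / scale) - 1)
    c1 = min(image.shape[1], int((cx + r_um) / scale) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx * scale - cx
    dy = yy * scale - cy
    d2 = inv[0, 0] * dx**2 + 2 * inv[0, 1] * dx * dy + inv[1, 1] * dy**2
    dip = depth * np.exp(-0.5 * d2)
    dip[d2 > 4.0] = 0.0  # truncate at the ellipse boundary (2 sigma)
    image[r0:r1, c0:c1] -= dip


def _place_in_band(rng: np.random.Generator, band: tuple[float, float],
                   width_um: float, margin: float, existing: list,
                   min_spacing: float, layer_name: str,
                   max_attempts: int = 10_000) -> tuple[float, float]:
    y0, y1 = band
    lo_y = min(y0 + margin, y1)
    hi_y = max(y1 - margin, lo_y)
    lo_x = min(margin, width_um)
    hi_x = max(width_um - margin, lo_x)
    for _ in range(max_attempts):
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        ok = all((x - ex)**2 + (y - ey)**2 >= min_spacing**2
                 for ex, ey in existing)
        if ok:
            return x, y
    raise PlacementError(
        f"could not place a cell in layer '{layer_name}': density too high "
        f"for min_center_spacing_um={min_spacing}")


def generate_slide(config: SlideConfig):
    """Render a synthetic slide; returns ``(SlideImage, truth_cells)``.

    Cells are placed by rejection sampling (10 000 attempts per cell) —
    non-clustered cells respect the layer's minimum centre spacing, while
    the clustered fraction is laid out as touching pairs.  The image is
    Gaussian-blurred (sigma 0.5 px) and corrupted with additive noise; the
    truth list is sorted by id and identical for identical (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    scale = config.scale_um_per_px
    rows = int(round(config.height_um / scale))
    cols = int(round(config.width_um / scale))
    image = np.full((rows, cols), config.background_level, dtype=float)

    truth: list[GroundTruthCell] = []
    next_id = 0
    for layer, band in zip(config.layers, config.layer_bands_um()):
        placed_centers: list[tuple[float, float]] = []
        for arch_name, count in layer.counts.items():
            if count == 0:
                continue
            arch = config.archetypes[arch_name]
            n_pairs = int(round(layer.clustering * count)) // 2
            n_single = count - 2 * n_pairs
            for _ in range(n_single):
                major, minor = arch.sample_axes(rng)
                x, y = _place_in_band(
                    rng, band, config.width_um, major / 2, placed_centers,
                    layer.min_center_spacing_um, layer.name)
                placed_centers.append((x, y))
                truth.append(GroundTruthCell(
                    next_id, (x, y), major, minor,
                    rng.uniform(0, math.pi), layer.name, arch_name))
                next_id += 1
            for _ in range(n_pairs):
                maj_a, min_a = arch.sample_axes(rng)
                maj_b, min_b = arch.sample_axes(rng)
                x, y = _place_in_band(
                    rng, band, config.width_um, maj_a / 2, placed_centers,
                    layer.min_center_spacing_um, layer.name)
                # partner touches the anchor: centre distance ≈ 0.75 of the
                # summed semi-major axes, merging the two thresholded masks
                d = 0.75 * (maj_a / 2 + maj_b / 2)
                for _ in range(10_000):
                    phi = rng.uniform(0, 2 * math.pi)
                    xb, yb = x + d * math.cos(phi), y + d * math.sin(phi)
                    in_band = (band[0] + maj_b / 2 <= yb <= band[1] - maj_b / 2
                               and maj_b / 2 <= xb <= config.width_um - maj_b / 2)
                    clear = all((xb - ex)**2 + (yb - ey)**2
                                >= layer.min_center_spacing_um**2
                                for ex, ey in placed_centers)
                    if in_band and clear:
                        break
                else:
                    raise PlacementError(
                        f"could not place a touching pair in layer '{layer.name}'")
                placed_centers.append((x, y))
                placed_centers.append((xb, yb))
                truth.append(GroundTruthCell(
                    next_id, (x, y), maj_a, min_a,
                    rng.uniform(0, math.pi), layer.name, arch_name))
                truth.append(GroundTruthCell(
                    next_id + 1, (xb, yb), maj_b, min_b,
                    rng.uniform(0, math.pi), layer.name, arch_name))
                next_id += 2

    for cell in truth:
        depth = config.archetypes[cell.archetype].intensity_depth
        _render_cell(image, cell, depth, scale)

    image = ndimage.gaussian_filter(image, sigma=0.5)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    truth.sort(key=lambda c: c.id)
    return SlideImage(image, scale, cells_dark=True), truth


def layer_label_mask(config: SlideConfig) -> np.ndarray:
    """Label image of the layer bands: 1 molecular, 2 purkinje, 3 granular."""
    codes = {"molecular": 1, "purkinje": 2, "granular": 3}
    scale = config.scale_um_per_px
    rows = int(round(config.height_um / scale))
    cols = int(round(config.width_um / scale))
    mask = np.zeros((rows, cols), dtype=np.uint8)
    for layer, (y0, y1) in zip(config.layers, config.layer_bands_um()):
        r0 = int(round(y0 / scale))
        r1 = int(round(y1 / scale))
        mask[r0:r1, :] = codes.get(layer.name, 0)
    return mask


def truth_to_frame(truth: list[GroundTruthCell]) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [c.id for c in truth],
        "x_um": [c.center_xy_um[0] for c in truth],
        "y_um": [c.center_xy_um[1] for c in truth],
        "major_um": [c.major_axis_um for c in truth],
        "minor_um": [c.minor_axis_um for c in truth],
        "theta_rad": [c.orientation_rad for c in truth],
        "layer": [c.layer for c in truth],
        "archetype": [c.archetype for c in truth],
    })


def write_image(path, slide: SlideImage) -> None:
    """Write the slide as 16-bit TIFF or 8-bit PNG depending on suffix."""
    from pathlib import Path
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(p, np.round(slide.image * 65535).astype(np.uint16))
    else:
        from PIL import Image
        Image.fromarray(np.round(slide.image * 255).astype(np.uint8)).save(p)


def read_image(path, scale_um_per_px: float = 1.0,
               cells_dark: bool = True) -> SlideImage:
    from pathlib import Path
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(p)
    else:
        from PIL import Image
        arr = np.asarray(Image.open(p))
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return SlideImage(arr, scale_um_per_px, cells_dark)


# ---------------------------------------------------------------------------
# Cell-table generator
# ---------------------------------------------------------------------------

#: Granule-like baseline descriptor profile: area 83 µm², perimeter 30 µm,
#: axes 11 × 9 µm (the printed granule means), regular round shape, and a
#: densely packed neighbourhood.
DEFAULT_BASELINE_MEAN = np.array(
    [83.0, 30.0, 11.0, 9.0, 0.93, 0.72, 0.82, 0.90, 12.0, 40.0])

#: Within-animal (cell-level) SD per descriptor; size and density scatter is
#: proportional to the mean, regularity scatter absolute within [0, 1].
DEFAULT_WITHIN_SD = np.array(
    [12.0, 3.5, 1.4, 1.2, 0.035, 0.05, 0.06, 0.04, 3.0, 8.0])


@dataclass
class PopulationEffectSpec:
    """Population-level location and scale effects on the descriptor model.

    For population *j* and descriptor *k* a cell value is drawn as
    ``Y = mu_k + tau_jk + animal_sd * u_a * sd_k + s_jk * sd_k * eps`` with
    one standard-normal scalar ``u_a`` per animal shared across all
    descriptors — the animal-level random effect — and i.i.d. noise eps.
    Location shifts must satisfy the sum-to-zero convention over
    populations; scale multipliers must be positive.
    """

    populations: tuple[str, ...] = tuple(POPULATIONS)
    animals_per_population: int = 8
    cells_per_animal: int = 150
    baseline_mean: np.ndarray = field(
        default_factory=lambda: DEFAULT_BASELINE_MEAN.copy())
    within_sd: np.ndarray = field(
        default_factory=lambda: DEFAULT_WITHIN_SD.copy())
    animal_sd: float = 0.4  # between-animal SD in units of within_sd
    location_shift: dict[str, np.ndarray] = field(default_factory=dict)
    scale_mult: dict[str, np.ndarray] = field(default_factory=dict)
    layer: str = "granular"
    cell_type: str = "granule"

    def __post_init__(self) -> None:
        if self.animals_per_population < 2:
            raise ValueError("need at least 2 animals per population")
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.within_sd = np.asarray(self.within_sd, dtype=float)
        p = len(DESCRIPTORS)
        for pop in self.populations:
            self.location_shift.setdefault(pop, np.zeros(p))
            self.scale_mult.setdefault(pop, np.ones(p))
            self.location_shift[pop] = np.asarray(self.location_shift[pop], float)
            self.scale_mult[pop] = np.asarray(self.scale_mult[pop], float)
            if np.any(self.scale_mult[pop] <= 0):
                raise ValueError(f"scale multipliers for '{pop}' must be positive")
        tau_sum = sum(self.location_shift[pop] for pop in self.populations)
        tol = 1e-8 * (1.0 + np.abs(self.baseline_mean))
        if np.any(np.abs(tau_sum) > tol):
            raise ValueError("location shifts must sum to zero over populations")

    @classmethod
    def from_sd_effects(cls, effects: dict[str, float],
                        descriptors: list[str] | None = None,
                        aspect: str = "location", **kwargs):
        """Build a spec from per-population effect sizes in SD units.

        ``aspect='location'`` shifts the listed descriptors by
        ``effect × within_sd``; ``aspect='scatter'`` multiplies their
        cell-level SD by the effect value instead.
        """
        spec = cls(**kwargs)
        cols = [DESCRIPTORS.index(d) for d in (descriptors or DESCRIPTORS)]
        for pop, e in effects.items():
            if aspect == "location":
                tau = np.zeros(len(DESCRIPTORS))
                tau[cols] = e * spec.within_sd[cols]
                spec.location_shift[pop] = tau
            elif aspect == "scatter":
                s = np.ones(len(DESCRIPTORS))
                s[cols] = e
                spec.scale_mult[pop] = s
            else:
                raise ValueError(f"unknown aspect '{aspect}'")
        if aspect == "location":
            mean_tau = sum(spec.location_shift[p] for p in spec.populations) / len(
                spec.populations)
            for pop in spec.populations:
                spec.location_shift[pop] = spec.location_shift[pop] - mean_tau
        return spec


def generate_cell_table(spec: PopulationEffectSpec, seed: int) -> pd.DataFrame:
    """Draw a full cell-record table from the additive population model.

    Regularity descriptors are clipped to [0, 1] and density counts to
    non-negative values; rows come out in deterministic population-major
    order with unique ``animal_id`` values across populations.
    """
    rng = np.random.default_rng(seed)
    p = len(DESCRIPTORS)
    reg_cols = [DESCRIPTORS.index(d) for d in REGULARITY_DESCRIPTORS]
    frames = []
    cell_id = 0
    for pop in spec.populations:
        tau = spec.location_shift[pop]
        s = spec.scale_mult[pop]
        for a in range(spec.animals_per_population):
            u = rng.normal()
            eps = rng.normal(size=(spec.cells_per_animal, p))
            values = (spec.baseline_mean + tau
                      + spec.animal_sd * u * spec.within_sd
                      + s * spec.within_sd * eps)
            values[:, reg_cols] = np.clip(values[:, reg_cols], 0.0, 1.0)
            values[:, -2:] = np.clip(values[:, -2:], 0.0, None)
            df = pd.DataFrame(values, columns=DESCRIPTORS)
            df.insert(0, "cell_type", spec.cell_type)
            df.insert(0, "layer", spec.layer)
            df.insert(0, "population", pop)
            df.insert(0, "animal_id", f"{pop}{a:02d}")
            df.insert(0, "cell_id",
                      np.arange(cell_id, cell_id + spec.cells_per_animal))
            cell_id += spec.cells_per_animal
            frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[RECORD_COLUMNS]
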