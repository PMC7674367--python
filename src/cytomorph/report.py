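"""Exploratory outputs: per-domain PCA, k-means clustering, contour plots.

These complement the inferential matrices with descriptive views: the
first principal component of each domain summarizes a population's
multidimensional tendency (a right-shifted histogram reads as "larger in
that domain"), k-means probes whether populations separate without using
the labels, and bivariate kernel-density contours visualize joint shifts
and spread.  Population colors follow a fixed convention: orange = F,
green = FM, light blue = M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DOMAINS

POPULATION_COLORS = {"F": "orange", "FM": "green", "M": "lightblue"}


@dataclass
class PCAResult:
    domain: str
    scores: pd.Series               # first-component score per cell
    loadings: pd.Series             # per retained descriptor
    explained_fraction: float
    dropped: list[str]


def pca_by_domain(records: pd.DataFrame, domain: str) -> PCAResult:
    """First principal component of one domain's standardized descriptors.

    The projection uses the pooled correlation matrix (descriptors are
    z-scored first); the component sign is fixed so the loading on the
    domain's first descriptor is positive, making histograms comparable
    across runs.  Constant descriptors are dropped with a warning.
    """
    descs = list(DOMAINS[domain])
    X = records[descs].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [d for d, k in zip(descs, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant descriptors: {dropped}")
    descs = [d for d, k in zip(descs, keep) if k]
    if not descs:
        raise ValueError("no varying descriptors left in the domain")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if len(descs) == 1:
        scores = Z[:, 0]
        loadings = np.array([1.0])
        explained = 1.0
    else:
        corr = np.corrcoef(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        lead = evecs[:, -1]
        if lead[0] < 0:
            lead = -lead
        scores = Z @ lead
        loadings = lead
        explained = float(evals[-1] / evals.sum())
    return PCAResult(domain, pd.Series(scores, index=records.index),
                     pd.Series(loadings, index=descs), explained, dropped)


def kmeans_populations(records: pd.DataFrame, k: int, seed: int = 0,
                       descriptors: list[str] | None = None):
    """Seeded k-means on the standardized descriptors.

    Returns ``(labels, contingency)`` where the contingency table crosses
    cluster labels with population labels.  Ten restarts with a fixed seed
    make the labels reproducible.
    """
    from sklearn.cluster import KMeans

    descs = descriptors or [d for ds in DOMAINS.values() for d in ds]
    X = records[descs].to_numpy(dtype=float)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(X):
        raise ValueError("k cannot exceed the number of cells")
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(Z)
    contingency = pd.crosstab(pd.Series(labels, name="cluster"),
                              records["population"].reset_index(drop=True))
    return labels, contingency


def kde_on_grid(xy: np.ndarray, grid_x: np.ndarray, grid_y: np.ndarray):
    """Gaussian kernel density of a 2-D sample evaluated on a mesh."""
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(xy.T)
    gx, gy = np.meshgrid(grid_x, grid_y)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    return dens


def density_difference(xy_a: np.ndarray, xy_b: np.ndarray,
                       n_grid: int = 60) -> float:
    """Integrated absolute difference of two bivariate KDEs (0 = identical)."""
    both = np.vstack([xy_a, xy_b])
    lo = both.min(axis=0)
    hi = both.max(axis=0)
    pad = 0.2 * (hi - lo + 1e-12)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], n_grid)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], n_grid)
    da = kde_on_grid(xy_a, gx, gy)
    db = kde_on_grid(xy_b, gx, gy)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    return float(np.abs(da - db).sum() * cell)


def contour_report(records: pd.DataFrame, descriptor_pairs, out_dir,
                   n_grid: int = 60, min_cells: int = 30) -> list:
    """Bivariate density contours per population, one figure per pair.

    Each population's joint distribution is drawn as kernel-density
    contours on shared axes with the fixed color map.  Returns the list of
    written figure paths; an empty pair list writes nothing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for dx, dy in descriptor_pairs:
        fig, ax = plt.subplots(figsize=(5, 4))
        lo = records[[dx, dy]].min().to_numpy()
        hi = records[[dx, dy]].max().to_numpy()
        pad = 0.2 * (hi - lo + 1e-12)
        gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], n_grid)
        gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], n_grid)
        for pop, group in records.groupby("population"):
            if len(group) < min_cells:
                continue
            dens = kde_on_grid(group[[dx, dy]].to_numpy(), gx, gy)
            ax.contour(gx, gy, dens, levels=5,
                       colors=POPULATION_COLORS.get(pop, "gray"))
        ax.set_xlabel(dx)
        ax.set_ylabel(dy)
        path = out_dir / f"contour_{dx}_vs_{dy}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
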