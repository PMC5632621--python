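"""Two-axis environmental ordination and kernel-smoothed occupancy grids.

The ordination is a principal component analysis calibrated on the whole
environmental background of the study area (every valid raster cell), so
the axes describe available climate, not the occurrences.  Occurrence
sets are projected onto the first two axes and smoothed with a Gaussian
product kernel onto an R x R grid spanning the background scores; the
resulting normalized occupancy surface p (sums to 1) is what the niche
overlap and randomization statistics operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class PcaModel:
    """PCA of standardized environmental variables.

    loadings: (n_vars, n_axes) orthonormal columns; explained_fraction:
    per-axis fraction of total variance (descending, sums to 1); mean and
    scale are the per-variable standardization vectors.
    """

    variables: list[str]
    loadings: np.ndarray
    explained_fraction: np.ndarray
    mean: np.ndarray
    scale: np.ndarray


@dataclass
class EnvSpaceGrid:
    """Kernel density surfaces of one lineage over 2-D environment space.

    o : occurrence kernel density at cell centers (R x R)
    e : background kernel density at cell centers
    z : occupancy; o / max(o) (uncorrected) or (o/e)/max(o/e) (corrected)
    p : z normalized to sum to 1 -- the comparable occupancy distribution
    """

    resolution: int
    x_edges: np.ndarray
    y_edges: np.ndarray
    o: np.ndarray
    e: np.ndarray
    z: np.ndarray
    p: np.ndarray
    bandwidth: tuple[float, float]

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0]) * (self.y_edges[1] - self.y_edges[0]))


def fit_pca_ent(background_env: np.ndarray, variables: list[str] | None = None) -> PcaModel:
    """Fit the background-calibrated PCA on standardized variables.

    All axes are returned; downstream analysis uses the first two.
    A constant (zero-variance) variable is an error since it cannot be
    standardized.
    """
    X = np.asarray(background_env, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a (cells x variables) matrix with >= 3 background cells")
    names = variables if variables is not None else [f"var{i}" for i in range(X.shape[1])]
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    zero = scale <= 0
    if zero.any():
        bad = [names[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"constant variable(s) with zero variance: {bad}")
    Z = (X - mean) / scale
    pca = PCA(n_components=min(Z.shape), svd_solver="full")
    pca.fit(Z)
    # sign convention: largest-|loading| element of each axis positive
    loadings = pca.components_.T.copy()
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    return PcaModel(
        variables=list(names),
        loadings=loadings,
        explained_fraction=pca.explained_variance_ratio_.copy(),
        mean=mean,
        scale=scale,
    )


def project(env_vectors: np.ndarray, model: PcaModel, n_axes: int = 2) -> np.ndarray:
    """Project environmental vectors onto the leading PCA axes."""
    X = np.atleast_2d(np.asarray(env_vectors, dtype=float))
    if X.shape[1] != len(model.variables):
        raise ValueError(
            f"env vector length {X.shape[1]} != model variables {len(model.variables)}"
        )
    Z = (X - model.mean) / model.scale
    return Z @ model.loadings[:, :n_axes]


def silverman_bandwidth(x: np.ndarray) -> float:
    """Normal-reference rule for one axis: 1.06 * sigma * n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sigma = x.std(ddof=1) if n > 1 else 1.0
    if sigma <= 0:
        sigma = 1.0
    return 1.06 * sigma * n ** (-0.2)


def _kde_on_grid(
    scores: np.ndarray,
    x_centers: np.ndarray,
    y_centers: np.ndarray,
    hx: float,
    hy: float,
) -> np.ndarray:
    """Gaussian product-kernel density at cell centers; rows index y."""
    x = scores[:, 0][:, None]
    y = scores[:, 1][:, None]
    gx = np.exp(-0.5 * ((x_centers[None, :] - x) / hx) ** 2)  # (n, R)
    gy = np.exp(-0.5 * ((y_centers[None, :] - y) / hy) ** 2)
    dens = gy.T @ gx  # (R, R), rows = y
    dens /= scores.shape[0] * 2.0 * np.pi * hx * hy
    return dens


def grid_axes(
    background_scores: np.ndarray, R: int = 100, margin: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Cell edges spanning the background scores, expanded by a margin.

    The margin avoids truncating kernels whose mode sits on the envelope
    boundary; every background score lies inside the edges.
    """
    lo = background_scores.min(axis=0)
    hi = background_scores.max(axis=0)
    pad = (hi - lo) * margin
    pad = np.where(pad > 0, pad, 1e-6)
    x_edges = np.linspace(lo[0] - pad[0], hi[0] + pad[0], R + 1)
    y_edges = np.linspace(lo[1] - pad[1], hi[1] + pad[1], R + 1)
    return x_edges, y_edges


def build_grid(
    occ_scores: np.ndarray,
    background_scores: np.ndarray,
    R: int = 100,
    mode: str = "uncorrected",
    bandwidth: tuple[float, float] | None = None,
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    precomputed_e: np.ndarray | None = None,
) -> EnvSpaceGrid:
    """Kernel-smoothed occupancy of one lineage in environment space.

    Bandwidths follow the per-axis normal-reference rule computed on the
    *background* scores and are reused for the occurrence density, so o
    and e are smoothed identically and stay comparable across lineages.
    Occurrences outside the background envelope are clipped to the
    boundary (and logged).  ``precomputed_e`` short-circuits the
    background density evaluation; randomization tests rebuild many
    occurrence grids against one fixed background and pass it in.
    """
    occ = np.atleast_2d(np.asarray(occ_scores, dtype=float))
    bg = np.atleast_2d(np.asarray(background_scores, dtype=float))
    if occ.shape[0] < 1:
        raise ValueError("need at least one occurrence score")
    if bg.shape[0] < 10:
        raise ValueError("need at least 10 background scores")
    if R < 10:
        raise ValueError("grid resolution R must be >= 10")
    if mode not in {"uncorrected", "corrected"}:
        raise ValueError(f"unknown occupancy mode {mode!r}")

    if axes is None:
        x_edges, y_edges = grid_axes(bg, R)
    else:
        x_edges, y_edges = axes
    lo = np.array([x_edges[0], y_edges[0]])
    hi = np.array([x_edges[-1], y_edges[-1]])
    n_out = int(((occ < lo) | (occ > hi)).any(axis=1).sum())
    if n_out:
        logger.info("build_grid: %d occurrence scores clipped to grid bounds", n_out)
        occ = np.clip(occ, lo, hi)

    if bandwidth is None:
        hx = silverman_bandwidth(bg[:, 0])
        hy = silverman_bandwidth(bg[:, 1])
    else:
        hx, hy = bandwidth
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    o = _kde_on_grid(occ, xc, yc, hx, hy)
    e = precomputed_e if precomputed_e is not None else _kde_on_grid(bg, xc, yc, hx, hy)

    if mode == "uncorrected":
        z = o / o.max()
    else:
        ratio = np.zeros_like(o)
        pos = e > 0
        ratio[pos] = o[pos] / e[pos]
        z = ratio / ratio.max()
    p = z / z.sum()
    return EnvSpaceGrid(
        resolution=int(x_edges.size - 1),
        x_edges=x_edges,
        y_edges=y_edges,
        o=o,
        e=e,
        z=z,
        p=p,
        bandwidth=(float(hx), float(hy)),
    )


def plot_env_grid(grid: EnvSpaceGrid, ax=None, title: str | None = None):
    """Shaded occurrence-density panel with 50% and 100% background envelopes.

    Dashed contour: densest background cells holding 50% of background
    density; solid contour: the full (100%) available environment.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (grid.x_edges[0], grid.x_edges[-1], grid.y_edges[0], grid.y_edges[-1])
    ax.imshow(
        grid.z, origin="lower", extent=extent, cmap="Greys", aspect="auto",
        vmin=0.0, vmax=grid.z.max() or 1.0,
    )
    e = grid.e / grid.e.sum()
    order = np.argsort(e, axis=None)[::-1]
    cum = np.cumsum(e.ravel()[order])
    thresh50 = e.ravel()[order][np.searchsorted(cum, 0.5)]
    thresh100 = e.ravel()[order][cum < 0.999][-1] if (cum < 0.999).any() else 0.0
    ax.contour(grid.x_centers, grid.y_centers, e, levels=[thresh50],
               colors="k", linestyles="dashed", linewidths=1)
    ax.contour(grid.x_centers, grid.y_centers, e, levels=[max(thresh100, e.max() * 1e-4)],
               colors="k", linestyles="solid", linewidths=1)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    return ax
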