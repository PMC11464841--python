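"""Cellular neighborhoods (CNs): windows, compositions, K-means, Voronoi.

A cell's window is itself plus its ``w`` nearest cells (Euclidean centroid
distance, default w = 20, so a 21-cell window), computed within each image
only. Windows are summarized as cell-type composition vectors and clustered
with K-means (default k = 15) into recurrent microenvironment motifs; each
cell inherits its window's cluster. A clipped Voronoi tessellation colors
the tissue by CN for visual validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from sklearn.cluster import KMeans

from .errors import ValidationError


@dataclass
class CNModel:
    """Fitted cellular-neighborhood model."""

    window_size: int            # neighbors per window (excluding the center)
    k: int                      # number of neighborhoods
    n_types: int
    centroids: np.ndarray       # (k, n_types) composition space; rows sum to 1
    labels: np.ndarray          # per-cell CN in 0..k-1
    seed: int


def knn_windows(centroids: np.ndarray, w: int = 20,
                image_ids: np.ndarray | None = None,
                include_center: bool = True) -> list[np.ndarray]:
    """Per-cell neighbor index lists (global indices), within-image only.

    Returns, for each cell, its own index followed by the indices of its
    ``w`` nearest cells in the same image. Distance ties are broken by cell
    index order. Images with fewer than ``w + 1`` cells use all available
    cells with a warning; a single-cell image yields the window ``{self}``.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = len(pts)
    if image_ids is None:
        image_ids = np.zeros(n)
    image_ids = np.asarray(image_ids)
    windows: list[np.ndarray | None] = [None] * n
    for img in pd.unique(image_ids):
        sel = np.flatnonzero(image_ids == img)
        m = len(sel)
        w_img = w
        if m <= w:
            warnings.warn(f"image {img!r} has {m} cells; window reduced to {m - 1}")
            w_img = m - 1
        sub = pts[sel]
        d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
        order = np.argsort(d, axis=1, kind="stable")
        for local_i, row in enumerate(order):
            others = row[row != local_i][:w_img]
            if include_center:
                win = np.concatenate([[sel[local_i]], sel[others]])
            else:
                win = sel[others]
            windows[sel[local_i]] = win
    return windows  # type: ignore[return-value]


def composition_vectors(windows: list[np.ndarray], type_labels: np.ndarray,
                        n_types: int) -> np.ndarray:
    """Row i = fraction of each cell type among the cells of window i."""
    types = np.asarray(type_labels, dtype=int)
    if types.size and (types.max() >= n_types or types.min() < 0):
        raise ValidationError("type labels must lie in 0..n_types-1")
    comp = np.zeros((len(windows), n_types))
    for i, win in enumerate(windows):
        counts = np.bincount(types[win], minlength=n_types)
        comp[i] = counts / len(win)
    return comp


def kmeans_cn(compositions: np.ndarray, k: int = 15, seed: int = 0, *,
              n_init: int = 10, window_size: int = 20) -> CNModel:
    """K-means over composition space (k-means++ init, fixed seed).

    Centroids are recomputed as empirical means of their members, so every
    centroid is a probability vector. If clusters come out empty (degenerate
    identical compositions), labels are compacted to a contiguous range.
    """
    comp = np.asarray(compositions, dtype=float)
    n, T = comp.shape
    if n < k:
        warnings.warn(f"n={n} windows < k={k}; k reduced to {n}")
        k = n
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init).fit(comp)
    labels = km.labels_.astype(int)
    present = np.unique(labels)
    if len(present) < k:
        warnings.warn(f"{k - len(present)} empty neighborhood clusters compacted")
    remap = {old: new for new, old in enumerate(present)}
    labels = np.array([remap[v] for v in labels])
    centroids = np.vstack([comp[labels == c].mean(axis=0)
                           for c in range(len(present))])
    return CNModel(window_size=window_size, k=len(present), n_types=T,
                   centroids=centroids, labels=labels, seed=seed)


def assign_neighborhoods(table: pd.DataFrame, *, w: int = 20, k: int = 15,
                         seed: int = 0, type_col: str = "phenotype",
                         image_col: str = "image_id",
                         include_center: bool = True) -> tuple[pd.DataFrame, CNModel]:
    """Convenience wrapper: windows -> compositions -> K-means -> ``cn`` column."""
    pts = table[["x", "y"]].to_numpy(dtype=float)
    types = table[type_col].to_numpy(dtype=int)
    n_types = int(types.max()) + 1 if len(types) else 0
    wins = knn_windows(pts, w=w, image_ids=table[image_col].to_numpy(),
                       include_center=include_center)
    comp = composition_vectors(wins, types, n_types)
    model = kmeans_cn(comp, k=k, seed=seed, window_size=w)
    out = table.copy()
    out["cn"] = model.labels
    return out, model


@dataclass
class VoronoiCell:
    cell_index: int
    polygon: Polygon
    cn: int


def voronoi_map(centroids: np.ndarray, cn_labels: np.ndarray,
                bounds: tuple[float, float, float, float]) -> list[VoronoiCell]:
    """Bounded Voronoi tessellation clipped to the field.

    ``bounds`` is (xmin, ymin, xmax, ymax). Each cell's region is made finite
    by mirroring the points across the four field edges before tessellating,
    then clipping to the field box. Fewer than 3 cells, or all-collinear
    cells, cannot be tessellated; use a plain scatter plot in that case.
    """
    from scipy.spatial import Voronoi

    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    cn_labels = np.asarray(cn_labels)
    n = len(pts)
    if n < 3:
        raise ValidationError(
            "Voronoi map needs >= 3 cells; fall back to a scatter plot")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
        raise ValidationError(
            "all cells are collinear; fall back to a scatter plot")
    xmin, ymin, xmax, ymax = bounds
    mirrors = [
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ]
    vor = Voronoi(np.vstack([pts] + mirrors))
    field = box(xmin, ymin, xmax, ymax)
    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(field)
        cells.append(VoronoiCell(i, poly, int(cn_labels[i])))
    return cells


def voronoi_to_frame(cells: list[VoronoiCell]) -> pd.DataFrame:
    """Polygon CSV export: cell index, CN class, vertex list as WKT."""
    return pd.DataFrame({
        "cell_index": [c.cell_index for c in cells],
        "cn": [c.cn for c in cells],
        "polygon_wkt": [c.polygon.wkt for c in cells],
    })


def plot_voronoi(cells: list[VoronoiCell], path=None, cmap: str = "tab20"):
    """Render the CN map (SVG/PNG via matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    fig, ax = plt.subplots(figsize=(6, 6))
    palette = colormaps[cmap]
    for c in cells:
        if c.polygon.is_empty:
            continue
        xs, ys = c.polygon.exterior.xy
        ax.fill(xs, ys, color=palette(c.cn % palette.N), edgecolor="white",
                linewidth=0.3)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_title("Cellular neighborhoods")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
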