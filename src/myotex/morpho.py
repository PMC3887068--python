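"""Per-cell morphometric features and per-specimen summaries.

Six features per myocyte: cross-sectional area (um^2), nucleus count,
eccentricity of the moment-matched ellipse, convexity (area / convex-hull
area), nearest-neighbour cell-to-cell distance (um) and pericellular area
(um^2).  "Pericellular area" is defined by partitioning the extracellular
(label-0) pixels inside the tissue region among cells by nearest-cell
assignment, which conserves the total extracellular area; the tissue region
is the convex hull of all cell pixels, so background outside the section
never enters the fraction.

Cell-to-cell distance is an edge-to-edge gap: the minimum pixel-centre
distance between one cell's boundary pixels and any other cell's, minus one
pixel (the two half-pixels the centres sit in), clipped at zero — so
perfectly abutting cells are 0 um apart and a g-pixel empty gap reads g um
at 1 um/px.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image

from .containers import LabelMap

__all__ = [
    "FEATURE_COLUMNS",
    "compute_cell_features",
    "cell_feature_table",
    "pericellular_area_map",
    "cell_to_cell_distances",
    "sample_cells",
    "specimen_summary",
]

FEATURE_COLUMNS = [
    "area_um2",
    "nuclei_count",
    "eccentricity",
    "convexity",
    "cell_to_cell_distance_um",
    "pericellular_area_um2",
]


def pericellular_area_map(label_map: LabelMap):
    """Per-cell pericellular area (um^2) and global pericellular fraction.

    Returns ``(per_cell, fraction)`` where ``per_cell`` is a
    ``pandas.Series`` indexed by cell id.  Every label-0 pixel inside the
    convex hull of the cells is assigned to its nearest cell via the
    Euclidean distance transform, so the per-cell areas sum to the total
    pericellular area exactly.
    """
    labels = label_map.labels
    if label_map.n_cells == 0:
        raise ValueError("no cells in label map")
    cell_mask = labels > 0
    hull = convex_hull_image(cell_mask)
    peri = hull & ~cell_mask
    # nearest-cell assignment of extracellular pixels
    _, (ir, ic) = ndi.distance_transform_edt(~cell_mask, return_indices=True)
    owner = labels[ir, ic]
    ids = label_map.cell_ids
    counts = np.bincount(owner[peri], minlength=int(ids.max()) + 1)
    px_area = label_map.pixel_size_um**2
    per_cell = pd.Series(counts[ids] * px_area, index=ids, name="pericellular_area_um2")
    fraction = float(peri.sum() / hull.sum())
    return per_cell, fraction


def _boundaries(labels: np.ndarray):
    """Per-cell boundary pixel coordinates (mask minus its erosion)."""
    out = {}
    for k, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == k
        bound = mask & ~ndi.binary_erosion(mask, border_value=0)
        pts = np.argwhere(bound).astype(float)
        pts += [sl[0].start, sl[1].start]
        out[k] = pts
    return out


def cell_to_cell_distances(label_map: LabelMap) -> pd.Series:
    """Nearest-neighbour boundary gap for every cell, in micrometres.

    With a single cell the distance is undefined and reported as NaN with a
    warning.
    """
    ids = label_map.cell_ids
    if len(ids) < 2:
        warnings.warn("cell-to-cell distance undefined with fewer than 2 cells")
        return pd.Series(np.nan, index=ids, name="cell_to_cell_distance_um")
    bounds = _boundaries(label_map.labels)
    all_pts = np.vstack([bounds[k] for k in ids])
    all_lab = np.concatenate([np.full(len(bounds[k]), k) for k in ids])
    tree = cKDTree(all_pts)
    out = {}
    kq = min(64, len(all_pts))
    for k in ids:
        pts = bounds[k]
        dist, idx = tree.query(pts, k=kq)
        other = all_lab[idx] != k
        if other.any():
            d = dist[other].min()
        else:  # all near neighbours were own pixels: exact per-cell fallback
            mask_other = all_lab != k
            d = cKDTree(all_pts[mask_other]).query(pts)[0].min()
        out[k] = max(d - 1.0, 0.0) * label_map.pixel_size_um
    return pd.Series(out, name="cell_to_cell_distance_um")


def _nuclei_counts(nuclei, ids) -> pd.Series:
    nuclei = np.asarray(nuclei).reshape(-1, 3)
    counts = pd.Series(0, index=ids, name="nuclei_count")
    if len(nuclei):
        vc = pd.Series(nuclei[:, 2]).value_counts()
        counts.loc[counts.index.intersection(vc.index)] = vc
    return counts.astype(int)


def cell_feature_table(label_map: LabelMap, nuclei, fish_id: str = "") -> pd.DataFrame:
    """All six features for every cell in the map.

    ``nuclei`` is an ``(n, 3)`` array of ``(row, col, cell_id)`` centroids.
    The returned frame has one row per cell with a ``border`` flag for cells
    touching the image frame (these are excluded later from sampling).
    """
    if label_map.n_cells == 0:
        raise ValueError("no cells in label map")
    px = label_map.pixel_size_um
    props = regionprops(label_map.labels)
    peri, _fraction = pericellular_area_map(label_map)
    dists = cell_to_cell_distances(label_map) if label_map.n_cells >= 2 else None
    nuc = _nuclei_counts(nuclei, label_map.cell_ids)
    rows = []
    for p in props:
        k = p.label
        rows.append({
            "fish_id": fish_id,
            "cell_id": k,
            "area_um2": p.area * px**2,
            "nuclei_count": int(nuc.get(k, 0)),
            "eccentricity": p.eccentricity,
            "convexity": p.solidity,
            "cell_to_cell_distance_um": (np.nan if dists is None
                                         else float(dists.get(k, np.nan))),
            "pericellular_area_um2": float(peri.get(k, 0.0)),
            "border": k in label_map.border_labels,
        })
    return pd.DataFrame(rows)


def compute_cell_features(label_map: LabelMap, nuclei, cell_id: int) -> pd.Series:
    """Feature row of a single cell (convenience over
    :func:`cell_feature_table`)."""
    table = cell_feature_table(label_map, nuclei)
    match = table[table["cell_id"] == cell_id]
    if match.empty:
        raise KeyError(f"cell_id {cell_id} not present in label map")
    return match.iloc[0]


def sample_cells(features: pd.DataFrame, n_target: int = 200,
                 seed: int = 0) -> pd.DataFrame:
    """Uniform random sample of non-border cells, without replacement.

    Sampling 200 cells per specimen mirrors the original morphometric
    protocol; when fewer are available the whole pool is returned with a
    warning.  Deterministic for a fixed seed.
    """
    pool = features[~features["border"]] if "border" in features else features
    if len(pool) == 0:
        raise ValueError("no non-border cells available to sample")
    if len(pool) < n_target:
        warnings.warn(f"only {len(pool)} cells available; requested {n_target}")
        n = len(pool)
    else:
        n = n_target
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)


def specimen_summary(features: pd.DataFrame, pericellular_fraction: float,
                     fish_id: str = None) -> pd.Series:
    """Per-specimen mean and sd of each feature plus the global
    pericellular fraction.

    The sd of a single-cell table is 0 by convention (logged).
    """
    if features.empty:
        raise ValueError("empty feature table")
    if fish_id is None:
        fish_id = features["fish_id"].iloc[0] if "fish_id" in features else ""
    out = {"fish_id": fish_id, "n_cells_sampled": len(features)}
    single = len(features) == 1
    if single:
        warnings.warn("single-cell table: sd reported as 0 by convention")
    for col in FEATURE_COLUMNS:
        vals = features[col].to_numpy(dtype=float)
        out[f"{col}_mean"] = float(np.nanmean(vals))
        if single or np.ptp(vals[np.isfinite(vals)]) == 0:
            out[f"{col}_sd"] = 0.0  # constant feature: exactly zero spread
        else:
            out[f"{col}_sd"] = float(np.nanstd(vals, ddof=1))
    out["pericellular_fraction"] = float(pericellular_fraction)
    return pd.Series(out)
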