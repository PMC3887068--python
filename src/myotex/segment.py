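"""Myocyte and nucleus segmentation from HE-like cross-section images.

The stage is "semi-automatic" in the sense of the original workflow:
markers for the marker-controlled watershed are proposed automatically from
the image, and a user-supplied seed set (one interior point per intended
cell) can override them, standing in for interactive correction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .containers import LabelMap, TissueImage

__all__ = ["preprocess_image", "segment_myocytes", "detect_nuclei", "SegmentParams"]


class SegmentParams:
    """Tunable knobs of the watershed stage.

    min_area_px
        Regions smaller than this are dropped to label 0 (default 100 px,
        well below any plausible myocyte cross-section).
    border_drop_fraction
        A cell whose frame-touching pixels exceed this fraction of its
        boundary is dropped; any frame contact at all flags the cell as
        ``border`` so feature sampling can exclude it.
    core_smooth_sigma_px
        Extra smoothing applied before proposing markers.
    """

    def __init__(self, min_area_px: int = 100, border_drop_fraction: float = 0.8,
                 core_smooth_sigma_px: float = 1.0):
        self.min_area_px = min_area_px
        self.border_drop_fraction = border_drop_fraction
        self.core_smooth_sigma_px = core_smooth_sigma_px


def _as_float_gray(image) -> np.ndarray:
    px = image.pixels if isinstance(image, TissueImage) else np.asarray(image)
    if px.size == 0:
        raise ValueError("empty image")
    if px.ndim == 3:
        px = rgb2gray(px)
    px = px.astype(float)
    if px.max() > 1.0:  # integer dtypes: rescale by full range
        px = px / np.iinfo(image.pixels.dtype if isinstance(image, TissueImage)
                           else np.asarray(image).dtype).max
    return px


def preprocess_image(image, smoothing_sigma_px: float = 1.0) -> np.ndarray:
    """Denoise and contrast-normalize to a single-channel float in [0, 1].

    RGB input is converted to luminance; a Gaussian filter with the given
    sigma denoises (sigma 0 leaves intensities rank-identical); min-max
    normalization maps the result onto [0, 1].  A constant image is
    returned unchanged apart from clipping (no NaNs).
    """
    px = _as_float_gray(image)
    if smoothing_sigma_px > 0:
        px = ndi.gaussian_filter(px, smoothing_sigma_px)
    lo, hi = px.min(), px.max()
    if hi - lo < 1e-12:
        return np.clip(px, 0.0, 1.0)
    return (px - lo) / (hi - lo)


def _propose_markers(pre: np.ndarray, foreground: np.ndarray,
                     params: SegmentParams) -> np.ndarray:
    """One marker blob per cell interior.

    Within the dark foreground, cell bodies are brighter than their
    membrane rings and than nuclei, so a second (foreground-restricted)
    Otsu split isolates the interiors; their connected components are the
    markers.
    """
    vals = pre[foreground]
    if vals.size == 0 or np.ptp(vals) < 1e-9:
        return np.zeros(pre.shape, dtype=np.int32)
    t_core = threshold_otsu(vals)
    # eroding the foreground kills thin bright bridges between near-abutting
    # cells that blurring pulled just under the background threshold
    inner = ndi.binary_erosion(foreground, iterations=2, border_value=1)
    core = inner & (ndi.gaussian_filter(pre, params.core_smooth_sigma_px)
                    > t_core)
    core = _drop_small(core, max(params.min_area_px // 4, 8))
    markers, _ = ndi.label(core)
    return markers.astype(np.int32)


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def segment_myocytes(image, params: SegmentParams = None, seeds=None,
                     pixel_size_um: float = None) -> LabelMap:
    """Marker-controlled watershed segmentation of myocytes.

    Parameters
    ----------
    image
        A :class:`TissueImage` or raw array; it is preprocessed internally.
    params
        :class:`SegmentParams`; defaults used when omitted.
    seeds
        Optional sequence of ``(row, col)`` interior markers, one per
        intended cell, overriding automatic marker proposal
        (``provenance="seeded"``).
    pixel_size_um
        Required when ``image`` is a bare array.

    Returns
    -------
    LabelMap
        Labels 1..K renumbered contiguously; cells touching the frame are
        kept but flagged in ``border_labels``.  An image where nothing
        segments yields an empty map with a warning, not an error.
    """
    params = params or SegmentParams()
    if isinstance(image, TissueImage):
        pixel_size_um = image.pixel_size_um
    elif pixel_size_um is None:
        raise ValueError("pixel_size_um required for bare arrays")
    pre = preprocess_image(image)

    provenance = "automatic"
    if np.ptp(pre) < 1e-9:
        warnings.warn("flat image: nothing to segment")
        return LabelMap(np.zeros(pre.shape, np.int32), pixel_size_um, provenance)

    # tissue foreground: everything darker than the bright background /
    # pericellular space
    t = threshold_otsu(pre)
    foreground = pre < t
    foreground = ndi.binary_fill_holes(foreground)

    if seeds is not None:
        markers = np.zeros(pre.shape, dtype=np.int32)
        for i, (r, c) in enumerate(np.asarray(seeds, dtype=float), start=1):
            r, c = int(round(r)), int(round(c))
            if not (0 <= r < pre.shape[0] and 0 <= c < pre.shape[1]):
                raise ValueError(f"seed ({r}, {c}) outside image bounds")
            markers[r, c] = i
        provenance = "seeded"
    else:
        markers = _propose_markers(pre, foreground, params)

    if markers.max() == 0:
        warnings.warn("no markers found: empty segmentation")
        return LabelMap(np.zeros(pre.shape, np.int32), pixel_size_um, provenance)

    labels = watershed(-pre, markers=markers, mask=foreground)
    labels = _filter_regions(labels, params)
    border = _flag_border(labels)
    return LabelMap(labels, pixel_size_um, provenance, frozenset(border))


def _filter_regions(labels: np.ndarray, params: SegmentParams) -> np.ndarray:
    """Drop small regions and heavily frame-truncated regions; renumber."""
    out = labels.astype(np.int32).copy()
    h, w = labels.shape
    frame = np.zeros_like(labels, dtype=bool)
    frame[0, :] = frame[-1, :] = frame[:, 0] = frame[:, -1] = True
    dropped = 0
    for k, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == k
        area = int(mask.sum())
        if area < params.min_area_px:
            out[sl][mask] = 0
            dropped += 1
            continue
        bound = mask & ~ndi.binary_erosion(mask, border_value=0)
        on_frame = int((bound & frame[sl]).sum())
        if on_frame > params.border_drop_fraction * max(int(bound.sum()), 1):
            out[sl][mask] = 0
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} region(s) below size/frame criteria")
    # renumber 1..K preserving label order
    ids = np.unique(out)
    ids = ids[ids > 0]
    remap = np.zeros(out.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[out]


def _flag_border(labels: np.ndarray) -> set:
    edge = np.concatenate([labels[0, :], labels[-1, :],
                           labels[:, 0], labels[:, -1]])
    return set(int(v) for v in np.unique(edge) if v > 0)


def detect_nuclei(image, label_map: LabelMap, threshold: float = 0.22,
                  min_px: int = 4) -> np.ndarray:
    """Dark-blob nucleus detection within segmented cells.

    Thresholding is on the absolute intensity scale (fraction of the image
    dtype's full range, not min-max normalized), so nuclei — the darkest
    structures — separate from membrane rings, and an image without dark
    blobs yields an empty result.  Blobs whose centroid falls in label-0
    space are discarded.

    Returns an ``(n, 3)`` array of ``(row, col, cell_id)``.
    """
    px = _as_float_gray(image)
    px = ndi.gaussian_filter(px, 0.5)
    mask = px < threshold
    mask = _drop_small(mask, min_px)
    blobs, n = ndi.label(mask)
    if n == 0:
        return np.zeros((0, 3), dtype=int)
    centroids = ndi.center_of_mass(mask, blobs, index=np.arange(1, n + 1))
    out = []
    for r, c in centroids:
        ri, ci = int(round(r)), int(round(c))
        cell = int(label_map.labels[ri, ci])
        if cell != 0:
            out.append((ri, ci, cell))
    return np.array(out, dtype=int).reshape(-1, 3)
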