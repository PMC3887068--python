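"""Synthetic data with known ground truth for the texture-analysis pipelines.

Three generators emulate the structure of the study data:

* :func:`generate_tissue_image` — an HE-like muscle cross-section built as a
  Voronoi mosaic of myocytes.  A single ``detachment`` knob contracts each
  cell toward its seed, opening pericellular (label-0) space between cells,
  which is the morphological correlate of soft fillet texture.
* :func:`generate_cohort` — a cohort of fish with breaking forces drawn over
  a given span and per-fish pericellular fractions following a quadratic
  (curvilinear, decreasing) relation to force, realised as tissue images.
* :func:`generate_spectra_set` — endomysial FT-IR absorbance spectra on the
  instrument grid (750 cm^-1 upward in 4 cm^-1 steps), as Gaussian bands
  distorted by per-spectrum multiplicative scaling, polynomial additive
  baselines and noise — exactly the distortion family EMSC removes.  Bands
  of sulfated glycosaminoglycans (850, 925, 1314 cm^-1) carry a larger
  amplitude in the "hard" group.

All randomness flows from a single integer seed through a local
``numpy.random.Generator``; fixed seed gives bit-identical output.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import convex_hull_image

from .containers import (
    Band,
    CohortSpec,
    FirmnessRecord,
    SpectraSet,
    TissueImage,
    TissueTruth,
)
from .firmstats import assign_firmness_group

__all__ = [
    "generate_tissue_image",
    "generate_cohort",
    "generate_spectra_set",
    "default_band_table",
    "CohortMember",
    "DEFAULT_RELATION_PARAMS",
]

# Quadratic pericellular-fraction-vs-force relation used by generate_cohort
# when CohortSpec.relation_params is None.  Chosen so the fraction is 0.30 at
# 6.6 N and 0.04 at 20.9 N with the curve's minimum at 23 N, i.e. decreasing
# and convex over the whole calibrated force span.
DEFAULT_RELATION_PARAMS = (0.555567568, -0.045208845, 0.000982801)

# Rendering intensities (fraction of full scale) for the synthetic HE image.
_BG_LEVEL = 0.92      # background and pericellular space
_CELL_LEVEL = 0.60    # myocyte interior
_BOUNDARY_LEVEL = 0.35  # cell membrane ring
_NUCLEUS_LEVEL = 0.10
_NUCLEUS_RADIUS_PX = 3


def _jittered_grid_seeds(n_cells, shape, rng):
    """Poisson-disk-like seed layout: a square grid with uniform jitter,
    subsampled to exactly ``n_cells`` points."""
    h, w = shape
    spacing = np.sqrt(h * w / n_cells)
    rows = int(np.ceil(h / spacing))
    cols = int(np.ceil(w / spacing))
    rr, cc = np.meshgrid(
        (np.arange(rows) + 0.5) * h / rows,
        (np.arange(cols) + 0.5) * w / cols,
        indexing="ij",
    )
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    jitter = rng.uniform(-0.3, 0.3, size=pts.shape) * spacing
    pts = np.clip(pts + jitter, [1, 1], [h - 2, w - 2])
    idx = rng.choice(len(pts), size=n_cells, replace=False)
    return pts[np.sort(idx)]


def generate_tissue_image(
    n_cells: int = 50,
    detachment: float = 0.15,
    pixel_size_um: float = 1.0,
    image_shape: tuple = (512, 512),
    seed: int = 0,
    noise_sd: float = 0.01,
    blur_sigma: float = 0.6,
):
    """Render one synthetic muscle cross-section and its ground truth.

    Parameters
    ----------
    n_cells
        Number of myocytes in the mosaic.
    detachment
        Mean contraction factor in ``[0, 1)`` pulling each cell toward its
        Voronoi seed; 0 gives a perfectly tiled section with no
        pericellular space.  Each cell's factor is jittered by +/-20 %.
    pixel_size_um, image_shape, seed
        Physical pixel size (um/px), raster size ``(rows, cols)``, RNG seed.
    noise_sd, blur_sigma
        Speckle noise standard deviation and Gaussian blur applied to the
        rendered image (the truth label map is never degraded).

    Returns
    -------
    (TissueImage, TissueTruth)
    """
    if not 0 <= detachment < 1:
        raise ValueError("detachment must lie in [0, 1)")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    h, w = image_shape
    if np.sqrt(h * w / n_cells) < 10:
        raise ValueError("overcrowded: mean cell diameter below 10 px")

    rng = np.random.default_rng(seed)
    seeds = _jittered_grid_seeds(n_cells, image_shape, rng)
    # per-cell contraction with +/-20 % jitter, drawn before use so the same
    # seed yields the same jitter at every detachment value
    jitter_u = rng.uniform(-0.2, 0.2, size=n_cells)
    contraction = np.clip(detachment * (1.0 + jitter_u), 0.0, 0.95)

    tree = cKDTree(seeds)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    _, owner = tree.query(pix)

    if detachment > 0:
        # a pixel stays in its cell iff its preimage under the contraction
        # (scaling about the cell seed) is still in the same Voronoi region
        scale = 1.0 - contraction[owner]
        pre = seeds[owner] + (pix - seeds[owner]) / scale[:, None]
        _, owner_pre = tree.query(pre)
        labels_flat = np.where(owner_pre == owner, owner + 1, 0)
    else:
        labels_flat = owner + 1
    label_map = labels_flat.reshape(h, w).astype(np.int32)

    nuclei = _place_nuclei(label_map, rng)
    img = _render(label_map, nuclei, rng, noise_sd, blur_sigma)

    hull = convex_hull_image(label_map > 0)
    tissue_px = int(hull.sum())
    peri_px = int((hull & (label_map == 0)).sum())
    fraction = peri_px / tissue_px if tissue_px else 0.0

    truth = TissueTruth(
        label_map=label_map,
        nuclei_centroids=nuclei,
        pericellular_fraction=fraction,
        pixel_size_um=pixel_size_um,
    )
    return TissueImage(pixels=img, pixel_size_um=pixel_size_um), truth


def _place_nuclei(label_map, rng, min_separation=6.0, margin=3):
    """1-4 nuclei per cell, near the cell periphery, pairwise separated.

    Candidates are mask pixels whose distance to the cell edge is between
    ``margin`` and ~40 % of the cell's inradius, matching the peripheral
    nuclear position of healthy myocytes.
    """
    out = []
    objects = ndi.find_objects(label_map)
    for k, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = label_map[sl] == k
        dist = ndi.distance_transform_edt(mask)
        dmax = dist.max()
        lo, hi = margin, max(margin + 1, 0.4 * dmax)
        cand = np.argwhere((dist >= lo) & (dist <= hi))
        if len(cand) == 0:
            cand = np.argwhere(dist >= min(margin, dmax * 0.5))
        if len(cand) == 0:
            continue
        n_nuc = int(rng.integers(1, 5))
        order = rng.permutation(len(cand))
        chosen = []
        for i in order:
            p = cand[i]
            if all(np.hypot(*(p - q)) >= min_separation for q in chosen):
                chosen.append(p)
                if len(chosen) == n_nuc:
                    break
        for p in chosen:
            out.append((p[0] + sl[0].start, p[1] + sl[1].start, k))
    return np.array(out, dtype=int).reshape(-1, 3)


def _render(label_map, nuclei, rng, noise_sd, blur_sigma):
    h, w = label_map.shape
    img = np.full((h, w), _BG_LEVEL, dtype=float)
    cell_mask = label_map > 0
    # slight per-cell shade variation, as in real staining
    n_cells = int(label_map.max())
    shades = _CELL_LEVEL + rng.uniform(-0.03, 0.03, size=n_cells + 1)
    img[cell_mask] = shades[label_map[cell_mask]]
    # ~2 px membrane ring inside each cell
    eroded = np.zeros_like(cell_mask)
    for k, sl in enumerate(ndi.find_objects(label_map), start=1):
        if sl is None:
            continue
        m = label_map[sl] == k
        eroded[sl] |= ndi.binary_erosion(m, iterations=2, border_value=0)
    img[cell_mask & ~eroded] = _BOUNDARY_LEVEL
    if len(nuclei):
        yy, xx = np.mgrid[-_NUCLEUS_RADIUS_PX : _NUCLEUS_RADIUS_PX + 1,
                          -_NUCLEUS_RADIUS_PX : _NUCLEUS_RADIUS_PX + 1]
        disk = yy**2 + xx**2 <= _NUCLEUS_RADIUS_PX**2
        dy, dx = np.nonzero(disk)
        dy, dx = dy - _NUCLEUS_RADIUS_PX, dx - _NUCLEUS_RADIUS_PX
        for r, c, _k in nuclei:
            rs, cs = r + dy, c + dx
            ok = (rs >= 0) & (rs < h) & (cs >= 0) & (cs < w)
            img[rs[ok], cs[ok]] = _NUCLEUS_LEVEL
    if blur_sigma > 0:
        img = ndi.gaussian_filter(img, blur_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 1)
    return (img * 255).round().astype(np.uint8)


class CohortMember:
    """One simulated fish: firmness record, tissue image, ground truth, and
    the noiseless-model pericellular fraction targeted for it."""

    __slots__ = ("record", "image", "truth", "model_fraction")

    def __init__(self, record, image, truth, model_fraction):
        self.record = record
        self.image = image
        self.truth = truth
        self.model_fraction = model_fraction

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.record, self.image, self.truth))


def generate_cohort(spec: CohortSpec) -> list:
    """Simulate a firmness-spanning cohort of fish with tissue sections.

    Breaking forces are uniform over ``spec.force_range_N``; each fish's
    target pericellular fraction is ``c0 + c1*F + c2*F**2`` plus Gaussian
    noise, clipped to ``[0, 0.5]``, and the tissue image's detachment is set
    to realise that fraction (area removed by contracting every cell by a
    factor ``d`` is ``1 - (1-d)**2`` of the section, so ``d = 1 - sqrt(1-f)``).
    """
    params = spec.relation_params or DEFAULT_RELATION_PARAMS
    c0, c1, c2 = params
    lo, hi = spec.force_range_N
    grid = np.linspace(lo, hi, 201)
    model = c0 + c1 * grid + c2 * grid**2
    if not np.any((model >= 0) & (model <= 0.5)):
        raise ValueError("infeasible relation: model fraction outside [0, 0.5] "
                         "over the whole force range")

    rng = np.random.default_rng(spec.seed)
    if spec.group_stratified:
        from .firmstats import GROUP_BOUNDS_N

        if spec.n_fish % len(GROUP_BOUNDS_N):
            raise ValueError("group_stratified requires n_fish divisible by "
                             f"{len(GROUP_BOUNDS_N)}")
        per = spec.n_fish // len(GROUP_BOUNDS_N)
        forces = np.concatenate([rng.uniform(glo, ghi, size=per)
                                 for glo, ghi in GROUP_BOUNDS_N.values()])
    else:
        forces = rng.uniform(lo, hi, size=spec.n_fish)
    members = []
    for i, force in enumerate(forces):
        target = c0 + c1 * force + c2 * force**2
        if spec.noise_sd > 0:
            target += rng.normal(0, spec.noise_sd)
        target = float(np.clip(target, 0.0, 0.5))
        detachment = 1.0 - np.sqrt(1.0 - target)
        image, truth = generate_tissue_image(
            n_cells=spec.n_cells,
            detachment=detachment,
            pixel_size_um=spec.pixel_size_um,
            image_shape=spec.image_shape,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        record = FirmnessRecord(
            fish_id=f"fish_{i + 1:02d}",
            breaking_force_N=float(force),
            group=assign_firmness_group(float(force)),
        )
        members.append(CohortMember(record, image, truth, target))
    return members


def default_band_table() -> list:
    """Endomysial connective-tissue band model.

    Protein amide and C-H bands are common to both texture groups; the three
    sulfated-glycosaminoglycan bands (850, 925, 1314 cm^-1) are amplified in
    the hard group, reflecting the higher Aggrecan-type glycoprotein content
    of firm-fillet endomysium.
    """
    return [
        Band(3300.0, 60.0, 0.55),   # amide A (N-H stretch)
        Band(2930.0, 35.0, 0.45),   # C-H stretch
        Band(1655.0, 28.0, 1.00),   # amide I
        Band(1548.0, 22.0, 0.65),   # amide II
        Band(1240.0, 20.0, 0.30),   # amide III
        Band(1080.0, 24.0, 0.28),   # carbohydrate C-O
        Band(1314.0, 12.0, 0.16, hard_multiplier=1.6),  # sulfated GAG
        Band(925.0, 10.0, 0.10, hard_multiplier=1.8),   # sulfated GAG
        Band(850.0, 10.0, 0.12, hard_multiplier=1.8),   # sulfated GAG
    ]


def instrument_grid(lo_cm1: float = 750.0, hi_cm1: float = 4000.0,
                    step_cm1: float = 4.0) -> np.ndarray:
    """Wavenumber grid anchored at the lower bound, ascending in fixed steps
    up to (and not beyond) the upper bound."""
    n = int(np.floor((hi_cm1 - lo_cm1) / step_cm1)) + 1
    return lo_cm1 + step_cm1 * np.arange(n)


def generate_spectra_set(
    n_per_group: int = 30,
    bands: list = None,
    seed: int = 0,
    scale_range: tuple = (0.7, 1.3),
    offset_range: tuple = (-0.05, 0.05),
    slope_range: tuple = (-0.02, 0.02),
    curvature_range: tuple = (-0.02, 0.02),
    noise_sd: float = 0.001,
    grid: np.ndarray = None,
) -> SpectraSet:
    """Simulate hard- and soft-group endomysial absorbance spectra.

    Each spectrum is ``b * signal + a + d1*x + d2*x**2 + noise`` where
    ``signal`` is the Gaussian band sum for the spectrum's group, ``x`` is
    the wavenumber rescaled to [-1, 1], and ``(a, b, d1, d2)`` are drawn
    uniformly per spectrum from the stated ranges — the multiplicative /
    polynomial-baseline distortion family of the EMSC model.  Soft-group
    rows come first; ``groups`` carries the labels.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    bands = default_band_table() if bands is None else bands
    wn = instrument_grid() if grid is None else np.asarray(grid, dtype=float)
    for band in bands:
        if not wn[0] <= band.center_cm1 <= wn[-1]:
            warnings.warn(f"band centre {band.center_cm1} cm^-1 outside grid")

    def band_sum(hard: bool) -> np.ndarray:
        y = np.zeros_like(wn)
        for band in bands:
            amp = band.amplitude * (band.hard_multiplier if hard else 1.0)
            y += amp * np.exp(-0.5 * ((wn - band.center_cm1) / band.width_cm1) ** 2)
        return y

    signals = {"soft": band_sum(False), "hard": band_sum(True)}
    x = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0

    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = np.array(["soft"] * n_per_group + ["hard"] * n_per_group)
    b = rng.uniform(*scale_range, size=n)
    a = rng.uniform(*offset_range, size=n)
    d1 = rng.uniform(*slope_range, size=n)
    d2 = rng.uniform(*curvature_range, size=n)
    spectra = np.empty((n, wn.size))
    for i in range(n):
        clean = signals[groups[i]]
        spectra[i] = b[i] * clean + a[i] + d1[i] * x + d2[i] * x**2
    if noise_sd > 0:
        spectra += rng.normal(0, noise_sd, size=spectra.shape)
    return SpectraSet(
        wavenumbers=wn,
        absorbance=spectra,
        groups=groups,
        processing_log=[{"step": "generate_spectra_set", "seed": seed,
                         "n_per_group": n_per_group, "noise_sd": noise_sd}],
    )
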