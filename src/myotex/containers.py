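"""Shared data containers for the histomorphometry and spectroscopy pipelines.

Pixel coordinates are 0-based ``(row, col)`` throughout; physical areas are
``pixel count * pixel_size_um**2`` and distances are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The five instrumental-firmness classes, ordered soft -> hard, plus the
#: fallback for breaking forces outside the calibrated span.
FIRMNESS_GROUPS = ("soft", "low", "medium", "high", "hard")
UNCLASSIFIED = "unclassified"


@dataclass
class TissueImage:
    """A grayscale muscle cross-section raster with its physical pixel size."""

    pixels: np.ndarray  # 2-D, uint8 or float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("tissue image must be 2-D (or RGB 3-D)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class TissueTruth:
    """Ground truth attached to a simulated tissue image.

    ``label_map`` uses 0 for extracellular (pericellular) space and
    contiguous labels ``1..K`` for the K myocytes.  ``nuclei_centroids`` is
    an ``(n, 3)`` array of ``(row, col, cell_id)``.  ``pericellular_fraction``
    is the fraction of tissue-region pixels (convex hull of all cell pixels)
    that carry label 0.
    """

    label_map: np.ndarray
    nuclei_centroids: np.ndarray
    pericellular_fraction: float
    pixel_size_um: float

    @property
    def n_cells(self) -> int:
        return int(self.label_map.max())


@dataclass
class LabelMap:
    """Integer-labelled myocyte segmentation.

    Label 0 is background / pericellular space; nonzero labels are cells,
    renumbered contiguously.  ``border_labels`` flags cells touching the
    image frame; those are kept for pericellular accounting but excluded
    from per-cell feature sampling because truncation biases shape features.
    """

    labels: np.ndarray
    pixel_size_um: float
    provenance: str = "automatic"  # {"truth", "automatic", "seeded"}
    border_labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.provenance not in ("truth", "automatic", "seeded"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def interior_cell_ids(self) -> np.ndarray:
        """Cell ids not flagged as touching the image border."""
        return np.array(
            [i for i in self.cell_ids if i not in self.border_labels], dtype=int
        )


@dataclass
class FirmnessRecord:
    """Instrumental firmness of one fish: breaking force of a flat-cylinder
    puncture test, in Newton, and the texture class it falls in."""

    fish_id: str
    breaking_force_N: float
    group: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.breaking_force_N <= 0:
            raise ValueError("breaking force must be positive")


@dataclass
class CohortSpec:
    """Parameters of a simulated fish cohort.

    ``relation_params`` are the quadratic coefficients ``(c0, c1, c2)`` of the
    pericellular-fraction-vs-breaking-force model plus the standard deviation
    of the per-fish Gaussian deviation from that curve.
    """

    n_fish: int = 15
    force_range_N: tuple = (6.6, 20.9)
    relation_params: tuple = None  # (c0, c1, c2); default set in synthgen
    noise_sd: float = 0.01
    seed: int = 0
    n_cells: int = 50
    image_shape: tuple = (512, 512)
    pixel_size_um: float = 1.0
    #: draw n_fish/5 forces inside each of the five class intervals instead
    #: of uniformly over the whole span, mirroring a selection design that
    #: guarantees every texture group is represented
    group_stratified: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.force_range_N
        if not lo < hi:
            raise ValueError("force_range_N must satisfy min < max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_fish < 1:
            raise ValueError("n_fish must be at least 1")


@dataclass
class Band:
    """One Gaussian absorbance band: centre and width in cm^-1, base
    amplitude in absorbance units, and the multiplier applied to the
    amplitude in the hard-texture group (1.0 = no group difference)."""

    center_cm1: float
    width_cm1: float
    amplitude: float
    hard_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.width_cm1 <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0 or self.hard_multiplier < 0:
            raise ValueError("band amplitudes must be non-negative")


@dataclass
class SpectraSet:
    """A matrix of absorbance spectra on a shared, evenly spaced wavenumber
    grid, with optional group labels and a log of applied processing steps.

    ``absorbance`` has one row per spectrum; column j corresponds to
    ``wavenumbers[j]``.  Every processing operation appends a
    ``{"step": name, **params}`` entry to ``processing_log`` so a chain can
    be re-run verbatim.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    groups: Optional[np.ndarray] = None
    processing_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError("absorbance column count must match grid length")
        dv = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not np.all(dv > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.size != self.absorbance.shape[0]:
                raise ValueError("one group label per spectrum required")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def grid_step(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def copy_with(self, absorbance=None, wavenumbers=None, log_entry=None) -> "SpectraSet":
        """Return a new set sharing labels, with an appended log entry."""
        new = SpectraSet(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            absorbance=self.absorbance if absorbance is None else absorbance,
            groups=None if self.groups is None else self.groups.copy(),
            processing_log=list(self.processing_log),
        )
        if log_entry is not None:
            new.processing_log.append(log_entry)
        return new
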