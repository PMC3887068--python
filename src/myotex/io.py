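"""Readers and writers for the pipeline's on-disk formats.

Images are 8-bit grayscale PNG/TIFF, label maps 16-bit single-channel TIFF,
ground-truth metadata JSON sidecars, spectra plain CSV with a
``wavenumber_cm-1`` first column and one column per spectrum, group labels
in a companion CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.io import imread, imsave

from .containers import LabelMap, SpectraSet, TissueImage, TissueTruth


def save_image(image: TissueImage, path) -> None:
    path = Path(path)
    px = image.pixels
    if px.dtype != np.uint8:
        px = np.clip(px, 0, 1) if px.max() <= 1 else px / px.max()
        px = (px * 255).round().astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        imsave(path, px, check_contrast=False)


def load_image(path, pixel_size_um: float) -> TissueImage:
    return TissueImage(pixels=imread(path), pixel_size_um=pixel_size_um)


def save_labelmap(label_map: LabelMap, path) -> None:
    labels = label_map.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label map")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))
    sidecar = Path(path).with_suffix(".json")
    sidecar.write_text(json.dumps({
        "pixel_size_um": label_map.pixel_size_um,
        "provenance": label_map.provenance,
        "border_labels": sorted(int(b) for b in label_map.border_labels),
    }, indent=2))


def load_labelmap(path) -> LabelMap:
    labels = tifffile.imread(Path(path)).astype(np.int32)
    sidecar = Path(path).with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return LabelMap(
        labels,
        pixel_size_um=meta.get("pixel_size_um", 1.0),
        provenance=meta.get("provenance", "automatic"),
        border_labels=frozenset(meta.get("border_labels", ())),
    )


def save_truth_json(truth: TissueTruth, path) -> None:
    Path(path).write_text(json.dumps({
        "pericellular_fraction": truth.pericellular_fraction,
        "pixel_size_um": truth.pixel_size_um,
        "n_cells": truth.n_cells,
        "nuclei_centroids": truth.nuclei_centroids.tolist(),
    }, indent=2))


def save_spectra_csv(spectra: SpectraSet, path, groups_path=None) -> None:
    path = Path(path)
    cols = {"wavenumber_cm-1": spectra.wavenumbers}
    for i in range(spectra.n_spectra):
        cols[f"spectrum_{i:03d}"] = spectra.absorbance[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    if spectra.groups is not None:
        gp = Path(groups_path) if groups_path else path.with_name(
            path.stem + "_groups.csv")
        pd.DataFrame({
            "spectrum": [f"spectrum_{i:03d}" for i in range(spectra.n_spectra)],
            "group": spectra.groups,
        }).to_csv(gp, index=False)


def load_spectra_csv(path, groups_path=None) -> SpectraSet:
    df = pd.read_csv(Path(path))
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    absorbance = df.iloc[:, 1:].to_numpy(dtype=float).T
    groups = None
    if groups_path is not None:
        gdf = pd.read_csv(Path(groups_path))
        order = {name: i for i, name in enumerate(df.columns[1:])}
        gdf = gdf.sort_values("spectrum", key=lambda s: s.map(order))
        groups = gdf["group"].to_numpy()
    return SpectraSet(wavenumbers=wn, absorbance=absorbance, groups=groups)
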