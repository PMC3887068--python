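import warnings

import numpy as np
import pytest

from myotex import segment, spectra, synthgen
from myotex.containers import CohortSpec
from myotex.pipeline import analyze_cohort


@pytest.fixture(scope="session")
def default_tissue():
    """The reference synthetic section: 50 cells, detachment 0.15, seed 1."""
    return synthgen.generate_tissue_image(n_cells=50, detachment=0.15, seed=1)


@pytest.fixture(scope="session")
def default_segmentation(default_tissue):
    image, _truth = default_tissue
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segment.segment_myocytes(image)


@pytest.fixture(scope="session")
def default_spectra():
    """30 spectra per texture group at generator defaults, seed 1."""
    return synthgen.generate_spectra_set(n_per_group=30, seed=1)


@pytest.fixture(scope="session")
def corrected_spectra(default_spectra):
    """Second derivative followed by EMSC against the set mean."""
    deriv = spectra.sg_second_derivative(default_spectra)
    return spectra.emsc_correct(deriv).corrected


@pytest.fixture(scope="session")
def cohort_analysis():
    """Low-noise 15-fish cohort pushed through morphometry on truth labels."""
    members = synthgen.generate_cohort(CohortSpec(noise_sd=0.01, seed=11))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, summaries, groups, fit = analyze_cohort(
            members, use_truth_labels=True)
    return members, records, summaries, groups, fit


def match_truth_cells(truth_labels: np.ndarray, pred_labels: np.ndarray):
    """Per-truth-cell IoU against the best-overlapping predicted cell."""
    ious = []
    for k in range(1, int(truth_labels.max()) + 1):
        mask = truth_labels == k
        vals, counts = np.unique(pred_labels[mask], return_counts=True)
        order = np.argsort(-counts)
        best = 0
        for i in order:
            if vals[i] != 0:
                best = vals[i]
                break
        if best == 0:
            ious.append(0.0)
            continue
        pred = pred_labels == best
        ious.append(float((mask & pred).sum() / (mask | pred).sum()))
    return np.array(ious)
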