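"""End-to-end convenience drivers tying the modules together.

`analyze_specimen` takes one tissue image to a specimen summary; the
`analyze_cohort` driver runs a whole simulated cohort through morphometry,
grouping, and the group-level curvilinear regression of pericellular
fraction on breaking force.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import morpho, segment
from .containers import LabelMap
from .firmstats import CurvilinearFit, fit_firmness_vs_pericellular, group_summary


def analyze_specimen(image, fish_id: str = "", n_sample: int = 200,
                     seed: int = 0, label_map: LabelMap = None,
                     seeds=None) -> pd.Series:
    """Segment one cross-section (unless a label map is supplied), compute
    features, sample cells, and summarize the specimen."""
    if label_map is None:
        label_map = segment.segment_myocytes(image, seeds=seeds)
    nuclei = segment.detect_nuclei(image, label_map)
    table = morpho.cell_feature_table(label_map, nuclei, fish_id=fish_id)
    sampled = morpho.sample_cells(table, n_target=n_sample, seed=seed)
    _, fraction = morpho.pericellular_area_map(label_map)
    return morpho.specimen_summary(sampled, fraction, fish_id=fish_id)


def truth_label_map(truth) -> LabelMap:
    """Wrap a simulator ground truth as a LabelMap (provenance "truth"),
    flagging frame-touching cells like the automatic stage does."""
    labels = truth.label_map
    edge = np.concatenate([labels[0, :], labels[-1, :],
                           labels[:, 0], labels[:, -1]])
    border = frozenset(int(v) for v in np.unique(edge) if v > 0)
    return LabelMap(labels, truth.pixel_size_um, provenance="truth",
                    border_labels=border)


def analyze_cohort(members, n_sample: int = 200, seed: int = 0,
                   use_truth_labels: bool = False):
    """Morphometry + firmness statistics for a simulated cohort.

    Returns ``(records, summaries, groups, fit)``: per-fish firmness
    records and specimen summaries as DataFrames, the per-group mean table,
    and the quadratic :class:`CurvilinearFit` of group-mean pericellular
    fraction on group-mean breaking force.
    """
    rng = np.random.default_rng(seed)
    rec_rows, sum_rows = [], []
    for m in members:
        lm = truth_label_map(m.truth) if use_truth_labels else None
        summary = analyze_specimen(
            m.image, fish_id=m.record.fish_id, n_sample=n_sample,
            seed=int(rng.integers(0, 2**31 - 1)), label_map=lm,
        )
        sum_rows.append(summary)
        rec_rows.append({"fish_id": m.record.fish_id,
                         "breaking_force_N": m.record.breaking_force_N,
                         "group": m.record.group})
    records = pd.DataFrame(rec_rows)
    summaries = pd.DataFrame(sum_rows)
    groups = group_summary(records, summaries)
    fit = fit_firmness_vs_pericellular(
        groups["breaking_force_N"], groups["pericellular_fraction"])
    return records, summaries, groups, fit
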