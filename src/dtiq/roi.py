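"""ROI aggregation: voxel-wise metric maps -> long-format metric table.

The metric table is the unit of exchange with the statistics stage: one
row per (subject, timepoint, ROI, metric) holding the ROI-mean value and
the voxel count, serialised as CSV with a fixed header.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import ROI_NAMES, SyntheticCohort

__all__ = [
    "METRIC_NAMES",
    "TABLE_COLUMNS",
    "extract_roi_means",
    "assemble_cohort_table",
]

METRIC_NAMES = ("MD", "FA", "L", "q")
TABLE_COLUMNS = ("subject_id", "group", "timepoint", "roi", "metric", "value", "n_voxels")

# map map-dict keys (lowercase) to table metric names
_MAP_KEYS = {"MD": "md", "FA": "fa", "L": "l", "q": "q"}


def extract_roi_means(
    metric_maps: dict[str, np.ndarray],
    label_map: np.ndarray,
    roi_vocabulary: dict[str, int],
) -> pd.DataFrame:
    """ROI-mean of each metric map over each labelled region.

    NaN voxels (non-fitted) inside an ROI are excluded from the mean and
    from the reported voxel count.

    Parameters
    ----------
    metric_maps : dict with keys ``md``, ``fa``, ``l``, ``q`` (3-D arrays).
    label_map : integer volume on the same grid.
    roi_vocabulary : mapping ROI name -> integer code; every listed code
        must be present in the label map.

    Returns
    -------
    DataFrame with columns ``roi, metric, value, n_voxels``.

    Raises
    ------
    ValueError on grid mismatch or a missing/empty ROI.
    """
    label_map = np.asarray(label_map)
    rows = []
    for roi, code in roi_vocabulary.items():
        in_roi = label_map == code
        if not np.any(in_roi):
            raise ValueError(f"ROI {roi!r} (code {code}) missing from label map")
        for metric in METRIC_NAMES:
            volume = np.asarray(metric_maps[_MAP_KEYS[metric]])
            if volume.shape != label_map.shape:
                raise ValueError(
                    f"metric map {metric} grid {volume.shape} != labels {label_map.shape}"
                )
            values = volume[in_roi]
            values = values[np.isfinite(values)]
            if values.size == 0:
                raise ValueError(f"ROI {roi!r} has no fitted voxels for {metric}")
            rows.append(
                {
                    "roi": roi,
                    "metric": metric,
                    "value": float(values.mean()),
                    "n_voxels": int(values.size),
                }
            )
    return pd.DataFrame(rows, columns=["roi", "metric", "value", "n_voxels"])


def assemble_cohort_table(
    cohort: SyntheticCohort,
    maps_by_key: dict[tuple[str, str], dict[str, np.ndarray]],
) -> pd.DataFrame:
    """Assemble the complete long-format metric table for a cohort.

    ``maps_by_key`` maps (subject_id, timepoint) to that acquisition's
    metric maps.  The result has exactly one row per (subject, timepoint,
    ROI, metric) and is sorted canonically (subject, timepoint, ROI,
    metric order as declared), so shuffled inputs yield identical tables.

    Raises
    ------
    ValueError naming every missing (subject, timepoint) pair.
    """
    expected = [
        (sid, tp) for sid, _ in cohort.subjects for tp in cohort.spec.timepoints
    ]
    missing = [key for key in expected if key not in maps_by_key]
    if missing:
        raise ValueError(f"missing subject-timepoint maps: {missing}")

    vocabulary = {
        name: ROI_NAMES.index(name) + 1 for name in cohort.phantom.roi_names
    }
    frames = []
    for sid, tp in expected:
        part = extract_roi_means(maps_by_key[(sid, tp)], cohort.label_map, vocabulary)
        part.insert(0, "subject_id", sid)
        part.insert(1, "group", cohort.group_of(sid))
        part.insert(2, "timepoint", tp)
        frames.append(part)
    table = pd.concat(frames, ignore_index=True)

    order = {
        "subject_id": {s: i for i, (s, _) in enumerate(cohort.subjects)},
        "timepoint": {t: i for i, t in enumerate(cohort.spec.timepoints)},
        "roi": {r: i for i, r in enumerate(vocabulary)},
        "metric": {m: i for i, m in enumerate(METRIC_NAMES)},
    }
    table = table.sort_values(
        ["subject_id", "timepoint", "roi", "metric"],
        key=lambda col: col.map(order[col.name]),
        kind="stable",
    ).reset_index(drop=True)

    cells = table[["subject_id", "timepoint", "roi", "metric"]]
    if cells.duplicated().any():
        raise ValueError("duplicate (subject, timepoint, ROI, metric) rows")
    return table[list(TABLE_COLUMNS)]
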