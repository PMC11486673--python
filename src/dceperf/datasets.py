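"""Bundled reference cohort: per-dog mean Ktrans and rBF values.

A published canine cohort of ten intracranial tumours imaged with DCE-MRI:
after one exclusion for an unusable arterial input function, six dogs with
histopathologically confirmed meningiomas and three with mimicking tumours
(histiocytic sarcoma, glial cell tumour, granular cell tumour) entered the
analysis. The tables below carry the per-dog VOI means exactly as printed —
the paired table at five decimals, the group table at nine for the
meningioma Ktrans column — so the package's exact tests can be exercised on
real desk-scale data without any image download. Ktrans is in min^-1; rBF
values are the source software's unitless flow estimates (all comparisons
are rank-based, so units cancel).
"""

from __future__ import annotations

import pandas as pd

from .voistats import VOISummary

__all__ = ["paired_meningioma_table", "group_comparison_table", "cohort_summaries"]

# CE tumour VOI vs contralateral control VOI, six meningioma dogs.
_PAIRED = {
    "ktrans_tumour": [0.07554, 0.10379, 0.011755, 0.031141, 0.054707, 0.039027],
    "ktrans_control": [0.001555, 0.007604, 0.000313, 0.006121, 0.003139, 0.000417],
    "rbf_tumour": [8.182527, 10.46861, 2.773495, 2.008031, 5.798886, 2.747369],
    "rbf_control": [0.661594, 1.27435, 0.127114, 0.623004, 0.797508, 1.087866],
}

# Meningioma group vs other intracranial tumours, tumour VOI values.
_GROUPS = {
    "ktrans_meningioma": [0.075540319, 0.103790104, 0.011755032, 0.031140747, 0.054707296, 0.039027199],
    "ktrans_other": [0.019257911, 0.012620783, 0.016456641],
    "rbf_meningioma": [8.182527, 10.46861, 2.773495, 2.008031, 5.798886, 2.747369],
    "rbf_other": [1.62082, 1.347984, 1.561967],
}


def paired_meningioma_table() -> pd.DataFrame:
    """Tumour and control VOI means for the six meningioma dogs."""
    return pd.DataFrame(_PAIRED)


def group_comparison_table() -> dict[str, list[float]]:
    """Tumour VOI means split by histopathological group (unequal lengths)."""
    return {k: list(v) for k, v in _GROUPS.items()}


def cohort_summaries() -> list[VOISummary]:
    """The cohort as VOISummary rows, ready for group_comparison_report.

    Meningioma rows use the higher-precision group-table Ktrans values; the
    paired control rows come from the paired table. Voxel counts and volumes
    were not published and are filled with placeholders / NaN.
    """
    rows: list[VOISummary] = []
    for i in range(6):
        sid = f"men{i + 1}"
        rows.append(VOISummary(sid, "meningioma", "tumour_CE", 1, 0,
                               _GROUPS["ktrans_meningioma"][i], _GROUPS["rbf_meningioma"][i]))
        rows.append(VOISummary(sid, "meningioma", "control", 1, 0,
                               _PAIRED["ktrans_control"][i], _PAIRED["rbf_control"][i]))
    for i in range(3):
        rows.append(VOISummary(f"oth{i + 1}", "other", "tumour_CE", 1, 0,
                               _GROUPS["ktrans_other"][i], _GROUPS["rbf_other"][i]))
    return rows
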