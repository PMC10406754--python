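"""Per-case agreement metrics between reference and predicted label volumes.

Implements the standard overlap metrics for 3D segmentation evaluation —
Dice, Jaccard, true positive rate — plus the symmetric mean surface distance
(MSD) in millimetres and physical structure volumes in mL.

Conventions (all flagged in the output rather than silently applied):

* both masks empty -> Dice = Jaccard = 1 (perfect agreement on absence);
* reference empty  -> TPR = 1;
* either mask empty -> MSD is missing (``None`` / NaN), never a sentinel
  number, and cohort summaries report how many cases were excluded.

Surface extraction uses 6-connectivity face neighbours with the grid edge
counting as outside; distances are Euclidean between voxel centres scaled by
the voxel spacing, and the symmetric MSD is the arithmetic mean of the two
directed mean distances.  Directed components are exposed so either reading
of "mean surface distance" can be reconstructed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .label_volumes import LabelMap, LabelVolume, check_comparable

__all__ = [
    "CaseMetrics",
    "binary_counts",
    "dice",
    "jaccard",
    "tpr",
    "boundary_mask",
    "directed_surface_distances",
    "mean_surface_distance",
    "label_volume_ml",
    "evaluate_case",
    "summarize_metrics",
    "metrics_to_csv",
    "metrics_from_csv",
    "METRIC_CSV_COLUMNS",
]

METRIC_CSV_COLUMNS = [
    "case_id",
    "label",
    "dice",
    "jaccard",
    "tpr",
    "msd_mm",
    "ref_volume_ml",
    "pred_volume_ml",
    "ref_empty",
    "pred_empty",
]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class CaseMetrics:
    """Agreement record for one case and one named label."""

    case_id: str
    label_name: str
    dice: float
    jaccard: float
    tpr: float
    msd_mm: float | None  # None when either mask is empty
    ref_volume_ml: float
    pred_volume_ml: float
    ref_empty: bool
    pred_empty: bool


def binary_counts(
    reference: LabelVolume, prediction: LabelVolume, label: int
) -> tuple[int, int, int]:
    """Voxelwise (TP, FP, FN) for one label.

    TP: both volumes carry ``label``; FP: prediction only; FN: reference only.
    """
    check_comparable(reference, prediction)
    ref = reference.mask(label)
    pred = prediction.mask(label)
    tp = int(np.count_nonzero(ref & pred))
    fp = int(np.count_nonzero(pred) - tp)
    fn = int(np.count_nonzero(ref) - tp)
    return tp, fp, fn


def dice(tp: int, fp: int, fn: int) -> float:
    """Dice coefficient 2·TP/(2·TP+FP+FN); 1 when both masks are empty."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def jaccard(tp: int, fp: int, fn: int) -> float:
    """Jaccard index TP/(TP+FP+FN); 1 when both masks are empty."""
    denom = tp + fp + fn
    if denom == 0:
        return 1.0
    return tp / denom


def tpr(tp: int, fn: int) -> float:
    """True positive rate TP/(TP+FN); 1 when the reference is empty."""
    denom = tp + fn
    if denom == 0:
        return 1.0
    return tp / denom


def boundary_mask(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask voxels with a face-adjacent outside neighbour.

    The grid edge counts as outside, so a mask touching the edge has boundary
    there (``border_value=0`` in the erosion).
    """
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    interior = ndimage.binary_erosion(
        mask, structure=_FACE_STRUCTURE, border_value=0
    )
    return mask & ~interior


def directed_surface_distances(
    reference: LabelVolume, prediction: LabelVolume, label: int
) -> tuple[float, float] | None:
    """Directed mean boundary distances (ref->pred, pred->ref) in mm.

    Returns ``None`` if either mask is empty.  Each direction averages, over
    the boundary voxels of one mask, the Euclidean distance (voxel centres
    scaled by spacing) to the nearest boundary voxel of the other mask.
    """
    check_comparable(reference, prediction)
    ref_b = boundary_mask(reference.mask(label))
    pred_b = boundary_mask(prediction.mask(label))
    if not ref_b.any() or not pred_b.any():
        return None
    spacing = np.asarray(reference.spacing)
    ref_pts = np.argwhere(ref_b) * spacing
    pred_pts = np.argwhere(pred_b) * spacing
    d_ref_to_pred = cKDTree(pred_pts).query(ref_pts)[0].mean()
    d_pred_to_ref = cKDTree(ref_pts).query(pred_pts)[0].mean()
    return float(d_ref_to_pred), float(d_pred_to_ref)


def mean_surface_distance(
    reference: LabelVolume, prediction: LabelVolume, label: int
) -> float | None:
    """Symmetric MSD in mm, or ``None`` if either mask is empty."""
    directed = directed_surface_distances(reference, prediction, label)
    if directed is None:
        return None
    return 0.5 * (directed[0] + directed[1])


def label_volume_ml(volume: LabelVolume, label: int) -> float:
    """Physical volume of a label in millilitres (1 mL = 1000 mm^3)."""
    count = int(np.count_nonzero(volume.mask(label)))
    return count * volume.voxel_volume_mm3 / 1000.0


def evaluate_case(
    reference: LabelVolume,
    prediction: LabelVolume,
    labels: LabelMap | None = None,
    case_id: str | None = None,
) -> list[CaseMetrics]:
    """Full per-label agreement record for one reference/prediction pair."""
    check_comparable(reference, prediction)
    if labels is None:
        labels = LabelMap()
    if case_id is None:
        case_id = reference.source_id or prediction.source_id
    records = []
    for name, value in labels.items():
        tp, fp, fn = binary_counts(reference, prediction, value)
        ref_empty = (tp + fn) == 0
        pred_empty = (tp + fp) == 0
        records.append(
            CaseMetrics(
                case_id=case_id,
                label_name=name,
                dice=dice(tp, fp, fn),
                jaccard=jaccard(tp, fp, fn),
                tpr=tpr(tp, fn),
                msd_mm=mean_surface_distance(reference, prediction, value),
                ref_volume_ml=label_volume_ml(reference, value),
                pred_volume_ml=label_volume_ml(prediction, value),
                ref_empty=ref_empty,
                pred_empty=pred_empty,
            )
        )
    return records


def summarize_metrics(records: Sequence[CaseMetrics]) -> pd.DataFrame:
    """Per-label mean ± sample SD (ddof=1) for each metric.

    Missing MSD values are excluded from the MSD mean/SD; the count of values
    actually used is reported per metric (``n_*`` columns).  With a single
    record the SD is reported as 0.0 and ``n == 1`` makes that visible.
    """
    if not records:
        raise ValueError("no metric records to summarize")
    rows = []
    frame = pd.DataFrame([asdict(r) for r in records])
    for label_name, group in frame.groupby("label_name", sort=True):
        row: dict[str, object] = {"label": label_name, "n_cases": len(group)}
        for metric in ("dice", "jaccard", "tpr", "msd_mm", "ref_volume_ml", "pred_volume_ml"):
            values = group[metric].dropna().astype(float)
            n = len(values)
            row[f"{metric}_mean"] = float(values.mean()) if n else math.nan
            row[f"{metric}_sd"] = float(values.std(ddof=1)) if n > 1 else 0.0
            row[f"{metric}_n"] = n
        row["msd_missing"] = int(group["msd_mm"].isna().sum())
        rows.append(row)
    return pd.DataFrame(rows)


def metrics_to_csv(records: Iterable[CaseMetrics], path: str | Path) -> None:
    """Write per-case metrics as CSV; missing MSD serialises as an empty cell."""
    frame = pd.DataFrame([asdict(r) for r in records])
    frame = frame.rename(columns={"label_name": "label"})[METRIC_CSV_COLUMNS]
    frame.to_csv(path, index=False)


def metrics_from_csv(path: str | Path) -> list[CaseMetrics]:
    """Read a metrics CSV written by :func:`metrics_to_csv`."""
    frame = pd.read_csv(path)
    missing = set(METRIC_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        msd = getattr(row, "msd_mm")
        records.append(
            CaseMetrics(
                case_id=str(row.case_id),
                label_name=str(row.label),
                dice=float(row.dice),
                jaccard=float(row.jaccard),
                tpr=float(row.tpr),
                msd_mm=None if pd.isna(msd) else float(msd),
                ref_volume_ml=float(row.ref_volume_ml),
                pred_volume_ml=float(row.pred_volume_ml),
                ref_empty=bool(row.ref_empty),
                pred_empty=bool(row.pred_empty),
            )
        )
    return records
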