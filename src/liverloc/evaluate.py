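"""Tumour-centre localisation accuracy: reference centres, target
registration error (TRE), observer averaging, per-tumour method ranking and
summary tables.

The reference standard for a tumour is the centre of gravity of its
volumetric segmentation on the original intraprocedural scan. The TRE of a
method is the Euclidean distance (mm) between the centre the method
annotated on the virtually unenhanced CT and that reference centre; a
perfect match gives 0 mm. Tumours for which any method failed (e.g. a
registration whose livers do not overlap) are excluded from the paired
comparison for *all* methods, preserving the paired design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Mask
from .phantom import ObserverAnnotationSet

__all__ = [
    "TRERecord",
    "StudyTable",
    "centre_of_gravity",
    "tre",
    "average_observers",
    "rank_methods",
    "summarize",
]

#: canonical method names, in reporting order
METHODS = ("non-rigid", "rigid", "mental")

#: truth variants: centre-of-gravity of the volumetric segmentation
#: (computer methods) vs the expert's in-plane annotation (mental method)
TRUTH_COMPUTED = "computed"
TRUTH_IN_PLANE = "in-plane"


@dataclass
class TRERecord:
    tumour_id: str
    method: str
    annotated_centre_mm: np.ndarray | None
    truth_centre_mm: np.ndarray
    tre_mm: float | None
    failed: bool = False
    truth_variant: str = TRUTH_COMPUTED
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.failed:
            self.tre_mm = None
        elif self.tre_mm is None:
            raise ValueError("non-failed record needs a TRE")
        elif self.tre_mm < 0:
            raise ValueError("TRE cannot be negative")


@dataclass
class StudyTable:
    """All per-tumour, per-method localisation records of an experiment."""

    records: list = field(default_factory=list)

    def add(self, record: TRERecord) -> None:
        self.records.append(record)

    @property
    def methods(self) -> list:
        seen = []
        for r in self.records:
            if r.method not in seen:
                seen.append(r.method)
        return seen

    @property
    def tumour_ids(self) -> list:
        seen = []
        for r in self.records:
            if r.tumour_id not in seen:
                seen.append(r.tumour_id)
        return seen

    def excluded_tumours(self) -> list:
        """Tumours with at least one failed method (excluded pairwise)."""
        return sorted({r.tumour_id for r in self.records if r.failed})

    def ranked_tumours(self) -> list:
        """Tumours that have a valid TRE for every method."""
        excluded = set(self.excluded_tumours())
        per_tumour: dict[str, set] = {}
        for r in self.records:
            if r.tumour_id not in excluded and not r.failed:
                per_tumour.setdefault(r.tumour_id, set()).add(r.method)
        want = set(self.methods)
        return [t for t in self.tumour_ids if per_tumour.get(t, set()) == want]

    def tre_matrix(self) -> pd.DataFrame:
        """Ranked tumours × methods matrix of TREs (mm)."""
        ranked = self.ranked_tumours()
        lut = {(r.tumour_id, r.method): r.tre_mm for r in self.records if not r.failed}
        return pd.DataFrame(
            {m: [lut[(t, m)] for t in ranked] for m in self.methods},
            index=pd.Index(ranked, name="tumour_id"),
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            a = r.annotated_centre_mm
            t = r.truth_centre_mm
            rows.append(
                {
                    "case_id": r.case_id,
                    "tumour_id": r.tumour_id,
                    "method": r.method,
                    "annot_x_mm": None if a is None else float(a[0]),
                    "annot_y_mm": None if a is None else float(a[1]),
                    "annot_z_mm": None if a is None else float(a[2]),
                    "truth_x_mm": float(t[0]),
                    "truth_y_mm": float(t[1]),
                    "truth_z_mm": float(t[2]),
                    "tre_mm": r.tre_mm,
                    "failed": r.failed,
                    "truth_variant": r.truth_variant,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StudyTable":
        table = cls()
        for _, row in df.iterrows():
            failed = bool(row["failed"])
            annot = (
                None
                if failed or pd.isna(row["annot_x_mm"])
                else np.array([row["annot_x_mm"], row["annot_y_mm"], row["annot_z_mm"]])
            )
            table.add(
                TRERecord(
                    tumour_id=str(row["tumour_id"]),
                    method=str(row["method"]),
                    annotated_centre_mm=annot,
                    truth_centre_mm=np.array(
                        [row["truth_x_mm"], row["truth_y_mm"], row["truth_z_mm"]]
                    ),
                    tre_mm=None if failed else float(row["tre_mm"]),
                    failed=failed,
                    truth_variant=str(row.get("truth_variant", TRUTH_COMPUTED)),
                    case_id=str(row.get("case_id", "")),
                )
            )
        return table


def centre_of_gravity(tumour_mask: Mask) -> np.ndarray:
    """Unweighted centroid of the member-voxel centres, in world mm."""
    if tumour_mask.is_empty():
        raise ValueError("cannot compute the centre of gravity of an empty mask")
    idx = np.argwhere(tumour_mask.data)
    return tumour_mask.voxel_to_world(idx).mean(axis=0)


def tre(annotated_mm, truth_mm) -> float:
    """Target registration error: Euclidean distance in mm."""
    a = np.asarray(annotated_mm, dtype=float).reshape(3)
    t = np.asarray(truth_mm, dtype=float).reshape(3)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(t))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - t))


def average_observers(annotations: ObserverAnnotationSet | np.ndarray) -> np.ndarray:
    """Component-wise mean annotation per tumour over observers.

    Accepts an :class:`ObserverAnnotationSet` or a raw
    ``(n_observers, n_tumours, 3)`` array; missing values (NaN) raise,
    naming the gaps.
    """
    ann = (
        annotations.annotations_mm
        if isinstance(annotations, ObserverAnnotationSet)
        else np.asarray(annotations, dtype=float)
    )
    if ann.ndim != 3 or ann.shape[2] != 3 or ann.shape[0] < 1:
        raise ValueError("annotations must have shape (n_observers, n_tumours, 3)")
    missing = np.argwhere(np.isnan(ann).any(axis=2))
    if len(missing):
        gaps = ", ".join(f"(observer {o}, tumour {t})" for o, t in missing)
        raise ValueError(f"missing annotations: {gaps}")
    return ann.mean(axis=0)


def rank_methods(table: StudyTable) -> pd.DataFrame:
    """Winner counts: per ranked tumour, the method with the strictly
    smallest TRE is most accurate. Exact ties leave the tumour without a
    winner (counted separately) — awarding ties would bias the counts.
    Percentages are over ranked tumours, to 1 decimal.
    """
    matrix = table.tre_matrix()
    if matrix.empty:
        raise ValueError("no ranked tumours to compare")
    wins = {m: 0 for m in matrix.columns}
    ties = 0
    for _, row in matrix.iterrows():
        best = row.min()
        winners = row.index[row == best]
        if len(winners) == 1:
            wins[winners[0]] += 1
        else:
            ties += 1
    if ties:
        warnings.warn(f"{ties} tumour(s) had an exact TRE tie; no winner recorded", stacklevel=2)
    n = len(matrix)
    out = pd.DataFrame(
        {
            "wins": [wins[m] for m in matrix.columns],
            "n_ranked": n,
            "percent": [round(100.0 * wins[m] / n, 1) for m in matrix.columns],
        },
        index=pd.Index(matrix.columns, name="method"),
    )
    out.attrs["ties"] = ties
    return out


def summarize(table: StudyTable) -> pd.DataFrame:
    """Per-method median, mean, sample sd and n over ranked tumours (mm, 1
    decimal in the formatted columns; sd absent for a single record)."""
    matrix = table.tre_matrix()
    if matrix.empty:
        raise ValueError("no ranked tumours to summarise")
    rows = []
    for m in matrix.columns:
        vals = matrix[m].to_numpy(dtype=float)
        rows.append(
            {
                "method": m,
                "n": len(vals),
                "median_tre_mm": float(np.median(vals)),
                "mean_tre_mm": float(np.mean(vals)),
                "sd_tre_mm": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("method")
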