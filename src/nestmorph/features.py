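"""The eight per-core mathematical parameters of tumor-nest morphology.

For a core with nests i = 1..n, of pixel area ``A_i`` and contour perimeter
``P_i`` (Moore chain-code length, axial step 1, diagonal step sqrt(2)):

=========================  =====================================
number                     n
total_perimeter            sum_i P_i
average_perimeter          (sum_i P_i) / n
total_area                 sum_i A_i
average_area               (sum_i A_i) / n
ta_over_tp                 (sum_i A_i) / (sum_i P_i)
avg_a_over_p               (1/n) sum_i (A_i / P_i)
circularity                (1/n) sum_i (4 pi A_i / P_i^2)
=========================  =====================================

All geometric quantities are in pixels; no micron conversion is attempted.
Circularity is 1 for a continuous disk and is deliberately not clamped:
digitization can push small objects slightly above 1, and the minimum-size
filter in the segmentation layer bounds that distortion.

The perimeter convention is the single most consequential choice here and is
recorded in every output row (``perimeter_convention`` metadata constant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import NestSegmentation, contour_chain_length

__all__ = [
    "NestShape",
    "CoreFeatures",
    "FEATURE_COLUMNS",
    "PERIMETER_CONVENTION",
    "measure_nest",
    "measure_all_nests",
    "compute_core_features",
    "features_frame",
    "nest_frame",
    "aggregate_patients",
]

PERIMETER_CONVENTION = "moore-chain-code(axial=1,diagonal=sqrt2)"

FEATURE_COLUMNS = (
    "number",
    "total_perimeter",
    "average_perimeter",
    "total_area",
    "average_area",
    "ta_over_tp",
    "avg_a_over_p",
    "circularity",
)


@dataclass(frozen=True)
class NestShape:
    """Area (pixel count) and perimeter (chain-code length) of one nest."""

    nest_id: int
    area_px: float
    perimeter_px: float


@dataclass(frozen=True)
class CoreFeatures:
    """The 8 mathematical parameters of one core.

    A core with zero nests is ``degenerate``: ``number`` and the totals are
    0 and every ratio/average field is NaN (missing); degenerate cores are
    excluded from downstream grading rather than imputed.
    """

    core_id: str
    number: int
    total_perimeter: float
    average_perimeter: float
    total_area: float
    average_area: float
    ta_over_tp: float
    avg_a_over_p: float
    circularity: float
    degenerate: bool = False

    def to_row(self) -> dict:
        row = {"core_id": self.core_id}
        for c in FEATURE_COLUMNS:
            row[c] = getattr(self, c)
        row["degenerate"] = self.degenerate
        row["perimeter_convention"] = PERIMETER_CONVENTION
        return row


def measure_nest(segmentation: NestSegmentation, nest_id: int) -> NestShape:
    """Pixel area and Moore-contour perimeter of one labeled nest."""
    if nest_id not in segmentation.contours:
        raise KeyError(f"nest_id {nest_id} not present in segmentation")
    area = int((segmentation.label_mask == nest_id).sum())
    perimeter = contour_chain_length(segmentation.contours[nest_id])
    return NestShape(nest_id=nest_id, area_px=float(area), perimeter_px=perimeter)


def measure_all_nests(segmentation: NestSegmentation) -> list[NestShape]:
    return [measure_nest(segmentation, k) for k in sorted(segmentation.contours)]


def compute_core_features(shapes: Sequence[NestShape], core_id: str = "") -> CoreFeatures:
    """Evaluate the 8 parameters from per-nest areas and perimeters."""
    n = len(shapes)
    if n == 0:
        nan = float("nan")
        return CoreFeatures(core_id=core_id, number=0, total_perimeter=0.0,
                            average_perimeter=nan, total_area=0.0,
                            average_area=nan, ta_over_tp=nan,
                            avg_a_over_p=nan, circularity=nan, degenerate=True)
    A = np.array([s.area_px for s in shapes], float)
    P = np.array([s.perimeter_px for s in shapes], float)
    if np.any(P <= 0):
        raise ValueError("every nest must have a positive perimeter")
    if np.any(A <= 0):
        raise ValueError("every nest must have a positive area")
    ta, tp = float(A.sum()), float(P.sum())
    return CoreFeatures(
        core_id=core_id,
        number=n,
        total_perimeter=tp,
        average_perimeter=tp / n,
        total_area=ta,
        average_area=ta / n,
        ta_over_tp=ta / tp,
        avg_a_over_p=float(np.mean(A / P)),
        circularity=float(np.mean(4.0 * np.pi * A / P**2)),
    )


def features_frame(features: Iterable[CoreFeatures],
                   patient_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """One CSV-ready row per core; optionally with a patient_id column."""
    rows = [f.to_row() for f in features]
    df = pd.DataFrame(rows)
    if patient_ids is not None:
        df.insert(1, "patient_id", list(patient_ids))
    return df


def nest_frame(segmentation: NestSegmentation, core_id: str = "") -> pd.DataFrame:
    """Nest-level table (nest_id, area, perimeter) for one core."""
    shapes = measure_all_nests(segmentation)
    return pd.DataFrame({
        "core_id": core_id,
        "nest_id": [s.nest_id for s in shapes],
        "area_px": [s.area_px for s in shapes],
        "perimeter_px": [s.perimeter_px for s in shapes],
    })


def aggregate_patients(df: pd.DataFrame, how: str = "mean") -> pd.DataFrame:
    """Aggregate per-core features to one row per patient.

    Degenerate (zero-nest) cores are dropped with no imputation; a patient
    whose every core is degenerate disappears from the output.  ``how`` is
    one of ``mean`` (default), ``max`` or ``first``.
    """
    if how not in ("mean", "max", "first"):
        raise ValueError("how must be one of {'mean', 'max', 'first'}")
    if "patient_id" not in df.columns:
        raise ValueError("features table lacks a patient_id column")
    ok = df.loc[~df["degenerate"].astype(bool)]
    g = ok.groupby("patient_id", sort=True)[list(FEATURE_COLUMNS)]
    return getattr(g, how)().reset_index()
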