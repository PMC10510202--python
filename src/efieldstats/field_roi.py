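"""Spherical region-of-interest averaging of sampled E-fields.

The outcome measure for every protocol is the mean E-field magnitude
(Euclidean norm, V/m) within a 10 mm-radius sphere centred on the
stimulation target, restricted to gray matter.  Solver meshes are
abstracted as weighted point samples (element centroid + volume), so any
discretization that can be exported as points works.  Averaging is
volume-weighted by default; pass equal weights for an unweighted mean.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FieldSample",
    "ROISpec",
    "EmptyROIError",
    "roi_mean_magnitude",
    "read_field_samples",
    "write_field_samples",
    "MOTOR_ROI",
    "PREFRONTAL_ROI",
]

FIELD_COLUMNS = ("x_mm", "y_mm", "z_mm", "volume_mm3", "tissue", "Ex", "Ey", "Ez")


class EmptyROIError(ValueError):
    """No sample passed the sphere-and-tissue filter (distinct from a zero field)."""


@dataclass(frozen=True)
class FieldSample:
    """A spatial E-field sample: position (mm, RAS), volume weight (mm^3),
    tissue label, and field vector (V/m)."""

    position: tuple[float, float, float]
    weight: float
    tissue: str
    field: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"sample weight must be positive, got {self.weight}")
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite sample position {self.position}")


@dataclass(frozen=True)
class ROISpec:
    """A spherical ROI: centre (mm), radius (mm), and the tissue labels
    admitted to the average (None = no tissue filtering)."""

    center: tuple[float, float, float]
    radius: float
    tissue_filter: frozenset[str] | None = frozenset({"gray_matter"})

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")


# Cortical projections of the C3 (motor) and F3 (prefrontal) scalp sites,
# MNI coordinates in mm.
MOTOR_ROI = ROISpec(center=(-52.2, -16.4, 57.8), radius=10.0)
PREFRONTAL_ROI = ROISpec(center=(-35.5, 49.4, 32.4), radius=10.0)


def roi_mean_magnitude(
    samples: Sequence[FieldSample],
    roi: ROISpec,
    weighted: bool = True,
) -> float:
    """Mean E-field magnitude over samples inside the ROI sphere.

    A sample is included when ``||position - center|| <= radius`` (closed
    boundary) and its tissue label is admitted by ``roi.tissue_filter``.
    With ``weighted=True`` the mean is weighted by sample volume.

    Raises :class:`EmptyROIError` when no sample passes the filter.
    """
    samples = list(samples)
    if not samples:
        raise EmptyROIError("no field samples supplied")
    pos = np.array([s.position for s in samples], dtype=float)
    vec = np.array([s.field for s in samples], dtype=float)
    w = np.array([s.weight for s in samples], dtype=float)
    inside = np.linalg.norm(pos - np.asarray(roi.center, dtype=float), axis=1) <= roi.radius
    if roi.tissue_filter is not None:
        tissue_ok = np.array([s.tissue in roi.tissue_filter for s in samples])
        inside &= tissue_ok
    if not inside.any():
        raise EmptyROIError(
            f"no sample within {roi.radius} mm of {roi.center} "
            f"with tissue in {sorted(roi.tissue_filter) if roi.tissue_filter else 'any'}"
        )
    mags = np.linalg.norm(vec[inside], axis=1)
    if not weighted:
        return float(mags.mean())
    return float(np.average(mags, weights=w[inside]))


def read_field_samples(path: str | Path) -> list[FieldSample]:
    """Read a delimited field-sample table (columns: x_mm,y_mm,z_mm,
    volume_mm3,tissue,Ex,Ey,Ez)."""
    df = pd.read_csv(path)
    missing = set(FIELD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FieldSample(
            position=(float(r.x_mm), float(r.y_mm), float(r.z_mm)),
            weight=float(r.volume_mm3),
            tissue=str(r.tissue),
            field=(float(r.Ex), float(r.Ey), float(r.Ez)),
        )
        for r in df.itertuples(index=False)
    ]


def write_field_samples(samples: Iterable[FieldSample], path: str | Path) -> None:
    rows = [
        (*s.position, s.weight, s.tissue, *s.field)
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(FIELD_COLUMNS)).to_csv(path, index=False)
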