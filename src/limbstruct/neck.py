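"""Superior/inferior cortical thickness of femoral-neck sections.

In transverse sections through the femoral neck, the ratio of superior to
inferior cortical thickness separates habitual bipeds from other hominoids:
the human abductor mechanism concentrates compressive load on the inferior
cortex, giving thin superior and thick inferior walls (ratios well below 1),
while more generalized loading in apes keeps the two similar. The
measurement here is the cortical intercept length of a superoinferior line
through the section, taken separately through the superior and inferior
cortex.

Masks must be oriented with the superior direction at the top of the image
(row 0 side); anterior/posterior orientation is irrelevant to the
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SectionGeometryError, SectionMask

__all__ = ["NeckCortexMeasurement", "measure_neck_cortices"]

LOCATIONS = ("mid-neck", "neck-base")


@dataclass
class NeckCortexMeasurement:
    """Superior and inferior cortical thicknesses (mm) and their ratio."""

    superior_thickness: float
    inferior_thickness: float
    ratio: float
    location: str = "mid-neck"

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}")


def _runs(column: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs in a 1-D boolean array as (start, stop) pairs."""
    padded = np.concatenate(([False], column, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    stops = np.nonzero(diff == -1)[0]
    return list(zip(starts, stops))


def measure_neck_cortices(
    mask: SectionMask, axis_x: float = 0.0, location: str = "mid-neck"
) -> NeckCortexMeasurement:
    """Measure superior and inferior cortical intercepts along a vertical line.

    The measurement line is vertical (superoinferior) and placed ``axis_x``
    mm mediolaterally from the cortical-area centroid (default 0: through
    the centroid itself). Each thickness is the total cortical intercept of
    the line on that side of the centroid — the sum of contiguous cortical
    runs, so single-pixel cracks do not zero the measurement. The line must
    cross the cortex exactly twice (one superior wall, one inferior wall).

    Whether the section is mid-neck or base-of-neck is metadata only; the
    procedure is identical.
    """
    arr = mask.oriented()
    if not arr.any():
        raise SectionGeometryError("mask contains no cortical pixels")
    ps = float(mask.pixel_size)
    rows, cols = np.nonzero(arr)
    c_col = cols.mean()
    c_row = rows.mean()
    col = int(round(c_col + axis_x / ps))
    if not (0 <= col < arr.shape[1]):
        raise SectionGeometryError(
            f"measurement line at axis_x={axis_x} mm falls outside the image"
        )
    column = arr[:, col]
    runs = _runs(column)
    if len(runs) != 2:
        raise SectionGeometryError(
            f"measurement line crosses the cortex {len(runs)} times; "
            "expected exactly 2 (superior and inferior walls)"
        )
    # image row 0 is superior; classify runs by their position relative to
    # the centroid row
    runs_sorted = sorted(runs, key=lambda r: r[0])
    sup_start, sup_stop = runs_sorted[0]
    inf_start, inf_stop = runs_sorted[1]
    if sup_start > c_row or inf_stop < c_row:
        raise SectionGeometryError(
            "cortical intercepts do not bracket the section centroid"
        )
    superior = (sup_stop - sup_start) * ps
    inferior = (inf_stop - inf_start) * ps
    if superior <= 0 or inferior <= 0:
        raise SectionGeometryError("degenerate (zero-thickness) cortical intercept")
    return NeckCortexMeasurement(
        superior_thickness=float(superior),
        inferior_thickness=float(inferior),
        ratio=float(superior / inferior),
        location=location,
    )
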