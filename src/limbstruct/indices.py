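"""Derived indices: bilateral asymmetry, property conversions, strength ratios.

Comparative datasets assembled over decades rarely share one measurement
protocol, so a handful of conversions are standard machinery: polar section
moduli approximated from the polar second moment as J^0.75, planar moduli
from planar second moments as SMA^0.73, regression transfers between nearby
section locations (e.g. humeral 35% from 40%), and simple mean-ratio
adjustments. Bilateral asymmetry of paired elements is scored as the signed
percent difference ((R - L) / ((R + L) / 2)) * 100, positive when the right
side is stronger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .allometry import AllometryError, BivariateSample

__all__ = [
    "FossilRecord",
    "ConversionModel",
    "bilateral_asymmetry",
    "asymmetry_sensitivity",
    "power_convert",
    "fit_conversion",
    "apply_conversion",
    "strength_ratio",
]

#: Numeric fields a fossil record may carry (all optional, all > 0 if present).
FOSSIL_FIELDS = (
    "F50Zp", "H35Zp", "FHDSI", "TPLML", "HDARTML",
    "F80Zx", "F80Zy", "length_prime", "neck_length",
)


@dataclass
class FossilRecord:
    """One comparative fossil individual with a sparse set of measurements.

    Section moduli in mm^3, articular breadths and lengths in mm. Fields:
    F50Zp / H35Zp — femoral 50% and humeral 35% polar section moduli;
    FHDSI — femoral head superoinferior breadth; TPLML / HDARTML — proximal
    tibial and distal humeral M-L articular breadths; F80Zx / F80Zy —
    femoral 80% A-P and M-L section moduli; length_prime — biomechanical
    bone length; neck_length — femoral biomechanical neck length.
    """

    taxon: str
    specimen: str
    date_myr: float | None = None
    F50Zp: float | None = None
    H35Zp: float | None = None
    FHDSI: float | None = None
    TPLML: float | None = None
    HDARTML: float | None = None
    F80Zx: float | None = None
    F80Zy: float | None = None
    length_prime: float | None = None
    neck_length: float | None = None

    def __post_init__(self) -> None:
        for name in FOSSIL_FIELDS:
            v = getattr(self, name)
            if v is not None:
                v = float(v)
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(f"{self.specimen}: field {name} must be > 0")
                setattr(self, name, v)

    def get(self, name: str) -> float | None:
        if name not in FOSSIL_FIELDS:
            raise KeyError(f"unknown fossil variable {name!r}")
        return getattr(self, name)


def bilateral_asymmetry(right: float, left: float) -> float:
    """Signed percent bilateral asymmetry, ((R - L) / ((R + L) / 2)) * 100.

    Positive values mean the right side is larger/stronger. Bounded in
    (-200, 200) for positive inputs.
    """
    if right <= 0 or left <= 0:
        raise ValueError("right and left values must be positive")
    return (right - left) / ((right + left) / 2.0) * 100.0


def asymmetry_sensitivity(
    right_series: Sequence[tuple[float, float]],
    left_series: Sequence[tuple[float, float]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Asymmetry over every pairing of right and left section offsets.

    When the exact proximodistal concordance of right and left sections is
    uncertain, the asymmetry is recomputed for all combinations of candidate
    locations (offsets in mm from the best estimate on each side). Returns
    the full pairing table and a min/median/max summary.
    """
    if not len(right_series) or not len(left_series):
        raise ValueError("offset series must be non-empty")
    rows = []
    for r_off, r_val in right_series:
        for l_off, l_val in left_series:
            rows.append(
                {
                    "right_offset_mm": float(r_off),
                    "left_offset_mm": float(l_off),
                    "right": float(r_val),
                    "left": float(l_val),
                    "asymmetry_pct": bilateral_asymmetry(r_val, l_val),
                }
            )
    table = pd.DataFrame(rows)
    asym = table["asymmetry_pct"]
    summary = {
        "min": float(asym.min()),
        "median": float(asym.median()),
        "max": float(asym.max()),
    }
    return table, summary


def power_convert(value: float, exponent: float) -> float:
    """Power-law surrogate for a section modulus, e.g. Zp ~ J^0.75, Z ~ SMA^0.73."""
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError("value must be positive")
    out = value**exponent
    return float(out) if out.ndim == 0 else out


@dataclass
class ConversionModel:
    """A fitted conversion between two related structural measurements.

    Exactly one parameterization is populated depending on ``kind``:
    ``power`` -> exponent (y = x^exponent, fitted through the origin on
    log10 scale); ``loglinear`` -> slope and intercept of a least-squares
    fit of log10 y on log10 x; ``mean-ratio`` -> the arithmetic mean of the
    pairwise ratios y/x.
    """

    kind: str
    exponent: float | None = None
    slope: float | None = None
    intercept: float | None = None
    ratio: float | None = None
    r: float | None = None
    pct_see: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("power", "loglinear", "mean-ratio"):
            raise ValueError(f"unknown conversion kind {self.kind!r}")


def fit_conversion(pairs: BivariateSample, kind: str) -> ConversionModel:
    """Fit a conversion model of the given kind to paired measurements."""
    x = np.asarray(pairs.x, dtype=float)
    y = np.asarray(pairs.y, dtype=float)
    if pairs.pre_logged:
        raise AllometryError("conversion fits expect raw (unlogged) pairs")
    if kind == "mean-ratio":
        return ConversionModel(
            kind=kind, ratio=float(np.mean(y / x)), source=pairs.label
        )
    if x.size < 3:
        raise AllometryError("regression conversions need at least 3 pairs")
    lx = np.log10(x)
    ly = np.log10(y)
    if lx.std() == 0:
        raise AllometryError("degenerate variance in conversion predictor")
    r = float(np.corrcoef(lx, ly)[0, 1])
    if kind == "power":
        # through-origin least squares on log scale: pure exponent surrogate
        exponent = float((lx * ly).sum() / (lx * lx).sum())
        resid = ly - exponent * lx
        see = float(np.sqrt((resid**2).sum() / (lx.size - 1)))
        return ConversionModel(
            kind=kind, exponent=exponent, r=r,
            pct_see=(10.0**see - 1.0) * 100.0, source=pairs.label,
        )
    if kind == "loglinear":
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (intercept + slope * lx)
        see = float(np.sqrt((resid**2).sum() / (lx.size - 2)))
        return ConversionModel(
            kind=kind, slope=float(slope), intercept=float(intercept), r=r,
            pct_see=(10.0**see - 1.0) * 100.0, source=pairs.label,
        )
    raise ValueError(f"unknown conversion kind {kind!r}")


def apply_conversion(model: ConversionModel, value: float) -> float:
    """Apply a fitted conversion to a raw measurement."""
    value = np.asarray(value, dtype=float)
    if model.kind == "mean-ratio":
        out = model.ratio * value
    else:
        if np.any(value <= 0):
            raise ValueError("log-scale conversions require positive input")
        if model.kind == "power":
            out = value**model.exponent
        else:
            out = 10.0 ** (model.intercept + model.slope * np.log10(value))
    return float(out) if out.ndim == 0 else out


def strength_ratio(numerator: float, denominator: float) -> float:
    """Simple strength/size ratio, e.g. F80Zy/F80Zx or femoral/humeral Zp."""
    if numerator <= 0 or denominator <= 0:
        raise ValueError("ratio inputs must be positive")
    return numerator / denominator
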