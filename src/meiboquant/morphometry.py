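"""Eye-opening (palpebral fissure) shape metrics.

The fissure outline is treated as an ellipse with semi-major axis a and
semi-minor axis b measured under a slit lamp.  Two equivalent scalars
describe its elongation: the eccentricity e = sqrt(1 - b^2/a^2) (0 for
a round eye, approaching 1 for a slit) and the short-to-long axis ratio
b/a (1 for a round eye).  They satisfy e^2 + (b/a)^2 = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["EyeAxes", "ellipticity", "axis_ratio", "annotate_measurements"]


@dataclass(frozen=True)
class EyeAxes:
    """Semi-major (a) and semi-minor (b) ellipse axes, same length unit."""

    a: float
    b: float

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError("semi-minor axis must be positive")
        if self.b > self.a:
            raise ValueError("semi-major axis must be the longer one (a >= b)")


def ellipticity(axes: EyeAxes) -> float:
    """Eccentricity e = sqrt(1 - (b/a)^2), in [0, 1)."""
    r = axes.b / axes.a
    return math.sqrt(1.0 - r * r)


def axis_ratio(axes: EyeAxes) -> float:
    """Short-to-long axis ratio b/a, in (0, 1]."""
    return axes.b / axes.a


def annotate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Append ellipticity and axis-ratio columns to a measurement table.

    Expects columns ``a`` and ``b`` (any consistent length unit);
    additional columns such as animal_id and genotype pass through.
    """
    if not {"a", "b"}.issubset(df.columns):
        raise ValueError("measurement table needs columns 'a' and 'b'")
    out = df.copy()
    axes = [EyeAxes(row.a, row.b) for row in df.itertuples()]
    out["axis_ratio"] = [axis_ratio(ax) for ax in axes]
    out["ellipticity"] = [ellipticity(ax) for ax in axes]
    return out
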