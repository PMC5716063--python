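"""Structural-complexity summaries and the ordinal-scale bridge.

From 2012 onwards divers record the percentage of the survey cylinder in
five substrate-height bins (<0.20, 0.20-0.50, 0.50-1, 1-1.5, >1.5 m);
before that, an ordinal complexity score was used.  This module reduces a
height-bin vector to a mean substrate height and fits the linear
conversion between the two encodings from externally supplied co-scored
pairs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "HEIGHT_BIN_LABELS",
    "HEIGHT_BIN_MIDPOINTS_M",
    "ConversionFit",
    "DegenerateDesignError",
    "mean_substrate_height",
    "fit_complexity_conversion",
]

HEIGHT_BIN_LABELS: tuple[str, ...] = (
    "<0.20 m", "0.20-0.50 m", "0.50-1 m", "1-1.5 m", ">1.5 m")

#: Representative height of each bin.  The open top bin ">1.5 m" has no
#: printed upper edge; 1.75 m assumes an effective 1.5-2 m span and is
#: configurable.
HEIGHT_BIN_MIDPOINTS_M: tuple[float, ...] = (0.10, 0.35, 0.75, 1.25, 1.75)


class DegenerateDesignError(ValueError):
    """The regression design has no spread in the predictor."""


@dataclass(frozen=True)
class ConversionFit:
    """OLS line linking the ordinal complexity score and mean height."""

    slope: float
    intercept: float
    r_squared: float
    stderr: float
    n: int
    direction: str = "score_to_height"

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def mean_substrate_height(
    percentages: Sequence[float],
    midpoints_m: Sequence[float] = HEIGHT_BIN_MIDPOINTS_M,
) -> float:
    """Area-weighted mean substrate height (m) of a height-bin vector.

    ``percentages`` are the five bin percentages; they must sum to
    100 +/- 0.5.  The result is sum(fraction * bin midpoint).
    """
    p = np.asarray(percentages, dtype=float)
    m = np.asarray(midpoints_m, dtype=float)
    if p.shape != m.shape:
        raise ValueError(
            f"expected {len(m)} bin percentages, got {p.shape}")
    if np.any(p < 0) or np.any(p > 100):
        raise ValueError("bin percentages must lie in [0, 100]")
    total = p.sum()
    if abs(total - 100.0) > 0.5:
        raise ValueError(
            f"bin percentages must sum to 100 +/- 0.5, got {total}")
    return float(p @ m / total)


def fit_complexity_conversion(
    scores: Sequence[float],
    heights_m: Sequence[float],
    direction: str = "score_to_height",
) -> ConversionFit:
    """Ordinary least squares conversion between the pre-2012 ordinal
    complexity score and the height-bin mean substrate height.

    ``direction="score_to_height"`` regresses mean height on the score;
    ``"height_to_score"`` the reverse.  Requires >= 3 pairs with at least
    two distinct predictor values.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(heights_m, dtype=float)
    if direction == "height_to_score":
        x, y = y, x
    elif direction != "score_to_height":
        raise ValueError(f"unknown direction {direction!r}")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and heights must be equal-length 1-D")
    if len(x) < 3:
        raise DegenerateDesignError("need at least 3 calibration pairs")
    if len(np.unique(x)) < 2:
        raise DegenerateDesignError(
            "predictor has a single distinct value; slope unidentifiable")
    res = stats.linregress(x, y)
    return ConversionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        stderr=float(res.stderr),
        n=len(x),
        direction=direction,
    )
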