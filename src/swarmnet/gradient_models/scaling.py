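"""Predictor standardization shared by both model stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ..errors import ValidationError


@dataclass(frozen=True)
class ScaleParams:
    mean: float
    sd: float  # sample sd (ddof=1)


def scale_predictors(
    table: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, ScaleParams]]:
    """z-score the given columns (sample sd, ddof=1); return scaled copy + params.

    Raises on a zero-variance column: a constant predictor cannot be
    standardized and carries no gradient information.
    """
    out = table.copy()
    params: dict[str, ScaleParams] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        mean = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if not sd > 0:
            raise ValidationError(f"column {col!r} has zero variance; cannot scale")
        out[col] = (x - mean) / sd
        params[col] = ScaleParams(mean, sd)
    return out, params


def squeeze_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Map proportions from [0,1] into the open interval (0,1).

    Uses y' = (y (n−1) + 1/2) / n, the standard compression for
    beta-distributed responses that can attain the boundary (complete
    networks give clustering exactly 1).  Monotone in y.
    """
    y = np.asarray(y, dtype=float)
    if n is None:
        n = y.size
    if n < 2:
        raise ValidationError("need n >= 2 to squeeze a unit-interval response")
    return (y * (n - 1) + 0.5) / n
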