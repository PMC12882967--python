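"""NDVI-based habitat-suitability metric for a forest fragment.

Suitability is the proportion of cells in a buffer (default 200 m)
around a fragment whose NDVI falls within the fragment's own NDVI
envelope (default 10th–90th percentile, chosen conservatively because
NDVI varies widely even within intact tropical forest).  A fragment
embedded in continuous forest scores 1; an isolated fragment surrounded
by pasture or water scores near 0.

The implementation is grid-native: the buffer is the set of non-fragment
cells whose center lies within the buffer distance of the nearest
fragment-cell center (Euclidean).  NDVI rasters are handled as numpy
grids with an optional missing-data mask; plain-text ESRI ASCII grids
are read and written directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError


@dataclass
class NdviRaster:
    """NDVI grid with square cells; ``mask`` flags missing cells (cloud/water)."""

    values: np.ndarray  # 2-D float
    cell_size: float  # meters
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the lower-left corner
    mask: np.ndarray | None = None  # True = missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("NDVI raster must be 2-D")
        if not self.cell_size > 0:
            raise ValidationError("cell size must be > 0")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError("mask shape must match raster shape")
            self.mask = self.mask | ~np.isfinite(self.values)
        valid = self.values[~self.mask]
        if valid.size and (valid.min() < -1 or valid.max() > 1):
            raise ValidationError("NDVI values must lie in [-1, 1] or be masked")


@dataclass(frozen=True)
class SuitabilityResult:
    suitability: float  # matched / n_buffer_cells
    envelope: tuple[float, float]  # (lower, upper) NDVI percentile bounds
    n_buffer_cells: int
    n_matched: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "suitability": self.suitability,
                "envelope_lo": self.envelope[0],
                "envelope_hi": self.envelope[1],
                "n_buffer_cells": self.n_buffer_cells,
                "n_matched": self.n_matched,
            },
            indent=2,
        )


def fragment_envelope(
    raster: NdviRaster,
    fragment: np.ndarray,
    *,
    lower: float = 10.0,
    upper: float = 90.0,
) -> tuple[float, float]:
    """Empirical NDVI percentile envelope of the fragment's unmasked cells.

    Percentiles use linear interpolation between order statistics (the
    numpy default); conventions differ at small n, so this is pinned.
    """
    fragment = _check_fragment(raster, fragment)
    vals = raster.values[fragment & ~raster.mask]
    if vals.size == 0:
        raise ValidationError("all fragment cells are masked")
    if not 0 <= lower <= upper <= 100:
        raise ValidationError("percentiles must satisfy 0 <= lower <= upper <= 100")
    p_lo, p_hi = np.percentile(vals, [lower, upper])
    return float(p_lo), float(p_hi)


def buffer_cells(
    fragment: np.ndarray,
    *,
    distance: float = 200.0,
    cell_size: float,
) -> np.ndarray:
    """Cells outside the fragment within ``distance`` of the fragment edge.

    Distance is Euclidean, cell center to nearest fragment-cell center.
    """
    fragment = np.asarray(fragment, dtype=bool)
    if not distance > 0:
        raise ValidationError("buffer distance must be > 0")
    if not fragment.any():
        raise ValidationError("fragment mask has no cells")
    # Distance from each cell center to the nearest fragment-cell center.
    dist = ndimage.distance_transform_edt(~fragment, sampling=cell_size)
    buf = (~fragment) & (dist <= distance)
    if not buf.any():
        raise ValidationError(
            "empty buffer: fragment fills the grid or distance is below "
            "the cell size"
        )
    return buf


def suitability(
    raster: NdviRaster,
    fragment: np.ndarray,
    *,
    distance: float = 200.0,
    lower: float = 10.0,
    upper: float = 90.0,
) -> SuitabilityResult:
    """Proportion of buffer cells whose NDVI matches the fragment envelope.

    The envelope is inclusive at both bounds; masked buffer cells are
    excluded from the denominator.
    """
    fragment = _check_fragment(raster, fragment)
    p_lo, p_hi = fragment_envelope(raster, fragment, lower=lower, upper=upper)
    buf = buffer_cells(fragment, distance=distance, cell_size=raster.cell_size)
    buf = buf & ~raster.mask
    n = int(buf.sum())
    if n == 0:
        raise ValidationError("all buffer cells are masked")
    vals = raster.values[buf]
    matched = int(((vals >= p_lo) & (vals <= p_hi)).sum())
    return SuitabilityResult(
        suitability=matched / n,
        envelope=(p_lo, p_hi),
        n_buffer_cells=n,
        n_matched=matched,
    )


def _check_fragment(raster: NdviRaster, fragment: np.ndarray) -> np.ndarray:
    fragment = np.asarray(fragment, dtype=bool)
    if fragment.shape != raster.values.shape:
        raise ValidationError("fragment mask shape must match raster shape")
    if not fragment.any():
        raise ValidationError("fragment mask has no cells")
    return fragment


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain text raster interchange)

def read_ascii_grid(path: str | Path) -> NdviRaster:
    """Read a single-band ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValidationError(f"{path}: missing ASCII-grid header field {req!r}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(f"{path}: grid shape does not match header")
    nodata = header.get("nodata_value")
    mask = (values == nodata) if nodata is not None else None
    if mask is not None:
        values = np.where(mask, np.nan, values)
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    return NdviRaster(values=values, cell_size=header["cellsize"], origin=(xll, yll), mask=mask)


def write_ascii_grid(raster: NdviRaster, path: str | Path, *, nodata: float = -9999.0) -> None:
    vals = np.where(raster.mask, nodata, raster.values)
    lines = [
        f"ncols {raster.values.shape[1]}",
        f"nrows {raster.values.shape[0]}",
        f"xllcorner {raster.origin[0]}",
        f"yllcorner {raster.origin[1]}",
        f"cellsize {raster.cell_size}",
        f"nodata_value {nodata}",
    ]
    lines += [" ".join(repr(float(v)) for v in row) for row in vals]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True
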