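"""Resistance-surface construction for odonate movement modelling.

A categorical land-cover raster is reclassified into a three-level
resistance surface (low = 1, medium = 10, high = 100): wetlands and open
water are primary breeding habitat (low), semi-natural cover provides
resources but not habitat (medium), and built surfaces are hostile
(high). A randomised "representative" buffer is padded around the study
area so that map edges do not inflate resistance, and focal nodes are
scattered on the outer perimeter of that buffer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .raster import CLASS_CODES, CODE_TO_CLASS, Raster

__all__ = [
    "RESISTANCE_VALUES",
    "default_scheme",
    "load_scheme",
    "classify",
    "ResistanceRaster",
    "resistance_proportions",
    "add_buffer",
    "NodeSet",
    "place_perimeter_nodes",
]

#: Permitted resistance levels.
RESISTANCE_VALUES = (1, 10, 100)

_DEFAULT_SCHEME = {
    "crop_pasture": 10,
    "grassland": 10,
    "large_rivers": 10,
    "rock_barren": 10,
    "sand_gravel": 10,
    "settlement": 100,
    "transportation": 100,
    "wooded_area": 10,
    "wetlands": 1,
    "water": 1,
}


def default_scheme() -> dict[str, int]:
    """The standard ten-class odonate resistance scheme.

    Wetlands and water are low resistance (1); crop/pasture, grassland,
    large rivers, rock barren, sand/gravel and wooded area are medium
    (10); settlement and transportation are high (100).
    """
    return dict(_DEFAULT_SCHEME)


def load_scheme(path=None) -> dict[str, int]:
    """Load a resistance scheme from a two-column CSV (class,resistance).

    With no path, reads the packaged default scheme file.
    """
    if path is None:
        ref = resources.files("pondnet.data").joinpath("resistance_scheme.csv")
        with ref.open() as fh:
            return _parse_scheme(fh)
    with open(path) as fh:
        return _parse_scheme(fh)


def _parse_scheme(fh) -> dict[str, int]:
    scheme = {}
    for row in csv.DictReader(fh):
        value = int(row["resistance"])
        if value not in RESISTANCE_VALUES:
            raise ValueError(f"resistance for {row['class']!r} must be one of {RESISTANCE_VALUES}, got {value}")
        scheme[row["class"].strip()] = value
    return scheme


@dataclass
class ResistanceRaster:
    """Per-cell movement resistance plus a mask of the original study area.

    ``study_mask`` is True on study-area cells and False on buffer cells
    added by :func:`add_buffer`.
    """

    raster: Raster
    study_mask: np.ndarray

    def __post_init__(self) -> None:
        self.study_mask = np.asarray(self.study_mask, dtype=bool)
        if self.study_mask.shape != self.raster.shape:
            raise ValueError("study_mask shape must match raster shape")
        vals = self.raster.values
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("resistance values must be finite and > 0")

    @property
    def values(self) -> np.ndarray:
        return self.raster.values

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


def classify(landcover: Raster, scheme: dict[str, int] | None = None) -> ResistanceRaster:
    """Reclassify a land-cover raster (class codes) into resistance values.

    Every class code present in the raster must have an entry in the
    scheme; an unmapped class raises a ``KeyError`` naming it.
    """
    if scheme is None:
        scheme = default_scheme()
    codes = np.unique(landcover.values)
    lut = np.zeros(int(codes.max()) + 1, dtype=float)
    for code in codes:
        name = CODE_TO_CLASS.get(int(code))
        if name is None or name not in scheme:
            label = name if name is not None else f"code {int(code)}"
            raise KeyError(f"land-cover class {label!r} has no resistance mapping")
        lut[int(code)] = scheme[name]
    out = Raster(
        lut[landcover.values.astype(int)],
        cell_size=landcover.cell_size,
        xll=landcover.xll,
        yll=landcover.yll,
    )
    return ResistanceRaster(out, np.ones(out.shape, dtype=bool))


def resistance_proportions(rr: ResistanceRaster, mask_to_study: bool = False) -> tuple[float, float, float]:
    """Fraction of cells in the (low, medium, high) resistance levels."""
    vals = rr.values[rr.study_mask] if mask_to_study else rr.values.ravel()
    n = vals.size
    if n == 0:
        raise ValueError("no cells selected (empty mask)")
    low = float(np.count_nonzero(vals == 1)) / n
    med = float(np.count_nonzero(vals == 10)) / n
    high = float(np.count_nonzero(vals == 100)) / n
    return (low, med, high)


def add_buffer(
    rr: ResistanceRaster,
    width_m: float,
    target_ratio: tuple[float, float, float] = (0.142, 0.348, 0.510),
    seed: int | None = None,
) -> ResistanceRaster:
    """Pad the raster with a randomised, representative resistance buffer.

    The grid grows by ``ceil(width_m / cell_size)`` cells on all four
    sides; new cells are iid draws from {1, 10, 100} with probabilities
    ``target_ratio``, and are flagged False in the study mask. Interior
    cells are untouched.
    """
    if width_m <= 0:
        raise ValueError("buffer width must be > 0")
    ratio = np.asarray(target_ratio, dtype=float)
    if ratio.min() < 0 or abs(ratio.sum() - 1.0) > 1e-9:
        raise ValueError("target_ratio must be non-negative and sum to 1")
    pad = int(np.ceil(width_m / rr.raster.cell_size))
    rng = np.random.default_rng(seed)
    nrows, ncols = rr.shape
    out = np.empty((nrows + 2 * pad, ncols + 2 * pad), dtype=float)
    draw = rng.choice(np.array(RESISTANCE_VALUES, dtype=float), size=out.shape, p=ratio)
    out[:] = draw
    out[pad : pad + nrows, pad : pad + ncols] = rr.values
    mask = np.zeros(out.shape, dtype=bool)
    mask[pad : pad + nrows, pad : pad + ncols] = rr.study_mask
    raster = Raster(
        out,
        cell_size=rr.raster.cell_size,
        xll=rr.raster.xll - pad * rr.raster.cell_size,
        yll=rr.raster.yll - pad * rr.raster.cell_size,
        metadata={**rr.raster.metadata, "buffer_cells": pad, "buffer_seed": seed},
    )
    return ResistanceRaster(raster, mask)


@dataclass
class NodeSet:
    """Focal nodes on the outermost cell ring of a buffered raster."""

    rows: np.ndarray
    cols: np.ndarray
    seed: int | None = None
    xy: np.ndarray | None = field(default=None)

    def __len__(self) -> int:
        return len(self.rows)

    def flat_indices(self, ncols: int) -> np.ndarray:
        return self.rows * ncols + self.cols


def place_perimeter_nodes(rr: ResistanceRaster, n: int, seed: int | None = None) -> NodeSet:
    """Sample ``n`` distinct cells uniformly from the outer perimeter ring."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    nrows, ncols = rr.shape
    top = [(0, c) for c in range(ncols)]
    bottom = [(nrows - 1, c) for c in range(ncols)] if nrows > 1 else []
    left = [(r, 0) for r in range(1, nrows - 1)]
    right = [(r, ncols - 1) for r in range(1, nrows - 1)] if ncols > 1 else []
    ring = top + bottom + left + right
    if n > len(ring):
        raise ValueError(f"requested {n} nodes but the perimeter ring has only {len(ring)} cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ring), size=n, replace=False)
    rows = np.array([ring[i][0] for i in idx])
    cols = np.array([ring[i][1] for i in idx])
    xy = np.array([rr.raster.cell_center(r, c) for r, c in zip(rows, cols)])
    return NodeSet(rows=rows, cols=cols, seed=seed, xy=xy)
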