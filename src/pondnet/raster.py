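"""Minimal projected-grid raster container with ESRI ASCII grid I/O.

Rasters are stored row-major with row 0 at the *top* (north edge), the
convention used by the ESRI ASCII grid format. Coordinates are assumed to
be in a projected CRS with metre units; no reprojection is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Raster", "LAND_COVER_CLASSES", "CLASS_CODES", "CODE_TO_CLASS", "majority_resample"]

#: The ten land-cover classes of the urban mosaic, with fixed integer codes.
#: The code order doubles as the deterministic tie-break order for
#: majority resampling.
LAND_COVER_CLASSES = (
    "crop_pasture",
    "grassland",
    "large_rivers",
    "rock_barren",
    "sand_gravel",
    "settlement",
    "transportation",
    "wooded_area",
    "wetlands",
    "water",
)

CLASS_CODES = {name: i + 1 for i, name in enumerate(LAND_COVER_CLASSES)}
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}

_NODATA = -9999


@dataclass
class Raster:
    """A single-band raster on a regular grid.

    Parameters
    ----------
    values
        2-D array, row 0 at the top of the map.
    cell_size
        Cell edge length in metres.
    xll, yll
        Coordinates of the lower-left corner of the lower-left cell.
    """

    values: np.ndarray
    cell_size: float = 10.0
    xll: float = 0.0
    yll: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, same shape as values."""
        nrows, ncols = self.shape
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        x = self.xll + (cols + 0.5) * self.cell_size
        y = self.yll + (nrows - rows - 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.shape[0]
        return (
            self.xll + (col + 0.5) * self.cell_size,
            self.yll + (nrows - row - 0.5) * self.cell_size,
        )

    def copy(self) -> "Raster":
        return replace(self, values=self.values.copy(), metadata=dict(self.metadata))

    # ------------------------------------------------------------------ I/O

    def write_ascii(self, path, fmt: str | None = None) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        nrows, ncols = self.shape
        vals = self.values
        if fmt is None:
            fmt = "%d" if np.issubdtype(vals.dtype, np.integer) else "%.10g"
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.xll:.6f}\n"
            f"yllcorner {self.yll:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {_NODATA}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt=fmt)

    @classmethod
    def read_ascii(cls, path, dtype=None) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            pos = fh.tell()
            for _ in range(6):
                pos = fh.tell()
                line = fh.readline()
                parts = line.split()
                if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
                }:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    fh.seek(pos)
                    break
            data = np.loadtxt(fh, dtype=dtype if dtype is not None else float)
        data = np.atleast_2d(data)
        nrows, ncols = int(header["nrows"]), int(header["ncols"])
        if data.shape != (nrows, ncols):
            data = data.reshape(nrows, ncols)
        return cls(
            values=data,
            cell_size=header.get("cellsize", 1.0),
            xll=header.get("xllcorner", 0.0),
            yll=header.get("yllcorner", 0.0),
        )


def majority_resample(fine: Raster, factor: int) -> Raster:
    """Aggregate a categorical raster by the majority class per block.

    Blocks of ``factor x factor`` fine cells collapse to one coarse cell
    holding the most frequent class code; ties break toward the smallest
    code. Trailing rows/columns that do not fill a block are discarded.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vals = fine.values
    nrows = (vals.shape[0] // factor) * factor
    ncols = (vals.shape[1] // factor) * factor
    if nrows == 0 or ncols == 0:
        raise ValueError("raster smaller than one block")
    blocks = vals[:nrows, :ncols].reshape(nrows // factor, factor, ncols // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(nrows // factor, ncols // factor, factor * factor)
    codes = np.unique(vals)
    # count per code; argmax over the code axis breaks ties toward the
    # smallest code because np.unique sorts ascending
    counts = np.stack([(blocks == c).sum(axis=2) for c in codes], axis=2)
    out = codes[np.argmax(counts, axis=2)]
    n_fine_rows = vals.shape[0]
    # keep the top-left alignment: yll moves up past any discarded rows
    yll = fine.yll + (n_fine_rows - nrows) * fine.cell_size
    return Raster(out.astype(vals.dtype), cell_size=fine.cell_size * factor, xll=fine.xll, yll=yll)
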