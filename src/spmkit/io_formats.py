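"""Reading and writing of scanning-probe image formats.

The toolkit's interchange format is the XYZ ASCII dialect: plain text with
three whitespace-separated columns holding the X, Y and Z coordinate of one
image point per line, optionally preceded by free-text header lines.  A
compact little-endian binary container (the ``.s94`` dialect defined in
:data:`S94_MAGIC` and friends) is supported for raw-file conversion, and
images can be exported as 8-bit greyscale PNG rasters.

Coordinate convention (frozen): grid row 0 holds the smallest Y, column 0
the smallest X.  PNG rasters follow the standard top-down raster order, i.e.
they are vertically flipped relative to the physical Y axis.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "ScanImage",
    "ImageSeries",
    "read_xyz_ascii",
    "write_xyz_ascii",
    "read_s94",
    "write_s94_fixture",
    "write_png",
    "grey_levels",
]


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ScanImage:
    """One topograph or constant-height current map.

    Parameters
    ----------
    z_grid : ndarray, shape (rows, cols)
        Z value of every image point (picometres for topography, current
        units for constant-height mode).  Row ``r`` corresponds to
        ``y_coords[r]``, column ``c`` to ``x_coords[c]``.
    x_coords, y_coords : ndarray
        Strictly increasing physical positions (nanometres) of the columns
        and rows.
    metadata : dict
        Free-form acquisition record (source file name, scan mode, sample
        bias, tunnelling setpoint, electrode potential, frame index...).
    """

    z_grid: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        if self.z_grid.ndim != 2:
            raise ValueError("z_grid must be 2-D")
        rows, cols = self.z_grid.shape
        if self.y_coords.shape != (rows,) or self.x_coords.shape != (cols,):
            raise ValueError(
                f"axis lengths ({len(self.y_coords)}, {len(self.x_coords)}) "
                f"do not match grid shape {self.z_grid.shape}"
            )
        for name, ax in (("x_coords", self.x_coords), ("y_coords", self.y_coords)):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(self.z_grid)):
            raise ValueError("z_grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_grid.shape

    def with_z(self, z_grid: np.ndarray) -> "ScanImage":
        """Copy of this image with a replaced Z grid (axes/metadata kept)."""
        return ScanImage(z_grid, self.x_coords.copy(), self.y_coords.copy(),
                         dict(self.metadata))


@dataclass
class ImageSeries:
    """Ordered sequence of frames from one experiment."""

    frames: list[ScanImage]
    indices: list[int] | None = None

    def __post_init__(self) -> None:
        if self.indices is None:
            self.indices = list(range(len(self.frames)))
        if len(self.indices) != len(self.frames):
            raise ValueError("one index per frame required")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("indices must be strictly increasing")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have differing grid dimensions: {shapes}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[ScanImage]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> ScanImage:
        return self.frames[i]

    def file_names(self) -> list[str]:
        return [f.metadata.get("filename", f"frame_{i:04d}")
                for i, f in zip(self.indices, self.frames)]


# ---------------------------------------------------------------------------
# XYZ ASCII
# ---------------------------------------------------------------------------


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_xyz_ascii(path: str | Path, header_policy: int | str = "auto") -> ScanImage:
    """Parse an XYZ ASCII file into a :class:`ScanImage`.

    Points are placed on the grid by their (X, Y) coordinate, so any
    complete-grid line permutation parses identically.

    Parameters
    ----------
    path : path
        Input text file.
    header_policy : int or "auto"
        Number of leading header lines to skip, or ``"auto"`` to skip
        leading lines whose first token is not numeric.

    Raises
    ------
    FormatError
        On non-numeric data lines, on incomplete rectangular grids (the
        first missing (X, Y) pair is named) and on duplicate points.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    if header_policy == "auto":
        n_header = 0
        for line in lines:
            tokens = line.split()
            if tokens and _is_number(tokens[0]):
                break
            n_header += 1
        if n_header:
            logger.info("%s: skipped %d header line(s)", path.name, n_header)
    else:
        n_header = int(header_policy)

    xs, ys, zs = [], [], []
    for lineno, line in enumerate(lines[n_header:], start=n_header + 1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) < 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 numeric fields, "
                              f"got {len(tokens)}")
        try:
            x, y, z = (float(t) for t in tokens[:3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric field") from exc
        xs.append(x)
        ys.append(y)
        zs.append(z)

    if not xs:
        raise FormatError(f"{path}: no data points")

    x_arr, y_arr, z_arr = np.array(xs), np.array(ys), np.array(zs)
    x_coords = np.unique(x_arr)
    y_coords = np.unique(y_arr)
    rows, cols = len(y_coords), len(x_coords)

    ci = np.searchsorted(x_coords, x_arr)
    ri = np.searchsorted(y_coords, y_arr)
    grid = np.full((rows, cols), np.nan)
    if len(z_arr) > rows * cols or np.any(~np.isnan(grid[ri, ci])):
        # find the first duplicated point for the message
        seen = set()
        for x, y in zip(x_arr, y_arr):
            if (x, y) in seen:
                raise FormatError(f"{path}: duplicate point (X={x:g}, Y={y:g})")
            seen.add((x, y))
    grid[ri, ci] = z_arr

    missing = np.argwhere(np.isnan(grid))
    if missing.size:
        r, c = missing[0]
        raise FormatError(
            f"{path}: incomplete {rows}x{cols} grid; first missing point "
            f"(X={x_coords[c]:g}, Y={y_coords[r]:g})"
        )

    return ScanImage(grid, x_coords, y_coords, {"filename": path.name})


_FMT = "%.10g"


def write_xyz_ascii(img: ScanImage, path: str | Path) -> None:
    """Write an XYZ ASCII file, X varying fastest (inner loop over columns).

    The emitted file reads back to an image equal to ``img`` up to the
    printed precision (10 significant digits).
    """
    path = Path(path)
    with path.open("w") as fh:
        for r, y in enumerate(img.y_coords):
            for c, x in enumerate(img.x_coords):
                fh.write(f"{_FMT % x} {_FMT % y} {_FMT % img.z_grid[r, c]}\n")


# ---------------------------------------------------------------------------
# s94 dialect (toolkit-defined)
# ---------------------------------------------------------------------------

S94_MAGIC = b"S94F"
S94_VERSION = 1
_S94_HEADER = struct.Struct("<4sHHHddd")  # magic, version, cols, rows, xsz, ysz, zscale


def write_s94_fixture(path: str | Path, counts: np.ndarray,
                      x_size_nm: float = 100.0, y_size_nm: float = 100.0,
                      z_scale: float = 1.0) -> None:
    """Write an ``.s94``-dialect file from int16 raw counts (row-major)."""
    counts = np.ascontiguousarray(counts, dtype="<i2")
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D")
    rows, cols = counts.shape
    with Path(path).open("wb") as fh:
        fh.write(_S94_HEADER.pack(S94_MAGIC, S94_VERSION, cols, rows,
                                  x_size_nm, y_size_nm, z_scale))
        fh.write(counts.tobytes())


def read_s94(path: str | Path) -> ScanImage:
    """Read an ``.s94``-dialect file (see module docstring for the layout).

    Z values are the stored int16 counts multiplied by the header scale
    factor; physical axes span the header scan sizes.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _S94_HEADER.size:
        raise FormatError(f"{path}: truncated header "
                          f"({len(raw)} < {_S94_HEADER.size} bytes)")
    magic, version, cols, rows, x_size, y_size, z_scale = _S94_HEADER.unpack_from(raw)
    if magic != S94_MAGIC:
        raise FormatError(f"{path}: unknown magic {magic!r}")
    if version != S94_VERSION:
        raise FormatError(f"{path}: unsupported version {version}")
    expected = _S94_HEADER.size + 2 * rows * cols
    if len(raw) != expected:
        raise FormatError(f"{path}: expected {expected} bytes, got {len(raw)}")
    counts = np.frombuffer(raw, dtype="<i2", offset=_S94_HEADER.size)
    z = counts.reshape(rows, cols).astype(float) * z_scale
    x = np.linspace(0.0, x_size, cols) if cols > 1 else np.array([0.0])
    y = np.linspace(0.0, y_size, rows) if rows > 1 else np.array([0.0])
    return ScanImage(z, x, y, {"filename": path.name, "z_scale": z_scale})


# ---------------------------------------------------------------------------
# PNG export
# ---------------------------------------------------------------------------


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(v + 0.5)


def grey_levels(z: np.ndarray) -> np.ndarray:
    """Linear greyscale map: 0 at the minimum Z, 255 at the maximum.

    A degenerate (constant) image maps to all zeros.  Rounding is
    half-up for cross-platform determinism.
    """
    z = np.asarray(z, dtype=float)
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        return np.zeros(z.shape, dtype=np.uint8)
    return _round_half_up(255.0 * (z - zmin) / (zmax - zmin)).astype(np.uint8)


def write_png(img: ScanImage, path: str | Path,
              levels: np.ndarray | None = None) -> None:
    """Export an 8-bit greyscale PNG (row 0 at top = largest physical Y).

    ``levels`` overrides the linear map with precomputed uint8 intensities
    (used for segmented label images).
    """
    inten = grey_levels(img.z_grid) if levels is None else np.asarray(levels, np.uint8)
    Image.fromarray(np.flipud(inten), mode="L").save(Path(path))


def load_series(paths: Sequence[str | Path],
                header_policy: int | str = "auto") -> ImageSeries:
    """Read an ordered list of XYZ files as one :class:`ImageSeries`."""
    frames = []
    for i, p in enumerate(paths):
        img = read_xyz_ascii(p, header_policy)
        img.metadata["index"] = i
        frames.append(img)
    return ImageSeries(frames)
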