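"""Image filtering: line-wise parabolic flattening and percentile equalisation.

Raw scanning-probe images carry an apparent inclination (sample tilt,
piezo drift/creep) and sparse Z outliers (instrumental spikes, terraces,
aggregates).  Flattening removes a least-squares parabola from every scan
line independently; equalisation clips the Z distribution at user-chosen
percentile extrema and rebases the minimum to zero.  Flattening is always
applied before equalisation, because the tilt would otherwise distort the
Z distribution on which the percentile limits are computed.

Both steps are exposed as stateless scikit-learn transformers
(:class:`LineFlattener`, :class:`PercentileEqualizer`) operating on 2-D Z
grids, plus thin functions on :class:`~spmkit.io_formats.ScanImage` and a
folder-level batch driver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import FormatError, ScanImage, read_xyz_ascii, write_png, write_xyz_ascii

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "LineFlattener",
    "PercentileEqualizer",
    "flatten_line_parabola",
    "equalize",
    "filter_folder",
]


@dataclass
class FilterConfig:
    """Boolean flags and percentile limits driving the batch filter."""

    apply_flatten: bool = True
    apply_equalize: bool = True
    lower_percentile: float = 1.0
    upper_percentile: float = 99.0
    emit_control_plots: bool = False
    emit_png: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.lower_percentile < self.upper_percentile <= 100:
            raise ValueError(
                f"require 0 <= lower ({self.lower_percentile}) < "
                f"upper ({self.upper_percentile}) <= 100"
            )


class LineFlattener(BaseEstimator, TransformerMixin):
    """Per-scan-line polynomial background subtraction.

    For every image row independently, a degree-2 polynomial in the
    physical X coordinate is fitted by least squares to the (X, Z) data of
    that row and subtracted, leaving residuals orthogonal to {1, X, X²}.
    The operation is idempotent.

    Parameters
    ----------
    degree : int, default 2
        Polynomial degree of the per-row background model (parabola).
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X: np.ndarray, y: None = None) -> "LineFlattener":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D Z grid")
        if X.shape[1] < self.degree + 1:
            raise ValueError(
                f"rows have {X.shape[1]} points; a degree-{self.degree} fit "
                f"needs at least {self.degree + 1} — reduce the degree"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray, x_coords: np.ndarray | None = None) -> np.ndarray:
        """Return ``X`` minus the per-row fitted polynomial.

        ``x_coords`` gives the physical X positions of the columns;
        defaults to the column index.
        """
        X = np.asarray(X, dtype=float)
        self.fit(X)
        x = np.arange(X.shape[1], dtype=float) if x_coords is None else np.asarray(x_coords, float)
        # shared Vandermonde solve for all rows at once
        V = np.vander(x, self.degree + 1, increasing=True)
        coeffs, *_ = np.linalg.lstsq(V, X.T, rcond=None)
        self.coeffs_ = coeffs.T  # (rows, degree+1), ascending powers
        return X - (V @ coeffs).T


class PercentileEqualizer(BaseEstimator, TransformerMixin):
    """Clip Z at percentile extrema and rebase the minimum to zero.

    The lower/upper percentile values L, U of the image's Z distribution
    (linear-interpolation convention between order statistics) become hard
    limits: Z < L is reassigned to L, Z > U to U; the image is then shifted
    so its minimum is exactly 0.  Relative differences among unclipped
    points are preserved and ordering is never inverted.
    """

    def __init__(self, lower_percentile: float = 1.0, upper_percentile: float = 99.0):
        self.lower_percentile = lower_percentile
        self.upper_percentile = upper_percentile

    def fit(self, X: np.ndarray, y: None = None) -> "PercentileEqualizer":
        if not 0 <= self.lower_percentile < self.upper_percentile <= 100:
            raise ValueError("require 0 <= lower < upper <= 100")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        X = np.asarray(X, dtype=float)
        lo, hi = np.percentile(X, [self.lower_percentile, self.upper_percentile],
                               method="linear")
        self.limits_ = (lo, hi)
        out = np.clip(X, lo, hi)
        return out - out.min()


def flatten_line_parabola(img: ScanImage) -> ScanImage:
    """Subtract a least-squares parabola from every row of ``img``.

    The fit uses the physical X axis.  Rows must hold at least 3 points.
    """
    z = LineFlattener(degree=2).transform(img.z_grid, x_coords=img.x_coords)
    return img.with_z(z)


def equalize(img: ScanImage, lower_percentile: float = 1.0,
             upper_percentile: float = 99.0) -> ScanImage:
    """Percentile-clip the Z distribution and rebase the minimum to zero."""
    eq = PercentileEqualizer(lower_percentile, upper_percentile)
    return img.with_z(eq.transform(img.z_grid))


@dataclass
class FilterSummary:
    processed: list[str] = field(default_factory=list)
    failed: list[str] = field(default_factory=list)

    @property
    def n_processed(self) -> int:
        return len(self.processed)

    @property
    def n_failed(self) -> int:
        return len(self.failed)


def _control_plot(raw: ScanImage, out: ScanImage, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    axes[0].hist(raw.z_grid.ravel(), bins=100)
    axes[0].set_title("raw Z distribution")
    axes[1].hist(out.z_grid.ravel(), bins=100)
    axes[1].set_title("filtered Z distribution")
    for ax in axes:
        ax.set_xlabel("Z")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def filter_folder(in_dir: str | Path, config: FilterConfig,
                  out_dir: str | Path, pattern: str = "*.txt") -> FilterSummary:
    """Filter every XYZ file in ``in_dir`` in lexicographic order.

    Flattening, when enabled, always precedes equalisation.  Unparseable
    files are logged, skipped and counted; an empty folder is an error.
    Outputs: one XYZ file per input (same structure), optionally a
    greyscale PNG and a Z-histogram control plot.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    paths = sorted(in_dir.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files matching {pattern!r} in {in_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = FilterSummary()
    for path in paths:
        try:
            raw = read_xyz_ascii(path)
        except (FormatError, OSError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            summary.failed.append(path.name)
            continue
        img = raw
        if config.apply_flatten:
            img = flatten_line_parabola(img)
        if config.apply_equalize:
            img = equalize(img, config.lower_percentile, config.upper_percentile)
        write_xyz_ascii(img, out_dir / path.name)
        if config.emit_png:
            write_png(img, out_dir / (path.stem + ".png"))
        if config.emit_control_plots:
            _control_plot(raw, img, out_dir / (path.stem + "_control.png"))
        summary.processed.append(path.name)
    return summary
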