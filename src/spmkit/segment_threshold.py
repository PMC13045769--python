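"""Fixed-threshold segmentation of equalized image series.

For long, strongly correlated series (video frames) a cheaper alternative
to per-image mixture fitting: the average Z range ("maximum extension of
the Z values distribution") over the first N frames — assumed to be at the
equilibrium condition — is divided into a user-chosen number of equal
intervals, and the resulting threshold values are frozen for the whole
series.  Each pixel's label is the interval containing its Z value; the
per-interval pixel fractions then track the response of the monolayer to
the external stimulus against the initial condition.

Intervals are anchored at Z = 0 because the upstream equalisation rebases
every image minimum to zero; Z values beyond the calibrated extension fall
into the top interval rather than erroring, so fractions always conserve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io_formats import ImageSeries, ScanImage, write_png
from .segment_gmm import segmented_levels

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdScheme",
    "ThresholdSegmenter",
    "calibrate_scheme",
    "apply_scheme",
    "segment_series_threshold",
]


@dataclass
class ThresholdScheme:
    """Frozen equal-width interval boundaries calibrated on the first N frames."""

    n_intervals: int
    reference_extension: float
    boundaries: np.ndarray          # (n_intervals - 1,) interior thresholds, ascending
    n_calibration: int
    calibration_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.reference_extension <= 0:
            raise ValueError("reference_extension must be positive")
        if len(self.boundaries) != self.n_intervals - 1:
            raise ValueError("need n_intervals - 1 boundaries")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly ascending")

    def interval_bounds(self) -> list[tuple[float, float]]:
        """(lower, upper) per interval; outermost bounds are infinite."""
        edges = np.concatenate([[-np.inf], self.boundaries, [np.inf]])
        return list(zip(edges[:-1], edges[1:]))


class ThresholdSegmenter(BaseEstimator):
    """Equal-width interval labelling with boundaries frozen at fit time.

    Parameters
    ----------
    n_intervals : int
        Number of equally spaced Z intervals.
    n_calibration : int
        Number of leading frames whose average Z range sets the interval
        width.

    Attributes
    ----------
    scheme_ : ThresholdScheme
        The calibrated boundaries; never recomputed by ``predict``.
    """

    def __init__(self, n_intervals: int = 3, n_calibration: int = 10):
        self.n_intervals = n_intervals
        self.n_calibration = n_calibration

    def fit(self, series: ImageSeries, y: None = None) -> "ThresholdSegmenter":
        self.scheme_ = calibrate_scheme(series, self.n_calibration, self.n_intervals)
        return self

    def predict(self, img: ScanImage | np.ndarray) -> np.ndarray:
        z = img.z_grid if isinstance(img, ScanImage) else np.asarray(img, float)
        labels, _ = apply_scheme_array(z, self.scheme_)
        return labels

    def transform(self, series: ImageSeries) -> pd.DataFrame:
        return segment_series_threshold(series, self.scheme_)


def calibrate_scheme(series: ImageSeries, n: int, n_intervals: int) -> ThresholdScheme:
    """Average the Z range of the first ``n`` frames and split it evenly.

    ``extension_i = max(Z_i) - min(Z_i)`` per calibration frame;
    ``reference_extension`` is their mean; interior boundaries sit at
    ``(i+1) * reference_extension / n_intervals``, anchored at Z = 0.
    Zero-extension frames are excluded from the mean with a warning.
    """
    if n < 1 or n > len(series):
        raise ValueError(f"n = {n} outside [1, {len(series)}]")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")

    names = series.file_names()[:n]
    extensions = []
    for i, frame in enumerate(series.frames[:n]):
        ext = float(frame.z_grid.max() - frame.z_grid.min())
        if ext <= 0:
            logger.warning("calibration frame %d has zero Z extension; excluded", i)
            continue
        extensions.append(ext)
    if not extensions:
        raise ValueError("all calibration frames have zero Z extension")

    ref = float(np.mean(extensions))
    boundaries = np.arange(1, n_intervals) * ref / n_intervals
    return ThresholdScheme(n_intervals, ref, boundaries, n, names)


def apply_scheme_array(z: np.ndarray, scheme: ThresholdScheme
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Label an array under the half-open interval convention.

    Interval i covers ``[boundaries[i-1], boundaries[i])``; interval 0 is
    open below and the top interval closed above at +inf, so values beyond
    the calibrated extension land in the top interval.  Linear in pixel
    count: a single vectorised binary search, no iteration.
    """
    z = np.asarray(z, dtype=float)
    labels = np.searchsorted(scheme.boundaries, z, side="right")
    counts = np.bincount(labels.ravel(), minlength=scheme.n_intervals)
    return labels, counts / counts.sum()


def apply_scheme(img: ScanImage, scheme: ThresholdScheme
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Return (label grid, per-interval pixel fractions) for one image."""
    return apply_scheme_array(img.z_grid, scheme)


def segment_series_threshold(series: ImageSeries, scheme: ThresholdScheme,
                             out_dir: str | Path | None = None) -> pd.DataFrame:
    """Apply a frozen scheme to every frame of a series.

    Per frame: a segmented PNG (same grey-level convention as the GMM
    segmenter) and one table row per interval with its bounds and pixel
    fraction.  The cumulative table is returned and, when ``out_dir`` is
    given, written as ``threshold_intervals.txt`` (tab-separated).
    """
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    bounds = scheme.interval_bounds()
    rows = []
    for idx, img, name in zip(series.indices, series.frames, series.file_names()):
        try:
            labels, fracs = apply_scheme(img, scheme)
        except ValueError as exc:
            logger.warning("frame %d (%s): labelling failed: %s", idx, name, exc)
            continue
        for j in range(scheme.n_intervals):
            lo, hi = bounds[j]
            rows.append({"image_index": idx, "file_name": name, "interval": j,
                         "lower": lo, "upper": hi, "pixel_fraction": fracs[j]})
        if out_dir is not None:
            write_png(img, out_dir / f"{Path(name).stem}_thr.png",
                      levels=segmented_levels(labels, scheme.n_intervals))

    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(out_dir / "threshold_intervals.txt", sep="\t", index=False)
    return table
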