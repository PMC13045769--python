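"""Gaussian-mixture segmentation of Z-value distributions.

Filtered images of molecular monolayers show a small number of discrete
apparent heights (substrate/ligand background, dark molecules, bright
molecules), so the set of all pixel Z values of one image is well modelled
as a univariate Gaussian mixture.  Fitting a K-component mixture by
expectation-maximisation and labelling each pixel with its maximum-
posterior component segments the image without any spatial prior; the
differences between sorted component means are the average height
differences between the molecular regions, and each component weight
("responsibility": the component's share of the total distribution) is the
pixel fraction of that region.

The fit itself runs on :class:`sklearn.mixture.GaussianMixture` with
frozen settings (k-means initialisation from an explicit seed,
log-likelihood tolerance 1e-6, 500 iterations max, variance floor 1e-12)
so that a fixed seed yields bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .io_formats import ImageSeries, ScanImage, write_png

logger = logging.getLogger(__name__)

__all__ = [
    "GmmResult",
    "GaussianMixtureSegmenter",
    "fit_gmm",
    "gmm_sweep",
    "cluster_heights",
    "pixel_fractions",
    "segment_series_gmm",
    "segmented_levels",
]


@dataclass
class GmmResult:
    """One mixture fit: components sorted ascending by mean."""

    n_clusters: int
    means: np.ndarray        # (K,) cluster centres, ascending
    variances: np.ndarray    # (K,)
    weights: np.ndarray      # (K,) mixture weights, sum to 1
    labels: np.ndarray       # integer grid aligned with the source z values
    log_likelihood: float
    seed: int

    def __post_init__(self) -> None:
        assert abs(self.weights.sum() - 1.0) < 1e-9
        assert np.all(np.diff(self.means) >= 0)


class GaussianMixtureSegmenter(BaseEstimator):
    """Univariate GMM over pixel Z values with mean-sorted components.

    Parameters
    ----------
    n_components : int
        Number of Gaussian clusters K.
    random_state : int
        Seed for the k-means++ initialisation; fixed seed gives
        bit-identical fits on identical input.
    tol, max_iter, reg_covar
        EM convergence tolerance, iteration cap and variance floor.

    Attributes
    ----------
    means_, variances_, weights_ : ndarray, shape (K,)
        Components sorted ascending by mean; weights sum to 1.
    log_likelihood_ : float
        Total log-likelihood of the training data.
    labels_ : ndarray
        Maximum-posterior component per training point, in the shape of
        the input.
    """

    def __init__(self, n_components: int = 3, random_state: int = 0,
                 tol: float = 1e-6, max_iter: int = 500, reg_covar: float = 1e-12):
        self.n_components = n_components
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar

    def _check(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite Z values in input")
        if z.size < self.n_components:
            raise ValueError(
                f"{z.size} points cannot support {self.n_components} components")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        return z

    def fit(self, z: np.ndarray, y: None = None) -> "GaussianMixtureSegmenter":
        z = self._check(z)
        flat = z.reshape(-1, 1)
        gm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="diag",
            tol=self.tol,
            max_iter=self.max_iter,
            reg_covar=self.reg_covar,
            init_params="kmeans",
            n_init=1,
            random_state=self.random_state,
        )
        gm.fit(flat)
        order = np.argsort(gm.means_[:, 0], kind="stable")
        self._gm = gm
        self._order = order
        self.means_ = gm.means_[order, 0]
        self.variances_ = gm.covariances_[order, 0]
        self.weights_ = gm.weights_[order]
        self.weights_ = self.weights_ / self.weights_.sum()
        self.log_likelihood_ = float(gm.score(flat) * flat.shape[0])
        self.labels_ = self.predict(z)
        return self

    def predict(self, z: np.ndarray) -> np.ndarray:
        """Maximum-posterior component index (mean-sorted) per point."""
        z = np.asarray(z, dtype=float)
        raw = self._gm.predict(z.reshape(-1, 1))
        relabel = np.empty(self.n_components, dtype=int)
        relabel[self._order] = np.arange(self.n_components)
        return relabel[raw].reshape(z.shape)

    def predict_proba(self, z: np.ndarray) -> np.ndarray:
        """Posterior responsibilities per point, columns mean-sorted."""
        z = np.asarray(z, dtype=float)
        return self._gm.predict_proba(z.reshape(-1, 1))[:, self._order]

    def result(self, seed: int | None = None) -> GmmResult:
        return GmmResult(
            n_clusters=self.n_components,
            means=self.means_.copy(),
            variances=self.variances_.copy(),
            weights=self.weights_.copy(),
            labels=self.labels_.copy(),
            log_likelihood=self.log_likelihood_,
            seed=self.random_state if seed is None else seed,
        )


def fit_gmm(z_values: np.ndarray, k: int, seed: int = 0) -> GmmResult:
    """Fit a K-component univariate Gaussian mixture to pixel Z values."""
    seg = GaussianMixtureSegmenter(n_components=k, random_state=seed).fit(z_values)
    return seg.result()


def gmm_sweep(z_values: np.ndarray, k_max: int, seed: int = 0,
              out_dir: str | Path | None = None,
              image: ScanImage | None = None) -> list[GmmResult]:
    """Fit mixtures for every K from 2 to ``k_max`` on the same data.

    Each K is fitted independently with the same seed policy.  When
    ``out_dir`` (and a 2-D input or ``image``) is given, a segmented PNG
    per K is written as a control sheet for choosing the minimum cluster
    number by visual inspection.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    z = np.asarray(z_values, dtype=float)
    results = [fit_gmm(z, k, seed) for k in range(2, k_max + 1)]
    if out_dir is not None:
        grid_img = image
        if grid_img is None and z.ndim == 2:
            rows, cols = z.shape
            grid_img = ScanImage(z, np.arange(cols, dtype=float),
                                 np.arange(rows, dtype=float))
        if grid_img is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            for res in results:
                labels = res.labels.reshape(grid_img.shape)
                write_png(grid_img, out_dir / f"sweep_k{res.n_clusters}.png",
                          levels=segmented_levels(labels, res.n_clusters))
    return results


def cluster_heights(result: GmmResult) -> np.ndarray:
    """Height of every cluster referenced to the lowest cluster mean.

    Returns ``means[i] - means[0]`` for i = 1..K-1; with three clusters
    over (background, dark, bright) these are the dark- and
    bright-molecule heights.  K = 1 gives an empty list.
    """
    return result.means[1:] - result.means[0]


def pixel_fractions(result: GmmResult) -> np.ndarray:
    """Fraction of pixels labelled with each cluster; sums to 1 exactly."""
    counts = np.bincount(result.labels.ravel(), minlength=result.n_clusters)
    return counts / counts.sum()


def segmented_levels(labels: np.ndarray, k: int) -> np.ndarray:
    """Grey level per cluster: lowest black, highest white, evenly spaced."""
    if k == 1:
        return np.zeros(labels.shape, dtype=np.uint8)
    lut = np.array([round(255 * j / (k - 1)) for j in range(k)], dtype=np.uint8)
    return lut[labels]


def segment_series_gmm(series: ImageSeries, k: int, seed: int = 0,
                       out_dir: str | Path | None = None) -> pd.DataFrame:
    """Segment every frame of a series independently with a fresh GMM fit.

    Per frame: one segmented PNG (K fixed grey levels) and one table row
    per cluster with the cluster centre, variance, weight, pixel fraction
    and height relative to the lowest cluster.  A per-frame fit failure is
    flagged in the table (NaN statistics) and processing continues.

    Returns the cumulative table; when ``out_dir`` is given it is also
    written there as ``gmm_clusters.txt`` (tab-separated).
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    names = series.file_names()
    for idx, img, name in zip(series.indices, series.frames, names):
        try:
            res = fit_gmm(img.z_grid, k, seed)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("frame %d (%s): GMM fit failed: %s", idx, name, exc)
            rows.append({"image_index": idx, "file_name": name, "cluster": -1,
                         "mean": np.nan, "variance": np.nan, "weight": np.nan,
                         "pixel_fraction": np.nan, "height_vs_lowest": np.nan,
                         "status": "failed"})
            continue
        fracs = pixel_fractions(res)
        heights = np.concatenate([[0.0], cluster_heights(res)])
        for j in range(k):
            rows.append({"image_index": idx, "file_name": name, "cluster": j,
                         "mean": res.means[j], "variance": res.variances[j],
                         "weight": res.weights[j], "pixel_fraction": fracs[j],
                         "height_vs_lowest": heights[j], "status": "ok"})
        if out_dir is not None:
            labels = res.labels.reshape(img.shape)
            write_png(img, out_dir / f"{Path(name).stem}_seg.png",
                      levels=segmented_levels(labels, k))

    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(out_dir / "gmm_clusters.txt", sep="\t", index=False)
    return table
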