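"""Translational drift correction of image series from manual anchor tracks.

Long series acquired at one sample location slowly lose their position:
the whole frame translates between images (a slow drift distinct from
intra-frame creep distortions).  The correction pipeline here is:

1. every frame is embedded in a zero-valued border (:func:`expand_grid`)
   so that rigid translations stay on the canvas and leave a visible
   trace of the original position;
2. the user records the pixel centre of one visually recognisable feature
   on a sample of frames — the anchor track, a headless tab-separated
   list of (file name, x centre, y centre);
3. deviations of the anchors from the first (reference) anchor are fitted
   per axis with a natural cubic spline or a least-squares polynomial of
   the frame index and evaluated at every frame
   (:func:`build_drift_model`);
4. each frame is rigidly translated by the negated, whole-pixel-rounded
   deviation (:func:`apply_correction`), preserving Z values bit-exactly.

Coordinates: ``x`` is the column index, ``y`` the row index of the
expanded pixel frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

from .io_formats import ImageSeries, ScanImage

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorTrack",
    "DriftModel",
    "DriftCorrector",
    "expand_grid",
    "load_anchor_track",
    "build_drift_model",
    "apply_correction",
    "default_pad",
]


@dataclass
class AnchorTrack:
    """Feature-centre samples in the expanded-image pixel frame."""

    entries: list[tuple[int, str, float, float]]  # (frame_index, file, x, y)
    box_size: int = 16

    def __post_init__(self) -> None:
        idx = [e[0] for e in self.entries]
        if len(set(idx)) != len(idx):
            dup = sorted({i for i in idx if idx.count(i) > 1})[0]
            raise ValueError(f"duplicate anchor for frame {dup}")
        self.entries = sorted(self.entries, key=lambda e: e[0])

    @property
    def frames(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries])

    @property
    def centres(self) -> np.ndarray:
        """(n, 2) array of (x, y) centres."""
        return np.array([[e[2], e[3]] for e in self.entries], dtype=float)

    def deviations(self) -> np.ndarray:
        """Anchor centres relative to the first (reference) anchor."""
        c = self.centres
        return c - c[0]


@dataclass
class DriftModel:
    """Fitted per-frame (dx, dy) deviations from the reference frame."""

    deviations: np.ndarray  # (n_frames, 2)
    fit_kind: str           # "cubic_spline" | "polynomial"
    poly_degree: int | None
    anchors: AnchorTrack | None = None

    def __post_init__(self) -> None:
        self.deviations = np.asarray(self.deviations, dtype=float)

    def rounded(self) -> np.ndarray:
        """Whole-pixel deviations (round half up)."""
        return np.floor(self.deviations + 0.5).astype(int)


def expand_grid(img: ScanImage, pad: int) -> ScanImage:
    """Embed the image in a border of exact zeros, ``pad`` pixels wide.

    The physical axes are extended with the original (uniform) spacing;
    non-uniform axes make the extension undefined and raise.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if pad == 0:
        return img.with_z(img.z_grid.copy())

    def extend(ax: np.ndarray, n: int) -> np.ndarray:
        if len(ax) < 2:
            raise ValueError("cannot extend a single-point axis")
        steps = np.diff(ax)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
            raise ValueError("non-uniform axis spacing; grid extension undefined")
        d = steps[0]
        return np.concatenate([ax[0] + d * np.arange(-n, 0), ax,
                               ax[-1] + d * np.arange(1, n + 1)])

    z = np.pad(img.z_grid, pad, mode="constant", constant_values=0.0)
    return ScanImage(z, extend(img.x_coords, pad), extend(img.y_coords, pad),
                     dict(img.metadata))


def load_anchor_track(path: str | Path, series: ImageSeries,
                      box_size: int = 16, check_bounds: bool = True) -> AnchorTrack:
    """Parse a headless anchor-track file against a series.

    Format: tab- (or whitespace-) separated ``file_name  x_centre
    y_centre``, one line per sampled frame, ``#`` comments allowed.  File
    names are resolved to frame indices; unknown names and out-of-bounds
    centres raise.  Input line order does not matter: entries are sorted
    by frame index and the earliest frame becomes the reference.
    """
    path = Path(path)
    name_to_idx = {n: i for i, n in zip(series.indices, series.file_names())}
    rows, cols = series.frames[0].shape

    entries = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 'file x y'")
        name, xs, ys = tokens
        if name not in name_to_idx:
            raise KeyError(f"{path}: line {lineno}: unknown file name {name!r}")
        x, y = float(xs), float(ys)
        if check_bounds and not (0 <= x < cols and 0 <= y < rows):
            raise ValueError(
                f"{path}: line {lineno}: centre ({x:g}, {y:g}) outside "
                f"{rows}x{cols} image bounds")
        entries.append((name_to_idx[name], name, x, y))
    if not entries:
        raise ValueError(f"{path}: no anchor entries")
    return AnchorTrack(entries, box_size=box_size)


class DriftCorrector(BaseEstimator):
    """Anchor-based rigid translational drift correction.

    Parameters
    ----------
    fit_kind : {"cubic_spline", "polynomial"}
        Smooth model of deviation vs. frame index, fitted per axis: a
        natural cubic spline through the anchor deviations, or a
        least-squares polynomial.
    poly_degree : int
        Polynomial degree when ``fit_kind="polynomial"``.

    Attributes
    ----------
    model_ : DriftModel
        Per-frame fitted deviations; exactly (0, 0) at the reference frame.
    """

    def __init__(self, fit_kind: str = "cubic_spline", poly_degree: int = 3):
        self.fit_kind = fit_kind
        self.poly_degree = poly_degree

    def fit(self, track: AnchorTrack, n_frames: int) -> "DriftCorrector":
        self.model_ = build_drift_model(track, n_frames, self.fit_kind,
                                        self.poly_degree)
        return self

    def transform(self, series: ImageSeries) -> ImageSeries:
        return apply_correction(series, self.model_)


def build_drift_model(track: AnchorTrack, n_frames: int,
                      fit_kind: str = "cubic_spline",
                      poly_degree: int = 3) -> DriftModel:
    """Fit anchor deviations per axis and evaluate at every frame.

    Frames outside the anchored span hold the boundary fitted value
    constant (spline/polynomial extrapolation diverges); the reference
    frame's deviation is forced to exactly (0, 0).
    """
    if fit_kind not in ("cubic_spline", "polynomial"):
        raise ValueError(f"unknown fit_kind {fit_kind!r}")
    frames = track.frames
    dev = track.deviations()
    if fit_kind == "cubic_spline" and len(frames) < 2:
        raise ValueError("cubic spline needs at least 2 anchors")
    if fit_kind == "polynomial" and len(frames) < poly_degree + 1:
        raise ValueError(
            f"degree-{poly_degree} polynomial needs at least "
            f"{poly_degree + 1} anchors, got {len(frames)}")

    t = np.arange(n_frames, dtype=float)
    t_clip = np.clip(t, frames[0], frames[-1])  # constant beyond the anchored span
    out = np.empty((n_frames, 2))
    for ax in range(2):
        if fit_kind == "cubic_spline":
            f = CubicSpline(frames, dev[:, ax], bc_type="natural")
            out[:, ax] = f(t_clip)
        else:
            coeffs = np.polynomial.polynomial.polyfit(frames, dev[:, ax], poly_degree)
            out[:, ax] = np.polynomial.polynomial.polyval(t_clip, coeffs)

    extrap = (t < frames[0]) | (t > frames[-1])
    for fr in np.nonzero(extrap)[0]:
        logger.info("frame %d outside anchored span; holding boundary deviation", fr)

    ref = track.entries[0][0]
    if 0 <= ref < n_frames:
        out[ref] = 0.0
    return DriftModel(out, fit_kind,
                      poly_degree if fit_kind == "polynomial" else None, track)


def _translate(z: np.ndarray, shift_rows: int, shift_cols: int) -> np.ndarray:
    """Rigid integer translation with zero fill (no wrap-around)."""
    out = np.zeros_like(z)
    rows, cols = z.shape
    r0, r1 = max(0, shift_rows), min(rows, rows + shift_rows)
    c0, c1 = max(0, shift_cols), min(cols, cols + shift_cols)
    sr0, sr1 = max(0, -shift_rows), min(rows, rows - shift_rows)
    sc0, sc1 = max(0, -shift_cols), min(cols, cols - shift_cols)
    out[r0:r1, c0:c1] = z[sr0:sr1, sc0:sc1]
    return out


def apply_correction(series: ImageSeries, model: DriftModel) -> ImageSeries:
    """Translate frame t by the negated rounded deviation (-dx, -dy).

    Frames must already be grid-expanded with a pad large enough that no
    non-zero pixel leaves the canvas; otherwise the offending frame and
    the minimum sufficient pad are named in the error.  The multiset of
    non-zero Z values of every frame is preserved exactly.
    """
    if model.deviations.shape[0] < len(series):
        raise ValueError("drift model covers fewer frames than the series")
    shifts = model.rounded()
    corrected = []
    for pos, (idx, img) in enumerate(zip(series.indices, series.frames)):
        dx, dy = shifts[pos]
        if dx == 0 and dy == 0:
            corrected.append(img.with_z(img.z_grid.copy()))
            continue
        nz = np.nonzero(img.z_grid)
        if nz[0].size:
            rows, cols = img.shape
            r_lo, r_hi = nz[0].min(), nz[0].max()
            c_lo, c_hi = nz[1].min(), nz[1].max()
            if (r_lo - dy < 0 or r_hi - dy >= rows
                    or c_lo - dx < 0 or c_hi - dx >= cols):
                need = int(max(abs(dy) - min(r_lo, rows - 1 - r_hi),
                               abs(dx) - min(c_lo, cols - 1 - c_hi)))
                raise ValueError(
                    f"frame {idx}: translation ({-dx}, {-dy}) px exceeds the "
                    f"zero pad; expand by at least {need} more pixel(s)")
        corrected.append(img.with_z(_translate(img.z_grid, -dy, -dx)))
    return ImageSeries(corrected, list(series.indices))


def default_pad(track: AnchorTrack) -> int:
    """Pad heuristic: ceil(1.5 x the largest anchor deviation magnitude)."""
    dev = track.deviations()
    return int(np.ceil(1.5 * np.abs(dev).max())) if len(dev) else 0
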