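"""Synthetic monolayer topographs and drifting series with known ground truth.

The generator emulates the statistical structure that the analysis modules
assume about molecular-monolayer scanning-probe images: a periodic lattice
of blob-shaped molecules drawn from a few discrete height classes over a
low background, smooth per-scan-line background offsets (up to quadratic
in X), additive Gaussian noise, sparse single-pixel Z outliers and, for
series, a smooth nonlinear translational drift of the whole scene.

Molecules are isotropic flat-topped blobs (a plateau at the class height
offset with a Gaussian rolloff edge, support truncated 3 sigma beyond the
plateau) on a square or triangular lattice, emulating the plateau-like
molecular regions of close-packed monolayers; the internal structure of
real molecules is deliberately not modelled — only the height-class
statistics matter to the analysis.  One global seed
drives independent substreams for placement/classes, backgrounds, noise
and outliers, so changing one knob never reshuffles the others.

Default conditions mirror the monolayer the analysis targets: three
height classes at 0 (background/ethyl), +25 (dark molecules) and +45 pm
(bright molecules) with 5 pm noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .drift import AnchorTrack
from .io_formats import ImageSeries, ScanImage

__all__ = [
    "MonolayerSpec",
    "MonolayerTruth",
    "DriftSpec",
    "make_monolayer_image",
    "make_drift_series",
    "polynomial_trajectory",
    "sinusoidal_trajectory",
]

Trajectory = Callable[[float], tuple[float, float]]


@dataclass
class MonolayerSpec:
    """Parameters of one synthetic monolayer topograph.

    Z offsets are picometres; lengths are pixels.  ``class_offsets[0]``
    is the background class (offset 0 by convention);
    ``line_background_coeff_ranges`` gives (low, high) uniform ranges for
    the per-row background ``a + b*x + c*x**2`` coefficients.
    """

    rows: int = 128
    cols: int = 128
    lattice_spacing: float = 16.0
    blob_sigma: float = 0.5
    core_radius: float | None = None  # default: spacing/2 - 3*sigma (close-packed)
    class_offsets: tuple[float, ...] = (0.0, 25.0, 45.0)
    class_probabilities: tuple[float, ...] = (0.5, 0.3, 0.2)
    noise_sd: float = 5.0
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 200.0
    line_background_coeff_ranges: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))
    lattice: str = "triangular"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probabilities) - 1.0) > 1e-9:
            raise ValueError("class_probabilities must sum to 1")
        if len(self.class_probabilities) != len(self.class_offsets):
            raise ValueError("one probability per class required")
        if self.blob_sigma <= 0 or self.lattice_spacing <= 0:
            raise ValueError("blob_sigma and lattice_spacing must be positive")
        if self.core_radius is None:
            self.core_radius = self.lattice_spacing / 2 - 3.0 * self.blob_sigma
        if self.core_radius <= 0:
            raise ValueError("lattice too dense for blob size: no room for a "
                             "plateau inside half a lattice spacing")
        # adjacent truncated supports must not overlap, so centre Z is exact
        if self.lattice_spacing < 2.0 * (self.core_radius + 3.0 * self.blob_sigma):
            raise ValueError(
                f"lattice too dense for blob size: spacing "
                f"{self.lattice_spacing} < 2 x (core + 3 sigma) "
                f"({2 * (self.core_radius + 3 * self.blob_sigma)})")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.lattice not in ("square", "triangular"):
            raise ValueError("lattice must be 'square' or 'triangular'")


@dataclass
class MonolayerTruth:
    """Everything needed to predict the analysis results without running it."""

    centres: np.ndarray            # (n_mol, 2) integer (row, col)
    classes: np.ndarray            # (n_mol,) class index per molecule
    class_offsets: np.ndarray      # (n_classes,) programmed height offsets, pm
    row_background: np.ndarray     # (rows, 3) per-row (a, b, c)
    outlier_pixels: np.ndarray     # (n_out, 2) spiked (row, col)
    spec: MonolayerSpec | None = None


def _lattice_centres(spec: MonolayerSpec) -> np.ndarray:
    """Integer-pixel blob centres inside the image, row-major order."""
    s = spec.lattice_spacing
    centres = []
    if spec.lattice == "square":
        for r in np.arange(s / 2, spec.rows, s):
            for c in np.arange(s / 2, spec.cols, s):
                centres.append((round(r), round(c)))
    else:  # triangular: alternate rows offset by half a spacing
        pitch = s * np.sqrt(3) / 2
        for i, r in enumerate(np.arange(s / 2, spec.rows, pitch)):
            off = (s / 2) * (i % 2)
            for c in np.arange(s / 2 + off, spec.cols, s):
                centres.append((round(r), round(c)))
    out = np.array([(r, c) for r, c in centres
                    if 0 <= r < spec.rows and 0 <= c < spec.cols], dtype=int)
    return out


def _blob_field(spec: MonolayerSpec, centres: np.ndarray,
                amplitudes: np.ndarray) -> np.ndarray:
    """Sum of flat-topped blobs; exact amplitude on each plateau."""
    z = np.zeros((spec.rows, spec.cols))
    core = float(spec.core_radius)
    cut = core + 3.0 * spec.blob_sigma
    rad = int(np.ceil(cut))
    dr = np.arange(-rad, rad + 1)
    rr, cc = np.meshgrid(dr, dr, indexing="ij")
    dist = np.sqrt((rr ** 2 + cc ** 2).astype(float))
    stamp = np.where(
        dist <= core, 1.0,
        np.exp(-(dist - core) ** 2 / (2.0 * spec.blob_sigma ** 2)))
    stamp[dist >= cut] = 0.0  # truncate support
    for (r, c), amp in zip(centres, amplitudes):
        if amp == 0.0:
            continue
        r0, r1 = max(0, r - rad), min(spec.rows, r + rad + 1)
        c0, c1 = max(0, c - rad), min(spec.cols, c + rad + 1)
        z[r0:r1, c0:c1] += amp * stamp[r0 - (r - rad):r1 - (r - rad),
                                       c0 - (c - rad):c1 - (c - rad)]
    return z


def _row_background(spec: MonolayerSpec, rng: np.random.Generator,
                    x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranges = np.asarray(spec.line_background_coeff_ranges, dtype=float)
    coeffs = rng.uniform(ranges[:, 0], ranges[:, 1], size=(spec.rows, 3))
    bg = (coeffs[:, 0:1] + coeffs[:, 1:2] * x[None, :]
          + coeffs[:, 2:3] * x[None, :] ** 2)
    return bg, coeffs


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_monolayer_image(spec: MonolayerSpec) -> tuple[ScanImage, MonolayerTruth]:
    """Render one monolayer topograph and its ground-truth record.

    Deterministic for a fixed seed.  With zero noise, zero backgrounds and
    no outliers, the Z value at every molecule centre equals its class
    offset exactly (blob supports never overlap by the spacing invariant).
    """
    place_rng, bg_rng, noise_rng, out_rng = _streams(spec.seed, 4)

    centres = _lattice_centres(spec)
    classes = place_rng.choice(len(spec.class_offsets), size=len(centres),
                               p=spec.class_probabilities)
    offsets = np.asarray(spec.class_offsets, dtype=float)
    z = _blob_field(spec, centres, offsets[classes])

    x = np.arange(spec.cols, dtype=float)
    y = np.arange(spec.rows, dtype=float)
    bg, coeffs = _row_background(spec, bg_rng, x)
    z += bg

    if spec.noise_sd > 0:
        z += noise_rng.normal(0.0, spec.noise_sd, size=z.shape)

    n_out = int(round(spec.outlier_fraction * z.size))
    if n_out:
        flat = out_rng.choice(z.size, size=n_out, replace=False)
        signs = out_rng.choice([-1.0, 1.0], size=n_out)
        z.flat[flat] += signs * spec.outlier_magnitude
        outliers = np.column_stack(np.unravel_index(flat, z.shape))
    else:
        outliers = np.empty((0, 2), dtype=int)

    img = ScanImage(z, x, y, {"filename": "synthetic.txt", "synthetic": True})
    truth = MonolayerTruth(centres, classes, offsets, coeffs, outliers, spec)
    return img, truth


# ---------------------------------------------------------------------------
# Drifting series
# ---------------------------------------------------------------------------


def polynomial_trajectory(coeffs_x: tuple[float, ...],
                          coeffs_y: tuple[float, ...]) -> Trajectory:
    """(dx, dy)(t) as polynomials in the frame index, pinned to (0,0) at t=0."""
    cx, cy = np.asarray(coeffs_x, float), np.asarray(coeffs_y, float)

    def traj(t: float) -> tuple[float, float]:
        p = np.polynomial.polynomial.polyval
        return (float(p(t, cx) - p(0.0, cx)), float(p(t, cy) - p(0.0, cy)))

    return traj


def sinusoidal_trajectory(amplitude: tuple[float, float] = (12.0, 8.0),
                          period: tuple[float, float] = (240.0, 180.0),
                          ) -> Trajectory:
    """Smooth nonlinear drift: per-axis sine ramps starting at (0, 0)."""
    ax, ay = amplitude
    px, py = period

    def traj(t: float) -> tuple[float, float]:
        return (ax * np.sin(2 * np.pi * t / px), ay * np.sin(2 * np.pi * t / py))

    return traj


@dataclass
class DriftSpec:
    """Drift trajectory and optional mid-series class dimming for a series.

    The dim schedule emulates a potential step that darkens part of one
    molecular class (a drop in the concentration of bright/grey
    molecules): from ``dim_frame`` onward, a seeded random subset of
    ``dim_fraction`` of the class-``dim_class`` molecules has its height
    offset multiplied by ``dim_factor`` (0 = dimmed fully down to the
    background class).  The subset grows linearly over ``dim_ramp``
    frames and is nested, so the dimmed population is monotone in time.
    """

    n_frames: int = 60
    trajectory: Trajectory = field(default_factory=sinusoidal_trajectory)
    dim_frame: int | None = None
    dim_class: int = 1
    dim_fraction: float = 0.6
    dim_factor: float = 0.0
    dim_ramp: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        d0 = self.trajectory(0)
        if abs(d0[0]) > 1e-9 or abs(d0[1]) > 1e-9:
            raise ValueError(f"trajectory(0) must be (0, 0), got {d0}")
        if not 0 <= self.dim_fraction <= 1:
            raise ValueError("dim_fraction must be in [0, 1]")

    def dimmed_count(self, t: int, n_class: int) -> int:
        """Number of dimmed molecules (out of ``n_class``) at frame t."""
        if self.dim_frame is None or t < self.dim_frame:
            return 0
        ramp = max(1, self.dim_ramp)
        f = self.dim_fraction * min(1.0, (t - self.dim_frame + 1) / ramp)
        return int(round(f * n_class))


def make_drift_series(mono: MonolayerSpec, drift: DriftSpec, pad: int
                      ) -> tuple[ImageSeries, AnchorTrack]:
    """Render a drifting series plus the ground-truth anchor track.

    Frame t is the frame-0 scene translated by the rounded trajectory and
    embedded in a zero pad, with fresh noise and outliers per frame.  The
    returned track records, for every frame, the true pixel centre of one
    reference molecule (the highest-offset molecule nearest the image
    centre), so drift correction can be validated against ground truth.
    """
    place_rng, _, _, _ = _streams(mono.seed, 4)
    centres = _lattice_centres(mono)
    classes = place_rng.choice(len(mono.class_offsets), size=len(centres),
                               p=mono.class_probabilities)
    offsets = np.asarray(mono.class_offsets, dtype=float)

    # reference feature: brightest-class molecule nearest the image centre
    top = int(np.argmax(offsets))
    cand = np.nonzero(classes == top)[0]
    if cand.size == 0:
        cand = np.arange(len(centres))
    mid = np.array([mono.rows / 2, mono.cols / 2])
    ref_mol = cand[np.argmin(np.sum((centres[cand] - mid) ** 2, axis=1))]
    r0, c0 = centres[ref_mol]

    shifts = np.array([[int(np.floor(v + 0.5)) for v in drift.trajectory(t)]
                       for t in range(drift.n_frames)])  # (n, 2) = (dx, dy)
    if np.abs(shifts).max() > pad:
        raise ValueError(
            f"trajectory excursion {np.abs(shifts).max()} px exceeds pad {pad}")

    frame_streams = np.random.SeedSequence((drift.seed, mono.seed)).spawn(
        drift.n_frames)
    rows_e, cols_e = mono.rows + 2 * pad, mono.cols + 2 * pad
    x = np.arange(cols_e, dtype=float)
    y = np.arange(rows_e, dtype=float)

    # nested dimming order over the molecules of the dimmed class
    dim_rng = np.random.default_rng(np.random.SeedSequence((drift.seed, 7)))
    dim_pool = dim_rng.permutation(np.nonzero(classes == drift.dim_class)[0])

    frames, entries = [], []
    for t in range(drift.n_frames):
        amps = offsets[classes]
        n_dim = drift.dimmed_count(t, len(dim_pool))
        if n_dim:
            amps = amps.copy()
            amps[dim_pool[:n_dim]] *= drift.dim_factor
        scene = _blob_field(mono, centres, amps)

        rng = np.random.default_rng(frame_streams[t])
        if mono.noise_sd > 0:
            scene = scene + rng.normal(0.0, mono.noise_sd, size=scene.shape)
        n_out = int(round(mono.outlier_fraction * scene.size))
        if n_out:
            flat = rng.choice(scene.size, size=n_out, replace=False)
            scene.flat[flat] += (rng.choice([-1.0, 1.0], size=n_out)
                                 * mono.outlier_magnitude)

        dx, dy = shifts[t]
        z = np.zeros((rows_e, cols_e))
        z[pad + dy:pad + dy + mono.rows, pad + dx:pad + dx + mono.cols] = scene

        name = f"frame_{t:04d}.txt"
        frames.append(ScanImage(z, x, y, {"filename": name, "index": t,
                                          "synthetic": True}))
        entries.append((t, name, float(pad + c0 + dx), float(pad + r0 + dy)))

    box = 2 * int(np.ceil(3 * mono.blob_sigma))
    return ImageSeries(frames), AnchorTrack(entries, box_size=box)
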