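"""Grid expansion, anchor tracks, trajectory fitting and rigid correction."""

import numpy as np
import pytest

from spmkit import (
    AnchorTrack,
    ImageSeries,
    ScanImage,
    apply_correction,
    build_drift_model,
    default_pad,
    expand_grid,
    load_anchor_track,
)
from spmkit.drift import DriftCorrector
from spmkit.synthetic import (
    DriftSpec,
    MonolayerSpec,
    make_drift_series,
    sinusoidal_trajectory,
)
from conftest import random_image


def _track(points, box=8):
    """points: list of (frame, x, y)."""
    return AnchorTrack([(f, f"frame_{f:04d}.txt", x, y) for f, x, y in points],
                       box_size=box)


class TestExpandGrid:
    def test_placement_and_border(self, rng):
        img = random_image(rng, 4, 4)
        out = expand_grid(img, 2)
        assert out.shape == (8, 8)
        np.testing.assert_array_equal(out.z_grid[2:6, 2:6], img.z_grid)
        border = out.z_grid.copy()
        border[2:6, 2:6] = 0
        assert np.all(border == 0)

    def test_pad_zero_is_identity(self, rng):
        img = random_image(rng, 4, 5)
        out = expand_grid(img, 0)
        np.testing.assert_array_equal(out.z_grid, img.z_grid)

    def test_sum_preserved(self, rng):
        img = random_image(rng, 6, 6)
        assert expand_grid(img, 3).z_grid.sum() == pytest.approx(img.z_grid.sum())

    def test_axes_extended_with_original_spacing(self, rng):
        img = random_image(rng, 4, 4)
        out = expand_grid(img, 2)
        np.testing.assert_allclose(np.diff(out.x_coords), 1.0)
        assert out.x_coords[2] == img.x_coords[0]

    def test_non_uniform_axis_rejected(self, rng):
        z = rng.normal(size=(3, 3))
        img = ScanImage(z, np.array([0.0, 1.0, 3.0]), np.arange(3, dtype=float))
        with pytest.raises(ValueError, match="spacing"):
            expand_grid(img, 1)


class TestAnchorTrack:
    def _series(self, n=21, shape=(32, 32)):
        frames = [ScanImage(np.zeros(shape), np.arange(shape[1], dtype=float),
                            np.arange(shape[0], dtype=float),
                            {"filename": f"frame_{i:04d}.txt"})
                  for i in range(n)]
        return ImageSeries(frames)

    def test_basic_parse(self, tmp_path):
        p = tmp_path / "track.tsv"
        p.write_text("# comment line\nframe_0000.txt\t5\t6\n"
                     "frame_0010.txt\t7\t8\nframe_0020.txt\t9\t10\n")
        track = load_anchor_track(p, self._series())
        assert [e[0] for e in track.entries] == [0, 10, 20]
        np.testing.assert_array_equal(track.deviations(),
                                      [[0, 0], [2, 2], [4, 4]])

    def test_unknown_file_rejected(self, tmp_path):
        p = tmp_path / "track.tsv"
        p.write_text("nope.txt\t5\t6\n")
        with pytest.raises(KeyError, match="nope.txt"):
            load_anchor_track(p, self._series())

    def test_out_of_bounds_centre_rejected(self, tmp_path):
        p = tmp_path / "track.tsv"
        p.write_text("frame_0000.txt\t500\t6\n")
        with pytest.raises(ValueError, match="bounds"):
            load_anchor_track(p, self._series())

    def test_duplicate_frame_rejected(self, tmp_path):
        p = tmp_path / "track.tsv"
        p.write_text("frame_0000.txt\t5\t6\nframe_0000.txt\t7\t8\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_anchor_track(p, self._series())

    def test_shuffled_lines_give_identical_track(self, tmp_path):
        lines = ["frame_0010.txt\t7\t8", "frame_0000.txt\t5\t6",
                 "frame_0020.txt\t9\t10"]
        (tmp_path / "a.tsv").write_text("\n".join(lines) + "\n")
        (tmp_path / "b.tsv").write_text("\n".join(reversed(lines)) + "\n")
        a = load_anchor_track(tmp_path / "a.tsv", self._series())
        b = load_anchor_track(tmp_path / "b.tsv", self._series())
        assert a.entries == b.entries


class TestBuildDriftModel:
    def test_two_point_spline_is_linear(self):
        model = build_drift_model(_track([(0, 50, 50), (10, 60, 55)]), 11,
                                  "cubic_spline")
        np.testing.assert_allclose(model.deviations[5], [5.0, 2.5])

    def test_reference_frame_deviation_is_zero(self):
        for kind in ("cubic_spline", "polynomial"):
            model = build_drift_model(
                _track([(0, 50, 50), (5, 53, 51), (10, 60, 55)]), 11, kind,
                poly_degree=2)
            np.testing.assert_array_equal(model.deviations[0], [0.0, 0.0])

    def test_interpolation_reproduces_anchors(self):
        pts = [(0, 50, 50), (7, 55, 48), (13, 61, 52), (20, 57, 59)]
        track = _track(pts)
        dev = track.deviations()
        spline = build_drift_model(track, 21, "cubic_spline")
        poly = build_drift_model(track, 21, "polynomial", poly_degree=3)
        for model in (spline, poly):
            for (f, _, _), d in zip(pts, dev):
                np.testing.assert_allclose(model.deviations[f], d, atol=1e-9)

    def test_constant_extrapolation_beyond_last_anchor(self):
        model = build_drift_model(_track([(0, 50, 50), (10, 60, 55)]), 20,
                                  "cubic_spline")
        np.testing.assert_allclose(model.deviations[15], model.deviations[10])
        np.testing.assert_allclose(model.deviations[19], [10.0, 5.0])

    def test_spline_and_polynomial_agree_on_polynomial_trajectory(self):
        # anchors sampled from a quadratic path
        pts = [(f, 50 + 0.02 * f ** 2, 50 + 0.5 * f) for f in range(0, 61, 10)]
        track = _track(pts)
        spline = build_drift_model(track, 61, "cubic_spline")
        poly = build_drift_model(track, 61, "polynomial", poly_degree=2)
        assert np.abs(spline.deviations - poly.deviations).max() < 1.0

    def test_insufficient_anchors_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            build_drift_model(_track([(0, 5, 5), (1, 6, 6)]), 5,
                              "polynomial", poly_degree=3)


class TestApplyCorrection:
    def _frame(self, feature_rc, shape=(80, 80)):
        z = np.zeros(shape)
        z[feature_rc] = 7.0
        return ScanImage(z, np.arange(shape[1], dtype=float),
                         np.arange(shape[0], dtype=float))

    def test_sign_convention(self):
        # feature drifted to (x=60, y=55); deviation (10, 5) -> back to (50, 50)
        series = ImageSeries([self._frame((50, 50)), self._frame((55, 60))])
        model = build_drift_model(_track([(0, 50, 50), (1, 60, 55)]), 2,
                                  "cubic_spline")
        out = apply_correction(series, model)
        assert out.frames[1].z_grid[50, 50] == 7.0
        assert out.frames[1].z_grid[55, 60] == 0.0

    def test_reference_frame_unchanged(self, rng):
        img = expand_grid(random_image(rng, 8, 8), 4)
        series = ImageSeries([img, img.with_z(img.z_grid.copy())])
        model = build_drift_model(_track([(0, 8, 8), (1, 9, 9)]), 2,
                                  "cubic_spline")
        out = apply_correction(series, model)
        np.testing.assert_array_equal(out.frames[0].z_grid, img.z_grid)

    def test_nonzero_multiset_preserved(self, rng):
        img = expand_grid(random_image(rng, 8, 8), 6)
        series = ImageSeries([img, img.with_z(np.roll(img.z_grid, (3, 2), (0, 1)))])
        model = build_drift_model(_track([(0, 10, 10), (1, 12, 13)]), 2,
                                  "cubic_spline")
        out = apply_correction(series, model)
        for src, dst in zip(series.frames, out.frames):
            a = np.sort(src.z_grid[src.z_grid != 0])
            b = np.sort(dst.z_grid[dst.z_grid != 0])
            np.testing.assert_array_equal(a, b)

    def test_translation_exceeding_pad_names_frame(self):
        series = ImageSeries([self._frame((40, 40), (50, 50)),
                              self._frame((40, 40), (50, 50))])
        model = build_drift_model(_track([(0, 35, 10), (1, 10, 10)]), 2,
                                  "cubic_spline")
        with pytest.raises(ValueError, match="frame 1"):
            apply_correction(series, model)

    def test_programmed_drift_recovered(self):
        mono = MonolayerSpec(seed=9)
        dspec = DriftSpec(n_frames=60, trajectory=sinusoidal_trajectory(), seed=9)
        series, truth = make_drift_series(mono, dspec, pad=16)
        anchors = AnchorTrack([truth.entries[i] for i in range(0, 60, 10)],
                              truth.box_size)
        corr = DriftCorrector(fit_kind="cubic_spline").fit(anchors, 60)
        corr.transform(series)
        shifts = corr.model_.rounded()
        pos = np.array([(x - shifts[t, 0], y - shifts[t, 1])
                        for t, (_, _, x, y) in enumerate(truth.entries)])
        assert np.all(pos.std(axis=0) <= 1.0)

    def test_correcting_twice_is_identity(self):
        mono = MonolayerSpec(seed=2, noise_sd=0.0)
        dspec = DriftSpec(n_frames=12, seed=2)
        series, truth = make_drift_series(mono, dspec, pad=16)
        model = build_drift_model(
            AnchorTrack(truth.entries, truth.box_size), 12, "cubic_spline")
        once = apply_correction(series, model)
        # anchors recomputed on the corrected series are constant,
        # so the rebuilt model is (0, 0) everywhere and correction is a no-op
        shifts = model.rounded()
        const = AnchorTrack(
            [(f, n, x - shifts[f, 0], y - shifts[f, 1])
             for (f, n, x, y) in truth.entries], truth.box_size)
        again = apply_correction(once, build_drift_model(const, 12, "cubic_spline"))
        for a, b in zip(once.frames, again.frames):
            np.testing.assert_array_equal(a.z_grid, b.z_grid)

    def test_default_pad_heuristic(self):
        track = _track([(0, 50, 50), (10, 58, 50)])
        assert default_pad(track) == 12
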