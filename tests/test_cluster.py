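"""Cluster photometry: focus search, box and Gaussian-mask ROI methods."""

import numpy as np
import pytest

from fretcal import (
    BoundaryError,
    ChannelStack,
    FitFailedError,
    InvalidInputError,
    find_focus_plane,
    measure_anaphase_cluster,
    measure_metaphase_cluster,
    quantify_cell,
)
from conftest import gaussian_plane, gaussian_stack


def _stack(voxels, channel="donor"):
    return ChannelStack(np.asarray(voxels, dtype=float), channel=channel)


class TestFindFocusPlane:
    def test_unique_maximum(self):
        v = np.zeros((8, 16, 16))
        v[3, 5, 5] = 10.0
        res = find_focus_plane(_stack(v), (5, 5), search_radius_px=3)
        assert (res.z, res.peak_yx) == (3, (5, 5))
        assert not res.no_signal

    def test_gaussian_spot_between_planes_picks_nearer_plane(self):
        # generating axial center at z=4.4: the voxel-grid argmax of the
        # generating function itself is the oracle
        v = gaussian_stack((9, 16, 16), 100.0, 4.4, 8.0, 8.0, 1.5, 1.2)
        oracle_z = np.unravel_index(np.argmax(v), v.shape)[0]
        assert oracle_z == 4
        res = find_focus_plane(_stack(v), (8, 8), search_radius_px=3)
        assert res.z == 4

    def test_tie_breaks_to_lowest_z_then_row_major(self):
        v = np.zeros((8, 16, 16))
        v[2, 5, 5] = 7.0
        v[6, 5, 5] = 7.0
        assert find_focus_plane(_stack(v), (5, 5), 2).z == 2
        v2 = np.zeros((3, 16, 16))
        v2[1, 4, 6] = 7.0
        v2[1, 6, 4] = 7.0
        assert find_focus_plane(_stack(v2), (5, 5), 3).peak_yx == (4, 6)

    def test_all_zero_neighbourhood_flagged_no_signal(self):
        v = np.zeros((4, 16, 16))
        v[0, 14, 14] = 5.0  # outside the search disk
        res = find_focus_plane(_stack(v), (4, 4), search_radius_px=2)
        assert res.no_signal

    def test_seed_outside_image_rejected(self):
        v = np.zeros((4, 16, 16))
        with pytest.raises(InvalidInputError):
            find_focus_plane(_stack(v), (20, 5), 2)


class TestMetaphaseBox:
    def test_flat_background_cancels_exactly(self):
        plane = np.full((20, 20), 7.5)
        corr, roi = measure_metaphase_cluster(plane, (10, 10))
        assert corr == 0.0
        assert roi.mask_pixel_count == 36

    def test_single_pixel_on_flat_background(self):
        plane = np.full((20, 20), 3.0)
        plane[10, 10] += 42.0
        corr, _ = measure_metaphase_cluster(plane, (10, 10))
        assert corr == pytest.approx(42.0)

    def test_matches_generating_function_oracle(self):
        # oracle: evaluate the generating Gaussian directly over the chosen
        # box and ring (independent arithmetic on the analytic function)
        A, s, b = 1000.0, 1.2, 17.0
        plane = gaussian_plane((25, 25), A, 12.0, 12.0, s, s, b)
        corr, roi = measure_metaphase_cluster(plane, (12, 12))
        oy, ox = roi.box_origin
        yy, xx = np.mgrid[oy - 1 : oy + 7, ox - 1 : ox + 7].astype(float)
        box8 = b + A * np.exp(-0.5 * (((yy - 12) / s) ** 2 + ((xx - 12) / s) ** 2))
        ring = np.concatenate([box8[0], box8[7], box8[1:7, 0], box8[1:7, 7]])
        oracle = box8[1:7, 1:7].sum() - 36 * np.median(ring)
        assert corr == pytest.approx(oracle, rel=1e-12)

    @pytest.mark.parametrize("sigma", [0.69, 0.9, 1.1, 1.2])
    @pytest.mark.parametrize("center", [(12.0, 12.0), (12.5, 12.5)])
    def test_recovers_at_least_90pct_of_spot_mass(self, sigma, center):
        A = 500.0
        plane = gaussian_plane((25, 25), A, center[0], center[1], sigma, sigma, 40.0)
        corr, _ = measure_metaphase_cluster(
            plane, (int(round(center[0])), int(round(center[1])))
        )
        total_mass = 2 * np.pi * A * sigma**2
        assert corr >= 0.90 * total_mass

    def test_translation_equivariance(self):
        A, s = 800.0, 1.0
        ref, _ = measure_metaphase_cluster(
            gaussian_plane((30, 30), A, 10.0, 10.0, s, s, 20.0), (10, 10)
        )
        for dy, dx in [(3, 0), (0, 5), (4, 4), (-2, 6)]:
            shifted, _ = measure_metaphase_cluster(
                gaussian_plane((30, 30), A, 10.0 + dy, 10.0 + dx, s, s, 20.0),
                (10 + dy, 10 + dx),
            )
            assert shifted == pytest.approx(ref, rel=1e-3)

    def test_linearity_in_intensity(self):
        plane = gaussian_plane((25, 25), 300.0, 12.0, 12.0, 1.1, 1.1, 0.0)
        base, _ = measure_metaphase_cluster(plane, (12, 12))
        scaled, _ = measure_metaphase_cluster(3.5 * plane, (12, 12))
        assert scaled == pytest.approx(3.5 * base, rel=1e-12)

    def test_peak_too_close_to_edge_raises(self):
        plane = np.random.default_rng(0).poisson(50, (20, 20)).astype(float)
        with pytest.raises(BoundaryError):
            measure_metaphase_cluster(plane, (0, 10))

    def test_negative_corrected_intensity_preserved(self):
        plane = 100.0 - gaussian_plane((20, 20), 50.0, 10.0, 10.0, 1.0, 1.0)
        corr, _ = measure_metaphase_cluster(plane, (10, 10))
        assert corr < 0


class TestAnaphaseGaussian:
    def test_matches_generating_function_over_chosen_mask(self):
        # primary oracle: sum the generating function over the mask the
        # implementation chose, minus the generating offset
        A, sy, sx, b = 800.0, 1.6, 1.3, 25.0
        plane = gaussian_plane((41, 41), A, 20.2, 19.7, sy, sx, b)
        corr, roi = measure_anaphase_cluster(plane, (20, 20), fit_window_px=9)
        p = roi.gaussian_params
        yy, xx = np.mgrid[:41, :41].astype(float)
        mask = (
            ((yy - p["center_y"]) / p["sigma_y"]) ** 2
            + ((xx - p["center_x"]) / p["sigma_x"]) ** 2
        ) <= roi.mask_sigma**2
        oracle = (
            A * np.exp(-0.5 * (((yy - 20.2) / sy) ** 2 + ((xx - 19.7) / sx) ** 2))
        )[mask].sum()
        assert corr == pytest.approx(oracle, rel=1e-3)

    @pytest.mark.parametrize("sy,sx,cy,cx", [
        (2.0, 2.0, 20.0, 20.0),
        (2.0, 2.0, 20.5, 20.2),
        (2.2, 1.8, 20.25, 19.75),
    ])
    def test_closed_form_ellipse_mass_on_well_sampled_spot(self, sy, sx, cy, cx):
        # analytic mass inside the 2.5-sigma ellipse: 2*pi*A*sx*sy*(1-e^{-s^2/2})
        A = 600.0
        plane = gaussian_plane((41, 41), A, cy, cx, sy, sx, 30.0)
        corr, _ = measure_anaphase_cluster(plane, (20, 20), fit_window_px=9)
        analytic = 2 * np.pi * A * sy * sx * (1 - np.exp(-(2.5**2) / 2))
        assert corr == pytest.approx(analytic, rel=5e-3)

    def test_flat_image_raises_fit_failed(self):
        with pytest.raises(FitFailedError):
            measure_anaphase_cluster(np.full((31, 31), 12.0), (15, 15))

    def test_offset_invariance(self):
        plane = gaussian_plane((41, 41), 500.0, 20.0, 20.0, 1.8, 1.8, 10.0)
        base, _ = measure_anaphase_cluster(plane, (20, 20))
        raised, _ = measure_anaphase_cluster(plane + 50.0, (20, 20))
        assert raised == pytest.approx(base, rel=1e-6)

    def test_mask_sigma_controls_mask_size(self):
        plane = gaussian_plane((41, 41), 500.0, 20.0, 20.0, 2.0, 2.0, 5.0)
        _, roi_small = measure_anaphase_cluster(plane, (20, 20), mask_sigma=1.5)
        _, roi_big = measure_anaphase_cluster(plane, (20, 20), mask_sigma=3.0)
        assert roi_big.mask_pixel_count > roi_small.mask_pixel_count


class TestQuantifyCell:
    def _cell_stacks(self, masses=(1000.0, 1000.0, 1000.0), shape=(7, 24, 24)):
        stacks = {}
        for channel, mass in zip(("donor", "acceptor", "fret"), masses):
            A = mass  # peak amplitude, not integrated mass; fine for symmetry tests
            v = gaussian_stack(shape, A, 3.0, 12.0, 12.0, 1.4, 1.0, 5.0)
            stacks[channel] = _stack(v, channel)
        return stacks

    def test_identical_channels_give_identical_intensities(self):
        m = quantify_cell(self._cell_stacks(), (12, 12), "metaphase")
        vals = list(m.intensities.values())
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[0] == pytest.approx(vals[2], rel=1e-12)

    def test_roi_is_shared_across_channels(self):
        m = quantify_cell(self._cell_stacks((900, 50, 10)), (12, 12), "metaphase")
        assert m.roi.method == "metaphase_box"
        # a single RoiSpec object is recorded; intensities used it unchanged
        m2 = quantify_cell(self._cell_stacks((900, 50, 10)), (12, 12), "anaphase")
        assert m2.roi.method == "anaphase_gaussian"
        assert m2.roi.gaussian_params is not None

    def test_zero_acceptor_channel_measures_zero(self):
        stacks = self._cell_stacks((1000.0, 0.0, 1000.0))
        m = quantify_cell(stacks, (12, 12), "metaphase")
        assert m["acceptor"] == pytest.approx(0.0, abs=1e-9)
        assert m["donor"] > 0

    def test_shape_mismatch_rejected(self):
        stacks = self._cell_stacks()
        stacks["fret"] = _stack(np.zeros((5, 24, 24)), "fret")
        with pytest.raises(InvalidInputError):
            quantify_cell(stacks, (12, 12), "metaphase")

    def test_anaphase_shared_roi_channel_scaling(self):
        # scaling one channel scales its corrected intensity linearly under
        # the shared-geometry ROI
        stacks = self._cell_stacks((1000.0, 1000.0, 1000.0))
        m1 = quantify_cell(stacks, (12, 12), "anaphase")
        stacks2 = dict(stacks)
        stacks2["fret"] = _stack(stacks["fret"].voxels * 0.25, "fret")
        m2 = quantify_cell(stacks2, (12, 12), "anaphase")
        assert m2["fret"] == pytest.approx(0.25 * m1["fret"], rel=1e-9)
        assert m2["donor"] == pytest.approx(m1["donor"], rel=1e-12)
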