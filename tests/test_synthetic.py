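import math

import numpy as np
import pytest
from scipy.ndimage import maximum_filter

from credkit.distortion import DistortionModel, fit_elliptical_distortion
from credkit.frames import FrameKind
from credkit.physics import InvalidArgumentError, electron_wavelength
from credkit.schedule import build_schedule
from credkit.screening import isolation_filter
from credkit.synthetic import (SyntheticExperiment, disc_overlap_fraction,
                               reciprocal_basis, ring_points_from_truth,
                               rotation_about, simulate_crystal_field,
                               simulate_pattern_classes,
                               simulate_rotation_series)
from oracles import brute_force_isolation


class TestGeometryHelpers:
    def test_cubic_reciprocal_basis(self):
        rec = reciprocal_basis((10, 10, 10, 90, 90, 90))
        assert np.allclose(rec, np.eye(3) * 0.1)

    def test_rotation_matrix_is_orthonormal(self):
        r = rotation_about((1, 0, 0), 33.0)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0)

    @pytest.mark.parametrize("offset,expected", [
        (0.0, 1.0),                      # concentric, fully inside
        (10.0, 0.0),                     # disjoint
        (0.75 - 0.35, 1.0),              # just tangent internally
    ])
    def test_disc_overlap_limits(self, offset, expected):
        assert disc_overlap_fraction(offset, 0.35, 0.75) == pytest.approx(expected)

    def test_disc_overlap_monotone_decreasing(self):
        vals = [disc_overlap_fraction(d, 0.35, 0.75) for d in np.linspace(0, 1.2, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestRotationSeries:
    def test_spot_radii_match_projection_oracle(self, steady_series):
        """r_px = L * lambda / (d * pixel_pitch) for every rendered spot."""
        exp = steady_series["exp"]
        truth = steady_series["truth"]
        lam = electron_wavelength(exp.voltage_kv)
        px_mm = exp.pixel_pitch * 1e-3
        checked = 0
        for frame_spots in truth.spots:
            for s in frame_spots:
                r = math.hypot(s["x"] - exp.beam_center[0],
                               s["y"] - exp.beam_center[1])
                oracle = lam * exp.camera_length / (s["d"] * px_mm)
                assert r == pytest.approx(oracle, rel=5e-3)
                checked += 1
        assert checked > 50

    def test_cubic_100_spot_radius_example(self):
        # a = 10 A, 200 kV, L = 1000 mm -> 45.6 px for d = 10 A
        exp = SyntheticExperiment()
        lam = electron_wavelength(200.0)
        r_px = lam * 1000.0 / (10.0 * 0.055)
        assert r_px == pytest.approx(45.6, abs=0.05)

    def test_zero_drift_attenuation_all_one(self, steady_series):
        att = np.array(steady_series["truth"].attenuation)
        assert att == pytest.approx(np.ones_like(att))

    def test_drift_attenuation_monotone_and_reaches_low(self, drifting_series):
        att = np.array(drifting_series["truth"].attenuation)
        assert (np.diff(att) <= 1e-12).all()
        assert att[0] == pytest.approx(1.0)
        assert att[-1] < 0.5

    def test_defocus_slots_render_crystal_silhouette(self, drifting_series):
        frames = drifting_series["frames"]
        schedule = drifting_series["schedule"]
        defocus = [f for f in frames if f.kind == FrameKind.DEFOCUS_TRACKING]
        assert len(defocus) == schedule.n_defocus_frames
        # silhouette is a bright disc: a defocus frame has a large connected
        # bright region instead of isolated spots
        f = defocus[0]
        bright = f.pixels > 25
        assert bright.sum() > 500

    def test_reproducible_given_seed(self):
        schedule = build_schedule(n_data=4, n_interval=10)
        exp = SyntheticExperiment(seed=5)
        f1, t1 = simulate_rotation_series(exp, schedule)
        f2, t2 = simulate_rotation_series(exp, schedule)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.pixels, b.pixels)
        assert t1.attenuation == t2.attenuation

    def test_empty_reciprocal_set_warns_and_blank(self):
        schedule = build_schedule(n_data=2, n_interval=10)
        exp = SyntheticExperiment(cell=(2, 2, 2, 90, 90, 90), d_min=5.0, seed=1)
        with pytest.warns(UserWarning):
            frames, truth = simulate_rotation_series(exp, schedule)
        assert all(len(s) == 0 for s in truth.spots)

    def test_excitation_count_matches_sphere_crossing_oracle(self):
        """Over a full turn each reflection is excited in as many angular
        clusters as it has Ewald-sphere crossings (two, for reflections not
        on the rotation axis)."""
        exp = SyntheticExperiment(d_min=5.0, excitation_tolerance=0.005,
                                  peak_counts=100.0, seed=2,
                                  orientation=np.eye(3))
        # 180 slots x 2 deg = 360 deg; start away from 0 so no crossing
        # cluster straddles the ends of the angular range
        schedule = build_schedule(n_data=180, n_interval=10**9,
                                  frame_time=1.0, rotation_speed=2.0,
                                  start_angle=17.0)
        _, truth = simulate_rotation_series(exp, schedule)

        # independent oracle: sign changes of the excitation error over angle
        rec = reciprocal_basis(exp.cell)
        lam = exp.wavelength
        k0 = 1.0 / lam
        for hkl in [(0, 1, 0), (0, 0, 1), (0, 1, 1)]:
            g0 = np.array(hkl, dtype=float) @ rec
            angles = np.arange(0.0, 360.0, 0.05)
            s = np.array([
                np.linalg.norm(rotation_about((1, 0, 0), a) @ g0
                               + np.array([0, 0, k0])) - k0
                for a in angles
            ])
            crossings = int((np.diff(np.sign(s)) != 0).sum())
            # frames where the simulator excited this hkl
            excited = [
                i for i, frame in enumerate(truth.spots)
                if any(tuple(sp["hkl"]) == hkl for sp in frame)
            ]
            clusters = sum(1 for a, b in zip([-10] + excited, excited)
                           if b - a > 1)
            assert crossings == 2
            assert clusters <= 2
            assert len(excited) >= 1

    def test_distorted_series_recovers_eccentricity(self):
        """Forward-distorted spot positions on one ring refit to e within 0.01."""
        model = DistortionModel(eccentricity=0.22, azimuth=0.0,
                                center=(258.0, 258.0))
        # L = 500 mm keeps the d ~ 1.11 A ring (r ~ 205 px) on the detector
        exp = SyntheticExperiment(d_min=0.9, excitation_tolerance=0.004,
                                  camera_length=500.0,
                                  beam_center=(258.0, 258.0), seed=3)
        schedule = build_schedule(n_data=120, n_interval=10**9,
                                  frame_time=1.0, rotation_speed=1.5)
        _, truth = simulate_rotation_series(exp, schedule, distortion=model)
        # {h00}-family ring at d = 10/9 ~ 1.111 A spans azimuth as the
        # crystal rotates
        pts = ring_points_from_truth(truth, d_target=10.0 / 9.0, rel_tol=0.001)
        assert len(pts) >= 20
        fitted = fit_elliptical_distortion(pts)
        assert abs(fitted.eccentricity - 0.22) < 0.01


class TestPatternClasses:
    def test_deterministic_per_seed(self):
        a, la, _ = simulate_pattern_classes(5, seed=9, size=80)
        b, lb, _ = simulate_pattern_classes(5, seed=9, size=80)
        assert np.array_equal(a, b)
        assert np.array_equal(la, lb)

    def test_labels_and_shapes(self):
        imgs, labels, names = simulate_pattern_classes(
            4, classes=("spots", "rings", "blank"), seed=1, size=96)
        assert imgs.shape == (12, 96, 96)
        assert imgs.min() >= 0 and imgs.max() <= 1
        assert labels.tolist() == [1] * 4 + [0] * 8
        assert names[:4] == ["spots"] * 4

    def test_spot_class_has_sharp_local_maxima(self):
        imgs, _, _ = simulate_pattern_classes(6, classes=("spots",), seed=4)
        for img in imgs:
            background = np.median(img)
            noise = img[img <= np.percentile(img, 50)].std()
            peaks = (img == maximum_filter(img, size=9)) & \
                    (img > background + 5 * max(noise, 1e-3))
            assert peaks.sum() >= 5

    def test_ring_class_azimuthally_uniform(self):
        imgs, _, _ = simulate_pattern_classes(4, classes=("rings",), seed=8)
        for img in imgs:
            size = img.shape[0]
            yy, xx = np.mgrid[0:size, 0:size]
            r = np.hypot(xx - size / 2, yy - size / 2).astype(int)
            radial = np.bincount(r.ravel(), weights=img.ravel()) / \
                np.maximum(np.bincount(r.ravel()), 1)
            ring_r = np.argmax(radial[12:size // 2]) + 12
            band = (np.abs(np.hypot(xx - size / 2, yy - size / 2) - ring_r) < 1.5)
            theta = np.arctan2(yy - size / 2, xx - size / 2)[band]
            vals = img[band]
            bins = np.digitize(theta, np.linspace(-np.pi, np.pi, 19))
            means = np.array([vals[bins == b].mean() for b in range(1, 19)])
            cv = means.std() / means.mean()
            assert cv < 0.2

    def test_unknown_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_pattern_classes(2, classes=("swirl",), seed=0)


class TestCrystalField:
    def test_planted_pair_removed_by_filter(self):
        field = simulate_crystal_field(n_crystals=40, seed=6,
                                       planted_close_pairs=3, pair_distance=1.0)
        kept = set(isolation_filter(field["positions"], field["frame"]).tolist())
        n = 40
        for i in field["planted_pair_indices"]:
            assert i not in kept            # original of the pair
            assert (n + i) not in kept      # planted mate

    def test_zero_crystals(self):
        field = simulate_crystal_field(n_crystals=0, seed=0,
                                       planted_close_pairs=0)
        assert field["positions"].shape[0] == 0

    def test_filter_matches_oracle_on_200_crystal_map(self):
        field = simulate_crystal_field(n_crystals=200, seed=13)
        kept = isolation_filter(field["positions"], field["frame"])
        assert kept.tolist() == brute_force_isolation(field["positions"],
                                                      field["frame"])
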