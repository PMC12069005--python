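"""UWF vessel-tree metrics: ROI geometry, fractal dimension, widths, tortuosity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from oculovasc import synth, uwf
from oculovasc.uwf import (
    Landmarks,
    RobustWidthModel,
    aggregate_vessel_metrics,
    box_count_fd,
    build_roi_masks,
    fit_width_model,
    sample_widths_along_path,
    sandbox_fd,
    tortuosity_density,
)


class TestROIMasks:
    def landmarks(self, shape=(1200, 1200)):
        return Landmarks(disc_center=(shape[0] / 2, shape[1] / 2),
                         disc_radius_px=80.0,
                         fovea=(shape[0] / 2, shape[1] / 2 - 470))

    def test_disc_center_in_no_roi(self):
        roi = build_roi_masks((1200, 1200), self.landmarks())
        assert not roi.standard[600, 600]
        assert not roi.posterior[600, 600] and not roi.midperiphery[600, 600]

    def test_point_inside_posterior_annulus(self):
        roi = build_roi_masks((1200, 1200), self.landmarks())
        # 4 mm = 400 px from the disc centre, outside the 0.8 mm disc
        assert roi.posterior[600, 600 + 400]
        assert not roi.midperiphery[600, 600 + 400]

    @pytest.mark.parametrize("seed", range(20))
    def test_posterior_and_midperiphery_partition_standard(self, seed):
        rng = np.random.default_rng(seed)
        shape = (400, 400)
        disc = rng.uniform(120, 280, size=2)
        fovea = disc + rng.uniform(-90, 90, size=2)
        if np.hypot(*(fovea - disc)) < 20:
            fovea = disc + np.array([0.0, 60.0])
        lm = Landmarks(disc_center=tuple(disc), disc_radius_px=25.0,
                       fovea=tuple(fovea))
        roi = build_roi_masks(shape, lm, pixel_scale_um=30.0)
        assert not (roi.posterior & roi.midperiphery).any()
        assert ((roi.posterior | roi.midperiphery) == roi.standard).all()

    def test_coincident_landmarks_rejected(self):
        lm = Landmarks(disc_center=(100, 100), disc_radius_px=10, fovea=(100, 100))
        with pytest.raises(ValueError):
            build_roi_masks((200, 200), lm)


class TestSandboxFD:
    def test_translation_and_rotation_invariance_on_carpet(self):
        img, _ = synth.gen_fractal_fixture("sierpinski_carpet", 5)
        base = sandbox_fd(img, seed=0)
        shifted = np.roll(np.roll(img, 3, axis=0), -5, axis=1)
        rotated = np.rot90(img)
        assert abs(sandbox_fd(shifted, seed=0) - base) <= 0.02
        assert abs(sandbox_fd(rotated, seed=0) - base) <= 0.02

    def test_denser_posterior_scene_has_higher_posterior_fd(self):
        def scene_with(n_per_quadrant):
            vessels = [synth.VesselTruth(width_intercept_um=90,
                                         width_gradient_um_per_mm=-3,
                                         tortuosity="arc", amplitude_mm=0.2 + 0.1 * k,
                                         quadrant=q, length_mm=5.0)
                       for q in uwf.QUADRANTS for k in range(n_per_quadrant)]
            s, _ = synth.gen_vessel_scene(vessels, image_shape=(1200, 1200),
                                          pixel_scale_um=10.0, seed=1)
            return s

        sparse, dense = scene_with(1), scene_with(3)
        roi = build_roi_masks(sparse.vessel_map.shape, sparse.landmarks,
                              pixel_scale_um=10.0)
        fd_sparse = sandbox_fd(sparse.vessel_map, roi.posterior, seed=0)
        fd_dense = sandbox_fd(dense.vessel_map, roi.posterior, seed=0)
        assert fd_dense > fd_sparse

    def test_too_few_pixels_raises(self):
        img = np.zeros((200, 200), dtype=bool)
        img[100, 100:120] = True
        with pytest.raises(ValueError, match="too few"):
            sandbox_fd(img)

    def test_explicit_radius_without_admissible_seed_raises(self):
        img, _ = synth.gen_fractal_fixture("line", 5)   # 243 px wide
        with pytest.raises(ValueError, match="largest sandbox"):
            sandbox_fd(img, radii=[2, 4, 200], seed=0)


class TestWidthSampling:
    def test_constant_width_vessel_recovered_within_one_pixel(self):
        vessels = [synth.VesselTruth(width_intercept_um=100.0,
                                     width_gradient_um_per_mm=0.0,
                                     quadrant="IN", length_mm=6.0)]
        scene, _ = synth.gen_vessel_scene(vessels, image_shape=(1300, 1300),
                                          pixel_scale_um=10.0, seed=0)
        prof = sample_widths_along_path(scene, 0)
        assert np.all(np.abs(prof.widths_um - 100.0) <= 10.0)

    def test_linear_taper_width_at_distance(self, taper_scene):
        scene, truth = taper_scene
        prof = sample_widths_along_path(scene, 0)
        idx = np.argmin(np.abs(prof.distances_mm - 5.0))
        expected = truth.width_intercept_um + truth.width_gradient_um_per_mm * 5.0
        assert abs(prof.widths_um[idx] - expected) <= 10.0  # one pixel-width

    def test_micron_widths_scale_with_pixel_scale(self, taper_scene):
        scene, _ = taper_scene
        prof1 = sample_widths_along_path(scene, 0)
        doubled = uwf.VesselScene(vessel_map=scene.vessel_map,
                                  centerlines=scene.centerlines,
                                  landmarks=scene.landmarks,
                                  pixel_scale_um=scene.pixel_scale_um * 2)
        prof2 = sample_widths_along_path(doubled, 0)
        # with the scale doubled, every second sample of the rescaled profile
        # sits at the same pixel position as the original samples
        aligned = prof2.widths_um[::2]
        n = min(len(prof1.widths_um), len(aligned))
        np.testing.assert_allclose(aligned[:n], 2 * prof1.widths_um[:n], rtol=1e-6)

    def test_centerline_off_map_raises(self, taper_scene):
        scene, _ = taper_scene
        broken = uwf.VesselScene(
            vessel_map=scene.vessel_map,
            centerlines=[uwf.Centerline(
                points=scene.centerlines[0].points + 300.0,
                vessel_class="arteriole", quadrant="ST", vessel_id=0)],
            landmarks=scene.landmarks, pixel_scale_um=10.0)
        with pytest.raises(ValueError, match="leaves the vessel map"):
            sample_widths_along_path(broken, 0)


def lts_slope_bruteforce(d, w, keep_frac=0.8):
    """Least-trimmed-squares oracle: best OLS over all keep_frac subsets."""
    from itertools import combinations

    n = len(d)
    k = int(round(keep_frac * n))
    best = (np.inf, None)
    for subset in combinations(range(n), k):
        idx = list(subset)
        X = np.column_stack([np.ones(k), d[idx]])
        coef, res, *_ = np.linalg.lstsq(X, w[idx], rcond=None)
        ssr = float(res[0]) if len(res) else float(((w[idx] - X @ coef) ** 2).sum())
        if ssr < best[0]:
            best = (ssr, coef)
    return best[1][1]


class TestRobustWidthModel:
    def test_exact_recovery_on_noiseless_taper(self):
        d = np.linspace(0, 10, 11)
        m = RobustWidthModel().fit(d, 120 - 4 * d)
        assert abs(m.slope_ + 4.0) < 1e-9 and abs(m.intercept_ - 120.0) < 1e-9

    def test_constant_profile(self):
        d = np.linspace(0, 10, 11)
        m = RobustWidthModel().fit(d, np.full(11, 100.0))
        assert abs(m.slope_) < 1e-9 and abs(m.intercept_ - 100.0) < 1e-9

    def test_contaminated_slope_matches_lts_oracle(self):
        d = np.arange(10, dtype=float)
        w = 120 - 4 * d
        w[[3, 7]] += 40.0                      # 20% contamination
        robust = RobustWidthModel().fit(d, w).slope_
        lts = lts_slope_bruteforce(d, w)
        ols = np.polyfit(d, w, 1)[0]
        assert abs(robust - (-4.0)) <= 0.2
        assert abs(robust - lts) <= 0.2
        assert abs(ols - (-4.0)) > 0.2         # OLS is pulled off; the robust fit isn't

    def test_clean_fit_agrees_with_ols(self, rng):
        d = np.linspace(0, 8, 20)
        w = 110 - 3 * d + rng.normal(0, 1.0, 20)
        robust = RobustWidthModel().fit(d, w).slope_
        ols = np.polyfit(d, w, 1)[0]
        assert abs(robust - ols) < 0.15

    def test_ground_truth_recovery_under_noise(self, rng):
        # 100 vessels, caliber noise SD 2 um on a 0.25 mm sampling grid
        wg_err, wi_err = [], []
        d = np.arange(0, 8.01, 0.25)
        for _ in range(100):
            wi = rng.uniform(80, 160)
            wg = rng.uniform(-6, -2)
            w = wi + wg * d + rng.normal(0, 2.0, len(d))
            m = RobustWidthModel().fit(d, w)
            wg_err.append(abs(m.slope_ - wg))
            wi_err.append(abs(m.intercept_ - wi))
        assert np.mean(wg_err) < 0.3
        assert np.mean(wi_err) < 5.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            RobustWidthModel().fit([1, 2, 3], [1, 2, 3])          # too few
        with pytest.raises(ValueError):
            RobustWidthModel().fit(np.ones(6), np.arange(6.0))    # equal distances

    def test_sklearn_style_params_roundtrip(self):
        m = RobustWidthModel(tuning_constant=3.0)
        assert m.get_params()["tuning_constant"] == 3.0
        m.set_params(tol=1e-6)
        assert m.tol == 1e-6
        with pytest.raises(ValueError):
            m.set_params(bogus=1)


def tort_oracle_sinusoid(amplitude, length, periods):
    """Direct evaluation of the tortuosity-density formula for a sinusoid.

    Inflections of a*sin(2*pi*k*t/L) sit at the half-period zeros, giving
    n = 2k curve segments; arcs come from quadrature of the arclength
    integrand, chords are the straight spans between zeros.
    """
    k = periods
    n = 2 * k
    half = length / n
    omega = 2 * math.pi * k / length

    def ds(t):
        return math.sqrt(1 + (amplitude * omega * math.cos(omega * t)) ** 2)

    arc, _ = quad(ds, 0, half)
    total = arc * n
    excess = n * (arc / half - 1.0)
    return (n - 1) / n / total * excess


class TestTortuosity:
    def path(self, f, length=10.0, n=400):
        t = np.linspace(0, length, n)
        return np.column_stack([f(t), t])

    def test_straight_path_scores_zero(self):
        assert tortuosity_density(self.path(lambda t: 0 * t)) == 0.0

    def test_single_arc_scores_zero(self):
        theta = np.linspace(0, math.pi, 300)
        semi = np.column_stack([5 * np.sin(theta), 5 * np.cos(theta)])
        assert tortuosity_density(semi) == 0.0

    @pytest.mark.parametrize("periods", [2, 3, 4])
    def test_sinusoid_matches_direct_formula(self, periods):
        a, L = 0.5, 10.0
        path = self.path(lambda t: a * np.sin(2 * math.pi * periods * t / L), L)
        got = tortuosity_density(path)
        expected = tort_oracle_sinusoid(a, L, periods)
        assert got == pytest.approx(expected, rel=0.10)

    def test_monotone_in_inflection_count(self):
        vals = [tortuosity_density(
            self.path(lambda t, k=k: 0.5 * np.sin(2 * math.pi * k * t / 10.0)))
            for k in (2, 3, 4)]
        assert vals[0] < vals[1] < vals[2]

    def test_uniform_scaling_divides_tort_by_scale(self):
        path = self.path(lambda t: 0.5 * np.sin(2 * math.pi * 3 * t / 10.0))
        t1 = tortuosity_density(path)
        t2 = tortuosity_density(path * 2.0)
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-6)

    def test_non_negative_on_random_walks(self, rng):
        for _ in range(20):
            steps = rng.normal(size=(60, 2))
            path = np.cumsum(steps, axis=0)
            assert tortuosity_density(path) >= 0.0

    def test_short_or_degenerate_paths_rejected(self):
        with pytest.raises(ValueError):
            tortuosity_density(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            tortuosity_density(np.zeros((20, 2)))   # zero length


class TestAggregation:
    def records(self, **overrides):
        rows = []
        for q, wg in zip(uwf.QUADRANTS, (-3.0, -4.0, -5.0, -6.0)):
            rows.append({"vessel_class": "arteriole", "quadrant": q,
                         "WG": overrides.get(q, wg)})
        return pd.DataFrame(rows)

    def test_identical_quadrants_pass_through(self):
        df = self.records(ST=-4.0, SN=-4.0, IT=-4.0, IN=-4.0)
        agg = aggregate_vessel_metrics(df)
        for scope in ("temporal", "nasal", "global"):
            assert agg.loc[("arteriole", scope), "WG"] == -4.0

    def test_global_is_hand_computed_mean(self):
        agg = aggregate_vessel_metrics(self.records())
        assert agg.loc[("arteriole", "global"), "WG"] == pytest.approx(-4.5)
        assert agg.loc[("arteriole", "temporal"), "WG"] == pytest.approx(-4.0)
        assert agg.loc[("arteriole", "nasal"), "WG"] == pytest.approx(-5.0)

    def test_empty_scope_is_missing_not_zero(self):
        df = self.records().query("quadrant in ('ST', 'IT')")
        agg = aggregate_vessel_metrics(df)
        assert np.isnan(agg.loc[("arteriole", "nasal"), "WG"])
        assert not np.isnan(agg.loc[("arteriole", "temporal"), "WG"])
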