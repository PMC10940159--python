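"""Local curvature estimation and curvature-calcium correlation."""

import numpy as np
import pytest
from skimage import draw

from lysomech import synthetic as syn
from lysomech.curvature import (
    ContourTooShortError,
    NoEligiblePixelsError,
    analyze_movie,
    average_over_frames,
    frame_correlation,
    local_curvature,
    local_intensity,
    select_sampling_points,
)
from lysomech.segmentation import trace_boundary
from tests.conftest import disk_mask, single_object


def disk_boundary(radius_px):
    return trace_boundary(single_object(disk_mask(radius_px)))


class TestLocalCurvature:
    @pytest.mark.parametrize("radius", [10, 20, 40])
    def test_circle_reciprocal_radius(self, radius):
        k = local_curvature(disk_boundary(radius), window_k=5)
        assert np.median(k) == pytest.approx(1.0 / radius, rel=0.05)

    def test_scale_covariance(self):
        # doubling the radius halves the estimated curvature; each median
        # is individually within 5% of 1/r, so the ratio is within ~10%
        med = {r: np.median(local_curvature(disk_boundary(r), 5)) for r in (10, 20, 40)}
        for r in (10, 20, 40):
            assert med[r] == pytest.approx(1.0 / r, rel=0.05)
        assert med[10] / med[20] == pytest.approx(2.0, rel=0.10)
        assert med[20] / med[40] == pytest.approx(2.0, rel=0.10)

    def test_collinear_triple_is_zero(self):
        pts = np.column_stack([np.zeros(12, int), np.arange(12)])
        # direct Menger evaluation on a straight run (no closure assumption
        # matters for interior points)
        k = local_curvature(pts, window_k=1, smooth_window=1)
        assert k[5] == 0.0

    def test_ellipse_vertex_curvature(self):
        m = np.zeros((71, 121), dtype=np.uint8)
        rr, cc = draw.ellipse(35, 60, 22.5, 45)
        m[rr, cc] = 1
        b = trace_boundary(single_object(m))
        k = local_curvature(b, window_k=5)
        vertex = float(np.max(k))  # brute-force max-kappa search finds vertex
        assert vertex == pytest.approx(45 / 22.5**2, rel=0.10)

    def test_rotation_and_translation_invariance(self):
        m = np.zeros((71, 121), dtype=np.uint8)
        rr, cc = draw.ellipse(35, 60, 22.5, 45)
        m[rr, cc] = 1
        k0 = local_curvature(trace_boundary(single_object(m)), 5)
        m90 = np.rot90(m).copy()
        k90 = local_curvature(trace_boundary(single_object(m90)), 5)
        shifted = np.zeros((91, 141), dtype=np.uint8)
        shifted[13 : 13 + 71, 7 : 7 + 121] = m
        ks = local_curvature(trace_boundary(single_object(shifted)), 5)
        assert np.median(k90) == pytest.approx(np.median(k0), rel=0.03)
        assert np.median(ks) == pytest.approx(np.median(k0), rel=1e-9)

    def test_short_contour_raises(self):
        with pytest.raises(ContourTooShortError):
            local_curvature(np.zeros((8, 2)), window_k=5)
        with pytest.raises(ValueError):
            local_curvature(disk_boundary(10), window_k=0)


class TestSelection:
    def test_all_convex_circle_fully_retained(self):
        k = local_curvature(disk_boundary(15), 5)
        assert select_sampling_points(k).all()

    def test_concave_neck_removed(self, five_lobe):
        # analytic lobed shape has concave arcs between lobes
        keep = select_sampling_points(five_lobe.kappa_per_um)
        assert 0 < keep.sum() < five_lobe.n_points

    def test_retained_count_matches_truth_on_rendered_shape(self, five_lobe):
        fix = syn.render_movie(five_lobe, syn.CouplingSpec(), n_frames=1)
        from lysomech.segmentation import extract_objects

        obj = extract_objects(fix.labels[0], fix.movie[0, 0])[0]
        b = trace_boundary(obj)
        k = local_curvature(b, 5)
        frac_est = select_sampling_points(k).mean()
        # pixel contours sample the curve uniformly in arc length, so the
        # ground-truth fraction must be arc-length weighted (the analytic
        # points are uniform in theta, which oversamples slow-arc regions)
        ds = five_lobe.arc_lengths_um()
        frac_true = ds[five_lobe.kappa_per_um >= 0].sum() / ds.sum()
        assert frac_est == pytest.approx(frac_true, abs=0.05)


class TestLocalIntensity:
    def test_uniform_image(self):
        img = np.full((20, 20), 100.0)
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mean, n = local_intensity(img, (10, 10), mask)
        assert mean == 100.0 and n == 25

    def test_half_plane_edge_counts_15_pixels(self):
        img = np.ones((20, 20))
        mask = np.zeros((20, 20), bool)
        mask[:, :10] = True  # object fills columns 0..9; edge at col 9
        mean, n = local_intensity(img, (10, 9), mask)
        assert n == 15  # 3 eligible columns x 5 rows

    def test_no_eligible_pixels_raises(self):
        img = np.ones((20, 20))
        mask = np.zeros((20, 20), bool)
        with pytest.raises(NoEligiblePixelsError):
            local_intensity(img, (10, 10), mask)

    def test_recovers_clean_coupling_on_rendered_movie(self, five_lobe):
        coup = syn.CouplingSpec(alpha=200.0, beta_um=120.0, sigma=10.0, seed=4)
        fix = syn.render_movie(five_lobe, coup, n_frames=1)
        mask = fix.labels[0] > 0
        truth = fix.truth
        idx = np.linspace(0, len(truth) - 1, 60, dtype=int)
        resid = []
        for i in idx:
            row = truth.iloc[i]
            pt = (int(round(row.y_px)), int(round(row.x_px)))
            if not mask[pt]:
                continue
            mean, _ = local_intensity(fix.movie[0, 1], pt, mask)
            resid.append(mean - row.clean_calcium)
        # local window means scatter around the clean level with sd of the
        # order of the block-noise sigma
        assert np.abs(np.mean(resid)) < 10.0
        assert np.std(resid) < 3 * coup.sigma


class TestCorrelation:
    def test_exact_linear_coupling(self):
        k = np.linspace(0, 1, 50)
        assert frame_correlation(k, 2 * k) == pytest.approx(1.0)
        assert frame_correlation(k, -k) == pytest.approx(-1.0)

    def test_undefined_cases(self):
        assert np.isnan(frame_correlation([1, 2], [1, 2]))
        assert np.isnan(frame_correlation([1, 1, 1], [1, 2, 3]))
        assert np.isnan(frame_correlation([1, 2, 3], [2, 2, 2]))

    def test_spearman_option(self):
        k = np.linspace(0, 1, 30)
        assert frame_correlation(k, np.exp(5 * k), method="spearman") == pytest.approx(1.0)

    def test_null_distribution_scale(self):
        rng = np.random.default_rng(0)
        rs = [
            frame_correlation(rng.normal(size=200), rng.normal(size=200))
            for _ in range(100)
        ]
        # sd of a null Pearson r is ~1/sqrt(n); |r| < 0.2 almost always
        assert np.mean(np.abs(rs) < 0.2) >= 0.95

    def test_average_over_frames(self):
        assert average_over_frames([0.5, 0.7]) == (pytest.approx(0.6), 2)
        assert average_over_frames([0.3]) == (pytest.approx(0.3), 1)
        r_bar, n = average_over_frames([0.4, float("nan"), 0.8])
        assert (r_bar, n) == (pytest.approx(0.6), 2)
        with pytest.raises(ValueError):
            average_over_frames([float("nan")])


class TestEndToEnd:
    def test_estimator_consistency_noise_free(self, five_lobe):
        # with zero noise the estimated correlation approaches the
        # ground-truth correlation (which is exactly 1 for beta > 0)
        coup = syn.CouplingSpec(alpha=200.0, beta_um=120.0, sigma=0.0)
        fix = syn.render_movie(five_lobe, coup, n_frames=2)
        _, per_frame, per_lyso = analyze_movie(
            fix.movie, fix.labels, fix.pixel_size_um
        )
        assert per_lyso.r_bar.iloc[0] > 0.9

    def test_drifting_object_tracked_and_analyzed(self, five_lobe):
        coup = syn.CouplingSpec(alpha=200.0, beta_um=120.0, sigma=5.0, seed=2)
        fix = syn.render_movie(
            five_lobe, coup, n_frames=4, drift_um_per_frame=(0.15, 0.1)
        )
        _, per_frame, per_lyso = analyze_movie(
            fix.movie, fix.labels, fix.pixel_size_um
        )
        assert len(per_lyso) == 1  # one persistent track
        assert per_lyso.n_frames_used.iloc[0] == 4
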