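import numpy as np
import pytest

from scolioclass import (
    ContractError,
    DegenerateGeometryError,
    compute_indices,
    curvature_profile,
    find_apexes,
    interpolate,
    normalize,
    project,
)
from scolioclass.curve import PlanarCurve
from scolioclass.synthetic import _HEIGHTS, SpineParams, generate_spine

from conftest import analytic_sequence, mirror_laterally


def _circular_arc_sequence(R):
    """Planar spine lying on a circle of radius R (frontal plane), chord 500 mm."""
    return analytic_sequence(fx=lambda y: R - np.sqrt(R * R - (y - 250.0) ** 2))


class TestInterpolate:
    def test_straight_spine_stays_straight(self, straight_sequence):
        curve = interpolate(normalize(straight_sequence))
        assert len(curve.arc_s) == 501  # 500 mm at 1 mm spacing, endpoints included
        assert np.abs(curve.positions[:, [0, 2]]).max() < 1e-9

    def test_arc_spacing_within_one_percent(self):
        seq = generate_spine(SpineParams(lateral_amplitude=40, noise_sd=0, seed=0))
        curve = interpolate(normalize(seq))
        steps = np.diff(curve.arc_s)[:-1]  # final partial step exempt
        assert np.all(np.abs(steps - 1.0) < 0.01)

    def test_curve_passes_through_every_centroid(self):
        """Interpolating, not smoothing: densely sampled curve comes within
        a milli-millimetre of every centroid."""
        seq = generate_spine(SpineParams(lateral_amplitude=35, noise_sd=1.0, seed=5))
        norm = normalize(seq)
        curve = interpolate(norm, spacing_mm=0.1)
        a, b = curve.positions[:-1], curve.positions[1:]
        ab = b - a
        denom = (ab * ab).sum(axis=1)
        for p in norm.positions:
            t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
            d = np.linalg.norm(a + t[:, None] * ab - p, axis=1).min()
            assert d < 1e-3

    def test_lt_split_is_exhaustive_and_exclusive(self):
        seq = generate_spine(SpineParams(seed=1))
        curve = interpolate(normalize(seq))
        region = curve.region
        assert set(region) == {"lumbar", "thoracic"}
        lum = curve.lumbar_mask
        assert np.all(lum[: lum.sum()]) and not np.any(lum[lum.sum():])
        assert curve.arc_s[lum].max() <= curve.lt_arc_s < curve.arc_s[~lum].min()

    def test_duplicate_consecutive_centroids_rejected(self, straight_sequence):
        pos = straight_sequence.positions.copy()
        pos[3] = pos[2]
        with pytest.raises(DegenerateGeometryError):
            interpolate(normalize(straight_sequence.with_positions(pos)))

    def test_halving_spacing_barely_moves_indices(self):
        """Resolution stability: 0.5 mm sampling shifts large quantities by
        <0.5% and near-zero index values by <0.005 absolute."""
        seq = generate_spine(SpineParams(lateral_amplitude=20, noise_sd=0.7, seed=11))
        norm = normalize(seq)

        def values(spacing):
            c = interpolate(norm, spacing_mm=spacing)
            std, idx = compute_indices(project(c, "frontal"), project(c, "sagittal"))
            return std.as_array(), np.array([idx.s, idx.v, idx.kl])

        std1, idx1 = values(1.0)
        std05, idx05 = values(0.5)
        for a, b in zip(std1, std05):
            assert abs(b - a) < max(0.005 * abs(a), 0.05)
        np.testing.assert_allclose(idx05, idx1, atol=0.005)


class TestCurvature:
    def test_straight_segment_zero(self, straight_sequence):
        prof = curvature_profile(project(interpolate(normalize(straight_sequence)), "frontal"))
        assert np.all(prof.kappa < 1e-12)

    def test_planar_circle_radius_100(self):
        s = np.arange(0.0, 150.0, 1.0)
        theta = s / 100.0
        pc = PlanarCurve(
            plane="frontal",
            displacement=100.0 * (1 - np.cos(theta)),
            height_or_axis=100.0 * np.sin(theta),
            arc_s=s,
            lumbar_mask=s < 50,
        )
        kappa = curvature_profile(pc).kappa[2:-2]
        np.testing.assert_allclose(kappa, 0.01, rtol=0.01)

    def test_circular_arc_spine_recovers_one_over_r(self):
        R = 300.0
        prof = curvature_profile(
            project(interpolate(normalize(_circular_arc_sequence(R))), "frontal")
        )
        interior = prof.kappa[100:-100]  # natural-spline end ringing excluded
        np.testing.assert_allclose(interior, 1.0 / R, rtol=0.01)

    def test_sine_crest_matches_analytic_second_derivative(self):
        a, lam = 8.0, 250.0
        seq = analytic_sequence(fx=lambda y: a * np.sin(2 * np.pi * y / lam))
        prof = curvature_profile(project(interpolate(normalize(seq)), "frontal"))
        crest = prof.kappa[40:85].max()  # first crest near y = lam/4
        assert crest == pytest.approx(a * (2 * np.pi / lam) ** 2, rel=0.02)

    def test_smoothing_window_validated(self, straight_sequence):
        planar = project(interpolate(normalize(straight_sequence)), "frontal")
        with pytest.raises(ContractError):
            curvature_profile(planar, smooth_window=4)


class TestProject:
    def test_frontal_of_straight_spine_is_flat(self, straight_sequence):
        planar = project(interpolate(normalize(straight_sequence)), "frontal")
        assert np.abs(planar.displacement).max() < 1e-9

    def test_mirror_negates_frontal_only(self):
        seq = generate_spine(SpineParams(lateral_amplitude=30, noise_sd=0.4, seed=8))
        c = interpolate(normalize(seq))
        cm = interpolate(normalize(mirror_laterally(seq)))
        np.testing.assert_allclose(
            project(cm, "frontal").displacement, -project(c, "frontal").displacement, atol=1e-9
        )
        np.testing.assert_allclose(
            project(cm, "sagittal").displacement, project(c, "sagittal").displacement, atol=1e-9
        )

    def test_axial_returns_xz_pairs(self):
        seq = generate_spine(SpineParams(seed=2))
        c = interpolate(normalize(seq))
        ax = project(c, "axial")
        np.testing.assert_array_equal(ax.displacement, c.positions[:, 0])
        np.testing.assert_array_equal(ax.height_or_axis, c.positions[:, 2])

    def test_unknown_plane_rejected(self, straight_sequence):
        with pytest.raises(ContractError):
            project(interpolate(normalize(straight_sequence)), "coronal-ish")


class TestApexes:
    def test_straight_spine_has_no_side_apex(self, straight_sequence):
        records = {a.name: a for a in find_apexes(normalize(straight_sequence))}
        assert "ApexS_left" not in records and "ApexS_right" not in records
        assert records["ApexT"].displacement == 0.0
        assert records["ApexL"].displacement == 0.0

    def test_right_convex_curve_apexes_at_construction_level(self):
        seq = generate_spine(
            SpineParams(lateral_amplitude=40, apex_level="T8", convexity="right", noise_sd=0)
        )
        records = {a.name: a for a in find_apexes(normalize(seq))}
        assert records["ApexS_right"].label == "T8"
        assert records["ApexS_right"].displacement == pytest.approx(40.0, rel=0.02)
        assert "ApexS_left" not in records  # no leftward displacement exists

    def test_one_sided_displacement_leaves_other_apex_absent(self):
        """A spine with no leftward frontal displacement has no left apex."""
        seq = analytic_sequence(fx=lambda y: max(0.0, 20.0 * np.sin(np.pi * (y - 150) / 200))
                                if 150 <= y <= 350 else 0.0)
        names = {a.name for a in find_apexes(normalize(seq))}
        assert "ApexS_right" in names and "ApexS_left" not in names

    def test_sagittal_apex_ties_break_caudally(self, balanced_sagittal_sequence):
        records = {a.name: a for a in find_apexes(normalize(balanced_sagittal_sequence))}
        # lumbar lordotic apex is anterior (z<0), thoracic kyphotic apex posterior
        assert records["ApexL"].displacement < 0 < records["ApexT"].displacement
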