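"""Edge-pair localization, the evaluation metric and its invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fieldfocus import (
    EdgePair,
    FieldImage,
    GradientProfile,
    InvertedEdgesError,
    IntensityProfile,
    MeasurementSettings,
    NoFieldDetectedError,
    estimate_magnification,
    evaluation_value,
    extract_profile,
    gradient_1d,
    locate_edge_pair,
    measure_separation,
    metric_variants,
    render_field,
    smooth_profile,
    subpixel_refine,
)


def dense_parabola_argmax(y_minus, y_center, y_plus):
    """Oracle: argmax of the quadratic through (-1, 0, +1) on a dense grid."""
    coeffs = np.polyfit([-1.0, 0.0, 1.0], [y_minus, y_center, y_plus], 2)
    x = np.linspace(-0.5, 0.5, 200001)
    y = np.polyval(coeffs, x)
    return x[np.argmax(y)] if coeffs[0] < 0 else x[np.argmin(y)]


class TestSubpixelRefine:
    def test_symmetric_triple_centered(self):
        assert subpixel_refine(3.0, 4.0, 3.0).offset == 0.0

    def test_asymmetric_triple_matches_dense_grid_oracle(self):
        off, flat = subpixel_refine(1.0, 4.0, 3.0)
        assert not flat
        assert off == pytest.approx(0.25, abs=1e-5)
        assert off == pytest.approx(dense_parabola_argmax(1.0, 4.0, 3.0), abs=1e-5)

    def test_scale_and_offset_invariance(self):
        assert subpixel_refine(10.0, 40.0, 30.0).offset == pytest.approx(0.25)
        a, b = 3.7, 11.0
        ref = subpixel_refine(1.0, 4.0, 3.0).offset
        assert subpixel_refine(a * 1 + b, a * 4 + b, a * 3 + b).offset == pytest.approx(ref)

    def test_flat_triple_flagged(self):
        off, flat = subpixel_refine(2.0, 2.0, 2.0)
        assert off == 0.0 and flat

    def test_non_extremum_rejected(self):
        with pytest.raises(ValueError):
            subpixel_refine(1.0, 2.0, 10.0)
        with pytest.raises(ValueError):
            subpixel_refine(1.0, 2.0, 3.0)  # monotone with zero curvature

    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(-100, 100),
        st.floats(-100, 100),
        st.floats(-100, 100),
    )
    def test_offset_always_within_half_pixel(self, y_minus, y_center, y_plus):
        if not (y_center >= max(y_minus, y_plus) or y_center <= min(y_minus, y_plus)):
            return
        off, _ = subpixel_refine(y_minus, y_center, y_plus)
        assert -0.5 <= off <= 0.5


def grad_from(values):
    values = np.asarray(values, dtype=float)
    return GradientProfile(values, np.arange(values.size) + 0.5, order=1)


class TestLocateEdgePair:
    def test_simple_pair(self):
        pair = locate_edge_pair(grad_from([0, 1, 5, 1, 0, -1, -5, -1]), refine=False)
        assert pair.x_rise == 2.5
        assert pair.x_fall == 6.5
        assert pair.g_max == 5 and pair.g_min == -5

    def test_no_field_on_flat_gradient(self):
        with pytest.raises(NoFieldDetectedError):
            locate_edge_pair(grad_from([0.0, 0.0, 0.0, 0.0]))

    def test_inverted_edges_detected(self):
        with pytest.raises(InvertedEdgesError):
            locate_edge_pair(grad_from([0, -5, 0, 5, 0]))

    def test_ties_resolve_to_smaller_index(self):
        pair = locate_edge_pair(grad_from([0, 4, 4, 0, -4, -4, 0]), refine=False)
        assert pair.x_rise == 1.5
        assert pair.x_fall == 4.5

    def test_separation_matches_w0_in_focus(self, quiet_small_config):
        img = render_field(quiet_small_config, 0.0)
        pair = measure_separation(img)
        assert pair.d == pytest.approx(quiet_small_config.w0, abs=1.0)


class TestInvariances:
    def test_lateral_shift_moves_both_edges_not_d(self, quiet_small_config):
        base = measure_separation(render_field(quiet_small_config, 10.0))
        shifted = measure_separation(
            render_field(quiet_small_config, 10.0, offset=17.0)
        )
        assert shifted.x_rise - base.x_rise == pytest.approx(17.0, abs=0.05)
        assert shifted.x_fall - base.x_fall == pytest.approx(17.0, abs=0.05)
        assert abs(shifted.d - base.d) < 0.05

    def test_intensity_scaling_leaves_positions_unchanged(self, quiet_small_config):
        # positive scaling preserves extremum locations and the vertex
        # formula; power-of-two factors commute with binary floating point,
        # so they round-trip bit-exactly, others to machine precision
        img = render_field(quiet_small_config, 10.0)
        a = measure_separation(img)
        for c, tol in ((2.0, 0.0), (0.5, 0.0), (2.5, 1e-9)):
            scaled = FieldImage(
                img.pixels.astype(np.float64) * c, img.pixel_pitch
            )
            b = measure_separation(scaled)
            assert abs(b.x_rise - a.x_rise) <= tol
            assert abs(b.x_fall - a.x_fall) <= tol
            assert abs(b.d - a.d) <= tol


class TestEvaluationValue:
    def test_in_focus_definition(self):
        assert evaluation_value(3333.0, 3333.0) == 0.0

    def test_one_micron_step_at_reference_slope(self):
        d0 = 3333.0
        assert evaluation_value(d0 - 24.103, d0) == pytest.approx(-24.103)

    def test_zero_reference(self):
        assert evaluation_value(120.0, 0.0) == 120.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            evaluation_value(np.nan, 10.0)
        with pytest.raises(ValueError):
            evaluation_value(10.0, np.inf)


class TestMagnification:
    def test_arithmetic(self):
        pair = EdgePair(x_rise=0.0, x_fall=2000.0, g_max=1.0, g_min=-1.0)
        assert estimate_magnification(pair, 5.0, 1.0) == pytest.approx(10.0)

    def test_in_focus_magnification_is_paraxial_product(self, quiet_small_config):
        pair = measure_separation(render_field(quiet_small_config, 0.0))
        m = estimate_magnification(
            pair, quiet_small_config.pixel_pitch, quiet_small_config.source_width
        )
        assert m == pytest.approx(200.0 / 12.0, rel=1e-3)

    def test_magnification_decreases_with_z(self, quiet_small_config):
        ms = []
        for z in (-40.0, -20.0, 0.0, 20.0, 40.0):
            pair = measure_separation(render_field(quiet_small_config, z))
            ms.append(
                estimate_magnification(
                    pair,
                    quiet_small_config.pixel_pitch,
                    quiet_small_config.source_width,
                )
            )
        assert all(a > b for a, b in zip(ms, ms[1:]))

    def test_nonpositive_source_width_rejected(self, quiet_small_config):
        pair = measure_separation(render_field(quiet_small_config, 0.0))
        with pytest.raises(ValueError):
            estimate_magnification(pair, 5.0, 0.0)


@pytest.fixture(scope="module")
def sweep(quiet_small_config):
    out = {}
    for z in (-30.0, -15.0, 0.0, 15.0, 30.0):
        img = render_field(quiet_small_config, z)
        prof = smooth_profile(extract_profile(img, 0.5), 5.0)
        out[z] = metric_variants(prof)
    return out


class TestMetricVariants:
    def test_position_difference_monotone_in_z(self, sweep):
        ds = [sweep[z].grad_pos_diff for z in sorted(sweep)]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_gradient_magnitude_peaks_at_focus(self, sweep):
        mags = {z: m.grad_extreme_mag for z, m in sweep.items()}
        assert mags[0.0] == max(mags.values())
        assert mags[-30.0] < mags[-15.0] and mags[30.0] < mags[15.0]

    def test_second_derivative_magnitude_decays_faster(self, sweep):
        # higher-order metric: sharper peak around focus
        rel1 = sweep[15.0].grad_extreme_mag / sweep[0.0].grad_extreme_mag
        rel2 = sweep[15.0].second_extreme_mag / sweep[0.0].second_extreme_mag
        assert rel2 < rel1

    def test_second_order_separation_matches_first_order(self, sweep):
        for z, m in sweep.items():
            assert m.second_pos_diff == pytest.approx(m.grad_pos_diff, abs=1.0)

    def test_constant_profile_raises_no_field(self):
        with pytest.raises(NoFieldDetectedError):
            metric_variants(IntensityProfile(np.full(50, 3.0)))
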