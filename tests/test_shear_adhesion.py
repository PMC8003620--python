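"""Force-trace analysis: segmentation, friction ratios, trapezoidal work."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swallowmetrics.shear_adhesion import (
    ForceTrace,
    adhesion_metrics,
    composite_trapezoid,
    detachment_work_mJ,
    dynamic_cof,
    peak_detachment_force,
    segment_regions,
    static_cof,
    stick_slip_events,
    trapezoid_area,
    work_of_adhesion,
)
from swallowmetrics.synthetic import GeneratorConfig, gen_force_trace


def flat_trace(level: float, n: int = 100) -> ForceTrace:
    return ForceTrace(np.linspace(0, 50, n), np.full(n, level))


class TestSegmentation:
    def test_spike_and_trough_located_at_injected_positions(self, quiet_cfg):
        synth = gen_force_trace(
            0.45, 0.15, quiet_cfg, spike_center_mm=5.0, spike_width_mm=3.0
        )
        regions = segment_regions(synth.trace)
        assert synth.trace.distance[regions.peak_index] == pytest.approx(5.0, abs=0.1)
        assert synth.trace.distance[regions.trough] == pytest.approx(8.0, abs=0.1)

    def test_flat_zero_trace_has_no_peak(self):
        regions = segment_regions(flat_trace(0.0))
        assert not regions.has_peak
        assert regions.peak == slice(0, 0)

    def test_stick_slip_trace_anchors_on_global_maximum(self):
        cfg = GeneratorConfig(seed=3, mode="uncoated")
        synth = gen_force_trace(0.85, 0.25, cfg, n_drops=5)
        regions = segment_regions(synth.trace)
        gmax = int(np.argmax(synth.trace.force))
        assert regions.onset <= gmax <= regions.trough

    def test_metrics_invariant_under_distance_translation(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        base = synth.trace
        shifted = ForceTrace(
            base.distance + 5.0, base.force, extension_range=base.extension_range + 5.0
        )
        assert peak_detachment_force(shifted) == pytest.approx(peak_detachment_force(base))
        assert static_cof(shifted) == pytest.approx(static_cof(base))
        assert dynamic_cof(shifted) == pytest.approx(dynamic_cof(base))
        assert detachment_work_mJ(shifted) == pytest.approx(detachment_work_mJ(base))


class TestPeakAndFrictionRatios:
    def test_injected_peak_recovered(self, noisy_cfg):
        synth = gen_force_trace(0.45, 0.15, noisy_cfg, onset_force_n=0.30)
        assert peak_detachment_force(synth.trace) == pytest.approx(0.45, abs=0.03)

    def test_constant_trace_peak_is_its_level(self):
        assert peak_detachment_force(flat_trace(0.2)) == pytest.approx(0.2)

    def test_static_ratio_uses_onset_force(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        assert static_cof(synth.trace) == pytest.approx(0.6, abs=0.01)

    def test_onset_force_equal_to_normal_force_gives_unity(self, quiet_cfg):
        synth = gen_force_trace(0.5, 0.15, quiet_cfg, onset_force_n=0.5)
        assert static_cof(synth.trace) == pytest.approx(1.0, abs=0.01)

    def test_dynamic_ratio_is_plateau_over_normal(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        assert dynamic_cof(synth.trace) == pytest.approx(0.3, abs=0.01)

    def test_noisy_plateau_converges_to_mean_ratio(self):
        cfg = GeneratorConfig(seed=5, noise_sd=0.01)
        synth = gen_force_trace(0.45, 0.20, cfg, onset_force_n=0.30, n_samples=5001)
        assert dynamic_cof(synth.trace) == pytest.approx(0.4, abs=0.01)

    def test_stick_exceeds_slip_for_spiked_traces(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        regions = segment_regions(synth.trace)
        mu_s = static_cof(synth.trace, regions)
        mu_d = dynamic_cof(synth.trace, regions)
        assert mu_d <= mu_s <= peak_detachment_force(synth.trace) / synth.trace.normal_force

    def test_flat_trace_has_no_onset(self):
        with pytest.raises(ValueError):
            static_cof(flat_trace(0.0))


class TestTrapezoidalIntegration:
    @pytest.mark.parametrize(
        "h, b1, b2, expected",
        [(2.0, 3.0, 5.0, 8.0), (4.0, 3.0, 3.0, 12.0), (0.0, 3.0, 5.0, 0.0)],
    )
    def test_single_trapezium(self, h, b1, b2, expected):
        assert trapezoid_area(h, b1, b2) == expected

    def test_linear_integrand_is_exact(self):
        x = np.linspace(0.0, 1.0, 5)
        assert composite_trapezoid(x, x) == pytest.approx(0.5)

    def test_parabola_hand_value_and_quadratic_convergence(self):
        x4 = np.linspace(0.0, 2.0, 5)
        approx4 = composite_trapezoid(x4, x4**2)
        assert approx4 == pytest.approx(2.75)
        exact = 8.0 / 3.0
        x8 = np.linspace(0.0, 2.0, 9)
        err4 = abs(approx4 - exact)
        err8 = abs(composite_trapezoid(x8, x8**2) - exact)
        assert err4 / err8 == pytest.approx(4.0, rel=0.05)  # O(Δx²)

    @given(
        ys=st.lists(st.floats(-2.0, 5.0), min_size=2, max_size=30),
        span=st.floats(min_value=0.5, max_value=50.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_equals_sum_of_elementary_trapezia_on_any_polyline(self, ys, span):
        ys = np.asarray(ys)
        xs = np.linspace(0.0, span, ys.size)
        segmentwise = sum(
            trapezoid_area(b - a, ya, yb)
            for a, b, ya, yb in zip(xs, xs[1:], ys, ys[1:])
        )
        assert composite_trapezoid(xs, ys) == pytest.approx(segmentwise, abs=1e-9)

    def test_resampling_density_invariance_on_smooth_trace(self):
        x1 = np.linspace(0.0, 10.0, 501)
        x2 = np.linspace(0.0, 10.0, 2001)
        f = lambda x: 0.3 * np.exp(-((x - 5) ** 2) / 2.0)
        a1 = composite_trapezoid(x1, f(x1))
        a2 = composite_trapezoid(x2, f(x2))
        assert abs(a1 - a2) / a2 < 0.01

    def test_spike_area_recovery_within_half_percent(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        measured = detachment_work_mJ(synth.trace)
        assert measured == pytest.approx(synth.spike_area_mJ, rel=0.005)

    def test_work_of_adhesion_scales_by_contact_area(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        wa1 = work_of_adhesion(synth.trace, contact_area_mm2=1.0)
        wa2 = work_of_adhesion(synth.trace, contact_area_mm2=2.0)
        assert wa1 == pytest.approx(2.0 * wa2)
        assert wa1 == pytest.approx(detachment_work_mJ(synth.trace) * 1e-3)

    def test_full_trace_option_covers_sliding_region_too(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        assert detachment_work_mJ(synth.trace, region="full") > detachment_work_mJ(
            synth.trace, region="peak"
        )


class TestStickSlip:
    def test_coated_trace_counts_at_most_one_event(self, noisy_cfg):
        synth = gen_force_trace(0.45, 0.15, noisy_cfg, onset_force_n=0.30)
        assert stick_slip_events(synth.trace) <= 1

    @pytest.mark.parametrize("n_drops", [3, 5, 7])
    def test_sawtooth_counts_injected_drops(self, n_drops):
        cfg = GeneratorConfig(seed=2, noise_sd=0.005, mode="uncoated")
        synth = gen_force_trace(0.85, 0.25, cfg, n_drops=n_drops)
        assert stick_slip_events(synth.trace) == n_drops

    def test_constant_trace_has_no_events(self):
        assert stick_slip_events(flat_trace(0.2)) == 0


class TestTraceValidation:
    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ForceTrace(np.linspace(0, 50, 5), np.zeros(5))

    def test_distance_outside_extension_rejected(self):
        with pytest.raises(ValueError):
            ForceTrace(np.linspace(0, 60, 20), np.zeros(20), extension_range=50.0)

    def test_non_finite_forces_rejected(self):
        f = np.zeros(20)
        f[3] = np.inf
        with pytest.raises(ValueError):
            ForceTrace(np.linspace(0, 50, 20), f)

    def test_bundle_metrics_consistent(self, quiet_cfg):
        synth = gen_force_trace(0.45, 0.15, quiet_cfg, onset_force_n=0.30)
        m = adhesion_metrics(synth.trace, contact_area_mm2=1.0)
        assert m.peak_force == pytest.approx(0.45, abs=1e-6)
        assert m.peak_distance_mm == pytest.approx(5.0, abs=0.1)
        assert m.mu_static == pytest.approx(0.6, abs=0.01)
        assert m.mu_dynamic == pytest.approx(0.3, abs=0.01)
        assert m.work_of_adhesion == pytest.approx(synth.spike_area_mJ * 1e-3, rel=0.005)
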