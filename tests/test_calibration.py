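import math

import numpy as np
import pytest

from wexsim.bloch import ResponseMap, apply_pulse, equilibrium, single_pulse_response
from wexsim.calibration import (
    CalibrationError,
    calibrate_amplitude,
    default_delta_f_grid,
    mean_rf_power,
    phase_offset_sweep,
    relative_rf_power,
    suppression_band,
)
from wexsim.pulses import PulseKind, PulseParams, make_pulse, table_pulse_params


class TestCalibrateAmplitude:
    # Regression values computed with this package's Bloch engine at the
    # protocol-table settings (LIBOR includes its 0.1 ms inter-subpulse gap).
    @pytest.mark.parametrize(
        "name, power_factor",
        [("libor", 1.5477), ("libre", 3.1182), ("borr", 3.1753)],
    )
    def test_power_factors_regression(self, calibrations, name, power_factor):
        assert calibrations[name].power_factor == pytest.approx(power_factor, abs=2e-3)

    def test_power_ordering_libor_lowest(self, calibrations):
        assert (
            calibrations["libor"].power_factor
            < calibrations["libre"].power_factor
            < calibrations["borr"].power_factor
        )

    def test_interface_angle_consistency(self, calibrations):
        for cal in calibrations.values():
            assert cal.interface_angle / cal.nominal_alpha == pytest.approx(
                cal.power_factor, abs=1e-9
            )

    def test_rect_reference_is_unity(self):
        cal = calibrate_amplitude(table_pulse_params("bssfp"))
        assert cal.power_factor == 1.0
        assert cal.interface_angle == 50.0

    def test_calibrated_rotation_hits_target(self, calibrations):
        for cal in calibrations.values():
            m = apply_pulse(equilibrium(), cal.pulse, 0.0)
            polar = math.degrees(math.acos(m[2]))
            assert polar == pytest.approx(50.0, abs=1e-4)

    def test_rotation_monotonic_below_first_maximum(self):
        # justifies the bracketed root search
        params = table_pulse_params("libor")
        ref = math.radians(50) / (2 * params.tau)
        angles = []
        for k in np.linspace(0.1, 1.5477, 12):
            m = apply_pulse(equilibrium(), make_pulse(params, k * ref), 0.0)
            angles.append(math.acos(m[2]))
        assert np.all(np.diff(angles) > 0)

    def test_unreachable_rotation_raises(self):
        # BORR with a 0.1 ms inter-subpulse gap saturates below 50 degrees
        params = PulseParams(kind=PulseKind.BORR, tau=1.3e-3, f_rf=500.0, gap=1e-4)
        with pytest.raises(CalibrationError, match="unreachable"):
            calibrate_amplitude(params)


class TestSuppressionBand:
    def test_calibrated_libor_band_contains_fat(self, calibrations, delta_f_grid):
        rmap = single_pulse_response(calibrations["libor"].pulse, delta_f_grid)
        met = suppression_band(rmap)
        assert met.band_low <= -220.0 <= met.band_high
        assert 50.0 <= met.bandwidth <= 200.0
        assert met.bandwidth == met.band_high - met.band_low

    def test_invariant_under_uniform_rescaling(self, calibrations, delta_f_grid):
        rmap = single_pulse_response(calibrations["borr"].pulse, delta_f_grid)
        scaled = ResponseMap(delta_f=rmap.delta_f, values=0.37 * rmap.values)
        a, b = suppression_band(rmap), suppression_band(scaled)
        assert (a.band_low, a.band_high, a.bandwidth) == (b.band_low, b.band_high, b.bandwidth)

    def test_all_zero_map_spans_full_grid(self, delta_f_grid):
        rmap = ResponseMap(delta_f=delta_f_grid, values=np.zeros((1, delta_f_grid.size)))
        met = suppression_band(rmap)
        assert met.bandwidth == delta_f_grid[-1] - delta_f_grid[0]

    def test_flat_maximum_map_has_zero_bandwidth(self, delta_f_grid):
        rmap = ResponseMap(delta_f=delta_f_grid, values=np.full((1, delta_f_grid.size), 0.5))
        met = suppression_band(rmap)
        assert met.bandwidth == 0.0
        assert met.residual_at_fat == 0.5

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            suppression_band(ResponseMap(delta_f=np.array([]), values=np.zeros((1, 0))))


@pytest.fixture(scope="module")
def sweep():
    return phase_offset_sweep()


class TestPhaseOffsetSweep:
    def test_output_shape(self, sweep):
        assert sweep.map.values.shape == (37, 161)

    def test_optimum_in_published_range(self, sweep):
        assert 270.0 <= sweep.optimal_phase <= 310.0

    def test_optimal_band_contains_fat(self, sweep):
        i = int(np.argmin(np.abs(sweep.map.axis2 - sweep.optimal_phase)))
        met = suppression_band(sweep.map, axis2_index=i)
        assert met.band_low <= -220.0 <= met.band_high
        assert met.bandwidth == sweep.bandwidths[i] > 0

    def test_in_phase_binomial_far_narrower_than_optimum(self, sweep):
        i0 = int(np.argmin(np.abs(sweep.map.axis2 - 0.0)))
        assert sweep.bandwidths[i0] < 0.5 * sweep.bandwidths.max()

    def test_every_phase_recalibrated_to_nominal(self, sweep):
        target = math.sin(math.radians(50))
        i_center = sweep.map.delta_f.size // 2
        for i, cal in enumerate(sweep.calibrations):
            if cal is not None:
                assert abs(sweep.map.values[i, i_center]) == pytest.approx(target, abs=1e-4)


class TestRelativeRFPower:
    def test_self_ratio_is_exactly_one(self, calibrations):
        protocols = {"libor": (calibrations["libor"].pulse, 4.9e-3)}
        assert relative_rf_power(protocols, reference="libor")["libor"] == 1.0

    def test_ratios_follow_squared_amplitude_factors(self, calibrations):
        # LIBOR's 0.1 ms gap does not transmit RF, so at equal TR and active
        # duration the power ratio is the squared amplitude-factor ratio
        protocols = {
            name: (calibrations[name].pulse, 4.9e-3) for name in ("borr", "libre", "libor")
        }
        ratios = relative_rf_power(protocols, reference="libor")
        for name in ("borr", "libre"):
            expected = (
                calibrations[name].power_factor / calibrations["libor"].power_factor
            ) ** 2
            assert ratios[name] == pytest.approx(expected, rel=1e-9)
        assert ratios["borr"] > ratios["libre"] > 1.0

    def test_mean_power_definition(self, calibrations):
        pulse = calibrations["borr"].pulse
        expected = sum(s.amplitude**2 * s.duration for s in pulse.segments) / 4.9e-3
        assert mean_rf_power(pulse, 4.9e-3) == expected

    def test_zero_tr_rejected(self, calibrations):
        with pytest.raises(ValueError):
            mean_rf_power(calibrations["borr"].pulse, 0.0)
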