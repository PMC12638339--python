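import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wexsim.bloch import (
    ResponseMap,
    TissueParams,
    equilibrium,
    free_precess,
    ode_oracle,
    rotate_segment,
    single_pulse_response,
)
from wexsim.pulses import RFSegment, make_pulse, table_pulse_params


class TestRotateSegment:
    def test_on_resonance_rect_tip(self):
        # 0.3 ms rect calibrated to 50 deg: |Mxy| = sin(50), mz = cos(50)
        seg = RFSegment(0.3e-3, math.radians(50) / 0.3e-3)
        m = rotate_segment(equilibrium(), seg, 0.0)
        assert np.hypot(m[0], m[1]) == pytest.approx(math.sin(math.radians(50)), abs=1e-12)
        assert m[2] == pytest.approx(math.cos(math.radians(50)), abs=1e-12)

    def test_90_degree_pulse_nulls_mz(self):
        seg = RFSegment(0.3e-3, math.radians(90) / 0.3e-3)
        m = rotate_segment(equilibrium(), seg, 0.0)
        assert m[2] == pytest.approx(0.0, abs=1e-12)

    @given(
        duration=st.floats(1e-5, 3e-3),
        amplitude=st.floats(0, 5000),
        intercept=st.floats(-7, 7),
        slope=st.floats(-5000, 5000),
        delta_f=st.floats(-1000, 1000),
        mx=st.floats(-1, 1),
        my=st.floats(-1, 1),
    )
    def test_norm_conserved(self, duration, amplitude, intercept, slope, delta_f, mx, my):
        mz = math.sqrt(max(0.0, 1 - min(1.0, mx * mx + my * my)))
        m0 = np.array([mx, my, mz])
        m0 /= np.linalg.norm(m0) or 1.0
        seg = RFSegment(duration, amplitude, intercept, slope)
        m1 = rotate_segment(m0, seg, delta_f)
        assert np.linalg.norm(m1) == pytest.approx(np.linalg.norm(m0), abs=1e-12)

    def test_split_segment_composability(self):
        # evolving through one segment equals evolving through its two halves
        # (second half continues the phase ramp)
        seg = RFSegment(1.3e-3, 900.0, 0.4, 2 * math.pi * 270.0)
        half1 = RFSegment(0.65e-3, 900.0, 0.4, seg.phase_slope)
        half2 = RFSegment(
            0.65e-3, 900.0, 0.4 + seg.phase_slope * 0.65e-3, seg.phase_slope
        )
        for df in (-220.0, 0.0, 137.0):
            a = rotate_segment(equilibrium(), seg, df)
            b = rotate_segment(rotate_segment(equilibrium(), half1, df), half2, df)
            assert a == pytest.approx(b, abs=1e-12)

    def test_vectorized_matches_scalar(self):
        seg = RFSegment(1.3e-3, 700.0, 0.1, 2 * math.pi * 500.0)
        dfs = np.array([-300.0, 0.0, 410.0])
        m = rotate_segment(equilibrium(dfs.shape), seg, dfs)
        for i, df in enumerate(dfs):
            assert m[i] == pytest.approx(rotate_segment(equilibrium(), seg, df), abs=1e-13)


class TestFreePrecess:
    def test_zero_duration_is_identity(self, water):
        m0 = np.array([0.3, -0.2, 0.5])
        assert free_precess(m0, 0.0, 123.0, water) == pytest.approx(m0, abs=0)

    def test_t2_decay_closed_form(self):
        tissue = TissueParams(t1=1.0, t2=0.25)
        m = free_precess(np.array([1.0, 0.0, 0.0]), 0.25, 0.0, tissue)
        assert m[0] ** 2 + m[1] ** 2 == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_long_time_reaches_equilibrium(self):
        tissue = TissueParams(t1=0.5, t2=0.1)
        m = free_precess(np.zeros(3), 50.0, 80.0, tissue)
        assert m == pytest.approx([0.0, 0.0, 1.0], abs=1e-12)

    def test_precession_angle(self):
        m = free_precess(np.array([1.0, 0.0, 0.0]), 1e-3, 250.0, None)
        ang = 2 * math.pi * 250.0 * 1e-3
        assert m == pytest.approx([math.cos(ang), math.sin(ang), 0.0], abs=1e-12)

    def test_negative_duration_rejected(self, water):
        with pytest.raises(ValueError):
            free_precess(equilibrium(), -1e-3, 0.0, water)


class TestSinglePulseResponse:
    def test_rect_response_peaks_on_resonance(self, delta_f_grid):
        pulse = make_pulse(table_pulse_params("bssfp"), math.radians(50) / 0.3e-3)
        rmap = single_pulse_response(pulse, delta_f_grid)
        mag = rmap.magnitude[0]
        assert rmap.delta_f[np.argmax(mag)] == 0.0
        assert mag.max() == pytest.approx(math.sin(math.radians(50)), abs=1e-12)

    def test_magnitude_bounded_by_unity(self, calibrations, delta_f_grid):
        for cal in calibrations.values():
            rmap = single_pulse_response(cal.pulse, delta_f_grid)
            assert np.all(rmap.magnitude <= 1.0 + 1e-12)

    def test_empty_grid_rejected(self):
        pulse = make_pulse(table_pulse_params("bssfp"), 100.0)
        with pytest.raises(ValueError):
            single_pulse_response(pulse, [])

    def test_calibrated_pulses_excite_water_to_nominal(self, calibrations):
        # all water-excitation kinds reach |Mxy| = sin(50 deg) at 0 Hz
        target = math.sin(math.radians(50))
        for name, cal in calibrations.items():
            resp = single_pulse_response(cal.pulse, [0.0]).slice()[0]
            assert abs(resp) == pytest.approx(target, abs=1e-5), name

    def test_fat_suppressed_below_ten_percent(self, calibrations, delta_f_grid):
        i220 = int(np.argmin(np.abs(delta_f_grid + 220.0)))
        for name, cal in calibrations.items():
            mag = single_pulse_response(cal.pulse, delta_f_grid).magnitude[0]
            assert mag[i220] <= 0.10 * mag.max(), name


class TestResponseMap:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ResponseMap(delta_f=np.arange(5.0), values=np.zeros((2, 4)))

    def test_dataframe_long_format(self, delta_f_grid):
        pulse = make_pulse(table_pulse_params("bssfp"), 100.0)
        df = single_pulse_response(pulse, delta_f_grid).to_dataframe()
        assert list(df.columns) == ["delta_f_hz", "slice", "re", "im", "abs"]
        assert len(df) == delta_f_grid.size

    def test_hdf5_roundtrip(self, tmp_path, delta_f_grid):
        import h5py

        pulse = make_pulse(table_pulse_params("borr"), 900.0)
        rmap = single_pulse_response(pulse, delta_f_grid)
        path = tmp_path / "maps.h5"
        rmap.to_hdf5(path, name="borr")
        with h5py.File(path) as fh:
            assert np.allclose(fh["borr/values"][()], rmap.values)
            assert np.allclose(fh["borr/delta_f_hz"][()], delta_f_grid)


class TestOdeOracle:
    @pytest.mark.parametrize("name", ["bssfp", "borr", "libre", "libor"])
    def test_exact_rotations_match_fine_integration(self, name, calibrations):
        if name == "bssfp":
            pulse = make_pulse(table_pulse_params(name), math.radians(50) / 0.3e-3)
        else:
            pulse = calibrations[name].pulse
        for df in (-400.0, -220.0, 0.0, 137.0, 400.0):
            exact = single_pulse_response(pulse, [df]).slice()[0]
            m = ode_oracle(pulse, df, dt=5e-7)
            assert abs(abs(exact) - np.hypot(m[0], m[1])) < 1e-6
            assert abs(exact.real - m[0]) < 1e-6 and abs(exact.imag - m[1]) < 1e-6

    def test_rect_on_resonance_sine(self):
        pulse = make_pulse(table_pulse_params("bssfp"), math.radians(50) / 0.3e-3)
        m = ode_oracle(pulse, 0.0, dt=5e-7)
        assert np.hypot(m[0], m[1]) == pytest.approx(math.sin(math.radians(50)), abs=1e-9)

    def test_borr_phase_agreement_on_resonance(self, calibrations):
        pulse = calibrations["borr"].pulse
        exact = single_pulse_response(pulse, [0.0]).slice()[0]
        m = ode_oracle(pulse, 0.0, dt=5e-7)
        assert abs(np.angle(exact) - np.angle(m[0] + 1j * m[1])) < 1e-6

    def test_coarse_step_rejected(self):
        pulse = make_pulse(table_pulse_params("bssfp"), 100.0)
        with pytest.raises(ValueError):
            ode_oracle(pulse, 0.0, dt=1e-5)
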