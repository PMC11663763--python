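import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cinepc.protocol import ScanProtocol
from cinepc.signal_model import (FlowSpec, TissueParams, band_null_offset,
                                 bloch_transient, inflow_signal,
                                 ssfp_steady_state)


@pytest.fixture()
def protocol():
    return ScanProtocol(tr_ms=2.98, te_ms=1.37, flip_deg=60.0,
                        phase_increments_deg=[90.0, 270.0])


MYO = TissueParams(t1_ms=1000.0, t2_ms=200.0)


def settled_n_tr(tissue, protocol):
    """TR count for the transient to decay below float tolerance: the
    bSSFP transient decays with rate cos^2(a/2)/T1 + sin^2(a/2)/T2."""
    a = np.deg2rad(protocol.flip_deg)
    t_star = 1.0 / (np.cos(a / 2) ** 2 / tissue.t1_ms
                    + np.sin(a / 2) ** 2 / tissue.t2_ms)
    return int(np.ceil(30.0 * t_star / protocol.tr_ms))


class TestSteadyState:
    def test_vanishing_flip_angle_kills_signal(self, protocol):
        p = ScanProtocol(tr_ms=2.98, te_ms=1.37, flip_deg=1e-5,
                         phase_increments_deg=[90.0, 270.0])
        assert abs(ssfp_steady_state(MYO, p, 180.0)) < 1e-5

    def test_linear_in_density(self, protocol):
        t0 = TissueParams(1000, 200, rho=0.0)
        t2 = TissueParams(1000, 200, rho=2.0)
        assert ssfp_steady_state(t0, protocol, 180.0) == 0
        assert ssfp_steady_state(t2, protocol, 90.0, df_hz=40.0) == pytest.approx(
            2.0 * ssfp_steady_state(TissueParams(1000, 200), protocol, 90.0,
                                    df_hz=40.0))

    def test_matches_bloch_iteration_at_3000_tr(self, protocol):
        ss = ssfp_steady_state(MYO, protocol, 180.0)
        last = bloch_transient(MYO, protocol, 180.0, n_tr=3000)[-1]
        assert abs(ss - last) / abs(ss) < 1e-5

    def test_profile_periodic_in_one_over_tr(self, protocol):
        df = 37.0
        period = 1.0 / protocol.tr_s
        for k in (1, 2, -1):
            m0 = abs(ssfp_steady_state(MYO, protocol, 90.0, df_hz=df))
            mk = abs(ssfp_steady_state(MYO, protocol, 90.0, df_hz=df + k * period))
            assert mk == pytest.approx(m0, rel=1e-9)

    def test_t2_exceeding_t1_rejected(self):
        with pytest.raises(ValueError):
            TissueParams(t1_ms=100.0, t2_ms=200.0)

    @settings(max_examples=30, deadline=None)
    @given(delta=st.floats(-720, 720), df=st.floats(-300, 300),
           psi=st.floats(0.5, 360))
    def test_phase_cycling_equivalence(self, delta, df, psi):
        """Shifting psi rigidly translates the banding profile in frequency."""
        protocol = ScanProtocol(tr_ms=2.98, te_ms=1.37, flip_deg=60.0,
                                phase_increments_deg=[90.0, 270.0])
        m1 = abs(ssfp_steady_state(MYO, protocol, psi, df_hz=df))
        df_shift = df + (delta / 360.0) / protocol.tr_s
        m2 = abs(ssfp_steady_state(MYO, protocol, psi + delta, df_hz=df_shift))
        assert m2 == pytest.approx(m1, rel=1e-10, abs=1e-12)

    def test_one_magnitude_minimum_per_period(self, protocol):
        df = np.linspace(0.0, 1.0 / protocol.tr_s, 3600, endpoint=False)
        for psi in (0.0, 90.0, 180.0, 222.0):
            mag = np.abs(ssfp_steady_state(MYO, protocol, psi, df_hz=df))
            interior = (mag < np.roll(mag, 1)) & (mag < np.roll(mag, -1))
            assert interior.sum() == 1
            null = df[np.argmin(mag)]
            expected = band_null_offset(protocol, psi)
            period = 1.0 / protocol.tr_s
            d = abs(null - expected) % period
            assert min(d, period - d) <= period / len(df) + 1e-9


class TestBlochTransient:
    def test_first_echo_is_single_pulse_geometry(self):
        p = ScanProtocol(tr_ms=2.98, te_ms=1e-6, flip_deg=60.0,
                         phase_increments_deg=[90.0, 270.0])
        first = bloch_transient(MYO, p, 180.0, n_tr=1)[0]
        assert abs(first) == pytest.approx(np.sin(np.deg2rad(60.0)), rel=1e-5)

    def test_zero_tr_count_rejected(self, protocol):
        with pytest.raises(ValueError):
            bloch_transient(MYO, protocol, 180.0, n_tr=0)

    def test_convergence_over_parameter_grid(self, protocol):
        """The iterator converges to the closed form over a broad grid."""
        rng = np.random.default_rng(11)
        worst = 0.0
        n_checked = 0
        for _ in range(120):
            t2 = rng.uniform(30, 300)
            t1 = t2 + rng.uniform(1, 1800)
            tissue = TissueParams(t1_ms=t1, t2_ms=t2)
            flip = rng.uniform(10, 90)
            p = ScanProtocol(tr_ms=2.98, te_ms=1.37, flip_deg=flip,
                             phase_increments_deg=[90.0, 270.0])
            psi = rng.uniform(0.5, 360)
            df = rng.uniform(-300, 300)
            ss = ssfp_steady_state(tissue, p, psi, df_hz=df)
            last = bloch_transient(tissue, p, psi, settled_n_tr(tissue, p),
                                   df_hz=df)[-1]
            worst = max(worst, abs(ss - last) / abs(ss))
            n_checked += 1
        assert n_checked >= 100
        assert worst < 1e-5


class TestInflow:
    def test_zero_velocity_recovers_stationary_signal(self, protocol):
        flow = FlowSpec(velocity_mm_s=[0.0] * 4, slice_thickness_mm=8.0)
        out = inflow_signal(flow, protocol, 180.0, df_hz=np.array(100.0))
        ss = abs(ssfp_steady_state(flow.tissue, protocol, 180.0, df_hz=100.0))
        assert np.allclose(out, ss)

    def test_fast_flow_hyperenhances_at_the_band(self, protocol):
        """Fully refreshed spins give the first-echo magnitude, far above the
        steady-state null."""
        null = band_null_offset(protocol, 180.0)
        flow = FlowSpec(velocity_mm_s=[4000.0], slice_thickness_mm=8.0)
        out = inflow_signal(flow, protocol, 180.0, df_hz=np.array(null))
        expected = flow.tissue.rho * np.sin(np.deg2rad(60.0)) * np.exp(
            -protocol.te_ms / flow.tissue.t2_ms)
        assert out[0] == pytest.approx(expected, rel=1e-6)
        ss = abs(ssfp_steady_state(flow.tissue, protocol, 180.0, df_hz=null))
        assert out[0] > 10 * ss

    def test_linear_in_density_and_nonnegative(self, protocol):
        v = [0.0, 120.0, 400.0, 60.0]
        f1 = FlowSpec(velocity_mm_s=v, slice_thickness_mm=8.0,
                      tissue=TissueParams(1900, 250, rho=1.0, df_hz=80.0))
        f2 = FlowSpec(velocity_mm_s=v, slice_thickness_mm=8.0,
                      tissue=TissueParams(1900, 250, rho=2.0, df_hz=80.0))
        o1 = inflow_signal(f1, protocol, 90.0, df_hz=np.array(80.0))
        o2 = inflow_signal(f2, protocol, 90.0, df_hz=np.array(80.0))
        assert np.all(o1 >= 0)
        assert np.allclose(o2, 2 * o1)


class TestBandNull:
    def test_zero_increment_nulls_on_resonance(self, protocol):
        assert band_null_offset(protocol, 0.0) == 0.0

    def test_half_cycle_null_at_half_period(self, protocol):
        assert band_null_offset(protocol, 180.0) == pytest.approx(
            1.0 / (2 * protocol.tr_s))

    @pytest.mark.parametrize("psi", [0.0, 45.0, 90.0, 300.0])
    def test_opposite_increments_offset_by_half_period(self, protocol, psi):
        period = 1.0 / protocol.tr_s
        d = (band_null_offset(protocol, psi + 180.0)
             - band_null_offset(protocol, psi)) % period
        assert d == pytest.approx(period / 2, abs=1e-9)
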