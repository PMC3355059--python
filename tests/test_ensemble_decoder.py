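"""Spike-vector summation, linear feedback brainstem, kinematic metrics."""

import math

import numpy as np
import pytest

from colliculus import (
    BrainstemConfig,
    DecoderConfig,
    MapPoint,
    SaccadeVector,
    SpikeTrain,
    afferent_map,
    brainstem_feedback,
    decode_trajectory,
    kinematics,
    spike_vector,
)
from colliculus.ensemble_decoder import EyeTrace

DEC = DecoderConfig(rho=6.25)


class TestSpikeVector:
    def test_site_of_10deg_rightward(self):
        site = afferent_map(SaccadeVector(10.0, 0.0))
        sv = spike_vector(site, DEC)
        assert sv[0] == pytest.approx(DEC.kappa * 10.0, rel=1e-9)
        assert sv[1] == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_sites_cancel_vertically(self):
        site = afferent_map(SaccadeVector(10.0, 30.0))
        mirrored = MapPoint(site.u, -site.v)
        total = spike_vector(site, DEC) + spike_vector(mirrored, DEC)
        assert total[1] == pytest.approx(0.0, abs=1e-12)
        assert total[0] > 0

    def test_magnitude_grows_caudally(self):
        mags = [
            np.hypot(*spike_vector(MapPoint(u, 0.0), DEC))
            for u in np.linspace(0.2, 3.8, 15)
        ]
        assert np.all(np.diff(mags) > 0)


class TestDecodeTrajectory:
    def test_all_spikes_at_one_site(self):
        site = afferent_map(SaccadeVector(10.0, 0.0))
        train = SpikeTrain([5.0, 10.0, 15.0, 20.0])
        t, de = decode_trajectory([(site, train)], DEC)
        assert np.allclose(de[-1], 4 * spike_vector(site, DEC))
        # cumulative displacement is non-decreasing in magnitude here
        assert np.all(np.diff(np.hypot(de[:, 0], de[:, 1])) >= -1e-12)

    def test_empty_population_is_identically_zero(self):
        t, de = decode_trajectory([], DEC, np.arange(0.0, 50.0))
        assert np.all(de == 0.0)

    def test_additive_over_populations(self):
        s1 = afferent_map(SaccadeVector(8.0, 10.0))
        s2 = afferent_map(SaccadeVector(15.0, -20.0))
        grid = np.arange(0.0, 60.0)
        _, a = decode_trajectory([(s1, SpikeTrain([3.0, 7.0]))], DEC, grid)
        _, b = decode_trajectory([(s2, SpikeTrain([5.0, 9.0]))], DEC, grid)
        _, both = decode_trajectory(
            [(s1, SpikeTrain([3.0, 7.0])), (s2, SpikeTrain([5.0, 9.0]))], DEC, grid
        )
        assert np.allclose(both, a + b)

    def test_dense_ideal_population_decodes_its_amplitude(self):
        """Numerical-integration oracle: a full Gaussian population whose
        expected counts follow N0*exp(-d^2/2 sigma0^2) on a dense grid
        must decode to within 5% of its target amplitude."""
        step = 0.1
        cfg = DecoderConfig(rho=1.0 / step**2)
        for R in (5.0, 10.0, 20.0):
            center = afferent_map(SaccadeVector(R, 0.0))
            total = np.zeros(2)
            for u in np.arange(center.u - 2.0, center.u + 2.0, step):
                for v in np.arange(center.v - 2.0, center.v + 2.0, step):
                    d2 = (u - center.u) ** 2 + (v - center.v) ** 2
                    n = cfg.N0 * math.exp(-d2 / (2 * cfg.sigma0**2))
                    total += n * spike_vector(MapPoint(u, v), cfg)
            assert np.hypot(*total) == pytest.approx(R, rel=0.05)

    def test_calibrated_kappa_gives_unit_gain_at_reference(self):
        cfg = DecoderConfig(rho=100.0).calibrated()
        center = afferent_map(SaccadeVector(10.0, 0.0))
        step = 0.05
        total = np.zeros(2)
        for u in np.arange(center.u - 2.0, center.u + 2.0, step):
            for v in np.arange(center.v - 2.0, center.v + 2.0, step):
                d2 = (u - center.u) ** 2 + (v - center.v) ** 2
                n = cfg.N0 * math.exp(-d2 / (2 * cfg.sigma0**2)) * step**2 * cfg.rho
                total += n * spike_vector(MapPoint(u, v), cfg)
        assert np.hypot(*total) == pytest.approx(10.0, rel=1e-3)


class TestBrainstemFeedback:
    def test_step_response_matches_first_order_closed_form(self):
        cfg = BrainstemConfig(B=60.0, delay_sc=0.0, delay_fb=0.0)
        t = np.arange(0.0, 200.0)
        step = np.tile([10.0, 0.0], (t.size, 1))
        trace = brainstem_feedback(t, step, cfg)
        assert trace.position[-1, 0] == pytest.approx(10.0, abs=1e-6)
        analytic = 10.0 * (1.0 - np.exp(-60.0 * trace.t * 1e-3))
        assert np.max(np.abs(trace.position[:, 0] - analytic)) < 0.35  # Euler step error

    def test_zero_input_no_movement(self):
        t = np.arange(0.0, 100.0)
        trace = brainstem_feedback(t, np.zeros((t.size, 2)))
        assert np.all(trace.position == 0.0)
        assert trace.onset is None

    def test_channel_symmetry_for_diagonal_input(self):
        t = np.arange(0.0, 150.0)
        step = np.tile([7.0, 7.0], (t.size, 1))
        trace = brainstem_feedback(t, step)
        assert np.allclose(trace.position[:, 0], trace.position[:, 1])

    def test_superposition(self):
        t = np.arange(0.0, 150.0)
        a = np.tile([5.0, 0.0], (t.size, 1))
        b = np.outer(np.minimum(t / 50.0, 1.0), [3.0, 1.0])
        ta = brainstem_feedback(t, a)
        tb = brainstem_feedback(t, b)
        tab = brainstem_feedback(t, a + b)
        assert np.allclose(tab.position, ta.position + tb.position, atol=1e-9)

    def test_unstable_loop_rejected(self):
        with pytest.raises(ValueError):
            BrainstemConfig(B=400.0, delay_fb=5.0)

    def test_onset_refinement_walks_back_to_low_velocity_boundary(self):
        from colliculus import detect_saccade

        t = np.arange(0.0, 100.0)
        speed = np.clip(np.minimum(t * 2.0, (80.0 - t) * 5.0), 0.0, None)
        vel = np.column_stack([speed, np.zeros_like(speed)])
        # bare crossing: first sample with speed >= 30 is t = 15
        on_bare, off = detect_saccade(t, vel, 30.0, refine_threshold=None)
        assert on_bare == 15.0
        # refined onset walks back to the 10 deg/s boundary (t = 5)
        on_ref, off_ref = detect_saccade(t, vel, 30.0, refine_threshold=10.0)
        assert on_ref == 5.0
        assert off_ref == off  # the offset keeps the strict criterion


class TestKinematics:
    def _trace(self, t, pos, vel, onset, offset):
        return EyeTrace(t, pos, vel, onset, offset)

    def test_symmetric_triangular_speed_has_zero_skewness(self):
        t = np.arange(0.0, 101.0)
        speed = np.concatenate([np.linspace(0, 100, 51), np.linspace(100, 0, 51)[1:]])
        vel = np.column_stack([speed, np.zeros_like(speed)])
        pos = np.column_stack([np.cumsum(speed) * 1e-3, np.zeros_like(speed)])
        k = kinematics(self._trace(t, pos, vel, 0.0, 100.0))
        assert k["velocity_skewness"] == pytest.approx(0.0, abs=1e-9)

    def test_straight_trajectory_has_zero_straightness_index(self):
        t = np.arange(0.0, 51.0)
        vel = np.tile([100.0, 50.0], (t.size, 1))
        pos = np.cumsum(vel, axis=0) * 1e-3
        k = kinematics(self._trace(t, pos, vel, 0.0, 50.0))
        assert k["straightness"] == pytest.approx(0.0, abs=1e-12)

    def test_step_response_duration_matches_threshold_crossings(self):
        cfg = BrainstemConfig(B=60.0, delay_sc=0.0, delay_fb=0.0)
        t = np.arange(0.0, 400.0)
        step = np.tile([10.0, 0.0], (t.size, 1))
        trace = brainstem_feedback(t, step, cfg, speed_threshold=30.0)
        k = kinematics(trace)
        # speed = 600*exp(-B t): crosses 30 deg/s at t = ln(600/30)/60 s
        expected = math.log(600.0 / 30.0) / 60.0 * 1e3
        assert k["duration"] == pytest.approx(expected, abs=2.0)

    def test_undetected_movement_flagged(self):
        t = np.arange(0.0, 50.0)
        trace = self._trace(t, np.zeros((t.size, 2)), np.zeros((t.size, 2)), None, None)
        with pytest.raises(ValueError):
            kinematics(trace)
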