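import math

import numpy as np
import pytest

from conftest import make_animal
from dbsweep.cohort import (
    EXCLUDED,
    CohortConfig,
    apomorphine_challenge,
    expected_rotations,
    frequency_gain,
    ramp_deficit_factor,
    sample_animal,
    simulate_session,
    titrate_I0,
)
from dbsweep.errors import PrecisionError, TitrationError
from dbsweep.protocols import build_amplitude_protocol, build_frequency_protocol
from dbsweep.rotometry import assess_lesion
from dbsweep.waveforms import PulseShape, PulseTrainSpec

TEMPLATE_130 = PulseTrainSpec(PulseShape.RECT, 1.0, 65.0, 130.0, 100.0)


class TestSampleAnimal:
    def test_deterministic_given_seed_and_index(self, cohort_config):
        a = sample_animal(cohort_config, 3)
        b = sample_animal(cohort_config, 3)
        assert a == b

    def test_distinct_indices_differ(self, cohort_config):
        assert sample_animal(cohort_config, 0) != sample_animal(cohort_config, 1)

    def test_frequency_knot_anchors(self, cohort_config):
        animal = sample_animal(cohort_config, 0)
        assert frequency_gain(animal, 130.0) == pytest.approx(1.0)
        assert frequency_gain(animal, 15.0) == pytest.approx(0.0625)
        assert frequency_gain(animal, 250.0) == pytest.approx(1.75)

    def test_rect_efficacy_is_one(self, cohort_config):
        for i in range(10):
            animal = sample_animal(cohort_config, i)
            assert animal.shape_efficacy[PulseShape.RECT] == 1.0
            for s in (PulseShape.SINE, PulseShape.TRI, PulseShape.LIN_DEC):
                assert 0.5 < animal.shape_efficacy[s] < 0.95

    def test_threshold_and_ceiling_ranges(self, cohort_config):
        for i in range(20):
            animal = sample_animal(cohort_config, i)
            assert animal.I0_true_ua > 0
            assert animal.r_at_2I0 > 1.0
            assert animal.r_at_I0 == 0.25

    def test_exclusion_fraction_matches_config(self):
        config = CohortConfig(seed=7, exclusion_prob=1 / 3)
        n = 600
        frac = np.mean([sample_animal(config, i).dyskinesia_prone for i in range(n)])
        # binomial 99.9% envelope around 1/3 with n = 600
        assert abs(frac - 1 / 3) < 3.3 * math.sqrt((1 / 3) * (2 / 3) / n)


class TestExpectedRotations:
    def _train(self, amp, shape=PulseShape.RECT, f=130.0, pw=65.0):
        return PulseTrainSpec(shape, amp, pw, f, 100.0)

    def test_quarter_rotation_at_threshold(self, nf_animal):
        assert expected_rotations(nf_animal, self._train(60.0)) == pytest.approx(0.25)

    def test_six_rotations_at_double_threshold(self, nf_animal):
        assert expected_rotations(nf_animal, self._train(120.0)) == pytest.approx(6.0)

    def test_clipped_at_zero(self, nf_animal):
        assert expected_rotations(nf_animal, self._train(5.0)) == 0.0

    def test_non_rect_at_2q0_equals_rect_at_1p5q0(self, nf_animal):
        # kappa = 0.75: m_eff of alternatives at 2xQ0 is exactly 1.5
        from dbsweep.waveforms import charge_per_phase, equivalent_amplitude

        q0 = charge_per_phase(PulseShape.RECT, 60.0, 100.0)
        rect = self._train(1.5 * 60.0, pw=100.0)
        for shape in (PulseShape.SINE, PulseShape.TRI, PulseShape.LIN_DEC):
            amp = equivalent_amplitude(shape, 2.0 * q0, 100.0)
            alt = self._train(amp, shape=shape, pw=100.0)
            assert expected_rotations(nf_animal, alt) == pytest.approx(
                expected_rotations(nf_animal, rect), rel=1e-12
            )

    def test_frequency_gain_scales_response(self, nf_animal):
        r130 = expected_rotations(nf_animal, self._train(120.0, f=130.0))
        r15 = expected_rotations(nf_animal, self._train(120.0, f=15.0))
        r250 = expected_rotations(nf_animal, self._train(120.0, f=250.0))
        assert r15 / r130 == pytest.approx(0.0625)
        assert r250 / r130 == pytest.approx(1.75)


class TestSimulateSession:
    def test_noise_free_single_episode_closed_form(self, cohort_config):
        animal = make_animal(r_at_2I0=4.0 + 0.25)  # R = 4 at amplitude 2*I0
        proto = build_amplitude_protocol(60.0)
        traj = simulate_session(animal, proto, cohort_config, seed=0)
        # last ON episode runs at 2xI0 -> R = 4 -> 1440 deg steady state
        final_window = traj.angle_deg[-1] - traj.angle_deg[
            int(round((proto.end_s - 30.0) / cohort_config.dt_s))
        ]
        omega_bar = 360.0 * 4.0 / 30.0
        assert abs(final_window - 1440.0) < 2 * cohort_config.onset_tau_s * omega_bar

    def test_same_seed_bit_identical(self, cohort_config):
        animal = make_animal(noise_free=False)
        proto = build_amplitude_protocol(60.0)
        t1 = simulate_session(animal, proto, cohort_config, seed=99)
        t2 = simulate_session(animal, proto, cohort_config, seed=99)
        np.testing.assert_array_equal(t1.angle_deg, t2.angle_deg)
        np.testing.assert_array_equal(t1.x_cm, t2.x_cm)

    def test_different_seed_differs(self, cohort_config):
        animal = make_animal(noise_free=False)
        proto = build_amplitude_protocol(60.0)
        t1 = simulate_session(animal, proto, cohort_config, seed=1)
        t2 = simulate_session(animal, proto, cohort_config, seed=2)
        assert not np.array_equal(t1.angle_deg, t2.angle_deg)

    def test_position_stays_in_bowl(self, cohort_config):
        animal = make_animal(noise_free=False)
        proto = build_amplitude_protocol(60.0)
        traj = simulate_session(animal, proto, cohort_config, seed=5)
        r = np.hypot(traj.x_cm, traj.y_cm)
        assert np.all(r <= cohort_config.bowl_radius_cm + 1e-9)

    def test_rate_cap(self, cohort_config):
        animal = make_animal(noise_free=False)
        proto = build_amplitude_protocol(60.0)
        traj = simulate_session(animal, proto, cohort_config, seed=5)
        steps = np.abs(np.diff(traj.angle_deg)) / cohort_config.dt_s
        assert np.max(steps) <= 720.0 + 1e-9

    def test_coarse_dt_rejected(self):
        animal = make_animal()
        proto = build_amplitude_protocol(60.0)
        with pytest.raises(PrecisionError):
            simulate_session(animal, proto, CohortConfig(dt_s=2.0), seed=0)

    def test_with_position_false_drops_xy(self, cohort_config):
        animal = make_animal()
        proto = build_amplitude_protocol(60.0)
        traj = simulate_session(animal, proto, cohort_config, seed=0, with_position=False)
        assert not traj.has_position


class TestTitration:
    def test_within_one_grid_step_of_analytic_threshold(self, cohort_config):
        animal = make_animal(I0_true_ua=60.0, r_at_2I0=6.0)
        ramp = ramp_deficit_factor(30.0, cohort_config.onset_tau_s)
        # smallest amplitude whose max rotation reaches the 30 deg floor
        m_star = 1.0 + (30.0 / (360.0 * ramp) - 0.25) / (6.0 - 0.25)
        analytic = m_star * 60.0
        got = titrate_I0(animal, cohort_config, TEMPLATE_130, grid_step_ua=0.5)
        assert analytic <= got <= analytic + 0.5

    def test_dyskinesia_prone_excluded(self, cohort_config):
        animal = make_animal(dyskinesia_prone=True)
        assert titrate_I0(animal, cohort_config, TEMPLATE_130) is EXCLUDED

    def test_oversensitive_first_grid_point_excluded(self, cohort_config):
        animal = make_animal(I0_true_ua=0.5)  # 180 deg already passed at 1 grid step
        assert (
            titrate_I0(animal, cohort_config, TEMPLATE_130, grid_step_ua=5.0)
            is EXCLUDED
        )

    def test_exact_180_does_not_qualify(self, cohort_config):
        # construct a probe landing exactly on 180 deg: window is [30, 180)
        animal = make_animal(I0_true_ua=60.0, r_at_2I0=6.0)
        ramp = ramp_deficit_factor(30.0, cohort_config.onset_tau_s)
        m180 = 1.0 + (180.0 / (360.0 * ramp) - 0.25) / 5.75
        amp180 = m180 * 60.0 * (1.0 + 1e-9)  # nudge above fp round-off
        got = titrate_I0(animal, cohort_config, TEMPLATE_130, grid_step_ua=amp180)
        assert got is EXCLUDED  # first grid point reaches 180 -> not < 180

    def test_skipped_window_raises(self, cohort_config):
        animal = make_animal(I0_true_ua=60.0, r_at_2I0=6.0)
        with pytest.raises(TitrationError):
            titrate_I0(animal, cohort_config, TEMPLATE_130, grid_step_ua=40.0)

    def test_grid_exhaustion_raises(self, cohort_config):
        animal = make_animal(I0_true_ua=1e7)
        with pytest.raises(TitrationError):
            titrate_I0(animal, cohort_config, TEMPLATE_130, grid_step_ua=5.0, max_steps=10)


class TestApomorphineChallenge:
    def test_noise_free_arithmetic(self):
        animal = make_animal()
        traj = apomorphine_challenge(animal, lesioned=True, seed=0, rate_rpm=5.0)
        assert traj.angle_deg[-1] / 360.0 == pytest.approx(150.0, rel=1e-9)

    def test_lesioned_cohort_passes_assessment(self):
        animal = make_animal(noise_free=False)
        passes = [
            assess_lesion(apomorphine_challenge(animal, lesioned=True, seed=s, dt_s=0.5))
            for s in range(300)
        ]
        assert np.mean(passes) >= 0.94  # Normal(5,1) above 3 rpm ~ 97.7%

    def test_non_lesioned_fails_assessment(self):
        animal = make_animal(noise_free=False)
        passes = [
            assess_lesion(apomorphine_challenge(animal, lesioned=False, seed=s, dt_s=0.5))
            for s in range(200)
        ]
        assert np.mean(passes) <= 0.01
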