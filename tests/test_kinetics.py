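import numpy as np
import pytest

from footkin.frames import JOINTS, SegmentPoseSeries
from footkin.kinematics import GaitEvents, joint_angle_pipeline
from footkin.kinetics import (
    GRAVITY,
    JOINT_CENTER_SEGMENT,
    build_anthropometrics,
    cpcross_mask,
    inverse_dynamics,
    joint_power,
    segment_inertial_state,
)
from footkin.synthetic import generate_trial, healthy_default_spec, naive_inverse_dynamics
from footkin.trial_io import ForcePlateRecord, TrialConfig


class TestAnthropometrics:
    def test_toeless_apportioning(self):
        a = build_anthropometrics(1.0, foot_mass_fraction=1.0, toe_volume_fraction=0.0)
        assert a.segment_masses["hindfoot"] == pytest.approx(0.5)
        assert a.segment_masses["midfoot"] == pytest.approx(0.25)
        assert a.segment_masses["forefoot"] == pytest.approx(0.25)
        assert a.segment_masses["hallux"] == pytest.approx(0.0)

    def test_default_toe_fraction_apportioning(self):
        a = build_anthropometrics(1.0, foot_mass_fraction=1.0, toe_volume_fraction=0.08)
        assert a.segment_masses["hindfoot"] == pytest.approx(0.46)
        assert a.segment_masses["midfoot"] == pytest.approx(0.23)
        assert a.segment_masses["forefoot"] == pytest.approx(0.23)
        assert a.segment_masses["hallux"] == pytest.approx(0.08)

    def test_mass_conservation(self, rng):
        for _ in range(20):
            bm = rng.uniform(30, 120)
            tau = rng.uniform(0.0, 0.49)
            a = build_anthropometrics(bm, toe_volume_fraction=tau)
            assert sum(a.segment_masses.values()) == pytest.approx(
                a.foot_mass, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_anthropometrics(-1.0)
        with pytest.raises(ValueError):
            build_anthropometrics(70.0, toe_volume_fraction=0.6)
        with pytest.raises(ValueError):
            build_anthropometrics(70.0, radii_of_gyration=(1.5, 0.2, 0.2))


def _static_pose(name="hindfoot", n=60, origin=(0.0, 100.0, 0.0),
                 axis=(100.0, 100.0, 0.0)):
    return SegmentPoseSeries(
        name=name,
        orientation=np.tile(np.eye(3), (n, 1, 1)),
        origin=np.tile(np.asarray(origin, float), (n, 1)),
        axis_end=np.tile(np.asarray(axis, float), (n, 1)),
    )


class TestInertialState:
    def test_stationary_pose_has_zero_derivatives(self):
        anthro = build_anthropometrics(70.0)
        st = segment_inertial_state(_static_pose(), anthro, rate=60.0)
        np.testing.assert_allclose(st.com_vel, 0.0, atol=1e-12)
        np.testing.assert_allclose(st.com_acc, 0.0, atol=1e-12)
        np.testing.assert_allclose(st.omega, 0.0, atol=1e-12)
        np.testing.assert_allclose(st.alpha, 0.0, atol=1e-12)

    def test_free_fall_acceleration_recovered(self):
        n, rate = 60, 60.0
        t = np.arange(n) / rate
        drop = -0.5 * GRAVITY * t ** 2 * 1000.0  # mm
        pose = _static_pose(n=n)
        pose.origin[:, 1] += drop
        pose.axis_end[:, 1] += drop
        anthro = build_anthropometrics(70.0)
        st = segment_inertial_state(pose, anthro, rate=rate)
        interior = slice(2, -2)
        np.testing.assert_allclose(st.com_acc[interior, 1], -GRAVITY, rtol=0.01)

    def test_constant_spin_omega_recovered(self):
        n, rate, w = 120, 60.0, 2.0
        t = np.arange(n) / rate
        c, s = np.cos(w * t), np.sin(w * t)
        R = np.zeros((n, 3, 3))
        R[:, 0, 0], R[:, 0, 1] = c, -s
        R[:, 1, 0], R[:, 1, 1] = s, c
        R[:, 2, 2] = 1.0
        pose = _static_pose(n=n)
        pose.orientation = R
        anthro = build_anthropometrics(70.0)
        st = segment_inertial_state(pose, anthro, rate=rate)
        interior = slice(2, -2)
        mags = np.linalg.norm(st.omega[interior], axis=1)
        np.testing.assert_allclose(mags, w, atol=1e-3)
        np.testing.assert_allclose(st.alpha[interior], 0.0, atol=0.01)

    def test_short_window_rejected(self):
        anthro = build_anthropometrics(70.0)
        with pytest.raises(ValueError, match="5 frames"):
            segment_inertial_state(_static_pose(n=4), anthro, rate=60.0)


def _static_trial():
    spec = healthy_default_spec(seed=5)
    spec.waveforms = {}
    spec.walking_speed = 0.0
    spec.shank_tilt_deg = 0.0
    spec.vertical_bob_mm = 0.0
    traj, fp, gt = generate_trial(spec)
    res = joint_angle_pipeline(traj, fp, TrialConfig(body_mass=spec.body_mass,
                                                     filter_cutoff=None))
    return spec, res


def _constant_plate(n, force, cop, rate=60.0, tz=0.0):
    return ForcePlateRecord(
        force=np.tile(np.asarray(force, float), (n, 1)),
        cop=np.tile(np.asarray(cop, float), (n, 1)),
        tz=np.full(n, float(tz)), rate=rate,
    )


class TestInverseDynamics:
    def test_massless_static_pure_lever(self):
        spec, res = _static_trial()
        n = res.poses["shank"].n_frames
        anthro = build_anthropometrics(1.0, foot_mass_fraction=0.0)
        ankle = res.poses["midfoot"].origin[0]  # V_Ankle_JC, mm
        cop = np.array([ankle[0] + 100.0, 0.0, ankle[2]])  # 0.1 m anterior
        fp = _constant_plate(n, [0.0, 600.0, 0.0], cop)
        events = GaitEvents(heel_strike=2, toe_off=40, cycle_end=n - 2)
        kin = inverse_dynamics(res.poses, anthro, fp, events, rate=60.0)
        M = kin["ankle"].moment_lab * anthro.body_mass  # N*m
        mags = np.linalg.norm(M, axis=1)
        # expected: pure moment about the medio-lateral axis,
        # |M| = 600 N * (0.1 m anterior + 0.075 m below the centre lever)
        lever = np.array([0.1, -ankle[1] * 1e-3, 0.0])
        expected = -np.cross(lever, [0.0, 600.0, 0.0])
        np.testing.assert_allclose(M, np.tile(expected, (101, 1)), atol=1e-9)
        assert np.hypot(expected[0], expected[2]) == pytest.approx(60.0)
        # clinical sagittal component: plantarflexion-resisting, positive
        assert (kin["ankle"].moment[:, 0] > 0).all()

    def test_zero_grf_static_equals_gravity_loads(self):
        spec, res = _static_trial()
        n = res.poses["shank"].n_frames
        anthro = build_anthropometrics(spec.body_mass)
        fp = _constant_plate(n, [0.0, 0.0, 0.0], [np.nan] * 3)
        events = GaitEvents(heel_strike=2, toe_off=40, cycle_end=n - 2)
        kin = inverse_dynamics(res.poses, anthro, fp, events, rate=60.0)
        g = np.array([0.0, -GRAVITY, 0.0])
        for joint in JOINTS:
            center = res.poses[JOINT_CENTER_SEGMENT[joint]].origin[0] * 1e-3
            expected = np.zeros(3)
            from footkin.kinetics import DISTAL_SEGMENTS
            for seg in DISTAL_SEGMENTS[joint]:
                pose = res.poses[seg]
                com = 0.5 * (pose.origin[0] + pose.axis_end[0]) * 1e-3
                expected += np.cross(com - center,
                                     -anthro.segment_masses[seg] * g)
            np.testing.assert_allclose(
                kin[joint].moment_lab * anthro.body_mass,
                np.tile(expected, (101, 1)), atol=1e-9)

    def test_oracle_equivalence_on_dynamic_trial(self, healthy_trial, healthy_result):
        spec, traj, _, _ = healthy_trial
        res = healthy_result
        anthro = build_anthropometrics(spec.body_mass)
        kin = inverse_dynamics(res.poses, anthro, res.force, res.events, traj.rate)
        oracle = naive_inverse_dynamics(res.poses, anthro, res.force, traj.rate)
        from footkin.kinematics import normalize_gait_cycle
        for joint in JOINTS:
            o = normalize_gait_cycle(oracle[joint], res.events)
            err = np.max(np.abs(kin[joint].moment_lab * anthro.body_mass - o))
            assert err < 1e-6, joint

    def test_grf_superposition(self, healthy_trial, healthy_result):
        spec, traj, _, _ = healthy_trial
        res = healthy_result
        anthro = build_anthropometrics(spec.body_mass)
        fp = res.force
        fp2 = ForcePlateRecord(force=2 * fp.force, cop=fp.cop, tz=2 * fp.tz,
                               rate=fp.rate)
        fp0 = ForcePlateRecord(force=0 * fp.force, cop=fp.cop, tz=0 * fp.tz,
                               rate=fp.rate)
        args = (res.poses, anthro)
        kw = dict(events=res.events, rate=traj.rate)
        # the contact threshold scales with the load so all three runs
        # agree on which samples carry external load
        k1 = inverse_dynamics(*args, fp=fp, contact_threshold=20.0, **kw)
        k2 = inverse_dynamics(*args, fp=fp2, contact_threshold=40.0, **kw)
        k0 = inverse_dynamics(*args, fp=fp0, contact_threshold=20.0, **kw)
        for joint in JOINTS:
            np.testing.assert_allclose(
                k2[joint].moment_lab,
                2 * k1[joint].moment_lab - k0[joint].moment_lab, atol=1e-12)

    def test_missing_cop_during_load_errors(self, healthy_trial, healthy_result):
        spec, traj, _, _ = healthy_trial
        res = healthy_result
        anthro = build_anthropometrics(spec.body_mass)
        bad = ForcePlateRecord(force=res.force.force,
                               cop=np.full_like(res.force.cop, np.nan),
                               tz=res.force.tz, rate=res.force.rate)
        with pytest.raises(ValueError, match="CoP missing"):
            inverse_dynamics(res.poses, anthro, bad, res.events, traj.rate)

    def test_left_right_moment_equivalence(self, healthy_trial):
        spec, traj, fp, _ = healthy_trial
        out = {}
        for side in ("right", "left"):
            s = healthy_default_spec(seed=7)
            s.side = side
            tr, fpl, _ = generate_trial(s)
            cfg = TrialConfig(body_mass=s.body_mass, side=side, filter_cutoff=None)
            res = joint_angle_pipeline(tr, fpl, cfg)
            anthro = build_anthropometrics(s.body_mass)
            out[side] = inverse_dynamics(res.poses, anthro, res.force, res.events,
                                         tr.rate, side=side)
        for joint in JOINTS:
            np.testing.assert_allclose(out["left"][joint].moment,
                                       out["right"][joint].moment, atol=1e-9)
            np.testing.assert_allclose(out["left"][joint].power,
                                       out["right"][joint].power, atol=1e-9)


class TestJointPower:
    def test_no_relative_motion_zero_power(self, rng):
        M = rng.normal(size=(10, 3))
        w = rng.normal(size=(10, 3))
        np.testing.assert_allclose(joint_power(M, w, w, 70.0), 0.0, atol=1e-12)

    def test_dot_product_value(self):
        M = np.array([[1.0, 0.0, 0.0]])
        w = np.array([[2.0, 0.0, 0.0]])
        assert joint_power(M, w, 0 * w, 1.0)[0] == pytest.approx(2.0)

    def test_antisymmetry_in_relative_velocity(self, rng):
        M = rng.normal(size=(5, 3))
        wc = rng.normal(size=(5, 3))
        wp = rng.normal(size=(5, 3))
        p1 = joint_power(M, wc, wp, 70.0)
        p2 = joint_power(M, wp, wc, 70.0)
        np.testing.assert_allclose(p1, -p2, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            joint_power(np.zeros((5, 3)), np.zeros((4, 3)), np.zeros((4, 3)), 70.0)


class TestCPcross:
    @staticmethod
    def _kinetics(healthy_trial, healthy_result):
        spec, traj, _, _ = healthy_trial
        anthro = build_anthropometrics(spec.body_mass)
        return inverse_dynamics(healthy_result.poses, anthro, healthy_result.force,
                                healthy_result.events, traj.rate)

    def test_monotone_crossing_order(self, healthy_trial, healthy_result):
        kin = self._kinetics(healthy_trial, healthy_result)
        masked = cpcross_mask(kin, healthy_result.force, healthy_result.poses,
                              healthy_result.events)
        order = [masked[j].crossing_index for j in
                 ("ankle", "chopart", "lisfranc", "mtp1")]
        assert all(k is not None for k in order)
        assert order == sorted(order)

    def test_masking_never_alters_values(self, healthy_trial, healthy_result):
        kin = self._kinetics(healthy_trial, healthy_result)
        masked = cpcross_mask(kin, healthy_result.force, healthy_result.poses,
                              healthy_result.events)
        for joint in JOINTS:
            assert masked[joint].moment.tobytes() == kin[joint].moment.tobytes()
            assert masked[joint].power.tobytes() == kin[joint].power.tobytes()
            k = masked[joint].crossing_index
            assert masked[joint].masked[:k].all()
            assert not masked[joint].masked[k:].any()

    def test_posterior_cop_fully_masks(self, healthy_trial, healthy_result):
        kin = self._kinetics(healthy_trial, healthy_result)
        fp = healthy_result.force
        cop = fp.cop.copy()
        cop[:, 0] = -1000.0
        fp_back = ForcePlateRecord(force=fp.force, cop=cop, tz=fp.tz, rate=fp.rate,
                                   cop_valid=fp.cop_valid)
        with pytest.warns(UserWarning, match="never crosses"):
            masked = cpcross_mask(kin, fp_back, healthy_result.poses,
                                  healthy_result.events)
        for joint in JOINTS:
            assert masked[joint].masked.all()
            assert masked[joint].crossing_index is None

    def test_constructed_ramp_crossing_index(self, healthy_trial, healthy_result):
        kin = self._kinetics(healthy_trial, healthy_result)
        res = healthy_result
        fp = res.force
        ev = res.events
        # CoP tracks the first-MTP centre, jumping 1 mm ahead at 40% cycle
        center = res.poses["hallux"].origin
        k_target = 40
        frame_star = ev.heel_strike + (ev.cycle_end - ev.heel_strike) * k_target / 100
        cop = center.copy()
        cop[:, 0] += np.where(np.arange(len(cop)) >= frame_star, 1.0, -1.0)
        fp_ramp = ForcePlateRecord(force=fp.force, cop=cop, tz=fp.tz, rate=fp.rate,
                                   cop_valid=np.ones(len(cop), bool))
        masked = cpcross_mask(kin, fp_ramp, res.poses, res.events,
                              progression_axis=np.array([1.0, 0.0, 0.0]))
        assert abs(masked["mtp1"].crossing_index - k_target) <= 1
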