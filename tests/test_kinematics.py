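import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from canalfill.core import RigidTransform
from canalfill.kinematics import (bone_loading, correct_rigid_motion,
                                  estimate_rigid_pose, find_analysis_points,
                                  implant_stability)
from canalfill.phantom import LoadProtocol, simulate_tracking_sequence

PROTOCOL = LoadProtocol(blocks=((220.0, 10), (520.0, 10), (820.0, 10)))


def make_sequence(**kwargs):
    defaults = dict(protocol=PROTOCOL, noise_sd_um=0.0, seed=0)
    defaults.update(kwargs)
    return simulate_tracking_sequence(**defaults)


class TestRigidPoseEstimation:
    def test_identical_sets_give_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        fit = estimate_rigid_pose(pts, pts)
        assert fit.pose.almost_identity(1e-12, 1e-9)
        assert fit.rms_mm == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered_exactly(self):
        pts = np.random.default_rng(1).normal(size=(5, 3))
        fit = estimate_rigid_pose(pts, pts + [1.0, 2.0, 3.0])
        assert np.allclose(fit.pose.translation, [1, 2, 3], atol=1e-12)
        assert fit.pose.rotation_angle_deg() < 1e-10

    def test_random_rotations_match_independent_solver(self):
        # oracle: scipy's Davenport q-method (align_vectors), an
        # algorithmically independent route to the same least-squares fit
        rng = np.random.default_rng(2)
        for _ in range(20):
            ref = rng.normal(size=(10, 3)) * 10
            rot = Rotation.random(rng=rng)
            t = rng.normal(size=3) * 5
            cur = ref @ rot.as_matrix().T + t
            fit = estimate_rigid_pose(ref, cur)
            oracle, _ = Rotation.align_vectors(
                cur - cur.mean(axis=0), ref - ref.mean(axis=0))
            delta = (Rotation.from_matrix(fit.pose.rotation)
                     * oracle.inv()).magnitude()
            assert delta < 1e-6

    def test_reflection_never_returned(self):
        # near-planar cloud with a noisy mirror image still yields det=+1
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(8, 3))
        ref[:, 2] *= 0.01
        cur = ref.copy()
        cur[:, 2] *= -1
        fit = estimate_rigid_pose(ref, cur)
        assert np.linalg.det(fit.pose.rotation) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_rigid_pose(line, line)


class TestRigidMotionCorrection:
    @staticmethod
    def drift(t):
        return RigidTransform(
            Rotation.from_euler("z", 3.0 * t, degrees=True).as_matrix(),
            np.array([0.2 * t, -0.1 * t, 0.05 * t]))

    def test_embedding_becomes_stationary(self):
        seq = correct_rigid_motion(make_sequence(global_motion=self.drift))
        emb = seq.frames["embedding"]
        assert np.allclose(emb, emb[0], atol=1e-9)

    def test_noise_free_drift_removed_exactly(self):
        kwargs = dict(implant_subsidence_mm=(0.1, 0.2, 0.3),
                      bone_elastic_amplitude_um=(40, 60, 80),
                      bone_plastic_drift_um=(10, 15, 20))
        plain = correct_rigid_motion(make_sequence(**kwargs))
        drifted = correct_rigid_motion(
            make_sequence(global_motion=self.drift, **kwargs))
        for body in plain.frames:
            assert np.allclose(plain.frames[body], drifted.frames[body],
                               atol=1e-9)

    def test_idempotent(self):
        seq = make_sequence(global_motion=self.drift)
        once = correct_rigid_motion(seq)
        twice = correct_rigid_motion(once)
        for body in once.frames:
            assert np.allclose(once.frames[body], twice.frames[body],
                               atol=1e-9)

    def test_missing_embedding_rejected(self):
        seq = make_sequence()
        del seq.frames["embedding"]
        with pytest.raises(ValueError, match="embedding"):
            correct_rigid_motion(seq)


class TestStabilityMetrics:
    def test_generator_closure_subsidence_and_tilt(self):
        seq = correct_rigid_motion(make_sequence(
            implant_subsidence_mm=(0.1, 0.2, 0.3),
            implant_tilt_deg=(0.5, 1.0, 2.0),
            bone_elastic_amplitude_um=(40, 60, 80),
            bone_plastic_drift_um=(10, 15, 20)))
        m = implant_stability(seq)
        for blk, s, a in (("220", 0.1, 0.5), ("520", 0.2, 1.0),
                          ("820", 0.3, 2.0)):
            assert m.s_implant_mm[blk] == pytest.approx(s, abs=1e-4)
            assert m.alpha_implant_deg[blk] == pytest.approx(a, abs=1e-3)

    def test_static_implant_reads_zero(self):
        m = implant_stability(correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(40, 60, 80),
            bone_plastic_drift_um=(10, 15, 20))))
        for blk in ("220", "520", "820"):
            assert abs(m.s_implant_mm[blk]) < 1e-9
            assert abs(m.alpha_implant_deg[blk]) < 1e-9

    def test_missing_analysis_points_rejected(self):
        seq = make_sequence()
        del seq.analysis_points["d"]
        with pytest.raises(ValueError, match="analysis points"):
            implant_stability(seq)


class TestBoneLoadingMetrics:
    def test_elastic_amplitude_appears_as_hysteresis_width(self):
        m = bone_loading(correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(80, 80, 80),
            bone_plastic_drift_um=(0, 0, 0))))
        for blk in ("220", "520", "820"):
            assert m.s_bone_hw_um[blk] == pytest.approx(80.0, abs=1e-7)
            assert m.s_bone_tot_um[blk] == pytest.approx(0.0, abs=1e-7)

    def test_plastic_drift_accumulates_as_total_deformation(self):
        m = bone_loading(correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(0, 0, 0),
            bone_plastic_drift_um=(50, 50, 50))))
        for blk, tot in (("220", 50.0), ("520", 100.0), ("820", 150.0)):
            assert m.s_bone_tot_um[blk] == pytest.approx(tot, abs=1e-7)
            assert m.s_bone_hw_um[blk] == pytest.approx(0.0, abs=1e-7)

    def test_axial_component_option_matches_magnitude_for_axial_motion(self):
        seq = correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(40, 60, 80),
            bone_plastic_drift_um=(10, 15, 20)))
        mag = bone_loading(seq, component="magnitude")
        axial = bone_loading(seq, component="axial")
        for blk in ("220", "520", "820"):
            assert mag.s_bone_hw_um[blk] == pytest.approx(
                axial.s_bone_hw_um[blk], abs=1e-9)

    def test_zero_motion_reads_zero(self):
        m = bone_loading(correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(0, 0, 0),
            bone_plastic_drift_um=(0, 0, 0))))
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in m.s_bone_hw_um.values())


class TestInvariants:
    def test_gauge_invariance_under_random_rigid_motion(self):
        rng = np.random.default_rng(5)
        kwargs = dict(implant_subsidence_mm=(0.1, 0.2, 0.3),
                      implant_tilt_deg=(0.3, 0.6, 1.0),
                      bone_elastic_amplitude_um=(40, 60, 80),
                      bone_plastic_drift_um=(10, 15, 20))
        ref_stab = implant_stability(
            correct_rigid_motion(make_sequence(**kwargs)))
        for _ in range(3):
            p = rng.uniform(-5, 5, 6)

            def gauge(t, p=p):
                return RigidTransform.from_params(*(p * t))

            stab = implant_stability(correct_rigid_motion(
                make_sequence(global_motion=gauge, **kwargs)))
            for blk in ("220", "520", "820"):
                assert stab.s_implant_mm[blk] == pytest.approx(
                    ref_stab.s_implant_mm[blk], abs=1e-8)
                assert stab.alpha_implant_deg[blk] == pytest.approx(
                    ref_stab.alpha_implant_deg[blk], abs=1e-8)

    def test_noise_floor_scales_with_inverse_sqrt_marker_count(self):
        # centroid-based metrics under pure noise: sd ~ noise_sd / sqrt(m)
        from canalfill.phantom import DEFAULT_LAYOUTS
        rng = np.random.default_rng(11)
        sds = {}
        for m_markers in (4, 16):
            layouts = {k: v.copy() for k, v in DEFAULT_LAYOUTS.items()}
            pts = rng.normal(scale=8.0, size=(m_markers, 3))
            layouts["bone"] = pts
            vals = []
            for seed in range(60):
                seq = make_sequence(marker_layouts=layouts,
                                    bone_elastic_amplitude_um=(0, 0, 0),
                                    bone_plastic_drift_um=(0, 0, 0),
                                    noise_sd_um=4.9, seed=seed)
                m = bone_loading(seq, component="axial")
                vals.append(m.s_bone_tot_um["820"])
            sds[m_markers] = np.std(vals)
        ratio = sds[4] / sds[16]
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_native_vs_implanted_ordering(self):
        # native bone sees more load-sharing: larger elastic amplitudes
        native = bone_loading(correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(52, 78, 104),
            bone_plastic_drift_um=(5, 8, 10), noise_sd_um=4.9)))
        high_fill = bone_loading(correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(20, 30, 40),
            bone_plastic_drift_um=(5, 8, 10), noise_sd_um=4.9, seed=1)))
        low_fill = bone_loading(correct_rigid_motion(make_sequence(
            bone_elastic_amplitude_um=(36, 54, 72),
            bone_plastic_drift_um=(5, 8, 10), noise_sd_um=4.9, seed=2)))
        for blk in ("220", "520", "820"):
            assert native.s_bone_hw_um[blk] > low_fill.s_bone_hw_um[blk] \
                > high_fill.s_bone_hw_um[blk]


class TestAnalysisPointRecovery:
    def test_points_recovered_from_actuator_trace(self):
        seq = make_sequence(implant_subsidence_mm=(0.1, 0.2, 0.3),
                            bone_elastic_amplitude_um=(40, 60, 80),
                            bone_plastic_drift_um=(10, 15, 20))
        assert find_analysis_points(seq) == seq.analysis_points
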