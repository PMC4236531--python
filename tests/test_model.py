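"""Hill-type muscle model: forces, weakness scaling, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capgap as cg
from capgap.model import force_length, force_velocity


def simple_muscle(**kw):
    defaults = dict(
        name="m",
        max_isometric_force=1000.0,
        optimal_fiber_length=0.1,
        spanned_dofs=["ankle"],
        moment_arm_coeffs={"ankle": [0.05]},
    )
    defaults.update(kw)
    return cg.MuscleParams(**defaults)


class TestCurves:
    def test_unity_at_isometric_optimum(self):
        assert force_length(1.0) == pytest.approx(1.0)
        assert force_velocity(0.0) == pytest.approx(1.0)

    def test_force_length_symmetric_gaussian(self):
        assert force_length(1.2) == pytest.approx(np.exp(-((0.2 / 0.45) ** 2)))
        assert force_length(0.8) == pytest.approx(force_length(1.2))

    def test_force_velocity_limits(self):
        assert force_velocity(-1.0) == 0.0
        assert force_velocity(-2.0) == 0.0  # clamped beyond max shortening
        assert force_velocity(5.0) == pytest.approx(1.4, abs=1e-6)
        # continuous and increasing through zero
        assert force_velocity(-1e-9) == pytest.approx(1.0, abs=1e-6)
        v = np.linspace(-1, 1, 201)
        assert np.all(np.diff(force_velocity(v)) >= 0)


class TestActiveForce:
    def test_isometric_optimum_returns_f0(self):
        m = simple_muscle()
        st_ = cg.MuscleState(fiber_length=0.1, fiber_velocity=0.0)
        assert cg.active_force(m, st_, 1.0) == pytest.approx(1000.0)
        assert cg.active_force(m, st_, 0.0) == 0.0

    def test_off_optimum_matches_curve_product(self):
        # direct evaluation of the curve formulas as the oracle
        m = simple_muscle(max_isometric_force=800.0)
        lnorm, vnorm = 1.2, -0.3
        state = cg.MuscleState(fiber_length=lnorm * 0.1, fiber_velocity=vnorm * 0.1 * 10.0)
        expected = 0.5 * 800.0 * np.exp(-((0.2 / 0.45) ** 2)) * (1 - 0.3) / (1 + 0.3 / 0.25)
        assert cg.active_force(m, state, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_rejects_invalid_inputs(self):
        m = simple_muscle()
        state = cg.MuscleState(fiber_length=0.1, fiber_velocity=0.0)
        with pytest.raises(ValueError):
            cg.active_force(m, state, 1.5)
        with pytest.raises(ValueError):
            cg.active_force(m, cg.MuscleState(fiber_length=0.1, fiber_velocity=np.nan), 0.5)
        with pytest.raises(ValueError):
            cg.MuscleState(fiber_length=-0.1, fiber_velocity=0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0.0, 1.0),
        f0=st.floats(1.0, 5000.0),
        lnorm=st.floats(0.5, 1.5),
        vnorm=st.floats(-0.9, 0.9),
    )
    def test_linear_in_activation_and_f0(self, a, f0, lnorm, vnorm):
        m = simple_muscle(max_isometric_force=f0)
        state = cg.MuscleState(fiber_length=lnorm * 0.1, fiber_velocity=vnorm * 1.0)
        base = cg.active_force(m, state, 1.0)
        assert cg.active_force(m, state, a) == pytest.approx(a * base, rel=1e-12, abs=1e-12)
        m2 = simple_muscle(max_isometric_force=2 * f0)
        assert cg.active_force(m2, state, 1.0) == pytest.approx(2 * base, rel=1e-12)


class TestWeakness:
    def test_scales_f0_only_and_preserves_input(self, model):
        weak = cg.apply_weakness(model, cg.WeaknessLevel(0.3))
        for m0, m1 in zip(model.muscles, weak.muscles):
            assert m1.max_isometric_force == pytest.approx(0.7 * m0.max_isometric_force)
            assert m1.optimal_fiber_length == m0.optimal_fiber_length
            assert m1.moment_arm_coeffs == m0.moment_arm_coeffs
        assert model.muscles[0].max_isometric_force == 1500.0  # untouched

    def test_identity_and_zero_limits(self, model):
        same = cg.apply_weakness(model, cg.WeaknessLevel(0.0))
        assert all(
            a.max_isometric_force == b.max_isometric_force
            for a, b in zip(same.muscles, model.muscles)
        )
        gone = cg.apply_weakness(model, cg.WeaknessLevel(1.0))
        state = cg.MuscleState(fiber_length=0.1, fiber_velocity=0.0)
        assert all(
            cg.active_force(m, state, 1.0) == 0.0 for m in gone.muscles
        )

    def test_weakness_fraction_bounds(self):
        with pytest.raises(ValueError):
            cg.WeaknessLevel(1.2)

    def test_force_scales_by_one_minus_w_for_any_state(self, model, rng):
        w = cg.WeaknessLevel(0.45)
        weak = cg.apply_weakness(model, w)
        for m0, m1 in zip(model.muscles, weak.muscles):
            for _ in range(5):
                state = cg.MuscleState(
                    fiber_length=m0.optimal_fiber_length * rng.uniform(0.7, 1.3),
                    fiber_velocity=rng.uniform(-0.5, 0.5),
                )
                a = rng.uniform(0, 1)
                assert cg.active_force(m1, state, a) == pytest.approx(
                    0.55 * cg.active_force(m0, state, a), rel=1e-12, abs=1e-12
                )


class TestGeometry:
    def test_moment_arm_polynomial(self):
        m = simple_muscle(moment_arm_coeffs={"ankle": [0.05, -0.01]})
        assert cg.moment_arm(m, "ankle", 0.0) == pytest.approx(0.05)
        assert cg.moment_arm(m, "ankle", 0.5) == pytest.approx(0.045)
        with pytest.raises(KeyError):
            cg.moment_arm(m, "knee", 0.0)

    def test_fiber_length_from_exact_integral(self):
        m = simple_muscle(
            optimal_fiber_length=0.12,
            reference_fiber_length=0.12,
            moment_arm_coeffs={"ankle": [0.05]},
        )
        state = cg.muscle_kinematics(m, {"ankle": 0.2}, {"ankle": 0.0})
        assert state.fiber_length == pytest.approx(0.12 - 0.05 * 0.2)
        assert state.fiber_velocity == 0.0
        state = cg.muscle_kinematics(m, {"ankle": 0.0}, {"ankle": 1.0})
        assert state.fiber_velocity == pytest.approx(-0.05)

    def test_nonpositive_fiber_length_raises(self):
        m = simple_muscle(optimal_fiber_length=0.01, reference_fiber_length=0.01)
        with pytest.raises(ValueError, match="fiber length"):
            cg.muscle_kinematics(m, {"ankle": 0.5}, {"ankle": 0.0})

    def test_velocity_is_length_time_derivative(self, model):
        # finite-difference of fiber length along a dense trajectory
        t = np.linspace(0, 1, 2001)
        dt = t[1] - t[0]
        traj = {
            "hip": -0.3 + 0.2 * np.sin(2 * np.pi * t),
            "knee": -0.5 + 0.3 * np.cos(2 * np.pi * t),
            "ankle": 0.1 * np.sin(4 * np.pi * t),
        }
        vel = {
            "hip": 0.2 * 2 * np.pi * np.cos(2 * np.pi * t),
            "knee": -0.3 * 2 * np.pi * np.sin(2 * np.pi * t),
            "ankle": 0.1 * 4 * np.pi * np.cos(4 * np.pi * t),
        }
        for m in model.muscles:
            lengths = np.array(
                [
                    cg.muscle_kinematics(
                        m,
                        {d: traj[d][i] for d in traj},
                        {d: 0.0 for d in traj},
                    ).fiber_length
                    for i in range(len(t))
                ]
            )
            interior = range(100, len(t) - 100, 100)
            v_model = np.array(
                [
                    cg.muscle_kinematics(
                        m,
                        {d: traj[d][i] for d in traj},
                        {d: vel[d][i] for d in vel},
                    ).fiber_velocity
                    for i in interior
                ]
            )
            v_fd = np.gradient(lengths, dt)[list(interior)]
            assert np.allclose(v_model, v_fd, atol=5e-5)


class TestMaxFeasibleMoment:
    def test_single_muscle_closed_form(self):
        model = cg.MusculoskeletalModel(
            dofs=[cg.DOF("ankle")],
            muscles=[simple_muscle()],
            segment_properties=[cg.SegmentProperties("foot", 1.0, 0.2, 0.1, 0.01)],
            body_mass=60.0,
        )
        q = {"ankle": 0.0}
        qd = {"ankle": 0.0}
        assert cg.max_feasible_moment(model, "ankle", q, qd, +1) == pytest.approx(50.0)
        assert cg.max_feasible_moment(model, "ankle", q, qd, -1) == 0.0

    def test_scales_with_weakness_and_vanishes_at_full(self, model):
        q = {d: -0.2 for d in model.dof_names}
        q["ankle"] = 0.1
        qd = {d: 0.0 for d in model.dof_names}
        base = cg.max_feasible_moment(model, "knee", q, qd, +1)
        weak = cg.apply_weakness(model, cg.WeaknessLevel(0.6))
        assert cg.max_feasible_moment(weak, "knee", q, qd, +1) == pytest.approx(
            0.4 * base, rel=1e-12
        )
        gone = cg.apply_weakness(model, cg.WeaknessLevel(1.0))
        assert cg.max_feasible_moment(gone, "knee", q, qd, +1) == 0.0


class TestModelIO:
    def test_planar9_composition(self, model):
        assert model.dof_names == ["hip", "knee", "ankle"]
        assert len(model.muscles) == 9
        names = {m.name for m in model.muscles}
        assert {"hamstrings", "rectus_femoris", "gastrocnemius"} <= names
        biarticular = [m for m in model.muscles if len(m.spanned_dofs) == 2]
        assert len(biarticular) == 3

    def test_yaml_roundtrip(self, tmp_path, model):
        import yaml

        cfg = {
            "name": "tiny",
            "body_mass": 70.0,
            "dofs": [{"name": "ankle"}],
            "segments": [
                {"name": "foot", "mass": 1.0, "length": 0.2, "com": 0.1, "inertia": 0.01}
            ],
            "muscles": [
                {
                    "name": "pf",
                    "max_isometric_force": 2000,
                    "optimal_fiber_length": 0.15,
                    "moment_arm_coeffs": {"ankle": [0.05]},
                }
            ],
        }
        p = tmp_path / "tiny.yaml"
        p.write_text(yaml.safe_dump(cfg))
        m = cg.load_model(p)
        assert m.body_mass == 70.0
        assert m.muscles[0].name == "pf"

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError, match="unknown DOFs"):
            cg.MusculoskeletalModel(
                dofs=[cg.DOF("ankle")],
                muscles=[simple_muscle(spanned_dofs=["knee"], moment_arm_coeffs={"knee": [0.1]})],
                segment_properties=[cg.SegmentProperties("foot", 1.0, 0.2, 0.1, 0.01)],
                body_mass=60.0,
            )
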