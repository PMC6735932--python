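"""Superposition, screw algebra and helical parameters."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filaweaver import (
    RigidTransform,
    ScrewParams,
    angle_between_axes,
    compose,
    helical_params,
    screw_from_transform,
    superpose,
    transform_from_screw,
)
from filaweaver.screw_geometry import DegenerateFitError, UndefinedHelixError
from filaweaver.structure_io import AtomRecord, Structure

from conftest import random_rigid_transform

Z = np.array([0.0, 0.0, 1.0])


def _ca_structure(coords):
    atoms = [
        AtomRecord(i + 1, "CA", "GLY", i + 1, "A", c, element="C")
        for i, c in enumerate(coords)
    ]
    return Structure(atoms)


class TestSuperpose:
    def test_identity(self, rng):
        s = _ca_structure(rng.normal(scale=10, size=(20, 3)))
        t, rmsd = superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert t.isclose(RigidTransform.identity(), atol=1e-9)

    def test_pure_translation_recovered(self, rng):
        ref = _ca_structure(rng.normal(scale=10, size=(20, 3)))
        mob = ref.with_coords(ref.coords() + np.array([5.0, 0.0, 0.0]))
        t, rmsd = superpose(mob, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_noisy_rotation_recovered(self, rng):
        ref = _ca_structure(rng.normal(scale=10, size=(50, 3)))
        R = Rotation.random(random_state=7).as_matrix()
        noisy = ref.coords() @ R.T + rng.normal(scale=0.01, size=(50, 3))
        mob = ref.with_coords(noisy)
        t, rmsd = superpose(mob, ref)
        err = Rotation.from_matrix(t.rotation @ R).magnitude()
        assert err < 1e-3
        assert rmsd < 0.05

    def test_too_few_pairs(self):
        s = _ca_structure([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateFitError, match="matched atom pairs"):
            superpose(s, s)

    def test_collinear_pairs(self):
        s = _ca_structure([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFitError, match="collinear"):
            superpose(s, s)


class TestScrewDecomposition:
    def test_60deg_z_screw(self):
        t = transform_from_screw(ScrewParams(Z, np.zeros(3), 60.0, 15.0))
        s = screw_from_transform(t)
        assert s.angle_deg == pytest.approx(60.0, abs=1e-9)
        assert s.translation == pytest.approx(15.0, abs=1e-9)
        np.testing.assert_allclose(s.axis_direction, Z, atol=1e-9)

    def test_pure_translation_branch(self):
        t = RigidTransform(np.eye(3), np.array([0.0, 0.0, 7.0]))
        s = screw_from_transform(t)
        assert s.angle_deg == pytest.approx(0.0)
        assert s.translation == pytest.approx(7.0)
        np.testing.assert_allclose(s.axis_direction, Z, atol=1e-12)

    def test_identity_transform(self):
        s = screw_from_transform(RigidTransform.identity())
        assert s.angle_deg == 0.0 and s.translation == 0.0

    def test_half_turn_branch(self):
        t = transform_from_screw(
            ScrewParams(np.array([0.0, 1.0, 0.0]), np.array([3.0, 0.0, 1.0]), 180.0, 4.0)
        )
        s = screw_from_transform(t)
        t2 = transform_from_screw(s)
        assert np.abs(t2.matrix() - t.matrix()).max() < 1e-9

    @pytest.mark.parametrize("trial", range(20))
    def test_roundtrip_random(self, trial):
        rng = np.random.default_rng(1000 + trial)
        t = random_rigid_transform(rng)
        s = screw_from_transform(t)
        t2 = transform_from_screw(s)
        assert np.abs(t2.matrix() - t.matrix()).max() < 1e-9

    def test_axis_point_invariance(self, rng):
        s = ScrewParams(Z, np.array([4.0, -2.0, 0.0]), 37.0, 5.5)
        t = transform_from_screw(s)
        on_axis = s.axis_point + 3.3 * s.axis_direction
        moved = t.apply(on_axis)
        np.testing.assert_allclose(moved, on_axis + s.translation * s.axis_direction, atol=1e-9)

    def test_full_turn_is_identity(self):
        t = transform_from_screw(
            ScrewParams(np.array([1.0, 1.0, 1.0]), np.zeros(3), 360.0, 0.0)
        )
        assert np.abs(t.matrix() - np.eye(4)).max() < 1e-9

    def test_canonical_is_idempotent(self, rng):
        for _ in range(50):
            u = rng.normal(size=3)
            s = ScrewParams(u, rng.normal(size=3), rng.uniform(-180, 180), rng.normal())
            c1 = s.canonical()
            c2 = c1.canonical()
            assert c1.angle_deg == pytest.approx(c2.angle_deg, abs=1e-12)
            assert c1.translation == pytest.approx(c2.translation, abs=1e-12)
            np.testing.assert_allclose(c1.axis_direction, c2.axis_direction, atol=1e-12)
            np.testing.assert_allclose(c1.axis_point, c2.axis_point, atol=1e-12)

    def test_canonical_translation_nonnegative(self):
        s = ScrewParams(Z, np.zeros(3), 60.0, -15.0).canonical()
        assert s.translation >= 0
        # same rigid motion
        t1 = transform_from_screw(ScrewParams(Z, np.zeros(3), 60.0, -15.0))
        t2 = transform_from_screw(s)
        assert np.abs(t1.matrix() - t2.matrix()).max() < 1e-9


class TestCompose:
    def test_identity_neutral(self, rng):
        t = random_rigid_transform(rng)
        assert compose(t, RigidTransform.identity()).isclose(t)
        assert compose(RigidTransform.identity(), t).isclose(t)

    def test_inverse(self, rng):
        t = random_rigid_transform(rng)
        assert compose(t, t.inverse()).isclose(RigidTransform.identity(), atol=1e-9)

    def test_pointwise_equivalence(self, rng):
        a = random_rigid_transform(rng)
        b = random_rigid_transform(rng)
        pts = rng.normal(scale=30, size=(100, 3))
        np.testing.assert_allclose(
            compose(a, b).apply(pts), a.apply(b.apply(pts)), atol=1e-9
        )

    def test_composed_screw_preserves_pitch(self):
        s = ScrewParams(Z, np.zeros(3), 58.4, 15.4)
        t = transform_from_screw(s)
        t3 = compose(t, compose(t, t))
        s3 = screw_from_transform(t3)
        h1 = helical_params(s)
        h3 = helical_params(
            ScrewParams(s3.axis_direction, s3.axis_point, s3.angle_deg / 3, s3.translation / 3)
        )
        assert h3.pitch == pytest.approx(h1.pitch, abs=1e-6)


class TestHelicalParams:
    def test_arithmetic(self):
        h = helical_params(ScrewParams(Z, np.zeros(3), 60.0, 15.0))
        assert h.monomers_per_turn == pytest.approx(6.0)
        assert h.pitch == pytest.approx(90.0)
        assert h.handedness == "right"

    def test_left_handed_after_canonicalization(self):
        h = helical_params(ScrewParams(Z, np.zeros(3), -60.0, 15.0))
        assert h.pitch == pytest.approx(90.0)
        assert h.handedness == "left"

    def test_zero_angle_is_undefined(self):
        with pytest.raises(UndefinedHelixError):
            helical_params(ScrewParams(Z, np.zeros(3), 0.0, 7.0))


class TestAngleBetweenAxes:
    def test_equal_axes(self):
        assert angle_between_axes(Z, Z) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert angle_between_axes(Z, [1, 0, 0]) == pytest.approx(90.0)

    def test_constructed_20p5(self):
        R = Rotation.from_rotvec(np.array([1.0, 0.0, 0.0]) * math.radians(20.5))
        assert angle_between_axes(Z, R.apply(Z)) == pytest.approx(20.5, abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            angle_between_axes([0, 0, 0], Z)
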