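"""Registration: initialisation, similarity metric, failure detection,
point/mask transfer, and parameter recovery on phantoms."""

import numpy as np
import pytest
import scipy.spatial.transform as st

from conftest import make_mask, make_volume, small_config

from liverloc.deenhance import DeenhanceParams, deenhance
from liverloc.evaluate import centre_of_gravity
from liverloc.phantom import generate_phantom
from liverloc.register import (
    RegistrationParams,
    check_failure,
    initial_alignment,
    register_bspline,
    register_rigid,
    resample_volume,
    similarity,
    transform_mask,
    transform_point,
)
from liverloc.transforms import BSplineDeformation, ComposedTransform, RigidTransform


def ball_mask(shape, centre, radius, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape).transpose(1, 2, 3, 0)
    world = idx * np.asarray(spacing)
    return make_mask(np.linalg.norm(world - centre, axis=-1) <= radius, spacing=spacing)


def case_vuct(case, seed=0):
    hypo = [m for m, k in zip(case.tumour_masks_intra, case.tumour_types) if k == "hypo"]
    return deenhance(case.intraproc_cect, case.liver_mask_intra, hypo, DeenhanceParams(seed=seed))


def rotation_error_deg(recovered: RigidTransform, truth: RigidTransform) -> float:
    rel = recovered.matrix @ truth.matrix.T
    return float(np.degrees(np.linalg.norm(st.Rotation.from_matrix(rel).as_rotvec())))


class TestInitialAlignment:
    def test_identical_masks_give_identity(self):
        m = ball_mask((30, 30, 30), (15, 15, 15), 8)
        t = initial_alignment(m, m)
        assert np.allclose(t.matrix, np.eye(3))
        assert np.allclose(t.translation_mm, 0.0)

    def test_recovers_centroid_shift(self):
        fixed = ball_mask((40, 40, 40), (15, 15, 20), 6)
        moving = ball_mask((40, 40, 40), (35, 5, 25), 6)  # shifted by (20, -10, 5)
        t = initial_alignment(fixed, moving)
        assert np.all(np.abs(t.translation_mm - [20, -10, 5]) < 1.0)

    def test_axes_recover_180_degree_rotation(self):
        fixed = ball_mask((40, 40, 40), (20, 20, 20), 8)
        axis_f = np.array([[20.0, 30.0, 20.0], [20.0, 5.0, 20.0]])
        axis_m = axis_f.copy()
        axis_m[:, :2] = 40.0 - axis_f[:, :2]  # axis flipped in-plane
        t = initial_alignment(fixed, fixed, axis_f, axis_m)
        assert abs(abs(t.rotation_angle_deg()) - 180.0) < 1.0

    def test_empty_mask_raises(self):
        m = ball_mask((20, 20, 20), (10, 10, 10), 5)
        with pytest.raises(ValueError):
            initial_alignment(m, make_mask(np.zeros((20, 20, 20), bool)))


class TestSimilarity:
    def test_self_similarity_is_two(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.normal(0, 30, (24, 24, 24)))
        mask = make_mask(np.ones(vol.shape, bool))
        assert similarity(vol, vol, mask) == pytest.approx(2.0, abs=1e-9)

    def test_independent_images_approach_one(self):
        rng = np.random.default_rng(1)
        a = make_volume(rng.uniform(0, 100, (40, 40, 40)))
        b = make_volume(rng.uniform(0, 100, (40, 40, 40)))
        mask = make_mask(np.ones(a.shape, bool))
        assert similarity(a, b, mask) == pytest.approx(1.0, abs=0.02)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        a = make_volume(rng.normal(0, 10, (20, 20, 20)))
        b = make_volume(rng.normal(5, 20, (20, 20, 20)))
        mask = make_mask(rng.uniform(size=a.shape) > 0.3)
        assert similarity(a, b, mask) == pytest.approx(similarity(b, a, mask), abs=1e-12)

    def test_constant_image_defined_degenerate_value(self):
        a = make_volume(np.zeros((10, 10, 10)))
        mask = make_mask(np.ones((10, 10, 10), bool))
        assert similarity(a, a, mask) == 2.0


class TestCheckFailure:
    def test_identical_masks(self):
        m = ball_mask((20, 20, 20), (10, 10, 10), 6)
        dice, failed = check_failure(m, m, 0.3)
        assert dice == 1.0 and not failed

    def test_disjoint_masks_fail(self):
        a = ball_mask((40, 40, 40), (10, 10, 10), 4)
        b = ball_mask((40, 40, 40), (30, 30, 30), 4)
        dice, failed = check_failure(a, b, 0.3)
        assert dice == 0.0 and failed

    def test_half_overlap_closed_form(self):
        base = np.zeros((20, 20, 20), bool)
        a, b = base.copy(), base.copy()
        a[0:10, :, :] = True
        b[5:15, :, :] = True  # equal volumes, half overlapping
        dice, _ = check_failure(make_mask(a), make_mask(b), 0.3)
        assert dice == pytest.approx(0.5)

    def test_both_empty_raises(self):
        e = make_mask(np.zeros((10, 10, 10), bool))
        with pytest.raises(ValueError):
            check_failure(e, e, 0.3)


class TestTransformPointAndMask:
    def test_identity_point(self):
        p = np.array([[3.0, 4.0, 5.0]])
        np.testing.assert_array_equal(transform_point(RigidTransform.identity(), p), p)

    def test_pure_translation_point(self):
        t = RigidTransform(translation_mm=(1.0, -2.0, 0.25))
        p = np.array([[3.0, 4.0, 5.0]])
        np.testing.assert_array_equal(transform_point(t, p), p + [1.0, -2.0, 0.25])

    def test_point_outside_lattice_warns_and_uses_rigid(self):
        bs = BSplineDeformation(
            grid_origin_mm=np.zeros(3),
            grid_spacing_mm=np.full(3, 10.0),
            coefficients=np.random.default_rng(0).uniform(-2, 2, (5, 5, 5, 3)),
        )
        comp = ComposedTransform(RigidTransform(translation_mm=(1, 1, 1)), bs)
        p = np.array([[500.0, 500.0, 500.0]])
        with pytest.warns(UserWarning, match="rigid-only"):
            out = transform_point(comp, p)
        np.testing.assert_array_equal(out, p + 1.0)

    def test_identity_mask_unchanged(self):
        m = ball_mask((30, 30, 30), (15, 15, 15), 7)
        out = transform_mask(RigidTransform.identity(), m, m)
        np.testing.assert_array_equal(out.data, m.data)

    def test_whole_voxel_shift_conserves_count(self):
        m = ball_mask((40, 40, 40), (16, 16, 16), 6, spacing=(2, 2, 2))
        # transform maps fixed->moving; shifting the lookup by -k voxels
        # moves the mask by +k voxels on the fixed grid
        t = RigidTransform(translation_mm=(-4.0, -6.0, -2.0))
        out = transform_mask(t, m, m)
        assert out.n_voxels == m.n_voxels
        np.testing.assert_array_equal(out.data[2:, 3:, 1:], m.data[:-2, :-3, :-1])

    def test_smooth_warp_consistency_with_point_transform(self, moved_case):
        # centroid of the warped sphere tracks the transformed centroid
        truth = moved_case.true_transform
        comp = ComposedTransform(truth.rigid, truth.deformation)
        mask = moved_case.tumour_masks_diag[0]
        # invert: find intra-grid mask whose pullback lands on the tumour
        warped = transform_mask(comp, mask, moved_case.intraproc_cect)
        assert 0.8 < warped.n_voxels / mask.n_voxels < 1.2
        pulled_centroid = comp.apply(centre_of_gravity(warped)[None])[0]
        assert np.linalg.norm(pulled_centroid - centre_of_gravity(mask)) < np.linalg.norm(
            mask.spacing
        )

    def test_mask_mapped_outside_fov_warns_empty(self):
        m = ball_mask((20, 20, 20), (10, 10, 10), 4)
        t = RigidTransform(translation_mm=(500.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="outside the target"):
            out = transform_mask(t, m, m)
        assert out.is_empty()


class TestRegistration:
    @pytest.fixture(scope="class")
    def rigid_case(self):
        # full-size grid: registration accuracy claims are made at the
        # study's native resolution
        from liverloc.phantom import PhantomConfig

        cfg = PhantomConfig(
            rotation_deg=10.0, translation_mm=(8.0, -6.0, 4.0), noise_sd_hu=0.0, seed=55
        )
        return generate_phantom(cfg)

    def test_self_registration_stays_at_identity(self, identity_case):
        vol = identity_case.intraproc_cect
        liver = identity_case.liver_mask_intra
        out = register_rigid(vol, vol, liver, RigidTransform(centre_mm=vol.centre_mm()))
        assert rotation_error_deg(out, RigidTransform.identity()) < 0.5
        c = vol.centre_mm()
        assert np.linalg.norm(out.apply(c[None])[0] - c) < 0.5

    def test_recovers_known_rigid_motion(self, rigid_case):
        vuct = case_vuct(rigid_case, seed=55)
        init = initial_alignment(rigid_case.liver_mask_intra, rigid_case.liver_mask_diag)
        out = register_rigid(vuct, rigid_case.diagnostic_cect, rigid_case.liver_mask_intra, init)
        truth = rigid_case.true_transform.rigid
        assert rotation_error_deg(out, truth) < 1.0
        liver_c = centre_of_gravity(rigid_case.liver_mask_intra)
        err = np.linalg.norm(out.apply(liver_c[None])[0] - truth.apply(liver_c[None])[0])
        assert err < 1.0

    def test_registration_is_deterministic(self, rigid_case):
        vuct = case_vuct(rigid_case, seed=55)
        init = initial_alignment(rigid_case.liver_mask_intra, rigid_case.liver_mask_diag)
        a = register_rigid(vuct, rigid_case.diagnostic_cect, rigid_case.liver_mask_intra, init)
        b = register_rigid(vuct, rigid_case.diagnostic_cect, rigid_case.liver_mask_intra, init)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(a.translation_mm, b.translation_mm)

    def test_similarity_improves_monotonically(self, full_case, full_case_vuct):
        case, vuct = full_case, full_case_vuct
        hypo_d = [m for m, k in zip(case.tumour_masks_diag, case.tumour_types) if k == "hypo"]
        diag_vuct = deenhance(
            case.diagnostic_cect, case.liver_mask_diag, hypo_d, DeenhanceParams(seed=13)
        )
        init = initial_alignment(case.liver_mask_intra, case.liver_mask_diag)
        rigid = register_rigid(vuct, case.diagnostic_cect, case.liver_mask_intra, init)
        res = register_bspline(
            vuct, diag_vuct, case.liver_mask_intra, rigid, moving_liver=case.liver_mask_diag
        )
        mask = case.liver_mask_intra

        def nmi(tf):
            return similarity(vuct, resample_volume(tf, case.diagnostic_cect, vuct), mask)

        s_init = nmi(ComposedTransform(init))
        s_rigid = nmi(ComposedTransform(rigid))
        s_nonrigid = nmi(res.transform)
        tol = 1e-3  # optimiser tolerance
        assert s_rigid >= s_init - tol
        assert s_nonrigid >= s_rigid - tol
        assert not res.failed

    def test_zero_deformation_pair_yields_small_displacement(self, rigid_case):
        vuct = case_vuct(rigid_case, seed=55)
        hypo_d = [
            m for m, k in zip(rigid_case.tumour_masks_diag, rigid_case.tumour_types) if k == "hypo"
        ]
        diag_vuct = deenhance(
            rigid_case.diagnostic_cect, rigid_case.liver_mask_diag, hypo_d, DeenhanceParams(seed=56)
        )
        res = register_bspline(
            vuct,
            diag_vuct,
            rigid_case.liver_mask_intra,
            rigid_case.true_transform.rigid,
            moving_liver=rigid_case.liver_mask_diag,
        )
        liver_pts = rigid_case.liver_mask_intra.voxel_to_world(
            np.argwhere(rigid_case.liver_mask_intra.data)[::19]
        )
        disp = np.linalg.norm(res.deformation.displacement_at(liver_pts), axis=1)
        assert disp.mean() < np.min(rigid_case.intraproc_cect.spacing)  # < 1 voxel

    def test_disjoint_init_with_zero_iterations_flags_failure(self, identity_case):
        vol = identity_case.intraproc_cect
        liver = identity_case.liver_mask_intra
        bad_init = RigidTransform(translation_mm=(150.0, 150.0, 0.0))
        params = RegistrationParams(demons_iterations=(0, 0))
        res = register_bspline(vol, vol, liver, bad_init, params, moving_liver=liver)
        assert res.failed
        assert res.liver_overlap_dice < 0.3
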