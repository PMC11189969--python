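import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

import footmorph as fm
from footmorph.morphing import KERNEL_FAMILIES


def random_landmarks(seed, n=16, scale=100.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(-scale, scale, size=(n, 3))


class TestAffine:
    def test_identity_when_target_equals_source(self, template):
        t = fm.fit_affine(template.landmarks, template.landmarks)
        np.testing.assert_allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_recovers_known_matrix(self):
        rng = np.random.default_rng(5)
        m0 = np.eye(4)
        m0[:3, :3] = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        m0[:3, 3] = rng.uniform(-30, 30, 3)
        src = random_landmarks(6)
        tgt = src @ m0[:3, :3].T + m0[:3, 3]
        t = fm.fit_affine(src, tgt)
        np.testing.assert_allclose(t.matrix, m0, atol=1e-9)

    def test_exact_with_four_points(self):
        src = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
        tgt = src * 1.3 + [1, 2, 3]
        t = fm.fit_affine(src, tgt)
        np.testing.assert_allclose(t.apply(src), tgt, atol=1e-8)

    def test_coplanar_sources_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="coplanar"):
            fm.fit_affine(src, src)

    def test_too_few_pairs_rejected(self):
        src = np.eye(3)
        with pytest.raises(ValueError, match="4"):
            fm.fit_affine(src, src)

    def test_mismatched_names_rejected(self, template):
        other = fm.LandmarkSet(tuple(reversed(template.landmarks.names)),
                               template.landmarks.points)
        with pytest.raises(ValueError, match="correspond"):
            fm.fit_affine(template.landmarks, other)


class TestKernels:
    @pytest.mark.parametrize("family,r,expected", [
        ("TRI", 2.0, 8.0),
        ("TRI", 0.0, 0.0),
        ("THI", 1.0, 0.0),
        ("THI", 0.0, 0.0),
        ("THI", np.e, np.e ** 2),
        ("MUL", 0.0, np.sqrt(0.2)),
        ("MUL", 3.0, np.sqrt(9.2)),
    ])
    def test_values(self, family, r, expected):
        assert fm.kernel_eval(fm.RBFKernel(family), r) == pytest.approx(expected, rel=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            fm.kernel_eval(fm.RBFKernel("TRI"), -1.0)

    def test_printed_multiquadric_errors_on_imaginary_argument(self):
        kernel = fm.RBFKernel("MUL", beta=0.2, printed_form=True)
        assert fm.kernel_eval(kernel, 1.0) == pytest.approx(np.sqrt(0.8))
        with pytest.raises(ValueError, match="imaginary"):
            fm.kernel_eval(kernel, 0.1)

    def test_mul_requires_positive_beta(self):
        with pytest.raises(ValueError):
            fm.RBFKernel("MUL", beta=0.0)


class TestFitRBF:
    @pytest.mark.parametrize("family", KERNEL_FAMILIES)
    def test_zero_displacement_gives_zero_coefficients(self, family):
        src = random_landmarks(1)
        t = fm.fit_rbf(src, src, fm.RBFKernel(family))
        assert np.abs(t.coefficients).max() < 1e-10
        pts = random_landmarks(2, n=40)
        np.testing.assert_allclose(fm.apply_rbf(t, pts), pts, atol=1e-8)

    @pytest.mark.parametrize("family", KERNEL_FAMILIES)
    def test_affine_tail_absorbs_affine_correspondence(self, family):
        src = random_landmarks(3)
        m = np.array([[1.1, 0.02, 0.0], [0.0, 0.95, 0.05], [-0.03, 0.0, 1.02]])
        tgt = src @ m.T + [5.0, -3.0, 8.0]
        t = fm.fit_rbf(src, tgt, fm.RBFKernel(family), with_affine_tail=True)
        assert np.linalg.norm(t.coefficients) < 1e-8

    @pytest.mark.parametrize("family", KERNEL_FAMILIES)
    def test_interpolation_exactness_on_16_landmarks(self, family, benchmark):
        template, target, _ = benchmark
        t = fm.fit_rbf(template.landmarks.points, target.landmarks.points,
                       fm.RBFKernel(family))
        mapped = fm.apply_rbf(t, template.landmarks.points)
        residual = np.linalg.norm(mapped - target.landmarks.points, axis=1).max()
        assert residual < 1e-6

    def test_moment_side_conditions_hold(self):
        src = random_landmarks(9)
        tgt = src + np.random.default_rng(10).normal(scale=4.0, size=src.shape)
        t = fm.fit_rbf(src, tgt, fm.RBFKernel("THI"))
        assert np.abs(t.coefficients.sum(axis=0)).max() < 1e-8
        assert np.abs(t.coefficients.T @ t.sources).max() < 1e-6

    def test_duplicate_sources_rejected(self):
        src = random_landmarks(4)
        src[3] = src[0]
        with pytest.raises(ValueError, match="duplicate"):
            fm.fit_rbf(src, src + 1.0, fm.RBFKernel("TRI"))

    def test_translation_maps_midpoints_exactly(self):
        src = random_landmarks(12, n=8)
        shift = np.array([3.0, -7.0, 2.0])
        t = fm.fit_rbf(src, src + shift, fm.RBFKernel("THI"))
        mid = 0.5 * (src[0] + src[1])
        np.testing.assert_allclose(fm.apply_rbf(t, mid)[0], mid + shift, atol=1e-8)

    @pytest.mark.parametrize("family,scipy_kernel", [
        ("TRI", "cubic"), ("THI", "thin_plate_spline")])
    def test_matches_scipy_rbf_interpolator(self, family, scipy_kernel):
        """Cross-check against an independent RBF implementation."""
        rng = np.random.default_rng(21)
        src = random_landmarks(13, n=20)
        tgt = src + rng.normal(scale=5.0, size=src.shape)
        ours = fm.fit_rbf(src, tgt, fm.RBFKernel(family))
        ref = RBFInterpolator(src, tgt - src, kernel=scipy_kernel, degree=1)
        query = random_landmarks(14, n=30, scale=80.0)
        np.testing.assert_allclose(fm.apply_rbf(ours, query), query + ref(query),
                                   atol=1e-6)

    def test_pure_rbf_without_tail_still_interpolates(self):
        src = random_landmarks(15, n=10)
        tgt = src + np.random.default_rng(16).normal(scale=2.0, size=src.shape)
        t = fm.fit_rbf(src, tgt, fm.RBFKernel("TRI"), with_affine_tail=False)
        assert t.affine_tail is None
        np.testing.assert_allclose(fm.apply_rbf(t, src), tgt, atol=1e-6)


class TestMorphRBFPT:
    def test_identity_targets_give_identity_morph(self, template):
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, template.landmarks)
        assert np.abs(res.morphed_surface.vertices - template.surface.vertices).max() < 1e-8
        assert np.abs(res.morphed_bone.vertices - template.bone.vertices).max() < 1e-8

    def test_affine_targets_reproduce_affine_image(self, template):
        m = np.diag([1.1, 0.95, 1.05, 1.0])
        m[:3, 3] = [4.0, -2.0, 6.0]
        affine = fm.AffineTransform(m)
        tgt_lms = fm.LandmarkSet(template.landmarks.names,
                                 affine.apply(template.landmarks.points))
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, tgt_lms)
        np.testing.assert_allclose(res.morphed_surface.vertices,
                                   affine.apply(template.surface.vertices), atol=1e-6)

    def test_landmarks_land_exactly(self, benchmark):
        template, target, _ = benchmark
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, target.landmarks)
        stage = res.provenance["stages"][-1]
        assert stage["max_source_residual_mm"] < 1e-6

    def test_topology_preserved(self, benchmark):
        template, target, _ = benchmark
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, target.landmarks)
        np.testing.assert_array_equal(res.morphed_surface.faces, template.surface.faces)
        np.testing.assert_array_equal(res.morphed_bone.faces, template.bone.faces)

    def test_beats_affine_only_on_nonlinear_target(self, benchmark):
        template, target, _ = benchmark
        affine = fm.fit_affine(template.landmarks, target.landmarks)
        affine_surface = template.surface.with_vertices(
            affine.apply(template.surface.vertices))
        affine_err = fm.summarize(fm.error_map(affine_surface, target.surface)).mean_abs
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, target.landmarks)
        rbfpt_err = fm.summarize(fm.error_map(res.morphed_surface, target.surface)).mean_abs
        assert rbfpt_err <= affine_err


class TestSampling:
    def test_every_vertex_paired_when_n_equals_count(self, benchmark):
        template, target, _ = benchmark
        n = template.surface.n_vertices
        src, tgt = fm.sample_correspondences(template.surface, target.surface, n, seed=0)
        assert len(src) == len(tgt) == n

    def test_identical_surfaces_give_zero_separation(self, template):
        src, tgt = fm.sample_correspondences(template.surface, template.surface,
                                             50, seed=1)
        assert np.linalg.norm(src - tgt, axis=1).max() < 1e-9

    def test_deterministic_under_seed(self, benchmark):
        template, target, _ = benchmark
        a = fm.sample_correspondences(template.surface, target.surface, 64, seed=9)
        b = fm.sample_correspondences(template.surface, target.surface, 64, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_oversampling_rejected(self, template):
        with pytest.raises(ValueError, match="vertices"):
            fm.sample_correspondences(template.surface, template.surface,
                                      template.surface.n_vertices + 1, seed=0)


class TestMorphRBFST:
    def test_second_stage_is_identity_when_target_already_matched(self, benchmark):
        template, target, _ = benchmark
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, target.landmarks)
        refined = fm.morph_rbfst(res, res.morphed_surface, n_sample_points=100, seed=2)
        assert np.abs(refined.morphed_surface.vertices
                      - res.morphed_surface.vertices).max() < 1e-8

    def test_refinement_does_not_worsen_fit(self, benchmark):
        template, target, _ = benchmark
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, target.landmarks)
        before = fm.summarize(fm.error_map(res.morphed_surface, target.surface)).mean_abs
        refined = fm.morph_rbfst(res, target.surface, n_sample_points=300, seed=3)
        after = fm.summarize(fm.error_map(refined.morphed_surface, target.surface)).mean_abs
        assert after <= before

    def test_seed_change_keeps_error_within_factor_two(self, benchmark):
        template, target, _ = benchmark
        res = fm.morph_rbfpt(template.surface, template.bone,
                             template.landmarks, target.landmarks)
        errors = []
        for seed in (0, 1, 2):
            refined = fm.morph_rbfst(res, target.surface, n_sample_points=200, seed=seed)
            errors.append(fm.summarize(
                fm.error_map(refined.morphed_surface, target.surface)).mean_abs)
        assert max(errors) <= 2.0 * min(errors) + 1e-6


class TestPipeline:
    def test_rbfpt_method_has_one_stage(self, benchmark):
        template, target, _ = benchmark
        res = fm.run_pipeline(fm.MorphConfig(method="RBFPT"), template,
                              target.surface, target.landmarks)
        assert len(res.rbf_stages) == 1

    def test_full_method_has_two_stages(self, benchmark):
        template, target, _ = benchmark
        res = fm.run_pipeline(fm.MorphConfig(n_sample_points=200), template,
                              target.surface, target.landmarks)
        assert len(res.rbf_stages) == 2
        assert res.provenance["config"]["method"] == "RBFPT+RBFST"

    def test_bit_reproducible_under_fixed_seed(self, benchmark):
        template, target, _ = benchmark
        cfg = fm.MorphConfig(kernel=fm.RBFKernel("THI"), n_sample_points=150, seed=4)
        a = fm.run_pipeline(cfg, template, target.surface, target.landmarks)
        b = fm.run_pipeline(cfg, template, target.surface, target.landmarks)
        np.testing.assert_array_equal(a.morphed_surface.vertices,
                                      b.morphed_surface.vertices)
        np.testing.assert_array_equal(a.morphed_bone.vertices, b.morphed_bone.vertices)

    def test_all_four_variants_beat_affine_only(self, benchmark):
        template, target, _ = benchmark
        affine = fm.fit_affine(template.landmarks, target.landmarks)
        affine_err = fm.summarize(fm.error_map(
            template.surface.with_vertices(affine.apply(template.surface.vertices)),
            target.surface)).mean_abs
        configs = [fm.MorphConfig(method="RBFPT")] + [
            fm.MorphConfig(kernel=fm.RBFKernel(fam), n_sample_points=200, seed=5)
            for fam in ("THI", "MUL", "TRI")]
        for cfg in configs:
            res = fm.run_pipeline(cfg, template, target.surface, target.landmarks)
            err = fm.summarize(fm.error_map(res.morphed_surface, target.surface)).mean_abs
            assert np.isfinite(err)
            assert err <= affine_err

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fm.MorphConfig(method="ICP")
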