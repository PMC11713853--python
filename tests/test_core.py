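"""Matrix-analysis core: log transform, hybrid matrix, eigensolvers, lambda_r,
grid harmonization and the per-pixel map pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mahm.core import (
    EPS_RATIO,
    HybridSymmetric,
    build_hybrid,
    compute_eigenmaps,
    default_harmonization_subsets,
    eig2x2_approx,
    eig2x2_exact,
    eig_sym,
    eigvec2x2,
    harmonize_grid,
    lambda_ratio,
    lambda_ratio_values,
    log_transform,
)
from mahm.grid import AcquisitionGrid, HybridStack
from mahm.phantom import make_phantom, simulate_signal, two_region_spec


E = np.e


class TestLogTransform:
    @pytest.mark.parametrize(
        "values, expected, floored",
        [
            ([[E, E], [1, 1]], [[1, 1], [0, 0]], False),
            (np.ones((3, 3)), np.zeros((3, 3)), False),
        ],
    )
    def test_exact_logs(self, values, expected, floored):
        lnA, fl = log_transform(np.asarray(values, float), 1e-6)
        np.testing.assert_allclose(lnA, expected, atol=1e-15)
        assert fl is floored

    def test_floor_policy(self):
        lnA, fl = log_transform(np.array([[E, 0.0], [1.0, 1.0]]), 1e-6)
        assert lnA[0, 1] == pytest.approx(np.log(1e-6))
        assert fl is True

    def test_all_nonpositive_pixel_is_invalid(self):
        assert log_transform(np.zeros((2, 3)), 1e-6) is None

    def test_nonfinite_signal_names_indices(self):
        bad = np.ones((2, 2))
        bad[1, 0] = np.nan
        with pytest.raises(ValueError, match=r"\[1, 0\]"):
            log_transform(bad, 1e-6)


class TestBuildHybrid:
    def test_expanded_entries(self):
        h = build_hybrid(np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]]))
        np.testing.assert_allclose(h.h, [[3.0, 0.0], [0.0, 0.0]])
        assert h.orientation == "te-major"

    def test_identity(self):
        h = build_hybrid(np.eye(3))
        np.testing.assert_allclose(h.h, np.eye(3))

    def test_against_double_loop_oracle(self, rng):
        lnA = rng.normal(size=(3, 4))
        h = build_hybrid(lnA)
        oracle = np.empty((3, 3))
        for i in range(3):
            for k in range(3):
                oracle[i, k] = sum(lnA[i, j] * lnA[k, j] for j in range(4))
        np.testing.assert_allclose(h.h, oracle, rtol=1e-13)

    def test_tall_matrix_uses_transposed_order(self, rng):
        lnA = rng.normal(size=(4, 3))
        h = build_hybrid(lnA)
        assert h.orientation == "b-major"
        assert h.k == 3
        np.testing.assert_allclose(h.h, lnA.T @ lnA, rtol=1e-13)

    def test_nonfinite_rejected(self):
        lnA = np.ones((2, 3))
        lnA[0, 2] = np.inf
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            build_hybrid(lnA)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        hnp.arrays(
            float,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=5),
            elements=st.floats(-10, 10),
        )
    )
    def test_gram_matrix_is_symmetric_psd(self, lnA):
        h = build_hybrid(lnA).h
        np.testing.assert_allclose(h, h.T, atol=1e-10)
        w = np.linalg.eigvalsh(h)
        assert w.min() >= -1e-10 * max(w.max(), 1.0)


class TestEigSym:
    def test_diagonal(self):
        r = eig_sym(HybridSymmetric(np.diag([3.0, 0.0]), "te-major"))
        np.testing.assert_allclose(r.eigenvalues, [3.0, 0.0])
        np.testing.assert_allclose(r.eigenvectors[:, 0], [1.0, 0.0])

    def test_classic_symmetric_pair(self):
        r = eig_sym(HybridSymmetric(np.array([[2.0, 1.0], [1.0, 2.0]]), "te-major"))
        np.testing.assert_allclose(r.eigenvalues, [3.0, 1.0])
        np.testing.assert_allclose(
            np.abs(r.eigenvectors[:, 0]), np.full(2, 1 / np.sqrt(2)), rtol=1e-12
        )

    def test_matches_svd_oracle(self, rng):
        """Eigenvalues of B B^T are the squared singular values of B."""
        for _ in range(100):
            B = rng.normal(size=(3, 5))
            r = eig_sym(build_hybrid(B))
            sv2 = np.linalg.svd(B, compute_uv=False) ** 2
            np.testing.assert_allclose(r.eigenvalues, sv2, rtol=1e-9)

    def test_conservation_and_residual(self, rng):
        for _ in range(50):
            h = build_hybrid(rng.normal(size=(4, 4)) * 3)
            r = eig_sym(h)
            assert np.isclose(r.eigenvalues.sum(), h.trace, rtol=1e-10)
            assert np.isclose(np.prod(r.eigenvalues), h.det, rtol=1e-8, atol=1e-8)
            # eigen residual and orthonormality
            resid = h.h @ r.eigenvectors - r.eigenvectors * r.eigenvalues
            assert np.abs(resid).max() <= 1e-8 * r.eigenvalues[0]
            gram = r.eigenvectors.T @ r.eigenvectors
            np.testing.assert_allclose(gram, np.eye(h.k), atol=1e-10)

    def test_sign_convention(self, rng):
        for _ in range(20):
            r = eig_sym(build_hybrid(rng.normal(size=(3, 4))))
            for i in range(3):
                v = r.eigenvectors[:, i]
                assert v[np.argmax(np.abs(v))] > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="not symmetric"):
            eig_sym(HybridSymmetric(np.array([[1.0, 2.0], [0.0, 1.0]]), "te-major"))

    def test_orientation_invariance_square(self, rng):
        """Both product orders share the nonzero spectrum (squared singular
        values of lnA)."""
        lnA = rng.normal(size=(3, 3))
        w1 = eig_sym(HybridSymmetric(lnA @ lnA.T, "te-major")).eigenvalues
        w2 = eig_sym(HybridSymmetric(lnA.T @ lnA, "b-major")).eigenvalues
        np.testing.assert_allclose(w1, w2, rtol=1e-9)

    def test_scale_sensitivity(self, grid33, mono_profile, rng):
        """Global signal scaling shifts lnA and changes the eigenvalues:
        raw eigenvalues are not comparable across scanner gains."""
        s = simulate_signal(mono_profile, grid33) + rng.uniform(0, 5, (3, 3))
        w1 = eig_sym(build_hybrid(np.log(s))).eigenvalues
        w2 = eig_sym(build_hybrid(np.log(2.0 * s))).eigenvalues
        assert not np.allclose(w1, w2, rtol=1e-3)


class Test2x2ClosedForms:
    @pytest.mark.parametrize(
        "h, expected",
        [
            ([[2.0, 1.0], [1.0, 2.0]], (3.0, 1.0)),
            ([[3.0, 0.0], [0.0, 0.0]], (3.0, 0.0)),
        ],
    )
    def test_exact_examples(self, h, expected):
        lam = eig2x2_exact(HybridSymmetric(np.array(h), "te-major"))
        np.testing.assert_allclose(lam, expected, atol=1e-14)

    def test_exact_matches_general_solver(self, rng):
        for _ in range(200):
            h = build_hybrid(rng.normal(size=(2, 3)) * 2)
            lam = np.array(eig2x2_exact(h))
            ref = eig_sym(h).eigenvalues
            np.testing.assert_allclose(lam, ref, rtol=1e-12, atol=1e-12)

    def test_approx_examples(self):
        h = HybridSymmetric(np.array([[3.0, 0.0], [0.0, 0.0]]), "te-major")
        assert eig2x2_approx(h) == pytest.approx((3.0, 0.0))
        h = HybridSymmetric(np.array([[2.0, 1.0], [1.0, 2.0]]), "te-major")
        assert eig2x2_approx(h) == pytest.approx((3.25, 0.75))

    def test_approx_error_small_when_det_small(self, rng):
        """First-order approximation is within 2% when det/tr^2 <= 0.01."""
        checked = 0
        while checked < 200:
            B = rng.normal(size=(2, 3))
            B[1] = B[0] * rng.normal(1, 0.1) + rng.normal(0, 0.05, 3)
            h = build_hybrid(B)
            if h.det / h.trace**2 > 0.01:
                continue
            exact = np.array(eig2x2_exact(h))
            approx = np.array(eig2x2_approx(h))
            ok = exact > 1e-12 * exact[0]
            np.testing.assert_allclose(approx[ok], exact[ok], rtol=0.02)
            checked += 1

    def test_approx_error_vanishes_with_det(self):
        """Relative error -> 0 as det(H)/tr(H)^2 -> 0 (fixed trace)."""
        errs = []
        for eps in (1e-2, 1e-4, 1e-6, 1e-8):
            h = HybridSymmetric(np.diag([1.0, eps]), "te-major")
            exact = np.array(eig2x2_exact(h))
            approx = np.array(eig2x2_approx(h))
            errs.append(np.abs(approx / exact - 1).max())
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-7

    def test_approx_zero_trace_rejected(self):
        with pytest.raises(ValueError, match="trace"):
            eig2x2_approx(HybridSymmetric(np.zeros((2, 2)), "te-major"))


class TestEigvec2x2:
    def test_direction(self):
        h = HybridSymmetric(np.array([[2.0, 1.0], [1.0, 2.0]]), "te-major")
        v = eigvec2x2(h, 3.0)
        assert v[0] == pytest.approx(v[1])

    def test_diagonal_axis_fallback(self):
        h = HybridSymmetric(np.array([[3.0, 0.0], [0.0, 0.0]]), "te-major")
        np.testing.assert_allclose(eigvec2x2(h, 3.0), [1.0, 0.0])
        np.testing.assert_allclose(eigvec2x2(h, 0.0), [0.0, 1.0])

    def test_matches_general_solver(self, rng):
        for _ in range(100):
            h = build_hybrid(rng.normal(size=(2, 4)))
            r = eig_sym(h)
            for i, lam in enumerate(r.eigenvalues):
                v = eigvec2x2(h, lam)
                resid = h.h @ v - lam * v
                assert np.abs(resid).max() <= 1e-8 * max(
                    np.abs(v).max() * r.eigenvalues[0], 1e-300
                )
                vn = v / np.linalg.norm(v)
                ref = r.eigenvectors[:, i]
                assert min(
                    np.abs(vn - ref).max(), np.abs(vn + ref).max()
                ) < 1e-8


class TestLambdaRatio:
    @pytest.mark.parametrize(
        "lams, expected", [((4.0, 2.0, 1.0), 2.0), ((1.0, 1.0, 1.0), 1.0)]
    )
    def test_arithmetic(self, lams, expected):
        value, capped = lambda_ratio_values(lams)
        assert value == pytest.approx(expected)
        assert not capped

    def test_rank2_pixel_capped(self, grid33, mono_profile):
        """Mono-exponential signal has lambda3 ~ 0, so lambda_r caps."""
        s = simulate_signal(mono_profile, grid33)
        r = eig_sym(build_hybrid(np.log(s)), lambda_r_cap=100.0)
        assert r.eigenvalues[2] <= 1e-9 * r.eigenvalues[0]
        value, capped = lambda_ratio(r, cap=100.0)
        assert capped and value == 100.0

    def test_too_few_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="3 eigenvalues"):
            lambda_ratio_values((2.0, 1.0))


class TestHarmonization:
    def test_default_drops_match_modal_protocol(self, grid44):
        tes, bs = default_harmonization_subsets(grid44, 3, 3)
        assert tes == (57.0, 80.0, 150.0)
        assert bs == (0.0, 1000.0, 1500.0)

    def test_identity_when_target_equals_size(self, noiseless_phantom):
        stack, _, _ = noiseless_phantom
        out = harmonize_grid(stack, 3, 3)
        np.testing.assert_array_equal(out.signal, stack.signal)

    def test_explicit_subsets_override(self, grid44):
        stack = HybridStack(np.ones((2, 2, 1, 4, 4)), grid44)
        out = harmonize_grid(stack, 2, 2, keep_tes=(57.0, 200.0),
                             keep_bs=(0.0, 1500.0))
        assert out.grid.tes == (57.0, 200.0)
        assert out.grid.bvalues == (0.0, 1500.0)

    def test_unknown_subset_lists_available(self, grid44):
        stack = HybridStack(np.ones((2, 2, 1, 4, 4)), grid44)
        with pytest.raises(ValueError, match="available"):
            harmonize_grid(stack, 2, 2, keep_tes=(57.0, 99.0), keep_bs=(0.0, 1500.0))

    def test_target_larger_than_grid_rejected(self, grid44):
        stack = HybridStack(np.ones((2, 2, 1, 4, 4)), grid44)
        with pytest.raises(ValueError, match="exceeds"):
            harmonize_grid(stack, 5, 3)


class TestComputeEigenmaps:
    def test_uniform_phantom_gives_constant_maps(self, grid33, mono_profile):
        s = simulate_signal(mono_profile, grid33)
        stack = HybridStack(np.broadcast_to(s, (4, 4, 1, 3, 3)).copy(), grid33)
        maps = compute_eigenmaps(stack)
        for i in range(3):
            vals = maps.eigenvalues[..., i][maps.valid]
            assert np.ptp(vals) <= 1e-12 * max(abs(vals[0]), 1)

    def test_two_region_maps_follow_geometry(self, noiseless_phantom):
        stack, labels, masks = noiseless_phantom
        maps = compute_eigenmaps(stack, labels > 0)
        l1 = maps.eigenvalues[..., 0]
        for m in masks.values():
            assert np.ptp(l1[m]) <= 1e-9 * abs(l1[m][0])
        assert not np.isclose(
            l1[masks["cancer"]][0], l1[masks["normal_pz"]][0], rtol=1e-3
        )

    def test_matches_scalar_pipeline_per_pixel(self, rng, grid44):
        signal = rng.uniform(0.5, 1000.0, size=(3, 3, 2, 4, 4))
        stack = HybridStack(signal, grid44)
        maps = compute_eigenmaps(stack, cap=1e12)
        x, y, z = 1, 2, 0
        floor = 1e-6 * np.median(signal[:, :, z][signal[:, :, z] > 0])
        lnA, _ = log_transform(signal[x, y, z], floor)
        r = eig_sym(build_hybrid(lnA), lambda_r_cap=1e12)
        # summation order differs between the batched and scalar paths, so
        # agreement is to round-off relative to the dominant eigenvalue
        lam1 = r.eigenvalues[0]
        np.testing.assert_allclose(
            maps.eigenvalues[x, y, z], r.eigenvalues, rtol=1e-9,
            atol=1e-12 * lam1,
        )
        np.testing.assert_allclose(
            maps.eigenvectors[x, y, z], r.eigenvectors, rtol=1e-6, atol=1e-9
        )
        value, _ = lambda_ratio(r, cap=1e12)
        assert maps.lambda_r[x, y, z] == pytest.approx(value, rel=1e-8)

    def test_invalid_pixels_absent_not_zero(self, grid33, mono_profile):
        s = simulate_signal(mono_profile, grid33)
        signal = np.zeros((2, 2, 1, 3, 3))
        signal[0, 0, 0] = s
        stack = HybridStack(signal, grid33)
        maps = compute_eigenmaps(stack, np.ones((2, 2, 1), bool))
        assert maps.valid[0, 0, 0]
        assert not maps.valid[1, 1, 0]
        assert np.isnan(maps.lambda_r[1, 1, 0])
        assert np.isnan(maps.eigenvalues[1, 1, 0]).all()

    def test_empty_mask_rejected(self, noiseless_phantom):
        stack, _, _ = noiseless_phantom
        with pytest.raises(ValueError, match="no pixels"):
            compute_eigenmaps(stack, np.zeros(stack.spatial_shape, bool))

    def test_psd_and_conservation_across_noise(self, grid44):
        spec = two_region_spec(shape=(10, 10), roi_size=4, snr=20, seed=3)
        stack, labels, _ = make_phantom(spec)
        maps = compute_eigenmaps(stack, labels > 0)
        w = maps.eigenvalues[maps.valid]
        assert (w >= 0).all()
        assert (w[:, 0] >= w[:, 1]).all() and (w[:, 1] >= w[:, 2]).all()


class TestGridInvariants:
    @pytest.mark.parametrize(
        "tes, bs, msg",
        [
            ((100.0, 50.0), (0.0, 1000.0), "increasing"),
            ((50.0,), (0.0, 1000.0), "at least 2"),
            ((0.0, 50.0), (0.0, 1000.0), "positive"),
            ((50.0, 100.0), (-5.0, 1000.0), "non-negative"),
        ],
    )
    def test_bad_grids_rejected(self, tes, bs, msg):
        with pytest.raises(ValueError, match=msg):
            AcquisitionGrid(tes, bs)
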