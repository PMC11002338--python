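import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glymphdti.alps import (
    AlpsRoiSpec,
    SphereROI,
    alps_from_means,
    compute_alps,
    roi_mean,
    sphere_mask,
)
from glymphdti.synth import PhantomSpec, LesionSpec, build_phantom, phantom_roi_spec
from glymphdti.tensor import fit_tensor
from conftest import ALPS_SLABS


def centered_affine(shape, vox=2.0):
    aff = np.diag([vox, vox, vox, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * vox
    return aff


class TestSphereMask:
    def test_tiny_sphere_on_voxel_center_is_single_voxel(self):
        shape = (9, 9, 9)
        aff = centered_affine(shape)
        mask = sphere_mask((0, 0, 0), 1.0, shape, aff)
        assert mask.sum() == 1

    def test_5mm_sphere_on_2mm_grid_is_face_neighbourhood(self):
        # radius 2.5 mm: centre + 6 face neighbours at 2 mm; diagonals at
        # 2.83 mm are excluded (brute-force distance enumeration)
        shape = (9, 9, 9)
        aff = centered_affine(shape)
        mask = sphere_mask((0, 0, 0), 5.0, shape, aff)
        assert mask.sum() == 7
        # brute force check
        n = 0
        for i in range(9):
            for j in range(9):
                for k in range(9):
                    w = aff @ np.array([i, j, k, 1.0])
                    if np.linalg.norm(w[:3]) <= 2.5:
                        n += 1
                        assert mask[i, j, k]
        assert n == 7

    def test_translation_equivariance_by_one_voxel(self):
        shape = (11, 11, 11)
        aff = centered_affine(shape)
        a = sphere_mask((0, 0, 0), 5.0, shape, aff)
        b = sphere_mask((2.0, 0, 0), 5.0, shape, aff)
        assert np.array_equal(np.roll(a, 1, axis=0), b)

    def test_outside_grid_raises(self):
        with pytest.raises(ValueError, match="does not intersect"):
            sphere_mask((500, 0, 0), 5.0, (5, 5, 5), centered_affine((5, 5, 5)))


class TestRoiMean:
    def test_constant_map(self):
        roi = np.zeros((4, 4, 4), dtype=bool)
        roi[1:3, 1:3, 1:3] = True
        mu, n_used, n_excl = roi_mean(np.full((4, 4, 4), 1.2e-3), roi)
        assert mu == pytest.approx(1.2e-3)
        assert (n_used, n_excl) == (8, 0)

    def test_lesioned_half_excluded(self):
        vals = np.full((4, 4, 4), 1.0)
        roi = np.zeros_like(vals, dtype=bool)
        roi[0, 0, :4] = True
        lesion = np.zeros_like(roi)
        lesion[0, 0, :2] = True
        vals[lesion] = 99.0
        mu, n_used, n_excl = roi_mean(vals, roi, lesion)
        assert mu == 1.0 and n_used == 2 and n_excl == 2

    def test_matches_hand_loop(self, rng):
        vals = rng.random((5, 5, 5))
        roi = rng.random((5, 5, 5)) > 0.5
        lesion = rng.random((5, 5, 5)) > 0.8
        if not (roi & ~lesion).any():
            roi[0, 0, 0], lesion[0, 0, 0] = True, False
        acc = [vals[i] for i in np.ndindex(5, 5, 5) if roi[i] and not lesion[i]]
        mu, n_used, _ = roi_mean(vals, roi, lesion)
        assert mu == pytest.approx(np.mean(acc), rel=1e-12)
        assert n_used == len(acc)

    def test_fully_excluded_names_roi(self):
        roi = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="dxx_proj_left"):
            roi_mean(np.zeros((3, 3, 3)), roi, roi, label="dxx_proj_left")


class TestAlpsFromMeans:
    def test_reference_ratios(self):
        assert alps_from_means(1.2e-3, 1.2e-3, 0.6e-3, 0.6e-3) == pytest.approx(2.0)
        assert alps_from_means(1e-3, 1e-3, 1e-3, 1e-3) == pytest.approx(1.0)
        assert alps_from_means(1.0e-3, 1.4e-3, 0.8e-3, 0.4e-3) == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            alps_from_means(1e-3, 0.0, 1e-3, 1e-3)

    @given(
        d=st.tuples(*[st.floats(1e-4, 3e-3)] * 4),
        c=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_uniform_scaling(self, d, c):
        a = alps_from_means(*d)
        b = alps_from_means(*(c * x for x in d))
        assert a == pytest.approx(b, rel=1e-9)


@pytest.fixture(scope="module")
def slab_phantom():
    spec = PhantomSpec(shape=(24, 24, 10), noise_model="none",
                       proj_f=0.0, assoc_f=0.0, background_f=0.0, **ALPS_SLABS)
    dwi, truth = build_phantom(spec)
    return spec, fit_tensor(dwi), truth


class TestComputeAlps:
    def test_anisotropic_slabs_give_two(self, slab_phantom):
        spec, tm, truth = slab_phantom
        res = compute_alps(tm, phantom_roi_spec(spec), truth.lesion_mask.data)
        assert res.left == pytest.approx(2.0, abs=1e-6)
        assert res.right == pytest.approx(2.0, abs=1e-6)
        assert res.mean == pytest.approx(2.0, abs=1e-6)

    def test_mean_is_average_of_sides(self, slab_phantom):
        spec, tm, truth = slab_phantom
        res = compute_alps(tm, phantom_roi_spec(spec))
        assert res.mean == (res.left + res.right) / 2.0

    def test_isotropic_phantom_gives_one(self):
        spec = PhantomSpec(shape=(24, 24, 10), noise_model="none",
                           proj_evals=(0.8e-3,) * 3, assoc_evals=(0.8e-3,) * 3,
                           proj_f=0.0, assoc_f=0.0, background_f=0.0)
        dwi, _ = build_phantom(spec)
        res = compute_alps(fit_tensor(dwi), phantom_roi_spec(spec))
        assert res.mean == pytest.approx(1.0, abs=1e-6)

    def test_lesion_exclusion_leaves_result_unchanged(self):
        base = dict(shape=(24, 24, 10), noise_model="none",
                    proj_f=0.0, assoc_f=0.0, background_f=0.0, **ALPS_SLABS)
        clean_spec = PhantomSpec(**base)
        rois = phantom_roi_spec(clean_spec)
        # lesion centred on one voxel of the proj_left ROI (voxel centres sit
        # at odd world coordinates on this grid)
        lesion_center = tuple(c + d for c, d in zip(rois.proj_left.center_mm, (-1, -1, -1)))
        lesioned_spec = PhantomSpec(
            lesions=(LesionSpec(center_mm=lesion_center, radius_mm=1.0,
                                diffusivity=2.4e-3, f=0.8),),
            **base,
        )
        clean_dwi, _ = build_phantom(clean_spec)
        les_dwi, les_truth = build_phantom(lesioned_spec)
        res_clean = compute_alps(fit_tensor(clean_dwi), rois)
        res_les = compute_alps(fit_tensor(les_dwi), rois, les_truth.lesion_mask.data)
        assert res_les.left == pytest.approx(res_clean.left, rel=1e-12)
        assert res_les.mean == pytest.approx(res_clean.mean, rel=1e-12)
        assert any(n_excl > 0 for (_, n_excl) in res_les.counts.values())

    def test_scaling_all_maps_leaves_index_unchanged(self, slab_phantom):
        spec, tm, _ = slab_phantom
        res1 = compute_alps(tm, phantom_roi_spec(spec))

        class Scaled:
            dxx = tm.dxx * 3.7
            dyy = tm.dyy * 3.7
            dzz = tm.dzz * 3.7
            affine = tm.affine

        res2 = compute_alps(Scaled, phantom_roi_spec(spec))
        assert res2.mean == pytest.approx(res1.mean, rel=1e-12)


def test_roi_spec_requires_distinct_centers():
    s = SphereROI((0.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="distinct"):
        AlpsRoiSpec(proj_left=s, proj_right=s, assoc_left=SphereROI((1, 0, 0)),
                    assoc_right=SphereROI((2, 0, 0)))
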