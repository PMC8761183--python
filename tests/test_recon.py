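"""OSEM/MLEM and BSREM reconstruction behaviour on small problems."""

import numpy as np
import pytest

from petquant.grid import ActivityImage, VoxelGrid
from petquant.phantom import Cylinder, CompartmentSpec, PhantomSpec, build_phantom, fractional_occupancy
from petquant.projector import Projector, forward_project, sample_counts
from petquant.recon import (
    ReconParams,
    bsrem_reconstruct,
    mlem_reconstruct,
    osem_reconstruct,
    poisson_log_likelihood,
    rdp_gradient,
    rdp_penalty,
)


@pytest.fixture(scope="module")
def cylinder_setup(small_grid, uniform_cylinder, small_projector):
    noiseless = forward_project(small_projector, uniform_cylinder, duration=150.0)
    noisy = sample_counts(noiseless, seed=11)
    interior = (
        fractional_occupancy(
            small_grid, Cylinder((0, 0, 0), (28, 28), small_grid.extent[2])
        )
        > 0.99
    )
    return noiseless, noisy, interior


class TestOsem:
    def test_mlem_converges_on_consistent_data(self, cylinder_setup, small_projector, uniform_cylinder):
        noiseless, _, interior = cylinder_setup
        rec = mlem_reconstruct(noiseless, small_projector, iterations=200)
        err = np.abs(rec.values[interior] - 1.8) / 1.8
        assert err.max() < 0.01

    def test_log_likelihood_monotone_in_iterations(self, cylinder_setup, small_projector):
        noiseless, _, _ = cylinder_setup
        lls = [
            poisson_log_likelihood(
                noiseless, small_projector, mlem_reconstruct(noiseless, small_projector, i).values
            )
            for i in (1, 2, 4, 8, 16)
        ]
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(lls, lls[1:]))

    def test_count_conservation_after_full_iteration(self, cylinder_setup, small_projector):
        _, noisy, _ = cylinder_setup
        for iters in (1, 3):
            rec = mlem_reconstruct(noisy, small_projector, iterations=iters)
            refit = forward_project(
                small_projector, rec, duration=noisy.duration, sensitivity=noisy.sensitivity
            )
            assert refit.total_counts == pytest.approx(noisy.total_counts, rel=1e-6)

    def test_truth_is_an_exact_fixed_point_of_consistent_data(
        self, cylinder_setup, small_projector, uniform_cylinder
    ):
        # counts generated from the truth itself: the EM ratio is 1 everywhere
        # data exist, so one update leaves the truth unchanged to round-off
        noiseless, _, _ = cylinder_setup
        x2 = mlem_reconstruct(
            noiseless, small_projector, iterations=1, initial=uniform_cylinder
        )
        np.testing.assert_allclose(
            x2.values, uniform_cylinder.values, atol=1e-9 * uniform_cylinder.values.max()
        )

    def test_nonnegativity_and_subset_equivalence_scale(self, cylinder_setup, small_projector):
        _, noisy, _ = cylinder_setup
        rec = osem_reconstruct(noisy, small_projector, subsets=16, iterations=2)
        assert rec.values.min() >= 0.0
        assert rec.values.max() > 0.0

    def test_noise_amplifies_with_iterations(self, cylinder_setup, small_projector):
        _, noisy, interior = cylinder_setup
        sds = [
            osem_reconstruct(noisy, small_projector, subsets=16, iterations=i).values[interior].std()
            for i in (2, 5, 10, 25)
        ]
        assert all(b >= a for a, b in zip(sds, sds[1:]))


class TestRdp:
    def test_uniform_image_has_zero_penalty_and_gradient(self, small_grid):
        img = ActivityImage(grid=small_grid, values=np.full(small_grid.shape, 3.3))
        assert rdp_penalty(img, gamma=2.0) == 0.0
        np.testing.assert_array_equal(rdp_gradient(img, gamma=2.0), 0.0)

    def test_scaling_is_nearly_homogeneous_of_degree_one(self):
        g = VoxelGrid.centered((8, 8, 8))
        rng = np.random.default_rng(5)
        x = rng.random(g.shape) + 0.5
        img = ActivityImage(grid=g, values=x)
        img_scaled = ActivityImage(grid=g, values=7.0 * x)
        r1 = rdp_penalty(img, gamma=2.0)
        r7 = rdp_penalty(img_scaled, gamma=2.0)
        assert r7 == pytest.approx(7.0 * r1, rel=1e-6)

    def test_gradient_matches_finite_differences(self):
        g = VoxelGrid.centered((6, 6, 6))
        rng = np.random.default_rng(6)
        x = rng.random(g.shape) + 0.5
        img = ActivityImage(grid=g, values=x)
        grad = rdp_gradient(img, gamma=2.0)
        eps = 1e-6
        idx_list = [(0, 0, 0), (3, 2, 4), (5, 5, 5), (2, 3, 1)]
        for idx in idx_list:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            fd = (
                rdp_penalty(ActivityImage(grid=g, values=xp), 2.0)
                - rdp_penalty(ActivityImage(grid=g, values=xm), 2.0)
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_penalty_nonnegative(self):
        g = VoxelGrid.centered((8, 8, 8))
        rng = np.random.default_rng(7)
        img = ActivityImage(grid=g, values=rng.random(g.shape))
        assert rdp_penalty(img, 2.0) >= 0.0


class TestBsrem:
    def test_beta_zero_single_subset_reduces_to_mlem(self, cylinder_setup, small_projector):
        _, noisy, _ = cylinder_setup
        params = ReconParams(
            algorithm="BSREM", subsets=1, iterations=10, beta=0.0, relaxation_decay=0.0
        )
        b = bsrem_reconstruct(noisy, small_projector, params)
        m = mlem_reconstruct(noisy, small_projector, iterations=10)
        np.testing.assert_allclose(b.values, m.values, atol=1e-6 * m.values.max())

    def test_smoothing_strictly_monotone_in_beta(self, cylinder_setup, small_projector):
        _, noisy, interior = cylinder_setup
        sds = []
        for beta in (0.0, 50.0, 200.0, 800.0):
            params = ReconParams(algorithm="BSREM", subsets=16, iterations=15, beta=beta, psf_fwhm=0.0)
            rec = bsrem_reconstruct(noisy, small_projector, params)
            sds.append(rec.values[interior].std())
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_penalized_objective_stable_over_final_iterations(self, cylinder_setup, small_projector):
        noiseless, _, _ = cylinder_setup
        params = ReconParams(algorithm="BSREM", subsets=8, iterations=12, beta=200.0, psf_fwhm=0.0)
        # would raise ReconDivergenceError on 3 consecutive objective drops
        rec = bsrem_reconstruct(noiseless, small_projector, params)
        assert rec.values.min() >= 0.0

    def test_wrong_algorithm_rejected(self, cylinder_setup, small_projector):
        _, noisy, _ = cylinder_setup
        with pytest.raises(ValueError):
            bsrem_reconstruct(noisy, small_projector, ReconParams(algorithm="OSEM"))


class TestReconParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ReconParams(algorithm="FBP")
        with pytest.raises(ValueError):
            ReconParams(subsets=0)
        with pytest.raises(ValueError):
            ReconParams(beta=-1.0)

    def test_labels_distinguish_settings(self):
        a = ReconParams(subsets=24, iterations=2)
        b = ReconParams(algorithm="BSREM", subsets=32, iterations=25, beta=300)
        assert a.label != b.label
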