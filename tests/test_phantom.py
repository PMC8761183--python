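"""Phantom construction: grids, sphere rasterization, compositing, decay."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petquant.grid import ActivityImage, VoxelGrid
from petquant.isotopes import F18, NA22, STABLE, decay_factor, get_isotope
from petquant.phantom import (
    Box,
    CompartmentSpec,
    Cylinder,
    Ellipsoid,
    LesionSpec,
    PhantomSpec,
    Sphere,
    build_phantom,
    fractional_occupancy,
    rasterize_sphere,
    sphere_volume_ml,
)
from petquant.probeiq import COMPARTMENT_TABLE, liver_lung_section, probe_iq_pelvis


class TestVoxelGrid:
    def test_world_index_round_trip_is_bijective(self):
        g = VoxelGrid.centered((10, 12, 8), (3.65, 3.65, 3.27))
        idx = np.array([[0, 0, 0], [9, 11, 7], [3, 5, 2]])
        back = g.world_to_index(g.index_to_world(idx))
        np.testing.assert_allclose(back, idx, atol=1e-12)

    def test_voxel_volume_and_validation(self):
        g = VoxelGrid((4, 4, 4), (3.65, 3.65, 3.27))
        assert g.voxel_volume == pytest.approx(3.65 * 3.65 * 3.27 / 1000.0)
        with pytest.raises(ValueError):
            VoxelGrid((0, 4, 4))
        with pytest.raises(ValueError):
            VoxelGrid((4, 4, 4), (1.0, -1.0, 1.0))


class TestRasterizeSphere:
    def test_total_volume_matches_closed_form(self, small_grid):
        f = rasterize_sphere(small_grid, (0.0, 0.0, 0.0), 10.0)
        vol = f.sum() * small_grid.voxel_volume
        assert vol == pytest.approx(0.5236, rel=5e-3)

    @pytest.mark.parametrize("diameter", [3.0, 5.0, 8.0, 16.0])
    def test_conservation_any_alignment(self, diameter):
        g = VoxelGrid.centered((24, 24, 16))
        rng = np.random.default_rng(3)
        for _ in range(3):
            c = rng.uniform(-2, 2, 3)
            vol = rasterize_sphere(g, c, diameter).sum() * g.voxel_volume
            assert vol == pytest.approx(sphere_volume_ml(diameter), rel=5e-3)

    def test_fully_contained_voxel_has_fraction_one(self):
        g = VoxelGrid.centered((16, 16, 16), (2.0, 2.0, 2.0))
        f = rasterize_sphere(g, g.index_to_world((8, 8, 8)), 10.0)
        assert f[8, 8, 8] == 1.0

    def test_matches_brute_force_supersampling_per_voxel(self):
        # independent oracle: 64x finer uniform subcell counting
        g = VoxelGrid.centered((8, 8, 8), (2.0, 2.0, 2.0))
        center, diam = np.array([0.3, -0.4, 0.2]), 6.0
        f = rasterize_sphere(g, center, diam)
        n = 64
        off = (np.arange(n) + 0.5) / n - 0.5
        xs, ys, zs = g.voxel_centers()
        brute = np.zeros(g.shape)
        for i in range(g.shape[0]):
            for j in range(g.shape[1]):
                for k in range(g.shape[2]):
                    px = xs[i, j, k] + off * 2.0
                    inside = (
                        (px[:, None, None] - center[0]) ** 2
                        + (ys[i, j, k] + off[None, :, None] * 2.0 - center[1]) ** 2
                        + (zs[i, j, k] + off[None, None, :] * 2.0 - center[2]) ** 2
                    ) <= (diam / 2) ** 2
                    brute[i, j, k] = inside.mean()
        assert np.abs(f - brute).max() < 0.02

    def test_sphere_outside_grid_raises(self, small_grid):
        with pytest.raises(ValueError):
            rasterize_sphere(small_grid, (500.0, 0.0, 0.0), 6.0)


class TestBuildPhantom:
    def test_liver_voxel_matches_design_concentration(self):
        spec = liver_lung_section()
        img = build_phantom(spec, time=0.0)
        liver_center = spec.compartments[1].geometry.center
        assert img.values[img.grid.world_to_nearest_voxel(liver_center)] == pytest.approx(9.9)

    def test_lesion_interior_voxel_keeps_cast_concentration(self):
        spec = probe_iq_pelvis()
        img = build_phantom(spec, time=0.0)
        les = spec.lesion("les_16mm")
        assert img.values[img.grid.world_to_nearest_voxel(les.center)] == pytest.approx(57.6)

    def test_dual_isotope_decay_over_one_half_life(self, small_grid):
        les_center = tuple(small_grid.index_to_world((16, 16, 4)))  # exact voxel centre
        spec = PhantomSpec(
            grid=small_grid,
            compartments=[
                CompartmentSpec("b", Cylinder((0, 0, 0), (45, 45), small_grid.extent[2]), 1.8, F18)
            ],
            lesions=[LesionSpec("l", les_center, 10.0, 57.6, NA22)],
        )
        img0 = build_phantom(spec, 0.0)
        img1 = build_phantom(spec, 109.7)
        bkg_vox = img0.grid.world_to_nearest_voxel((30.0, 0.0, 0.0))
        les_vox = img0.grid.world_to_nearest_voxel(les_center)
        assert img1.values[bkg_vox] == pytest.approx(0.5 * img0.values[bkg_vox], rel=1e-12)
        na22_factor = 2.0 ** (-109.7 / NA22.half_life)
        assert img1.values[les_vox] == pytest.approx(img0.values[les_vox] * na22_factor, rel=1e-9)
        assert na22_factor == pytest.approx(0.99994, abs=5e-5)

    def test_mass_conservation_against_analytic_composition(self, small_grid):
        bkg, lesion_conc = 2.0, 30.0
        # box faces on voxel centres so the 4x4x4 face fraction (0.5) is exact
        size = tuple(n_vox * s for n_vox, s in zip((29, 29, 7), small_grid.spacing))
        body = Box(center=(0, 0, 0), size=size)
        spec = PhantomSpec(
            grid=small_grid,
            compartments=[CompartmentSpec("b", body, bkg)],
            lesions=[LesionSpec("l", (5.0, -5.0, 0.0), 12.0, lesion_conc)],
        )
        img = build_phantom(spec)
        v_les = sphere_volume_ml(12.0)
        expected = body.volume_ml * bkg + v_les * (lesion_conc - bkg)
        assert img.total_activity == pytest.approx(expected, rel=5e-3)

    def test_shell_less_compositing_never_dips_below_background(self, small_grid):
        spec = PhantomSpec(
            grid=small_grid,
            compartments=[
                CompartmentSpec("b", Box((0, 0, 0), tuple(small_grid.extent)), 1.8)
            ],
            lesions=[LesionSpec("l", (3.0, 2.0, -1.0), 8.0, 57.6)],
        )
        img = build_phantom(spec)
        assert img.values.min() >= 1.8 - 1e-12

    def test_monotone_lesion_to_background_contrast(self, small_grid):
        spec = PhantomSpec(
            grid=small_grid,
            compartments=[
                CompartmentSpec("b", Box((0, 0, 0), tuple(small_grid.extent)), 4.41, F18)
            ],
            lesions=[LesionSpec("l", (0, 0, 0), 10.0, 57.6, NA22)],
        )
        les_vox = small_grid.world_to_nearest_voxel((0.0, 0.0, 0.0))
        bkg_vox = small_grid.world_to_nearest_voxel((30.0, 30.0, 0.0))
        ratios = []
        for t in (0.0, 60.0, 200.0, 400.0):
            img = build_phantom(spec, t)
            ratios.append(img.values[les_vox] / img.values[bkg_vox])
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_lesion_outside_compartments_raises(self, small_grid):
        spec = PhantomSpec(
            grid=small_grid,
            compartments=[CompartmentSpec("b", Sphere((0, 0, 0), 20.0), 1.0)],
            lesions=[LesionSpec("l", (25.0, 25.0, 0.0), 6.0, 10.0)],
        )
        with pytest.raises(ValueError, match="lesion"):
            build_phantom(spec)

    def test_duplicate_lesion_ids_rejected(self, small_grid):
        les = LesionSpec("dup", (0, 0, 0), 5.0, 10.0)
        with pytest.raises(ValueError):
            PhantomSpec(
                grid=small_grid,
                compartments=[CompartmentSpec("b", Sphere((0, 0, 0), 40.0), 1.0)],
                lesions=[les, les],
            )


class TestDesignTables:
    def test_compartment_volumes_within_ten_percent(self):
        for factory in (lambda: probe_iq_pelvis(lesions=[]), liver_lung_section):
            spec = factory()
            for comp in spec.compartments:
                target = COMPARTMENT_TABLE[comp.name][0]
                measured = (
                    fractional_occupancy(spec.grid, comp.geometry).sum()
                    * spec.grid.voxel_volume
                )
                # body compartments include nested organs painted over later
                if comp.name in ("pelvis", "thorax"):
                    nested = sum(
                        COMPARTMENT_TABLE[c.name][0]
                        for c in spec.compartments
                        if c.name != comp.name
                    )
                    measured -= nested
                assert measured == pytest.approx(target, rel=0.10), comp.name

    def test_relative_concentrations_recompute_from_design(self):
        bkg = COMPARTMENT_TABLE["pelvis"][1]
        for name, (_, conc, rel) in COMPARTMENT_TABLE.items():
            assert conc / bkg == pytest.approx(rel, rel=0.05), name


class TestIsotopes:
    @pytest.mark.parametrize(
        "dt,expected", [(109.7, 0.5), (0.0, 1.0), (219.4, 0.25), (-109.7, 2.0)]
    )
    def test_f18_decay_factors(self, dt, expected):
        assert decay_factor(F18, dt) == pytest.approx(expected, rel=1e-12)

    def test_half_life_invariant(self):
        for iso in (F18, NA22):
            assert decay_factor(iso, iso.half_life) == pytest.approx(0.5, abs=1e-12)

    @given(st.floats(min_value=-500, max_value=500), st.floats(min_value=-500, max_value=500))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_decay_composes_multiplicatively(self, t1, t2):
        assert decay_factor(F18, t1 + t2) == pytest.approx(
            decay_factor(F18, t1) * decay_factor(F18, t2), rel=1e-9
        )

    def test_isotope_lookup(self):
        assert get_isotope("18F") is F18
        assert get_isotope("Na-22") is NA22
        with pytest.raises(KeyError):
            get_isotope("Tc-99m")

    def test_stable_isotope_never_decays(self):
        assert decay_factor(STABLE, 1e9) == 1.0
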