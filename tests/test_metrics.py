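"""Volumes, histograms, conformity/gradient indices, iso-surfaces."""

import numpy as np
import pytest

from bed3d.dose import GridSpec
from bed3d.errors import (
    EmptyMeshError,
    ShapeMismatchError,
    UndefinedMetricError,
)
from bed3d.metrics import (
    StructureMask,
    dvh,
    extract_isosurface,
    gradient_index,
    isolevel_volume,
    mask_volume,
    paddick_ci,
    percent_volume_at,
)
from bed3d.synth import gen_ellipsoid_mask


def gaussian_field(spec: GridSpec, center, fwhm: float, peak: float = 10.0):
    """Isotropic Gaussian dose field with the given FWHM."""
    w = fwhm / (2.0 * np.sqrt(np.log(2.0)))
    c = spec.coords()
    r2 = ((c - center[0])[:, None, None] ** 2
          + (c - center[1])[None, :, None] ** 2
          + (c - center[2])[None, None, :] ** 2)
    return peak * np.exp(-r2 / w**2)


SPEC = GridSpec(n_per_axis=40, spacing=1.0)
CENTER = (20.0, 20.0, 20.0)


class TestMaskVolume:
    def test_counts_voxels(self):
        vox = np.zeros(SPEC.shape, dtype=bool)
        vox.flat[:10] = True
        assert mask_volume(StructureMask(SPEC, vox)) == 10.0

    def test_sphere_volume(self):
        m = gen_ellipsoid_mask(CENTER, (10.0,) * 3, SPEC)
        assert mask_volume(m) == pytest.approx(4188.79, rel=0.02)

    def test_ellipsoid_volume(self):
        m = gen_ellipsoid_mask(CENTER, (10.0, 8.0, 6.0), SPEC)
        assert mask_volume(m) == pytest.approx(4.0 / 3.0 * np.pi * 480.0,
                                               rel=0.02)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            v = mask_volume(StructureMask(SPEC, np.zeros(SPEC.shape, bool)))
        assert v == 0.0


class TestDvh:
    def test_uniform_field(self):
        field = np.full(SPEC.shape, 10.0)
        m = gen_ellipsoid_mask(CENTER, (5.0,) * 3, SPEC)
        h = dvh(_as_grid(field), m, bin_width=1.0)
        vol = mask_volume(m)
        k = int(np.nonzero(h.differential_volume)[0][0])
        assert h.bin_edges[k] == 10.0
        assert h.differential_volume[k] == vol
        assert h.differential_volume.sum() == vol
        # cumulative: full volume at or below the 10 Gy edge, 0 above
        assert np.all(h.cumulative_volume[h.bin_edges <= 10.0] == vol)
        assert np.all(h.cumulative_volume[h.bin_edges > 10.0] == 0.0)

    def test_conservation_and_monotonicity_random_fields(self):
        rng = np.random.default_rng(17)
        m = gen_ellipsoid_mask(CENTER, (8.0, 6.0, 7.0), SPEC)
        for _ in range(5):
            field = rng.gamma(2.0, 3.0, SPEC.shape)
            h = dvh(_as_grid(field), m, bin_width=0.5)
            assert h.differential_volume.sum() == pytest.approx(
                mask_volume(m), abs=1e-6)
            assert np.all(np.diff(h.cumulative_volume) <= 0)
            assert h.cumulative_volume[0] == pytest.approx(mask_volume(m))

    def test_linear_ramp_median(self):
        # ramp 0 -> 20 Gy along x inside a box mask
        c = SPEC.coords()
        field = np.broadcast_to(
            (20.0 * (c - 1.0) / (SPEC.n_per_axis - 1.0))[:, None, None],
            SPEC.shape).copy()
        m = StructureMask(SPEC, np.ones(SPEC.shape, bool))
        h = dvh(_as_grid(field), m, bin_width=1.0)
        total = h.cumulative_volume[0]
        # median: edge where cumulative crosses half the volume
        k = int(np.argmax(h.cumulative_volume <= total / 2.0))
        assert h.bin_edges[k] == pytest.approx(10.0, abs=1.0)

    def test_shape_mismatch(self):
        m = gen_ellipsoid_mask(CENTER, (5.0,) * 3, SPEC)
        with pytest.raises(ShapeMismatchError):
            dvh(_as_grid(np.zeros((10, 10, 10))), m)


class TestIsolevelVolume:
    def test_level_above_max_is_zero(self):
        f = gaussian_field(SPEC, CENTER, fwhm=8.0)
        assert isolevel_volume(_as_grid(f), 11.0) == 0.0

    def test_halfmax_sphere_volume(self):
        spec = GridSpec(n_per_axis=120, spacing=0.25)
        f = gaussian_field(spec, (15.0,) * 3, fwhm=8.0)
        r50 = 4.0
        assert isolevel_volume(_as_grid(f, spec), 5.0) == pytest.approx(
            4.0 / 3.0 * np.pi * r50**3, rel=0.03)

    def test_quarter_to_half_volume_ratio(self):
        spec = GridSpec(n_per_axis=120, spacing=0.25)
        f = gaussian_field(spec, (15.0,) * 3, fwhm=8.0)
        ratio = (isolevel_volume(_as_grid(f, spec), 2.5)
                 / isolevel_volume(_as_grid(f, spec), 5.0))
        assert ratio == pytest.approx(2.0**1.5, rel=0.05)


class TestPaddickCI:
    def test_perfect_conformity(self):
        m = gen_ellipsoid_mask(CENTER, (6.0,) * 3, SPEC)
        field = np.where(m.voxels, 20.0, 1.0)
        assert paddick_ci(_as_grid(field), m, 10.0) == 1.0

    def test_target_inside_double_piv(self):
        # PIV covers the mask plus as much again: CI = TV/PIV = 0.5
        m = gen_ellipsoid_mask(CENTER, (6.0,) * 3, SPEC)
        piv = gen_ellipsoid_mask(CENTER, (6.0,) * 3, SPEC).voxels
        extra = int(piv.sum())
        flat = np.where(piv.ravel())[0]
        out = np.where(~piv.ravel())[0][:extra]
        field = np.zeros(SPEC.shape).ravel()
        field[flat] = 20.0
        field[out] = 20.0
        field = field.reshape(SPEC.shape)
        assert paddick_ci(_as_grid(field), m, 10.0) == pytest.approx(0.5)

    def test_disjoint_is_zero(self):
        m = gen_ellipsoid_mask((10.0,) * 3, (4.0,) * 3, SPEC)
        field = np.zeros(SPEC.shape)
        field[30:35, 30:35, 30:35] = 20.0
        assert paddick_ci(_as_grid(field), m, 10.0) == 0.0

    def test_empty_piv_raises(self):
        m = gen_ellipsoid_mask(CENTER, (4.0,) * 3, SPEC)
        with pytest.raises(UndefinedMetricError):
            paddick_ci(_as_grid(np.zeros(SPEC.shape)), m, 10.0)


class TestGradientIndex:
    def test_gaussian_value(self):
        spec = GridSpec(n_per_axis=120, spacing=0.25)
        f = gaussian_field(spec, (15.0,) * 3, fwhm=8.0)
        assert gradient_index(_as_grid(f, spec), 5.0) == pytest.approx(
            2.0**1.5, rel=0.05)

    def test_steeper_falloff_smaller_gi(self):
        spec = GridSpec(n_per_axis=120, spacing=0.25)
        sharp = gaussian_field(spec, (15.0,) * 3, fwhm=6.0)
        broad = gaussian_field(spec, (15.0,) * 3, fwhm=10.0)
        # GI of a pure Gaussian is scale-free; compare against a flatter,
        # non-Gaussian composite which must spread more
        composite = 0.5 * broad + 0.5 * gaussian_field(spec, (15.0,) * 3,
                                                       fwhm=16.0, peak=2.0)
        gi_sharp = gradient_index(_as_grid(sharp, spec), sharp.max() / 2.0)
        gi_comp = gradient_index(_as_grid(composite, spec),
                                 composite.max() / 2.0)
        assert gi_sharp < gi_comp

    def test_empty_prescription_volume(self):
        with pytest.raises(UndefinedMetricError):
            gradient_index(_as_grid(np.zeros(SPEC.shape)), 5.0)

    def test_stability_under_refinement(self):
        center = (30.0, 30.0, 30.0)
        coarse = GridSpec(n_per_axis=60, spacing=1.0)
        fine = GridSpec(n_per_axis=120, spacing=0.5)
        fc = gaussian_field(coarse, center, fwhm=14.0)
        ff = gaussian_field(fine, center, fwhm=14.0)
        gc = gradient_index(_as_grid(fc, coarse), 5.0)
        gf = gradient_index(_as_grid(ff, fine), 5.0)
        assert abs(gc - gf) / gf < 0.03
        m_c = gen_ellipsoid_mask(center, (7.0,) * 3, coarse)
        m_f = gen_ellipsoid_mask(center, (7.0,) * 3, fine)
        cc = paddick_ci(_as_grid(fc, coarse), m_c, 5.0)
        cf = paddick_ci(_as_grid(ff, fine), m_f, 5.0)
        assert abs(cc - cf) / cf < 0.03


class TestPercentVolume:
    def test_trivial_levels(self):
        m = gen_ellipsoid_mask(CENTER, (6.0,) * 3, SPEC)
        f = gaussian_field(SPEC, CENTER, fwhm=8.0)
        assert percent_volume_at(_as_grid(f), m, 1e-9) == 100.0
        assert percent_volume_at(_as_grid(f), m, 99.0) == 0.0

    def test_half_ramp(self):
        c = SPEC.coords()
        field = np.broadcast_to(
            (20.0 * (c - 1.0) / (SPEC.n_per_axis - 1.0))[:, None, None],
            SPEC.shape).copy()
        m = StructureMask(SPEC, np.ones(SPEC.shape, bool))
        assert percent_volume_at(_as_grid(field), m, 10.0) == pytest.approx(
            50.0, abs=3.0)


class TestIsoSurface:
    def test_sphere_vertex_radii(self):
        spec = GridSpec(n_per_axis=60, spacing=1.0)
        f = gaussian_field(spec, (30.0,) * 3, fwhm=10.0)
        mesh = extract_isosurface(_as_grid(f, spec), 5.0)
        radii = np.linalg.norm(mesh.vertices - 30.0, axis=1)
        assert np.all(np.abs(radii - 5.0) < 0.6)

    def test_enclosed_volume_matches_isolevel_volume(self):
        spec = GridSpec(n_per_axis=120, spacing=0.25)
        f = gaussian_field(spec, (15.0,) * 3, fwhm=8.0)
        mesh = extract_isosurface(_as_grid(f, spec), 5.0)
        assert mesh.enclosed_volume() == pytest.approx(
            isolevel_volume(_as_grid(f, spec), 5.0), rel=0.05)

    def test_level_out_of_range(self):
        f = gaussian_field(SPEC, CENTER, fwhm=8.0)
        with pytest.raises(EmptyMeshError):
            extract_isosurface(_as_grid(f), 11.0)

    def test_vertices_inside_grid(self):
        f = gaussian_field(SPEC, CENTER, fwhm=8.0)
        mesh = extract_isosurface(_as_grid(f), 5.0)
        c = SPEC.coords()
        assert mesh.vertices.min() >= c[0] - 1e-9
        assert mesh.vertices.max() <= c[-1] + 1e-9
        assert mesh.faces.max() < len(mesh.vertices)


def _as_grid(values, spec: GridSpec = SPEC):
    """Wrap a bare field so metric calls read naturally in the tests."""
    from bed3d.dose import DoseGrid

    return DoseGrid(spec=spec, values=np.asarray(values, float))
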