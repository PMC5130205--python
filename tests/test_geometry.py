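"""Section geometry: raster properties against analytic closed forms."""

import numpy as np
import pytest

import limbstruct as ls
from limbstruct.geometry import SectionGeometryError

from conftest import ELLIPSE_GRID, PROPERTY_KEYS, at_resolution


def rel_err(a, b):
    return abs(a - b) / abs(b)


DISC_RADIUS = 10.0


@pytest.fixture(scope="module")
def disc_props():
    mask = ls.render_section(
        ls.EllipseSectionSpec(DISC_RADIUS, DISC_RADIUS, pixel_size=0.05)
    )
    return ls.compute_section_properties(mask)


class TestSolidDisc:
    """A solid circular disc has textbook closed forms."""

    r = DISC_RADIUS

    def test_areas(self, disc_props):
        props = disc_props
        area = np.pi * self.r**2
        assert rel_err(props.TA, area) < 1e-3
        assert props.CA == props.TA
        assert props.pctCA == 100.0

    def test_second_moments(self, disc_props):
        props = disc_props
        i = np.pi * self.r**4 / 4
        assert rel_err(props.Ix, i) < 1e-3
        assert rel_err(props.Iy, i) < 1e-3
        assert rel_err(props.J, 2 * i) < 1e-3

    def test_section_moduli(self, disc_props):
        props = disc_props
        z = np.pi * self.r**3 / 4
        assert rel_err(props.Zx, z) < 0.01
        assert rel_err(props.Zy, z) < 0.01
        assert rel_err(props.Zp, 2 * z) < 0.01


def test_hollow_ellipse_reference_values(hollow_ellipse_mask):
    """Centered hollow ellipse (outer 15x10, inner 9x6 mm) against the
    hollow-ellipse closed forms TA = pi*ao*bo, Ix = pi/4*(ao*bo^3 - ai*bi^3),
    etc., each within 1%."""
    ao, bo, ai, bi = 15.0, 10.0, 9.0, 6.0
    expected = {
        "TA": np.pi * ao * bo,
        "CA": np.pi * (ao * bo - ai * bi),
        "Ix": np.pi / 4 * (ao * bo**3 - ai * bi**3),
        "Iy": np.pi / 4 * (bo * ao**3 - bi * ai**3),
    }
    expected["J"] = expected["Ix"] + expected["Iy"]
    expected["Zx"] = expected["Ix"] / bo
    expected["Zy"] = expected["Iy"] / ao
    expected["Zp"] = expected["J"] / ao
    props = ls.compute_section_properties(hollow_ellipse_mask)
    for key, val in expected.items():
        assert rel_err(getattr(props, key), val) < 0.01, key


def test_eccentric_canal_composite_oracle():
    """Eccentric-canal section agrees with the parallel-axis composite
    oracle within 1% at 0.05 mm pixels."""
    spec = ls.EllipseSectionSpec(12, 9, 6, 4, dx=1.5, dy=-1.0, pixel_size=0.05)
    oracle = ls.closed_form_properties(spec).to_dict()
    props = ls.compute_section_properties(ls.render_section(spec)).to_dict()
    for key in PROPERTY_KEYS:
        assert rel_err(props[key], oracle[key]) < 0.01, key


class TestFillPeriosteal:
    def make_annulus(self):
        return ls.render_section(
            ls.EllipseSectionSpec(10, 10, 6, 6, pixel_size=0.1)
        )

    def test_annulus_fills_to_disc(self):
        annulus = self.make_annulus()
        disc = ls.render_section(ls.EllipseSectionSpec(10, 10, pixel_size=0.1))
        filled = ls.fill_periosteal(annulus)
        assert filled.pixels.sum() == disc.pixels.sum()
        # cortical pixel set unchanged: every cortical pixel still foreground
        assert np.all(filled.pixels[annulus.pixels])

    def test_solid_disc_identity(self):
        disc = ls.render_section(ls.EllipseSectionSpec(10, 10, pixel_size=0.1))
        filled = ls.fill_periosteal(disc)
        assert np.array_equal(filled.pixels, disc.pixels)

    def test_disjoint_rings_error(self):
        ring = self.make_annulus().pixels
        two = np.zeros((ring.shape[0], 2 * ring.shape[1] + 10), dtype=bool)
        two[:, : ring.shape[1]] = ring
        two[:, -ring.shape[1]:] = ring
        mask = ls.SectionMask(two, pixel_size=0.1)
        with pytest.raises(SectionGeometryError, match="2 connected components"):
            ls.fill_periosteal(mask)

    def test_empty_mask_error(self):
        mask = ls.SectionMask(np.zeros((5, 5), dtype=bool), pixel_size=0.1)
        with pytest.raises(SectionGeometryError, match="no cortical"):
            ls.compute_section_properties(mask)


class TestPercentCorticalArea:
    @pytest.mark.parametrize(
        "ta, ca, expected",
        [
            (330.1, 197.6, 59.9),  # femur midshaft
            (479.5, 206.3, 43.0),  # femur distal
            (214.8, 112.9, 52.6),  # right humerus distal
            (208.5, 108.0, 51.8),  # left humerus proximal
            (100.0, 100.0, 100.0),  # fully solid section
        ],
    )
    def test_values(self, ta, ca, expected):
        assert round(ls.percent_cortical_area(ta, ca), 1) == expected

    @pytest.mark.parametrize("ta, ca", [(100.0, 150.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_invalid_inputs(self, ta, ca):
        with pytest.raises(SectionGeometryError):
            ls.percent_cortical_area(ta, ca)


@pytest.fixture(scope="module")
def eccentric_mask():
    return ls.render_section(
        ls.EllipseSectionSpec(12, 9, 6, 4, dx=1.5, dy=-1.0, pixel_size=0.05)
    )


class TestInvariants:

    def test_polar_and_principal_sums(self, eccentric_mask):
        mask = eccentric_mask
        p = ls.compute_section_properties(mask)
        assert p.J == p.Ix + p.Iy
        assert p.Imax + p.Imin == pytest.approx(p.Ix + p.Iy, rel=1e-12)
        assert p.Imax >= p.Imin
        for key in PROPERTY_KEYS:
            assert getattr(p, key) > 0

    def test_quarter_rotation_swaps_planes(self, eccentric_mask):
        mask = eccentric_mask
        p0 = ls.compute_section_properties(mask)
        rot = ls.SectionMask(np.rot90(mask.pixels), pixel_size=mask.pixel_size)
        p90 = ls.compute_section_properties(rot)
        for key in ("TA", "CA", "J", "Imax", "Imin", "Zp"):
            assert getattr(p90, key) == pytest.approx(getattr(p0, key), rel=1e-12)
        assert p90.Ix == pytest.approx(p0.Iy, rel=1e-12)
        assert p90.Iy == pytest.approx(p0.Ix, rel=1e-12)
        assert p90.Zx == pytest.approx(p0.Zy, rel=1e-12)
        assert p90.Zy == pytest.approx(p0.Zx, rel=1e-12)

    def test_arbitrary_rotation_near_invariance(self):
        base = ls.EllipseSectionSpec(14, 9, 8, 5, pixel_size=0.05)
        rot = ls.EllipseSectionSpec(14, 9, 8, 5, rotation_deg=37.0, pixel_size=0.05)
        p0 = ls.compute_section_properties(ls.render_section(base))
        p1 = ls.compute_section_properties(ls.render_section(rot))
        for key in ("TA", "CA", "J", "Imax", "Imin"):
            assert rel_err(getattr(p1, key), getattr(p0, key)) < 0.01, key

    def test_mirror_invariance(self, eccentric_mask):
        mask = eccentric_mask
        p0 = ls.compute_section_properties(mask)
        left = ls.SectionMask(
            mask.pixels[:, ::-1], pixel_size=mask.pixel_size, side="left"
        )
        p1 = ls.compute_section_properties(left)
        for key in PROPERTY_KEYS:
            assert getattr(p1, key) == pytest.approx(getattr(p0, key), rel=1e-12)

    def test_theta_tracks_spec_rotation(self):
        spec = ls.EllipseSectionSpec(14, 9, 8, 5, rotation_deg=30.0, pixel_size=0.05)
        p = ls.compute_section_properties(ls.render_section(spec))
        assert p.theta == pytest.approx(30.0, abs=0.2)


def test_convergence_with_pixel_refinement():
    """Halving the pixel size reduces the raster-vs-closed-form error for
    every property on a synthetic hollow ellipse."""
    spec_c = at_resolution(ELLIPSE_GRID[3], 0.1)
    spec_f = at_resolution(ELLIPSE_GRID[3], 0.05)
    oracle = ls.closed_form_properties(spec_c).to_dict()
    coarse = ls.compute_section_properties(ls.render_section(spec_c)).to_dict()
    fine = ls.compute_section_properties(ls.render_section(spec_f)).to_dict()
    for key in PROPERTY_KEYS:
        e_coarse = rel_err(coarse[key], oracle[key])
        e_fine = rel_err(fine[key], oracle[key])
        assert e_fine < e_coarse or e_coarse < 1e-5, key


class TestPropertiesFromStack:
    def test_singleton_matches_single_computation(self):
        mask = ls.render_section(ls.EllipseSectionSpec(10, 10, 6, 6, pixel_size=0.1))
        [(off, p)] = ls.properties_from_stack([mask], [0.0])
        assert off == 0.0
        assert p.TA == ls.compute_section_properties(mask).TA

    def test_identical_masks_constant(self):
        mask = ls.render_section(ls.EllipseSectionSpec(10, 10, 6, 6, pixel_size=0.1))
        out = ls.properties_from_stack([mask] * 3, [-1.0, 0.0, 1.0])
        tas = [p.TA for _, p in out]
        assert tas[0] == tas[1] == tas[2]
        assert [o for o, _ in out] == [-1.0, 0.0, 1.0]

    def test_shrinking_discs_monotone_ta(self):
        masks = [
            ls.render_section(ls.EllipseSectionSpec(r, r, pixel_size=0.1))
            for r in (10.0, 9.0, 8.0)
        ]
        out = ls.properties_from_stack(masks, [0.0, 1.0, 2.0])
        tas = [p.TA for _, p in out]
        assert tas[0] > tas[1] > tas[2]

    def test_length_mismatch_error(self):
        mask = ls.render_section(ls.EllipseSectionSpec(10, 10, pixel_size=0.2))
        with pytest.raises(SectionGeometryError, match="offsets"):
            ls.properties_from_stack([mask], [0.0, 1.0])
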