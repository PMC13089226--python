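"""CSM volume integration against closed-form solids, and soft-tissue rules."""

import math

import numpy as np
import pytest

from plesiomass.csm_volumetrics import (
    POINT,
    BodyModel,
    LimbPlanform,
    Slab,
    SoftTissueConfig,
    apply_soft_tissue,
    blend_contours,
    body_mass,
    contour_area,
    limb_volume,
    resample_contour,
    slab_volume,
    volume_report,
)
from plesiomass.pipeline import reconstruct
from plesiomass.ribcage_geometry import Contour
from plesiomass.synthetic_data import gen_parametric_body, gen_skeleton

from conftest import make_circle, make_ellipse


class TestContourArea:
    def test_unit_square(self):
        sq = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert contour_area(sq) == 1.0

    def test_polygon_circle_area(self):
        c = make_circle(1.0, 512)
        assert contour_area(c) == pytest.approx(math.pi, rel=1e-4)

    def test_mirrored_contour_same_area(self):
        c = make_ellipse(0.8, 0.3, 256)
        mv = c.vertices[::-1].copy()
        mv[:, 0] *= -1
        assert contour_area(Contour(mv)) == pytest.approx(contour_area(c),
                                                          rel=1e-12)

    def test_self_intersecting_rejected(self):
        bowtie = Contour(np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float))
        with pytest.raises(ValueError):
            contour_area(bowtie)


class TestResampleContour:
    def test_idempotence(self):
        c = make_ellipse(0.6, 0.4, 300)
        r1 = resample_contour(c, 256)
        r2 = resample_contour(r1, 256)
        assert np.max(np.abs(r1.vertices - r2.vertices)) < 1e-12

    def test_circle_radius_spread(self):
        r = resample_contour(make_circle(1.0, 1024), 256)
        center = np.array([0.0, 1.0])
        radii = np.hypot(*(r.vertices - center).T)
        assert np.ptp(radii) / radii.mean() < 1e-4

    def test_starts_at_ventral_midline(self):
        r = resample_contour(make_ellipse(0.5, 0.3), 128)
        assert r.vertices[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert r.vertices[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_area_preserved_on_smooth_contour(self):
        c = make_ellipse(0.7, 0.35, 1024)
        r = resample_contour(c, 512)
        assert r.area == pytest.approx(c.area, rel=1e-4)

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            resample_contour(make_circle(1.0), 8)


class TestBlendContours:
    def test_endpoints(self):
        a, b = make_circle(1.0, 256), make_circle(2.0, 256)
        assert blend_contours(a, b, 0.0).area == pytest.approx(a.area)
        assert blend_contours(a, b, 1.0).area == pytest.approx(b.area)

    def test_concentric_circles_midpoint(self):
        # circles share the center (0, 0): radii 1 and 3 blend to radius 2
        t = np.linspace(0, 2 * math.pi, 257)[:-1] - math.pi / 2
        a = Contour(np.column_stack([np.cos(t), np.sin(t)]))
        b = Contour(3 * np.column_stack([np.cos(t), np.sin(t)]))
        mid = blend_contours(a, b, 0.5)
        assert mid.area == pytest.approx(4 * math.pi, rel=1e-3)

    def test_self_blend_is_identity(self):
        c = make_ellipse(0.5, 0.25, 256)
        for t in (0.0, 0.3, 1.0):
            assert np.allclose(blend_contours(c, c, t).vertices, c.vertices)

    def test_t_outside_unit_interval(self):
        c = make_circle(1.0, 256)
        with pytest.raises(ValueError):
            blend_contours(c, c, 1.5)


class TestSlabVolume:
    def test_cylinder_is_exact(self):
        c = make_circle(0.5)
        A = contour_area(c)
        v = slab_volume(Slab(c, c, 2.0, 100))
        assert v == pytest.approx(A * 2.0, rel=1e-12)

    def test_cone(self):
        c = make_circle(1.0)
        v = slab_volume(Slab(c, POINT, 3.0, 100))
        assert v == pytest.approx(math.pi, rel=1e-4)

    def test_frustum(self):
        a, b = make_circle(1.0), make_circle(2.0)
        v = slab_volume(Slab(a, b, 3.0, 100))
        assert v == pytest.approx(7 * math.pi, rel=1e-4)

    def test_error_scales_as_inverse_square_of_subslabs(self):
        c = make_circle(1.0)
        exact = contour_area(c) * 3.0 / 3.0
        e25 = abs(slab_volume(Slab(c, POINT, 3.0, 25)) - exact)
        e100 = abs(slab_volume(Slab(c, POINT, 3.0, 100)) - exact)
        assert e25 / e100 == pytest.approx(16.0, rel=0.05)

    def test_subdivision_invariance(self):
        a = make_ellipse(0.4, 0.2, 512)
        b = make_ellipse(0.5, 0.35, 512)
        full = slab_volume(Slab(a, b, 1.0, 100))
        t = 0.37
        mid = blend_contours(a, b, t)
        split = (slab_volume(Slab(a, mid, t, 37))
                 + slab_volume(Slab(mid, b, 1 - t, 63)))
        assert split == pytest.approx(full, rel=1e-9)

    def test_double_point_slab_rejected(self):
        with pytest.raises(ValueError):
            Slab(POINT, POINT, 1.0)


class TestLimbVolume:
    def test_constant_section_prism(self):
        p = LimbPlanform(span=1.0, chords=(0.2,) * 6,
                         thickness_fractions=(0.2,) * 6,
                         section_area_coefficient=0.685)
        assert limb_volume(p) == pytest.approx(0.685 * 0.2 * 0.04 * 1.0)

    def test_zero_chords_zero_volume(self):
        p = LimbPlanform(span=1.0, chords=(0.0,) * 6)
        assert limb_volume(p) == 0.0

    def test_volume_quadratic_in_chord(self):
        chords = (0.3, 0.25, 0.2, 0.15, 0.1, 0.05)
        p1 = LimbPlanform(span=1.2, chords=chords)
        p2 = LimbPlanform(span=1.2, chords=tuple(2 * c for c in chords))
        assert limb_volume(p2) == pytest.approx(4 * limb_volume(p1))


def plesiosaur_model():
    return reconstruct(gen_skeleton("cryptoclidid-like")).skeletal_model


class TestSoftTissue:
    def test_ribcage_sections_widen_by_25_percent(self):
        model = plesiosaur_model()
        staged = apply_soft_tissue(model, SoftTissueConfig())
        for i in (2, 3):  # trunk slabs carry the three ribcage sections
            before = model.axial_slabs[i]
            after = staged.axial_slabs[i]
            assert after.front.width == pytest.approx(1.25 * before.front.width)
            assert after.back.width == pytest.approx(1.25 * before.back.width)
            # areas obey the affine law exactly
            assert after.front.area == pytest.approx(
                1.25**2 * before.front.area, rel=1e-12
            )

    def test_tail_lengthens_by_5_percent(self):
        model = plesiosaur_model()
        staged = apply_soft_tissue(model, SoftTissueConfig())
        assert staged.axial_slabs[4].length == pytest.approx(
            1.05 * model.axial_slabs[4].length
        )

    def test_skull_section_unscaled(self):
        model = plesiosaur_model()
        staged = apply_soft_tissue(model, SoftTissueConfig())
        assert staged.axial_slabs[1].front.area == pytest.approx(
            model.axial_slabs[1].front.area, rel=1e-12
        )

    def test_identity_config_changes_nothing(self):
        model = plesiosaur_model()
        staged = apply_soft_tissue(
            model, SoftTissueConfig(section_linear_scale=1.0,
                                    tail_extension_fraction=0.0)
        )
        assert body_mass(staged)[1] == pytest.approx(body_mass(model)[1],
                                                     rel=1e-12)


class TestBodyMass:
    def test_mass_volume_ratio_is_density(self):
        model, _ = gen_parametric_body({"family": "cylinder", "r": 0.3,
                                        "length": 1.0})
        volume, mass = body_mass(model)
        assert mass / volume == pytest.approx(1027.0, rel=1e-12)

    def test_unit_volume_gives_1027_kg(self):
        r = math.sqrt(1.0 / math.pi)
        model, analytic = gen_parametric_body(
            {"family": "cylinder", "r": r, "length": 1.0}
        )
        _, mass = body_mass(model)
        assert analytic == pytest.approx(1.0, rel=1e-12)
        assert mass == pytest.approx(1027.0, rel=1e-3)

    def test_zero_chord_limbs_equal_no_limbs(self):
        model, _ = gen_parametric_body({"family": "cylinder", "r": 0.3,
                                        "length": 1.0})
        limbed = BodyModel(
            axial_slabs=model.axial_slabs,
            limb_slabs=tuple(
                LimbPlanform(span=1.0, chords=(0.0,) * 6) for _ in range(4)
            ),
        )
        assert body_mass(limbed)[1] == body_mass(model)[1]

    def test_geometric_similarity_s_cubed(self):
        base, _ = gen_parametric_body(
            {"family": "lofted_ellipse", "a": 0.4, "b": 0.3, "scale2": 1.5,
             "length": 2.0}
        )
        s = 1.7
        scaled, _ = gen_parametric_body(
            {"family": "lofted_ellipse", "a": 0.4 * s, "b": 0.3 * s,
             "scale2": 1.5, "length": 2.0 * s}
        )
        v1, m1 = body_mass(base)
        v2, m2 = body_mass(scaled)
        assert v2 / v1 == pytest.approx(s**3, rel=1e-9)
        assert m2 / m1 == pytest.approx(s**3, rel=1e-9)

    def test_volume_report_totals(self):
        model, _ = gen_parametric_body(
            {"family": "cone_capped_cylinder", "r": 0.3, "length": 1.0,
             "cap_length": 0.4}
        )
        df = volume_report(model)
        total_row = df[df["slab"] == "total"].iloc[0]
        parts = df[df["slab"] != "total"]["volume_m3"].sum()
        assert total_row["volume_m3"] == pytest.approx(parts)
        assert total_row["mass_kg"] == pytest.approx(parts * 1027.0)


class TestParametricBodyBattery:
    @pytest.mark.parametrize("shape,tol", [
        ({"family": "cylinder", "r": 0.5, "length": 2.0}, 1e-4),
        ({"family": "cone_capped_cylinder", "r": 0.4, "length": 1.5,
          "cap_length": 0.8}, 1e-4),
        ({"family": "spheroid", "a": 0.5, "b": 0.5, "c": 0.5}, 5e-4),
        ({"family": "spheroid", "a": 0.3, "b": 0.45, "c": 1.2}, 5e-4),
        ({"family": "lofted_ellipse", "a": 1.0, "b": 0.6, "scale2": 2.0,
          "length": 3.0}, 1e-4),
    ])
    def test_csm_matches_closed_form(self, shape, tol):
        model, analytic = gen_parametric_body(shape)
        volume = sum(slab_volume(s) for s in model.axial_slabs)
        assert volume == pytest.approx(analytic, rel=tol)

    def test_spheroid_analytic_value(self):
        _, analytic = gen_parametric_body(
            {"family": "spheroid", "a": 0.5, "b": 0.5, "c": 0.5}
        )
        assert analytic == pytest.approx(4 / 3 * math.pi * 0.125)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            gen_parametric_body({"family": "klein_bottle"})
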