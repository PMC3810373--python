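import numpy as np
import pytest
from shapely.geometry import LinearRing, Point, Polygon

from anchor3d import (DEFAULT_SITES, AnchorParams, SiteAnnotation, SiteConfig,
                      annotate_sites, generate_synthetic_anchor, layout_strip,
                      snap_to_grid)
from anchor3d.errors import (AnnotationError, DegeneracyError, GeometryError,
                             ParameterError)
from anchor3d.template import NORMAL, Template2D


class TestGenerator:
    def test_output_satisfies_template_invariants(self):
        tpl = generate_synthetic_anchor(AnchorParams(seed=1))
        tpl.validate()
        ring = LinearRing(tpl.outline)
        assert ring.is_simple and ring.is_ccw
        assert len(tpl.outline) >= 8

    def test_deterministic_for_fixed_seed(self):
        a = generate_synthetic_anchor(AnchorParams(seed=5, ornament_bumps=3))
        b = generate_synthetic_anchor(AnchorParams(seed=5, ornament_bumps=3))
        np.testing.assert_array_equal(a.outline, b.outline)
        np.testing.assert_array_equal(a.medial_path, b.medial_path)

    def test_different_seeds_differ_with_ornaments(self):
        a = generate_synthetic_anchor(AnchorParams(seed=1, ornament_bumps=3))
        b = generate_synthetic_anchor(AnchorParams(seed=2, ornament_bumps=3))
        assert not np.array_equal(a.outline, b.outline)

    def test_ear_adds_lobe_inside_site_vi(self):
        off = generate_synthetic_anchor(AnchorParams(seed=3))
        on = generate_synthetic_anchor(AnchorParams(seed=3, ear=True))
        p_off, p_on = Polygon(off.outline), Polygon(on.outline)
        assert p_on.area > p_off.area
        lobe = p_on.difference(p_off)
        c = np.array(lobe.centroid.coords[0])
        # the lobe centroid's nearest medial position falls in site VI's band
        s = off.medial_arclength()
        d = np.linalg.norm(off.medial_path - c, axis=1)
        s_lobe = s[np.argmin(d)]
        vi = next(a for a in DEFAULT_SITES if a.label == "VI")
        assert vi.s_start <= s_lobe <= vi.s_end

    @pytest.mark.parametrize("field,value", [
        ("shaft_length", -1.0),
        ("inner_root_width", 10.0),  # must stay below inner_root_length
        ("ornament_bumps", -2),
        ("outer_root_lobes", 0),
    ])
    def test_invalid_params_name_offending_field(self, field, value):
        with pytest.raises(ParameterError, match=field.split("_")[0]):
            generate_synthetic_anchor(AnchorParams(**{field: value}))

    @pytest.mark.parametrize("seed", range(10))
    def test_many_seeds_produce_valid_templates(self, seed):
        p = AnchorParams(seed=seed, ear=bool(seed % 2), ornament_bumps=seed % 4)
        generate_synthetic_anchor(p).validate()


class TestSnapToGrid:
    def test_points_already_on_grid_unchanged(self):
        square = Template2D(
            "sq",
            np.array([[0, 0], [2, 0], [4, 0], [4, 2], [4, 4], [2, 4], [0, 4], [0, 2]], float),
            np.array([[1.0, 2.0], [3.0, 2.0]]),
        )
        same = snap_to_grid(square, 1.0)
        np.testing.assert_array_equal(same.outline, square.outline)

    def test_rounding_to_nearest_grid_multiple(self):
        outline = np.array([[0, 0], [2, -1], [4, 0], [5, 2], [4, 4],
                            [2, 5], [1.24, 3.76], [0, 2]], float)
        tpl = Template2D("odd", outline, np.array([[1.0, 1.0], [3.0, 2.0]]))
        snapped = snap_to_grid(tpl, 0.5)
        assert [1.0, 4.0] in snapped.outline.tolist()

    def test_idempotent(self):
        tpl = generate_synthetic_anchor(AnchorParams(seed=4))
        once = snap_to_grid(tpl, 0.25)
        twice = snap_to_grid(once, 0.25)
        np.testing.assert_array_equal(once.outline, twice.outline)
        np.testing.assert_array_equal(once.medial_path, twice.medial_path)

    def test_coarse_snap_of_fine_spiral_raises(self):
        # thin spiral band collapses/self-intersects at coarse spacing
        t = np.linspace(0, 4 * np.pi, 200)
        r_out = 1.0 + 0.45 * t
        r_in = r_out - 0.35
        outer = np.stack([r_out * np.cos(t), r_out * np.sin(t)], axis=1)
        inner = np.stack([r_in * np.cos(t), r_in * np.sin(t)], axis=1)[::-1]
        outline = np.vstack([outer, inner])
        mid = 0.5 * (r_out + r_in)
        medial = np.stack([mid * np.cos(t), mid * np.sin(t)], axis=1)[10:-10]
        spiral = Template2D("spiral", outline, medial)
        with pytest.raises(DegeneracyError):
            snap_to_grid(spiral, 2.0)


class TestAnnotateSites:
    def test_empty_annotation_is_all_normal(self, rect_template):
        tpl = annotate_sites(rect_template, [])
        assert tpl.sites == ()
        assert tpl.site_at(0.5) == NORMAL

    def test_packaged_annotation_has_seven_distinct_sites(self, template):
        labels = {a.label for a in template.sites if a.label != NORMAL}
        assert labels == {"I", "II", "III", "IV", "V", "VI", "VII"}

    def test_overlapping_intervals_rejected(self, rect_template):
        anns = [SiteAnnotation("I", 0.1, 0.3), SiteAnnotation("II", 0.2, 0.4)]
        with pytest.raises(AnnotationError):
            annotate_sites(rect_template, anns)

    def test_duplicate_label_rejected(self, rect_template):
        anns = [SiteAnnotation("I", 0.1, 0.2), SiteAnnotation("I", 0.5, 0.6)]
        with pytest.raises(AnnotationError):
            annotate_sites(rect_template, anns)


class TestSiteConfig:
    def test_odd_or_small_counts_rejected(self):
        with pytest.raises(ParameterError):
            SiteConfig({NORMAL: 4, "I": 5})
        with pytest.raises(ParameterError):
            SiteConfig({NORMAL: 2})

    @pytest.mark.parametrize("count,expected", [
        (4, (2, 2)), (6, (3, 2)), (8, (4, 2)), (16, (4, 4)),
        (10, (5, 2)), (20, (5, 4)),
    ])
    def test_factorization(self, count, expected):
        cfg = SiteConfig({NORMAL: 4, "I": count})
        assert cfg.factorize("I") == expected
        n_along, n_across = expected
        assert n_along >= 2 and n_across >= 2 and n_along * n_across == count


class TestLayoutStrip:
    def test_all_normal_rectangle_three_stations(self, rect_template):
        lay = layout_strip(rect_template, SiteConfig({NORMAL: 4}), n_normal_stations=3)
        assert len(lay.stations) == 3
        assert all(st.n_across == 2 for st in lay.stations)

    def test_site_vi_gets_four_stations_of_four(self, template):
        lay = layout_strip(template, SiteConfig())
        vi = [st for st in lay.stations if st.site == "VI"]
        assert len(vi) == 4
        assert all(st.n_across == 4 for st in vi)
        assert lay.site_points("VI") == 16

    def test_per_site_point_totals_match_config(self, template):
        cfg = SiteConfig()
        lay = layout_strip(template, cfg)
        for label in ("I", "II", "III", "IV", "V", "VI", "VII"):
            assert lay.site_points(label) == cfg.count(label)

    def test_all_points_inside_outline(self, template):
        lay = layout_strip(template, SiteConfig())
        poly = Polygon(template.outline).buffer(1e-9)
        for st in lay.stations:
            for p in st.points:
                assert poly.contains(Point(p))

    def test_stations_sorted_by_arclength(self, template):
        lay = layout_strip(template, SiteConfig())
        ss = [st.s for st in lay.stations]
        assert ss == sorted(ss)

    def test_requires_two_normal_stations(self, rect_template):
        with pytest.raises(ParameterError):
            layout_strip(rect_template, SiteConfig(), n_normal_stations=1)

    @pytest.mark.parametrize("seed", range(8))
    def test_layout_invariants_over_seeded_anchors(self, seed):
        from anchor3d import generate_synthetic_anchor

        tpl = generate_synthetic_anchor(AnchorParams(seed=seed, ear=bool(seed % 2)))
        cfg = SiteConfig()
        lay = layout_strip(tpl, cfg)
        poly = Polygon(tpl.outline).buffer(1e-9)
        assert all(a.s <= b.s for a, b in zip(lay.stations, lay.stations[1:]))
        assert all(poly.contains(Point(p)) for st in lay.stations for p in st.points)
        for label in ("I", "IV", "VI"):
            assert lay.site_points(label) == cfg.count(label)
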