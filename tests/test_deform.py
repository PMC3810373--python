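import numpy as np
import pytest
from shapely.geometry import LinearRing, MultiPoint, Point, Polygon

from anchor3d import (SiteConfig, anchor_variants, assemble_mesh, build_final_model,
                      correspond_pilots, deform_by_coordinates, extrude_strip,
                      fit_report, fit_to_template, layout_strip, move_pilots,
                      rotate_views, silhouette, validate_mesh)
from anchor3d.deform import FitTolerances
from anchor3d.errors import GeometryError, LookupError_, TableError
from anchor3d.io import coordinate_table_from_model
from anchor3d.template import NORMAL, Template2D

from conftest import rectangle_template


def own_silhouette_template(model, levels=None):
    lv = model.display_levels if levels is None else levels
    sil = silhouette(model.control_mesh, lv)
    t = model.template_ref
    return Template2D("own", sil, t.medial_path, sites=t.sites)


class TestSilhouette:
    def test_one_block_level0_is_front_rectangle(self, rect_template):
        lay = layout_strip(rect_template, SiteConfig({NORMAL: 4}), 2)
        mesh = assemble_mesh(*extrude_strip(lay))
        sil = Polygon(silhouette(mesh, 0))
        front = mesh.vertices[mesh.vertices[:, 2] > 0][:, :2]
        expected = MultiPoint(front).convex_hull
        assert sil.symmetric_difference(expected).area < 1e-9

    def test_area_bounded_by_projected_hull(self, model):
        sil = Polygon(silhouette(model.control_mesh, 1))
        hull = MultiPoint(model.control_mesh.vertices[:, :2]).convex_hull
        assert sil.area <= hull.area + 1e-9

    def test_invariant_under_z_translation(self, model):
        mesh = model.control_mesh
        shifted = type(mesh)(mesh.vertices + np.array([0, 0, 5.0]), mesh.faces)
        np.testing.assert_allclose(silhouette(mesh, 1), silhouette(shifted, 1))


class TestFitReport:
    def test_identical_polygons(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        tpl = Template2D("sq", np.array([[0, 0], [0.5, 0], [1, 0], [1, 0.5],
                                         [1, 1], [0.5, 1], [0, 1], [0, 0.5]], float),
                         np.array([[0.3, 0.5], [0.7, 0.5]]))
        rep = fit_report(sq, tpl)
        assert rep.mean_sym_dist < 1e-9
        assert rep.hausdorff < 1e-9
        assert rep.iou == pytest.approx(1.0)

    def test_disjoint_shift_gives_zero_iou(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        rep = fit_report(sq, sq + np.array([1.0, 0.0]))
        assert rep.iou == pytest.approx(0.0)

    def test_concentric_double_square_iou_quarter(self):
        sq = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
        rep = fit_report(sq, 2.0 * sq)
        assert rep.iou == pytest.approx(0.25)

    def test_degenerate_polygon_rejected(self):
        line = np.array([[0, 0], [1, 0], [2, 0], [1, 0]], float)
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        with pytest.raises(GeometryError):
            fit_report(line, sq)


class TestCorrespondence:
    def test_own_control_silhouette_maps_near_identity(self, model):
        target = own_silhouette_template(model, levels=0)
        corr = correspond_pilots(model, target)
        loop = model.boundary_loop()
        xy = model.control_mesh.vertices[loop][:, :2]
        d = [np.linalg.norm(xy[i] - corr.pairs[v]) for i, v in enumerate(loop)]
        # boundary pilots lie on the level-0 silhouette up to grid resampling
        assert np.mean(d) < 0.15

    def test_mapped_points_lie_on_target_outline(self, model, template):
        corr = correspond_pilots(model, template)
        ring = LinearRing(template.outline)
        for p in corr.pairs.values():
            assert ring.distance(Point(p)) < 1e-6

    def test_cyclic_roll_of_target_changes_offset_not_cost(self, model, template):
        rolled = Template2D(template.name, np.roll(template.outline, 120, axis=0),
                            template.medial_path, sites=template.sites)
        c0 = correspond_pilots(model, template)
        c1 = correspond_pilots(model, rolled)
        loop = model.boundary_loop()
        xy = model.control_mesh.vertices[loop][:, :2]
        cost = lambda c: np.mean([np.linalg.norm(xy[i] - c.pairs[v])
                                  for i, v in enumerate(loop)])
        # small residual differences stem from ring resampling discretization
        assert cost(c1) == pytest.approx(cost(c0), rel=0.05)


class TestMovePilots:
    def test_empty_selection_identity(self, model):
        out = move_pilots(model, [], {})
        np.testing.assert_array_equal(out.control_mesh.vertices,
                                      model.control_mesh.vertices)

    def test_single_vertex_exact_displacement(self, model):
        out = move_pilots(model, [5], {5: np.array([1.0, 0.0, 0.0])})
        diff = out.control_mesh.vertices - model.control_mesh.vertices
        assert diff[5, 0] == pytest.approx(1.0)
        assert np.count_nonzero(diff) == 1

    def test_topology_preserved(self, model):
        out = move_pilots(model, [0, 1], {0: [0, 0, 1.0], 1: [0.5, 0, 0]})
        np.testing.assert_array_equal(out.control_mesh.faces, model.control_mesh.faces)

    def test_unknown_id_rejected(self, model):
        with pytest.raises(LookupError_):
            move_pilots(model, [10 ** 6], {10 ** 6: [1, 0, 0]})


class TestFitToTemplate:
    def test_self_target_converges_immediately(self, model):
        res = fit_to_template(model, own_silhouette_template(model))
        assert res.converged
        assert res.iterations <= 2
        assert res.fit.mean_sym_dist < 1e-6

    def test_uniform_scale_recovered(self, model):
        sil = silhouette(model.control_mesh, model.display_levels)
        target = Template2D("scaled", 1.5 * sil, 1.5 * model.template_ref.medial_path,
                            sites=model.template_ref.sites)
        res = fit_to_template(model, target)
        assert res.converged
        fitted = Polygon(silhouette(res.model.control_mesh, model.display_levels))
        b0, b1 = Polygon(sil).bounds, fitted.bounds
        d0 = np.hypot(b0[2] - b0[0], b0[3] - b0[1])
        d1 = np.hypot(b1[2] - b1[0], b1[3] - b1[1])
        assert d1 / d0 == pytest.approx(1.5, rel=0.01)

    def test_recovery_from_seeded_pilot_displacement(self, model):
        rng = np.random.default_rng(7)
        sel = rng.choice(model.control_mesh.n_vertices, size=30, replace=False)
        disp = {int(i): np.append(rng.uniform(-0.6, 0.6, 2), 0.0) for i in sel}
        jittered = move_pilots(model, disp.keys(), disp)
        sil = silhouette(jittered.control_mesh, model.display_levels)
        target = Template2D("jittered", sil, model.template_ref.medial_path,
                            sites=model.template_ref.sites)
        res = fit_to_template(model, target)
        assert res.fit.iou >= 0.95

    def test_trace_monotone_and_topology_constant(self, model):
        target = anchor_variants(2, base_seed=3)[1]
        res = fit_to_template(model, target)
        dists = [f.mean_sym_dist for f in res.trace]
        assert all(a >= b - 1e-12 for a, b in zip(dists, dists[1:]))
        np.testing.assert_array_equal(res.model.control_mesh.faces,
                                      model.control_mesh.faces)

    def test_z_coordinates_preserved(self, model):
        target = anchor_variants(1, base_seed=5)[0]
        res = fit_to_template(model, target)
        np.testing.assert_allclose(res.model.control_mesh.vertices[:, 2],
                                   model.control_mesh.vertices[:, 2])


class TestDeformByCoordinates:
    def test_identity_table(self, model):
        table = coordinate_table_from_model(model)
        out = deform_by_coordinates(model, table)
        np.testing.assert_array_equal(out.control_mesh.vertices,
                                      model.control_mesh.vertices)

    def test_route_equivalence_with_fit(self, model, template):
        target = anchor_variants(1, base_seed=9)[0]
        res = fit_to_template(model, target)
        table = coordinate_table_from_model(res.model)
        fresh = build_final_model(template)
        replayed = deform_by_coordinates(fresh, table)
        assert np.abs(replayed.control_mesh.vertices
                      - res.model.control_mesh.vertices).max() <= 1e-9

    def test_row_count_mismatch_rejected(self, model):
        table = coordinate_table_from_model(model)
        short = type(table)(ids=table.ids[:-1], xyz=table.xyz[:-1],
                            sites=table.sites[:-1])
        with pytest.raises(TableError):
            deform_by_coordinates(model, short)


class TestRotateViews:
    def test_zero_angle_matches_unrotated(self, model):
        mesh = model.control_mesh
        (_, sil0), = rotate_views(mesh, "x", [0.0], levels=1)
        base = silhouette(mesh, 1)
        assert Polygon(sil0).symmetric_difference(Polygon(base)).area < 1e-6

    def test_eight_views(self, model):
        angles = [0, 45, 90, 135, 180, 225, 270, 315]
        views = rotate_views(model.control_mesh, "x", angles, levels=0)
        assert [a for a, _ in views] == [float(a) for a in angles]
        assert all(Polygon(s).area > 0 for _, s in views)

    def test_full_turn_periodicity(self, model):
        mesh = model.control_mesh
        (_, s0), (_, s360) = rotate_views(mesh, "y", [0.0, 360.0], levels=0)
        assert Polygon(s0).symmetric_difference(Polygon(s360)).area < 1e-6

    def test_rotation_preserves_edge_lengths(self, model):
        mesh = model.control_mesh
        from anchor3d.deform import _rotation_matrix

        R = _rotation_matrix("x", 45.0)
        rot = type(mesh)(mesh.vertices @ R.T, mesh.faces)
        e = sorted(mesh.edges())
        l0 = np.linalg.norm(mesh.vertices[[a for a, b in e]]
                            - mesh.vertices[[b for a, b in e]], axis=1)
        l1 = np.linalg.norm(rot.vertices[[a for a, b in e]]
                            - rot.vertices[[b for a, b in e]], axis=1)
        assert np.abs(l0 - l1).max() < 1e-9
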