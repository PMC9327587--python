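"""Ray engine tests: intersection oracles, first-hit, reflection, refraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyflux.mesh import MeshResolution, build_canopy_mesh
from canopyflux.rays import (FacetIndex, first_hit, generate_beams,
                             ray_triangle_intersect, reflect_direction,
                             refract_direction, trace_secondary)
from canopyflux.solar import SiteTime, solar_position

from conftest import random_small_scene

DOWN = np.array([0.0, 0.0, -1.0])


def barycentric_oracle(origin, direction, tri):
    """Independent hit test: solve origin + t d = v0 + u e1 + v e2."""
    tri = np.asarray(tri, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    m = np.column_stack([-d, tri[1] - tri[0], tri[2] - tri[0]])
    if abs(np.linalg.det(m)) < 1e-12:
        return None
    t, u, v = np.linalg.solve(m, np.asarray(origin, float) - tri[0])
    if t <= 0 or u < 0 or v < 0 or u + v > 1:
        return None
    return origin + t * d, t


class TestRayTriangle:
    def test_straight_down_hit(self):
        h = ray_triangle_intersect([0.5, 0.5, 10], DOWN,
                                   [[0, 0, 0], [2, 0, 0], [0, 2, 0]])
        assert h.t == pytest.approx(10.0)
        assert h.point == pytest.approx([0.5, 0.5, 0.0])
        assert h.incidence_cosine == pytest.approx(1.0)

    def test_parallel_ray_misses(self):
        assert ray_triangle_intersect([0, 0, 1], [1, 0, 0],
                                      [[0, 0, 0], [2, 0, 0], [0, 2, 0]]) is None

    def test_behind_origin_misses(self):
        assert ray_triangle_intersect([0.5, 0.5, -1], DOWN,
                                      [[0, 0, 0], [2, 0, 0], [0, 2, 0]]) is None

    def test_degenerate_triangle_misses(self):
        assert ray_triangle_intersect([0, 0, 1], DOWN,
                                      [[0, 0, 0], [1, 0, 0], [2, 0, 0]]) is None

    def test_matches_barycentric_oracle(self, rng):
        hits = 0
        for _ in range(2000):
            tri = rng.uniform(-2, 2, (3, 3))
            origin = rng.uniform(-3, 3, 3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            mine = ray_triangle_intersect(origin, direction, tri)
            ref = barycentric_oracle(origin, direction, tri)
            assert (mine is None) == (ref is None)
            if mine is not None:
                hits += 1
                assert np.allclose(mine.point, ref[0], atol=1e-9)
                assert mine.t == pytest.approx(ref[1], abs=1e-9)
        assert hits > 30  # the comparison actually exercised both branches


class TestFirstHit:
    def test_upper_of_stacked_facets_wins(self):
        from canopyflux.mesh import CanopyMesh
        verts = np.array([[0, 0, 5.], [2, 0, 5], [0, 2, 5],
                          [0, 0, 2], [2, 0, 2], [0, 2, 2]])
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = CanopyMesh(
            vertices=verts, triangles=tris,
            tree_index=np.array([0, 0]), tree_ids=("t",),
            species=np.array(["conifer", "conifer"]),
            normals=np.array([[0, 0, 1.], [0, 0, 1]]),
            areas=np.array([2.0, 2.0]),
            tree_facet_offsets=np.array([0, 2]))
        hb = first_hit(np.array([[0.5, 0.5, 10.0]]), DOWN, mesh)
        assert hb.facet.tolist() == [0]
        assert hb.t == pytest.approx([5.0])

    def test_miss_means_ground(self, conifer_mesh):
        hb = first_hit(np.array([[200.0, 200.0, 100.0]]), DOWN, conifer_mesh)
        assert hb.n_hits == 0 and hb.n_miss == 1

    def test_accelerated_equals_brute_force(self, rng):
        res = MeshResolution(None, 3, 9)
        for _ in range(8):
            scene = random_small_scene(rng)
            mesh = build_canopy_mesh(scene, res)
            d = np.array([rng.normal(), rng.normal(), -abs(rng.normal()) - 0.3])
            d /= np.linalg.norm(d)
            origins = np.column_stack([rng.uniform(0, 20, (60, 2)),
                                       np.full(60, 40.0)])
            fast = first_hit(origins, d, mesh, accelerated=True)
            slow = first_hit(origins, d, mesh, accelerated=False)
            assert np.array_equal(fast.ray_index, slow.ray_index)
            assert np.array_equal(fast.facet, slow.facet)
            assert np.allclose(fast.t, slow.t, rtol=1e-12, atol=1e-12)

    def test_hits_invariant_under_scene_translation(self, rng):
        scene = random_small_scene(rng)
        mesh = build_canopy_mesh(scene, MeshResolution(None, 3, 9))
        shift = np.array([13.0, -7.0, 4.0])
        import copy
        mesh2 = copy.deepcopy(mesh)
        mesh2.vertices = mesh.vertices + shift
        d = np.array([0.3, -0.2, -0.9])
        origins = np.column_stack([rng.uniform(0, 20, (80, 2)),
                                   np.full(80, 50.0)])
        a = first_hit(origins, d, mesh)
        b = first_hit(origins + shift, d, mesh2)
        assert np.array_equal(a.facet, b.facet)
        assert np.allclose(a.t, b.t, atol=1e-9)


class TestBeamGrid:
    def test_density_from_spacing(self):
        box = np.array([[24.0, 24.0, 0.0], [26.0, 26.0, 0.0]])
        grid = generate_beams(DOWN, box, spacing=0.2)
        assert grid.n_beams == 100            # 2 m x 2 m at 25 beams/m^2
        assert grid.density == pytest.approx(25.0)

    def test_vertical_sun_footprint_equals_bounds(self):
        box = np.array([[0.0, 0.0, 0.0], [50.0, 50.0, 0.0]])
        grid = generate_beams(DOWN, box, spacing=0.5)
        xy = grid.source_points[:, :2]
        assert xy.min() >= 0.0 and xy.max() <= 50.0
        assert grid.n_beams == 100 * 100

    def test_culling_preserves_hits(self, conifer_mesh):
        state = solar_position(SiteTime(32.076, 166, 9.0))
        mb = conifer_mesh.bounds()
        box = np.array([np.minimum(mb[0], [0.0, 0.0, 0.0]),
                        np.maximum(mb[1], [50.0, 50.0, 0.0])])
        culled = generate_beams(state.beam_direction, box, spacing=2.0)
        full = generate_beams(state.beam_direction, box, spacing=2.0,
                              cull=False)
        idx = FacetIndex(conifer_mesh)
        hc = first_hit(culled.source_points, culled.direction, conifer_mesh,
                       index=idx)
        hf = first_hit(full.source_points, full.direction, conifer_mesh,
                       index=idx)
        assert culled.n_beams < full.n_beams
        assert hc.n_hits == hf.n_hits
        assert np.array_equal(hc.facet, hf.facet)

    def test_upward_direction_rejected(self):
        with pytest.raises(ValueError):
            generate_beams(np.array([0.0, 0.0, 1.0]),
                           np.array([[0., 0, 0], [1, 1, 1]]))


class TestReflection:
    def test_normal_incidence_bounces_back(self):
        out = reflect_direction(np.array([0.0, 0.0, -1.0]),
                                np.array([0.0, 0.0, 1.0]))
        assert out == pytest.approx([0.0, 0.0, 1.0])

    def test_mirror_symmetry(self):
        inc = np.array([1.0, 0.0, -1.0]) / math.sqrt(2)
        out = reflect_direction(inc, np.array([0.0, 0.0, 1.0]))
        assert out == pytest.approx(np.array([1.0, 0.0, 1.0]) / math.sqrt(2))

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_involution_and_norm(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        out = reflect_direction(d, n)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
        assert out @ n == pytest.approx(-(d @ n), abs=1e-12)
        assert reflect_direction(out, n) == pytest.approx(d, abs=1e-12)


class TestRefraction:
    def test_normal_incidence_passes_straight(self):
        d = np.array([0.0, 0.0, -1.0])
        out = refract_direction(d, np.array([0.0, 0.0, 1.0]), e=0.37)
        assert out == pytest.approx(d)

    def test_e_equal_one_is_identity(self, rng):
        for _ in range(20):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            if d @ n >= -1e-6:
                n = -n
            assert refract_direction(d, n, e=1.0) == pytest.approx(d, abs=1e-12)

    def test_closed_form_snell_example(self):
        out = refract_direction(np.array([0.8660254, 0.0, -0.5]),
                                np.array([0.0, 0.0, 1.0]), e=0.5)
        assert out == pytest.approx([0.4330127, 0.0, -0.9013878], abs=1e-6)

    def test_sine_ratio(self, rng):
        for _ in range(100):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            if d @ n > 0:
                n = -n
            if abs(d @ n) < 1e-3:
                continue
            e = rng.uniform(0.2, 1.0)
            out = refract_direction(d, n, e)
            sin_in = math.sqrt(max(0.0, 1.0 - (d @ n) ** 2))
            sin_out = math.sqrt(max(0.0, 1.0 - (out @ n) ** 2))
            assert sin_out == pytest.approx(e * sin_in, abs=1e-9)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)


class TestSecondary:
    def test_isolated_tree_has_no_transmitted_hits(self, single_cone_scene):
        mesh = build_canopy_mesh(single_cone_scene, MeshResolution(None, 4, 12))
        state = solar_position(SiteTime(32.076, 166, 12.0))
        grid = generate_beams(state.beam_direction, mesh.bounds(), spacing=0.5)
        hits = first_hit(grid.source_points, grid.direction, mesh)
        refl, trans = trace_secondary(hits, mesh)
        assert hits.n_hits > 0
        assert trans.n_hits == 0          # nothing behind the only tree
        assert refl.n_hits <= hits.n_hits
        assert trans.n_rays == hits.n_hits

    def test_low_sun_lights_the_rear_tree(self, two_tree_scene):
        mesh = build_canopy_mesh(two_tree_scene, MeshResolution(0.5))
        # winter noon: low southern sun, beams travel northwards
        state = solar_position(SiteTime(32.076, 355, 12.0))
        assert 30.0 < state.altitude < 40.0
        box = np.array([[0.0, 0.0, 0.0], [50.0, 50.0, 22.0]])
        grid = generate_beams(state.beam_direction, box, spacing=0.25)
        hits = first_hit(grid.source_points, grid.direction, mesh)
        rear = mesh.tree_ids.index("rear")
        rear_incident = (mesh.tree_index[hits.facet] == rear).sum()
        assert rear_incident == 0         # fully shaded by the front tree
        refl, trans = trace_secondary(hits, mesh)
        rear_trans = (mesh.tree_index[trans.facet] == rear).sum()
        assert rear_trans > 0             # but transmission reaches it

    def test_transmission_skips_own_tree(self, two_tree_scene, rng):
        mesh = build_canopy_mesh(two_tree_scene, MeshResolution(None, 4, 10))
        state = solar_position(SiteTime(32.076, 355, 12.0))
        grid = generate_beams(state.beam_direction, mesh.bounds(), spacing=0.5)
        hits = first_hit(grid.source_points, grid.direction, mesh)
        refl, trans = trace_secondary(hits, mesh)
        parent_tree = mesh.tree_index[hits.facet[trans.parent]]
        receiving_tree = mesh.tree_index[trans.facet]
        assert (parent_tree != receiving_tree).all()
        # reflected rays never land back on the very facet they left
        assert (hits.facet[refl.parent] != refl.facet).all()

    def test_secondary_brute_equals_accelerated(self, rng):
        scene = random_small_scene(rng)
        mesh = build_canopy_mesh(scene, MeshResolution(None, 3, 9))
        d = np.array([0.4, 0.3, -0.85])
        d /= np.linalg.norm(d)
        origins = np.column_stack([rng.uniform(0, 20, (100, 2)),
                                   np.full(100, 40.0)])
        hits = first_hit(origins, d, mesh)
        ra, ta = trace_secondary(hits, mesh, accelerated=True)
        rb, tb = trace_secondary(hits, mesh, accelerated=False)
        for a, b in ((ra, rb), (ta, tb)):
            assert np.array_equal(a.parent, b.parent)
            assert np.array_equal(a.facet, b.facet)
            assert np.allclose(a.t, b.t, atol=1e-12)
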