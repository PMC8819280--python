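"""Scene generator: rendering geometry, boundary oracle, path planning,
route generation and walkthroughs."""

import math

import numpy as np
import pytest

from spvsim import scene


class TestRendering:
    def test_frontal_wall_depth_equals_distance(self, corridor):
        """A camera staring at the end wall sees constant planar depth."""
        d = 6.0
        pose = scene.CameraPose(position=(1.5, corridor.length_m - d, 1.25))
        view = scene.render_view(corridor, None, pose, resolution=120)
        far = view.surface_id == 5
        assert far.mean() > 0.4
        assert np.abs(view.depth[far] - d).max() < 1e-9

    def test_box_projected_height_matches_pinhole_formula(self, corridor, single_box_layout):
        """Projected pixel height of a 1.80 m box follows f*H/Z with
        f = 240 / tan(17.5 deg)."""
        pose = scene.CameraPose(position=(1.5, 6.0, 0.9))
        view = scene.render_view(corridor, single_box_layout, pose, resolution=480)
        box = view.surface_id == 6
        rows = np.nonzero(box.any(axis=1))[0]
        h_px = rows.max() - rows.min() + 1
        z = 12.0 - 6.0 - 0.15  # distance to the front face
        f = 240 / math.tan(math.radians(17.5))
        assert h_px == pytest.approx(f * 1.80 / z, abs=2)

    def test_textures_change_rgb_but_not_boundaries(self, corridor, complex_corridor,
                                                    single_box_layout):
        pose = scene.CameraPose(position=(1.5, 6.0, 1.7))
        plain = scene.render_view(corridor, single_box_layout, pose, resolution=160)
        cplx = scene.render_view(complex_corridor, single_box_layout, pose, resolution=160)
        assert np.array_equal(plain.gt_boundary, cplx.gt_boundary)
        diff = np.abs(plain.rgb - cplx.rgb).max(axis=-1) > 1e-9
        assert diff.any()
        # texture differences live inside surfaces, off the boundary lines
        assert (diff & plain.gt_boundary).sum() / diff.sum() < 0.1

    def test_pose_outside_corridor_rejected(self, corridor):
        pose = scene.CameraPose(position=(5.0, 1.0, 1.7))
        with pytest.raises(scene.InvalidPoseError):
            scene.render_view(corridor, None, pose, resolution=32)

    def test_depth_positive_and_normals_unit(self, entrance_view):
        assert (entrance_view.depth > 0).all()
        norms = np.linalg.norm(entrance_view.normals, axis=-1)
        assert np.allclose(norms, 1.0)


class TestBoundaryOracle:
    def test_matches_brute_force_neighbor_scan(self, corridor, single_box_layout):
        """Vectorized mask equals a per-pixel 4-neighbor comparison."""
        pose = scene.CameraPose(position=(1.2, 8.0, 1.5))
        view = scene.render_view(corridor, single_box_layout, pose, resolution=64)
        mask = scene.ground_truth_boundaries(view, 0.05, 20.0)
        depth, normals = view.depth, view.normals
        cos_t = math.cos(math.radians(20.0))
        brute = np.zeros_like(mask)
        h, w = depth.shape
        for i in range(h):
            for j in range(w):
                for di, dj in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < h and 0 <= jj < w):
                        continue
                    d1, d2 = depth[i, j], depth[ii, jj]
                    if abs(d1 - d2) > 0.05 * min(d1, d2):
                        brute[i, j] = True
                    if float(normals[i, j] @ normals[ii, jj]) < cos_t:
                        brute[i, j] = True
        assert np.array_equal(mask, brute)

    def test_empty_corridor_has_only_junction_lines(self, corridor):
        pose = scene.CameraPose(position=(1.5, 2.0, 1.25))
        view = scene.render_view(corridor, None, pose, resolution=120)
        mask = view.gt_boundary
        # junction pixels separate surfaces with different ids (within 1 px)
        sid = view.surface_id
        near_junction = np.zeros_like(mask)
        near_junction[:, :-1] |= sid[:, :-1] != sid[:, 1:]
        near_junction[:, 1:] |= sid[:, :-1] != sid[:, 1:]
        near_junction[:-1, :] |= sid[:-1, :] != sid[1:, :]
        near_junction[1:, :] |= sid[:-1, :] != sid[1:, :]
        assert mask.sum() > 0
        # besides junction lines, only far-end grazing pixels may fire
        extra = mask & ~near_junction
        if extra.any():
            assert view.depth[extra].min() > 10.0

    def test_requires_channels(self):
        view = scene.RenderedView(rgb=np.zeros((8, 8, 3)), depth=None, normals=None,
                                  gt_boundary=np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            scene.ground_truth_boundaries(view)


class TestShortestPath:
    def test_empty_corridor_is_straight_line(self, corridor):
        empty = scene.RouteLayout((), "empty")
        assert scene.shortest_path_length(empty, corridor) == pytest.approx(22.0)

    def test_single_box_matches_grid_dijkstra(self, corridor, single_box_layout):
        vis = scene.shortest_path_length(single_box_layout, corridor)
        grid = scene.grid_shortest_path_length(single_box_layout, corridor)
        assert vis > 22.0
        assert abs(grid - vis) / vis < 0.01

    def test_mirror_symmetry(self, corridor, layouts):
        for base, mirrored in zip(layouts[:7], layouts[7:]):
            a = scene.shortest_path_length(base, corridor)
            b = scene.shortest_path_length(mirrored, corridor)
            assert a == pytest.approx(b, abs=1e-9)

    def test_blocked_corridor_returns_inf(self, corridor):
        # wall of boxes spanning the full inflatable width
        boxes = tuple(
            scene.ObstacleSpec("large", x, 10.0) for x in (0.4, 1.15, 1.9, 2.65)
        )
        layout = scene.RouteLayout(boxes, "blocked")
        assert scene.shortest_path_length(layout, corridor) == math.inf


class TestRouteGeneration:
    def test_seven_routes_plus_mirrors(self, layouts):
        assert len(layouts) == 14
        assert sum(not l.mirrored for l in layouts) == 7
        assert sum(l.mirrored for l in layouts) == 7

    def test_layout_counts_and_validity(self, corridor, layouts):
        for l in layouts:
            l.validate(corridor)  # 7 small + 6 large, in bounds, non-overlapping

    def test_difficulty_matched_within_tolerance(self, corridor, layouts):
        lengths = [scene.shortest_path_length(l, corridor) for l in layouts[:7]]
        med = np.median(lengths)
        assert all(abs(x - med) <= 0.02 * med + 1e-9 for x in lengths)

    def test_single_route_zero_tolerance_succeeds(self, corridor):
        got = scene.generate_route_layouts(1, corridor, tolerance=0.0, seed=9)
        assert len(got) == 2

    def test_deterministic_given_seed(self, corridor):
        a = scene.generate_route_layouts(2, corridor, seed=33)
        b = scene.generate_route_layouts(2, corridor, seed=33)
        assert [l.to_json() for l in a] == [l.to_json() for l in b]

    def test_search_failure_names_budget(self, corridor):
        with pytest.raises(scene.RouteSearchError, match="attempts"):
            scene.generate_route_layouts(40, corridor, tolerance=0.0, seed=1,
                                         max_attempts=45)


class TestWalkthrough:
    def test_empty_corridor_pose_count_and_spacing(self, corridor):
        empty = scene.RouteLayout((), "empty")
        poses = scene.walkthrough(empty, corridor, speed_mps=1.0, frame_rate_hz=10.0)
        assert len(poses) == 221  # 22 m at 0.1 m per frame, inclusive endpoints
        pts = np.array([p.position[:2] for p in poses])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.allclose(steps, 0.1, atol=1e-9)

    def test_zero_speed_rejected(self, corridor):
        empty = scene.RouteLayout((), "empty")
        with pytest.raises(ValueError):
            scene.walkthrough(empty, corridor, speed_mps=0.0)

    def test_poses_spacing_with_obstacles(self, corridor, layouts):
        poses = scene.walkthrough(layouts[0], corridor, speed_mps=1.4, frame_rate_hz=5.0)
        pts = np.array([p.position[:2] for p in poses])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        # uniform arc-length steps except at the final partial step;
        # straight-line steps can cut corners, never exceed the step size
        assert (steps[:-1] <= 1.4 / 5.0 + 1e-9).all()
        assert np.median(steps) == pytest.approx(1.4 / 5.0, rel=1e-6)


class TestLayoutIO:
    def test_json_roundtrip(self, layouts):
        text = layouts[3].to_json()
        back = scene.RouteLayout.from_json(text)
        assert back == layouts[3]

    def test_overlapping_footprints_rejected(self, corridor):
        boxes = (scene.ObstacleSpec("large", 1.5, 10.0), scene.ObstacleSpec("small", 1.5, 10.1))
        with pytest.raises(ValueError, match="overlap"):
            scene.RouteLayout(boxes, "bad").validate(corridor, require_counts=False)
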