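"""Synthetic indoor obstacle-course environment.

Builds the corridor mobility course used throughout the package: a 3 m wide,
22 m long corridor containing 13 cardboard-box obstacles (seven small,
30x50x90 cm, and six large, 30x75x180 cm), rendered either "plain" (uniform
surfaces) or "complex" (procedural wallpaper/tape-like stripe textures on
floor, walls and box faces).

The renderer is a pinhole ray caster that produces, besides the shaded RGB
frame, ground-truth depth and surface-normal maps and a geometry-derived
surface-boundary mask (depth or orientation discontinuities).  Those
channels play the role of an ideal monocular depth/normal/boundary
predictor, so the downstream contour-extraction stage can be exercised both
with classical edge detection on the RGB frame and with ideal surface
boundaries.

Route difficulty is quantified by the length of the shortest collision-free
2-D path from the corridor entrance to the far end, with obstacle
footprints inflated by the agent radius.  Two independent planners are
provided: an exact visibility-graph planner (the production path) and a
dense-grid Dijkstra planner used for cross-checking.

Coordinate conventions: corridor frame with x across the width, y along the
length, z up.  Image rasters are row-major, origin top-left, pixel centers
at half-integer coordinates.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "CorridorSpec",
    "ObstacleSpec",
    "RouteLayout",
    "CameraPose",
    "RenderedView",
    "InvalidPoseError",
    "RouteSearchError",
    "BlockedLayoutError",
    "SMALL_BOX_SIZE",
    "LARGE_BOX_SIZE",
    "render_view",
    "ground_truth_boundaries",
    "shortest_path_length",
    "shortest_path",
    "grid_shortest_path_length",
    "generate_route_layouts",
    "mirror_layout",
    "walkthrough",
]

# Box dimensions (width across corridor x, depth along corridor y, height z), m.
SMALL_BOX_SIZE = (0.50, 0.30, 0.90)
LARGE_BOX_SIZE = (0.75, 0.30, 1.80)


class InvalidPoseError(ValueError):
    """Camera pose outside the corridor volume."""


class RouteSearchError(RuntimeError):
    """Difficulty-matched route search exhausted its attempt budget."""


class BlockedLayoutError(RuntimeError):
    """No collision-free path exists through the layout."""


@dataclass(frozen=True)
class CorridorSpec:
    """Geometry and appearance of the corridor environment.

    ``complexity`` selects between the plain course (uniform albedo per
    surface) and the complex course, where stripe textures emulate the
    wallpaper and tape gradients added to floor, walls and boxes.
    """

    width_m: float = 3.0
    length_m: float = 22.0
    wall_height_m: float = 2.5
    complexity: Literal["plain", "complex"] = "plain"
    stripe_period_m: float = 0.55
    stripe_contrast: float = 0.35
    texture_seed: int = 7

    def __post_init__(self) -> None:
        if self.width_m <= 0 or self.length_m <= 0 or self.wall_height_m <= 0:
            raise ValueError("corridor dimensions must be positive")
        if self.complexity not in ("plain", "complex"):
            raise ValueError(f"unknown complexity {self.complexity!r}")


@dataclass(frozen=True)
class ObstacleSpec:
    """One cardboard box, axis aligned in corridor coordinates.

    ``center_x``/``center_y`` locate the footprint center (m); the footprint
    extents and the height follow from the size class.
    """

    size_class: Literal["small", "large"]
    center_x: float
    center_y: float

    @property
    def dimensions(self) -> tuple[float, float, float]:
        return SMALL_BOX_SIZE if self.size_class == "small" else LARGE_BOX_SIZE

    @property
    def height_m(self) -> float:
        return self.dimensions[2]

    @property
    def footprint(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the footprint rectangle in meters."""
        w, d, _ = self.dimensions
        return (
            self.center_x - w / 2,
            self.center_y - d / 2,
            self.center_x + w / 2,
            self.center_y + d / 2,
        )

    def inside(self, corridor: CorridorSpec) -> bool:
        x0, y0, x1, y1 = self.footprint
        return x0 >= 0 and y0 >= 0 and x1 <= corridor.width_m and y1 <= corridor.length_m


@dataclass(frozen=True)
class RouteLayout:
    """One arrangement of the 13 obstacle boxes along the corridor."""

    obstacles: tuple[ObstacleSpec, ...]
    layout_id: str = "layout"
    mirrored: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "obstacles", tuple(self.obstacles))

    def validate(self, corridor: CorridorSpec, *, require_counts: bool = True) -> None:
        if require_counts:
            n_small = sum(o.size_class == "small" for o in self.obstacles)
            n_large = sum(o.size_class == "large" for o in self.obstacles)
            if (n_small, n_large) != (7, 6):
                raise ValueError(
                    f"layout must contain 7 small + 6 large boxes, got {n_small}+{n_large}"
                )
        for o in self.obstacles:
            if not o.inside(corridor):
                raise ValueError(f"obstacle footprint outside corridor: {o}")
        rects = [o.footprint for o in self.obstacles]
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                a, b = rects[i], rects[j]
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ValueError(f"overlapping obstacle footprints: {i} and {j}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "layout_id": self.layout_id,
                "mirrored": self.mirrored,
                "obstacles": [
                    {"size_class": o.size_class, "center_x": o.center_x, "center_y": o.center_y}
                    for o in self.obstacles
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RouteLayout":
        d = json.loads(text)
        return cls(
            obstacles=tuple(ObstacleSpec(**o) for o in d["obstacles"]),
            layout_id=d["layout_id"],
            mirrored=d["mirrored"],
        )


def mirror_layout(layout: RouteLayout, corridor: CorridorSpec) -> RouteLayout:
    """Reflect a layout across the corridor midline (x -> width - x)."""
    return RouteLayout(
        obstacles=tuple(
            replace(o, center_x=corridor.width_m - o.center_x) for o in layout.obstacles
        ),
        layout_id=layout.layout_id,
        mirrored=not layout.mirrored,
    )


@dataclass(frozen=True)
class CameraPose:
    """Pinhole camera pose.  yaw 0 faces +y (down the corridor); pitch 0 is
    level; fov_deg is the full angle of the square field of view."""

    position: tuple[float, float, float]
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    fov_deg: float = 35.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fov_deg < 180.0:
            raise ValueError("fov_deg must be in (0, 180)")

    def validate(self, corridor: CorridorSpec) -> None:
        x, y, z = self.position
        if not (0 <= x <= corridor.width_m and 0 <= y <= corridor.length_m and 0 <= z <= corridor.wall_height_m):
            raise InvalidPoseError(f"camera position {self.position} outside corridor")


@dataclass
class RenderedView:
    """Rendered frame with ground-truth channels.

    ``rgb`` is float in [0, 1]; ``depth`` holds distance along the camera's
    forward axis (m); ``normals`` are unit vectors in the corridor frame;
    ``gt_boundary`` is the binary surface-boundary mask."""

    rgb: np.ndarray
    depth: np.ndarray
    normals: np.ndarray
    gt_boundary: np.ndarray
    surface_id: np.ndarray = field(repr=False, default=None)

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            rgb=self.rgb,
            depth=self.depth,
            normals=self.normals,
            gt_boundary=self.gt_boundary.astype(np.uint8),
        )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# Stylized flat shading: each surface (and each box face orientation) gets a
# fixed gray level, chosen so that surfaces that can abut in the image
# differ in brightness -- emulating a lab corridor of visually distinct
# materials (dark floor, lighter walls, cardboard faces shaded per
# orientation).  Within a surface the level is constant, so in the plain
# course photometric gradients occur only at surface boundaries.
_SURFACE_LEVEL = {
    "floor": 0.02,
    "ceiling": 0.85,
    "wall_left": 0.64,
    "wall_right": 0.36,
    "wall_near": 0.64,
    "wall_far": 0.21,
}
# Box face levels keyed by (size_class, outward normal axis/sign).
_BOX_FACE_LEVEL = {
    ("small", 2, +1): 0.50,  # top
    ("small", 1, -1): 0.99,  # front (faces the walking camera)
    ("small", 1, +1): 0.99,  # back
    ("small", 0, -1): 0.26,  # left face
    ("small", 0, +1): 0.68,  # right face
    ("large", 2, +1): 0.50,
    ("large", 1, -1): 0.82,
    ("large", 1, +1): 0.82,
    ("large", 0, -1): 0.44,
    ("large", 0, +1): 0.14,
}


def _camera_basis(pose: CameraPose) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    yaw = math.radians(pose.yaw_deg)
    pitch = math.radians(pose.pitch_deg)
    forward = np.array(
        [math.sin(yaw) * math.cos(pitch), math.cos(yaw) * math.cos(pitch), math.sin(pitch)]
    )
    right = np.array([math.cos(yaw), -math.sin(yaw), 0.0])
    up = np.cross(right, forward)
    return forward, right, up


def _ray_grid(pose: CameraPose, res: int) -> np.ndarray:
    """(res, res, 3) unit ray directions, pixel centers at half-integers."""
    forward, right, up = _camera_basis(pose)
    tan_half = math.tan(math.radians(pose.fov_deg) / 2)
    c = (np.arange(res) + 0.5) / (res / 2) - 1.0  # -1..1
    u = c * tan_half  # columns -> right
    v = c * tan_half  # rows -> down
    dirs = (
        forward[None, None, :]
        + u[None, :, None] * right[None, None, :]
        - v[:, None, None] * up[None, None, :]
    )
    return dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)


def _intersect_plane(origin, dirs, axis, value, normal_sign, bounds, sid):
    """Ray/axis-aligned-plane intersection restricted to a rectangle.

    Returns (t, normal axis, normal sign, surface id, hit mask)."""
    d = dirs[..., axis]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (value - origin[axis]) / d
    hit = (t > 1e-9) & np.isfinite(t)
    pts = origin[None, None, :] + t[..., None] * dirs
    (a0, a1, lo0, hi0, lo1, hi1) = bounds
    hit &= (pts[..., a0] >= lo0 - 1e-9) & (pts[..., a0] <= hi0 + 1e-9)
    hit &= (pts[..., a1] >= lo1 - 1e-9) & (pts[..., a1] <= hi1 + 1e-9)
    t = np.where(hit, t, np.inf)
    return t, axis, normal_sign, sid


def _intersect_aabb(origin, dirs, lo, hi):
    """Slab-method ray/AABB intersection.

    Returns (t_enter, entry_axis, entry_sign) with t=inf where missed."""
    safe = np.where(np.abs(dirs) < 1e-300, 1e-300, dirs)
    inv = 1.0 / safe
    t_lo = (lo[None, None, :] - origin[None, None, :]) * inv
    t_hi = (hi[None, None, :] - origin[None, None, :]) * inv
    t_near = np.minimum(t_lo, t_hi)
    t_far = np.maximum(t_lo, t_hi)
    t_enter_axis = np.argmax(t_near, axis=-1)
    t_enter = np.max(t_near, axis=-1)
    t_exit = np.min(t_far, axis=-1)
    hit = (t_enter <= t_exit) & (t_exit > 1e-9) & (t_enter > 1e-9)
    t_enter = np.where(hit, t_enter, np.inf)
    # entry face normal opposes the ray along the entry axis
    sign = -np.sign(
        np.take_along_axis(dirs, t_enter_axis[..., None], axis=-1)[..., 0]
    )
    return t_enter, t_enter_axis, sign


_SURFACE_IDS = ["floor", "ceiling", "wall_left", "wall_right", "wall_near", "wall_far"]


def _stripe_factor(u: np.ndarray, period: float, contrast: float, phase: float) -> np.ndarray:
    """Square-wave stripe multiplier emulating tape/wallpaper bands."""
    s = np.floor(u / period + phase).astype(np.int64) % 2
    return 1.0 + contrast * (2.0 * s - 1.0)


def render_view(
    corridor: CorridorSpec,
    layout: RouteLayout | None,
    pose: CameraPose,
    *,
    resolution: int = 480,
    boundary_depth_frac: float = 0.05,
    boundary_normal_deg: float = 20.0,
) -> RenderedView:
    """Ray-cast the corridor scene from ``pose``.

    Produces shaded RGB (flat Lambertian with a fixed directional light),
    ground-truth depth along the camera forward axis, world-frame unit
    normals and the surface-boundary mask derived from depth/normal
    discontinuities.  The complex condition multiplies per-surface stripe
    textures into the albedo; geometry (hence depth, normals and the
    boundary mask) is unaffected by texture.
    """
    pose.validate(corridor)
    if layout is not None:
        layout.validate(corridor, require_counts=False)
    W, L, H = corridor.width_m, corridor.length_m, corridor.wall_height_m
    origin = np.asarray(pose.position, dtype=float)
    dirs = _ray_grid(pose, resolution)

    res = resolution
    best_t = np.full((res, res), np.inf)
    normal = np.zeros((res, res, 3))
    sid = np.full((res, res), -1, dtype=np.int32)

    planes = [
        (2, 0.0, +1.0, (0, 1, 0.0, W, 0.0, L), 0),  # floor
        (2, H, -1.0, (0, 1, 0.0, W, 0.0, L), 1),    # ceiling
        (0, 0.0, +1.0, (1, 2, 0.0, L, 0.0, H), 2),  # left wall (x=0)
        (0, W, -1.0, (1, 2, 0.0, L, 0.0, H), 3),    # right wall
        (1, 0.0, +1.0, (0, 2, 0.0, W, 0.0, H), 4),  # near wall (y=0)
        (1, L, -1.0, (0, 2, 0.0, W, 0.0, H), 5),    # far wall
    ]
    for axis, value, nsign, bounds, s in planes:
        t, ax, sg, s_ = _intersect_plane(origin, dirs, axis, value, nsign, bounds, s)
        closer = t < best_t
        best_t = np.where(closer, t, best_t)
        sid = np.where(closer, s_, sid)
        n = np.zeros(3)
        n[ax] = sg
        normal = np.where(closer[..., None], n[None, None, :], normal)

    obstacles = layout.obstacles if layout is not None else ()
    for k, obs in enumerate(obstacles):
        x0, y0, x1, y1 = obs.footprint
        lo = np.array([x0, y0, 0.0])
        hi = np.array([x1, y1, obs.height_m])
        t, ent_axis, ent_sign = _intersect_aabb(origin, dirs, lo, hi)
        closer = t < best_t
        best_t = np.where(closer, t, best_t)
        sid = np.where(closer, 6 + k, sid)
        for ax in range(3):
            for sg in (-1.0, 1.0):
                m = closer & (ent_axis == ax) & (ent_sign == sg)
                if m.any():
                    n = np.zeros(3)
                    n[ax] = sg
                    normal[m] = n

    forward, _, _ = _camera_basis(pose)
    # planar (z-) depth: distance along the camera forward axis
    depth = best_t * (dirs @ forward)
    depth = np.where(np.isfinite(best_t), depth, np.inf)
    points = origin[None, None, :] + best_t[..., None] * dirs

    level = np.zeros((res, res))
    for s, name in enumerate(_SURFACE_IDS):
        level[sid == s] = _SURFACE_LEVEL[name]
    for k, obs in enumerate(obstacles):
        m = sid == 6 + k
        if not m.any():
            continue
        for (size, ax, sg), val in _BOX_FACE_LEVEL.items():
            if size != obs.size_class:
                continue
            face = m & (np.abs(normal[..., ax] - sg) < 0.5)
            level[face] = val

    tex = np.ones((res, res))
    if corridor.complexity == "complex":
        rng = np.random.default_rng(corridor.texture_seed)
        phases = rng.uniform(0, 1, size=6 + len(obstacles) * 3)
        period, contrast = corridor.stripe_period_m, corridor.stripe_contrast
        # floor/ceiling: stripes along y; side walls: stripes along y;
        # end walls: stripes along x
        plane_u = [points[..., 1], points[..., 1], points[..., 1],
                   points[..., 1], points[..., 0], points[..., 0]]
        for s in range(6):
            m = sid == s
            if m.any():
                tex[m] = _stripe_factor(plane_u[s][m], period, contrast, phases[s])
        for k in range(len(obstacles)):
            m = sid == 6 + k
            if m.any():
                # per-face coordinate: vertical bands on side faces, x-bands on top
                nz = np.abs(normal[..., 2]) > 0.5
                u = np.where(nz, points[..., 0], points[..., 2])
                tex[m] = _stripe_factor(u[m], period * 0.45, contrast, phases[6 + k])

    gray = np.clip(level * tex, 0.0, 1.0)
    rgb = np.repeat(gray[..., None], 3, axis=-1)

    view = RenderedView(rgb=rgb, depth=depth, normals=normal,
                        gt_boundary=np.zeros((res, res), dtype=bool), surface_id=sid)
    view.gt_boundary = ground_truth_boundaries(
        view, depth_jump_frac=boundary_depth_frac, normal_angle_deg=boundary_normal_deg
    )
    return view


def ground_truth_boundaries(
    view: RenderedView,
    depth_jump_frac: float = 0.05,
    normal_angle_deg: float = 20.0,
) -> np.ndarray:
    """Surface-boundary mask from ground-truth depth and normals.

    A pixel is a boundary pixel iff, for any of its 4-neighbors, the depth
    jump exceeds ``depth_jump_frac`` times the nearer of the two depths, or
    the angle between the unit normals exceeds ``normal_angle_deg``.  The
    mask depends only on geometry, never on textures or shading.
    """
    if view.depth is None or view.normals is None:
        raise ValueError("view must carry depth and normal channels")
    depth, normals = view.depth, view.normals
    cos_thresh = math.cos(math.radians(normal_angle_deg))
    mask = np.zeros(depth.shape, dtype=bool)
    for axis in (0, 1):
        d1 = np.take(depth, range(depth.shape[axis] - 1), axis=axis)
        d2 = np.take(depth, range(1, depth.shape[axis]), axis=axis)
        f1, f2 = np.isfinite(d1), np.isfinite(d2)
        with np.errstate(invalid="ignore"):
            jump = np.abs(d1 - d2) > depth_jump_frac * np.minimum(d1, d2)
        jump = np.where(f1 & f2, jump, f1 != f2)
        n1 = np.take(normals, range(depth.shape[axis] - 1), axis=axis)
        n2 = np.take(normals, range(1, depth.shape[axis]), axis=axis)
        bend = np.sum(n1 * n2, axis=-1) < cos_thresh
        edge = jump | bend
        if axis == 0:
            mask[:-1, :] |= edge
            mask[1:, :] |= edge
        else:
            mask[:, :-1] |= edge
            mask[:, 1:] |= edge
    return mask


# ---------------------------------------------------------------------------
# Path planning
# ---------------------------------------------------------------------------

def _inflated_rects(layout: RouteLayout, r: float) -> np.ndarray:
    rects = []
    for o in layout.obstacles:
        x0, y0, x1, y1 = o.footprint
        rects.append((x0 - r, y0 - r, x1 + r, y1 + r))
    return np.asarray(rects).reshape(-1, 4)


def _segment_blocked(p: np.ndarray, q: np.ndarray, rects: np.ndarray, eps: float = 1e-9) -> bool:
    """True if segment p-q passes through the open interior of any rect.

    Liang-Barsky clipping against rectangles shrunk by ``eps`` so that
    grazing contact along an edge or corner does not count as blocking.
    """
    if len(rects) == 0:
        return False
    d = q - p
    x0 = rects[:, 0] + eps
    y0 = rects[:, 1] + eps
    x1 = rects[:, 2] - eps
    y1 = rects[:, 3] - eps
    t0 = np.zeros(len(rects))
    t1 = np.ones(len(rects))
    ok = np.ones(len(rects), dtype=bool)
    for dim, lo, hi in ((0, x0, x1), (1, y0, y1)):
        dd = d[dim]
        pp = p[dim]
        if abs(dd) < 1e-15:
            ok &= (pp > lo) & (pp < hi)
        else:
            ta = (lo - pp) / dd
            tb = (hi - pp) / dd
            tmin = np.minimum(ta, tb)
            tmax = np.maximum(ta, tb)
            t0 = np.maximum(t0, tmin)
            t1 = np.minimum(t1, tmax)
    ok &= t0 < t1
    return bool(ok.any())


def _point_in_rects(p: np.ndarray, rects: np.ndarray, eps: float = 1e-9) -> bool:
    if len(rects) == 0:
        return False
    return bool(
        (
            (p[0] > rects[:, 0] + eps)
            & (p[0] < rects[:, 2] - eps)
            & (p[1] > rects[:, 1] + eps)
            & (p[1] < rects[:, 3] - eps)
        ).any()
    )


def shortest_path(
    layout: RouteLayout,
    corridor: CorridorSpec,
    agent_radius_m: float = 0.30,
) -> tuple[float, np.ndarray]:
    """Exact shortest collision-free 2-D path via a visibility graph.

    Start is the corridor entrance midline; the goal is the far-end line
    y = length.  Obstacle footprints are inflated by the agent radius, and
    the lateral workspace is restricted to x in [r, width - r].  Returns
    ``(length, waypoints)``; length is ``inf`` (empty waypoints) when the
    corridor is blocked.
    """
    W, L = corridor.width_m, corridor.length_m
    r = agent_radius_m
    rects = _inflated_rects(layout, r)
    start = np.array([W / 2, 0.0])

    nodes = [start]
    for rect in rects:
        for cx, cy in ((rect[0], rect[1]), (rect[0], rect[3]), (rect[2], rect[1]), (rect[2], rect[3])):
            p = np.array([cx, cy])
            if not (r - 1e-12 <= cx <= W - r + 1e-12) or not (0 <= cy <= L):
                continue
            if _point_in_rects(p, rects):
                continue
            nodes.append(p)
    n = len(nodes)
    GOAL = n  # virtual goal: the line y = L

    adj: list[list[tuple[int, float]]] = [[] for _ in range(n + 1)]
    for i in range(n):
        for j in range(i + 1, n):
            if not _segment_blocked(nodes[i], nodes[j], rects):
                w = float(np.hypot(*(nodes[i] - nodes[j])))
                adj[i].append((j, w))
                adj[j].append((i, w))
        # vertical drop to the goal line is the optimal final leg
        top = np.array([nodes[i][0], L])
        if not _segment_blocked(nodes[i], top, rects):
            adj[i].append((GOAL, float(L - nodes[i][1])))

    dist = np.full(n + 1, np.inf)
    prev = np.full(n + 1, -1, dtype=int)
    dist[0] = 0.0
    pq = [(0.0, 0)]
    while pq:
        d, u = heapq.heappop(pq)
        if d > dist[u] + 1e-15:
            continue
        if u == GOAL:
            break
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v] - 1e-15:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(pq, (nd, v))

    if not np.isfinite(dist[GOAL]):
        return math.inf, np.empty((0, 2))
    path = []
    u = GOAL
    while u != -1:
        if u == GOAL:
            path.append(np.array([nodes[prev[u]][0], L]))
        else:
            path.append(nodes[u])
        u = prev[u]
    return float(dist[GOAL]), np.array(path[::-1])


def shortest_path_length(
    layout: RouteLayout,
    corridor: CorridorSpec,
    agent_radius_m: float = 0.30,
) -> float:
    """Length (m) of the shortest collision-free path; ``inf`` if blocked."""
    length, _ = shortest_path(layout, corridor, agent_radius_m)
    return length


def grid_shortest_path_length(
    layout: RouteLayout,
    corridor: CorridorSpec,
    agent_radius_m: float = 0.30,
    cell_m: float = 0.05,
    move_radius: int = 5,
) -> float:
    """Dense-grid Dijkstra path length, for cross-checking the visibility graph.

    Free cells are grid points (spacing ``cell_m``) outside all inflated
    footprints; moves connect cells within a ``move_radius`` neighborhood of
    coprime offsets, each move requiring every traversed cell to be free.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra as _dijkstra

    W, L = corridor.width_m, corridor.length_m
    r = agent_radius_m
    rects = _inflated_rects(layout, r)
    xs = r + cell_m * np.arange(int(round((W - 2 * r) / cell_m)) + 1)
    ys = cell_m * np.arange(int(round(L / cell_m)) + 1)
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    free = np.ones((nx, ny), dtype=bool)
    for x0, y0, x1, y1 in rects:
        free &= ~((X > x0) & (X < x1) & (Y > y0) & (Y < y1))

    idx = -np.ones((nx, ny), dtype=np.int64)
    idx[free] = np.arange(free.sum())
    n_free = int(free.sum())

    moves = []
    for dx in range(-move_radius, move_radius + 1):
        for dy in range(0, move_radius + 1):
            if (dx, dy) == (0, 0) or (dy == 0 and dx <= 0):
                continue
            if math.gcd(abs(dx), dy) != 1:
                continue
            moves.append((dx, dy))

    rows, cols, ws = [], [], []
    for dx, dy in moves:
        # all intermediate lattice-adjacent cells along the move must be free
        steps = 2 * max(abs(dx), abs(dy))
        passable = free.copy()
        for k in range(1, steps + 1):
            ox = int(round(dx * k / steps))
            oy = int(round(dy * k / steps))
            shifted = np.zeros_like(free)
            sx0, sx1 = max(0, -ox), min(nx, nx - ox)
            sy0, sy1 = max(0, -oy), min(ny, ny - oy)
            shifted[sx0:sx1, sy0:sy1] = free[sx0 + ox:sx1 + ox, sy0 + oy:sy1 + oy]
            passable &= shifted
        src = idx[passable]
        di, dj = np.nonzero(passable)
        dst = idx[di + dx, dj + dy]
        w = cell_m * math.hypot(dx, dy)
        rows.append(src)
        cols.append(dst)
        ws.append(np.full(len(src), w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    ws = np.concatenate(ws)
    graph = coo_matrix((ws, (rows, cols)), shape=(n_free, n_free))

    si = int(np.argmin(np.abs(xs - W / 2)))
    if not free[si, 0]:
        return math.inf
    start = idx[si, 0]
    dist = _dijkstra(graph, directed=False, indices=start)
    goal_ids = idx[:, ny - 1][free[:, ny - 1]]
    if len(goal_ids) == 0:
        return math.inf
    return float(np.min(dist[goal_ids]))


# ---------------------------------------------------------------------------
# Route generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlotGrid:
    """Candidate obstacle slots: 13 longitudinal stations, each with a set
    of lateral center positions.  Stations alternate small/large boxes
    (7 small + 6 large)."""

    y_start: float = 2.0
    y_spacing: float = 1.5
    lateral_fracs: tuple[float, ...] = (0.19, 0.5, 0.81)

    def stations(self, corridor: CorridorSpec) -> list[tuple[float, str, list[float]]]:
        out = []
        for k in range(13):
            y = self.y_start + k * self.y_spacing
            size = "small" if k % 2 == 0 else "large"
            xs = [f * corridor.width_m for f in self.lateral_fracs]
            out.append((y, size, xs))
        return out


def generate_route_layouts(
    n_routes: int,
    corridor: CorridorSpec | None = None,
    *,
    tolerance: float = 0.02,
    seed: int = 0,
    agent_radius_m: float = 0.30,
    slot_grid: SlotGrid | None = None,
    max_attempts: int = 400,
) -> list[RouteLayout]:
    """Sample difficulty-matched route layouts and their mirrored versions.

    Draws candidate layouts on the slot grid, computes each candidate's
    shortest-path length, and keeps ``n_routes`` layouts whose lengths all
    lie within ``tolerance`` (a fraction) of their median.  The mirrored
    version of each kept layout is appended, so ``2 * n_routes`` layouts are
    returned.  Deterministic given ``seed``.
    """
    if n_routes < 1:
        raise ValueError("n_routes must be >= 1")
    corridor = corridor or CorridorSpec()
    slot_grid = slot_grid or SlotGrid()
    rng = np.random.default_rng(seed)
    stations = slot_grid.stations(corridor)

    candidates: list[tuple[RouteLayout, float]] = []
    for attempt in range(max_attempts):
        obstacles = []
        for y, size, xs in stations:
            obstacles.append(ObstacleSpec(size, float(rng.choice(xs)), y))
        layout = RouteLayout(tuple(obstacles), layout_id=f"route-{seed}-{attempt}")
        try:
            layout.validate(corridor)
        except ValueError:
            continue
        length = shortest_path_length(layout, corridor, agent_radius_m)
        if not math.isfinite(length):
            continue
        candidates.append((layout, length))
        if len(candidates) >= n_routes:
            picked = _matched_subset(candidates, n_routes, tolerance)
            if picked is not None:
                base = [candidates[i][0] for i in picked]
                return base + [mirror_layout(l, corridor) for l in base]
    raise RouteSearchError(
        f"could not find {n_routes} layouts within {tolerance:.1%} of median "
        f"difficulty after {max_attempts} attempts"
    )


def _matched_subset(candidates, n_routes: int, tolerance: float):
    """Indices of n_routes candidates whose lengths lie within tolerance of
    their median, or None."""
    order = sorted(range(len(candidates)), key=lambda i: candidates[i][1])
    lengths = [candidates[i][1] for i in order]
    for a in range(len(order) - n_routes + 1):
        window = lengths[a:a + n_routes]
        med = float(np.median(window))
        if all(abs(l - med) <= tolerance * med + 1e-12 for l in window):
            return [order[a + k] for k in range(n_routes)]
    return None


def walkthrough(
    layout: RouteLayout,
    corridor: CorridorSpec,
    speed_mps: float = 1.0,
    frame_rate_hz: float = 10.0,
    *,
    eye_height_m: float = 1.70,
    agent_radius_m: float = 0.30,
    fov_deg: float = 35.0,
) -> list[CameraPose]:
    """Camera poses walking the shortest path at constant speed.

    Poses are spaced ``speed_mps / frame_rate_hz`` apart in arc length
    (inclusive of both endpoints), with yaw facing along the local path
    tangent."""
    if speed_mps <= 0:
        raise ValueError("speed_mps must be positive")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    length, pts = shortest_path(layout, corridor, agent_radius_m)
    if not math.isfinite(length):
        raise BlockedLayoutError("no collision-free path through layout")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    step = speed_mps / frame_rate_hz
    n_steps = int(math.floor(length / step + 1e-9))
    s_vals = np.minimum(np.arange(n_steps + 1) * step, length)
    if s_vals[-1] < length - 1e-9:
        s_vals = np.append(s_vals, length)
    xs = np.interp(s_vals, cum, pts[:, 0])
    ys = np.interp(s_vals, cum, pts[:, 1])
    poses = []
    for s, x, y in zip(s_vals, xs, ys):
        k = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        k = max(k, 0)
        tangent = seg[k] / max(seg_len[k], 1e-12)
        yaw = math.degrees(math.atan2(tangent[0], tangent[1]))
        poses.append(
            CameraPose(position=(float(x), float(y), eye_height_m), yaw_deg=yaw, fov_deg=fov_deg)
        )
    return poses
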