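"""Solar beam generation, first-hit ray casting, reflection and refraction.

Primary beams are parallel rays cast from a cell-centered lattice on a
horizontal source plane (default 100 m up, 0.2 m spacing, i.e. 25 beams/m^2)
along the current solar direction.  Each beam is intercepted by the first
facet it meets; one specular reflection and one Snell refraction are spawned
per hit and traced a single bounce further.

Two tracing paths exist deliberately: a brute-force all-pairs intersection
used as the oracle in tests, and an accelerated path that groups facets by
owning tree behind per-tree axis-aligned bounding boxes (facets of one tree
are contiguous in the mesh).  Both resolve ties toward the lowest facet
index, so their hit sets are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .mesh import CanopyMesh

__all__ = ["BeamGrid", "Hit", "HitBatch", "SecondaryBatch", "FacetIndex",
           "generate_beams", "ray_triangle_intersect", "first_hit",
           "reflect_direction", "refract_direction", "trace_secondary"]

PARALLEL_TOL = 1e-12     # on the normalized plane-alignment factor F
INSIDE_TOL = 1e-12       # barycentric slack at facet edges
SELF_HIT_EPS = 1e-6      # m, secondary-ray origin offset along its direction
SOURCE_PLANE_HALF = 400.0  # m, conceptual 800 x 800 m source plane half-size


@dataclass(frozen=True)
class BeamGrid:
    """Parallel solar beams from a horizontal source-plane lattice.

    ``source_points`` are the cell centers (z = ``source_height``) whose
    rays can reach the scene's bounding box; the conceptual full plane is
    800 x 800 m, and culling to the scene box never changes any hit.
    ``density`` is spacing^-2 beams per m^2 of horizontal plane.
    """

    spacing: float
    source_height: float
    direction: np.ndarray          # unit, downward
    source_points: np.ndarray      # (N, 3)

    @property
    def density(self) -> float:
        return self.spacing ** -2

    @property
    def n_beams(self) -> int:
        return len(self.source_points)


def generate_beams(direction: np.ndarray, scene_box: np.ndarray,
                   spacing: float = 0.2, source_height: float = 100.0,
                   cull: bool = True,
                   plane_center: tuple[float, float] = (25.0, 25.0)) -> BeamGrid:
    """Lay out the source lattice for one solar direction.

    ``direction`` is the unit beam vector (negative z); ``scene_box`` is a
    (2, 3) min/max box enclosing everything a beam may hit (crowns plus the
    ground rectangle of the plot).  With ``cull`` the lattice is restricted
    to cells whose rays intersect that box, computed by sliding the box's
    corners up to the source plane along the beam; cells are always taken
    from the fixed global lattice so culling cannot shift sample positions.
    """
    d = np.asarray(direction, dtype=float)
    if d[2] >= 0:
        raise ValueError("beam direction must point downward (sun above horizon)")
    d = d / np.linalg.norm(d)
    scene_box = np.asarray(scene_box, dtype=float)
    if scene_box.shape != (2, 3):
        raise ValueError("scene_box must be a (2, 3) min/max array")

    x0 = plane_center[0] - SOURCE_PLANE_HALF
    y0 = plane_center[1] - SOURCE_PLANE_HALF
    n_cells = int(round(2 * SOURCE_PLANE_HALF / spacing))

    if cull:
        # Project the 8 box corners onto the source plane along -direction.
        corners = np.array([[scene_box[i, 0], scene_box[j, 1], scene_box[k, 2]]
                            for i in (0, 1) for j in (0, 1) for k in (0, 1)])
        back = (source_height - corners[:, 2]) / (-d[2])
        src = corners[:, :2] + np.outer(back, -d[:2])
        # Tight index window: a cell center strictly outside the projected
        # interval (beyond float slack) cannot send its ray into the box.
        slack = 1e-9
        lo_i = math.ceil((src[:, 0].min() - x0) / spacing - 0.5 - slack)
        hi_i = math.floor((src[:, 0].max() - x0) / spacing - 0.5 + slack)
        lo_j = math.ceil((src[:, 1].min() - y0) / spacing - 0.5 - slack)
        hi_j = math.floor((src[:, 1].max() - y0) / spacing - 0.5 + slack)
    else:
        lo_i = lo_j = 0
        hi_i = hi_j = n_cells - 1
    lo_i, hi_i = max(0, lo_i), min(n_cells - 1, hi_i)
    lo_j, hi_j = max(0, lo_j), min(n_cells - 1, hi_j)

    xs = x0 + (np.arange(lo_i, hi_i + 1) + 0.5) * spacing
    ys = y0 + (np.arange(lo_j, hi_j + 1) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(),
                           np.full(gx.size, float(source_height))])
    return BeamGrid(spacing=float(spacing), source_height=float(source_height),
                    direction=d, source_points=pts)


@dataclass(frozen=True)
class Hit:
    """A single ray-facet intersection."""

    beam_index: int
    triangle_index: int
    point: np.ndarray
    t: float
    incidence_cosine: float


def ray_triangle_intersect(origin, direction, triangle) -> Hit | None:
    """Reference single-ray intersection via the plane/inside-test route.

    The facet plane is met at t = N.(p1 - origin) / F with F = N.direction;
    |F| below ``PARALLEL_TOL`` (after normalizing) means the ray runs
    parallel to the plane.  The point-in-triangle test checks that the
    cross products of the three vertex-to-point vectors agree in direction.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    tri = np.asarray(triangle, dtype=float)
    direction = direction / np.linalg.norm(direction)
    n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-300 or 0.5 * n_norm < 1e-10:   # zero-area facet
        return None
    f = float(n @ direction)
    if abs(f) / n_norm < PARALLEL_TOL:
        return None
    t = float(n @ (tri[0] - origin)) / f
    if t <= 0.0:
        return None
    p = origin + t * direction
    n1, n2, n3 = p - tri[0], p - tri[1], p - tri[2]
    c12, c23, c13 = np.cross(n1, n2), np.cross(n2, n3), np.cross(n1, n3)
    scale = n_norm ** 2
    if (c12 @ c23 < -INSIDE_TOL * scale or c12 @ c13 > INSIDE_TOL * scale
            or c23 @ c13 > INSIDE_TOL * scale):
        # c13 points opposite c12/c23 for interior points (vertex order).
        return None
    cos_inc = abs(f) / n_norm
    return Hit(beam_index=-1, triangle_index=-1, point=p, t=t,
               incidence_cosine=cos_inc)


@njit(cache=False)
def _trace_kernel(origins, dirs, v0, e1, e2, inv2area, tree_off,
                  box_min, box_max, skip_tree, skip_facet):
    n_rays = origins.shape[0]
    n_trees = tree_off.shape[0] - 1
    out_idx = np.full(n_rays, -1, np.int64)
    out_t = np.full(n_rays, np.inf)
    for r in range(n_rays):
        ox, oy, oz = origins[r, 0], origins[r, 1], origins[r, 2]
        dx, dy, dz = dirs[r, 0], dirs[r, 1], dirs[r, 2]
        best_t = np.inf
        best_j = -1
        for tr in range(n_trees):
            if tr == skip_tree[r]:
                continue
            # slab test against the tree's AABB
            tmin = 0.0
            tmax = best_t if best_t < np.inf else 1e30
            ok = True
            for ax in range(3):
                o = origins[r, ax]
                dd = dirs[r, ax]
                if abs(dd) < 1e-300:
                    if o < box_min[tr, ax] or o > box_max[tr, ax]:
                        ok = False
                        break
                else:
                    inv = 1.0 / dd
                    t1 = (box_min[tr, ax] - o) * inv
                    t2 = (box_max[tr, ax] - o) * inv
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tmin:
                        tmin = t1
                    if t2 < tmax:
                        tmax = t2
                    if tmin > tmax:
                        ok = False
                        break
            if not ok:
                continue
            for j in range(tree_off[tr], tree_off[tr + 1]):
                if j == skip_facet[r]:
                    continue
                # Moller-Trumbore with the parallel test on the
                # normalized alignment factor F = N.d / |N|.
                px = dy * e2[j, 2] - dz * e2[j, 1]
                py = dz * e2[j, 0] - dx * e2[j, 2]
                pz = dx * e2[j, 1] - dy * e2[j, 0]
                det = px * e1[j, 0] + py * e1[j, 1] + pz * e1[j, 2]
                if abs(det) * inv2area[j] < PARALLEL_TOL:
                    continue
                inv_det = 1.0 / det
                tx = ox - v0[j, 0]
                ty = oy - v0[j, 1]
                tz = oz - v0[j, 2]
                u = (tx * px + ty * py + tz * pz) * inv_det
                if u < -INSIDE_TOL or u > 1.0 + INSIDE_TOL:
                    continue
                qx = ty * e1[j, 2] - tz * e1[j, 1]
                qy = tz * e1[j, 0] - tx * e1[j, 2]
                qz = tx * e1[j, 1] - ty * e1[j, 0]
                v = (dx * qx + dy * qy + dz * qz) * inv_det
                if v < -INSIDE_TOL or u + v > 1.0 + INSIDE_TOL:
                    continue
                t = (e2[j, 0] * qx + e2[j, 1] * qy + e2[j, 2] * qz) * inv_det
                if t <= PARALLEL_TOL:
                    continue
                if t < best_t:
                    best_t = t
                    best_j = j
        out_idx[r] = best_j
        out_t[r] = best_t
    return out_idx, out_t


class FacetIndex:
    """Precomputed per-tree bounding boxes and edge vectors for tracing."""

    def __init__(self, mesh: CanopyMesh):
        self.mesh = mesh
        fv = mesh.facet_vertices()
        self.v0 = np.ascontiguousarray(fv[:, 0])
        self.e1 = np.ascontiguousarray(fv[:, 1] - fv[:, 0])
        self.e2 = np.ascontiguousarray(fv[:, 2] - fv[:, 0])
        with np.errstate(divide="ignore"):
            self.inv2area = np.where(mesh.areas > 0, 1.0 / (2.0 * mesh.areas),
                                     np.inf)
        off = mesh.tree_facet_offsets
        n_trees = len(off) - 1
        self.box_min = np.empty((n_trees, 3))
        self.box_max = np.empty((n_trees, 3))
        for tr in range(n_trees):
            sl = fv[off[tr]:off[tr + 1]].reshape(-1, 3)
            self.box_min[tr] = sl.min(axis=0)
            self.box_max[tr] = sl.max(axis=0)

    def trace(self, origins: np.ndarray, dirs: np.ndarray,
              skip_tree: np.ndarray | None = None,
              skip_facet: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
        n = len(origins)
        if skip_tree is None:
            skip_tree = np.full(n, -1, np.int64)
        if skip_facet is None:
            skip_facet = np.full(n, -1, np.int64)
        return _trace_kernel(np.ascontiguousarray(origins, dtype=float),
                             np.ascontiguousarray(dirs, dtype=float),
                             self.v0, self.e1, self.e2, self.inv2area,
                             self.mesh.tree_facet_offsets,
                             self.box_min, self.box_max,
                             np.asarray(skip_tree, np.int64),
                             np.asarray(skip_facet, np.int64))


def _trace_brute(origins: np.ndarray, dirs: np.ndarray, mesh: CanopyMesh,
                 skip_tree: np.ndarray | None = None,
                 skip_facet: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive all-pairs first hit (vectorized); the acceleration oracle."""
    fv = mesh.facet_vertices()
    v0 = fv[:, 0]
    e1 = fv[:, 1] - fv[:, 0]
    e2 = fv[:, 2] - fv[:, 0]
    inv2area = np.where(mesh.areas > 0, 1.0 / (2.0 * mesh.areas), np.inf)
    n = len(origins)
    out_idx = np.full(n, -1, np.int64)
    out_t = np.full(n, np.inf)
    for r in range(n):
        d = dirs[r]
        p = np.cross(d[None, :], e2)
        det = np.einsum("ij,ij->i", p, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = 1.0 / det
            tvec = origins[r] - v0
            u = np.einsum("ij,ij->i", tvec, p) * inv_det
            q = np.cross(tvec, e1)
            v = (q @ d) * inv_det
            t = np.einsum("ij,ij->i", e2, q) * inv_det
        ok = ((np.abs(det) * inv2area >= PARALLEL_TOL)
              & (u >= -INSIDE_TOL) & (v >= -INSIDE_TOL)
              & (u + v <= 1.0 + INSIDE_TOL) & (t > PARALLEL_TOL))
        if skip_tree is not None and skip_tree[r] >= 0:
            ok &= mesh.tree_index != skip_tree[r]
        if skip_facet is not None and skip_facet[r] >= 0:
            ok[skip_facet[r]] = False
        if ok.any():
            cand = np.nonzero(ok)[0]
            # lowest facet index among minimal t (argmin returns first)
            j = cand[np.argmin(t[cand])]
            out_idx[r] = j
            out_t[r] = t[j]
    return out_idx, out_t


@dataclass
class HitBatch:
    """First hits of a batch of rays (misses dropped).

    ``ray_index`` refers to the input ray ordering; ``n_rays`` and
    ``n_miss`` keep the bookkeeping of beams that reached the ground.
    """

    ray_index: np.ndarray     # (H,)
    facet: np.ndarray         # (H,)
    t: np.ndarray             # (H,)
    point: np.ndarray         # (H, 3)
    cos_inc: np.ndarray       # (H,) |N.d|, folded into [0, 1]
    direction: np.ndarray     # (H, 3) propagation direction of each ray
    n_rays: int

    @property
    def n_hits(self) -> int:
        return len(self.facet)

    @property
    def n_miss(self) -> int:
        return self.n_rays - self.n_hits


def first_hit(origins: np.ndarray, dirs: np.ndarray, mesh: CanopyMesh,
              index: FacetIndex | None = None, accelerated: bool = True,
              skip_tree: np.ndarray | None = None,
              skip_facet: np.ndarray | None = None) -> HitBatch:
    """First-hit resolution for a ray batch.

    Every ray is assigned the facet with minimal positive t (ties to the
    lowest facet index) or dropped as a miss; ``accelerated`` switches
    between the per-tree-box path and the exhaustive oracle path.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    if len(dirs) == 1 and len(origins) > 1:
        dirs = np.broadcast_to(dirs, origins.shape)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    if accelerated:
        if index is None:
            index = FacetIndex(mesh)
        idx, t = index.trace(origins, dirs, skip_tree, skip_facet)
    else:
        idx, t = _trace_brute(origins, dirs, mesh, skip_tree, skip_facet)
    hit = idx >= 0
    rays = np.nonzero(hit)[0]
    facets = idx[hit]
    th = t[hit]
    pts = origins[rays] + th[:, None] * dirs[rays]
    cos_inc = np.abs(np.einsum("ij,ij->i", mesh.normals[facets], dirs[rays]))
    cos_inc = np.clip(cos_inc, 0.0, 1.0)
    return HitBatch(ray_index=rays, facet=facets, t=th, point=pts,
                    cos_inc=cos_inc, direction=np.ascontiguousarray(dirs[rays]),
                    n_rays=len(origins))


def reflect_direction(incident: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Mirror reflection r = d - 2 (d.n) n; unit in, unit out.

    Vectorized over leading dimensions.
    """
    incident = np.asarray(incident, dtype=float)
    normal = np.asarray(normal, dtype=float)
    dot = np.sum(incident * normal, axis=-1, keepdims=True)
    return incident - 2.0 * dot * normal


def refract_direction(incident: np.ndarray, normal: np.ndarray,
                      e: float = 0.5) -> np.ndarray:
    """Snell refraction t = e d + (e c1 - c2) n for a ray entering a surface.

    ``normal`` must oppose the incident direction (n.d < 0); c1 = -n.d and
    c2 = sqrt(1 - e^2 (1 - c1^2)).  With e <= 1 the radicand cannot go
    negative, but it is checked anyway.
    """
    incident = np.asarray(incident, dtype=float)
    normal = np.asarray(normal, dtype=float)
    c1 = -np.sum(incident * normal, axis=-1, keepdims=True)
    radicand = 1.0 - e * e * (1.0 - c1 * c1)
    if np.any(radicand < 0):
        raise ValueError("total internal reflection: e sin(theta) > 1")
    c2 = np.sqrt(radicand)
    out = e * incident + (e * c1 - c2) * normal
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


@dataclass
class SecondaryBatch:
    """Second-bounce hits with their parent-hit bookkeeping.

    ``parent`` indexes into the originating ``HitBatch`` arrays; ``facet``
    and ``cos_inc`` describe the receiving facet.  ``n_rays`` is the number
    of secondary rays launched (one per parent hit).
    """

    kind: str                 # "reflected" or "transmitted"
    parent: np.ndarray        # (S,)
    facet: np.ndarray         # (S,)
    t: np.ndarray
    point: np.ndarray
    cos_inc: np.ndarray
    n_rays: int

    @property
    def n_hits(self) -> int:
        return len(self.facet)


def trace_secondary(hits: HitBatch, mesh: CanopyMesh,
                    index: FacetIndex | None = None,
                    refraction_index: float = 0.5,
                    accelerated: bool = True
                    ) -> tuple[SecondaryBatch, SecondaryBatch]:
    """Spawn and trace one reflected and one refracted ray per first hit.

    Reflected rays may re-hit the originating tree but not the originating
    facet; transmitted rays pass through the whole originating crown and
    may only hit *other* trees.  Recursion stops after this single bounce.
    """
    if index is None and accelerated:
        index = FacetIndex(mesh)
    normals = mesh.normals[hits.facet]
    d = hits.direction
    # Facet normals are stored outward/upward; flip any that do not oppose
    # the incoming ray so reflection and Snell's law see a proper interface.
    sign = np.where(np.sum(normals * d, axis=1, keepdims=True) > 0, -1.0, 1.0)
    n_opp = normals * sign

    out = []
    for kind in ("reflected", "transmitted"):
        if kind == "reflected":
            new_dir = reflect_direction(d, n_opp)
            skip_tree = None
            skip_facet = hits.facet
        else:
            new_dir = refract_direction(d, n_opp, refraction_index)
            skip_tree = mesh.tree_index[hits.facet]
            skip_facet = hits.facet
        origins = hits.point + SELF_HIT_EPS * new_dir
        sub = first_hit(origins, new_dir, mesh, index=index,
                        accelerated=accelerated, skip_tree=skip_tree,
                        skip_facet=skip_facet)
        out.append(SecondaryBatch(kind=kind, parent=sub.ray_index,
                                  facet=sub.facet, t=sub.t, point=sub.point,
                                  cos_inc=sub.cos_inc, n_rays=hits.n_hits))
    return out[0], out[1]
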