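"""Cortical folding metrics on the gray-white junction surface.

Three per-vertex measures are computed against the convex hull, the
"unfolded" reference envelope:

* **surface area** — triangle areas summed per lobe (each triangle credited
  to the majority region of its three vertices);
* **local gyrification index (LGI)** — ratio of the surface area within a
  geodesic patch of radius ``patch_radius`` around the vertex to the hull
  area within a Euclidean ball of the same radius centred at the vertex's
  nearest hull point; about 1 for a smooth convex surface, larger with
  folding;
* **sulcal depth** — exact Euclidean distance from the vertex to the nearest
  point (not vertex) of the matching hemisphere's hull.

Geodesic distances are graph shortest paths over the mesh vertices.  The
path graph joins every vertex pair within ``chord_hops`` mesh edges by a
straight-line chord: on marching-cubes meshes, pure edge paths overestimate
geodesic distance by 10-15% because paths must zigzag along grid-aligned
edges, which would bias patch areas (and hence LGI) low by ~20%; chords spanning
a few hops (a few mm) cut that distortion below ~1.5% while remaining far
too short to tunnel across sulci at the fold wavelengths modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .errors import ValidationError
from .surface import HEMI_CODES, HullMesh, SurfaceMesh
from .volume import LOBES


@dataclass(frozen=True)
class LGIParams:
    """Parameters of the local gyrification index.

    patch_radius:
        Geodesic radius (mm) of the circular patch; must exceed three mean
        edge lengths of the mesh for the patch to be resolved.
    chord_hops:
        Hop count of the chord augmentation of the geodesic graph.
    """

    patch_radius: float = 15.0
    chord_hops: int = 4

    def __post_init__(self) -> None:
        if self.patch_radius <= 0:
            raise ValidationError("patch_radius must be positive")
        if self.chord_hops < 1:
            raise ValidationError("chord_hops must be >= 1")


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex associated area: one third of each incident triangle."""
    areas = np.zeros(len(mesh.vertices))
    fa = mesh.mesh.area_faces
    for i in range(3):
        np.add.at(areas, mesh.faces[:, i], fa / 3.0)
    return areas


def geodesic_graph(mesh: SurfaceMesh, chord_hops: int = 4) -> csr_matrix:
    """Symmetric sparse graph of chord distances between near-by vertices.

    Vertices within ``chord_hops`` mesh edges are connected by their
    Euclidean (chord) distance; shortest paths on this graph approximate
    surface geodesics with low metric distortion.
    """
    nv = len(mesh.vertices)
    E = mesh.mesh.edges_unique
    ones = np.ones(2 * len(E))
    B = csr_matrix(
        (ones, (np.r_[E[:, 0], E[:, 1]], np.r_[E[:, 1], E[:, 0]])), shape=(nv, nv)
    )
    B.data[:] = 1.0
    reach = B.copy()
    power = B.copy()
    for _ in range(chord_hops - 1):
        power = power @ B
        power.data[:] = 1.0
        reach = reach + power
    reach = csr_matrix(reach)
    reach.setdiag(0)
    reach.eliminate_zeros()
    r, c = reach.nonzero()
    w = np.linalg.norm(mesh.vertices[r] - mesh.vertices[c], axis=1)
    return csr_matrix((w, (r, c)), shape=(nv, nv))


def geodesic_patch_areas(
    graph: csr_matrix,
    weights: np.ndarray,
    radius: float,
    sources: np.ndarray | None = None,
    batch: int = 512,
    soft_width: float = 0.0,
) -> np.ndarray:
    """Summed ``weights`` over vertices within geodesic ``radius`` of each source.

    With ``soft_width > 0`` vertices in a band of that width around the patch
    boundary are partially counted (linear ramp), which suppresses the
    boundary-discretization jitter of a hard cutoff.
    """
    nv = graph.shape[0]
    if sources is None:
        sources = np.arange(nv)
    limit = radius + soft_width
    out = np.empty(len(sources))
    for start in range(0, len(sources), batch):
        idx = sources[start : start + batch]
        d = dijkstra(graph, indices=idx, limit=limit)
        if soft_width > 0:
            with np.errstate(invalid="ignore"):
                w = np.clip(0.5 + (radius - d) / soft_width, 0.0, 1.0)
            w[~np.isfinite(d)] = 0.0
        else:
            w = np.where(np.isfinite(d) & (d <= radius), 1.0, 0.0)
        out[start : start + batch] = w @ weights
    return out


# -- exact point-to-triangle distances ----------------------------------------


def _point_triangle_distance(
    p: np.ndarray, tri: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distance and closest point from each ``p[i]`` to triangle ``tri[i]``.

    Vectorized closest-point-on-triangle (barycentric region test).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    closest[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    closest[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    closest[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    closest[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return np.linalg.norm(p - closest, axis=1), closest


def closest_on_hull(points: np.ndarray, hull: HullMesh) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest hull-surface point and distance for each query point.

    Candidate triangles are pruned with a KD-tree on face centroids, with a
    certified radius check so the true minimiser is never missed.
    """
    tris = hull.mesh.triangles.view(np.ndarray)
    centroids = tris.mean(axis=1)
    # max distance from a centroid to its triangle's far corner
    slack = np.linalg.norm(tris - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)

    k = min(32, len(tris))
    dc, idx = tree.query(points, k=k)
    if k == 1:
        dc, idx = dc[:, None], idx[:, None]
    n = len(points)
    flat_p = np.repeat(points, k, axis=0)
    flat_t = tris[idx.ravel()]
    d, cp = _point_triangle_distance(flat_p, flat_t)
    d = d.reshape(n, k)
    cp = cp.reshape(n, k, 3)
    best = d.argmin(axis=1)
    dist = d[np.arange(n), best]
    closest = cp[np.arange(n), best]

    # certify: any triangle closer than dist must have centroid within
    # dist + slack; if the k-th centroid is nearer than that, re-examine.
    uncertified = dc[:, -1] < dist + slack
    for i in np.nonzero(uncertified)[0]:
        cand = tree.query_ball_point(points[i], dist[i] + slack)
        di, cpi = _point_triangle_distance(
            np.repeat(points[i][None], len(cand), axis=0), tris[cand]
        )
        j = int(np.argmin(di))
        if di[j] < dist[i]:
            dist[i], closest[i] = di[j], cpi[j]
    return dist, closest


def _subdivided_face_samples(
    mesh, max_edge: float
) -> tuple[np.ndarray, np.ndarray]:
    """Centroids and areas of mesh faces subdivided until edges <= max_edge."""
    import trimesh as _trimesh

    v, f = _trimesh.remesh.subdivide_to_size(
        mesh.vertices.view(np.ndarray), mesh.faces.view(np.ndarray), max_edge
    )
    tris = v[f]
    centroids = tris.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1
    )
    return centroids, areas


def sulcal_depth(mesh: SurfaceMesh, hull: HullMesh) -> np.ndarray:
    """Per-vertex sulcal depth (mm) against the matching hemisphere's hull.

    Returns a full-length array with NaN at vertices outside the hull's
    hemisphere; with a whole-surface hull every vertex gets a depth.
    """
    if hull.hemisphere == "both":
        sel = np.ones(len(mesh.vertices), dtype=bool)
    elif hull.hemisphere in HEMI_CODES:
        sel = mesh.hemisphere == HEMI_CODES[hull.hemisphere]
        if not sel.any():
            raise ValidationError(
                f"mesh has no vertices in hemisphere {hull.hemisphere!r}"
            )
    else:
        raise ValidationError(f"unknown hull hemisphere {hull.hemisphere!r}")
    depth = np.full(len(mesh.vertices), np.nan)
    dist, _ = closest_on_hull(mesh.vertices[sel], hull)
    depth[sel] = dist
    return depth


def local_gyrification_index(
    mesh: SurfaceMesh,
    hull: HullMesh,
    params: LGIParams = LGIParams(),
    graph: csr_matrix | None = None,
) -> np.ndarray:
    """Per-vertex local gyrification index.

    Numerator: associated vertex areas within geodesic ``patch_radius`` of
    the vertex.  Denominator: hull vertex areas within a Euclidean ball of
    the same radius centred at the vertex's nearest hull point (a vertex-area
    discretization of the ball-hull intersection).  Vertices outside the
    hull's hemisphere get NaN.
    """
    mean_edge = float(mesh.mesh.edges_unique_length.mean())
    if params.patch_radius <= 3.0 * mean_edge:
        raise ValidationError(
            f"patch_radius {params.patch_radius} mm does not resolve a mesh "
            f"with mean edge length {mean_edge:.2f} mm"
        )
    if hull.hemisphere == "both":
        sel = np.ones(len(mesh.vertices), dtype=bool)
    elif hull.hemisphere in HEMI_CODES:
        sel = mesh.hemisphere == HEMI_CODES[hull.hemisphere]
        if not sel.any():
            raise ValidationError(
                f"mesh has no vertices in hemisphere {hull.hemisphere!r}"
            )
    else:
        raise ValidationError(f"unknown hull hemisphere {hull.hemisphere!r}")

    if graph is None:
        graph = geodesic_graph(mesh, params.chord_hops)
    weights = vertex_areas(mesh)
    numerator = geodesic_patch_areas(
        graph,
        weights,
        params.patch_radius,
        sources=np.nonzero(sel)[0],
        soft_width=mean_edge,
    )

    _, anchors = closest_on_hull(mesh.vertices[sel], hull)
    # hull faces can be large and flat; subdivide them so the ball-intersected
    # area is resolved at the same scale as the surface mesh
    soft = mean_edge
    centroids, face_areas = _subdivided_face_samples(hull.mesh, max_edge=soft)
    tree = cKDTree(centroids)
    radius = params.patch_radius
    denominator = np.empty(len(anchors))
    chunk = 256
    for start in range(0, len(anchors), chunk):
        block = anchors[start : start + chunk]
        neighborhoods = tree.query_ball_point(block, radius + soft)
        for j, nb in enumerate(neighborhoods):
            d = np.linalg.norm(centroids[nb] - block[j], axis=1)
            w = np.clip(0.5 + (radius - d) / soft, 0.0, 1.0)
            denominator[start + j] = (w * face_areas[nb]).sum()
    if np.any(denominator <= 0):
        raise ValidationError(
            "empty hull patch: patch_radius too small for the hull resolution"
        )

    lgi = np.full(len(mesh.vertices), np.nan)
    lgi[sel] = numerator / denominator
    return lgi


# -- lobar aggregation --------------------------------------------------------


@dataclass
class LobeFeatures:
    """Per-lobe and global (four-lobe combined) folding summaries.

    Areas are mm^2; missing lobes (no vertices) carry NaN.
    """

    area: dict[str, float] = field(default_factory=dict)
    mean_lgi: dict[str, float] = field(default_factory=dict)
    mean_depth: dict[str, float] = field(default_factory=dict)

    def as_row(self, prefix: str = "") -> dict[str, float]:
        row: dict[str, float] = {}
        for lobe in (*LOBES, "global"):
            row[f"{prefix}area_{lobe}"] = self.area.get(lobe, np.nan)
            row[f"{prefix}lgi_{lobe}"] = self.mean_lgi.get(lobe, np.nan)
            row[f"{prefix}depth_{lobe}"] = self.mean_depth.get(lobe, np.nan)
        return row


def triangle_regions(mesh: SurfaceMesh) -> np.ndarray:
    """Majority region label per triangle (tie: region of the lowest vertex index)."""
    if not mesh.has_regions:
        raise ValidationError("mesh has no region assignment")
    vr = mesh.region[mesh.faces]  # (nf, 3)
    out = np.empty(len(vr), dtype=np.int32)
    # majority of three: if any pair agrees, that label wins; else first vertex
    ab = vr[:, 0] == vr[:, 1]
    ac = vr[:, 0] == vr[:, 2]
    bc = vr[:, 1] == vr[:, 2]
    out[:] = vr[:, 0]
    only_bc = bc & ~ab & ~ac
    out[only_bc] = vr[only_bc, 1]
    distinct = ~(ab | ac | bc)
    if distinct.any():
        rows = np.nonzero(distinct)[0]
        col = mesh.faces[rows].argmin(axis=1)
        out[rows] = vr[rows, col]
    return out


def lobe_surface_area(
    mesh: SurfaceMesh, hemisphere: str | None = None
) -> dict[str, float]:
    """Surface area (mm^2) per lobe, pooled over hemispheres by default."""
    tri_region = triangle_regions(mesh)
    fa = mesh.mesh.area_faces
    if hemisphere is not None:
        tri_hemi = _triangle_hemispheres(mesh)
        keep = tri_hemi == HEMI_CODES[hemisphere]
        tri_region, fa = tri_region[keep], fa[keep]
    out: dict[str, float] = {}
    for lobe in LOBES:
        sel = np.zeros(len(tri_region), dtype=bool)
        for label in _lobe_labels(lobe, hemisphere):
            sel |= tri_region == label
        out[lobe] = float(fa[sel].sum())
    return out


def _lobe_labels(lobe: str, hemisphere: str | None) -> list[int]:
    from .volume import region_label

    hemis = [hemisphere] if hemisphere else ["left", "right"]
    return [region_label(lobe, h) for h in hemis]


def _triangle_hemispheres(mesh: SurfaceMesh) -> np.ndarray:
    """Majority hemisphere per triangle."""
    vh = mesh.hemisphere[mesh.faces]
    return (vh.sum(axis=1) >= 2).astype(np.int8)


def aggregate_features(
    mesh: SurfaceMesh,
    lgi: np.ndarray,
    depth: np.ndarray,
    hemisphere: str | None = None,
) -> LobeFeatures:
    """Area-weighted lobar means and the global four-lobe combination.

    Lobe means weight each vertex by its associated area; the global mean is
    the area-weighted mean over the four lobes (equivalently over their
    vertices), and the global area is the sum of the lobe areas.  A lobe
    without vertices is reported as NaN and excluded from the global
    combination.
    """
    if not mesh.has_regions:
        raise ValidationError("mesh has no region assignment")
    areas = lobe_surface_area(mesh, hemisphere)
    weights = vertex_areas(mesh)
    feat = LobeFeatures(area=dict(areas))

    hemi_sel = (
        np.ones(len(mesh.vertices), dtype=bool)
        if hemisphere is None
        else mesh.hemisphere == HEMI_CODES[hemisphere]
    )
    lobe_w: dict[str, float] = {}
    for lobe in LOBES:
        sel = np.isin(mesh.region, _lobe_labels(lobe, hemisphere)) & hemi_sel
        if not sel.any():
            feat.area[lobe] = np.nan
            feat.mean_lgi[lobe] = np.nan
            feat.mean_depth[lobe] = np.nan
            continue
        w = weights[sel]
        lobe_w[lobe] = float(w.sum())
        for name, values in (("mean_lgi", lgi), ("mean_depth", depth)):
            v = values[sel]
            ok = np.isfinite(v)
            getattr(feat, name)[lobe] = (
                float(np.average(v[ok], weights=w[ok])) if ok.any() else np.nan
            )

    present = [l for l in LOBES if np.isfinite(feat.area.get(l, np.nan))]
    if present:
        feat.area["global"] = float(sum(feat.area[l] for l in present))
        for name in ("mean_lgi", "mean_depth"):
            vals = np.array([getattr(feat, name)[l] for l in present])
            w = np.array([lobe_w[l] for l in present])
            ok = np.isfinite(vals)
            getattr(feat, name)["global"] = (
                float(np.average(vals[ok], weights=w[ok])) if ok.any() else np.nan
            )
    else:
        feat.area["global"] = np.nan
        feat.mean_lgi["global"] = np.nan
        feat.mean_depth["global"] = np.nan
    return feat
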