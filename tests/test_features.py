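"""Folding metrics: patch areas, gyrification index, sulcal depth, aggregation."""

import heapq
import math

import numpy as np
import pytest
import trimesh

from fetalfold import (
    LabelVolume,
    LGIParams,
    SurfaceMesh,
    ValidationError,
    aggregate_features,
    convex_hull_mesh,
    extract_junction_mesh,
    lobe_surface_area,
    local_gyrification_index,
    sulcal_depth,
    vertex_areas,
)
from fetalfold.features import geodesic_graph, geodesic_patch_areas
from fetalfold.volume import region_label

from conftest import cuboid_label_volume


def _icosphere_surface(radius=10.0, subdivisions=3) -> SurfaceMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    hemi = (m.vertices[:, 0] > 0).astype(np.int8)
    return SurfaceMesh(mesh=m, hemisphere=hemi)


def test_vertex_areas_sum_to_total(sphere_mesh):
    assert vertex_areas(sphere_mesh).sum() == pytest.approx(sphere_mesh.area)


# -- geodesic patch oracle -----------------------------------------------------


def _dijkstra_oracle(graph, source, limit):
    """Plain binary-heap Dijkstra, independent of scipy's implementation."""
    n = graph.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    indptr, indices, data = graph.indptr, graph.indices, graph.data
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u] or d > limit:
            continue
        for k in range(indptr[u], indptr[u + 1]):
            v = indices[k]
            nd = d + data[k]
            if nd < dist[v] and nd <= limit:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def test_patch_areas_match_exhaustive_geodesic_oracle():
    mesh = _icosphere_surface(radius=10.0, subdivisions=2)
    graph = geodesic_graph(mesh, chord_hops=4).tocsr()
    weights = vertex_areas(mesh)
    radius = 5.0
    soft = float(mesh.mesh.edges_unique_length.mean())
    ours = geodesic_patch_areas(graph, weights, radius, soft_width=soft)
    for v in range(len(mesh.vertices)):
        d = _dijkstra_oracle(graph, v, radius + soft)
        w = np.clip(0.5 + (radius - d) / soft, 0.0, 1.0)
        w[~np.isfinite(d)] = 0.0
        expected = float(w @ weights)
        assert ours[v] == pytest.approx(expected, rel=1e-6)


# -- LGI -----------------------------------------------------------------------


def test_convex_surface_lgi_near_one(sphere_mesh):
    hull = convex_hull_mesh(sphere_mesh, "both")
    lgi = local_gyrification_index(sphere_mesh, hull, LGIParams(patch_radius=10.0))
    assert np.all(np.isfinite(lgi))
    assert 0.95 <= np.min(lgi) and np.max(lgi) <= 1.05


def test_lgi_radius_must_resolve_mesh(sphere_mesh):
    hull = convex_hull_mesh(sphere_mesh, "both")
    with pytest.raises(ValidationError):
        local_gyrification_index(sphere_mesh, hull, LGIParams(patch_radius=1.0))


def test_lgi_scale_equivariance(sphere_mesh):
    """Uniform scaling by k leaves LGI unchanged when the radius scales too."""
    hull = convex_hull_mesh(sphere_mesh, "both")
    lgi = local_gyrification_index(sphere_mesh, hull, LGIParams(patch_radius=10.0))
    k = 2.0
    scaled = sphere_mesh.scaled(k)
    hull_s = convex_hull_mesh(scaled, "both")
    lgi_s = local_gyrification_index(scaled, hull_s, LGIParams(patch_radius=10.0 * k))
    assert np.allclose(lgi, lgi_s, atol=1e-9)


# -- sulcal depth --------------------------------------------------------------


def test_hull_vertices_have_zero_depth(sphere_mesh):
    from scipy.spatial import cKDTree

    hull = convex_hull_mesh(sphere_mesh, "both")
    depth = sulcal_depth(sphere_mesh, hull)
    d_to_hull_vertex, _ = cKDTree(hull.vertices).query(sphere_mesh.vertices)
    on_hull = d_to_hull_vertex < 1e-9
    assert on_hull.any()
    assert np.all(depth[on_hull] < 1e-6)


def test_depth_scales_linearly(sphere_mesh):
    hull = convex_hull_mesh(sphere_mesh, "both")
    depth = sulcal_depth(sphere_mesh, hull)
    k = 3.0
    scaled = sphere_mesh.scaled(k)
    hull_s = convex_hull_mesh(scaled, "both")
    depth_s = sulcal_depth(scaled, hull_s)
    assert np.allclose(depth_s, k * depth, atol=1e-8)


def test_radial_pit_depth_matches_construction():
    """A cylindrical pit carved into a sphere reads back its analytic depth.

    The hull bridges the pit mouth with a plane through the mouth ring at
    height sqrt(R^2 - r_pit^2), so the expected depth at the pit bottom is
    that height minus the bottom's height, not the raw carving depth.
    """
    R, pit_depth, pit_radius, spacing = 20.0, 8.0, 6.0, 1.0
    n = int(2 * (R + 5) / spacing)
    c = (n - 1) / 2 * spacing
    ax = np.arange(n) * spacing - c
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = X**2 + Y**2 + Z**2 <= R**2
    pit = (X**2 + Y**2 <= pit_radius**2) & (Z > R - pit_depth)
    data = np.where(inside & ~pit, 2, 0).astype(np.int16)
    seg = LabelVolume(data, (spacing,) * 3)
    mesh = extract_junction_mesh(seg, ("wm",))
    hull = convex_hull_mesh(mesh, "both")
    depth = sulcal_depth(mesh, hull)
    rel = mesh.vertices - c
    bottom = (rel[:, 0] ** 2 + rel[:, 1] ** 2 <= (pit_radius / 3) ** 2) & (
        rel[:, 2] > 0
    )
    assert bottom.any()
    # the isosurface of the carved bottom sits half a voxel above the cut
    bottom_height = (R - pit_depth) + spacing / 2
    expected = np.sqrt(R**2 - pit_radius**2) - bottom_height
    assert np.max(depth[bottom]) == pytest.approx(expected, abs=0.5)


def test_depth_matches_sampled_hull_oracle(sphere_mesh):
    rng = np.random.default_rng(0)
    hull = convex_hull_mesh(sphere_mesh, "left")
    depth = sulcal_depth(sphere_mesh, hull)
    sel = ~np.isnan(depth)
    samples, _ = trimesh.sample.sample_surface(hull.mesh, 100_000, seed=1)
    sub = rng.choice(np.nonzero(sel)[0], 200, replace=False)
    for v in sub:
        brute = np.linalg.norm(samples - sphere_mesh.vertices[v], axis=1).min()
        # sampled minimum can only overestimate the true distance
        assert depth[v] <= brute + 1e-9
        assert brute - depth[v] < 0.5  # sampling resolution bound


def test_depth_requires_matching_hemisphere(sphere_mesh):
    left_only = SurfaceMesh(
        mesh=sphere_mesh.mesh,
        hemisphere=np.zeros(len(sphere_mesh.vertices), dtype=np.int8),
        region=sphere_mesh.region,
    )
    hull_right = convex_hull_mesh(sphere_mesh, "right")
    with pytest.raises(ValidationError):
        sulcal_depth(left_only, hull_right)


def test_perturbing_one_hemisphere_leaves_other_depths_identical(sphere_mesh):
    hull_left = convex_hull_mesh(sphere_mesh, "left")
    base = sulcal_depth(sphere_mesh, hull_left)
    perturbed = sphere_mesh.scaled(1.0)
    right = perturbed.hemisphere == 1
    perturbed.mesh.vertices[right] *= 1.05  # inflate the right hemisphere
    hull_left2 = convex_hull_mesh(perturbed, "left")
    after = sulcal_depth(perturbed, hull_left2)
    sel = sphere_mesh.hemisphere == 0
    assert np.array_equal(base[sel], after[sel])


# -- lobar aggregation ---------------------------------------------------------


def _toy_two_region_mesh():
    """Flat 3-triangle strip with hand-assignable regions and areas."""
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 0, 0]], dtype=float
    )
    faces = np.array([[0, 1, 2], [1, 3, 2], [1, 4, 3]])
    m = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    region = np.array(
        [
            region_label("frontal", "left"),
            region_label("frontal", "left"),
            region_label("frontal", "left"),
            region_label("parietal", "left"),
            region_label("parietal", "left"),
        ],
        dtype=np.int32,
    )
    return SurfaceMesh(
        mesh=m, hemisphere=np.zeros(5, dtype=np.int8), region=region
    )


def test_lobe_area_majority_rule_hand_computed():
    mesh = _toy_two_region_mesh()
    areas = lobe_surface_area(mesh)
    # triangles 0,1 majority frontal (2/3 and tie->lowest vertex); tri 2 parietal
    assert areas["frontal"] == pytest.approx(1.0)
    assert areas["parietal"] == pytest.approx(0.5)
    assert sum(areas.values()) == pytest.approx(mesh.area)


def test_single_lobe_mesh_gets_total_area(sphere_mesh):
    uniform = SurfaceMesh(
        mesh=sphere_mesh.mesh,
        hemisphere=sphere_mesh.hemisphere,
        region=np.full(len(sphere_mesh.vertices), region_label("frontal", "left"),
                       dtype=np.int32),
    )
    areas = lobe_surface_area(uniform)
    assert areas["frontal"] == pytest.approx(uniform.area)
    assert areas["parietal"] == 0.0


def test_sphere_hemispheric_regions_split_area_evenly(sphere_mesh):
    """Hemispheric regions on a sphere carry half the area each.

    The divider sits between voxel rows (no vertex exactly on it); the
    analytic expectation is the spherical-zone area on each side.
    """
    left = region_label("frontal", "left")
    right = region_label("frontal", "right")
    R = 20.0
    offset = 0.5  # mm off the sphere centre, between voxel rows
    divider = sphere_mesh.mid_sagittal_x + offset
    split = SurfaceMesh(
        mesh=sphere_mesh.mesh,
        hemisphere=(sphere_mesh.vertices[:, 0] > divider).astype(np.int8),
        region=np.where(
            sphere_mesh.vertices[:, 0] <= divider, left, right
        ).astype(np.int32),
    )
    areas_l = lobe_surface_area(split, hemisphere="left")
    areas_r = lobe_surface_area(split, hemisphere="right")
    assert areas_l["frontal"] + areas_r["frontal"] == pytest.approx(
        split.area, rel=1e-9
    )
    # spherical zone area is proportional to the slab height
    expected_left = split.area * (R + offset) / (2 * R)
    assert areas_l["frontal"] == pytest.approx(expected_left, rel=0.02)


def test_constant_field_aggregates_to_constant():
    mesh = _toy_two_region_mesh()
    c = 3.25
    lgi = np.full(5, c)
    depth = np.full(5, 2 * c)
    feats = aggregate_features(mesh, lgi, depth)
    assert feats.mean_lgi["frontal"] == pytest.approx(c)
    assert feats.mean_lgi["global"] == pytest.approx(c)
    assert feats.mean_depth["global"] == pytest.approx(2 * c)
    assert feats.area["global"] == pytest.approx(sum(
        feats.area[l] for l in ("frontal", "parietal", "temporal", "occipital")
        if np.isfinite(feats.area[l])
    ))


def test_hand_computed_weighted_mean():
    mesh = _toy_two_region_mesh()
    lgi = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    depth = np.zeros(5)
    w = vertex_areas(mesh)
    feats = aggregate_features(mesh, lgi, depth)
    sel = mesh.region == region_label("frontal", "left")
    expected = np.average(lgi[sel], weights=w[sel])
    assert feats.mean_lgi["frontal"] == pytest.approx(expected, abs=1e-12)


def test_empty_lobe_flagged_missing_not_zero():
    mesh = _toy_two_region_mesh()
    feats = aggregate_features(mesh, np.ones(5), np.ones(5))
    assert math.isnan(feats.area["temporal"])
    assert math.isnan(feats.mean_lgi["temporal"])
    assert np.isfinite(feats.area["global"])


def test_mesh_without_regions_rejected():
    m = _icosphere_surface()
    with pytest.raises(ValidationError):
        lobe_surface_area(m)


def test_cuboid_bisected_area_bookkeeping():
    seg = cuboid_label_volume((20.0, 20.0, 20.0), spacing=1.0)
    mesh = extract_junction_mesh(seg, ("wm",))
    nx = seg.shape[0]
    half = (nx - 1) / 2 * seg.spacing[0]
    frontal = region_label("frontal", "left")
    parietal = region_label("parietal", "left")
    mesh.region = np.where(
        mesh.vertices[:, 2] <= half, frontal, parietal
    ).astype(np.int32)
    areas = lobe_surface_area(mesh)
    assert areas["frontal"] + areas["parietal"] == pytest.approx(mesh.area)
    # each half carries one 20x20 face plus half of the four side faces
    assert areas["frontal"] == pytest.approx(1200.0, rel=0.05)
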