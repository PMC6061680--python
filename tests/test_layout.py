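"""Regions, constrained spring layout, curvature, labels, hulls — each
geometric operation checked against an independent brute-force oracle."""

import math

import numpy as np
import pytest

from pathvis.errors import ConfigurationError
from pathvis.layout import (
    DEFAULT_REGION_FRACTIONS,
    LayoutParams,
    Region,
    clamp_to_region,
    compute_curvature,
    compute_hull,
    estimate_label_extent,
    layout_compartmental,
    layout_free,
    make_regions,
    place_labels,
    region_for_compartment,
    _curve_point,
    _slot_rect,
    _rects_overlap,
)
from pathvis.model import Interaction, build_graph
from pathvis.synthetic import SyntheticSpec, generate_pathway

# --------------------------------------------------------------------------
# oracles


def grid_nearest_valid(point, region, radius, canvas_width, step=0.5):
    """Brute-force nearest valid circle center on a fine grid."""
    xs = np.arange(radius, canvas_width - radius + 1e-9, step)
    ys = np.arange(region.y_top + radius, region.y_bottom - radius + 1e-9, step)
    gx, gy = np.meshgrid(xs, ys)
    d2 = (gx - point[0]) ** 2 + (gy - point[1]) ** 2
    idx = np.unravel_index(np.argmin(d2), d2.shape)
    return (float(gx[idx]), float(gy[idx]))


def gift_wrap(points):
    """Jarvis-march convex hull, independent of shapely."""
    pts = sorted(set(points))
    if len(pts) < 3:
        return pts
    hull = []
    start = min(pts)
    current = start
    while True:
        hull.append(current)
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            if cross < 0:
                candidate = p
        current = candidate
        if current == start:
            break
    return hull


def point_in_polygon(point, polygon):
    x, y = point
    inside = False
    n = len(polygon)
    for i in range(n):
        x0, y0 = polygon[i]
        x1, y1 = polygon[(i + 1) % n]
        if (y0 > y) != (y1 > y):
            t = (y - y0) / (y1 - y0)
            if x < x0 + t * (x1 - x0):
                inside = not inside
    return inside


# --------------------------------------------------------------------------
# make_regions


def test_default_band_boundaries():
    regions = make_regions(640, 1000)
    names = [r.name for r in regions]
    assert names == [
        "extracellular", "membrane", "cytosol", "nucleus", "phenotype_layer"
    ]
    cytosol = regions[2]
    # cumulative fractions 0.10 + 0.12 = 0.22 top, + 0.56 = 0.78 bottom
    assert cytosol.y_top == pytest.approx(220.0)
    assert cytosol.y_bottom == pytest.approx(780.0)


def test_uniform_fractions_give_equal_bands():
    regions = make_regions(100, 100, (0.2,) * 5)
    assert all(r.height == pytest.approx(20.0) for r in regions)


def test_bands_tile_the_canvas_exactly():
    regions = make_regions(640, 480)
    assert len(regions) == 5
    assert regions[0].y_top == 0.0
    assert regions[-1].y_bottom == 480.0
    for upper, lower in zip(regions, regions[1:]):
        assert upper.y_bottom == lower.y_top


def test_bad_fractions_rejected():
    with pytest.raises(ValueError):
        make_regions(100, 100, (0.3, 0.3, 0.3, 0.3, 0.3))


def test_default_fractions_sum_to_one():
    assert abs(sum(DEFAULT_REGION_FRACTIONS) - 1.0) < 1e-12


# --------------------------------------------------------------------------
# clamp_to_region


def test_clamp_identity_inside_band():
    region = Region("cytosol", 100, 400, "#fff")
    assert clamp_to_region((50, 200), region, 10, 640) == (50, 200)


def test_clamp_projects_orthogonally_from_above():
    region = Region("cytosol", 100, 400, "#fff")
    assert clamp_to_region((50, 80), region, 10, 640) == (50, 110)


def test_clamp_too_thin_region_is_configuration_error():
    region = Region("membrane", 0, 15, "#fff")
    with pytest.raises(ConfigurationError):
        clamp_to_region((1, 1), region, 10, 640)


def test_clamp_matches_grid_search_oracle():
    rng = np.random.default_rng(42)
    region = Region("cytosol", 40, 140, "#fff")
    radius, width = 8.0, 200.0
    for _ in range(200):
        point = (float(rng.uniform(-60, 260)), float(rng.uniform(-40, 220)))
        ours = clamp_to_region(point, region, radius, width)
        oracle = grid_nearest_valid(point, region, radius, width)
        assert math.hypot(ours[0] - oracle[0], ours[1] - oracle[1]) <= 1.0


# --------------------------------------------------------------------------
# constrained layout


def _in_band(position, region, radius):
    return region.y_top + radius - 1e-9 <= position[1] <= region.y_bottom - radius + 1e-9


def test_membrane_and_nucleus_nodes_stay_in_their_bands():
    g = build_graph(
        [Interaction("R", "TF", "activation")],
        annotations={"R": ("protein", "membrane"), "TF": ("protein", "nucleus")},
    )
    regions = make_regions(640, 480)
    layout = layout_compartmental(g, regions, LayoutParams(seed=1))
    assert _in_band(layout.positions["R"], regions[1], 12)
    assert _in_band(layout.positions["TF"], regions[3], 12)


def test_repulsion_separates_coincident_nodes():
    g = build_graph([Interaction("A", "B", "ppi"), Interaction("C", "D", "ppi")])
    regions = make_regions(640, 480)
    layout = layout_compartmental(g, regions, LayoutParams(seed=3))
    positions = list(layout.positions.values())
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            assert math.dist(positions[i], positions[j]) > 1.0


def test_layout_deterministic_per_seed_and_varies_across_seeds():
    interactions, annotations, groups = generate_pathway(SyntheticSpec(seed=5))
    g = build_graph(interactions, annotations, groups)
    regions = make_regions(640, 480)
    a = layout_compartmental(g, regions, LayoutParams(seed=7))
    b = layout_compartmental(g, regions, LayoutParams(seed=7))
    c = layout_compartmental(g, regions, LayoutParams(seed=8))
    assert a.positions == b.positions
    assert a.curvature == b.curvature
    assert a.labels == b.labels
    assert a.positions != c.positions
    # All constraints satisfied regardless of seed.
    for layout in (a, c):
        for eid, pos in layout.positions.items():
            region = region_for_compartment(regions, g.entities[eid].compartment)
            assert _in_band(pos, region, 12)


def test_empty_graph_gives_empty_layout():
    g = build_graph([Interaction("A", "B", "ppi")])
    g.entities.clear()
    g.interactions.clear()
    layout = layout_compartmental(g, make_regions(640, 480))
    assert layout.positions == {}


def test_auto_compartment_confined_to_cytosol_band():
    g = build_graph(
        [Interaction("A", "B", "activation"), Interaction("B", "C", "inhibition")]
    )
    regions = make_regions(640, 480)
    layout = layout_compartmental(g, regions, LayoutParams(seed=2))
    cytosol = regions[2]
    for pos in layout.positions.values():
        assert _in_band(pos, cytosol, 12)


# --------------------------------------------------------------------------
# free layout


def analytic_equilibrium(params):
    """Positive real root of k_s d^2 (d - L) = k_r."""
    roots = np.roots(
        [params.spring_constant, -params.spring_constant * params.rest_length,
         0.0, -params.repulsion_constant]
    )
    real = [r.real for r in roots if abs(r.imag) < 1e-9 and r.real > 0]
    assert len(real) == 1
    return real[0]


def test_two_body_free_layout_matches_closed_form_equilibrium():
    params = LayoutParams(seed=5)
    g = build_graph([Interaction("A", "B", "activation")])
    layout = layout_free(g, 640, 480, params, finish=False)
    d = math.dist(layout.positions["A"], layout.positions["B"])
    d_star = analytic_equilibrium(params)
    assert abs(d - d_star) / d_star < 0.10


def test_free_layout_repulsion_only_keeps_nodes_apart():
    g = build_graph([Interaction("A", "B", "ppi")])
    g.interactions.clear()
    for eid in "CDEF":
        g.entities[eid] = g.entities["A"].__class__(id=eid)
    layout = layout_free(g, 640, 480, LayoutParams(seed=9), finish=False)
    ids = list(layout.positions)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            assert math.dist(layout.positions[ids[i]], layout.positions[ids[j]]) > 0


def test_free_layout_determinism():
    interactions, annotations, groups = generate_pathway(SyntheticSpec(seed=2))
    g = build_graph(interactions, annotations, groups)
    a = layout_free(g, 640, 480, LayoutParams(seed=4))
    b = layout_free(g, 640, 480, LayoutParams(seed=4))
    assert a.positions == b.positions and a.hulls == b.hulls


# --------------------------------------------------------------------------
# curvature


def _static_layout(positions):
    from pathvis.layout import Layout

    return Layout(positions={k: tuple(map(float, v)) for k, v in positions.items()})


def test_single_unobstructed_edge_is_straight():
    g = build_graph([Interaction("A", "B", "activation")])
    layout = _static_layout({"A": (0, 0), "B": (100, 0)})
    assert compute_curvature(g, layout) == {0: 0.0}


def test_antiparallel_edges_alternate_offsets():
    g = build_graph(
        [Interaction("A", "B", "activation"), Interaction("B", "A", "inhibition")]
    )
    layout = _static_layout({"A": (0, 0), "B": (100, 0)})
    offsets = compute_curvature(g, layout, k=20.0)
    assert offsets == {0: 20.0, 1: -20.0}


def test_obstructed_edge_takes_smallest_clearing_multiple():
    g = build_graph([Interaction("A", "B", "activation")])
    # C sits exactly on the A-B chord.
    layout = _static_layout({"A": (0, 0), "B": (200, 0), "C": (100, 0)})
    g.entities["C"] = g.entities["A"].__class__(id="C")
    k, radius, margin = 20.0, 12.0, 4.0
    offsets = compute_curvature(g, layout, k=k, node_radius=radius, margin=margin)
    chosen = offsets[0]
    assert chosen != 0.0
    # Oracle: sweep candidate multiples in the documented order; the first
    # whose sampled curve clears C by radius+margin must equal the choice.
    p0, p1, c = np.array([0.0, 0.0]), np.array([200.0, 0.0]), np.array([100.0, 0.0])
    t = np.linspace(0, 1, 32)

    def clears(offset):
        pts = _curve_point(p0, p1, offset, t)
        return np.linalg.norm(pts - c, axis=1).min() > radius + margin

    for candidate in [0.0, k, -k, 2 * k, -2 * k, 3 * k, -3 * k]:
        if clears(candidate):
            assert chosen == candidate
            break


def test_four_parallel_edges_fan_out():
    inters = [
        Interaction("A", "B", "activation", "direct"),
        Interaction("A", "B", "activation", "indirect"),
        Interaction("A", "B", "inhibition", "direct"),
        Interaction("A", "B", "ppi", "direct"),
    ]
    g = build_graph(inters)
    layout = _static_layout({"A": (0, 0), "B": (100, 0)})
    offsets = compute_curvature(g, layout, k=15.0)
    assert sorted(offsets.values()) == [-30.0, -15.0, 15.0, 30.0]


# --------------------------------------------------------------------------
# labels


def test_isolated_node_gets_east_slot():
    g = build_graph([Interaction("A", "B", "ppi")])
    layout = _static_layout({"A": (100, 100), "B": (500, 400)})
    anchors, collisions = place_labels(g, layout)
    assert anchors["A"][2] == "E"
    assert collisions == 0


def test_crowded_neighbor_forbids_west_slot():
    g = build_graph([Interaction("L", "R", "ppi")])
    # R is just east of L: R's W slot would overlap L's circle and
    # L's E slot would overlap R's circle.
    layout = _static_layout({"L": (100, 100), "R": (126, 100)})
    anchors, _ = place_labels(g, layout)
    assert anchors["R"][2] != "W"
    assert anchors["L"][2] != "E"


def test_collision_count_matches_pairwise_rectangle_oracle():
    rng = np.random.default_rng(7)
    for case in range(30):
        n = int(rng.integers(4, 12))
        ids = [f"N{i}" for i in range(n)]
        inters = [Interaction(ids[i], ids[i + 1], "ppi") for i in range(n - 1)]
        g = build_graph(inters)
        positions = {
            eid: (float(rng.uniform(0, 160)), float(rng.uniform(0, 120)))
            for eid in ids
        }
        layout = _static_layout(positions)
        anchors, reported = place_labels(g, layout)
        # Oracle: rebuild every rectangle and count intersecting pairs.
        rects = []
        for eid in ids:
            x0, y0, slot = anchors[eid]
            w, h = estimate_label_extent(g.entities[eid].label)
            rects.append((x0, y0, x0 + w, y0 + h))
        brute = sum(
            1
            for i in range(n)
            for j in range(i + 1, n)
            if _rects_overlap(rects[i], rects[j])
        )
        assert reported == brute, f"case {case}"


def test_slot_rect_positions_relative_to_node():
    rect_e = _slot_rect((0, 0), 10, "E", (30, 14))
    assert rect_e[0] == pytest.approx(13.0)  # radius + gap
    rect_w = _slot_rect((0, 0), 10, "W", (30, 14))
    assert rect_w[2] == pytest.approx(-13.0)


# --------------------------------------------------------------------------
# hulls


def test_single_member_hull_is_circle_of_padded_radius():
    polygon = compute_hull([(50.0, 50.0)], radius=10, padding=5)
    dists = [math.dist(p, (50, 50)) for p in polygon]
    assert min(dists) == pytest.approx(15.0, rel=0.02)
    assert max(dists) == pytest.approx(15.0, rel=0.02)


def test_two_member_hull_contains_both_circles():
    polygon = compute_hull([(0.0, 0.0), (80.0, 0.0)], radius=10, padding=5)
    for center in [(0, 0), (80, 0)]:
        for angle in np.linspace(0, 2 * math.pi, 16, endpoint=False):
            p = (center[0] + 10 * math.cos(angle), center[1] + 10 * math.sin(angle))
            assert point_in_polygon(p, polygon)


def test_hull_matches_gift_wrapping_oracle():
    rng = np.random.default_rng(13)
    for _ in range(50):
        n = int(rng.integers(3, 16))
        points = [
            (float(rng.uniform(0, 300)), float(rng.uniform(0, 300)))
            for _ in range(n)
        ]
        polygon = compute_hull(points, radius=10, padding=5)
        # Containment: every member strictly inside.
        for p in points:
            assert point_in_polygon(p, polygon)
        # Convexity: all cross products share a sign.
        crosses = []
        m = len(polygon) - 1  # closed ring repeats first point
        for i in range(m):
            ax, ay = polygon[i]
            bx, by = polygon[(i + 1) % m]
            cx, cy = polygon[(i + 2) % m]
            crosses.append((bx - ax) * (cy - ay) - (by - ay) * (cx - ax))
        nonzero = [c for c in crosses if abs(c) > 1e-9]
        assert all(c > 0 for c in nonzero) or all(c < 0 for c in nonzero)
        # Oracle hull vertices must all lie inside the padded polygon.
        for v in gift_wrap(points):
            assert point_in_polygon(v, polygon)


def test_empty_hull_rejected():
    with pytest.raises(ValueError):
        compute_hull([])
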