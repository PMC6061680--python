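"""Layout engines: free spring layout and the compartment-constrained layout.

The compartmental mode arranges a signaling cascade top-down the way
biologists draw it: extracellular space at the top, then the cell membrane
(receptors), the cytosol, the nucleus (transcription factors) and a bottom
layer for phenotypes.  Nodes annotated with a compartment are confined to
its horizontal band; unconstrained nodes (compartment ``auto``) move freely
inside the cytosol bounding box, which keeps them out of the membrane and
the nucleus.

Both modes run the same damped force simulation:

* spring force ``F = k_s * (d - L)`` along every edge toward rest length L,
* inverse-square repulsion ``F = k_r / d**2`` between every node pair,
* per-step velocity damping, then hard projection of every node back into
  its band (free mode projects onto the canvas only).

The simulation is fully seeded and deterministic: identical graph, params
and seed produce a bit-identical layout.  On top of the positions the
module computes quadratic-curve offsets for parallel or obstructed edges,
greedy label placement around eight candidate slots, and padded convex
hulls for user-defined node groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint

from .errors import ConfigurationError
from .model import PathwayGraph
from .style import THEME

CANONICAL_REGION_ORDER = (
    "extracellular",
    "membrane",
    "cytosol",
    "nucleus",
    "phenotype_layer",
)

#: Default vertical fractions of the canvas taken by each band, top to
#: bottom.  The cytosol dominates; the four fixed layers are thin strips.
DEFAULT_REGION_FRACTIONS = (0.10, 0.12, 0.56, 0.12, 0.10)

DEFAULT_NODE_RADIUS = 12.0


@dataclass(frozen=True)
class Region:
    """One horizontal band of the canvas with containment semantics."""

    name: str
    y_top: float
    y_bottom: float
    fill: str

    @property
    def height(self) -> float:
        return self.y_bottom - self.y_top


@dataclass(frozen=True)
class LayoutParams:
    """Force-model constants; all overridable, defaults documented in docs.

    ``spring_constant`` is force per unit spring extension, ``rest_length``
    the preferred edge length in canvas units, ``repulsion_constant`` the
    strength of the inverse-square pair repulsion, ``damping`` the per-step
    velocity retention.
    """

    spring_constant: float = 0.05
    rest_length: float = 60.0
    repulsion_constant: float = 5000.0
    damping: float = 0.85
    max_steps: int = 500
    convergence_eps: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        for name in ("spring_constant", "rest_length", "repulsion_constant",
                     "convergence_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Layout:
    """Positions, edge curvature, label anchors and group hulls."""

    positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    curvature: dict[int, float] = field(default_factory=dict)
    labels: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    hulls: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    canvas: tuple[float, float] = (640.0, 480.0)
    seed: int = 0
    steps_run: int = 0
    label_collisions: int = 0


# --------------------------------------------------------------------------
# Regions


def make_regions(
    canvas_width: float,
    canvas_height: float,
    fractions: tuple[float, ...] | None = None,
) -> list[Region]:
    """Tile the canvas height into the five canonical bands.

    Four fixed layers (extracellular, membrane, nucleus, phenotype) plus
    the cytosol band between membrane and nucleus; bands tile the height
    top-to-bottom with no gap or overlap.
    """
    if canvas_width <= 0 or canvas_height <= 0:
        raise ValueError("canvas dimensions must be positive")
    fracs = tuple(fractions) if fractions is not None else DEFAULT_REGION_FRACTIONS
    if len(fracs) != 5:
        raise ValueError("fractions must have exactly 5 entries")
    if any(f <= 0 for f in fracs):
        raise ValueError("fractions must be positive")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(fracs)}, expected 1")
    regions: list[Region] = []
    y = 0.0
    for name, frac in zip(CANONICAL_REGION_ORDER, fracs):
        y_next = y + frac * canvas_height
        regions.append(
            Region(name=name, y_top=y, y_bottom=y_next, fill=THEME[f"region.{name}"])
        )
        y = y_next
    # Close the tiling exactly despite floating-point accumulation.
    regions[-1] = Region(
        regions[-1].name, regions[-1].y_top, canvas_height, regions[-1].fill
    )
    return regions


def region_for_compartment(regions: list[Region], compartment: str) -> Region:
    """Map an entity compartment to its band; ``auto`` goes to the cytosol."""
    name = "cytosol" if compartment == "auto" else compartment
    for region in regions:
        if region.name == name:
            return region
    raise ValueError(f"no region for compartment {compartment!r}")


def clamp_to_region(
    position: tuple[float, float],
    region: Region,
    radius: float,
    canvas_width: float,
) -> tuple[float, float]:
    """Nearest point whose circle of given radius fits inside the band.

    Horizontal containment is against ``[0, canvas_width]``.  Points already
    valid come back unchanged (orthogonal projection onto an axis-aligned
    box is coordinate-wise clamping).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if region.height <= 2 * radius:
        raise ConfigurationError(
            f"region {region.name!r} of height {region.height} cannot hold "
            f"a node of radius {radius}"
        )
    x, y = position
    x = min(max(x, radius), canvas_width - radius)
    y = min(max(y, region.y_top + radius), region.y_bottom - radius)
    return (x, y)


# --------------------------------------------------------------------------
# Force simulation


def _simulate(
    n: int,
    edges: np.ndarray,
    initial: np.ndarray,
    bounds: np.ndarray,
    params: LayoutParams,
) -> tuple[np.ndarray, int]:
    """Run the damped spring/repulsion simulation with per-step projection.

    ``bounds`` is (n, 4): x_min, x_max, y_min, y_max per node (circle center
    limits).  Returns final positions and the number of steps run.
    """
    pos = initial.astype(np.float64).copy()
    vel = np.zeros_like(pos)
    k_s, rest = params.spring_constant, params.rest_length
    k_r = params.repulsion_constant
    steps = 0
    for steps in range(1, params.max_steps + 1):
        force = np.zeros_like(pos)
        # Pairwise inverse-square repulsion.
        delta = pos[:, None, :] - pos[None, :, :]  # (n, n, 2)
        dist = np.linalg.norm(delta, axis=-1)
        # Coincident nodes get a deterministic symmetry-breaking direction.
        coincident = (dist < 1e-9) & ~np.eye(n, dtype=bool)
        if coincident.any():
            ii, jj = np.nonzero(coincident)
            angles = 0.1 + 0.7 * (ii * n + jj)
            delta[ii, jj, 0] = np.cos(angles) * 1e-3
            delta[ii, jj, 1] = np.sin(angles) * 1e-3
            dist[ii, jj] = 1e-3
        np.fill_diagonal(dist, np.inf)
        inv = k_r / (dist**2)
        force += (delta / dist[..., None] * inv[..., None]).sum(axis=1)
        # Spring attraction along edges toward the rest length.
        if len(edges):
            src, dst = edges[:, 0], edges[:, 1]
            d = pos[dst] - pos[src]
            length = np.linalg.norm(d, axis=1)
            length = np.where(length < 1e-9, 1e-9, length)
            pull = k_s * (length - rest)
            f = d / length[:, None] * pull[:, None]
            np.add.at(force, src, f)
            np.add.at(force, dst, -f)
        vel = (vel + force) * params.damping
        new_pos = pos + vel
        new_pos[:, 0] = np.clip(new_pos[:, 0], bounds[:, 0], bounds[:, 1])
        new_pos[:, 1] = np.clip(new_pos[:, 1], bounds[:, 2], bounds[:, 3])
        displacement = np.abs(new_pos - pos).max() if n else 0.0
        pos = new_pos
        if displacement <= params.convergence_eps:
            break
    return pos, steps


def _node_bounds(
    graph: PathwayGraph,
    regions: list[Region] | None,
    canvas_width: float,
    canvas_height: float,
    radius: float,
) -> np.ndarray:
    ids = list(graph.entities)
    bounds = np.empty((len(ids), 4))
    for i, eid in enumerate(ids):
        if regions is None:
            y_top, y_bottom = 0.0, canvas_height
        else:
            region = region_for_compartment(regions, graph.entities[eid].compartment)
            if region.height <= 2 * radius:
                raise ConfigurationError(
                    f"region {region.name!r} too thin for node radius {radius}"
                )
            y_top, y_bottom = region.y_top, region.y_bottom
        bounds[i] = (radius, canvas_width - radius, y_top + radius, y_bottom - radius)
    return bounds


def _edge_index(graph: PathwayGraph) -> np.ndarray:
    index = {eid: i for i, eid in enumerate(graph.entities)}
    return np.array(
        [[index[i.source], index[i.target]] for i in graph.interactions],
        dtype=np.int64,
    ).reshape(-1, 2)


def _run_layout(
    graph: PathwayGraph,
    regions: list[Region] | None,
    canvas_width: float,
    canvas_height: float,
    params: LayoutParams,
    node_radius: float,
) -> Layout:
    ids = list(graph.entities)
    n = len(ids)
    layout = Layout(canvas=(canvas_width, canvas_height), seed=params.seed)
    if n == 0:
        return layout
    bounds = _node_bounds(graph, regions, canvas_width, canvas_height, node_radius)
    rng = np.random.default_rng(params.seed)
    initial = np.empty((n, 2))
    initial[:, 0] = rng.uniform(bounds[:, 0], bounds[:, 1])
    initial[:, 1] = rng.uniform(bounds[:, 2], bounds[:, 3])
    pos, steps = _simulate(n, _edge_index(graph), initial, bounds, params)
    layout.positions = {eid: (float(x), float(y)) for eid, (x, y) in zip(ids, pos)}
    layout.steps_run = steps
    return layout


def layout_compartmental(
    graph: PathwayGraph,
    regions: list[Region],
    params: LayoutParams = LayoutParams(),
    canvas_width: float = 640.0,
    node_radius: float = DEFAULT_NODE_RADIUS,
    finish: bool = True,
) -> Layout:
    """Compartment-constrained spring layout.

    Every node starts at a seeded uniform-random point inside its band and
    is projected back into the band after every simulation step, so the
    final layout satisfies all region constraints exactly.  The canvas
    height is the bottom of the last band.
    """
    canvas_height = max(r.y_bottom for r in regions)
    layout = _run_layout(
        graph, regions, canvas_width, canvas_height, params, node_radius
    )
    return finish_layout(graph, layout, node_radius) if finish else layout


def compute_curvature(
    graph: PathwayGraph,
    layout: Layout,
    k: float = 20.0,
    node_radius: float = DEFAULT_NODE_RADIUS,
    margin: float = 4.0,
    max_multiple: int = 10,
) -> dict[int, float]:
    """Signed perpendicular control-point offsets for quadratic edge curves.

    Offsets are expressed in the canonical frame of each unordered node
    pair (direction from the lexicographically smaller id to the larger),
    so two antiparallel edges get ``+k`` and ``-k`` and bow to opposite
    sides.  Single edges stay straight unless their chord passes within
    ``node_radius + margin`` of a non-endpoint node, in which case the
    smallest multiple of ``k`` (alternating sign) that clears every
    obstacle is chosen.  Deterministic in graph order.
    """
    pos = layout.positions
    # Group edges by unordered endpoint pair, in graph order.
    by_pair: dict[tuple[str, str], list[int]] = {}
    for idx, inter in enumerate(graph.interactions):
        pair = tuple(sorted((inter.source, inter.target)))
        by_pair.setdefault(pair, []).append(idx)

    offsets: dict[int, float] = {}
    candidates = [0.0]
    for m in range(1, max_multiple + 1):
        candidates.extend((m * k, -m * k))

    others = np.array(
        [pos[eid] for eid in graph.entities], dtype=np.float64
    ).reshape(-1, 2)
    id_index = {eid: i for i, eid in enumerate(graph.entities)}

    for pair, edge_indices in by_pair.items():
        a, b = pair
        p0 = np.asarray(pos[a])
        p1 = np.asarray(pos[b])
        if len(edge_indices) > 1:
            # Parallel/antiparallel bundle: alternate +k, -k, +2k, -2k, ...
            for rank, idx in enumerate(edge_indices):
                mult = rank // 2 + 1
                sign = 1.0 if rank % 2 == 0 else -1.0
                offsets[idx] = sign * mult * k
            continue
        idx = edge_indices[0]
        if a == b:
            offsets[idx] = k  # self loop: always bowed
            continue
        mask = np.ones(len(others), dtype=bool)
        mask[id_index[a]] = False
        mask[id_index[b]] = False
        obstacles = others[mask]
        clearance = node_radius + margin
        chosen = candidates[-1]
        for offset in candidates:
            if _curve_clears(p0, p1, offset, obstacles, clearance):
                chosen = offset
                break
        offsets[idx] = chosen
    return offsets


def _curve_point(p0: np.ndarray, p1: np.ndarray, offset: float, t: np.ndarray) -> np.ndarray:
    """Points on the quadratic Bezier with perpendicular control offset."""
    chord = p1 - p0
    length = np.linalg.norm(chord)
    if length < 1e-9:
        return np.repeat(p0[None, :], len(t), axis=0)
    normal = np.array([-chord[1], chord[0]]) / length
    ctrl = (p0 + p1) / 2 + offset * normal
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * ctrl + t**2 * p1


def _curve_clears(
    p0: np.ndarray,
    p1: np.ndarray,
    offset: float,
    obstacles: np.ndarray,
    clearance: float,
    samples: int = 32,
) -> bool:
    if len(obstacles) == 0:
        return True
    t = np.linspace(0.0, 1.0, samples)
    points = _curve_point(p0, p1, offset, t)
    d = np.linalg.norm(points[:, None, :] - obstacles[None, :, :], axis=-1)
    return bool(d.min() > clearance)


# --------------------------------------------------------------------------
# Label placement

#: Candidate slots in preference order; (dx, dy) are unit directions from
#: the node center to the near edge of the label rectangle.
_SLOT_ORDER = ("E", "W", "N", "S", "NE", "NW", "SE", "SW")
_SLOT_DIRECTIONS = {
    "E": (1.0, 0.0),
    "W": (-1.0, 0.0),
    "N": (0.0, -1.0),
    "S": (0.0, 1.0),
    "NE": (0.7071, -0.7071),
    "NW": (-0.7071, -0.7071),
    "SE": (0.7071, 0.7071),
    "SW": (-0.7071, 0.7071),
}
_LABEL_GAP = 3.0

# Fixed per-character width table for text-extent estimation (no font
# engine in a headless renderer); widths in canvas units at 12 px.
_CHAR_WIDTH_DEFAULT = 7.0
_CHAR_WIDTHS = {
    "i": 3.3, "j": 3.3, "l": 3.3, "f": 4.0, "t": 4.5, "r": 4.7, " ": 3.5,
    "m": 10.5, "w": 9.5, "M": 10.5, "W": 11.5, ".": 3.5, ",": 3.5,
    "-": 4.5, "_": 7.0, "1": 5.5,
}
LABEL_FONT_SIZE = 12.0
LABEL_HEIGHT = 14.0


def estimate_label_extent(text: str, font_size: float = LABEL_FONT_SIZE) -> tuple[float, float]:
    """Estimated (width, height) of a label from the char-width table."""
    scale = font_size / 12.0
    width = sum(_CHAR_WIDTHS.get(c, _CHAR_WIDTH_DEFAULT) for c in text) * scale
    return (width, LABEL_HEIGHT * scale)


def _slot_rect(
    center: tuple[float, float],
    radius: float,
    slot: str,
    extent: tuple[float, float],
) -> tuple[float, float, float, float]:
    """Label rectangle (x0, y0, x1, y1) for a slot around a node."""
    cx, cy = center
    w, h = extent
    dx, dy = _SLOT_DIRECTIONS[slot]
    ax = cx + dx * (radius + _LABEL_GAP)
    ay = cy + dy * (radius + _LABEL_GAP)
    if dx > 0.1:
        x0 = ax
    elif dx < -0.1:
        x0 = ax - w
    else:
        x0 = ax - w / 2
    if dy > 0.1:
        y0 = ay
    elif dy < -0.1:
        y0 = ay - h
    else:
        y0 = ay - h / 2
    return (x0, y0, x0 + w, y0 + h)


def _rects_overlap(a: tuple[float, float, float, float], b: tuple[float, float, float, float]) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def _rect_overlap_area(a, b) -> float:
    w = min(a[2], b[2]) - max(a[0], b[0])
    h = min(a[3], b[3]) - max(a[1], b[1])
    return max(0.0, w) * max(0.0, h)


def _rect_circle_overlap(rect, center, radius) -> bool:
    cx, cy = center
    nx = min(max(cx, rect[0]), rect[2])
    ny = min(max(cy, rect[1]), rect[3])
    return (nx - cx) ** 2 + (ny - cy) ** 2 < radius**2


def place_labels(
    graph: PathwayGraph,
    layout: Layout,
    label_extents: dict[str, tuple[float, float]] | None = None,
    node_radius: float = DEFAULT_NODE_RADIUS,
) -> tuple[dict[str, tuple[float, float, str]], int]:
    """Greedy label placement around eight candidate slots per node.

    Each label takes the first slot (E, W, N, S, NE, NW, SE, SW) whose
    rectangle overlaps no node circle and no previously placed label; if
    every slot collides the least-overlapping one is taken.  Returns the
    anchors (rectangle top-left x, baseline-free y, slot name) and the
    number of intersecting label-rectangle pairs in the final placement.
    Deterministic in entity order.
    """
    if label_extents is None:
        label_extents = {
            eid: estimate_label_extent(ent.label)
            for eid, ent in graph.entities.items()
        }
    placed_rects: list[tuple[float, float, float, float]] = []
    anchors: dict[str, tuple[float, float, str]] = {}
    collisions = 0
    centers = {eid: layout.positions[eid] for eid in graph.entities}
    for eid in graph.entities:
        center = centers[eid]
        extent = label_extents[eid]
        best_slot, best_rect, best_cost = None, None, float("inf")
        chosen = None
        for slot in _SLOT_ORDER:
            rect = _slot_rect(center, node_radius, slot, extent)
            circle_hit = any(
                _rect_circle_overlap(rect, c, node_radius)
                for other, c in centers.items()
                if other != eid
            )
            label_cost = sum(_rect_overlap_area(rect, r) for r in placed_rects)
            if not circle_hit and label_cost == 0.0:
                chosen = (slot, rect)
                break
            cost = label_cost + (node_radius**2 if circle_hit else 0.0)
            if cost < best_cost:
                best_cost, best_slot, best_rect = cost, slot, rect
        if chosen is None:
            chosen = (best_slot, best_rect)
        slot, rect = chosen
        collisions += sum(1 for r in placed_rects if _rects_overlap(rect, r))
        placed_rects.append(rect)
        anchors[eid] = (rect[0], rect[1], slot)
    return anchors, collisions


# --------------------------------------------------------------------------
# Group hulls

_HULL_SEGMENTS = 16  # quarter-circle resolution of the buffer offset


def compute_hull(
    member_positions: list[tuple[float, float]],
    radius: float = DEFAULT_NODE_RADIUS,
    padding: float = 10.0,
) -> list[tuple[float, float]]:
    """Padded convex hull polygon around a group of node centers.

    The convex hull of the centers is offset outward by ``radius +
    padding`` so every member circle lies entirely inside.  One member
    yields a near-circle polygon, two a stadium shape.
    """
    if not member_positions:
        raise ValueError("hull needs at least one member position")
    geom = MultiPoint([tuple(p) for p in member_positions]).convex_hull
    poly = geom.buffer(radius + padding, quad_segs=_HULL_SEGMENTS)
    coords = list(poly.exterior.coords)
    return [(float(x), float(y)) for x, y in coords]


# --------------------------------------------------------------------------
# Full pipelines


def finish_layout(
    graph: PathwayGraph,
    layout: Layout,
    node_radius: float = DEFAULT_NODE_RADIUS,
    curvature_unit: float = 20.0,
    hull_padding: float = 10.0,
) -> Layout:
    """Add curvature, labels and hulls to a positioned layout in place."""
    layout.curvature = compute_curvature(
        graph, layout, k=curvature_unit, node_radius=node_radius
    )
    layout.labels, layout.label_collisions = place_labels(
        graph, layout, node_radius=node_radius
    )
    layout.hulls = {
        name: compute_hull(
            [layout.positions[m] for m in members],
            radius=node_radius,
            padding=hull_padding,
        )
        for name, members in graph.groups.items()
        if members
    }
    return layout


def layout_free(
    graph: PathwayGraph,
    canvas_width: float = 640.0,
    canvas_height: float = 480.0,
    params: LayoutParams = LayoutParams(),
    node_radius: float = DEFAULT_NODE_RADIUS,
    finish: bool = True,
) -> Layout:
    """Classical free spring layout over the whole canvas.

    Identical force model to the compartmental mode, but the only
    constraint is the canvas rectangle itself.
    """
    layout = _run_layout(
        graph, None, canvas_width, canvas_height, params, node_radius
    )
    return finish_layout(graph, layout, node_radius) if finish else layout
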