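"""Serialize a graph + layout + styles into standard SVG 1.1 text.

Draw order, back to front: compartment bands, group hulls, edges, nodes,
labels.  Edges are quadratic Bezier paths whose control point carries the
layout's curvature offset; activation arrowheads and inhibition T-bars are
marker definitions in ``defs`` so dash patterns do not distort terminals.
Edge endpoints are trimmed to the node-circle boundary so terminals touch,
not pierce, nodes.  Output is byte-identical for identical inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from lxml import etree

from .errors import RenderError
from .layout import DEFAULT_NODE_RADIUS, Layout, Region
from .model import PathwayGraph
from .style import DEFAULT_REGISTRY, THEME, StyleRegistry, style_for_entity, style_for_interaction

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass
class RenderOptions:
    width: float = 640.0
    height: float = 480.0
    show_hulls: bool = True
    hull_highlight: set[str] = field(default_factory=set)
    title: str = ""
    node_radius: float = DEFAULT_NODE_RADIUS
    font_size: float = 12.0


def _fmt(value: float) -> str:
    """Fixed two-decimal coordinate formatting keeps output deterministic."""
    return f"{value:.2f}"


def _marker_id(terminal: str, stroke: str) -> str:
    return f"{terminal}-{stroke.lstrip('#')}"


def _add_markers(defs: etree._Element, styles: list) -> None:
    seen: set[str] = set()
    for style in styles:
        if style.terminal not in ("arrow", "tbar"):
            continue
        mid = _marker_id(style.terminal, style.stroke)
        if mid in seen:
            continue
        seen.add(mid)
        marker = etree.SubElement(
            defs,
            f"{{{SVG_NS}}}marker",
            id=mid,
            orient="auto",
            markerWidth="12",
            markerHeight="12",
            refX="9",
            refY="5",
            markerUnits="userSpaceOnUse",
        )
        if style.terminal == "arrow":
            etree.SubElement(
                marker,
                f"{{{SVG_NS}}}path",
                d="M 0 1 L 9 5 L 0 9 Z",
                fill=style.stroke,
            )
        else:  # tbar
            etree.SubElement(
                marker,
                f"{{{SVG_NS}}}path",
                d="M 8 0 L 8 10",
                stroke=style.stroke,
                attrib={"stroke-width": "2.4"},
            )


def _quad_path(
    p0: tuple[float, float],
    p1: tuple[float, float],
    canonical_offset: float,
    source_id: str,
    target_id: str,
    radius: float,
) -> str:
    """Path data for the trimmed quadratic edge curve.

    The curvature offset is stored in the canonical frame of the unordered
    id pair; convert it to this edge's own frame before building the curve.
    """
    offset = canonical_offset if source_id <= target_id else -canonical_offset
    x0, y0 = p0
    x1, y1 = p1
    dx, dy = x1 - x0, y1 - y0
    length = math.hypot(dx, dy)
    if length < 1e-9:
        # Degenerate self-edge: tiny loop above the node.
        return (
            f"M {_fmt(x0)} {_fmt(y0 - radius)} "
            f"q {_fmt(radius)} {_fmt(-2 * radius)} 0 0"
        )
    nx, ny = -dy / length, dx / length
    cx = (x0 + x1) / 2 + offset * nx
    cy = (y0 + y1) / 2 + offset * ny
    # Trim endpoints to the node-circle boundary along the tangent toward
    # the control point, so terminals touch rather than pierce nodes.
    for_end = []
    for (px, py), toward in (((x0, y0), (cx, cy)), ((x1, y1), (cx, cy))):
        tx, ty = toward[0] - px, toward[1] - py
        t_len = math.hypot(tx, ty) or 1.0
        for_end.append((px + tx / t_len * radius, py + ty / t_len * radius))
    (sx, sy), (ex, ey) = for_end
    return f"M {_fmt(sx)} {_fmt(sy)} Q {_fmt(cx)} {_fmt(cy)} {_fmt(ex)} {_fmt(ey)}"


def _node_shape(parent: etree._Element, x: float, y: float, style, r_scale: float = 1.0):
    r = style.radius * r_scale
    common = {"fill": style.fill, "stroke": style.stroke, "stroke-width": "1.2"}
    if style.shape == "circle":
        return etree.SubElement(
            parent,
            f"{{{SVG_NS}}}circle",
            cx=_fmt(x),
            cy=_fmt(y),
            r=_fmt(r),
            attrib=common,
        )
    if style.shape == "rectangle":
        return etree.SubElement(
            parent,
            f"{{{SVG_NS}}}rect",
            x=_fmt(x - 1.3 * r),
            y=_fmt(y - 0.8 * r),
            width=_fmt(2.6 * r),
            height=_fmt(1.6 * r),
            rx=_fmt(2.0),
            attrib=common,
        )
    if style.shape == "diamond":
        points = [(x, y - r), (x + r, y), (x, y + r), (x - r, y)]
    elif style.shape == "octagon":
        points = [
            (
                x + r * math.cos(math.pi / 8 + i * math.pi / 4),
                y + r * math.sin(math.pi / 8 + i * math.pi / 4),
            )
            for i in range(8)
        ]
    else:
        raise RenderError(f"unknown node shape {style.shape!r}")
    pts = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in points)
    return etree.SubElement(
        parent, f"{{{SVG_NS}}}polygon", points=pts, attrib=common
    )


def render_svg(
    graph: PathwayGraph,
    layout: Layout,
    regions: list[Region] | None = None,
    registry: StyleRegistry = DEFAULT_REGISTRY,
    options: RenderOptions | None = None,
) -> str:
    """Render the pathway as standalone SVG 1.1 text.

    Raises :class:`RenderError` if any entity lacks a position.  Group
    hulls are gray, except groups named in ``options.hull_highlight`` which
    render red with the group name shown.
    """
    options = options or RenderOptions()
    for eid in graph.entities:
        if eid not in layout.positions:
            raise RenderError(f"entity {eid!r} has no layout position")

    root = etree.Element(
        f"{{{SVG_NS}}}svg",
        nsmap={None: SVG_NS},
        version="1.1",
        width=_fmt(options.width),
        height=_fmt(options.height),
        viewBox=f"0 0 {_fmt(options.width)} {_fmt(options.height)}",
    )
    if options.title:
        title_el = etree.SubElement(root, f"{{{SVG_NS}}}title")
        title_el.text = options.title

    defs = etree.SubElement(root, f"{{{SVG_NS}}}defs")
    edge_styles = [
        style_for_interaction(i.interaction_class, i.modifier, registry)
        for i in graph.interactions
    ]
    _add_markers(defs, edge_styles)

    # 1. Region bands.
    bands = etree.SubElement(root, f"{{{SVG_NS}}}g", id="regions")
    for region in regions or []:
        etree.SubElement(
            bands,
            f"{{{SVG_NS}}}rect",
            x="0",
            y=_fmt(region.y_top),
            width=_fmt(options.width),
            height=_fmt(region.height),
            fill=region.fill,
        )

    # 2. Group hulls.
    hulls_g = etree.SubElement(root, f"{{{SVG_NS}}}g", id="hulls")
    if options.show_hulls:
        for name, polygon in layout.hulls.items():
            highlighted = name in options.hull_highlight
            fill = THEME["hull.highlight"] if highlighted else THEME["hull.fill"]
            pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in polygon)
            etree.SubElement(
                hulls_g,
                f"{{{SVG_NS}}}polygon",
                points=pts,
                fill=fill,
                attrib={"fill-opacity": "0.35", "data-group": name},
            )
            if highlighted and polygon:
                top = min(polygon, key=lambda p: p[1])
                text = etree.SubElement(
                    hulls_g,
                    f"{{{SVG_NS}}}text",
                    x=_fmt(top[0]),
                    y=_fmt(top[1] - 4),
                    fill=THEME["hull.highlight"],
                    attrib={
                        "font-size": _fmt(options.font_size),
                        "font-family": "sans-serif",
                        "text-anchor": "middle",
                    },
                )
                text.text = name

    # 3. Edges.
    edges_g = etree.SubElement(root, f"{{{SVG_NS}}}g", id="edges")
    for idx, inter in enumerate(graph.interactions):
        style = edge_styles[idx]
        p0 = layout.positions[inter.source]
        p1 = layout.positions[inter.target]
        d = _quad_path(
            p0,
            p1,
            layout.curvature.get(idx, 0.0),
            inter.source,
            inter.target,
            options.node_radius,
        )
        attrib = {
            "fill": "none",
            "stroke": style.stroke,
            "stroke-width": _fmt(style.width),
            "stroke-opacity": _fmt(style.opacity),
        }
        if style.dash:
            attrib["stroke-dasharray"] = style.dash
        if style.terminal in ("arrow", "tbar") and inter.directed:
            attrib["marker-end"] = f"url(#{_marker_id(style.terminal, style.stroke)})"
        etree.SubElement(edges_g, f"{{{SVG_NS}}}path", d=d, attrib=attrib)

    # 4. Nodes.
    nodes_g = etree.SubElement(root, f"{{{SVG_NS}}}g", id="nodes")
    for eid, entity in graph.entities.items():
        style = style_for_entity(entity.entity_class, registry)
        x, y = layout.positions[eid]
        _node_shape(nodes_g, x, y, style)

    # 5. Labels.
    labels_g = etree.SubElement(root, f"{{{SVG_NS}}}g", id="labels")
    for eid, entity in graph.entities.items():
        if eid in layout.labels:
            lx, ly, _slot = layout.labels[eid]
            ly += options.font_size  # rect top -> text baseline
        else:
            x, y = layout.positions[eid]
            lx, ly = x + options.node_radius + 3, y + options.font_size / 3
        text = etree.SubElement(
            labels_g,
            f"{{{SVG_NS}}}text",
            x=_fmt(lx),
            y=_fmt(ly),
            fill=THEME["label.fill"],
            attrib={
                "font-size": _fmt(options.font_size),
                "font-family": "sans-serif",
            },
        )
        text.text = entity.label

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")
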