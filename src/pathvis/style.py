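"""Style registries: entity class -> node glyph, interaction -> edge glyph.

Entities draw as circles except the conventional exceptions: complexes are
octagons, phenotypes rectangles, small molecules and chemicals diamonds.
Causal edge semantics follow standard signaling-diagram convention: an
arrowhead terminal means activation, a perpendicular T-bar means
inhibition, physical edges have no terminal.  Modifier subclasses
(indirect, transcriptional) are told apart by dash pattern and a single
reduced-opacity level shared across the registry.

Both registries are extensible; extension copies, never mutates, the
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import RegistryError
from .model import normalize_class

# Central theme table; every color in the package resolves through here.
THEME: dict[str, str] = {
    "region.extracellular": "#eef5fb",
    "region.membrane": "#f6e8a9",  # membrane band: yellow
    "region.cytosol": "#fdfdfd",
    "region.nucleus": "#ddcfec",  # nucleus band: lilac
    "region.phenotype_layer": "#ededed",
    "node.protein": "#7fb2d9",
    "node.external_protein": "#c9a0dc",
    "node.chemical": "#8fd08f",
    "node.small_molecule": "#b5d96b",
    "node.complex": "#e8a86b",
    "node.protein_family": "#a3c4e0",
    "node.phenotype": "#d9d9d9",
    "node.stimulus": "#f2d06b",
    "node.stroke": "#333333",
    "edge.activation": "#1a7f37",
    "edge.inhibition": "#c0392b",
    "edge.binding": "#666666",
    "edge.ppi": "#666666",
    "edge.complex_formation": "#666666",
    "hull.fill": "#9e9e9e",
    "hull.highlight": "#d93025",
    "label.fill": "#111111",
}


@dataclass(frozen=True)
class NodeStyle:
    shape: str  # circle | octagon | rectangle | diamond
    fill: str
    stroke: str
    radius: float = 12.0


@dataclass(frozen=True)
class EdgeStyle:
    terminal: str  # arrow | tbar | none
    dash: str  # SVG dash-array; "" means solid
    opacity: float
    stroke: str = "#666666"
    width: float = 1.6


#: The single opacity level below 1.0 used across the edge registry.
INDIRECT_OPACITY = 0.55

_DASH_SOLID = ""
_DASH_INDIRECT = "7,4"
_DASH_TRANSCRIPTIONAL = "2,3"
_DASH_BINDING = "12,3"
_DASH_COMPLEX_FORMATION = "3,3"


def _default_node_registry(theme: dict[str, str] | None = None) -> dict[str, NodeStyle]:
    theme = theme or THEME

    def node(cls: str, shape: str) -> NodeStyle:
        return NodeStyle(
            shape=shape, fill=theme[f"node.{cls}"], stroke=theme["node.stroke"]
        )

    return {
        "protein": node("protein", "circle"),
        "external_protein": node("external_protein", "circle"),
        "chemical": node("chemical", "diamond"),
        "small_molecule": node("small_molecule", "diamond"),
        "complex": node("complex", "octagon"),
        "protein_family": node("protein_family", "circle"),
        "phenotype": node("phenotype", "rectangle"),
        "stimulus": node("stimulus", "circle"),
    }


def _default_edge_registry(
    theme: dict[str, str] | None = None
) -> dict[tuple[str, str], EdgeStyle]:
    theme = theme or THEME

    def edge(cls: str, terminal: str, dash: str, opacity: float) -> EdgeStyle:
        return EdgeStyle(
            terminal=terminal,
            dash=dash,
            opacity=opacity,
            stroke=theme[f"edge.{cls}"],
        )

    reg: dict[tuple[str, str], EdgeStyle] = {}
    for cls, terminal in (("activation", "arrow"), ("inhibition", "tbar")):
        reg[(cls, "direct")] = edge(cls, terminal, _DASH_SOLID, 1.0)
        reg[(cls, "indirect")] = edge(cls, terminal, _DASH_INDIRECT, INDIRECT_OPACITY)
        reg[(cls, "transcriptional")] = edge(cls, terminal, _DASH_TRANSCRIPTIONAL, 1.0)
    reg[("ppi", "direct")] = edge("ppi", "none", _DASH_SOLID, 1.0)
    reg[("binding", "direct")] = edge("binding", "none", _DASH_BINDING, 1.0)
    reg[("complex_formation", "direct")] = edge(
        "complex_formation", "none", _DASH_COMPLEX_FORMATION, 1.0
    )
    return reg


class StyleRegistry:
    """Holds the node and edge style tables; copy-on-extend."""

    def __init__(
        self,
        node_styles: dict[str, NodeStyle] | None = None,
        edge_styles: dict[tuple[str, str], EdgeStyle] | None = None,
    ) -> None:
        self.node_styles = (
            dict(node_styles) if node_styles is not None else _default_node_registry()
        )
        self.edge_styles = (
            dict(edge_styles) if edge_styles is not None else _default_edge_registry()
        )

    @property
    def entity_classes(self) -> frozenset[str]:
        return frozenset(self.node_styles)

    @property
    def interaction_classes(self) -> frozenset[str]:
        return frozenset(cls for cls, _mod in self.edge_styles)

    def register_entity_class(self, name: str, style: NodeStyle) -> "StyleRegistry":
        """Return a new registry with an extra entity class; defaults untouched."""
        nodes = dict(self.node_styles)
        nodes[normalize_class(name)] = style
        return StyleRegistry(nodes, self.edge_styles)

    def register_edge_style(
        self, interaction_class: str, modifier: str, style: EdgeStyle
    ) -> "StyleRegistry":
        edges = dict(self.edge_styles)
        edges[(normalize_class(interaction_class), normalize_class(modifier))] = style
        return StyleRegistry(self.node_styles, edges)


DEFAULT_REGISTRY = StyleRegistry()


def style_for_entity(
    entity_class: str, registry: StyleRegistry = DEFAULT_REGISTRY
) -> NodeStyle:
    """Total, deterministic lookup of a node glyph; unknown class raises."""
    cls = normalize_class(entity_class)
    try:
        return registry.node_styles[cls]
    except KeyError:
        raise RegistryError(f"entity class {cls!r} not in style registry") from None


def style_for_interaction(
    interaction_class: str,
    modifier: str = "direct",
    registry: StyleRegistry = DEFAULT_REGISTRY,
) -> EdgeStyle:
    """Look up an edge glyph for a (class, modifier) pair.

    Pairs absent from the registry but with a registered class are composed:
    terminal and stroke come from the class's direct entry, dash and opacity
    from the modifier convention.  Unknown classes raise.
    """
    cls = normalize_class(interaction_class)
    mod = normalize_class(modifier)
    style = registry.edge_styles.get((cls, mod))
    if style is not None:
        return style
    base = registry.edge_styles.get((cls, "direct"))
    if base is None:
        raise RegistryError(f"interaction class {cls!r} not in style registry")
    if mod == "indirect":
        return EdgeStyle(base.terminal, _DASH_INDIRECT, INDIRECT_OPACITY, base.stroke)
    if mod == "transcriptional":
        return EdgeStyle(base.terminal, _DASH_TRANSCRIPTIONAL, 1.0, base.stroke)
    return base


def load_theme(text: str) -> dict[str, str]:
    """Parse a ``key=value`` theme override file into a dict."""
    overrides: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"theme line {lineno} is not key=value: {raw!r}")
        key, _, value = line.partition("=")
        overrides[key.strip()] = value.strip()
    return overrides


def themed_registry(overrides: dict[str, str]) -> StyleRegistry:
    """Build a registry from the default theme plus overrides."""
    theme = dict(THEME)
    theme.update(overrides)
    return StyleRegistry(_default_node_registry(theme), _default_edge_registry(theme))
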