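"""Domain model: entities, typed interactions, pathway graphs and filters.

A pathway is modeled as a set of typed entities (proteins, complexes,
chemicals, phenotypes, ...) connected by typed causal or physical
interactions.  Causal edges (activation, inhibition) are directed; physical
edges (binding, plain protein-protein interaction) are undirected.  Each
entity carries a compartment assignment used by the compartmental layout:
``auto`` means the node is unconstrained and will be confined to the cytosol
band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import MembershipError, RegistryError

#: Entity classes known to the default style registry (exactly eight).
DEFAULT_ENTITY_CLASSES: tuple[str, ...] = (
    "protein",
    "external_protein",
    "chemical",
    "small_molecule",
    "complex",
    "protein_family",
    "phenotype",
    "stimulus",
)

#: Interaction classes known by default (extensible via the style registry).
DEFAULT_INTERACTION_CLASSES: tuple[str, ...] = (
    "activation",
    "inhibition",
    "binding",
    "ppi",
    "complex_formation",
)

MODIFIERS: tuple[str, ...] = ("direct", "indirect", "transcriptional")

COMPARTMENTS: tuple[str, ...] = (
    "extracellular",
    "membrane",
    "cytosol",
    "nucleus",
    "phenotype_layer",
    "auto",
)

#: Classes whose edges are inherently directed / undirected.
_DIRECTED_CLASSES = frozenset({"activation", "inhibition"})
_UNDIRECTED_CLASSES = frozenset({"binding", "ppi", "complex_formation"})


def normalize_class(name: str) -> str:
    """Case-fold an interaction/entity class and normalize separators.

    ``Up-Regulates`` and ``up_regulates`` map to the same token.
    """
    return name.strip().lower().replace("-", "_").replace(" ", "_")


@dataclass(frozen=True)
class Entity:
    id: str
    label: str = ""
    entity_class: str = "protein"
    compartment: str = "auto"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("entity id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for entity {self.id!r}"
            )
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    interaction_class: str = "ppi"
    modifier: str = "direct"
    score: float | None = None
    directed: bool | None = None
    meta: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        cls = normalize_class(self.interaction_class)
        object.__setattr__(self, "interaction_class", cls)
        mod = normalize_class(self.modifier)
        if mod not in MODIFIERS:
            raise ValueError(f"unknown modifier {self.modifier!r}")
        object.__setattr__(self, "modifier", mod)
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if cls in _DIRECTED_CLASSES:
            directed = True
        elif cls in _UNDIRECTED_CLASSES:
            directed = False
        else:
            directed = True if self.directed is None else self.directed
        object.__setattr__(self, "directed", directed)

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Identity tuple used for duplicate collapse."""
        return (self.source, self.target, self.interaction_class, self.modifier)


@dataclass
class PathwayGraph:
    """Entities + interactions + named groups; the unit the filters act on."""

    entities: dict[str, Entity] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for inter in self.interactions:
            for eid in (inter.source, inter.target):
                if eid not in self.entities:
                    raise MembershipError(
                        f"interaction endpoint {eid!r} has no entity"
                    )
        for name, members in self.groups.items():
            for eid in members:
                if eid not in self.entities:
                    raise MembershipError(
                        f"group {name!r} references unknown entity {eid!r}"
                    )

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)


def build_graph(
    interactions: list[Interaction],
    annotations: dict[str, tuple[str, str]] | None = None,
    groups: dict[str, list[str]] | None = None,
    entity_classes: tuple[str, ...] | frozenset[str] | None = None,
) -> PathwayGraph:
    """Assemble a validated PathwayGraph from raw interactions.

    Every id mentioned by an interaction gets an Entity; unannotated ids
    default to class ``protein`` with compartment ``auto``.  Exact duplicate
    edges (same source, target, class, modifier) collapse keeping the max
    score.  Annotation classes must exist in the registry; unknown classes
    are rejected rather than silently defaulted.

    Parameters
    ----------
    interactions:
        Non-empty list of edges.
    annotations:
        Optional ``id -> (entity_class, compartment)`` map.  Either element
        may be ``""`` to keep the default.
    groups:
        Optional ``name -> [entity ids]`` map, validated for membership.
    entity_classes:
        The active class registry; defaults to the built-in eight.
    """
    if not interactions:
        raise ValueError("interaction list must be non-empty")
    registry = frozenset(entity_classes or DEFAULT_ENTITY_CLASSES)
    annotations = annotations or {}
    groups = groups or {}

    for eid, (cls, _compartment) in annotations.items():
        if cls and normalize_class(cls) not in registry:
            raise RegistryError(
                f"entity class {cls!r} (entity {eid!r}) not in registry"
            )

    entities: dict[str, Entity] = {}
    ordered_ids: list[str] = []
    for inter in interactions:
        for eid in (inter.source, inter.target):
            if eid not in entities:
                ordered_ids.append(eid)
                cls, compartment = annotations.get(eid, ("", ""))
                entities[eid] = Entity(
                    id=eid,
                    entity_class=normalize_class(cls) if cls else "protein",
                    compartment=compartment or "auto",
                )
    # Annotated ids that no interaction mentions still become entities.
    for eid, (cls, compartment) in annotations.items():
        if eid not in entities:
            ordered_ids.append(eid)
            entities[eid] = Entity(
                id=eid,
                entity_class=normalize_class(cls) if cls else "protein",
                compartment=compartment or "auto",
            )

    collapsed: dict[tuple[str, str, str, str], Interaction] = {}
    for inter in interactions:
        prev = collapsed.get(inter.key)
        if prev is None:
            collapsed[inter.key] = inter
        else:
            scores = [s for s in (prev.score, inter.score) if s is not None]
            best = max(scores) if scores else None
            if best != prev.score:
                collapsed[inter.key] = replace(prev, score=best)

    validated_groups: dict[str, list[str]] = {}
    for name, members in groups.items():
        for eid in members:
            if eid not in entities:
                raise MembershipError(
                    f"group {name!r} references id {eid!r} absent from "
                    "all interactions and annotations"
                )
        validated_groups[name] = list(members)

    return PathwayGraph(
        entities={eid: entities[eid] for eid in ordered_ids},
        interactions=list(collapsed.values()),
        groups=validated_groups,
    )


def filter_by_type(
    graph: PathwayGraph, allowed: set[tuple[str, str]]
) -> PathwayGraph:
    """Keep only interactions whose (class, modifier) pair is allowed.

    Entities are retained even if isolated, so toggling filters never
    re-layouts surviving nodes; groups pass through unchanged.
    """
    if not allowed:
        raise ValueError("allowed set must be non-empty")
    allowed_norm = {
        (normalize_class(c), normalize_class(m)) for c, m in allowed
    }
    kept = [
        i
        for i in graph.interactions
        if (i.interaction_class, i.modifier) in allowed_norm
    ]
    return PathwayGraph(
        entities=dict(graph.entities),
        interactions=kept,
        groups={k: list(v) for k, v in graph.groups.items()},
    )


def filter_by_score(graph: PathwayGraph, threshold: float) -> PathwayGraph:
    """Keep interactions with score >= threshold.

    Unscored interactions count as having no evidence of confidence: they
    survive only at threshold 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if threshold == 0.0:
        kept = list(graph.interactions)
    else:
        kept = [
            i
            for i in graph.interactions
            if i.score is not None and i.score >= threshold
        ]
    return PathwayGraph(
        entities=dict(graph.entities),
        interactions=kept,
        groups={k: list(v) for k, v in graph.groups.items()},
    )
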