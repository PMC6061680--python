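"""Seeded generator of synthetic signaling pathways for testing.

Emulates the structure of a curated cascade: stimuli and ligands in the
extracellular space, receptors at the membrane, kinases and complexes in
the cytosol, transcription factors in the nucleus and phenotypes at the
bottom.  Edges are drawn preferentially downstream (extracellular →
membrane → cytosol → nucleus → phenotype), so compartmental layouts of the
output look like real pathway figures.  Topology is otherwise random —
no scale-free fitting is attempted.

The generator is fully deterministic per seed and always produces output
that passes graph-build validation.  It can also emit all three input
dialects (links-JSON, PSI-MI TAB, SIGNOR-style TSV) to exercise the
parsers end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import Interaction

_LAYERS = (
    ("extracellular", "EX"),
    ("membrane", "R"),
    ("cytosol", "C"),
    ("nucleus", "TF"),
    ("phenotype_layer", "PH"),
)

#: Default entity-class mix per layer (probabilities sum to 1 per layer).
DEFAULT_CLASS_MIX: dict[str, dict[str, float]] = {
    "extracellular": {"stimulus": 0.4, "external_protein": 0.3, "chemical": 0.3},
    "membrane": {"protein": 1.0},
    "cytosol": {
        "protein": 0.6,
        "complex": 0.15,
        "small_molecule": 0.15,
        "protein_family": 0.1,
    },
    "nucleus": {"protein": 1.0},
    "phenotype_layer": {"phenotype": 1.0},
}

#: Fraction of edges forced to point down-layer; keeps cascades top-down.
DOWNSTREAM_BIAS = 0.8

#: Modifier mix for causal edges.
_MODIFIER_MIX = (("direct", 0.70), ("indirect", 0.15), ("transcriptional", 0.15))


@dataclass(frozen=True)
class SyntheticSpec:
    """Composition parameters of a generated pathway."""

    n_receptors: int = 5
    n_cytosolic: int = 10
    n_tfs: int = 4
    n_phenotypes: int = 2
    n_extracellular: int = 3
    edge_density: float = 2.0
    class_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_MIX.items()}
    )
    causal_fraction: float = 0.7
    score_distribution: dict = field(
        default_factory=lambda: {"kind": "uniform01", "none_fraction": 0.1}
    )
    n_groups: int = 1
    group_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.layer_counts
        if any(c < 0 for c in counts.values()):
            raise ValueError("layer counts must be nonnegative")
        if sum(counts.values()) < 2:
            raise ValueError("need at least 2 entities in total")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must lie in [0, 1]")
        if self.edge_density < 0:
            raise ValueError("edge_density must be nonnegative")
        for layer, mix in self.class_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"class_mix for layer {layer!r} sums to {total}, expected 1"
                )
        none_fraction = self.score_distribution.get("none_fraction", 0.0)
        if not 0.0 <= none_fraction <= 1.0:
            raise ValueError("none_fraction must lie in [0, 1]")

    @property
    def layer_counts(self) -> dict[str, int]:
        return {
            "extracellular": self.n_extracellular,
            "membrane": self.n_receptors,
            "cytosol": self.n_cytosolic,
            "nucleus": self.n_tfs,
            "phenotype_layer": self.n_phenotypes,
        }

    @property
    def n_entities(self) -> int:
        return sum(self.layer_counts.values())


def _sample_score(rng: np.random.Generator, dist: dict) -> float | None:
    if rng.uniform() < dist.get("none_fraction", 0.0):
        return None
    kind = dist.get("kind", "uniform01")
    if kind == "uniform01":
        return float(rng.uniform())
    if kind == "beta":
        return float(rng.beta(dist.get("a", 2.0), dist.get("b", 2.0)))
    raise ValueError(f"unknown score distribution kind {kind!r}")


def generate_pathway(
    spec: SyntheticSpec,
) -> tuple[list[Interaction], dict[str, tuple[str, str]], dict[str, list[str]]]:
    """Generate (interactions, annotations, groups) for a synthetic pathway.

    The edge count is Poisson with mean ``edge_density * n_entities``; a
    fraction :data:`DOWNSTREAM_BIAS` of edges connect a shallower layer to
    a strictly deeper one.  Causal edges are split evenly between
    activation and inhibition; the rest are undirected ppi.  Groups sample
    from cytosolic entities.
    """
    rng = np.random.default_rng(spec.seed)
    counts = spec.layer_counts

    ids: list[str] = []
    layer_of: dict[str, int] = {}
    annotations: dict[str, tuple[str, str]] = {}
    for layer_idx, (layer, prefix) in enumerate(_LAYERS):
        mix = spec.class_mix.get(layer, DEFAULT_CLASS_MIX[layer])
        classes = sorted(mix)
        probs = np.array([mix[c] for c in classes])
        for i in range(counts[layer]):
            eid = f"{prefix}{i + 1}"
            cls = classes[int(rng.choice(len(classes), p=probs))]
            ids.append(eid)
            layer_of[eid] = layer_idx
            annotations[eid] = (cls, layer)

    n = len(ids)
    n_edges = max(1, int(rng.poisson(spec.edge_density * n)))
    by_layer: list[list[str]] = [
        [eid for eid in ids if layer_of[eid] == li] for li in range(len(_LAYERS))
    ]
    nonempty = [li for li, members in enumerate(by_layer) if members]

    interactions: list[Interaction] = []
    seen: set[tuple[str, str, str, str]] = set()
    attempts = 0
    while len(interactions) < n_edges and attempts < 20 * n_edges:
        attempts += 1
        if rng.uniform() < DOWNSTREAM_BIAS and len(nonempty) >= 2:
            # Pick an ordered pair of distinct nonempty layers, shallow first.
            li, lj = sorted(rng.choice(nonempty, size=2, replace=False))
            source = by_layer[li][int(rng.integers(len(by_layer[li])))]
            target = by_layer[lj][int(rng.integers(len(by_layer[lj])))]
        else:
            source, target = (ids[int(i)] for i in rng.choice(n, size=2, replace=False))
        if source == target:
            continue
        if rng.uniform() < spec.causal_fraction:
            cls = "activation" if rng.uniform() < 0.5 else "inhibition"
            mod_names, mod_probs = zip(*_MODIFIER_MIX)
            modifier = mod_names[int(rng.choice(len(mod_names), p=np.array(mod_probs)))]
        else:
            cls, modifier = "ppi", "direct"
        key = (source, target, cls, modifier)
        if key in seen:
            continue
        seen.add(key)
        interactions.append(
            Interaction(
                source=source,
                target=target,
                interaction_class=cls,
                modifier=modifier,
                score=_sample_score(rng, spec.score_distribution),
            )
        )

    groups: dict[str, list[str]] = {}
    cytosolic = by_layer[2]
    for g in range(spec.n_groups):
        size = min(spec.group_size, len(cytosolic))
        if size < 1:
            break
        members = [cytosolic[int(i)] for i in rng.choice(len(cytosolic), size=size, replace=False)]
        groups[f"group_{g + 1}"] = members
    return interactions, annotations, groups


# --------------------------------------------------------------------------
# Dialect emitters (to exercise the parsers end to end)


def to_links_json(
    interactions: list[Interaction],
    annotations: dict[str, tuple[str, str]] | None = None,
    groups: dict[str, list[str]] | None = None,
) -> str:
    links = []
    for inter in interactions:
        rec: dict = {
            "source": inter.source,
            "target": inter.target,
            "type": inter.interaction_class,
            "modifier": inter.modifier,
        }
        if inter.score is not None:
            rec["score"] = round(inter.score, 6)
        links.append(rec)
    doc: dict = {"links": links}
    if annotations:
        doc["annotations"] = {
            eid: {"class": cls, "compartment": comp}
            for eid, (cls, comp) in annotations.items()
        }
    if groups:
        doc["groups"] = groups
    return json.dumps(doc, indent=1, sort_keys=True)


_MITAB_TYPE_FOR_CLASS = {
    "ppi": 'psi-mi:"MI:0915"(physical association)',
    "binding": 'psi-mi:"MI:0407"(direct interaction)',
    "complex_formation": 'psi-mi:"MI:0915"(physical association)',
    "activation": 'psi-mi:"MI:2235"(up-regulates)',
    "inhibition": 'psi-mi:"MI:2240"(down-regulates)',
}


def to_mitab(interactions: list[Interaction]) -> str:
    """Emit a 15-column PSI-MI TAB 2.5 document."""
    lines = ["#ID(s) interactor A\tID(s) interactor B\t" + "\t".join(
        f"column{i}" for i in range(3, 16)
    )]
    for inter in interactions:
        row = ["-"] * 15
        row[0] = f"uniprotkb:{inter.source}"
        row[1] = f"uniprotkb:{inter.target}"
        row[11] = _MITAB_TYPE_FOR_CLASS.get(
            inter.interaction_class, 'psi-mi:"MI:0915"(physical association)'
        )
        if inter.score is not None:
            row[14] = f"intact-miscore:{inter.score:.4f}"
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


_SIGNOR_EFFECT_FOR = {
    ("activation", "direct"): "up-regulates",
    ("activation", "indirect"): "indirectly up-regulates",
    ("activation", "transcriptional"): "up-regulates quantity by expression",
    ("inhibition", "direct"): "down-regulates",
    ("inhibition", "indirect"): "indirectly down-regulates",
    ("inhibition", "transcriptional"): "down-regulates quantity by expression",
    ("binding", "direct"): "binds",
    ("ppi", "direct"): "binds",
    ("complex_formation", "direct"): "form complex",
}

_SIGNOR_TYPE_FOR_CLASS = {
    "protein": "protein",
    "external_protein": "protein",
    "complex": "complex",
    "protein_family": "proteinfamily",
    "small_molecule": "smallmolecule",
    "chemical": "chemical",
    "phenotype": "phenotype",
    "stimulus": "stimulus",
}


def to_signor_tsv(
    interactions: list[Interaction],
    annotations: dict[str, tuple[str, str]] | None = None,
) -> str:
    """Emit a SIGNOR-style causal TSV with header-named columns."""
    annotations = annotations or {}
    lines = ["ENTITYA\tTYPEA\tIDA\tENTITYB\tTYPEB\tIDB\tEFFECT\tMECHANISM\tSCORE"]
    for inter in interactions:
        effect = _SIGNOR_EFFECT_FOR.get(
            (inter.interaction_class, inter.modifier), "binds"
        )
        type_a = _SIGNOR_TYPE_FOR_CLASS.get(
            annotations.get(inter.source, ("protein", ""))[0], "protein"
        )
        type_b = _SIGNOR_TYPE_FOR_CLASS.get(
            annotations.get(inter.target, ("protein", ""))[0], "protein"
        )
        score = "-" if inter.score is None else f"{inter.score:.4f}"
        lines.append(
            "\t".join(
                [
                    inter.source,
                    type_a,
                    inter.source,
                    inter.target,
                    type_b,
                    inter.target,
                    effect,
                    "-",
                    score,
                ]
            )
        )
    return "\n".join(lines) + "\n"
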