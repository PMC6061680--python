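# pathvis

Static, scriptable visualization of **signaling pathways** and
protein–protein interaction networks.

Curated signaling resources describe pathways as sets of *causal
interactions* — an entity up- or down-regulates a target — alongside plain
physical interactions. Biologists read such pathways as a top-down cascade:
stimulus in the extracellular space, receptor at the membrane, a relay
through the cytosol, transcription factors in the nucleus, phenotypes at the
bottom. Generic network viewers lay all of this out in free space, where
compartments, entity types and edge semantics are indistinguishable.

`pathvis` parses interaction files (a minimal links-JSON dialect, PSI-MI TAB
2.5/2.7 as served by PSICQUIC databases, and SIGNOR-style causal TSV), lays
the network out either **freely** or in a **compartmental** top-down model,
and renders publication-quality SVG 1.1 — entirely headless and
deterministic. There is no browser, no interactivity and no network access:
files in, SVG/CSV out.

## The model

Both layout modes run the same damped force simulation. For node positions
$x_i$, every edge $(i,j)$ exerts a spring force of magnitude
$k_s\,(\lVert x_i - x_j\rVert - L)$ toward rest length $L$, every node pair
repels with an inverse-square force $k_r / \lVert x_i - x_j\rVert^2$,
velocities are damped by a factor $\gamma$ each step, and every node is then
**projected back into its compartment band** (hard constraint, not a
penalty). Defaults: $k_s = 0.05$, $L = 60$, $k_r = 5000$, $\gamma = 0.85$,
at most 500 steps or until the largest per-step displacement falls below
0.01 canvas units.

The compartmental mode tiles the canvas into five horizontal bands — four
fixed layers spanning three named compartments (extracellular, membrane,
nucleus) plus a phenotype layer, with the cytosol band between membrane and
nucleus. Nodes annotated with a compartment stay in its band; unconstrained
nodes move freely inside the cytosol bounding box, which keeps them out of
the membrane and the nucleus. On top of the positions, the package computes
quadratic-curve offsets for parallel or obstructed edges, greedy label
placement over eight candidate slots, and padded convex hulls around
user-defined groups (e.g. complex subunits).

Entities draw as circles except complexes (octagons), phenotypes
(rectangles) and small molecules/chemicals (diamonds); eight entity classes
ship by default and the registry is extensible. Activation edges end in an
arrowhead, inhibition in a T-bar; indirect and transcriptional variants are
distinguished by dash pattern and a single reduced-opacity level.

## Worked example

```python
import pathvis as pv
from pathvis.synthetic import SyntheticSpec, generate_pathway

# A synthetic 24-entity cascade: 3 extracellular entities, 5 receptors,
# 10 cytosolic entities, 4 transcription factors, 2 phenotypes.
interactions, annotations, groups = generate_pathway(SyntheticSpec(seed=42))
graph = pv.build_graph(interactions, annotations, groups)
print("entities:", graph.n_entities)            # entities: 24
print("interactions:", graph.n_interactions)    # interactions: 54
print("groups:", dict(graph.groups))            # {'group_1': ['C2', 'C10', 'C8']}

strong = pv.filter_by_score(graph, 0.5)
print("score >= 0.5:", strong.n_interactions)   # score >= 0.5: 21

regions = pv.make_regions(640, 480)
layout = pv.layout_compartmental(graph, regions, pv.LayoutParams(seed=7))
print("label collisions:", layout.label_collisions)  # label collisions: 0

svg = pv.render_svg(graph, layout, regions)
print("SVG size (bytes):", len(svg))            # SVG size (bytes): 15651
open("pathway.svg", "w").write(svg)
```

The 54 interactions are what remains after exact-duplicate collapse of the
generator's raw edge list; the score filter keeps the 21 edges whose
confidence is at least 0.5; rerunning with the same seeds reproduces the
SVG byte for byte.

The same pipeline from the shell:

```sh
pathvis synth --seed 42 --out pathway.json
pathvis render pathway.json --layout compartmental --seed 7 \
    --min-score 0.5 --types activation,inhibition --out pathway.svg \
    --export-csv pathway.csv
```

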