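# Methods

## Scope and shape

`pathvis` is a headless pathway-figure engine: parse → filter → lay out →
render. Everything a GUI toolbar would do interactively (type filters,
score threshold, SVG/CSV export, group-hull highlighting) is exposed as
library functions and CLI flags; browser behaviors (click pop-ups, hover
effects, live database queries) are deliberately absent.

## Graph model

An `Entity` has an id, a display label, an entity class from an extensible
registry (default eight: protein, external_protein, chemical,
small_molecule, complex, protein_family, phenotype, stimulus), and a
compartment (extracellular, membrane, cytosol, nucleus, phenotype_layer, or
`auto` = unconstrained). An `Interaction` has a class (activation,
inhibition, binding, ppi, complex_formation — extensible), a modifier
(direct, indirect, transcriptional), an optional confidence score in
[0, 1], and a direction implied by its class: causal classes are directed,
physical classes undirected. Class strings are case-folded and
hyphen/underscore-normalized on input.

Graph building fills in a default `protein`/`auto` entity for every id an
interaction mentions, rejects unknown annotation classes (never silently
defaults them), validates group membership, and collapses exact duplicate
edges — same (source, target, class, modifier) — keeping the maximum score,
since a figure should show the strongest evidence.

Filter semantics, pinned by tests:

* `filter_by_type` keeps interactions whose (class, modifier) pair is in
  the allowed set. Entities survive even if isolated, so toggling filters
  never changes the layout of surviving nodes.
* `filter_by_score` uses an inclusive `>=` threshold. Edges without a
  score are kept at threshold 0 and dropped at any positive threshold —
  an absent score is treated as absent evidence of confidence, not as
  perfect confidence.
* The two filters are idempotent, score filtering is monotone in the
  threshold, and the two commute; these are property-tested.

## Input dialects

* **links-JSON** — a list of `{source, target, type, score?}` records,
  optionally wrapped in an object with `annotations` and `groups` maps.
  Unknown record keys are preserved into the edge's metadata.
* **PSI-MI TAB 2.5/2.7** — 15+ tab-separated columns, `-` for missing.
  Source and target are the first identifier of columns 1–2 (alternatives
  go to metadata); the score is the first numeric `key:value` entry of
  column 15, clamped to [0, 1]; a non-numeric score warns and stays unset.
  Edges are undirected ppi unless the column-12 interaction-type term is
  in a small promotion table (MI:2235 up-regulates → activation, MI:2240
  down-regulates → inhibition); everything else conservatively stays ppi.
* **SIGNOR-style causal TSV** — columns resolved by header name,
  case-insensitively, never by position, so column-order drift in exports
  is harmless. `up-regulates*` effects map to activation and
  `down-regulates*` to inhibition via an explicit, overridable effect
  table; `indirectly`/`by expression` qualifiers select the modifier.
  Effects absent from the table are returned in a rejects report, never
  guessed. Entity-type columns populate class annotations.

Export is RFC-4180 CSV (`source,target,interaction_class,modifier,score`),
and `read_csv` re-imports it; the write→read round trip preserves the edge
multiset exactly, including unset scores.

## Force model and compartment constraints

Both layouts integrate the same damped dynamics with unit time step:

* spring force `k_s · (d − L)` along each edge (attractive beyond the rest
  length, repulsive inside it),
* inverse-square repulsion `k_r / d²` between all node pairs,
* `v ← (v + F) · γ`, `x ← x + v`,
* hard projection of every node into its allowed box after every step.

Defaults: `k_s = 0.05`, `L = 60`, `k_r = 5000`, `γ = 0.85`, `max_steps =
500`, convergence when the largest per-step displacement ≤ 0.01 canvas
units. The constants are conventional spring-embedder values at this canvas
scale; all are overridable through `LayoutParams`. Energy is *not*
monotone (damped simulations oscillate), so termination is defined by the
displacement criterion or the step cap, never by an energy assertion.

For a two-node, one-edge graph the stationary separation solves
`k_s · d² · (d − L) = k_r`; with the defaults the positive root is
≈ 76.9 units, and the simulated free layout lands within 10% of it (the
acceptance suite measures ~2%).

Compartment handling is projection, not penalty: the band boundary can
never be crossed at the end of a step, so the constraint holds exactly for
every node in every layout, regardless of whether the simulation has
converged. Membrane and nucleus nodes are not frozen — they slide
horizontally and within their band. `auto` nodes are confined to the
cytosol band, which is what keeps unconstrained nodes out of the membrane
and nucleus. Coincident nodes get a deterministic, index-derived
symmetry-breaking displacement so repulsion can separate them
reproducibly.

The five bands tile the canvas top-to-bottom in the order extracellular,
membrane, cytosol, nucleus, phenotype with default height fractions
0.10 / 0.12 / 0.56 / 0.12 / 0.10 — thin fixed strips around a dominant
cytosol, configurable per call. Membrane fills yellow and nucleus lilac;
all colors live in one theme table and can be overridden from a
`key=value` theme file.

Randomness: one named, seedable generator (`numpy.random.default_rng`)
drives initial placement; the seed is recorded in the `Layout` for
provenance. Same graph + params + seed ⇒ bit-identical layout.

## Edge curvature

Edges default to straight (offset 0). Multiple edges between the same node
pair fan out with alternating perpendicular offsets ±k, ±2k, … (k = 20
units by default). Offsets are stored in the canonical frame of the
unordered id pair — direction from the lexicographically smaller id — so
two antiparallel edges receive +k and −k and visually bow to opposite
sides; the renderer converts to each edge's own frame. A single edge whose
chord passes within (node radius + 4) of a non-endpoint node takes the
smallest alternating multiple of k whose sampled quadratic curve clears
every obstacle (32 samples; capped at 10k if nothing clears). All choices
are deterministic in graph order.

## Label placement

Text extents are estimated from a fixed per-character width table at 12 px
(no font engine exists in a headless renderer); the table errs a little
wide, which is conservative for overlap avoidance but means collision
counts refer to estimated, not rendered, rectangles. Each label greedily
takes the first of eight slots (E, W, N, S, NE, NW, SE, SW) whose rectangle
overlaps no node circle and no previously placed label; if all eight
collide, the slot with the least total overlap is taken. The reported
collision count is the number of intersecting label-rectangle pairs in the
final placement — computed incrementally, it equals an independent
brute-force pairwise intersection count, which is how it is verified.

## Group hulls

A group's hull is the convex hull of its members' centers offset outward by
(node radius + padding, default 12 + 10), computed via shapely's buffer;
degenerate groups come out right by construction (one member → a
near-circle polygon, two → a stadium). Tests verify containment and
convexity against a hand-written gift-wrapping oracle. Hulls render gray;
highlighted groups render red with the group name shown — the static
equivalent of an interactive hover highlight.

## Rendering

Output is standalone SVG 1.1 with a single namespace, drawn back to front:
region bands, hulls, edges, nodes, labels. Arrowheads and T-bars are marker
definitions in `defs`, one per (terminal, color), so dash patterns do not
distort terminals; edge endpoints are trimmed to the node-circle boundary
along the tangent toward the control point so terminals touch rather than
pierce nodes. Coordinates are formatted to two decimals; identical inputs
produce byte-identical files, verified across separate processes.

Edge glyph distinctness: the interaction class fixes the terminal and a
base dash (solid for causal classes and ppi, long-dash for binding,
short-dash for complex formation); the modifier contributes the dash
override and opacity (indirect = dashed at the registry's single reduced
opacity 0.55, transcriptional = dotted at full opacity). Every registered
(class, modifier) pair therefore has a unique (terminal, dash, opacity)
triple, and exactly one opacity level below 1.0 exists in the registry.

## Synthetic pathways

The generator emulates the *structure* of a curated cascade so every stage
is testable without downloads: entities per layer (defaults 3
extracellular, 5 receptors, 10 cytosolic, 4 transcription factors, 2
phenotypes), a per-layer class mix (e.g. stimuli and chemicals
extracellular, complexes and small molecules cytosolic), Poisson edge count
with mean `edge_density × n_entities` (default density 2), 80% of edges
forced downstream so compartmental layouts look like pathway figures, a
causal fraction (default 0.7, split evenly between activation and
inhibition; causal modifiers 70% direct / 15% indirect / 15%
transcriptional), and scores from a configurable distribution with a
configurable unscored fraction (default uniform on [0, 1], 10% unscored).
It emits all three input dialects to exercise the parsers end to end.

What it does **not** emulate: degree distributions of real interactomes
(no scale-free fitting), identifier vocabularies, or biologically coherent
sign structure. Passing tests therefore demonstrate correctness of
parsing, constraint satisfaction, determinism and geometry — not that real
pathways become *legible*, which remains a judgment call on real data.

## Problem sizes used in the checks

The constraint sweep runs 200 graphs of 20–200 nodes (100 in the
acceptance script) at 100 simulation steps — projection makes constraint
satisfaction independent of convergence, so fewer steps check the same
property. Oracle comparisons use 1000/500/100 random cases (clamp / hull /
labels) in the test suite and 500/300/100 in the script; round trips use
100 fixtures. These sizes keep the full suite around twenty seconds while
exercising every code path.

## Known limitations

* The force model is the classical spring embedder only; no alternative
  layouts (layered/Sugiyama, orthogonal) are provided.
* Label placement is greedy and order-dependent by design (deterministic),
  so a globally better assignment may exist.
* Text metrics are estimates; a renderer with real font metrics may show
  slightly different spacing than the collision counts assume.
* PSI-MI XML and MI-JSON inputs are out of scope, as are live PSICQUIC
  queries; only files are read.
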