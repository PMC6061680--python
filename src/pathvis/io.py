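"""Readers for the three supported input dialects and the CSV exporter.

Supported inputs:

* **links-JSON** — the minimal record format: a list of link objects with
  ``source``, ``target``, ``type`` and optionally ``score``, plus optional
  sibling maps for node annotations and groups.
* **PSI-MI TAB 2.5 / 2.7** — the tab-separated molecular-interaction
  exchange format served by PSICQUIC-compliant databases; 15 columns in
  version 2.5, extended in 2.7, missing values written ``-``.
* **SIGNOR-style causal TSV** — header-named columns carrying entity names,
  types, a causal effect string (``up-regulates`` and friends), mechanism
  and confidence score.

All parsers are pure text-in / records-out; no network access ever.
Output is RFC-4180 CSV with one row per interaction.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
import warnings
from dataclasses import dataclass

from .errors import FormatError, RecordError
from .model import Interaction, PathwayGraph, normalize_class

# --------------------------------------------------------------------------
# links-JSON


def parse_links_json(
    text: str,
) -> tuple[list[Interaction], dict[str, tuple[str, str]], dict[str, list[str]]]:
    """Parse the minimal links record format.

    Accepts either a bare list of link records or an object with a
    ``links`` list plus optional ``annotations`` (id -> {class, compartment}
    or [class, compartment]) and ``groups`` maps.  Unknown link keys are
    preserved into the interaction's meta map.
    """
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(
            f"malformed links-JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc

    if isinstance(data, list):
        records, raw_annotations, raw_groups = data, {}, {}
    elif isinstance(data, dict):
        records = data.get("links", [])
        raw_annotations = data.get("annotations", {})
        raw_groups = data.get("groups", {})
    else:
        raise FormatError("links-JSON top level must be a list or object")

    known = {"source", "target", "type", "interaction_class", "modifier",
             "score", "directed"}
    interactions: list[Interaction] = []
    for index, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise RecordError(f"link record {index} is not an object")
        source = rec.get("source")
        target = rec.get("target")
        if not source or not target:
            raise RecordError(f"link record {index} missing source or target")
        cls = rec.get("type") or rec.get("interaction_class") or "ppi"
        score = rec.get("score")
        meta = tuple(
            (k, str(v)) for k, v in sorted(rec.items()) if k not in known
        )
        interactions.append(
            Interaction(
                source=str(source),
                target=str(target),
                interaction_class=str(cls),
                modifier=str(rec.get("modifier", "direct")),
                score=float(score) if score is not None else None,
                meta=meta,
            )
        )

    annotations: dict[str, tuple[str, str]] = {}
    for eid, ann in raw_annotations.items():
        if isinstance(ann, dict):
            annotations[eid] = (
                ann.get("class", ann.get("entity_class", "")),
                ann.get("compartment", ""),
            )
        else:
            cls, compartment = (list(ann) + ["", ""])[:2]
            annotations[eid] = (cls, compartment)
    groups = {name: [str(m) for m in members] for name, members in raw_groups.items()}
    return interactions, annotations, groups


# --------------------------------------------------------------------------
# PSI-MI TAB

#: Conservative MI-term -> causal class promotion table.  Only the PSI-MI
#: causal-statement terms promote a physical edge to a causal one; any
#: other interaction-type term stays plain ppi.
MITAB_CAUSAL_TERMS: dict[str, str] = {
    "MI:2235": "activation",  # up-regulates
    "MI:2240": "inhibition",  # down-regulates
}

_MITAB_MIN_COLUMNS = 15


def _first_mitab_identifier(field: str) -> tuple[str, list[str]]:
    """Return (first identifier accession, remaining alternatives)."""
    entries = field.split("|")
    first = entries[0]
    acc = first.split(":", 1)[1] if ":" in first else first
    return acc.strip().strip('"'), entries[1:]


def _mitab_score(field: str) -> float | None:
    """First numeric value of a ``scorer:value`` list, clamped to [0, 1]."""
    if field == "-" or not field:
        return None
    for entry in field.split("|"):
        value = entry.rsplit(":", 1)[-1].strip('"')
        try:
            score = float(value)
        except ValueError:
            continue
        return min(1.0, max(0.0, score))
    warnings.warn(f"non-numeric MITAB confidence field {field!r}; score unset")
    return None


def parse_mitab(text: str, version: str = "2.5") -> list[Interaction]:
    """Parse a PSI-MI TAB 2.5 or 2.7 document into interactions.

    Source and target are the first identifier of columns 1-2; the edge is
    plain undirected ppi unless the column-12 interaction-type MI term is in
    :data:`MITAB_CAUSAL_TERMS`; the score is the first numeric entry of
    column 15.  ``#`` header lines are skipped; ``-`` means unset.
    """
    if version not in ("2.5", "2.7"):
        raise ValueError(f"unsupported MITAB version {version!r}")
    interactions: list[Interaction] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        columns = line.split("\t")
        if len(columns) < _MITAB_MIN_COLUMNS:
            raise FormatError(
                f"MITAB line {lineno} has {len(columns)} columns; "
                f"at least {_MITAB_MIN_COLUMNS} required"
            )
        source, alt_a = _first_mitab_identifier(columns[0])
        target, alt_b = _first_mitab_identifier(columns[1])
        if not source or not target or columns[0] == "-" or columns[1] == "-":
            raise FormatError(f"MITAB line {lineno} missing an interactor id")

        interaction_class, modifier = "ppi", "direct"
        type_field = columns[11]
        for term, causal_class in MITAB_CAUSAL_TERMS.items():
            if term in type_field:
                interaction_class = causal_class
                break

        score = _mitab_score(columns[14])
        meta: list[tuple[str, str]] = []
        if alt_a:
            meta.append(("alt_ids_a", "|".join(alt_a)))
        if alt_b:
            meta.append(("alt_ids_b", "|".join(alt_b)))
        if type_field != "-":
            meta.append(("mi_interaction_type", type_field))
        interactions.append(
            Interaction(
                source=source,
                target=target,
                interaction_class=interaction_class,
                modifier=modifier,
                score=score,
                meta=tuple(meta),
            )
        )
    return interactions


# --------------------------------------------------------------------------
# SIGNOR-style causal TSV


def _causal_effect_table() -> dict[str, tuple[str, str]]:
    """Default effect-string -> (interaction_class, modifier) table.

    ``up-regulates*`` maps to activation and ``down-regulates*`` to
    inhibition; qualifier substrings (``indirect``, ``by expression`` /
    ``transcription``) select the modifier.
    """
    table: dict[str, tuple[str, str]] = {}
    for prefix, cls in (("up-regulates", "activation"), ("down-regulates", "inhibition")):
        table[prefix] = (cls, "direct")
        table[f"{prefix} activity"] = (cls, "direct")
        table[f"{prefix} quantity"] = (cls, "direct")
        table[f"{prefix} quantity by expression"] = (cls, "transcriptional")
        table[f"{prefix} quantity by stabilization"] = (cls, "direct")
        table[f"{prefix} quantity by destabilization"] = (cls, "direct")
        table[f"indirectly {prefix}"] = (cls, "indirect")
        table[f"{prefix} indirectly"] = (cls, "indirect")
    table["binds"] = ("binding", "direct")
    table["form complex"] = ("complex_formation", "direct")
    table["forms complex"] = ("complex_formation", "direct")
    return table


DEFAULT_EFFECT_TABLE = _causal_effect_table()

#: SIGNOR entity-type vocabulary -> registry class.
_SIGNOR_TYPE_MAP = {
    "protein": "protein",
    "complex": "complex",
    "proteinfamily": "protein_family",
    "protein family": "protein_family",
    "smallmolecule": "small_molecule",
    "small molecule": "small_molecule",
    "chemical": "chemical",
    "phenotype": "phenotype",
    "stimulus": "stimulus",
}

_REQUIRED_SIGNOR_COLUMNS = ("entitya", "entityb", "effect")


@dataclass
class SignorReject:
    """A row whose effect string could not be mapped; reported, not guessed."""

    row: int
    effect: str


def parse_signor_tsv(
    text: str,
    effect_table: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[Interaction], dict[str, tuple[str, str]], list[SignorReject]]:
    """Parse a SIGNOR-style causal TSV.

    Columns are resolved by header name, case-insensitively, never by
    position.  Entity type columns populate the annotations map.  Rows with
    an effect absent from the table are collected into the rejects report.
    """
    effect_table = effect_table if effect_table is not None else DEFAULT_EFFECT_TABLE
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty SIGNOR document")
    header = [h.strip().lower() for h in lines[0].rstrip("\r").split("\t")]
    col = {name: i for i, name in enumerate(header)}
    for required in _REQUIRED_SIGNOR_COLUMNS:
        if required not in col:
            raise FormatError(f"SIGNOR header missing required column {required!r}")

    def get(fields: list[str], name: str) -> str:
        idx = col.get(name)
        if idx is None or idx >= len(fields):
            return ""
        value = fields[idx].strip()
        return "" if value == "-" else value

    interactions: list[Interaction] = []
    annotations: dict[str, tuple[str, str]] = {}
    rejects: list[SignorReject] = []
    for rowno, raw in enumerate(lines[1:], 2):
        fields = raw.rstrip("\r").split("\t")
        name_a = get(fields, "entitya")
        name_b = get(fields, "entityb")
        effect = get(fields, "effect").lower()
        if not name_a or not name_b:
            raise RecordError(f"SIGNOR row {rowno} missing entity A or B")
        mapped = effect_table.get(effect)
        if mapped is None:
            rejects.append(SignorReject(row=rowno, effect=effect))
            continue
        interaction_class, modifier = mapped
        score_text = get(fields, "score")
        try:
            score = float(score_text) if score_text else None
        except ValueError:
            warnings.warn(f"SIGNOR row {rowno}: non-numeric score {score_text!r}")
            score = None
        mechanism = get(fields, "mechanism")
        meta = (("mechanism", mechanism),) if mechanism else ()
        interactions.append(
            Interaction(
                source=name_a,
                target=name_b,
                interaction_class=interaction_class,
                modifier=modifier,
                score=score,
                meta=meta,
            )
        )
        for name, type_col in ((name_a, "typea"), (name_b, "typeb")):
            signor_type = get(fields, type_col).lower()
            cls = _SIGNOR_TYPE_MAP.get(signor_type)
            if cls and name not in annotations:
                annotations[name] = (cls, "")
    return interactions, annotations, rejects


# --------------------------------------------------------------------------
# CSV export / import

_CSV_HEADER = ["source", "target", "interaction_class", "modifier", "score"]


def write_csv(graph: PathwayGraph) -> str:
    """Serialize the graph's interactions as RFC-4180 CSV text.

    One row per interaction in graph order; an unset score becomes an empty
    field.  Parsing the CSV back reproduces the edge multiset.
    """
    buffer = _stdio.StringIO()
    writer = csv.writer(buffer, lineterminator="\n")
    writer.writerow(_CSV_HEADER)
    for inter in graph.interactions:
        writer.writerow(
            [
                inter.source,
                inter.target,
                inter.interaction_class,
                inter.modifier,
                "" if inter.score is None else format(inter.score, "g"),
            ]
        )
    return buffer.getvalue()


def read_csv(text: str) -> list[Interaction]:
    """Re-import interactions written by :func:`write_csv`."""
    reader = csv.reader(_stdio.StringIO(text))
    rows = list(reader)
    if not rows:
        return []
    header = [h.strip().lower() for h in rows[0]]
    if header[:2] != ["source", "target"]:
        raise FormatError("CSV header must start with source,target")
    col = {name: i for i, name in enumerate(header)}
    interactions = []
    for rowno, fields in enumerate(rows[1:], 2):
        if not any(fields):
            continue
        if len(fields) < 2:
            raise RecordError(f"CSV row {rowno} missing source/target")
        score_text = fields[col["score"]] if "score" in col and col["score"] < len(fields) else ""
        interactions.append(
            Interaction(
                source=fields[col["source"]],
                target=fields[col["target"]],
                interaction_class=(
                    fields[col["interaction_class"]]
                    if "interaction_class" in col
                    else "ppi"
                ),
                modifier=(
                    fields[col["modifier"]] if "modifier" in col else "direct"
                ),
                score=float(score_text) if score_text else None,
            )
        )
    return interactions


def normalize_effect(effect: str) -> str:
    """Canonical lower-case form of a causal effect string."""
    return normalize_class(effect).replace("_", " ")
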