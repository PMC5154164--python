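"""Reading and writing the package's file formats.

* native pathway collection: JSON with top-level keys
  ``{schema_version, compounds, reactions, pathways}`` (schema shipped in
  ``schemas/collection.schema.json``); pathways reference reactions by id
* omics tables: tab-delimited UTF-8 text, header row, first column = entity id
* saved collages: versioned JSON, lossless round-trip
* viewer export: a Cytoscape-style elements/style graph JSON dialect
  (``schemas/viewer.schema.json``)
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional

from . import minischema
from .errors import (
    CollectionValidationError,
    FormatError,
    SchemaVersionError,
)
from .model import (
    CollageGraph,
    ColorScheme,
    Compound,
    EdgeGlyph,
    Glyph,
    MergeRecord,
    OmicsDataset,
    Pathway,
    PathwayCollection,
    PathwayLayout,
    PlacedLayout,
    Reaction,
    ReactionParticipant,
    StyleConfig,
    ZoomPolicy,
    validate_collection,
)

logger = logging.getLogger(__name__)

COLLECTION_SCHEMA_VERSION = "1.0"
COLLAGE_SCHEMA_VERSION = "1.0"

#: tolerance used when comparing saved/loaded coordinates
COORD_TOL = 1e-9


def _load_schema(name: str) -> dict:
    ref = resources.files("pathwaycollage").joinpath("schemas", name)
    return json.loads(ref.read_text(encoding="utf-8"))


def _read_json(path) -> object:
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(
            f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc


# ---------------------------------------------------------------------------
# pathway collections
# ---------------------------------------------------------------------------

def read_pathway_collection(path) -> PathwayCollection:
    """Parse and validate a native collection file.

    Raises :class:`FormatError` for malformed JSON or shape problems,
    :class:`SchemaVersionError` for unknown versions, and
    :class:`CollectionValidationError` listing every invariant breach.
    """
    doc = _read_json(path)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: top level must be a JSON object")
    version = doc.get("schema_version")
    if version != COLLECTION_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: unknown collection schema_version {version!r} "
            f"(this build reads {COLLECTION_SCHEMA_VERSION!r})"
        )
    errors = minischema.validate(doc, _load_schema("collection.schema.json"))
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))
    collection = collection_from_dict(doc)
    violations = validate_collection(collection)
    if violations:
        raise CollectionValidationError(violations)
    return collection


def collection_from_dict(doc: dict) -> PathwayCollection:
    compounds = [
        Compound(
            id=c["id"],
            name=c.get("name", ""),
            synonyms=list(c.get("synonyms", [])),
        )
        for c in doc["compounds"]
    ]
    reactions = {}
    for r in doc["reactions"]:
        reactions[r["id"]] = Reaction(
            id=r["id"],
            direction=r.get("direction", "forward"),
            enzyme_labels=list(r.get("enzyme_labels", [])),
            gene_ids=list(r.get("gene_ids", [])),
            participants=[
                ReactionParticipant(
                    compound_id=p["compound_id"],
                    side=p["side"],
                    role=p["role"],
                    coefficient=p.get("coefficient", 1.0),
                )
                for p in r["participants"]
            ],
        )
    pathways = []
    for pw in doc["pathways"]:
        missing = [rid for rid in pw["reaction_ids"] if rid not in reactions]
        if missing:
            raise FormatError(
                f"pathway {pw['id']} references undeclared reactions: "
                + ", ".join(missing)
            )
        pathways.append(
            Pathway(
                id=pw["id"],
                name=pw.get("name", ""),
                reactions=[reactions[rid] for rid in pw["reaction_ids"]],
                links=[tuple(l) for l in pw.get("links", [])],
                class_path=list(pw.get("class_path", [])),
            )
        )
    return PathwayCollection(
        schema_version=doc["schema_version"],
        compounds=compounds,
        pathways=pathways,
    )


def collection_to_dict(collection: PathwayCollection) -> dict:
    reactions: dict[str, Reaction] = {}
    for pw in collection.pathways:
        for r in pw.reactions:
            reactions.setdefault(r.id, r)
    return {
        "schema_version": collection.schema_version,
        "compounds": [
            {"id": c.id, "name": c.name, "synonyms": list(c.synonyms)}
            for c in collection.compounds
        ],
        "reactions": [
            {
                "id": r.id,
                "direction": r.direction,
                "enzyme_labels": list(r.enzyme_labels),
                "gene_ids": list(r.gene_ids),
                "participants": [
                    {
                        "compound_id": p.compound_id,
                        "side": p.side,
                        "role": p.role,
                        "coefficient": p.coefficient,
                    }
                    for p in r.participants
                ],
            }
            for r in reactions.values()
        ],
        "pathways": [
            {
                "id": pw.id,
                "name": pw.name,
                "reaction_ids": [r.id for r in pw.reactions],
                "links": [list(l) for l in pw.links],
                "class_path": list(pw.class_path),
            }
            for pw in collection.pathways
        ],
    }


def write_pathway_collection(collection: PathwayCollection, path) -> None:
    Path(path).write_text(
        json.dumps(collection_to_dict(collection), indent=1), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# omics tables
# ---------------------------------------------------------------------------

def read_omics_table(path, data_type: str) -> OmicsDataset:
    """Parse a TSV omics table.

    Header row gives column labels (first cell is the id column and is
    skipped).  Empty and non-numeric cells become missing values.  Duplicate
    entity ids keep the last row, with a logged warning.
    """
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty omics table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(
            f"{path}: omics table needs an id column plus >= 1 value column"
        )
    columns = header[1:]
    rows: dict[str, list[Optional[float]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        entity = cells[0]
        values = cells[1:]
        if len(values) > len(columns):
            raise FormatError(
                f"{path}:{lineno}: row has {len(values)} values for "
                f"{len(columns)} columns"
            )
        vec: list[Optional[float]] = []
        for cell in values:
            cell = cell.strip()
            try:
                v: Optional[float] = float(cell)
                if v != v:  # NaN literal
                    v = None
            except ValueError:
                v = None
            vec.append(v)
        vec.extend([None] * (len(columns) - len(vec)))
        if entity in rows:
            logger.warning(
                "%s:%d: duplicate entity id %r; last row wins", path, lineno, entity
            )
        rows[entity] = vec
    if not rows:
        raise FormatError(f"{path}: omics table has no data rows")
    return OmicsDataset(data_type=data_type, columns=columns, rows=rows)


def read_color_scheme(path) -> ColorScheme:
    doc = _read_json(path)
    if not isinstance(doc, dict) or "breakpoints" not in doc or "colors" not in doc:
        raise FormatError(f"{path}: scheme needs 'breakpoints' and 'colors'")
    return ColorScheme(
        breakpoints=[float(b) for b in doc["breakpoints"]],
        colors=list(doc["colors"]),
        missing_color=doc.get("missing_color", "#bbbbbb"),
    )


# ---------------------------------------------------------------------------
# collage save / load
# ---------------------------------------------------------------------------

def _glyph_to_dict(g: Glyph) -> dict:
    return {
        "uid": g.uid,
        "kind": g.kind,
        "ref": g.ref_id,
        "x": g.x,
        "y": g.y,
        "w": g.width,
        "h": g.height,
        "color": g.color,
        "label": g.label_text,
        "visible": g.visible,
        "parent": g.parent_uid,
        "hides_parent": g.hides_parent,
    }


def _glyph_from_dict(d: dict) -> Glyph:
    return Glyph(
        uid=d["uid"],
        kind=d["kind"],
        ref_id=d["ref"],
        x=d["x"],
        y=d["y"],
        width=d["w"],
        height=d["h"],
        color=d["color"],
        label_text=d["label"],
        visible=d["visible"],
        parent_uid=d.get("parent"),
        hides_parent=d.get("hides_parent", False),
    )


def _edge_to_dict(e: EdgeGlyph) -> dict:
    return {
        "uid": e.uid,
        "kind": e.kind,
        "source": e.source_uid,
        "target": e.target_uid,
        "ref": e.ref_id,
        "color": e.color,
        "thickness": e.thickness,
        "arrow": e.arrow,
    }


def _edge_from_dict(d: dict) -> EdgeGlyph:
    return EdgeGlyph(
        uid=d["uid"],
        kind=d["kind"],
        source_uid=d["source"],
        target_uid=d["target"],
        ref_id=d["ref"],
        color=d["color"],
        thickness=d["thickness"],
        arrow=d["arrow"],
    )


def _style_to_dict(s: StyleConfig) -> dict:
    return {
        "show_pathway_boxes": s.show_pathway_boxes,
        "show_pathway_labels": s.show_pathway_labels,
        "show_enzyme_labels": s.show_enzyme_labels,
        "show_gene_labels": s.show_gene_labels,
        "show_omics": s.show_omics,
        "show_connections": s.show_connections,
        "font_sizes": dict(s.font_sizes),
        "colors": dict(s.colors),
        "edge_thickness": s.edge_thickness,
    }


def _style_from_dict(d: dict) -> StyleConfig:
    return StyleConfig(**d)


def collage_to_dict(collage: CollageGraph) -> dict:
    doc = {
        "schema_version": collage.schema_version,
        "style": _style_to_dict(collage.style),
        "layouts": [
            {
                "offset": [p.dx, p.dy],
                "pathway_id": p.layout.pathway_id,
                "glyphs": [_glyph_to_dict(g) for g in p.layout.glyphs],
                "edges": [_edge_to_dict(e) for e in p.layout.edges],
                "bbox": list(p.layout.bbox),
                "backbone": list(p.layout.backbone),
                "genes": {k: list(v) for k, v in p.layout.genes.items()},
            }
            for p in collage.layouts
        ],
        "connections": [_edge_to_dict(e) for e in collage.connections],
        "merges": [
            {"survivor": m.survivor, "absorbed": list(m.absorbed)}
            for m in collage.merges
        ],
        "painted_uids": list(collage.painted_uids),
        "omics": None,
    }
    if collage.omics is not None:
        dataset, scheme = collage.omics
        doc["omics"] = {
            "dataset": {
                "data_type": dataset.data_type,
                "columns": list(dataset.columns),
                "rows": {k: list(v) for k, v in dataset.rows.items()},
            },
            "scheme": {
                "breakpoints": list(scheme.breakpoints),
                "colors": list(scheme.colors),
                "missing_color": scheme.missing_color,
            },
        }
    return doc


def collage_from_dict(doc: dict) -> CollageGraph:
    version = doc.get("schema_version")
    if version != COLLAGE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unknown collage schema_version {version!r} "
            f"(this build reads {COLLAGE_SCHEMA_VERSION!r})"
        )
    omics = None
    if doc.get("omics") is not None:
        od = doc["omics"]["dataset"]
        os_ = doc["omics"]["scheme"]
        omics = (
            OmicsDataset(
                data_type=od["data_type"],
                columns=list(od["columns"]),
                rows={k: list(v) for k, v in od["rows"].items()},
            ),
            ColorScheme(
                breakpoints=list(os_["breakpoints"]),
                colors=list(os_["colors"]),
                missing_color=os_["missing_color"],
            ),
        )
    return CollageGraph(
        schema_version=version,
        style=_style_from_dict(doc["style"]),
        layouts=[
            PlacedLayout(
                layout=PathwayLayout(
                    pathway_id=p["pathway_id"],
                    glyphs=[_glyph_from_dict(g) for g in p["glyphs"]],
                    edges=[_edge_from_dict(e) for e in p["edges"]],
                    bbox=tuple(p["bbox"]),
                    backbone=list(p["backbone"]),
                    genes={k: list(v) for k, v in p.get("genes", {}).items()},
                ),
                dx=p["offset"][0],
                dy=p["offset"][1],
            )
            for p in doc["layouts"]
        ],
        connections=[_edge_from_dict(e) for e in doc["connections"]],
        merges=[
            MergeRecord(survivor=m["survivor"], absorbed=list(m["absorbed"]))
            for m in doc["merges"]
        ],
        painted_uids=list(doc.get("painted_uids", [])),
        omics=omics,
    )


def save_collage(collage: CollageGraph, path) -> None:
    """Write a collage as versioned JSON (numbers at full precision)."""
    Path(path).write_text(
        json.dumps(collage_to_dict(collage)), encoding="utf-8"
    )


def load_collage(path) -> CollageGraph:
    doc = _read_json(path)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: collage file must contain a JSON object")
    return collage_from_dict(doc)


# ---------------------------------------------------------------------------
# deep equality (exact for ids/strings, tolerant for coordinates)
# ---------------------------------------------------------------------------

def _num_eq(a: float, b: float) -> bool:
    return abs(a - b) <= COORD_TOL


def collages_equal(a: CollageGraph, b: CollageGraph) -> bool:
    return _deep_eq(collage_to_dict(a), collage_to_dict(b))


def _deep_eq(a, b) -> bool:
    if isinstance(a, bool) or isinstance(b, bool):
        return a is b
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return _num_eq(float(a), float(b))
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(_deep_eq(a[k], b[k]) for k in a)
    if isinstance(a, list) and isinstance(b, list):
        return len(a) == len(b) and all(_deep_eq(x, y) for x, y in zip(a, b))
    return a == b


# ---------------------------------------------------------------------------
# viewer export
# ---------------------------------------------------------------------------

def export_viewer_json(collage: CollageGraph) -> dict:
    """Convert a collage to the elements/style graph dialect.

    Each visible glyph becomes a node object with its collage-global center
    position; each reaction and connection edge becomes an edge object.
    """
    elements: list[dict] = []
    for g, placed in collage.iter_glyphs():
        if not g.visible:
            continue
        cx, cy = g.center
        elements.append(
            {
                "group": "nodes",
                "data": {
                    "id": g.uid,
                    "label": g.label_text,
                    "kind": g.kind,
                    "ref": g.ref_id,
                    "color": g.color,
                },
                "position": {"x": cx + placed.dx, "y": cy + placed.dy},
            }
        )
    present = {g.uid for g, _ in collage.iter_glyphs()}
    for e in collage.iter_edges():
        if e.source_uid not in present or e.target_uid not in present:
            continue
        elements.append(
            {
                "group": "edges",
                "data": {
                    "id": e.uid,
                    "source": e.source_uid,
                    "target": e.target_uid,
                    "kind": "connection"
                    if e.kind == "connection-edge"
                    else "reaction",
                    "ref": e.ref_id,
                    "color": e.color,
                },
            }
        )
    style = collage.style
    style_section = [
        {
            "selector": f'node[kind = "{kind}"]',
            "style": {"background-color": style.color_for_kind(kind)},
        }
        for kind in sorted(style.colors)
        if not kind.endswith("edge")
    ] + [
        {
            "selector": f'edge[kind = "{name}"]',
            "style": {
                "line-color": style.color_for_kind(f"{name}-edge"),
                "width": style.edge_thickness,
            },
        }
        for name in ("reaction", "connection")
    ]
    return {"elements": elements, "style": style_section}


def validate_viewer_json(doc: dict) -> list[str]:
    """Check a viewer export against the checked-in schema."""
    return minischema.validate(doc, _load_schema("viewer.schema.json"))
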