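"""Relative placement of pathway layouts and inter-pathway connections.

Placement groups pathways into category bands ordered left-to-right
(biosynthesis, energy, other, degradation) so that biosynthetic pathways end
up to the left and degradative pathways to the right whenever both are
present.  Within a band, layouts are shelf-packed (rows filled left to
right) in descending height order.  Shared metabolites deliberately do NOT
influence placement.

Connections link node occurrences of the same compound: a star from one
chosen node, or — for the all-compounds operation — a Euclidean minimum
spanning tree per compound, which bounds clutter at k - 1 edges.
"""

from __future__ import annotations

import copy
import math

from .errors import (
    ConflictError,
    EntityNotFoundError,
    SizingError,
)
from .model import (
    ARROW_NONE,
    CATEGORIES,
    CollageGraph,
    EdgeGlyph,
    Pathway,
    PathwayCollection,
    PathwayLayout,
    PlacedLayout,
    StyleConfig,
)

#: keyword table mapping the root ontology label to a placement category
_CATEGORY_KEYWORDS = (
    ("Biosynthesis", "biosynthesis"),
    ("Degradation", "degradation"),
    ("Generation of Precursor Metabolites and Energy", "energy"),
    ("Energy", "energy"),
)


def category_of(pathway: Pathway) -> str:
    """Placement category from the most general ontology label."""
    if not pathway.class_path:
        return "other"
    root = pathway.class_path[0]
    for keyword, category in _CATEGORY_KEYWORDS:
        if keyword in root:
            return category
    return "other"


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _shelf_pack(
    layouts: list[PathwayLayout], budget: float, gap: float
) -> tuple[list[tuple[float, float]], float, float]:
    """Pack layouts into rows of width <= budget.

    Input order is preserved.  Returns (local offsets, block width, block
    height); offsets are top-left corners relative to the block origin.
    """
    offsets: list[tuple[float, float]] = []
    x = 0.0
    y = 0.0
    row_h = 0.0
    width = 0.0
    for lay in layouts:
        w, h = lay.width, lay.height
        if x > 0.0 and x + w > budget:
            y += row_h + gap
            x = 0.0
            row_h = 0.0
        offsets.append((x, y))
        x += w + gap
        row_h = max(row_h, h)
        width = max(width, x - gap)
    return offsets, width, y + row_h


def assemble_collage(
    layouts: list[PathwayLayout],
    pathways: list[Pathway],
    max_width: float = 1200.0,
    gap: float = 20.0,
    style: StyleConfig | None = None,
) -> CollageGraph:
    """Place layouts into a collage within ``max_width``.

    Category bands run left to right in the fixed order biosynthesis,
    energy, other, degradation; each band is shelf-packed internally with
    layouts sorted by descending height (ties by pathway id).  Bounding
    boxes end up pairwise disjoint with at least ``gap`` separation.
    Deterministic.
    """
    if not layouts:
        raise ValueError("need at least one layout")
    if len(layouts) != len(pathways):
        raise ValueError("layouts and pathways must match one-to-one")
    widest = max(lay.width for lay in layouts)
    if max_width < widest + 2 * gap:
        raise SizingError(
            f"max_width {max_width} cannot fit widest layout ({widest}) "
            f"plus margins"
        )

    by_cat: dict[str, list[PathwayLayout]] = {}
    for lay, pw in zip(layouts, pathways):
        if lay.pathway_id != pw.id:
            raise ValueError(
                f"layout {lay.pathway_id} does not match pathway {pw.id}"
            )
        by_cat.setdefault(category_of(pw), []).append(lay)

    blocks = [c for c in CATEGORIES if c in by_cat]
    for cat in blocks:
        by_cat[cat].sort(key=lambda l: (-l.height, l.pathway_id))

    # band width budgets: each band needs at least its widest member; spare
    # width is shared equally
    base = {c: max(l.width for l in by_cat[c]) for c in blocks}
    avail = max_width - gap * (len(blocks) + 1)
    spare = avail - sum(base.values())
    if spare < 0:
        raise SizingError(
            f"max_width {max_width} cannot fit {len(blocks)} category bands "
            f"side by side (need {sum(base.values()) + gap * (len(blocks) + 1)})"
        )
    budgets = {c: base[c] + spare / len(blocks) for c in blocks}

    collage = CollageGraph(style=style or StyleConfig())
    x_cursor = gap
    for cat in blocks:
        members = by_cat[cat]
        offsets, block_w, _ = _shelf_pack(members, budgets[cat], gap)
        for lay, (ox, oy) in zip(members, offsets):
            collage.layouts.append(
                PlacedLayout(layout=lay, dx=x_cursor + ox, dy=gap + oy)
            )
        x_cursor += block_w + gap
    return collage


def add_pathway_to_collage(
    collage: CollageGraph, layout: PathwayLayout, gap: float = 20.0
) -> CollageGraph:
    """Place an additional laid-out pathway below the existing collage."""
    out = copy.deepcopy(collage)
    if any(p.layout.pathway_id == layout.pathway_id for p in out.layouts):
        raise ConflictError(
            f"pathway {layout.pathway_id} already present in collage"
        )
    if not out.layouts:
        dx, dy = gap, gap
    else:
        x0, _, _, y1 = out.bbox()
        dx = x0 - layout.bbox[0]
        dy = y1 + gap - layout.bbox[1]
    out.layouts.append(PlacedLayout(layout=copy.deepcopy(layout), dx=dx, dy=dy))
    return out


# ---------------------------------------------------------------------------
# connections
# ---------------------------------------------------------------------------

def _metabolite_nodes(collage: CollageGraph) -> list:
    return [
        (g, placed)
        for g, placed in collage.iter_glyphs()
        if g.kind == "metabolite-node"
    ]


def _connection_exists(collage: CollageGraph, a: str, b: str) -> bool:
    for e in collage.connections:
        if {e.source_uid, e.target_uid} == {a, b}:
            return True
    return False


def _add_connection(collage: CollageGraph, a: str, b: str, ref_id: str) -> None:
    collage.connections.append(
        EdgeGlyph(
            uid=f"conn:{a}--{b}",
            kind="connection-edge",
            source_uid=a,
            target_uid=b,
            ref_id=ref_id,
            color=collage.style.color_for_kind("connection-edge"),
            thickness=collage.style.edge_thickness,
            arrow=ARROW_NONE,
        )
    )


def connect_metabolite(collage: CollageGraph, node_uid: str) -> CollageGraph:
    """Connect one metabolite node to every other occurrence of its
    compound (a star).  Idempotent."""
    out = copy.deepcopy(collage)
    try:
        g, _ = out.find_glyph(node_uid)
    except KeyError:
        raise EntityNotFoundError(f"unknown glyph uid: {node_uid}")
    if g.kind != "metabolite-node":
        raise EntityNotFoundError(
            f"glyph {node_uid} is a {g.kind}, not a metabolite node"
        )
    for other, _ in _metabolite_nodes(out):
        if other.uid == node_uid or other.ref_id != g.ref_id:
            continue
        if not _connection_exists(out, node_uid, other.uid):
            _add_connection(out, node_uid, other.uid, g.ref_id)
    return out


def euclidean_mst(points: list[tuple[str, float, float]]) -> list[tuple[str, str]]:
    """Prim's algorithm over a complete Euclidean graph.

    Deterministic: ties broken by uid pair.  Returns k - 1 undirected edges.
    """
    if len(points) < 2:
        return []
    points = sorted(points, key=lambda p: p[0])
    in_tree = {points[0][0]}
    coords = {uid: (x, y) for uid, x, y in points}
    edges: list[tuple[str, str]] = []
    while len(in_tree) < len(points):
        best = None
        for a in sorted(in_tree):
            ax, ay = coords[a]
            for b, (bx, by) in coords.items():
                if b in in_tree:
                    continue
                d = math.hypot(ax - bx, ay - by)
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        assert best is not None
        _, a, b = best
        in_tree.add(b)
        edges.append((a, b))
    return edges


def connect_all(
    collage: CollageGraph, exclude: set[str] | frozenset[str] = frozenset()
) -> CollageGraph:
    """For each compound with >= 2 node occurrences, add the Euclidean
    minimum-spanning-tree connection edges over those occurrences.

    ``exclude`` lists compound ids (e.g. currency metabolites) to skip.
    """
    out = copy.deepcopy(collage)
    by_compound: dict[str, list[tuple[str, float, float]]] = {}
    for g, placed in _metabolite_nodes(out):
        cx, cy = g.center
        by_compound.setdefault(g.ref_id, []).append(
            (g.uid, cx + placed.dx, cy + placed.dy)
        )
    for cid in sorted(by_compound):
        if cid in exclude:
            continue
        pts = by_compound[cid]
        if len(pts) < 2:
            continue
        for a, b in euclidean_mst(pts):
            if not _connection_exists(out, a, b):
                _add_connection(out, a, b, cid)
    return out


# ---------------------------------------------------------------------------
# queries
# ---------------------------------------------------------------------------

def pathways_for_metabolite(
    compound_id: str, collection: PathwayCollection
) -> list[str]:
    """Sorted ids of every pathway with a reaction in which the compound
    participates, in any role on either side."""
    if compound_id not in collection.compound_ids():
        raise EntityNotFoundError(f"unknown compound id: {compound_id}")
    hits = {
        pw.id
        for pw in collection.pathways
        for r in pw.reactions
        for p in r.participants
        if p.compound_id == compound_id
    }
    return sorted(hits)
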