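"""Scripted equivalents of interactive collage refinements.

Every operation takes a collage, deep-copies it, applies one change and
returns the copy — callers can diff states.  Untouched glyphs are preserved
bit-identically.
"""

from __future__ import annotations

import copy
from dataclasses import fields

from .errors import EntityNotFoundError, MergeError
from .model import CollageGraph, Glyph, MergeRecord, PlacedLayout


def _descendants(layout_glyphs: list[Glyph], uid: str) -> list[Glyph]:
    """Glyphs attached (transitively) to *uid* via parent links."""
    out: list[Glyph] = []
    frontier = {uid}
    while frontier:
        nxt = set()
        for g in layout_glyphs:
            if g.parent_uid in frontier and g.uid not in {d.uid for d in out}:
                out.append(g)
                nxt.add(g.uid)
        frontier = nxt
    return out


def move_node(collage: CollageGraph, uid: str, dx: float, dy: float) -> CollageGraph:
    """Translate one glyph (and any attached omics grid) by (dx, dy)."""
    out = copy.deepcopy(collage)
    try:
        g, placed = out.find_glyph(uid)
    except KeyError:
        raise EntityNotFoundError(f"unknown glyph uid: {uid}")
    for t in [g] + _descendants(placed.layout.glyphs, uid):
        t.x += dx
        t.y += dy
    return out


def move_pathway(
    collage: CollageGraph, pathway_id: str, dx: float, dy: float
) -> CollageGraph:
    """Translate an entire pathway; connection-edge endpoints follow because
    edge geometry is resolved from glyph positions plus the layout offset."""
    out = copy.deepcopy(collage)
    try:
        placed = out.placed_for(pathway_id)
    except KeyError:
        raise EntityNotFoundError(f"unknown pathway id: {pathway_id}")
    placed.dx += dx
    placed.dy += dy
    return out


def delete_element(collage: CollageGraph, target: str) -> CollageGraph:
    """Delete a glyph, an edge, or a whole pathway by id.

    Deleting a node removes its incident edges and attached grids; deleting
    a pathway removes all of its glyphs, edges, and any connection edges
    touching them.
    """
    out = copy.deepcopy(collage)

    def _prune_incident(gone: set[str]) -> None:
        # merges can leave edges pointing across layouts, so prune everywhere
        for placed in out.layouts:
            placed.layout.edges = [
                e
                for e in placed.layout.edges
                if e.source_uid not in gone and e.target_uid not in gone
            ]
        out.connections = [
            e
            for e in out.connections
            if e.source_uid not in gone and e.target_uid not in gone
        ]

    for i, placed in enumerate(out.layouts):
        if placed.layout.pathway_id == target:
            gone = {g.uid for g in placed.layout.glyphs}
            del out.layouts[i]
            _prune_incident(gone)
            return out

    for placed in out.layouts:
        lay = placed.layout
        for g in lay.glyphs:
            if g.uid == target:
                gone = {target} | {
                    d.uid for d in _descendants(lay.glyphs, target)
                }
                lay.glyphs = [x for x in lay.glyphs if x.uid not in gone]
                lay.backbone = [u for u in lay.backbone if u not in gone]
                _prune_incident(gone)
                return out
        for e in lay.edges:
            if e.uid == target:
                lay.edges = [x for x in lay.edges if x.uid != target]
                return out

    for e in out.connections:
        if e.uid == target:
            out.connections = [x for x in out.connections if x.uid != target]
            return out

    raise EntityNotFoundError(f"unknown element or pathway id: {target}")


def merge_nodes(collage: CollageGraph, uids: list[str]) -> CollageGraph:
    """Merge metabolite nodes of the same compound.

    The first uid survives at its position; edges incident to absorbed
    nodes are re-targeted to it, duplicate parallel edges are collapsed,
    self-loop connection edges are dropped, and the merge is recorded.
    """
    if len(uids) < 2:
        raise MergeError("merge needs at least 2 node uids")
    if len(set(uids)) != len(uids):
        raise MergeError("merge uids must be distinct")
    index = collage.glyph_index()
    ref_ids = set()
    for uid in uids:
        if uid not in index:
            raise EntityNotFoundError(f"unknown glyph uid: {uid}")
        g = index[uid][0]
        if g.kind != "metabolite-node":
            raise MergeError(f"glyph {uid} is a {g.kind}, not a metabolite node")
        ref_ids.add(g.ref_id)
    if len(ref_ids) != 1:
        raise MergeError(
            f"cannot merge nodes of different compounds: {sorted(ref_ids)}"
        )

    out = copy.deepcopy(collage)
    survivor = uids[0]
    absorbed = set(uids[1:])
    remap = {uid: survivor for uid in absorbed}

    for placed in out.layouts:
        lay = placed.layout
        # attached grids of absorbed nodes go away with them
        grid_gone = set()
        for uid in absorbed:
            if any(g.uid == uid for g in lay.glyphs):
                grid_gone |= {d.uid for d in _descendants(lay.glyphs, uid)}
        lay.glyphs = [
            g
            for g in lay.glyphs
            if g.uid not in absorbed and g.uid not in grid_gone
        ]
        lay.backbone = [u for u in lay.backbone if u not in absorbed]
        for e in lay.edges:
            e.source_uid = remap.get(e.source_uid, e.source_uid)
            e.target_uid = remap.get(e.target_uid, e.target_uid)
        lay.edges = _dedupe_edges(lay.edges, directed=True)

    for e in out.connections:
        e.source_uid = remap.get(e.source_uid, e.source_uid)
        e.target_uid = remap.get(e.target_uid, e.target_uid)
    out.connections = [
        e for e in out.connections if e.source_uid != e.target_uid
    ]
    out.connections = _dedupe_edges(out.connections, directed=False)

    out.merges.append(MergeRecord(survivor=survivor, absorbed=sorted(absorbed)))
    return out


def _dedupe_edges(edges: list, directed: bool) -> list:
    seen = set()
    kept = []
    for e in edges:
        if directed:
            key = (e.kind, e.source_uid, e.target_uid)
        else:
            key = (e.kind, frozenset((e.source_uid, e.target_uid)))
        if key in seen:
            continue
        seen.add(key)
        kept.append(e)
    return kept


def highlight(collage: CollageGraph, uid: str, color: str) -> CollageGraph:
    """Set the display color of one glyph or edge."""
    out = copy.deepcopy(collage)
    for g, _ in out.iter_glyphs():
        if g.uid == uid:
            g.color = color
            return out
    for e in out.iter_edges():
        if e.uid == uid:
            e.color = color
            return out
    raise EntityNotFoundError(f"unknown element uid: {uid}")


def relabel(collage: CollageGraph, uid: str, text: str) -> CollageGraph:
    """Replace a glyph's label text verbatim."""
    out = copy.deepcopy(collage)
    for g, _ in out.iter_glyphs():
        if g.uid == uid:
            g.label_text = text
            return out
    raise EntityNotFoundError(f"unknown glyph uid: {uid}")


_TOGGLE_KINDS = {
    "show_pathway_boxes": ("pathway-box",),
    "show_pathway_labels": ("pathway-label",),
    "show_enzyme_labels": ("enzyme-label",),
    "show_gene_labels": ("gene-label",),
    "show_omics": ("omics-grid", "omics-box"),
}


def set_style(collage: CollageGraph, updates: dict) -> CollageGraph:
    """Apply style-field updates and synchronize glyph visibility flags."""
    valid = {f.name for f in fields(collage.style)}
    for key in updates:
        if key not in valid:
            raise EntityNotFoundError(f"unknown style field: {key}")
    out = copy.deepcopy(collage)
    for key, value in updates.items():
        setattr(out.style, key, value)
    sync_visibility(out)
    return out


def sync_visibility(collage: CollageGraph) -> None:
    """Make glyph ``visible`` flags agree with the style toggles.

    Enzyme labels replaced by a gene-expression omics grid stay hidden
    while the grid is shown; turning omics display off restores them.
    """
    style = collage.style
    hidden_by_grid = {
        g.parent_uid
        for g, _ in collage.iter_glyphs()
        if g.kind == "omics-grid" and g.hides_parent and style.show_omics
    }
    for g, _ in collage.iter_glyphs():
        for flag, kinds in _TOGGLE_KINDS.items():
            if g.kind in kinds:
                g.visible = bool(getattr(style, flag))
        if g.kind == "enzyme-label" and g.uid in hidden_by_grid:
            g.visible = False
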