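"""Painting omics data onto a collage.

Single-value datasets color the matched elements directly; multi-column
(time-series / condition-series) datasets become one single-row grid of
colored boxes per matched entity: below metabolite nodes, in place of enzyme
labels (which are hidden), or beside reaction-edge midpoints for flux data.

Matching is by exact, case-sensitive id.  Layout positions are never
recomputed to accommodate omics data; constricted grids are fixed by moving
them like any other node.
"""

from __future__ import annotations

import copy
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional

from .edit import sync_visibility
from .errors import OverlayModeError
from .model import (
    CollageGraph,
    ColorScheme,
    Glyph,
    OmicsDataset,
)

#: geometry of overlay grid boxes, in layout units
BOX_W = 8.0
BOX_H = 8.0
GRID_GAP = 2.0


def color_for(value: Optional[float], scheme: ColorScheme) -> str:
    """Bin a value into the scheme's half-open bins.

    ``None`` (missing) maps to the missing color; values below the first
    breakpoint to ``colors[0]``; a value in ``[b[i], b[i+1])`` to
    ``colors[i+1]``; values at or above the last breakpoint to the last
    color.  A value exactly equal to a breakpoint falls in the bin whose
    lower bound it is.
    """
    if value is None or value != value:  # NaN counts as missing
        return scheme.missing_color
    return scheme.colors[bisect_right(scheme.breakpoints, value)]


@dataclass
class MatchResult:
    """Outcome of matching dataset entities against collage elements."""

    #: entity id -> uids of matched glyphs and/or edges
    targets: dict[str, list[str]] = field(default_factory=dict)
    matched_ids: list[str] = field(default_factory=list)
    unmatched_ids: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "matched": len(self.matched_ids),
            "unmatched": len(self.unmatched_ids),
            "unmatched_ids": list(self.unmatched_ids),
        }


def match_entities(collage: CollageGraph, dataset: OmicsDataset) -> MatchResult:
    """Resolve dataset rows to collage elements.

    gene rows match reactions listing that gene (targets: the enzyme-label
    glyph and the reaction's edges); metabolite rows match every
    metabolite-node occurrence; flux rows match reaction edges.
    """
    res = MatchResult()
    if dataset.data_type == "metabolite":
        nodes: dict[str, list[str]] = {}
        for g, _ in collage.iter_glyphs():
            if g.kind == "metabolite-node":
                nodes.setdefault(g.ref_id, []).append(g.uid)
        for entity in dataset.rows:
            uids = nodes.get(entity, [])
            _record(res, entity, uids)
    elif dataset.data_type == "flux":
        edges: dict[str, list[str]] = {}
        for placed in collage.layouts:
            for e in placed.layout.edges:
                if e.kind == "reaction-edge":
                    edges.setdefault(e.ref_id, []).append(e.uid)
        for entity in dataset.rows:
            _record(res, entity, edges.get(entity, []))
    else:  # gene
        gene_to_reactions: dict[str, list[str]] = {}
        for placed in collage.layouts:
            for rid, gids in placed.layout.genes.items():
                for gid in gids:
                    gene_to_reactions.setdefault(gid, []).append(rid)
        labels: dict[str, list[str]] = {}
        edges = {}
        for g, _ in collage.iter_glyphs():
            if g.kind == "enzyme-label":
                labels.setdefault(g.ref_id, []).append(g.uid)
        for placed in collage.layouts:
            for e in placed.layout.edges:
                if e.kind == "reaction-edge":
                    edges.setdefault(e.ref_id, []).append(e.uid)
        for entity in dataset.rows:
            uids: list[str] = []
            for rid in gene_to_reactions.get(entity, []):
                uids.extend(labels.get(rid, []))
                uids.extend(edges.get(rid, []))
            _record(res, entity, uids)
    return res


def _record(res: MatchResult, entity: str, uids: list[str]) -> None:
    if uids:
        res.targets[entity] = list(uids)
        res.matched_ids.append(entity)
    else:
        res.unmatched_ids.append(entity)


# ---------------------------------------------------------------------------
# clearing and applying overlays
# ---------------------------------------------------------------------------

def clear_overlay(collage: CollageGraph) -> CollageGraph:
    """Remove grids, restore painted colors and hidden labels."""
    out = copy.deepcopy(collage)
    painted = set(out.painted_uids)
    for placed in out.layouts:
        lay = placed.layout
        lay.glyphs = [
            g for g in lay.glyphs if g.kind not in ("omics-grid", "omics-box")
        ]
        for g in lay.glyphs:
            if g.uid in painted:
                g.color = out.style.color_for_kind(g.kind)
        for e in lay.edges:
            if e.uid in painted:
                e.color = out.style.color_for_kind(e.kind)
    for e in out.connections:
        if e.uid in painted:
            e.color = out.style.color_for_kind(e.kind)
    out.painted_uids = []
    out.omics = None
    sync_visibility(out)
    return out


def apply_single_overlay(
    collage: CollageGraph, dataset: OmicsDataset, scheme: ColorScheme
) -> CollageGraph:
    """Color matched elements by their single data value."""
    if len(dataset.columns) != 1:
        raise OverlayModeError(
            f"dataset has {len(dataset.columns)} columns; single-value "
            "overlay needs exactly 1 (use the time-series overlay)"
        )
    out = clear_overlay(collage)
    match = match_entities(out, dataset)
    glyph_by_uid = {g.uid: g for g, _ in out.iter_glyphs()}
    edge_by_uid = {e.uid: e for e in out.iter_edges()}
    painted: set[str] = set()
    # when several entities match one element (e.g. two genes on one
    # reaction) the first dataset row in order wins
    for entity, uids in match.targets.items():
        color = color_for(dataset.rows[entity][0], scheme)
        for uid in uids:
            if uid in painted:
                continue
            if uid in glyph_by_uid:
                glyph_by_uid[uid].color = color
            elif uid in edge_by_uid:
                edge_by_uid[uid].color = color
            painted.add(uid)
    out.painted_uids = sorted(painted)
    out.omics = (copy.deepcopy(dataset), copy.deepcopy(scheme))
    return out


def apply_timeseries_overlay(
    collage: CollageGraph, dataset: OmicsDataset, scheme: ColorScheme
) -> CollageGraph:
    """Attach one single-row grid of colored boxes per matched entity."""
    if len(dataset.columns) < 2:
        raise OverlayModeError(
            "dataset has 1 column; time-series overlay needs >= 2 "
            "(use the single-value overlay)"
        )
    out = clear_overlay(collage)
    match = match_entities(out, dataset)

    for placed in out.layouts:
        lay = placed.layout
        glyph_by_uid = {g.uid: g for g in lay.glyphs}
        edge_by_uid = {e.uid: e for e in lay.edges}
        anchored: set[str] = set()
        new_glyphs: list[Glyph] = []
        for entity in match.matched_ids:
            vec = dataset.rows[entity]
            for uid in match.targets[entity]:
                anchor = None  # (x, y, parent_uid, hides_parent)
                if uid in glyph_by_uid:
                    g = glyph_by_uid[uid]
                    if dataset.data_type == "metabolite" and g.kind == "metabolite-node":
                        anchor = (g.x, g.y + g.height + GRID_GAP, g.uid, False)
                    elif dataset.data_type == "gene" and g.kind == "enzyme-label":
                        anchor = (g.x, g.y, g.uid, True)
                elif uid in edge_by_uid and dataset.data_type == "flux":
                    e = edge_by_uid[uid]
                    try:
                        src = lay.glyph(e.source_uid)
                        dst = lay.glyph(e.target_uid)
                    except KeyError:
                        continue  # endpoint lives in another layout (merged)
                    mx = (src.center[0] + dst.center[0]) / 2
                    my = (src.center[1] + dst.center[1]) / 2
                    anchor = (
                        mx - len(dataset.columns) * BOX_W - 6.0,
                        my - BOX_H / 2,
                        e.uid,
                        False,
                    )
                if anchor is None or uid in anchored:
                    continue
                anchored.add(uid)
                new_glyphs.extend(
                    _make_grid(out, uid, anchor, vec, dataset, scheme)
                )
        lay.glyphs.extend(new_glyphs)

    out.omics = (copy.deepcopy(dataset), copy.deepcopy(scheme))
    sync_visibility(out)
    return out


def _make_grid(
    collage: CollageGraph,
    anchor_uid: str,
    anchor: tuple[float, float, str, bool],
    vec: list[Optional[float]],
    dataset: OmicsDataset,
    scheme: ColorScheme,
) -> list[Glyph]:
    x, y, parent, hides = anchor
    n = len(vec)
    grid_uid = f"omics:{anchor_uid}"
    grid = Glyph(
        uid=grid_uid,
        kind="omics-grid",
        ref_id=anchor_uid,
        x=x,
        y=y,
        width=n * BOX_W,
        height=BOX_H,
        color=collage.style.color_for_kind("omics-grid"),
        visible=collage.style.show_omics,
        parent_uid=parent,
        hides_parent=hides,
    )
    boxes = [
        Glyph(
            uid=f"{grid_uid}:{j}",
            kind="omics-box",
            ref_id=dataset.columns[j],
            x=x + j * BOX_W,
            y=y,
            width=BOX_W,
            height=BOX_H,
            color=color_for(vec[j], scheme),
            visible=collage.style.show_omics,
            parent_uid=grid_uid,
        )
        for j in range(n)
    ]
    return [grid] + boxes
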