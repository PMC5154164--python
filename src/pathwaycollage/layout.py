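"""Automatic layout of a single pathway.

Backbone extraction follows the pathway's reaction-link graph; geometry is
topology-specific: linear pathways become a vertical chain, cyclic pathways a
circle anchored at 12 o'clock, branched pathways a layered top-down tree with
branch arms offset into their own columns.

All geometric constants live in :class:`LayoutConfig`.  Label rectangle width
is estimated as ``len(text) * 0.6 * font_size`` so overlap checking needs no
font metrics.  Layouts are deterministic: identical input gives identical
output, and the finished layout is normalized so its bbox min corner is
``(0, 0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx

from .errors import EntityNotFoundError, StructuralError
from .model import (
    ARROW_BOTH,
    ARROW_FORWARD,
    CONTAINER_KINDS,
    DIRECTION_REVERSIBLE,
    EdgeGlyph,
    Glyph,
    Pathway,
    PathwayLayout,
    ROLE_SIDE,
    SIDE_PRODUCT,
    SIDE_SUBSTRATE,
    StyleConfig,
)

TOPOLOGY_LINEAR = "linear"
TOPOLOGY_CYCLIC = "cyclic"
TOPOLOGY_BRANCHED = "branched"


@dataclass(frozen=True)
class LayoutConfig:
    node_diameter: float = 10.0
    #: backbone node spacing = 3x node diameter
    spacing: float = 30.0
    #: horizontal distance between branch-arm columns
    column_spacing: float = 90.0
    label_gap: float = 4.0
    char_width_factor: float = 0.6
    box_padding: float = 8.0
    side_offset: float = 18.0

    def text_width(self, text: str, font_size: float) -> float:
        return max(1.0, len(text)) * self.char_width_factor * font_size


DEFAULT_CONFIG = LayoutConfig()


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def classify_topology(pathway: Pathway) -> str:
    """``cyclic`` if the link graph has a directed cycle; ``linear`` if it is
    an unbranched chain; ``branched`` otherwise."""
    g = pathway.link_graph()
    if not nx.is_directed_acyclic_graph(g):
        return TOPOLOGY_CYCLIC
    if all(g.in_degree(n) <= 1 and g.out_degree(n) <= 1 for n in g.nodes):
        return TOPOLOGY_LINEAR
    return TOPOLOGY_BRANCHED


def _between_compound(pred, succ) -> str:
    """Backbone compound between two linked reactions: a shared main
    product/substrate when one exists, else the predecessor's first main
    product."""
    shared = set(pred.mains(SIDE_PRODUCT)) & set(succ.mains(SIDE_SUBSTRATE))
    if shared:
        return min(shared)
    prods = pred.mains(SIDE_PRODUCT)
    if not prods:
        raise StructuralError(f"reaction {pred.id} has no main product")
    return prods[0]


def _chain_order(pathway: Pathway) -> list[str]:
    """Reaction ids of a linear pathway in link order."""
    g = pathway.link_graph()
    sources = sorted(n for n in g.nodes if g.in_degree(n) == 0)
    if not sources:
        raise StructuralError(f"pathway {pathway.id}: no chain start")
    order = [sources[0]]
    while True:
        succs = list(g.successors(order[-1]))
        if not succs:
            break
        order.append(succs[0])
    if len(order) != g.number_of_nodes():
        raise StructuralError(
            f"pathway {pathway.id}: link graph is not a single chain"
        )
    return order


def _cycle_order(pathway: Pathway) -> list[str]:
    g = pathway.link_graph()
    try:
        cyc = nx.find_cycle(g, orientation="original")
    except nx.NetworkXNoCycle:  # pragma: no cover - guarded by classify
        raise StructuralError(f"pathway {pathway.id}: no cycle found")
    return [e[0] for e in cyc]


def _longest_path(pathway: Pathway) -> list[str]:
    """Longest simple source-to-sink reaction path; ties broken
    lexicographically by the concatenation of reaction ids."""
    g = pathway.link_graph()
    sources = [n for n in g.nodes if g.in_degree(n) == 0]
    sinks = [n for n in g.nodes if g.out_degree(n) == 0]
    best: Optional[list[str]] = None
    for s in sorted(sources):
        for t in sorted(sinks):
            if s == t:
                paths = [[s]]
            else:
                paths = nx.all_simple_paths(g, s, t)
            for p in paths:
                if (
                    best is None
                    or len(p) > len(best)
                    or (len(p) == len(best) and "".join(p) < "".join(best))
                ):
                    best = list(p)
    if best is None:
        raise StructuralError(f"pathway {pathway.id}: no reaction path")
    return best


def _chain_compounds(pathway: Pathway, rids: list[str]) -> list[str]:
    """Main compounds along an ordered reaction chain: input of the first
    reaction, the shared compound at each link step, the output of the last.
    """
    rs = [pathway.reaction(rid) for rid in rids]
    subs = rs[0].mains(SIDE_SUBSTRATE)
    if not subs:
        raise StructuralError(f"reaction {rs[0].id} has no main substrate")
    compounds = [subs[0]]
    for pred, succ in zip(rs, rs[1:]):
        compounds.append(_between_compound(pred, succ))
    prods = rs[-1].mains(SIDE_PRODUCT)
    if not prods:
        raise StructuralError(f"reaction {rs[-1].id} has no main product")
    compounds.append(prods[0])
    return compounds


def extract_backbone(pathway: Pathway) -> list[str]:
    """Ordered main-compound occurrences along the pathway's principal axis.

    Linear: the alternating compound/reaction chain in link order.  Cyclic:
    the cycle's compounds starting at the lexicographically smallest id,
    following link direction.  Branched: compounds along the longest
    reaction path (lexicographic tie-break).
    """
    topo = classify_topology(pathway)
    if topo == TOPOLOGY_LINEAR:
        return _chain_compounds(pathway, _chain_order(pathway))
    if topo == TOPOLOGY_CYCLIC:
        rids = _cycle_order(pathway)
        rs = [pathway.reaction(rid) for rid in rids]
        n = len(rs)
        # compound i sits between reaction i-1 and reaction i (wrapping)
        compounds = [_between_compound(rs[i - 1], rs[i]) for i in range(n)]
        k = compounds.index(min(compounds))
        return compounds[k:] + compounds[:k]
    return _chain_compounds(pathway, _longest_path(pathway))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def rects_overlap(a: tuple, b: tuple) -> bool:
    """Strict interior intersection of two (x0, y0, x1, y1) rectangles."""
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def layout_overlaps(layout: PathwayLayout) -> list[tuple[str, str]]:
    """All-pairs overlap census over non-container glyphs (brute force)."""
    gs = [g for g in layout.glyphs if g.kind not in CONTAINER_KINDS]
    bad = []
    for i, a in enumerate(gs):
        for b in gs[i + 1:]:
            if rects_overlap(a.rect, b.rect):
                bad.append((a.uid, b.uid))
    return bad


def _resolve_overlaps(
    glyphs: list[Glyph],
    movable: dict[str, tuple[float, float]],
    step: float = 2.0,
    max_iter: int = 500,
) -> None:
    """Slide each movable glyph along its unit direction until it overlaps
    nothing.  Deterministic: glyphs are processed in sorted-uid order and the
    pass repeats to a fixpoint."""
    solid = [g for g in glyphs if g.kind not in CONTAINER_KINDS]
    order = sorted((g for g in solid if g.uid in movable), key=lambda g: g.uid)
    for _ in range(max_iter):
        moved = False
        for g in order:
            ux, uy = movable[g.uid]
            guard = 0
            while any(
                o is not g and rects_overlap(g.rect, o.rect) for o in solid
            ):
                g.x += ux * step
                g.y += uy * step
                moved = True
                guard += 1
                if guard > 10_000:  # pragma: no cover - safety valve
                    raise StructuralError("overlap resolution did not converge")
        if not moved:
            return


# ---------------------------------------------------------------------------
# the main layout operation
# ---------------------------------------------------------------------------

def layout_pathway(
    pathway: Pathway,
    style: Optional[StyleConfig] = None,
    config: LayoutConfig = DEFAULT_CONFIG,
) -> PathwayLayout:
    """Produce a :class:`PathwayLayout` with topology-appropriate geometry.

    One metabolite-node glyph per main-compound occurrence, one reaction edge
    per reaction (plus joiner edges at branch merge points), enzyme and gene
    labels beside each edge, a pathway label and background box.  No two
    non-container glyph rectangles overlap.
    """
    style = style or StyleConfig()
    topo = classify_topology(pathway)
    builder = _Builder(pathway, style, config)
    if topo == TOPOLOGY_LINEAR:
        builder.build_chain(_chain_order(pathway))
    elif topo == TOPOLOGY_CYCLIC:
        builder.build_cycle()
    else:
        builder.build_tree()
    return builder.finish()


class _Builder:
    def __init__(self, pathway: Pathway, style: StyleConfig, config: LayoutConfig):
        self.pw = pathway
        self.style = style
        self.cfg = config
        self.glyphs: list[Glyph] = []
        self.edges: list[EdgeGlyph] = []
        self.backbone: list[str] = []
        self.slide_dirs: dict[str, tuple[float, float]] = {}
        self._node_n = 0
        self._edge_n = 0

    # -- glyph factories --------------------------------------------------

    def node(self, compound_id: str, cx: float, cy: float, backbone: bool) -> Glyph:
        d = self.cfg.node_diameter
        uid = f"{self.pw.id}:n{self._node_n}"
        self._node_n += 1
        g = Glyph(
            uid=uid,
            kind="metabolite-node",
            ref_id=compound_id,
            x=cx - d / 2,
            y=cy - d / 2,
            width=d,
            height=d,
            color=self.style.color_for_kind("metabolite-node"),
            label_text=compound_id,
        )
        self.glyphs.append(g)
        if backbone:
            self.backbone.append(uid)
        return g

    def edge(self, src: Glyph, dst: Glyph, reaction) -> EdgeGlyph:
        uid = f"{self.pw.id}:edge{self._edge_n}"
        self._edge_n += 1
        e = EdgeGlyph(
            uid=uid,
            kind="reaction-edge",
            source_uid=src.uid,
            target_uid=dst.uid,
            ref_id=reaction.id,
            color=self.style.color_for_kind("reaction-edge"),
            thickness=self.style.edge_thickness,
            arrow=ARROW_BOTH
            if reaction.direction == DIRECTION_REVERSIBLE
            else ARROW_FORWARD,
        )
        self.edges.append(e)
        return e

    def labels(
        self,
        reaction,
        mid: tuple[float, float],
        direction: tuple[float, float] = (1.0, 0.0),
    ) -> None:
        """Enzyme label and gene label stacked beside an edge midpoint,
        extending along ``direction`` (unit vector away from the diagram)."""
        cfg = self.cfg
        fs_e = self.style.font_sizes["enzyme-label"]
        fs_g = self.style.font_sizes["gene-label"]
        texts = []
        enz = " / ".join(reaction.enzyme_labels) or reaction.id
        texts.append(("enzyme-label", enz, fs_e))
        if reaction.gene_ids:
            texts.append(("gene-label", " / ".join(reaction.gene_ids), fs_g))
        anchor_x = mid[0] + direction[0] * (cfg.node_diameter / 2 + cfg.label_gap)
        anchor_y = mid[1] + direction[1] * (cfg.node_diameter / 2 + cfg.label_gap)
        total_h = sum(fs for _, _, fs in texts) + 2.0 * (len(texts) - 1)
        y = anchor_y - total_h / 2
        for kind, text, fs in texts:
            w = cfg.text_width(text, fs)
            x = anchor_x if direction[0] >= 0 else anchor_x - w
            uid = f"{self.pw.id}:{'e' if kind == 'enzyme-label' else 'g'}{self._edge_n - 1}"
            g = Glyph(
                uid=uid,
                kind=kind,
                ref_id=reaction.id,
                x=x,
                y=y,
                width=w,
                height=fs,
                color=self.style.color_for_kind(kind),
                label_text=text,
                visible=(
                    self.style.show_enzyme_labels
                    if kind == "enzyme-label"
                    else self.style.show_gene_labels
                ),
            )
            self.glyphs.append(g)
            self.slide_dirs[uid] = direction
            y += fs + 2.0

    # -- topology builders ------------------------------------------------

    def build_chain(self, rids: list[str]) -> None:
        compounds = _chain_compounds(self.pw, rids)
        sp = self.cfg.spacing
        nodes = [
            self.node(cid, 0.0, i * sp, backbone=True)
            for i, cid in enumerate(compounds)
        ]
        for i, rid in enumerate(rids):
            r = self.pw.reaction(rid)
            self.edge(nodes[i], nodes[i + 1], r)
            mid = (0.0, (i + 0.5) * sp)
            self.labels(r, mid, (1.0, 0.0))

    def build_cycle(self) -> None:
        rids = _cycle_order(self.pw)
        rs = [self.pw.reaction(rid) for rid in rids]
        n = len(rs)
        compounds = [_between_compound(rs[i - 1], rs[i]) for i in range(n)]
        k = compounds.index(min(compounds))
        compounds = compounds[k:] + compounds[:k]
        rs = rs[k:] + rs[:k]
        radius = self.cfg.spacing * n / (2 * math.pi)
        # first backbone node at 12 o'clock, order clockwise (screen coords)
        nodes = []
        for i, cid in enumerate(compounds):
            theta = -math.pi / 2 + 2 * math.pi * i / n
            cx = radius * math.cos(theta)
            cy = radius * math.sin(theta)
            nodes.append(self.node(cid, cx, cy, backbone=True))
        for i in range(n):
            src = nodes[i]
            dst = nodes[(i + 1) % n]
            # compounds[i] is consumed by rs[i] and produced compound sits at
            # node i+1, so the edge i -> i+1 carries reaction rs[i]
            r = rs[i]
            self.edge(src, dst, r)
            mx = (src.center[0] + dst.center[0]) / 2
            my = (src.center[1] + dst.center[1]) / 2
            norm = math.hypot(mx, my)
            if norm < 1e-9:
                direction = (1.0, 0.0)
            else:
                direction = (mx / norm, my / norm)
            # push the label anchor out to the circle's edge first
            anchor = (
                direction[0] * max(norm, radius),
                direction[1] * max(norm, radius),
            )
            self.labels(r, anchor, direction)

    def build_tree(self) -> None:
        path = _longest_path(self.pw)
        g = self.pw.link_graph()
        sp = self.cfg.spacing
        csp = self.cfg.column_spacing

        placed: dict[str, tuple[Glyph, Glyph]] = {}  # rid -> (in node, out node)
        cells: set[tuple[int, int]] = set()
        next_col = [1]

        def new_col() -> int:
            c = next_col[0]
            next_col[0] += 1
            return c

        def place_reaction(rid: str, in_node: Glyph, col: int, out_row: int) -> None:
            r = self.pw.reaction(rid)
            while (col, out_row) in cells:
                col = new_col()
            prods = r.mains(SIDE_PRODUCT)
            if not prods:
                raise StructuralError(f"reaction {rid} has no main product")
            out_node = self.node(
                prods[0], col * csp, out_row * sp, backbone=rid in path_set
            )
            cells.add((col, out_row))
            placed[rid] = (in_node, out_node)
            self.edge(in_node, out_node, r)
            mx = (in_node.center[0] + out_node.center[0]) / 2
            my = (in_node.center[1] + out_node.center[1]) / 2
            self.labels(r, (mx, my), (1.0, 0.0))

        path_set = set(path)
        # the spine: column 0, rows down the page
        first = self.pw.reaction(path[0])
        subs = first.mains(SIDE_SUBSTRATE)
        if not subs:
            raise StructuralError(f"reaction {first.id} has no main substrate")
        head = self.node(subs[0], 0.0, 0.0, backbone=True)
        cells.add((0, 0))
        in_node = head
        for i, rid in enumerate(path):
            place_reaction(rid, in_node, 0, i + 1)
            in_node = placed[rid][1]

        # remaining reactions: BFS out from the spine over the undirected
        # link graph, deterministic order
        remaining = sorted(set(g.nodes) - path_set)
        und = g.to_undirected()
        frontier = list(path)
        visited = set(path)
        order: list[str] = []
        while frontier:
            nxt: list[str] = []
            for rid in frontier:
                for nb in sorted(und.neighbors(rid)):
                    if nb not in visited:
                        visited.add(nb)
                        order.append(nb)
                        nxt.append(nb)
            frontier = nxt
        # weak connectivity guarantees everything is reached
        for rid in sorted(set(remaining) - set(order)):
            order.append(rid)  # isolated reactions (no links)

        for rid in order:
            r = self.pw.reaction(rid)
            preds = sorted(p for p in g.predecessors(rid) if p in placed)
            if preds:
                in_node = placed[preds[0]][1]
                in_row = round(in_node.center[1] / sp)
                # branch arm: new column whenever the straight-down cell
                # is taken, handled inside place_reaction
                col = round(in_node.center[0] / csp)
                place_reaction(rid, in_node, col, in_row + 1)
                # joiner edges from any additional placed predecessors
                for extra in preds[1:]:
                    self.edge(placed[extra][1], placed[rid][1], r)
            else:
                succs = sorted(s for s in g.successors(rid) if s in placed)
                if succs:
                    target_in = placed[succs[0]][0]
                    row = round(target_in.center[1] / sp) - 1
                    col = new_col()
                    subs = r.mains(SIDE_SUBSTRATE)
                    if not subs:
                        raise StructuralError(
                            f"reaction {rid} has no main substrate"
                        )
                    src = self.node(subs[0], col * csp, row * sp, backbone=False)
                    cells.add((col, row))
                    placed[rid] = (src, target_in)
                    self.edge(src, target_in, r)
                    mx = (src.center[0] + target_in.center[0]) / 2
                    my = (src.center[1] + target_in.center[1]) / 2
                    self.labels(r, (mx, my), (1.0, 0.0))
                else:
                    # disconnected single reaction (n == 1 pathways)
                    col = new_col() if placed else 0
                    subs = r.mains(SIDE_SUBSTRATE)
                    src = self.node(subs[0], col * csp, 0.0, backbone=not placed)
                    cells.add((col, 0))
                    place_reaction(rid, src, col, 1)

    # -- finishing --------------------------------------------------------

    def finish(self) -> PathwayLayout:
        cfg = self.cfg
        _resolve_overlaps(self.glyphs, self.slide_dirs)

        xs0 = [g.rect[0] for g in self.glyphs]
        ys0 = [g.rect[1] for g in self.glyphs]
        xs1 = [g.rect[2] for g in self.glyphs]
        ys1 = [g.rect[3] for g in self.glyphs]
        min_x, min_y, max_x, max_y = min(xs0), min(ys0), max(xs1), max(ys1)

        fs = self.style.font_sizes["pathway-label"]
        label_text = self.pw.name or self.pw.id
        label = Glyph(
            uid=f"{self.pw.id}:label",
            kind="pathway-label",
            ref_id=self.pw.id,
            x=min_x,
            y=min_y - fs - cfg.label_gap,
            width=cfg.text_width(label_text, fs),
            height=fs,
            color=self.style.color_for_kind("pathway-label"),
            label_text=label_text,
            visible=self.style.show_pathway_labels,
        )
        self.glyphs.append(label)

        min_x = min(min_x, label.rect[0])
        min_y = min(min_y, label.rect[1])
        max_x = max(max_x, label.rect[2])
        max_y = max(max_y, label.rect[3])

        pad = cfg.box_padding
        box = Glyph(
            uid=f"{self.pw.id}:box",
            kind="pathway-box",
            ref_id=self.pw.id,
            x=min_x - pad,
            y=min_y - pad,
            width=(max_x - min_x) + 2 * pad,
            height=(max_y - min_y) + 2 * pad,
            color=self.style.color_for_kind("pathway-box"),
            visible=self.style.show_pathway_boxes,
        )
        self.glyphs.insert(0, box)

        # normalize: bbox min corner to (0, 0)
        dx, dy = -box.x, -box.y
        for g in self.glyphs:
            g.x += dx
            g.y += dy
        bbox = (0.0, 0.0, box.width, box.height)
        return PathwayLayout(
            pathway_id=self.pw.id,
            glyphs=self.glyphs,
            edges=self.edges,
            bbox=bbox,
            backbone=self.backbone,
            genes={r.id: list(r.gene_ids) for r in self.pw.reactions},
        )


# ---------------------------------------------------------------------------
# side metabolites
# ---------------------------------------------------------------------------

def _side_uid(
    pathway_id: str, rid: str, compound_id: str, side: str, occ: int
) -> str:
    return f"{pathway_id}:side:{rid}:{compound_id}:{side}:{occ}"


def add_side_metabolites(
    layout: PathwayLayout,
    pathway: Pathway,
    reaction_id: Optional[str] = None,
    compound_id: Optional[str] = None,
    style: Optional[StyleConfig] = None,
    config: LayoutConfig = DEFAULT_CONFIG,
) -> PathwayLayout:
    """Return a copy of *layout* with side-metabolite node glyphs added.

    Reaction mode adds one node per side participant of that reaction;
    compound mode adds one node per reaction in which that compound has role
    side.  Deterministic uids make the operation idempotent.  Side substrates
    sit on the incoming half of the edge, side products on the outgoing half,
    offset perpendicular to it; new glyphs slide further out if they would
    overlap anything.
    """
    if (reaction_id is None) == (compound_id is None):
        raise ValueError("give exactly one of reaction_id / compound_id")
    style = style or StyleConfig()

    targets: list[tuple[str, str, str]] = []  # (rid, compound, side)
    if reaction_id is not None:
        try:
            r = pathway.reaction(reaction_id)
        except KeyError:
            raise EntityNotFoundError(f"unknown reaction id: {reaction_id}")
        for p in r.participants:
            if p.role == ROLE_SIDE:
                targets.append((r.id, p.compound_id, p.side))
    else:
        known = {
            p.compound_id for r in pathway.reactions for p in r.participants
        }
        if compound_id not in known:
            raise EntityNotFoundError(f"unknown compound id: {compound_id}")
        for r in pathway.reactions:
            for p in r.participants:
                if p.role == ROLE_SIDE and p.compound_id == compound_id:
                    targets.append((r.id, p.compound_id, p.side))

    import copy

    out = copy.deepcopy(layout)
    existing = {g.uid for g in out.glyphs}
    d = config.node_diameter * 0.8
    new_glyphs: list[Glyph] = []
    slide: dict[str, tuple[float, float]] = {}
    per_edge_count: dict[str, int] = {}
    occ_count: dict[tuple[str, str, str], int] = {}
    for rid, cid, side in targets:
        key = (rid, cid, side)
        occ = occ_count.get(key, 0)
        occ_count[key] = occ + 1
        uid = _side_uid(out.pathway_id, rid, cid, side, occ)
        if uid in existing:
            continue
        edges = [e for e in out.edges if e.ref_id == rid]
        if not edges:
            continue
        e = edges[0]
        src = out.glyph(e.source_uid)
        dst = out.glyph(e.target_uid)
        sx, sy = src.center
        tx, ty = dst.center
        t = 0.25 if side == SIDE_SUBSTRATE else 0.75
        px = sx + (tx - sx) * t
        py = sy + (ty - sy) * t
        vx, vy = tx - sx, ty - sy
        norm = math.hypot(vx, vy) or 1.0
        # perpendicular pointing left of travel (labels go right)
        ux, uy = vy / norm, -vx / norm
        k = per_edge_count.get(e.uid, 0)
        per_edge_count[e.uid] = k + 1
        off = config.side_offset * (1 + k * 0.6)
        g = Glyph(
            uid=uid,
            kind="metabolite-node",
            ref_id=cid,
            x=px + ux * off - d / 2,
            y=py + uy * off - d / 2,
            width=d,
            height=d,
            color=style.color_for_kind("metabolite-node"),
            label_text=cid,
        )
        new_glyphs.append(g)
        slide[uid] = (ux, uy)
        # side substrate flows into the reaction (toward the product end);
        # side product flows out of it
        if side == SIDE_SUBSTRATE:
            link_src, link_dst = uid, dst.uid
        else:
            link_src, link_dst = src.uid, uid
        out.edges.append(
            EdgeGlyph(
                uid=f"{uid}:link",
                kind="reaction-edge",
                source_uid=link_src,
                target_uid=link_dst,
                ref_id=rid,
                color=style.color_for_kind("reaction-edge"),
                thickness=style.edge_thickness * 0.6,
                arrow=ARROW_FORWARD,
            )
        )

    if not new_glyphs:
        return out
    out.glyphs.extend(new_glyphs)
    _resolve_overlaps(out.glyphs, slide)
    # grow bbox (and the background box glyph) if side nodes poked out
    xs0 = [g.rect[0] for g in out.glyphs]
    ys0 = [g.rect[1] for g in out.glyphs]
    xs1 = [g.rect[2] for g in out.glyphs]
    ys1 = [g.rect[3] for g in out.glyphs]
    out.bbox = (min(xs0), min(ys0), max(xs1), max(ys1))
    for g in out.glyphs:
        if g.kind == "pathway-box":
            g.x = min(g.x, out.bbox[0])
            g.y = min(g.y, out.bbox[1])
            g.width = max(g.rect[2], out.bbox[2]) - g.x
            g.height = max(g.rect[3], out.bbox[3]) - g.y
            break
    return out
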