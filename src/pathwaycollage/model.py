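"""Domain types shared by every other module, plus collection validation.

Coordinate convention: screen coordinates, origin at top-left, y increases
downward, real-valued layout units.  A glyph's ``(x, y)`` is the top-left
corner of its bounding rectangle; node circles are inscribed in that
rectangle.  Identifiers are case-sensitive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import networkx as nx

from .errors import EntityNotFoundError

# ---------------------------------------------------------------------------
# enumerations (plain strings; kept as module constants for reuse)
# ---------------------------------------------------------------------------

SIDE_SUBSTRATE = "substrate"
SIDE_PRODUCT = "product"
ROLE_MAIN = "main"
ROLE_SIDE = "side"

DIRECTION_FORWARD = "forward"
DIRECTION_REVERSIBLE = "reversible"

GLYPH_KINDS = (
    "metabolite-node",
    "enzyme-label",
    "gene-label",
    "pathway-label",
    "pathway-box",
    "omics-grid",
    "omics-box",
)
#: container kinds whose rectangle legitimately encloses other glyphs and is
#: therefore exempt from pairwise-overlap requirements
CONTAINER_KINDS = ("pathway-box", "omics-grid")

EDGE_KINDS = ("reaction-edge", "connection-edge")

ARROW_NONE = "none"
ARROW_FORWARD = "forward"
ARROW_BOTH = "both"

DATA_TYPES = ("gene", "metabolite", "flux")

CATEGORIES = ("biosynthesis", "energy", "other", "degradation")


# ---------------------------------------------------------------------------
# chemistry-side types
# ---------------------------------------------------------------------------

@dataclass
class Compound:
    id: str
    name: str = ""
    synonyms: list[str] = field(default_factory=list)


@dataclass
class ReactionParticipant:
    compound_id: str
    side: str  # substrate | product
    role: str  # main | side
    coefficient: float = 1.0


@dataclass
class Reaction:
    id: str
    participants: list[ReactionParticipant] = field(default_factory=list)
    direction: str = DIRECTION_FORWARD
    enzyme_labels: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def mains(self, side: str) -> list[str]:
        """Sorted main-compound ids on the given side."""
        return sorted(
            p.compound_id
            for p in self.participants
            if p.side == side and p.role == ROLE_MAIN
        )

    def sides(self, side: str) -> list[ReactionParticipant]:
        return [
            p for p in self.participants if p.side == side and p.role == ROLE_SIDE
        ]


@dataclass
class Pathway:
    id: str
    name: str = ""
    reactions: list[Reaction] = field(default_factory=list)
    #: ordered (predecessor reaction id, successor reaction id) pairs
    links: list[tuple[str, str]] = field(default_factory=list)
    #: ontology labels, most general first
    class_path: list[str] = field(default_factory=list)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def link_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(r.id for r in self.reactions)
        g.add_edges_from(self.links)
        return g


@dataclass
class PathwayCollection:
    """In-memory form of the native collection schema."""

    schema_version: str = "1.0"
    compounds: list[Compound] = field(default_factory=list)
    pathways: list[Pathway] = field(default_factory=list)

    def compound_ids(self) -> set[str]:
        return {c.id for c in self.compounds}

    def pathway(self, pid: str) -> Pathway:
        for p in self.pathways:
            if p.id == pid:
                return p
        raise EntityNotFoundError(f"unknown pathway id: {pid}")


# ---------------------------------------------------------------------------
# geometry-side types
# ---------------------------------------------------------------------------

@dataclass
class Glyph:
    uid: str
    kind: str
    ref_id: str
    x: float
    y: float
    width: float
    height: float
    color: str = "#000000"
    label_text: str = ""
    visible: bool = True
    #: glyph this one is attached to (omics grids/boxes); moves with it
    parent_uid: Optional[str] = None
    #: true for omics grids that occupy the space of (and hide) their parent
    hides_parent: bool = False

    @property
    def rect(self) -> tuple[float, float, float, float]:
        return (self.x, self.y, self.x + self.width, self.y + self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)


@dataclass
class EdgeGlyph:
    uid: str
    kind: str  # reaction-edge | connection-edge
    source_uid: str
    target_uid: str
    ref_id: str
    color: str = "#000000"
    thickness: float = 1.5
    arrow: str = ARROW_FORWARD


@dataclass
class PathwayLayout:
    pathway_id: str
    glyphs: list[Glyph] = field(default_factory=list)
    edges: list[EdgeGlyph] = field(default_factory=list)
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    #: metabolite-node uids along the principal axis, in order
    backbone: list[str] = field(default_factory=list)
    #: reaction id -> gene ids, retained for omics matching after layout
    genes: dict[str, list[str]] = field(default_factory=dict)

    def glyph(self, uid: str) -> Glyph:
        for g in self.glyphs:
            if g.uid == uid:
                return g
        raise KeyError(uid)

    @property
    def width(self) -> float:
        return self.bbox[2] - self.bbox[0]

    @property
    def height(self) -> float:
        return self.bbox[3] - self.bbox[1]


@dataclass
class PlacedLayout:
    layout: PathwayLayout
    dx: float = 0.0
    dy: float = 0.0

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        x0, y0, x1, y1 = self.layout.bbox
        return (x0 + self.dx, y0 + self.dy, x1 + self.dx, y1 + self.dy)


@dataclass
class MergeRecord:
    survivor: str
    absorbed: list[str]


# ---------------------------------------------------------------------------
# omics types
# ---------------------------------------------------------------------------

@dataclass
class OmicsDataset:
    data_type: str  # gene | metabolite | flux
    columns: list[str]
    #: entity id -> vector of values (None = missing), len == len(columns)
    rows: dict[str, list[Optional[float]]]

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown omics data type: {self.data_type!r}")
        if len(self.columns) < 1:
            raise ValueError("omics dataset needs at least one column")
        n = len(self.columns)
        for entity, vec in self.rows.items():
            if len(vec) != n:
                raise ValueError(
                    f"row {entity!r} has {len(vec)} values, expected {n}"
                )


@dataclass
class ColorScheme:
    """Ordered breakpoints mapping a value to one of ``n + 1`` bin colors.

    ``colors[0]`` is the below-minimum bin; ``colors[i + 1]`` covers the
    half-open interval ``[breakpoints[i], breakpoints[i + 1])``, and the last
    color covers everything at or above the final breakpoint.
    """

    breakpoints: list[float]
    colors: list[str]
    missing_color: str = "#bbbbbb"

    def __post_init__(self) -> None:
        if len(self.breakpoints) < 1:
            raise ValueError("need at least one breakpoint")
        if any(
            b2 <= b1
            for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])
        ):
            raise ValueError("breakpoints must be strictly ascending")
        if len(self.colors) != len(self.breakpoints) + 1:
            raise ValueError(
                f"need {len(self.breakpoints) + 1} colors, "
                f"got {len(self.colors)}"
            )


# ---------------------------------------------------------------------------
# styling / zoom
# ---------------------------------------------------------------------------

def _default_font_sizes() -> dict[str, float]:
    return {
        "pathway-label": 14.0,
        "metabolite-label": 10.0,
        "enzyme-label": 10.0,
        "gene-label": 10.0,
    }


def _default_colors() -> dict[str, str]:
    return {
        "metabolite-node": "#2b6cb0",
        "enzyme-label": "#7b3294",
        "gene-label": "#008837",
        "pathway-label": "#333333",
        "pathway-box": "#f5f5f0",
        "omics-grid": "#ffffff",
        "omics-box": "#cccccc",
        "reaction-edge": "#4169e1",
        "connection-edge": "#2e8b57",  # green, per the connection convention
    }


@dataclass
class StyleConfig:
    show_pathway_boxes: bool = True
    show_pathway_labels: bool = True
    show_enzyme_labels: bool = True
    show_gene_labels: bool = True
    show_omics: bool = True
    show_connections: bool = True
    font_sizes: dict[str, float] = field(default_factory=_default_font_sizes)
    colors: dict[str, str] = field(default_factory=_default_colors)
    edge_thickness: float = 1.5

    def __post_init__(self) -> None:
        for k, v in self.font_sizes.items():
            if v <= 0:
                raise ValueError(f"font size for {k!r} must be > 0")
        if self.edge_thickness <= 0:
            raise ValueError("edge thickness must be > 0")

    def color_for_kind(self, kind: str) -> str:
        return self.colors.get(kind, "#000000")


@dataclass
class ZoomPolicy:
    """Minimum zoom factor at which each label kind becomes visible."""

    thresholds: dict[str, float] = field(
        default_factory=lambda: {
            "pathway-label": 0.25,
            "metabolite-label": 0.5,
            "enzyme-label": 0.75,
            "gene-label": 0.75,
        }
    )

    def __post_init__(self) -> None:
        for k, v in self.thresholds.items():
            if v <= 0:
                raise ValueError(f"zoom threshold for {k!r} must be > 0")

    def threshold(self, kind: str) -> float:
        return self.thresholds.get(kind, 1.0)


# ---------------------------------------------------------------------------
# the collage
# ---------------------------------------------------------------------------

@dataclass
class CollageGraph:
    schema_version: str = "1.0"
    layouts: list[PlacedLayout] = field(default_factory=list)
    connections: list[EdgeGlyph] = field(default_factory=list)
    merges: list[MergeRecord] = field(default_factory=list)
    style: StyleConfig = field(default_factory=StyleConfig)
    omics: Optional[tuple[OmicsDataset, ColorScheme]] = None
    #: uids whose color was painted by the current single-value overlay
    painted_uids: list[str] = field(default_factory=list)

    # -- lookups ----------------------------------------------------------

    def iter_glyphs(self) -> Iterator[tuple[Glyph, PlacedLayout]]:
        for placed in self.layouts:
            for g in placed.layout.glyphs:
                yield g, placed

    def iter_edges(self) -> Iterator[EdgeGlyph]:
        for placed in self.layouts:
            yield from placed.layout.edges
        yield from self.connections

    def glyph_index(self) -> dict[str, tuple[Glyph, PlacedLayout]]:
        return {g.uid: (g, placed) for g, placed in self.iter_glyphs()}

    def find_glyph(self, uid: str) -> tuple[Glyph, PlacedLayout]:
        for g, placed in self.iter_glyphs():
            if g.uid == uid:
                return g, placed
        raise KeyError(uid)

    def global_center(self, uid: str) -> tuple[float, float]:
        g, placed = self.find_glyph(uid)
        cx, cy = g.center
        return (cx + placed.dx, cy + placed.dy)

    def placed_for(self, pathway_id: str) -> PlacedLayout:
        for placed in self.layouts:
            if placed.layout.pathway_id == pathway_id:
                return placed
        raise KeyError(pathway_id)

    def bbox(self) -> tuple[float, float, float, float]:
        if not self.layouts:
            return (0.0, 0.0, 0.0, 0.0)
        boxes = [p.bbox for p in self.layouts]
        return (
            min(b[0] for b in boxes),
            min(b[1] for b in boxes),
            max(b[2] for b in boxes),
            max(b[3] for b in boxes),
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    """One invariant breach found by :func:`validate_collection`."""

    entity: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.entity}: {self.message}"


def validate_collection(collection: PathwayCollection) -> list[Violation]:
    """Check every domain invariant; returns one record per breach.

    Side-effect free and idempotent: violations are data, not exceptions.
    """
    out: list[Violation] = []
    seen_compounds: set[str] = set()
    for c in collection.compounds:
        if not c.id:
            out.append(Violation("<compound>", "compound-id", "empty id"))
        elif c.id in seen_compounds:
            out.append(
                Violation(c.id, "compound-unique", "duplicate compound id")
            )
        seen_compounds.add(c.id)

    declared = collection.compound_ids()
    seen_reactions: set[str] = set()
    seen_pathways: set[str] = set()
    for pw in collection.pathways:
        if pw.id in seen_pathways:
            out.append(Violation(pw.id, "pathway-unique", "duplicate pathway id"))
        seen_pathways.add(pw.id)

        rids: list[str] = []
        for r in pw.reactions:
            rids.append(r.id)
            if r.id not in seen_reactions:
                seen_reactions.add(r.id)
                out.extend(_validate_reaction(r, declared))
        dup = {rid for rid in rids if rids.count(rid) > 1}
        for rid in sorted(dup):
            out.append(
                Violation(
                    pw.id, "reaction-unique", f"reaction {rid} repeated in pathway"
                )
            )

        rid_set = set(rids)
        for pred, succ in pw.links:
            for rid in (pred, succ):
                if rid not in rid_set:
                    out.append(
                        Violation(
                            pw.id,
                            "link-reference",
                            f"link references unknown reaction {rid}",
                        )
                    )
        if len(pw.reactions) >= 2:
            g = pw.link_graph().to_undirected()
            g.add_nodes_from(rid_set)
            n_comp = nx.number_connected_components(g)
            if n_comp > 1:
                out.append(
                    Violation(
                        pw.id,
                        "link-connectivity",
                        f"link graph has {n_comp} components",
                    )
                )
    return out


def _validate_reaction(r: Reaction, declared: set[str]) -> list[Violation]:
    out: list[Violation] = []
    subs = [p for p in r.participants if p.side == SIDE_SUBSTRATE]
    prods = [p for p in r.participants if p.side == SIDE_PRODUCT]
    if not subs:
        out.append(Violation(r.id, "reaction-substrate", "no substrate participants"))
    if not prods:
        out.append(Violation(r.id, "reaction-product", "no product participants"))
    if subs and not any(p.role == ROLE_MAIN for p in subs):
        out.append(Violation(r.id, "reaction-main", "no main substrate"))
    if prods and not any(p.role == ROLE_MAIN for p in prods):
        out.append(Violation(r.id, "reaction-main", "no main product"))
    for p in r.participants:
        if p.coefficient <= 0:
            out.append(
                Violation(
                    r.id,
                    "participant-coefficient",
                    f"coefficient {p.coefficient} for {p.compound_id} not > 0",
                )
            )
        if p.compound_id not in declared:
            out.append(
                Violation(
                    r.id,
                    "participant-reference",
                    f"undeclared compound {p.compound_id}",
                )
            )
        if p.side not in (SIDE_SUBSTRATE, SIDE_PRODUCT):
            out.append(Violation(r.id, "participant-side", f"bad side {p.side!r}"))
        if p.role not in (ROLE_MAIN, ROLE_SIDE):
            out.append(Violation(r.id, "participant-role", f"bad role {p.role!r}"))
    return out
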