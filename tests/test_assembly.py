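import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathwaycollage.assembly import (
    add_pathway_to_collage,
    assemble_collage,
    category_of,
    connect_all,
    connect_metabolite,
    euclidean_mst,
    pathways_for_metabolite,
)
from pathwaycollage.errors import (
    ConflictError,
    EntityNotFoundError,
    SizingError,
)
from pathwaycollage.fixtures import generate_collection
from pathwaycollage.layout import layout_pathway
from pathwaycollage.model import CollageGraph, Pathway

from conftest import make_reaction, wrap_collection


def boxes_disjoint_with_gap(collage, gap):
    boxes = [p.bbox for p in collage.layouts]
    for a, b in itertools.combinations(boxes, 2):
        grown = (a[0] - gap, a[1] - gap, a[2] + gap, a[3] + gap)
        if grown[0] < b[2] and b[0] < grown[2] and grown[1] < b[3] and b[1] < grown[3]:
            return False
    return True


def brute_force_mst_length(points):
    """Minimum total length over all spanning trees (k <= 6)."""
    import networkx as nx

    k = len(points)
    uids = [p[0] for p in points]
    coords = {p[0]: (p[1], p[2]) for p in points}
    all_edges = [
        (a, b, math.dist(coords[a], coords[b]))
        for a, b in itertools.combinations(uids, 2)
    ]
    best = math.inf
    for subset in itertools.combinations(all_edges, k - 1):
        g = nx.Graph()
        g.add_nodes_from(uids)
        g.add_edges_from((a, b) for a, b, _ in subset)
        if nx.is_connected(g):
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestCategoryOf:
    def test_biosynthesis_root(self):
        pw = Pathway(id="P", class_path=["Biosynthesis", "Amino Acids"])
        assert category_of(pw) == "biosynthesis"

    def test_degradation_root(self):
        pw = Pathway(id="P", class_path=["Degradation/Utilization/Assimilation"])
        assert category_of(pw) == "degradation"

    def test_energy_root(self):
        pw = Pathway(
            id="P", class_path=["Generation of Precursor Metabolites and Energy"]
        )
        assert category_of(pw) == "energy"

    def test_empty_class_path_is_other(self):
        assert category_of(Pathway(id="P")) == "other"


class TestAssembleCollage:
    def test_single_pathway_offset_is_gap(self, linear_pathway):
        lay = layout_pathway(linear_pathway)
        collage = assemble_collage([lay], [linear_pathway], 800.0, 20.0)
        placed = collage.layouts[0]
        assert (placed.dx, placed.dy) == (20.0, 20.0)
        x0, y0, _, _ = collage.bbox()
        assert (x0, y0) == (20.0, 20.0)

    def test_biosynthesis_left_of_degradation(
        self, linear_pathway, branched_pathway
    ):
        lays = [layout_pathway(p) for p in (linear_pathway, branched_pathway)]
        collage = assemble_collage(
            lays, [linear_pathway, branched_pathway], 1200.0, 20.0
        )
        bio = collage.placed_for("PL").bbox  # Biosynthesis class
        deg = collage.placed_for("PB").bbox  # Degradation class
        assert bio[2] < deg[0]

    def test_shelf_packing_wraps_rows_within_width(self):
        collection = generate_collection(5, 0.0, seed=3)
        # force same category so they share one band
        for pw in collection.pathways:
            pw.class_path = ["Biosynthesis"]
        lays = [layout_pathway(pw) for pw in collection.pathways]
        widest = max(l.width for l in lays)
        max_width = widest + 2 * 20.0 + 10.0
        collage = assemble_collage(lays, collection.pathways, max_width, 20.0)
        x0, _, x1, _ = collage.bbox()
        assert x1 - x0 <= max_width
        assert boxes_disjoint_with_gap(collage, 20.0 - 1e-9)
        rows = {round(p.dy, 6) for p in collage.layouts}
        assert len(rows) > 1  # actually wrapped

    def test_same_category_contiguous(self):
        collection = generate_collection(8, 0.0, seed=5)
        lays = [layout_pathway(pw) for pw in collection.pathways]
        collage = assemble_collage(lays, collection.pathways, 2000.0, 20.0)
        cats = [
            category_of(collection.pathway(p.layout.pathway_id))
            for p in collage.layouts
        ]
        seen = set()
        for cat, group in itertools.groupby(cats):
            assert cat not in seen  # each category appears in one block
            seen.add(cat)

    def test_too_small_width_raises(self, linear_pathway):
        lay = layout_pathway(linear_pathway)
        with pytest.raises(SizingError):
            assemble_collage([lay], [linear_pathway], lay.width, 20.0)

    def test_deterministic(self, gen_collection):
        lays = [layout_pathway(pw) for pw in gen_collection.pathways]
        a = assemble_collage(lays, gen_collection.pathways, 1200.0, 20.0)
        b = assemble_collage(lays, gen_collection.pathways, 1200.0, 20.0)
        assert [(p.dx, p.dy) for p in a.layouts] == [
            (p.dx, p.dy) for p in b.layouts
        ]


class TestConnectMetabolite:
    def _shared_uids(self, collage):
        by_ref = {}
        for g, _ in collage.iter_glyphs():
            if g.kind == "metabolite-node":
                by_ref.setdefault(g.ref_id, []).append(g.uid)
        return {r: u for r, u in by_ref.items() if len(u) >= 2}

    def test_star_edges_to_all_other_occurrences(self, gen_collage):
        shared = self._shared_uids(gen_collage)
        ref, uids = sorted(shared.items())[0]
        out = connect_metabolite(gen_collage, uids[0])
        assert len(out.connections) == len(uids) - 1
        for e in out.connections:
            assert uids[0] in (e.source_uid, e.target_uid)

    def test_unique_occurrence_adds_nothing(self, gen_collage):
        singles = [
            g.uid
            for g, _ in gen_collage.iter_glyphs()
            if g.kind == "metabolite-node"
        ]
        shared = {u for us in self._shared_uids(gen_collage).values() for u in us}
        lone = next(u for u in singles if u not in shared)
        out = connect_metabolite(gen_collage, lone)
        assert out.connections == []

    def test_idempotent(self, gen_collage):
        uids = sorted(self._shared_uids(gen_collage).items())[0][1]
        once = connect_metabolite(gen_collage, uids[0])
        twice = connect_metabolite(once, uids[0])
        assert len(twice.connections) == len(once.connections)

    def test_non_node_uid_raises(self, gen_collage):
        label = next(
            g.uid
            for g, _ in gen_collage.iter_glyphs()
            if g.kind == "enzyme-label"
        )
        with pytest.raises(EntityNotFoundError):
            connect_metabolite(gen_collage, label)


class TestConnectAll:
    def test_frozen_collinear_example(self):
        # occurrences at (0,0), (1,0), (5,0): of the 3 spanning trees the
        # minimal one keeps {(0,0)-(1,0), (1,0)-(5,0)} with length 5
        pts = [("a", 0.0, 0.0), ("b", 1.0, 0.0), ("c", 5.0, 0.0)]
        assert brute_force_mst_length(pts) == 5.0  # oracle
        edges = euclidean_mst(pts)
        assert sorted(tuple(sorted(e)) for e in edges) == [("a", "b"), ("b", "c")]

    def test_spanning_tree_per_compound(self, connected_collage):
        import networkx as nx

        by_ref = {}
        for g, placed in connected_collage.iter_glyphs():
            if g.kind == "metabolite-node":
                cx, cy = g.center
                by_ref.setdefault(g.ref_id, []).append(
                    (g.uid, cx + placed.dx, cy + placed.dy)
                )
        edges_by_ref = {}
        for e in connected_collage.connections:
            edges_by_ref.setdefault(e.ref_id, []).append(e)
        for ref, pts in by_ref.items():
            k = len(pts)
            edges = edges_by_ref.get(ref, [])
            if k < 2:
                assert edges == []
                continue
            assert len(edges) == k - 1
            g = nx.Graph()
            g.add_nodes_from(p[0] for p in pts)
            g.add_edges_from((e.source_uid, e.target_uid) for e in edges)
            assert nx.is_connected(g)
            if k <= 6:
                coords = {p[0]: (p[1], p[2]) for p in pts}
                total = sum(
                    math.dist(coords[e.source_uid], coords[e.target_uid])
                    for e in edges
                )
                assert total == pytest.approx(
                    brute_force_mst_length(pts), rel=1e-9
                )

    def test_no_cross_compound_edges(self, connected_collage):
        ref_of = {
            g.uid: g.ref_id
            for g, _ in connected_collage.iter_glyphs()
            if g.kind == "metabolite-node"
        }
        for e in connected_collage.connections:
            assert ref_of[e.source_uid] == ref_of[e.target_uid]

    def test_no_shared_compounds_is_unchanged(self):
        collection = generate_collection(1, 0.0, seed=2)
        lays = [layout_pathway(pw) for pw in collection.pathways]
        collage = assemble_collage(lays, collection.pathways, 1200.0, 20.0)
        # single linear pathway: each compound occurs once
        out = connect_all(collage)
        assert out.connections == []

    def test_exclusion_list_respected(self, gen_collage):
        full = connect_all(gen_collage)
        excluded_refs = {e.ref_id for e in full.connections}
        out = connect_all(gen_collage, exclude=excluded_refs)
        assert out.connections == []

    @settings(max_examples=30, deadline=None)
    @given(
        pts=st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=2,
            max_size=6,
            unique=True,
        )
    )
    def test_prim_matches_brute_force(self, pts):
        points = [(f"p{i}", x, y) for i, (x, y) in enumerate(pts)]
        edges = euclidean_mst(points)
        coords = {u: (x, y) for u, x, y in points}
        total = sum(math.dist(coords[a], coords[b]) for a, b in edges)
        assert total == pytest.approx(
            brute_force_mst_length(points), rel=1e-9, abs=1e-9
        )


class TestPathwaysForMetabolite:
    def test_compound_in_two_pathways(self, small_collection):
        # brute-force oracle: scan every reaction of every pathway
        expected = sorted(
            pw.id
            for pw in small_collection.pathways
            if any(
                p.compound_id == "A"
                for r in pw.reactions
                for p in r.participants
            )
        )
        assert expected == ["PB", "PL"]  # frozen from the oracle
        assert pathways_for_metabolite("A", small_collection) == expected

    def test_side_only_participation_counts(self, small_collection):
        assert pathways_for_metabolite("NADP", small_collection) == ["PL"]

    def test_unknown_compound_raises(self, small_collection):
        with pytest.raises(EntityNotFoundError):
            pathways_for_metabolite("XYZZY", small_collection)

    def test_compound_in_no_pathway(self):
        pw = Pathway(id="P", reactions=[make_reaction("R", "A", "B")])
        collection = wrap_collection(pw)
        from pathwaycollage.model import Compound

        collection.compounds.append(Compound(id="ORPHAN", name="orphan"))
        assert pathways_for_metabolite("ORPHAN", collection) == []


class TestAddPathwayToCollage:
    def test_added_below_existing(self, gen_collage, cyclic_pathway):
        lay = layout_pathway(cyclic_pathway)
        _, _, _, y1 = gen_collage.bbox()
        out = add_pathway_to_collage(gen_collage, lay, gap=20.0)
        new = out.placed_for("PC").bbox
        for p in gen_collage.layouts:
            assert new[1] >= p.bbox[3] + 20.0 - 1e-9
        assert new[1] == pytest.approx(y1 + 20.0)

    def test_add_to_empty_collage(self, cyclic_pathway):
        lay = layout_pathway(cyclic_pathway)
        out = add_pathway_to_collage(CollageGraph(), lay, gap=20.0)
        assert (out.layouts[0].dx, out.layouts[0].dy) == (20.0, 20.0)

    def test_two_sequential_adds_stack(self, cyclic_pathway, linear_pathway):
        c = add_pathway_to_collage(CollageGraph(), layout_pathway(cyclic_pathway))
        c = add_pathway_to_collage(c, layout_pathway(linear_pathway))
        first = c.placed_for("PC").bbox
        second = c.placed_for("PL").bbox
        assert second[1] > first[3]

    def test_duplicate_pathway_raises(self, gen_collage):
        existing = gen_collage.layouts[0].layout
        with pytest.raises(ConflictError):
            add_pathway_to_collage(gen_collage, existing)
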