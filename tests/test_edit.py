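import copy

import pytest

from pathwaycollage.assembly import connect_metabolite
from pathwaycollage.edit import (
    delete_element,
    highlight,
    merge_nodes,
    move_node,
    move_pathway,
    relabel,
    set_style,
)
from pathwaycollage.errors import EntityNotFoundError, MergeError
from pathwaycollage.io import collages_equal


def shared_node_uids(collage):
    by_ref = {}
    for g, _ in collage.iter_glyphs():
        if g.kind == "metabolite-node":
            by_ref.setdefault(g.ref_id, []).append(g.uid)
    return {r: u for r, u in by_ref.items() if len(u) >= 2}


def all_glyph_uids(collage):
    return {g.uid for g, _ in collage.iter_glyphs()}


class TestMoveNode:
    def test_zero_move_is_identity(self, gen_collage):
        uid = gen_collage.layouts[0].layout.backbone[0]
        out = move_node(gen_collage, uid, 0.0, 0.0)
        assert collages_equal(out, gen_collage)

    def test_exact_translation(self, gen_collage):
        uid = gen_collage.layouts[0].layout.backbone[0]
        g0, _ = gen_collage.find_glyph(uid)
        out = move_node(gen_collage, uid, 10.0, -5.0)
        g1, _ = out.find_glyph(uid)
        assert (g1.x, g1.y) == (g0.x + 10.0, g0.y - 5.0)

    def test_nothing_else_moves(self, gen_collage):
        uid = gen_collage.layouts[0].layout.backbone[0]
        out = move_node(gen_collage, uid, 7.0, 3.0)
        for g, _ in gen_collage.iter_glyphs():
            if g.uid == uid:
                continue
            moved, _ = out.find_glyph(g.uid)
            assert (moved.x, moved.y) == (g.x, g.y)

    def test_attached_grid_moves_with_parent(self, gen_collage, scheme):
        from pathwaycollage.fixtures import generate_omics
        from pathwaycollage.overlay import apply_timeseries_overlay

        from conftest import wrap_collection

        # build an overlay so a grid exists, then move its parent node
        ids = [
            g.ref_id
            for g, _ in gen_collage.iter_glyphs()
            if g.kind == "metabolite-node"
        ]
        ds_rows = {ids[0]: [1.0, 2.0, 3.0]}
        from pathwaycollage.model import OmicsDataset

        ds = OmicsDataset(data_type="metabolite", columns=["a", "b", "c"], rows=ds_rows)
        c = apply_timeseries_overlay(gen_collage, ds, scheme)
        grid = next(g for g, _ in c.iter_glyphs() if g.kind == "omics-grid")
        node_uid = grid.parent_uid
        boxes_before = {
            g.uid: (g.x, g.y)
            for g, _ in c.iter_glyphs()
            if g.kind in ("omics-grid", "omics-box")
        }
        out = move_node(c, node_uid, 4.0, 9.0)
        for g, _ in out.iter_glyphs():
            if g.uid in boxes_before:
                bx, by = boxes_before[g.uid]
                if g.parent_uid == node_uid or g.kind == "omics-box":
                    assert (g.x, g.y) == (bx + 4.0, by + 9.0)

    def test_unknown_uid_raises(self, gen_collage):
        with pytest.raises(EntityNotFoundError):
            move_node(gen_collage, "nope", 1.0, 1.0)


class TestMovePathway:
    def test_translate_untranslate_is_identity(self, gen_collage):
        pid = gen_collage.layouts[0].layout.pathway_id
        out = move_pathway(move_pathway(gen_collage, pid, 33.0, -7.5), pid, -33.0, 7.5)
        assert collages_equal(out, gen_collage)

    def test_all_glyphs_shift_together(self, gen_collage):
        pid = gen_collage.layouts[0].layout.pathway_id
        out = move_pathway(gen_collage, pid, 12.0, 8.0)
        for g, _ in gen_collage.iter_glyphs():
            before = gen_collage.global_center(g.uid)
            after = out.global_center(g.uid)
            _, placed = gen_collage.find_glyph(g.uid)
            if placed.layout.pathway_id == pid:
                assert after == (before[0] + 12.0, before[1] + 8.0)
            else:
                assert after == before

    def test_connection_endpoint_follows(self, connected_collage):
        e = next(
            e
            for e in connected_collage.connections
            if connected_collage.find_glyph(e.source_uid)[1].layout.pathway_id
            != connected_collage.find_glyph(e.target_uid)[1].layout.pathway_id
        )
        pid = connected_collage.find_glyph(e.source_uid)[1].layout.pathway_id
        out = move_pathway(connected_collage, pid, 5.0, 5.0)
        src_before = connected_collage.global_center(e.source_uid)
        dst_before = connected_collage.global_center(e.target_uid)
        assert out.global_center(e.source_uid) == (
            src_before[0] + 5.0,
            src_before[1] + 5.0,
        )
        assert out.global_center(e.target_uid) == dst_before

    def test_unknown_pathway_raises(self, gen_collage):
        with pytest.raises(EntityNotFoundError):
            move_pathway(gen_collage, "nope", 1.0, 1.0)


class TestDeleteElement:
    def test_node_deletion_removes_incident_edges(self, gen_collage):
        uid = gen_collage.layouts[0].layout.backbone[1]
        incident = [
            e
            for e in gen_collage.iter_edges()
            if uid in (e.source_uid, e.target_uid)
        ]
        assert incident
        out = delete_element(gen_collage, uid)
        assert uid not in all_glyph_uids(out)
        remaining = {e.uid for e in out.iter_edges()}
        for e in incident:
            assert e.uid not in remaining

    def test_edge_counts_decrease_exactly(self, gen_collage):
        uid = gen_collage.layouts[0].layout.backbone[1]
        degree = sum(
            1
            for e in gen_collage.iter_edges()
            if uid in (e.source_uid, e.target_uid)
        )
        out = delete_element(gen_collage, uid)
        assert (
            len(list(out.iter_edges()))
            == len(list(gen_collage.iter_edges())) - degree
        )

    def test_pathway_deletion_removes_everything(self, connected_collage):
        pid = connected_collage.layouts[0].layout.pathway_id
        gone = {
            g.uid for g in connected_collage.layouts[0].layout.glyphs
        }
        out = delete_element(connected_collage, pid)
        assert all(p.layout.pathway_id != pid for p in out.layouts)
        present = all_glyph_uids(out)
        assert not (gone & present)
        for e in out.iter_edges():
            assert e.source_uid in present and e.target_uid in present

    def test_connection_edge_deletion_keeps_nodes(self, connected_collage):
        e = connected_collage.connections[0]
        out = delete_element(connected_collage, e.uid)
        present = all_glyph_uids(out)
        assert e.source_uid in present and e.target_uid in present
        assert e.uid not in {x.uid for x in out.iter_edges()}

    def test_orphan_freedom(self, connected_collage):
        uid = sorted(shared_node_uids(connected_collage).items())[0][1][0]
        out = delete_element(connected_collage, uid)
        present = all_glyph_uids(out)
        for e in out.iter_edges():
            assert e.source_uid in present and e.target_uid in present

    def test_unknown_target_raises(self, gen_collage):
        with pytest.raises(EntityNotFoundError):
            delete_element(gen_collage, "nope")


class TestMergeNodes:
    def test_node_count_decreases(self, gen_collage):
        uids = sorted(shared_node_uids(gen_collage).items())[0][1]
        n_before = sum(
            1 for g, _ in gen_collage.iter_glyphs() if g.kind == "metabolite-node"
        )
        out = merge_nodes(gen_collage, uids)
        n_after = sum(
            1 for g, _ in out.iter_glyphs() if g.kind == "metabolite-node"
        )
        assert n_after == n_before - (len(uids) - 1)
        assert out.merges[-1].survivor == uids[0]

    def test_survivor_keeps_position(self, gen_collage):
        uids = sorted(shared_node_uids(gen_collage).items())[0][1]
        before = gen_collage.global_center(uids[0])
        out = merge_nodes(gen_collage, uids)
        assert out.global_center(uids[0]) == before

    def test_edges_redirected_to_survivor(self, gen_collage):
        uids = sorted(shared_node_uids(gen_collage).items())[0][1]
        out = merge_nodes(gen_collage, uids)
        absorbed = set(uids[1:])
        for e in out.iter_edges():
            assert e.source_uid not in absorbed
            assert e.target_uid not in absorbed

    def test_self_loop_connection_removed(self, gen_collage):
        uids = sorted(shared_node_uids(gen_collage).items())[0][1]
        with_conn = connect_metabolite(gen_collage, uids[0])
        n_conn = len(with_conn.connections)
        assert n_conn >= 1
        out = merge_nodes(with_conn, uids)
        # edge census: all connections among merged nodes collapse away
        for e in out.connections:
            assert e.source_uid != e.target_uid
        assert len(out.connections) == n_conn - (len(uids) - 1)

    def test_mixed_compounds_rejected_without_change(self, gen_collage):
        by_ref = shared_node_uids(gen_collage)
        refs = sorted(by_ref)
        a = by_ref[refs[0]][0]
        other = next(
            g.uid
            for g, _ in gen_collage.iter_glyphs()
            if g.kind == "metabolite-node" and g.ref_id != refs[0]
        )
        before = copy.deepcopy(gen_collage)
        with pytest.raises(MergeError):
            merge_nodes(gen_collage, [a, other])
        assert collages_equal(gen_collage, before)

    def test_fewer_than_two_uids_rejected(self, gen_collage):
        uids = sorted(shared_node_uids(gen_collage).items())[0][1]
        with pytest.raises(MergeError):
            merge_nodes(gen_collage, uids[:1])

    def test_merge_preserves_uid_uniqueness(self, gen_collage):
        uids = sorted(shared_node_uids(gen_collage).items())[0][1]
        out = merge_nodes(gen_collage, uids)
        all_uids = [g.uid for g, _ in out.iter_glyphs()]
        assert len(all_uids) == len(set(all_uids))


class TestHighlightRelabelStyle:
    def test_highlight_changes_only_color(self, gen_collage):
        uid = gen_collage.layouts[0].layout.backbone[0]
        out = highlight(gen_collage, uid, "#ff0000")
        g, _ = out.find_glyph(uid)
        assert g.color == "#ff0000"
        g0, _ = gen_collage.find_glyph(uid)
        assert (g.x, g.y, g.label_text, g.visible) == (
            g0.x,
            g0.y,
            g0.label_text,
            g0.visible,
        )

    def test_highlight_edge(self, connected_collage):
        e = connected_collage.connections[0]
        out = highlight(connected_collage, e.uid, "#123456")
        assert next(
            x for x in out.iter_edges() if x.uid == e.uid
        ).color == "#123456"

    def test_relabel_verbatim(self, gen_collage):
        uid = next(
            g.uid
            for g, _ in gen_collage.iter_glyphs()
            if g.kind == "enzyme-label"
        )
        out = relabel(gen_collage, uid, "my enzyme")
        g, _ = out.find_glyph(uid)
        assert g.label_text == "my enzyme"

    def test_box_toggle_involution(self, gen_collage):
        off = set_style(gen_collage, {"show_pathway_boxes": False})
        assert all(
            not g.visible
            for g, _ in off.iter_glyphs()
            if g.kind == "pathway-box"
        )
        on = set_style(off, {"show_pathway_boxes": True})
        assert collages_equal(on, gen_collage)

    def test_unknown_style_field_raises(self, gen_collage):
        with pytest.raises(EntityNotFoundError):
            set_style(gen_collage, {"show_everything": True})

    def test_edits_are_pure(self, gen_collage):
        before = copy.deepcopy(gen_collage)
        uid = gen_collage.layouts[0].layout.backbone[0]
        move_node(gen_collage, uid, 5.0, 5.0)
        highlight(gen_collage, uid, "#fff000")
        assert collages_equal(gen_collage, before)
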