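"""Semantic-zoom visibility resolution and SVG / PNG emission.

Visibility is monotone in zoom: raising the zoom factor never removes an
element.  SVG output is built from plain strings with fixed float
formatting, so identical input yields identical bytes.  PNG export
rasterizes this package's own SVG dialect with Pillow (no external SVG
engine required).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from io import BytesIO

from PIL import Image, ImageDraw

from .model import CollageGraph, StyleConfig, ZoomPolicy

MARGIN = 10.0

_LABEL_KINDS = {
    "pathway-label": "show_pathway_labels",
    "enzyme-label": "show_enzyme_labels",
    "gene-label": "show_gene_labels",
}


def visible_elements(
    collage: CollageGraph,
    zoom: float,
    policy: ZoomPolicy | None = None,
    style: StyleConfig | None = None,
) -> set[str]:
    """Uids of every glyph and edge drawn at the given zoom factor.

    Metabolite nodes, edges, and pathway boxes are always present (subject
    to their style toggles); a label of kind *k* appears iff
    ``zoom >= policy[k]`` and its toggle is on; omics grids follow the
    omics toggle.  Per-glyph ``visible`` flags are honored throughout.
    """
    if zoom <= 0:
        raise ValueError("zoom must be > 0")
    policy = policy or ZoomPolicy()
    style = style or collage.style
    out: set[str] = set()
    for g, _ in collage.iter_glyphs():
        if not g.visible:
            continue
        if g.kind == "metabolite-node":
            out.add(g.uid)
        elif g.kind == "pathway-box":
            if style.show_pathway_boxes:
                out.add(g.uid)
        elif g.kind in _LABEL_KINDS:
            if getattr(style, _LABEL_KINDS[g.kind]) and zoom >= policy.threshold(
                g.kind
            ):
                out.add(g.uid)
        elif g.kind in ("omics-grid", "omics-box"):
            if style.show_omics:
                out.add(g.uid)
        else:  # pragma: no cover - future kinds default to visible
            out.add(g.uid)
    # edges are drawable only while both endpoints still exist somewhere
    index = {g.uid for g, _ in collage.iter_glyphs()}
    for placed in collage.layouts:
        for e in placed.layout.edges:
            if e.source_uid in index and e.target_uid in index:
                out.add(e.uid)
    if style.show_connections:
        for e in collage.connections:
            if e.source_uid in index and e.target_uid in index:
                out.add(e.uid)
    return out


def _f(v: float) -> str:
    s = f"{v:.4f}".rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def render_svg(
    collage: CollageGraph,
    zoom: float = 1.0,
    policy: ZoomPolicy | None = None,
) -> str:
    """Emit an SVG document: one element per visible glyph/edge, all
    coordinates scaled by the zoom factor."""
    policy = policy or ZoomPolicy()
    style = collage.style
    vis = visible_elements(collage, zoom, policy, style)

    x0, y0, x1, y1 = collage.bbox()
    width = (x1 - x0) * zoom + 2 * MARGIN
    height = (y1 - y0) * zoom + 2 * MARGIN

    def tx(x: float) -> float:
        return (x - x0) * zoom + MARGIN

    def ty(y: float) -> float:
        return (y - y0) * zoom + MARGIN

    parts: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_f(width)}" height="{_f(height)}" '
        f'viewBox="0 0 {_f(width)} {_f(height)}">',
    ]

    index = collage.glyph_index()

    def center_of(uid: str) -> tuple[float, float]:
        g, placed = index[uid]
        cx, cy = g.center
        return tx(cx + placed.dx), ty(cy + placed.dy)

    # draw order: boxes, edges, grids, nodes, labels
    boxes, grids, nodes, labels = [], [], [], []
    for g, placed in collage.iter_glyphs():
        if g.uid not in vis:
            continue
        gx, gy = tx(g.x + placed.dx), ty(g.y + placed.dy)
        gw, gh = g.width * zoom, g.height * zoom
        if g.kind == "pathway-box":
            boxes.append(
                f'<rect role="glyph" class="pathway-box" data-uid="{_esc(g.uid)}" '
                f'x="{_f(gx)}" y="{_f(gy)}" width="{_f(gw)}" height="{_f(gh)}" '
                f'fill="{g.color}" stroke="#999999" stroke-width="1"/>'
            )
        elif g.kind in ("omics-grid", "omics-box"):
            grids.append(
                f'<rect role="glyph" class="{g.kind}" data-uid="{_esc(g.uid)}" '
                f'x="{_f(gx)}" y="{_f(gy)}" width="{_f(gw)}" height="{_f(gh)}" '
                f'fill="{g.color}" stroke="#666666" stroke-width="0.5"/>'
            )
        elif g.kind == "metabolite-node":
            r = min(gw, gh) / 2
            label = ""
            if g.label_text and zoom >= policy.threshold("metabolite-label"):
                fs = style.font_sizes.get("metabolite-label", 10.0) * zoom
                label = (
                    f'<text x="{_f(gx + gw / 2)}" y="{_f(gy + gh + fs)}" '
                    f'font-size="{_f(fs)}" text-anchor="middle" '
                    f'font-family="sans-serif" fill="#222222">'
                    f"{_esc(g.label_text)}</text>"
                )
            nodes.append(
                f'<g role="glyph" class="metabolite-node" data-uid="{_esc(g.uid)}">'
                f'<circle cx="{_f(gx + gw / 2)}" cy="{_f(gy + gh / 2)}" '
                f'r="{_f(r)}" fill="{g.color}"/>{label}</g>'
            )
        else:  # label kinds
            fs = g.height * zoom
            labels.append(
                f'<text role="glyph" class="{g.kind}" data-uid="{_esc(g.uid)}" '
                f'x="{_f(gx)}" y="{_f(gy + fs * 0.8)}" font-size="{_f(fs)}" '
                f'font-family="sans-serif" fill="{g.color}">'
                f"{_esc(g.label_text)}</text>"
            )

    edges = []
    for e in collage.iter_edges():
        if e.uid not in vis:
            continue
        sx, sy = center_of(e.source_uid)
        txx, tyy = center_of(e.target_uid)
        dash = ' stroke-dasharray="4 2"' if e.kind == "connection-edge" else ""
        marker = ""
        if e.arrow in ("forward", "both"):
            marker = _arrow_head(sx, sy, txx, tyy, e.color)
        if e.arrow == "both":
            marker += _arrow_head(txx, tyy, sx, sy, e.color)
        edges.append(
            f'<g role="edge" class="{e.kind}" data-uid="{_esc(e.uid)}">'
            f'<line x1="{_f(sx)}" y1="{_f(sy)}" x2="{_f(txx)}" y2="{_f(tyy)}" '
            f'stroke="{e.color}" stroke-width="{_f(e.thickness * zoom)}"{dash}/>'
            f"{marker}</g>"
        )

    parts.extend(boxes)
    parts.extend(edges)
    parts.extend(grids)
    parts.extend(nodes)
    parts.extend(labels)
    parts.append("</svg>")
    return "\n".join(parts)


def _arrow_head(sx, sy, txx, tyy, color) -> str:
    """Small triangle at the target end of a segment."""
    dx, dy = txx - sx, tyy - sy
    norm = math.hypot(dx, dy)
    if norm < 1e-9:
        return ""
    ux, uy = dx / norm, dy / norm
    size = 5.0
    bx, by = txx - ux * size, tyy - uy * size
    px, py = -uy * size * 0.5, ux * size * 0.5
    return (
        f'<polygon points="{_f(txx)},{_f(tyy)} {_f(bx + px)},{_f(by + py)} '
        f'{_f(bx - px)},{_f(by - py)}" fill="{color}"/>'
    )


# ---------------------------------------------------------------------------
# PNG export
# ---------------------------------------------------------------------------

def png_dimensions(
    canvas_w: float, canvas_h: float, scale: float, max_dim: int
) -> tuple[int, int]:
    """Raster dimensions: ceil(canvas x scale), uniformly downscaled so
    neither dimension exceeds ``max_dim`` (aspect ratio preserved)."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if max_dim <= 0:
        raise ValueError("max_dim must be > 0")
    f = scale
    biggest = max(canvas_w, canvas_h) * scale
    if biggest > max_dim:
        f = scale * max_dim / biggest
    return (
        max(1, math.ceil(canvas_w * f)),
        max(1, math.ceil(canvas_h * f)),
    )


def export_png(
    svg: str, scale: float = 1.0, max_dim: int = 8192
) -> Image.Image:
    """Rasterize an SVG document produced by :func:`render_svg`.

    Only this package's SVG dialect (rect / circle / line / polygon / text,
    possibly wrapped in ``<g>``) is supported.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    root = ET.fromstring(svg)
    w = float(root.get("width"))
    h = float(root.get("height"))
    out_w, out_h = png_dimensions(w, h, scale, max_dim)
    f = out_w / w if w else 1.0

    img = Image.new("RGB", (out_w, out_h), "#ffffff")
    draw = ImageDraw.Draw(img)
    ns = "{http://www.w3.org/2000/svg}"

    def walk(el):
        tag = el.tag.replace(ns, "")
        if tag == "rect":
            x, y = float(el.get("x")) * f, float(el.get("y")) * f
            ww, hh = float(el.get("width")) * f, float(el.get("height")) * f
            draw.rectangle(
                [x, y, x + ww, y + hh],
                fill=el.get("fill"),
                outline=el.get("stroke"),
            )
        elif tag == "circle":
            cx, cy = float(el.get("cx")) * f, float(el.get("cy")) * f
            r = float(el.get("r")) * f
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=el.get("fill"))
        elif tag == "line":
            draw.line(
                [
                    float(el.get("x1")) * f,
                    float(el.get("y1")) * f,
                    float(el.get("x2")) * f,
                    float(el.get("y2")) * f,
                ],
                fill=el.get("stroke"),
                width=max(1, round(float(el.get("stroke-width", "1")) * f)),
            )
        elif tag == "polygon":
            pts = [
                tuple(float(c) * f for c in p.split(","))
                for p in el.get("points").split()
            ]
            draw.polygon(pts, fill=el.get("fill"))
        elif tag == "text":
            x, y = float(el.get("x")) * f, float(el.get("y")) * f
            draw.text((x, y), el.text or "", fill=el.get("fill") or "#000000")
        for child in el:
            walk(child)

    for child in root:
        walk(child)
    return img


def write_png(svg: str, path, scale: float = 1.0, max_dim: int = 8192) -> None:
    img = export_png(svg, scale=scale, max_dim=max_dim)
    img.save(path, format="PNG")


def png_bytes(svg: str, scale: float = 1.0, max_dim: int = 8192) -> bytes:
    buf = BytesIO()
    export_png(svg, scale=scale, max_dim=max_dim).save(buf, format="PNG")
    return buf.getvalue()
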