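# pathwaycollage

Scriptable construction of *pathway collages*: personalized multi-pathway
metabolic diagrams. The library lays out individual pathways automatically
(vertical chains, anchored circles, layered trees), assembles many layouts
into one collage grouped by functional class, draws connection edges between
occurrences of the same metabolite, supports scripted editing (move, delete,
merge, highlight, relabel, style), paints omics data onto the diagram
(single-value coloring or time-series box grids), and renders with semantic
zooming to SVG and PNG. Collages round-trip losslessly through a versioned
JSON format and export to a Cytoscape-style elements/style graph JSON.

## Library overview

| module | purpose |
|---|---|
| `pathwaycollage.model` | domain types (compounds, reactions, pathways, glyphs, collage, omics, style) and `validate_collection` |
| `pathwaycollage.io` | collection JSON, omics TSV, collage save/load, viewer JSON export |
| `pathwaycollage.layout` | `classify_topology`, `extract_backbone`, `layout_pathway`, `add_side_metabolites` |
| `pathwaycollage.assembly` | `assemble_collage`, `connect_metabolite` / `connect_all` (per-compound Euclidean MST), `pathways_for_metabolite`, `add_pathway_to_collage` |
| `pathwaycollage.edit` | pure copy-and-return edits: move, delete, merge, highlight, relabel, set_style |
| `pathwaycollage.overlay` | `color_for` bin rule, entity matching, single-value and time-series overlays |
| `pathwaycollage.render` | `visible_elements` (semantic zoom), `render_svg` (byte-deterministic), `export_png` |
| `pathwaycollage.fixtures` | seeded generators for collections and omics tables |

```python
from pathwaycollage import *
from pathwaycollage.fixtures import generate_collection, generate_omics

collection = generate_collection(5, shared_compound_rate=0.3, seed=7)
layouts = [layout_pathway(pw) for pw in collection.pathways]
collage = assemble_collage(layouts, collection.pathways, max_width=1200, gap=20)
collage = connect_all(collage)
scheme = ColorScheme(breakpoints=[-1, 0, 1], colors=["#00441b", "#74c476", "#fdae6b", "#a50f15"])
collage = apply_timeseries_overlay(collage, generate_omics(collection, "gene", 5), scheme)
svg = render_svg(collage, zoom=1.0)
```

## CLI

```sh
pathway-collage fixtures fx --n-pathways 5 --seed 3     # demo inputs
pathway-collage build fx/collection.json -o collage.json
pathway-collage build fx/collection.json -m SHR-0 -o collage.json   # by metabolite
pathway-collage edit collage.json script.json -o edited.json
pathway-collage overlay edited.json fx/omics_gene_series.tsv \
    --data-type gene --scheme fx/scheme.json -o overlaid.json --json
pathway-collage render overlaid.json out.svg --zoom 1.5
pathway-collage render overlaid.json out.png --scale 2
pathway-collage export overlaid.json viewer.json
```

Edit scripts are JSON lists applied atomically in order, e.g.
`[{"op": "merge", "args": {"uids": ["PWY000-LIN:n1", "PWY002-BRA:n4"]}},
{"op": "connect_all", "args": {}}]`. Available ops: `move_node`,
`move_pathway`, `delete`, `merge`, `highlight`, `relabel`, `set_style`,
`connect_metabolite`, `connect_all`.

Exit codes: 0 ok, 1 user error (bad input or unknown id), 2 internal error.

## File formats

* **Pathway collection** — JSON `{schema_version, compounds, reactions,
  pathways}`; pathways list `reaction_ids`, ordering `links`
  (predecessor/successor pairs) and an ontology `class_path`. Schema:
  `src/pathwaycollage/schemas/collection.schema.json`.
* **Omics table** — UTF-8 TSV, header row, first column entity id; empty or
  non-numeric cells are missing values; duplicate ids: last row wins.
* **Color scheme** — JSON `{breakpoints, colors, missing_color}` with
  `len(colors) == len(breakpoints) + 1`; bins are half-open at the lower
  bound, with a below-minimum bin.
* **Saved collage** — versioned JSON, deep-equal after load (coordinates
  compared at 1e-9).
* **Viewer export** — elements/style graph JSON; schema:
  `src/pathwaycollage/schemas/viewer.schema.json`.

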