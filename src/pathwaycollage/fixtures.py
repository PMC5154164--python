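"""Deterministic generators for pathway collections and omics tables.

Everything is driven by one seeded :class:`random.Random` per call — no
global state — so the same arguments always produce deep-equal output.
A small pool of currency pseudo-compounds (NADP-like co-substrates) is
shared across pathways to guarantee connect/merge test material.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Optional

from .model import (
    CATEGORIES,
    Compound,
    OmicsDataset,
    Pathway,
    PathwayCollection,
    Reaction,
    ReactionParticipant,
)

#: currency pool: compounds that recur as side participants everywhere
CURRENCY_POOL = (
    "CCY-NADP",
    "CCY-NADPH",
    "CCY-ATP",
    "CCY-ADP",
    "CCY-NAD",
    "CCY-NADH",
    "CCY-COA",
    "CCY-PPI",
)

#: shared-backbone pool used by generate_collection
SHARED_POOL = tuple(f"SHR-{i}" for i in range(4))

_CLASS_PATHS = {
    "biosynthesis": ["Biosynthesis", "Amino Acid Biosynthesis"],
    "degradation": ["Degradation/Utilization/Assimilation", "Sugar Degradation"],
    "energy": ["Generation of Precursor Metabolites and Energy", "Fermentation"],
    "other": ["Detoxification"],
}

TOPOLOGIES = ("linear", "cyclic", "branched")


def _participant(cid: str, side: str, role: str) -> ReactionParticipant:
    return ReactionParticipant(compound_id=cid, side=side, role=role)


def generate_pathway(
    topology: str,
    n_reactions: int,
    seed: int,
    pathway_id: Optional[str] = None,
    category: str = "biosynthesis",
) -> Pathway:
    """One valid pathway of the requested topology.

    Each reaction carries one main substrate, one main product, 0-2 side
    participants from the currency pool, an enzyme label and 1-2 gene ids.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if topology == "cyclic" and n_reactions < 3:
        raise ValueError("cyclic pathways need >= 3 reactions")
    if topology == "branched" and n_reactions < 3:
        raise ValueError("branched pathways need >= 3 reactions")

    rng = random.Random(seed)
    pid = pathway_id or f"PWY-{topology[:3].upper()}-{seed}"

    n = n_reactions
    if topology == "cyclic":
        chain = [f"C-{pid}-{i}" for i in range(n)]
        subs = chain
        prods = [chain[(i + 1) % n] for i in range(n)]
        links = [(f"R-{pid}-{i}", f"R-{pid}-{(i + 1) % n}") for i in range(n)]
        parents = None
    elif topology == "linear":
        chain = [f"C-{pid}-{i}" for i in range(n + 1)]
        subs = chain[:-1]
        prods = chain[1:]
        links = [(f"R-{pid}-{i}", f"R-{pid}-{i + 1}") for i in range(n - 1)]
        parents = None
    else:  # branched tree over reactions
        parents = [None] + [rng.randrange(i) for i in range(1, n)]
        if all(parents[i] == i - 1 for i in range(1, n)):
            parents[n - 1] = 0  # force an actual branch
        chain = [f"C-{pid}-{i}" for i in range(n + 1)]
        prods = [chain[i + 1] for i in range(n)]
        subs = [
            chain[0] if parents[i] is None else prods[parents[i]]
            for i in range(n)
        ]
        links = [
            (f"R-{pid}-{parents[i]}", f"R-{pid}-{i}")
            for i in range(1, n)
        ]

    reactions = []
    for i in range(n):
        parts = [
            _participant(subs[i], "substrate", "main"),
            _participant(prods[i], "product", "main"),
        ]
        for _ in range(rng.randint(0, 2)):
            cid = rng.choice(CURRENCY_POOL)
            side = rng.choice(("substrate", "product"))
            parts.append(_participant(cid, side, "side"))
        reactions.append(
            Reaction(
                id=f"R-{pid}-{i}",
                participants=parts,
                direction="reversible" if rng.random() < 0.2 else "forward",
                enzyme_labels=[f"Enz{i}.{seed % 97}"],
                gene_ids=[
                    f"g{seed % 97}x{i}{chr(97 + j)}"
                    for j in range(rng.randint(1, 2))
                ],
            )
        )
    return Pathway(
        id=pid,
        name=f"{topology} pathway {seed}",
        reactions=reactions,
        links=links,
        class_path=list(_CLASS_PATHS[category]),
    )


def collection_for(pathways: list[Pathway]) -> PathwayCollection:
    """Wrap pathways into a collection, declaring every participant."""
    cids = sorted(
        {
            p.compound_id
            for pw in pathways
            for r in pw.reactions
            for p in r.participants
        }
    )
    return PathwayCollection(
        compounds=[Compound(id=c, name=c) for c in cids],
        pathways=pathways,
    )


def generate_collection(
    n_pathways: int,
    shared_compound_rate: float = 0.3,
    seed: int = 0,
) -> PathwayCollection:
    """A mixed-topology, mixed-category collection.

    With ``n_pathways >= 2`` the first two pathways are biosynthesis- and
    degradation-classed so category placement is exercised.  About
    ``shared_compound_rate`` of each pathway's own backbone compounds are
    remapped into a small shared pool, guaranteeing cross-pathway
    duplicates whenever the rate is positive.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    if not 0.0 <= shared_compound_rate <= 1.0:
        raise ValueError("shared_compound_rate must be in [0, 1]")
    rng = random.Random(seed)
    pathways: list[Pathway] = []
    for i in range(n_pathways):
        topology = TOPOLOGIES[i % 3]
        if i == 0:
            category = "biosynthesis"
        elif i == 1:
            category = "degradation"
        else:
            category = CATEGORIES[i % 4]
        n_reactions = rng.randint(3, 8) if topology != "linear" else rng.randint(1, 8)
        pw = generate_pathway(
            topology,
            n_reactions,
            seed=seed * 1009 + i,
            pathway_id=f"PWY{i:03d}-{topology[:3].upper()}",
            category=category,
        )
        _remap_shared(pw, shared_compound_rate, rng)
        pathways.append(pw)

    if shared_compound_rate > 0 and n_pathways >= 2:
        _ensure_cross_pathway_duplicate(pathways)
    return collection_for(pathways)


def _remap_shared(pw: Pathway, rate: float, rng: random.Random) -> None:
    """Remap ~rate of the pathway's own main-chain compounds into the
    shared pool (consistently across all occurrences within the pathway)."""
    own = sorted(
        {
            p.compound_id
            for r in pw.reactions
            for p in r.participants
            if p.role == "main"
        }
    )
    remap = {
        cid: rng.choice(SHARED_POOL)
        for cid in own
        if rng.random() < rate
    }
    for r in pw.reactions:
        for p in r.participants:
            p.compound_id = remap.get(p.compound_id, p.compound_id)


def _ensure_cross_pathway_duplicate(pathways: list[Pathway]) -> None:
    """Deterministic fix-up: force one shared main compound between the
    first two pathways if random remapping produced none."""
    def mains(pw: Pathway) -> set[str]:
        return {
            p.compound_id
            for r in pw.reactions
            for p in r.participants
            if p.role == "main"
        }

    sets = [mains(pw) for pw in pathways]
    for i, a in enumerate(sets):
        for b in sets[i + 1:]:
            if a & b:
                return
    for pw in pathways[:2]:
        r = pw.reactions[-1]
        for p in r.participants:
            if p.side == "product" and p.role == "main":
                p.compound_id = SHARED_POOL[0]
                break


def generate_omics(
    collection: PathwayCollection,
    data_type: str,
    n_columns: int,
    coverage: float = 1.0,
    seed: int = 0,
) -> OmicsDataset:
    """A seeded omics table over ~``coverage`` of the matching entities.

    Values are standard-normal draws; ~5% of cells are missing.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rng = random.Random(seed)
    if data_type == "gene":
        ids = sorted(
            {g for pw in collection.pathways for r in pw.reactions for g in r.gene_ids}
        )
    elif data_type == "metabolite":
        ids = sorted(collection.compound_ids())
    elif data_type == "flux":
        ids = sorted(
            {r.id for pw in collection.pathways for r in pw.reactions}
        )
    else:
        raise ValueError(f"unknown data type {data_type!r}")
    k = max(1, round(coverage * len(ids)))
    chosen = sorted(rng.sample(ids, k))
    columns = [f"t{j}" for j in range(n_columns)]
    rows = {
        entity: [
            None if rng.random() < 0.05 else round(rng.gauss(0.0, 1.0), 6)
            for _ in range(n_columns)
        ]
        for entity in chosen
    }
    return OmicsDataset(data_type=data_type, columns=columns, rows=rows)


def write_omics_tsv(dataset: OmicsDataset, path) -> None:
    lines = ["id\t" + "\t".join(dataset.columns)]
    for entity, vec in dataset.rows.items():
        cells = ["" if v is None else repr(v) for v in vec]
        lines.append(entity + "\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture_dir(
    out_dir,
    n_pathways: int = 5,
    shared_compound_rate: float = 0.3,
    seed: int = 0,
) -> dict[str, str]:
    """Write a complete fixture set (collection, omics tables, scheme)."""
    from .io import write_pathway_collection
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection = generate_collection(n_pathways, shared_compound_rate, seed)
    files = {}
    cpath = out / "collection.json"
    write_pathway_collection(collection, cpath)
    files["collection"] = str(cpath)
    for data_type in ("gene", "metabolite", "flux"):
        for n_cols, tag in ((1, "single"), (5, "series")):
            ds = generate_omics(collection, data_type, n_cols, 1.0, seed + n_cols)
            p = out / f"omics_{data_type}_{tag}.tsv"
            write_omics_tsv(ds, p)
            files[f"omics_{data_type}_{tag}"] = str(p)
    scheme = {
        "breakpoints": [-2.0, -1.0, 0.0, 1.0, 2.0],
        "colors": [
            "#313695", "#74add1", "#e0f3f8", "#fee090", "#f46d43", "#a50026",
        ],
        "missing_color": "#bbbbbb",
    }
    spath = out / "scheme.json"
    spath.write_text(json.dumps(scheme, indent=1), encoding="utf-8")
    files["scheme"] = str(spath)
    return files
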