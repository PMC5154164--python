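"""Shared fixtures: small hand-built pathways with known geometry plus
seeded generated collections."""

from __future__ import annotations

import pytest

from pathwaycollage.assembly import assemble_collage, connect_all
from pathwaycollage.fixtures import generate_collection, generate_omics
from pathwaycollage.layout import layout_pathway
from pathwaycollage.model import (
    ColorScheme,
    Compound,
    Pathway,
    PathwayCollection,
    Reaction,
    ReactionParticipant,
    StyleConfig,
)


def make_reaction(
    rid: str,
    sub: str,
    prod: str,
    sides=(),
    direction: str = "forward",
    genes=(),
    enzymes=(),
) -> Reaction:
    """A reaction with one main substrate/product and optional side
    participants given as (compound_id, side) pairs."""
    parts = [
        ReactionParticipant(compound_id=sub, side="substrate", role="main"),
        ReactionParticipant(compound_id=prod, side="product", role="main"),
    ]
    for cid, side in sides:
        parts.append(
            ReactionParticipant(compound_id=cid, side=side, role="side")
        )
    return Reaction(
        id=rid,
        participants=parts,
        direction=direction,
        enzyme_labels=list(enzymes) or [f"E-{rid}"],
        gene_ids=list(genes),
    )


def wrap_collection(*pathways: Pathway) -> PathwayCollection:
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
        pathways=list(pathways),
    )


@pytest.fixture
def linear_pathway() -> Pathway:
    """A -> B -> C -> D chain of three reactions."""
    return Pathway(
        id="PL",
        name="test chain",
        reactions=[
            make_reaction("R1", "A", "B", genes=["gA"]),
            make_reaction("R2", "B", "C", sides=[("NADP", "substrate")], genes=["gB"]),
            make_reaction("R3", "C", "D", genes=["gC", "gD"]),
        ],
        links=[("R1", "R2"), ("R2", "R3")],
        class_path=["Biosynthesis", "Amino Acids"],
    )


@pytest.fixture
def cyclic_pathway() -> Pathway:
    """Four reactions in a closed loop over C1..C4."""
    return Pathway(
        id="PC",
        name="test cycle",
        reactions=[
            make_reaction("Q1", "C1", "C2"),
            make_reaction("Q2", "C2", "C3"),
            make_reaction("Q3", "C3", "C4"),
            make_reaction("Q4", "C4", "C1"),
        ],
        links=[("Q1", "Q2"), ("Q2", "Q3"), ("Q3", "Q4"), ("Q4", "Q1")],
        class_path=["Generation of Precursor Metabolites and Energy"],
    )


@pytest.fixture
def branched_pathway() -> Pathway:
    """A -> B -> C with a second branch B -> D."""
    return Pathway(
        id="PB",
        name="test branch",
        reactions=[
            make_reaction("RAB", "A", "B"),
            make_reaction("RBC", "B", "C"),
            make_reaction("RBD", "B", "D"),
        ],
        links=[("RAB", "RBC"), ("RAB", "RBD")],
        class_path=["Degradation/Utilization/Assimilation"],
    )


@pytest.fixture
def small_collection(linear_pathway, branched_pathway) -> PathwayCollection:
    return wrap_collection(linear_pathway, branched_pathway)


@pytest.fixture
def gen_collection() -> PathwayCollection:
    return generate_collection(5, 0.4, seed=7)


@pytest.fixture
def gen_collage(gen_collection):
    layouts = [layout_pathway(pw) for pw in gen_collection.pathways]
    return assemble_collage(layouts, gen_collection.pathways, 1200.0, 20.0)


@pytest.fixture
def connected_collage(gen_collage):
    return connect_all(gen_collage)


@pytest.fixture
def scheme() -> ColorScheme:
    return ColorScheme(
        breakpoints=[-1.0, 0.0, 1.0],
        colors=["#000004", "#31688e", "#35b779", "#fde725"],
        missing_color="#bbbbbb",
    )


@pytest.fixture
def style() -> StyleConfig:
    return StyleConfig()
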