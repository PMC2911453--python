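"""Shared fixtures: tiny cover graphs and synthetic proteome helpers."""

from __future__ import annotations

import pytest

from txpselect.combinations import Epitope
from txpselect.covergraph import CoverGraph


def make_graph(cover_map: dict[str, list[str]], side: str = "c") -> CoverGraph:
    """Build a CoverGraph from epitope-name → covered-protein-list.

    Every edge gets its own peptide species, so none of these fixtures are
    affected by robinson semantics unless a test removes them explicitly.
    """
    edges = set()
    edge_peptides = {}
    proteins: set[str] = set()
    epitopes: set[Epitope] = set()
    for name, covered in cover_map.items():
        e = Epitope(sequence=name, side=side)
        epitopes.add(e)
        for p in covered:
            proteins.add(p)
            edges.add((e, p))
            edge_peptides[(e, p)] = frozenset({f"pep_{name}_{p}"})
    return CoverGraph(
        proteins=proteins, epitopes=epitopes, edges=edges, edge_peptides=edge_peptides
    )


@pytest.fixture
def star_graph() -> CoverGraph:
    """One dominant epitope covering everything, two redundant singletons."""
    return make_graph({"EAAA": ["P1", "P2", "P3"], "EBBB": ["P1"], "ECCC": ["P2"]})


@pytest.fixture
def pathological_graph() -> CoverGraph:
    """Classic greedy-suboptimal family: greedy picks 3 sets, optimum is 2.

    Six proteins; two 'column' epitopes covering three each (the optimum),
    and 'row' epitopes of sizes 4 and 2 arranged so greedy takes the big row
    first and then still needs both leftovers.
    """
    return make_graph(
        {
            "COLA": ["P1", "P2", "P3"],
            "COLB": ["P4", "P5", "P6"],
            "ROWA": ["P1", "P2", "P4", "P5"],
        }
    )
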