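"""Bipartite protein–epitope cover graph and solution scoring.

After filtering, the selection problem lives on a bipartite graph: protein
vertices on one side, epitope vertices on the other, with an edge wherever at
least one detectable combination links the pair. Choosing antibodies is then
a set-cover problem on this graph.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .combinations import CombinationSet, Epitope

__all__ = ["CoverGraph", "Solution", "build_graph", "remove_robinson", "score_solution"]

logger = logging.getLogger(__name__)


@dataclass
class CoverGraph:
    """Bipartite graph G = (P ∪ A, E) of proteins and epitopes.

    ``edge_peptides`` maps each (epitope, protein) edge to the set of
    detectable peptide sequences (molecular species) supporting it.
    ``uncoverable`` lists requested target proteins for which the filtered
    combination set offers no epitope at all.
    """

    proteins: set[str]
    epitopes: set[Epitope]
    edges: set[tuple[Epitope, str]]
    edge_peptides: dict[tuple[Epitope, str], frozenset[str]]
    uncoverable: set[str] = field(default_factory=set)

    def neighbors_of_epitope(self, epitope: Epitope) -> set[str]:
        return {p for (e, p) in self.edges if e == epitope}

    def adjacency(self) -> dict[Epitope, set[str]]:
        adj: dict[Epitope, set[str]] = {e: set() for e in self.epitopes}
        for e, p in self.edges:
            adj[e].add(p)
        return adj

    def protein_degrees(self) -> dict[str, int]:
        deg = {p: 0 for p in self.proteins}
        for _, p in self.edges:
            deg[p] += 1
        return deg

    def write_edges_tsv(self, path: str | Path) -> None:
        rows = [
            (e.sequence, e.side, p, ",".join(sorted(self.edge_peptides[(e, p)])))
            for (e, p) in sorted(
                self.edges, key=lambda ep: (ep[0].side, ep[0].sequence, ep[1])
            )
        ]
        pd.DataFrame(
            rows, columns=["epitope_sequence", "side", "protein", "supporting_peptides"]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class Solution:
    """A selected epitope set with its per-protein coverage bookkeeping."""

    selected: list[Epitope]
    cover_count: dict[str, int]
    coverage_score: float
    uncovered: set[str]

    @property
    def n_single_covered(self) -> int:
        return sum(1 for c in self.cover_count.values() if c == 1)

    @property
    def n_multi_covered(self) -> int:
        return sum(1 for c in self.cover_count.values() if c >= 2)

    def is_full_cover(self) -> bool:
        return not self.uncovered

    def summary(self) -> dict:
        return {
            "n_selected": len(self.selected),
            "coverage_score": self.coverage_score,
            "n_proteins": len(self.cover_count),
            "n_single_covered": self.n_single_covered,
            "n_multi_covered": self.n_multi_covered,
            "n_uncovered": len(self.uncovered),
        }

    def write_tsv(self, graph: "CoverGraph", path: str | Path) -> None:
        adj = graph.adjacency()
        rows = [
            (e.sequence, e.side, len(adj[e]), ",".join(sorted(adj[e])))
            for e in self.selected
        ]
        pd.DataFrame(
            rows, columns=["epitope_sequence", "side", "n_proteins_covered", "proteins"]
        ).to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def build_graph(
    cset: CombinationSet, targets: Optional[Iterable[str]] = None
) -> CoverGraph:
    """Build the cover graph from a *filtered* combination set.

    Only detectable combinations create edges. When ``targets`` is given, the
    protein side is restricted to targets present in the set; targets with no
    detectable combination are recorded as uncoverable. Epitope loads for
    filtering must already have been computed against the full background —
    restriction happens here, after filtering.
    """
    edge_peptides: dict[tuple[Epitope, str], set[str]] = {}
    for combo in cset.detectable():
        edge_peptides.setdefault((combo.epitope, combo.protein), set()).add(
            combo.peptide.sequence
        )

    present = {p for (_, p) in edge_peptides}
    uncoverable: set[str] = set()
    if targets is not None:
        targets = set(targets)
        uncoverable = targets - present
        keep = targets & present
        if not keep:
            raise ValueError(
                "no requested target protein has any detectable combination; "
                f"uncoverable targets: {sorted(uncoverable)}"
            )
        edge_peptides = {
            (e, p): peps for (e, p), peps in edge_peptides.items() if p in keep
        }
        if uncoverable:
            logger.warning(
                "targets without any detectable combination: %s",
                ", ".join(sorted(uncoverable)),
            )
        proteins = keep
    else:
        proteins = present

    edges = set(edge_peptides)
    epitopes = {e for (e, _) in edges}
    return CoverGraph(
        proteins=proteins,
        epitopes=epitopes,
        edges=edges,
        edge_peptides={k: frozenset(v) for k, v in edge_peptides.items()},
        uncoverable=uncoverable,
    )


def remove_robinson(graph: CoverGraph) -> CoverGraph:
    """Remove epitopes that capture only one peptide species from one protein.

    A one-peptide/one-protein ("robinson") antibody is never preferable to a
    broader one covering the same protein, so such epitopes are pruned before
    optimization. Guard: a robinson epitope that is its protein's only
    remaining cover is kept (removing it would orphan the protein); such
    cases are logged.
    """
    adj = graph.adjacency()
    degrees = graph.protein_degrees()

    def is_robinson(e: Epitope) -> bool:
        if len(adj[e]) != 1:
            return False
        species: set[str] = set()
        for p in adj[e]:
            species |= graph.edge_peptides[(e, p)]
        return len(species) == 1

    candidates = sorted(
        (e for e in graph.epitopes if is_robinson(e)),
        key=lambda e: (e.side, e.sequence),
    )

    removed: set[Epitope] = set()
    for e in candidates:
        protein = next(iter(adj[e]))
        if degrees[protein] <= 1:
            logger.info(
                "keeping robinson epitope %s-%s: sole cover of protein %s",
                e.side, e.sequence, protein,
            )
            continue
        removed.add(e)
        degrees[protein] -= 1

    edges = {(e, p) for (e, p) in graph.edges if e not in removed}
    return CoverGraph(
        proteins=set(graph.proteins),
        epitopes={e for e in graph.epitopes if e not in removed},
        edges=edges,
        edge_peptides={k: v for k, v in graph.edge_peptides.items() if k in edges},
        uncoverable=set(graph.uncoverable),
    )


def score_solution(graph: CoverGraph, selected: Sequence[Epitope]) -> Solution:
    """Score a selected epitope list against the graph.

    The coverage score is |L| / |P| — the number of antibodies needed per
    target protein; lower is better. Raises if a selected epitope is not a
    graph vertex.
    """
    missing = [e for e in selected if e not in graph.epitopes]
    if missing:
        raise ValueError(
            f"epitopes not in graph: {[(e.side, e.sequence) for e in missing]}"
        )
    adj = graph.adjacency()
    cover_count = {p: 0 for p in graph.proteins}
    for e in selected:
        for p in adj[e]:
            cover_count[p] += 1
    uncovered = {p for p, c in cover_count.items() if c == 0}
    score = len(selected) / len(graph.proteins) if graph.proteins else 0.0
    return Solution(
        selected=list(selected),
        cover_count=cover_count,
        coverage_score=score,
        uncovered=uncovered,
    )
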