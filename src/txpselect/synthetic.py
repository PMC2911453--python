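"""Seeded synthetic proteomes and cover-graph fixtures with planted structure.

Real proteomes exercise the pipeline through three structural motifs: groups
of proteins whose tryptic peptides share a terminal epitope (the reason TXP
antibodies pay off), near-isobaric peptide pairs inside one capture group
(what the weight filter removes), and promiscuous epitopes carried by very
many peptides (what the high-abundant-epitope filter removes). The generator
plants exactly these motifs into otherwise random tryptic peptides, so that
digesting the output recovers the planted peptides verbatim and each filter's
effect can be asserted against a manifest of planted truths.

Filler residues avoid K, R (no accidental cleavage sites), M (no accidental
methionine-filter hits), P (no accidental cleavage suppression) and all
ambiguity codes, so the planted structure survives digestion untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .combinations import Epitope
from .covergraph import CoverGraph
from .digest import ProteinRecord, default_mass_table, peptide_mass

__all__ = ["SyntheticSpec", "generate_proteome", "generate_cover_instance",
           "write_fasta", "write_manifest"]

#: residues safe to use as filler (no K/R/M/P, no ambiguity codes)
FILLER_ALPHABET = "ACDEFGHILNQSTVWY"

#: near-isobaric prefix pair: monoisotopic masses differ by ~1.068 Da
_ISOBARIC_PREFIXES = ("AYEQ", "HLEI")


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic proteome.

    ``shared_terminus_groups``: list of (epitope_sequence, side, n_proteins)
    — each group plants one tryptic peptide carrying the epitope into that
    many proteins. ``near_isobaric_pairs`` plants that many peptide pairs
    sharing a fresh C-terminal epitope with masses within 2 Da.
    ``abundant_epitope``: (sequence, load) plants ``load`` distinct peptides
    all ending in the given epitope.
    """

    n_proteins: int = 20
    protein_length_range: tuple[int, int] = (60, 120)
    shared_terminus_groups: list[tuple[str, str, int]] = field(default_factory=list)
    near_isobaric_pairs: int = 0
    abundant_epitope: Optional[tuple[str, int]] = None
    seed: int = 0
    filler_alphabet: str = FILLER_ALPHABET

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.protein_length_range
        if not (1 <= lo <= hi):
            raise ValueError("protein_length_range must satisfy 1 <= min <= max")
        for seq, side, count in self.shared_terminus_groups:
            _validate_planted_epitope(seq, side)
            if count < 1 or count > self.n_proteins:
                raise ValueError(
                    f"group size {count} for epitope {seq!r} must be in "
                    f"[1, n_proteins={self.n_proteins}]"
                )
        if self.abundant_epitope is not None:
            seq, load = self.abundant_epitope
            _validate_planted_epitope(seq, "c")
            if load < 1:
                raise ValueError("abundant epitope load must be >= 1")
        if self.near_isobaric_pairs < 0:
            raise ValueError("near_isobaric_pairs must be >= 0")


def _validate_planted_epitope(seq: str, side: str) -> None:
    if side not in ("n", "c"):
        raise ValueError(f"side must be 'n' or 'c', got {side!r}")
    if not seq:
        raise ValueError("planted epitope must be non-empty")
    if any(ch in "XBZJ" for ch in seq):
        raise ValueError(f"planted epitope {seq!r} contains an ambiguity code")
    if seq[0] == "P":
        raise ValueError(
            f"planted epitope {seq!r} starts with P: the preceding cleavage "
            "site would be suppressed"
        )
    body = seq[:-1] if side == "c" else seq
    for i, ch in enumerate(body):
        if ch in "KR" and (i + 1 >= len(seq) or seq[i + 1] != "P"):
            raise ValueError(
                f"planted epitope {seq!r} has an internal cleavage site at "
                f"position {i}: trypsin would split the planted peptide"
            )
    if side == "c" and seq[-1] not in "KR":
        raise ValueError(
            f"C-terminal planted epitope {seq!r} must end in K or R to be a "
            "tryptic peptide terminus"
        )


def _random_filler(rng: np.random.Generator, length: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _random_peptide(rng: np.random.Generator, alphabet: str,
                    min_len: int = 6, max_len: int = 14) -> str:
    n = int(rng.integers(min_len, max_len + 1))
    terminal = "K" if rng.random() < 0.5 else "R"
    return _random_filler(rng, n - 1, alphabet) + terminal


def generate_proteome(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], dict]:
    """Generate a proteome with planted structure plus a manifest of truths.

    Returns (records, manifest). The manifest records for every planted
    motif which proteins carry it and which peptide sequences realise it;
    the test suite and the acceptance script consume it instead of
    re-deriving ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    table = default_mass_table()
    alphabet = spec.filler_alphabet

    # per-protein list of planted peptides, to be mixed with random filler
    planted: dict[int, list[str]] = {i: [] for i in range(spec.n_proteins)}
    manifest: dict = {
        "seed": spec.seed,
        "groups": [],
        "near_isobaric": [],
        "abundant": None,
        "roles": {},
    }

    def protein_name(i: int) -> str:
        return f"SYN{i:04d}"

    # shared-terminus groups: members get one peptide carrying the epitope,
    # with prefix/suffix lengths staggered so member masses are well separated
    for g, (epi_seq, side, count) in enumerate(spec.shared_terminus_groups):
        members = [int(x) for x in rng.choice(spec.n_proteins, size=count,
                                              replace=False)]
        peptides = []
        for k, m in enumerate(members):
            pad = 6 + 2 * k  # staggered length => pairwise mass gaps >> 2 Da
            if side == "c":
                pep = _random_filler(rng, pad, alphabet) + epi_seq
            else:
                terminal = "K" if rng.random() < 0.5 else "R"
                pep = epi_seq + _random_filler(rng, pad, alphabet) + terminal
            planted[m].append(pep)
            peptides.append(pep)
        manifest["groups"].append(
            {"epitope": epi_seq, "side": side,
             "proteins": [protein_name(m) for m in members],
             "peptides": peptides}
        )

    # near-isobaric pairs: two peptides sharing a fresh C-terminal epitope,
    # identical but for prefixes whose monoisotopic masses differ by ~1.068 Da
    for k in range(spec.near_isobaric_pairs):
        epi = _random_filler(rng, 3, alphabet) + ("K" if rng.random() < 0.5 else "R")
        tail = _random_filler(rng, 3, alphabet) + epi
        pep_a = _ISOBARIC_PREFIXES[0] + tail
        pep_b = _ISOBARIC_PREFIXES[1] + tail
        hosts = [int(x) for x in rng.choice(spec.n_proteins, size=2, replace=False)]
        planted[hosts[0]].append(pep_a)
        planted[hosts[1]].append(pep_b)
        delta = abs(peptide_mass(pep_a, table) - peptide_mass(pep_b, table))
        manifest["near_isobaric"].append(
            {"epitope": epi, "side": "c",
             "proteins": [protein_name(h) for h in hosts],
             "peptides": [pep_a, pep_b], "mass_delta": delta}
        )

    # abundant epitope: `load` distinct peptides all ending in the epitope,
    # spread round-robin over the proteins, lengths staggered to keep masses apart
    if spec.abundant_epitope is not None:
        epi_seq, load = spec.abundant_epitope
        peptides = []
        for k in range(load):
            pep = _random_filler(rng, 4 + (k % 18), alphabet) + epi_seq
            host = k % spec.n_proteins
            planted[host].append(pep)
            peptides.append(pep)
        manifest["abundant"] = {"epitope": epi_seq, "side": "c", "load": load,
                                "peptides": peptides}

    lo, hi = spec.protein_length_range
    records: list[ProteinRecord] = []
    for i in range(spec.n_proteins):
        target_len = int(rng.integers(lo, hi + 1))
        parts = list(planted[i])
        rng.shuffle(parts)
        current = sum(len(p) for p in parts)
        while current < target_len:
            pep = _random_peptide(rng, alphabet)
            pos = int(rng.integers(0, len(parts) + 1))
            parts.insert(pos, pep)
            current += len(pep)
        if not parts:  # degenerate: tiny target length, no planted peptides
            parts = [_random_peptide(rng, alphabet)]
        sequence = "".join(parts)
        roles = sorted(planted[i])
        name = protein_name(i)
        manifest["roles"][name] = roles
        records.append(ProteinRecord(accession=name, sequence=sequence))

    return records, manifest


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    lines = []
    for r in records:
        lines.append(f">{r.accession}")
        for i in range(0, len(r.sequence), 60):
            lines.append(r.sequence[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def generate_cover_instance(
    n_proteins: int, n_epitopes: int, density: float, seed: int
) -> CoverGraph:
    """Random bipartite cover instance, feasible by construction.

    Every protein is guaranteed degree ≥ 1 (a random edge is added where the
    density draw left a protein isolated); epitopes that end up isolated are
    attached to one random protein so vertex counts match the request.
    """
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    if n_epitopes < 1:
        raise ValueError("n_epitopes must be >= 1")
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    epitopes = [Epitope(sequence=f"E{j:03d}", side="c") for j in range(n_epitopes)]

    adj = rng.random((n_proteins, n_epitopes)) < density
    for i in range(n_proteins):
        if not adj[i].any():
            adj[i, int(rng.integers(n_epitopes))] = True
    for j in range(n_epitopes):
        if not adj[:, j].any():
            adj[int(rng.integers(n_proteins)), j] = True

    edges = {
        (epitopes[j], proteins[i])
        for i in range(n_proteins)
        for j in range(n_epitopes)
        if adj[i, j]
    }
    edge_peptides = {
        (e, p): frozenset({f"PEP_{e.sequence}_{p}"}) for (e, p) in edges
    }
    return CoverGraph(
        proteins=set(proteins),
        epitopes=set(epitopes),
        edges=edges,
        edge_peptides=edge_peptides,
    )
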