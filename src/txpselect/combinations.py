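"""Enumeration of peptide–antibody combinations.

A TXP antibody recognises a short terminal sequence (the epitope) and pulls
down every tryptic peptide in the digest that carries it. A *combination*
links one protein, one of its peptides, a terminus side, and the terminal
epitope of a given length; the combination set over a whole digest is the raw
input to the detectability filter pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digest import Peptide

__all__ = [
    "Epitope",
    "Combination",
    "CombinationSet",
    "enumerate_combinations",
    "write_combinations_tsv",
    "read_combinations_tsv",
]

SIDES = ("n", "c")


@dataclass(frozen=True, order=True)
class Epitope:
    """A terminal epitope: the pair (sequence, side).

    The same sequence at opposite termini is two distinct epitopes, because
    a terminus-specific antibody only binds one end of a peptide.
    """

    sequence: str
    side: str  # "n" or "c"

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"epitope side must be 'n' or 'c', got {self.side!r}")
        if not self.sequence:
            raise ValueError("epitope sequence must be non-empty")

    def matches(self, peptide_sequence: str) -> bool:
        """True if the peptide carries this epitope at the declared terminus."""
        if self.side == "n":
            return peptide_sequence.startswith(self.sequence)
        return peptide_sequence.endswith(self.sequence)


def terminal_epitope(peptide_sequence: str, length: int, side: str) -> Epitope:
    """Read the epitope of the given length off one end of a peptide."""
    if length > len(peptide_sequence):
        raise ValueError("epitope longer than peptide")
    seq = peptide_sequence[:length] if side == "n" else peptide_sequence[-length:]
    return Epitope(sequence=seq, side=side)


@dataclass
class Combination:
    """The quadruple (protein, peptide, terminus side, epitope).

    ``detectable`` starts True; the weight filter clears it for combinations
    whose peptide cannot be told apart by mass from another peptide captured
    by the same antibody. Undetectable combinations are kept for traceability
    but never contribute to protein coverage.
    """

    protein: str
    peptide: Peptide
    epitope: Epitope
    detectable: bool = True

    def __post_init__(self) -> None:
        if not self.epitope.matches(self.peptide.sequence):
            raise ValueError(
                f"epitope {self.epitope.sequence!r} ({self.epitope.side}) does not "
                f"match peptide {self.peptide.sequence!r}"
            )


class CombinationSet:
    """An ordered collection of combinations with a by-epitope index.

    The subsets indexed by epitope are the capture groups C^e: everything a
    single antibody would pull down. Enumeration order (protein, peptide,
    length ascending, n before c) is preserved throughout the pipeline so
    runs are deterministic.
    """

    def __init__(self, combinations: Iterable[Combination] = ()) -> None:
        self.combinations: list[Combination] = list(combinations)
        self.by_epitope: dict[Epitope, list[Combination]] = {}
        for combo in self.combinations:
            self.by_epitope.setdefault(combo.epitope, []).append(combo)

    def __len__(self) -> int:
        return len(self.combinations)

    def __iter__(self):
        return iter(self.combinations)

    def detectable(self) -> list[Combination]:
        return [c for c in self.combinations if c.detectable]

    def epitopes(self, detectable_only: bool = True) -> set[Epitope]:
        if detectable_only:
            return {c.epitope for c in self.combinations if c.detectable}
        return set(self.by_epitope)

    def proteins(self, detectable_only: bool = True) -> set[str]:
        return {
            c.protein
            for c in self.combinations
            if c.detectable or not detectable_only
        }

    def counts(self) -> tuple[int, int, int]:
        """(#epitopes, #proteins, #combinations) over detectable combinations."""
        det = self.detectable()
        return (
            len({c.epitope for c in det}),
            len({c.protein for c in det}),
            len(det),
        )


def enumerate_combinations(
    digest: Mapping[str, Sequence[Peptide]],
    lengths: Iterable[int] = (4, 5),
    sides: Iterable[str] = SIDES,
) -> CombinationSet:
    """Enumerate every (protein, peptide, side, epitope) combination.

    For every peptide, every epitope length not exceeding the peptide length,
    and every requested terminus, exactly one combination is produced. A
    peptide exactly as long as the epitope is included — the whole peptide is
    then the epitope.
    """
    lengths = sorted(set(lengths))
    if not lengths or any(l < 1 for l in lengths):
        raise ValueError("epitope lengths must be a non-empty set of integers >= 1")
    sides = [s for s in SIDES if s in set(sides)]
    if not sides:
        raise ValueError("at least one terminus side ('n' or 'c') is required")

    combos: list[Combination] = []
    for accession, peptides in digest.items():
        for peptide in peptides:
            for length in lengths:
                if length > len(peptide.sequence):
                    continue
                for side in sides:
                    combos.append(
                        Combination(
                            protein=accession,
                            peptide=peptide,
                            epitope=terminal_epitope(peptide.sequence, length, side),
                        )
                    )
    return CombinationSet(combos)


_COLUMNS = [
    "protein",
    "peptide_index",
    "peptide_sequence",
    "peptide_mass",
    "side",
    "epitope_sequence",
    "detectable",
]


def write_combinations_tsv(cset: CombinationSet, path: str | Path) -> None:
    rows = [
        (
            c.protein,
            c.peptide.index_in_protein,
            c.peptide.sequence,
            "" if c.peptide.mass is None else f"{c.peptide.mass:.5f}",
            c.epitope.side,
            c.epitope.sequence,
            int(c.detectable),
        )
        for c in cset
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_combinations_tsv(path: str | Path) -> CombinationSet:
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein": str, "peptide_sequence": str, "epitope_sequence": str,
               "side": str},
    )
    combos = []
    for row in frame.itertuples(index=False):
        mass = None if pd.isna(row.peptide_mass) else float(row.peptide_mass)
        peptide = Peptide(
            parent_accession=str(row.protein),
            index_in_protein=int(row.peptide_index),
            sequence=str(row.peptide_sequence),
            mass=mass,
        )
        combos.append(
            Combination(
                protein=str(row.protein),
                peptide=peptide,
                epitope=Epitope(sequence=str(row.epitope_sequence), side=str(row.side)),
                detectable=bool(row.detectable),
            )
        )
    return CombinationSet(combos)
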