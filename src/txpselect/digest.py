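"""In-silico tryptic digestion and peptide mass computation.

The digest model is deliberately simple: trypsin cleaves after every lysine
(K) or arginine (R) that is not followed by proline (P), and the digest is
complete — no missed or mis-cleavages. Peptide masses default to monoisotopic
values, which is what a MALDI-TOF read-out of an immunoprecipitated peptide
fraction measures in practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pmass

__all__ = [
    "ProteinRecord",
    "Peptide",
    "MassTable",
    "read_fasta",
    "cleave_tryptic",
    "tryptic_digest",
    "digest_proteome",
    "peptide_mass",
    "write_digest_tsv",
    "read_digest_tsv",
]

#: residues whose mass is never computable (ambiguity codes)
AMBIGUOUS_RESIDUES = frozenset("XBZJ")

_WATER_MONO = _pmass.calculate_mass(formula="H2O")
_WATER_AVG = _pmass.calculate_mass(formula="H2O", average=True)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of the background proteome."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r} has an empty sequence")


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide, positioned within its parent protein.

    ``mass`` is None when any residue lacks a mass (ambiguity codes such as X).
    """

    parent_accession: str
    index_in_protein: int
    sequence: str
    mass: Optional[float]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MassTable:
    """Residue masses (Da) plus the mass of water added on hydrolysis."""

    residue_masses: Mapping[str, float]
    water_mass: float

    @classmethod
    def monoisotopic(cls, unknown: frozenset[str] = AMBIGUOUS_RESIDUES) -> "MassTable":
        """Standard monoisotopic residue masses (includes U and O).

        ``unknown`` lists residues to treat as mass-less; by default the
        ambiguity codes X, B, Z, J. Selenocysteine (U) and pyrrolysine (O)
        keep their standard masses unless added to ``unknown``.
        """
        masses = {k: v for k, v in _pmass.std_aa_mass.items()
                  if len(k) == 1 and k not in unknown}
        return cls(residue_masses=masses, water_mass=_WATER_MONO)

    @classmethod
    def average(cls, unknown: frozenset[str] = AMBIGUOUS_RESIDUES) -> "MassTable":
        """Average (chemical) residue masses derived from elemental composition."""
        masses = {
            aa: _pmass.calculate_mass(composition=comp, average=True)
            for aa, comp in _pmass.std_aa_comp.items()
            if len(aa) == 1 and aa not in unknown
        }
        return cls(residue_masses=masses, water_mass=_WATER_AVG)


_DEFAULT_TABLE: Optional[MassTable] = None


def default_mass_table() -> MassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = MassTable.monoisotopic()
    return _DEFAULT_TABLE


def _accession_from_header(header: str) -> str:
    """Extract the accession from a FASTA header token.

    UniProt-style pipe-delimited headers (``db|ACC|NAME``) yield ACC;
    anything else yields the first whitespace-delimited token.
    """
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA into a list of :class:`ProteinRecord`.

    Sequences are upper-cased and '*' stop characters stripped. Duplicate
    accessions and empty sequences raise ``ValueError``; an unreadable path
    raises the underlying ``OSError``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(entry.description or entry.id)
        sequence = str(entry.seq).upper().replace("*", "")
        if not sequence:
            raise ValueError(f"FASTA entry {accession!r} has an empty sequence")
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        records.append(ProteinRecord(accession=accession, sequence=sequence))
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def cleave_tryptic(sequence: str) -> list[str]:
    """Split a sequence after every K or R not followed by P (complete digest)."""
    fragments: list[str] = []
    start = 0
    for i, residue in enumerate(sequence[:-1]):
        if residue in "KR" and sequence[i + 1] != "P":
            fragments.append(sequence[start : i + 1])
            start = i + 1
    fragments.append(sequence[start:])
    return fragments


def peptide_mass(sequence: str, table: Optional[MassTable] = None) -> Optional[float]:
    """Peptide mass in Da: sum of residue masses plus water.

    Returns None when any residue is absent from the table (e.g. X).
    """
    if not sequence:
        raise ValueError("cannot compute the mass of an empty sequence")
    if table is None:
        table = default_mass_table()
    total = table.water_mass
    for residue in sequence:
        m = table.residue_masses.get(residue)
        if m is None:
            return None
        total += m
    return total


def tryptic_digest(
    protein: ProteinRecord, table: Optional[MassTable] = None
) -> list[Peptide]:
    """Complete tryptic digest of one protein, peptides in N→C order."""
    if table is None:
        table = default_mass_table()
    return [
        Peptide(
            parent_accession=protein.accession,
            index_in_protein=i,
            sequence=frag,
            mass=peptide_mass(frag, table),
        )
        for i, frag in enumerate(cleave_tryptic(protein.sequence))
    ]


def digest_proteome(
    proteins: Sequence[ProteinRecord], table: Optional[MassTable] = None
) -> dict[str, list[Peptide]]:
    """Digest every protein; returns accession → peptides, input order preserved."""
    if table is None:
        table = default_mass_table()
    return {p.accession: tryptic_digest(p, table) for p in proteins}


def write_digest_tsv(digest: Mapping[str, Sequence[Peptide]], path: str | Path) -> None:
    rows = [
        (p.parent_accession, p.index_in_protein, p.sequence,
         "" if p.mass is None else f"{p.mass:.5f}")
        for peptides in digest.values()
        for p in peptides
    ]
    frame = pd.DataFrame(rows, columns=["accession", "peptide_index", "sequence", "mass"])
    frame.to_csv(path, sep="\t", index=False)


def read_digest_tsv(path: str | Path) -> dict[str, list[Peptide]]:
    frame = pd.read_csv(path, sep="\t", dtype={"accession": str, "sequence": str})
    digest: dict[str, list[Peptide]] = {}
    for row in frame.itertuples(index=False):
        mass = None if pd.isna(row.mass) else float(row.mass)
        digest.setdefault(str(row.accession), []).append(
            Peptide(
                parent_accession=str(row.accession),
                index_in_protein=int(row.peptide_index),
                sequence=str(row.sequence),
                mass=mass,
            )
        )
    return digest
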