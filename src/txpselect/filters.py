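"""Detectability filter pipeline for peptide–antibody combinations.

Six filters remove combinations that a mass-spectrometric read-out could not
use, before the cover-graph optimization:

* ``unknown_positions`` — peptides whose mass cannot be computed (residue X
  or other ambiguity codes) are useless to the read-out.
* ``methionine`` — epitopes containing M are avoided because methionine
  oxidation can abolish antibody recognition.
* ``high_abundant_epitope`` — epitopes capturing more peptides than an
  antibody can resolve (load above a threshold) would be cluttered and
  insensitive; the whole capture group is dropped.
* ``weight`` — two different peptides captured by the same antibody whose
  masses lie within Δ_min of each other produce overlapping peaks; both are
  marked undetectable (the epitope survives if other peptides remain).
* ``length`` — peptides outside the spectrometer's detection range.
* ``stoplist`` — every epitope that occurs on a peptide of a high-abundant
  protein (actin, tubulin, ...) is banned outright, because the abundant
  protein's peptides would dominate the captured fraction.

Filters that score an epitope's capture group (high-abundant-epitope, weight)
must run before filters that change those groups, hence the hard ordering
high_abundant_epitope → weight → length. The unknown-positions, methionine
and stoplist filters commute freely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .combinations import Combination, CombinationSet

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_unknown_positions",
    "filter_methionine",
    "filter_high_abundant_epitope",
    "filter_weight",
    "filter_length",
    "filter_stoplist",
    "run_pipeline",
    "read_stoplist",
]

logger = logging.getLogger(__name__)

DEFAULT_FILTER_ORDER = (
    "unknown_positions",
    "methionine",
    "high_abundant_epitope",
    "weight",
    "length",
    "stoplist",
)

#: pairs (earlier, later) that any configured order must respect
_ORDER_CONSTRAINTS = (
    ("high_abundant_epitope", "weight"),
    ("weight", "length"),
)


@dataclass
class FilterConfig:
    """Thresholds for the filter pipeline.

    Defaults: epitope load cap 600 combinations, Δ_min 2.0 Da (the permissive
    end of the 2–10 Da MALDI-TOF range), peptide length window 8–30 residues.
    """

    max_epitope_load: int = 600
    delta_min: float = 2.0
    min_peptide_len: int = 8
    max_peptide_len: int = 30
    stoplist_accessions: frozenset[str] = frozenset()
    filter_order: tuple[str, ...] = DEFAULT_FILTER_ORDER

    def __post_init__(self) -> None:
        if self.delta_min <= 0:
            raise ValueError("delta_min must be positive")
        if not (1 <= self.min_peptide_len <= self.max_peptide_len):
            raise ValueError("peptide length window must satisfy 1 <= min <= max")
        if self.max_epitope_load < 1:
            raise ValueError("max_epitope_load must be >= 1")
        self.stoplist_accessions = frozenset(self.stoplist_accessions)
        validate_filter_order(self.filter_order)


def validate_filter_order(order: Sequence[str]) -> None:
    unknown = set(order) - set(DEFAULT_FILTER_ORDER)
    if unknown:
        raise ValueError(f"unknown filter names: {sorted(unknown)}")
    if len(set(order)) != len(order):
        raise ValueError("filter_order contains duplicates")
    pos = {name: i for i, name in enumerate(order)}
    for earlier, later in _ORDER_CONSTRAINTS:
        if earlier in pos and later in pos and pos[earlier] > pos[later]:
            raise ValueError(
                f"invalid filter order: {earlier!r} must precede {later!r} "
                "(capture-group statistics would otherwise be computed on a "
                "modified distribution)"
            )


@dataclass
class FilterReport:
    """Per-stage counts of epitopes, proteins and detectable combinations."""

    rows: list[tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, stage: str, cset: CombinationSet) -> None:
        n_epi, n_prot, n_comb = cset.counts()
        self.rows.append((stage, n_epi, n_prot, n_comb))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["filter", "n_epitopes", "n_proteins", "n_combinations"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_unknown_positions(cset: CombinationSet) -> CombinationSet:
    """Drop combinations whose peptide mass is unknown (contains X etc.)."""
    return CombinationSet(c for c in cset if c.peptide.mass is not None)


def filter_methionine(cset: CombinationSet) -> CombinationSet:
    """Drop combinations whose *epitope* contains methionine.

    Peptides carrying M outside the epitope are kept: the antibody does not
    touch those positions.
    """
    return CombinationSet(c for c in cset if "M" not in c.epitope.sequence)


def filter_high_abundant_epitope(
    cset: CombinationSet, max_load: int = 600
) -> CombinationSet:
    """Drop every combination of epitopes whose load exceeds ``max_load``.

    The load |C^e| is evaluated at this pipeline stage; the bound is strict
    (a load of exactly ``max_load`` survives).
    """
    if max_load < 1:
        raise ValueError("max_load must be >= 1")
    overloaded = {e for e, combos in cset.by_epitope.items() if len(combos) > max_load}
    return CombinationSet(c for c in cset if c.epitope not in overloaded)


def filter_weight(cset: CombinationSet, delta_min: float = 2.0) -> CombinationSet:
    """Mark near-isobaric peptides within each capture group undetectable.

    Within a capture group C^e, distinct peptide *sequences* are one
    molecular species each (the same sequence occurring in several proteins
    gives one peak). Any two species whose masses differ by strictly less
    than ``delta_min`` would overlap in the spectrum, so both are marked
    undetectable — the peak is ambiguous for both parties. Combinations stay
    in the set with ``detectable=False``; the epitope survives as long as one
    detectable combination remains.
    """
    if delta_min <= 0:
        raise ValueError("delta_min must be positive")
    conflicted: set[tuple[str, str, str]] = set()  # (epi seq, side, peptide seq)
    for epitope, combos in cset.by_epitope.items():
        species: dict[str, Optional[float]] = {}
        for c in combos:
            species.setdefault(c.peptide.sequence, c.peptide.mass)
        known = sorted(
            ((m, s) for s, m in species.items() if m is not None)
        )
        for (m1, s1), (m2, s2) in zip(known, known[1:]):
            if m2 - m1 < delta_min:
                conflicted.add((epitope.sequence, epitope.side, s1))
                conflicted.add((epitope.sequence, epitope.side, s2))
    if not conflicted:
        return CombinationSet(cset)
    out = []
    for c in cset:
        key = (c.epitope.sequence, c.epitope.side, c.peptide.sequence)
        if key in conflicted and c.detectable:
            c = Combination(c.protein, c.peptide, c.epitope, detectable=False)
        out.append(c)
    return CombinationSet(out)


def filter_length(
    cset: CombinationSet, min_len: int = 8, max_len: int = 30
) -> CombinationSet:
    """Drop combinations whose peptide length falls outside [min_len, max_len]."""
    if not (1 <= min_len <= max_len):
        raise ValueError("length window must satisfy 1 <= min <= max")
    return CombinationSet(
        c for c in cset if min_len <= len(c.peptide.sequence) <= max_len
    )


def filter_stoplist(
    cset: CombinationSet, stoplist: Iterable[str]
) -> CombinationSet:
    """Ban every epitope that occurs on a peptide of a stoplisted protein.

    All combinations carrying a banned epitope are removed, not just the
    stoplisted proteins' own: the antibody cannot tell the target's peptide
    from the abundant protein's.
    """
    stoplist = set(stoplist)
    if not stoplist:
        return CombinationSet(cset)
    present = {c.protein for c in cset}
    missing = stoplist - present
    if missing:
        logger.warning(
            "stoplist accessions absent from the combination set: %s",
            ", ".join(sorted(missing)),
        )
    banned = {c.epitope for c in cset if c.protein in stoplist}
    return CombinationSet(c for c in cset if c.epitope not in banned)


def run_pipeline(
    cset: CombinationSet, config: Optional[FilterConfig] = None
) -> tuple[CombinationSet, FilterReport]:
    """Apply the configured filters in order; returns the result and a report.

    The report's first row ("unfiltered") records the input counts; each
    following row records the counts after one stage, mirroring the usual
    filter-impact table layout.
    """
    if config is None:
        config = FilterConfig()
    validate_filter_order(config.filter_order)

    stages = {
        "unknown_positions": filter_unknown_positions,
        "methionine": filter_methionine,
        "high_abundant_epitope": lambda s: filter_high_abundant_epitope(
            s, config.max_epitope_load
        ),
        "weight": lambda s: filter_weight(s, config.delta_min),
        "length": lambda s: filter_length(
            s, config.min_peptide_len, config.max_peptide_len
        ),
        "stoplist": lambda s: filter_stoplist(s, config.stoplist_accessions),
    }

    report = FilterReport()
    report.record("unfiltered", cset)
    for name in config.filter_order:
        cset = stages[name](cset)
        report.record(name, cset)
    return cset, report


def read_stoplist(path: str | Path) -> frozenset[str]:
    """Read a stoplist file: one accession per line, '#' comments allowed."""
    accessions = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            accessions.add(line)
    return frozenset(accessions)
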