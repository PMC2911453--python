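"""The detectability filter pipeline."""

import numpy as np
import pytest

from txpselect.combinations import CombinationSet, Epitope, enumerate_combinations
from txpselect.digest import Peptide, peptide_mass
from txpselect.filters import (
    DEFAULT_FILTER_ORDER,
    FilterConfig,
    filter_high_abundant_epitope,
    filter_length,
    filter_methionine,
    filter_stoplist,
    filter_unknown_positions,
    filter_weight,
    read_stoplist,
    run_pipeline,
)


def _pep(acc, idx, seq):
    return Peptide(parent_accession=acc, index_in_protein=idx, sequence=seq,
                   mass=peptide_mass(seq) if not set(seq) & set("XBZJ") else None)


def _cset(*entries, lengths=(4,), sides=("c",)):
    """entries: (accession, peptide_sequence) pairs."""
    digest = {}
    for acc, seq in entries:
        digest.setdefault(acc, []).append(_pep(acc, len(digest.get(acc, [])), seq))
    return enumerate_combinations(digest, lengths, sides)


class TestUnknownPositions:
    def test_peptide_with_x_removed(self):
        cset = _cset(("P1", "AXLLGYR"), ("P2", "AYEQLGYR"))
        out = filter_unknown_positions(cset)
        assert {c.peptide.sequence for c in out} == {"AYEQLGYR"}

    def test_clean_set_is_identity(self):
        cset = _cset(("P1", "AYEQLGYR"), ("P2", "HLEILGYR"))
        assert len(filter_unknown_positions(cset)) == len(cset)


class TestMethionine:
    def test_methionine_in_epitope_removed(self):
        # C-terminal 4-mer epitope MGYR contains M
        cset = _cset(("P1", "AAEQMGYR"))
        assert len(filter_methionine(cset)) == 0

    def test_methionine_outside_epitope_kept(self):
        # peptide starts with M but the c-terminal epitope LGYR is clean
        cset = _cset(("P1", "MAYEQLGYR"))
        assert len(filter_methionine(cset)) == 1


class TestHighAbundantEpitope:
    def _loaded_cset(self, n):
        # n distinct peptides sharing c-terminal epitope GGGR
        entries = [(f"P{i}", "AADE"[: 1 + i % 4] * 2 + "GGGR") for i in range(n)]
        # ensure distinct sequences by varying prefix length
        entries = [(f"P{i}", "A" * (1 + i) + "GGGR") for i in range(n)]
        return _cset(*entries)

    def test_strictly_above_threshold_removed(self):
        cset = self._loaded_cset(11)
        out = filter_high_abundant_epitope(cset, max_load=10)
        assert Epitope("GGGR", "c") not in out.by_epitope

    def test_exactly_at_threshold_kept(self):
        cset = self._loaded_cset(10)
        out = filter_high_abundant_epitope(cset, max_load=10)
        assert len(out.by_epitope[Epitope("GGGR", "c")]) == 10

    def test_load_one_everywhere_is_identity(self):
        cset = _cset(("P1", "AYEQLGYR"), ("P2", "GGGGGGK"))
        assert len(filter_high_abundant_epitope(cset, max_load=1)) == len(cset)


class TestWeight:
    def test_near_isobaric_pair_marked_undetectable(self):
        cset = _cset(("P1", "AYEQLGYR"), ("P2", "HLEILGYR"))
        out = filter_weight(cset, delta_min=2.0)
        assert all(not c.detectable for c in out)
        # combinations retained for traceability, not dropped
        assert len(out) == 2

    def test_pair_survives_a_tighter_tolerance(self):
        cset = _cset(("P1", "AYEQLGYR"), ("P2", "HLEILGYR"))
        out = filter_weight(cset, delta_min=1.0)  # Δ = 1.068 >= 1.0
        assert all(c.detectable for c in out)

    def test_identical_peptide_from_two_proteins_is_one_species(self):
        cset = _cset(("P1", "AYEQLGYR"), ("P2", "AYEQLGYR"))
        out = filter_weight(cset, delta_min=2.0)
        assert all(c.detectable for c in out)

    def test_conflict_is_scoped_to_the_capture_group(self):
        # same masses but different epitopes never conflict
        cset = _cset(("P1", "AYEQLGYR"), ("P2", "HLEIGLYR"))
        out = filter_weight(cset, delta_min=2.0)
        assert all(c.detectable for c in out)

    def test_transitive_chain_all_removed(self):
        # three peptides in one group with consecutive gaps < delta_min
        a, b, c = "GGGGGGGR", "AGGGGGGR", "GAGGGGGR"
        cset = _cset(("P1", a), ("P2", b), ("P3", c), lengths=(3,))
        masses = sorted(peptide_mass(s) for s in (a, b, c))
        assert masses[1] - masses[0] < 75 and masses[2] - masses[1] < 75
        out = filter_weight(cset, delta_min=75.0)
        assert all(not x.detectable for x in out)


class TestLength:
    @pytest.mark.parametrize("length,kept", [(7, False), (8, True), (30, True), (31, False)])
    def test_inclusive_window(self, length, kept):
        seq = "A" * (length - 1) + "R"
        cset = _cset(("P1", seq))
        out = filter_length(cset, 8, 30)
        assert (len(out) == 1) is kept


class TestStoplist:
    def test_shared_epitope_banned_everywhere(self):
        # ACTB and the target share the c-terminal epitope LGYR
        cset = _cset(("ACTB", "AYEQLGYR"), ("TGT1", "HLEILGYR"), ("TGT2", "GGGGGGGK"))
        out = filter_stoplist(cset, {"ACTB"})
        assert {c.protein for c in out} == {"TGT2"}

    def test_empty_stoplist_identity(self):
        cset = _cset(("P1", "AYEQLGYR"))
        assert len(filter_stoplist(cset, set())) == len(cset)

    def test_absent_accession_warns_not_fails(self, caplog):
        cset = _cset(("P1", "AYEQLGYR"))
        with caplog.at_level("WARNING"):
            out = filter_stoplist(cset, {"NOPE"})
        assert len(out) == len(cset)
        assert "NOPE" in caplog.text

    def test_stoplist_file_parsing(self, tmp_path):
        f = tmp_path / "stop.txt"
        f.write_text("# abundant proteins\nACTB\nTUBB # tubulin\n\n")
        assert read_stoplist(f) == {"ACTB", "TUBB"}


class TestPipeline:
    def test_misordered_pipeline_rejected_before_any_work(self):
        order = ("unknown_positions", "methionine", "weight",
                 "high_abundant_epitope", "length", "stoplist")
        with pytest.raises(ValueError, match="must precede"):
            FilterConfig(filter_order=order)

    def test_length_before_weight_rejected(self):
        order = ("length", "weight", "high_abundant_epitope")
        with pytest.raises(ValueError, match="must precede"):
            FilterConfig(filter_order=order)

    def test_empty_input_gives_zero_report(self):
        out, report = run_pipeline(CombinationSet())
        assert len(out) == 0
        frame = report.to_frame()
        assert (frame[["n_epitopes", "n_proteins", "n_combinations"]] == 0).all().all()
        assert list(frame["filter"]) == ["unfiltered", *DEFAULT_FILTER_ORDER]

    def test_counts_monotonically_non_increasing(self):
        rng = np.random.default_rng(11)
        alphabet = "ACDEFGHIKLMNPQRSTVWXY"
        entries = [
            (f"P{i}", "".join(rng.choice(list(alphabet), size=12)) + "R")
            for i in range(40)
        ]
        cset = _cset(*entries, lengths=(4, 5), sides=("n", "c"))
        _, report = run_pipeline(cset, FilterConfig(max_epitope_load=3))
        counts = report.to_frame()["n_combinations"].tolist()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_order_free_filters_commute(self):
        rng = np.random.default_rng(7)
        alphabet = "ACDEFGHIKLMNPQRSTVWXY"
        entries = [
            (f"P{i}", "".join(rng.choice(list(alphabet), size=10)) + "K")
            for i in range(30)
        ]
        cset = _cset(*entries, lengths=(4,), sides=("n", "c"))
        stop = {"P0", "P5"}

        def signature(c):
            return (c.protein, c.peptide.sequence, c.epitope.side,
                    c.epitope.sequence, c.detectable)

        import itertools
        results = []
        steps = {
            "u": filter_unknown_positions,
            "m": filter_methionine,
            "s": lambda s: filter_stoplist(s, stop),
        }
        for perm in itertools.permutations("ums"):
            out = cset
            for name in perm:
                out = steps[name](out)
            results.append(sorted(signature(c) for c in out))
        assert all(r == results[0] for r in results)

    def test_permissive_settings_are_identity_on_clean_input(self):
        """With the thresholds wide open the pipeline changes nothing."""
        entries = [("P1", "AYEQLGYR"), ("P2", "HLEIGGGK"), ("P3", "CCDDEEFFGGR")]
        cset = _cset(*entries, lengths=(4, 5), sides=("n", "c"))
        config = FilterConfig(
            max_epitope_load=10**9,
            delta_min=1e-9,
            min_peptide_len=1,
            max_peptide_len=10**6,
        )
        out, _ = run_pipeline(cset, config)
        assert len(out) == len(cset)
        assert all(c.detectable for c in out)

    def test_report_row_order_matches_configured_order(self):
        cset = _cset(("P1", "AYEQLGYR"))
        _, report = run_pipeline(cset)
        assert list(report.to_frame()["filter"]) == [
            "unfiltered", *DEFAULT_FILTER_ORDER
        ]
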