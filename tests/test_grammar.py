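import pytest
from hypothesis import given
from hypothesis import strategies as st

from segtail.grammar import (
    ADENINE,
    SPACER,
    BUILTIN_PATTERNS,
    PatternError,
    Segment,
    TailDesign,
    design_from_sequence,
    design_report,
    get_builtin,
    is_novel_design_compliant,
    longest_adenine_run,
    parse_pattern,
    render_sequence,
    total_length,
)


class TestParsePattern:
    def test_homopolymer(self):
        d = parse_pattern("A90")
        assert len(d.segments) == 1
        assert d.segments[0].kind == ADENINE
        assert d.segments[0].length == 90

    def test_compact_repeated_groups(self):
        d = parse_pattern("A30(CA15)11")
        adenines = [s for s in d.segments if s.kind == ADENINE]
        spacers = [s for s in d.segments if s.kind == SPACER]
        assert len(adenines) == 12
        assert [s.length for s in adenines] == [30] + [15] * 11
        assert len(spacers) == 11
        assert all(s.sequence == "C" for s in spacers)

    def test_explicit_notation_with_long_spacer(self):
        d = parse_pattern("A30-GCATATGACT-A70")
        kinds = [s.kind for s in d.segments]
        assert kinds == [ADENINE, SPACER, ADENINE]
        assert d.segments[1].sequence == "GCATATGACT"
        assert (d.segments[0].length, d.segments[2].length) == (30, 70)

    def test_multibase_spacer_in_compact_group(self):
        d = parse_pattern("A20(GCA10)3")
        spacers = [s for s in d.segments if s.kind == SPACER]
        assert [s.sequence for s in spacers] == ["GC"] * 3

    def test_case_and_u_t_interchangeable(self):
        assert parse_pattern("a30(cu a15)2").segments == parse_pattern("A30(CTA15)2").segments

    @pytest.mark.parametrize("bad", ["", "   ", "A30(CA15)0", "A30(C)3", "30A", "A30(XA5)2", "A30-QQ-A5"])
    def test_malformed_patterns_raise(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad)

    def test_parse_error_names_offending_token(self):
        with pytest.raises(PatternError, match="QQ"):
            parse_pattern("A30-QQ-A5")

    def test_all_adenine_spacer_rejected(self):
        with pytest.raises(PatternError):
            parse_pattern("A30(AA15)2")

    def test_adjacent_spacers_merge(self):
        # zero-length tract inside a group puts spacers back to back
        d = parse_pattern("A30(CA0)3")
        spacers = [s for s in d.segments if s.kind == SPACER]
        assert len(spacers) == 1
        assert spacers[0].sequence == "CCC"
        d2 = parse_pattern("A10-GC-TT-A5")
        assert [s.sequence for s in d2.segments if s.kind == SPACER] == ["GCTT"]

    def test_raw_sequence_input(self):
        d = parse_pattern("AAACAAAA")
        assert [(s.kind, s.length) for s in d.segments] == [
            (ADENINE, 3),
            (SPACER, 1),
            (ADENINE, 4),
        ]


class TestLengthAndRuns:
    @pytest.mark.parametrize(
        "pattern,expected",
        [("A30(CA15)11", 206), ("A30(CA15)6", 126), ("A1", 1), ("A20(CA20)5", 125)],
    )
    def test_total_length(self, pattern, expected):
        assert total_length(parse_pattern(pattern)) == expected

    @pytest.mark.parametrize(
        "pattern,expected",
        [("A30(CA15)11", 30), ("A90", 90), ("A30-GCATATGACT-A70", 70)],
    )
    def test_longest_adenine_run(self, pattern, expected):
        assert longest_adenine_run(parse_pattern(pattern)) == expected

    def test_run_joined_through_spacer_adenines(self):
        # spacer GA followed by a 10-tract: the spacer's A extends the run
        d = parse_pattern("A5-GA-A10")
        assert longest_adenine_run(d) == 11


class TestRender:
    def test_dna_sense(self):
        assert render_sequence(parse_pattern("A3")) == "AAA"
        assert (
            render_sequence(parse_pattern("A30-GCATATGACT-A70"))
            == "A" * 30 + "GCATATGACT" + "A" * 70
        )

    def test_dna_antisense_is_reverse_complement(self):
        assert render_sequence(parse_pattern("A3"), "DNA", "antisense") == "TTT"
        assert (
            render_sequence(parse_pattern("A2-GC-A1"), "DNA", "antisense") == "TGCTT"
        )

    def test_rna_uses_u(self):
        assert render_sequence(parse_pattern("A2(TA2)1"), "RNA") == "AAUAA"

    def test_antisense_rna_rejected(self):
        with pytest.raises(ValueError):
            render_sequence(parse_pattern("A3"), "RNA", "antisense")


class TestReport:
    def test_segmented_design_counts(self):
        rep = design_report(parse_pattern("A30(CA15)6"))
        assert rep["total_length"] == 126
        assert rep["adenine_count"] == 120
        assert rep["n_spacers"] == 6
        assert rep["longest_adenine_run"] == 30
        assert rep["has_5prime_A30"] is True

    def test_no_leading_a30_flag(self):
        assert design_report(parse_pattern("A10(CA10)11"))["has_5prime_A30"] is False

    def test_homopolymer_report(self):
        rep = design_report(parse_pattern("A90"))
        assert rep["n_spacers"] == 0
        assert rep["has_5prime_A30"] is True
        assert rep["novel_design_compliant"] is False  # 90 > 45-nt tract range

    def test_segment_table_half_open_coordinates(self):
        table = design_report(parse_pattern("A30-GCATATGACT-A70"))["segments"]
        assert list(table["start"]) == [0, 30, 40]
        assert list(table["end"]) == [30, 40, 110]

    def test_compliance_flags(self):
        assert is_novel_design_compliant(parse_pattern("A30(CA15)11"))
        assert not is_novel_design_compliant(parse_pattern("A30-GCATATGACT-A70"))


class TestBuiltins:
    def test_known_lengths(self):
        assert total_length(get_builtin("R1")) == 90
        assert total_length(get_builtin("R2")) == 110
        assert total_length(get_builtin("S14")) == 206
        assert total_length(get_builtin("S8")) == 126

    def test_design_set_length_range(self):
        novel = [get_builtin(n) for n in BUILTIN_PATTERNS if n.startswith("S")]
        lengths = [total_length(d) for d in novel]
        assert max(lengths) == 206
        assert all(120 <= x <= 206 for x in lengths)

    def test_unknown_builtin(self):
        with pytest.raises(KeyError):
            get_builtin("S99")


# --- property tests -------------------------------------------------------

# compact patterns whose spacers contain no adenine: the only case where the
# raw-sequence segmentation can recover the design exactly
compact_patterns = st.builds(
    lambda head, groups: f"A{head}" + "".join(
        f"({sp}A{ln}){k}" for sp, ln, k in groups
    ),
    st.integers(1, 60),
    st.lists(
        st.tuples(
            st.text(alphabet="CGT", min_size=1, max_size=6),
            st.integers(1, 40),
            st.integers(1, 4),
        ),
        max_size=4,
    ),
)


@given(compact_patterns)
def test_roundtrip_parse_render_parse(pattern):
    d = parse_pattern(pattern)
    rendered = render_sequence(d)
    d2 = parse_pattern(rendered)
    assert d2.segments == d.segments
    assert render_sequence(d2) == rendered


@given(compact_patterns)
def test_total_length_matches_rendered_sequence(pattern):
    d = parse_pattern(pattern)
    assert total_length(d) == len(render_sequence(d))


@given(compact_patterns)
def test_run_and_count_orderings(pattern):
    d = parse_pattern(pattern)
    rep = design_report(d)
    assert rep["longest_adenine_run"] <= rep["adenine_count"] <= rep["total_length"]


def test_rendered_sequence_roundtrips_even_with_adenine_spacers():
    # segmentation differs (the spacer's A's split it) but content is exact
    d = parse_pattern("A30-GCATATGACT-A70")
    rendered = render_sequence(d)
    assert render_sequence(parse_pattern(rendered)) == rendered
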