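"""CIF syntax layer: parsing, serialization, round-trip guarantees."""

import string

import pytest
from hypothesis import given, settings, strategies as st

from sascifio.cif import (
    Category,
    CifFile,
    CifSyntaxError,
    CifValue,
    CifWriteError,
    DataBlock,
    INAPPLICABLE,
    MISSING,
    get_column,
    parse_cif,
    set_category,
    write_cif,
)


class TestParse:
    def test_minimal_file(self):
        f = parse_cif("data_MAIN\n_sas_scan.title 'Lysozyme run'")
        assert [b.name for b in f.blocks] == ["MAIN"]
        assert f.blocks[0]["sas_scan"].scalar("title") == "Lysozyme run"

    def test_smallest_loop(self):
        f = parse_cif("data_A\nloop_\n_c.x\n_c.y\n1 2\n3 4")
        cat = f.blocks[0]["c"]
        assert cat.is_loop
        assert cat.item_names == ["x", "y"]
        assert cat.n_rows == 2

    def test_loop_arity_rejected(self):
        with pytest.raises(CifSyntaxError, match="multiple"):
            parse_cif("data_A\nloop_\n_c.x\n_c.y\n1 2 3")

    def test_item_before_block_rejected(self):
        with pytest.raises(CifSyntaxError, match="data_"):
            parse_cif("_c.x 1")

    def test_unterminated_semicolon_block(self):
        with pytest.raises(CifSyntaxError, match="semicolon"):
            parse_cif("data_A\n_c.x\n;abc\ndef")

    def test_unterminated_quote(self):
        with pytest.raises(CifSyntaxError, match="quote"):
            parse_cif("data_A\n_c.x 'oops")

    def test_comments_discarded_outside_quotes(self):
        f = parse_cif("data_A # trailing\n_c.x 'a # b' # real comment\n")
        assert f.blocks[0]["c"].scalar("x") == "a # b"

    def test_semicolon_text_verbatim(self):
        f = parse_cif("data_A\n_c.x\n;line1\n line2\n;\n")
        assert f.blocks[0]["c"].scalar("x") == "line1\n line2"

    def test_placeholders(self):
        f = parse_cif("data_A\n_c.a ?\n_c.b .\n_c.c '?'")
        cat = f.blocks[0]["c"]
        assert cat["a"][0] is MISSING or cat["a"][0] == MISSING
        assert cat["b"][0] == INAPPLICABLE
        assert cat["c"][0] == CifValue.of("?")

    def test_duplicate_category_rejected(self):
        with pytest.raises(CifSyntaxError, match="once"):
            parse_cif("data_A\nloop_\n_c.x\n1\nloop_\n_c.y\n2")


class TestWrite:
    def test_quoting_of_spaces(self):
        f = CifFile([DataBlock("A", [Category("c", {"x": ["two words"]})])])
        assert "'two words'" in write_cif(f)

    def test_multiline_uses_semicolon_block(self):
        f = CifFile([DataBlock("A", [Category("c", {"x": ["line1\nline2"]})])])
        assert "\n;line1\nline2\n;" in write_cif(f)

    def test_unrepresentable_value_raises(self):
        f = CifFile([DataBlock("A", [Category("c", {"x": ["a\n;b"]})])])
        with pytest.raises(CifWriteError):
            write_cif(f)

    def test_placeholder_text_is_quoted(self):
        f = CifFile([DataBlock("A", [Category("c", {"x": ["?"]})])])
        text = write_cif(f)
        assert "'?'" in text
        assert parse_cif(text).blocks[0]["c"]["x"][0] == CifValue.of("?")

    def test_idempotent_serialization(self):
        text = "data_A\nloop_\n_c.x\n_c.y\n1 'a b'\n? .\n_d.z ?\n"
        once = write_cif(parse_cif(text))
        assert write_cif(parse_cif(once)) == once


class TestAccessors:
    @pytest.fixture()
    def file(self):
        return parse_cif(
            "data_MAIN\n_sas_scan.title 'Lysozyme run'\n"
            "loop_\n_c.x\n_c.y\n1 2\n3 4\n"
        )

    def test_get_scalar_column(self, file):
        assert [v.text for v in get_column(file, "MAIN", "sas_scan", "title")] == [
            "Lysozyme run"
        ]

    def test_absent_is_none_not_error(self, file):
        assert get_column(file, "MAIN", "nope", "x") is None
        assert get_column(file, "NOPE", "c", "x") is None
        assert get_column(file, "MAIN", "c", "nope") is None

    def test_loop_column_order(self, file):
        assert [v.text for v in get_column(file, "MAIN", "c", "y")] == ["2", "4"]

    def test_lookup_case_insensitive(self, file):
        assert get_column(file, "main", "SAS_SCAN", "Title") is not None

    def test_set_category_scalar(self):
        f = CifFile([DataBlock("MAIN")])
        set_category(f, "MAIN", "sas_result", {"Rg_from_PR": ["38.7"]})
        assert f.blocks[0]["sas_result"].scalar("rg_from_pr") == "38.7"

    def test_set_twice_replaces(self):
        f = CifFile([DataBlock("MAIN")])
        set_category(f, "MAIN", "sas_result", {"dmax": ["100"]})
        set_category(f, "MAIN", "sas_result", {"dmax": ["120"]})
        assert len(f.blocks[0].categories) == 1
        assert f.blocks[0]["sas_result"].scalar("dmax") == "120"

    def test_ragged_columns_rejected(self):
        f = CifFile([DataBlock("MAIN")])
        with pytest.raises(ValueError, match="ragged"):
            set_category(f, "MAIN", "c", {"x": ["1", "2", "3"], "y": ["1", "2"]},
                         is_loop=True)


# --- property tests -------------------------------------------------------

_name = st.from_regex(r"[a-z][a-z0-9_]{0,8}", fullmatch=True)
_plain = st.text(
    alphabet=string.ascii_letters + string.digits + " _'\"#.?$-()[]",
    max_size=18,
)
_multiline = st.lists(
    st.text(alphabet=string.ascii_letters + " '\"", max_size=8).filter(
        lambda s: not s.startswith(";")
    ),
    min_size=2, max_size=3,
).map("\n".join)
_value = st.one_of(
    _plain.map(CifValue.of),
    _multiline.map(CifValue.of),
    st.just(MISSING),
    st.just(INAPPLICABLE),
)


@st.composite
def cif_files(draw):
    blocks = []
    for bi in range(draw(st.integers(1, 3))):
        cats = []
        cat_names = draw(st.lists(_name, min_size=1, max_size=3, unique=True))
        for cname in cat_names:
            items = draw(st.lists(_name, min_size=1, max_size=3, unique=True))
            is_loop = draw(st.booleans())
            n_rows = draw(st.integers(1, 3)) if is_loop else 1
            cols = {
                item: [draw(_value) for _ in range(n_rows)] for item in items
            }
            cats.append(Category(cname, cols, is_loop=is_loop))
        blocks.append(DataBlock(f"B{bi}", cats))
    return CifFile(blocks)


@settings(max_examples=120, derandomize=True, deadline=None)
@given(cif_files())
def test_roundtrip_identity(file):
    """parse(write(F)) reproduces blocks, categories, values and order."""
    assert parse_cif(write_cif(file)) == file


@settings(max_examples=120, derandomize=True, deadline=None)
@given(cif_files())
def test_write_is_byte_stable(file):
    once = write_cif(file)
    assert write_cif(parse_cif(once)) == once


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    items=st.lists(_name, min_size=1, max_size=4, unique=True),
    n_values=st.integers(1, 12),
)
def test_loop_arity_property(items, n_values):
    """Every loop whose value count is not a multiple of its item count fails."""
    body = "data_A\nloop_\n"
    body += "".join(f"_c.{i}\n" for i in items)
    body += " ".join(["1"] * n_values)
    if n_values % len(items) == 0:
        parsed = parse_cif(body)
        assert parsed.blocks[0]["c"].n_rows == n_values // len(items)
    else:
        with pytest.raises(CifSyntaxError):
            parse_cif(body)


def test_gemmi_reads_our_output(entry):
    """Independent CIF oracle: gemmi parses our serialization identically."""
    gemmi = pytest.importorskip("gemmi")
    from sascifio.model import assemble_entry

    text = write_cif(assemble_entry(entry))
    doc = gemmi.cif.read_string(text)
    ours = parse_cif(text)
    assert [b.name for b in doc] == [b.name for b in ours.blocks]
    block = doc[0]
    mine = ours.blocks[0]
    assert block.find_value("_sas_scan.title").strip("'\"") == mine[
        "sas_scan"
    ].scalar("title")
    s_col = [x for x in block.find_loop("_sas_scan_intensity.momentum_transfer")]
    assert s_col == [v.text for v in mine["sas_scan_intensity"]["momentum_transfer"]]
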