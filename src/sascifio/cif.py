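"""Order-preserving CIF 1.1 reader and writer.

CIF (crystallographic information file) is a line-oriented text format built
from ``data_`` blocks holding ``_category.keyword value`` pairs and ``loop_``
tables.  This module implements the data-file subset used by sasCIF and
mmCIF data files: no save frames, no nested loops, no CIF2 bracket values.

The in-memory model (:class:`CifFile` / :class:`DataBlock` /
:class:`Category`) keeps blocks, categories, items and rows in insertion
order, so a parse → serialize cycle reproduces the original layout and a
serialize → parse cycle reproduces the original model.  Values are plain
text plus the two CIF placeholders: ``?`` (missing) and ``.``
(inapplicable), modelled explicitly so that a *quoted* ``'?'`` never
collapses into a placeholder on a round trip.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "CifSyntaxError",
    "CifWriteError",
    "ValueKind",
    "CifValue",
    "MISSING",
    "INAPPLICABLE",
    "Category",
    "DataBlock",
    "CifFile",
    "parse_cif",
    "write_cif",
    "get_column",
    "set_category",
]


class CifSyntaxError(ValueError):
    """Malformed CIF input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CifWriteError(ValueError):
    """A value cannot be represented in CIF 1.1 syntax."""


class ValueKind(Enum):
    TEXT = "text"
    MISSING = "missing"
    INAPPLICABLE = "inapplicable"


@dataclass(frozen=True)
class CifValue:
    """One CIF item value: text, or one of the two placeholders."""

    kind: ValueKind
    text: str = ""

    @staticmethod
    def of(text: str) -> "CifValue":
        return CifValue(ValueKind.TEXT, text)

    def as_text(self, default: str | None = None) -> str | None:
        """The text payload, or *default* for either placeholder."""
        return self.text if self.kind is ValueKind.TEXT else default

    @property
    def is_placeholder(self) -> bool:
        return self.kind is not ValueKind.TEXT

    def __repr__(self) -> str:  # compact, for test diffs
        if self.kind is ValueKind.TEXT:
            return f"CifValue({self.text!r})"
        return f"CifValue(<{self.kind.value}>)"


MISSING = CifValue(ValueKind.MISSING)
INAPPLICABLE = CifValue(ValueKind.INAPPLICABLE)


def _as_value(v: "CifValue | str | float | int | None") -> CifValue:
    if isinstance(v, CifValue):
        return v
    if v is None:
        return MISSING
    return CifValue.of(str(v))


class Category:
    """A named set of items; scalar (one row) or a ``loop_`` table.

    Columns are parallel lists of :class:`CifValue`, one list per item, all
    of equal length.  Item names are stored lowercase; lookups are
    case-insensitive.
    """

    def __init__(
        self,
        name: str,
        columns: Mapping[str, Sequence["CifValue | str | float | int | None"]] | None = None,
        is_loop: bool = False,
    ):
        self.name = name.lower()
        self.is_loop = is_loop
        self._columns: dict[str, list[CifValue]] = {}
        if columns:
            for item, col in columns.items():
                self._columns[item.lower()] = [_as_value(v) for v in col]
        self._check()

    def _check(self) -> None:
        lengths = {len(c) for c in self._columns.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"category {self.name}: ragged columns (lengths {sorted(lengths)})"
            )
        if not self.is_loop and lengths and lengths != {1}:
            raise ValueError(
                f"category {self.name}: scalar category must have exactly one row"
            )

    @property
    def item_names(self) -> list[str]:
        return list(self._columns)

    @property
    def n_rows(self) -> int:
        for col in self._columns.values():
            return len(col)
        return 0

    def __contains__(self, item: str) -> bool:
        return item.lower() in self._columns

    def __getitem__(self, item: str) -> list[CifValue]:
        return self._columns[item.lower()]

    def get(self, item: str) -> list[CifValue] | None:
        return self._columns.get(item.lower())

    def scalar(self, item: str, default: str | None = None) -> str | None:
        """Text of a one-row item; *default* when absent or a placeholder."""
        col = self.get(item)
        if not col:
            return default
        return col[0].as_text(default)

    def rows(self) -> Iterator[dict[str, CifValue]]:
        names = self.item_names
        for i in range(self.n_rows):
            yield {n: self._columns[n][i] for n in names}

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Category)
            and self.name == other.name
            and self.is_loop == other.is_loop
            and self._columns == other._columns
        )

    def __repr__(self) -> str:
        kind = "loop" if self.is_loop else "scalar"
        return f"Category({self.name!r}, {kind}, items={self.item_names}, rows={self.n_rows})"


class DataBlock:
    """An ordered mapping of category name → :class:`Category`."""

    def __init__(self, name: str, categories: Iterable[Category] = ()):
        self.name = name
        self._categories: dict[str, Category] = {}
        for cat in categories:
            self.add(cat)

    def add(self, category: Category, replace: bool = True) -> None:
        if not replace and category.name in self._categories:
            raise ValueError(
                f"category {category.name} already present in block {self.name}"
            )
        # assignment to an existing key keeps its insertion slot
        self._categories[category.name] = category

    @property
    def categories(self) -> list[Category]:
        return list(self._categories.values())

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._categories

    def get(self, name: str) -> Category | None:
        return self._categories.get(name.lower())

    def __getitem__(self, name: str) -> Category:
        return self._categories[name.lower()]

    def remove(self, name: str) -> None:
        self._categories.pop(name.lower(), None)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, DataBlock)
            and self.name == other.name
            and list(self._categories.items()) == list(other._categories.items())
        )

    def __repr__(self) -> str:
        return f"DataBlock({self.name!r}, categories={list(self._categories)})"


class CifFile:
    """An ordered list of data blocks.

    Block labels need not be unique: a sasCIF concentration series stores
    several MAIN-family blocks in one file.
    """

    def __init__(self, blocks: Iterable[DataBlock] = ()):
        self.blocks: list[DataBlock] = list(blocks)

    def block(self, label: str) -> DataBlock | None:
        """First block with this label (case-insensitive), or None."""
        low = label.lower()
        for b in self.blocks:
            if b.name.lower() == low:
                return b
        return None

    def ensure_block(self, label: str) -> DataBlock:
        b = self.block(label)
        if b is None:
            b = DataBlock(label)
            self.blocks.append(b)
        return b

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CifFile) and self.blocks == other.blocks

    def __repr__(self) -> str:
        return f"CifFile(blocks={[b.name for b in self.blocks]})"


# ---------------------------------------------------------------------------
# tokenizer

@dataclass
class _Token:
    kind: str  # data | loop | name | value
    text: str
    line: int
    quoted: bool = False


_WS = " \t"


def _tokenize(text: str) -> Iterator[_Token]:
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        lineno = i + 1
        if line.startswith(";"):
            # semicolon-delimited text block
            body: list[str] = [line[1:]]
            j = i + 1
            while j < n and not lines[j].startswith(";"):
                body.append(lines[j])
                j += 1
            if j >= n:
                raise CifSyntaxError("unterminated semicolon text block", lineno)
            yield _Token("value", "\n".join(body), lineno, quoted=True)
            i = j + 1
            continue
        pos = 0
        length = len(line)
        while pos < length:
            ch = line[pos]
            if ch in _WS:
                pos += 1
                continue
            if ch == "#":
                break  # comment to end of line
            if ch in "'\"":
                quote = ch
                j = pos + 1
                end = None
                while j < length:
                    if line[j] == quote and (j + 1 >= length or line[j + 1] in _WS):
                        end = j
                        break
                    j += 1
                if end is None:
                    raise CifSyntaxError("unterminated quoted string", lineno)
                yield _Token("value", line[pos + 1 : end], lineno, quoted=True)
                pos = end + 1
                continue
            # bare token up to whitespace
            j = pos
            while j < length and line[j] not in _WS:
                j += 1
            tok = line[pos:j]
            low = tok.lower()
            if low.startswith("data_"):
                yield _Token("data", tok[5:], lineno)
            elif low == "loop_":
                yield _Token("loop", tok, lineno)
            elif tok.startswith("_"):
                yield _Token("name", tok[1:], lineno)
            elif low in ("stop_", "global_") or low.startswith("save_"):
                raise CifSyntaxError(f"unsupported STAR directive {tok!r}", lineno)
            else:
                yield _Token("value", tok, lineno)
            pos = j
        i += 1


def _split_name(name: str, line: int) -> tuple[str, str]:
    cat, sep, kw = name.partition(".")
    if not sep or not cat or not kw:
        raise CifSyntaxError(
            f"item name _{name} lacks a category.keyword structure", line
        )
    return cat.lower(), kw.lower()


def _to_value(tok: _Token) -> CifValue:
    if not tok.quoted:
        if tok.text == "?":
            return MISSING
        if tok.text == ".":
            return INAPPLICABLE
    return CifValue.of(tok.text)


def parse_cif(text: str) -> CifFile:
    """Parse CIF text into an ordered :class:`CifFile`.

    Raises :class:`CifSyntaxError` (with line number) for a loop whose value
    count is not an exact multiple of its item count, unterminated quoting,
    or items appearing before any ``data_`` directive.
    """
    file = CifFile()
    block: DataBlock | None = None
    tokens = list(_tokenize(text))
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok.kind == "data":
            block = DataBlock(tok.text)
            file.blocks.append(block)
            i += 1
            continue
        if block is None:
            raise CifSyntaxError(
                f"{tok.text!r} appears before any data_ directive", tok.line
            )
        if tok.kind == "name":
            cat_name, kw = _split_name(tok.text, tok.line)
            if i + 1 >= n or tokens[i + 1].kind != "value":
                raise CifSyntaxError(f"item _{tok.text} has no value", tok.line)
            value = _to_value(tokens[i + 1])
            cat = block.get(cat_name)
            if cat is not None and cat.is_loop:
                raise CifSyntaxError(
                    f"category {cat_name} given both as loop and scalar", tok.line
                )
            if cat is None:
                cat = Category(cat_name)
                block.add(cat)
            if kw in cat:
                raise CifSyntaxError(
                    f"duplicate item _{cat_name}.{kw}", tok.line
                )
            cat._columns[kw] = [value]
            i += 2
            continue
        if tok.kind == "loop":
            loop_line = tok.line
            i += 1
            names: list[tuple[str, str]] = []
            while i < n and tokens[i].kind == "name":
                names.append(_split_name(tokens[i].text, tokens[i].line))
                i += 1
            if not names:
                raise CifSyntaxError("loop_ with no item names", loop_line)
            cats = {c for c, _ in names}
            if len(cats) != 1:
                raise CifSyntaxError(
                    f"loop_ mixes categories {sorted(cats)}", loop_line
                )
            values: list[CifValue] = []
            while i < n and tokens[i].kind == "value":
                values.append(_to_value(tokens[i]))
                i += 1
            if len(values) % len(names) != 0:
                raise CifSyntaxError(
                    f"loop_ has {len(values)} values for {len(names)} items "
                    "(not an exact multiple)",
                    loop_line,
                )
            cat_name = next(iter(cats))
            if cat_name in block:
                raise CifSyntaxError(
                    f"category {cat_name} occurs more than once in block "
                    f"{block.name!r}",
                    loop_line,
                )
            cat = Category(cat_name, is_loop=True)
            kws = [kw for _, kw in names]
            if len(set(kws)) != len(kws):
                raise CifSyntaxError("duplicate item name in loop_", loop_line)
            for col_idx, kw in enumerate(kws):
                cat._columns[kw] = values[col_idx :: len(kws)]
            block.add(cat)
            continue
        raise CifSyntaxError(f"unexpected value {tok.text!r}", tok.line)
    return file


# ---------------------------------------------------------------------------
# writer

_NEEDS_QUOTE = re.compile(r"[\s'\"]")
_RESERVED_FIRST = "_#$[]"


def _bare_ok(text: str) -> bool:
    if text == "" or text in ("?", "."):
        return False
    if _NEEDS_QUOTE.search(text):
        return False
    if text[0] in _RESERVED_FIRST or text.startswith(";"):
        return False
    low = text.lower()
    if low.startswith("data_") or low in ("loop_", "stop_", "global_") or low.startswith("save_"):
        return False
    return True


def _quotable(text: str, quote: str) -> bool:
    """Can *text* sit inside CIF quotes of kind *quote* on one line?"""
    for i, ch in enumerate(text):
        if ch == quote and (i + 1 >= len(text) or text[i + 1] in _WS):
            return False
    return not text.endswith(quote)


def _format_value(value: CifValue) -> str:
    """Render a value for a scalar slot or loop row (single line or ; block)."""
    if value.kind is ValueKind.MISSING:
        return "?"
    if value.kind is ValueKind.INAPPLICABLE:
        return "."
    text = value.text
    if "\n" in text:
        for ln in text.split("\n"):
            if ln.startswith(";"):
                raise CifWriteError(
                    "multiline value contains a line starting with ';' — "
                    "not representable in CIF 1.1"
                )
        return f"\n;{text}\n;"
    if _bare_ok(text):
        return text
    if _quotable(text, "'"):
        return f"'{text}'"
    if _quotable(text, '"'):
        return f'"{text}"'
    if text.startswith(";"):
        raise CifWriteError(
            f"value {text!r} starts with ';' and contains both quote kinds — "
            "not representable in CIF 1.1"
        )
    return f"\n;{text}\n;"


def write_cif(file: CifFile) -> str:
    """Serialize a :class:`CifFile`; output re-parses to an equal model."""
    out: list[str] = []
    for block in file.blocks:
        out.append(f"data_{block.name}")
        for cat in block.categories:
            if cat.is_loop:
                out.append("loop_")
                for item in cat.item_names:
                    out.append(f"_{cat.name}.{item}")
                for row in cat.rows():
                    parts: list[str] = []
                    for item in cat.item_names:
                        rendered = _format_value(row[item])
                        if rendered.startswith("\n"):
                            if parts:
                                out.append(" ".join(parts))
                                parts = []
                            out.append(rendered.lstrip("\n"))
                        else:
                            parts.append(rendered)
                    if parts:
                        out.append(" ".join(parts))
            else:
                width = max(
                    (len(cat.name) + len(i) + 2 for i in cat.item_names), default=0
                )
                for item in cat.item_names:
                    rendered = _format_value(cat[item][0])
                    tag = f"_{cat.name}.{item}"
                    if rendered.startswith("\n"):
                        out.append(tag + rendered)
                    else:
                        out.append(f"{tag:<{width}} {rendered}")
            out.append("")
        out.append("")
    # collapse trailing blank lines to a single newline at EOF
    while out and out[-1] == "":
        out.pop()
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# plumbing accessors

_ABSENT: list[CifValue] = []


def get_column(
    file: CifFile, block_label: str, category: str, item: str
) -> list[CifValue] | None:
    """Column values, or ``None`` when block/category/item is absent.

    Lookup is case-insensitive; absence is a status, not an error.
    """
    block = file.block(block_label)
    if block is None:
        return None
    cat = block.get(category)
    if cat is None:
        return None
    col = cat.get(item)
    if col is None:
        return None
    return list(col)


def set_category(
    file: CifFile,
    block_label: str,
    category: str,
    columns: Mapping[str, Sequence["CifValue | str | float | int | None"]],
    is_loop: bool = False,
) -> CifFile:
    """Replace or append *category* in the named block (created if needed).

    A category occurs at most once per block, so setting it twice replaces
    the first version in place.  Ragged columns raise ``ValueError``.
    """
    block = file.ensure_block(block_label)
    block.add(Category(category, columns, is_loop=is_loop))
    return file
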