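"""Readers and writers for character matrices and partition maps.

NEXUS ``CHARACTERS``/``DATA`` blocks are parsed with dendropy (interleaved
and non-interleaved dialects, declared ``MISSING``/``GAP``/``SYMBOLS`` tokens,
``{..}``/``(..)`` polymorphism).  TNT ``xread`` has no parser in the installed
stack, so a small one lives here; it accepts ``?`` missing, ``-`` gap and
``[..]`` polymorphism.  Both writers round-trip token-identically through
their matching reader.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy

from .matrix import GAP, MISSING, CellValue, CharacterMatrix

__all__ = [
    "read_nexus",
    "read_tnt",
    "read_matrix",
    "write_matrix",
    "read_partition_map",
    "MatrixParseError",
]


class MatrixParseError(ValueError):
    """Raised when a matrix file cannot be interpreted."""


def _cell_from_dendropy(state) -> CellValue:
    if state.symbol == "?":
        return MISSING
    if state.symbol == "-":
        return GAP
    members = state.member_states
    if members is None or len(members) <= 1:
        return CellValue.of(state.symbol)
    tokens = [s.symbol for s in members if s.symbol not in ("?", "-")]
    if not tokens:
        return MISSING
    return CellValue.of(*tokens)


def read_nexus(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS or DATA block into a :class:`CharacterMatrix`."""
    path = Path(path)
    try:
        ds = dendropy.DataSet.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise MatrixParseError(f"{path}: {exc}") from exc
    if not ds.char_matrices:
        raise MatrixParseError(f"{path}: no CHARACTERS or DATA block found")
    cm = ds.char_matrices[0]
    labels, cells = [], []
    for taxon in cm:
        labels.append(taxon.label)
        cells.append([_cell_from_dendropy(s) for s in cm[taxon]])
    widths = {len(r) for r in cells}
    if len(widths) > 1:
        raise MatrixParseError(f"{path}: rows of unequal length {sorted(widths)}")
    return CharacterMatrix(labels, cells, provenance=f"{path}:nexus")


_XREAD_RE = re.compile(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)(.*?);", re.S | re.I)


def _tokenize_tnt_row(text: str, n_char: int, label: str) -> list[CellValue]:
    cells: list[CellValue] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise MatrixParseError(f"unterminated '[' in row {label!r}")
            tokens = [t for t in text[i + 1 : j] if not t.isspace()]
            if not tokens:
                raise MatrixParseError(f"empty polymorphism in row {label!r}")
            cells.append(CellValue.of(*tokens))
            i = j + 1
        elif ch == "?":
            cells.append(MISSING)
            i += 1
        elif ch == "-":
            cells.append(GAP)
            i += 1
        else:
            cells.append(CellValue.of(ch))
            i += 1
    if len(cells) != n_char:
        raise MatrixParseError(
            f"row {label!r} has {len(cells)} characters, expected {n_char}"
        )
    return cells


def read_tnt(path: str | Path) -> CharacterMatrix:
    """Read a TNT ``xread`` block into a :class:`CharacterMatrix`."""
    path = Path(path)
    text = path.read_text()
    m = _XREAD_RE.search(text)
    if not m:
        raise MatrixParseError(f"{path}: no xread block found")
    n_char, n_otu = int(m.group(1)), int(m.group(2))
    body = m.group(3)
    labels: list[str] = []
    rows: list[list[CellValue]] = []
    for line in body.splitlines():
        line = line.strip()
        if not line or line.startswith("'"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise MatrixParseError(f"{path}: cannot split label from states: {line!r}")
        label, states = parts
        labels.append(label)
        rows.append(_tokenize_tnt_row(states, n_char, label))
    if len(labels) != n_otu:
        raise MatrixParseError(
            f"{path}: xread declares {n_otu} taxa but body has {len(labels)}"
        )
    return CharacterMatrix(labels, rows, provenance=f"{path}:tnt")


def read_matrix(path: str | Path, format: str | None = None) -> CharacterMatrix:
    """Dispatch on ``format`` or file suffix (.nex/.nexus -> NEXUS, .tnt/.ss -> TNT)."""
    path = Path(path)
    fmt = format
    if fmt is None:
        fmt = "tnt" if path.suffix.lower() in (".tnt", ".ss", ".run") else "nexus"
    if fmt == "nexus":
        return read_nexus(path)
    if fmt == "tnt":
        return read_tnt(path)
    raise ValueError(f"unknown matrix format {fmt!r}")


def _nexus_token(cell: CellValue) -> str:
    if cell.kind == "polymorphic":
        return "{" + "".join(sorted(cell.states)) + "}"
    return cell.token()


def _tnt_token(cell: CellValue) -> str:
    if cell.kind == "polymorphic":
        return "[" + "".join(sorted(cell.states)) + "]"
    return cell.token()


def _safe_label(label: str) -> str:
    return label.replace(" ", "_")


def write_matrix(matrix: CharacterMatrix, path: str | Path, format: str = "nexus") -> Path:
    """Write ``matrix`` as NEXUS or TNT; the file re-reads to an equal matrix."""
    path = Path(path)
    if format == "nexus":
        symbols = sorted({s for c in range(matrix.n_char) for s in matrix.state_symbols(c)})
        width = max((len(lab) for lab in matrix.otu_labels), default=1)
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"DIMENSIONS NTAX={matrix.n_otu} NCHAR={matrix.n_char};",
            f"FORMAT DATATYPE=STANDARD SYMBOLS=\"{''.join(symbols)}\" MISSING=? GAP=-;",
            "MATRIX",
        ]
        for i, lab in enumerate(matrix.otu_labels):
            row = "".join(_nexus_token(c) for c in matrix.cells[i])
            lines.append(f"{_safe_label(lab):<{width}} {row}")
        lines += [";", "END;", ""]
        path.write_text("\n".join(lines))
    elif format == "tnt":
        lines = [f"xread {matrix.n_char} {matrix.n_otu}"]
        for i, lab in enumerate(matrix.otu_labels):
            row = "".join(_tnt_token(c) for c in matrix.cells[i])
            lines.append(f"{_safe_label(lab)} {row}")
        lines += [";", ""]
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return path


_RANGE_RE = re.compile(r"^(\d+)(?:-(\d+))?$")


def read_partition_map(path: str | Path, n_char: int | None = None) -> dict[int, str]:
    """Read a partition map: lines ``start-end<TAB>label``, 1-based inclusive.

    Returns a 0-based character-index -> label dict.  Single indices
    (``17<TAB>C``) are accepted as one-character ranges.
    """
    partitions: dict[int, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rng, label = line.split("\t", 1)
        except ValueError as exc:
            raise MatrixParseError(f"partition map line {ln}: need <range>\\t<label>") from exc
        m = _RANGE_RE.match(rng.strip())
        if not m:
            raise MatrixParseError(f"partition map line {ln}: bad range {rng!r}")
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if start < 1 or end < start:
            raise MatrixParseError(f"partition map line {ln}: bad range {rng!r}")
        for i in range(start - 1, end):
            if n_char is not None and i >= n_char:
                raise MatrixParseError(
                    f"partition map line {ln}: index {i + 1} beyond {n_char} characters"
                )
            partitions[i] = label.strip()
    return partitions
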