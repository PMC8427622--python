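"""Canonical in-memory representation of a discrete morphological character matrix.

A matrix is an OTU x character grid of :class:`CellValue` objects.  Cells are
either a single observed state, a set of states (polymorphism), missing
(unobservable, ``?``) or a gap (inapplicable, ``-``).  The per-character state
alphabet is the set of tokens actually observed in that column, not whatever
the source file's SYMBOLS declaration promised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CellValue",
    "CharacterMatrix",
    "MISSING",
    "GAP",
    "merge_otus",
    "binarize",
]


@dataclass(frozen=True)
class CellValue:
    """One cell of a character matrix.

    ``kind`` is one of ``state``, ``polymorphic``, ``missing``, ``gap``.
    ``states`` is a frozenset of state tokens: a singleton for ``state``,
    two or more for ``polymorphic``, empty otherwise.
    """

    kind: str
    states: frozenset = frozenset()

    def __post_init__(self):
        if self.kind == "state" and len(self.states) != 1:
            raise ValueError("state cell needs exactly one state token")
        if self.kind == "polymorphic" and len(self.states) < 2:
            raise ValueError("polymorphic cell needs >=2 state tokens")
        if self.kind in ("missing", "gap") and self.states:
            raise ValueError(f"{self.kind} cell carries no state tokens")
        if self.kind not in ("state", "polymorphic", "missing", "gap"):
            raise ValueError(f"unknown cell kind {self.kind!r}")

    @property
    def is_scored(self) -> bool:
        """True if the cell contributes signal (a state or a polymorphism)."""
        return self.kind in ("state", "polymorphic")

    @property
    def state(self) -> str:
        if self.kind != "state":
            raise ValueError("cell is not a singleton state")
        return next(iter(self.states))

    @classmethod
    def of(cls, *tokens: str) -> "CellValue":
        toks = frozenset(tokens)
        if len(toks) == 1:
            return cls("state", toks)
        return cls("polymorphic", toks)

    def token(self) -> str:
        """Render the cell as the token it would occupy in a sequence."""
        if self.kind == "missing":
            return "?"
        if self.kind == "gap":
            return "-"
        if self.kind == "state":
            return self.state
        return "{" + "".join(sorted(self.states)) + "}"


MISSING = CellValue("missing")
GAP = CellValue("gap")


class CharacterMatrix:
    """OTU x character grid of :class:`CellValue` with optional partitions.

    Character indices are 0-based internally; all user-facing output
    (CSV, TNT scripts, reports) is 1-based except TNT ``ccode`` character
    numbers, which follow TNT's own 0-based convention.
    """

    def __init__(
        self,
        otu_labels: Sequence[str],
        cells: Sequence[Sequence[CellValue]],
        partitions: Mapping[int, str] | None = None,
        provenance: str = "",
    ):
        self.otu_labels = list(otu_labels)
        if len(set(self.otu_labels)) != len(self.otu_labels):
            raise ValueError("OTU labels must be unique")
        self.cells = [list(row) for row in cells]
        if len(self.cells) != len(self.otu_labels):
            raise ValueError("one row of cells per OTU required")
        widths = {len(row) for row in self.cells}
        if len(widths) > 1:
            raise ValueError(f"ragged matrix: row widths {sorted(widths)}")
        self.n_char = widths.pop() if widths else 0
        self.partitions = dict(partitions) if partitions else {}
        for idx in self.partitions:
            if not 0 <= idx < self.n_char:
                raise ValueError(f"partition index {idx} out of range")
        self.provenance = provenance

    @property
    def n_otu(self) -> int:
        return len(self.otu_labels)

    def cell(self, otu: int, char: int) -> CellValue:
        return self.cells[otu][char]

    def column(self, char: int) -> list[CellValue]:
        return [row[char] for row in self.cells]

    def state_symbols(self, char: int) -> list[str]:
        """Sorted alphabet of state tokens observed in this column."""
        seen: set[str] = set()
        for row in self.cells:
            seen.update(row[char].states)
        return sorted(seen)

    def row_tokens(self, otu: int) -> list[str]:
        return [c.token() for c in self.cells[otu]]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.otu_labels == other.otu_labels
            and self.cells == other.cells
            and self.partitions == other.partitions
        )

    def __repr__(self) -> str:
        return (
            f"CharacterMatrix({self.n_otu} OTUs x {self.n_char} characters"
            + (f", {len(set(self.partitions.values()))} partitions" if self.partitions else "")
            + ")"
        )


def merge_otus(
    matrix: CharacterMatrix, labels: Iterable[str], merged_label: str | None = None,
    strict: bool = True,
) -> CharacterMatrix:
    """Collapse several OTUs (e.g. duplicate scorings of one taxon) into one row.

    The merged cell is scored if any constituent scores it.  Conflicting
    singleton states raise an error under ``strict=True``; with
    ``strict=False`` the conflicting states are unioned into a polymorphic
    cell.  Missing beats gap only in the sense that a gap survives if no
    constituent has any information at all beyond it.
    """
    labels = list(labels)
    idx = []
    for lab in labels:
        if lab not in matrix.otu_labels:
            raise KeyError(f"OTU {lab!r} not in matrix")
        idx.append(matrix.otu_labels.index(lab))
    if len(set(idx)) < 1:
        raise ValueError("no OTUs to merge")
    merged_label = merged_label or labels[0]

    merged_row: list[CellValue] = []
    for c in range(matrix.n_char):
        cells = [matrix.cells[i][c] for i in sorted(set(idx))]
        scored = [cl for cl in cells if cl.is_scored]
        if not scored:
            merged_row.append(GAP if all(cl.kind == "gap" for cl in cells) else MISSING)
            continue
        union = frozenset().union(*(cl.states for cl in scored))
        if strict:
            # any two scored cells must share at least one state
            for a in scored:
                for b in scored:
                    if not (a.states & b.states):
                        raise ValueError(
                            f"conflicting states {a.token()} vs {b.token()} at "
                            f"character {c + 1} while merging {labels}"
                        )
            # keep the most restrictive consistent reading
            inter = scored[0].states
            for cl in scored[1:]:
                inter = inter & cl.states
            chosen = inter if inter else union
        else:
            chosen = union
        merged_row.append(CellValue.of(*chosen))

    new_labels, new_cells = [], []
    inserted = False
    for i in range(matrix.n_otu):
        if i in set(idx):
            if not inserted:
                new_labels.append(merged_label)
                new_cells.append(merged_row)
                inserted = True
            continue
        new_labels.append(matrix.otu_labels[i])
        new_cells.append(matrix.cells[i])
    return CharacterMatrix(new_labels, new_cells, matrix.partitions, matrix.provenance)


def binarize(matrix: CharacterMatrix) -> tuple[CharacterMatrix, dict[int, list[int]]]:
    """Split every k-state character (k > 2) into k one-vs-rest binary characters.

    Returns the new matrix and a provenance map old-index -> new-indices.
    Binary (and degenerate) characters pass through unchanged.  A missing or
    gap cell stays missing/gap in every derived character; a polymorphic cell
    scores 1 for each listed state's derived character and 0 elsewhere.
    """
    new_columns: list[list[CellValue]] = []
    index_map: dict[int, list[int]] = {}
    new_partitions: dict[int, str] = {}
    for c in range(matrix.n_char):
        alphabet = matrix.state_symbols(c)
        col = matrix.column(c)
        if len(alphabet) <= 2:
            index_map[c] = [len(new_columns)]
            if c in matrix.partitions:
                new_partitions[len(new_columns)] = matrix.partitions[c]
            new_columns.append(col)
            continue
        index_map[c] = []
        for state in alphabet:
            derived = []
            for cell in col:
                if not cell.is_scored:
                    derived.append(cell)
                elif cell.kind == "state":
                    derived.append(CellValue.of("1" if cell.state == state else "0"))
                else:  # polymorphic: presence of this state among the listed ones
                    derived.append(CellValue.of("1" if state in cell.states else "0"))
            index_map[c].append(len(new_columns))
            if c in matrix.partitions:
                new_partitions[len(new_columns)] = matrix.partitions[c]
            new_columns.append(derived)
    cells = [[new_columns[j][i] for j in range(len(new_columns))] for i in range(matrix.n_otu)]
    out = CharacterMatrix(matrix.otu_labels, cells, new_partitions, matrix.provenance)
    return out, index_map
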