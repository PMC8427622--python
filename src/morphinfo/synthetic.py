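"""Synthetic character matrices with known information properties.

Three generators cover the test surface of the rest of the package:

* :func:`table2_fixture` — the fixed 9-taxon, 3-binary-character worked
  example (all eight binary triples, with taxon 7 scored twice as 7 and 7.1);
* :func:`generate_matrix` — seeded random matrices with per-character state
  distributions, optional noisy-copy dependencies between character pairs,
  and missing-completely-at-random cells;
* :func:`generate_clean_matrix_on_tree` — a homoplasy-free binary matrix
  whose characters are the clades of a given tree (CI = RI = 1 on it).

Generation is fully deterministic given the seed: the same spec yields a
byte-identical matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .matrix import MISSING, CellValue, CharacterMatrix, merge_otus

__all__ = [
    "GeneratorSpec",
    "table2_fixture",
    "generate_matrix",
    "generate_clean_matrix_on_tree",
]

# Worked 9 x 3 example: every binary triple once, plus a duplicate scoring
# of taxon 7 (labelled 7.1), over characters Tail / Feather / Five digits.
_TABLE2_ROWS = {
    "1": "000",
    "2": "001",
    "3": "010",
    "4": "100",
    "5": "011",
    "6": "101",
    "7": "110",
    "7.1": "110",
    "8": "111",
}
TABLE2_CHAR_NAMES = ("Tail", "Feather", "Five digits")


def table2_fixture(merged: bool = False) -> CharacterMatrix:
    """The fixed 9-taxon x 3-character demonstration matrix.

    With ``merged=True`` the identically scored taxa 7 and 7.1 are collapsed
    into a single OTU, leaving the 8 distinct binary triples exactly once —
    the configuration in which every character has 1 bit of entropy and
    every character pair has zero mutual information.
    """
    labels = list(_TABLE2_ROWS)
    cells = [[CellValue.of(tok) for tok in row] for row in _TABLE2_ROWS.values()]
    m = CharacterMatrix(labels, cells, provenance="table2_fixture")
    if merged:
        m = merge_otus(m, ["7", "7.1"], merged_label="7")
    return m


@dataclass
class GeneratorSpec:
    """Recipe for a seeded random matrix.

    ``char_probs`` gives one state-probability vector per character (states
    are named "0", "1", ... in order).  ``dependencies`` is a list of
    (source_char, copy_char, flip_probability): the copy column is generated
    by copying the source and re-drawing each cell uniformly from the other
    states with the given probability, which for uniform binary sources gives
    the pair an analytic mutual information of 1 - H2(flip_probability).
    ``missingness`` is the MCAR probability applied to every cell last.
    """

    n_otu: int
    char_probs: list[list[float]]
    dependencies: list[tuple[int, int, float]] = field(default_factory=list)
    missingness: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_otu < 1:
            raise ValueError("n_otu must be positive")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        for i, probs in enumerate(self.char_probs):
            if len(probs) < 1 or any(p < 0 for p in probs):
                raise ValueError(f"character {i}: invalid probabilities")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"character {i}: probabilities sum to {sum(probs)}")
        n_char = len(self.char_probs)
        for src, dst, eps in self.dependencies:
            if not (0 <= src < n_char and 0 <= dst < n_char) or src == dst:
                raise ValueError(f"bad dependency pair ({src}, {dst})")
            if not 0.0 <= eps <= 1.0:
                raise ValueError("flip probability must be in [0, 1]")


def generate_matrix(spec: GeneratorSpec) -> CharacterMatrix:
    """Draw a random matrix from a :class:`GeneratorSpec` (one seeded stream)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_char = len(spec.char_probs)
    columns: list[np.ndarray] = []
    for probs in spec.char_probs:
        columns.append(rng.choice(len(probs), size=spec.n_otu, p=probs))
    for src, dst, eps in spec.dependencies:
        k = len(spec.char_probs[src])
        copy = columns[src].copy()
        flip = rng.random(spec.n_otu) < eps
        if k > 1:
            shift = rng.integers(1, k, size=spec.n_otu)
            copy[flip] = (copy[flip] + shift[flip]) % k
        columns[dst] = copy
    miss = rng.random((spec.n_otu, n_char)) < spec.missingness
    cells = [
        [
            MISSING if miss[i, c] else CellValue.of(str(int(columns[c][i])))
            for c in range(n_char)
        ]
        for i in range(spec.n_otu)
    ]
    labels = [f"otu{i + 1}" for i in range(spec.n_otu)]
    return CharacterMatrix(labels, cells, provenance=f"generate_matrix(seed={spec.seed})")


def generate_clean_matrix_on_tree(
    tree: dendropy.Tree, chars_per_internal_edge: int = 1
) -> CharacterMatrix:
    """Homoplasy-free binary matrix from the clades of a tree.

    Every internal edge that splits the tips non-trivially contributes
    ``chars_per_internal_edge`` identical binary characters scoring 1 for the
    tips on its child side.  On the generating tree each character needs
    exactly one step, so CI = RI = 1 there; on a different topology the same
    matrix is generally homoplastic.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) < 4:
        raise ValueError("tree must have at least 4 tips")
    if chars_per_internal_edge < 1:
        raise ValueError("chars_per_internal_edge must be >= 1")
    clades: list[set[str]] = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        clade = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 1 < len(clade) < len(tips):
            clades.append(clade)
    if not clades:
        raise ValueError("tree has no internal edges (star tree)")
    cells = [
        [
            CellValue.of("1" if tip in clade else "0")
            for clade in clades
            for _ in range(chars_per_internal_edge)
        ]
        for tip in tips
    ]
    return CharacterMatrix(tips, cells, provenance="clean_matrix_on_tree")
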