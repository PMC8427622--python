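"""Tree-versus-matrix fit: Fitch step counts and ensemble CI/RI.

Characters are unordered (nonadditive) with unit cost.  Step counts use the
Fitch-Hartigan recursion, which is exact on arbitrary (including polytomous)
trees: at each internal node the children's preferred state sets vote, the
node keeps the plurality states, and each non-voting child costs one step.
Missing/gap tips are free to take any observed state; polymorphic tips any of
their listed states.

Per character, m is the minimum conceivable step count (observed states - 1),
g the maximum (steps on a completely unresolved tree), and s the observed
Fitch count.  The ensemble consistency index is CI = sum(m)/sum(s) and the
retention index RI = (sum(g) - sum(s)) / (sum(g) - sum(m)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy

from .matrix import CharacterMatrix

__all__ = [
    "read_newick",
    "fitch_steps",
    "char_step_bounds",
    "ensemble_ci_ri",
    "TreeFitStats",
]


def read_newick(
    path: str | Path, underscores_to_spaces: bool = False
) -> list[dendropy.Tree]:
    """Read one or more newick trees from a file.

    By default tip labels keep their underscores verbatim (the common usage in
    matrix files); pass ``underscores_to_spaces=True`` for strict newick
    quoting rules.  Duplicate tip labels raise an error.
    """
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema="newick",
            preserve_underscores=not underscores_to_spaces,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels: {exc}") from exc
    return list(trees)


def _tip_state_sets(
    tree: dendropy.Tree, matrix: CharacterMatrix, char: int
) -> dict[str, frozenset]:
    """Map tip label -> allowed state set; unscored tips get the full
    observed alphabet of the character among the tree's tips."""
    otu_index = {lab: i for i, lab in enumerate(matrix.otu_labels)}
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing_labels = [t for t in tips if t not in otu_index]
    if missing_labels:
        raise KeyError(f"tree tips not found in matrix: {missing_labels}")
    observed: set[str] = set()
    for t in tips:
        observed |= matrix.cells[otu_index[t]][char].states
    full = frozenset(observed)
    sets = {}
    for t in tips:
        cell = matrix.cells[otu_index[t]][char]
        sets[t] = frozenset(cell.states) if cell.is_scored else full
    return sets


def fitch_steps(tree: dendropy.Tree, matrix: CharacterMatrix, char: int) -> int:
    """Minimum number of unordered state changes of one character on a tree.

    Root-placement invariant; tolerates polytomies.  Characters with fewer
    than two scored tips, or no observed variation, cost 0 steps.
    """
    sets = _tip_state_sets(tree, matrix, char)
    observed = frozenset().union(*sets.values()) if sets else frozenset()
    n_scored = sum(
        1
        for leaf in tree.leaf_node_iter()
        if matrix.cells[matrix.otu_labels.index(leaf.taxon.label)][char].is_scored
    )
    if n_scored < 2 or len(observed) < 2:
        return 0

    steps = 0
    node_set: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_set[id(node)] = sets[node.taxon.label]
            continue
        votes: dict[str, int] = {}
        children = node.child_nodes()
        for ch in children:
            for s in node_set[id(ch)]:
                votes[s] = votes.get(s, 0) + 1
        top = max(votes.values())
        node_set[id(node)] = frozenset(s for s, v in votes.items() if v == top)
        steps += len(children) - top
    return steps


def _resolve_polymorphic(matrix: CharacterMatrix, char: int, tips: list[str]) -> list[str]:
    """Singleton-state view of a character over the given tips.

    Polymorphic tips resolve to the globally most frequent of their listed
    states (global frequencies via fractional 1/|set| weights; ties broken
    toward the lexically smallest token).  Unscored tips are omitted.
    """
    otu_index = {lab: i for i, lab in enumerate(matrix.otu_labels)}
    cells = [matrix.cells[otu_index[t]][char] for t in tips]
    weights: dict[str, float] = {}
    for cell in cells:
        for s in cell.states:
            weights[s] = weights.get(s, 0.0) + 1.0 / len(cell.states)
    resolved = []
    for cell in cells:
        if not cell.is_scored:
            continue
        if cell.kind == "state":
            resolved.append(cell.state)
        else:
            resolved.append(min(cell.states, key=lambda s: (-weights[s], s)))
    return resolved


def char_step_bounds(
    matrix: CharacterMatrix, char: int, tree: dendropy.Tree
) -> tuple[int, int]:
    """(m, g): minimum and maximum conceivable steps of a character.

    m = number of observed states among scored tips minus one (0 if <= 1);
    g = scored tips minus the count of the most frequent state, i.e. the step
    count on a completely unresolved tree.
    """
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    resolved = _resolve_polymorphic(matrix, char, tips)
    if len(resolved) < 2:
        return 0, 0
    counts: dict[str, int] = {}
    for s in resolved:
        counts[s] = counts.get(s, 0) + 1
    m = max(len(counts) - 1, 0)
    g = len(resolved) - max(counts.values())
    return m, g


@dataclass
class TreeFitStats:
    """Per-character m/s/g step counts and the ensemble CI and RI."""

    m: list[int]
    s: list[int]
    g: list[int]
    used: list[bool]
    dropped_otus: list[str]

    @property
    def sums(self) -> tuple[int, int, int]:
        M = sum(m for m, u in zip(self.m, self.used) if u)
        S = sum(s for s, u in zip(self.s, self.used) if u)
        G = sum(g for g, u in zip(self.g, self.used) if u)
        return M, S, G

    @property
    def CI(self) -> float:
        M, S, _ = self.sums
        return M / S if S > 0 else 1.0

    @property
    def RI(self) -> float:
        """(sum g - sum s)/(sum g - sum m); NaN when no character can show
        homoplasy (sum g == sum m)."""
        M, S, G = self.sums
        if G == M:
            return math.nan
        return (G - S) / (G - M)

    @property
    def n_char_used(self) -> int:
        return sum(self.used)

    def weighted_indices(self, weights: list[float]) -> tuple[float, float]:
        """CI and RI with per-character weights applied to all three sums."""
        if len(weights) != len(self.s):
            raise ValueError("one weight per character required")
        M = sum(w * m for w, m, u in zip(weights, self.m, self.used) if u)
        S = sum(w * s for w, s, u in zip(weights, self.s, self.used) if u)
        G = sum(w * g for w, g, u in zip(weights, self.g, self.used) if u)
        ci = M / S if S > 0 else 1.0
        ri = (G - S) / (G - M) if G != M else math.nan
        return ci, ri


def ensemble_ci_ri(matrix: CharacterMatrix, tree: dendropy.Tree) -> TreeFitStats:
    """Evaluate a tree against a matrix: per-character m, s, g and CI/RI.

    OTUs absent from the tree are dropped (recorded in ``dropped_otus``);
    the tree must cover at least four matrix OTUs.  Characters with g = 0
    (constant, or under two scored tips) do not contribute to the sums.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    absent_tips = sorted(tips - set(matrix.otu_labels))
    if absent_tips:
        raise KeyError(f"tree tips not found in matrix: {absent_tips}")
    covered = [lab for lab in matrix.otu_labels if lab in tips]
    if len(covered) < 4:
        raise ValueError("tree must cover at least 4 matrix OTUs")
    dropped = [lab for lab in matrix.otu_labels if lab not in tips]

    m_list, s_list, g_list, used = [], [], [], []
    for c in range(matrix.n_char):
        m, g = char_step_bounds(matrix, c, tree)
        s = fitch_steps(tree, matrix, c)
        m_list.append(m)
        s_list.append(s)
        g_list.append(g)
        used.append(g > 0)
    return TreeFitStats(m_list, s_list, g_list, used, dropped)
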