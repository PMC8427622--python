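"""Independent brute-force oracles used to cross-check the library.

These deliberately share no code with morphinfo: entropies come from direct
tabulation of complete-data columns with collections.Counter, and tree
lengths from exhaustive enumeration of internal-node state assignments.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def tabulated_entropy(column: list[str]) -> float:
    """Plug-in entropy of a list of tokens by direct counting."""
    counts = Counter(column)
    n = len(column)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def tabulated_joint_entropy(columns: list[list[str]]) -> float:
    """Entropy of the tuple-valued variable formed by zipping columns."""
    return tabulated_entropy(list(zip(*columns)))


def tabulated_mi(col_a: list[str], col_b: list[str]) -> float:
    """I(A,B) = H(A) + H(B) - H(A,B) by direct tabulation."""
    return (
        tabulated_entropy(col_a)
        + tabulated_entropy(col_b)
        - tabulated_joint_entropy([col_a, col_b])
    )


def exhaustive_tree_length(adjacency, tip_sets, internal_nodes, states) -> int:
    """Minimum unit-cost changes on a tree by enumerating every assignment.

    ``adjacency`` is a list of (parent, child) edges over node ids;
    ``tip_sets`` maps tip node id -> allowed state set; ``internal_nodes`` is
    the list of internal node ids; ``states`` the candidate state tokens.
    """
    best = math.inf
    for assign in itertools.product(states, repeat=len(internal_nodes)):
        state_of = dict(zip(internal_nodes, assign))
        cost = 0
        for parent, child in adjacency:
            ps = state_of[parent]
            if child in tip_sets:
                cost += 0 if ps in tip_sets[child] else 1
            else:
                cost += 0 if ps == state_of[child] else 1
            if cost >= best:
                break
        best = min(best, cost)
    return int(best)


def tree_length_oracle(tree, matrix, char) -> int:
    """Exhaustive minimum step count of one character on a dendropy tree."""
    otu_index = {lab: i for i, lab in enumerate(matrix.otu_labels)}
    observed = set()
    tip_sets = {}
    internal = []
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            edges.append((id(node.parent_node), id(node)))
        if node.is_leaf():
            cell = matrix.cells[otu_index[node.taxon.label]][char]
            observed |= set(cell.states)
            tip_sets[id(node)] = set(cell.states)
        else:
            internal.append(id(node))
    n_scored = sum(1 for s in tip_sets.values() if s)
    if n_scored < 2 or len(observed) < 2:
        return 0
    for nid, s in tip_sets.items():
        if not s:  # unscored tip: free choice among observed states
            tip_sets[nid] = set(observed)
    return exhaustive_tree_length(edges, tip_sets, internal, sorted(observed))
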