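"""Entropy, mutual information, and joint-entropy prefix curves.

All quantities are Shannon measures in bits (base-2 logarithm) over the
empirical, plug-in distributions of character-state tokens:

* per-character entropy  H = -sum_i p_i log2 p_i,
* pairwise mutual information  I(A,B) = H(A) + H(B) - H(A,B),
* joint entropy of the first i characters, from the empirical distribution
  of the i-length state sequences across OTUs.

Missing data can be handled two ways.  The *redistribution* rule spreads a
character's missing mass equally over its observed states (a binary character
scored 0 in 20% of OTUs, 1 in 40%, missing in 40% becomes p = (0.4, 0.6));
the alternative simply renormalises over scored OTUs.  Polymorphic cells
contribute fractional weight 1/|states| to each listed state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellValue, CharacterMatrix

__all__ = [
    "StateDistribution",
    "EntropyProfile",
    "MutualInfoMatrix",
    "JointEntropyCurve",
    "state_distribution",
    "char_entropy",
    "entropy_profile",
    "mutual_information",
    "conditional_entropy",
    "mi_matrix",
    "joint_entropy_prefix",
]


def _plogp_sum(probs) -> float:
    """-sum p log2 p with the 0*log2(0) := 0 convention."""
    return float(-sum(p * math.log2(p) for p in probs if p > 0.0))


def _cell_weights(cell: CellValue, gap_is_state: bool) -> dict[str, float]:
    """Fractional state weights contributed by one cell (empty if unscored)."""
    if cell.kind == "gap" and gap_is_state:
        return {"-": 1.0}
    if not cell.is_scored:
        return {}
    w = 1.0 / len(cell.states)
    return {s: w for s in cell.states}


@dataclass
class StateDistribution:
    """Per-character state probabilities p_i, optionally with missing mass
    redistributed equally over the observed states."""

    char_index: int
    probs: dict[str, float]
    n_scored: int
    n_missing: int
    redistributed: bool

    @property
    def degenerate(self) -> bool:
        return not self.probs

    @property
    def k(self) -> int:
        return len(self.probs)


def state_distribution(
    matrix: CharacterMatrix,
    char: int,
    redistribute: bool = True,
    gap_is_state: bool = False,
) -> StateDistribution:
    """Empirical state distribution of one character.

    With ``redistribute=True`` each observed state's whole-matrix frequency
    gains (missing fraction)/k, where k is the number of observed states;
    with ``redistribute=False`` probabilities are renormalised over scored
    OTUs only.  A character with no scored cells is returned degenerate
    (empty ``probs``, ``n_scored == 0``).
    """
    if not 0 <= char < matrix.n_char:
        raise IndexError(f"character {char} out of range")
    weights: dict[str, float] = {}
    n_scored = 0
    for cell in matrix.column(char):
        cw = _cell_weights(cell, gap_is_state)
        if cw:
            n_scored += 1
        for s, w in cw.items():
            weights[s] = weights.get(s, 0.0) + w
    n_missing = matrix.n_otu - n_scored
    if n_scored == 0:
        return StateDistribution(char, {}, 0, n_missing, redistribute)
    k = len(weights)
    if redistribute:
        miss_frac = n_missing / matrix.n_otu
        probs = {s: w / matrix.n_otu + miss_frac / k for s, w in weights.items()}
    else:
        probs = {s: w / n_scored for s, w in weights.items()}
    return StateDistribution(char, probs, n_scored, n_missing, redistribute)


def char_entropy(dist: StateDistribution) -> float:
    """Shannon entropy of a state distribution in bits; degenerate -> 0."""
    if dist.degenerate:
        return 0.0
    return _plogp_sum(dist.probs.values())


@dataclass
class EntropyProfile:
    """Per-character entropies plus a mean-entropy-by-state-count summary."""

    H: list[float]
    k: list[int]
    redistributed: bool

    @property
    def mean_by_k(self) -> dict[int, float]:
        groups: dict[int, list[float]] = {}
        for h, kk in zip(self.H, self.k):
            if kk > 0:
                groups.setdefault(kk, []).append(h)
        return {kk: float(np.mean(v)) for kk, v in sorted(groups.items())}

    def to_frame(self, raw: "EntropyProfile | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "char": np.arange(1, len(self.H) + 1),
                "k": self.k,
                "H": np.round(self.H, 4),
            }
        )
        if raw is not None:
            df["H_raw"] = np.round(raw.H, 4)
        return df


def entropy_profile(
    matrix: CharacterMatrix, redistribute: bool = True, gap_is_state: bool = False
) -> EntropyProfile:
    """Entropy of every character in the matrix, in bits."""
    H, k = [], []
    for c in range(matrix.n_char):
        d = state_distribution(matrix, c, redistribute, gap_is_state)
        H.append(char_entropy(d))
        k.append(d.k)
    return EntropyProfile(H, k, redistribute)


def _joint_weights(
    matrix: CharacterMatrix, a: int, b: int, gap_is_state: bool
) -> tuple[dict[tuple[str, str], float], int]:
    """Joint state weights over OTUs scored for both characters."""
    joint: dict[tuple[str, str], float] = {}
    n_joint = 0
    for row in matrix.cells:
        wa = _cell_weights(row[a], gap_is_state)
        wb = _cell_weights(row[b], gap_is_state)
        if not wa or not wb:
            continue
        n_joint += 1
        for sa, pa in wa.items():
            for sb, pb in wb.items():
                joint[(sa, sb)] = joint.get((sa, sb), 0.0) + pa * pb
    return joint, n_joint


def _mi_from_joint(joint: dict[tuple[str, str], float]) -> tuple[float, float, float, float]:
    """(I, H_A, H_B, H_AB) from an unnormalised joint weight table."""
    total = sum(joint.values())
    pa: dict[str, float] = {}
    pb: dict[str, float] = {}
    for (sa, sb), w in joint.items():
        pa[sa] = pa.get(sa, 0.0) + w
        pb[sb] = pb.get(sb, 0.0) + w
    h_a = _plogp_sum(w / total for w in pa.values())
    h_b = _plogp_sum(w / total for w in pb.values())
    h_ab = _plogp_sum(w / total for w in joint.values())
    mi = h_a + h_b - h_ab
    return max(mi, 0.0), h_a, h_b, h_ab


def _joint_table(
    matrix: CharacterMatrix,
    a: int,
    b: int,
    policy: str,
    gap_is_state: bool,
) -> tuple[dict[tuple[str, str], float], int]:
    joint, n_joint = _joint_weights(matrix, a, b, gap_is_state)
    if policy == "pairwise-complete":
        return joint, n_joint
    if policy == "redistributed":
        # spread the mass of OTUs unscored in either character uniformly
        # over the observed joint support
        n_unscored = matrix.n_otu - n_joint
        if joint and n_unscored > 0:
            extra = n_unscored / len(joint)
            joint = {k: w + extra for k, w in joint.items()}
        return joint, n_joint
    raise ValueError(f"unknown MI policy {policy!r}")


def mutual_information(
    matrix: CharacterMatrix,
    a: int,
    b: int,
    policy: str = "pairwise-complete",
    gap_is_state: bool = False,
) -> float:
    """Mutual information I(A,B) in bits between two characters.

    Under ``pairwise-complete`` (default) the joint distribution uses only
    OTUs scored for both characters, with marginals recomputed on that
    subset, so I >= 0 holds.  Under ``redistributed`` the missing mass is
    spread uniformly over the observed joint support first.  Fewer than two
    informing OTUs -> 0.
    """
    joint, n_joint = _joint_table(matrix, a, b, policy, gap_is_state)
    if n_joint < 2:
        return 0.0
    return _mi_from_joint(joint)[0]


def conditional_entropy(
    matrix: CharacterMatrix,
    a: int,
    b: int,
    policy: str = "pairwise-complete",
    gap_is_state: bool = False,
) -> float:
    """H(A|B) = H(A,B) - H(B) in bits on the pair's informing OTU subset."""
    joint, n_joint = _joint_table(matrix, a, b, policy, gap_is_state)
    if n_joint < 2:
        return 0.0
    _, _, h_b, h_ab = _mi_from_joint(joint)
    return max(h_ab - h_b, 0.0)


@dataclass
class MutualInfoMatrix:
    """Symmetric n_char x n_char MI grid in bits with its estimation policy."""

    mi: np.ndarray
    n_joint: np.ndarray
    policy: str
    char_order: list[int]
    partition_labels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-form (a, b, n_joint, MI) table, 1-based, upper triangle incl. diagonal."""
        rows = []
        n = self.mi.shape[0]
        for i in range(n):
            for j in range(i, n):
                rows.append(
                    {
                        "a": self.char_order[i] + 1,
                        "b": self.char_order[j] + 1,
                        "n_joint": int(self.n_joint[i, j]),
                        "MI": round(float(self.mi[i, j]), 4),
                    }
                )
        return pd.DataFrame(rows)


def mi_matrix(
    matrix: CharacterMatrix,
    policy: str = "pairwise-complete",
    order: str = "matrix",
    gap_is_state: bool = False,
) -> MutualInfoMatrix:
    """Full pairwise MI grid.

    ``order="partition"`` groups rows/columns by the matrix's partition map
    (label-sorted blocks, matrix order within a block); it requires
    partitions to be present.
    """
    n = matrix.n_char
    if order == "matrix":
        char_order = list(range(n))
        labels = None
    elif order == "partition":
        if not matrix.partitions:
            raise ValueError("partition ordering requires a partition map")
        char_order = sorted(range(n), key=lambda c: (matrix.partitions.get(c, "~"), c))
        labels = [matrix.partitions.get(c, "") for c in char_order]
    else:
        raise ValueError(f"unknown ordering {order!r}")

    mi = np.zeros((n, n))
    n_joint = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            a, b = char_order[i], char_order[j]
            joint, nj = _joint_table(matrix, a, b, policy, gap_is_state)
            val = _mi_from_joint(joint)[0] if nj >= 2 else 0.0
            mi[i, j] = mi[j, i] = val
            n_joint[i, j] = n_joint[j, i] = nj
    return MutualInfoMatrix(mi, n_joint, policy, char_order, labels)


@dataclass
class JointEntropyCurve:
    """Joint entropy of character prefixes and the unique-sequence registry.

    ``registry[i]`` lists the unique state sequences of the first i+1
    characters in order of first appearance down the matrix, so
    ``sequence(i, j)`` is the paper-style j-th unique sequence (1-based)."""

    order: list[int]
    H_joint: list[float]
    registry: list[list[tuple[str, int]]] = field(repr=False)
    source_entropy_bound: float = 0.0
    policy: str = "distinct"

    def sequence(self, i: int, j: int) -> str:
        """The j-th unique sequence of the first i characters (both 1-based)."""
        return self.registry[i - 1][j - 1][0]

    def n_unique(self, i: int) -> int:
        return len(self.registry[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prefix_len": np.arange(1, len(self.H_joint) + 1),
                "H_joint": np.round(self.H_joint, 4),
                "n_unique_sequences": [len(r) for r in self.registry],
            }
        )


def joint_entropy_prefix(
    matrix: CharacterMatrix,
    order: list[int] | None = None,
    missing_token_policy: str = "distinct",
) -> JointEntropyCurve:
    """Joint entropy of the first i characters, for i = 1..len(order).

    Each OTU contributes its sequence of cell tokens over the prefix.  With
    ``missing_token_policy="distinct"`` (default) ``?``, ``-`` and
    polymorphism renderings are symbols of their own, which keeps every OTU
    in the curve and makes it nondecreasing; ``"drop-otu"`` instead excludes
    OTUs not completely scored within the prefix.
    """
    if order is None:
        order = list(range(matrix.n_char))
    if not order:
        raise ValueError("empty character order")
    if sorted(set(order)) != sorted(order) or any(
        not 0 <= c < matrix.n_char for c in order
    ):
        raise ValueError("order must be distinct valid character indices")
    if missing_token_policy not in ("distinct", "drop-otu"):
        raise ValueError(f"unknown policy {missing_token_policy!r}")

    tokens = [[matrix.cells[i][c].token() for c in order] for i in range(matrix.n_otu)]
    H_joint: list[float] = []
    registry: list[list[tuple[str, int]]] = []
    for i in range(1, len(order) + 1):
        seqs = []
        for r, row in enumerate(tokens):
            prefix = row[:i]
            if missing_token_policy == "drop-otu" and any(
                not matrix.cells[r][c].is_scored for c in order[:i]
            ):
                continue
            seqs.append("".join(prefix))
        counts: dict[str, int] = {}
        uniq: list[str] = []
        for s in seqs:
            if s not in counts:
                uniq.append(s)
            counts[s] = counts.get(s, 0) + 1
        total = len(seqs)
        H_joint.append(_plogp_sum(c / total for c in counts.values()) if total else 0.0)
        registry.append([(s, counts[s]) for s in uniq])
    return JointEntropyCurve(
        list(order),
        H_joint,
        registry,
        source_entropy_bound=math.log2(matrix.n_otu) if matrix.n_otu else 0.0,
        policy=missing_token_policy,
    )
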