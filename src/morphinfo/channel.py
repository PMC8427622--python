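"""Channel-capacity view of a character matrix under the AWGN analogy.

The number of characters plays the role of bandwidth B.  Among the first B
characters, scored cells are signal power S and unscored (missing + gap)
cells are noise power N, giving the Shannon-Hartley capacity

    C(B) = B * log2(1 + S(B) / N(B))   [bits].

Because real matrices mix well-scored and poorly-scored characters, C(B)
typically rises, peaks and falls: the peak is the saturation bandwidth,
beyond which adding characters adds more noise than signal.  With noise
accruing at constant density n0 (N = n0 * B) and fixed S, capacity is
bounded by S/n0 * log2(e) ~ 1.44 * S/n0 as B grows without limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infotheory import entropy_profile
from .matrix import CharacterMatrix

__all__ = [
    "NoiseProfile",
    "CapacityCurve",
    "noise_profile",
    "capacity_curve",
    "fixed_signal_capacity",
    "repetition_code_accuracy",
]


@dataclass
class NoiseProfile:
    """Unscored-cell counts per taxon or per character, in matrix order."""

    axis: str
    labels: list[str]
    counts: list[int]

    @property
    def total(self) -> int:
        return sum(self.counts)

    def to_frame(self) -> pd.DataFrame:
        key = "taxon" if self.axis == "taxon" else "char"
        return pd.DataFrame({key: self.labels, "n_unscored": self.counts})


def noise_profile(matrix: CharacterMatrix, axis: str = "taxon") -> NoiseProfile:
    """Count missing+gap cells along one axis of the matrix."""
    if axis == "taxon":
        counts = [sum(1 for cell in row if not cell.is_scored) for row in matrix.cells]
        labels = list(matrix.otu_labels)
    elif axis == "character":
        counts = [
            sum(1 for cell in matrix.column(c) if not cell.is_scored)
            for c in range(matrix.n_char)
        ]
        labels = [str(c + 1) for c in range(matrix.n_char)]
    else:
        raise ValueError(f"axis must be 'taxon' or 'character', got {axis!r}")
    return NoiseProfile(axis, labels, counts)


@dataclass
class CapacityCurve:
    """C(B), S(B), N(B) over bandwidths B = 1..n_char plus saturation summary.

    ``C[b-1]`` is infinite where the prefix is noiseless (N(B) = 0); such
    prefixes are excluded from the saturation argmax unless every prefix is
    noiseless, in which case saturation is the full bandwidth."""

    order: list[int]
    S: list[int]
    N: list[int]
    C: list[float]
    n_otu: int

    @property
    def n_char(self) -> int:
        return len(self.order)

    @property
    def noise_density(self) -> float:
        """Mean noise per bandwidth unit, n0 = N(n_char)/n_char."""
        return self.N[-1] / self.n_char

    @property
    def is_noiseless(self) -> list[bool]:
        return [n == 0 for n in self.N]

    @property
    def saturation_B(self) -> int:
        candidates = [i for i, n in enumerate(self.N) if n > 0]
        if not candidates:
            return self.n_char
        cmax = max(self.C[i] for i in candidates)
        # smallest B attaining the maximum
        return next(i for i in candidates if self.C[i] == cmax) + 1

    @property
    def saturation_fraction(self) -> float:
        """Saturation bandwidth as a percentage of the total character count."""
        return 100.0 * self.saturation_B / self.n_char

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "B": np.arange(1, self.n_char + 1),
                "S": self.S,
                "N": self.N,
                "C": [round(c, 4) if math.isfinite(c) else np.inf for c in self.C],
                "is_noiseless": self.is_noiseless,
            }
        )


def capacity_curve(
    matrix: CharacterMatrix,
    order: str = "matrix",
    seed: int | None = None,
) -> CapacityCurve:
    """Capacity C(B) as bandwidth grows character by character.

    ``order`` selects the character ordering: ``matrix`` (as-is, the
    reproducible default), ``entropy-desc`` (most informative first), or
    ``random`` with ``seed``.  C(n_char) is order-invariant; the saturation
    point generally is not.
    """
    if matrix.n_char < 1:
        raise ValueError("matrix has no characters")
    if order == "matrix":
        char_order = list(range(matrix.n_char))
    elif order == "entropy-desc":
        prof = entropy_profile(matrix, redistribute=True)
        char_order = sorted(range(matrix.n_char), key=lambda c: (-prof.H[c], c))
    elif order == "random":
        rng = np.random.default_rng(seed)
        char_order = list(rng.permutation(matrix.n_char))
    else:
        raise ValueError(f"unknown order {order!r}")

    scored_per_char = [
        sum(1 for cell in matrix.column(c) if cell.is_scored) for c in range(matrix.n_char)
    ]
    S, N, C = [], [], []
    s = n = 0
    for b, c in enumerate(char_order, start=1):
        s += scored_per_char[c]
        n += matrix.n_otu - scored_per_char[c]
        S.append(s)
        N.append(n)
        C.append(b * math.log2(1 + s / n) if n > 0 else math.inf)
    return CapacityCurve([int(c) for c in char_order], S, N, C, matrix.n_otu)


def fixed_signal_capacity(S: float, n0: float, B: float) -> float:
    """C = B * log2(1 + S/(n0*B)): capacity at bandwidth B with fixed signal
    power S and noise density n0.  Nondecreasing in B and bounded above by
    S * log2(e) / n0 (about 1.44*S/n0), the wideband limit."""
    if S <= 0 or n0 <= 0 or B <= 0:
        raise ValueError("S, n0 and B must be positive")
    return B * math.log2(1.0 + S / (n0 * B))


def repetition_code_accuracy(p: float, r: int) -> float:
    """Probability that an r-fold repetition code decodes correctly.

    Each of the r copies is independently correct with probability p and the
    decoder takes the majority, so the answer is P[Binomial(r, p) > r/2].
    r must be odd so the majority is always defined; r = 1 returns p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if r < 1 or r % 2 == 0:
        raise ValueError("repeat count must be odd and >= 1")
    return float(
        sum(math.comb(r, i) * p**i * (1.0 - p) ** (r - i) for i in range((r + 1) // 2, r + 1))
    )
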