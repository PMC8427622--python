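"""Character weights from entropies, and their export for TNT.

A character's Shannon entropy measures how informative it is on its own, so
it can serve directly as a parsimony weight with no prior tree or initial
weights.  TNT wants bounded integer weights, so the default scaling maps the
highest-entropy character to 100 (half-up rounding); zero-entropy characters
get weight 0 and are deactivated in the exported script.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .infotheory import EntropyProfile

__all__ = ["WeightSet", "entropy_weights", "export_tnt_weights", "parse_tnt_weights"]

SCALE_MAX = 100


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


@dataclass
class WeightSet:
    """Raw (entropy, bits) and scaled integer parsimony weights per character."""

    raw: list[float]
    scaled: list[int]
    scale: str
    redistributed: bool

    @property
    def n_char(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "char": range(1, self.n_char + 1),
                "H": [round(h, 4) for h in self.raw],
                "scaled_weight": self.scaled,
            }
        )


def entropy_weights(profile: EntropyProfile, scale: str = "max100") -> WeightSet:
    """Turn an entropy profile into parsimony weights.

    ``scale="max100"`` maps the maximum entropy to 100 with half-up rounding
    (a 0.61-bit character next to a 1-bit one scales to 61 vs 100);
    ``scale="raw-float"`` keeps the entropies themselves.  A profile with no
    informative character is an error.
    """
    raw = list(profile.H)
    if any(h < 0 for h in raw):
        raise ValueError("negative entropy in profile")
    hmax = max(raw, default=0.0)
    if hmax == 0.0:
        raise ValueError("no informative characters: all entropies are zero")
    if scale == "max100":
        scaled = [_round_half_up(SCALE_MAX * h / hmax) if h > 0 else 0 for h in raw]
    elif scale == "raw-float":
        scaled = raw  # type: ignore[assignment]
    else:
        raise ValueError(f"unknown scale policy {scale!r}")
    return WeightSet(raw, scaled, scale, profile.redistributed)


def export_tnt_weights(weights: WeightSet, path: str | Path) -> Path:
    """Write a TNT ``ccode`` script assigning each character its scaled weight.

    TNT numbers characters from 0, so indices here are 0-based (the only
    user-facing place where they are).  Zero-weight characters are
    deactivated (``ccode ]``) rather than weighted.
    """
    if weights.scale != "max100":
        raise ValueError("only integer (max100) weights can be exported to TNT")
    groups: dict[int, list[int]] = {}
    for idx, w in enumerate(weights.scaled):
        groups.setdefault(w, []).append(idx)
    lines = [
        f"/* character weights = scaled information entropy"
        f" (redistributed={str(weights.redistributed).lower()}, scale={weights.scale}) */"
    ]
    for w in sorted(groups, reverse=True):
        chars = " ".join(str(i) for i in groups[w])
        if w == 0:
            lines.append(f"ccode ] {chars};")
        else:
            lines.append(f"ccode /{w} {chars};")
    lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines))
    return path


_CCODE_RE = re.compile(r"ccode\s+(\]|/(\d+))\s+([0-9 ]+);")


def parse_tnt_weights(path: str | Path, n_char: int) -> list[int]:
    """Read back a ``ccode`` weight script into a 0-based weight list
    (deactivated characters read as weight 0)."""
    weights = [None] * n_char
    for m in _CCODE_RE.finditer(Path(path).read_text()):
        w = 0 if m.group(1) == "]" else int(m.group(2))
        for tok in m.group(3).split():
            weights[int(tok)] = w
    unset = [i for i, w in enumerate(weights) if w is None]
    if unset:
        raise ValueError(f"characters without a ccode assignment: {unset}")
    return weights  # type: ignore[return-value]
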