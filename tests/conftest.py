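import sys
from pathlib import Path

import dendropy
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from morphinfo import CellValue, CharacterMatrix, table2_fixture


@pytest.fixture
def table2():
    """The 9 x 3 worked example matrix as printed (7 and 7.1 separate)."""
    return table2_fixture(merged=False)


@pytest.fixture
def table2_merged():
    """The worked example with taxa 7/7.1 collapsed: 8 distinct binary triples."""
    return table2_fixture(merged=True)


def matrix_from_strings(rows: dict[str, str]) -> CharacterMatrix:
    """Build a matrix from {label: token string}; '?' missing, '-' gap,
    '{..}' polymorphism."""
    labels, cells = [], []
    for lab, row in rows.items():
        labels.append(lab)
        parsed, i = [], 0
        while i < len(row):
            ch = row[i]
            if ch == "?":
                parsed.append(CellValue("missing"))
                i += 1
            elif ch == "-":
                parsed.append(CellValue("gap"))
                i += 1
            elif ch == "{":
                j = row.index("}", i)
                parsed.append(CellValue.of(*row[i + 1 : j]))
                i = j + 1
            else:
                parsed.append(CellValue.of(ch))
                i += 1
        cells.append(parsed)
    return CharacterMatrix(labels, cells)


@pytest.fixture
def quartet_tree():
    return dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")


def random_tree(labels: list[str], seed: int) -> dendropy.Tree:
    """Random topology over the given tip labels (seeded)."""
    import random

    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(labels)
    return dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        taxon_namespace=taxa,
        num_extant_tips=len(labels),
        rng=rng,
    )
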