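"""Entropy, mutual information and joint-entropy curves, checked against
hand counts and brute-force tabulation oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphinfo import (
    GeneratorSpec,
    char_entropy,
    conditional_entropy,
    entropy_profile,
    generate_matrix,
    joint_entropy_prefix,
    mi_matrix,
    mutual_information,
    state_distribution,
)
from morphinfo.infotheory import StateDistribution

from conftest import matrix_from_strings
from oracles import tabulated_entropy, tabulated_joint_entropy, tabulated_mi


def complete_matrix(columns: list[str]) -> "CharacterMatrix":
    rows = {f"T{i}": "".join(col[i] for col in columns) for i in range(len(columns[0]))}
    return matrix_from_strings(rows)


class TestStateDistribution:
    def test_missing_mass_redistributed_equally(self):
        # binary character: 0 in 20% of OTUs, 1 in 40%, missing 40%
        m = matrix_from_strings(
            {f"T{i}": s for i, s in enumerate(["0", "0", "1", "1", "1", "1", "?", "?", "?", "?"])}
        )
        d = state_distribution(m, 0, redistribute=True)
        assert d.probs == pytest.approx({"0": 0.4, "1": 0.6})
        raw = state_distribution(m, 0, redistribute=False)
        assert raw.probs == pytest.approx({"0": 2 / 6, "1": 4 / 6})

    def test_no_missing_flag_is_noop(self):
        m = complete_matrix(["0011"])
        a = state_distribution(m, 0, redistribute=True)
        b = state_distribution(m, 0, redistribute=False)
        assert a.probs == pytest.approx(b.probs)

    def test_polymorphic_half_weights(self):
        m = matrix_from_strings({"A": "0", "B": "1", "C": "{01}"})
        d = state_distribution(m, 0)
        assert d.probs == pytest.approx({"0": 0.5, "1": 0.5})
        assert d.n_scored == 3

    def test_all_missing_is_degenerate(self):
        m = matrix_from_strings({"A": "?", "B": "-"})
        d = state_distribution(m, 0)
        assert d.degenerate and d.n_scored == 0
        assert char_entropy(d) == 0.0

    def test_gap_as_state_option(self):
        m = matrix_from_strings({"A": "0", "B": "-", "C": "0", "D": "-"})
        d = state_distribution(m, 0, gap_is_state=True)
        assert d.probs == pytest.approx({"0": 0.5, "-": 0.5})

    def test_redistribution_shrinks_toward_uniform(self):
        for n_one in range(1, 6):
            tokens = ["1"] * n_one + ["0"] * (6 - n_one) + ["?"] * 4
            m = matrix_from_strings({f"T{i}": t for i, t in enumerate(tokens)})
            red = state_distribution(m, 0, redistribute=True).probs["1"]
            raw = state_distribution(m, 0, redistribute=False).probs["1"]
            assert abs(red - 0.5) <= abs(raw - 0.5) + 1e-12


class TestCharEntropy:
    @pytest.mark.parametrize(
        "probs,expected,tol",
        [
            ({"1": 12 / 80, "0": 68 / 80}, 0.61, 0.005),  # premaxillary-teeth example
            ({"0": 0.5, "1": 0.5}, 1.0, 1e-12),
            ({"0": 1.0}, 0.0, 1e-12),
            ({"0": 1 / 3, "1": 1 / 3, "2": 1 / 3}, math.log2(3), 1e-12),
        ],
    )
    def test_known_values(self, probs, expected, tol):
        d = StateDistribution(0, probs, n_scored=10, n_missing=0, redistributed=False)
        assert char_entropy(d) == pytest.approx(expected, abs=tol)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_entropy_bounds(self, weights):
        total = sum(weights)
        probs = {str(i): w / total for i, w in enumerate(weights)}
        d = StateDistribution(0, probs, 10, 0, False)
        h = char_entropy(d)
        assert -1e-9 <= h <= math.log2(len(probs)) + 1e-9


class TestEntropyProfile:
    def test_table2_merged_all_one_bit(self, table2_merged):
        prof = entropy_profile(table2_merged)
        assert prof.H == pytest.approx([1.0, 1.0, 1.0])

    def test_constant_plus_uniform(self):
        m = complete_matrix(["0000", "0101"])
        prof = entropy_profile(m)
        assert prof.H == pytest.approx([0.0, 1.0])
        assert prof.k == [1, 2]

    def test_mean_by_state_count(self):
        m = complete_matrix(["0101", "1010", "0123", "3210"])
        prof = entropy_profile(m)
        assert prof.mean_by_k == pytest.approx({2: 1.0, 4: 2.0})


class TestMutualInformation:
    def test_table2_all_pairs_zero(self, table2_merged):
        for a in range(3):
            for b in range(a + 1, 3):
                assert mutual_information(table2_merged, a, b) == pytest.approx(0.0, abs=1e-12)

    def test_self_mi_is_entropy_on_complete_data(self):
        m = complete_matrix(["00110", "01100"])
        for c in range(2):
            h = char_entropy(state_distribution(m, c))
            assert mutual_information(m, c, c) == pytest.approx(h, abs=1e-12)

    def test_worked_pair(self):
        m = complete_matrix(["0001", "0011"])
        expected = 0.8112781 + 1.0 - 1.5
        assert mutual_information(m, 0, 1) == pytest.approx(expected, abs=1e-6)
        assert mutual_information(m, 0, 1) == pytest.approx(0.3113, abs=5e-5)

    def test_pairwise_complete_uses_shared_otus_only(self):
        # char 0 fully scored; char 1 scored only where char 0 is constant
        m = matrix_from_strings({"A": "00", "B": "01", "C": "1?", "D": "1?"})
        assert mutual_information(m, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_informing_otus(self):
        m = matrix_from_strings({"A": "00", "B": "0?", "C": "?1"})
        assert mutual_information(m, 0, 1) == 0.0

    def test_mi_identities_on_complete_data(self):
        m = complete_matrix(["001122", "010212"])
        h_a = char_entropy(state_distribution(m, 0))
        mi = mutual_information(m, 0, 1)
        assert mi == pytest.approx(h_a - conditional_entropy(m, 0, 1), abs=1e-12)
        cols = [[m.cells[i][c].state for i in range(6)] for c in range(2)]
        assert mi == pytest.approx(tabulated_mi(*cols), abs=1e-12)

    def test_conditional_entropy_examples(self):
        same = complete_matrix(["0101", "0101"])
        assert conditional_entropy(same, 0, 1) == pytest.approx(0.0, abs=1e-12)
        ind = complete_matrix(["0011", "0101"])
        assert conditional_entropy(ind, 0, 1) == pytest.approx(1.0, abs=1e-12)
        worked = complete_matrix(["0001", "0011"])
        assert conditional_entropy(worked, 0, 1) == pytest.approx(0.5, abs=1e-12)

    def test_mi_bounded_by_pairwise_entropies(self):
        m = matrix_from_strings(
            {"A": "01", "B": "1?", "C": "{01}0", "D": "00", "E": "11", "F": "-1"}
        )
        mi = mutual_information(m, 0, 1)
        assert mi >= 0.0


class TestMiMatrix:
    def test_table2_grid(self, table2_merged):
        grid = mi_matrix(table2_merged)
        assert np.allclose(np.diag(grid.mi), [1.0, 1.0, 1.0])
        off = grid.mi[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)
        assert (grid.n_joint == 8).all()

    def test_symmetry_and_duplicate_columns(self):
        m = complete_matrix(["00101", "00101", "01110"])
        grid = mi_matrix(m)
        assert np.allclose(grid.mi, grid.mi.T)
        h0 = char_entropy(state_distribution(m, 0))
        assert grid.mi[0, 1] == pytest.approx(h0, abs=1e-12)

    def test_independent_characters_near_zero(self):
        spec = GeneratorSpec(
            n_otu=512, char_probs=[[0.5, 0.5]] * 4, missingness=0.0, seed=7
        )
        m = generate_matrix(spec)
        grid = mi_matrix(m)
        off = grid.mi[~np.eye(4, dtype=bool)]
        assert (off < 0.02).all()

    def test_partition_order_requires_map(self, table2_merged):
        with pytest.raises(ValueError, match="partition"):
            mi_matrix(table2_merged, order="partition")
        table2_merged.partitions = {0: "C", 1: "A", 2: "C"}
        grid = mi_matrix(table2_merged, order="partition")
        assert grid.char_order == [1, 0, 2]
        assert grid.partition_labels == ["A", "C", "C"]


class TestJointEntropyPrefix:
    def test_table2_full_prefix(self, table2_merged):
        curve = joint_entropy_prefix(table2_merged)
        assert curve.H_joint == pytest.approx([1.0, 2.0, 3.0])
        assert curve.n_unique(3) == 8
        assert curve.source_entropy_bound == pytest.approx(3.0)

    def test_sequence_registry(self, table2_merged):
        curve = joint_entropy_prefix(table2_merged)
        assert curve.sequence(2, 1) == "00"
        assert curve.sequence(3, 3) == "010"

    def test_duplicate_character_adds_nothing(self):
        m = complete_matrix(["0011", "0011"])
        curve = joint_entropy_prefix(m)
        assert curve.H_joint[0] == pytest.approx(curve.H_joint[1])

    def test_first_point_matches_char_entropy_distinct_policy(self):
        m = matrix_from_strings({"A": "0", "B": "1", "C": "?", "D": "0"})
        curve = joint_entropy_prefix(m)
        # '?' is a distinct token: distribution (2,1,1)/4
        assert curve.H_joint[0] == pytest.approx(1.5)

    def test_drop_otu_policy(self):
        m = matrix_from_strings({"A": "00", "B": "01", "C": "?1", "D": "10"})
        curve = joint_entropy_prefix(m, missing_token_policy="drop-otu")
        assert curve.H_joint[1] == pytest.approx(math.log2(3))

    def test_empty_order_rejected(self, table2_merged):
        with pytest.raises(ValueError, match="empty"):
            joint_entropy_prefix(table2_merged, order=[])


@st.composite
def complete_small_matrices(draw):
    n_otu = draw(st.integers(2, 6))
    n_char = draw(st.integers(1, 4))
    cols = [
        "".join(draw(st.sampled_from("012")) for _ in range(n_otu))
        for _ in range(n_char)
    ]
    return cols


@given(cols=complete_small_matrices())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_oracle_equivalence_small_matrices(cols):
    """Entropies, MI and joint entropies all match brute-force tabulation of
    the joint distribution on tiny complete matrices."""
    m = complete_matrix(cols)
    for c, col in enumerate(cols):
        assert char_entropy(state_distribution(m, c)) == pytest.approx(
            tabulated_entropy(list(col)), abs=1e-12
        )
    if len(cols) >= 2:
        assert mutual_information(m, 0, 1) == pytest.approx(
            tabulated_mi(list(cols[0]), list(cols[1])), abs=1e-12
        )
    curve = joint_entropy_prefix(m)
    for i in range(1, len(cols) + 1):
        assert curve.H_joint[i - 1] == pytest.approx(
            tabulated_joint_entropy([list(c) for c in cols[:i]]), abs=1e-12
        )


@given(seed=st.integers(0, 10_000))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_joint_entropy_monotone_and_capped(seed):
    """The prefix curve never decreases and never exceeds log2(#OTUs)."""
    rng = np.random.default_rng(seed)
    n_otu = int(rng.integers(3, 12))
    n_char = int(rng.integers(2, 8))
    spec = GeneratorSpec(
        n_otu=n_otu,
        char_probs=[[0.5, 0.5]] * n_char,
        missingness=float(rng.uniform(0, 0.5)),
        seed=seed,
    )
    curve = joint_entropy_prefix(generate_matrix(spec))
    bound = math.log2(n_otu)
    prev = 0.0
    for h in curve.H_joint:
        assert h >= prev - 1e-9
        assert h <= bound + 1e-9
        prev = h


def test_parameter_recovery_at_t1000():
    """Entropy of a generated 15/85 binary character converges to the
    analytic 0.6098 bits within the plug-in bias scale at T=1000."""
    spec = GeneratorSpec(n_otu=1000, char_probs=[[0.15, 0.85]] * 3, seed=11)
    m = generate_matrix(spec)
    prof = entropy_profile(m)
    h_true = -(0.15 * math.log2(0.15) + 0.85 * math.log2(0.85))
    for h in prof.H:
        assert h == pytest.approx(h_true, abs=0.05)
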